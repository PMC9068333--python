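"""Decode probability/label masks back into geometric landmarks.

This is the postprocessing stage that inverts the label encoders: the
thresholded sphere mask of a point detector collapses to its centroid, a
tubular curve mask is skeletonised and traced into a closed 3D curve, and
a two-label split of the blood pool yields a fitted plane through the
inter-label boundary.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import ndimage

from .geometry import Curve3D, Plane3D, Point3D
from .volume_io import LabelMask, ProbabilityMask, VolumeGrid

__all__ = [
    "binarize",
    "refine_segmentation",
    "decode_point",
    "decode_curve",
    "decode_plane",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.5

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def binarize(p: VolumeGrid, threshold: float = DEFAULT_THRESHOLD) -> LabelMask:
    """Threshold a probability mask: label 1 iff probability >= threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    return LabelMask((np.asarray(p.data) >= threshold).astype(np.uint8), p.spacing.copy(), p.origin.copy())


def _largest_component(data: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(data > 0, structure=_STRUCT26)
    if n == 0:
        raise ValueError("empty mask: no foreground component")
    if n == 1:
        return data > 0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def refine_segmentation(
    m: LabelMask,
    intensity: VolumeGrid | None = None,
    mode: str = "largest_component",
    *,
    watershed_band: int = 3,
    combine: str = "intersect",
) -> LabelMask:
    """Clean up a binarized segmentation with classical image analysis.

    ``largest_component`` keeps the single largest 26-connected foreground
    component.  ``watershed`` runs a marker-based watershed on the intensity
    gradient (markers: eroded mask = object, complement of the dilated mask
    = background) and combines it with the input per ``combine``
    ({intersect, union, replace}); the result is always constrained to a
    ``watershed_band``-voxel dilation of the input so refinement cannot
    wander far from the network mask.
    """
    fg = m.data > 0
    if not fg.any():
        raise ValueError("empty mask")
    if mode == "none":
        out = fg
    elif mode == "largest_component":
        out = _largest_component(fg)
    elif mode == "watershed":
        if intensity is None:
            raise ValueError("watershed refinement requires the intensity volume")
        if not m.same_geometry(intensity):
            raise ValueError("mask and intensity volume are on different grids")
        from skimage.segmentation import watershed

        body = _largest_component(fg)
        grad = ndimage.gaussian_gradient_magnitude(np.asarray(intensity.data, dtype=float), sigma=1.0)
        inner = ndimage.binary_erosion(body, iterations=2)
        if not inner.any():
            inner = body
        band = ndimage.binary_dilation(body, iterations=watershed_band)
        markers = np.zeros(m.shape, dtype=np.int32)
        markers[~band] = 1
        markers[inner] = 2
        ws = watershed(grad, markers) == 2
        if combine == "intersect":
            out = ws & body
        elif combine == "union":
            out = ws | body
        elif combine == "replace":
            out = ws
        else:
            raise ValueError(f"unknown combine mode {combine!r}")
        out &= band
        out = _largest_component(out)
    else:
        raise ValueError(f"unknown refinement mode {mode!r}")
    return LabelMask(out.astype(np.uint8), m.spacing.copy(), m.origin.copy())


def _as_binary(mask, threshold: float) -> LabelMask:
    if isinstance(mask, LabelMask):
        return LabelMask((mask.data > 0).astype(np.uint8), mask.spacing.copy(), mask.origin.copy())
    return binarize(mask, threshold)


def decode_point(p: ProbabilityMask | LabelMask, threshold: float = DEFAULT_THRESHOLD) -> Point3D:
    """Centroid of the thresholded detection region (after cleanup)."""
    b = _as_binary(p, threshold)
    if not (b.data > 0).any():
        raise ValueError("no detection: mask is empty after thresholding")
    comp = _largest_component(b.data)
    idx = np.argwhere(comp)
    world = b.origin + idx * b.spacing
    return Point3D.from_array(world.mean(axis=0))


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    idx = np.argwhere(skel)
    voxels = {tuple(v): i for i, v in enumerate(idx)}
    g = nx.Graph()
    g.add_nodes_from(range(len(idx)))
    # half of the 26-neighbourhood (avoid duplicate edges)
    half = [
        (o[0] - 1, o[1] - 1, o[2] - 1)
        for o in np.ndindex(3, 3, 3)
        if (o[0] - 1, o[1] - 1, o[2] - 1) > (0, 0, 0)
    ]
    for i, v in enumerate(idx):
        for d in half:
            nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            j = voxels.get(nb)
            if j is not None:
                w = float(np.linalg.norm(np.array(d) * spacing))
                g.add_edge(i, j, weight=w)
    return g, idx


def _farthest_node(g: nx.Graph, source: int) -> int:
    lengths = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    return max(lengths, key=lengths.get)


def _smooth_closed(vertices: np.ndarray, window: int = 5) -> np.ndarray:
    if len(vertices) < window:
        return vertices
    kernel = np.ones(window) / window
    out = np.empty_like(vertices)
    for ax in range(3):
        padded = np.concatenate([vertices[-(window // 2):, ax], vertices[:, ax], vertices[: window // 2, ax]])
        out[:, ax] = np.convolve(padded, kernel, mode="valid")
    return out


def decode_curve(
    p: ProbabilityMask | LabelMask,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_window: int = 5,
) -> Curve3D:
    """Trace the centreline cycle of a tubular detection mask.

    Pipeline: threshold, keep the largest 26-connected component,
    skeletonise, build a graph of skeleton voxels with Euclidean edge
    weights, and extract the long cycle: take the two graph-farthest
    skeleton nodes, connect them by the shortest path, remove that path's
    interior, and connect them again by the shortest remaining path; the
    two paths form the cycle.  If no return path exists the tube is open
    and an open curve is returned with ``closed=False``.
    """
    from skimage.morphology import skeletonize

    b = _as_binary(p, threshold)
    if not (b.data > 0).any():
        raise ValueError("no detection: mask is empty after thresholding")
    comp = _largest_component(b.data)

    # work inside the component's bounding box (skeletonization cost)
    bbox = ndimage.find_objects(comp.astype(np.uint8))[0]
    sub = np.pad(comp[bbox], 1)
    skel = skeletonize(sub)
    if not skel.any():
        raise ValueError("skeletonization produced an empty result")

    g, idx = _skeleton_graph(skel, b.spacing)
    # largest connected piece of the skeleton
    comp_nodes = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp_nodes).copy()

    start = next(iter(comp_nodes))
    a = _farthest_node(g, start)
    z = _farthest_node(g, a)
    path1 = nx.shortest_path(g, a, z, weight="weight")

    g2 = g.copy()
    g2.remove_nodes_from(path1[1:-1])
    closed = nx.has_path(g2, a, z) and len(path1) > 2
    if closed:
        path2 = nx.shortest_path(g2, a, z, weight="weight")
        order = path1 + path2[-2:0:-1]
    else:
        warnings.warn("no cycle found in the skeleton; returning an open curve")
        order = path1

    offset = np.array([s.start for s in bbox]) - 1  # undo pad
    voxel_idx = idx[order] + offset
    world = b.origin + voxel_idx * b.spacing
    if closed and smooth_window > 1:
        world = _smooth_closed(world, smooth_window)
    return Curve3D(world, closed=closed)


def decode_plane(m: LabelMask) -> Plane3D:
    """Fit a plane through the boundary between label-1 and label-2 voxels.

    The boundary cloud contains the midpoints of all face-adjacent
    (6-neighbour) voxel pairs carrying labels (1, 2).  A total-least-squares
    fit (smallest principal direction of the cloud's covariance) gives the
    normal, oriented towards the label-2 side; the plane's point is the
    boundary centroid.
    """
    lab = np.asarray(m.data)
    if not ((lab == 1).any() and (lab == 2).any()):
        raise ValueError("plane decoding needs both labels 1 and 2")

    points = []
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        la, lb = lab[tuple(a)], lab[tuple(b)]
        pair = ((la == 1) & (lb == 2)) | ((la == 2) & (lb == 1))
        idx = np.argwhere(pair).astype(float)
        if idx.size:
            idx[:, ax] += 0.5  # midpoint between the two voxel centres
            points.append(m.origin + idx * m.spacing)
    if not points:
        raise ValueError("no boundary: labels 1 and 2 are not face-adjacent")
    pts = np.concatenate(points, axis=0)

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # degenerate boundary (tied smallest singular values): lexicographic tie-break
    if len(svals) == 3 and svals[1] - svals[2] < 1e-9 * max(svals[0], 1e-12):
        warnings.warn("degenerate boundary cloud; normal tie broken lexicographically")
        candidates = vt[1:]
        keys = [tuple(np.round(-np.abs(c), 12)) for c in candidates]
        normal = candidates[int(np.lexsort(np.array(keys).T[::-1])[0])]
    else:
        normal = vt[-1]

    label2_centroid = (m.origin + np.argwhere(lab == 2) * m.spacing).mean(axis=0)
    if (label2_centroid - centroid) @ normal < 0:
        normal = -normal
    return Plane3D(Point3D.from_array(centroid), normal)
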