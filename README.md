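# laaoplan

Automated cardiac-CT landmark analysis for planning **left atrial appendage
occlusion (LAAO)** — the transcatheter closure of the LAA to reduce stroke
risk in atrial fibrillation. Planning an LAAO procedure from a multislice
CT scan means finding a handful of anatomical landmarks and measuring them:
the **anatomical ostium** (the 3D plane at the appendage entrance), a
device-specific **landing zone** plane, the appendage **depth**, the
**fossa ovalis** (a closed curve on the interatrial septum, for the
transseptal puncture), the **mitral-valve annulus**, and a segmentation of
the left atrium + appendage (LA(A)) blood pool.

This package implements everything around the detection networks of such a
workflow, for tool builders and imaging researchers:

* **Label encoding** — geometry → voxel training targets: a labelled sphere
  for a point, a swept-sphere tube for a closed curve, a two-label split of
  the blood pool for a plane.
* **Decoding** — predicted masks → geometry: inclusive-threshold
  binarization, classical refinement (largest component, marker-based
  watershed), centroid point decoding, skeleton-cycle curve extraction,
  total-least-squares plane fitting on the inter-label voxel boundary.
* **Measurements** — the closed appendage contour in each detected plane
  with four diameters (area-based `2√(A/π)`, perimeter-based `P/π`,
  caliper minimum and maximum), the Amulet depth (ostium centroid → roof
  along the plane normal) and the Watchman FLX depth (landing-zone
  centroid → appendage tip, tip found as the intramask-geodesically
  farthest point).
* **Metrics** — Sørensen–Dice, Hausdorff distance, curve-centroid distance,
  signed diameter differences, plane angles, and mean ± SD observer-style
  comparison tables.
* **Phantom** — a synthetic contrast-CT left atrium + appendage with
  exactly known landmarks, replacing patient data for all testing.
* **Predictors** — the inference contract, with an exact oracle and a
  perturbed oracle (blur, jitter, speckle) standing in for trained models.

## Worked example

```python
import laaoplan as lp

# a synthetic case with exactly known anatomy
volume, truth = lp.generate_phantom(lp.default_spec(seed=3))

# run the full workflow with the exact oracle standing in for the networks
report = lp.run_case(volume, lp.make_oracle(truth), lp.PipelineConfig(), case_id="demo")

d = report.ostium_section.diameters
print(f"ostium perimeter-based diameter: {d.perimeter_based:.2f} mm")
print(f"ostium min/max diameter: {d.minimum:.2f} / {d.maximum:.2f} mm")
print(f"Amulet depth: {report.depth_amulet_mm:.2f} mm")
print(f"Watchman FLX depth: {report.depth_watchman_mm:.2f} mm")

true_d = truth.sections["ostium"].diameters
print(f"analytic truth at the ostium: {true_d.perimeter_based:.2f} mm")
```

Output:

```
ostium perimeter-based diameter: 16.35 mm
ostium min/max diameter: 16.24 / 16.47 mm
Amulet depth: 29.37 mm
Watchman FLX depth: 27.13 mm
analytic truth at the ostium: 16.45 mm
```

The phantom's ostium is a circular tube section, so all four diameters
nearly coincide and match the analytic value (here within 0.1 mm); on a
real anatomy minimum < area-based < maximum would spread. The Amulet depth
is the distance from that contour's centroid to the appendage roof; the
Watchman FLX depth is the distance from the landing-zone centroid to the
appendage tip.

The same workflow is available from the shell:

```bash
laaoplan generate --out case0 --seed 3
laaoplan analyze  --input case0/volume.nii.gz --truth case0/truth.json --out report.json
laaoplan evaluate --pred report.json --truth case0/truth.json
laaoplan batch    --n-cases 25 --seed 0 --jitter 1 --blur 1 --out batch_out
```

`analyze` drives the pipeline with the oracle predictors (trained networks
are not shipped); `batch` runs a phantom battery and prints the
mean ± SD comparison table per landmark and metric.

## Documentation

`docs/methods.md` describes the models, the phantom and its ground-truth
construction, numerical choices, and known limitations.
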