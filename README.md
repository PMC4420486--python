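# ectplan

Electric-field simulation and voltage optimization for
electroporation-based treatments of liver tumors, with robustness
analyses for nearby hepatic vessels and for errors in their
segmentation.

## The problem

Electrochemotherapy (ECT) and irreversible electroporation (IRE) kill
tumor cells by exposing them to short high-voltage pulses delivered
through needle electrodes. A treatment succeeds only if the whole tumor
experiences an electric field above the treatment's target value —
400 V/cm for ECT, 600 V/cm for IRE — so deep-seated liver tumors are
planned on patient-specific numerical models. Large hepatic vessels
(highly conductive blood) act as field sinks: ignoring them, or
segmenting them inaccurately, can silently leave part of the tumor
under-treated. This package reproduces that analysis computationally,
for researchers in treatment planning and tissue bioelectromagnetics.

The core model is the nonlinear electrostatic problem

    div( sigma(|grad phi|) * grad phi ) = 0

on a labeled voxel grid (liver, tumor, vessel wall, blood, electrodes),
where each tissue's conductivity ramps from `sigma0` to `sigma1` as the
local field crosses its reversible (`E0`) and irreversible (`E1`)
electroporation thresholds, with no resealing between pulses. Electrode
pairs are driven sequentially at two optimized voltages (outer-pair and
diagonal); the per-voxel maximum field over the sequence — the field
envelope — is compared against the target field to give the tumor
coverage percentage (success: >= 99.9%). See `docs/methods.md` for the
full model, discretization, and known limitations.

## Worked example

Coverage of a 10 mm tumor treated by ECT through four needle electrodes
placed 2 mm outside the tumor edge, at the published optimal voltages
(600 V between neighboring electrodes, 1000 V across the diagonals):

```python
import ectplan as ep

scene = ep.build_simplified_scene(tumor_diameter=10, spacing=0.5)
electrodes = ep.place_electrodes(scene, "ECT", 10, 4)
scene = ep.rasterize_electrodes(scene, electrodes)

plan = ep.make_pulse_plan(4, U_outer=600, U_diag=1000)
envelope = ep.solve_sequence(scene, plan)
report = ep.coverage(envelope, scene, "ECT")
print(f"coverage {report.tumor_coverage_pct:.3f}%  "
      f"liver>400V/cm {report.liver_ire_volume_mm3:.0f} mm^3  "
      f"currents {[round(c, 2) for c in report.currents_A]} A")
```

prints

```
coverage 100.000%  liver>400V/cm 11660 mm^3  currents [2.15, 2.22, 2.24, 2.33, 3.7, 3.79] A
```

— the tumor is fully covered at 400 V/cm, about 11.7 cm^3 of healthy
liver sits above the liver IRE threshold, and each of the six
electrode-pair drives draws 2–4 A, well under the 50 A generator limit.
Adding a 7 mm vessel touching the tumor, perpendicular to the
electrodes (`ep.build_simplified_scene(10, 7.0, 0.0, "perpendicular",
spacing=0.5)`), drops coverage to ~94% at the same voltages: the
planning error committed by ignoring the vessel.

The same machinery drives the study pipelines
(`ep.run_ignore_vessel_study`, `ep.run_segmentation_error_study`,
`ep.run_no_vessel_comparison`) and a CLI:

```bash
ectplan scene build --tumor-diameter 10 --vessel-diameter 7 --distance 0 \
    --orientation perpendicular --spacing 0.5 --out scene.nii.gz
ectplan solve scene.nii.gz --treatment ECT --tumor-diameter 10 \
    --n-electrodes 4 --u-outer 600 --u-diag 1000 --vtk-out field.vtk
ectplan study seg-error --out segerr.csv
```

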