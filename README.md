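# spineplan

Patient-specific planning of posterior instrumentation for adolescent
idiopathic scoliosis (AIS). Given a 3D spine geometry (per-vertebra
landmarks, T1→pelvis), `spineplan`:

1. quantifies the deformity with twelve standard geometric descriptors —
   proximal thoracic (PT), main thoracic (MT) and thoracolumbar/lumbar
   (TL/L) coronal Cobb angles, apical vertebral translation (AVT),
   thoracic kyphosis (TK), lumbar lordosis (LL), three apical vertebral
   rotations (AVR, Stokes pedicle method) and three plane-of-maximum-
   curvature orientations (PMC) — plus the unfused-vertebra count F;
2. scores candidate strategies with a surgeon-weighted corrective
   objective Ф;
3. simulates each strategy's manoeuvres (rod attachment, rod derotation,
   compression/distraction) on a simplified quasi-static flexible-
   multibody spine model;
4. searches the six-variable strategy space — upper and lower instrumented
   vertebrae (UIV/LIV), implant density and type, thoracic and lumbar rod
   bends — with a U-type uniform design, per-descriptor linear regression
   surrogates, and discrete minimization of Ф, verifying the optimum by
   re-simulation.

It is aimed at computational-biomechanics researchers studying how
surgeon-specific correction objectives shape instrumentation strategies.
A parametric synthetic-patient generator (with a calibration loop that
hits requested deformity measures) stands in for radiographic 3D
reconstruction, so the whole pipeline runs from code alone.

## The corrective objective

For a descriptor set θ with preoperative values θ⁰ (floored at 5°, AVT at
0.5 cm), chosen normal sagittal targets θⁿ, and unfused count F with space
maximum F⁰:

    Ф = W1·[a1·(θPT/θPT⁰)² + a2·(θMT/θMT⁰)² + a3·(θTL/L/θTL/L⁰)²
            + a4·(X_AVT/X_AVT⁰)²]
      + W2·[b1·((θTK−θTKⁿ)/(θTK⁰−θTKⁿ))² + b2·((θLL−θLLⁿ)/(θLL⁰−θLLⁿ))²]
      + W3·[c1..c3 · AVR ratios² + c4..c6 · PMC ratios²]
      + W4·(F⁰/F)²

with all weight groups (given in percent, as surgeons specify them)
normalized so that Ф = 1 at the preoperative state with F = F⁰. The
package ships the weight table of eleven surgeon profiles (S1–S11) and a
table of eleven published strategy outcomes used for summary-statistics
checks.

## Worked example

Generate the packaged index patient (Lenke 2B: PT 51° left, MT 56° right,
TL/L 38° left, TK 22°, LL 44°), measure it, and simulate one strategy:

    spineplan generate src/spineplan/data/index_patient.yaml -o patient.csv --tol 0.1
    spineplan measure patient.csv

    descriptor     value  unit
      theta_PT 51.000762   deg
      theta_MT 55.998205   deg
     theta_TLL 38.001710   deg
         X_AVT -2.987809    cm
      theta_TK 22.069952   deg
      theta_LL 43.969614   deg
    ...

The five calibrated measures reproduce the target deformity to ~0.1°;
AVT ≈ −3 cm says the main-curve apex sits 3 cm to the patient's right of
the T1 plumb line. Simulating a T4–L2 strategy with screws at the end and
apical vertebrae (`density: ends_apex`) and a 20°/30° rod
(`spineplan simulate patient.csv strategy.yaml -o out/`) attaches and
derotates the rod and writes the post-operative landmarks, descriptors and
a convergence log; on this example the main thoracic Cobb drops from 56.0°
to 13.0° while kyphosis moves toward the rod's thoracic bend — the coronal
deformity is rotated into the sagittal profile, which is the point of the
derotation manoeuvre.

The full search (`spineplan optimize patient.csv --profile S3 -o report/`)
simulates a 702-run uniform design over the 1296-strategy default space,
fits the surrogates, minimizes Ф for surgeon profile S3 and re-simulates
the winner, writing the design matrix, response table, surrogate
coefficients and the optimal strategy. `spineplan report strategies.csv`
prints min/max/mean/population-SD summaries of a strategy table.

The same functionality is available as a library:

```python
from spineplan import (index_patient_fixture, compute_all, make_context,
                       load_weight_profiles, build_design_space,
                       uniform_design, run_batch, fit_surrogate, minimize_phi)

spine = index_patient_fixture()
preop = compute_all(spine)
ctx = make_context(preop, tk_normal=35.0, ll_normal=50.0, F0=10)
space = build_design_space()
rt = run_batch(spine, uniform_design(space, 702, seed=0))
opt = minimize_phi(fit_surrogate(rt), ctx, load_weight_profiles()[0],
                   verify_on=spine)
print(opt.config.uiv, opt.config.liv, opt.predicted_phi)
```

## Landmark file dialect

CSV with header `label,landmark,x,y,z`, one row per (vertebra, landmark)
pair, 18 records (T1..T12, L1..L5, PELVIS) with 13 landmarks each:
`body_center, sup_center, inf_center, sup_c1..sup_c4, inf_c1..inf_c4,
ped_L, ped_R`. Coordinates in mm; global frame: origin at the pelvis
center, +z cephalad, +x anterior, +y patient-left. A three-vertebra
excerpt:

    label,landmark,x,y,z
    T7,body_center,15.63,-29.85,305.85
    T7,sup_center,14.22,-25.85,312.63
    T7,inf_center,17.03,-33.85,299.06
    T7,sup_c1,23.75,-8.25,304.24
    ...
    T8,body_center,17.82,-37.17,283.64
    T8,ped_L,-5.11,-27.38,284.41
    T8,ped_R,2.87,-57.13,284.14
    ...
    T9,body_center,13.26,-29.90,260.42
    ...

An equivalent nested JSON form (`.json` extension) is read and written by
the same functions. Patient parameters, instrumentation strategies and run
configurations are YAML.

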