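# kinemet

Depth-camera energy-expenditure estimation from skeletal kinematics.

`kinemet` is a research pipeline for estimating the energy expenditure
(EE) of treadmill activities — quiet standing, walking and running — from
3-D skeleton sequences recorded by a depth camera (Kinect-v1 style: 20
joints at 30 Hz).  EE is expressed in METs (1 MET = 1 kcal per kg of body
mass per hour) against breath-by-breath indirect-calorimetry ground
truth.  It is written for movement scientists and digital-health
engineers who want a contact-free alternative to wearing a portable
metabolic analyser.

Because no public recordings accompany this problem, the package ships a
first-class synthetic generator that simulates the full study: a cohort
with realistic anthropometrics (weight 60.20 ± 7.60 kg, age 21.90 ± 1.55 y),
six treadmill bouts (standing; walking at 4.8/5.6/6.4 km/h; running at
8.0/8.3 km/h), and three camera views (side, rear-side, rear; tripod
0.9 m high, ~2 m standoff).

## Method

For each frame the skeleton is re-referenced to the shoulder-centre
joint,

&nbsp;&nbsp;&nbsp;&nbsp;(xᵢ′, yᵢ′, zᵢ′) = (xᵢ − xᵣ, yᵢ − yᵣ, zᵢ − zᵣ),

denoised with a centred 5-point moving average
x*ₖ = (1/5) Σₙ₌ₖ₋₂^ₖ₊₂ xₙ′, and trimmed to the steady-state window (first
3 min of each bout discarded, next 2 min kept).  Six left-side joints
(shoulder, elbow, wrist, hip, knee, ankle) are differenced into per-frame
velocities

&nbsp;&nbsp;&nbsp;&nbsp;(vxₖ, vyₖ, vzₖ) = (p*ₖ − p*ₖ₋₁)/(tₖ − tₖ₋₁),

giving an 18-dimensional feature vector (optionally PCA-reduced to the
smallest component set explaining ≥ 90% of variance).  A one-against-all
RBF-kernel SVM classifies each row as standing/walking/running, and MET
is regressed by one of three families:

* **LR** — ordinary least squares (the linear baseline);
* **MLP** — 3 logistic hidden layers (70 nodes by default; a node sweep
  over 10…90 re-derives the width on any dataset);
* **CNN** — a 1-D conv-net over the 18×1 velocity vector (two length-3
  convolutions with ReLU, two max-pools, a 2 × 16-unit dense head).

Models are evaluated with MAE, MSE and RMSE (MET units) under 10-fold
cross-validation.  The *hierarchical* configuration first classifies each
row and then routes it to its activity-specific model (by default: CNN on
the rear view for standing, CNN on the side view for walking, MLP on the
rear view for running), which lowers the error for light and moderate
activities relative to one general model.

## Worked example

```python
import pandas as pd
import kinemet as km
from kinemet.harness import build_datasets
from kinemet.model import EnergyExpenditureModel

protocol = km.Protocol().scaled(n_subjects=4, duration=1.5)   # small demo
ds = build_datasets(protocol, seed=0, discard_min=0.4, keep_min=1.0)["side"]
ds = ds.subsample(6000, seed=0)

df = pd.DataFrame(ds.X, columns=list(ds.columns))
df["met"], df["activity"] = ds.met, ds.activity

res = EnergyExpenditureModel.from_dataframe(
    df, family="mlp", n_nodes=30, epochs=150
).fit(seed=0, cv_folds=10)
print(res.summary())
```

```
        Energy Expenditure Regression Results
========================================================
Strategy:        general       Rows:      6000
Family:          mlp           Features:  18
Seed:            0
Architecture:    MLP(18-30-30-30-1, logistic)
--------------------------------------------------------
In-sample errors (MET):
  MAE    0.3977    MSE    0.2356    RMSE    0.4854
Cross-validated errors (MET):
  MAE    0.4104    MSE    0.2533    RMSE    0.5033
========================================================
```

The cross-validated RMSE of ~0.50 MET means a typical per-frame EE error
of half a MET; for a 60 kg person exercising for an hour, an 0.55 MET
error corresponds to `km.met_to_kcal(0.55, 60, 1.0) == 33.0` kcal.

The same machinery is scriptable from the shell:

```bash
kinemet simulate --out sim/ --seed 1
kinemet preprocess --in sim/S000_walking_4.8_side_skeleton.csv --out pre.csv
kinemet extract --in pre.csv --out features.csv
kinemet evaluate --subjects 2 --duration 1.0 --discard-min 0.3 --keep-min 0.6 \
    --folds 5 --max-rows 3000 --out tables/ --seed 1
```

`kinemet evaluate` writes the full grid: general models per
view × family × PCA flag, classification accuracy per view, per-activity
models, and the hierarchical-vs-general comparison.

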