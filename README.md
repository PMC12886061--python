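# reirrad

Multi-centre benchmarking of image registration and dose accumulation for
thoracic reirradiation.

## The problem

Safe reirradiation of lung cancer requires knowing how much dose the
organs-at-risk (OARs) already received in the previous course. That means
transferring the previous-course dose distribution from the old planning CT
(CT_prev) onto the current one (CT_current) through a spatial registration —
rigid (RIR, 6 degrees of freedom) or deformable (DIR, a dense displacement
field) — converting it to an equieffective dose, and accumulating it with the
current plan. Different centres make different registration choices, and that
variability propagates directly into the cumulative doses that clinical
constraints are checked against.

`reirrad` is a reusable pipeline for quantifying that variability. Because
patient imaging from such exercises cannot be shared, the package ships a
synthetic-data module that generates thorax-like phantom cases — paired
previous/current anatomies related by a known smooth deformation, eight
thoracic OARs (aorta, bronchi, oesophagus, heart, both lungs, spinal cord,
trachea), and two dose distributions with overlapping mid-level isodoses —
and simulates a configurable number of centres, each submitting one RIR and
one DIR registration with centre-specific error. The same evaluation chain
runs unchanged on real multi-centre data in the package's on-disk format
(NIfTI volumes plus a JSON sidecar).

It is intended for medical physicists and trial QA groups designing
registration benchmarking or credentialing exercises, and for method
developers who need a controlled testbed with ground truth.

## What it computes

**Consensus structures.** Transferred OAR masks from all centres are fused
with the STAPLE expectation–maximisation algorithm at a 50% agreement
threshold; transferred structures are compared both to this consensus and to
the OARs delineated on CT_current.

**Geometric metrics.** Within the cranio-caudal extent where the current
plan's EQD2 dose reaches 2 Gy (full transversal extent retained):
Dice similarity coefficient (DSC), surface Dice within 3 mm (SDSC-3 mm),
mean surface distance (MSD), 98th-percentile Hausdorff distance (HD-98%)
and distance between centres of mass (DCM).

**Dose accumulation.** The previous-course physical dose is mapped onto
CT_current and then converted voxelwise to the equieffective dose in 2 Gy
fractions,

```
EQD2 = D · (d + α/β) / (2 + α/β),   d = D / n,
```

with α/β = 2 Gy for spinal cord and 3 Gy for the other OARs, each organ
converted with its own ratio; cumulative dose is the voxelwise EQD2 sum of
mapped-previous and current courses.

**Variability statistics.** Cumulative DVHs sampled at 0.1 Gy; near-maximum
constraints D_0.3cm³; inter-centre DVH bands and the band area (the integral
over dose of the inter-centre interquartile range of volume, Gy·%);
constraint values symmetrised about each case/organ/method midpoint. The
effect of registration method is tested with linear mixed-effects models
(method fixed; patient and centre as crossed random intercepts; REML; two-
sided Wald test at the 5% level), with dose variability entering as explicit
dispersion responses.

## Worked example

```python
from reirrad import (PhantomParams, CentreErrorModel, generate_case,
                     simulate_centres, staple, evaluate_all, to_eqd2)
from reirrad.geometry_metrics import records_to_frame

params = PhantomParams.for_clinical_case(3, size=(48, 48, 32),
                                         spacing=(4.0, 4.0, 6.0), seed=42)
case = generate_case(params)
subs = simulate_centres(case, n_centres=6, error_model=CentreErrorModel(seed=42))

consensus = {organ: staple([s.masks[organ] for s in subs]).mask
             for organ in case.organs}
current_eqd2 = to_eqd2(case.dose_current, alpha_beta_Gy=3.0)
records = evaluate_all(subs, {"consensus": consensus,
                              "delineated": dict(case.masks_current)},
                       current_eqd2, case_id=case.case_id)
frame = records_to_frame(records)
print(frame[frame.defined & (frame.reference == "delineated")]
      .groupby(["method", "metric"])["value"].mean().unstack().round(3))
```

prints

```
metric    DCM    DSC   HD98    MSD  SDSC3
method
DIR     0.886  0.952  3.353  0.248  0.939
RIR     2.569  0.805  4.684  1.101  0.750
```

— with the default error model (1 mm RMS deformable residual vs 3 mm rigid
residual plus ROI-preference jitter), the deformable registrations align the
OARs visibly better on every metric: higher overlap (DSC, SDSC-3 mm), smaller
surface distances (MSD, HD-98%) and smaller centroid offsets (DCM), all in mm
except the dimensionless Dice variants.

The full benchmark — seven cases (the seventh an atelectasis-like stress case
that the pipeline flags and excludes from dose analyses), six centres, STAPLE
consensus, dose mapping, DVH/constraint/band statistics and mixed models —
runs from the command line:

```
reirrad-benchmark run --config phantom.yaml --out run_dir --seed 1
reirrad-benchmark evaluate --cases DIR --submissions DIR --config cfg.yaml
```

and writes `metrics.csv`, `dvh.csv`, `constraints.csv`, `bands.csv`,
`models.csv`, a `manifest.json` (config, seeds, dialect flags) and a plain
text summary. `reirrad-benchmark --version` prints the implementation's
dialect flags (surface and percentile conventions etc.).

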