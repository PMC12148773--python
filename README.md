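# oartmotion

Quantification of intra-fractional bladder motion — and its dosimetric
consequences — during CBCT-guided online adaptive radiotherapy (oART) for
pelvic targets.

In an oART session the daily plan is re-optimized on a *planning* CBCT
(pCBCT) while the patient lies on the couch; a *verification* CBCT (vCBCT)
acquired ~20 minutes later, just before delivery, shows how much the anatomy
has already drifted. For the bladder that drift is dominated by filling:
anisotropic, mostly cranial and anterior, and large enough to matter when
margins shrink. This package provides the complete evaluation chain for that
question, for medical physicists and image-analysis researchers:

- **Contour metrics** — volume change, expansion rate (cc/min), directed
  Hausdorff distance and its robust 95th percentile (HD95%), Dice
  similarity coefficient `DSC = 2|A∩B| / (|A|+|B|)`.
- **Deformable registration** — rigid + multiresolution Gaussian-regularized
  demons (SimpleITK backend) with structure guidance, validated by the DSC
  between the warped planning bladder and the verification bladder; import
  of externally computed displacement fields.
- **Displacement-field analysis** — fraction of bladder volume displaced
  beyond 3/5/7 mm per cardinal axis (the margin-design table), cumulative
  deformation histograms, Jacobian-determinant maps (local volume change:
  1 = preserving, 2 = doubling), per-course mean/SD motion maps.
- **Dosimetry** — "treated" dose estimated by warping the intended dose
  through the displacement field (`treated(x) = intended(x + d(x))`),
  cumulative DVHs and clinical metrics (Vx%, Dy%, Dc cc), intended-vs-treated
  plan comparison against goal lists.
- **Cohort statistics** — group means, intra-/inter-patient SD
  decomposition, pooled OLS time trends with the slope t-test, weekly box
  statistics.
- **Synthetic phantom** — a deterministic pelvic phantom cohort with
  closed-form ground-truth deformations (anisotropic radial filling model,
  full/empty protocols, conformal dose with PTV margin), so every stage can
  be validated against analytic truth.

See `docs/methods.md` for models, conventions (LPS frame, pull-back
displacement fields) and numerical choices.

## Worked example

Simulate three fractions of a full-bladder-protocol patient, compare the
contour pair, recover the motion by registration, tabulate exceedance
against ground truth, and measure the dosimetric impact:

```python
from oartmotion import (PhantomSpec, generate_cohort, geometric_report,
                        deformable_register, directional_exceedance,
                        analytic_exceedance, warp_dose, compute_dvh,
                        dose_metric)
from oartmotion.dosimetry import DoseMetricSpec
from oartmotion.geometry import dilate_mask

spec = PhantomSpec(n_fractions=3, seed=42)      # full protocol, 128x128x96 @ 2 mm
cohort = generate_cohort(spec, patient_id="P01")
rec = cohort[0]

rep = geometric_report(rec.bladder_p, rec.bladder_v, rec.t_p, rec.t_v)
res = deformable_register(rec.vcbct, rec.pcbct,
                          fixed_mask=rec.bladder_v, moving_mask=rec.bladder_p)
treated = warp_dose(rec.dose_intended, res.dvf)
```

Output (printed by the snippet in full, see `geometric_report` and friends):

```
fraction 1: 245.6 -> 286.6 cc (1.96 cc/min over 20.9 min), HD95% = 7.2 mm, DSC = 0.923
registration: validation DSC = 0.998
  CrCa >3/5/7 mm:    7/  0/  0 % (truth    4/  0/  0 %)
  AP   >3/5/7 mm:    1/  0/  0 % (truth    0/  0/  0 %)
  LR   >3/5/7 mm:    0/  0/  0 % (truth    0/  0/  0 %)
CTV V100%: intended 100.0 % -> treated 100.0 %
PTV V95%:  intended 100.0 % -> treated 99.0 %
```

Reading it: the bladder gained 41 cc during the 21-minute adaptation
interval; the contour pair overlaps at DSC 0.92 with a 7.2 mm HD95%. The
registration recovers the motion (validation DSC 0.998), the exceedance
table localizes it to the cranial-caudal axis and agrees with the phantom's
analytic truth, and — because the motion stays inside the 7 mm PTV margin —
target (CTV) coverage is untouched while PTV coverage dips slightly, the
expected signature of cranial filling against a fixed dose cloud.

## Command line

```bash
oart simulate --config cohort.yaml --seed 0 --out cohort/   # phantom + manifest CSV
oart contours --manifest cohort/manifest.csv --out contours.csv
oart register --fixed v.nii.gz --moving p.nii.gz \
     --fixed-mask bv.nii.gz --moving-mask bp.nii.gz --out dvf.mha
oart deformation --dvf dvf.mha --mask bv.nii.gz --out exceedance.csv
oart dose --intended rtdose.dcm --dvf dvf.mha --structures rois.yaml \
     --goals goals.yaml --out comparison.csv
oart cohort --table contours.csv --out summary.csv
oart all --manifest cohort/manifest.csv --out report/      # full pipeline
```

Clinical inputs are read from DICOM (image series, RTSTRUCT contours,
RTDOSE with DoseGridScaling, acquisition timestamps) or NIfTI/MetaImage;
phantom cohorts are written as NIfTI plus a manifest CSV.

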