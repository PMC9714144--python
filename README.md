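# flow4d

Intracardiac 4D flow CMR analysis for studies of right-ventricular (RV)
function — in particular pulmonary arterial hypertension (PAH) cohorts —
covering the full chain from time-resolved velocity fields to cohort-level
statistics:

* **Four-component flow decomposition.** End-diastolic blood is seeded at
  voxel centers of the segmented blood pool and traced with 4th-order
  Runge–Kutta pathlines forward over systole and backward over the preceding
  diastole through the periodic cardiac cycle. Each particle is labelled by
  time-varying mask membership:

  | component | entered in diastole | ejected in systole |
  |---|---|---|
  | direct flow | yes | yes |
  | retained inflow | yes | no |
  | delayed ejection flow | no | yes |
  | residual volume | no | no |

  Reported per ventricle as percentages of seeded particles, plus the
  *fractional flow ratio* (RV direct flow / RV residual volume).

* **Kinetic energy.** Per frame, KE(t) = Σ ½ ρ V_voxel |v|², normalized to
  end-diastolic volume (KEI_EDV, µJ/ml), with peak-systolic, average-systolic
  and peak E-wave summaries, and the *KE discordance* (RV/LV ratio of average
  systolic KEI_EDV).

* **Cine metrics.** Remodelling index RVEDV/LVEDV and its adverse cutoff
  (control mean + 3 SD), ejection fraction, TAPSE, inter-ventricular
  synchrony index, planimetered atrial area, end-systolic GLS, and
  pulmonary-artery relative area change 100 % × (max − min)/min.

* **CPET.** Peak VO₂ (highest 10-s averaged exercise sample), % predicted,
  VE/VCO₂ slope (OLS of VE on VCO₂ from exercise start to peak), default
  imputation for incomplete tests, threshold stratification, and composite
  1–3 risk grading.

* **Cohort statistics.** Normality-gated group comparisons with Bonferroni
  families, Pearson correlation, univariate screen + stepwise multivariable
  regression (optionally on ln-transformed outcomes), ROC with
  Youden-optimal thresholds, the DeLong test for correlated AUCs, nested
  logistic incremental χ², and Bland–Altman / coefficient-of-variation
  reproducibility.

* **Synthetic data.** Analytic phantoms with closed-form ground truth
  (uniform, rigid rotation, plug-transit, two-channel) and simulated
  control/PAH cohorts whose marginals follow published summary statistics,
  so every stage is verifiable without patient data.

## Worked example

Build the two-channel phantom — a plug-flow channel (transit distances
a = 24 and b = 28 voxels along a 40-voxel chamber) in parallel with an
equal-volume static channel, giving exact analytic component fractions
(15, 15, 20, 50) % — and run the full pipeline on it:

```bash
python - <<'PY'
from flow4d import data_model as dm
from flow4d.synthetic import PhantomSpec, make_phantom
fld, mask, gt = make_phantom(PhantomSpec(kind="two_channel"))
dm.write_velocity_field(fld, "demo")
dm.write_masks(mask, "demo_mask.nii.gz")
PY
flow4d analyze --velocity demo --mask demo_mask.nii.gz \
    --ventricle RV --ed-frame 0 --es-frame 12 --out demo.json
```

`demo.json` then contains (abridged):

```
"n_particles": 16000,
"direct_flow": 15.0,
"retained_inflow": 15.0,
"delayed_ejection_flow": 20.0,
"residual_volume": 50.0,
"fractional_flow_ratio": 0.3,
"summary": {"peak_systolic": 6.412, "average_systolic": 6.412,
            "peak_e_wave": 1.913}
```

The recovered fractions equal the phantom's analytic partition exactly:
16 000 seeded particles, of which 15 % entered during diastole and were
ejected the same cycle (direct flow), and the static channel contributes
the 50 % residual volume. The KEI_EDV summaries are flat within each phase
because the plug speeds are constant over systole (6.412 µJ/ml is
½ρu_s² scaled by the moving fraction of the pool).

Library use mirrors the CLI:

```python
from flow4d import make_phantom, PhantomSpec, analyze_ventricle, RV
fld, mask, gt = make_phantom(PhantomSpec(kind="two_channel"))
res = analyze_ventricle(fld, mask, RV, ed_frame=0, es_frame=12)
print(res.percentages())   # {'direct_flow': 15.0, ...}
```

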