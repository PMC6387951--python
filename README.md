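# plicasym

Interhemispheric microstructural asymmetry statistics in the posterior
limb of the internal capsule (PLIC) for stroke motor-outcome analysis.

## The problem

After a middle-cerebral-artery ischemic stroke, degeneration of the
corticospinal tract (CST) alters diffusion-MRI microstructural indices
— fractional anisotropy (FA), the NODDI orientation dispersion index
(ODI), generalized FA (GFA), and the diffusivities — on the lesioned
(ipsilesional) side while the opposite (contralesional) side stays
close to normal. Because the PLIC is the white-matter bottleneck of the
motor pathway, the *asymmetry* between the two PLICs in a baseline scan
carries prognostic information about upper-extremity motor recovery,
measured by the Fugl-Meyer Upper Extremity (FM-UE) score (0–66) at a
~5-week follow-up.

`plicasym` implements that analysis end to end for researchers working
with co-registered scalar parameter maps, region labels and lesion
masks, and ships a synthetic cohort generator so every stage is
testable without patient data.

## The statistics

For voxel samples C (contralesional) and I (ipsilesional) of one
parameter in one region:

* **Mean asymmetry**  ΔPLIC_Mean(C, I) = C̄ − Ī.
* **Distributional asymmetry**  the half Kullback–Leibler divergence

      ΔPLIC_KLD(C, I) = ½ Σᵢ p_C(i) ln( p_C(i) / p_I(i) )

  on a shared 10-bin histogram, with bin probabilities estimated by
  James–Stein shrinkage toward the uniform distribution
  (λ* = (1 − Σθ̂²) / ((N−1) Σ(1/B − θ̂ₖ)²), clipped to [0, 1]).
  Its natural log is the regression predictor.

* **Validation** — every split of the 9 stroke subjects into 6 training
  and 3 test points (84 splits) gets an OLS line; lines are scored by
  test NRMSE (normalized by the outcome range); the reported r² is
  optimism-adjusted: r²_adj = r²_full − mean(r²_train − r²_full).
* **Group tests** — paired two-tailed t-tests (hemispheric differences
  within controls and within stroke subjects) and Welch t-tests (stroke
  ipsilesional vs controls), Holm step-down corrected per region and
  test kind.
* **Lesion metrics** — lesion volume (mL) and lesion load (percent of
  each CST label overlapped by the lesion), correlated with FM-UE
  outcomes via Pearson r and the t-transform p-value.

## Worked example

```python
from dataclasses import asdict
import pandas as pd
from plicasym import CohortConfig, generate_cohort, asymmetry_table, run_validation_grid

subjects, samples = generate_cohort(CohortConfig(seed=1))
subjects_df = pd.DataFrame([asdict(s) for s in subjects])
grid = run_validation_grid(asymmetry_table(samples), subjects_df,
                           outcomes=("fm_ue_tp2",))
print(grid[["parameter", "predictor_type", "r2_adjusted", "final_nrmse"]])
```

prints (among other rows):

```
parameter predictor_type  r2_full  r2_adjusted  mean_nrmse_test  final_nrmse
      ODI     delta_mean 0.888715     0.873746         0.143995     0.130700
      ODI  log_delta_kld 0.836202     0.823469         0.181066     0.161698
```

On this seeded cohort the ODI mean asymmetry explains ~87% of the
follow-up FM-UE variance after optimism adjustment, and the log-KLD
predictor ~82%; the final NRMSE says the selected line misses the
observed scores by ~13% / ~16% of the outcome range. Control subjects'
asymmetries sit near zero (their ΔPLIC_KLD reflects only sampling
noise), while the stroke subjects' injected ipsilesional shift drives
both statistics.

The same analysis runs from disk (NIfTI maps/labels/lesions + CSV
subject table) through a thin CLI:

```bash
plicasym simulate --out cohort/ --seed 1
plicasym run-all --root cohort/ --out results/
```

The `examples/` directory holds one short script per capability.

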