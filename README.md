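# cardiodose

Dose to cardiac substructures — the four chambers, the great vessels and
the whole heart — is increasingly implicated in the survival of lung
cancer patients treated with stereotactic body radiotherapy (SBRT).
Establishing *which* substructure's dose matters is hard: substructure
dose parameters are strongly collinear, auto-generated contours carry
delineation uncertainty that propagates into every DVH point, and the
fractionation-sensitivity parameter α/β of the heart is itself uncertain.

`cardiodose` is a reusable, tested implementation of an analysis pipeline
built for exactly this problem, aimed at radiotherapy outcome researchers:

* **Contour-uncertainty propagation** — binary structure masks are
  expanded and contracted by physical margins derived from
  segmentation-agreement statistics (mean surface distance MSD ± 2 SD),
  via the exact Euclidean distance transform on the anisotropic voxel
  lattice. Dice, HD95 and MSD metrics and the DSC > 0.80 / MSD < 2 mm
  inclusion rule are included.
* **EQD2 dosimetry** — voxel-wise conversion of planned physical dose to
  the equivalent dose in 2 Gy fractions,
  `EQD2 = D · (d + α/β) / (2 + α/β)` with fraction dose `d = D/n`,
  followed by extraction of Dmean and D0.1cc (maximum-dose surrogate) per
  structure, per contour variation, per α/β scenario.
* **Ensemble variable selection** — bootstrapped elastic-net Cox models
  (mixing parameter tuned between ridge and lasso by cross-validated
  partial likelihood on every resample; per-feature selection
  percentages) and ensembles of random survival forests (tree-level
  out-of-bag permutation importance, median over forests against a 0.01
  threshold), run across a 2 × 4 design: {contracted, original, expanded}
  contours and an all-3 Gy α/β scenario, each with dose-only and
  dose-plus-confounder covariate sets. Features influential in *both*
  approaches in *every* run form the consensus that enters a final
  multivariable Cox model.
* **Dose-threshold finding** — the cutpoint maximizing the two-sample
  log-rank statistic, stabilized as the median over 100 two-thirds
  subsamples, with Kaplan–Meier median-survival contrast between strata.
* **Synthetic cohorts with known ground truth** — a voxel thorax phantom
  (masks, dose grids, covariates, Weibull proportional-hazards survival)
  and a fast feature-level generator, so the whole pipeline is testable
  end to end without any clinical data.

## Worked example

Run the parameter-recovery benchmark: a synthetic cohort of 300 patients
in which the left atrial mean EQD2 is the sole dose-linked hazard term
(hazard ratio 1.05 per Gy), analysed blind by the full 8-run stack.

```python
from cardiodose.benchmarks import recovery_experiment

report = recovery_experiment(n_patients=300, seed=1)
print(report["consensus"])
print(report["final_cox"]["original/standard"])
for run in report["runs"][:2]:
    print(run["run"], run["driver_pct"], round(run["driver_vimp"], 4))
```

prints

```
['LA_mean_eqd2']
{'hazard_ratio': 1.0491318673813812, 'ci_low': 1.0384180091323651,
 'ci_high': 1.0599562656610695, 'log_se': 0.005237146827695013,
 'within_2se': True}
original/standard/dose_only 100.0 0.0218
original/standard/complete 100.0 0.02
```

— the consensus is exactly the designed driver, its elastic-net selection
percentage is 100% with a median VIMP well above the 0.01 flag, and the
final multivariable Cox hazard ratio (1.049 per Gy EQD2, CI 1.038–1.060)
covers the simulated truth of 1.05.

The full study pipeline on a voxel-phantom cohort runs from a single YAML
config:

```bash
cardiodose run --config study.yaml           # simulate → … → report
cardiodose simulate --config study.yaml --out sim/ --seed 1
cardiodose threshold --features f.csv --cohort c.csv \
    --feature-name LA_mean_eqd2 --config study.yaml --out thr/
```

with `study.yaml` like

```yaml
seed: 1
out_dir: study_out
cohort: {n_patients: 300}
model: {n_boot: 100, n_forests: 4, n_trees: 150, cv_folds: 3}
margins: {policy: symmetric, LA: {msd_mm: 1.2, sd_mm: 0.4}}
```

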