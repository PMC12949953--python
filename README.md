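# estro-mr

Drug-target Mendelian randomisation (MR) of oestrogen-receptor perturbation
on neuropsychiatric and brain-structural outcomes — as a tested, reusable
Python package.

Menopausal hormone therapy acts by binding the oestrogen receptors ERα and
ERβ (encoded by *ESR1* and *ESR2*). Whether perturbing these targets alters
the risk of Alzheimer's disease, depression, anxiety, or brain structure can
be probed without a trial by *cis* drug-target MR: SNPs in or near the target
gene that shift a positive-control biomarker (bone mineral density, SHBG, or
haemoglobin — downstream readouts of receptor activity) serve as instrumental
variables, and their effects on the outcomes are combined into causal
estimates from GWAS summary statistics alone. This package implements that
workflow end to end for epidemiologists and methodologists who want to
reproduce, audit, or extend such analyses: instrument selection with a full
exclusion ledger, two-sample harmonisation, the five standard estimators,
FDR control, and a synthetic-data generator with known ground truth.

## Methods at a glance

For harmonised per-variant effects β̂_Xj (variant → biomarker) and β̂_Yj
(variant → outcome) with standard errors σ_Xj, σ_Yj:

- **Wald ratio** (single-variant instruments): θ̂ = β̂_Y/β̂_X with first-order
  SE σ_Y/|β̂_X|.
- **IVW** (primary for ≥ 2 variants): zero-intercept weighted regression,
  θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂_Xj², w_j = σ_Yj⁻²; multiplicative
  random-effects SE inflated by max(1, √(Q/(L−1))) with Cochran's Q.
- **MR-Egger**: weighted regression with a free intercept (directional
  pleiotropy diagnostic), exposure effects re-oriented non-negative,
  t-inference with L−2 df.
- **Weighted median**: 50th percentile of the weight-ordered per-variant
  ratio distribution; bootstrap SE.
- **Simple / weighted mode**: argmax of a Gaussian-kernel density over the
  per-variant ratios; bootstrap SE.

Benjamini–Hochberg FDR (5%) is applied across the family of primary
(IVW/Wald) estimates only. Instruments are selected from catalog-style
candidate tables by p < 5×10⁻⁸, ±200 kb around the gene, sex- and
ancestry-based exclusions and a biomarker allowlist, then pruned to pairwise
r² < 0.1 with main-SNP tie-breaks (multi-study evidence, then sample size,
then summary-statistic availability).

## Worked example

Simulate a 7-variant instrument with true causal effect θ = 0.5, harmonise,
and estimate:

```python
from estro_mr.synthetic_data import SimulationConfig, simulate_pair
from estro_mr.harmonisation import harmonise, analysis_ready
from estro_mr.mr_estimators import ivw, mr_egger, weighted_median

study = simulate_pair(SimulationConfig(seed=42, n_snp=7, theta=0.5))
kept = analysis_ready(harmonise(list(study.exposure), list(study.outcome)))
est = ivw(kept)
print(f"IVW      beta={est.beta:.3f}  95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]  p={est.p:.4g}  Q={est.q_stat:.2f}")
wm = weighted_median(kept, n_boot=1000, seed=1)
print(f"W-median beta={wm.beta:.3f}  95% CI [{wm.ci_low:.3f}, {wm.ci_high:.3f}]  p={wm.p:.4g}")
slope, intercept = mr_egger(kept)
print(f"Egger    beta={slope.beta:.3f}  intercept={intercept.beta:.4f} (p={intercept.p:.3f})")
```

prints

```
IVW      beta=0.547  95% CI [0.430, 0.664]  p=5.57e-20  Q=5.81
W-median beta=0.558  95% CI [0.404, 0.712]  p=1.367e-12
Egger    beta=0.645  intercept=-0.0062 (p=0.719)
```

The IVW and weighted-median intervals cover the true θ = 0.5; the Egger
intercept is compatible with zero, i.e. no directional pleiotropy — as
simulated. The same stages are scriptable from the shell:

```sh
estro-mr simulate --seed 42 --out-dir sim/
estro-mr harmonise --instruments sim/exposure.tsv --outcome sim/outcome.tsv --out sim/pairs.tsv
estro-mr mr --pairs sim/pairs.tsv --seed 1 --out sim/estimates.tsv
estro-mr run --config plan.yaml --out results/   # full multi-outcome pipeline
```

`estro-mr select` applies the candidate filters and LD pruning (with a
per-stage exclusion ledger), and `estro-mr fdr` appends BH q-values.

## Scope

Live GWAS-Catalog queries, outcome-GWAS downloads, LD estimation from
genotype panels, proxy-SNP lookup and figure rendering are out of scope;
LD is consumed as a precomputed r² matrix and forest-plot data are exported
as TSV.
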