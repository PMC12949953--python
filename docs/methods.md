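# Methods

## Model and assumptions

The package estimates the causal effect θ of genetically proxied
oestrogen-receptor perturbation on an outcome from two-sample GWAS summary
statistics. Each instrument variant j carries a harmonised pair
(β̂_Xj, σ_Xj; β̂_Yj, σ_Yj) of biomarker and outcome effects per copy of the
same effect allele. Under the instrumental-variable assumptions (relevance,
independence from confounders, and exclusion restriction — the variant
affects the outcome only through the receptor pathway proxied by the
biomarker), each per-variant Wald ratio θ_j = β̂_Yj/β̂_Xj estimates θ.

Estimates inherit the input scale: SD units of the outcome (or log-odds for
binary outcomes) per SD-unit change in the positive-control biomarker. For a
biomarker that proxies perturbation *inversely* (receptor agonism lowers
haemoglobin), the stored estimate keeps the biomarker orientation and the
pipeline's forest export carries a display-layer sign-flip flag instead of
modifying the estimate.

## Instrument selection

Candidates (one row per variant-biomarker-study association) pass five
filters applied in a fixed ledger order: genome-wide significance
(p < 5×10⁻⁸), position within the flanked gene span (±200 kb, 1-based
inclusive on both edges), removal of male-only discovery samples, restriction
to an ancestry allowlist (European by default), and a biomarker allowlist.
Stage counts depend on the order (a row failing several filters is charged to
the first); the surviving set does not. The ledger satisfies
`initial = retained + Σ excluded` by construction, checked in tests.

Survivors of the same biomarker are clustered by LD: connected components of
the graph with an edge wherever r² ≥ 0.1. Pairs *below* 0.1 are treated as
effectively independent, so retained instrument SNPs are pairwise r² < 0.1
(uncorrelated in the weak sense conventional for instrument pruning). One
main SNP is chosen per cluster by the lexicographic key (reported in more
than one study, largest reporting-study sample size, summary statistics
available), with residual ties broken by rsID lexical order so selection is
deterministic and order-invariant; the chosen SNP's statistics come from its
largest-n study. Summary-statistic availability is supplied as an optional
rsID set because association records themselves carry no such field.

## Harmonisation

Outcome effects are aligned to each instrument variant's effect allele:
direct letter match (kept), other-allele match (beta negated), strand
complement for non-palindromic variants, and allele-frequency concordance
for palindromic (A/T, C/G) variants — the outcome effect allele corresponds
to the exposure effect allele iff both frequencies fall on the same side of
0.5. A palindromic variant is dropped when either frequency is missing or
lies inside the ambiguity window |eaf − 0.5| < 0.08 (window configurable;
applying it to *either* side is deliberately conservative — a frequency near
0.5 on one side alone already makes concordance unreliable). Variants absent
from the outcome table are dropped, never proxied.

Catalog-style exposure records often print no other allele. Such a variant is
aligned only if the outcome allele pair contains the exposure effect allele,
read at face value on the reported strand; complements are never guessed, and
unalignable variants are excluded with a per-variant reason. This containment
rule intentionally skips the palindromic drop (without the exposure allele
pair the palindromic test could only be made on the outcome side, and the
letter match is then taken as authoritative); users who need stricter
behaviour should supply complete exposure allele pairs.

## Estimators

- **Wald ratio** (single variant): first-order delta SE σ_Y/|β̂_X|, ignoring
  exposure-beta uncertainty; a second-order variant adding
  β̂_Y²σ_X²/β̂_X⁴ is available behind a flag. First-order is the default
  because it is the convention of standard two-sample MR toolkits and
  reproduces published CI widths.
- **IVW** (≥ 2 variants; the primary estimator): zero-intercept weighted
  regression with weights σ_Y⁻², algebraically the inverse-variance-weighted
  mean of the θ_j. Default variance model is multiplicative random-effects:
  the fixed-effects SE times max(1, √(Q/(L−1))), Q = Cochran's statistic over
  the per-variant ratios; under-dispersion is floored at 1, making the test
  mildly conservative when the ratios are homogeneous. Fixed-effects is
  selectable. Instruments of exactly two variants are routed to IVW (the
  estimator is defined there); single variants to the Wald ratio.
- **MR-Egger** (≥ 3 variants): weighted regression with free intercept after
  re-orienting all β̂_X ≥ 0; SEs from the weighted normal equations scaled by
  max(1, RSS_w/(L−2)); t-inference with L−2 df. The intercept estimates the
  mean directional pleiotropy under InSIDE.
- **Weighted median** (≥ 3): the ratio distribution's 50th percentile with
  each ordered ratio centred at cumulative standardised weight
  cum_j − w_j/2, linearly interpolated; weights σ_j⁻² with
  σ_j = σ_Yj/|β̂_Xj|. Consistent when ≥ 50% of weight comes from valid
  instruments.
- **Mode-based estimates** (≥ 3): argmax of a Gaussian-kernel density over
  the θ_j (equal weights for the simple mode, σ_j⁻² for the weighted mode);
  bandwidth = φ × 0.9·min(sd, MAD·1.4826)·L^(−1/5) with φ = 1 by default.
  The argmax is located on a 512-point grid and refined by bounded scalar
  optimisation (xatol 10⁻¹²); tests pin it against an independent
  iteratively-refined grid search to 10⁻⁶. Degenerate ratio sets (all equal,
  or zero bandwidth) return the common ratio exactly.

Median and mode SEs come from a seeded parametric bootstrap (default 1000
draws) resampling both β̂_X and β̂_Y from their sampling distributions and
recomputing ratios *and* weights per draw. Confidence intervals use the exact
normal 97.5% quantile Φ⁻¹(0.975) = 1.959964… (t-quantile for Egger) rather
than 1.96 — below print precision, but it keeps oracle tests exact. p-values
are two-sided normal (t for Egger) and floored at the smallest positive
double so they stay in (0, 1].

`p_from_ci` inverts a printed (estimate, 95% CI) pair back to its implied
normal p-value; it exists to audit the internal consistency of published
estimate/CI/p triples, and the BH family recomputed from CI-derived raw
p-values reproduces a published adjusted column at full precision where the
printed 3-decimal raw p-values are too coarse.

## Multiple testing

BH step-up adjustment is applied across the primary family only — one IVW or
Wald-ratio p-value per (instrument, outcome) cell; in the packaged
three-instrument × six-outcome design that family has 18 members.
Sensitivity estimates are reported unadjusted. The implementation delegates
to `statsmodels.stats.multitest` and is tested against a literal step-up
oracle to 10⁻¹².

## Synthetic data generator

`simulate_pair` emulates the summary-statistic inputs of a cis drug-target MR
study. Per variant: true exposure effect b_j with magnitude uniform on
[0.4, 1.6]·`beta_x_scale` (defaults give |b| ∈ [0.02, 0.08] with SEs near
0.002, the scale of the packaged instrument records, and all b_j > 0 — the
exposure-increasing orientation conventional for instruments); observed
β̂_X ~ N(b_j, σ_Xj²); pleiotropy α_j ~ N(μ_α, σ_α²); observed
β̂_Y ~ N(θ·b_j + α_j, σ_Yj²); per-variant SEs jittered ±25% around their
scales. Defaults: 7 variants (the multi-variant instrument size of the study
design), θ = 0.5, no pleiotropy, 10% palindromic alleles, outcome allele
order randomly swapped to exercise harmonisation. The generator also emits
decoy candidate rows failing exactly one selection filter each, LD
"satellite" rows correlated with a chosen main SNP (built to lose the
main-SNP tie-break), and a block-structured LD matrix; identical config and
seed reproduce all outputs bit for bit.

Two deliberate simplifications: exposure-row p-values are computed from the
latent true effect rather than the noisy observed beta, so instrument rows
are genome-wide significant by construction and the decoy guarantee is exact;
and exposure-side noise *is* present while Wald/IVW use first-order SEs, so
the regression-dilution bias this induces is real but, at the default scales
(σ_X/b ≲ 0.1), an order of magnitude below the Monte-Carlo resolution of the
recovery tests. The generator does not emulate LD-correlated effect sizes,
sample overlap between exposure and outcome GWAS, winner's-curse selection of
instruments, or non-normal effect distributions — passing tests therefore
certify the estimators and plumbing, not robustness of real-data conclusions
to those phenomena.

## Problem sizes and numerical choices

Monte-Carlo properties (estimator bias, IVW coverage, type-I error,
Egger-intercept recovery) are evaluated over 500 replicate studies of
50-variant instruments — large enough that 3 Monte-Carlo SEs of the mean
resolve biases near 0.004 on θ = 0.5 while the whole suite stays
interactive-fast. Bias tests compare each estimator's replicate mean to the
truth within 3 Monte-Carlo SEs; coverage is required in [0.92, 0.97]; the
nominal-5% null rejection rate within 3 binomial SEs of 0.05. Oracle
equivalence tolerances: 10⁻¹⁰ for the normal-equation solves (IVW, Egger),
10⁻¹² for BH, 10⁻⁶ for the quantile/grid-search oracles.

Residual tie-breaks everywhere are lexicographic on rsID (selection) or
stable-sort order (median), so all pipeline outputs are deterministic under a
fixed seed; per-cell bootstrap seeds are derived from the plan seed and the
cell index.

## Known limitations

- No proxy-variant lookup, MR-PRESSO/outlier removal, Steiger filtering,
  multivariable MR or colocalisation — deliberately outside scope.
- The Wald/IVW first-order SE understates uncertainty when instruments are
  weak (σ_X comparable to b); the second-order Wald flag mitigates this for
  single-variant instruments only.
- The containment rule for exposure records lacking an other allele cannot
  detect palindromic strand ambiguity; results for such variants assume the
  two sources report on the same strand.
- Packaged instrument-record genomic positions are synthetic placeholders
  inside the annotated gene spans (the published record prints none); they
  matter only to the region filter, which they satisfy by construction.
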