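# Methods

This note documents the models and procedures implemented in `escctraj`,
their assumptions, the defaults that matter, and the design choices made
where the underlying conventions are genuinely open.

## Normalization and QC

Protein abundances arrive as reporter intensities with a pooled internal
reference channel per multiplex.  `normalize_to_reference` forms
`log2(intensity / reference)` per protein and drops the reference column;
proteins with non-positive reference intensity cannot be ratioed and are
set missing with a warning.  Mean-centering follows.  **Centering axis:**
the convention "log2-transformed and mean-centered" does not pin down the
axis; we default to per-sample (column) centering because batch and
loading effects manifest as sample-level shifts, and column centering
makes the output invariant to rescaling any sample's raw intensities by a
constant (a property the tests assert).  Per-protein centering is
available via `center="protein"`.

**Missing data:** no imputation anywhere.  Downstream statistics use
pairwise-complete values; proteins with insufficient data in a comparison
are flagged, not guessed.  `filter_by_quantification(m, f)` keeps proteins
quantified in at least `ceil(f * n_samples)` samples; `f = 0.5` mirrors a
"quantifiable in at least half the samples" set and `f = 1.0` the
"quantified across all samples" set.

QC uses (i) PCA restricted to housekeeping proteins — centered, unscaled
covariance PCA with a deterministic sign convention (the largest-magnitude
loading of each component is made positive), since structure among
housekeeping proteins indicates technical rather than biological
variation — and (ii) pairwise-complete Pearson correlation between samples
followed by hierarchical clustering of the correlation matrix (Euclidean
distance, complete linkage).  Sample pairs sharing fewer than 3 quantified
proteins are an error; constant samples are excluded and flagged.

The immunohistochemistry composite score is the product of the staining
intensity grade (0–3) and the positive-cell percentage grade (0–4), range
0–12.

## Differential testing and direction labels

Per protein, groups are compared with the two-sided Wilcoxon rank-sum
test: exact enumeration when `min(nA, nB) <= 8` and the pooled values are
tie-free, otherwise the normal approximation with tie correction and a 0.5
continuity correction.  The effect size is the difference of group means
on the log2 scale (so fold change = `2**log2fc`); a median-based variant
is deliberately not offered to keep one convention.  Paired NAT–Tumor
samples are still tested unpaired, matching the analysis the pipeline
reproduces; the pairing enters the synthetic generator (below), not the
test.  Multiplicity control is Benjamini–Hochberg (step-up, monotone,
order-preserving; NaNs propagate).

`classify_de` labels a protein U/D/S: significant (adjusted p < alpha,
default 0.01) with positive/negative log2fc, optionally additionally gated
on fold change > 1.5 (`require_fc`).  The default is the p-only gate;
the fold-change gate is exposed because published analyses use both
readings in different places.

Set enrichment: `fisher_overlap` reports the conditional hypergeometric
exact p and the plain cross-product odds ratio (with a separately-reported
Haldane +0.5 version when a cell is zero).  `annotation_enrichment_1d`
scores a set by the two-sided rank-sum of member vs non-member values with
the rank-biserial score `s = 2·AUC − 1 ∈ [−1, 1]`; the 2D variant scores
each dimension separately and combines significance conservatively as the
max of the two dimension p-values before BH — an approximation chosen
because the reference tool's 2D significance rule is not public.

## Nine-mode taxonomy

Each protein in the universe testable in both transitions gets
`mode = label(NAT vs Healthy) + label(Tumor vs NAT)`, nine values from
`SS` to `DD`.  The universe is always reported alongside the counts
because mode counts are only interpretable relative to it.  `mode_set`
materializes the protein sets; `"All"` is the union of the eight non-SS
modes.  `tasa_concordance` checks a user-supplied marker list (e.g.
tumor-adjacent specific activation genes) for the UD pattern.

## Synthetic cohorts

`generate_cohort(SimConfig)` is first-class, tested code.  Defaults are
the study conditions: 20 Healthy donors, 124 patients with paired
NAT/Tumor samples, 2000 proteins, mode proportions equal to the observed
nine-way mode frequencies of the esophageal Healthy/NAT/Tumor proteome
(SS 3621/6873, US 1164/6873, …), effect size 1.0 log2 units per
transition step (so a planted change of fold 2.0 clears a 1.5 gate with
margin), i.i.d. Gaussian noise sd 0.5 on the log2 scale (t with df = 5
behind `heavy_tails` for robustness checks), and a shared NAT/Tumor
patient intercept of sd 0.2 to emulate within-patient correlation.

Planted structure is kept *internally consistent with the mode truth*:

* the two-subtype NAT signature (300 SS proteins, subtype-2 fraction
  79/124) is applied **mean-centered across the NAT group** — subtype-2
  samples shift up by `shift·(1−f₂)` and subtype-1 down by `shift·f₂` —
  so the between-subtype contrast equals `subtype_shift` (default 1.0)
  while the NAT group mean, and hence the proteins' planted SS mode, is
  untouched;
* cell signatures shift in directions their modes already have: the
  immune signature (SS proteins) is subtype-linked and centered like the
  subtype signature; the stroma signature lives on DS proteins and is
  additionally elevated in Healthy samples; the epithelial signature
  lives on SU proteins and is elevated in Tumor samples;
* the latent survival risk is a patient factor `z ~ N(0,1)` expressed as
  `risk_loading · z` (default 0.5) in 50 designated US-mode proteins of
  both of a patient's samples — mean zero, so the US mode is preserved.

Survival: event times are exponential with hazard
`baseline_hazard · exp(log(subtype_hr)·[subtype 2] + risk_beta·z)`
(baseline 1/1500 per day ≈ median 2.8 years; DFS baseline 1.4× higher),
censoring is an independent exponential whose rate is solved numerically
(Brent) so the expected censored fraction equals the target (default
0.30).  Two scenarios are intended: the default (`subtype_hr = 2`,
`risk_beta = 0`), where the subtype is the sole hazard source and its
marginal Cox HR is therefore recoverable, and the model-selection scenario
(`subtype_hr = 1`, `risk_beta ≈ 0.7`), where only US proteins carry
signal.  They are separate because of Cox non-collapsibility: an omitted
latent risk factor would attenuate the marginal subtype HR below its
planted value.

All randomness flows from one NumPy PCG64 generator seeded by
`SimConfig.seed`; identical seeds give bit-identical cohorts.

**What the generator does not emulate:** peptide-level quantification and
protein inference, reporter-ion interference, missingness that depends on
abundance (values are missing completely at random if masked at all),
correlated protein modules beyond the planted signatures, and
non-proportional hazards.  Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration under its stated model, not
robustness to every artifact of real TMT data.

## Consensus subtyping

`consensus_cluster` is the Monti procedure: z-score each feature protein,
subsample 80% of samples without replacement `n_resamples` times (library
default 1000; the bundled pipeline config and the validation suite use
100–200, which bounds the Monte-Carlo error of consensus entries by about
`1/√100 = 0.1` — ample for the planted separations), cluster each
subsample (inner k-means with 10 restarts by default; complete-linkage
hierarchical as an alternative), and set
`consensus[i,j] = co-clustered / co-sampled`.  Final labels come from
complete-linkage hierarchical clustering of `1 − consensus`; silhouette
widths on the same distance summarize stability, and `chosen_k` maximizes
the average silhouette (reported for every k, never silently applied —
ties prefer smaller k).  Subtype–clinical association uses the Pearson
chi-squared test without continuity correction; agreement between two
labelings is the maximum-agreement matching (Hungarian) fraction.

## Cell-composition scoring

`ssgsea_score` implements the single-sample rank running-sum statistic:
per sample, proteins are ranked by descending value (average ranks on
ties); the score is `Σ_positions (P_in − P_out)` where `P_in` accumulates
member weights `rank^w` (default exponent `w = 0.25`) and `P_out`
accumulates non-members uniformly.  Scores are rank statistics — invariant
to any strictly monotone per-sample transform (tested).  This one scorer
stands in for both a cell-type enrichment tool and a gene-set variation
scorer: spillover compensation and kernel CDF estimation are intentionally
out of scope, because every downstream statistic needs only a score
matrix over user-supplied signatures.  Which signatures aggregate into
ImmuneScore/StromaScore (plain sums) is user configuration, shipped as an
editable example, not asserted truth.  Survival dichotomization of a score
uses the median by default (ties to the low arm), with the log-rank test.

## Survival models

`cox_fit` maximizes the Efron-ties partial likelihood by damped
Newton–Raphson to a gradient norm below 1e-8 (step-halving, non-finite
steps rejected); Wald HRs and CIs come from the observed information.  It
agrees with an established implementation to ~1e-5 on tied and untied
data (asserted in the tests against lifelines).

`ridge_cox_fit` minimizes `−ℓ(β) + (λ/2)‖β‖²` on internally standardized
features, returning coefficients on the original scale.  For `λ > 0` the
optimum lies in the row space of X, so the fit runs exactly in
`min(n, p)` dimensions via SVD — this is what makes per-mode models with
p ≫ n cheap.  λ is chosen from a grid by 10-fold (configurable)
cross-validated partial-likelihood deviance, fold k contributing
`−2·[ℓ_all(β̂_−k) − ℓ_−k(β̂_−k)]`; the model is then refit on all data at
the chosen λ.  This CV-deviance rule is adopted by analogy with
penalized-Cox practice since no single published rule is fixed for the
ridge variant.  At λ = 0 on a well-conditioned problem the path endpoint
equals the unpenalized fit to 1e-4 (tested).

Metrics: Harrell's C counts pairs with `t_i < t_j` and `event_i = 1`
(tied event times are not compared; tied scores count 0.5).  `td_auc` is
the cumulative-case / dynamic-control AUC with inverse-probability-of-
censoring weights from the Kaplan–Meier estimate of the censoring
distribution evaluated at `t⁻`; with no censoring it reduces exactly to
the static Mann–Whitney AUC (the anchor the tests assert to 1e-10), and
it matches scikit-survival's estimator to the same precision.

Constructions: the "subtype + pTNM" model is a Cox fit on the subtype
indicator and pTNM encoded ordinally I..IV = 1..4 (dummy coding would
spend degrees of freedom the 124-patient design cannot afford; the
encoding is a documented choice).  The "3c" staging applies 1-D k-means
(k = 3, 50 seeded restarts) to that model's risk scores and names the
clusters low/medium/high by ascending mean risk (strict ascent is an
asserted invariant).  `train_test_split` draws a seeded 82/124 split and
redraws (incrementing the seed, cap 100, final seed reported) until no
balance variable differs at `alpha = 0.05` (chi-squared for categorical,
rank-sum for continuous).  Survival prediction uses the Breslow baseline
cumulative hazard: `S(t|x) = exp(−H0(t)·e^{xβ})`.  Decision curves report
`NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` against treat-all and treat-none;
patients unresolved at the horizon (censored before t) are excluded with
their count reported — simpler than IPCW re-weighting and conservative
for the comparisons made here.

Lasso, spike-and-slab lasso and boosting variants are intentionally not
implemented; `compare_mode_models` accepts any coefficient vector through
`risk_score` for external comparisons.

## Problem sizes in the validation suite

The recovery benchmarks (also run by `scripts/acceptance.py`) use: the
default cohort for mode recovery; 20 null cohorts for type-I behaviour;
20 subtype cohorts at 100 consensus resamples; 50 replicates (200
proteins — the protein count is irrelevant to a subtype-only Cox fit) for
HR coverage; 20 replicates of the US-risk scenario with a 4-point λ grid
and 5-fold CV for model selection; and the bundled 2000-protein config,
run twice, for end-to-end byte-determinism.  These sizes keep each
benchmark's Monte-Carlo error well inside the margins being asserted.

## Known limitations

* The ssGSEA scorer is a surrogate for both xCell-style cell scoring and
  GSVA-style set scoring; absolute score values are not comparable to
  those tools, only the rank structure they induce.
* The 2D enrichment max-p rule is conservative; a set must be significant
  in both dimensions to survive.
* Decision-curve censoring handling (exclusion) mildly biases net benefit
  when censoring is informative.
* The Wald CI for the subtype HR relies on the asymptotic normal
  approximation; at n = 124 with ~30% censoring its empirical coverage of
  the planted HR is about 92–98% across replicate batches (measured by
  the benchmark), consistent with the nominal 95%.
* `staging_3c` assumes the risk-score distribution is at least roughly
  3-clustered; on unimodal scores the low/medium/high cut is stable but
  arbitrary.
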