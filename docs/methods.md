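# Methods

This note documents the statistical procedures, the synthetic-data model,
and the numerical and design choices behind `clpnet`.

## Questionnaire scoring

The 30 QLQ-C30 items map onto 15 subscales (5 functional, 9 symptom
scales/items, 1 global health scale); the version 3.0 item map ships as a
YAML data file so other instrument versions can be swapped in. A scale's
raw score is the mean of its available items; functional scales are scored
`(1 − (RS − 1)/range) × 100`, symptom and global scales
`((RS − 1)/range) × 100`, so functional scores rise with better
functioning and symptom scores with severity. No reverse-coding is applied
anywhere — negative network edges from functional to symptom nodes then
read directly as protective temporal relationships. A scale is scored when
at least half of its items are answered (the instrument manual's
half-rule); otherwise the score is reported absent, never imputed as zero.

## Synthetic-data generator

The generator is a first-order linear Gaussian VAR on the z-scale:

* wave-1 latent scores `z₁ ~ MVN(0, Σ₁)`, with Σ₁ exchangeable at ρ = 0.3
  within the functional (Q1–Q5) and symptom (Q6–Q14) blocks and zero
  between blocks — symptom-cluster correlation without hand-tuning 105
  entries;
* transitions `z_{t+1} = Bᵀ z_t + ε`, `ε ~ MVN(0, diag(σ²))`, where B is a
  15 × 15 cross-lagged matrix (row = predictor, column = outcome, diagonal
  = autoregressive continuity);
* observed scores are `marginal_mean + marginal_sd · z`, clipped to
  [0, 100] when `clip_mode="clip"`.

The study-like configuration (`make_paper_like_config`) uses n = 337,
the published per-wave marginal means/SDs for all 15 nodes, the five
strongest published T1→T2 edges (role→insomnia −0.291; global health →
social −0.221, → fatigue −0.220, → cognitive −0.173, → physical −0.120),
the three published T2→T3 nausea edges (→ appetite loss 0.154, → insomnia
0.072, → global health 0.265), and an autoregressive diagonal of 0.3 — a
stand-in, since wave-1 covariances and AR magnitudes are not published.
Innovation SDs are solved so every latent node keeps unit variance at
every wave; the affine map then reproduces the target marginal SDs
(up to clipping), and the generating B is exactly the estimand of the
standardized node-wise regressions.

What the generator does **not** emulate: item-level response processes
(scores are continuous unless `round_scores` is on), dropout/missingness
(the pipeline is complete-case by contract), floor/ceiling-induced
skewness beyond hard clipping, and any cross-lagged structure beyond the
planted sparse edges. Passing recovery tests therefore demonstrate that
the estimator finds sparse linear Gaussian signal at study scale — not
that real panel data satisfy those assumptions.

Clipping emulates the instrument's bounded range; an unclipped mode exists
because exact parameter recovery is only well-defined for the exact linear
model. Generation is fully reproducible from the config seed (Cholesky
factor times seeded standard normals, so results are stable across
platforms).

## Descriptive trajectories

Per node, a one-way within-subject ANOVA across the three waves:
`SS_total = SS_subjects + SS_time + SS_error`, `F = MS_time / MS_error`
with df = (w−1, (w−1)(n−1)). No sphericity correction is applied by
default, matching the plain-F reporting convention of the study design
this package mirrors; a Greenhouse–Geisser option exists. Post-hoc
comparisons are paired t-tests with Bonferroni adjustment
(`p_adj = min(1, 3p)`). Zero within-subject error variance is flagged as a
degenerate result (F = 0 or ∞) rather than raising a division error.

Superscript letters are assigned from the maximal cliques of the
"not-significantly-different" graph over waves, ordered by earliest wave.
Two waves share a letter iff their adjusted comparison is non-significant
at α = 0.05; intransitive patterns resolve naturally to multi-letter
strings (a, ab, b). Direction strings ("T1≈T2 < T3") combine consecutive-
wave significance with the ordering of means.

## Network estimation

Scores are z-standardized within each wave (sample SD, n−1 denominator);
constant columns are a hard error. Each of the 15 outcome regressions uses
all 15 wave-t predictors simultaneously and minimizes
`(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁` (unpenalized intercept), so
`λ_max = max_j |x_jᵀy|/n` independent of n. The coordinate-descent solver
is scikit-learn's, which optimizes this exact objective; solver tolerance
is 1e-8 and coefficients below 1e-8 in magnitude are reported as exactly
zero — that threshold also defines a "non-zero edge" when counting.

λ selection is two-stage:

1. **CV candidates.** A log-spaced path of 100 values from λ_max down to
   0.001·λ_max; 10-fold cross-validated prediction MSE; the candidate set
   is every grid value in the closed interval between the MSE-minimizing λ
   and the one-standard-error λ — the smallest defensible set containing
   both conventional choices.
2. **EBIC.** On the full dataset, `EBIC = n·log(RSS/n) + k·log n +
   2γ·k·log p` with γ = 0.5, k the number of selected coefficients and
   p the per-regression predictor count (15; configurable — total network
   parameters would be the alternative reading). The EBIC-minimizing
   candidate wins; exact ties go to the larger λ (sparser model).

The same CV seed — hence the identical fold assignment — is reused for all
15 node regressions and recorded, with the grid specification and a
grid/seed hash, in each network's reproducibility manifest. The raw fit
always retains autoregressive (diagonal) paths; `drop_autoregressive`
produces the view used for centrality. Estimation is complete-case only.

## Centrality

Out-EI = row sums, In-EI = column sums, Bridge-EI = the same sums
restricted to edges crossing the community partition (default: the
instrument's functional / symptom / global taxonomy; both directions
counted, outgoing-only configurable). The AR diagonal is excluded except
in the dedicated sensitivity variant. Ranking ties break by canonical node
order. Signed and absolute variants are always computed side by side: for
networks whose strongest edges are negative (typical of protective
T1→T2 effects), the two variants can rank drivers very differently, and
published Out-EI values are sometimes positive even when the underlying
listed edges are negative — so neither variant is privileged, and users
should state which they report. One-step expected influence only; no
higher-order variants.

## Stability

Case-drop bootstrap: for each drop proportion q in {0.05, 0.10, …, 0.75},
subsamples of ⌈(1−q)n⌉ subjects are drawn without replacement, the network
and centralities re-estimated, and the subsample centrality correlated
(Pearson by default, Spearman available) with the full-sample values
across the 15 nodes. The CS coefficient is the largest q such that at
least 95% of correlations reach 0.7 at q *and at every smaller tested
proportion* (the monotone reading avoids crediting isolated noisy passes).
CS > 0.25 is the conventional acceptability threshold, > 0.5 preferred.
The total iteration budget is split evenly across the tested proportions;
whether a reported budget is per-proportion or total is often ambiguous in
the literature, so the grid and per-proportion counts are always recorded.
A subsample whose centrality vector is constant (e.g. an empty network)
carries no ranking information and is scored as a failed correlation.
Proportions whose subsamples are too small to estimate are marked
infeasible and excluded.

Edge CIs: subjects resampled with replacement (whole three-wave records,
preserving panel dependence; never wave-wise), the network re-estimated
per replicate, percentile 2.5/97.5% bounds per off-diagonal edge. The
percentile interval of re-estimates need not contain the point estimate;
lower ≤ upper always holds. Failed replicates are dropped and counted;
more than 5% failures aborts. Both procedures are fully determined by
(seed, n_boot).

## Sensitivity analyses

Two variations, sharing every line of estimation code with the primary
analysis (a no-op variation reproduces it exactly): (1) centralities
computed with the AR diagonal retained; (2) the pipeline re-run on a
subject subgroup, expressed as a generic predicate on subject metadata
(e.g. excluding Stage IV patients) rather than a hard-coded filter. Each
report compares top-driver identity and full rank deltas per transition.

## Problem sizes and numerical choices in the test suite

Monte-Carlo checks run at the study's own scale, n = 337: 100 replicates
for edge-support and driver-ranking recovery, 200 for single-predictor
recovery, 100 bootstrap iterations for the study-scale CS check, and 20
replicates for the null false-positive rate — sizes chosen to keep
binomial noise on the asserted rates small relative to their margins while
the full suite completes in minutes. Recovery assertions target the
strongest planted edge per transition (|β| ≥ 0.265): the weakest planted
edges (−0.120, 0.072) sit at 1–2 standard errors at n = 337 and are
selected only sporadically under EBIC γ = 0.5, which is the expected —
and intended — conservatism of that criterion, so support recovery is
additionally summarized as a Jaccard overlap (≥ 0.6) rather than per-edge
certainty. The convergence of the wave-1 sample correlation matrix to Σ₁
is asserted at n = 200,000, where the sampling floor of the full-matrix
Frobenius distance (~√(2·105)/√n) sits comfortably below the 0.05 bound.

## Known limitations

* The CLPN captures temporal precedence, not causality; suppressor-type
  sign flips can occur when correlated predictors enter jointly, and
  single anomalous coefficients should not be over-read against the
  centrality-based summary.
* LASSO coefficients are shrunk; reported edge weights are conservative
  magnitudes, and comparisons across transitions inherit the different
  selected λ values.
* The EBIC stage assumes the 15-predictor-per-regression penalty scale;
  with many more nodes the p-in-penalty convention matters more.
* Complete-case only: no imputation, no dropout modelling.
* The generator's unplanted structure (AR level, within-block ρ) is a
  documented stand-in, not an estimate from data.
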