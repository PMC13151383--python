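# clpnet

Cross-lagged panel network (CLPN) analysis of longitudinal quality-of-life
panel data, built for three-wave EORTC QLQ-C30 cohorts (e.g. cancer
patients assessed at admission, discharge, and one month post-discharge)
and for methodologists who want the whole pipeline — scoring, descriptives,
regularized network estimation, driver identification, and bootstrap
stability — reproducible from a single seeded configuration.

## The problem and the model

Symptom-management research increasingly treats patient-reported outcomes
as a network: not "which symptom is worst?" but "which symptom *drives*
the others over time?". With the 15 QLQ-C30 subscales measured at waves
t ∈ {T1, T2, T3}, the CLPN for a transition t → t+1 is estimated by
node-wise penalized regression. After z-standardizing scores within each
wave, for every outcome node *j*:

```
z_j^(t+1) = β0 + Σ_i β_ij z_i^(t) + ε,    minimize (1/2n)‖y − β0 − Xβ‖² + λ‖β‖₁
```

yielding a directed, weighted 15 × 15 coefficient matrix **B** per
transition (entry *i → j* is the standardized effect of node *i* on node
*j* one wave later, controlling for all other nodes). λ is selected per
node regression in two stages: 10-fold cross-validation produces candidate
values (the grid between the CV-MSE minimum and the one-standard-error λ),
then the Extended Bayesian Information Criterion, EBIC = n·log(RSS/n) +
k·log n + 2γ·k·log p with γ = 0.5, picks the final λ on the full data.

Driver nodes are ranked by **Out-Expected Influence** (row sums of **B**
with the autoregressive diagonal removed); In-EI and Bridge-EI (the part
of a node's influence crossing the functional / symptom / global domain
boundary) are computed alongside, in both signed and absolute variants.
Robustness is quantified by case-drop bootstrap correlation-stability (CS)
coefficients and percentile bootstrap edge-weight CIs.

Because raw patient data of this kind are rarely deposited, the package
ships a seeded synthetic-data generator: a linear Gaussian VAR on the
z-scale whose default configuration reproduces the published per-wave
marginal means/SDs and the strongest published cross-lagged edges
(protective functional→symptom effects in T1→T2; a nausea-driven positive
cascade in T2→T3), affinely mapped to the 0–100 instrument scale.

## Worked example

```bash
$ clpnet simulate --seed 7 --n 337 -o qol_panel.tsv
wrote 337 subjects x 3 waves to qol_panel.tsv

$ clpnet estimate qol_panel.tsv --transition "T2->T3" --seed 7 -o edges.tsv
T2->T3: 6 cross-lagged edges (21 incl. AR) -> edges.tsv

$ clpnet centrality qol_panel.tsv --transition "T2->T3" --seed 7 -o cent.tsv
T2->T3: top out-EI node Q7 -> cent.tsv
```

The estimated network keeps 6 cross-lagged edges (plus 15 autoregressive
paths, which are retained in the raw fit but excluded from centrality).
The top of the signed centrality table:

```
node   out_ei     in_ei  bridge_ei
  Q7 0.205895  0.000000   0.095194
  Q9 0.075203  0.000000   0.000000
  Q4 0.037585 -0.072303   0.100795
```

Q7 (nausea/vomiting) ranks first by out-expected influence: its outgoing
edges to appetite loss and global health status survive the LASSO + EBIC
selection, identifying it as the T2→T3 driver — exactly the structure the
generator planted. Coefficients are LASSO-shrunk, so estimated weights sit
somewhat below the generating values; support and ranking, not raw
magnitude, are the interpretable output.

The same analysis is available as a library (`estimate_transition`,
`compute_centrality`, `rank_drivers`, `cs_coefficient`, ...) and as one
call, `clpnet run-all`, which writes the full report bundle (descriptives
table with compact-letter display, edge lists, adjacency matrices, GraphML,
centrality tables in both variants, stability curves, sensitivity
comparisons, and a reproducibility manifest).

## Layout

- `clpnet.scoring` — EORTC QLQ-C30 item scoring (0–100 linear transform,
  half-rule, no reverse-coding); item map in a swappable data file
- `clpnet.simulate` — seeded VAR generator + study-like configuration
- `clpnet.descriptives` — repeated-measures ANOVA, Bonferroni post-hocs,
  compact letter display
- `clpnet.estimation` — node-wise LASSO, two-stage λ selection, network
  assembly and export
- `clpnet.metrics` — Out-/In-/Bridge-Expected-Influence, driver ranking
- `clpnet.stability` — case-drop CS coefficients, edge-weight bootstrap CIs
- `clpnet.sensitivity` — AR-retained and subgroup-excluded re-analyses
- `clpnet.pipeline` / `clpnet.cli` — orchestration and the `clpnet` command

See `docs/methods.md` for the statistical details and design choices.
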