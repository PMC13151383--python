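"""Per-node longitudinal descriptives: one-way repeated-measures ANOVA
across the three waves with Bonferroni-corrected paired post-hoc tests and
compact letter display, mirroring the usual "mean +/- SD with superscript
letters" summary table.

The ANOVA is the classical within-subject decomposition

    SS_total = SS_subjects + SS_time + SS_error,
    F = MS_time / MS_error,  df = (w - 1, (w - 1)(n - 1))

with no sphericity correction by default (an option exists). Post-hoc
pairwise comparisons are paired t-tests on wave differences with the
Bonferroni adjustment ``p_adj = min(1, 3 p)``. Two waves share a
superscript letter iff their adjusted comparison is non-significant at
alpha = 0.05; letters are the maximal cliques of the
"not-significantly-different" graph, which handles intransitive patterns
(a, ab, b) without special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .nodes import NODE_NAMES
from .panel import PanelDataset

__all__ = ["AnovaResult", "PairwiseComparison", "rm_anova", "letter_display",
           "describe_all", "descriptives_table"]

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseComparison:
    waves: tuple[str, str]
    t: float
    p_raw: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < ALPHA


@dataclass(frozen=True)
class AnovaResult:
    node: str
    wave_labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    F: float
    df_time: int
    df_error: int
    p: float
    pairwise: tuple[PairwiseComparison, ...]
    letters: tuple[str, ...]
    direction: str
    degenerate: bool = False  # zero within-subject error variance
    sphericity_correction: str = "none"


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # all differences equal: either no effect (d == 0) or an exact shift
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return np.inf if d.mean() > 0 else -np.inf, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def letter_display(
    significant: dict[tuple[str, str], bool], waves: tuple[str, ...]
) -> tuple[str, ...]:
    """Compact letter display from pairwise significance decisions.

    Two waves share a letter iff their comparison is non-significant.
    Letters correspond to maximal cliques of the non-significance graph,
    ordered by earliest wave, so the assignment is deterministic and
    handles intransitive patterns via multi-letter strings.
    """
    g = nx.Graph()
    g.add_nodes_from(waves)
    for (a, b), sig in significant.items():
        if not sig:
            g.add_edge(a, b)
    order = {w: i for i, w in enumerate(waves)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: [order[w] for w in c],
    )
    labels = "abcdefghijklmnopqrstuvwxyz"
    per_wave: dict[str, list[str]] = {w: [] for w in waves}
    for letter, clique in zip(labels, cliques):
        for w in clique:
            per_wave[w].append(letter)
    return tuple("".join(sorted(per_wave[w])) for w in waves)


def _direction(
    means: np.ndarray, significant: dict[tuple[str, str], bool], waves: tuple[str, ...]
) -> str:
    """Summary string like ``"T1≈T2 < T3"`` from means and significance of
    consecutive-wave comparisons."""
    parts = [waves[0]]
    for a, b in zip(waves[:-1], waves[1:]):
        key = (a, b) if (a, b) in significant else (b, a)
        if not significant[key]:
            parts.append(f"≈{b}")
        elif means[list(waves).index(a)] < means[list(waves).index(b)]:
            parts.append(f" < {b}")
        else:
            parts.append(f" > {b}")
    return "".join(parts)


def rm_anova(
    data: PanelDataset, node: str, sphericity_correction: str = "none"
) -> AnovaResult:
    """One-way repeated-measures ANOVA for one node across the waves.

    ``sphericity_correction`` may be ``"none"`` (default, plain F test) or
    ``"greenhouse-geisser"`` (epsilon-adjusted degrees of freedom).
    """
    j = list(data.node_codes).index(node)
    y = np.column_stack([data.wave_matrix(w)[:, j] for w in data.waves])
    n, w = y.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA requires at least 3 subjects")

    grand = y.mean()
    wave_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_time = n * np.sum((wave_means - grand) ** 2)
    ss_subj = w * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = max(ss_total - ss_time - ss_subj, 0.0)
    df_time, df_error = w - 1, (w - 1) * (n - 1)
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error

    degenerate = np.isclose(ms_error, 0.0)
    if degenerate:
        F = 0.0 if np.isclose(ms_time, 0.0) else np.inf
        p = 1.0 if F == 0.0 else 0.0
    else:
        F = ms_time / ms_error
        eff_df = (df_time, df_error)
        if sphericity_correction == "greenhouse-geisser":
            eps = _gg_epsilon(y)
            eff_df = (df_time * eps, df_error * eps)
        elif sphericity_correction != "none":
            raise ValueError(f"unknown sphericity correction {sphericity_correction!r}")
        p = float(stats.f.sf(F, *eff_df))

    pairwise = []
    sig: dict[tuple[str, str], bool] = {}
    n_pairs = w * (w - 1) // 2
    for a in range(w):
        for b in range(a + 1, w):
            t, p_raw = _paired_t(y[:, a], y[:, b])
            p_adj = min(1.0, n_pairs * p_raw)
            pc = PairwiseComparison(
                waves=(data.waves[a], data.waves[b]), t=t, p_raw=p_raw, p_adj=p_adj
            )
            pairwise.append(pc)
            sig[pc.waves] = pc.significant
    letters = letter_display(sig, data.waves)
    return AnovaResult(
        node=node,
        wave_labels=data.waves,
        means=tuple(float(m) for m in wave_means),
        sds=tuple(float(s) for s in y.std(axis=0, ddof=1)),
        F=float(F),
        df_time=df_time,
        df_error=df_error,
        p=p,
        pairwise=tuple(pairwise),
        letters=letters,
        direction=_direction(wave_means, sig, data.waves),
        degenerate=bool(degenerate),
        sphericity_correction=sphericity_correction,
    )


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of waves."""
    S = np.cov(y, rowvar=False)
    w = S.shape[0]
    mean_diag = np.trace(S) / w
    mean_all = S.mean()
    num = (w * (mean_diag - mean_all)) ** 2
    den = (w - 1) * (np.sum(S**2) - 2 * w * np.sum(S.mean(axis=1) ** 2) + w**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def describe_all(
    data: PanelDataset, sphericity_correction: str = "none"
) -> list[AnovaResult]:
    """ANOVA results for every node, in Q1..Q15 order."""
    return [rm_anova(data, c, sphericity_correction) for c in data.node_codes]


def descriptives_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Summary table: per-wave ``mean ± SD (letter)``, F, p, direction."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "node": r.node,
            "name": NODE_NAMES.get(r.node, r.node),
        }
        for wlab, m, s, letter in zip(r.wave_labels, r.means, r.sds, r.letters):
            row[wlab] = f"{m:.2f} ± {s:.2f} {letter}"
        row["F"] = round(r.F, 3) if np.isfinite(r.F) else r.F
        row["p"] = "<0.001" if r.p < 0.001 else f"{r.p:.3f}"
        row["direction"] = r.direction
        row["degenerate"] = r.degenerate
        rows.append(row)
    return pd.DataFrame(rows)
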