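"""Robustness variations of the primary analysis.

Two variations, sharing all estimation code with the primary pipeline so
that a no-op variation reproduces it exactly:

* retaining autoregressive paths when computing centralities (the primary
  analysis zeroes the diagonal first), and
* re-running the pipeline on a subject subgroup (e.g. excluding Stage IV
  patients), expressed as a generic predicate on subject metadata.

Each returns a report comparing driver rankings against the primary
analysis: the key question is whether the top Out-EI node per transition
is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import drop_autoregressive, estimate_transition
from .metrics import CentralityTable, compute_centrality, rank_drivers
from .nodes import TRANSITIONS, normalize_transition
from .panel import PanelDataset

__all__ = [
    "SensitivityReport",
    "sensitivity_ar_retained",
    "sensitivity_exclude_subgroup",
    "stage_filter",
]

SubjectFilter = Callable[[Mapping[str, object]], bool]


@dataclass(frozen=True)
class SensitivityReport:
    variant: str  # "ar_retained" | "subgroup_excluded"
    transitions: tuple[str, ...]
    primary_tables: dict[str, CentralityTable]
    variant_tables: dict[str, CentralityTable]
    top_primary: dict[str, str]
    top_variant: dict[str, str]
    rank_agreement: dict[str, bool]  # per transition: same #1 out-EI node?
    n_retained: int | None = None    # subjects kept (subgroup variant only)

    @property
    def agrees_everywhere(self) -> bool:
        return all(self.rank_agreement.values())

    def comparison_table(self, metric: str = "out_ei") -> pd.DataFrame:
        """Side-by-side primary vs variant centralities with rank deltas."""
        rows = []
        for tr in self.transitions:
            prim = self.primary_tables[tr].table[metric]
            var = self.variant_tables[tr].table[metric]
            prim_rank = {c: r + 1 for r, c in enumerate(rank_drivers(self.primary_tables[tr], metric))}
            var_rank = {c: r + 1 for r, c in enumerate(rank_drivers(self.variant_tables[tr], metric))}
            for code in prim.index:
                rows.append({
                    "transition": tr, "node": code,
                    f"{metric}_primary": prim[code], f"{metric}_variant": var[code],
                    "rank_primary": prim_rank[code], "rank_variant": var_rank[code],
                    "rank_delta": var_rank[code] - prim_rank[code],
                })
        return pd.DataFrame(rows)


def _build_report(
    variant: str,
    transitions: Sequence[str],
    primary: dict[str, CentralityTable],
    alt: dict[str, CentralityTable],
    n_retained: int | None = None,
) -> SensitivityReport:
    top_p = {tr: rank_drivers(primary[tr])[0] for tr in primary}
    top_v = {tr: rank_drivers(alt[tr])[0] for tr in alt}
    agreement = {tr: top_p[tr] == top_v[tr] for tr in primary}
    return SensitivityReport(
        variant=variant, transitions=tuple(transitions),
        primary_tables=primary, variant_tables=alt,
        top_primary=top_p, top_variant=top_v, rank_agreement=agreement,
        n_retained=n_retained,
    )


def sensitivity_ar_retained(
    data: PanelDataset,
    transitions: Sequence[str] = TRANSITIONS,
    gamma: float = 0.5,
    seed: int = 0,
    partition: dict[str, str] | None = None,
    variant: str = "signed",
) -> SensitivityReport:
    """Primary pipeline with centralities computed on the full coefficient
    matrix, autoregressive diagonal included."""
    transitions = [normalize_transition(t) for t in transitions]
    primary, alt = {}, {}
    for tr in transitions:
        net = estimate_transition(data, tr, gamma=gamma, seed=seed)
        primary[tr] = compute_centrality(
            drop_autoregressive(net), partition=partition, variant=variant
        )
        alt[tr] = compute_centrality(
            net, partition=partition, variant=variant, include_ar=True
        )
    return _build_report("ar_retained", transitions, primary, alt)


def stage_filter(excluded_stages: Sequence[str]) -> SubjectFilter:
    """Predicate keeping subjects whose ``stage`` is not in ``excluded_stages``."""
    excluded = set(excluded_stages)

    def keep(meta_row: Mapping[str, object]) -> bool:
        return meta_row.get("stage") not in excluded

    return keep


def sensitivity_exclude_subgroup(
    data: PanelDataset,
    subject_filter: SubjectFilter | np.ndarray,
    transitions: Sequence[str] = TRANSITIONS,
    gamma: float = 0.5,
    seed: int = 0,
    partition: dict[str, str] | None = None,
    variant: str = "signed",
    min_subjects: int = 50,
) -> SensitivityReport:
    """Primary pipeline re-run on a subject subgroup.

    ``subject_filter`` is either a boolean keep-mask over subjects or a
    predicate applied to each row of ``data.subject_meta``.
    """
    transitions = [normalize_transition(t) for t in transitions]
    if callable(subject_filter):
        if data.subject_meta is None:
            raise ValueError("predicate filters require subject_meta on the dataset")
        mask = np.array([
            bool(subject_filter(row)) for row in data.subject_meta.to_dict("records")
        ])
    else:
        mask = np.asarray(subject_filter, dtype=bool)
        if mask.shape != (data.n_subjects,):
            raise ValueError("boolean filter must have one entry per subject")
    n_kept = int(mask.sum())
    if n_kept < min_subjects:
        raise ValueError(
            f"subgroup too small: {n_kept} subjects retained, need >= {min_subjects}"
        )
    subset = data.subset(mask)
    primary, alt = {}, {}
    for tr in transitions:
        primary[tr] = compute_centrality(
            drop_autoregressive(estimate_transition(data, tr, gamma=gamma, seed=seed)),
            partition=partition, variant=variant,
        )
        alt[tr] = compute_centrality(
            drop_autoregressive(estimate_transition(subset, tr, gamma=gamma, seed=seed)),
            partition=partition, variant=variant,
        )
    return _build_report("subgroup_excluded", transitions, primary, alt, n_retained=n_kept)
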