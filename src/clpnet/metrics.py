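"""Expected-influence centralities on a cross-lagged network.

Out-Expected Influence (Out-EI) of a node is the sum of its outgoing edge
weights — its cumulative predictive effect on the next wave — and In-EI the
sum of its incoming weights. Bridge-EI restricts the sums to edges crossing
community boundaries (by default the instrument's functional / symptom /
global taxonomy), capturing cross-domain connectivity.

Both a signed variant (raw weights, so protective negative edges offset
aggravating positive ones) and an absolute variant (magnitudes, overall
predictive involvement) are computed and reported side by side; which of
the two a given study reports is not always stated, and for networks with
predominantly negative edges the two can rank nodes very differently.

Autoregressive (diagonal) entries are excluded by default; sensitivity
analyses may include them via ``include_ar=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CrossLaggedNetwork
from .nodes import DEFAULT_PARTITION

__all__ = [
    "CentralityTable",
    "out_expected_influence",
    "in_expected_influence",
    "bridge_expected_influence",
    "compute_centrality",
    "rank_drivers",
]

VARIANTS = ("signed", "absolute")


def _weights(net: CrossLaggedNetwork, variant: str, include_ar: bool) -> np.ndarray:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    W = net.B_hat.copy()
    if not include_ar:
        np.fill_diagonal(W, 0.0)
    return np.abs(W) if variant == "absolute" else W


def out_expected_influence(
    net: CrossLaggedNetwork, variant: str = "signed", include_ar: bool = False
) -> pd.Series:
    """Row sums of the (possibly absolute) weight matrix."""
    W = _weights(net, variant, include_ar)
    return pd.Series(W.sum(axis=1), index=list(net.node_codes), name="out_ei")


def in_expected_influence(
    net: CrossLaggedNetwork, variant: str = "signed", include_ar: bool = False
) -> pd.Series:
    """Column sums of the (possibly absolute) weight matrix."""
    W = _weights(net, variant, include_ar)
    return pd.Series(W.sum(axis=0), index=list(net.node_codes), name="in_ei")


def bridge_expected_influence(
    net: CrossLaggedNetwork,
    partition: dict[str, str] | None = None,
    variant: str = "signed",
    include_ar: bool = False,
    direction: str = "both",
) -> pd.Series:
    """Expected influence carried by community-crossing edges.

    For node i this sums outgoing weights to nodes of other communities
    plus, when ``direction="both"`` (default), incoming weights from other
    communities; ``direction="out"`` counts outgoing only.
    """
    if partition is None:
        partition = DEFAULT_PARTITION
    missing = [c for c in net.node_codes if c not in partition]
    if missing:
        raise KeyError(f"partition lacks node(s): {missing}")
    if direction not in ("both", "out"):
        raise ValueError("direction must be 'both' or 'out'")
    W = _weights(net, variant, include_ar)
    comm = np.array([partition[c] for c in net.node_codes])
    cross = comm[:, None] != comm[None, :]
    out_part = (W * cross).sum(axis=1)
    if direction == "both":
        out_part = out_part + (W * cross).sum(axis=0)
    return pd.Series(out_part, index=list(net.node_codes), name="bridge_ei")


@dataclass(frozen=True)
class CentralityTable:
    """Per-node Out-EI / In-EI / Bridge-EI for one network and variant."""

    table: pd.DataFrame  # index Q1..Q15, columns out_ei, in_ei, bridge_ei
    variant: str
    ar_excluded: bool
    transition: str

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "node", df.index)
        df["variant"] = self.variant
        df["ar_excluded"] = self.ar_excluded
        df["transition"] = self.transition
        return df.reset_index(drop=True)


def compute_centrality(
    net: CrossLaggedNetwork,
    partition: dict[str, str] | None = None,
    variant: str = "signed",
    include_ar: bool = False,
    bridge_direction: str = "both",
) -> CentralityTable:
    """All three expected-influence metrics for one network."""
    table = pd.DataFrame(
        {
            "out_ei": out_expected_influence(net, variant, include_ar),
            "in_ei": in_expected_influence(net, variant, include_ar),
            "bridge_ei": bridge_expected_influence(
                net, partition, variant, include_ar, bridge_direction
            ),
        }
    )
    return CentralityTable(
        table=table,
        variant=variant,
        ar_excluded=not include_ar,
        transition=net.transition,
    )


def rank_drivers(table: CentralityTable, metric: str = "out_ei") -> list[str]:
    """Node codes sorted by the metric, descending; ties break by canonical
    node order (Q1..Q15) so the ordering is deterministic."""
    if metric not in table.table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    s = table.table[metric]
    pos = {c: k for k, c in enumerate(s.index)}
    return sorted(s.index, key=lambda c: (-s[c], pos[c]))
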