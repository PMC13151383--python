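"""Panel data container: subjects x waves x 15 subscale scores.

The canonical file form is long format (one row per subject per wave with
columns ``subject_id``, ``wave``, ``Q1`` .. ``Q15``); wide format (one row
per subject with ``Q1_T1`` .. ``Q15_T3`` columns) is accepted and
normalized on read. Scores live on the 0-100 instrument scale. The dataset
is complete-case by contract: every subject appears in every wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nodes import NODE_CODES, WAVES

__all__ = ["PanelDataset", "PanelValidationError", "validate_long", "read_panel"]


class PanelValidationError(ValueError):
    """Raised when an input table violates the panel contract."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid panel data:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


@dataclass
class PanelDataset:
    """Complete-case three-wave panel of subscale scores.

    ``scores[wave]`` is an (n_subjects, 15) float array in Q1..Q15 column
    order, row-aligned with ``subject_ids`` across all waves. Optional
    ``subject_meta`` carries per-subject covariates (e.g. tumor stage) for
    subgroup sensitivity analyses, index-aligned with ``subject_ids``.
    """

    subject_ids: np.ndarray
    scores: dict[str, np.ndarray]
    waves: tuple[str, ...] = WAVES
    node_codes: tuple[str, ...] = NODE_CODES
    subject_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        n = len(self.subject_ids)
        for w in self.waves:
            if w not in self.scores:
                raise ValueError(f"missing wave {w!r}")
            m = np.asarray(self.scores[w], dtype=float)
            if m.shape != (n, len(self.node_codes)):
                raise ValueError(
                    f"wave {w}: score matrix shape {m.shape}, "
                    f"expected {(n, len(self.node_codes))}"
                )
            self.scores[w] = m
        if self.subject_meta is not None and len(self.subject_meta) != n:
            raise ValueError("subject_meta length does not match subject_ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def wave_matrix(self, wave: str) -> np.ndarray:
        """(n, 15) score matrix for one wave."""
        if wave not in self.scores:
            raise KeyError(f"unknown wave {wave!r}")
        return self.scores[wave]

    def subset(self, mask: np.ndarray) -> "PanelDataset":
        """New dataset restricted to subjects where ``mask`` is True (or an
        integer index array, which may repeat rows for bootstrap resampling)."""
        mask = np.asarray(mask)
        meta = None
        if self.subject_meta is not None:
            meta = self.subject_meta.iloc[np.arange(self.n_subjects)[mask] if mask.dtype == bool else mask]
            meta = meta.reset_index(drop=True)
        return replace(
            self,
            subject_ids=self.subject_ids[mask],
            scores={w: m[mask] for w, m in self.scores.items()},
            subject_meta=meta,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame (subject_id, wave, Q1..Q15)."""
        frames = []
        for w in self.waves:
            df = pd.DataFrame(self.scores[w], columns=list(self.node_codes))
            df.insert(0, "wave", w)
            df.insert(0, "subject_id", self.subject_ids)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame, waves: tuple[str, ...] = WAVES) -> "PanelDataset":
        """Build from a long-format table; raises on contract violations."""
        ds, errors = validate_long(df, waves=waves)
        if errors:
            raise PanelValidationError(errors)
        assert ds is not None
        return ds


def validate_long(
    df: pd.DataFrame, waves: tuple[str, ...] = WAVES
) -> tuple[PanelDataset | None, list[str]]:
    """Validate a long-format table; collect all problems, do not fail fast.

    Checks: required columns, duplicate subject-wave pairs, score range
    [0, 100], missing values, and wave completeness (every subject present
    at every wave). Returns ``(dataset, [])`` or ``(None, errors)``.
    """
    errors: list[str] = []
    required = ["subject_id", "wave", *NODE_CODES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return None, [f"missing columns: {missing}"]

    unknown = sorted(set(df["wave"].astype(str)) - set(waves))
    if unknown:
        errors.append(f"unknown wave labels {unknown}; expected {list(waves)}")

    dup = df.duplicated(subset=["subject_id", "wave"], keep=False)
    for row in df.index[dup]:
        errors.append(
            f"row {row}: duplicate record for subject "
            f"{df.at[row, 'subject_id']!r} at wave {df.at[row, 'wave']!r}"
        )

    for code in NODE_CODES:
        col = pd.to_numeric(df[code], errors="coerce")
        for row in df.index[col.isna() & df[code].notna()]:
            errors.append(f"row {row}: column {code} is not numeric: {df.at[row, code]!r}")
        bad = (col < 0) | (col > 100)
        for row in df.index[bad.fillna(False)]:
            errors.append(
                f"row {row}: column {code} value {col[row]:g} outside [0, 100]"
            )
        for row in df.index[df[code].isna()]:
            errors.append(f"row {row}: column {code} is missing")

    counts = df.groupby("subject_id")["wave"].apply(lambda s: tuple(sorted(set(s))))
    for sid, present in counts.items():
        if set(present) != set(waves):
            absent = sorted(set(waves) - set(present))
            errors.append(
                f"subject {sid!r}: missing wave(s) {absent} (complete cases required)"
            )

    if errors:
        return None, errors

    first = df[df["wave"] == waves[0]]["subject_id"].to_numpy()
    mats = {}
    for w in waves:
        sub = df[df["wave"] == w].set_index("subject_id")
        mats[w] = sub.loc[first, list(NODE_CODES)].to_numpy(dtype=float)
    return PanelDataset(subject_ids=first, scores=mats, waves=waves), []


def read_panel(path: str, waves: tuple[str, ...] = WAVES) -> PanelDataset:
    """Read a delimited panel file (long or wide format, CSV or TSV).

    Wide format is detected by the absence of a ``wave`` column and the
    presence of ``Q1_T1``-style columns; it is melted to long form first.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "wave" not in df.columns:
        wide_cols = [f"{c}_{w}" for w in waves for c in NODE_CODES]
        absent = [c for c in wide_cols if c not in df.columns]
        if absent:
            raise PanelValidationError(
                [f"neither long format (no 'wave' column) nor wide format "
                 f"(missing {absent[:3]}...)"]
            )
        frames = []
        for w in waves:
            sub = df[["subject_id"] + [f"{c}_{w}" for c in NODE_CODES]].copy()
            sub.columns = ["subject_id", *NODE_CODES]
            sub.insert(1, "wave", w)
            frames.append(sub)
        df = pd.concat(frames, ignore_index=True)
    return PanelDataset.from_long(df, waves=waves)
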