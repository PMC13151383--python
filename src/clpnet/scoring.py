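"""EORTC QLQ-C30 scoring: raw 30-item responses to 15 subscale scores.

Scoring follows the standard EORTC algorithm. For a scale with items on a
1..(range+1) response format, the raw score RS is the mean of the available
items and

* functional scales:        score = (1 - (RS - 1) / range) * 100
* symptom and global scale: score = ((RS - 1) / range) * 100

so functional scores increase with better functioning while symptom scores
increase with symptom severity. No reverse-coding is applied anywhere: the
original scoring conventions are kept so that negative cross-lagged edges
from functional nodes to symptom nodes are directly interpretable as
protective temporal relationships.

A scale is scored when at least half of its items are answered (the
instrument manual's half-rule); otherwise the score is reported absent
rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .nodes import NODE_CODES

N_ITEMS = 30

__all__ = [
    "ScaleDefinition",
    "SubscaleScore",
    "ScoringError",
    "ResponseRangeError",
    "MissingScaleError",
    "load_scale_definitions",
    "score_subscale",
    "score_questionnaire",
    "score_table",
]


class ScoringError(ValueError):
    """Base class for questionnaire scoring failures."""


class ResponseRangeError(ScoringError):
    """An item response falls outside the scale's admissible range."""

    def __init__(self, scale_code: str, item_id: int, value: float, valid_max: int):
        self.scale_code = scale_code
        self.item_id = item_id
        self.value = value
        super().__init__(
            f"scale {scale_code}: item {item_id} has response {value!r}, "
            f"expected an integer in 1..{valid_max}"
        )


class MissingScaleError(ScoringError):
    """Too many missing items to score a scale under the half-rule."""

    def __init__(self, scale_code: str, n_present: int, n_items: int):
        self.scale_code = scale_code
        super().__init__(
            f"scale {scale_code}: only {n_present} of {n_items} items present; "
            f"at least half are required"
        )


@dataclass(frozen=True)
class ScaleDefinition:
    """One subscale: which items feed it and how they are transformed."""

    code: str
    name: str
    category: str  # functional | symptom | global
    item_ids: tuple[int, ...]
    item_range: int  # 3 for 4-point items, 6 for 7-point global items

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise ValueError(f"scale {self.code}: empty item list")
        if self.category not in ("functional", "symptom", "global"):
            raise ValueError(f"scale {self.code}: bad category {self.category!r}")
        if (self.category == "global") != (self.item_range == 6):
            raise ValueError(
                f"scale {self.code}: item_range 6 is reserved for the global scale"
            )


@dataclass(frozen=True)
class SubscaleScore:
    code: str
    value: float  # in [0, 100]
    n_items_used: int


def load_scale_definitions(path: str | None = None) -> list[ScaleDefinition]:
    """Load the 15 scale definitions, by default the packaged version 3.0 map.

    The mapping lives in a data file so that other instrument versions can be
    swapped in. Validates that the definitions partition items 1..30.
    """
    if path is None:
        text = (
            resources.files("clpnet").joinpath("data/qlqc30_v3.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["scales"]
    defs = [
        ScaleDefinition(
            code=d["code"],
            name=d["name"],
            category=d["category"],
            item_ids=tuple(int(i) for i in d["items"]),
            item_range=int(d["item_range"]),
        )
        for d in raw
    ]
    codes = [d.code for d in defs]
    if codes != list(NODE_CODES):
        raise ValueError(f"scale codes must be Q1..Q15 in order, got {codes}")
    all_items = [i for d in defs for i in d.item_ids]
    if len(set(all_items)) != len(all_items):
        raise ValueError("item ids are not disjoint across scales")
    if set(all_items) != set(range(1, N_ITEMS + 1)):
        raise ValueError("scale definitions do not cover items 1..30 exactly")
    return defs


def _is_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


def score_subscale(
    responses: Sequence[object], scale: ScaleDefinition
) -> SubscaleScore:
    """Score one subscale from its item responses (aligned to ``item_ids``).

    Missing responses are ``None``/NaN. Raises :class:`ResponseRangeError`
    for out-of-range values and :class:`MissingScaleError` when fewer than
    half of the items are present.
    """
    if len(responses) != len(scale.item_ids):
        raise ScoringError(
            f"scale {scale.code}: expected {len(scale.item_ids)} responses, "
            f"got {len(responses)}"
        )
    valid_max = scale.item_range + 1
    present: list[float] = []
    for item_id, v in zip(scale.item_ids, responses):
        if _is_missing(v):
            continue
        fv = float(v)  # type: ignore[arg-type]
        if not fv.is_integer() or not (1 <= fv <= valid_max):
            raise ResponseRangeError(scale.code, item_id, v, valid_max)
        present.append(fv)
    n_needed = math.ceil(len(scale.item_ids) / 2)
    if len(present) < n_needed:
        raise MissingScaleError(scale.code, len(present), len(scale.item_ids))
    rs = sum(present) / len(present)
    if scale.category == "functional":
        value = (1.0 - (rs - 1.0) / scale.item_range) * 100.0
    else:
        value = ((rs - 1.0) / scale.item_range) * 100.0
    return SubscaleScore(code=scale.code, value=value, n_items_used=len(present))


def score_questionnaire(
    responses: Mapping[int, object] | Sequence[object],
    definitions: Iterable[ScaleDefinition] | None = None,
) -> dict[str, SubscaleScore]:
    """Score a full 30-item record into the 15 subscale scores.

    ``responses`` is either a mapping from item id (1..30) to value or a
    sequence of 30 values in item order. Per-scale errors are re-raised with
    the scale code attached (they carry it already).
    """
    if definitions is None:
        definitions = load_scale_definitions()
    defs = list(definitions)
    if isinstance(responses, Mapping):
        get = responses.get
    else:
        seq = list(responses)
        if len(seq) != N_ITEMS:
            raise ScoringError(f"expected {N_ITEMS} item responses, got {len(seq)}")
        get = lambda i, _=None: seq[i - 1]  # noqa: E731
    return {
        d.code: score_subscale([get(i) for i in d.item_ids], d) for d in defs
    }


def score_table(
    items: pd.DataFrame, definitions: Iterable[ScaleDefinition] | None = None
) -> pd.DataFrame:
    """Score a table of raw records into subscale columns.

    Input columns: ``subject_id``, ``wave``, ``item_1`` .. ``item_30``
    (blank cells are missing). Output columns: ``subject_id``, ``wave``,
    ``Q1`` .. ``Q15``. A scale that cannot be scored under the half-rule
    yields NaN for that record.
    """
    if definitions is None:
        definitions = load_scale_definitions()
    defs = list(definitions)
    item_cols = [f"item_{i}" for i in range(1, N_ITEMS + 1)]
    missing_cols = [c for c in ("subject_id", "wave", *item_cols) if c not in items]
    if missing_cols:
        raise ScoringError(f"input table lacks columns: {missing_cols}")
    out = {"subject_id": items["subject_id"].to_numpy(), "wave": items["wave"].to_numpy()}
    values = items[item_cols].to_numpy(dtype=float)
    for d in defs:
        col = np.empty(len(items))
        idx = [i - 1 for i in d.item_ids]
        for r in range(len(items)):
            try:
                col[r] = score_subscale(list(values[r, idx]), d).value
            except MissingScaleError:
                col[r] = np.nan
        out[d.code] = col
    return pd.DataFrame(out)
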