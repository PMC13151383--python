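"""Node metadata for the 15 QLQ-C30 subscales used as network nodes.

The EORTC QLQ-C30 yields five functional scales, nine symptom scales/items
and a global health status scale. Throughout this package nodes are keyed
Q1..Q15 in the fixed order below; all matrices and tables follow this order.
"""

from __future__ import annotations

# (code, name, category)
NODES: tuple[tuple[str, str, str], ...] = (
    ("Q1", "physical functioning", "functional"),
    ("Q2", "role functioning", "functional"),
    ("Q3", "emotional functioning", "functional"),
    ("Q4", "cognitive functioning", "functional"),
    ("Q5", "social functioning", "functional"),
    ("Q6", "fatigue", "symptom"),
    ("Q7", "nausea and vomiting", "symptom"),
    ("Q8", "pain", "symptom"),
    ("Q9", "dyspnea", "symptom"),
    ("Q10", "insomnia", "symptom"),
    ("Q11", "appetite loss", "symptom"),
    ("Q12", "constipation", "symptom"),
    ("Q13", "diarrhea", "symptom"),
    ("Q14", "financial difficulties", "symptom"),
    ("Q15", "global health status", "global"),
)

NODE_CODES: tuple[str, ...] = tuple(code for code, _, _ in NODES)
NODE_NAMES: dict[str, str] = {code: name for code, name, _ in NODES}
NODE_CATEGORIES: dict[str, str] = {code: cat for code, _, cat in NODES}

#: Default community partition for bridge centrality: the instrument's own
#: scale taxonomy (functional / symptom / global health).
DEFAULT_PARTITION: dict[str, str] = dict(NODE_CATEGORIES)

WAVES: tuple[str, str, str] = ("T1", "T2", "T3")

#: Wave transitions for which cross-lagged networks are estimated.
TRANSITIONS: tuple[str, str] = ("T1->T2", "T2->T3")


def normalize_transition(label: str) -> str:
    """Map a transition label to canonical ``"T1->T2"`` / ``"T2->T3"`` form.

    Accepts the unicode-arrow spelling as well.
    """
    canon = label.replace("→", "->").replace(" ", "")
    if canon not in TRANSITIONS:
        raise ValueError(
            f"unknown transition {label!r}; expected one of {TRANSITIONS}"
        )
    return canon


def transition_waves(label: str) -> tuple[str, str]:
    """Return (from_wave, to_wave) for a transition label."""
    canon = normalize_transition(label)
    a, b = canon.split("->")
    return a, b


def node_index(code: str) -> int:
    """Position of a node code in the canonical Q1..Q15 order."""
    try:
        return NODE_CODES.index(code)
    except ValueError:
        raise KeyError(f"unknown node code {code!r}") from None
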