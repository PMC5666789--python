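"""Typing of Aux/IAA proteins from their motif composition.

Proteins fall into eleven types by which of the five motifs they carry
(type I = all five = canonical, through types IX/X with a single motif,
plus a residual "other" bucket), and the PB1 region is screened for the
GDVP / GDDP signature that separates Aux/IAA-like proteins from
ARF-derived truncations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .motifs import MotifPresenceProfile
from .seqio import SequenceRecord

__all__ = [
    "TypeAssignment",
    "PB1SignatureCall",
    "TYPE_TABLE",
    "classify_type",
    "classify_pb1_signature",
    "summarize_types",
]

TypeLabel = Literal["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "other"]

# Decision table: presence subset (of motifs 1..5) -> type label.
# Type IV covers {2,5} plus exactly one of {1,4} (motif 3 absent):
# domain I and III present with a half-complete domain IV.
TYPE_TABLE: dict[frozenset[int], TypeLabel] = {
    frozenset({1, 2, 3, 4, 5}): "I",
    frozenset({1, 2, 3, 5}): "II",
    frozenset({2, 3, 5}): "III",
    frozenset({1, 2, 5}): "IV",
    frozenset({2, 4, 5}): "IV",
    frozenset({1, 2, 3, 4}): "V",
    frozenset({1, 2, 3}): "VI",
    frozenset({1, 2, 4}): "VII",
    frozenset({1, 2}): "VIII",
    frozenset({2}): "IX",
    frozenset({1}): "X",
}


@dataclass(frozen=True)
class TypeAssignment:
    sequence_id: str
    type_label: TypeLabel
    canonical: bool

    def __post_init__(self) -> None:
        if self.canonical != (self.type_label == "I"):
            raise ValueError("canonical flag must mirror type I membership")


@dataclass(frozen=True)
class PB1SignatureCall:
    sequence_id: str
    signature: Literal["GDVP", "GDDP", "neither"]


def classify_type(profile: MotifPresenceProfile) -> TypeAssignment:
    """Map a five-motif presence profile to one of the eleven types.

    Total over all 32 presence subsets; anything not matching the
    decision table falls into "other".
    """
    subset = profile.present_set()
    label = TYPE_TABLE.get(frozenset(subset), "other")
    return TypeAssignment(profile.sequence_id, label, canonical=label == "I")


def classify_pb1_signature(protein: SequenceRecord | str) -> PB1SignatureCall:
    """GDVP (Aux/IAA-like) vs GDDP (ARF-derived) PB1 linker signature.

    If both substrings occur, the first occurrence along the sequence
    wins; real proteins carry one.
    """
    if isinstance(protein, SequenceRecord):
        seq_id, seq = protein.id, protein.residues
    else:
        seq_id, seq = "<anonymous>", protein
    i_v = seq.find("GDVP")
    i_d = seq.find("GDDP")
    if i_v < 0 and i_d < 0:
        sig = "neither"
    elif i_d < 0 or (0 <= i_v < i_d):
        sig = "GDVP"
    else:
        sig = "GDDP"
    return PB1SignatureCall(seq_id, sig)


def summarize_types(assignments: Iterable[TypeAssignment]) -> pd.DataFrame:
    """Per-type counts and percentages (one decimal place).

    Counts always sum to the number of assignments.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("summarize_types needs at least one assignment")
    order = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "other"]
    counts = {label: 0 for label in order}
    for a in assignments:
        counts[a.type_label] += 1
    n = len(assignments)
    df = pd.DataFrame(
        {
            "type": order,
            "count": [counts[t] for t in order],
            "percent": [round(100.0 * counts[t] / n, 1) for t in order],
        }
    )
    assert int(df["count"].sum()) == n
    return df
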