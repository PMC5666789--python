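"""Nuclear localization signal detection and classification.

Aux/IAA proteins carry two putative NLSs: a bipartite signal whose
first part is a KR basic doublet between domains I and II and whose
second part is an RxxRK basic stretch in domain II, and an SV40-like
signal (KRxRxxK) inside domain IV.  Each category is called intact,
degenerated (exactly one basic residue substituted) or lacking, with
search windows anchored on motif hits when available and on protein
thirds otherwise.  Two primordial lower-plant variants of Part 2
(QxxRK, KxxNK) are tagged on top of their degenerated status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .motifs import MotifHit, MotifPresenceProfile
from .seqio import SequenceRecord

__all__ = [
    "NLSPattern",
    "NLSCall",
    "NLSReport",
    "SpeciesNLSSummary",
    "NLS_PATTERNS",
    "SearchWindow",
    "locate_search_windows",
    "match_nls",
    "detect_species_variants",
    "scan_protein",
    "aggregate_species",
]

Category = Literal["bipartite_part1", "bipartite_part2", "sv40"]
Status = Literal["intact", "degenerated", "lack"]
CATEGORIES: tuple[Category, ...] = ("bipartite_part1", "bipartite_part2", "sv40")
STATUSES: tuple[Status, ...] = ("intact", "degenerated", "lack")


@dataclass(frozen=True)
class NLSPattern:
    """Canonical NLS pattern with ``x`` wildcards.

    ``basic_positions`` are the indices that hold K or R in the
    canonical form; a single substitution at one of them is what
    degrades (rather than abolishes) the signal.
    """

    category: Category
    pattern: str
    basic_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        for i in self.basic_positions:
            if self.pattern[i] not in "KR":
                raise ValueError(
                    f"basic position {i} of {self.pattern!r} is not K/R"
                )

    @property
    def width(self) -> int:
        return len(self.pattern)


NLS_PATTERNS: dict[Category, NLSPattern] = {
    "bipartite_part1": NLSPattern("bipartite_part1", "KR", (0, 1)),
    "bipartite_part2": NLSPattern("bipartite_part2", "RxxRK", (0, 3, 4)),
    # domain-IV SV40-like signal; the KRxRxxK form is the one used by the
    # per-species count table (the running text also prints KxRxxRK once).
    "sv40": NLSPattern("sv40", "KRxRxxK", (0, 1, 3, 6)),
}

PRIMORDIAL_VARIANTS: dict[str, str] = {"QxxRK": "QxxRK", "KxxNK": "KxxNK"}


@dataclass(frozen=True)
class NLSCall:
    sequence_id: str
    category: Category
    status: Status
    window_start: int | None = None
    matched: str | None = None
    variant_tag: str | None = None

    def __post_init__(self) -> None:
        if self.status == "lack" and self.matched is not None:
            raise ValueError("a 'lack' call cannot carry a match")
        if self.status != "lack" and self.matched is None:
            raise ValueError("intact/degenerated calls need a match")


@dataclass(frozen=True)
class NLSReport:
    sequence_id: str
    calls: tuple[NLSCall, NLSCall, NLSCall]

    def __post_init__(self) -> None:
        if tuple(c.category for c in self.calls) != CATEGORIES:
            raise ValueError("report must carry exactly one call per category")

    def call(self, category: Category) -> NLSCall:
        return self.calls[CATEGORIES.index(category)]


@dataclass(frozen=True)
class SpeciesNLSSummary:
    species: str
    counts: Mapping[Category, Mapping[Status, int]]
    n_proteins: int

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            total = sum(self.counts[cat][s] for s in STATUSES)
            if total != self.n_proteins:
                raise ValueError(
                    f"{self.species}/{cat}: statuses sum to {total}, "
                    f"expected {self.n_proteins}"
                )


@dataclass(frozen=True)
class SearchWindow:
    """A subsequence to scan plus its offset in the full protein."""

    start: int
    sequence: str


def _third(seq: str, which: int) -> SearchWindow:
    L = len(seq)
    a, b = (L * which) // 3, (L * (which + 1)) // 3
    return SearchWindow(a, seq[a:b])


def locate_search_windows(
    protein: SequenceRecord | str,
    profile: MotifPresenceProfile | None = None,
) -> dict[Category, SearchWindow]:
    """Category-specific search windows anchored on motif hits.

    Part 1 spans the region between the motif-5 hit and the motif-3 hit;
    Part 2 is the motif-3 hit padded by 10 residues; the SV40 window is
    the motif-4 hit padded by 10 residues.  When an anchoring motif is
    missing the fallback is the N-terminal / middle / C-terminal third
    respectively.  Windows may be empty strings; they never error.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    hits: dict[str, MotifHit | None] = {}
    if profile is not None:
        hits = dict(profile.best_hits)
    h3 = hits.get("m3")
    h4 = hits.get("m4")
    h5 = hits.get("m5")

    windows: dict[Category, SearchWindow] = {}
    if h5 is not None and h3 is not None and h5.start + len(h5.matched) <= h3.start:
        a = h5.start + len(h5.matched)
        windows["bipartite_part1"] = SearchWindow(a, seq[a : h3.start])
    else:
        windows["bipartite_part1"] = _third(seq, 0)
    if h3 is not None:
        a = max(0, h3.start - 10)
        b = min(len(seq), h3.start + len(h3.matched) + 10)
        windows["bipartite_part2"] = SearchWindow(a, seq[a:b])
    else:
        windows["bipartite_part2"] = _third(seq, 1)
    if h4 is not None:
        a = max(0, h4.start - 10)
        b = min(len(seq), h4.start + len(h4.matched) + 10)
        windows["sv40"] = SearchWindow(a, seq[a:b])
    else:
        windows["sv40"] = _third(seq, 2)
    return windows


def match_nls(
    window: str | SearchWindow,
    pattern: NLSPattern,
    sequence_id: str = "<anonymous>",
) -> NLSCall:
    """Classify one window against one canonical NLS pattern.

    Intact: some placement matches every non-wildcard position exactly.
    Degenerated: otherwise, some placement carries exactly one
    substitution, at a basic position, with every other literal position
    exact.  Anything else lacks the signal.  The leftmost qualifying
    placement wins.
    """
    if isinstance(window, SearchWindow):
        offset, seq = window.start, window.sequence
    else:
        offset, seq = 0, window
    w = pattern.width
    best_degen: tuple[int, str] | None = None
    for j in range(len(seq) - w + 1):
        sub = seq[j : j + w]
        mismatches = [
            k
            for k, (p, c) in enumerate(zip(pattern.pattern, sub))
            if p != "x" and p != c
        ]
        if not mismatches:
            return NLSCall(sequence_id, pattern.category, "intact", offset + j, sub)
        if (
            best_degen is None
            and len(mismatches) == 1
            and mismatches[0] in pattern.basic_positions
        ):
            best_degen = (offset + j, sub)
    if best_degen is not None:
        return NLSCall(
            sequence_id, pattern.category, "degenerated", best_degen[0], best_degen[1]
        )
    return NLSCall(sequence_id, pattern.category, "lack")


def detect_species_variants(
    window: str | SearchWindow, species: str | None = None
) -> str | None:
    """Tag the primordial Part-2 variants seen in basal land plants.

    QxxRK (first R of RxxRK replaced by Q, as in mosses) and KxxNK
    (R→K plus R→N, as in spikemosses) are flagged as
    ``primordial-variant`` annotations; they remain degenerated/lack
    calls in the main classification.  ``species`` is informational.
    """
    seq = window.sequence if isinstance(window, SearchWindow) else window
    for name in PRIMORDIAL_VARIANTS:
        w = len(name)
        for j in range(len(seq) - w + 1):
            sub = seq[j : j + w]
            if all(p == "x" or p == c for p, c in zip(name, sub)):
                return f"primordial-variant ({name})"
    return None


def scan_protein(
    protein: SequenceRecord,
    profile: MotifPresenceProfile | None = None,
    species: str | None = None,
) -> NLSReport:
    """Full three-category NLS report for one protein."""
    windows = locate_search_windows(protein, profile)
    calls = []
    for cat in CATEGORIES:
        call = match_nls(windows[cat], NLS_PATTERNS[cat], protein.id)
        if cat == "bipartite_part2" and call.status != "intact":
            tag = detect_species_variants(windows[cat], species)
            if tag is not None:
                call = NLSCall(
                    call.sequence_id,
                    call.category,
                    call.status,
                    call.window_start,
                    call.matched,
                    variant_tag=tag,
                )
        calls.append(call)
    return NLSReport(protein.id, tuple(calls))


def aggregate_species(
    reports: Iterable[NLSReport], species_of: Mapping[str, str]
) -> tuple[list[SpeciesNLSSummary], pd.DataFrame]:
    """Per-species status counts plus overall percentages.

    Every sequence must be mapped to a species.  The overall table gives,
    for each category and status, the count and its percentage of all
    scanned proteins (intact + degenerated + lack = n per category is
    asserted by construction).
    """
    reports = list(reports)
    by_species: dict[str, dict[Category, dict[Status, int]]] = {}
    totals: dict[str, int] = {}
    for rep in reports:
        if rep.sequence_id not in species_of:
            raise KeyError(f"sequence {rep.sequence_id!r} has no species mapping")
        sp = species_of[rep.sequence_id]
        if sp not in by_species:
            by_species[sp] = {c: {s: 0 for s in STATUSES} for c in CATEGORIES}
            totals[sp] = 0
        totals[sp] += 1
        for call in rep.calls:
            by_species[sp][call.category][call.status] += 1

    summaries = [
        SpeciesNLSSummary(sp, by_species[sp], totals[sp]) for sp in by_species
    ]
    n = len(reports)
    rows = []
    for cat in CATEGORIES:
        for status in STATUSES:
            count = sum(by_species[sp][cat][status] for sp in by_species)
            rows.append(
                {
                    "category": cat,
                    "status": status,
                    "count": count,
                    "percent": round(100.0 * count / n, 1) if n else 0.0,
                }
            )
    return summaries, pd.DataFrame(rows)
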