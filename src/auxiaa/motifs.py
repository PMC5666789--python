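"""Discovery and scanning of the five conserved Aux/IAA motifs.

The family's four domains map onto five ungapped motifs (domain I =
motif 5 with the LxLxLx repression repeat, domain II = motif 3 with the
VGWPPV degron, domain III = motif 2, domain IV = motifs 1 and 4).
Motifs can be found de novo with a ZOOPS ("zero or one occurrence per
sequence") expectation-maximization fit — a deliberately small
re-implementation of the classic EM motif finder — or called from the
packaged consensus anchors.  Presence calls feed the family typing
stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqio import SequenceRecord, load_consensus_patterns

__all__ = [
    "AMINO_ACIDS",
    "PositionWeightMatrix",
    "ConsensusPattern",
    "MotifHit",
    "MotifPresenceProfile",
    "discover_motifs_zoops",
    "scan_motif",
    "call_presence",
    "default_consensus_models",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

WIDTH_MIN_DEFAULT = 6
WIDTH_MAX_DEFAULT = 50
DEFAULT_WIDTH_CANDIDATES = (6, 8, 10, 12, 14, 16, 18, 20)


@dataclass
class PositionWeightMatrix:
    """Per-position residue probabilities for one ungapped motif.

    ``frequencies`` has shape (width, 20) over :data:`AMINO_ACIDS`;
    each row sums to 1.  ``background`` holds the 0-order residue
    frequencies the log-odds scores are taken against.
    """

    motif_id: str
    frequencies: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (WIDTH_MIN_DEFAULT <= self.width <= WIDTH_MAX_DEFAULT):
            raise ValueError(f"motif width {self.width} outside [6, 50]")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def log_odds(self) -> np.ndarray:
        """Log2 odds matrix (width, 20) against the background."""
        return np.log2(self.frequencies / self.background[None, :])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def score(self, window: str) -> float:
        """Log-odds score of one window; residues outside the 20-letter
        alphabet (e.g. X) contribute 0 bits."""
        lo = self.log_odds()
        total = 0.0
        for k, ch in enumerate(window):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                total += lo[k, idx]
        return total

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.frequencies.argmax(axis=1))

    def information_content_columns(self) -> np.ndarray:
        f = self.frequencies
        ic = f * np.log2(np.maximum(f, 1e-300) / self.background[None, :])
        return ic.sum(axis=1)

    def information_content_per_column(self) -> float:
        return float(self.information_content_columns().mean())


@dataclass(frozen=True)
class ConsensusPattern:
    """Literal motif anchor with ``x`` wildcards (matches any residue)."""

    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("consensus pattern must have length >= 2")

    @property
    def width(self) -> int:
        return len(self.pattern)

    def mismatches(self, window: str) -> int:
        """Mismatch count at non-wildcard positions (wildcards free)."""
        return sum(
            1 for p, c in zip(self.pattern, window) if p != "x" and p != c
        )


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif_id: str
    start: int  # 0-based
    matched: str
    score: float


@dataclass(frozen=True)
class MotifPresenceProfile:
    """Presence/absence of all five motifs in one protein.

    ``best_hits`` keeps the representative (best-scoring) hit per present
    motif so downstream stages can anchor windows on motif positions.
    """

    sequence_id: str
    present: Mapping[str, bool]
    best_hits: Mapping[str, MotifHit | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.present) != {"m1", "m2", "m3", "m4", "m5"}:
            raise ValueError("profile must cover exactly m1..m5")

    def present_set(self) -> frozenset[int]:
        return frozenset(
            int(m[1]) for m, ok in self.present.items() if ok
        )


def _encode(seq: str) -> np.ndarray:
    """Residues as indices into AMINO_ACIDS; unknown letters become -1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def _background_from(seqs: Sequence[str], pseudocount: float = 0.01) -> np.ndarray:
    counts = np.full(20, pseudocount)
    for s in seqs:
        for c in s:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def _window_ratios(
    enc: np.ndarray, freq: np.ndarray, background: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Likelihood ratio prod f/b for every window start; masked windows get 0."""
    L, w = enc.size, freq.shape[0]
    m = L - w + 1
    if m <= 0:
        return np.zeros(0)
    ratio = freq / background[None, :]
    out = np.ones(m)
    for k in range(w):
        col = enc[k : k + m]
        vals = np.ones(m)
        known = col >= 0
        vals[known] = ratio[k, col[known]]
        out *= vals
    # any window overlapping a masked residue is unavailable
    bad = np.convolve(mask.astype(float), np.ones(w), mode="valid") > 0
    out[bad] = 0.0
    return out


def _zoops_em_single(
    enc_seqs: list[np.ndarray],
    masks: list[np.ndarray],
    init_freq: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, float]:
    """Run ZOOPS EM from one initial PWM.

    Returns (frequencies, gamma, objective).  The likelihood is the
    ZOOPS mixture over "no site" and a uniform site-position prior; the
    constant background term is dropped (it does not affect the EM).
    The pseudocount acts as a Dirichlet prior, so the monotone objective
    is the penalized log-likelihood; it is asserted non-decreasing.
    """
    freq = init_freq.copy()
    w = freq.shape[0]
    gamma = 0.5
    prev_ll = -math.inf
    for _ in range(max_iter):
        ll = float(pseudocount * np.log(np.maximum(freq, 1e-300)).sum())
        site_counts = np.full((w, 20), pseudocount)
        gamma_num = 0.0
        n_used = 0
        for enc, mask in zip(enc_seqs, masks):
            ratios = _window_ratios(enc, freq, background, mask)
            m = ratios.size
            if m == 0:
                continue
            n_used += 1
            no_site = 1.0 - gamma
            with_site = gamma / m * ratios
            total = no_site + with_site.sum()
            ll += math.log(max(total, 1e-300))
            z = with_site / total
            gamma_num += z.sum()
            # accumulate weighted residue counts
            for j in np.nonzero(z > 1e-12)[0]:
                window = enc[j : j + w]
                zj = z[j]
                for k in range(w):
                    if window[k] >= 0:
                        site_counts[k, window[k]] += zj
        if n_used == 0:
            break
        assert ll >= prev_ll - 1e-9, "ZOOPS EM log-likelihood decreased"
        freq = site_counts / site_counts.sum(axis=1, keepdims=True)
        gamma = min(max(gamma_num / n_used, 1e-6), 1 - 1e-6)
        if ll - prev_ll < tol and prev_ll > -math.inf:
            prev_ll = ll
            break
        prev_ll = ll
    return freq, gamma, prev_ll


def _seed_pwm(seed: str, background: np.ndarray, strength: float = 0.7) -> np.ndarray:
    w = len(seed)
    freq = np.tile((1 - strength) * background, (w, 1))
    freq /= freq.sum(axis=1, keepdims=True)
    freq *= 1 - strength
    for k, c in enumerate(seed):
        idx = _AA_INDEX.get(c)
        if idx is not None:
            freq[k, idx] += strength
        else:
            freq[k] = background
    return freq / freq.sum(axis=1, keepdims=True)


def discover_motifs_zoops(
    proteins: Sequence[SequenceRecord],
    n_motifs: int = 5,
    width_min: int = WIDTH_MIN_DEFAULT,
    width_max: int = WIDTH_MAX_DEFAULT,
    seed: int = 0,
    width_candidates: Sequence[int] | None = None,
    max_seeds: int = 30,
    pseudocount: float = 0.01,
) -> list[PositionWeightMatrix]:
    """Discover up to ``n_motifs`` ungapped motifs by ZOOPS EM.

    Each sequence is assumed to carry zero or one occurrence of each
    motif.  For every candidate width, EM is started from PWMs seeded on
    a sample of length-w subsequences; the converged fit with the best
    likelihood is kept and widths compete on information content per
    column times the expected number of sites.  Sites of an accepted
    motif are masked before the next motif is sought.  Deterministic
    given ``seed``.
    """
    if len(proteins) < 5:
        raise ValueError("motif discovery needs at least 5 sequences")
    seqs = [p.residues for p in proteins]
    if all(len(s) < width_min for s in seqs):
        raise ValueError(f"all sequences shorter than width_min={width_min}")
    if width_candidates is None:
        width_candidates = [
            w for w in DEFAULT_WIDTH_CANDIDATES if width_min <= w <= width_max
        ]
    rng = np.random.default_rng(seed)
    background = _background_from(seqs, pseudocount)
    enc_seqs = [_encode(s) for s in seqs]
    masks = [np.zeros(len(s), dtype=bool) for s in seqs]

    results: list[PositionWeightMatrix] = []
    for motif_index in range(n_motifs):
        best = None  # (selection score, ll, freq, gamma)
        for w in width_candidates:
            # seed from every length-w subsequence of a small sample of
            # sequences (unmasked stretches only)
            seeds: list[str] = []
            order = rng.permutation(len(seqs))
            for si in order[: max(2, max_seeds // 10)]:
                s, mask = seqs[si], masks[si]
                for j in range(0, len(s) - w + 1):
                    if not mask[j : j + w].any():
                        seeds.append(s[j : j + w])
            if not seeds:
                continue
            seeds = list(dict.fromkeys(seeds))  # dedupe, order-stable
            # short EM from every seed, then converge the best
            trial = []
            for sd in seeds:
                freq0 = _seed_pwm(sd, background)
                freq, gamma, ll = _zoops_em_single(
                    enc_seqs, masks, freq0, background, pseudocount, max_iter=3
                )
                trial.append((ll, freq))
            trial.sort(key=lambda t: -t[0])
            freq, gamma, ll = _zoops_em_single(
                enc_seqs, masks, trial[0][1], background, pseudocount
            )
            pwm = PositionWeightMatrix(
                f"m{motif_index + 1}", freq, background, pseudocount
            )
            # score = bias-corrected total information x expected sites.
            # The per-column bias is the Miller-Madow small-sample term,
            # which is what an uninformative flank column contributes;
            # a wider motif must beat the incumbent by a 5% parsimony
            # margin so junk columns cannot drag the width up.
            exp_sites = gamma * len(seqs)
            bias = (len(AMINO_ACIDS) - 1) / (2.0 * math.log(2) * max(exp_sites, 1.0))
            icc = pwm.information_content_columns()
            sel = float(np.maximum(icc - bias, 0.0).sum()) * exp_sites
            if best is None or sel > 1.05 * best[0]:
                best = (sel, ll, freq, gamma)
        if best is None:
            break
        _, _, freq, gamma = best
        pwm = PositionWeightMatrix(
            f"m{motif_index + 1}", freq, background, pseudocount
        )
        results.append(pwm)
        # mask the MAP site in every sequence that likely carries one
        w = pwm.width
        for si, (enc, mask) in enumerate(zip(enc_seqs, masks)):
            ratios = _window_ratios(enc, freq, background, mask)
            if ratios.size == 0:
                continue
            m = ratios.size
            with_site = gamma / m * ratios
            total = (1 - gamma) + with_site.sum()
            z = with_site / total
            j = int(z.argmax())
            if z[j] > 0.5:
                mask[j : j + w] = True
    return results


def scan_motif(
    protein: SequenceRecord | str,
    model: PositionWeightMatrix | ConsensusPattern,
    threshold_fraction: float = 0.6,
) -> list[MotifHit]:
    """All hits of one motif model in one protein, sorted by position.

    PWM windows must score at least ``threshold_fraction`` of the
    maximum attainable log-odds; consensus windows may carry at most one
    mismatch at non-wildcard positions.  A protein shorter than the
    model returns an empty list.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    if isinstance(protein, SequenceRecord):
        seq_id, seq = protein.id, protein.residues
    else:
        seq_id, seq = "<anonymous>", protein
    w = model.width
    hits: list[MotifHit] = []
    if len(seq) < w:
        return hits
    if isinstance(model, PositionWeightMatrix):
        cutoff = threshold_fraction * model.max_score()
        for j in range(len(seq) - w + 1):
            window = seq[j : j + w]
            s = model.score(window)
            if s >= cutoff:
                hits.append(MotifHit(seq_id, model.motif_id, j, window, s))
    else:
        for j in range(len(seq) - w + 1):
            window = seq[j : j + w]
            mm = model.mismatches(window)
            if mm <= 1:
                hits.append(
                    MotifHit(seq_id, model.motif_id, j, window, float(w - mm))
                )
    return hits


def default_consensus_models() -> dict[str, ConsensusPattern]:
    """The packaged consensus anchors for motifs m1..m5."""
    return {
        mid: ConsensusPattern(mid, pat)
        for mid, pat in load_consensus_patterns().items()
    }


def call_presence(
    protein: SequenceRecord,
    models: Mapping[str, PositionWeightMatrix | ConsensusPattern] | None = None,
    threshold_fraction: float = 0.6,
) -> MotifPresenceProfile:
    """Presence profile over motifs m1..m5 for one protein.

    A motif is present iff :func:`scan_motif` yields at least one hit;
    the best-scoring hit (leftmost on ties) is kept as representative.
    With no ``models`` argument the packaged consensus patterns are used.
    """
    if models is None:
        models = default_consensus_models()
    if set(models) != {"m1", "m2", "m3", "m4", "m5"}:
        raise ValueError("models must cover exactly m1..m5")
    present: dict[str, bool] = {}
    best: dict[str, MotifHit | None] = {}
    for mid in ("m1", "m2", "m3", "m4", "m5"):
        hits = scan_motif(protein, models[mid], threshold_fraction)
        present[mid] = bool(hits)
        best[mid] = max(hits, key=lambda h: (h.score, -h.start)) if hits else None
    return MotifPresenceProfile(protein.id, present, best)
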