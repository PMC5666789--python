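"""Independent brute-force NG86 reference used only by tests.

Everything here is recomputed from the genetic code by explicit
enumeration — no tables or helpers are shared with the package's
estimator — so agreement between the two is a genuine cross-check.
"""

import itertools
import math

from Bio.Seq import Seq

NUCS = "ACGT"

CODE = {
    "".join(c): str(Seq("".join(c)).translate()) for c in itertools.product(NUCS, repeat=3)
}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def syn_fraction(codon):
    """Per-position synonymous fractions by explicit enumeration."""
    total = 0.0
    for pos in range(3):
        n_syn = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if CODE[alt] != "*" and CODE[alt] == CODE[codon]:
                n_syn += 1
        total += n_syn / 3.0
    return total


def pathway_counts(ca, cb):
    """(Sd, Nd) averaged over stop-free shortest pathways."""
    if ca == cb:
        return 0.0, 0.0
    positions = [i for i in range(3) if ca[i] != cb[i]]
    outcomes = []
    fallback = []
    for order in itertools.permutations(positions):
        cur = ca
        sd = nd = 0
        stopped = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                stopped = True
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if stopped else outcomes).append((sd, nd))
    use = outcomes or fallback
    return (
        sum(o[0] for o in use) / len(use),
        sum(o[1] for o in use) / len(use),
    )


def ng86(pairs):
    """Reference NG86: returns (Ka, Ks) or None where undefined."""
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, sb = syn_fraction(ca), syn_fraction(cb)
        # associate exactly as per-codon (syn, 3 - syn) pairs so the
        # saturation boundary p = 3/4 is hit bit-identically
        S += (sa + sb) / 2.0
        N += ((3.0 - sa) + (3.0 - sb)) / 2.0
        sd, nd = pathway_counts(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return None
        return 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    pn = Nd / N if N > 0 else 0.0
    ps = Sd / S if S > 0 else 0.0
    return jc(pn), jc(ps), (S, N)
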