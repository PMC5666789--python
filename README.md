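# auxiaa

Evolutionary analysis of the **Aux/IAA** gene family — the short-lived nuclear
repressors of auxin signaling in plants. The package re-implements, as a tested
and reusable library + CLI, the analysis pipeline used in genome-wide family
surveys:

* **Motif typing** — the family's four domains map onto five ungapped motifs
  (domain I = the LxLxLx repression repeat, domain II = the VGWPPV degron,
  domain III = VKVxM/RK, domain IV = GDVPW and the KRxRxxK cluster). Proteins
  are assigned one of 11 composition types (type I = all five motifs =
  canonical). Motifs can be called from packaged consensus anchors or
  discovered de novo with a ZOOPS ("zero or one occurrence per sequence")
  expectation–maximization fit.
* **PB1 signature** — the GDVP (Aux/IAA-like) vs GDDP (ARF-derived) linker
  between β3 and α2 of the PB1 domain, used to flag truncated-ARF candidates.
* **NLS classification** — bipartite NLS Part 1 (`KR`), Part 2 (`RxxRK`) and
  the SV40-like signal (`KRxRxxK`), each called intact / degenerated (exactly
  one basic-residue substitution) / lacking, with the primordial lower-plant
  Part-2 variants (`QxxRK`, `KxxNK`) tagged.
* **Duplication-mode calling** — tandem pairs (same chromosome, nearest gene
  boundaries ≤ 50 kb, protein identity > 50%) and segmental pairs (anchored in
  collinearity blocks), plus per-species Seg/Tan/Seg&Tan summaries.
* **Ka/Ks selection inference** — protein-guided codon alignment
  (global affine Gonnet-250 alignment, opening 10 / extension 0.1), then

  * **NG86**: fractional site counting, equal weighting of all shortest
    substitution pathways, Jukes–Cantor correction;
  * **MYN**: a modified Yang–Nielsen estimator with kappa (ts/tv) estimated
    from four-fold degenerate and nondegenerate sites, kappa- and
    codon-usage-weighted sites, and Kimura-type corrections applied
    separately to transitions/transversions at synonymous and nonsynonymous
    sites.

  ω = Ka/Ks < 1 indicates purifying and ω > 1 positive selection.
* **Phylogenies** — p-distance matrices (pairwise deletion), optional
  gamma + invariant-sites correction, Saitou–Nei neighbor joining, bootstrap
  supports by column resampling, and sister-pair (cherry) extraction at a
  strict >90% support threshold.
* **Synthetic families** — a generator producing gene families with full
  ground truth (motif scaffolds, planted NLS statuses, tandem/segmental events
  with coordinates and collinearity blocks, codon evolution under an
  MG94×HKY-style process with chosen ω and kappa), so every stage is testable
  without downloads.

The package also ships transcriptions of the survey's printed summary tables
(per-species gene counts, selected Ka/Ks pairs, per-species NLS counts) as
fixtures, available via `auxiaa.load_fixture_tables()`.

## Worked example

```python
import auxiaa
from auxiaa.codon import CodonAlignment, estimate_kaks_ng86, omega_ratio

# the six-codon worked example: one synonymous difference (TTT -> TTC)
a = ["ATG", "TTT", "GCT", "GCA", "GCC", "GCG"]
b = ["ATG", "TTC", "GCT", "GCA", "GCC", "GCG"]
r = estimate_kaks_ng86(CodonAlignment(tuple(zip(a, b))))
print(f"S={r.sites.S:.4f} Ka={r.ka} Ks={r.ks:.4f}")
# S=4.3333 Ka=0.0 Ks=0.2758
#   4 1/3 synonymous sites; the single synonymous difference gives
#   ps = 3/13, and the Jukes-Cantor correction -3/4 ln(1 - 4p/3) = 0.2758.

t2 = auxiaa.load_fixture_tables().table2
row = t2[t2.species == "Picea abies"].iloc[0]
print(omega_ratio(row.ka, row.ks))
# 1.672  — Ka/Ks > 1: this tandem pair evolved under positive selection.
```

End-to-end on a synthetic family:

```bash
auxiaa simulate --config sim.yaml --out family/     # seed, rates, omega, kappa
auxiaa run --config pipeline.yaml                   # motifs -> ... -> stats
```

The pipeline bundle contains `motif_presence.tsv`, `types.tsv`,
`nls_report.tsv`, `duplication_pairs.tsv`, `kaks.tsv`, `tree.nwk`,
`stats.json` and a `manifest.json` recording the seed and thresholds;
reruns with the same inputs and seed are byte-identical.

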