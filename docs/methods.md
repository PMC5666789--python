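# Methods

This note documents the models, parameter choices and numerical behavior of
the `auxiaa` pipeline, and what its synthetic-data tests do and do not show.

## Motif model

Five ungapped motifs stand in for the family's four domains, in N-to-C order
5–3–2–4–1. Two interchangeable representations are supported:

* **Consensus anchors** (packaged, default): `GDVPW` (m1), `VKVxM` (m2),
  `VGWPPV` (m3), `KRxRxxK` (m4), `LxLxLx` (m5), where `x` matches any
  residue. A window matches if it has at most **one** mismatch at
  non-wildcard positions — permissive enough to keep known degron variants
  (e.g. the proline→leucine substitution in `VGWPPV`) while rejecting noise.
* **Position weight matrices** fitted by ZOOPS EM (below), scanned with a
  log-odds threshold of `threshold_fraction` (default **0.6**) of the
  maximum attainable score. The default is deliberately permissive so that
  degenerated motifs still anchor downstream windows; it is validated
  against synthetic truth, not against any external standard.

A motif is "present" iff the scan yields ≥ 1 hit; the best-scoring
(leftmost on ties) hit is the representative used for window anchoring.
No presence threshold for calling a motif "lacking" is externally given;
the one-mismatch consensus rule and the 0.6 PWM fraction are this
package's choices.

### ZOOPS EM discovery

Each sequence carries zero or one occurrence of the motif (mixing weight
γ, uniform position prior). Initialization seeds a PWM from **every**
length-w subsequence of a small sample of sequences (3 short EM steps
each), then the best seed is run to convergence (penalized log-likelihood
gain < 1e-6, max 200 iterations). The pseudocount (0.01) acts as a
Dirichlet prior, so the quantity that is provably non-decreasing — and is
asserted every iteration — is the *penalized* log-likelihood. Sites of an
accepted motif are masked (windows overlapping a masked residue get zero
prior mass) before the next motif is fitted. Runs are deterministic given
the seed.

**Width selection.** Candidate widths (default 6–20 in steps of 2, within
the 6–50 bounds) compete on *bias-corrected total information ×
expected site count*: per-column information content minus the
Miller–Madow small-sample term (|A|−1)/(2 ln 2 · C) (C = expected sites),
floored at zero, summed over columns. A wider motif must beat the
incumbent by a 5% parsimony margin. A plain per-column-IC score cannot
distinguish a phase-complete motif from its own sub-window (both are near
point masses); the bias correction zeroes out uninformative flank columns
so the full-width motif wins without letting junk columns drag the width
upward.

**Behavior on background-only data.** There is no E-value/significance
machinery (out of scope). On uniform random sequences the MAP-EM still
converges to *some* sharp local optimum supported by a handful of
sequences; what distinguishes it from a real motif is its far smaller
information mass (tested as a ≥ 2× separation from planted-motif data),
not a low per-column IC.

## Family typing

Typing is a total function on the 32 presence subsets: {1,2,3,4,5}→I
(canonical), {1,2,3,5}→II, {2,3,5}→III, {2,5}+exactly one of {1,4}→IV,
{1,2,3,4}→V, {1,2,3}→VI, {1,2,4}→VII, {1,2}→VIII, {2}→IX, {1}→X,
everything else → "other". Type IV is interpreted as motif 3 absent with
motifs 2 and 5 present plus exactly one of motifs 1/4 ("domain I, domain
III, and an incomplete domain IV") — an interpretive reading, flagged
here because the verbal definition does not mention domain II. The PB1
signature call is a plain substring test (GDVP vs GDDP, first occurrence
winning on the rare dual hit).

## NLS classification

Patterns: Part 1 `KR` (both positions basic), Part 2 `RxxRK` (basic at
0, 3, 4), SV40 `KRxRxxK` (basic at 0, 1, 3, 6). The SV40 canonical form
follows the per-species count table and the motif-4 logo; the running
text's one-off `KxRxxRK` variant is noted but not used. Status rules:

* **intact** — some placement matches every literal position;
* **degenerated** — exactly one substitution, at a basic position, all
  other literal positions exact ("a non-synonymous mutation", singular,
  is read as a crisp one-substitution rule);
* **lack** — anything worse. Leftmost qualifying placement wins.

Search windows are anchored on motif hits: Part 1 between the motif-5 and
motif-3 hits, Part 2 = motif-3 hit ± 10 residues, SV40 = motif-4 hit ± 10
residues. Without an anchor the fallback is the N-terminal / middle /
C-terminal third respectively — a coarse approximation of the domain
layout that lets non-canonical proteins be scanned at all. Status is
monotone in mismatch count and invariant under window shifts (both
property-tested).

## Duplication-mode calling

Tandem: same chromosome, nearest-boundary distance ≤ 50 000 bp, global
protein identity > 50%. The 50-kb rule is measured **between nearest gene
boundaries** (end of the upstream gene to start of the downstream gene) —
the rule's distance convention is not externally specified, and the
boundary convention is the conservative, unambiguous choice. Identity is
identical columns over gap-free columns of the global alignment.
"Homology > 50%" is read as global protein identity. Strand is ignored.
Segmental: membership of the (unordered) pair in any collinearity-block
anchor list. Both rules satisfied → "both". Per-species summaries count a
*gene* toward Seg/Tan if it participates in ≥ 1 pair of that class
(percentages of the species total, two decimals), so Seg&Tan ≤
min(Seg, Tan) by construction.

## Codon alignment and Ka/Ks

Proteins are aligned globally with affine gaps (Gonnet-250 scoring,
opening 10, extension 0.1 — the classic ClustalX defaults) and the
alignment is projected onto the coding sequences codon-by-codon; columns
with a gap, a stop codon or an ambiguous base are dropped (and counted).
The CDS must be exactly 3× the protein length and translate to it.

**NG86.** Synonymous sites per codon are counted fractionally (changes to
stop codons count as nonsynonymous; the denominator stays 3 per position,
so S + N = 3 × codons *exactly* — asserted). Differences between codons
differing at k positions average over all k! shortest pathways; pathways
through stop codons are excluded and weights renormalized (if every
pathway is blocked, all are used). ps = Sd/S and pn = Nd/N get the
Jukes–Cantor correction −¾ ln(1 − 4p/3); p ≥ ¾ leaves the rate undefined
(reported, not thrown), and ω is defined only when Ks > 0. The test suite
checks NG86 against a fully independent brute-force enumeration on all
61 × 61 codon pairs and on random 200-codon alignments to 1e-10.

**MYN.** kappa (ts/tv rate ratio) is estimated from sites whose
degeneracy class agrees in both codons — four-fold degenerate and
nondegenerate — via the Kimura two-parameter decomposition (kappa = 2A/B),
combined across the two classes weighted by site counts. Sites are then
counted weighting each possible change by kappa (transitions) and by the
observed codon usage of the target (add-one smoothing over the 61 sense
codons). Differences are pathway-averaged as in NG86 but split into
ts/tv × syn/nonsyn, and Ks and Ka each get their own K2P correction.
The site/rate computation is iterated to a fixed point (tolerance 1e-8 on
Ka and Ks; it settles in two passes because the kappa estimate is closed
form). kappa is deliberately **not** refit from the synonymous-site ts/tv
split: synonymous changes are structurally transition-enriched (2-fold
degenerate third positions), so that split grossly overestimates the
mutational transition bias — an error mode found and removed during
development.

**Estimator behavior.** With a transition-unbiased process (kappa = 1)
both estimators recover ω to within a few percent (median over 50 pairs
of 500 codons, at ω ∈ {0.1, 0.5, 1.0}). Under transition bias
(kappa = 2) NG86 shows its textbook downward ω bias (≈ 15–20%: its
equal-rate site counting understates S, inflating Ks and deflating Ka),
while MYN stays within a few percent. The acceptance harness therefore
evaluates recovery at kappa = 1 — the condition under which the two
methods share their counting assumptions and can both be held to the
same 20% band — and the kappa = 2 behavior is characterized separately
in the simulator tests (NG86 still within 20% at ω = 0.5, t = 0.4).

## Phylogeny

p-distances use pairwise deletion; a pair with no comparable columns is
an error. The optional correction is the standard gamma + invariant-sites
transform d' = α(1 − p_inv)[(1 − d/(1 − p_inv))^(−1/α) − 1]. Correction
is **off by default**: the gamma shape and invariant proportion used by
the original analysis are nowhere stated, so no default is guessed. Note
the α → ∞ limit of this transform is −ln(1 − d) (the uncorrected
multiple-hit formula), not d itself; the identity holds only as d → 0.

NJ is the Saitou–Nei Q-criterion agglomeration with deterministic
tie-breaks (lexicographically smallest index pair), negative branch
lengths clamped to zero, and a trifurcating root. It recovers topology
*and* branch lengths exactly from additive matrices (property-tested on
200 random 5–12-leaf trees by comparing the full path-length metric).
Bootstrap resamples columns with replacement, rebuilds the tree, and
scores each reference bipartition by the percentage of replicates
containing it; replicates in which some pair loses all comparable columns
are skipped. Sister pairs are cherries with support **strictly** above
the threshold (default 90, matching the ">90%" convention). Newick output
writes supports as internal-node labels and quotes punctuated labels.

The pipeline's tree stage requires an aligned FASTA (equal-length
sequences); multiple alignment itself is out of scope, so unaligned
inputs are rejected with a pointer to `msa_fasta`.

## Summary statistics

Pearson r (two-sided p from the t transform, n − 2 df; zero variance is
an error), the classic equal-variance two-sample Student t (Welch behind
its own function), and the paired t on differences — all two-sided, all
delegated to scipy.stats with the degenerate cases pinned: fully
separated zero-variance samples report the limit p = 0 with a warning;
identical samples report t = 0, p = 1. Grouped ω means (lineage ×
duplication type, 4 decimals) exclude undefined ω values from numerator
and denominator and carry the exclusion count; empty cells are absent,
never zero. Null calibration of the t-test (type-I error at α = 0.05
within [0.04, 0.06]; Kolmogorov distance of null p-values from uniform
< 0.02 at 10 000 replicates) is part of the suite.

## Synthetic data

The generator emulates what the pipeline needs to be tested against
ground truth, with these defaults (chosen once as typical of plant
nuclear gene families, configurable):

| parameter | default | meaning |
|---|---|---|
| gene length | 200 codons | typical Aux/IAA size (~150–350 aa) |
| kappa | 2.0 | typical ts/tv bias of plant nuclear genes |
| omega | 0.2 | purifying selection, family norm |
| branch_length_syn | 0.3 | expected syn subs per syn site per epoch |
| tandem / segmental rate | 0.15 / 0.10 | events per gene per epoch |
| codon frequencies | uniform over 61 | simplest null |
| tandem child placement | 1–40 kb | inside the 50-kb rule |
| linker lengths | 10–40 aa uniform | realistic inter-domain spacing |

Codon evolution is a per-codon continuous-time Gillespie simulation
under an MG94×HKY-style process (single-nucleotide exchanges, transitions
× kappa, nonsynonymous × ω, proposals creating stops rejected), with time
scaled on the input sequence so the expected synonymous substitutions per
(kappa-weighted) synonymous site equal t. The calibration was verified by
direct event counting (realized 0.298 at t = 0.3).

Protein scaffolds place the requested motifs in domain order with random
linkers drawn from an alphabet (`ADEFHINQSTY`) disjoint from every motif
consensus and from K/R — so linker chance can neither fake nor break a
planted motif or NLS, which is what makes planted truth *exactly*
recoverable. Two consequences worth knowing:

* The SV40 NLS **is** the motif-4 consensus, so a plan combining an
  intact or degenerated SV40 with an absent motif 4 is contradictory and
  rejected; per-gene defaults set the SV40 status from the motif set.
* NLS/motif truth is guaranteed at emission time (branch length 0).
  Epochs of codon evolution can erode planted motifs and NLSs, so
  end-to-end truth tests on evolved families assert duplication and ω
  recovery, while NLS/typing truth is tested on unevolved scaffolds.

What the generator does **not** emulate: indel evolution (alignment is
tested on hand fixtures instead), genome rearrangements beyond simple
duplicate placement, codon-usage bias, rate variation across sites, and
real intron structure (gene length = CDS length). Passing recovery tests
therefore demonstrates correctness of the *rules and estimators*, not
performance on the messiness of real proteomes.

## Packaged fixtures

The three printed survey tables are transcribed verbatim as TSVs. Two
printed inconsistencies are preserved rather than silently fixed: the
per-species gene counts sum to 435 while the stated family total is 434
(`FixtureTables.total_mismatch`), and one Ka/Ks row prints 0.6163 where
its own Ka ÷ Ks gives 0.6155. The 52% bipartite-Part-1 figure reproduces
from the table against the stated 434 total; several other printed
percentages differ from table sums by ~0.1 point and are not asserted.

## Known limitations

* Consensus scanning allows exactly one mismatch — it cannot express
  position-specific tolerance; use discovered PWMs for that.
* MYN here is the package's modified-YN estimator (single kappa, K2P-type
  corrections with codon-usage-weighted sites); it does not reproduce any
  external calculator bit-for-bit, and printed Ka/Ks values for real gene
  pairs are validated only through their printed ratios.
* NJ is exact on additive matrices but, like all NJ, heuristic otherwise;
  no ML tree search is provided.
* The pipeline accepts pre-identified candidate sets; proteome-wide
  homology screening and conserved-domain confirmation are out of scope.
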