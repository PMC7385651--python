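# Methods

## The element model

A pipolin is modelled as a chromosomal interval bounded by two identical
direct repeats (att), containing at least one piPolB coding sequence and
arbitrary cargo, integrated at a tRNA gene: the right repeat (attR)
overlaps the tRNA, which lies on the opposite strand.  Two structural
assumptions drive reconstruction and are taken as axioms:

1. **Direct-repeat rule** — all att copies of one element head in the
   same direction; mixed strands within one contig (without a tRNA
   anchor) mean the hits contradict the model and the element is
   reported `inconsistent` rather than force-fit.
2. **attR/tRNA rule** — the att overlapping an opposite-strand tRNA is
   attR and is conventionally rightmost.  With no tRNA anchor the
   rightmost att (in canonical orientation) is used instead and the
   result is flagged low-confidence.  Two tRNA-anchored atts are an
   ambiguity error listing the candidates.

"Canonical orientation" of a fragment is the orientation placing its
atts on the `+` strand; with no att, the `+` strand of the
highest-scoring att hit genome-wide breaks the tie.

## Detection

BLAST-style searches are replaced by exact Smith–Waterman local
alignment with affine gaps (Gotoh), computed by Biopython's
`PairwiseAligner`.  A gap of length k costs `open + k·extend`.
Defaults mirror the common BLAST parameterizations:

| search | scoring | thresholds (defaults) |
|---|---|---|
| DNA (att, tRNA) | match +2 / mismatch −3, gap 5/2 | att: identity ≥ 85%, span ≥ 0.8 × reference; tRNA: ≥ 90% over ≥ 0.9 |
| protein (piPolB) | BLOSUM62, gap 11/1 | identity ≥ 85%, query coverage ≥ 0.3 |

The 0.3 coverage floor deliberately admits truncated piPolB fragments,
which occur in real elements.  Six-frame translation breaks frames at
stop codons rather than aligning through them; N bases never match
(including N–N).  Overlapping hits are resolved greedily by score, ties
by leftmost start then `+` strand.  Identity is matches over alignment
columns (gap columns included).  Repeated hits of one query on one
contig are found by best-hit extraction with N-masking.

In-silico PCR reports, for each forward-primer site, the nearest
downstream reverse-complemented reverse-primer site within the size cap
(the dominant short product); both strands are searched and coordinates
always index the forward strand.

## Reconstruction

Each contig carrying a piPolB or att hit contributes one fragment,
clipped at the element edge its att defines (attL: att start → contig
end; attR: contig start → att end; both on one contig: attL → attR).
Fragments are oriented into canonical direction, ordered
[attL fragment, att-less piPolB fragments by descending score, internal-att
fragments, attR fragment], and concatenated with runs of N (default
100 — the `assembly_gap` feature key denotes unknown length, but a
rendered sequence needs a concrete run; configurable).  All features are
lifted into rendered coordinates.  Structure classes:
`complete_single_contig`, `complete_scaffolded` (2 atts),
`three_att_prophage` (≥3 atts — prophage sharing the integration site),
`unbounded_piPolB_only` (≤1 att; element bounds are not guessed),
`inconsistent` (axiom violations; best-effort whole-contig scaffold,
flagged).  Att-less middle fragments are oriented so their piPolB strand
matches the majority piPolB strand of the att-anchored fragments (tie →
`+`).  Stray fragments that received no role are dropped with a log
record.

Because the element ends at attR, only the att-overlapping stub of the
tRNA (default 15 bp) is part of the rendered sequence; re-detection on a
rendered element therefore finds no full tRNA and falls back to the
rightmost-att rule — the structure itself is reproduced exactly
(idempotence is tested on the att/piPolB skeleton).

## Synthetic worlds

The generators state the world the tests live in; their defaults are
fixed once:

* att length 100 nt, randomly drawn per seed (real att length/sequence
  is element-specific and not modelled); tRNA 85 nt (typical tRNA gene);
  attR–tRNA overlap 15 nt.  The att tail is coupled to the tRNA start so
  the genomic segment under the tRNA interval reads a complete tRNA on
  the minus strand while the atts stay exact direct repeats.
* piPolB CDS 1,200 nt (400 aa — a substantial piPolB fragment; the full
  gene is ~3.7 kb, shortened for desk-scale runtimes), 2 cargo CDS of
  600 nt, spacers 300 nt, background i.i.d. uniform ACGT (GC dial
  available, default 0.5).
* simulated chromosomes use 10–12 kb of background rather than full
  genomes; detection is alignment-based and length-independent at these
  scales, so this is a runtime choice only.
* fragmentation: uniform breakpoints (optionally excluding feature
  neighbourhoods), independent contig flips with probability
  `flip_prob`, contig order shuffled; the fragment map is retained as
  the truth channel and reconstructs the source byte-exactly.
* tree pairs: random-join topologies with Exp(0.1) branch lengths; the
  element tree copies the host topology and applies `n_swaps`
  leaf-label transpositions.  Swaps (rather than SPR moves) keep the
  congruence dial trivially brute-force-verifiable and monotone in
  expectation.
* every generator stream is seeded through a domain-tagged seed sequence
  (`default_rng([tag, seed])`), so passing the same integer seed to the
  template, the genome and the fragmentation never aliases their
  streams (aliased streams reproduce template sequences inside the
  background, creating spurious homology).

What the generators do **not** emulate: read-level sequencing error,
real assembler behaviour beyond breakpoints+flips, codon usage, gene
models, or sequence divergence between element copies.  A green
recovery test therefore establishes correctness of the ordering/
orientation/scaffolding logic under the stated assembly model, not
detector robustness to biological divergence (that is exercised only
through the mutated-plant threshold tests).

## Pangenome arithmetic

Occupancy bands (f = fraction of genomes containing a gene cluster):
core f ≥ 0.99, soft-core 0.95 ≤ f < 0.99, shell 0.15 ≤ f < 0.95, cloud
f < 0.15.  Band membership is decided in integer arithmetic
(`100·count ⋛ threshold·n_genomes`), so boundary genes are classified
exactly.  Percentages for pangenome composition are **truncated** to two
decimals (matching the convention under which 29.4557…% prints as
29.45); prevalence tables round **half-up** to one decimal; whole-number
cloud fractions round half-up to integers.  The divergent conventions
are intentional and module-local.  Greedy clustering (longest-first,
join the first representative at ≥ 95% identity over ≥ 80% of the
shorter sequence) stands in for a full pangenome pipeline; paralogs
count once (presence is boolean).

## Cophylogeny

* Cophenetic distances are patristic path sums; missing branch lengths
  are an error, never silently unit.
* CCC: Pearson correlation of matched strictly-lower-triangle distance
  vectors; zero variance (equal-length star trees) is an undefined
  statistic, raised as such.
* PCoA: classical scaling; axes kept when eigenvalue > 1e-10 × the
  largest; negative eigenvalues are dropped with no Cailliez/Lingoes
  correction (simplest defensible default; recorded here).
* PACo: X and Y (host/element PCoA rows ordered by links, zero-padded
  to equal width) are superimposed by least-squares Procrustes with
  translation, rotation and uniform scaling ("shape" comparison).
  m²_XY is the residual sum of squares, decomposed exactly into
  per-link squared residuals.  The permutation null fully
  re-randomizes the one-to-one link map; default 999 permutations; the
  add-one p-value estimator never returns 0.
* Jackknife: leave-one-link-out refits give pseudovalues
  `n·r_j − (n−1)·r_j^(−i)`; each link gets its pseudovalue mean and a
  t-based 95% upper bound.
* Tanglegram: left order as parsed, right order after one bottom-up
  barycenter pass; crossings counted exactly.

Two degenerate plantings for per-link diagnostics are worth knowing:
swapping **sibling** leaf labels plants (almost) no incongruence — only
two terminal branch lengths move — and swapping the two **most distant**
leaves makes the optimal Procrustes rotation flip the whole
configuration, spreading the error over every link.  The planted-switch
demonstrations and tests therefore swap the leaf pair at the median
cophenetic distance, the regime where the jackknife is expected to
localize the signal.

Published CCC and PACo values for the real strain collections are not
reproducible from this package (they require the study's genomes and
unstated ordination/permutation settings); the property suite — perfect
fit for identical trees, null calibration, monotone degradation,
planted-switch localization — is the verifiable substitute.

## Determinism and budgets

All randomness flows from integer seeds through `numpy.random.default_rng`;
reruns are byte-identical (outputs carry no timestamps).  The recovery
experiment (200 simulations × detection + reconstruction) runs in ~2
minutes on one CPU; the full test suite in ~3–4 minutes.
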