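# pipolin-scout

Detection, reconstruction and comparative analysis of **pipolins** —
integrative mobile genetic elements defined by a primer-independent
family-B DNA polymerase gene (**piPolB**) — in bacterial genome
assemblies.

Pipolins sit in the chromosome between short **att** direct repeats,
typically inserted at a conserved Leu-tRNA gene, with the right-hand
repeat (attR) overlapping the tRNA on the opposite strand.  In draft
assemblies the element is often split across contigs of arbitrary
orientation, so finding a pipolin means more than finding its hallmark
gene: the att repeats must be assigned roles (attL/attR) via the tRNA
rule, the carrying contigs ordered and oriented so that all atts head in
the same direction, and the fragments joined into one continuous
sequence with explicit assembly gaps.  This package implements that
pipeline, plus the comparative statistics used to ask whether such
elements move horizontally between hosts.

## What's inside

| module (`pipolin_scout.*`) | purpose |
|---|---|
| `synthetic` | seeded generators: genomes with planted pipolins, fragmented assemblies with a truth channel, tree pairs with a congruence dial, presence/absence matrices with prescribed category structure |
| `seqsearch` | exact Smith–Waterman local alignment (affine gaps, BLAST-like defaults), six-frame translated piPolB search, att/tRNA detection, in-silico PCR |
| `reconstruct` | att role assignment, contig ordering/orientation, scaffolding with `assembly_gap` features, structure classification |
| `pangenome` | core / soft-core (95–99%) / shell (15–95%) / cloud (<15%) partition with exact band arithmetic; greedy gene clustering; percentage-reporting conventions |
| `cophylogeny` | cophenetic (patristic) distances, CCC, PCoA, PACo Procrustes global fit `m²_XY` with permutation test, jackknifed per-link residuals, tanglegram export |
| `reporting` | prevalence/contingency tables (half-up, 1 decimal), cohort orchestration, YAML config with provenance |
| `cli` | `pipolin-scout simulate|find|scaffold|pangenome|cophylo|report|run` |

The key statistics, in standard notation: the CCC is the Pearson
correlation of the matched lower-triangle entries of two trees'
cophenetic distance matrices; PACo superimposes the principal-coordinate
ordinations X (hosts) and Y (elements) by least-squares Procrustes
(translation, rotation, uniform scaling) and reports the residual sum of
squares `m²_XY = Σᵢ ‖xᵢ − ŷᵢ‖²`, small when the host tree predicts the
element tree, with significance from permuting the host–element link
assignment: `p = (1 + #{m²_perm ≤ m²_obs}) / (N_perm + 1)`.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data; each prints what it finds and writes tables under `results/`.

```bash
python analysis/01_simulate_cohort.py     # 20 assemblies, 5 with pipolins
python analysis/02_screen_and_reconstruct.py
```

The screen recovers exactly the planted elements:

```json
{
  "n_genomes": 20,
  "n_pipolin_positive": 5,
  "prevalence_percent": "25.0",
  "structure_classes": { "complete_single_contig": 5 }
}
```

`results/screen/<genome>/` then holds each reconstructed element as
FASTA + GFF3 (features `att` with its role, `piPolB`, `tRNA`, `CDS`,
`assembly_gap`) and a JSON summary with fragment provenance.

```bash
python analysis/03_pangenome_partition.py
```

partitions a 26-genome matrix with the host cohort's published
composition and prints core `29.45`% and cloud `45.13`% of 10,178 genes
(truncate-to-2-decimals convention), plus the combined-dataset cloud
fraction `67`% and the element-pangenome cloud fraction `85`%.

```bash
python analysis/04_cophylogeny.py
```

sweeps the congruence dial (leaf-label swaps applied to the element
tree) and shows congruence decaying:

```
 n_swaps  mean_ccc      mean_m2  median_p  mean_crossings
       0  1.000000 1.234705e-30    0.0010            0.00
       2  0.584894 9.715524e-01    0.0040           11.40
       8  0.083990 1.810445e+00    0.2675           17.80
      16 -0.007302 1.421746e+00    0.4950           17.45
```

With no swaps the trees are identical: `m² ≈ 0` and the permutation test
rejects the null at p = 0.001.  By 16 swaps the element tree no longer
tracks the host tree — CCC near 0 and p ≈ 0.5, the signature expected
under free horizontal exchange.  The script also plants a single host
switch among 10 congruent links and shows the two swapped links carrying
the largest jackknifed squared residuals.

```bash
python analysis/05_prevalence_table.py
```

recomputes a screening survey's percentages from its stratum counts
(half-up, 1 decimal; marginals summed from counts before dividing):
1.3 / 0.8 / 1.5 / 1.2 per stratum, 1.4 intestinal, 0.9 extraintestinal,
1.1 overall.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end from the given seed: it simulates a
fragmented cohort, screens it by in-silico PCR and translated search,
scaffolds every positive genome, partitions a prescribed pangenome
matrix, and runs CCC/PACo with a permutation test and jackknife on a
generated tree pair, printing a JSON summary of everything it measured.

## Limits

Desk-scale by design: alignment is exact (no k-mer seeding), so
searches are meant for references of ~10²–10³ residues against
assemblies of ~10⁴–10⁵ nt.  No gene re-annotation, no prophage calling,
no tree inference — trees are consumed, not built.  See
`docs/methods.md` for the model, defaults and numerical choices.
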