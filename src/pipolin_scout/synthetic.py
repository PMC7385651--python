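"""Synthetic worlds for exercising the pipeline without downloads.

Four generators, all pure functions of their seeds:

* genomes carrying a pipolin (piPolB gene bounded by direct att repeats)
  integrated at a tRNA locus, with the right-hand repeat overlapping the
  tRNA on the opposite strand — optionally with a third att and a
  cohabiting prophage block;
* assembly fragmentation that splits such a genome across contigs with
  random orientations, with a truth channel sufficient to reconstruct
  the unfragmented genome exactly;
* leaf-matched tree pairs whose topological congruence is dialled by
  random leaf-label swaps;
* gene presence/absence matrices with prescribed pangenome-category
  proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import FeatureHit, GenomeAssembly, revcomp
from .pangenome import PresenceAbsenceMatrix, occupancy_bands

__all__ = [
    "PipolinTemplate",
    "TruthAnnotation",
    "TreePairConfig",
    "generate_pipolin_genome",
    "fragment_assembly",
    "generate_tree_pair",
    "generate_presence_absence",
    "reconstruct_from_fragment_map",
    "random_cds",
    "random_dna",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx].tobytes().decode()


def random_cds(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence: ATG start, sense codons, no internal stops."""
    if length % 3 != 0 or length < 6:
        raise ValueError("CDS length must be a multiple of 3 and >= 6")
    n_codons = length // 3 - 1
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    return "ATG" + body


@dataclass
class PipolinTemplate:
    """Blueprint of one pipolin and its integration site.

    The rendered element is ``attL .. piPolB .. [cargo ..] .. attR`` with
    the atts as exact direct repeats; the attR tail is shared with the
    start of a tRNA gene lying on the opposite strand, so that attR and
    the tRNA interval overlap by ``trna_overlap`` bases, as at the
    conserved Leu-tRNA integration point.  With ``has_third_att`` a third
    att copy and an optional prophage block sit between the cargo and
    attR, emulating prophage-cohabiting elements.
    """

    att_seq: str
    pipolb_cds: str
    cargo_cds: list[str]
    trna_seq: str
    has_third_att: bool = False
    prophage_block: Optional[str] = None
    seed: int = 0
    spacer_length: int = 300
    trna_overlap: int = 15

    def __post_init__(self) -> None:
        if len(self.pipolb_cds) % 3 != 0:
            raise ValueError("piPolB CDS length must be divisible by 3")
        for i in range(3, len(self.pipolb_cds) - 3, 3):
            if self.pipolb_cds[i:i + 3] in _STOPS:
                raise ValueError("piPolB CDS contains an internal stop codon")
        if not (0 < self.trna_overlap < min(len(self.att_seq), len(self.trna_seq))):
            raise ValueError("trna_overlap must fit inside both att and tRNA")
        # couple attR tail to the tRNA so that the genomic segment under the
        # tRNA interval reads the tRNA on the '-' strand while the att stays
        # an exact direct repeat
        tail = revcomp(self.trna_seq)[: self.trna_overlap]
        self.att_seq = self.att_seq[: len(self.att_seq) - self.trna_overlap] + tail

    @classmethod
    def from_seed(
        cls,
        seed: int,
        att_length: int = 100,
        pipolb_length: int = 1200,
        n_cargo: int = 2,
        cargo_length: int = 600,
        trna_length: int = 85,
        has_third_att: bool = False,
        prophage_length: int = 2000,
        spacer_length: int = 300,
        gc: float = 0.5,
    ) -> "PipolinTemplate":
        # domain-tagged seed sequence: keeps this stream disjoint from the
        # genome/fragmentation streams even when the same integer seed is
        # passed everywhere
        rng = np.random.default_rng([0x7E11, seed])
        return cls(
            att_seq=random_dna(rng, att_length, gc),
            pipolb_cds=random_cds(rng, pipolb_length),
            cargo_cds=[random_cds(rng, cargo_length) for _ in range(n_cargo)],
            trna_seq=random_dna(rng, trna_length, gc),
            has_third_att=has_third_att,
            prophage_block=random_dna(rng, prophage_length, gc) if has_third_att else None,
            seed=seed,
        )

    @property
    def pipolb_protein(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.pipolb_cds).translate())

    def render(self, rng: np.random.Generator) -> tuple[str, list[tuple[str, int, int, str]]]:
        """Render the full insert (element + tRNA tail beyond attR).

        Returns (sequence, features) with features as
        (feature_type, start, end, strand) relative to the insert.
        """
        parts: list[str] = []
        feats: list[tuple[str, int, int, str]] = []
        pos = 0

        def add(seq: str, ftype: Optional[str] = None, strand: str = "+") -> None:
            nonlocal pos
            if ftype:
                feats.append((ftype, pos, pos + len(seq), strand))
            parts.append(seq)
            pos += len(seq)

        spacer = lambda: add(random_dna(rng, self.spacer_length))
        add(self.att_seq, "att")
        spacer()
        add(self.pipolb_cds, "piPolB")
        for cds in self.cargo_cds:
            spacer()
            add(cds, "CDS")
        if self.has_third_att:
            spacer()
            add(self.att_seq, "att")
            if self.prophage_block:
                spacer()
                add(self.prophage_block, "prophage")
        spacer()
        attr_start = pos
        add(self.att_seq, "att")
        # tRNA: starts trna_overlap before attR end, runs on '-' strand
        trna_start = pos - self.trna_overlap
        trna_tail = revcomp(self.trna_seq)[self.trna_overlap:]
        add(trna_tail)
        feats.append(("tRNA", trna_start, trna_start + len(self.trna_seq), "-"))
        assert trna_start + len(self.trna_seq) == pos
        assert attr_start < trna_start < attr_start + len(self.att_seq)
        return "".join(parts), feats


@dataclass
class TruthAnnotation:
    """Ground-truth channel: planted features plus the fragmentation map.

    ``fragment_map`` lists (contig_id, source_start, source_end, flipped)
    in source order; undoing flips and concatenating in that order
    reconstructs the unfragmented genome exactly.
    """

    features: list[FeatureHit] = field(default_factory=list)
    fragment_map: list[tuple[str, int, int, bool]] = field(default_factory=list)

    def of_type(self, ftype: str) -> list[FeatureHit]:
        return [f for f in self.features if f.feature_type == ftype]


class SizingError(ValueError):
    """Genome too short for the requested element."""


def generate_pipolin_genome(
    template: PipolinTemplate,
    genome_length: int = 50_000,
    rng_seed: int = 0,
    margin: int = 1000,
    gc: float = 0.5,
) -> tuple[GenomeAssembly, TruthAnnotation]:
    """One circular-free contig of random background of ``genome_length``
    bases with the rendered pipolin (plus its tRNA tail) inserted at a
    uniformly chosen position at least ``margin`` from either end.  Final
    contig length = genome_length + rendered insert length."""
    rng = np.random.default_rng([0x6E0, template.seed, rng_seed])
    insert, feats = template.render(rng)
    if genome_length <= len(insert) + 2 * margin:
        raise SizingError(
            f"genome_length {genome_length} too short for element of "
            f"{len(insert)} nt plus 2x margin {margin}"
        )
    background = random_dna(rng, genome_length, gc)
    pos = int(rng.integers(margin, genome_length - margin))
    seq = background[:pos] + insert + background[pos:]
    gid = f"genome_s{template.seed}_{rng_seed}"
    cid = f"{gid}_c0"
    assembly = GenomeAssembly(genome_id=gid, contigs={cid: seq})
    truth = TruthAnnotation(
        features=[
            FeatureHit(
                query_id=ftype, contig_id=cid, start=pos + s, end=pos + e,
                strand=strand, feature_type=ftype,
            )
            for ftype, s, e, strand in feats
        ],
        fragment_map=[(cid, 0, len(seq), False)],
    )
    return assembly, truth


def _map_interval(
    s: int, e: int, frag_s: int, frag_e: int, flipped: bool
) -> Optional[tuple[int, int]]:
    """Map source interval [s,e) into a fragment's contig coordinates;
    None if disjoint. Partially overlapping features are clipped."""
    a, b = max(s, frag_s), min(e, frag_e)
    if a >= b:
        return None
    if flipped:
        return frag_e - b, frag_e - a
    return a - frag_s, b - frag_s


def fragment_assembly(
    genome: GenomeAssembly,
    truth: TruthAnnotation,
    n_breaks: int,
    rng_seed: int = 0,
    flip_prob: float = 0.0,
    exclusion_margin: int = 0,
    breakpoints: Optional[list[int]] = None,
) -> tuple[GenomeAssembly, TruthAnnotation]:
    """Break a single-contig genome into contigs at random points, then
    reverse-complement each contig independently with probability
    ``flip_prob`` and shuffle contig order (assembler output order and
    orientation are arbitrary).

    With ``exclusion_margin`` > 0, breakpoints avoid every truth feature
    expanded by the margin on both sides; with the default 0 features may
    be split (split features appear clipped on each contig).  Explicit
    ``breakpoints`` override random sampling (n_breaks is then ignored).
    """
    if len(genome.contigs) != 1:
        raise ValueError("fragment_assembly expects a single-contig genome")
    (src_cid, seq), = genome.contigs.items()
    L = len(seq)
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    if n_breaks >= L:
        raise ValueError("n_breaks must be smaller than the genome length")
    rng = np.random.default_rng([0xF8A6, rng_seed])

    if breakpoints is not None:
        if any(not 0 < b < L for b in breakpoints):
            raise ValueError("breakpoints must lie strictly inside the genome")
        breaks = np.sort(np.unique(breakpoints))
    else:
        candidates = np.arange(1, L)
        if exclusion_margin > 0:
            mask = np.ones(L - 1, dtype=bool)
            for f in truth.features:
                lo = max(0, f.start - exclusion_margin)
                hi = min(L - 1, f.end + exclusion_margin)
                mask[lo:hi] = False
            candidates = candidates[mask[candidates - 1]]
            if len(candidates) < n_breaks:
                raise ValueError("not enough breakpoint positions outside exclusion zones")
        breaks = (np.sort(rng.choice(candidates, size=n_breaks, replace=False))
                  if n_breaks else np.empty(0, int))
    bounds = [0, *breaks.tolist(), L]

    fragment_map: list[tuple[str, int, int, bool]] = []
    contig_seqs: dict[str, str] = {}
    for i in range(len(bounds) - 1):
        fs, fe = bounds[i], bounds[i + 1]
        flipped = bool(rng.random() < flip_prob)
        cid = f"{genome.genome_id}_frag{i}"
        piece = seq[fs:fe]
        contig_seqs[cid] = revcomp(piece) if flipped else piece
        fragment_map.append((cid, fs, fe, flipped))

    order = rng.permutation(len(fragment_map))
    contigs = {fragment_map[i][0]: contig_seqs[fragment_map[i][0]] for i in order}

    new_features: list[FeatureHit] = []
    for f in truth.features:
        for cid, fs, fe, flipped in fragment_map:
            mapped = _map_interval(f.start, f.end, fs, fe, flipped)
            if mapped is None:
                continue
            strand = f.strand
            if flipped:
                strand = "-" if strand == "+" else "+"
            new_features.append(
                f.moved(contig_id=cid, start=mapped[0], end=mapped[1], strand=strand)
            )
    assembly = GenomeAssembly(genome_id=genome.genome_id, contigs=contigs)
    return assembly, TruthAnnotation(features=new_features, fragment_map=fragment_map)


def reconstruct_from_fragment_map(
    assembly: GenomeAssembly, fragment_map: list[tuple[str, int, int, bool]]
) -> str:
    """Undo flips and concatenate fragments in source order."""
    parts = []
    for cid, _fs, _fe, flipped in fragment_map:
        s = assembly.contigs[cid]
        parts.append(revcomp(s) if flipped else s)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Tree pairs with a congruence dial
# ---------------------------------------------------------------------------

@dataclass
class TreePairConfig:
    """Host/element tree pair: the element tree copies the host topology
    and then applies ``n_swaps`` random leaf-label transpositions, so
    n_swaps = 0 gives perfectly congruent trees and large n_swaps
    approaches a random leaf permutation."""

    n_leaves: int
    n_swaps: int = 0
    branch_length_mean: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")
        if self.branch_length_mean <= 0:
            raise ValueError("branch_length_mean must be positive")


def _random_topology(labels: list[str], rng: np.random.Generator, mean: float) -> str:
    """Random binary topology by repeated random joins; exponential branch
    lengths."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.exponential(mean, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


def generate_tree_pair(cfg: TreePairConfig) -> tuple[str, str, dict[str, str]]:
    """Returns (host_newick, element_newick, association host->element)."""
    rng = np.random.default_rng(cfg.seed)
    hosts = [f"H{i}" for i in range(cfg.n_leaves)]
    elements = [f"P{i}" for i in range(cfg.n_leaves)]
    host_nwk = _random_topology(hosts, rng, cfg.branch_length_mean)
    # element tree: same labelled shape, host labels renamed to element
    # labels, then swap labels pairwise n_swaps times
    perm = list(range(cfg.n_leaves))
    for _ in range(cfg.n_swaps):
        i, j = rng.choice(cfg.n_leaves, size=2, replace=False)
        perm[i], perm[j] = perm[j], perm[i]
    elem_nwk = host_nwk
    # two-phase rename to avoid collisions (H_i are unique tokens)
    for i, h in enumerate(hosts):
        elem_nwk = elem_nwk.replace(f"{h}:", f"@@{i}:")
    for i in range(cfg.n_leaves):
        elem_nwk = elem_nwk.replace(f"@@{i}:", f"{elements[perm[i]]}:")
    association = dict(zip(hosts, elements))
    return host_nwk, elem_nwk, association


# ---------------------------------------------------------------------------
# Presence/absence matrices with prescribed category structure
# ---------------------------------------------------------------------------

def _largest_remainder(fractions: tuple[float, ...], total: int) -> list[int]:
    ideal = [f * total for f in fractions]
    base = [math.floor(x) for x in ideal]
    rem = total - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: ideal[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def generate_presence_absence(
    n_genomes: int,
    category_fractions: tuple[float, float, float, float],
    n_genes: int,
    rng_seed: int = 0,
) -> PresenceAbsenceMatrix:
    """Gene x genome boolean matrix whose rows fall into the core /
    soft-core / shell / cloud occupancy bands in the requested
    proportions (largest-remainder rounding of fractions to counts).
    Each gene's occupancy is drawn uniformly within its band."""
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if any(f < 0 for f in category_fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(category_fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    counts = _largest_remainder(tuple(category_fractions), n_genes)
    bands = occupancy_bands(n_genomes)
    rows = np.zeros((n_genes, n_genomes), dtype=bool)
    gene_ids = []
    g = 0
    for cat, n_cat in zip(("core", "soft_core", "shell", "cloud"), counts):
        lo, hi = bands[cat]
        if n_cat > 0 and lo > hi:
            raise ValueError(
                f"category {cat!r} has no feasible occupancy count with "
                f"{n_genomes} genomes"
            )
        for _ in range(n_cat):
            k = int(rng.integers(lo, hi + 1))
            present = rng.choice(n_genomes, size=k, replace=False)
            rows[g, present] = True
            gene_ids.append(f"{cat}_{g:05d}")
            g += 1
    genome_ids = [f"G{i:03d}" for i in range(n_genomes)]
    return PresenceAbsenceMatrix(gene_cluster_ids=gene_ids,
                                 genome_ids=genome_ids, matrix=rows)
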