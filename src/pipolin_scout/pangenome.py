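"""Pangenome partitioning over a gene presence/absence matrix.

The partition follows the Roary occupancy bands, with f the fraction of
genomes a gene cluster occurs in:

* core:       f >= 0.99
* soft-core:  0.95 <= f < 0.99
* shell:      0.15 <= f < 0.95
* cloud:      f < 0.15

Band comparisons are exact (integer arithmetic on counts), so boundary
genes never drift with floating-point rounding.  A greedy single-linkage
clusterer over protein sequences stands in for a full pangenome pipeline
to produce the matrix from annotated proteomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .seqsearch import ScoringScheme, local_align_protein

__all__ = [
    "PresenceAbsenceMatrix",
    "PangenomeSummary",
    "Thresholds",
    "occupancy_bands",
    "categorize_pangenome",
    "cluster_genes",
    "report_percent",
]

CATEGORIES = ("core", "soft_core", "shell", "cloud")


@dataclass(frozen=True)
class Thresholds:
    core: Fraction = Fraction(99, 100)
    soft_core: Fraction = Fraction(95, 100)
    shell: Fraction = Fraction(15, 100)


DEFAULT_THRESHOLDS = Thresholds()


def occupancy_bands(
    n_genomes: int, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict[str, tuple[int, int]]:
    """Integer occupancy-count range [lo, hi] per category for a cohort of
    ``n_genomes`` (a gene present in 0 genomes is not representable)."""

    def ceil_frac(t: Fraction) -> int:
        return -((-t.numerator * n_genomes) // t.denominator)

    c, s, sh = (ceil_frac(getattr(thresholds, k)) for k in ("core", "soft_core", "shell"))
    return {
        "core": (c, n_genomes),
        "soft_core": (s, c - 1),
        "shell": (sh, s - 1),
        "cloud": (1, sh - 1),
    }


@dataclass
class PresenceAbsenceMatrix:
    """Boolean gene-cluster x genome matrix."""

    gene_cluster_ids: list[str]
    genome_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.gene_cluster_ids), len(self.genome_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("genome_ids must be unique")
        if len(self.genome_ids) < 2:
            raise ValueError("need at least 2 genomes")
        if self.matrix.size and not self.matrix.any(axis=1).all():
            raise ValueError("matrix contains an all-absent gene row")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_cluster_ids)

    def occupancy(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_cluster_ids,
                            columns=self.genome_ids)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        """Read a Roary-compatible gene_presence_absence table: a 'Gene'
        column plus one column per genome (non-empty cell = present).
        Roary's extra metadata columns, if present, are ignored."""
        df = pd.read_csv(path)
        if "Gene" not in df.columns:
            raise ValueError("expected a 'Gene' column")
        meta = {
            "Gene", "Non-unique Gene name", "Annotation", "No. isolates",
            "No. sequences", "Avg sequences per isolate", "Genome Fragment",
            "Order within Fragment", "Accessory Fragment",
            "Accessory Order with Fragment", "QC", "Min group size nuc",
            "Max group size nuc", "Avg group size nuc",
        }
        genome_cols = [c for c in df.columns if c not in meta]
        mat = df[genome_cols].notna().to_numpy()
        return cls(df["Gene"].astype(str).tolist(), genome_cols, mat)


@dataclass
class PangenomeSummary:
    counts: dict[str, int]
    total: int
    occupancy_fractions: np.ndarray
    thresholds: Thresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must sum to total")

    def rule(self) -> str:
        t = self.thresholds
        return (
            f"core f>={float(t.core)}; soft_core {float(t.soft_core)}<=f<{float(t.core)}; "
            f"shell {float(t.shell)}<=f<{float(t.soft_core)}; cloud f<{float(t.shell)}"
        )


def categorize_pangenome(
    matrix: PresenceAbsenceMatrix, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> PangenomeSummary:
    """Partition genes into core / soft-core / shell / cloud by occupancy.

    Comparisons are exact: a gene in c of n genomes is core iff
    c * den(core) >= num(core) * n, etc."""
    n = matrix.n_genomes
    occ = matrix.occupancy().astype(np.int64)

    def at_least(t: Fraction) -> np.ndarray:
        return occ * t.denominator >= t.numerator * n

    is_core = at_least(thresholds.core)
    is_soft = at_least(thresholds.soft_core) & ~is_core
    is_shell = at_least(thresholds.shell) & ~is_core & ~is_soft
    is_cloud = ~(is_core | is_soft | is_shell)
    counts = {
        "core": int(is_core.sum()),
        "soft_core": int(is_soft.sum()),
        "shell": int(is_shell.sum()),
        "cloud": int(is_cloud.sum()),
    }
    return PangenomeSummary(
        counts=counts,
        total=matrix.n_genes,
        occupancy_fractions=occ / n,
        thresholds=thresholds,
    )


def cluster_genes(
    protein_sets: dict[str, list[str]],
    identity_threshold: float = 95.0,
    min_coverage: float = 0.8,
    scoring: Optional[ScoringScheme] = None,
) -> PresenceAbsenceMatrix:
    """Greedy incremental clustering of protein sequences into gene
    clusters (a simplified stand-in for a full pangenome clusterer).

    Sequences are taken longest-first; each joins the first existing
    cluster whose representative aligns at >= ``identity_threshold``
    percent identity over >= ``min_coverage`` of the shorter sequence,
    otherwise it founds a new cluster."""
    if len(protein_sets) < 2:
        raise ValueError("need proteins from at least 2 genomes")
    if not any(protein_sets.values()):
        raise ValueError("no protein sequences supplied")
    scoring = scoring or ScoringScheme.protein()
    entries = [
        (seq.upper(), gid)
        for gid, seqs in protein_sets.items()
        for seq in seqs
    ]
    entries.sort(key=lambda t: (-len(t[0]), t[0], t[1]))
    reps: list[str] = []
    members: list[set[str]] = []
    for seq, gid in entries:
        placed = False
        for k, rep in enumerate(reps):
            shorter = min(len(seq), len(rep))
            aln = local_align_protein(seq, rep, scoring)
            if aln is None:
                continue
            cov = min(aln.query_end - aln.query_start,
                      aln.target_end - aln.target_start) / shorter
            if aln.identity >= identity_threshold and cov >= min_coverage:
                members[k].add(gid)
                placed = True
                break
        if not placed:
            reps.append(seq)
            members.append({gid})
    genome_ids = sorted(protein_sets)
    mat = np.zeros((len(reps), len(genome_ids)), dtype=bool)
    col = {g: j for j, g in enumerate(genome_ids)}
    for i, mset in enumerate(members):
        for g in mset:
            mat[i, col[g]] = True
    ids = [f"cluster_{i:05d}" for i in range(len(reps))]
    return PresenceAbsenceMatrix(ids, genome_ids, mat)


def report_percent(count: int, total: int, mode: str = "truncate2") -> str:
    """Format 100*count/total under one of the reporting conventions used
    for pangenome and prevalence figures.

    * ``truncate2`` — floor to 2 decimals (29.4557% -> "29.45")
    * ``round1`` — half-up to 1 decimal
    * ``round0`` — half-up to the nearest integer
    """
    from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal

    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(count) * 100 / Decimal(total)
    if mode == "truncate2":
        return str(pct.quantize(Decimal("0.01"), rounding=ROUND_FLOOR))
    if mode == "round1":
        return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    if mode == "round0":
        return str(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    raise ValueError(f"unknown mode {mode!r}")
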