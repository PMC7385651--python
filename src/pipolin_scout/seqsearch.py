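"""Local-alignment search primitives.

BLAST-style homology detection is replaced here by exact Smith-Waterman
local alignment with affine gap costs (Gotoh), computed by Biopython's
``PairwiseAligner``.  Default scoring mirrors the BLAST defaults: DNA
match +2 / mismatch -3, gap open 5 / extend 2; protein BLOSUM62 with gap
open 11 / extend 1 (a gap of length k costs open + k*extend).

Four searches are built on this primitive:

* :func:`translated_search` — six-frame translated search of a protein
  query (the piPolB hallmark gene) against an assembly, admitting
  truncated gene fragments via a coverage floor.
* :func:`find_att_repeats` — all non-overlapping nucleotide matches of a
  reference att direct repeat.
* :func:`find_trna` — tRNA loci from a reference sequence or from an
  existing GFF3 annotation.
* :func:`in_silico_pcr` — primer-pair amplicon prediction.

Hit coordinates always index the forward strand of the contig; for a hit
on the '-' strand the matched sequence is the reverse complement of the
reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import FeatureHit, GenomeAssembly, revcomp

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "local_align_dna",
    "local_align_protein",
    "translated_search",
    "find_att_repeats",
    "find_trna",
    "in_silico_pcr",
    "Amplicon",
]


def _dna_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    # N never matches anything, including N
    for x in "ACGTN":
        m["N", x] = mismatch
        m[x, "N"] = mismatch
    return m


@dataclass
class ScoringScheme:
    """Affine-gap scoring. Gap penalties are magnitudes (>= 0); a gap of
    length k costs ``gap_open + k * gap_extend``."""

    kind: str = "dna"  # 'dna' or 'protein'
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.kind not in {"dna", "protein"}:
            raise ValueError("kind must be 'dna' or 'protein'")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.kind == "dna" and self.match <= 0:
            raise ValueError("match score must be positive")

    @classmethod
    def dna(cls, **kw) -> "ScoringScheme":
        return cls(kind="dna", **kw)

    @classmethod
    def protein(cls, matrix_name: str = "BLOSUM62", gap_open: float = 11.0,
                gap_extend: float = 1.0) -> "ScoringScheme":
        return cls(kind="protein", matrix_name=matrix_name,
                   gap_open=gap_open, gap_extend=gap_extend)

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner(mode="local")
        if self.kind == "dna":
            al.substitution_matrix = _dna_matrix(self.match, self.mismatch)
        else:
            al.substitution_matrix = substitution_matrices.load(self.matrix_name)
        # first gap residue pays open + extend so a k-gap costs open + k*extend
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@dataclass
class LocalAlignment:
    """Best local alignment of query against target."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float          # matches / alignment columns * 100
    n_columns: int
    n_identities: int


def _best_local(query: str, target: str, aligner: Align.PairwiseAligner
                ) -> Optional[LocalAlignment]:
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    score = aligner.score(target, query)
    if score <= 0:
        return None
    aln = aligner.align(target, query)[0]
    c = aln.counts()
    ncols = c.identities + c.mismatches + c.internal_gaps
    tblocks, qblocks = aln.aligned
    return LocalAlignment(
        score=float(score),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        target_start=int(tblocks[0][0]),
        target_end=int(tblocks[-1][1]),
        identity=100.0 * c.identities / ncols if ncols else 0.0,
        n_columns=int(ncols),
        n_identities=int(c.identities),
    )


def local_align_dna(query: str, target: str,
                    scoring: Optional[ScoringScheme] = None
                    ) -> Optional[LocalAlignment]:
    """Optimal Smith-Waterman local DNA alignment; None if no positive-score
    alignment exists (reported downstream as a no-hit)."""
    scoring = scoring or ScoringScheme.dna()
    if scoring.kind != "dna":
        raise ValueError("local_align_dna requires a DNA scoring scheme")
    return _best_local(query.upper(), target.upper(), scoring.aligner())


def local_align_protein(query: str, target: str,
                        scoring: Optional[ScoringScheme] = None
                        ) -> Optional[LocalAlignment]:
    scoring = scoring or ScoringScheme.protein()
    if scoring.kind != "protein":
        raise ValueError("local_align_protein requires a protein scoring scheme")
    return _best_local(query.upper(), target.upper(), scoring.aligner())


# ---------------------------------------------------------------------------
# Translated (six-frame) search
# ---------------------------------------------------------------------------

def _frame_segments(seq: str, frame: int) -> list[tuple[int, str]]:
    """Translate one frame, split at stop codons.

    Returns (aa_offset, peptide) pairs where aa_offset is the 0-based
    amino-acid position of the segment start within the frame.
    """
    trimmed = seq[frame:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return []
    aa = str(Seq(trimmed).translate())
    segments = []
    pos = 0
    for part in aa.split("*"):
        if part:
            segments.append((pos, part))
        pos += len(part) + 1
    return segments


def translated_search(
    protein_query: str,
    assembly: GenomeAssembly,
    scoring: Optional[ScoringScheme] = None,
    min_identity: float = 85.0,
    min_coverage: float = 0.3,
    query_id: str = "piPolB",
) -> list[FeatureHit]:
    """Six-frame translated search of a protein query against an assembly.

    Frames are broken into ORF-like segments at stop codons; each segment
    is locally aligned against the query.  A hit must reach
    ``min_identity`` percent amino-acid identity and cover at least
    ``min_coverage`` of the query (the low default admits truncated gene
    fragments).  Coordinates are nucleotide intervals on the forward
    strand.
    """
    if not protein_query:
        raise ValueError("protein query must be non-empty")
    if not assembly.contigs:
        raise ValueError("assembly has no contigs")
    scoring = scoring or ScoringScheme.protein()
    aligner = scoring.aligner()
    query = protein_query.upper()
    qlen = len(query)
    raw: list[FeatureHit] = []
    for cid, contig in assembly.contigs.items():
        L = len(contig)
        for strand, seq in (("+", contig), ("-", revcomp(contig))):
            for frame in range(3):
                for aa_off, peptide in _frame_segments(seq, frame):
                    if len(peptide) < max(10, int(min_coverage * qlen * 0.5)):
                        continue
                    aln = _best_local(query, peptide, aligner)
                    if aln is None:
                        continue
                    coverage = (aln.query_end - aln.query_start) / qlen
                    if aln.identity < min_identity or coverage < min_coverage:
                        continue
                    # map back to nucleotide coords on this strand
                    nt_s = frame + 3 * (aa_off + aln.target_start)
                    nt_e = frame + 3 * (aa_off + aln.target_end)
                    if strand == "-":
                        nt_s, nt_e = L - nt_e, L - nt_s
                    raw.append(
                        FeatureHit(
                            query_id=query_id,
                            contig_id=cid,
                            start=nt_s,
                            end=nt_e,
                            strand=strand,
                            percent_identity=aln.identity,
                            aligned_length=aln.n_columns,
                            score=aln.score,
                            frame=frame,
                            feature_type="piPolB",
                        )
                    )
    return _greedy_nonoverlap(raw)


def _greedy_nonoverlap(hits: list[FeatureHit]) -> list[FeatureHit]:
    """Resolve overlapping hits greedily by score; ties broken by leftmost
    start, then '+' strand."""
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.strand != "+"))
    kept: list[FeatureHit] = []
    for h in ordered:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig_id, h.start))
    return kept


# ---------------------------------------------------------------------------
# att repeat search
# ---------------------------------------------------------------------------

def _iterative_hits(
    reference: str,
    contig_id: str,
    contig: str,
    scoring: ScoringScheme,
    min_identity: float,
    min_target_span: int,
    query_id: str,
    feature_type: str,
    max_hits: int = 50,
) -> list[FeatureHit]:
    """Repeated best-hit extraction with masking: find the best local hit on
    either strand, record it if above thresholds, replace its bases by N
    (N never matches), repeat."""
    aligner = scoring.aligner()
    work = contig
    rc_ref = revcomp(reference)
    hits: list[FeatureHit] = []
    for _ in range(max_hits):
        fwd = _best_local(reference, work, aligner)
        rev = _best_local(rc_ref, work, aligner)
        best, strand = fwd, "+"
        if rev is not None and (fwd is None or rev.score > fwd.score):
            best, strand = rev, "-"
        if best is None:
            break
        span = best.target_end - best.target_start
        if best.identity < min_identity or span < min_target_span:
            break
        hits.append(
            FeatureHit(
                query_id=query_id,
                contig_id=contig_id,
                start=best.target_start,
                end=best.target_end,
                strand=strand,
                percent_identity=best.identity,
                aligned_length=best.n_columns,
                score=best.score,
                feature_type=feature_type,
            )
        )
        work = work[: best.target_start] + "N" * span + work[best.target_end:]
    hits.sort(key=lambda h: h.start)
    return hits


def find_att_repeats(
    assembly: GenomeAssembly,
    reference_att: str,
    min_identity: float = 85.0,
    min_length_fraction: float = 0.8,
    scoring: Optional[ScoringScheme] = None,
) -> list[FeatureHit]:
    """All non-overlapping local matches of a reference att direct repeat,
    each with its strand. Defaults: identity >= 85%, matched span >= 0.8 x
    reference length."""
    if not reference_att:
        raise ValueError("reference att must be non-empty")
    scoring = scoring or ScoringScheme.dna()
    min_span = int(np.ceil(min_length_fraction * len(reference_att)))
    out: list[FeatureHit] = []
    for cid, contig in assembly.contigs.items():
        out.extend(
            _iterative_hits(
                reference_att.upper(), cid, contig, scoring,
                min_identity, min_span, "att", "att",
            )
        )
    return out


def find_trna(
    assembly: GenomeAssembly,
    trna_reference: Optional[str] = None,
    annotations: Optional[Sequence[FeatureHit]] = None,
    min_identity: float = 90.0,
    min_length_fraction: float = 0.9,
    scoring: Optional[ScoringScheme] = None,
) -> list[FeatureHit]:
    """tRNA loci, either passed through from GFF3-derived annotations or
    found by alignment against a reference tRNA sequence.

    Exactly one of ``trna_reference`` / ``annotations`` must be given.
    """
    if (trna_reference is None) == (annotations is None):
        raise ValueError("provide exactly one of trna_reference or annotations")
    if annotations is not None:
        out = []
        for a in annotations:
            if a.contig_id not in assembly.contigs:
                raise ValueError(f"annotation contig {a.contig_id!r} not in assembly")
            out.append(a.moved(feature_type="tRNA"))
        return out
    scoring = scoring or ScoringScheme.dna()
    min_span = int(np.ceil(min_length_fraction * len(trna_reference)))
    out = []
    for cid, contig in assembly.contigs.items():
        out.extend(
            _iterative_hits(
                trna_reference.upper(), cid, contig, scoring,
                min_identity, min_span, "tRNA", "tRNA",
            )
        )
    return out


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass
class Amplicon:
    contig_id: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _primer_sites(seq: str, primer: str, max_mismatches: int) -> np.ndarray:
    """Start positions where primer binds with <= max_mismatches. Template N
    never counts as a match."""
    n, k = len(seq), len(primer)
    if k > n:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    prim = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    mm = ((windows != prim) | (windows == ord("N"))).sum(axis=1)
    return np.flatnonzero(mm <= max_mismatches)


def in_silico_pcr(
    assembly: GenomeAssembly,
    fw_primer: str,
    rv_primer: str,
    max_mismatches: int = 0,
    max_amplicon: int = 5000,
) -> list[Amplicon]:
    """Predict PCR products: a forward-primer site followed downstream on
    the same strand by the reverse complement of the reverse primer, within
    ``max_amplicon``.  Both strands are searched; for each forward site the
    nearest compatible reverse site is reported (the dominant product).
    Amplicon length includes both primers; coordinates index the forward
    strand."""
    fw, rv = fw_primer.upper(), rv_primer.upper()
    if not fw or not rv:
        raise ValueError("primers must be non-empty")
    if max_amplicon <= len(fw) + len(rv):
        raise ValueError("max_amplicon must exceed the summed primer lengths")
    out: list[Amplicon] = []
    for cid, contig in assembly.contigs.items():
        L = len(contig)
        for strand, seq in (("+", contig), ("-", revcomp(contig))):
            fw_sites = _primer_sites(seq, fw, max_mismatches)
            rv_sites = _primer_sites(seq, revcomp(rv), max_mismatches)
            for f in fw_sites:
                # nearest reverse site whose product fits the size window
                ends = rv_sites[rv_sites >= f + len(fw) - len(rv)] + len(rv)
                ends = ends[(ends > f + len(fw)) & (ends - f <= max_amplicon)]
                if ends.size == 0:
                    continue
                e = int(ends.min())
                s = int(f)
                if strand == "-":
                    s, e = L - e, L - s
                out.append(Amplicon(cid, s, e, strand))
    out.sort(key=lambda a: (a.contig_id, a.start, a.strand))
    return out
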