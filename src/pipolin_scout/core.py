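"""Shared sequence containers and flat-file I/O.

All coordinates in this package are 0-based half-open on the forward
strand of the contig they refer to; GFF3 emission converts to the
1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Raised for malformed sequences or assemblies."""


@dataclass
class GenomeAssembly:
    """One strain's (draft) genome: an ordered set of named contigs.

    Sequences are uppercase-normalized on construction and must be
    non-empty strings over {A, C, G, T, N}.
    """

    genome_id: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SequenceError(f"assembly {self.genome_id!r} has no contigs")
        normalized: dict[str, str] = {}
        for cid, seq in self.contigs.items():
            if not seq:
                raise SequenceError(f"contig {cid!r} is empty")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise SequenceError(
                    f"contig {cid!r} contains invalid characters {sorted(bad)}"
                )
            normalized[cid] = seq
        self.contigs = normalized

    def __len__(self) -> int:
        return len(self.contigs)

    def contig_length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None) -> "GenomeAssembly":
        path = Path(path)
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(genome_id=genome_id or path.stem, contigs=contigs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(Path(path)), "fasta")


@dataclass
class FeatureHit:
    """A located, stranded match on a contig.

    ``feature_type`` distinguishes what the hit represents (piPolB, att,
    tRNA, CDS, primer, assembly_gap ...).  ``frame`` is set only for
    translated (protein-vs-DNA) hits and is the 0-based frame offset on
    the strand the hit lies on.
    """

    query_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    percent_identity: float = 100.0
    aligned_length: int = 0
    score: float = 0.0
    frame: Optional[int] = None
    feature_type: str = "match"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.query_id!r}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.frame is not None and self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "FeatureHit") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def moved(self, **kwargs) -> "FeatureHit":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# GFF3 emission / ingestion (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def write_gff3(
    path: str | Path,
    features: Iterable[FeatureHit],
    contig_lengths: Optional[dict[str, int]] = None,
    source: str = "pipolin_scout",
    attributes: Optional[dict[int, str]] = None,
) -> None:
    """Write features as GFF3. ``attributes`` maps feature index -> attr string."""
    lines = ["##gff-version 3"]
    if contig_lengths:
        for cid, length in contig_lengths.items():
            lines.append(f"##sequence-region {cid} 1 {length}")
    for i, f in enumerate(features):
        attr = (attributes or {}).get(i) or f"ID={f.feature_type}_{i};Name={f.query_id}"
        lines.append(
            "\t".join(
                [
                    f.contig_id,
                    source,
                    f.feature_type,
                    str(f.start + 1),
                    str(f.end),
                    f"{f.score:g}" if f.score else ".",
                    f.strand,
                    ".",
                    attr,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_features(
    path: str | Path, feature_types: Optional[set[str]] = None
) -> list[FeatureHit]:
    """Read GFF3 rows into FeatureHit objects (coordinates converted to
    0-based half-open). Only the columns this pipeline uses are kept."""
    hits: list[FeatureHit] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ValueError(f"malformed GFF3 row: {line!r}")
        seqid, _source, ftype, start, end, score, strand, _phase, _attr = cols[:9]
        if feature_types is not None and ftype not in feature_types:
            continue
        hits.append(
            FeatureHit(
                query_id=ftype,
                contig_id=seqid,
                start=int(start) - 1,
                end=int(end),
                strand=strand if strand in {"+", "-"} else "+",
                score=0.0 if score == "." else float(score),
                feature_type=ftype,
            )
        )
    return hits


def write_hits_tsv(path: str | Path, hits: Iterable[FeatureHit]) -> None:
    """BLAST outfmt-6-like hit table."""
    header = (
        "query\tcontig\tpident\tlength\tsstart\tsend\tstrand\tscore\tframe\ttype"
    )
    rows = [header]
    for h in hits:
        rows.append(
            f"{h.query_id}\t{h.contig_id}\t{h.percent_identity:.2f}\t"
            f"{h.aligned_length}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:g}\t"
            f"{'.' if h.frame is None else h.frame}\t{h.feature_type}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
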