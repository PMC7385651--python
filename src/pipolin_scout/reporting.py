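"""Prevalence tables, run orchestration and provenance.

Prevalence percentages follow survey-table convention: half-up rounding
to one decimal, with marginal rows always recomputed from summed counts
(never averaged from stratum percentages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .core import FeatureHit, GenomeAssembly, read_gff3_features, write_gff3
from .reconstruct import ScaffoldedPipolin, reconstruct_pipolin
from .seqsearch import find_att_repeats, find_trna, translated_search

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceTable",
    "RunConfig",
    "percent_half_up",
    "prevalence_summary",
    "analyze_genome",
    "run_pipeline",
]


def percent_half_up(count: int, total: int, decimals: int = 1) -> str:
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    return str((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceTable:
    """Strata of (source, infection_type, n_strains, n_positive)."""

    strata: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        for src, inf, n, k in self.strata:
            if n <= 0:
                raise ValueError(f"stratum ({src}, {inf}) has no strains")
            if not (0 <= k <= n):
                raise ValueError(f"stratum ({src}, {inf}): positives exceed strains")


def prevalence_summary(table: PrevalenceTable) -> pd.DataFrame:
    """Per-stratum, per-infection-type and overall prevalence percentages
    (half-up, 1 decimal).  Marginals sum counts before dividing."""
    rows = []
    for src, inf, n, k in table.strata:
        rows.append((src, inf, n, k, percent_half_up(k, n)))
    by_inf: dict[str, list[int]] = {}
    for _src, inf, n, k in table.strata:
        acc = by_inf.setdefault(inf, [0, 0])
        acc[0] += n
        acc[1] += k
    for inf, (n, k) in sorted(by_inf.items()):
        rows.append(("All", inf, n, k, percent_half_up(k, n)))
    tot_n = sum(n for _, _, n, _ in table.strata)
    tot_k = sum(k for _, _, _, k in table.strata)
    rows.append(("Total", "All", tot_n, tot_k, percent_half_up(tot_k, tot_n)))
    return pd.DataFrame(
        rows, columns=["source", "infection_type", "n_strains", "n_positive", "percent"]
    )


@dataclass
class RunConfig:
    """All knobs of one cohort run, serialized alongside its outputs."""

    assembly_dir: str
    pipolb_protein_fasta: str
    att_reference_fasta: str
    trna_reference_fasta: Optional[str] = None
    trna_gff: Optional[str] = None
    out_dir: str = "results/run"
    min_pipolb_identity: float = 85.0
    min_pipolb_coverage: float = 0.3
    min_att_identity: float = 85.0
    min_att_length_fraction: float = 0.8
    gap_length: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("min_pipolb_identity", "min_att_identity"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must lie in [0, 100]")
        for name in ("min_pipolb_coverage", "min_att_length_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.gap_length < 1:
            raise ValueError("gap_length must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _read_single_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(recs)}")
    return str(recs[0].seq)


def analyze_genome(
    assembly: GenomeAssembly,
    pipolb_protein: str,
    att_reference: str,
    trna_reference: Optional[str] = None,
    trna_annotations: Optional[list[FeatureHit]] = None,
    config: Optional[RunConfig] = None,
) -> tuple[dict, Optional[ScaffoldedPipolin]]:
    """Detection then reconstruction for one genome.  Returns a report
    dict and the scaffolded pipolin (None for pipolin-negative genomes)."""
    cfg = config
    kw = dict(
        min_identity=cfg.min_pipolb_identity if cfg else 85.0,
        min_coverage=cfg.min_pipolb_coverage if cfg else 0.3,
    )
    pipolb_hits = translated_search(pipolb_protein, assembly, **kw)
    logger.info("genome=%s stage=pipolb_search n_hits=%d",
                assembly.genome_id, len(pipolb_hits))
    if not pipolb_hits:
        return (
            {"genome_id": assembly.genome_id, "pipolin_found": False},
            None,
        )
    att_hits = find_att_repeats(
        assembly, att_reference,
        min_identity=cfg.min_att_identity if cfg else 85.0,
        min_length_fraction=cfg.min_att_length_fraction if cfg else 0.8,
    )
    logger.info("genome=%s stage=att_search n_hits=%d", assembly.genome_id, len(att_hits))
    if trna_annotations is not None:
        trna_hits = find_trna(assembly, annotations=trna_annotations)
    elif trna_reference is not None:
        trna_hits = find_trna(assembly, trna_reference=trna_reference)
    else:
        trna_hits = []
    logger.info("genome=%s stage=trna_search n_hits=%d", assembly.genome_id, len(trna_hits))
    pipolin = reconstruct_pipolin(
        assembly, pipolb_hits, att_hits, trna_hits,
        gap_length=cfg.gap_length if cfg else 100,
    )
    report = {"genome_id": assembly.genome_id, "pipolin_found": True}
    if pipolin is not None:
        report.update(pipolin.summary())
        if pipolin.low_confidence:
            logger.warning("genome=%s stage=reconstruct low_confidence=True",
                           assembly.genome_id)
        if pipolin.structure_class == "inconsistent":
            logger.warning("genome=%s stage=reconstruct structure=inconsistent",
                           assembly.genome_id)
    return report, pipolin


def run_pipeline(config: RunConfig) -> dict:
    """Cohort run: per-genome detection + reconstruction with isolated
    failures, followed by a cohort summary (prevalence, structure tally).
    Deterministic given the config; the serialized config and package
    version are written next to the outputs."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    pipolb_protein = _read_single_fasta(config.pipolb_protein_fasta)
    att_ref = _read_single_fasta(config.att_reference_fasta)
    trna_ref = (
        _read_single_fasta(config.trna_reference_fasta)
        if config.trna_reference_fasta else None
    )
    trna_ann = (
        read_gff3_features(config.trna_gff, feature_types={"tRNA"})
        if config.trna_gff else None
    )

    fastas = sorted(Path(config.assembly_dir).glob("*.fa")) + sorted(
        Path(config.assembly_dir).glob("*.fasta")
    )
    if not fastas:
        raise ValueError(f"no FASTA files in {config.assembly_dir}")

    reports: list[dict] = []
    tally: dict[str, int] = {}
    for fa in fastas:
        try:
            assembly = GenomeAssembly.from_fasta(fa)
            report, pipolin = analyze_genome(
                assembly, pipolb_protein, att_ref,
                trna_reference=trna_ref, trna_annotations=trna_ann, config=config,
            )
            if pipolin is not None:
                gdir = out / assembly.genome_id
                gdir.mkdir(exist_ok=True)
                GenomeAssembly(
                    genome_id=pipolin.genome_id,
                    contigs={f"{pipolin.genome_id}_pipolin": pipolin.sequence},
                ).to_fasta(gdir / "pipolin.fasta")
                write_gff3(
                    gdir / "pipolin.gff3",
                    pipolin.features,
                    contig_lengths={pipolin.genome_id: len(pipolin.sequence)},
                    attributes={
                        i: f"ID={f.feature_type}_{i};role={f.query_id}"
                        for i, f in enumerate(pipolin.features)
                    },
                )
                (gdir / "pipolin.json").write_text(
                    json.dumps(pipolin.summary(), indent=2, sort_keys=True)
                )
                tally[pipolin.structure_class] = tally.get(pipolin.structure_class, 0) + 1
        except Exception as exc:  # noqa: BLE001 — per-genome isolation
            logger.error("genome=%s stage=pipeline failed=%r", fa.stem, exc)
            report = {"genome_id": fa.stem, "pipolin_found": False, "error": str(exc)}
        reports.append(report)

    n = len(reports)
    k = sum(1 for r in reports if r.get("pipolin_found"))
    summary = {
        "version": __version__,
        "n_genomes": n,
        "n_pipolin_positive": k,
        "prevalence_percent": percent_half_up(k, n),
        "structure_classes": dict(sorted(tally.items())),
        "genomes": reports,
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
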