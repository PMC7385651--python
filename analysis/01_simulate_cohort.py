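"""Simulate the study cohort: 20 draft assemblies, 5 carrying a pipolin.

Positive genomes get the element planted at a tRNA locus and are then
fragmented (0-3 breaks, random contig orientations) to emulate draft
assemblies; negatives are plain background.  Writes assemblies, truth
GFF3 and the reference sequences (piPolB protein, att, tRNA) that the
downstream screen uses, under results/simulated/.
"""

import numpy as np

from pathlib import Path

from pipolin_scout.core import GenomeAssembly, write_gff3
from pipolin_scout.synthetic import (
    PipolinTemplate,
    fragment_assembly,
    generate_pipolin_genome,
    random_dna,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    asm_dir = OUT / "assemblies"
    asm_dir.mkdir(parents=True, exist_ok=True)
    template = PipolinTemplate.from_seed(SEED)
    rng = np.random.default_rng([0x51, SEED])
    n_positive = 0
    for i in range(20):
        carries = i % 4 == 0  # 5 of 20
        if carries:
            genome, truth = generate_pipolin_genome(
                template, 10_000, rng_seed=SEED * 100 + i)
            asm, tr = fragment_assembly(
                genome, truth, int(rng.integers(0, 4)),
                rng_seed=SEED * 100 + i, flip_prob=0.5, exclusion_margin=120)
            write_gff3(asm_dir / f"strain_{i:02d}.truth.gff3", tr.features,
                       {c: len(s) for c, s in asm.contigs.items()})
            n_positive += 1
        else:
            asm = GenomeAssembly(
                f"strain_{i:02d}", {f"strain_{i:02d}_c0": random_dna(rng, 9_000)})
        asm.to_fasta(asm_dir / f"strain_{i:02d}.fasta")
    (OUT / "pipolb.faa").write_text(f">piPolB\n{template.pipolb_protein}\n")
    (OUT / "att.fna").write_text(f">att\n{template.att_seq}\n")
    (OUT / "trna.fna").write_text(f">tRNA\n{template.trna_seq}\n")
    print(f"wrote 20 assemblies ({n_positive} pipolin-positive) to {asm_dir}")


if __name__ == "__main__":
    main()
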