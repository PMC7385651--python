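"""Prevalence survey arithmetic.

Takes the screening survey's printed stratum counts (source x infection
type, number of strains screened, number of element-positive strains)
and recomputes every percentage with half-up rounding to one decimal,
with all marginals summed from counts before dividing: 1.3% / 0.8% /
1.5% / 1.2% per stratum, 1.4% intestinal, 0.9% extraintestinal, 1.1%
overall.  Writes results/prevalence/table.tsv.
"""

from pathlib import Path

from pipolin_scout.reporting import PrevalenceTable, prevalence_summary

OUT = Path(__file__).resolve().parent.parent / "results" / "prevalence"

SURVEY = [
    ("Human", "Intestinal", 608, 8),
    ("Human", "Extraintestinal", 1061, 9),
    ("Swine", "Intestinal", 323, 5),
    ("Avian", "Extraintestinal", 246, 3),
]


def main() -> None:
    df = prevalence_summary(PrevalenceTable(SURVEY))
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "table.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
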