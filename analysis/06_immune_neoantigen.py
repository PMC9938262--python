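"""Immune infiltration classes, HLA-LOH timing and neoantigen filtering.

Writes immune_scores.tsv, til_classes.tsv and neoantigens.tsv; prints the
TIL class per patient and the neoepitope counts after each filter.
"""

from pathlib import Path

from mrith.cli import _load
from mrith.pipeline import (analyze_immune, analyze_neoantigens,
                            analyze_rna, analyze_variants)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main():
    cohort = _load(ROOT / "cohort")
    logx = analyze_rna(cohort, seed=SEED)["log_expr"]
    imm = analyze_immune(cohort, logx)
    presence = analyze_variants(cohort, seed=SEED)["clonality_clone"]
    neo = analyze_neoantigens(cohort, presence)
    imm["scores"].round(4).to_csv(ROOT / "immune_scores.tsv", sep="\t")
    imm["til"].patient_labels.rename("til_class").to_csv(
        ROOT / "til_classes.tsv", sep="\t")
    neo["summary"].to_csv(ROOT / "neoantigens.tsv", sep="\t", index=False)
    for pat, cls in imm["til"].patient_labels.items():
        print(f"  {pat}: TIL {cls}")
    timing = imm["hla_timing"]
    lost = timing[timing.timing != "none"]
    print(f"HLA-LOH: {(lost.timing == 'clonal').sum()} clonal, "
          f"{(lost.timing == 'subclonal').sum()} subclonal allele losses")
    print(neo["summary"].to_string(index=False))


if __name__ == "__main__":
    main()
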