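"""Copy-number instability: wGII, genome doubling, arm events, MSAI.

Writes wgii.tsv, arm_calls.tsv, scna_ith.tsv and msai_events.tsv and
prints the per-patient instability picture.
"""

from pathlib import Path

import pandas as pd

from mrith.cli import _load
from mrith.pipeline import analyze_scna

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = _load(ROOT / "cohort")
    res = analyze_scna(cohort)
    res["wgii"].to_csv(ROOT / "wgii.tsv", sep="\t", index=False)
    res["arm_events"].drop_duplicates(["patient", "arm"]).to_csv(
        ROOT / "arm_calls.tsv", sep="\t", index=False)
    res["scna_ith"].to_csv(ROOT / "scna_ith.tsv", sep="\t", index=False)
    pd.DataFrame([{"patient": e.patient, "arm": e.arm,
                   "regions": ",".join(e.regions), "n_snps": e.n_snps}
                  for e in res["msai"]]).to_csv(
        ROOT / "msai_events.tsv", sep="\t", index=False)
    w = res["wgii"].groupby("patient").agg(wgii=("wgii", "mean"),
                                           gd=("gd", "any"))
    ith = res["scna_ith"].set_index("patient")
    msai_pats = {e.patient for e in res["msai"]}
    for pat, row in w.iterrows():
        print(f"  {pat}: wGII {row.wgii:.3f}, GD={bool(row.gd)}, "
              f"subclonal SCNA "
              f"{ith.loc[pat, 'subclonal_fraction']:.2f}, "
              f"MSAI={'yes' if pat in msai_pats else 'no'}")
    print(f"{len(res['msai'])} mirrored allelic-imbalance events "
          f"in {len(msai_pats)} patients")


if __name__ == "__main__":
    main()
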