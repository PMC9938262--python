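"""Simulate the working multi-region multi-omics cohort.

Writes the cohort tables (variants, segments, SNP BAFs, methylation,
epialleles, expression, neoantigen candidates, HLA-LOH) plus the ground
truth to results/cohort/, the shared input of every downstream script.
"""

from pathlib import Path

from mrith.config import SimulationConfig
from mrith.simulate import simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 2024


def main():
    cfg = SimulationConfig(n_patients=8, seed=SEED)
    cohort = simulate_cohort(cfg)
    write_cohort(cohort, OUT)
    n_mut = len(cohort.truth.mutations)
    print(f"simulated {cfg.n_patients} patients, "
          f"{sum(len(p.regions) for p in cohort.truth.patients)} regions, "
          f"{n_mut} mutations, {cfg.n_cpg_bins} CpG bins, "
          f"{cfg.n_genes} genes -> {OUT}")
    for p in cohort.truth.patients:
        print(f"  {p.patient}: {len(p.regions)} regions, "
              f"{p.n_clones} clones ({p.pattern}), GD={p.gd}, "
              f"MSAI={'yes' if p.msai else 'no'}")


if __name__ == "__main__":
    main()
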