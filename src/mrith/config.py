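"""Simulation configuration and the synthetic mini-genome.

The generator works on a desk-scale genome: 22 autosomes of 10 Mb each,
split into p/q arms at 5 Mb, coordinates 0-based half-open. All sizes,
depths and effect magnitudes are configurable; the defaults describe a
realistic multi-region exome/RRBS/RNA-seq cohort scaled down to run in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: (chrom, arm, start, end), 0-based half-open.
Arm = tuple[str, str, int, int]

CHROM_LENGTH = 10_000_000
CENTROMERE = 5_000_000

IMMUNE_POPULATIONS = [
    "CD4_T", "TH1", "Treg", "dendritic", "B_cell", "mast", "NK",
    "NK_CD56neg", "neutrophils", "macrophages", "CD45", "CD8_T",
    "CD8_exhausted", "T_cells", "total_TIL", "cytotoxic",
]


def default_genome() -> list[Arm]:
    """22 autosomes, 10 Mb each, arm boundary at 5 Mb."""
    genome: list[Arm] = []
    for i in range(1, 23):
        chrom = f"chr{i}"
        genome.append((chrom, "p", 0, CENTROMERE))
        genome.append((chrom, "q", CENTROMERE, CHROM_LENGTH))
    return genome


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-region multi-omics cohort.

    Attributes
    ----------
    n_patients:
        Number of patients in the cohort.
    regions_per_patient:
        Inclusive (low, high) range for the number of tumor regions
        sampled per patient.
    n_clones:
        Inclusive (low, high) range for the number of clones per patient
        (including the truncal clone).
    depth:
        Mean sequencing depth (reads) for variant and SNP sites.
    purity:
        (low, high) range of per-region tumor purity in (0, 1].
    n_mutations:
        Somatic mutations assigned to each clone.
    genome:
        List of (chrom, arm, start, end) arm definitions.
    gd_fraction:
        Fraction of patients simulated with genome doubling (baseline
        2+2 allele copies instead of 1+1).
    msai_fraction:
        Fraction of patients with one planted mirrored subclonal allelic
        imbalance event (opposite parental alleles gained in two regions).
    n_cpg_bins:
        Number of CpG bins tiled along the genome.
    cpg_bin_size:
        Bin width in bp (1 kb, matching DMR-scale bins).
    meth_depth:
        Mean read depth per CpG site.
    dmr_fraction:
        Fraction of bins planted as DMRs (split evenly hyper/hypo).
    dmr_delta:
        Tumor-minus-normal methylation shift planted in DMR bins.
    variable_fraction:
        Fraction of bins with region-variable tumor methylation.
    epiallele_disorder:
        Baseline per-locus disorder in [0, 1]; each sequenced read flips
        each of the locus's 4 CpGs independently with probability
        disorder/2.
    epiallele_disorder_high:
        Disorder used on copy-altered segments when
        ``couple_disorder_to_scna`` is set.
    couple_disorder_to_scna:
        Whether loci over copy-altered arms receive the high disorder.
    n_epiallele_loci:
        Number of 4-CpG epiallele loci per patient.
    epiallele_depth:
        Mean reads per epiallele locus (kept above the 60-read analysis
        threshold).
    n_genes:
        Protein-coding genes in the expression matrix (immune marker
        genes are added on top).
    dosage_effect:
        log2 expression shift per somatic copy gained or lost relative
        to the diploid state.
    promoter_effect:
        log2 expression drop applied when a gene's promoter is planted
        hypermethylated in a region.
    promoter_coupled_fraction:
        Fraction of genes with a planted promoter-methylation/expression
        coupling.
    infiltration_states:
        (low, high) mean log2 marker expression of the two immune
        infiltration states.
    n_markers_per_population:
        Synthetic marker genes per immune cell population.
    normal_error_rate:
        Per-read sequencing error rate used for the matched normal and
        for absent sites.
    seed:
        Random seed; identical config + seed gives byte-identical output.
    """

    n_patients: int = 8
    regions_per_patient: tuple[int, int] = (3, 5)
    n_clones: tuple[int, int] = (2, 5)
    depth: float = 100.0
    purity: tuple[float, float] = (0.6, 0.9)
    n_mutations: int = 30
    genome: Sequence[Arm] = field(default_factory=default_genome)
    gd_fraction: float = 0.3
    msai_fraction: float = 0.5
    n_cpg_bins: int = 300
    cpg_bin_size: int = 1000
    meth_depth: float = 60.0
    dmr_fraction: float = 0.10
    dmr_delta: float = 0.40
    variable_fraction: float = 0.05
    epiallele_disorder: float = 0.10
    epiallele_disorder_high: float = 0.50
    couple_disorder_to_scna: bool = True
    n_epiallele_loci: int = 60
    epiallele_depth: float = 80.0
    n_genes: int = 400
    dosage_effect: float = 0.8
    promoter_effect: float = 1.5
    promoter_coupled_fraction: float = 0.05
    infiltration_states: tuple[float, float] = (2.0, 6.0)
    n_markers_per_population: int = 3
    snps_per_arm: int = 25
    normal_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _pair(v):
            lo, hi = v
            return float(lo), float(hi)

        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.regions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("regions_per_patient range invalid")
        lo, hi = self.n_clones
        if not (1 <= lo <= hi):
            raise ValueError("n_clones range invalid")
        plo, phi = _pair(self.purity)
        if not (0 < plo <= phi <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.depth <= 0 or self.meth_depth <= 0 or self.epiallele_depth <= 0:
            raise ValueError("depths must be positive")
        if self.n_mutations < 1 or self.n_cpg_bins < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.dmr_fraction <= 1:
            raise ValueError("dmr_fraction must lie in [0, 1]")
        if not 0 <= self.epiallele_disorder <= 1:
            raise ValueError("epiallele_disorder must lie in [0, 1]")
        if not self.genome:
            raise ValueError("genome must contain at least one arm")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["genome"] = [list(a) for a in self.genome]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genome"] = [tuple(a) for a in d["genome"]]
        for key in ("regions_per_patient", "n_clones", "purity",
                    "infiltration_states"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
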