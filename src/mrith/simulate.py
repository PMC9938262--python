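"""Render observable multi-omics data from the simulated ground truth.

Each rendered table mimics one of the pipeline's input formats:

* variant read counts — alt reads drawn binomially at the expected VAF
  implied by the clone's cancer cell fraction, the region's purity and the
  local total copy number (mutation multiplicity fixed at 1);
* allele-specific segments and phased het-SNP B-allele fractions — one
  segment per chromosome arm with integer haplotype copies;
* per-CpG methylation counts — the bulk level is the purity- and
  copy-weighted mixture of tumor and normal rates (the mixture the
  deconvolution formula inverts);
* epiallele pattern counts — per locus a dominant 4-CpG pattern; each read
  flips each CpG independently with probability disorder/2;
* a TPM expression matrix with copy-dosage, promoter-methylation and
  immune-infiltration effects, plus the marker registry;
* neoantigen candidates and HLA-LOH calls.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrith.config import SimulationConfig, IMMUNE_POPULATIONS
from mrith.truth import CohortTruth, PatientTruth, build_truth

PATTERNS = ["".join(p) for p in itertools.product("01", repeat=4)]
PATTERN_COLS = [f"c{p}" for p in PATTERNS]


def expected_vaf(ccf: np.ndarray, purity: float, cn_tumor: np.ndarray,
                 multiplicity: int = 1) -> np.ndarray:
    """Expected VAF of a mutation at the given CCF, purity and local CN.

    VAF = CCF * m * rho / (CN_t * rho + 2 * (1 - rho)); the inverse of the
    standard CCF estimator.
    """
    return ccf * multiplicity * purity / (cn_tumor * purity + 2.0 * (1.0 - purity))


def _arm_total_cn(pt: PatientTruth, arm: str, region: str) -> int:
    a, b = pt.arm_cn[arm][region]
    return a + b


# ---------------------------------------------------------------------------
# genomics

def render_genomics(truth: CohortTruth, config: SimulationConfig,
                    rng: np.random.Generator):
    """Variant read counts, allele segments, purity/ploidy and SNP BAFs."""
    arm_bounds = {f"{c}{a}": (c, s, e) for c, a, s, e in config.genome}
    err = config.normal_error_rate

    var_rows = []
    for pt in truth.patients:
        muts = truth.mutations[truth.mutations.patient == pt.patient]
        for j, reg in enumerate(pt.regions):
            rho = float(pt.purity[j])
            cn = np.array([_arm_total_cn(pt, a, reg) for a in muts.arm])
            ccf = pt.prevalence[muts.clone.to_numpy(), j]
            p = expected_vaf(ccf, rho, cn)
            p = p + err * (1.0 - p)
            dep = np.maximum(rng.poisson(config.depth, size=len(muts)), 1)
            alt = rng.binomial(dep, p)
            ndep = np.maximum(rng.poisson(config.depth, size=len(muts)), 1)
            nalt = rng.binomial(ndep, err)
            for (mid, chrom, pos, ref, altb), d, a, nd, na in zip(
                    muts[["mut_id", "chrom", "pos", "ref", "alt"]].itertuples(
                        index=False), dep, alt, ndep, nalt):
                var_rows.append((pt.patient, reg, chrom, pos, ref, altb,
                                 int(a), int(d - a), int(na), int(nd - na),
                                 mid))
    variants = pd.DataFrame(var_rows, columns=[
        "patient", "region", "chrom", "pos", "ref", "alt",
        "t_alt", "t_ref", "n_alt", "n_ref", "mut_id"])

    seg_rows, pp_rows = [], []
    for pt in truth.patients:
        ploidy = pt.region_ploidy(config.genome)
        for j, reg in enumerate(pt.regions):
            pp_rows.append((pt.patient, reg, float(pt.purity[j]),
                            round(ploidy[reg], 4)))
            for arm, (chrom, s, e) in arm_bounds.items():
                a, b = pt.arm_cn[arm][reg]
                seg_rows.append((pt.patient, reg, chrom, s, e,
                                 max(a, b), min(a, b)))
    segments = pd.DataFrame(seg_rows, columns=[
        "patient", "region", "chrom", "start", "end", "major_cn", "minor_cn"])
    purity_ploidy = pd.DataFrame(pp_rows, columns=[
        "patient", "region", "purity", "ploidy"])

    baf_rows = []
    for pt in truth.patients:
        for arm, (chrom, s, e) in arm_bounds.items():
            pos = np.sort(rng.integers(s + 1, e, size=config.snps_per_arm))
            hap = rng.integers(0, 2, size=config.snps_per_arm)  # ALT haplotype
            for j, reg in enumerate(pt.regions):
                rho = float(pt.purity[j])
                cna, cnb = pt.arm_cn[arm][reg]
                tot = rho * (cna + cnb) + 2.0 * (1.0 - rho)
                f_alt = np.where(hap == 0,
                                 (rho * cna + (1.0 - rho)) / tot,
                                 (rho * cnb + (1.0 - rho)) / tot)
                dep = np.maximum(rng.poisson(config.depth,
                                             size=config.snps_per_arm), 1)
                alt = rng.binomial(dep, f_alt)
                for p_, h_, d_, a_ in zip(pos, hap, dep, alt):
                    baf_rows.append((pt.patient, reg, chrom, int(p_),
                                     int(d_ - a_), int(a_),
                                     "A" if h_ == 0 else "B"))
    snp_baf = pd.DataFrame(baf_rows, columns=[
        "patient", "region", "chrom", "pos", "ref_reads", "alt_reads",
        "haplotype"])
    return variants, segments, purity_ploidy, snp_baf


# ---------------------------------------------------------------------------
# methylome + expression

def epiallele_pattern_probs(dominant: str, disorder: float) -> np.ndarray:
    """Probability of each of the 16 patterns under the flip model."""
    q = disorder / 2.0
    probs = np.empty(16)
    for i, pat in enumerate(PATTERNS):
        match = sum(a == b for a, b in zip(pat, dominant))
        probs[i] = (1 - q) ** match * q ** (4 - match)
    return probs


def render_methylome_expression(truth: CohortTruth, config: SimulationConfig,
                                rng: np.random.Generator):
    """Methylation counts, epiallele counts, TPM matrix and marker registry."""
    bins = truth.bins
    genes = truth.genes
    meth_rows = []
    epi_rows = []
    promoter_state = {}  # (patient, gene) -> set of regions with hyper promoter

    for pt in truth.patients:
        # per-bin per-region tumor rates: a patient-level baseline shift
        # (shared with the matched normal, so tumor-normal differences are
        # preserved) + exchangeable region jitter + variable bins
        n = len(bins)
        pat_shift = rng.normal(0.0, 0.06, size=n)
        base_t = np.clip(bins.tumor_rate.to_numpy() + pat_shift, 0.01, 0.99)
        normal_rate = np.clip(bins.normal_rate.to_numpy() + pat_shift,
                              0.01, 0.99)
        jitter = rng.normal(0.0, 0.02, size=(len(pt.regions), n))
        var_mask = bins.variable.to_numpy()
        region_rates = np.clip(base_t[None, :] + jitter, 0.01, 0.99)
        for j in range(len(pt.regions)):
            region_rates[j, var_mask] = np.clip(
                base_t[var_mask] + rng.uniform(-0.35, 0.35, var_mask.sum()),
                0.01, 0.99)

        cpg_offsets = [137, 411, 802]  # three CpGs per bin
        for j, reg in enumerate(pt.regions):
            rho = float(pt.purity[j])
            cn_t = np.array([_arm_total_cn(pt, a, reg) for a in bins.arm])
            m_t = region_rates[j]
            bulk = ((rho * cn_t * m_t + 2.0 * (1.0 - rho) * normal_rate)
                    / (rho * cn_t + 2.0 * (1.0 - rho)))
            for off in cpg_offsets:
                tot = np.maximum(rng.poisson(config.meth_depth, size=n), 1)
                met = rng.binomial(tot, bulk)
                meth_rows.append(pd.DataFrame({
                    "patient": pt.patient, "region": reg,
                    "chrom": bins.chrom, "pos": bins.start + off,
                    "meth_reads": met, "total_reads": tot}))
        # matched normal, one shared profile per patient
        for off in cpg_offsets:
            tot = np.maximum(rng.poisson(config.meth_depth, size=n), 1)
            met = rng.binomial(tot, normal_rate)
            meth_rows.append(pd.DataFrame({
                "patient": pt.patient, "region": "NORMAL",
                "chrom": bins.chrom, "pos": bins.start + off,
                "meth_reads": met, "total_reads": tot}))

        # promoter CpGs of coupled genes: hyper in one region
        coupled = genes[genes.promoter_coupled]
        for g in coupled.itertuples(index=False):
            hyper_reg = pt.regions[int(rng.integers(0, len(pt.regions)))]
            promoter_state[(pt.patient, g.gene)] = {hyper_reg}
            for j, reg in enumerate(pt.regions):
                rate = 0.85 if reg == hyper_reg else 0.15
                for off in (-150, 150):
                    tot = max(int(rng.poisson(config.meth_depth)), 1)
                    met = int(rng.binomial(tot, rate))
                    meth_rows.append(pd.DataFrame({
                        "patient": [pt.patient], "region": [reg],
                        "chrom": [g.chrom], "pos": [g.tss + off],
                        "meth_reads": [met], "total_reads": [tot]}))

        # epialleles
        loci = truth.epiallele_loci
        for li in loci.itertuples(index=False):
            dominant = PATTERNS[int(rng.integers(0, 16))]
            for j, reg in enumerate(pt.regions):
                disorder = float(li.base_disorder)
                if config.couple_disorder_to_scna:
                    base_total = 4 if pt.gd else 2
                    if _arm_total_cn(pt, li.arm, reg) != base_total:
                        disorder = config.epiallele_disorder_high
                nreads = max(int(rng.poisson(config.epiallele_depth)), 60)
                counts = rng.multinomial(
                    nreads, epiallele_pattern_probs(dominant, disorder))
                epi_rows.append((pt.patient, reg, li.locus, li.chrom,
                                 li.start, *counts.tolist()))

    methylation = pd.concat(meth_rows, ignore_index=True)
    epialleles = pd.DataFrame(epi_rows, columns=[
        "patient", "region", "locus", "chrom", "start", *PATTERN_COLS])

    # expression -----------------------------------------------------------
    sample_ids, cols = [], []
    class_sd = {"I": (1.5, 0.2), "II": (0.2, 0.2),
                "III": (1.5, 1.5), "IV": (0.2, 1.5)}
    intra_sd = np.array([class_sd[c][0] for c in genes.quadrant_class])
    inter_sd = np.array([class_sd[c][1] for c in genes.quadrant_class])
    base = genes.base_expr.to_numpy()
    marker_names = {
        pop: [f"MK_{pop}_{i + 1}"
              for i in range(config.n_markers_per_population)]
        for pop in IMMUNE_POPULATIONS}
    lo_state, hi_state = config.infiltration_states

    for pt in truth.patients:
        offs = rng.normal(0.0, 1.0, size=len(genes)) * inter_sd
        for j, reg in enumerate(pt.regions):
            cn_t = np.array([_arm_total_cn(pt, a, reg) for a in genes.arm])
            log2e = (base + offs
                     + rng.normal(0.0, 1.0, size=len(genes)) * intra_sd
                     + config.dosage_effect * (cn_t - 2))
            for gi, g in enumerate(genes.itertuples(index=False)):
                if g.promoter_coupled and \
                        reg in promoter_state.get((pt.patient, g.gene), ()):
                    log2e[gi] -= config.promoter_effect
            state = pt.infiltration[reg]
            mu = hi_state if state == "high" else lo_state
            mk = rng.normal(mu, 0.3,
                            size=len(IMMUNE_POPULATIONS)
                            * config.n_markers_per_population)
            col = np.concatenate([log2e, mk])
            col = np.maximum(col, 0.0)
            cols.append(np.power(2.0, col) - 1.0)       # back to TPM
            sample_ids.append(f"{pt.patient}_{reg}")

    all_genes = list(genes.gene) + [m for pop in IMMUNE_POPULATIONS
                                    for m in marker_names[pop]]
    expression = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(all_genes, name="gene"),
        columns=sample_ids)
    return methylation, epialleles, expression, marker_names, promoter_state


# ---------------------------------------------------------------------------
# immuno-genomics tables

_AA = list("ACDEFGHIKLMNPQRSTVWY")


def render_neoantigens(truth: CohortTruth, config: SimulationConfig,
                       rng: np.random.Generator):
    """Neoantigen candidate table and per-region HLA-LOH calls."""
    cand_rows, loh_rows = [], []
    alleles = ["HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02"]
    for pt in truth.patients:
        lost_allele = pt.hla_loh["allele"] if pt.hla_loh else None
        lost_regions = set(pt.hla_loh["regions"]) if pt.hla_loh else set()
        for reg in pt.regions:
            for al in alleles + ([lost_allele] if lost_allele
                                 and lost_allele not in alleles else []):
                loh_rows.append((pt.patient, reg, al,
                                 al == lost_allele and reg in lost_regions))
        muts = truth.mutations[truth.mutations.patient == pt.patient]
        # spread candidates across clones so subclonal neoepitopes exist
        step = max(1, len(muts) // 10)
        take = muts.iloc[::step].head(10)
        for m in take.itertuples(index=False):
            length = int(rng.integers(9, 12))
            pep = "".join(rng.choice(_AA, size=length))
            allele = (lost_allele if lost_allele and rng.random() < 0.4
                      else alleles[int(rng.integers(0, len(alleles)))])
            rank_mut = float(10 ** rng.uniform(-1.0, 1.5))
            rank_wt = float(10 ** rng.uniform(-0.5, 1.5))
            total = int(rng.poisson(20))
            alt = int(rng.binomial(total, 0.4)) if total else 0
            cand_rows.append((pt.patient, m.mut_id, pep, allele,
                              round(rank_mut, 3), round(rank_wt, 3),
                              total, alt, int(m.clone)))
    candidates = pd.DataFrame(cand_rows, columns=[
        "patient", "mut_id", "peptide", "allele", "rank_mut", "rank_wt",
        "rna_total_reads", "rna_alt_reads", "clone"])
    hla_loh = pd.DataFrame(loh_rows, columns=["patient", "region", "allele",
                                              "lost"])
    return candidates, hla_loh


# ---------------------------------------------------------------------------
# cohort container and I/O

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    truth: CohortTruth
    variants: pd.DataFrame
    segments: pd.DataFrame
    purity_ploidy: pd.DataFrame
    snp_baf: pd.DataFrame
    methylation: pd.DataFrame
    epialleles: pd.DataFrame
    expression: pd.DataFrame
    markers: dict
    neoantigen_candidates: pd.DataFrame
    hla_loh: pd.DataFrame


def simulate_cohort(config: SimulationConfig | None = None,
                    **overrides) -> SimulatedCohort:
    """Build truth and render every omic table for one cohort."""
    if config is None:
        config = SimulationConfig(**overrides)
    truth = build_truth(config)
    # rendering uses an independent stream so truth is stable under
    # render-parameter changes
    rng = np.random.default_rng(config.seed + 1_000_003)
    variants, segments, pp, snp_baf = render_genomics(truth, config, rng)
    methylation, epialleles, expression, markers, _ = \
        render_methylome_expression(truth, config, rng)
    candidates, hla_loh = render_neoantigens(truth, config, rng)
    return SimulatedCohort(config, truth, variants, segments, pp, snp_baf,
                           methylation, epialleles, expression, markers,
                           candidates, hla_loh)


def _truth_to_json(truth: CohortTruth) -> dict:
    pts = []
    for p in truth.patients:
        pts.append({
            "patient": p.patient, "regions": p.regions,
            "purity": [float(x) for x in p.purity],
            "parents": list(map(int, p.parents)),
            "prevalence": [[round(float(x), 6) for x in row]
                           for row in p.prevalence],
            "pattern": p.pattern, "gd": p.gd,
            "arm_cn": {a: {r: list(c) for r, c in d.items()}
                       for a, d in p.arm_cn.items()},
            "msai": p.msai, "hla_loh": p.hla_loh,
            "infiltration": p.infiltration,
        })
    return {
        "patients": pts,
        "mutations": truth.mutations.to_dict(orient="list"),
        "bins": truth.bins.to_dict(orient="list"),
        "epiallele_loci": truth.epiallele_loci.to_dict(orient="list"),
        "genes": truth.genes.to_dict(orient="list"),
    }


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Minimal multi-sample VCF 4.2 with per-region AD (ref,alt) counts."""
    samples = sorted({f"{p}_{r}" for p, r in
                      zip(variants.patient, variants.region)})
    keyed = {(row.patient, row.chrom, row.pos, row.ref, row.alt): {}
             for row in variants.itertuples(index=False)}
    for row in variants.itertuples(index=False):
        keyed[(row.patient, row.chrom, row.pos, row.ref, row.alt)][
            f"{row.patient}_{row.region}"] = (row.t_ref, row.t_alt)
    chroms = sorted({k[1] for k in keyed},
                    key=lambda c: int(c.replace("chr", "")))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Read depth per allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (pat, chrom, pos, ref, alt), per in sorted(
                keyed.items(), key=lambda kv: (int(kv[0][1][3:]), kv[0][2])):
            cells = []
            for s in samples:
                if s in per:
                    r, a = per[s]
                    cells.append(f"{r},{a}")
                else:
                    cells.append(".")
            fh.write(f"{chrom}\t{pos}\t{pat}\t{ref}\t{alt}\t.\tPASS\t.\tAD\t"
                     + "\t".join(cells) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF back into the long per-region count table."""
    import pysam

    vf = pysam.VariantFile(str(path))
    rows = []
    for rec in vf:
        pat = rec.id
        for s in rec.samples:
            ad = rec.samples[s].get("AD")
            if ad is None or ad[0] is None:
                continue
            if not s.startswith(pat + "_"):
                continue
            region = s[len(pat) + 1:]
            rows.append((pat, region, rec.chrom, rec.pos, rec.ref,
                         rec.alts[0], int(ad[1]), int(ad[0])))
    return pd.DataFrame(rows, columns=["patient", "region", "chrom", "pos",
                                       "ref", "alt", "t_alt", "t_ref"])


_TABLES = {
    "variants": "variants.tsv",
    "segments": "segments.seg.tsv",
    "purity_ploidy": "purity_ploidy.tsv",
    "snp_baf": "snp_baf.tsv",
    "methylation": "methylation.bedgraph.tsv",
    "epialleles": "epialleles.tsv",
    "neoantigen_candidates": "neoantigen_candidates.tsv",
    "hla_loh": "hla_loh.tsv",
}


def write_cohort(cohort: SimulatedCohort, out_dir) -> Path:
    """Write all cohort tables, truth JSON and config YAML to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLES.items():
        getattr(cohort, attr).to_csv(out / fname, sep="\t", index=False)
    cohort.expression.to_csv(out / "expression.tpm.tsv", sep="\t")
    write_vcf(cohort.variants, out / "variants.vcf")
    with open(out / "markers.yaml", "w") as fh:
        yaml.safe_dump(cohort.markers, fh, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(_truth_to_json(cohort.truth), fh, sort_keys=True)
    cohort.config.to_yaml(out / "config.yaml")
    return out


def read_cohort(in_dir) -> dict:
    """Read a written cohort directory back into a dict of DataFrames."""
    d = Path(in_dir)
    out = {attr: pd.read_csv(d / fname, sep="\t")
           for attr, fname in _TABLES.items()}
    out["expression"] = pd.read_csv(d / "expression.tpm.tsv", sep="\t",
                                    index_col=0)
    with open(d / "markers.yaml") as fh:
        out["markers"] = yaml.safe_load(fh)
    with open(d / "truth.json") as fh:
        out["truth"] = json.load(fh)
    out["config"] = SimulationConfig.from_yaml(d / "config.yaml")
    return out
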