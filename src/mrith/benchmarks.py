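"""Recovery benchmarks of every pipeline stage against simulated truth.

Each function simulates data at the package's study conditions, runs the
corresponding analysis stage, and measures how well the known ground
truth is recovered. They are used by the test suite and by the
acceptance script; all randomness flows from an explicit seed.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from mrith import methylome, rna, scna
from mrith import variants as var
from mrith.config import SimulationConfig
from mrith.simulate import simulate_cohort, expected_vaf
from mrith.truth import build_truth
from mrith.trees import build_clone_tree
from mrith.variants import CloneCluster
from mrith.signatures import fit_exposures


# ---------------------------------------------------------------------------
# clonality

def clonality_recovery(seed: int, n_patients: int = 10,
                       depth: float = 100.0,
                       purity: tuple[float, float] = (0.6, 0.9),
                       regions: tuple[int, int] = (3, 5)) -> dict:
    """Clonal/subclonal label accuracy and illusion detection vs truth.

    Truth label of a mutation: clonal iff its clone has positive
    prevalence in every region; truth illusion: subclonal with prevalence
    >= 0.9 in some region. Predicted labels come from the presence rule;
    illusion flags use clone-level (cluster posterior mean) CCFs.
    """
    cfg = SimulationConfig(n_patients=n_patients, depth=depth,
                           purity=purity, regions_per_patient=regions,
                           n_cpg_bins=10, n_epiallele_loci=2, n_genes=20,
                           seed=seed)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, _ = var.filter_variants(cohort.variants)
        clustering = var.cluster_ccf(kept, cohort.purity_ploidy,
                                     cohort.segments, max_components=8,
                                     n_restarts=8, seed=seed)
        ccfs = var.add_ccf(kept, cohort.purity_ploidy, cohort.segments)
        rows = []
        for pat, res in clustering.items():
            prev = {c.cluster_id: c.prevalence for c in res.clusters}
            for mut, cl in res.assignments.items():
                for j, reg in enumerate(res.regions):
                    rows.append((pat, mut, reg, float(prev[cl][j])))
        cl_tbl = pd.DataFrame(rows, columns=["patient", "mut_id", "region",
                                             "cluster_ccf"])
        merged = ccfs.merge(cl_tbl, on=["patient", "mut_id", "region"],
                            how="left")
        merged["ccf"] = merged.cluster_ccf.fillna(merged.ccf)
        pred = var.classify_clonality(merged)

    truth = cohort.truth
    mut_clone = truth.mutations.set_index("mut_id")
    n_correct = n_total = 0
    n_true_illusion = n_flagged_illusion = 0
    clone_flags: dict[tuple, list[bool]] = {}
    for r in pred.itertuples(index=False):
        clone = int(mut_clone.loc[r.mut, "clone"])
        pt = truth.get_patient(r.patient)
        p = pt.prevalence[clone]
        true_label = "clonal" if np.all(p > 0) else "subclonal"
        n_total += 1
        n_correct += (r.label == true_label)
        if true_label == "subclonal" and p.max() >= var.ILLUSION_CCF:
            n_true_illusion += 1
            n_flagged_illusion += bool(r.illusion)
            clone_flags.setdefault((r.patient, clone), []).append(
                bool(r.illusion))
    # a planted illusion clone is recovered when the majority of its
    # mutations carry the flag
    clone_recovered = [np.mean(v) > 0.5 for v in clone_flags.values()]
    return {
        "accuracy": n_correct / n_total,
        "n": n_total,
        "n_true_illusions": n_true_illusion,
        "illusion_recall": (n_flagged_illusion / n_true_illusion
                            if n_true_illusion else np.nan),
        "n_illusion_clones": len(clone_recovered),
        "illusion_clone_recall": (float(np.mean(clone_recovered))
                                  if clone_recovered else np.nan),
    }


# ---------------------------------------------------------------------------
# trees

def truth_clusters(pt) -> list[CloneCluster]:
    return [CloneCluster(i, [], pt.prevalence[i])
            for i in range(pt.n_clones)]


def tree_recovery(seed: int, n_patients: int = 20) -> dict:
    """Build trees from true clone prevalences; compare patterns to truth."""
    cfg = SimulationConfig(n_patients=n_patients, seed=seed)
    truth = build_truth(cfg)
    n_match = 0
    for pt in truth.patients:
        tree = build_clone_tree(truth_clusters(pt))
        n_match += (tree.evolution_pattern == pt.pattern)
    return {"pattern_match_rate": n_match / len(truth.patients),
            "n": len(truth.patients)}


# ---------------------------------------------------------------------------
# MSAI

def simulate_arm_baf(rng, planted: bool, n_snps: int = 40,
                     depth: float = 50.0, purity: float = 0.7,
                     arm=("chr1", 0, 5_000_000)) -> pd.DataFrame:
    """Phased SNP BAF table for one arm in two regions.

    Planted: haplotype A gained (2+1) in region 1, haplotype B gained in
    region 2; null: balanced 1+1 in both.
    """
    chrom, start, end = arm
    pos = np.sort(rng.integers(start + 1, end, size=n_snps))
    hap = rng.integers(0, 2, size=n_snps)
    rows = []
    for reg, (cna, cnb) in (("R1", (2, 1) if planted else (1, 1)),
                            ("R2", (1, 2) if planted else (1, 1))):
        tot = purity * (cna + cnb) + 2 * (1 - purity)
        f = np.where(hap == 0, (purity * cna + (1 - purity)) / tot,
                     (purity * cnb + (1 - purity)) / tot)
        dep = np.maximum(rng.poisson(depth, size=n_snps), 1)
        alt = rng.binomial(dep, f)
        for p, h, d, a in zip(pos, hap, dep, alt):
            rows.append(("P1", reg, chrom, int(p), int(d - a), int(a),
                         "A" if h == 0 else "B"))
    return pd.DataFrame(rows, columns=["patient", "region", "chrom", "pos",
                                       "ref_reads", "alt_reads",
                                       "haplotype"])


def msai_power(seed: int, n_sims: int = 200, depth: float = 50.0,
               purity: float = 0.7) -> dict:
    """Detection rate of planted mirrored arm events."""
    rng = np.random.default_rng(seed)
    arms = pd.DataFrame([("chr1p", "chr1", 0, 5_000_000)],
                        columns=["arm", "chrom", "start", "end"])
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            baf = simulate_arm_baf(rng, planted=True, depth=depth,
                                   purity=purity)
            hits += bool(scna.detect_msai(baf, arms))
    return {"detection_rate": hits / n_sims, "n": n_sims}


def msai_false_positive_rate(seed: int, n_sims: int = 1000,
                             depth: float = 50.0) -> dict:
    """MSAI call rate on balanced (null) arms."""
    rng = np.random.default_rng(seed)
    arms = pd.DataFrame([("chr1p", "chr1", 0, 5_000_000)],
                        columns=["arm", "chrom", "start", "end"])
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            baf = simulate_arm_baf(rng, planted=False, depth=depth)
            hits += bool(scna.detect_msai(baf, arms))
    return {"false_positive_rate": hits / n_sims, "n": n_sims}


# ---------------------------------------------------------------------------
# DMRs

def dmr_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Planted-DMR recovery and empirical false-call rate on null bins.

    One single-patient cohort per seed; DMRs are called on
    purity/copy-deconvolved counts against the matched normal.
    """
    rec_hit = rec_tot = fdr_hit = fdr_tot = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_patients=1, regions_per_patient=(3, 3),
                               n_genes=20, n_epiallele_loci=2,
                               seed=seed + s)
        cohort = simulate_cohort(cfg)
        truth_bins = cohort.truth.bins.set_index("bin_id")
        meth = cohort.methylation
        pat = cohort.truth.patients[0].patient
        pp = cohort.purity_ploidy
        purity_by_region = dict(zip(pp.region, pp.purity))
        tumor = meth[meth.region != "NORMAL"]
        normal = meth[meth.region == "NORMAL"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tumor = methylome.deconvolve_counts(
                tumor, normal, purity_by_region, cohort.segments)
            tb = pd.concat([
                methylome.bin_methylation(
                    g[["chrom", "pos", "meth_reads", "total_reads"]],
                    cfg.cpg_bin_size)
                for _, g in tumor.groupby("region")])
            nb = methylome.bin_methylation(
                normal[["chrom", "pos", "meth_reads", "total_reads"]],
                cfg.cpg_bin_size)
            dmrs = methylome.call_dmrs(tb, nb)
        # map called bins back to planted bins via coordinates
        coord_to_truth = {f"{c}:{(s0 // cfg.cpg_bin_size) * cfg.cpg_bin_size}":
                          d for c, s0, d in
                          zip(truth_bins.chrom, truth_bins.start,
                              truth_bins.dmr)}
        for r in dmrs.itertuples(index=False):
            t = coord_to_truth.get(r.bin_id)
            if t is None:
                continue
            if t in ("hyper", "hypo"):
                rec_tot += 1
                rec_hit += (r.status == t)
            else:
                fdr_tot += 1
                fdr_hit += (r.status != "none")
    return {"recovery": rec_hit / rec_tot, "n_planted": rec_tot,
            "null_call_rate": fdr_hit / fdr_tot, "n_null": fdr_tot}


# ---------------------------------------------------------------------------
# APITH

def apith_vs_region_count(seed: int, n_patients: int = 24) -> dict:
    """Regression of APITH on region count over exchangeable regions.

    Returns the OLS slope and its 95% CI; under exchangeability the CI
    should cover 0.
    """
    import statsmodels.api as sm

    cfg = SimulationConfig(n_patients=n_patients,
                           regions_per_patient=(2, 6), n_genes=20,
                           n_epiallele_loci=2, purity=(0.99, 1.0),
                           seed=seed)
    cohort = simulate_cohort(cfg)
    meth = cohort.methylation
    ks, vals = [], []
    for pat, pgrp in meth.groupby("patient"):
        tumor = pgrp[pgrp.region != "NORMAL"]
        levels = {}
        for reg, rgrp in tumor.groupby("region"):
            b = methylome.bin_methylation(
                rgrp[["chrom", "pos", "meth_reads", "total_reads"]],
                cfg.cpg_bin_size)
            levels[reg] = b.set_index("bin_id").level
        prof = pd.DataFrame(levels).dropna()
        if prof.shape[1] < 2:
            continue
        ks.append(prof.shape[1])
        vals.append(methylome.compute_apith(prof))
    X = sm.add_constant(np.array(ks, float))
    fit = sm.OLS(np.array(vals), X).fit()
    lo, hi = fit.conf_int()[1]
    return {"slope": float(fit.params[1]), "ci_low": float(lo),
            "ci_high": float(hi), "n": len(ks)}


# ---------------------------------------------------------------------------
# RNA

def rna_quadrant_recovery(seed: int, n_patients: int = 10) -> dict:
    """Planted quadrant-class recovery and class IV vs I concordance."""
    cfg = SimulationConfig(n_patients=n_patients,
                           regions_per_patient=(4, 4), n_genes=400,
                           n_cpg_bins=10, n_epiallele_loci=2,
                           dosage_effect=0.0,
                           promoter_coupled_fraction=0.0, seed=seed)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logx = rna.filter_normalize(cohort.expression)
    marker_genes = {g for gl in cohort.markers.values() for g in gl}
    coding = logx.loc[[g for g in logx.index if g not in marker_genes]]
    het = rna.heterogeneity_scores(coding)
    truth_class = cohort.truth.genes.set_index("gene").quadrant_class
    common = het.index.intersection(truth_class.index)
    acc = float((het.loc[common, "quadrant"]
                 == truth_class.loc[common]).mean())
    conc = rna.clustering_concordance(coding)
    iv = conc[truth_class.reindex(conc.index) == "IV"].dropna()
    i_ = conc[truth_class.reindex(conc.index) == "I"].dropna()
    stat, p = stats.ranksums(iv, i_, alternative="greater")
    return {"recovery": acc, "n": len(common),
            "concordance_iv_minus_i": float(iv.mean() - i_.mean()),
            "iv_gt_i_p": float(p)}


def dosage_shift(seed: int, n_patients: int = 6) -> dict:
    """Mean paired expression shift for genes on gained/lost segments."""
    cfg = SimulationConfig(n_patients=n_patients,
                           regions_per_patient=(3, 4), n_genes=300,
                           n_cpg_bins=10, n_epiallele_loci=2, seed=seed)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logx = rna.filter_normalize(cohort.expression)
        calls = scna.segment_calls(cohort.segments, cohort.purity_ploidy)
        genes = cohort.truth.genes[["gene", "chrom", "tss"]]
        gc = rna.gene_copy_state(genes, calls)
        deltas, tests = rna.dosage_association(logx, gc)
    out = {"n_pairs": int(len(deltas))}
    for r in tests.itertuples(index=False):
        out[f"mean_delta_{r.direction}"] = float(r.mean_delta)
        out[f"p_{r.direction}"] = float(r.p_value)
    return out


def promoter_coupling(seed: int, n_patients: int = 6) -> dict:
    """Planted promoter-hypermethylation/expression coupling by element.

    The generator silences genes whose promoter is hypermethylated in one
    region; the promoter stratum of the paired test should show a
    negative shift while the gene-body stratum (CpGs 4-20 kb from the
    TSS, unrelated to the planted effect) should not.
    """
    cfg = SimulationConfig(n_patients=n_patients,
                           regions_per_patient=(3, 4), n_genes=200,
                           promoter_coupled_fraction=0.15,
                           dosage_effect=0.0, gd_fraction=0.0,
                           n_epiallele_loci=2, seed=seed)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logx = rna.filter_normalize(cohort.expression)
        genes = cohort.truth.genes[["gene", "chrom", "tss"]]
        meth = cohort.methylation
        deltas, tests = rna.promoter_methylation_association(
            logx, meth[meth.region != "NORMAL"], genes)
    out = {"n_pairs": int(len(deltas))}
    for r in tests.itertuples(index=False):
        out[f"mean_delta_{r.element}"] = float(r.mean_delta)
        out[f"p_{r.element}"] = float(r.p_value)
        out[f"n_{r.element}"] = int(r.n)
    return out


def dosage_null_type1(seed: int, n_reps: int = 500, n_genes: int = 200,
                      alpha: float = 0.05) -> dict:
    """Type-I error of the paired dosage t-test under a null generator.

    Each replicate draws paired expression differences with no dosage
    effect (pure noise) and applies the same paired t-test.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        d = rng.normal(0.0, 1.0, size=n_genes)
        _, p = stats.ttest_1samp(d, 0.0)
        hits += (p < alpha)
    return {"type1_rate": hits / n_reps, "n": n_reps, "alpha": alpha}


# ---------------------------------------------------------------------------
# immune

def til_recovery(seed: int, n_seeds: int = 50) -> dict:
    """Region/patient infiltration-state recovery over repeated cohorts."""
    from mrith import immune as imm

    region_ok = region_tot = patient_ok = patient_tot = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_patients=6, regions_per_patient=(2, 4),
                               n_genes=20, n_cpg_bins=10,
                               n_epiallele_loci=2, seed=seed + s)
        cohort = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logx = rna.filter_normalize(cohort.expression)
            scores = imm.immune_scores(logx, cohort.markers)
            til = imm.classify_til(scores)
        for pt in cohort.truth.patients:
            truth_states = pt.infiltration
            for reg, state in truth_states.items():
                region_tot += 1
                region_ok += (til.region_labels[f"{pt.patient}_{reg}"]
                              == state)
            vals = set(truth_states.values())
            want = "heterogeneous" if len(vals) == 2 else vals.pop()
            patient_tot += 1
            patient_ok += (til.patient_labels[pt.patient] == want)
    return {"region_accuracy": region_ok / region_tot,
            "patient_accuracy": patient_ok / patient_tot,
            "n_regions": region_tot, "n_patients": patient_tot}


# ---------------------------------------------------------------------------
# signatures

def random_signatures(rng, n_signatures: int = 10) -> np.ndarray:
    """Sparse random 96-channel signature profiles (columns sum to 1)."""
    sig = rng.gamma(0.3, size=(96, n_signatures))
    return sig / sig.sum(axis=0)


def signature_mixture_recovery(seed: int, weights=(0.7, 0.3),
                               n_mutations: int = 1000) -> dict:
    """Recover a two-signature mixture from sampled context counts."""
    rng = np.random.default_rng(seed)
    sig = random_signatures(rng)
    w = np.zeros(sig.shape[1])
    w[0], w[1] = weights
    counts = rng.multinomial(n_mutations, sig @ w)
    est, resid = fit_exposures(counts.astype(float), sig)
    return {"exposure_1": float(est[0]), "exposure_2": float(est[1]),
            "max_abs_error": float(np.max(np.abs(est - w))),
            "residual": resid, "n": n_mutations}


# ---------------------------------------------------------------------------
# GD association (directional)

def gd_subclonal_scna(seed: int, n_patients: int = 16) -> dict:
    """Mean subclonal SCNA fraction, GD vs non-GD patients."""
    cfg = SimulationConfig(n_patients=n_patients, gd_fraction=0.5,
                           n_genes=20, n_cpg_bins=10, n_epiallele_loci=2,
                           seed=seed)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls = scna.segment_calls(cohort.segments, cohort.purity_ploidy)
        ith = scna.scna_ith_proportion(calls)
    gd = {p.patient: p.gd for p in cohort.truth.patients}
    ith["gd"] = ith.patient.map(gd)
    return {
        "mean_subclonal_gd": float(
            ith[ith.gd].subclonal_fraction.mean()),
        "mean_subclonal_nongd": float(
            ith[~ith.gd].subclonal_fraction.mean()),
        "n": len(ith),
    }
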