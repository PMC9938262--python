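"""End-to-end pipeline over a simulated (or loaded) multi-region cohort.

Stages run in dependency order: variants -> clonality/clustering/trees,
SCNA -> wGII/arm events/MSAI, methylome -> APITH/DMRs/epialleles,
RNA -> quadrants/RNA-ITH, immune -> TIL classes, neoantigens, and the
cross-omics integration. The per-patient summary (TSV + JSON) is a pure
function of (inputs, config, seed); floats are rounded to 6 digits so the
JSON is byte-stable across runs.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mrith import rna, scna, methylome, immune, integrate
from mrith import variants as var
from mrith.simulate import SimulatedCohort
from mrith.trees import build_clone_tree, TreeConstructionError

log = logging.getLogger(__name__)


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def analyze_variants(cohort: SimulatedCohort, seed: int = 0) -> dict:
    kept, rejected = var.filter_variants(cohort.variants)
    ccfs = var.add_ccf(kept, cohort.purity_ploidy, cohort.segments)
    clonality = var.classify_clonality(ccfs)
    clustering = var.cluster_ccf(kept, cohort.purity_ploidy, cohort.segments,
                                 max_components=8, n_restarts=8, seed=seed)
    # clone-level CCFs: each mutation inherits its cluster's prevalence
    rows = []
    trees = {}
    for pat, res in clustering.items():
        prev = {c.cluster_id: c.prevalence for c in res.clusters}
        # estimated prevalences are noisy; widen the tolerance stepwise
        # before giving up on a tree
        trees[pat] = None
        for eps in (0.05, 0.10, 0.20):
            try:
                trees[pat] = build_clone_tree(res.clusters, eps=eps)
                break
            except TreeConstructionError as e:
                err = e
        if trees[pat] is None:
            log.warning("patient %s: no feasible clone tree (%s)", pat, err)
        for mut, cl in res.assignments.items():
            for j, reg in enumerate(res.regions):
                rows.append((pat, mut, reg, int(cl),
                             float(prev[cl][j])))
    cluster_ccf_tbl = pd.DataFrame(rows, columns=["patient", "mut_id",
                                                  "region", "cluster",
                                                  "cluster_ccf"])
    # clonality with clone-level CCFs for illusion detection
    merged = ccfs.merge(cluster_ccf_tbl, on=["patient", "mut_id", "region"],
                        how="left")
    merged["ccf"] = merged.cluster_ccf.fillna(merged.ccf)
    clonality_clone = var.classify_clonality(merged)
    return {"kept": kept, "rejected": rejected, "ccfs": ccfs,
            "clonality": clonality, "clonality_clone": clonality_clone,
            "clustering": clustering, "trees": trees,
            "cluster_ccf": cluster_ccf_tbl}


def analyze_scna(cohort: SimulatedCohort) -> dict:
    calls = scna.segment_calls(cohort.segments, cohort.purity_ploidy)
    arms = scna.arms_from_genome(cohort.config.genome)
    arm_events = scna.call_arm_events(calls, arms)
    wgii = scna.wgii_table(cohort.segments, cohort.purity_ploidy)
    ith = scna.scna_ith_proportion(calls)
    msai = scna.detect_msai(cohort.snp_baf, arms)
    return {"calls": calls, "arm_events": arm_events, "wgii": wgii,
            "scna_ith": ith, "msai": msai}


def analyze_methylome(cohort: SimulatedCohort) -> dict:
    cfg = cohort.config
    meth = cohort.methylation
    apith = {}
    dmrs = {}
    pp = cohort.purity_ploidy
    for pat, pgrp in meth.groupby("patient"):
        tumor = pgrp[pgrp.region != "NORMAL"]
        normal = pgrp[pgrp.region == "NORMAL"]
        purity_by_region = dict(zip(pp[pp.patient == pat].region,
                                    pp[pp.patient == pat].purity))
        tumor = methylome.deconvolve_counts(
            tumor, normal, purity_by_region,
            cohort.segments[cohort.segments.patient == pat])
        levels = {}
        tumor_binned = []
        for reg, rgrp in tumor.groupby("region"):
            b = methylome.bin_methylation(
                rgrp[["chrom", "pos", "meth_reads", "total_reads"]],
                cfg.cpg_bin_size)
            levels[reg] = b.set_index("bin_id").level
            tumor_binned.append(b)
        prof = pd.DataFrame(levels).dropna()
        if prof.shape[1] >= 2:
            apith[pat] = methylome.compute_apith(prof)
        nb = methylome.bin_methylation(
            normal[["chrom", "pos", "meth_reads", "total_reads"]],
            cfg.cpg_bin_size)
        dmrs[pat] = methylome.call_dmrs(pd.concat(tumor_binned), nb)
    epi = methylome.epiallele_table(cohort.epialleles)
    return {"apith": apith, "dmrs": dmrs, "epiallele_metrics": epi}


def analyze_rna(cohort: SimulatedCohort, seed: int = 0) -> dict:
    logx = rna.filter_normalize(cohort.expression)
    marker_genes = {g for gl in cohort.markers.values() for g in gl}
    coding = logx.loc[[g for g in logx.index if g not in marker_genes]]
    het = rna.heterogeneity_scores(coding)
    patients = sorted({c.rsplit("_", 1)[0] for c in coding.columns})
    ith = {}
    for pat in patients:
        cols = [c for c in coding.columns if c.startswith(pat + "_")]
        if len(cols) < 2:
            continue
        score, _ = rna.patient_rna_ith(coding[cols], seed=seed)
        ith[pat] = score
    return {"log_expr": logx, "coding": coding, "heterogeneity": het,
            "rna_ith": ith}


def analyze_immune(cohort: SimulatedCohort, logx: pd.DataFrame) -> dict:
    scores = immune.immune_scores(logx, cohort.markers)
    til = immune.classify_til(scores)
    timing = immune.classify_hla_loh_timing(cohort.hla_loh)
    return {"scores": scores, "til": til, "hla_timing": timing}


def analyze_neoantigens(cohort: SimulatedCohort,
                        presence: pd.DataFrame) -> dict:
    # a clone's regions = regions where its candidate mutations are present
    cand = cohort.neoantigen_candidates
    clone_regions: dict = {}
    merged = cand.merge(
        cohort.variants[["patient", "mut_id", "region", "t_alt", "t_ref"]],
        on=["patient", "mut_id"], how="left")
    g = var.genotype_presence(merged.dropna(subset=["t_alt"]))
    for (pat, clone), grp in g[g.present].groupby(["patient", "clone"]):
        clone_regions[(pat, clone)] = set(grp.region)
    filtered = immune.filter_neoantigens(cand, cohort.hla_loh, clone_regions)
    summary = immune.neoantigen_summary(filtered, presence)
    return {"filtered": filtered, "summary": summary}


def analyze_integration(cohort: SimulatedCohort, results: dict) -> dict:
    calls = results["scna"]["calls"]
    cn_prof = calls.assign(sample=calls.patient + "_" + calls.region) \
        .pivot_table(index=["chrom", "start"], columns="sample",
                     values="total_cn")
    meth = cohort.methylation
    tumor = meth[meth.region != "NORMAL"]
    lv = {}
    for (pat, reg), grp in tumor.groupby(["patient", "region"]):
        b = methylome.bin_methylation(
            grp[["chrom", "pos", "meth_reads", "total_reads"]],
            cohort.config.cpg_bin_size)
        lv[f"{pat}_{reg}"] = b.set_index("bin_id").level
    meth_prof = pd.DataFrame(lv).dropna()
    profiles = {
        "scna": cn_prof.dropna(),
        "expression": results["rna"]["coding"],
        "methylation": meth_prof,
        "immune": results["immune"]["scores"].T,
    }
    dist = integrate.omic_distances(profiles)
    mds = {omic: integrate.mds_embed(dm.to_numpy())
           for omic, dm in dist.distances.items()}
    return {"distances": dist, "mds": mds}


def run_pipeline(cohort: SimulatedCohort, seed: int = 0,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage on a cohort; returns results plus the summary."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results: dict = {}
        results["variants"] = analyze_variants(cohort, seed=seed)
        results["scna"] = analyze_scna(cohort)
        results["methylome"] = analyze_methylome(cohort)
        results["rna"] = analyze_rna(cohort, seed=seed)
        results["immune"] = analyze_immune(cohort,
                                           results["rna"]["log_expr"])
        results["neoantigen"] = analyze_neoantigens(
            cohort, results["variants"]["clonality_clone"])
        results["integration"] = analyze_integration(cohort, results)

    summary = build_summary(cohort, results)
    results["summary"] = summary
    if out_dir is not None:
        write_outputs(results, cohort, Path(out_dir))
    return results


def build_summary(cohort: SimulatedCohort, results: dict) -> pd.DataFrame:
    clon = results["variants"]["clonality_clone"]
    trees = results["variants"]["trees"]
    wgii = results["scna"]["wgii"]
    ith = results["scna"]["scna_ith"].set_index("patient")
    msai_by_pat: dict[str, int] = {}
    for ev in results["scna"]["msai"]:
        msai_by_pat[ev.patient] = msai_by_pat.get(ev.patient, 0) + 1
    apith = results["methylome"]["apith"]
    rna_ith = results["rna"]["rna_ith"]
    til = results["immune"]["til"].patient_labels
    neo = results["neoantigen"]["summary"].set_index("patient")

    rows = []
    for pt in cohort.truth.patients:
        pat = pt.patient
        c = clon[clon.patient == pat]
        tree = trees.get(pat)
        w = wgii[wgii.patient == pat]
        rows.append({
            "patient": pat,
            "n_regions": len(pt.regions),
            "n_mutations": int(c.mut.nunique()),
            "snv_ith": _round(float(c.snv_ith.iloc[0])) if len(c) else None,
            "n_illusions": int(c.illusion.sum()) if len(c) else 0,
            "evolution_pattern": (tree.evolution_pattern if tree else None),
            "n_clones": (len(tree.clusters) if tree else None),
            "mean_wgii": _round(float(w.wgii.mean())),
            "gd": bool(w.gd.any()),
            "subclonal_scna_fraction":
                _round(float(ith.loc[pat, "subclonal_fraction"]))
                if pat in ith.index else None,
            "n_msai_events": msai_by_pat.get(pat, 0),
            "apith": _round(apith.get(pat)) if apith.get(pat) is not None
                else None,
            "rna_ith": _round(rna_ith.get(pat)) if rna_ith.get(pat)
                is not None else None,
            "til_class": til.get(pat),
            "n_putative_neoepitopes":
                int(neo.loc[pat, "n_retained"]) if pat in neo.index else 0,
            "n_expressed_neoepitopes":
                int(neo.loc[pat, "n_expressed"]) if pat in neo.index else 0,
        })
    return pd.DataFrame(rows)


def write_outputs(results: dict, cohort: SimulatedCohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary = results["summary"]
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    payload = {
        "schema_version": 1,
        "seed": int(cohort.config.seed),
        "n_patients": int(cohort.config.n_patients),
        "patients": json.loads(summary.to_json(orient="records")),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    results["variants"]["clonality_clone"].to_csv(
        out / "clonality.tsv", sep="\t", index=False)
    results["scna"]["wgii"].to_csv(out / "wgii.tsv", sep="\t", index=False)
    results["scna"]["arm_events"].to_csv(out / "arm_calls.tsv", sep="\t",
                                         index=False)
    results["methylome"]["epiallele_metrics"].to_csv(
        out / "epiallele_metrics.tsv", sep="\t", index=False)
    results["rna"]["heterogeneity"].to_csv(out / "gene_heterogeneity.tsv",
                                           sep="\t")
    results["neoantigen"]["summary"].to_csv(out / "neoantigens.tsv",
                                            sep="\t", index=False)
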