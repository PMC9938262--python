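"""Multi-region expression heterogeneity: quadrants, concordance, RNA-ITH.

Per-gene heterogeneity is split into a within-patient (intra) and a
between-patient (inter) component on log2(TPM+1) values:

    intra(g) = mean over patients of the SD of g across that patient's
               regions;
    inter(g) = SD over patients of the patient-mean of g.

Splitting both scores at their respective cohort means defines four gene
classes: I (intra-high only), II (both low), III (both high) and
IV (inter-high only) — class IV genes are stable within a tumor but
differ between tumors, class I genes vary regionally within tumors.

The patient-level RNA-ITH is the median pairwise (1 - Spearman rho)
between the patient's regions over retained genes, with a region-count
saturation curve from subsampled region sets.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

TPM_MIN = 1.0
PREVALENCE_MIN = 0.20


def _patients_of(columns) -> pd.Series:
    return pd.Series([c.rsplit("_", 1)[0] for c in columns], index=columns)


def filter_normalize(tpm: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with TPM >= 1 in >= 20% of samples; log2(TPM+1) transform."""
    if tpm.empty:
        raise ValueError("empty expression matrix")
    keep = (tpm >= TPM_MIN).mean(axis=1) >= PREVALENCE_MIN
    return np.log2(tpm[keep] + 1.0)


def heterogeneity_scores(log_expr: pd.DataFrame,
                         patients: pd.Series | None = None) -> pd.DataFrame:
    """Intra/inter heterogeneity scores and quadrant classes per gene.

    ``patients`` maps sample id -> patient; defaults to the prefix before
    the final underscore. Patients with a single region are excluded from
    the intra score with a warning.
    """
    if patients is None:
        patients = _patients_of(log_expr.columns)
    groups = patients.groupby(patients).groups
    multi = {p: idx for p, idx in groups.items() if len(idx) >= 2}
    single = set(groups) - set(multi)
    if single:
        warnings.warn(f"patients with one region excluded from intra score: "
                      f"{sorted(single)}")
    if len(groups) < 2 or not multi:
        raise ValueError("need >=2 patients with >=2 regions")
    intra = pd.concat(
        [log_expr[list(idx)].std(axis=1, ddof=1) for idx in multi.values()],
        axis=1).mean(axis=1)
    patient_means = pd.concat(
        {p: log_expr[list(idx)].mean(axis=1) for p, idx in groups.items()},
        axis=1)
    inter = patient_means.std(axis=1, ddof=1)
    mi, me = intra.mean(), inter.mean()
    quad = np.select(
        [(intra > mi) & (inter <= me),
         (intra <= mi) & (inter <= me),
         (intra > mi) & (inter > me)],
        ["I", "II", "III"], default="IV")
    return pd.DataFrame({"gene": log_expr.index, "intra": intra.to_numpy(),
                         "inter": inter.to_numpy(), "quadrant": quad}
                        ).set_index("gene")


def clustering_concordance(log_expr: pd.DataFrame,
                           patients: pd.Series | None = None) -> pd.Series:
    """Mean silhouette width of the patient partition per single gene.

    Computed on the 1-D value vector of each gene with Euclidean distance;
    1 means regions separate perfectly by patient on that gene alone,
    ~0 means no patient structure. Degenerate genes (all values equal)
    score 0.
    """
    if patients is None:
        patients = _patients_of(log_expr.columns)
    labels = patients[log_expr.columns].to_numpy()
    out = np.zeros(len(log_expr))
    x = log_expr.to_numpy()
    for i in range(len(log_expr)):
        v = x[i]
        if np.allclose(v, v[0]):
            out[i] = 0.0
            continue
        out[i] = float(silhouette_samples(v.reshape(-1, 1), labels).mean())
    return pd.Series(out, index=log_expr.index, name="concordance")


def patient_rna_ith(log_expr: pd.DataFrame, *, max_subsets: int = 20,
                    n_random: int = 100, seed: int = 0
                    ) -> tuple[float, pd.DataFrame]:
    """RNA-ITH of one patient and its region-count saturation curve.

    ``log_expr``: genes x regions of one patient. RNA-ITH = median
    pairwise (1 - Spearman rho). The saturation curve reports, for
    r = 2..k, the mean score over region subsets (all subsets when there
    are <= ``max_subsets``, else ``n_random`` seeded random ones).
    """
    k = log_expr.shape[1]
    if k < 2:
        raise ValueError("RNA-ITH needs >=2 regions")
    x = log_expr.to_numpy()
    cols = list(log_expr.columns)
    rho = stats.spearmanr(x).statistic if k > 2 else None

    def pair_d(i, j):
        if k == 2:
            return 1.0 - float(stats.spearmanr(x[:, i], x[:, j]).statistic)
        return 1.0 - float(rho[i, j])

    dist = {(i, j): pair_d(i, j) for i, j in combinations(range(k), 2)}

    def score(idx):
        vals = [dist[(min(i, j), max(i, j))]
                for i, j in combinations(sorted(idx), 2)]
        return float(np.median(vals))

    full = score(range(k))
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(2, k + 1):
        subsets = list(combinations(range(k), r))
        if len(subsets) > max_subsets:
            pick = rng.choice(len(subsets), size=n_random, replace=True)
            subsets = [subsets[i] for i in pick]
        rows.append((r, float(np.mean([score(s) for s in subsets])),
                     len(subsets)))
    curve = pd.DataFrame(rows, columns=["n_regions", "mean_score",
                                        "n_subsets"])
    return full, curve


# ---------------------------------------------------------------------------
# associations

def gene_copy_state(genes: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, region, gene) copy call from overlapping segments.

    ``genes`` columns: gene, chrom, tss. ``calls``: the segment-call
    table. Returns rows (patient, region, gene, call).
    """
    rows = []
    for (pat, reg), grp in calls.groupby(["patient", "region"]):
        for g in genes.itertuples(index=False):
            seg = grp[(grp.chrom == g.chrom) & (grp.start <= g.tss)
                      & (grp.end > g.tss)]
            call = seg.call.iloc[0] if len(seg) else "neutral"
            rows.append((pat, reg, g.gene,
                         "gain" if call == "amp" else call))
    return pd.DataFrame(rows, columns=["patient", "region", "gene", "call"])


def dosage_association(log_expr: pd.DataFrame, gene_calls: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression shift of copy-altered vs copy-neutral regions per gene.

    For every gene with, in the same patient, at least one region where it
    is gained (or lost) and one where it is neutral, the paired difference
    Delta = log2expr(altered) - log2expr(neutral) (region means within
    each state). Returns (per-gene deltas, per-direction paired t-tests).
    """
    pivot = gene_calls.pivot_table(index=["patient", "gene"],
                                   columns="region", values="call",
                                   aggfunc="first")
    rows = []
    for (pat, gene), calls in pivot.iterrows():
        calls = calls.dropna()
        for direction in ("gain", "loss"):
            alt_regions = [r for r, c in calls.items() if c == direction]
            neu_regions = [r for r, c in calls.items() if c == "neutral"]
            if not alt_regions or not neu_regions:
                continue
            if gene not in log_expr.index:
                continue
            e = log_expr.loc[gene]
            alt_cols = [f"{pat}_{r}" for r in alt_regions
                        if f"{pat}_{r}" in e.index]
            neu_cols = [f"{pat}_{r}" for r in neu_regions
                        if f"{pat}_{r}" in e.index]
            if not alt_cols or not neu_cols:
                continue
            rows.append((pat, gene, direction,
                         float(e[alt_cols].mean() - e[neu_cols].mean())))
    deltas = pd.DataFrame(rows, columns=["patient", "gene", "direction",
                                         "delta"])
    tests = []
    for direction, grp in deltas.groupby("direction"):
        d = grp.delta.to_numpy()
        if len(d) < 2:
            tests.append((direction, len(d), float(np.mean(d)) if len(d)
                          else np.nan, np.nan, np.nan))
            continue
        t, p = stats.ttest_1samp(d, 0.0)   # paired differences vs 0
        tests.append((direction, len(d), float(d.mean()), float(t),
                      float(p)))
    tests = pd.DataFrame(tests, columns=["direction", "n_genes",
                                         "mean_delta", "t", "p_value"])
    return deltas, tests


def copy_class_quadrant_enrichment(gene_classes: pd.Series,
                                   copy_classes: pd.Series) -> pd.DataFrame:
    """Fisher's exact enrichment of copy classes across the four quadrants.

    Both series are indexed by gene; copy classes are e.g. clonal_gain,
    subclonal_loss, no_change.
    """
    df = pd.DataFrame({"quadrant": gene_classes, "copy": copy_classes}
                      ).dropna()
    rows = []
    for q in sorted(df.quadrant.unique()):
        for c in sorted(df["copy"].unique()):
            a = int(((df.quadrant == q) & (df["copy"] == c)).sum())
            b = int((df.quadrant == q).sum()) - a
            cc = int((df["copy"] == c).sum()) - a
            d = len(df) - a - b - cc
            odds, p = stats.fisher_exact([[a, b], [cc, d]],
                                         alternative="two-sided")
            rows.append((q, c, a, odds, p))
    return pd.DataFrame(rows, columns=["quadrant", "copy_class", "n",
                                       "odds_ratio", "p_value"])


DEFAULT_ELEMENT_WINDOWS = {
    # offsets relative to the TSS, 0-based half-open
    "promoter": (-2000, 2000),
    "first_exon": (2000, 4000),
    "gene_body": (4000, 20000),
}


def promoter_methylation_association(
        log_expr: pd.DataFrame, cpgs: pd.DataFrame, genes: pd.DataFrame, *,
        windows: dict[str, tuple[int, int]] | None = None,
        alpha: float = 0.05, min_diff: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression shift between regions with differential element methylation.

    Per genomic element (promoter = TSS +/- 2 kb by default, plus first
    exon and gene body windows): an element is differentially methylated
    between two regions of a patient when at least one of its CpGs has a
    Fisher exact p < 0.05 on (meth, unmeth) counts AND an absolute level
    difference >= ``min_diff``. For each such (gene, region pair) the
    paired expression difference (hyper minus hypo region) is recorded;
    a one-sample t-test of the differences against 0 per element
    summarizes the coupling. Genes without CpG coverage in an element are
    skipped for that element.
    """
    if windows is None:
        windows = DEFAULT_ELEMENT_WINDOWS
    rows = []
    for g in genes.itertuples(index=False):
        if g.gene not in log_expr.index:
            continue
        for element, (lo, hi) in windows.items():
            win = cpgs[(cpgs.chrom == g.chrom)
                       & (cpgs.pos >= g.tss + lo)
                       & (cpgs.pos < g.tss + hi)]
            if win.empty:
                continue
            for pat, pgrp in win.groupby("patient"):
                regions = sorted(r for r in pgrp.region.unique()
                                 if r != "NORMAL")
                for r1, r2 in combinations(regions, 2):
                    merged = pgrp[pgrp.region == r1].merge(
                        pgrp[pgrp.region == r2], on=["chrom", "pos"],
                        suffixes=("_1", "_2"))
                    if merged.empty:
                        continue
                    diff_found, ddir = False, 0.0
                    for m in merged.itertuples(index=False):
                        l1 = m.meth_reads_1 / m.total_reads_1
                        l2 = m.meth_reads_2 / m.total_reads_2
                        if abs(l1 - l2) < min_diff:
                            continue
                        _, p = stats.fisher_exact(
                            [[m.meth_reads_1,
                              m.total_reads_1 - m.meth_reads_1],
                             [m.meth_reads_2,
                              m.total_reads_2 - m.meth_reads_2]])
                        if p < alpha:
                            diff_found = True
                            ddir = l1 - l2
                            break
                    if not diff_found:
                        continue
                    c1, c2 = f"{pat}_{r1}", f"{pat}_{r2}"
                    if c1 not in log_expr.columns \
                            or c2 not in log_expr.columns:
                        continue
                    e1 = float(log_expr.loc[g.gene, c1])
                    e2 = float(log_expr.loc[g.gene, c2])
                    # orient: expression of hyper region minus hypo region
                    delta = (e1 - e2) if ddir > 0 else (e2 - e1)
                    rows.append((element, pat, g.gene, r1, r2,
                                 float(abs(ddir)), delta))
    deltas = pd.DataFrame(rows, columns=["element", "patient", "gene",
                                         "region_1", "region_2",
                                         "meth_diff", "expr_delta"])
    tests = []
    for element, grp in deltas.groupby("element"):
        d = grp.expr_delta.to_numpy()
        if len(d) < 2:
            continue
        t, p = stats.ttest_1samp(d, 0.0)
        tests.append((element, len(d), float(d.mean()), float(t), float(p)))
    tests = pd.DataFrame(tests, columns=["element", "n", "mean_delta", "t",
                                         "p_value"])
    return deltas, tests
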