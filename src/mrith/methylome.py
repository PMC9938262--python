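"""RRBS methylome heterogeneity: deconvolution, DMRs, APITH, epialleles.

The observed bulk methylation rate m_b at a CpG is a purity- and
copy-weighted mixture of the tumor rate m_t (over n_t tumor copies at
purity rho) and the normal rate m_n (over n_n = 2 normal copies). The
deconvolved tumor rate inverts that mixture,

    m_t = [m_b (rho n_t + n_n (1 - rho)) - n_n m_n (1 - rho)] / (rho n_t),

clamped to [0, 1] against technical noise.

Epiallele diversity treats the 16 phased methylation patterns of a 4-CpG
locus as categories with read frequencies p: Shannon entropy -sum p log2 p
(bits), epipolymorphism 1 - sum p^2, and PDR, the fraction of reads that
are neither fully methylated (1111) nor fully unmethylated (0000). Loci
need >= 60 reads to be analyzed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mrith.simulate import PATTERN_COLS

MIN_CPGS_PER_BIN = 3
DMR_Q = 0.01
DMR_DIFF = 0.25
EPIALLELE_MIN_READS = 60
TOP_VARIABLE = 500


# ---------------------------------------------------------------------------
# deconvolution

def deconvolve_methylation(m_b, m_n, purity, n_t, n_n: float = 2.0):
    """Purity/copy-aware deconvolved tumor methylation rate, clamped to [0,1].

    ``n_t = 0`` sites are undefined and returned as NaN.
    """
    m_b = np.asarray(m_b, float)
    m_n = np.asarray(m_n, float)
    n_t = np.asarray(n_t, float)
    purity = np.asarray(purity, float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (m_b * (purity * n_t + n_n * (1.0 - purity))
               - n_n * m_n * (1.0 - purity)) / (purity * n_t)
    out = np.where(n_t > 0, np.clip(raw, 0.0, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def deconvolve_counts(tumor_cpgs: pd.DataFrame, normal_cpgs: pd.DataFrame,
                      purity_by_region: dict, segments: pd.DataFrame | None
                      ) -> pd.DataFrame:
    """Replace bulk methylated counts by purity/copy-deconvolved ones.

    For every tumor CpG with matched-normal coverage, the bulk rate is
    deconvolved with the region's purity and the local total copy number
    (from overlapping ``segments``; 2 where uncovered), and the
    methylated-read count is re-expressed as ``round(m_t * total_reads)``
    so downstream count-based tests operate on purified tumor levels.
    CpGs without normal coverage keep their bulk counts.
    """
    norm = normal_cpgs.groupby(["chrom", "pos"]).agg(
        n_meth=("meth_reads", "sum"), n_tot=("total_reads", "sum"))
    df = tumor_cpgs.copy().reset_index(drop=True)
    m_n = np.full(len(df), np.nan)
    key = list(zip(df.chrom, df.pos))
    hits = norm.reindex(key)
    with np.errstate(invalid="ignore"):
        m_n = (hits.n_meth / hits.n_tot).to_numpy()
    rho = df.region.map(purity_by_region).to_numpy(float)
    cn = np.full(len(df), 2.0)
    if segments is not None:
        seg = segments.copy()
        seg["total"] = seg.major_cn + seg.minor_cn
        for (reg, chrom), grp in df.groupby(["region", "chrom"]):
            s = seg[(seg.region == reg) & (seg.chrom == chrom)]
            if s.empty:
                continue
            starts, ends = s.start.to_numpy(), s.end.to_numpy()
            totals = s.total.to_numpy()
            for i, p in zip(grp.index, grp.pos.to_numpy()):
                hit = (starts <= p) & (p < ends)
                if hit.any():
                    cn[i] = totals[hit][0]
    m_b = df.meth_reads / df.total_reads
    ok = ~np.isnan(m_n) & ~np.isnan(rho) & (cn > 0)
    m_t = np.where(ok, deconvolve_methylation(m_b, np.nan_to_num(m_n),
                                              np.where(ok, rho, 1.0),
                                              np.where(ok, cn, 2.0)),
                   m_b)
    df["meth_reads"] = np.rint(m_t * df.total_reads).astype(int)
    return df


# ---------------------------------------------------------------------------
# binning

def bin_methylation(cpgs: pd.DataFrame, bin_size: int = 1000, *,
                    min_cpgs: int = MIN_CPGS_PER_BIN) -> pd.DataFrame:
    """Mean per-CpG methylation level in fixed genomic bins.

    ``cpgs`` columns: chrom, pos, meth_reads, total_reads. The bin level
    is the unweighted mean of per-CpG levels; bins with fewer than
    ``min_cpgs`` covered CpGs are dropped. Bin ids encode chrom and
    0-based bin start. Duplicate positions raise.
    """
    df = cpgs.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate CpG positions")
    if df.empty:
        return pd.DataFrame(columns=["bin_id", "chrom", "start", "level",
                                     "n_cpgs", "meth_reads", "total_reads"])
    level = df.meth_reads / df.total_reads
    start = (df.pos // bin_size) * bin_size
    out = (pd.DataFrame({"chrom": df.chrom, "start": start, "level": level,
                         "meth_reads": df.meth_reads,
                         "total_reads": df.total_reads})
           .groupby(["chrom", "start"], as_index=False)
           .agg(level=("level", "mean"), n_cpgs=("level", "size"),
                meth_reads=("meth_reads", "sum"),
                total_reads=("total_reads", "sum")))
    out = out[out.n_cpgs >= min_cpgs].reset_index(drop=True)
    out.insert(0, "bin_id", [f"{c}:{s}" for c, s in
                             zip(out.chrom, out.start)])
    return out


# ---------------------------------------------------------------------------
# DMRs

def call_dmrs(tumor_bins: pd.DataFrame, normal_bins: pd.DataFrame, *,
              q_threshold: float = DMR_Q,
              diff_threshold: float = DMR_DIFF) -> pd.DataFrame:
    """Differentially methylated bins between pooled tumor and normal counts.

    Per common bin, a two-proportion z-test on aggregated
    methylated/unmethylated read counts, BH-adjusted; hyper requires
    q < 0.01 and difference > +0.25, hypo q < 0.01 and difference < -0.25.
    """
    t = tumor_bins.groupby("bin_id").agg(
        t_meth=("meth_reads", "sum"), t_tot=("total_reads", "sum"))
    n = normal_bins.groupby("bin_id").agg(
        n_meth=("meth_reads", "sum"), n_tot=("total_reads", "sum"))
    common = t.join(n, how="inner")
    if common.empty:
        raise ValueError("no bins covered in both tumor and normal")
    p1 = common.t_meth / common.t_tot
    p2 = common.n_meth / common.n_tot
    pool = (common.t_meth + common.n_meth) / (common.t_tot + common.n_tot)
    se = np.sqrt(pool * (1 - pool)
                 * (1 / common.t_tot + 1 / common.n_tot))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    qval = multipletests(pval, method="fdr_bh")[1]
    diff = p1 - p2
    status = np.full(len(common), "none", dtype=object)
    status[(qval < q_threshold) & (diff > diff_threshold)] = "hyper"
    status[(qval < q_threshold) & (diff < -diff_threshold)] = "hypo"
    return pd.DataFrame({
        "bin_id": common.index, "diff": diff.to_numpy(),
        "p_value": pval, "q_value": qval, "status": status,
    }).reset_index(drop=True)


def element_enrichment(hits: set[str], universe: set[str],
                       annotations: dict[str, set[str]]) -> pd.DataFrame:
    """Fisher's exact enrichment of hit bins within annotated elements.

    ``annotations`` maps an element class (promoter, CpG island, LINE-1,
    ...) to the set of bin ids it covers.
    """
    rows = []
    for element, bins in annotations.items():
        a = len(hits & bins & universe)
        b = len(hits & universe) - a
        c = len(bins & universe) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((element, a, odds, p))
    out = pd.DataFrame(rows, columns=["element", "n_hits", "odds_ratio",
                                      "p_value"])
    if len(out):
        out["q_value"] = multipletests(out.p_value, method="fdr_bh")[1]
    return out


def variable_bins(region_levels: pd.DataFrame, *,
                  top_k: int = TOP_VARIABLE) -> pd.DataFrame:
    """Rank bins by standard deviation of level across tumor regions.

    ``region_levels``: bins x regions matrix of methylation levels
    (rows indexed by bin_id). Ties, including the all-zero-SD case, are
    broken by bin id for a stable ranking.
    """
    if region_levels.shape[1] < 2:
        raise ValueError("need >=2 regions")
    sd = region_levels.std(axis=1, ddof=1)
    out = (pd.DataFrame({"bin_id": region_levels.index, "sd": sd.to_numpy()})
           .sort_values(["sd", "bin_id"], ascending=[False, True])
           .reset_index(drop=True))
    if top_k > len(out):
        warnings.warn(f"requested top {top_k} of {len(out)} bins; "
                      "returning all")
    return out.head(top_k)


# ---------------------------------------------------------------------------
# APITH

def compute_apith(profiles: pd.DataFrame) -> float:
    """Average pairwise Euclidean distance between region profiles.

    ``profiles``: features x regions. APITH = (2/(k(k-1))) sum_{i<j} d_ij.
    """
    k = profiles.shape[1]
    if k < 2:
        raise ValueError("APITH needs >=2 regions")
    x = profiles.to_numpy(float).T
    dists = [float(np.linalg.norm(x[i] - x[j]))
             for i in range(k) for j in range(i + 1, k)]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# epialleles

def epiallele_metrics(counts, *, min_reads: int = EPIALLELE_MIN_READS):
    """Shannon entropy (bits), epipolymorphism and PDR of one locus.

    ``counts``: the 16 pattern counts (0000..1111 in binary order).
    Returns (entropy, epipolymorphism, pdr), or None when coverage is
    below ``min_reads``.
    """
    c = np.asarray(counts, float)
    if c.shape != (16,):
        raise ValueError("expected 16 pattern counts")
    if np.any(c < 0):
        raise ValueError("negative pattern counts")
    total = c.sum()
    if total < min_reads:
        return None
    p = c / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    epipoly = float(1.0 - (p ** 2).sum())
    pdr = float(1.0 - p[0] - p[15])
    return entropy, epipoly, pdr


def epiallele_table(epialleles: pd.DataFrame, *,
                    min_reads: int = EPIALLELE_MIN_READS) -> pd.DataFrame:
    """Per (patient, region, locus) diversity metrics; low-coverage loci
    are dropped."""
    rows = []
    for r in epialleles.itertuples(index=False):
        counts = np.array([getattr(r, c) for c in PATTERN_COLS], float)
        m = epiallele_metrics(counts, min_reads=min_reads)
        if m is None:
            continue
        rows.append((r.patient, r.region, r.locus, r.chrom, r.start,
                     int(counts.sum()), *m))
    return pd.DataFrame(rows, columns=[
        "patient", "region", "locus", "chrom", "start", "reads",
        "entropy", "epipolymorphism", "pdr"])


def compare_scna_vs_neutral(metrics: pd.DataFrame,
                            locus_altered: pd.Series,
                            value: str = "entropy") -> pd.DataFrame:
    """Wilcoxon rank-sum of a diversity metric, altered vs neutral loci.

    ``locus_altered``: boolean per (patient, region, locus) row aligned
    with ``metrics``. Empty strata yield NA with a warning.
    """
    df = metrics.assign(altered=locus_altered.to_numpy())
    rows = []
    for pat, grp in df.groupby("patient"):
        a = grp.loc[grp.altered, value].to_numpy()
        b = grp.loc[~grp.altered, value].to_numpy()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"{pat}: empty stratum for {value}")
            rows.append((pat, len(a), len(b), np.nan, np.nan, True))
            continue
        stat, p = stats.ranksums(a, b)
        rows.append((pat, len(a), len(b), float(stat), float(p),
                     len(a) < 2 or len(b) < 2))
    return pd.DataFrame(rows, columns=["patient", "n_altered", "n_neutral",
                                       "statistic", "p_value", "low_n"])
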