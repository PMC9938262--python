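"""Somatic-variant filtering, CCF estimation and clonality classification.

The variant unit is the (patient, mutation) pair observed across that
patient's tumor regions with a shared matched normal. Three quality filters
are applied before any downstream analysis:

(i)   total read depth > 10 in both the tumor region and the normal;
(ii)  normal VAF < 0.02 and no more than 3 variant-supporting reads in the
      normal;
(iii) tumor VAF > 0.05 with more than 5 variant-supporting reads.

A variant is retained when at least one tumor region passes all three. A
retained variant is then genotyped as *present* in a region when its VAF
exceeds 0.02 or more than 3 reads support the variant allele — the relaxed
multi-region presence rule that recovers low-VAF calls missed in individual
regions.

Clonality is defined on presence: a mutation shared by all regions is
clonal, anything else subclonal; the subclonal fraction is the SNV-ITH. A
subclonal mutation whose CCF reaches ~1 in some region is flagged as a
"clonal illusion" — it would look clonal in a single biopsy.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PRESENCE_VAF = 0.02
PRESENCE_ALT_READS = 3
ILLUSION_CCF = 0.9


# ---------------------------------------------------------------------------
# filtering and presence

def filter_variants(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three-part quality filter to a long per-region table.

    Parameters
    ----------
    raw:
        Columns patient, region, chrom, pos, ref, alt, t_alt, t_ref,
        n_alt, n_ref (and optionally mut_id).

    Returns
    -------
    kept, rejected:
        ``kept`` is the subset of rows belonging to variants that pass all
        filters in at least one tumor region. ``rejected`` lists one row
        per removed variant with the first filter it failed
        (``depth`` / ``normal_support`` / ``tumor_support``).
    """
    req = {"patient", "chrom", "pos", "ref", "alt", "t_alt", "t_ref",
           "n_alt", "n_ref"}
    missing = req - set(raw.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")

    df = raw.copy()
    t_dep = df.t_alt + df.t_ref
    n_dep = df.n_alt + df.n_ref
    t_vaf = np.where(t_dep > 0, df.t_alt / t_dep.replace(0, 1), 0.0)
    n_vaf = np.where(n_dep > 0, df.n_alt / n_dep.replace(0, 1), 0.0)

    ok_depth = (t_dep > 10) & (n_dep > 10)
    ok_normal = (n_vaf < 0.02) & (df.n_alt <= 3)
    ok_tumor = (t_vaf > 0.05) & (df.t_alt > 5)
    df["_pass"] = ok_depth & ok_normal & ok_tumor

    key = ["patient", "chrom", "pos", "ref", "alt"]
    any_pass = df.groupby(key)["_pass"].transform("any")
    kept = df[any_pass].drop(columns="_pass").reset_index(drop=True)

    rej_rows = []
    failed = df[~any_pass]
    for k, grp in failed.groupby(key):
        idx = grp.index
        if not ok_depth[idx].any():
            reason = "depth"
        elif not (ok_depth[idx] & ok_normal[idx]).any():
            reason = "normal_support"
        else:
            reason = "tumor_support"
        rej_rows.append((*k, reason))
    rejected = pd.DataFrame(rej_rows, columns=key + ["filter"])
    return kept, rejected


def genotype_presence(variants: pd.DataFrame) -> pd.DataFrame:
    """Presence call per (variant, region): VAF > 0.02 OR alt reads > 3."""
    df = variants.copy()
    dep = df.t_alt + df.t_ref
    vaf = np.where(dep > 0, df.t_alt / dep.replace(0, 1), 0.0)
    df["vaf"] = vaf
    df["present"] = (vaf > PRESENCE_VAF) | (df.t_alt > PRESENCE_ALT_READS)
    return df


# ---------------------------------------------------------------------------
# cancer cell fraction

def compute_ccf(vaf, purity, cn_tumor, multiplicity=1, *,
                printed_form: bool = False, cap: bool = True):
    """Cancer cell fraction from VAF, purity and local copy number.

    The default is the standard mixture-model rearrangement

        CCF = VAF * (CN_t * rho + 2 * (1 - rho)) / (m * rho),

    capped to [0, 1]. ``printed_form=True`` evaluates the alternative
    algebra with the copy-number term in the denominator
    (VAF * (1/rho) / (CN_t * rho + 2*(1-rho))), kept for comparison; it
    does not yield CCF ~ 1 for truncal heterozygous mutations.
    """
    vaf = np.asarray(vaf, float)
    purity = np.asarray(purity, float)
    cn_tumor = np.asarray(cn_tumor, float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    denom_mix = cn_tumor * purity + 2.0 * (1.0 - purity)
    if printed_form:
        ccf = vaf * (1.0 / purity) / denom_mix
    else:
        ccf = vaf * denom_mix / (multiplicity * purity)
    ccf = np.where((cn_tumor == 0) & (vaf > 0), np.nan, ccf)
    if cap:
        ccf = np.clip(ccf, 0.0, 1.0)
    if ccf.ndim == 0:
        return float(ccf)
    return ccf


def add_ccf(variants: pd.DataFrame, purity_ploidy: pd.DataFrame,
            segments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach per-region CCFs, using local total CN from segments if given."""
    df = genotype_presence(variants).reset_index(drop=True)
    pp = purity_ploidy.set_index(["patient", "region"])["purity"]
    df["purity"] = [pp.loc[(p, r)] for p, r in zip(df.patient, df.region)]
    if segments is not None:
        df["cn_tumor"] = _local_total_cn(df, segments)
    else:
        df["cn_tumor"] = 2
    df["ccf"] = compute_ccf(df.vaf.to_numpy(), df.purity.to_numpy(),
                            df.cn_tumor.to_numpy())
    return df


def _local_total_cn(df: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    seg = segments.copy()
    seg["total"] = seg.major_cn + seg.minor_cn
    out = np.full(len(df), 2.0)
    for (pat, reg, chrom), grp in df.groupby(["patient", "region", "chrom"]):
        s = seg[(seg.patient == pat) & (seg.region == reg)
                & (seg.chrom == chrom)]
        if s.empty:
            continue
        starts = s.start.to_numpy()
        ends = s.end.to_numpy()
        totals = s.total.to_numpy()
        pos = grp.pos.to_numpy()
        for i, p in zip(grp.index, pos):
            hit = (starts < p) & (p <= ends)   # pos is 1-based, segs 0-based
            if hit.any():
                out[i] = totals[hit][0]
    return out


# ---------------------------------------------------------------------------
# clonality

def classify_clonality(variants: pd.DataFrame, *,
                       illusion_ccf: float = ILLUSION_CCF) -> pd.DataFrame:
    """Per-mutation clonal/subclonal labels, illusion flags and SNV-ITH.

    Expects the per-region table with ``present`` and ``ccf`` columns;
    returns one row per (patient, mut) with columns label, illusion,
    n_regions, n_present, plus a per-patient ``snv_ith`` (subclonal /
    total) merged in.
    """
    key = ["patient", "chrom", "pos", "ref", "alt"]
    if "mut_id" in variants.columns:
        key = ["patient", "mut_id"]
    rows = []
    for pat, pgrp in variants.groupby("patient"):
        regions = pgrp.region.unique()
        if len(regions) < 2:
            raise ValueError(
                f"patient {pat}: clonality undefined with a single region")
        for k, grp in pgrp.groupby(key[1:] if len(key) == 2 else key[1:]):
            pres = grp[grp.present]
            n_present = pres.region.nunique()
            label = "clonal" if n_present == len(regions) else "subclonal"
            illusion = bool(label == "subclonal" and len(pres)
                            and np.nanmax(pres.ccf.to_numpy()) >= illusion_ccf)
            rows.append((pat, k if np.isscalar(k) else "|".join(map(str, k)),
                         label, illusion, len(regions), n_present))
    out = pd.DataFrame(rows, columns=["patient", "mut", "label", "illusion",
                                      "n_regions", "n_present"])
    ith = out.groupby("patient")["label"].apply(
        lambda s: float((s == "subclonal").mean())).rename("snv_ith")
    return out.merge(ith, on="patient")


# ---------------------------------------------------------------------------
# CCF clustering: finite binomial-mixture EM with BIC model selection

@dataclass
class CloneCluster:
    cluster_id: int
    members: list[str]
    prevalence: np.ndarray  # per region, in [0, 1]


@dataclass
class CcfClusteringResult:
    clusters: list[CloneCluster]
    regions: list[str]
    assignments: pd.Series      # mut -> cluster_id
    bic: float
    n_components_tried: list[int] = field(default_factory=list)


def _em_fit(alt, dep, coef, k, rng, n_iter=200, tol=1e-6):
    """EM for a k-component binomial mixture over per-region counts.

    ``coef`` maps CCF to expected VAF per (mutation, region):
    p = theta * coef, with coef = m * rho / (CN*rho + 2(1-rho)). The
    M-step update theta = sum(gamma*alt) / sum(gamma*dep*coef) is the exact
    MLE for this linear link. Missing regions carry dep=0.
    """
    n, R = alt.shape
    theta = rng.uniform(0.05, 1.0, size=(k, R))
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(n_iter):
        p = np.clip(theta[:, None, :] * coef[None, :, :], 1e-6, 1 - 1e-6)
        loglik = (alt[None] * np.log(p)
                  + (dep - alt)[None] * np.log1p(-p)).sum(axis=2)
        loglik += np.log(pi)[:, None]
        m = loglik.max(axis=0)
        w = np.exp(loglik - m)
        tot = w.sum(axis=0)
        ll = float((np.log(tot) + m).sum())
        gamma = (w / tot).T                       # n x k
        pi = np.maximum(gamma.mean(axis=0), 1e-12)
        pi = pi / pi.sum()
        num = gamma.T @ alt                       # k x R
        den = gamma.T @ (dep * coef)
        theta = np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), 0.0),
                        0.0, 1.0)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return theta, pi, gamma, ll


def cluster_ccf(variants: pd.DataFrame, purity_ploidy: pd.DataFrame,
                segments: pd.DataFrame | None = None, *,
                max_components: int = 10, n_restarts: int = 20,
                seed: int = 0) -> dict[str, CcfClusteringResult]:
    """Cluster mutations of each patient into clones in CCF space.

    A finite binomial-mixture EM over per-region (alt, depth) counts with
    per-cluster per-region CCFs; the number of components is selected by
    BIC over 1..max_components. Deterministic under a fixed seed. Patients
    with fewer than 5 mutations fall back to a single cluster with a
    warning.
    """
    df = add_ccf(variants, purity_ploidy, segments)
    results = {}
    for pat, pgrp in df.groupby("patient"):
        regions = sorted(pgrp.region.unique())
        mut_key = "mut_id" if "mut_id" in pgrp.columns else None
        if mut_key is None:
            pgrp = pgrp.assign(mut_id=[
                f"{c}:{p}:{r}>{a}" for c, p, r, a in
                zip(pgrp.chrom, pgrp.pos, pgrp.ref, pgrp.alt)])
        muts = sorted(pgrp.mut_id.unique())
        n, R = len(muts), len(regions)
        alt = np.zeros((n, R))
        dep = np.zeros((n, R))
        coef = np.zeros((n, R))
        midx = {m: i for i, m in enumerate(muts)}
        ridx = {r: j for j, r in enumerate(regions)}
        for row in pgrp.itertuples(index=False):
            i, j = midx[row.mut_id], ridx[row.region]
            alt[i, j] = row.t_alt
            dep[i, j] = row.t_alt + row.t_ref
            rho = row.purity
            coef[i, j] = rho / (row.cn_tumor * rho + 2.0 * (1.0 - rho))

        rng = np.random.default_rng(seed + zlib.crc32(pat.encode()) % 100_000)
        if n < 5:
            warnings.warn(f"patient {pat}: <5 mutations, single-cluster "
                          "fallback")
            theta = np.clip(
                alt.sum(0) / np.maximum((dep * coef).sum(0), 1e-12), 0, 1)
            assignments = pd.Series(0, index=muts)
            clusters = [CloneCluster(0, muts, theta)]
            results[pat] = CcfClusteringResult(clusters, regions,
                                               assignments, np.nan, [1])
            continue

        best = None
        tried = []
        kmax = min(max_components, n)
        for k in range(1, kmax + 1):
            best_ll, best_fit = -np.inf, None
            for _ in range(n_restarts):
                theta, pi, gamma, ll = _em_fit(alt, dep, coef, k, rng)
                if ll > best_ll:
                    best_ll, best_fit = ll, (theta, pi, gamma)
            n_par = k * R + (k - 1)
            bic = -2.0 * best_ll + n_par * np.log(n)
            tried.append(k)
            if best is None or bic < best[0]:
                best = (bic, k, best_fit)
        bic, k, (theta, pi, gamma) = best
        lab = gamma.argmax(axis=1)
        # drop empty components, renumber by decreasing mean prevalence
        keep = sorted(set(lab),
                      key=lambda c: -float(theta[c].mean()))
        remap = {c: i for i, c in enumerate(keep)}
        clusters = []
        assignments = pd.Series([remap[c] for c in lab], index=muts)
        for c in keep:
            members = [muts[i] for i in np.flatnonzero(lab == c)]
            # posterior-mean prevalence re-estimated from hard members
            sel = lab == c
            th = np.clip(alt[sel].sum(0)
                         / np.maximum((dep[sel] * coef[sel]).sum(0), 1e-12),
                         0.0, 1.0)
            clusters.append(CloneCluster(remap[c], members, th))
        results[pat] = CcfClusteringResult(clusters, regions, assignments,
                                           bic, tried)
    return results
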