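"""Cross-omics distances, correlations and classical MDS.

Per omic layer the pairwise Euclidean distance matrix over tumor regions
is computed; each region pair is labeled intra-patient or inter-patient
and the two groups are compared with a two-sided Wilcoxon rank-sum test.
Classical (Torgerson) MDS embeds a distance matrix by double-centering
and eigendecomposition, reproducing exactly-embeddable configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class OmicDistanceSet:
    distances: dict[str, pd.DataFrame]      # omic -> regions x regions
    pair_labels: pd.DataFrame               # sample_1, sample_2, label
    comparisons: pd.DataFrame               # omic, W, p, medians


def _pair_frame(samples, patients) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            rows.append((a, b, "intra" if patients[a] == patients[b]
                         else "inter"))
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "label"])


def omic_distances(profiles: dict[str, pd.DataFrame],
                   patients: pd.Series | None = None) -> OmicDistanceSet:
    """Euclidean distances per omic plus intra- vs inter-patient comparison.

    ``profiles`` maps an omic name to a features x samples frame; samples
    are tumor regions named ``<patient>_<region>``. Omics whose frame is
    empty are skipped with a warning.
    """
    mats = {}
    comparisons = []
    pair_labels = None
    for omic, prof in profiles.items():
        if prof is None or prof.empty:
            warnings.warn(f"omic '{omic}' missing, skipped")
            continue
        samples = list(prof.columns)
        if patients is None:
            pats = {s: s.rsplit("_", 1)[0] for s in samples}
        else:
            pats = patients.to_dict()
        d = squareform(pdist(prof.to_numpy(float).T, metric="euclidean"))
        dm = pd.DataFrame(d, index=samples, columns=samples)
        mats[omic] = dm
        pairs = _pair_frame(samples, pats)
        if pair_labels is None:
            pair_labels = pairs
        vals = np.array([dm.loc[a, b] for a, b in
                         zip(pairs.sample_1, pairs.sample_2)])
        intra = vals[pairs.label == "intra"]
        inter = vals[pairs.label == "inter"]
        if len(intra) and len(inter):
            w, p = stats.ranksums(intra, inter)
        else:
            w = p = np.nan
        comparisons.append((omic, float(np.median(intra)) if len(intra)
                            else np.nan,
                            float(np.median(inter)) if len(inter)
                            else np.nan, w, p))
    comparisons = pd.DataFrame(comparisons, columns=[
        "omic", "median_intra", "median_inter", "statistic", "p_value"])
    return OmicDistanceSet(mats, pair_labels, comparisons)


def cluster_purity(distance: pd.DataFrame, patients: pd.Series,
                   linkage_method: str = "complete") -> pd.DataFrame:
    """Hierarchical clustering of regions; per-patient cluster purity.

    Cuts the dendrogram at the number of patients and reports, per
    patient, the fraction of its regions landing in that patient's
    majority cluster.
    """
    n_pat = patients.nunique()
    lab = fcluster(linkage(squareform(distance.to_numpy(), checks=False),
                           method=linkage_method),
                   n_pat, criterion="maxclust")
    lab = pd.Series(lab, index=distance.index)
    rows = []
    for pat, idx in lab.groupby(patients).groups.items():
        counts = lab[idx].value_counts()
        rows.append((pat, len(idx), float(counts.iloc[0] / len(idx))))
    return pd.DataFrame(rows, columns=["patient", "n_regions", "purity"])


# ---------------------------------------------------------------------------
# correlations

def correlate(a, b, partial_on=None) -> dict:
    """Spearman and Pearson correlation, optionally partialled.

    ``partial_on`` is a vector (or matrix, observations x covariates) of
    covariates; the partial Pearson/Spearman correlations are computed on
    the residuals of regressing each variable on the covariates (with
    intercept). Constant inputs give NaN with a flag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if len(a) < 3:
        raise ValueError("need n >= 3")
    out = {"n": int(len(a)), "constant_input": False}
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        out.update(pearson_r=np.nan, pearson_p=np.nan, spearman_rho=np.nan,
                   spearman_p=np.nan, constant_input=True)
        return out
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    out.update(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
               spearman_rho=float(sr.statistic),
               spearman_p=float(sr.pvalue))
    if partial_on is not None:
        z = np.asarray(partial_on, float)
        if z.ndim == 1:
            z = z[:, None]
        X = np.column_stack([np.ones(len(a)), z])
        ra = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
        rb = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
        ppr = stats.pearsonr(ra, rb)
        psr = stats.spearmanr(ra, rb)
        out.update(partial_pearson_r=float(ppr.statistic),
                   partial_pearson_p=float(ppr.pvalue),
                   partial_spearman_rho=float(psr.statistic),
                   partial_spearman_p=float(psr.pvalue))
    return out


# ---------------------------------------------------------------------------
# classical MDS

def mds_embed(distance: np.ndarray | pd.DataFrame, dims: int = 2
              ) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and embeds on the top
    ``dims`` eigenvectors; for configurations exactly embeddable in
    ``dims`` dimensions the pairwise distances are reproduced to
    numerical precision. Requires a symmetric non-negative matrix.
    """
    d = np.asarray(distance, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)
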