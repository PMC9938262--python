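"""Immune infiltration scoring, TIL classification and neoantigen filtering.

Immune cell population scores follow the marker-gene-mean approach: a
population's score in a region is the mean log2(TPM+1) of its marker
genes. Regions are split into immune-high and immune-low by hierarchical
clustering (Ward linkage on Manhattan distances, cut at k=2); the group
with the higher mean total-TIL score is "high". A patient whose regions
fall in both groups is immune-heterogeneous.

Neoantigen filtering: a candidate is *putative* when its mutant percentile
rank is <= 2.0 and binds at least as well as the wild-type peptide
(rank_mut <= rank_wt; lower rank = stronger binding). Putative epitopes
bound by an HLA allele under clonal LOH are excluded; under subclonal LOH
an epitope is excluded only if every clone carrying it has lost the
allele. An *expressed* neoepitope additionally needs >= 5 RNA-seq reads
over the mutation with >= 3 carrying the mutant allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

RANK_THRESHOLD = 2.0
RNA_TOTAL_MIN = 5
RNA_ALT_MIN = 3


def immune_scores(log_expr: pd.DataFrame,
                  markers: dict[str, list[str]]) -> pd.DataFrame:
    """Regions x populations score matrix (mean marker log2 expression).

    Marker genes absent from the matrix are excluded with a warning;
    populations with no present marker are dropped.
    """
    cols = {}
    for pop, genes in markers.items():
        present = [g for g in genes if g in log_expr.index]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(f"{pop}: markers missing from expression matrix: "
                          f"{sorted(missing)}")
        if not present:
            warnings.warn(f"{pop}: no markers present, population dropped")
            continue
        cols[pop] = log_expr.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


@dataclass
class TilClassification:
    region_labels: pd.Series        # sample -> "high"|"low"
    patient_labels: pd.Series       # patient -> "high"|"low"|"heterogeneous"
    distances: pd.DataFrame         # Euclidean immune distance, regions^2


def classify_til(scores: pd.DataFrame,
                 patients: pd.Series | None = None,
                 total_column: str = "total_TIL") -> TilClassification:
    """Two-group TIL classification of regions plus immune distances.

    Ward-linkage hierarchical clustering on Manhattan distances between
    region score vectors, cut into two groups; the group with the higher
    mean total-TIL (fallback: overall mean score) is labeled high.
    """
    if len(scores) < 2:
        raise ValueError("need >=2 regions")
    if patients is None:
        patients = pd.Series([s.rsplit("_", 1)[0] for s in scores.index],
                             index=scores.index)
    x = scores.to_numpy(float)
    d = pdist(x, metric="cityblock")
    if np.allclose(d, 0.0):
        raise ValueError("all regions have identical scores; "
                         "two-group classification undefined")
    lab = fcluster(linkage(d, method="ward"), 2, criterion="maxclust")
    ref = scores[total_column] if total_column in scores.columns \
        else scores.mean(axis=1)
    m1 = ref[lab == 1].mean()
    m2 = ref[lab == 2].mean()
    high_group = 1 if m1 >= m2 else 2
    region_labels = pd.Series(
        np.where(lab == high_group, "high", "low"), index=scores.index)
    pat_rows = {}
    for pat, idx in region_labels.groupby(patients).groups.items():
        vals = set(region_labels[idx])
        pat_rows[pat] = "heterogeneous" if len(vals) == 2 else vals.pop()
    distances = pd.DataFrame(squareform(pdist(x, metric="euclidean")),
                             index=scores.index, columns=scores.index)
    return TilClassification(region_labels, pd.Series(pat_rows),
                             distances)


# ---------------------------------------------------------------------------
# HLA LOH

def classify_hla_loh_timing(hla_loh: pd.DataFrame) -> pd.DataFrame:
    """Clonal/subclonal/none timing per (patient, allele).

    ``hla_loh`` columns: patient, region, allele, lost (bool). Conflicting
    duplicate rows raise.
    """
    dup = hla_loh.groupby(["patient", "region", "allele"])["lost"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValueError(f"conflicting HLA-LOH calls for {bad}")
    rows = []
    for pat, pgrp in hla_loh.groupby("patient"):
        n_regions = pgrp.region.nunique()
        for allele, agrp in pgrp.groupby("allele"):
            lost = agrp.drop_duplicates(["region"])["lost"].sum()
            if lost == 0:
                timing = "none"
            elif lost == n_regions:
                timing = "clonal"
            else:
                timing = "subclonal"
            rows.append((pat, allele, int(lost), n_regions, timing))
    return pd.DataFrame(rows, columns=["patient", "allele", "n_lost",
                                       "n_regions", "timing"])


def _lost_regions(hla_loh: pd.DataFrame) -> dict:
    out: dict[tuple[str, str], set[str]] = {}
    for r in hla_loh.itertuples(index=False):
        if r.lost:
            out.setdefault((r.patient, r.allele), set()).add(r.region)
    return out


# ---------------------------------------------------------------------------
# neoantigen filtering

def filter_neoantigens(candidates: pd.DataFrame,
                       hla_loh: pd.DataFrame | None = None,
                       clone_regions: dict | None = None, *,
                       rank_threshold: float = RANK_THRESHOLD
                       ) -> pd.DataFrame:
    """Apply the binding, HLA-LOH and expression rules to candidates.

    Parameters
    ----------
    candidates:
        Columns patient, mut_id, peptide, allele, rank_mut, rank_wt and
        optionally rna_total_reads, rna_alt_reads, clone.
    hla_loh:
        Per-region loss calls (patient, region, allele, lost).
    clone_regions:
        Maps (patient, clone) -> set of regions the clone occupies; used
        for the subclonal-LOH exclusion ("excluded only if all clones with
        the neoepitope also exhibit loss of the allele"). With
        multiplicity-one clone assignments, a neoepitope's clones are the
        single clone carrying its mutation.

    Returns the candidate table with boolean columns ``putative``,
    ``excluded_loh`` and ``expressed`` (expressed implies putative and not
    excluded). Candidates with missing ranks are dropped with a warning.
    """
    df = candidates.copy()
    bad = df.rank_mut.isna() | df.rank_wt.isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} candidates skipped: missing rank")
        df = df[~bad].copy()
    if not df.peptide.str.len().isin([9, 10, 11]).all():
        raise ValueError("peptides must be 9-11 aa")

    df["putative"] = (df.rank_mut <= rank_threshold) \
        & (df.rank_mut <= df.rank_wt)

    timing = classify_hla_loh_timing(hla_loh) if hla_loh is not None else None
    lost = _lost_regions(hla_loh) if hla_loh is not None else {}
    excluded = np.zeros(len(df), bool)
    if timing is not None:
        tmap = timing.set_index(["patient", "allele"])["timing"]
        for i, r in enumerate(df.itertuples(index=False)):
            t = tmap.get((r.patient, r.allele), "none")
            if t == "clonal":
                excluded[i] = True
            elif t == "subclonal" and clone_regions is not None \
                    and hasattr(r, "clone"):
                clone_regs = clone_regions.get((r.patient, r.clone))
                if clone_regs is not None and clone_regs and \
                        clone_regs <= lost.get((r.patient, r.allele), set()):
                    excluded[i] = True
    df["excluded_loh"] = excluded & df.putative.to_numpy()

    if {"rna_total_reads", "rna_alt_reads"} <= set(df.columns):
        expr = (df.rna_total_reads >= RNA_TOTAL_MIN) \
            & (df.rna_alt_reads >= RNA_ALT_MIN)
    else:
        expr = pd.Series(False, index=df.index)
    df["expressed"] = df.putative & ~df.excluded_loh & expr
    return df


def neoantigen_summary(filtered: pd.DataFrame,
                       presence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient neoepitope counts and heterogeneity fraction.

    The heterogeneity fraction is the share of retained putative
    neoepitopes whose underlying mutation is not present in all regions
    (``presence``: per-(patient, mut_id) label table with columns patient,
    mut, label from the clonality step).
    """
    rows = []
    for pat, grp in filtered.groupby("patient"):
        put = grp[grp.putative & ~grp.excluded_loh]
        het = np.nan
        if presence is not None and len(put):
            lab = presence[presence.patient == pat].set_index("mut")["label"]
            shared = [lab.get(m, "subclonal") == "clonal"
                      for m in put.mut_id]
            het = float(1.0 - np.mean(shared))
        rows.append((pat, int(len(grp)), int(grp.putative.sum()),
                     int(grp.excluded_loh.sum()), int(len(put)),
                     int(grp.expressed.sum()), het))
    return pd.DataFrame(rows, columns=[
        "patient", "n_candidates", "n_putative", "n_excluded_loh",
        "n_retained", "n_expressed", "heterogeneity_fraction"])
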