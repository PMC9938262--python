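"""Copy-number heterogeneity: log2 ratios, arm events, wGII, MSAI.

Segment calls work on the ploidy-normalized log2 scale: the total copy
number is divided by the sample mean ploidy and log2-transformed. Gain,
loss and amplification thresholds are log2(2.5/2), log2(1.5/2) and
log2(4/2). Arm-level events are clonal when every region shows >=75% of
the arm altered in the same direction and at least one region reaches
90%; otherwise subclonal when any single region exceeds 75%.

wGII is the mean, over the 22 autosomes, of the fraction of covered
length whose total copy number differs from the sample baseline (the
rounded sample ploidy); genome doubling is flagged at ploidy >= 3.

MSAI (mirrored subclonal allelic imbalance) is called from phased
heterozygous SNP B-allele fractions: an arm shows MSAI when at least two
regions carry significant allelic imbalance in *opposite* parental
directions covering at least 75% of the arm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GAIN_THRESHOLD = float(np.log2(2.5 / 2.0))
LOSS_THRESHOLD = float(np.log2(1.5 / 2.0))
AMP_THRESHOLD = float(np.log2(4.0 / 2.0))
LOG2_FLOOR = -10.0
GD_PLOIDY = 3.0
ARM_CLONAL_ALL = 0.75
ARM_CLONAL_ONE = 0.90
ARM_SUBCLONAL = 0.75
MSAI_ARM_FRACTION = 0.75
MSAI_ALPHA = 0.01
MSAI_MIN_SNPS = 10
MSAI_MIN_COVERAGE = 10


def expected_log2ratio(purity, cn_seg, ploidy, cn_n: float = 2.0):
    """Expected log2 ratio of a segment given purity, CN and ploidy.

    log2((purity*cn_seg + (1-purity)*cn_n) / ploidy), floored at -10 for
    homozygous deletions at full purity.
    """
    purity = np.asarray(purity, float)
    cn_seg = np.asarray(cn_seg, float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(np.asarray(ploidy, float) <= 0):
        raise ValueError("ploidy must be positive")
    mix = purity * cn_seg + (1.0 - purity) * cn_n
    with np.errstate(divide="ignore"):
        r = np.log2(mix / ploidy)
    r = np.maximum(r, LOG2_FLOOR)
    return float(r) if r.ndim == 0 else r


def call_gain_loss(log2_ratios) -> np.ndarray:
    """Per-segment call on the ploidy-normalized log2 scale.

    Returns an array over {"amp", "gain", "neutral", "loss"}; amplification
    implies (and supersedes) gain.
    """
    r = np.asarray(log2_ratios, float)
    call = np.full(r.shape, "neutral", dtype=object)
    call[r >= GAIN_THRESHOLD] = "gain"
    call[r >= AMP_THRESHOLD] = "amp"
    call[r <= LOSS_THRESHOLD] = "loss"
    return call


def segment_calls(segments: pd.DataFrame,
                  purity_ploidy: pd.DataFrame) -> pd.DataFrame:
    """Attach ploidy-normalized log2 ratios and calls to a segment table."""
    df = segments.copy()
    df["total_cn"] = df.major_cn + df.minor_cn
    pp = purity_ploidy.set_index(["patient", "region"])
    ploidy = np.array([pp.loc[(p, r), "ploidy"]
                       for p, r in zip(df.patient, df.region)])
    with np.errstate(divide="ignore"):
        df["log2_ratio"] = np.maximum(
            np.log2(df.total_cn.to_numpy() / ploidy), LOG2_FLOOR)
    df["call"] = call_gain_loss(df.log2_ratio)
    return df


# ---------------------------------------------------------------------------
# arm-level events

def _arm_altered_fractions(calls: pd.DataFrame, arms: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per (patient, arm, region): fraction of arm length gained / lost."""
    rows = []
    for arm in arms.itertuples(index=False):
        sel = calls[(calls.chrom == arm.chrom)
                    & (calls.start < arm.end) & (calls.end > arm.start)]
        arm_len = arm.end - arm.start
        for (pat, reg), grp in sel.groupby(["patient", "region"]):
            ov = (np.minimum(grp.end, arm.end)
                  - np.maximum(grp.start, arm.start)).clip(lower=0)
            gained = ov[(grp.call == "gain") | (grp.call == "amp")].sum()
            lost = ov[grp.call == "loss"].sum()
            rows.append((pat, arm.arm, reg, gained / arm_len,
                         lost / arm_len))
    return pd.DataFrame(rows, columns=["patient", "arm", "region",
                                       "frac_gain", "frac_loss"])


def call_arm_events(calls: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    """Clonal/subclonal arm-level gains and losses.

    ``arms`` needs columns arm, chrom, start, end (0-based half-open).
    Clonal: all regions >=75% altered in the same direction and >=1 region
    >=90%. Subclonal: any region >75%. Clonal is evaluated first.
    """
    need = {"arm", "chrom", "start", "end"}
    if not need <= set(arms.columns):
        raise ValueError(f"arm table lacks columns: {sorted(need - set(arms.columns))}")
    fracs = _arm_altered_fractions(calls, arms)
    rows = []
    for (pat, arm), grp in fracs.groupby(["patient", "arm"]):
        call = "none"
        for direction in ("gain", "loss"):
            f = grp[f"frac_{direction}"]
            if (f >= ARM_CLONAL_ALL).all() and (f >= ARM_CLONAL_ONE).any():
                call = f"clonal_{direction}"
                break
            if (f > ARM_SUBCLONAL).any() and call == "none":
                call = f"subclonal_{direction}"
        rows.append((pat, arm, call,
                     float(grp.frac_gain.max()), float(grp.frac_loss.max())))
    out = pd.DataFrame(rows, columns=["patient", "arm", "call",
                                      "max_frac_gain", "max_frac_loss"])
    return out.merge(fracs, on=["patient", "arm"])


# ---------------------------------------------------------------------------
# wGII and genome doubling

def compute_wgii(segments: pd.DataFrame, ploidy: float) -> tuple[float, bool]:
    """Weighted genome instability index for one region.

    Per autosome, the fraction of covered length with total copy number
    different from the rounded sample ploidy; wGII is the unweighted mean
    over autosomes with coverage. The genome-doubled flag is ploidy >= 3.
    """
    df = segments
    total = (df.major_cn + df.minor_cn).to_numpy()
    baseline = int(round(ploidy))
    lengths = (df.end - df.start).to_numpy()
    fracs = []
    for chrom, idx in df.groupby("chrom").groups.items():
        li = lengths[df.index.get_indexer(idx)]
        ti = total[df.index.get_indexer(idx)]
        cov = li.sum()
        if cov <= 0:
            warnings.warn(f"{chrom}: no covered length, excluded from wGII")
            continue
        fracs.append(float(li[ti != baseline].sum() / cov))
    if not fracs:
        raise ValueError("no autosome coverage")
    return float(np.mean(fracs)), bool(ploidy >= GD_PLOIDY)


def wgii_table(segments: pd.DataFrame,
               purity_ploidy: pd.DataFrame) -> pd.DataFrame:
    rows = []
    pp = purity_ploidy.set_index(["patient", "region"])
    for (pat, reg), grp in segments.groupby(["patient", "region"]):
        ploidy = float(pp.loc[(pat, reg), "ploidy"])
        w, gd = compute_wgii(grp.reset_index(drop=True), ploidy)
        rows.append((pat, reg, w, ploidy, gd))
    return pd.DataFrame(rows, columns=["patient", "region", "wgii",
                                       "ploidy", "gd"])


# ---------------------------------------------------------------------------
# clonal/subclonal SCNA fractions

def scna_ith_proportion(calls: pd.DataFrame) -> pd.DataFrame:
    """Clonal vs subclonal altered-genome fractions per patient.

    The genome is partitioned into minimal intervals by the union of all
    region breakpoints; an altered interval is clonal when every region
    shows the same alteration direction over it, subclonal otherwise.
    Patients with no altered intervals get NA fractions.
    """
    rows = []
    for pat, pgrp in calls.groupby("patient"):
        regions = sorted(pgrp.region.unique())
        if len(regions) < 2:
            raise ValueError(f"patient {pat}: needs >=2 regions")
        clonal_len = subclonal_len = 0.0
        for chrom, cgrp in pgrp.groupby("chrom"):
            cuts = np.unique(np.concatenate([cgrp.start.to_numpy(),
                                             cgrp.end.to_numpy()]))
            for s, e in zip(cuts[:-1], cuts[1:]):
                dirs = []
                for reg in regions:
                    seg = cgrp[(cgrp.region == reg) & (cgrp.start <= s)
                               & (cgrp.end >= e)]
                    if seg.empty:
                        dirs.append("uncovered")
                        continue
                    c = seg.call.iloc[0]
                    dirs.append("gain" if c == "amp" else c)
                altered = [d for d in dirs if d in ("gain", "loss")]
                if not altered:
                    continue
                if len(altered) == len(regions) and len(set(altered)) == 1:
                    clonal_len += e - s
                else:
                    subclonal_len += e - s
        tot = clonal_len + subclonal_len
        if tot == 0:
            rows.append((pat, np.nan, np.nan, 0.0))
        else:
            rows.append((pat, clonal_len / tot, subclonal_len / tot, tot))
    return pd.DataFrame(rows, columns=["patient", "clonal_fraction",
                                       "subclonal_fraction", "altered_bp"])


# ---------------------------------------------------------------------------
# MSAI

@dataclass
class MsaiEvent:
    patient: str
    arm: str
    regions: list[str]
    directions: dict[str, int]      # region -> +1 (hap A over-represented)
    n_snps: int


def _arm_region_direction(baf_a: np.ndarray, positions: np.ndarray,
                          arm_start: int, arm_end: int,
                          n_windows: int = 10):
    """Direction, significance and arm-coverage of allelic imbalance.

    Returns (direction in {-1, 0, +1}, covered fraction). The direction
    tests the per-SNP haplotype-A allele fraction against 0.5 (one-sample
    t-test, alpha=0.01); coverage is the fraction of occupied windows of
    the arm whose mean deviates from 0.5 in the same direction.
    """
    if len(baf_a) < MSAI_MIN_SNPS:
        return 0, 0.0
    t, p = stats.ttest_1samp(baf_a, 0.5)
    if not np.isfinite(p) or p >= MSAI_ALPHA:
        return 0, 0.0
    direction = 1 if t > 0 else -1
    edges = np.linspace(arm_start, arm_end, n_windows + 1)
    which = np.clip(np.searchsorted(edges, positions, side="right") - 1,
                    0, n_windows - 1)
    occupied = matched = 0
    for w in range(n_windows):
        vals = baf_a[which == w]
        if len(vals) == 0:
            continue
        occupied += 1
        if np.sign(vals.mean() - 0.5) == direction:
            matched += 1
    coverage = matched / occupied if occupied else 0.0
    return direction, coverage


def detect_msai(snp_baf: pd.DataFrame, arms: pd.DataFrame
                ) -> list[MsaiEvent]:
    """Arm-level mirrored subclonal allelic imbalance events.

    ``snp_baf`` columns: patient, region, chrom, pos, ref_reads,
    alt_reads, haplotype ("A"/"B": the haplotype carrying the ALT
    allele). SNPs below 10x coverage are dropped; arms with fewer than
    10 SNPs in a region are skipped with a warning.
    """
    df = snp_baf.copy()
    dep = df.ref_reads + df.alt_reads
    df = df[dep >= MSAI_MIN_COVERAGE].copy()
    dep = df.ref_reads + df.alt_reads
    alt_frac = df.alt_reads / dep
    # fraction of reads supporting the haplotype-A allele
    df["frac_a"] = np.where(df.haplotype == "A", alt_frac, 1.0 - alt_frac)

    events = []
    for arm in arms.itertuples(index=False):
        sel = df[(df.chrom == arm.chrom) & (df.pos > arm.start)
                 & (df.pos <= arm.end)]
        for pat, pgrp in sel.groupby("patient"):
            dirs: dict[str, int] = {}
            nsnp = 0
            for reg, rgrp in pgrp.groupby("region"):
                if len(rgrp) < MSAI_MIN_SNPS:
                    warnings.warn(
                        f"{pat} {arm.arm} {reg}: <{MSAI_MIN_SNPS} SNPs, "
                        "arm skipped")
                    continue
                d, cov = _arm_region_direction(
                    rgrp.frac_a.to_numpy(), rgrp.pos.to_numpy(),
                    arm.start, arm.end)
                if d != 0 and cov >= MSAI_ARM_FRACTION:
                    dirs[reg] = d
                    nsnp = max(nsnp, len(rgrp))
            if len(dirs) >= 2 and len(set(dirs.values())) == 2:
                events.append(MsaiEvent(
                    patient=pat, arm=arm.arm, regions=sorted(dirs),
                    directions=dirs, n_snps=int(nsnp)))
    return events


def arms_from_genome(genome) -> pd.DataFrame:
    return pd.DataFrame(
        [(f"{c}{a}", c, s, e) for c, a, s, e in genome],
        columns=["arm", "chrom", "start", "end"])
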