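"""Ground truth for the synthetic cohort: clone trees, copy number, DMRs.

Clone trees are sampled so that every region satisfies the two phylogenetic
feasibility rules used downstream:

* cross rule — a descendant clone's cancer-cell prevalence never exceeds
  its ancestor's in any region;
* pigeonhole — the prevalences of a clone's children sum to at most the
  parent's prevalence in every region.

Both hold by construction: a single child's per-region prevalence is the
parent's times a factor in {0 (absent), 1 (regionally fixed), U(0.4, 0.8)},
and sibling subclones expand in disjoint region sets, which also makes
branching topologies identifiable from prevalences alone (each branch has a
region where its siblings are absent). Regional fixation off the truncal
clone is what creates "clonal illusion" mutations: prevalence exactly 1 in
some region while absent in another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from mrith.config import SimulationConfig, IMMUNE_POPULATIONS


class InfeasibleConfigError(ValueError):
    """Raised when a configuration cannot satisfy the tree constraints."""


@dataclass
class PatientTruth:
    patient: str
    regions: list[str]
    purity: np.ndarray                  # per region, (0, 1]
    parents: list[int]                  # parent index per clone, -1 = root
    prevalence: np.ndarray              # clones x regions, in [0, 1]
    pattern: str                        # "linear" | "branched"
    gd: bool
    arm_cn: dict                        # arm -> region -> (cn_hapA, cn_hapB)
    msai: Optional[dict] = None         # {"arm", "regions": (rA, rB)}
    hla_loh: Optional[dict] = None      # {"allele", "regions": [...]}
    infiltration: dict = field(default_factory=dict)  # region -> "high"|"low"

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    def region_ploidy(self, genome) -> dict:
        """Length-weighted mean total copy number per region."""
        lengths = {f"{c}{a}": e - s for c, a, s, e in genome}
        total = float(sum(lengths.values()))
        out = {}
        for j, reg in enumerate(self.regions):
            w = sum(lengths[arm] * sum(self.arm_cn[arm][reg])
                    for arm in lengths)
            out[reg] = w / total
        return out


@dataclass
class CohortTruth:
    config: SimulationConfig
    patients: list[PatientTruth]
    mutations: pd.DataFrame     # patient, mut_id, clone, chrom, pos, ref, alt
    bins: pd.DataFrame          # bin_id, chrom, start, dmr (hyper/hypo/none),
                                # variable, normal_rate, tumor_rate
    epiallele_loci: pd.DataFrame  # locus, chrom, start, base_disorder
    genes: pd.DataFrame         # gene, chrom, tss, quadrant_class,
                                # promoter_coupled

    def patient_ids(self) -> list[str]:
        return [p.patient for p in self.patients]

    def get_patient(self, patient: str) -> PatientTruth:
        for p in self.patients:
            if p.patient == patient:
                return p
        raise KeyError(patient)


# ---------------------------------------------------------------------------
# clone trees

def _sample_topology(k: int, branched: bool, rng: np.random.Generator) -> list[int]:
    parents = [-1]
    if not branched or k < 3:
        parents.extend(range(k - 1))
        return parents
    # two branches off the root, remaining clones attach anywhere
    parents.extend([0, 0])
    for i in range(3, k):
        parents.append(int(rng.integers(0, i)))
    return parents


def _children(parents: list[int]) -> dict[int, list[int]]:
    ch: dict[int, list[int]] = {i: [] for i in range(len(parents))}
    for i, p in enumerate(parents):
        if p >= 0:
            ch[p].append(i)
    return ch


def tree_pattern(parents: list[int]) -> str:
    """"linear" iff every clone has at most one child."""
    ch = _children(parents)
    return "linear" if all(len(v) <= 1 for v in ch.values()) else "branched"


def _sample_prevalence(parents: list[int], n_regions: int,
                       rng: np.random.Generator,
                       p_absent: float = 0.3,
                       p_fixed: float = 0.25) -> np.ndarray:
    """Sample per-region clone prevalences satisfying both tree rules.

    Returns a (n_clones, n_regions) array; raises InfeasibleConfigError if
    a node has more children than regions in which it is present
    (disjoint-expansion siblings cannot be placed).
    """
    k = len(parents)
    prev = np.zeros((k, n_regions))
    prev[0] = 1.0
    ch = _children(parents)
    order = list(range(k))  # parents precede children by construction
    for node in order:
        kids = ch[node]
        if not kids:
            continue
        active = np.flatnonzero(prev[node] > 0)
        if len(kids) >= 2:
            if len(kids) > len(active):
                raise InfeasibleConfigError(
                    f"clone {node} has {len(kids)} child branches but is "
                    f"present in only {len(active)} regions; disjoint sibling "
                    "expansion (pigeonhole/cross rules) cannot be satisfied")
            perm = rng.permutation(active)
            # each child gets a disjoint non-empty region subset
            cuts = sorted(rng.choice(np.arange(1, len(active)),
                                     size=len(kids) - 1, replace=False))
            parts = np.split(perm, cuts)
            for kid, part in zip(kids, parts):
                for r in part:
                    u = 1.0 if rng.random() < p_fixed else rng.uniform(0.4, 0.8)
                    prev[kid, r] = prev[node, r] * u
        else:
            kid = kids[0]
            while True:
                drew = False
                for r in active:
                    x = rng.random()
                    if x < p_absent:
                        continue
                    u = 1.0 if x < p_absent + p_fixed else rng.uniform(0.4, 0.8)
                    prev[kid, r] = prev[node, r] * u
                    drew = True
                if drew:
                    break
    return prev


# ---------------------------------------------------------------------------
# copy number

_BASES = np.array(list("ACGT"))


def _sample_arm_cn(arms: list[str], regions: list[str], gd: bool,
                   msai: bool, rng: np.random.Generator):
    """Haplotype-resolved arm copy numbers with clonal and subclonal events.

    GD patients start at 2+2 and receive extra subclonal events (doubling is
    coupled with segment instability). Returns (arm_cn, msai_event).
    """
    base = (2, 2) if gd else (1, 1)
    arm_cn = {arm: {reg: list(base) for reg in regions} for arm in arms}
    pool = list(rng.permutation(arms))

    def _alter(arm, regs, rng):
        hap = int(rng.integers(0, 2))
        delta = 1 if rng.random() < 0.5 else -1
        for reg in regs:
            cn = arm_cn[arm][reg]
            new = cn[hap] + delta
            if new < 0 or (cn[1 - hap] + new) < 1:
                new = cn[hap] + 1  # avoid homozygous total loss
            cn[hap] = new

    n_clonal = 2
    n_sub = 4 if gd else 2
    for _ in range(n_clonal):
        _alter(pool.pop(), regions, rng)
    for _ in range(n_sub):
        size = int(rng.integers(1, len(regions))) if len(regions) > 1 else 1
        regs = list(rng.choice(regions, size=size, replace=False))
        _alter(pool.pop(), regs, rng)

    msai_event = None
    if msai and len(regions) >= 2:
        arm = pool.pop()
        r_a, r_b = rng.choice(regions, size=2, replace=False)
        arm_cn[arm][r_a][0] += 1   # haplotype A gained in one region
        arm_cn[arm][r_b][1] += 1   # haplotype B gained in another
        msai_event = {"arm": arm, "regions": (str(r_a), str(r_b))}
    return {a: {r: tuple(c) for r, c in d.items()} for a, d in arm_cn.items()}, \
        msai_event


# ---------------------------------------------------------------------------
# cohort truth

def build_truth(config: SimulationConfig) -> CohortTruth:
    """Sample the full ground truth for one cohort.

    Guarantees at least one linear and one branched patient whenever
    ``n_patients >= 4``. Deterministic given config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms = [f"{c}{a}" for c, a, s, e in config.genome]
    arm_bounds = {f"{c}{a}": (c, s, e) for c, a, s, e in config.genome}

    n_gd = int(round(config.gd_fraction * config.n_patients))
    n_msai = int(round(config.msai_fraction * config.n_patients))
    gd_flags = np.zeros(config.n_patients, bool)
    gd_flags[rng.permutation(config.n_patients)[:n_gd]] = True
    msai_flags = np.zeros(config.n_patients, bool)
    msai_flags[rng.permutation(config.n_patients)[:n_msai]] = True

    patients: list[PatientTruth] = []
    mut_rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        n_regions = int(rng.integers(config.regions_per_patient[0],
                                     config.regions_per_patient[1] + 1))
        regions = [f"R{j + 1}" for j in range(n_regions)]
        purity = rng.uniform(config.purity[0], config.purity[1],
                             size=n_regions)
        k = int(rng.integers(config.n_clones[0], config.n_clones[1] + 1))
        # alternate forced patterns so both occur in any cohort of >= 2
        # (branching needs >= 3 clones, so it is skipped when the clone
        # range does not allow it)
        if i % 2 == 1 and config.n_clones[1] >= 3:
            k = max(k, 3)
            want_branched = True
        else:
            want_branched = False
        if want_branched and n_regions < 2:
            want_branched = False

        for attempt in range(50):
            parents = _sample_topology(k, want_branched, rng)
            try:
                prev = _sample_prevalence(parents, n_regions, rng)
            except InfeasibleConfigError:
                if attempt == 49:
                    raise
                continue
            if tree_pattern(parents) == ("branched" if want_branched
                                         else "linear"):
                break
        arm_cn, msai_event = _sample_arm_cn(
            arms, regions, bool(gd_flags[i]), bool(msai_flags[i]), rng)

        hla = None
        if rng.random() < 0.4:
            allele = f"HLA-A*{int(rng.integers(1, 3)):02d}:01"
            if rng.random() < 0.5:
                lost = list(regions)                      # clonal loss
            else:
                m = int(rng.integers(1, n_regions)) if n_regions > 1 else 1
                lost = [str(r) for r in
                        rng.choice(regions, size=m, replace=False)]
            hla = {"allele": allele, "regions": sorted(lost)}

        if rng.random() < 0.4 and n_regions >= 2:
            states = ["high" if rng.random() < 0.5 else "low"
                      for _ in regions]
            if len(set(states)) == 1:       # force heterogeneity
                states[0] = "low" if states[0] == "high" else "high"
        else:
            s = "high" if rng.random() < 0.5 else "low"
            states = [s] * n_regions
        infiltration = dict(zip(regions, states))

        patients.append(PatientTruth(
            patient=pid, regions=regions, purity=purity, parents=parents,
            prevalence=prev, pattern=tree_pattern(parents),
            gd=bool(gd_flags[i]), arm_cn=arm_cn, msai=msai_event,
            hla_loh=hla, infiltration=infiltration))

        # mutations: n_mutations per clone, placed uniformly on the genome
        for clone in range(k):
            for m in range(config.n_mutations):
                arm = arms[int(rng.integers(0, len(arms)))]
                chrom, s0, e0 = arm_bounds[arm]
                pos = int(rng.integers(s0 + 1, e0))      # 1-based
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                mut_rows.append((pid, f"{pid}_m{len(mut_rows)}", clone,
                                 chrom, pos, str(ref), str(alt), arm))
    mutations = pd.DataFrame(
        mut_rows, columns=["patient", "mut_id", "clone", "chrom", "pos",
                           "ref", "alt", "arm"])

    bins = _plant_bins(config, rng)
    loci = _plant_epiallele_loci(config, rng)
    genes = _plant_genes(config, rng)
    return CohortTruth(config=config, patients=patients, mutations=mutations,
                       bins=bins, epiallele_loci=loci, genes=genes)


def _tile_positions(config, n, rng):
    """Uniform random positions across the genome: (chrom, start, arm)."""
    arms = list(config.genome)
    idx = rng.integers(0, len(arms), size=n)
    out = []
    for i in idx:
        c, a, s, e = arms[i]
        out.append((c, int(rng.integers(s, e - config.cpg_bin_size)),
                    f"{c}{a}"))
    return out


def _plant_bins(config, rng):
    n = config.n_cpg_bins
    pos = _tile_positions(config, n, rng)
    n_dmr = int(round(config.dmr_fraction * n))
    status = np.array(["none"] * n, dtype=object)
    dmr_idx = rng.permutation(n)[:n_dmr]
    status[dmr_idx[: n_dmr // 2]] = "hyper"
    status[dmr_idx[n_dmr // 2:]] = "hypo"
    variable = np.zeros(n, bool)
    null_idx = np.flatnonzero(status == "none")
    n_var = int(round(config.variable_fraction * n))
    variable[rng.choice(null_idx, size=min(n_var, len(null_idx)),
                        replace=False)] = True

    # bimodal normal methylation; DMR bins get headroom for the planted shift
    low = rng.uniform(0.05, 0.3, size=n)
    high = rng.uniform(0.7, 0.95, size=n)
    normal = np.where(rng.random(n) < 0.5, low, high)
    normal[status == "hyper"] = rng.uniform(0.1, 0.55, size=(status == "hyper").sum())
    normal[status == "hypo"] = rng.uniform(0.45, 0.9, size=(status == "hypo").sum())
    tumor = normal.copy()
    tumor[status == "hyper"] += config.dmr_delta
    tumor[status == "hypo"] -= config.dmr_delta
    tumor = np.clip(tumor, 0.02, 0.98)
    return pd.DataFrame({
        "bin_id": [f"bin{i:05d}" for i in range(n)],
        "chrom": [p[0] for p in pos],
        "start": [p[1] for p in pos],
        "arm": [p[2] for p in pos],
        "dmr": status,
        "variable": variable,
        "normal_rate": normal,
        "tumor_rate": tumor,
    })


def _plant_epiallele_loci(config, rng):
    pos = _tile_positions(config, config.n_epiallele_loci, rng)
    return pd.DataFrame({
        "locus": [f"L{i:04d}" for i in range(config.n_epiallele_loci)],
        "chrom": [p[0] for p in pos],
        "start": [p[1] for p in pos],
        "arm": [p[2] for p in pos],
        "base_disorder": config.epiallele_disorder,
    })


_CLASS_SD = {  # quadrant class -> (within-patient SD, between-patient SD)
    "I": (1.5, 0.2), "II": (0.2, 0.2), "III": (1.5, 1.5), "IV": (0.2, 1.5),
}


def _plant_genes(config, rng):
    pos = _tile_positions(config, config.n_genes, rng)
    classes = rng.choice(np.array(["I", "II", "III", "IV"], dtype=object),
                         size=config.n_genes, p=[0.2, 0.4, 0.2, 0.2])
    coupled = rng.random(config.n_genes) < config.promoter_coupled_fraction
    return pd.DataFrame({
        "gene": [f"G{i:05d}" for i in range(config.n_genes)],
        "chrom": [p[0] for p in pos],
        "tss": [p[1] for p in pos],
        "arm": [p[2] for p in pos],
        "quadrant_class": classes,
        "promoter_coupled": coupled,
        "base_expr": rng.normal(5.0, 1.0, size=config.n_genes),
    })
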