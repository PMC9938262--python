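"""Generator: constraint validity, determinism, rendering and round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

from oracles import check_tree_bruteforce
from mrith.config import SimulationConfig
from mrith.simulate import (expected_vaf, simulate_cohort, write_cohort,
                            read_cohort, read_vcf, PATTERN_COLS)
from mrith.truth import build_truth, InfeasibleConfigError


def test_config_rejects_invalid_values():
    with pytest.raises(ValueError):
        SimulationConfig(purity=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=0)
    with pytest.raises(ValueError):
        SimulationConfig(dmr_fraction=1.5)


def test_single_clone_everything_clonal():
    cfg = SimulationConfig(n_patients=2, n_clones=(1, 1), seed=3)
    truth = build_truth(cfg)
    for pt in truth.patients:
        assert pt.n_clones == 1
        assert np.allclose(pt.prevalence, 1.0)


def test_truth_deterministic_under_seed():
    a = build_truth(SimulationConfig(n_patients=3, seed=7))
    b = build_truth(SimulationConfig(n_patients=3, seed=7))
    for pa, pb in zip(a.patients, b.patients):
        assert pa.parents == pb.parents
        assert np.array_equal(pa.prevalence, pb.prevalence)
        assert pa.arm_cn == pb.arm_cn
    pd.testing.assert_frame_equal(a.mutations, b.mutations)
    pd.testing.assert_frame_equal(a.bins, b.bins)


def test_sampled_trees_all_satisfy_constraints():
    """Every sampled clone tree passes the exhaustive rule checker (eps=0)."""
    n_checked = 0
    for seed in range(40):
        truth = build_truth(SimulationConfig(n_patients=25, seed=seed))
        for pt in truth.patients:
            assert check_tree_bruteforce(pt.prevalence, pt.parents, eps=1e-12)
            n_checked += 1
    assert n_checked == 1000


def test_linear_and_branched_both_present():
    truth = build_truth(SimulationConfig(n_patients=4, seed=2))
    patterns = {p.pattern for p in truth.patients}
    assert patterns == {"linear", "branched"}


def test_infeasible_topology_raises_named_error():
    """A node with more child branches than occupied regions cannot satisfy
    the disjoint sibling-expansion scheme."""
    from mrith.truth import _sample_prevalence

    rng = np.random.default_rng(0)
    with pytest.raises(InfeasibleConfigError, match="pigeonhole"):
        _sample_prevalence([-1, 0, 0, 0], n_regions=2, rng=rng)


def test_expected_vaf_clonal_diploid_full_purity():
    assert expected_vaf(1.0, 1.0, 2) == pytest.approx(0.5)
    assert expected_vaf(0.5, 0.8, 2) == pytest.approx(0.5 * 0.8 / 2.0)


def test_vaf_law_of_large_numbers():
    """At depth 1e5 the empirical VAF is within 0.01 of its expectation."""
    cfg = SimulationConfig(n_patients=1, n_clones=(2, 2), depth=1e5,
                           regions_per_patient=(3, 3), n_cpg_bins=10,
                           n_genes=10, n_epiallele_loci=2, seed=4)
    cohort = simulate_cohort(cfg)
    pt = cohort.truth.patients[0]
    muts = cohort.truth.mutations.set_index("mut_id")
    for r in cohort.variants.itertuples(index=False):
        clone = muts.loc[r.mut_id, "clone"]
        arm = muts.loc[r.mut_id, "arm"]
        j = pt.regions.index(r.region)
        cn = sum(pt.arm_cn[arm][r.region])
        exp = expected_vaf(pt.prevalence[clone, j], pt.purity[j], cn)
        emp = r.t_alt / (r.t_alt + r.t_ref)
        assert abs(emp - exp) < 0.01 + cfg.normal_error_rate


def test_msai_patient_baf_mirrored(small_cohort):
    """Phased BAF deviates above 0.5 in one region, below in the other."""
    found = False
    for pt in small_cohort.truth.patients:
        if not pt.msai:
            continue
        found = True
        arm = pt.msai["arm"]
        chrom, which = arm[:-1], arm[-1]
        baf = small_cohort.snp_baf
        lo, hi = (0, 5_000_000) if which == "p" else (5_000_000, 10_000_000)
        sel = baf[(baf.patient == pt.patient) & (baf.chrom == chrom)
                  & (baf.pos > lo) & (baf.pos <= hi)]
        means = {}
        for reg in pt.msai["regions"]:
            grp = sel[sel.region == reg]
            frac_alt = grp.alt_reads / (grp.alt_reads + grp.ref_reads)
            frac_a = np.where(grp.haplotype == "A", frac_alt, 1 - frac_alt)
            means[reg] = float(np.mean(frac_a))
        r1, r2 = pt.msai["regions"]
        assert (means[r1] - 0.5) * (means[r2] - 0.5) < 0
    assert found


def test_purity_one_bulk_equals_tumor_rate():
    """At purity 1 the expected bulk methylation is the tumor rate itself."""
    cfg = SimulationConfig(n_patients=1, purity=(1.0, 1.0),
                           regions_per_patient=(2, 2), meth_depth=500,
                           n_cpg_bins=60, n_genes=10, n_epiallele_loci=2,
                           variable_fraction=0.0, seed=9)
    cohort = simulate_cohort(cfg)
    bins = cohort.truth.bins
    meth = cohort.methylation
    tumor = meth[meth.region != "NORMAL"]
    # average observed level per bin vs planted tumor rate
    lvl = tumor.assign(level=tumor.meth_reads / tumor.total_reads,
                       start=(tumor.pos // cfg.cpg_bin_size)
                       * cfg.cpg_bin_size)
    obs = lvl.groupby(["chrom", "start"])["level"].mean()
    diffs = []
    for b in bins.itertuples(index=False):
        key = (b.chrom, (b.start // cfg.cpg_bin_size) * cfg.cpg_bin_size)
        if key in obs.index:
            diffs.append(abs(obs.loc[key] - b.tumor_rate))
    assert len(diffs) > 30  # bins straddling a 1-kb boundary do not match
    # patient baseline shift (sd 0.06) + region jitter + binomial noise
    assert np.mean(diffs) < 0.08
    assert np.quantile(diffs, 0.9) < 0.2


def test_hyper_dmr_mixture_expectation():
    """Planted hyper bins: bulk minus normal >= purity-attenuated shift."""
    cfg = SimulationConfig(n_patients=1, purity=(0.8, 0.8),
                           regions_per_patient=(3, 3), meth_depth=300,
                           n_cpg_bins=200, gd_fraction=0.0, seed=12)
    cohort = simulate_cohort(cfg)
    bins = cohort.truth.bins
    meth = cohort.methylation
    tumor = meth[meth.region != "NORMAL"]
    lvl = tumor.assign(level=tumor.meth_reads / tumor.total_reads,
                       start=(tumor.pos // cfg.cpg_bin_size)
                       * cfg.cpg_bin_size)
    obs = lvl.groupby(["chrom", "start"])["level"].mean()
    hyper = bins[bins.dmr == "hyper"]
    diffs = []
    for b in hyper.itertuples(index=False):
        key = (b.chrom, (b.start // cfg.cpg_bin_size) * cfg.cpg_bin_size)
        if key in obs.index:
            diffs.append(obs.loc[key] - b.normal_rate)
    # diploid arms at purity 0.8: attenuation 0.8*2/(0.8*2+0.4) = 0.8,
    # so the expected observed shift is 0.4 * 0.8 = 0.32 >= 0.24
    assert np.mean(diffs) >= 0.24


def test_disorder_zero_single_pattern():
    cfg = SimulationConfig(n_patients=1, epiallele_disorder=0.0,
                           couple_disorder_to_scna=False,
                           regions_per_patient=(2, 2), n_cpg_bins=10,
                           n_genes=10, n_epiallele_loci=6, seed=2)
    cohort = simulate_cohort(cfg)
    counts = cohort.epialleles[PATTERN_COLS].to_numpy()
    assert ((counts > 0).sum(axis=1) == 1).all()


def test_write_read_round_trip(tmp_path, tiny_cohort):
    out = write_cohort(tiny_cohort, tmp_path / "cohort")
    back = read_cohort(out)
    pd.testing.assert_frame_equal(
        back["variants"], tiny_cohort.variants, check_dtype=False)
    pd.testing.assert_frame_equal(
        back["segments"], tiny_cohort.segments, check_dtype=False)
    # truth JSON covers every patient appearing in every omic table
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    truth_pats = {p["patient"] for p in truth["patients"]}
    for tbl in (tiny_cohort.variants, tiny_cohort.methylation,
                tiny_cohort.epialleles, tiny_cohort.hla_loh):
        assert set(tbl.patient) <= truth_pats


def test_vcf_round_trip(tmp_path, tiny_cohort):
    out = write_cohort(tiny_cohort, tmp_path / "cohort")
    back = read_vcf(out / "variants.vcf")
    orig = tiny_cohort.variants[["patient", "region", "chrom", "pos", "ref",
                                 "alt", "t_alt", "t_ref"]]
    merged = orig.merge(back, on=["patient", "region", "chrom", "pos",
                                  "ref", "alt"], suffixes=("", "_vcf"))
    assert len(merged) == len(orig)
    assert (merged.t_alt == merged.t_alt_vcf).all()
    assert (merged.t_ref == merged.t_ref_vcf).all()
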