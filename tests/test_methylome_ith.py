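"""Methylome heterogeneity: deconvolution, bins, DMRs, APITH, epialleles."""

import numpy as np
import pandas as pd
import pytest

from oracles import epiallele_metrics_bruteforce, fisher_exact_bruteforce
from mrith import methylome as meth


class TestDeconvolution:
    def test_purity_one_identity(self):
        assert meth.deconvolve_methylation(0.37, 0.8, 1.0, 2) \
            == pytest.approx(0.37, abs=1e-12)

    def test_hand_value(self):
        # m_b 0.5, m_n 0.8, rho 0.5, n_t 2, n_n 2:
        # (0.5*(1+1) - 2*0.8*0.5) / 1 = 0.2
        assert meth.deconvolve_methylation(0.5, 0.8, 0.5, 2) \
            == pytest.approx(0.2, abs=1e-12)

    def test_negative_clamped_to_zero(self):
        # raw value (0.3*2 - 0.8) / 1 = -0.2 -> clamped
        assert meth.deconvolve_methylation(0.3, 0.8, 0.5, 2) == 0.0

    def test_cn_zero_flagged_nan(self):
        assert np.isnan(meth.deconvolve_methylation(0.5, 0.5, 0.5, 0))

    def test_purity_zero_errors(self):
        with pytest.raises(ValueError):
            meth.deconvolve_methylation(0.5, 0.5, 0.0, 2)

    def test_inverts_mixture_exactly(self):
        rng = np.random.default_rng(0)
        m_t = rng.uniform(0, 1, 50)
        m_n = rng.uniform(0, 1, 50)
        rho, n_t = 0.7, 3
        m_b = (rho * n_t * m_t + 2 * (1 - rho) * m_n) \
            / (rho * n_t + 2 * (1 - rho))
        back = meth.deconvolve_methylation(m_b, m_n, rho, n_t)
        assert np.allclose(back, m_t, atol=1e-12)


class TestBinning:
    def _cpgs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "meth_reads",
                                           "total_reads"])

    def test_mean_of_three_cpgs(self):
        df = self._cpgs([("chr1", 100, 2, 10), ("chr1", 200, 4, 10),
                         ("chr1", 300, 6, 10)])
        out = meth.bin_methylation(df, 1000)
        assert len(out) == 1
        assert out.level.iloc[0] == pytest.approx(0.4)
        assert out.bin_id.iloc[0] == "chr1:0"

    def test_bin_below_min_cpgs_dropped(self):
        df = self._cpgs([("chr1", 100, 5, 10), ("chr1", 200, 5, 10)])
        assert meth.bin_methylation(df, 1000).empty

    def test_empty_input(self):
        assert meth.bin_methylation(self._cpgs([]), 1000).empty

    def test_duplicate_positions_error(self):
        df = self._cpgs([("chr1", 100, 1, 10), ("chr1", 100, 2, 10)])
        with pytest.raises(ValueError, match="duplicate"):
            meth.bin_methylation(df, 1000)

    def test_unsorted_input_sorted_internally(self):
        df = self._cpgs([("chr1", 300, 6, 10), ("chr1", 100, 2, 10),
                         ("chr1", 200, 4, 10)])
        out = meth.bin_methylation(df, 1000)
        assert out.level.iloc[0] == pytest.approx(0.4)


class TestDmrs:
    def _bins(self, specs):
        rows = []
        for bin_id, m, t in specs:
            rows.append(dict(bin_id=bin_id, meth_reads=m, total_reads=t))
        return pd.DataFrame(rows)

    def test_identical_profiles_no_dmrs(self):
        t = self._bins([(f"b{i}", 50, 100) for i in range(20)])
        out = meth.call_dmrs(t, t.copy())
        assert (out.status == "none").all()

    def test_planted_shift_called(self):
        tumor = self._bins([("hot", 450, 500)]
                           + [(f"b{i}", 250, 500) for i in range(30)])
        normal = self._bins([("hot", 250, 500)]
                            + [(f"b{i}", 250, 500) for i in range(30)])
        out = meth.call_dmrs(tumor, normal).set_index("bin_id")
        assert out.loc["hot", "status"] == "hyper"
        assert (out.drop("hot").status == "none").all()

    def test_no_common_bins_errors(self):
        with pytest.raises(ValueError, match="common|covered"):
            meth.call_dmrs(self._bins([("a", 1, 10)]),
                           self._bins([("b", 1, 10)]))

    def test_promoter_enrichment_against_exact_oracle(self):
        universe = {f"b{i}" for i in range(40)}
        hits = {f"b{i}" for i in range(10)}
        annotations = {"promoter": {f"b{i}" for i in range(12)}}
        out = meth.element_enrichment(hits, universe, annotations)
        assert out.odds_ratio.iloc[0] > 1
        # all 10 hits inside the 12 promoter bins
        p_oracle = fisher_exact_bruteforce(10, 0, 2, 28)
        assert out.p_value.iloc[0] == pytest.approx(p_oracle, rel=1e-6)
        assert out.q_value.iloc[0] < 0.05


class TestVariableBins:
    def test_planted_variable_bin_ranks_first(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.4, 0.6, size=(20, 4))
        df = pd.DataFrame(base, index=[f"b{i}" for i in range(20)])
        df.loc["b7"] = [0.1, 0.9, 0.2, 0.8]
        out = meth.variable_bins(df, top_k=5)
        assert out.bin_id.iloc[0] == "b7"

    def test_identical_regions_stable_ranking(self):
        df = pd.DataFrame(0.5, index=[f"b{i}" for i in range(5)],
                          columns=list("ABC"))
        out = meth.variable_bins(df, top_k=5)
        assert (out.sd == 0).all()
        assert list(out.bin_id) == sorted(out.bin_id)

    def test_k_larger_than_bins_warns(self):
        df = pd.DataFrame(np.random.default_rng(1).random((3, 3)),
                          index=list("abc"))
        with pytest.warns(UserWarning, match="returning all"):
            out = meth.variable_bins(df, top_k=10)
        assert len(out) == 3

    def test_single_region_errors(self):
        with pytest.raises(ValueError):
            meth.variable_bins(pd.DataFrame({"R1": [0.1, 0.2]}))


class TestApith:
    def test_two_regions_is_their_distance(self):
        prof = pd.DataFrame({"R1": [0.0, 0.0], "R2": [3.0, 4.0]})
        assert meth.compute_apith(prof) == pytest.approx(5.0)

    def test_three_regions_mean_of_pairs(self):
        # collinear profiles with pair distances 1, 2, 3 -> mean 2
        prof = pd.DataFrame({"R1": [0.0], "R2": [1.0], "R3": [3.0]})
        assert meth.compute_apith(prof) == pytest.approx(2.0)

    def test_identical_regions_zero(self):
        prof = pd.DataFrame({"R1": [0.3, 0.7], "R2": [0.3, 0.7]})
        assert meth.compute_apith(prof) == 0.0

    def test_single_region_errors(self):
        with pytest.raises(ValueError):
            meth.compute_apith(pd.DataFrame({"R1": [0.1]}))


class TestEpialleles:
    def test_single_pattern_all_zero(self):
        counts = np.zeros(16)
        counts[15] = 80  # all reads 1111
        e, ep, pdr = meth.epiallele_metrics(counts)
        assert e == 0.0 and ep == 0.0 and pdr == 0.0

    def test_uniform_sixteen_closed_form(self):
        e, ep, pdr = meth.epiallele_metrics(np.full(16, 10))
        assert e == pytest.approx(4.0, abs=1e-12)
        assert ep == pytest.approx(0.9375, abs=1e-12)
        assert pdr == pytest.approx(0.875, abs=1e-12)

    def test_pdr_hand_value(self):
        counts = np.zeros(16)
        counts[0] = 48           # 0000
        counts[0b1010] = 12      # discordant
        _, _, pdr = meth.epiallele_metrics(counts)
        assert pdr == pytest.approx(0.2, abs=1e-12)

    def test_below_coverage_threshold_skipped(self):
        counts = np.zeros(16)
        counts[0] = 59
        assert meth.epiallele_metrics(counts) is None

    def test_negative_counts_error(self):
        counts = np.zeros(16)
        counts[0] = -1
        with pytest.raises(ValueError):
            meth.epiallele_metrics(counts)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(0, 30, size=16)
            if counts.sum() < 60:
                counts[0] += 60
            ours = meth.epiallele_metrics(counts)
            oracle = epiallele_metrics_bruteforce(counts)
            assert ours == pytest.approx(oracle, abs=1e-12)


class TestScnaVsNeutral:
    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(0)
        n = 200
        altered = np.arange(n) < n // 2
        entropy = np.where(altered, rng.normal(2.5, 0.3, n),
                           rng.normal(1.5, 0.3, n))
        metrics = pd.DataFrame({"patient": "P1", "region": "R1",
                                "locus": [f"L{i}" for i in range(n)],
                                "chrom": "chr1", "start": 0, "reads": 80,
                                "entropy": entropy,
                                "epipolymorphism": 0.5, "pdr": 0.5})
        out = meth.compare_scna_vs_neutral(metrics, pd.Series(altered))
        assert out.p_value.iloc[0] < 0.05
        assert out.statistic.iloc[0] > 0

    def test_single_locus_stratum_flagged(self):
        metrics = pd.DataFrame({"patient": "P1", "region": "R1",
                                "locus": ["L1", "L2"], "chrom": "chr1",
                                "start": 0, "reads": 80,
                                "entropy": [1.0, 2.0],
                                "epipolymorphism": 0.5, "pdr": 0.5})
        out = meth.compare_scna_vs_neutral(metrics,
                                           pd.Series([True, False]))
        assert bool(out.low_n.iloc[0])

    def test_empty_stratum_na(self):
        metrics = pd.DataFrame({"patient": "P1", "region": "R1",
                                "locus": ["L1"], "chrom": "chr1",
                                "start": 0, "reads": 80, "entropy": [1.0],
                                "epipolymorphism": 0.5, "pdr": 0.5})
        with pytest.warns(UserWarning, match="empty stratum"):
            out = meth.compare_scna_vs_neutral(metrics, pd.Series([True]))
        assert np.isnan(out.p_value.iloc[0])
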