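"""Variant filters, presence rule, CCF, clonality and CCF clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrith import variants as var


def _row(patient="P1", region="R1", pos=100, t_alt=10, t_ref=90,
         n_alt=0, n_ref=100, **kw):
    return dict(patient=patient, region=region, chrom="chr1", pos=pos,
                ref="A", alt="T", t_alt=t_alt, t_ref=t_ref, n_alt=n_alt,
                n_ref=n_ref, **kw)


class TestFilters:
    @pytest.mark.parametrize("row,kept,reason", [
        # VAF 0.10 with 10 alt reads, clean normal -> kept
        (_row(t_alt=10, t_ref=90, n_alt=1, n_ref=99), True, None),
        # 4 alt reads in the normal -> removed by normal-support filter
        (_row(t_alt=10, t_ref=90, n_alt=4, n_ref=396), False,
         "normal_support"),
        # tumor depth 9 -> removed by depth filter
        (_row(t_alt=5, t_ref=4), False, "depth"),
        # zero tumor depth fails the depth filter, no exception
        (_row(t_alt=0, t_ref=0), False, "depth"),
        # VAF 0.04 (below 0.05) -> tumor-support filter
        (_row(t_alt=8, t_ref=192), False, "tumor_support"),
        # alt reads 5 (not >5) at VAF 0.25 -> tumor-support filter
        (_row(t_alt=5, t_ref=15), False, "tumor_support"),
    ])
    def test_single_region_rules(self, row, kept, reason):
        kept_df, rejected = var.filter_variants(pd.DataFrame([row]))
        assert (len(kept_df) == 1) == kept
        if not kept:
            assert rejected.iloc[0]["filter"] == reason

    def test_kept_if_any_region_passes(self):
        rows = [_row(region="R1", t_alt=0, t_ref=100),
                _row(region="R2", t_alt=30, t_ref=70)]
        kept, _ = var.filter_variants(pd.DataFrame(rows))
        assert len(kept) == 2  # both region rows of the passing variant

    def test_missing_normal_errors(self):
        df = pd.DataFrame([_row()]).drop(columns=["n_alt", "n_ref"])
        with pytest.raises(ValueError, match="n_alt"):
            var.filter_variants(df)


class TestPresence:
    @pytest.mark.parametrize("t_alt,t_ref,present", [
        (3, 97, True),     # VAF 0.03 > 0.02
        (4, 396, True),    # alt reads 4 > 3 despite VAF 0.01
        (2, 98, False),    # VAF 0.02 not > 0.02, alt 2 not > 3
        (0, 100, False),
    ])
    def test_rule(self, t_alt, t_ref, present):
        df = var.genotype_presence(pd.DataFrame(
            [_row(t_alt=t_alt, t_ref=t_ref)]))
        assert bool(df.present.iloc[0]) == present


class TestCcf:
    def test_hand_values(self):
        assert var.compute_ccf(0.0, 1.0, 2) == 0.0
        assert var.compute_ccf(0.5, 1.0, 2) == pytest.approx(1.0, abs=1e-9)
        # vaf 0.25, purity 0.5, cn 2: 0.25 * (1 + 1) / 0.5 = 1.0
        assert var.compute_ccf(0.25, 0.5, 2) == pytest.approx(1.0, abs=1e-9)

    def test_printed_form_disagrees_for_truncal(self):
        """The literal printed algebra gives 0.25 for a clonal het mutation
        at purity 1, CN 2 — kept only for comparison."""
        assert var.compute_ccf(0.5, 1.0, 2, printed_form=True) \
            == pytest.approx(0.25, abs=1e-9)

    def test_purity_zero_errors(self):
        with pytest.raises(ValueError):
            var.compute_ccf(0.5, 0.0, 2)

    def test_cn_zero_with_signal_flagged(self):
        assert np.isnan(var.compute_ccf(0.1, 0.5, 0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.05, 1.0),
           st.integers(1, 6))
    def test_monotone_in_vaf(self, vaf, purity, cn):
        lo = var.compute_ccf(vaf * 0.9, purity, cn, cap=False)
        hi = var.compute_ccf(vaf, purity, cn, cap=False)
        assert hi > lo


class TestClonality:
    def _variants(self):
        rows = []
        regions = ["R1", "R2", "R3"]
        # 6 mutations present everywhere, 4 in R1 only with CCF ~0.95
        for m in range(10):
            for reg in regions:
                present = m < 6 or reg == "R1"
                rows.append(_row(region=reg, pos=m + 1,
                                 t_alt=40 if present else 0,
                                 t_ref=60 if present else 100,
                                 mut_id=f"m{m}"))
        df = var.genotype_presence(pd.DataFrame(rows))
        df["ccf"] = np.where(df.present, 0.95, 0.0)
        return df

    def test_enumerated_example(self):
        out = var.classify_clonality(self._variants())
        assert (out.label == "clonal").sum() == 6
        assert (out.label == "subclonal").sum() == 4
        assert out.illusion.sum() == 4
        assert out.snv_ith.iloc[0] == pytest.approx(0.4)

    def test_single_region_errors(self):
        df = var.genotype_presence(pd.DataFrame([_row(mut_id="m0")]))
        df["ccf"] = 1.0
        with pytest.raises(ValueError, match="single region"):
            var.classify_clonality(df)


class TestClustering:
    def _pp(self, purity=0.8):
        return pd.DataFrame({"patient": ["P1", "P1"],
                             "region": ["R1", "R2"],
                             "purity": [purity, purity],
                             "ploidy": [2.0, 2.0]})

    def test_all_clonal_single_cluster(self):
        rng = np.random.default_rng(0)
        rows = []
        for m in range(40):
            for reg in ("R1", "R2"):
                alt = rng.binomial(200, 0.4)
                rows.append(_row(region=reg, pos=m + 1, t_alt=alt,
                                 t_ref=200 - alt, mut_id=f"m{m}"))
        res = var.cluster_ccf(pd.DataFrame(rows), self._pp(), seed=1,
                              max_components=5, n_restarts=5)["P1"]
        assert len(res.clusters) == 1
        assert np.allclose(res.clusters[0].prevalence, 1.0, atol=0.1)

    def test_two_clusters_recovered(self):
        """100 clonal + 100 subclonal mutations at depth 200, purity 0.8."""
        rng = np.random.default_rng(1)
        rows = []
        coef = 0.8 / (2 * 0.8 + 2 * 0.2)  # CCF -> VAF
        for m in range(100):
            for reg, ccf in (("R1", 1.0), ("R2", 1.0)):
                alt = rng.binomial(200, ccf * coef)
                rows.append(_row(region=reg, pos=m + 1, t_alt=alt,
                                 t_ref=200 - alt, mut_id=f"a{m}"))
        for m in range(100):
            for reg, ccf in (("R1", 0.4), ("R2", 0.1)):
                alt = rng.binomial(200, ccf * coef)
                rows.append(_row(region=reg, pos=m + 200, t_alt=alt,
                                 t_ref=200 - alt, mut_id=f"b{m}"))
        res = var.cluster_ccf(pd.DataFrame(rows), self._pp(), seed=1)["P1"]
        assert len(res.clusters) == 2
        prevs = sorted([tuple(np.round(c.prevalence, 2))
                        for c in res.clusters], reverse=True)
        assert prevs[0] == pytest.approx((1.0, 1.0), abs=0.05)
        assert prevs[1] == pytest.approx((0.4, 0.1), abs=0.05)

    def test_duplicate_mutation_same_cluster(self):
        rng = np.random.default_rng(2)
        rows = []
        for m in range(20):
            for reg, p in (("R1", 0.4), ("R2", 0.4)):
                alt = rng.binomial(200, p if m < 10 else p / 4)
                rows.append(_row(region=reg, pos=m + 1, t_alt=alt,
                                 t_ref=200 - alt, mut_id=f"m{m}"))
        # duplicate of m0 with identical counts
        for r in [r for r in rows if r["mut_id"] == "m0"]:
            rows.append({**r, "mut_id": "dup", "pos": 999})
        res = var.cluster_ccf(pd.DataFrame(rows), self._pp(), seed=3)["P1"]
        assert res.assignments["dup"] == res.assignments["m0"]

    def test_few_mutations_fallback(self):
        rows = [_row(region=r, pos=1, t_alt=50, t_ref=50, mut_id="m0")
                for r in ("R1", "R2")]
        with pytest.warns(UserWarning, match="single-cluster"):
            res = var.cluster_ccf(pd.DataFrame(rows), self._pp())["P1"]
        assert len(res.clusters) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        rows = []
        for m in range(30):
            for reg in ("R1", "R2"):
                alt = rng.binomial(100, 0.2 if m < 15 else 0.4)
                rows.append(_row(region=reg, pos=m + 1, t_alt=alt,
                                 t_ref=100 - alt, mut_id=f"m{m}"))
        df = pd.DataFrame(rows)
        r1 = var.cluster_ccf(df, self._pp(), seed=7)["P1"]
        r2 = var.cluster_ccf(df, self._pp(), seed=7)["P1"]
        assert (r1.assignments == r2.assignments).all()
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert np.array_equal(c1.prevalence, c2.prevalence)
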