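"""Expression heterogeneity scores, quadrants, concordance, associations."""

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_exact_bruteforce
from mrith import rna
from scipy import stats


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"P{p + 1}_R{r + 1}" for p in range(2)
                          for r in range(values.shape[1] // 2)]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFilterNormalize:
    def test_prevalence_rule(self):
        tpm = pd.DataFrame(
            np.vstack([np.full(10, 5.0),           # passes everywhere
                       np.r_[np.full(1, 5.0), np.zeros(9)]]),  # 10% only
            index=["keep", "drop"],
            columns=[f"P1_R{i}" for i in range(10)])
        out = rna.filter_normalize(tpm)
        assert list(out.index) == ["keep"]

    def test_log_transform_zero(self):
        tpm = pd.DataFrame(np.ones((1, 5)), index=["g"],
                           columns=[f"P1_R{i}" for i in range(5)])
        tpm.iloc[0, 0] = 0.0
        tpm.iloc[0, 1:] = 1.0
        out = rna.filter_normalize(tpm)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 1.0

    def test_exact_row_count(self):
        rng = np.random.default_rng(0)
        tpm = pd.DataFrame(rng.uniform(0, 3, size=(100, 10)),
                           columns=[f"P1_R{i}" for i in range(10)])
        keep = (tpm >= 1).mean(axis=1) >= 0.2
        assert len(rna.filter_normalize(tpm)) == int(keep.sum())

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rna.filter_normalize(pd.DataFrame())


class TestHeterogeneityScores:
    def _planted(self, seed=0, n_per_class=30, n_pat=10, n_reg=4):
        rng = np.random.default_rng(seed)
        sds = {"I": (1.5, 0.1), "II": (0.1, 0.1), "III": (1.5, 1.5),
               "IV": (0.1, 1.5)}
        rows, classes = [], []
        for cls, (intra, inter) in sds.items():
            for g in range(n_per_class):
                offs = rng.normal(0, inter, size=n_pat)
                vals = np.concatenate([
                    5 + offs[p] + rng.normal(0, intra, size=n_reg)
                    for p in range(n_pat)])
                rows.append(vals)
                classes.append(cls)
        cols = [f"P{p}_R{r}" for p in range(n_pat) for r in range(n_reg)]
        return pd.DataFrame(rows, columns=cols), np.array(classes)

    def test_constant_gene_class_ii(self):
        mat = _matrix(np.vstack([np.full(8, 3.0),
                                 np.random.default_rng(0).random(8)]))
        out = rna.heterogeneity_scores(mat)
        assert out.loc["g0", "intra"] == 0.0
        assert out.loc["g0", "inter"] == 0.0
        assert out.loc["g0", "quadrant"] == "II"

    def test_planted_class_recovery(self):
        mat, classes = self._planted()
        out = rna.heterogeneity_scores(mat)
        assert (out.quadrant.to_numpy() == classes).mean() >= 0.9

    def test_region_permutation_invariance(self):
        mat, _ = self._planted(seed=1, n_per_class=5)
        out1 = rna.heterogeneity_scores(mat)
        rng = np.random.default_rng(2)
        cols = []
        for p in range(10):
            block = [f"P{p}_R{r}" for r in range(4)]
            cols.extend(rng.permutation(block))
        out2 = rna.heterogeneity_scores(mat[cols])
        assert np.allclose(out1.intra, out2.intra)
        assert np.allclose(out1.inter, out2.inter)

    def test_quadrants_partition(self):
        mat, _ = self._planted(seed=3, n_per_class=10)
        out = rna.heterogeneity_scores(mat)
        assert out.quadrant.isin(["I", "II", "III", "IV"]).all()
        assert len(out) == len(mat)


class TestConcordance:
    def test_perfect_separation(self):
        vals = [[1, 1, 5, 5, 9, 9]]
        mat = pd.DataFrame(vals, index=["g"],
                           columns=["P1_R1", "P1_R2", "P2_R1", "P2_R2",
                                    "P3_R1", "P3_R2"])
        assert rna.clustering_concordance(mat)["g"] > 0.9

    def test_degenerate_gene_zero(self):
        mat = _matrix(np.full((1, 8), 2.0))
        assert rna.clustering_concordance(mat)["g0"] == 0.0

    def test_iid_noise_scores_low(self):
        """Silhouette of a patient partition on pure noise carries no
        patient signal: well below any planted gene and negatively
        biased (random small clusters are closer to their neighbours
        than to themselves on average)."""
        rng = np.random.default_rng(4)
        cols = [f"P{p}_R{r}" for p in range(10) for r in range(4)]
        scores = []
        for _ in range(20):
            mat = pd.DataFrame(rng.normal(size=(5, 40)), columns=cols)
            scores.extend(rna.clustering_concordance(mat).tolist())
        assert np.mean(scores) < 0.1
        assert max(scores) < 0.5


class TestPatientRnaIth:
    def test_identical_regions_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200)
        mat = pd.DataFrame({"R1": v, "R2": v, "R3": v})
        score, _ = rna.patient_rna_ith(mat)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_region_robust(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(300, 4))
        mat = pd.DataFrame(base, columns=["R1", "R2", "R3", "R4"])
        s1, _ = rna.patient_rna_ith(mat)
        mat["R5"] = mat["R4"]
        s2, _ = rna.patient_rna_ith(mat)
        assert abs(s1 - s2) < 0.05

    def test_saturation_curve_shape(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(300, 6)),
                           columns=[f"R{i}" for i in range(6)])
        _, curve = rna.patient_rna_ith(mat, seed=3)
        assert list(curve.n_regions) == [2, 3, 4, 5, 6]
        # exchangeable regions: the curve is flat within sampling noise
        assert curve.mean_score.max() - curve.mean_score.min() < 0.1

    def test_single_region_errors(self):
        with pytest.raises(ValueError):
            rna.patient_rna_ith(pd.DataFrame({"R1": [1.0, 2.0]}))


class TestDosageAssociation:
    def _setup(self, effect=1.0, seed=0, n=200):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        cols = ["P1_R1", "P1_R2"]
        base = rng.normal(5, 1, size=n)
        expr = pd.DataFrame(
            {"P1_R1": base + effect, "P1_R2": base
             + rng.normal(0, 0.3, n)}, index=genes)
        calls = pd.DataFrame(
            [("P1", "R1", g, "gain") for g in genes]
            + [("P1", "R2", g, "neutral") for g in genes],
            columns=["patient", "region", "gene", "call"])
        return expr, calls

    def test_planted_gain_shift_positive(self):
        expr, calls = self._setup(effect=1.0)
        deltas, tests = rna.dosage_association(expr, calls)
        row = tests[tests.direction == "gain"].iloc[0]
        assert row.mean_delta > 0.5
        assert row.p_value < 0.05

    def test_neutral_in_both_regions_excluded(self):
        expr, calls = self._setup()
        calls["call"] = "neutral"
        deltas, _ = rna.dosage_association(expr, calls)
        assert deltas.empty

    def test_quadrant_enrichment_contingency(self):
        gene_classes = pd.Series(["I"] * 20 + ["IV"] * 20,
                                 index=[f"g{i}" for i in range(40)])
        copy_classes = pd.Series(["subclonal_gain"] * 20 + ["no_change"] * 20,
                                 index=gene_classes.index)
        out = rna.copy_class_quadrant_enrichment(gene_classes, copy_classes)
        row = out[(out.quadrant == "I")
                  & (out.copy_class == "subclonal_gain")].iloc[0]
        p_oracle = fisher_exact_bruteforce(20, 0, 0, 20)
        assert row.p_value == pytest.approx(p_oracle, rel=1e-6)


class TestPromoterAssociation:
    def _cpgs(self, rows):
        return pd.DataFrame(rows, columns=["patient", "region", "chrom",
                                           "pos", "meth_reads",
                                           "total_reads"])

    def test_differential_example_matches_exact_test(self):
        # region1 30/60 vs region2 54/60: diff 0.4, Fisher p < 0.05
        p = fisher_exact_bruteforce(30, 30, 54, 6)
        assert p < 0.05
        cpgs = self._cpgs([("P1", "R1", "chr1", 1000, 30, 60),
                           ("P1", "R2", "chr1", 1000, 54, 60)])
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                              "tss": [1500]})
        expr = pd.DataFrame({"P1_R1": [5.0], "P1_R2": [3.0]}, index=["g"])
        deltas, _ = rna.promoter_methylation_association(
            expr, cpgs, genes, windows={"promoter": (-2000, 2000)})
        assert len(deltas) == 1
        # hyper region (R2) minus hypo region (R1): 3 - 5 = -2
        assert deltas.expr_delta.iloc[0] == pytest.approx(-2.0)

    def test_small_difference_not_differential(self):
        cpgs = self._cpgs([("P1", "R1", "chr1", 1000, 300, 1000),
                           ("P1", "R2", "chr1", 1000, 450, 1000)])
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                              "tss": [1500]})
        expr = pd.DataFrame({"P1_R1": [5.0], "P1_R2": [3.0]}, index=["g"])
        deltas, _ = rna.promoter_methylation_association(
            expr, cpgs, genes, windows={"promoter": (-2000, 2000)})
        assert deltas.empty  # diff 0.15 < 0.2 regardless of p

    def test_gene_without_promoter_coverage_skipped(self):
        cpgs = self._cpgs([("P1", "R1", "chr2", 1000, 10, 60),
                           ("P1", "R2", "chr2", 1000, 55, 60)])
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                              "tss": [1500]})
        expr = pd.DataFrame({"P1_R1": [5.0], "P1_R2": [3.0]}, index=["g"])
        deltas, _ = rna.promoter_methylation_association(expr, cpgs, genes)
        assert deltas.empty
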