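"""Differential-expression engine: size factors, NB GLM, concordance."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm

from afmap.datamodel import SparseCountMatrix
from afmap.de import (
    assign_degs_to_celltypes,
    concordant_degs,
    nb_glm_de,
    pseudobulk_aggregate,
    size_factors,
    strand_artifact_check,
)
from afmap.simulate import _nb_draw


def _counts(arr):
    arr = np.asarray(arr)
    return SparseCountMatrix(
        sp.csr_matrix(arr),
        [f"s{i}" for i in range(arr.shape[0])],
        [f"g{j}" for j in range(arr.shape[1])],
    )


def _samples(conditions, **covs):
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(conditions))],
                       "condition": conditions})
    for k, v in covs.items():
        df[k] = v
    return df


class TestSizeFactors:
    def test_identical_samples(self):
        assert np.allclose(size_factors(_counts([[5, 10, 3], [5, 10, 3]])), [1, 1])

    def test_doubled_sample(self):
        # geometric-mean reference splits the factor symmetrically
        f = size_factors(_counts([[4, 10, 6], [8, 20, 12]]))
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_gene_with_zero_excluded_from_median(self):
        with_zero = size_factors(_counts([[4, 10, 0], [8, 20, 12]]))
        without = size_factors(_counts([[4, 10], [8, 20]]))
        assert np.allclose(with_zero, without)

    def test_no_common_gene_is_error(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(_counts([[1, 0], [0, 1]]))


class TestNbGlmDe:
    def test_all_zero_gene_missing_and_excluded_from_fdr(self, rng):
        y = rng.poisson(10, size=(8, 4))
        y[:, 2] = 0
        de = nb_glm_de(_counts(y), _samples(["AF"] * 4 + ["SR"] * 4))
        assert np.isnan(de.loc[2, "log2fc"])
        assert np.isnan(de.loc[2, "fdr"])
        assert de["fdr"].notna().sum() == 3

    def test_confounded_design_is_error(self, rng):
        y = rng.poisson(10, size=(6, 3))
        samples = _samples(["AF"] * 3 + ["SR"] * 3, batch=[1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="collinear.*batch"):
            nb_glm_de(_counts(y), samples, covariates=["batch"])

    def test_poisson_limit_matches_rate_ratio(self, rng):
        """At dispersion -> 0 and a balanced two-group design the fit equals
        the closed-form Poisson MLE: the ratio of offset-adjusted sums."""
        y = rng.poisson(20, size=(60, 6)).T  # 6 samples x 60 genes
        counts = _counts(y)
        de = nb_glm_de(counts, _samples(["AF"] * 3 + ["SR"] * 3), dispersion=0.0)
        sf = size_factors(counts)
        expected = np.log2(
            (y[:3].sum(axis=0) / sf[:3].sum()) / (y[3:].sum(axis=0) / sf[3:].sum())
        )
        assert np.allclose(de["log2fc"], expected, atol=1e-6)

    def test_matches_statsmodels_nb_glm(self, rng):
        """Cross-check coefficients and SEs against an independent fitter."""
        mu = np.array([15.0, 40.0, 8.0])
        y = _nb_draw(rng, np.tile(mu, (12, 1)), 0.2)
        counts = _counts(y)
        samples = _samples(["AF"] * 6 + ["SR"] * 6, sex=rng.integers(0, 2, 12))
        de = nb_glm_de(counts, samples, covariates=["sex"])
        sf = size_factors(counts)
        X = np.column_stack(
            [np.ones(12), (samples.condition == "AF").astype(float), samples.sex]
        )
        from afmap.de import _dispersion_mom

        alpha = _dispersion_mom(y / sf[:, None], samples.condition.to_numpy())
        for j in range(3):
            fit = sm.GLM(
                y[:, j], X, family=sm.families.NegativeBinomial(alpha=alpha[j]),
                offset=np.log(sf),
            ).fit()
            assert de.loc[j, "log2fc"] == pytest.approx(fit.params[1] / np.log(2), rel=1e-4)
            assert de.loc[j, "se"] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-3)

    def test_null_calibration_small(self, rng):
        """Identical distributions in both groups: ~5% nominal rejections."""
        mu = rng.lognormal(3, 1, size=400)
        y = _nb_draw(rng, np.tile(mu, (20, 1)), 0.2)
        de = nb_glm_de(_counts(y), _samples(["AF"] * 10 + ["SR"] * 10))
        rate = (de["p"] < 0.05).mean()
        assert 0.02 <= rate <= 0.09

    def test_planted_twofold_change_recovered(self, rng):
        """2-fold planted up on 25 and down on 25 of 400 genes (balanced,
        so median-of-ratios stays honest): mean log2fc within 0.1 of +-1."""
        mu = np.full((40, 400), 50.0)
        mu[:20, :25] *= 2.0  # AF samples, up genes
        mu[:20, 25:50] /= 2.0  # AF samples, down genes
        y = _nb_draw(rng, mu, 0.2)
        de = nb_glm_de(_counts(y), _samples(["AF"] * 20 + ["SR"] * 20))
        assert abs(de["log2fc"][:25].mean() - 1.0) < 0.1
        assert abs(de["log2fc"][25:50].mean() + 1.0) < 0.1

    def test_fdr_never_below_p(self, rng):
        y = rng.poisson(15, size=(10, 50))
        de = nb_glm_de(_counts(y), _samples(["AF"] * 5 + ["SR"] * 5))
        ok = de["p"].notna()
        assert np.all(de.loc[ok, "fdr"] >= de.loc[ok, "p"] - 1e-15)


class TestPseudobulk:
    def _nuclei(self, n, donors, cts, conds):
        return pd.DataFrame(
            {"nucleus_id": [f"s{i}" for i in range(n)], "donor_id": donors,
             "condition": conds, "cell_type": cts}
        )

    def test_single_nucleus_group_equals_its_counts(self):
        y = np.array([[3, 0, 7], [1, 2, 0]])
        nuclei = self._nuclei(2, ["d1", "d2"], ["CM", "CM"], ["AF", "SR"])
        with pytest.warns(UserWarning):
            pb = pseudobulk_aggregate(_counts(y), nuclei, min_frac=0.0)
        cm = pb["CM"]["counts"]
        assert np.array_equal(cm.to_dense()[cm.obs_ids.index("d1")],
                              y[0][np.array([True, True, True])])

    def test_detection_threshold_drops_rare_gene(self):
        # gene g1 nonzero in 4/100 CM nuclei -> dropped at min_frac=0.05
        y = np.zeros((100, 2), dtype=int)
        y[:, 0] = 10
        y[:4, 1] = 1
        nuclei = self._nuclei(
            100, ["d1"] * 25 + ["d2"] * 25 + ["d3"] * 25 + ["d4"] * 25,
            ["CM"] * 100, ["AF"] * 50 + ["SR"] * 50,
        )
        pb = pseudobulk_aggregate(_counts(y), nuclei, min_frac=0.05)
        assert pb["CM"]["counts"].feature_ids == ["g0"]

    def test_column_sums_conserved(self, small_multiome):
        cfg, gene_counts, _, nuclei, *_ = small_multiome
        pb = pseudobulk_aggregate(gene_counts, nuclei, min_frac=0.0)
        for ct, d in pb.items():
            mask = (nuclei["cell_type"] == ct).to_numpy()
            raw = np.asarray(gene_counts.matrix[mask].sum(axis=0)).ravel()
            agg = np.asarray(d["counts"].matrix.sum(axis=0)).ravel()
            assert np.array_equal(agg, raw)

    def test_untestable_celltype_flagged(self):
        y = np.ones((4, 2), dtype=int)
        nuclei = self._nuclei(4, ["d1", "d1", "d2", "d3"], ["CM"] * 4,
                              ["AF", "AF", "SR", "SR"])
        with pytest.warns(UserWarning, match="untestable"):
            pb = pseudobulk_aggregate(_counts(y), nuclei, min_frac=0.0)
        assert not pb["CM"]["testable"]


def _de_row(gene, lfc, fdr):
    return {"gene_id": gene, "base_mean": 10.0, "log2fc": lfc, "se": 0.1,
            "stat": lfc / 0.1, "p": fdr / 2, "fdr": fdr}


class TestConcordance:
    def test_rule_application(self):
        de1 = pd.DataFrame([_de_row("gA", 1.0, 0.01), _de_row("gB", 1.0, 0.01),
                            _de_row("gC", 1.0, 0.01)])
        de2 = pd.DataFrame([_de_row("gA", 0.5, 0.02), _de_row("gB", -1.0, 0.01),
                            _de_row("gC", 1.0, 0.2)])
        conc = concordant_degs(de1, de2, fdr=0.05)
        assert conc["gene_id"].tolist() == ["gA"]
        assert conc.loc[0, "sign"] == 1

    def test_symmetric_in_cohort_order(self, rng):
        de1 = pd.DataFrame([_de_row(f"g{i}", rng.normal(), rng.random())
                            for i in range(30)])
        de2 = pd.DataFrame([_de_row(f"g{i}", rng.normal(), rng.random())
                            for i in range(30)])
        a = concordant_degs(de1, de2)
        b = concordant_degs(de2, de1)
        assert set(a["gene_id"]) == set(b["gene_id"])

    def test_empty_intersection_warns(self):
        de1 = pd.DataFrame([_de_row("gA", 1.0, 0.01)])
        de2 = pd.DataFrame([_de_row("gB", 1.0, 0.01)])
        with pytest.warns(UserWarning, match="empty"):
            conc = concordant_degs(de1, de2)
        assert conc.empty


class TestAssignCelltypes:
    def test_assignment_and_empty_retention(self):
        bulk = pd.DataFrame({"gene_id": ["gA", "gB"], "sign": [1, 1]})
        per_ct = {
            "FB": pd.DataFrame([_de_row("gA", 0.8, 0.01), _de_row("gB", 0.9, 0.4)]),
            "CM": pd.DataFrame([_de_row("gA", -0.8, 0.01), _de_row("gB", 0.9, 0.3)]),
        }
        out = assign_degs_to_celltypes(bulk, per_ct, fdr=0.05)
        assert out.loc[out.gene_id == "gA", "cell_types"].iloc[0] == "FB"
        row_b = out.loc[out.gene_id == "gB"].iloc[0]
        assert row_b["cell_types"] == "" and row_b["n_celltypes"] == 0


class TestStrandCheck:
    def test_artifact_flagged_only_in_unstranded(self):
        stranded = pd.DataFrame([_de_row("plus", 1.0, 0.001), _de_row("minus", 0.0, 0.9)])
        unstranded = pd.DataFrame([_de_row("plus", 0.8, 0.001), _de_row("minus", 0.7, 0.01)])
        out = strand_artifact_check(stranded, unstranded, [("plus", "minus")])
        flags = out.set_index("gene_id")["flagged"]
        assert not flags["plus"] and flags["minus"]
        assert out.set_index("gene_id").loc["minus", "partner"] == "plus"

    def test_missing_pair_skipped_with_warning(self):
        stranded = pd.DataFrame([_de_row("plus", 1.0, 0.001)])
        with pytest.warns(UserWarning, match="skipped"):
            out = strand_artifact_check(stranded, stranded, [("plus", "gone")])
        assert out.empty

    def test_empty_pair_list(self):
        stranded = pd.DataFrame([_de_row("plus", 1.0, 0.001)])
        assert strand_artifact_check(stranded, stranded, []).empty
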