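"""Coexpression modules: filters, residualization, adjacency, TOM, detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from afmap.network import (
    detect_modules,
    module_eigengene,
    prefilter_genes,
    residualize_covariates,
    signed_adjacency,
    topological_overlap,
)
from afmap.simulate import generate_block_expression


def naive_tom(A):
    """O(n^3) triple-loop topological overlap oracle."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    out = np.eye(n)
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (L + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


class TestPrefilter:
    def test_all_three_filters_strict(self):
        de = pd.DataFrame(
            {
                "gene_id": ["keep", "low_bm", "low_lfc", "high_p", "bm_boundary"],
                "base_mean": [2.0, 0.5, 2.0, 2.0, 1.0],
                "log2fc": [0.1, 1.0, 0.05, 0.1, 0.1],
                "p": [0.01, 1e-6, 0.01, 0.5, 0.01],
            }
        )
        assert prefilter_genes(de) == ["keep"]


class TestResidualize:
    def test_exact_batch_removal_preserves_grand_mean(self):
        batch = np.array([0, 0, 1, 1, 1, 0])
        y = 5.0 + 2.0 * batch
        expr = pd.DataFrame({"g": y})
        out = residualize_covariates(expr, pd.DataFrame({"batch": batch}))
        assert out["g"].var() < 1e-20
        assert out["g"].iloc[0] == pytest.approx(5.0 + 2.0 * batch.mean())

    def test_orthogonal_covariate_leaves_gene_unchanged(self, rng):
        cov = np.tile([1.0, -1.0], 10)
        y = rng.normal(size=20)
        y = y - (y @ cov) / (cov @ cov) * cov  # project out the covariate
        out = residualize_covariates(pd.DataFrame({"g": y}), pd.DataFrame({"c": cov}))
        assert np.allclose(out["g"], y, atol=1e-12)

    def test_planted_batch_shift_removed_for_all_genes(self, rng):
        batch = rng.integers(0, 2, size=60).astype(float)
        expr = pd.DataFrame(rng.normal(size=(60, 40)),
                            columns=[f"g{j}" for j in range(40)])
        expr.iloc[:, :20] += 3.0 * batch[:, None]
        out = residualize_covariates(expr, pd.DataFrame({"batch": batch}))
        diff = out[batch == 1].mean() - out[batch == 0].mean()
        assert np.all(np.abs(diff) < 1e-10)

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError, match="collinear"):
            residualize_covariates(
                pd.DataFrame({"g": [1.0, 2.0, 3.0]}), pd.DataFrame({"c": [1, 1, 1]})
            )


class TestSignedAdjacency:
    def test_closed_forms(self):
        t = np.linspace(0, 1, 8)
        expr = pd.DataFrame({"a": t, "b": t * 2, "c": -t})
        adj = signed_adjacency(expr, power=9)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert adj.loc["a", "a"] == 1.0

    def test_zero_correlation_value(self, rng):
        # cor = 0 -> 0.5^9
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        adj = signed_adjacency(pd.DataFrame({"x": x, "y": y}), power=9)
        assert adj.loc["x", "y"] == pytest.approx(0.5**9)

    def test_constant_gene_is_error(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr)

    def test_entries_in_unit_interval_and_symmetric(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 15)))
        expr.columns = [f"g{j}" for j in range(15)]
        adj = signed_adjacency(expr).to_numpy()
        assert adj.min() >= 0 and adj.max() <= 1
        assert np.allclose(adj, adj.T, atol=1e-12)


class TestTopologicalOverlap:
    def test_isolated_perfect_pair(self):
        A = pd.DataFrame(np.eye(2))
        A.iloc[0, 1] = A.iloc[1, 0] = 1.0
        tom = topological_overlap(A)
        # (L + a) / (min(k) + 1 - a) = (0 + 1) / (1 + 1 - 1) = 1
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_offdiagonal_stays_zero(self):
        tom = topological_overlap(pd.DataFrame(np.eye(4)))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    def test_triple_loop_oracle(self, rng):
        for n in (5, 12, 25):
            cor = np.corrcoef(rng.normal(size=(n + 5, n)), rowvar=False)
            A = pd.DataFrame((0.5 * (1 + cor)) ** 6)
            tom = topological_overlap(A)
            assert np.allclose(tom.to_numpy(), naive_tom(A.to_numpy()), atol=1e-12)

    def test_symmetric_unit_interval(self, rng):
        cor = np.corrcoef(rng.normal(size=(30, 20)), rowvar=False)
        tom = topological_overlap(pd.DataFrame((0.5 * (1 + cor)) ** 9)).to_numpy()
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1


class TestModuleEigengene:
    def test_identical_genes_give_shared_profile(self, rng):
        profile = rng.normal(size=30)
        expr = pd.DataFrame({f"g{j}": profile for j in range(5)})
        labels = pd.Series([1] * 5, index=expr.columns)
        eig = module_eigengene(expr, labels)["ME1"]
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_orientation_positive_vs_mean_profile(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"g{j}" for j in range(6)])
        expr += rng.normal(size=(40, 1))  # shared component
        labels = pd.Series([1] * 6, index=expr.columns)
        eig = module_eigengene(expr, labels)["ME1"]
        mean_profile = ((expr - expr.mean()) / expr.std()).mean(axis=1)
        assert np.dot(eig, mean_profile) > 0

    def test_deterministic(self, rng):
        expr = pd.DataFrame(rng.normal(size=(25, 8)), columns=[f"g{j}" for j in range(8)])
        labels = pd.Series([1] * 4 + [2] * 4, index=expr.columns)
        a = module_eigengene(expr, labels)
        b = module_eigengene(expr, labels)
        pd.testing.assert_frame_equal(a, b)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        expr, labels = generate_block_expression(seed=0)
        tom = topological_overlap(signed_adjacency(expr))
        part = detect_modules(tom, expr)
        assert adjusted_rand_score(labels, part.labels) >= 0.9
        noise = labels.index[labels == 0]
        assert (part.labels[noise] == 0).mean() > 0.8

    def test_undersized_blocks_all_unassigned(self):
        expr, labels = generate_block_expression(
            block_sizes=(40, 40, 40), n_noise=60, seed=1
        )
        tom = topological_overlap(signed_adjacency(expr))
        part = detect_modules(tom, expr, min_module_size=50)
        assert (part.labels == 0).all()

    def test_highly_correlated_blocks_merge(self):
        expr, labels = generate_block_expression(
            block_sizes=(60, 60), within_cor=0.97, between_cor=0.95,
            n_noise=50, seed=2,
        )
        tom = topological_overlap(signed_adjacency(expr))
        part = detect_modules(tom, expr, merge_cut_height=0.25)
        block_labels = part.labels[labels > 0]
        assert set(block_labels) == {1}

    def test_no_module_below_min_size(self):
        expr, _ = generate_block_expression(seed=3)
        tom = topological_overlap(signed_adjacency(expr))
        part = detect_modules(tom, expr, min_module_size=50)
        sizes = part.labels[part.labels != 0].value_counts()
        assert (sizes >= 50).all()

    def test_invalid_cut_height(self):
        expr, _ = generate_block_expression(block_sizes=(10,), n_noise=0, seed=0)
        tom = topological_overlap(signed_adjacency(expr))
        with pytest.raises(ValueError, match="cut_height"):
            detect_modules(tom, expr, cut_height=1.5)
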