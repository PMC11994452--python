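"""Motif deviations with bias-matched backgrounds, and footprint profiles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from afmap.datamodel import MotifPeakMembership, SparseCountMatrix
from afmap.motif import (
    footprint_profile,
    motif_deviations,
    peak_bias,
    sample_background_peaks,
)


def _peaks(arr):
    arr = np.asarray(arr)
    return SparseCountMatrix(
        sp.csr_matrix(arr),
        [f"n{i}" for i in range(arr.shape[0])],
        [f"p{j}" for j in range(arr.shape[1])],
    )


class TestPeakBias:
    def test_identical_peaks_share_one_bin(self, rng):
        counts = _peaks(np.full((10, 8), 3))
        bias = peak_bias(counts, np.full(8, 0.5), n_bins=4)
        assert bias["joint_bin"].nunique() == 1

    def test_quantile_bins_equal_frequency(self, rng):
        counts = _peaks(rng.integers(0, 30, size=(20, 100)))
        bias = peak_bias(counts, rng.beta(5, 5, 100), n_bins=10)
        counts_per_bin = bias["gc_bin"].value_counts()
        assert counts_per_bin.max() - counts_per_bin.min() <= 1

    def test_fewer_peaks_than_bins_collapses(self, rng):
        counts = _peaks(rng.integers(0, 5, size=(4, 3)))
        with pytest.warns(UserWarning, match="collapsing"):
            bias = peak_bias(counts, np.array([0.3, 0.5, 0.7]), n_bins=10)
        assert bias["n_bins"].iloc[0] == 3

    def test_gc_length_mismatch_is_error(self, rng):
        with pytest.raises(ValueError, match="length"):
            peak_bias(_peaks(np.ones((2, 3))), np.array([0.5, 0.5]))


class TestBackgroundSampling:
    def test_single_bin_draws_from_all_peaks(self, rng):
        counts = _peaks(np.full((5, 20), 2))
        bias = peak_bias(counts, np.full(20, 0.5), n_bins=3)
        bg = sample_background_peaks(bias, n_bg=30, seed=0)
        assert bg.shape == (20, 30)
        assert set(np.unique(bg)) <= set(range(20))
        assert len(np.unique(bg)) > 5  # spread over the pool

    def test_backgrounds_respect_bins_exhaustively(self, rng):
        counts = _peaks(rng.integers(0, 40, size=(30, 200)))
        bias = peak_bias(counts, rng.beta(5, 5, 200), n_bins=5)
        bg = sample_background_peaks(bias, n_bg=10, seed=1)
        joint = bias["joint_bin"].to_numpy()
        sizes = bias["joint_bin"].value_counts()
        for i in range(200):
            if sizes[joint[i]] > 1:
                assert np.all(joint[bg[i]] == joint[i])

    def test_same_seed_identical(self, rng):
        counts = _peaks(rng.integers(0, 10, size=(10, 50)))
        bias = peak_bias(counts, rng.beta(5, 5, 50), n_bins=4)
        assert np.array_equal(
            sample_background_peaks(bias, seed=7), sample_background_peaks(bias, seed=7)
        )

    def test_empty_peak_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            sample_background_peaks(pd.DataFrame(), n_bg=5, seed=0)


class TestMotifDeviations:
    def test_all_peaks_motif_has_zero_raw_deviation(self, rng):
        counts = _peaks(rng.integers(0, 10, size=(15, 12)) + 1)
        membership = MotifPeakMembership({"all": set(counts.feature_ids)})
        bias = peak_bias(counts, rng.beta(5, 5, 12), n_bins=2)
        bg = sample_background_peaks(bias, n_bg=5, seed=0)
        dev = motif_deviations(counts, membership, bg)
        assert np.allclose(dev.raw["all"], 0.0, atol=1e-12)

    def test_z_invariant_to_global_count_scaling(self, rng):
        counts = rng.integers(0, 6, size=(40, 60))
        membership = MotifPeakMembership(
            {"m1": {f"p{j}" for j in range(0, 10)},
             "m2": {f"p{j}" for j in range(10, 25)}}
        )
        gc = rng.beta(5, 5, 60)
        z_vals = []
        for mult in (1, 2):
            pc = _peaks(mult * counts)
            bias = peak_bias(pc, gc, n_bins=4)
            bg = sample_background_peaks(bias, n_bg=30, seed=3)
            z_vals.append(motif_deviations(pc, membership, bg).z)
        diff = (z_vals[0] - z_vals[1]).abs().to_numpy()
        assert np.nanmean(diff) < 0.05

    def test_unknown_peak_reference_is_error(self, rng):
        counts = _peaks(rng.integers(0, 5, size=(5, 4)))
        membership = MotifPeakMembership({"m": {"p0", "ghost"}})
        with pytest.raises(Exception, match="ghost"):
            motif_deviations(counts, membership, np.zeros((4, 3), dtype=int))

    def test_null_z_centered_with_unit_scale(self, small_multiome):
        """Without a planted motif effect, per-motif z over nuclei should be
        roughly standard (chromVAR-style calibration)."""
        from tests.conftest import small_config
        from afmap.simulate import generate_multiome

        cfg = small_config(seed=21, driver_motif_effect=1.0, driver_celltype_effect=1.0)
        _, peak_counts, _, _, gc, membership, _ = generate_multiome(cfg)
        bias = peak_bias(peak_counts, gc, n_bins=10)
        bg = sample_background_peaks(bias, n_bg=50, seed=0)
        dev = motif_deviations(peak_counts, membership, bg)
        means = dev.z.mean(axis=0)
        sds = dev.z.std(axis=0)
        assert np.all(np.abs(means) < 0.1)
        assert np.all((sds > 0.7) & (sds < 1.3))

    def test_planted_driver_motif_recovered(self, small_multiome):
        cfg, _, peak_counts, nuclei, _, gc, membership, truth = small_multiome
        bias = peak_bias(peak_counts, gc, n_bins=10)
        bg = sample_background_peaks(bias, n_bg=50, seed=0)
        dev = motif_deviations(peak_counts, membership, bg)
        cm = (nuclei["cell_type"] == "CM").to_numpy()
        af = (nuclei["condition"] == "AF").to_numpy()
        z = dev.z[truth.driver_motif_id].to_numpy()
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(z[cm & af], z[cm & ~af], alternative="greater").pvalue
        assert p < 1e-4


def _sites(centers, width=10):
    return pd.DataFrame(
        {"chrom": "chrS", "start": [c - width // 2 for c in centers],
         "end": [c + width // 2 for c in centers]}
    )


class TestFootprint:
    def test_uniform_insertions_give_flat_profile(self, rng):
        pos = rng.integers(0, 10_000, size=60_000)
        frags = pd.DataFrame({"chrom": "chrS", "start": pos, "end": pos + 1,
                              "barcode": "n0"})
        prof = footprint_profile(frags, _sites([3000, 7000]), {"g": {"n0"}})
        vals = prof["g"].to_numpy()
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * se + 0.05
        # no systematic dip anywhere: the core matches the flanks
        assert abs(vals[np.abs(prof.index) <= 10].mean() - 1.0) < 0.2

    def test_protected_core_construction(self, rng):
        """Zero insertions inside +-10 bp, uniform outside: profile is 0 in
        the core and ~1 in the flanks."""
        center = 5000
        offs = np.concatenate([np.arange(-250, -10), np.arange(11, 251)])
        d = rng.choice(offs, size=40_000)
        frags = pd.DataFrame({"chrom": "chrS", "start": center + d,
                              "end": center + d + 1, "barcode": "n0"})
        prof = footprint_profile(frags, _sites([center]), {"g": {"n0"}})
        core = prof.loc[np.abs(prof.index) <= 10, "g"]
        flank = prof.loc[np.abs(prof.index) >= 200, "g"]
        assert np.all(core == 0.0)
        assert abs(flank.mean() - 1.0) < 0.05

    def test_empty_group_flagged(self):
        frags = pd.DataFrame({"chrom": ["chrS"], "start": [100], "end": [101],
                              "barcode": ["n0"]})
        with pytest.warns(UserWarning, match="no insertions"):
            prof = footprint_profile(frags, _sites([5000]), {"g": {"n1"}})
        assert prof["g"].isna().all()

    def test_minus_strand_orientation_flip(self, rng):
        # insertions only left of center; minus-strand site flips them right
        center = 5000
        d = rng.integers(-200, -50, size=5000)
        frags = pd.DataFrame({"chrom": "chrS", "start": center + d,
                              "end": center + d + 1, "barcode": "n0"})
        sites_plus = _sites([center]).assign(strand="+")
        sites_minus = _sites([center]).assign(strand="-")
        p_plus = footprint_profile(frags, sites_plus, {"g": {"n0"}})
        p_minus = footprint_profile(frags, sites_minus, {"g": {"n0"}})
        assert p_plus.loc[-100:-60, "g"].sum() > 0
        assert p_plus.loc[60:100, "g"].sum() == 0
        assert np.allclose(p_minus["g"].to_numpy(), p_plus["g"].to_numpy()[::-1])
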