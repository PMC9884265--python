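"""O/E maps, Pearson maps, PC1 calling, feature sorting, saddles, scaling, differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatloop import compartments as cp
from heatloop.core import ContactMatrix, GenomeLayout, SignalTrack
from heatloop.synth import SynthConfig, generate_dataset

TOEPLITZ = np.array([[4.0, 2, 1], [2, 4, 2], [1, 2, 4]])


def brute_diagonal_means(m):
    n = m.shape[0]
    return np.array([np.mean([m[i, i + d] for i in range(n - d)]) for d in range(n)])


class TestExpectedAndOE:
    def test_diagonal_means_against_bruteforce(self):
        np.testing.assert_allclose(cp.expected_by_distance(TOEPLITZ),
                                   brute_diagonal_means(TOEPLITZ))
        assert list(cp.expected_by_distance(TOEPLITZ)) == [4, 2, 1]

    def test_constant_matrix(self):
        m = np.full((5, 5), 3.0)
        np.testing.assert_allclose(cp.expected_by_distance(m), 3.0)

    def test_identity_2x2(self):
        np.testing.assert_allclose(cp.expected_by_distance(np.eye(2)), [1, 0])

    def test_oe_of_toeplitz_is_ones(self):
        np.testing.assert_allclose(cp.observed_over_expected(TOEPLITZ), 1.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 20.0))
    def test_oe_diagonal_means_one_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        m = rng.poisson(8.0, (12, 12)).astype(float) + 1
        m = np.triu(m) + np.triu(m, 1).T
        oe = cp.observed_over_expected(m)
        for d in range(12):
            assert abs(np.mean(np.diagonal(oe, d)) - 1) < 1e-9
        np.testing.assert_allclose(cp.observed_over_expected(scale * m), oe, rtol=1e-12)

    def test_masked_row_propagates(self):
        m = TOEPLITZ.copy()
        m[1, :] = np.nan
        m[:, 1] = np.nan
        oe = cp.observed_over_expected(m)
        assert np.isnan(oe[1]).all()


def test_all_nan_distance_stays_nan():
    m = np.array([[1.0, np.nan, 4], [np.nan, 1, np.nan], [4, np.nan, 1]])
    oe = cp.observed_over_expected(m)
    assert np.isnan(oe[0, 1])
    assert oe[0, 2] == pytest.approx(1.0)


class TestCorrelationMap:
    def test_identical_rows_correlate_one(self):
        oe = np.vstack([np.array([1.0, 2, 3, 4])] * 4) + np.diag([0, 0, 0, 0])
        c = cp.correlation_map(oe)
        assert c[0, 1] == pytest.approx(1.0)

    def test_negated_row(self):
        base = np.array([1.0, -2, 3, -4])
        oe = np.vstack([base, -base, base, -base])
        c = cp.correlation_map(oe)
        assert c[0, 1] == pytest.approx(-1.0)

    def test_checkerboard_block_structure_against_bruteforce(self):
        amp = 0.4
        lab = np.array([1, 1, -1, -1])
        oe = 1.0 + amp * np.outer(lab, lab)
        rng = np.random.default_rng(0)
        oe = oe + rng.normal(0, 0.01, (4, 4))
        oe = (oe + oe.T) / 2
        c = cp.correlation_map(oe)
        brute = np.corrcoef(oe)
        np.testing.assert_allclose(c[np.triu_indices(4, 1)], brute[np.triu_indices(4, 1)],
                                   atol=1e-12)
        assert c[0, 1] > 0 and c[2, 3] > 0 and c[0, 2] < 0 and c[1, 3] < 0


class TestPC1:
    def checkerboard_corr(self, n=16, amp=0.5, seed=0):
        lab = np.where(np.arange(n) % 4 < 2, 1, -1)
        rng = np.random.default_rng(seed)
        oe = 1.0 + amp * np.outer(lab, lab) + rng.normal(0, 0.02, (n, n))
        oe = (oe + oe.T) / 2
        return cp.correlation_map(oe), lab

    def test_recovers_planted_blocks(self):
        corr, lab = self.checkerboard_corr()
        act = SignalTrack("H3K9ac", 10, {"c1": np.where(lab == 1, 5.0, 0.5)})
        prof = cp.compartment_pc1({"c1": corr}, act)
        assert np.array_equal(prof.labels["c1"], lab)

    def test_flipping_activity_flips_labels(self):
        corr, lab = self.checkerboard_corr()
        act = SignalTrack("mark", 10, {"c1": np.where(lab == 1, 0.5, 5.0)})
        prof = cp.compartment_pc1({"c1": corr}, act)
        assert np.array_equal(prof.labels["c1"], -lab)

    def test_degenerate_constant_map_masks_all(self):
        corr = np.full((6, 6), 1.0)
        act = SignalTrack("mark", 10, {"c1": np.ones(6)})
        with pytest.warns(UserWarning, match="degenerate"):
            prof = cp.compartment_pc1({"c1": corr}, act)
        assert (prof.labels["c1"] == 0).all()


class TestSortMatrix:
    def test_identity_when_ascending(self):
        m = np.arange(16.0).reshape(4, 4)
        out, perm = cp.sort_matrix_by_feature(m, np.array([1.0, 2, 3, 4]))
        assert np.array_equal(perm, np.arange(4))
        np.testing.assert_array_equal(out, m)

    def test_reversed_feature_antitransposes(self):
        m = np.arange(16.0).reshape(4, 4)
        m = (m + m.T) / 2
        out, perm = cp.sort_matrix_by_feature(m, np.array([4.0, 3, 2, 1]))
        np.testing.assert_array_equal(out, m[::-1, ::-1])

    def test_nan_features_last_and_checkerboard_blocks(self):
        lab = np.array([1.0, -1, 1, -1])
        m = 1.0 + 0.5 * np.outer(lab, lab)
        feat = np.array([0.5, -0.5, 0.4, np.nan])
        out, perm = cp.sort_matrix_by_feature(m, feat)
        assert perm[-1] == 3
        # sorted by PC1-like feature: same-sign blocks contiguous
        top_left = out[:1, :1].mean()
        assert top_left == pytest.approx(1.5)


class TestSaddle:
    def make_profile(self, pc):
        lab = np.where(pc > 0, 1, -1)
        return cp.CompartmentProfile(pc1={"c1": pc}, labels={"c1": lab})

    def test_all_ones_oe_gives_strength_one(self):
        n = 40
        oe = np.ones((n, n))
        pc = np.linspace(-1, 1, n)
        res = cp.saddle({"c1": oe}, self.make_profile(pc), Q=8, corner=2)
        assert res.strength == pytest.approx(1.0)
        np.testing.assert_allclose(res.matrix[~np.isnan(res.matrix)], 1.0)

    def test_strength_monotone_in_amplitude(self):
        strengths = []
        for amp in (0.1, 0.2, 0.4):
            cfg = SynthConfig(amplitude=amp, n_gained_loops=0, n_stable_loops=0,
                              contact_assays=(("HiC", "0h"),),
                              generate_sequences=False, generate_fine_tracks=False)
            ds = generate_dataset(cfg, seed=11)
            oe = cp.oe_by_chrom(ds.contacts[("HiC", "0h")])
            corr = {c: cp.correlation_map(m) for c, m in oe.items()}
            prof = cp.compartment_pc1(corr, ds.tracks["H3K9ac"])
            strengths.append(cp.saddle(oe, prof).strength)
        assert strengths[0] < strengths[1] < strengths[2]

    def test_q_exceeding_bins_raises(self):
        oe = np.ones((5, 5))
        pc = np.linspace(-1, 1, 5)
        with pytest.raises(ValueError):
            cp.saddle({"c1": oe}, self.make_profile(pc), Q=10)


class TestScaling:
    def test_identical_matrices_identical_curves(self, preset_ds):
        cm = preset_ds.contacts[("HiC", "0h")]
        a = cp.scaling_curve(cm, "arm")
        b = cp.scaling_curve(cm, "arm")
        np.testing.assert_array_equal(a.frequency, b.frequency)

    def test_slope_recovery_of_planted_decay(self):
        cfg = SynthConfig(amplitude=0.0, n_gained_loops=0, n_stable_loops=0,
                          aa_boost=1.0, bb_damp=1.0,
                          contact_assays=(("HiC", "0h"),),
                          generate_sequences=False, generate_fine_tracks=False)
        ds = generate_dataset(cfg, seed=5)
        for cls in ("arm", "pericentromere"):
            curve = cp.scaling_curve(ds.contacts[("HiC", "0h")], cls)
            assert curve.slope == pytest.approx(-1.0, abs=0.05)


class TestDifferenceMap:
    def test_self_difference_zero(self, preset_ds):
        cm = preset_ds.contacts[("HiC", "0h")]
        d = cp.difference_map(cm, cm)
        for m in d.values():
            np.testing.assert_allclose(m, 0.0)

    def test_depth_invariance(self, tiny_layout):
        rng = np.random.default_rng(2)
        n = tiny_layout.n_bins("c1")
        m = rng.poisson(5.0, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        a = ContactMatrix(tiny_layout, {"c1": m})
        b = ContactMatrix(tiny_layout, {"c1": 2 * m})
        d = cp.difference_map(a, b)
        np.testing.assert_allclose(d["c1"], 0.0, atol=1e-9)

    def test_binning_mismatch_raises(self, tiny_layout):
        n = tiny_layout.n_bins("c1")
        a = ContactMatrix(tiny_layout, {"c1": np.ones((n, n))})
        other = GenomeLayout((("c1", 1_000_000),), bin_size=20_000)
        b = ContactMatrix(other, {"c1": np.ones((50, 50))})
        with pytest.raises(ValueError):
            cp.difference_map(a, b)

    def test_hichip_difference_highlights_planted_rnapii_loops(self, preset_ds):
        ds = preset_ds
        d = cp.difference_map(ds.contacts[("HiChIP", "1h")], ds.contacts[("HiC", "1h")])
        planted = {(l.chrom, min(l.bin1, l.bin2), max(l.bin1, l.bin2))
                   for l in ds.truth.loops if l.rnapii and l.folds["1h"] > 0}
        vals = []
        for chrom, m in d.items():
            iu, ju = np.triu_indices_from(m, k=1)
            for i, j, v in zip(iu, ju, m[iu, ju]):
                vals.append(((chrom, int(i), int(j)), v))
        vals.sort(key=lambda t: -t[1])
        top = {k for k, _ in vals[: max(1, len(vals) // 100)]}
        hit = sum(1 for key in planted if key in top)
        assert hit >= 0.9 * len(planted)
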