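"""Fisher z, seed maps, depth FC matrices, contrasts, laminar connectome."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from layervn.connectivity import (
    condition_contrast,
    cross_layer_difference,
    depth_fc_matrix,
    fisher_z,
    laminar_connectome,
    seed_fc_map,
)


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_odd_symmetry(self):
        r = np.linspace(-0.95, 0.95, 21)
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @given(st.floats(-5, 5))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_with_tanh(self, z):
        assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-12)


class TestSeedFCMap:
    def test_self_seed_is_maximal(self, rng):
        ts = rng.standard_normal((5, 200))
        z = seed_fc_map(ts[0], ts, method="pearson")
        assert np.argmax(z) == 0

    def test_null_distribution_of_glm_z(self, rng):
        n = 300
        seed = rng.standard_normal(n)
        targets = rng.standard_normal((400, n))
        z = seed_fc_map(seed, targets, method="glm")
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert z.std() == pytest.approx(1.0, rel=0.15)

    def test_null_distribution_of_pearson_z(self, rng):
        n = 300
        seed = rng.standard_normal(n)
        targets = rng.standard_normal((400, n))
        z = seed_fc_map(seed, targets, method="pearson")
        assert z.std() == pytest.approx(1 / np.sqrt(n - 3), rel=0.15)

    def test_methods_monotone_in_underlying_correlation(self, rng):
        n = 300
        seed = rng.standard_normal(n)
        targets = np.array([r * seed + np.sqrt(1 - r**2) * rng.standard_normal(n)
                            for r in (0.1, 0.4, 0.7)])
        for method in ("glm", "pearson"):
            z = seed_fc_map(seed, targets, method=method)
            assert z[0] < z[1] < z[2]

    def test_zero_variance_seed_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            seed_fc_map(np.ones(50), np.random.default_rng(0).standard_normal((2, 50)))


class TestDepthFCMatrix:
    def test_shared_signal_saturates_z(self, rng):
        common = rng.standard_normal(200)
        ts = common + 0.01 * rng.standard_normal((4, 200))
        m = depth_fc_matrix(ts)
        off = m.z[~np.eye(4, dtype=bool)]
        assert (off > 2.5).all()

    def test_independent_depths_near_zero(self, rng):
        ts = rng.standard_normal((6, 400))
        m = depth_fc_matrix(ts)
        off = m.z[m.offdiag_mask()]
        assert np.abs(off).max() < 4 / np.sqrt(400 - 3)

    def test_diagonal_masked_and_symmetric(self, rng):
        m = depth_fc_matrix(rng.standard_normal((5, 100)))
        assert np.isnan(np.diag(m.z)).all()
        assert np.allclose(m.z, m.z.T, equal_nan=True)

    def test_constant_row_warns_and_masks(self, rng):
        ts = rng.standard_normal((3, 50))
        ts[1] = 2.0
        with pytest.warns(RuntimeWarning, match="constant"):
            m = depth_fc_matrix(ts)
        assert np.isnan(m.z[0, 1]) and np.isnan(m.z[1, 2])
        assert np.isfinite(m.z[0, 2])  # cells not touching the constant row survive

    def test_averaging_over_columns(self, rng):
        a = rng.standard_normal((4, 150))
        b = rng.standard_normal((4, 150))
        za = depth_fc_matrix(a).z
        zb = depth_fc_matrix(b).z
        zm = depth_fc_matrix([a, b]).z
        assert np.allclose(zm, (za + zb) / 2, equal_nan=True)


class TestConditionContrast:
    def test_self_contrast_is_exactly_null(self, rng):
        mats = [depth_fc_matrix(rng.standard_normal((5, 80))) for _ in range(6)]
        res = condition_contrast(mats, mats)
        finite = np.isfinite(res.t)
        assert np.all(res.t[finite] == 0.0)
        assert not res.significant.any()

    def test_benjamini_hochberg_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        rej, padj, _, _ = multipletests([0.01, 0.02, 0.2], alpha=0.05, method="fdr_bh")
        assert np.allclose(padj, [0.03, 0.03, 0.2])

    def test_small_cohort_rejected(self, rng):
        mats = [depth_fc_matrix(rng.standard_normal((4, 60))) for _ in range(2)]
        with pytest.raises(ValueError, match="3 subjects"):
            condition_contrast(mats, mats)

    def test_subject_order_invariance(self, rng):
        a = [depth_fc_matrix(rng.standard_normal((4, 80))) for _ in range(5)]
        b = [depth_fc_matrix(rng.standard_normal((4, 80))) for _ in range(5)]
        r1 = condition_contrast(a, b)
        perm = [3, 1, 4, 0, 2]
        r2 = condition_contrast([a[i] for i in perm], [b[i] for i in perm])
        assert np.allclose(r1.t, r2.t, equal_nan=True)


class TestCrossLayerDifference:
    def test_identical_maps_give_zero_difference(self, rng):
        m = rng.standard_normal((6, 30))
        res = cross_layer_difference({"superficial": m, "deep": m.copy()})
        r = res[("superficial", "deep")]
        assert np.all(r.t[np.isfinite(r.t)] == 0)
        assert not r.significant.any()

    def test_antisymmetry(self, rng):
        a = rng.standard_normal((6, 30))
        b = rng.standard_normal((6, 30))
        r_ab = cross_layer_difference({"A": a, "B": b})[("A", "B")]
        r_ba = cross_layer_difference({"B": b, "A": a})[("B", "A")]
        assert np.allclose(r_ab.mean_effect, -r_ba.mean_effect)
        assert np.allclose(r_ab.t, -r_ba.t, equal_nan=True)

    def test_injected_superficial_edge_detected_only_there(self, rng):
        n_subj, n_targets = 10, 12
        base = rng.standard_normal((n_subj, n_targets)) * 0.1
        sup = base.copy()
        sup[:, 4] += 1.0  # superficial-only FC at target 4
        res = cross_layer_difference({"superficial": sup, "deep": base})
        r = res[("superficial", "deep")]
        assert r.significant[4]
        assert r.significant.sum() == 1

    def test_misaligned_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            cross_layer_difference({"a": rng.standard_normal((4, 10)),
                                    "b": rng.standard_normal((4, 11))})


class TestLaminarConnectome:
    @staticmethod
    def _subjects(rng, n_subj=8, r=0.0, edge=("deep", "superficial"), n=240):
        subs = []
        for _ in range(n_subj):
            src = rng.standard_normal(n)
            a = {lay: rng.standard_normal(n) for lay in ("superficial", "middle", "deep")}
            b = {lay: rng.standard_normal(n) for lay in ("superficial", "middle", "deep")}
            if r:
                a[edge[0]] = src
                b[edge[1]] = r * src + np.sqrt(1 - r**2) * rng.standard_normal(n)
            subs.append({"A": a, "B": b})
        return subs

    def test_planted_edge_is_hottest_cell(self, rng):
        subs = self._subjects(rng, r=0.6)
        res = laminar_connectome(subs, [("A", "B")])[("A", "B")]
        hot = np.unravel_index(np.argmax(res["stats"].mean_effect), (3, 3))
        assert res["layers_a"][hot[0]] == "deep"
        assert res["layers_b"][hot[1]] == "superficial"
        assert res["stats"].significant[hot]

    def test_null_network_mostly_clean(self, rng):
        hits = 0
        for _ in range(20):
            subs = self._subjects(rng, r=0.0)
            res = laminar_connectome(subs, [("A", "B")])[("A", "B")]
            hits += res["stats"].significant.sum()
        assert hits / (20 * 9) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (20 * 9))

    def test_symmetric_edge_gives_symmetric_matrix(self, rng):
        n = 400
        subs = []
        for _ in range(10):
            shared = rng.standard_normal(n)
            mk = lambda: {lay: 0.5 * shared + rng.standard_normal(n)
                          for lay in ("superficial", "middle", "deep")}
            subs.append({"A": mk(), "B": mk()})
        res = laminar_connectome(subs, [("A", "B")])[("A", "B")]
        m = res["stats"].mean_effect
        assert np.allclose(m, m.T, atol=3 / np.sqrt(n - 3))

    def test_missing_roi_named(self, rng):
        subs = self._subjects(rng)
        del subs[3]["B"]
        with pytest.raises(ValueError, match="subject 3 is missing ROI 'B'"):
            laminar_connectome(subs, [("A", "B")])
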