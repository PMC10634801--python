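"""Synthetic cortical-column generator: paradigms, leakage, pial blooming,
task/rest simulation, cohorts."""

import numpy as np
import pytest

from layervn.cortex import (
    BlockParadigm,
    ComplexTimeSeries,
    CorticalColumnSpec,
    LaminarNetworkSpec,
    default_network,
    double_peak_profile,
    leakage_operator,
    make_subject_cohort,
    n_volumes,
    pial_extravascular_term,
    simulate_rest,
    simulate_task,
    wrap_phase,
)
from layervn.layering import sample_layers
from layervn.vascular import PENETRATING_VEIN, vn_attenuation

LAYER3 = {"superficial": (0.85, 0.90), "middle": (0.45, 0.50), "deep": (0.10, 0.15)}


class TestBlockParadigm:
    @pytest.mark.parametrize(
        "n_blocks, expected", [(18, 270), (1, 15), (20, 300)]
    )
    def test_volume_count(self, n_blocks, expected):
        assert n_volumes(BlockParadigm(n_blocks=n_blocks)) == expected

    def test_non_integer_volume_count_rejected(self):
        with pytest.raises(ValueError):
            BlockParadigm(on_s=31.0, off_s=30.0, n_blocks=1, TR_s=4.0)

    def test_boxcar_duty_cycle(self):
        box = BlockParadigm(n_blocks=2).boxcar()
        # 30 s ON covers samples t=0,4,...,28: 8 of the 15 per block
        assert box.sum() == 2 * 8
        assert box[0] == 1.0  # ON first


class TestLeakageOperator:
    def test_no_drainage_is_local(self):
        lam = np.random.default_rng(0).standard_normal((5, 30))
        vw = np.linspace(0.1, 1.0, 5)
        out = leakage_operator(lam, 0.0, vw)
        assert np.allclose(out, vw[:, None] * lam)

    def test_lossless_drain_spreads_impulse_uniformly(self):
        lam = np.zeros((6, 4))
        lam[0] = 1.0  # impulse at the deepest layer
        vw = np.full(6, 0.7)
        out = leakage_operator(lam, 1.0, vw)
        assert np.allclose(out, 0.7)

    def test_geometric_decay_across_depth(self):
        lam = np.zeros((5, 1))
        lam[0, 0] = 1.0
        out = leakage_operator(lam, 0.5, np.ones(5))
        assert np.allclose(out[:, 0], [1, 0.5, 0.25, 0.125, 0.0625])

    def test_drain_fraction_domain(self):
        with pytest.raises(ValueError):
            leakage_operator(np.ones((3, 2)), 1.5, np.ones(3))

    def test_linear_and_causal_toward_surface(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 4, 10))
        vw = rng.uniform(0.1, 1, 4)
        f = 0.3
        lhs = leakage_operator(2 * a + 3 * b, f, vw)
        rhs = 2 * leakage_operator(a, f, vw) + 3 * leakage_operator(b, f, vw)
        assert np.allclose(lhs, rhs)
        # an impulse at depth k never reaches deeper positions
        imp = np.zeros((4, 1))
        imp[2, 0] = 1.0
        out = leakage_operator(imp, f, np.ones(4))
        assert np.all(out[:2] == 0)


class TestPialTerm:
    def test_surface_voxel_full_strength(self):
        col = CorticalColumnSpec(n_depths=4, cortical_thickness_mm=2.0)
        sig = np.ones(3)
        mag, phase = pial_extravascular_term(col, sig)
        d = col.depths
        factor = (0.15 / col.pial_distance(d)) ** 2
        assert np.allclose(mag, col.pial_mag_gain * factor[:, None])
        assert np.allclose(phase, col.phase_rad_per_unit * mag)

    def test_inverse_square_at_six_radii(self):
        col = CorticalColumnSpec()
        dist = col.pial_distance(col.depths)
        factor = (0.15 / dist) ** 2
        six = np.argmin(np.abs(dist - 6 * 0.15))
        assert factor[six] == pytest.approx(1 / 36, rel=0.2)

    def test_zero_signal_zero_perturbation(self):
        col = CorticalColumnSpec()
        mag, phase = pial_extravascular_term(col, np.zeros(10))
        assert not mag.any() and not phase.any()


class TestSimulateTask:
    def test_pure_forward_model_is_exact(self, paradigm):
        col = CorticalColumnSpec(
            drain_fraction=0.0, vein_gain=0.0, arterial_gain=0.0, pial_mag_gain=0.0
        )
        prof = double_peak_profile(col.depths)
        cts = simulate_task(col, paradigm, activation_profile=prof,
                            vn=0.0, noise_sd=0.0)
        from layervn.preprocess import double_gamma_hrf

        box = paradigm.boxcar()
        hrf = double_gamma_hrf(paradigm.TR_s)
        resp = np.convolve(box, hrf)[: box.size]
        expected = col.baseline + 2.0 * col.tissue_weight(col.depths)[:, None] * prof[:, None] * resp[None, :]
        assert np.allclose(cts.magnitude, expected)

    def test_vein_contribution_scales_by_vn_attenuation(self, paradigm):
        # isolate the vein compartment: no tissue/artery/pial response
        col = CorticalColumnSpec(arterial_gain=0.0, pial_mag_gain=0.0)
        kw = dict(noise_sd=0.0, paradigm=paradigm)
        b0 = simulate_task(col, vn=0.0, **kw)
        b7 = simulate_task(col, vn=7.0, **kw)
        col_novein = CorticalColumnSpec(arterial_gain=0.0, pial_mag_gain=0.0, vein_gain=0.0)
        t0 = simulate_task(col_novein, vn=0.0, **kw)
        t7 = simulate_task(col_novein, vn=7.0, **kw)
        vein0 = b0.magnitude - t0.magnitude
        vein7 = b7.magnitude - t7.magnitude
        big = np.abs(vein0) > 1e-3
        ratio = vein7[big] / vein0[big]
        assert np.allclose(ratio, vn_attenuation(7.0, PENETRATING_VEIN), atol=1e-8)

    def test_leakage_biases_flat_profile_superficially(self, paradigm):
        col = CorticalColumnSpec(drain_fraction=0.3, pial_mag_gain=0.0, arterial_gain=0.0)
        flat = np.ones(col.n_depths)
        cts = simulate_task(col, paradigm, activation_profile=flat, vn=0.0, noise_sd=0.0)
        evoked = cts.magnitude.std(axis=1)
        assert evoked[-3:].mean() > evoked[:3].mean()

    def test_seed_required_and_reproducible(self, column, paradigm):
        with pytest.raises(ValueError, match="seed"):
            simulate_task(column, paradigm, noise_sd=1.0)
        a = simulate_task(column, paradigm, noise_sd=1.0, seed=42)
        b = simulate_task(column, paradigm, noise_sd=1.0, seed=42)
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.phase, b.phase)

    def test_vein_variance_never_grows_with_b(self, paradigm):
        col = CorticalColumnSpec(arterial_gain=0.0, pial_mag_gain=0.0)
        base = CorticalColumnSpec(arterial_gain=0.0, pial_mag_gain=0.0, vein_gain=0.0)
        for b in (2.0, 7.0, 8.0):
            vb = simulate_task(col, paradigm, vn=b, noise_sd=0.0).magnitude - \
                simulate_task(base, paradigm, vn=b, noise_sd=0.0).magnitude
            v0 = simulate_task(col, paradigm, vn=0.0, noise_sd=0.0).magnitude - \
                simulate_task(base, paradigm, vn=0.0, noise_sd=0.0).magnitude
            assert vb.var() <= v0.var()

    def test_phase_is_wrapped(self, column, paradigm):
        cts = simulate_task(column, paradigm, noise_sd=1.0, seed=0)
        assert cts.phase.max() <= np.pi and cts.phase.min() > -np.pi


class TestSimulateRest:
    def test_null_edge_gives_null_correlation(self):
        net = LaminarNetworkSpec(rois=("A", "B"), edges=())
        cols = {r: CorticalColumnSpec(drain_fraction=0, vein_gain=0, pial_mag_gain=0)
                for r in net.rois}
        rest = simulate_rest(net, columns=cols, noise_sd=0.0, seed=9)
        sl = {r: sample_layers(rest[r].magnitude, rest[r].depths, LAYER3) for r in net.rois}
        r_hat = np.corrcoef(sl["A"]["deep"], sl["B"]["deep"])[0, 1]
        assert abs(r_hat) < 3 / np.sqrt(300)

    def test_planted_edge_recovered_noise_free(self):
        net = LaminarNetworkSpec(rois=("M1", "AG"),
                                 edges=(("M1", "deep", "AG", "superficial", 0.6),))
        cols = {r: CorticalColumnSpec(drain_fraction=0, vein_gain=0, pial_mag_gain=0)
                for r in net.rois}
        rest = simulate_rest(net, columns=cols, noise_sd=0.0, seed=7)
        sl = {r: sample_layers(rest[r].magnitude, rest[r].depths, LAYER3) for r in net.rois}
        r_hat = np.corrcoef(sl["M1"]["deep"], sl["AG"]["superficial"])[0, 1]
        # Fisher-z standard error at n=300
        assert abs(np.arctanh(r_hat) - np.arctanh(0.6)) < 2 / np.sqrt(300 - 3)

    def test_non_psd_network_rejected_with_edges_named(self):
        edges = (
            ("A", "deep", "B", "deep", 0.9),
            ("A", "deep", "B", "superficial", 0.9),
            ("B", "deep", "B", "superficial", -0.9),
        )
        net = LaminarNetworkSpec(rois=("A", "B"), edges=edges)
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_rest(net, noise_sd=0.0, seed=1)

    def test_drainage_inflates_intra_column_dependency_at_b0(self):
        net = default_network()
        col = {r: CorticalColumnSpec(drain_fraction=0.4, pial_mag_gain=0.0) for r in net.rois}
        out0 = simulate_rest(net, columns=col, vn=0.0, noise_sd=0.0, seed=21)
        out7 = simulate_rest(net, columns=col, vn=7.0, noise_sd=0.0, seed=21)

        def sup_deep_r(cts):
            sl = sample_layers(cts.magnitude, cts.depths, LAYER3)
            return np.corrcoef(sl["superficial"], sl["deep"])[0, 1]

        assert sup_deep_r(out0["M1"]) > sup_deep_r(out7["M1"])

    def test_seed_required_for_source_draws(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_rest(default_network(), noise_sd=0.0)


class TestCohort:
    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            make_subject_cohort(n_subjects=1, seed=0)

    def test_paired_runs_share_neural_sources(self, cohort14):
        subj = cohort14[0]
        m1_b0 = subj.runs[0.0]["M1"].magnitude
        m1_b7 = subj.runs[7.0]["M1"].magnitude
        # deep depths are nearly unaffected by VN, so paired runs correlate strongly
        r = np.corrcoef(m1_b0[4], m1_b7[4])[0, 1]
        assert r > 0.5

    def test_zero_between_subject_sd_gives_identical_physiology(self):
        coh = make_subject_cohort(n_subjects=3, between_subject_sd=0.0, seed=3)
        drains = {s.columns["M1"].drain_fraction for s in coh}
        assert len(drains) == 1

    def test_cohort_is_reproducible(self):
        a = make_subject_cohort(n_subjects=2, seed=99)
        b = make_subject_cohort(n_subjects=2, seed=99)
        assert np.array_equal(a[1].runs[7.0]["S1"].magnitude, b[1].runs[7.0]["S1"].magnitude)


class TestComplexTimeSeriesInvariants:
    def test_shape_congruence_enforced(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ComplexTimeSeries(
                magnitude=np.ones((3, 5)), phase=np.zeros((3, 4)), TR_s=4.0,
                sites=pd.DataFrame({"roi": ["x"] * 3, "depth": [0.1, 0.5, 0.9]}),
            )

    def test_wrap_phase_range_and_identity(self):
        phi = np.linspace(-10, 10, 101)
        w = wrap_phase(phi)
        assert (w > -np.pi).all() and (w <= np.pi).all()
        assert np.allclose(np.exp(1j * w), np.exp(1j * phi))
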