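"""Generator contracts: seeding, noiseless limits, truth retention."""

import numpy as np
import pytest

from ringfit import synthgen
from ringfit.binding import BindingModel


class TestSeedContract:
    def test_same_seed_identical_everywhere(self):
        a = synthgen.gen_titration(seed=42)
        b = synthgen.gen_titration(seed=42)
        np.testing.assert_array_equal(a.raw, b.raw)
        np.testing.assert_array_equal(a.series.signal, b.series.signal)
        ea = synthgen.gen_mp_events(seed=42)
        eb = synthgen.gen_mp_events(seed=42)
        np.testing.assert_array_equal(ea.events, eb.events)
        np.testing.assert_array_equal(ea.labels, eb.labels)
        ha = synthgen.gen_hdx_bimodal(seed=42)
        hb = synthgen.gen_hdx_bimodal(seed=42)
        np.testing.assert_array_equal(ha.intensity, hb.intensity)
        fa = synthgen.gen_fret_traces(n_traces=2, seed=42)
        fb = synthgen.gen_fret_traces(n_traces=2, seed=42)
        np.testing.assert_array_equal(fa[0].i_a, fb[0].i_a)
        np.testing.assert_array_equal(fa[1].latent_states, fb[1].latent_states)

    def test_different_seed_same_latent_different_noise(self):
        a = synthgen.gen_titration(seed=1)
        b = synthgen.gen_titration(seed=2)
        np.testing.assert_array_equal(a.clean_signal, b.clean_signal)
        assert not np.array_equal(a.raw, b.raw)


class TestTitrationGenerator:
    def test_noiseless_artifact_free_equals_model_curve(self):
        ds = synthgen.gen_titration(noise_sd=0.0, dilution_per_step=0.0,
                                    photobleach_per_scan=0.0, seed=0)
        np.testing.assert_allclose(ds.series.signal, ds.clean_signal, atol=1e-12)

    def test_correction_round_trip_with_artifacts(self):
        """Artifacts on, noise off: the correction algebra recovers the
        latent curve exactly from the raw ledger."""
        ds = synthgen.gen_titration(noise_sd=0.0, seed=0)
        assert not np.allclose(ds.raw / ds.raw[0], 1.0 - ds.clean_signal)
        np.testing.assert_allclose(ds.series.signal, ds.clean_signal, atol=1e-10)

    def test_biphasic_curvature_near_first_corner(self):
        ds = synthgen.gen_titration(seed=0)
        d2 = np.diff(ds.clean_signal, 2)
        corner_x = ds.series.x[1:-1][np.argmax(np.abs(d2))]
        assert abs(corner_x - 56.0) < 10.0

    def test_latent_curve_piecewise_linear_through_plateaus(self):
        truth = synthgen.TitrationTruth()
        x = np.array([0.0, 56.0, 158.0, 250.0])
        np.testing.assert_allclose(truth.latent(x), [0.0, 0.45, 0.75, 0.75])

    def test_isotherm_mode_uses_binding_model(self):
        m = BindingModel(0.4, 0.8, 5e-3, 2e-4, 50.0)
        truth = synthgen.TitrationTruth(model=m, mode="isotherm")
        ds = synthgen.gen_titration(truth=truth, noise_sd=0.0, seed=0)
        from ringfit.binding import predict_titration
        np.testing.assert_allclose(ds.clean_signal, predict_titration(m, ds.series.x),
                                   atol=1e-12)

    def test_dilution_budget_enforced(self):
        with pytest.raises(ValueError, match="5%"):
            synthgen.gen_titration(dilution_per_step=0.004, n_steps=30)

    @pytest.mark.parametrize("kwargs", [
        dict(n_steps=3),
        dict(noise_sd=-0.1),
        dict(dilution_per_step=0.2),
        dict(max_x=100.0),          # below the 158 nt corner
        dict(schedule="cubic"),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthgen.gen_titration(**kwargs)


class TestMpEventGenerator:
    def test_single_component_law_of_large_numbers(self):
        ev = synthgen.gen_mp_events([(524.0, 20.0, 1.0)], n_events=1000, seed=0)
        assert abs(ev.events.mean() - 524.0) < 3 * 20.0 / np.sqrt(1000)

    def test_dominant_component_label_share(self):
        ev = synthgen.gen_mp_events(n_events=5000, seed=1)
        share = np.mean(ev.labels == 1)
        assert abs(share - 0.85) < 0.02

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_mp_events([(500.0, 20.0, 0.6), (900.0, 30.0, 0.6)])

    def test_small_n_warns(self):
        with pytest.warns(UserWarning):
            synthgen.gen_mp_events(n_events=20, seed=0)


class TestHdxGenerator:
    def test_low_uptake_mass_fraction_matches_f1(self):
        ds = synthgen.gen_hdx_bimodal(f1=0.30, n_draws=20000, seed=0)
        midpoint = np.mean(ds.truth["means_Da"])
        low = ds.intensity[ds.centers < midpoint].sum() / ds.intensity.sum()
        assert low == pytest.approx(0.30, abs=0.02)

    def test_degenerate_f1_one_is_unimodal_at_low_centroid(self):
        ds = synthgen.gen_hdx_bimodal(f1=1.0, n_draws=5000, seed=0)
        mode = ds.centers[np.argmax(ds.intensity)]
        assert mode == pytest.approx(ds.truth["means_Da"][0], abs=0.5)

    def test_symmetric_mixture_symmetric_about_midpoint(self):
        ds = synthgen.gen_hdx_bimodal(f1=0.5, n_draws=50000, seed=0)
        mid = np.mean(ds.truth["means_Da"])
        low = ds.intensity[ds.centers < mid].sum()
        high = ds.intensity[ds.centers > mid].sum()
        assert low / (low + high) == pytest.approx(0.5, abs=0.02)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_hdx_bimodal(widths_Da=(0.0, 0.5))


class TestFretGenerator:
    def test_single_state_no_noise_exact(self):
        truth = synthgen.FretTruth(state_means=(0.2,), occupancies=(1.0,))
        traces = synthgen.gen_fret_traces(truth=truth, n_traces=2,
                                          noise_sd=0.0, seed=0)
        from ringfit.smfret import trace_efficiency
        for t in traces:
            e, _ = trace_efficiency(t)
            np.testing.assert_array_equal(e, 0.2)

    def test_two_state_noiseless_is_two_level(self):
        truth = synthgen.FretTruth(state_means=(0.2, 0.8), occupancies=(0.5, 0.5),
                                   dwell_mean_frames=10.0)
        traces = synthgen.gen_fret_traces(truth=truth, n_traces=1,
                                          frames_per_trace=500, noise_sd=0.0, seed=0)
        from ringfit.smfret import trace_efficiency
        e, _ = trace_efficiency(traces[0])
        assert set(np.round(e, 12)) == {0.2, 0.8}

    def test_stationary_occupancy_matches_truth(self):
        traces = synthgen.gen_fret_traces(n_traces=40, frames_per_trace=500, seed=1)
        emp = np.bincount(np.concatenate([t.latent_states for t in traces]),
                          minlength=4) / (40 * 500)
        np.testing.assert_allclose(emp, [0.70, 0.15, 0.10, 0.05], atol=0.03)

    def test_transition_matrix_stationary_distribution(self):
        truth = synthgen.FretTruth()
        T = truth.transition_matrix()
        occ = np.array(truth.occupancies)
        np.testing.assert_allclose(occ @ T, occ, atol=1e-12)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_no_zero_total_frames_even_at_high_noise(self):
        traces = synthgen.gen_fret_traces(noise_sd=400.0, n_traces=5, seed=2)
        for t in traces:
            assert np.all(t.i_a + t.i_d > 0)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            synthgen.FretTruth(state_means=(0.2, 1.5), occupancies=(0.5, 0.5))
        with pytest.raises(ValueError):
            synthgen.FretTruth(state_means=(0.2, 0.8), occupancies=(0.6, 0.6))
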