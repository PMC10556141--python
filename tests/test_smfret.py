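"""smFRET trace corrections, hidden-state segmentation, dwell statistics."""

import numpy as np
import pytest

from ringfit import synthgen
from ringfit.smfret import (
    FretTrace,
    dwell_table,
    segment_states,
    state_histogram,
    trace_efficiency,
    truncate_photobleached,
)


def square_wave_trace(e_levels=(0.2, 0.8), period=25, n_frames=200, total=1000.0):
    states = (np.arange(n_frames) // period) % 2
    e = np.array(e_levels)[states]
    return FretTrace(i_d=(1 - e) * total, i_a=e * total, latent_states=states)


class TestTraceEfficiency:
    def test_plain_ratio_when_uncorrected(self):
        t = FretTrace(i_d=np.full(10, 500.0), i_a=np.full(10, 500.0))
        e, flagged = trace_efficiency(t)
        np.testing.assert_array_equal(e, 0.5)
        assert not flagged

    def test_crosstalk_hand_value(self):
        # (300 - 0.1*1000) / (200 + 1000) = 1/6
        t = FretTrace(i_d=np.array([1000.0]), i_a=np.array([300.0]), crosstalk=0.1)
        e, _ = trace_efficiency(t)
        assert e[0] == pytest.approx(1 / 6)

    def test_donor_only_leakage_cancels(self, rng):
        i_d = 1000.0 + 20.0 * rng.standard_normal(500)
        i_a = 0.1 * i_d + 5.0 * rng.standard_normal(500)  # pure leakage
        t = FretTrace(i_d=i_d, i_a=i_a, crosstalk=0.1)
        e, _ = trace_efficiency(t)
        assert abs(e.mean()) < 0.01

    def test_cross_excitation_needs_reference(self, caplog):
        t = FretTrace(i_d=np.array([800.0]), i_a=np.array([400.0]),
                      cross_excitation=0.05)
        e, _ = trace_efficiency(t)  # delta silently forced to 0, logged
        assert e[0] == pytest.approx(400.0 / 1200.0)
        t_ref = FretTrace(i_d=np.array([800.0]), i_a=np.array([400.0]),
                          cross_excitation=0.05, i_ref=1000.0)
        e_ref, _ = trace_efficiency(t_ref)
        assert e_ref[0] == pytest.approx(350.0 / 1150.0)

    def test_negative_corrected_acceptor_flags_trace(self):
        t = FretTrace(i_d=np.full(10, 1000.0), i_a=np.full(10, 50.0), crosstalk=0.1)
        _, flagged = trace_efficiency(t)
        assert flagged

    def test_invalid_crosstalk_rejected(self):
        with pytest.raises(ValueError):
            FretTrace(i_d=np.ones(2), i_a=np.ones(2), crosstalk=0.6)


class TestSegmentation:
    def test_noiseless_square_wave_exact(self):
        traces = [square_wave_trace() for _ in range(3)]
        model = segment_states(traces, K=2, seed=0)
        np.testing.assert_allclose(np.sort(model.means), [0.2, 0.8], atol=1e-6)
        for t, path in zip(traces, model.paths):
            np.testing.assert_array_equal(path, t.latent_states)
        dwells = dwell_table(model)
        lengths = {d["frames"] for d in dwells}
        assert lengths == {25}  # exact square-wave dwell durations

    def test_four_state_occupancy_recovery(self):
        """Occupancies recovered within ±0.05 per state across seeds."""
        for seed in range(10):
            traces = synthgen.gen_fret_traces(seed=seed)
            model = segment_states(traces, K=4, seed=seed)
            emp = np.bincount(
                np.concatenate([t.latent_states for t in traces]), minlength=4
            ) / sum(len(t) for t in traces)
            np.testing.assert_allclose(model.occupancies, emp, atol=0.05)

    def test_noiseless_segmentation_is_exact(self):
        traces = synthgen.gen_fret_traces(noise_sd=0.0, n_traces=5, seed=1)
        model = segment_states(traces, K=4, seed=1)
        acc = np.mean(np.concatenate(model.paths)
                      == np.concatenate([t.latent_states for t in traces]))
        assert acc == 1.0

    def test_constant_trace_bic_selects_one_state(self):
        truth = synthgen.FretTruth(state_means=(0.2,), occupancies=(1.0,))
        traces = synthgen.gen_fret_traces(truth=truth, n_traces=3,
                                          frames_per_trace=120, noise_sd=10.0, seed=2)
        model = segment_states(traces, K=None, k_max=3, seed=2)
        assert model.n_states == 1
        assert model.means[0] == pytest.approx(0.2, abs=0.02)

    def test_loglik_monotone_and_beats_one_state(self):
        traces = synthgen.gen_fret_traces(n_traces=8, seed=3)
        m4 = segment_states(traces, K=4, seed=3)
        m1 = segment_states(traces, K=1, seed=3)
        tol = 1e-6 * abs(m4.loglik)
        assert np.all(np.diff(m4.loglik_history) >= -tol)
        assert m4.loglik > m1.loglik

    def test_transition_matrix_rows_and_occupancies_normalized(self):
        traces = synthgen.gen_fret_traces(n_traces=6, seed=4)
        model = segment_states(traces, K=4, seed=4)
        np.testing.assert_allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert model.occupancies.sum() == pytest.approx(1.0)

    def test_too_few_frames_rejected(self):
        traces = [square_wave_trace(n_frames=40)]
        with pytest.raises(ValueError, match="frames"):
            segment_states(traces, K=2, seed=0)


class TestDwellTable:
    def test_dwell_totals_equal_trace_lengths(self):
        traces = synthgen.gen_fret_traces(n_traces=5, seed=5)
        model = segment_states(traces, K=4, seed=5)
        dwells = dwell_table(model)
        for i, t in enumerate(traces):
            total = sum(d["frames"] for d in dwells if d["trace"] == i)
            assert total == len(t)

    def test_seconds_use_frame_time(self):
        traces = [square_wave_trace()]
        model = segment_states(traces * 3, K=2, seed=0)
        d = dwell_table(model, frame_time=0.150)[0]
        assert d["seconds"] == pytest.approx(d["frames"] * 0.150)


class TestHistogram:
    def test_dominant_low_fret_state_sets_the_mode(self):
        traces = synthgen.gen_fret_traces(seed=6)
        hist = state_histogram(traces, bin_width=0.05)
        assert abs(hist["mode"] - 0.2) <= 0.025 + 1e-12

    def test_uniform_efficiencies_flat(self, rng):
        e = rng.uniform(0.0, 1.0, size=100_000)
        t = FretTrace(i_d=(1 - e) * 1000.0, i_a=e * 1000.0)
        hist = state_histogram([t], bin_width=0.1)
        counts = hist["counts"]
        assert counts.max() / counts.min() < 1.5

    def test_two_equal_states_bimodal_equal_mass(self):
        truth = synthgen.FretTruth(state_means=(0.2, 0.8), occupancies=(0.5, 0.5))
        traces = synthgen.gen_fret_traces(truth=truth, n_traces=40,
                                          frames_per_trace=500, seed=7)
        hist = state_histogram(traces, bin_width=0.05)
        c = hist["counts"]
        low = c[hist["centers"] < 0.5].sum() / c.sum()
        assert low == pytest.approx(0.5, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            state_histogram([])

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            state_histogram([square_wave_trace()], bin_width=0.5)


class TestPhotobleachTruncation:
    def test_trace_cut_at_intensity_collapse(self):
        i_d = np.concatenate([np.full(80, 800.0), np.full(20, 10.0)])
        i_a = np.concatenate([np.full(80, 200.0), np.full(20, 5.0)])
        t = truncate_photobleached(FretTrace(i_d=i_d, i_a=i_a))
        assert len(t) == 80

    def test_untouched_without_bleaching(self):
        t = square_wave_trace()
        assert len(truncate_photobleached(t)) == len(t)
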