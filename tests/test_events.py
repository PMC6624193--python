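"""Event machinery: detection geometry, FWHM, exclusions, timing statistics."""

from types import SimpleNamespace

import numpy as np
import pytest

from larvascape import events
from larvascape.synthlarva import SimulationConfig, simulate_crawl_kinematics
from conftest import truth_tracks


def make_dtrace(time, distance, resting=None, pair_id="p"):
    d = np.asarray(distance, dtype=float)
    return events.DistanceTrace(
        pair_id=pair_id,
        time=np.asarray(time, dtype=float),
        distance=d,
        resting_length=float(resting if resting is not None else np.percentile(d, 90)),
    )


def triangle_trace(dt=0.1, apex_t=3.0, depth=40.0, half_dur=1.0, total=6.0, rest=100.0):
    t = np.arange(0, total + dt / 2, dt)
    d = rest - depth * np.clip(1 - np.abs(t - apex_t) / half_dur, 0, None)
    return make_dtrace(t, d, resting=rest)


class TestDistance:
    def test_static_pair_has_constant_distance(self):
        a = SimpleNamespace(cell_id="a", valid_start=0, valid_end=9,
                            positions=np.zeros((10, 3)), time=np.arange(10) / 10)
        b = SimpleNamespace(cell_id="b", valid_start=0, valid_end=9,
                            positions=np.tile([0.0, 80.0, 0.0], (10, 1)),
                            time=np.arange(10) / 10)
        tr = events.inter_cell_distance(a, b)
        np.testing.assert_allclose(tr.distance, 80.0)

    def test_identical_tracks_rejected_as_degenerate(self):
        a = SimpleNamespace(cell_id="a", valid_start=0, valid_end=9,
                            positions=np.ones((10, 3)), time=np.arange(10) / 10)
        with pytest.raises(ValueError, match="degenerate"):
            events.inter_cell_distance(a, a)

    def test_no_overlap_rejected(self):
        a = SimpleNamespace(cell_id="a", valid_start=0, valid_end=3,
                            positions=np.zeros((10, 3)), time=np.arange(10) / 10)
        b = SimpleNamespace(cell_id="b", valid_start=5, valid_end=9,
                            positions=np.ones((10, 3)), time=np.arange(10) / 10)
        with pytest.raises(ValueError, match="overlap"):
            events.inter_cell_distance(a, b)

    def test_crawl_pair_minimum_matches_ground_truth_segment_length(self):
        cfg = SimulationConfig(n_segments=3, duration=6.0)
        truth = simulate_crawl_kinematics(cfg)
        tracks = {t.cell_id: t for t in truth_tracks(truth)}
        tr = events.inter_cell_distance(tracks["ddaE_s1_L"], tracks["ddaE_s0_L"])
        assert abs(tr.distance.min() - truth.segment_lengths[1].min()) < 1.0


class TestDetection:
    def test_constant_distance_yields_no_events(self):
        tr = make_dtrace(np.arange(50) / 10, np.full(50, 90.0), resting=90.0)
        assert events.detect_contractions(tr) == []

    def test_triangular_dip_depth_and_fwhm_exact(self):
        tr = triangle_trace()
        evs = events.detect_contractions(tr, smoothing_s=0.0)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.depth == pytest.approx(40.0)
        assert ev.fwhm == pytest.approx(1.0)
        assert ev.t_max_contraction == pytest.approx(3.0)

    def test_two_identical_dips_give_identical_events(self):
        dt = 0.1
        t = np.arange(0, 12, dt)
        rest = 100.0
        d = rest - 40 * (
            np.clip(1 - np.abs(t - 3.0), 0, None) + np.clip(1 - np.abs(t - 8.0), 0, None)
        )
        tr = make_dtrace(t, d, resting=rest)
        evs = events.detect_contractions(tr, smoothing_s=0.0)
        assert len(evs) == 2
        assert evs[0].fwhm == pytest.approx(evs[1].fwhm)
        assert evs[0].depth == pytest.approx(evs[1].depth)

    @pytest.mark.parametrize("sigma", [0.3, 0.5, 0.8])
    def test_gaussian_dip_fwhm_matches_2355_sigma(self, sigma):
        dt = 0.1
        t = np.arange(0, 10, dt)
        d = 100.0 - 30.0 * np.exp(-((t - 5.0) ** 2) / (2 * sigma**2))
        tr = make_dtrace(t, d, resting=100.0)
        (ev,) = [e for e in events.detect_contractions(tr) if e.included]
        assert abs(ev.fwhm - 2.355 * sigma) <= dt

    def test_event_statistics_invariant_to_time_translation(self):
        a = triangle_trace(apex_t=2.5)
        evs_a = events.detect_contractions(a, smoothing_s=0.0)
        b = make_dtrace(a.time + 17.3, a.distance, resting=a.resting_length)
        evs_b = events.detect_contractions(b, smoothing_s=0.0)
        assert evs_b[0].t_max_contraction - evs_a[0].t_max_contraction == pytest.approx(17.3)
        assert evs_b[0].fwhm == pytest.approx(evs_a[0].fwhm)


class TestExclusions:
    def test_recovering_dip_is_included(self):
        tr = triangle_trace()
        evs = events.apply_exclusion_rules(
            events.detect_contractions(tr, smoothing_s=0.0), tr
        )
        assert evs[0].included

    def test_no_return_to_rest_excluded(self):
        dt = 0.1
        t = np.arange(0, 8, dt)
        d = np.where(t < 2, 100.0, np.nan)
        # dip at t=3 then sustained 20% shortening
        d = 100.0 - 40 * np.clip(1 - np.abs(t - 3.0), 0, None)
        d[t >= 3.8] = 80.0
        tr = make_dtrace(t, d, resting=100.0)
        evs = events.apply_exclusion_rules(
            events.detect_contractions(tr, smoothing_s=0.0), tr
        )
        assert not evs[0].included and evs[0].reason == "no-return"

    def test_max_two_events_per_neuron(self):
        dt = 0.1
        t = np.arange(0, 22, dt)
        rest = 100.0
        d = rest - 40 * sum(
            np.clip(1 - np.abs(t - c), 0, None) for c in (3.0, 8.0, 13.0, 18.0)
        )
        tr = make_dtrace(t, d, resting=rest)
        evs = events.apply_exclusion_rules(
            events.detect_contractions(tr, smoothing_s=0.0), tr
        )
        included = [e.included for e in evs]
        reasons = [e.reason for e in evs]
        assert included == [True, True, False, False]
        assert reasons[2] == reasons[3] == "max-two-per-neuron"


class TestNormalization:
    def test_time_scaled_copies_collapse_onto_one_curve(self):
        # two Gaussian dips with FWHM 0.8 s and 1.6 s, congruent after scaling
        aligned = []
        for sigma in (0.8 / 2.355, 1.6 / 2.355):
            dt = 0.05
            t = np.arange(0, 16, dt)
            d = 100.0 - 30.0 * np.exp(-((t - 8.0) ** 2) / (2 * sigma**2))
            tr = make_dtrace(t, d, resting=100.0)
            (ev,) = [e for e in events.detect_contractions(tr, smoothing_s=0.0)
                     if e.included]
            aligned.append(events.normalize_event(ev, tr))
        diff = np.abs(aligned[0].distance - aligned[1].distance)
        assert np.nanmax(diff) < 0.02 * 30.0

    def test_amplitude_normalized_peak_is_one(self):
        tr = triangle_trace()
        (ev,) = events.detect_contractions(tr, smoothing_s=0.0)
        rt = SimpleNamespace(time=tr.time, dff=np.exp(-((tr.time - 3.0) ** 2)))
        al = events.normalize_event(ev, tr, rt)
        assert np.nanmax(al.dff_normalized) == pytest.approx(1.0)

    def test_event_at_recording_edge_flagged_truncated(self):
        tr = triangle_trace(apex_t=1.0, total=4.0)
        (ev,) = [e for e in events.detect_contractions(tr, smoothing_s=0.0)
                 if e.included]
        al = events.normalize_event(ev, tr)
        assert al.truncated

    def test_excluded_event_refused(self):
        tr = triangle_trace()
        (ev,) = events.detect_contractions(tr, smoothing_s=0.0)
        ev.included = False
        ev.reason = "no-return"
        with pytest.raises(ValueError, match="excluded"):
            events.normalize_event(ev, tr)


class TestAveraging:
    def _aligned_pair(self, perturb=0.0):
        tr = triangle_trace()
        (ev,) = events.detect_contractions(tr, smoothing_s=0.0)
        base = np.exp(-((tr.time - 3.0) ** 2))
        out = []
        for sign in (+1, -1):
            rt = SimpleNamespace(time=tr.time, dff=base + sign * perturb * np.sin(tr.time))
            out.append(events.normalize_event(ev, tr, rt))
        return out

    def test_averaging_event_with_itself(self):
        a, b = self._aligned_pair(0.0)
        avg = events.average_events([a, b], use_normalized=False)
        np.testing.assert_allclose(avg["mean_dff"], a.dff, rtol=1e-12)
        finite = np.isfinite(avg["sd_dff"])
        np.testing.assert_allclose(avg["sd_dff"][finite], 0.0, atol=1e-12)

    def test_mirror_perturbations_cancel_in_mean(self):
        a, b = self._aligned_pair(0.1)
        clean, _ = self._aligned_pair(0.0)
        avg = events.average_events([a, b], use_normalized=False)
        np.testing.assert_allclose(avg["mean_dff"], clean.dff, atol=1e-12)

    def test_single_event_refused(self):
        a, _ = self._aligned_pair()
        with pytest.raises(ValueError, match="at least 2"):
            events.average_events([a])

    def test_noisy_events_average_to_truth_within_clt_bound(self):
        rng = np.random.default_rng(7)
        tr = triangle_trace()
        (ev,) = events.detect_contractions(tr, smoothing_s=0.0)
        shape = np.exp(-((tr.time - 3.0) ** 2))
        noise_sd = 0.05
        aligned = [
            events.normalize_event(
                ev, tr, SimpleNamespace(time=tr.time, dff=shape + rng.normal(0, noise_sd, tr.time.size))
            )
            for _ in range(20)
        ]
        clean = events.normalize_event(ev, tr, SimpleNamespace(time=tr.time, dff=shape))
        avg = events.average_events(aligned, use_normalized=False)
        # 4 sd of the mean; linear interpolation keeps per-point noise <= noise_sd
        bound = 4 * noise_sd / np.sqrt(20)
        ok = np.isfinite(avg["mean_dff"]) & np.isfinite(clean.dff)
        assert np.abs(avg["mean_dff"][ok] - clean.dff[ok]).max() < bound


class TestPhaseAndTiming:
    def _aligned_with(self, dff_fn):
        tr = triangle_trace()
        (ev,) = events.detect_contractions(tr, smoothing_s=0.0)
        tau = (tr.time - ev.t_max_contraction) / ev.fwhm
        rt = SimpleNamespace(time=tr.time, dff=dff_fn(tau))
        return events.normalize_event(ev, tr, rt)

    def test_null_signal_gives_zero_phases(self):
        al = self._aligned_with(lambda tau: np.zeros_like(tau))
        ps = events.phase_statistics(al)
        assert ps.resting_value == 0.0 and ps.contraction_value == 0.0

    def test_boxcar_gives_resting_zero_contraction_one(self):
        al = self._aligned_with(lambda tau: ((tau >= -0.5) & (tau <= 0.5)).astype(float))
        ps = events.phase_statistics(al)
        assert ps.resting_value == pytest.approx(0.0)
        assert ps.contraction_value == pytest.approx(1.0)

    def test_half_max_interpolation_arithmetic(self):
        grid = 0.05 * np.arange(4)
        vals = np.array([0.0, 0.2, 0.8, 1.0])
        t = events.half_max_time(grid, vals)
        assert t == pytest.approx(grid[1] + (0.5 - 0.2) / (0.8 - 0.2) * 0.05)

    def test_half_max_step_function(self):
        grid = 0.05 * np.arange(4)
        t = events.half_max_time(grid, np.array([0.0, 0.0, 1.0, 1.0]))
        assert grid[1] <= t <= grid[2]

    @pytest.mark.parametrize("delta", [-0.4, 0.15, 1.0])
    def test_half_max_shift_equivariance(self, delta):
        grid = np.arange(-3, 3.001, 0.05)
        vals = 1 / (1 + np.exp(-5 * grid))
        shifted = 1 / (1 + np.exp(-5 * (grid - delta)))
        t0 = events.half_max_time(grid, vals)
        t1 = events.half_max_time(grid, shifted)
        # edge sampling of the shifted sigmoid perturbs the max slightly
        assert t1 - t0 == pytest.approx(delta, abs=1e-3)

    def test_half_max_undefined_for_nonpositive_max(self):
        grid = np.arange(5.0)
        assert np.isnan(events.half_max_time(grid, -np.ones(5)))


class TestPairedLagTest:
    def test_hand_computed_example(self):
        res = events.paired_lag_test([0, 0, 0], [0.5, 1.0, 1.5])
        assert res["t"] == pytest.approx(3.4641, abs=1e-4)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(0.0371, abs=1e-3)

    def test_symmetric_differences_give_half(self):
        res = events.paired_lag_test([0.0, 0.0], [0.3, -0.3])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(0.5)

    def test_degenerate_variance_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            events.paired_lag_test([0.0, 0.0, 0.0], [0.2, 0.2, 0.2])

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError, match="at least 2"):
            events.paired_lag_test([0.0], [0.1])
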