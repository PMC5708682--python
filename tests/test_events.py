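import numpy as np
import pytest

from pbptraj import events
from pbptraj.events import (EndpointSummary, EventCall, MetricSeries, concatenate_runs,
                            detect_crossovers, endpoint_summary, find_events,
                            score_concurrency)
from pbptraj.synthetic import SyntheticConfig, generate_trajectory, make_toy_protein


def series(values, interval=20.0, boundaries=(), name="distance"):
    return MetricSeries(name, np.asarray(values, float), interval, boundaries)


class TestMetricSeries:
    def test_segments(self):
        s = series(np.zeros(10), boundaries=(4, 7))
        assert s.segments() == [(0, 4), (4, 7), (7, 10)]
        assert s.segment_of(5) == (4, 7)

    def test_bad_boundaries(self):
        with pytest.raises(ValueError):
            series(np.zeros(10), boundaries=(7, 4))
        with pytest.raises(ValueError):
            series(np.zeros(10), boundaries=(10,))

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            EndpointSummary("initial", (2.0, 1.0, 3.0), (0.0, 4.0), 5)


class TestEndpointSummary:
    def test_constant_series(self):
        s = series(np.full(500, 7.5))
        ini, fin = endpoint_summary(s)
        assert ini.quartiles == (7.5, 7.5, 7.5)
        assert fin.whiskers == (7.5, 7.5)

    def test_single_run_250_per_window(self):
        # one 50 ns run at 20 ps sampling: 2500 frames, 5 ns window = 250
        s = series(np.arange(2500.0))
        ini, fin = endpoint_summary(s, window_ns=5, sample_every_ps=20)
        assert ini.n_values == 250
        assert fin.n_values == 250
        assert ini.whiskers == (0.0, 249.0)
        assert fin.whiskers == (2250.0, 2499.0)

    def test_ten_runs_2500_per_box(self):
        vals = np.arange(25000.0)
        s = series(vals, boundaries=tuple(range(2500, 25000, 2500)))
        ini, fin = endpoint_summary(s)
        assert ini.n_values == 2500
        assert fin.n_values == 2500

    def test_quartiles_linear_interpolation(self):
        s = series(np.arange(500.0))
        ini, _ = endpoint_summary(s, window_ns=5, sample_every_ps=20)
        want = np.percentile(np.arange(250.0), [25, 50, 75])
        np.testing.assert_allclose(ini.quartiles, want)

    def test_permutation_invariant_within_window(self, rng):
        vals = rng.normal(size=600)
        s1 = series(vals)
        shuffled = vals.copy()
        rng.shuffle(shuffled[:250])
        s2 = series(shuffled)
        a, _ = endpoint_summary(s1)
        b, _ = endpoint_summary(s2)
        assert a == b

    def test_short_run_rejected(self):
        s = series(np.zeros(300))
        with pytest.raises(ValueError, match="shorter"):
            endpoint_summary(s, window_ns=5, sample_every_ps=20)

    def test_bad_sampling_stride(self):
        s = series(np.zeros(600))
        with pytest.raises(ValueError, match="multiple"):
            endpoint_summary(s, sample_every_ps=30)


class TestDetectCrossovers:
    def test_constant_delta_no_crossover(self):
        qo = np.full(500, 0.4)
        qc = np.full(500, 0.6)
        assert detect_crossovers(qo, qc) == []

    def test_constructed_step(self):
        qc = np.concatenate([np.full(500, 0.7), np.full(500, 0.3)])
        qo = np.concatenate([np.full(500, 0.5), np.full(500, 0.5)])
        calls = detect_crossovers(qo, qc)
        assert len(calls) == 1
        frame, dominant = calls[0]
        assert dominant == "open"
        assert abs(frame - 500) <= 13  # within half the smoothing window

    def test_mirrored_series_mirror_frames(self):
        qc = np.concatenate([np.full(400, 0.7), np.full(400, 0.3)])
        qo = np.full(800, 0.5)
        fwd = detect_crossovers(qo, qc)
        rev = detect_crossovers(qo[::-1].copy(), qc[::-1].copy())
        assert len(fwd) == len(rev) == 1
        assert abs((800 - 1 - rev[0][0]) - fwd[0][0]) <= events.SMOOTH_WINDOW_FRAMES

    def test_unsustained_flip_ignored(self):
        qc = np.full(600, 0.6)
        qo = np.full(600, 0.4)
        qo[300:310] = 0.9  # 10-frame blip, far below min_sustain
        assert detect_crossovers(qo, qc, smooth_window_frames=1) == []

    def test_boundary_exclusion(self):
        # run 1 ends closed-dominant; run 2 is open-dominant throughout:
        # the flip happens across the boundary and must not be reported
        qc = np.concatenate([np.full(300, 0.7), np.full(300, 0.3)])
        qo = np.full(600, 0.5)
        assert detect_crossovers(qo, qc, run_boundaries=(300,)) == []

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            detect_crossovers(np.zeros(5), np.zeros(6))

    def test_smoothing_window_too_long(self):
        with pytest.raises(ValueError, match="window"):
            detect_crossovers(np.zeros(10), np.ones(10), smooth_window_frames=10)


def bundle_with(crossframe, n=600, direction="opening", prominent=True):
    """Construct a five-metric bundle with synchronized extrema at crossframe."""
    rng = np.random.default_rng(0)
    out = {}
    for name in events.CONCURRENCY_METRICS:
        base = np.full(n, 10.0) if not prominent else rng.normal(scale=0.05, size=n) + 10.0
        if prominent:
            sign = 1.0
            if direction == "closing" and name != "rmsd":
                sign = -1.0
            base[crossframe - 5:crossframe + 5] += sign * 3.0
        out[name] = MetricSeries(name, base, 20.0)
    return out


class TestScoreConcurrency:
    def test_all_five_supporting(self):
        b = bundle_with(300, direction="opening")
        call = score_concurrency((300, "open"), b)
        assert set(call.supporting_metrics) == set(events.CONCURRENCY_METRICS)
        assert call.sustained and call.direction == "opening"

    def test_flat_metrics_unsupported(self):
        b = bundle_with(300, prominent=False)
        call = score_concurrency((300, "open"), b)
        assert call.supporting_metrics == ()
        assert not call.sustained

    def test_closing_pattern(self):
        b = bundle_with(300, direction="closing")
        call = score_concurrency((300, "closed"), b)
        assert set(call.supporting_metrics) == set(events.CONCURRENCY_METRICS)
        assert call.direction == "closing"

    def test_supporting_metrics_validated(self):
        with pytest.raises(ValueError, match="unknown supporting"):
            EventCall("opening", 1, "r", ("dihedral",), True)


@pytest.fixture(scope="module")
def two_run_setup():
    cfg = SyntheticConfig(n_residues=60, n_runs=2, run_length_ns=2.0,
                          noise_sigma=0.2, seed=21, label="pair",
                          event_schedule=((0, 1000.0, "opening"),))
    runs, truth = generate_trajectory(cfg)
    open_ref, closed_ref = make_toy_protein(cfg)
    bundle = concatenate_runs(runs, open_ref, closed_ref, cfg.partition,
                              sasa_n_points=60)
    return cfg, runs, truth, bundle


class TestConcatenateRuns:
    def test_boundary_recorded(self, two_run_setup):
        _, runs, _, bundle = two_run_setup
        assert bundle["distance"].run_boundaries == (runs[0].n_frames,)
        assert len(bundle) == len(events.METRIC_NAMES)
        assert all(b.values.size == sum(r.n_frames for r in runs) for b in bundle.values())

    def test_single_run_no_boundary(self, small_cfg, small_refs):
        runs, _ = generate_trajectory(small_cfg)
        o, c = small_refs
        bundle = concatenate_runs(runs, o, c, small_cfg.partition, sasa_n_points=60)
        assert bundle["distance"].run_boundaries == ()

    def test_interval_mismatch_rejected(self, small_cfg, small_refs):
        (r1,), _ = generate_trajectory(small_cfg)
        from pbptraj.model_io import Trajectory
        r2 = Trajectory(r1.atoms, r1.coords, r1.frame_interval_ps * 2)
        o, c = small_refs
        with pytest.raises(ValueError, match="interval"):
            concatenate_runs([r1, r2], o, c, small_cfg.partition)

    def test_event_found_in_scheduled_run(self, two_run_setup):
        cfg, runs, truth, bundle = two_run_setup
        calls = find_events(bundle)
        opening = [c for c in calls if c.direction == "opening"]
        assert len(opening) == 1
        true_frame = truth.events[0][0][0]
        assert abs(opening[0].crossover_frame - true_frame) <= events.SMOOTH_WINDOW_FRAMES
        assert opening[0].run_id == runs[0].run_id
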