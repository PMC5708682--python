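"""Endpoint-window summaries and crossover-based conformational-event calls.

The event procedure formalises a by-eye protocol: smooth the two
q(similarity) traces, find sign changes of ``q_closed - q_open`` that
persist, then ask whether the geometric/descriptor metrics show a
concurrent extremum of sufficient prominence.  All thresholds are explicit
keyword defaults so calls are deterministic and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import descriptors, geometry, similarity
from .model_io import DomainPartition, Structure, Trajectory

__all__ = [
    "MetricSeries",
    "EndpointSummary",
    "EventCall",
    "endpoint_summary",
    "detect_crossovers",
    "score_concurrency",
    "concatenate_runs",
    "find_events",
    "METRIC_NAMES",
    "CONCURRENCY_METRICS",
]

METRIC_NAMES = ("distance", "angle", "dihedral", "rmsd", "rg", "sas",
                "q_nc_open", "q_nc_closed", "q_sim_open", "q_sim_closed")

#: metrics consulted by score_concurrency (dihedral deliberately excluded:
#: it shows little sensitivity to the open/close motion)
CONCURRENCY_METRICS = ("distance", "angle", "rmsd", "rg", "sas")

# defaults, in frames at the standard 20 ps interval
SMOOTH_WINDOW_FRAMES = 25     # 0.5 ns
MIN_SUSTAIN_FRAMES = 50       # 1.0 ns
CONCURRENCY_WINDOW_FRAMES = 50
PROMINENCE_MADS = 3.0
MIN_METRICS = 3


@dataclass
class MetricSeries:
    """One named per-frame series over (possibly concatenated) runs."""

    name: str
    values: np.ndarray
    frame_interval_ps: float
    run_boundaries: tuple[int, ...] = ()
    run_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        b = tuple(int(x) for x in self.run_boundaries)
        if list(b) != sorted(b) or any(x <= 0 or x >= self.values.size for x in b):
            raise ValueError("run_boundaries must be sorted interior frame indices")
        self.run_boundaries = b

    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) frame spans of the constituent runs."""
        edges = (0, *self.run_boundaries, self.values.size)
        return list(zip(edges[:-1], edges[1:]))

    def segment_of(self, frame: int) -> tuple[int, int]:
        for s, e in self.segments():
            if s <= frame < e:
                return s, e
        raise IndexError(f"frame {frame} outside series")


@dataclass(frozen=True)
class EndpointSummary:
    """Quartile/whisker summary of one endpoint window pooled across runs."""

    window: str  # "initial" | "final"
    quartiles: tuple[float, float, float]
    whiskers: tuple[float, float]
    n_values: int

    def __post_init__(self) -> None:
        q1, med, q3 = self.quartiles
        lo, hi = self.whiskers
        if not (lo <= q1 <= med <= q3 <= hi):
            raise ValueError("summary ordering violated: min <= Q1 <= median <= Q3 <= max")


@dataclass(frozen=True)
class EventCall:
    """A detected opening or closure with its supporting metrics."""

    direction: str  # "opening" | "closing"
    crossover_frame: int
    run_id: str
    supporting_metrics: tuple[str, ...]
    sustained: bool

    def __post_init__(self) -> None:
        bad = set(self.supporting_metrics) - set(CONCURRENCY_METRICS)
        if bad:
            raise ValueError(f"unknown supporting metrics: {sorted(bad)}")


# ---------------------------------------------------------------------------
# endpoint summaries
# ---------------------------------------------------------------------------

def _summarize(values: np.ndarray, window: str) -> EndpointSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return EndpointSummary(window=window, quartiles=(float(q1), float(med), float(q3)),
                           whiskers=(float(values.min()), float(values.max())),
                           n_values=int(values.size))


def endpoint_summary(series: MetricSeries, window_ns: float = 5.0,
                     sample_every_ps: float = 20.0) -> tuple[EndpointSummary, EndpointSummary]:
    """Pooled first-/last-window summaries across the series' runs.

    Each run contributes one value per ``sample_every_ps`` from its first and
    last ``window_ns``; quartiles use linear interpolation so box values are
    reproducible bit-for-bit.
    """
    stride_f = sample_every_ps / series.frame_interval_ps
    stride = int(round(stride_f))
    if stride < 1 or abs(stride - stride_f) > 1e-9:
        raise ValueError("sample_every_ps must be a positive multiple of the frame interval")
    wframes = int(round(window_ns * 1000.0 / series.frame_interval_ps))
    initial, final = [], []
    for s, e in series.segments():
        if e - s < 2 * wframes:
            raise ValueError(
                f"run of {e - s} frames is shorter than two {window_ns} ns windows")
        initial.append(series.values[s:s + wframes][::stride])
        final.append(series.values[e - wframes:e][::stride])
    return (_summarize(np.concatenate(initial), "initial"),
            _summarize(np.concatenate(final), "final"))


# ---------------------------------------------------------------------------
# crossover detection
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    if window <= 1:
        return x.astype(float)
    c = np.cumsum(np.concatenate(([0.0], x)))
    n = x.size
    half = window // 2
    starts = np.maximum(np.arange(n) - half, 0)
    stops = np.minimum(np.arange(n) + (window - half), n)
    return (c[stops] - c[starts]) / (stops - starts)


def _filled_signs(delta: np.ndarray) -> np.ndarray:
    s = np.sign(delta)
    # forward-fill zeros with the previous non-zero sign; leading zeros take
    # the first non-zero sign so they never register as a change
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return s
    s[:nz[0]] = s[nz[0]]
    for i in range(nz[0] + 1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return s


def detect_crossovers(q_open: np.ndarray, q_closed: np.ndarray,
                      smooth_window_frames: int = SMOOTH_WINDOW_FRAMES,
                      min_sustain_frames: int = MIN_SUSTAIN_FRAMES,
                      run_boundaries: Sequence[int] = ()) -> list[tuple[int, str]]:
    """Frames where the dominant reference flips and the flip persists.

    Series are smoothed per run with a centered moving average; a sign change
    of ``q_closed - q_open`` is reported only when the new sign holds for
    ``min_sustain_frames`` consecutive frames.  Crossovers never span run
    boundaries.
    """
    q_open = np.asarray(q_open, dtype=float)
    q_closed = np.asarray(q_closed, dtype=float)
    if q_open.shape != q_closed.shape:
        raise ValueError("q_open and q_closed length mismatch")
    bundle = MetricSeries("delta", q_closed - q_open, 1.0, tuple(run_boundaries))
    out: list[tuple[int, str]] = []
    for s, e in bundle.segments():
        seg = bundle.values[s:e]
        if smooth_window_frames >= seg.size:
            raise ValueError("smoothing window must be shorter than the run")
        sm = _smooth(seg, smooth_window_frames)
        signs = _filled_signs(sm)
        current = signs[0] if signs.size else 0.0
        i = 1
        while i < signs.size:
            if signs[i] != current and signs[i] != 0:
                stretch = signs[i:i + min_sustain_frames]
                if stretch.size >= min_sustain_frames and np.all(stretch == signs[i]):
                    out.append((s + i, "open" if signs[i] < 0 else "closed"))
                    current = signs[i]
                    i += min_sustain_frames
                    continue
            i += 1
    return out


# ---------------------------------------------------------------------------
# concurrency scoring
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def score_concurrency(crossover: tuple[int, str],
                      metric_bundle: Mapping[str, MetricSeries],
                      window_frames: int = CONCURRENCY_WINDOW_FRAMES,
                      prominence_mads: float = PROMINENCE_MADS,
                      min_metrics: int = MIN_METRICS,
                      run_id: str = "") -> EventCall:
    """Grade a crossover by concurrent extrema in the geometric metrics.

    Opening events are expected to peak in all five metrics; closures show
    valleys in distance/angle/Rg/SAS together with a peak in RMSD.  An
    extremum counts when it exceeds the run's median by ``prominence_mads``
    median absolute deviations.
    """
    frame, new_dominant = crossover
    direction = "opening" if new_dominant == "open" else "closing"
    expected = {m: "peak" for m in CONCURRENCY_METRICS}
    if direction == "closing":
        expected.update({m: "valley" for m in ("distance", "angle", "rg", "sas")})
    supporting = []
    for name in CONCURRENCY_METRICS:
        series = metric_bundle.get(name)
        if series is None:
            continue
        s, e = series.segment_of(frame)
        seg = series.values[s:e]
        win = series.values[max(s, frame - window_frames):min(e, frame + window_frames + 1)]
        if win.size == 0:
            continue
        base = float(np.median(seg))
        thresh = prominence_mads * _mad(seg)
        if expected[name] == "peak":
            prominent = float(win.max()) - base > thresh
        else:
            prominent = base - float(win.min()) > thresh
        if prominent:
            supporting.append(name)
    if not run_id:
        any_series = next(iter(metric_bundle.values()), None)
        if any_series is not None and any_series.run_ids:
            for k, (s, e) in enumerate(any_series.segments()):
                if s <= frame < e and k < len(any_series.run_ids):
                    run_id = any_series.run_ids[k]
                    break
    return EventCall(direction=direction, crossover_frame=int(frame), run_id=run_id,
                     supporting_metrics=tuple(supporting),
                     sustained=len(supporting) >= min_metrics)


# ---------------------------------------------------------------------------
# pipeline: per-run metrics and concatenation
# ---------------------------------------------------------------------------

def compute_run_metrics(traj: Trajectory, open_ref: Structure, closed_ref: Structure,
                        partition: DomainPartition, *,
                        normalization: str = "unit_identity",
                        contact_cutoff: float = 8.0, separation: int = 2,
                        sasa_n_points: int = 960,
                        rmsd_reference: str = "first_frame") -> dict[str, np.ndarray]:
    """The ten per-frame metrics for one run.

    RMSD is measured against the run's first frame (``rmsd_reference =
    "first_frame"``), or against ``"open"``/``"closed"`` references; fit on
    heavy atoms, measured over CA.
    """
    out = geometry.interdomain_series(traj, partition)
    if rmsd_reference == "first_frame":
        ref = traj.frame(0)
    elif rmsd_reference == "open":
        ref = open_ref
    elif rmsd_reference == "closed":
        ref = closed_ref
    else:
        raise ValueError(f"unknown rmsd_reference {rmsd_reference!r}")
    out["rmsd"] = geometry.rmsd_series(traj, ref, fit_atoms="heavy", measure_atoms="ca")
    out["rg"] = descriptors.rg_series(traj)
    out["sas"] = descriptors.sasa_series(traj, n_points=sasa_n_points)
    qnc = similarity.similarity_series(traj, open_ref, closed_ref, "Q_NC",
                                       normalization, contact_cutoff, separation)
    qsim = similarity.similarity_series(traj, open_ref, closed_ref, "q_similarity",
                                        normalization, contact_cutoff, separation)
    out["q_nc_open"], out["q_nc_closed"] = qnc.q_open, qnc.q_closed
    out["q_sim_open"], out["q_sim_closed"] = qsim.q_open, qsim.q_closed
    return out


def concatenate_runs(trajectories: Sequence[Trajectory], open_ref: Structure,
                     closed_ref: Structure, partition: DomainPartition,
                     **metric_kwargs) -> dict[str, MetricSeries]:
    """Compute metrics per run, concatenate, and record run boundaries."""
    if not trajectories:
        raise ValueError("no trajectories given")
    interval = trajectories[0].frame_interval_ps
    roster = trajectories[0].template.roster
    for t in trajectories[1:]:
        if abs(t.frame_interval_ps - interval) > 1e-9:
            raise ValueError("frame interval mismatch between runs")
        if t.template.roster != roster:
            raise ValueError(f"atom roster of run {t.run_id!r} differs")
    per_run = [compute_run_metrics(t, open_ref, closed_ref, partition, **metric_kwargs)
               for t in trajectories]
    lengths = [t.n_frames for t in trajectories]
    boundaries = tuple(np.cumsum(lengths)[:-1].tolist())
    run_ids = tuple(t.run_id for t in trajectories)
    bundle = {}
    for name in METRIC_NAMES:
        values = np.concatenate([m[name] for m in per_run])
        bundle[name] = MetricSeries(name, values, interval, boundaries, run_ids)
    return bundle


def find_events(bundle: Mapping[str, MetricSeries],
                smooth_window_frames: int = SMOOTH_WINDOW_FRAMES,
                min_sustain_frames: int = MIN_SUSTAIN_FRAMES,
                window_frames: int = CONCURRENCY_WINDOW_FRAMES,
                prominence_mads: float = PROMINENCE_MADS,
                min_metrics: int = MIN_METRICS) -> list[EventCall]:
    """Crossovers in q(similarity) graded by metric concurrency."""
    qo = bundle["q_sim_open"]
    qc = bundle["q_sim_closed"]
    crossings = detect_crossovers(qo.values, qc.values, smooth_window_frames,
                                  min_sustain_frames, qo.run_boundaries)
    return [score_concurrency(c, bundle, window_frames, prominence_mads, min_metrics)
            for c in crossings]
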