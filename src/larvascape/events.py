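"""Contraction events, FWHM time-normalization, and activation-lag tests.

Segment contraction is proxied by the inter-cell distance d(t) between a
measured neuron and its homolog in the adjacent segment.  Contraction events
are local minima of d whose excursion from the resting length exceeds a depth
threshold; each event carries the time of maximum contraction (t = 0 by
convention) and the full width at half maximum (FWHM) of its excursion.

Because crawl speed varies strongly across animals, events are made
comparable by normalizing time in units of the event's own FWHM (1 A.U. =
one FWHM) and, optionally, normalizing dR/R0 amplitude to 1.  Phase windows
are defined on that axis: the contraction phase is the 2xFWHM window
centered at maximum contraction ([-1, +1] A.U.) and the resting phase the
0.5xFWHM window immediately prior ([-1.5, -1] A.U.).

Events are excluded from averaging when the distance does not return to the
resting length before the next event, and at most the first two qualifying
events per neuron are kept.  Activation order between cell types is tested
by comparing times at half-maximum calcium activity with a one-tailed paired
t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "DistanceTrace",
    "ContractionEvent",
    "AlignedEvent",
    "PhaseStats",
    "inter_cell_distance",
    "detect_contractions",
    "apply_exclusion_rules",
    "normalize_event",
    "average_events",
    "phase_statistics",
    "half_max_time",
    "paired_lag_test",
]

#: normalized time axis: [-3, 3] A.U. in steps of 0.05
GRID_LIMITS = (-3.0, 3.0)
GRID_STEP = 0.05


@dataclass
class DistanceTrace:
    """Inter-cell distance time series with its estimated resting length."""

    pair_id: str
    time: np.ndarray
    distance: np.ndarray
    resting_length: float
    direction: str = "posterior"


@dataclass
class ContractionEvent:
    """One peristaltic contraction: timing, width, depth, inclusion status."""

    pair_id: str
    t_max_contraction: float
    fwhm: float
    depth: float
    peak_index: int
    included: bool = True
    reason: str | None = None


@dataclass
class AlignedEvent:
    """Event resampled onto the common normalized-time grid."""

    event: ContractionEvent
    grid: np.ndarray
    distance: np.ndarray
    dff: np.ndarray | None = None
    dff_normalized: np.ndarray | None = None
    truncated: bool = False


@dataclass
class PhaseStats:
    """Resting-phase mean and contraction-phase max of dR/R0 for one event."""

    cell_id: str
    resting_value: float | None
    contraction_value: float | None
    resting_ok: bool = True
    contraction_ok: bool = True


def inter_cell_distance(
    track_a,
    track_b,
    pair_id: str | None = None,
    direction: str = "posterior",
    resting_quantile: float = 90.0,
) -> DistanceTrace:
    """Euclidean 3-D distance between two tracks on their time overlap.

    The resting length is estimated as a high quantile (default 90th
    percentile) of the distance, which is robust to the dwell time spent
    contracted.  Identical tracks (zero distance) are rejected as a
    degenerate pairing.
    """
    t0 = max(track_a.valid_start, track_b.valid_start)
    t1 = min(track_a.valid_end, track_b.valid_end)
    if t1 < t0:
        raise ValueError("tracks share no overlapping time range")
    idx = np.arange(t0, t1 + 1)
    d = np.linalg.norm(track_a.positions[idx] - track_b.positions[idx], axis=1)
    if not (d > 0).all():
        raise ValueError("degenerate pairing: zero inter-cell distance")
    return DistanceTrace(
        pair_id=pair_id or f"{track_a.cell_id}-{track_b.cell_id}",
        time=np.asarray(track_a.time[idx], dtype=float),
        distance=d,
        resting_length=float(np.percentile(d, resting_quantile)),
        direction=direction,
    )


def _half_crossings(time: np.ndarray, excursion: np.ndarray, peak: int) -> tuple[float, float] | None:
    """Sub-sample half-maximum crossing times left and right of a peak."""
    half = excursion[peak] / 2.0
    left = None
    for i in range(peak, 0, -1):
        if excursion[i - 1] < half <= excursion[i]:
            frac = (half - excursion[i - 1]) / (excursion[i] - excursion[i - 1])
            left = time[i - 1] + frac * (time[i] - time[i - 1])
            break
    right = None
    for i in range(peak, excursion.size - 1):
        if excursion[i + 1] < half <= excursion[i]:
            frac = (excursion[i] - half) / (excursion[i] - excursion[i + 1])
            right = time[i] + frac * (time[i + 1] - time[i])
            break
    if left is None or right is None:
        return None
    return left, right


def detect_contractions(
    dtrace: DistanceTrace,
    smoothing_s: float = 0.3,
    min_depth_frac: float = 0.15,
) -> list[ContractionEvent]:
    """Local minima of the (smoothed) distance deeper than a threshold.

    The distance is smoothed with a moving average (default 0.3 s) to
    suppress frame noise; events are minima whose excursion from the resting
    length is at least ``min_depth_frac`` of it.  FWHM is measured on the
    excursion with sub-sample linear interpolation.  Events whose half-max
    crossings fall outside the recording are excluded with reason ``edge``.
    """
    t = dtrace.time
    d = dtrace.distance
    if t.size < 2:
        raise ValueError("trace too short")
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smoothing_s / dt)))
    if win >= t.size:
        raise ValueError("trace shorter than the smoothing window")
    smooth = uniform_filter1d(d, size=win, mode="nearest") if win > 1 else d

    excursion = dtrace.resting_length - smooth
    min_depth = min_depth_frac * dtrace.resting_length
    peaks, _ = find_peaks(excursion, height=min_depth)
    events = []
    for pk in peaks:
        depth = float(excursion[pk])
        crossings = _half_crossings(t, excursion, pk)
        if crossings is None:
            events.append(
                ContractionEvent(
                    pair_id=dtrace.pair_id,
                    t_max_contraction=float(t[pk]),
                    fwhm=math.nan,
                    depth=depth,
                    peak_index=int(pk),
                    included=False,
                    reason="edge",
                )
            )
            continue
        events.append(
            ContractionEvent(
                pair_id=dtrace.pair_id,
                t_max_contraction=float(t[pk]),
                fwhm=float(crossings[1] - crossings[0]),
                depth=depth,
                peak_index=int(pk),
            )
        )
    return events


def apply_exclusion_rules(
    events: list[ContractionEvent],
    dtrace: DistanceTrace,
    return_tolerance: float = 0.05,
    max_per_neuron: int = 2,
) -> list[ContractionEvent]:
    """Flag events violating the return-to-rest and two-per-neuron rules.

    An event is excluded when the distance does not re-attain at least
    ``(1 - return_tolerance) * resting_length`` before the next event (or
    the end of the trace for the last one); after that, only the first
    ``max_per_neuron`` included events are kept for averaging.
    """
    order = np.argsort([ev.t_max_contraction for ev in events])
    thr = (1.0 - return_tolerance) * dtrace.resting_length
    sorted_events = [events[i] for i in order]
    for j, ev in enumerate(sorted_events):
        if not ev.included:
            continue
        t_hi = (
            sorted_events[j + 1].t_max_contraction
            if j + 1 < len(sorted_events)
            else np.inf
        )
        window = (dtrace.time >= ev.t_max_contraction) & (dtrace.time <= t_hi)
        if not window.any() or dtrace.distance[window].max() < thr:
            ev.included = False
            ev.reason = "no-return"
    n_kept = 0
    for ev in sorted_events:
        if not ev.included:
            continue
        n_kept += 1
        if n_kept > max_per_neuron:
            ev.included = False
            ev.reason = "max-two-per-neuron"
    return events


def _grid(limits: tuple[float, float] = GRID_LIMITS, step: float = GRID_STEP) -> np.ndarray:
    n = int(round((limits[1] - limits[0]) / step))
    return limits[0] + step * np.arange(n + 1)


def _interp_masked(grid: np.ndarray, tau: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.interp(grid, tau, values)
    out[(grid < tau[0]) | (grid > tau[-1])] = np.nan
    return out


def normalize_event(
    event: ContractionEvent,
    dtrace: DistanceTrace,
    ratio_trace=None,
    limits: tuple[float, float] = GRID_LIMITS,
    step: float = GRID_STEP,
) -> AlignedEvent:
    """Resample one event onto the normalized [-3, 3] A.U. grid.

    Time is mapped ``t -> (t - t_max) / FWHM``; distance and dR/R0 are
    linearly interpolated onto the grid.  Grid points outside the recording
    are NaN and flag the event as truncated.  The amplitude-normalized
    dR/R0 (max 1 within the window) is stored alongside the raw trace.
    """
    if not event.included:
        raise ValueError(f"event excluded ({event.reason}); cannot normalize")
    grid = _grid(limits, step)
    tau_d = (dtrace.time - event.t_max_contraction) / event.fwhm
    distance = _interp_masked(grid, tau_d, dtrace.distance)
    truncated = bool(np.isnan(distance).any())

    dff = dffn = None
    if ratio_trace is not None:
        defined = getattr(ratio_trace, "defined", None)
        tt = np.asarray(ratio_trace.time, dtype=float)
        vv = np.asarray(ratio_trace.dff, dtype=float)
        if defined is not None:
            tt, vv = tt[defined], vv[defined]
        tau_r = (tt - event.t_max_contraction) / event.fwhm
        dff = _interp_masked(grid, tau_r, vv)
        truncated = truncated or bool(np.isnan(dff).any())
        peak = np.nanmax(dff) if np.isfinite(dff).any() else np.nan
        if np.isfinite(peak) and peak > 0:
            dffn = dff / peak
    return AlignedEvent(
        event=event,
        grid=grid,
        distance=distance,
        dff=dff,
        dff_normalized=dffn,
        truncated=truncated,
    )


def average_events(aligned: list[AlignedEvent], use_normalized: bool = True) -> dict:
    """Pointwise mean +/- sd curves over aligned events (NaN-aware).

    Truncated events contribute wherever they are defined; the per-gridpoint
    sample count ``n`` is reported.  Requires at least two events.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned events to average")
    grid = aligned[0].grid
    dist = np.stack([a.distance for a in aligned])
    out = {
        "grid": grid,
        "mean_distance": np.nanmean(dist, axis=0),
        "sd_distance": _nanstd(dist),
        "n_distance": np.sum(np.isfinite(dist), axis=0),
    }
    attr = "dff_normalized" if use_normalized else "dff"
    curves = [getattr(a, attr) for a in aligned if getattr(a, attr) is not None]
    if curves:
        arr = np.stack(curves)
        out["mean_dff"] = np.nanmean(arr, axis=0)
        out["sd_dff"] = _nanstd(arr)
        out["n_dff"] = np.sum(np.isfinite(arr), axis=0)
    return out


def _nanstd(arr: np.ndarray) -> np.ndarray:
    n = np.sum(np.isfinite(arr), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(arr, axis=0, ddof=1)
    sd[n < 2] = np.nan
    return sd


def phase_statistics(
    aligned: AlignedEvent,
    cell_id: str = "",
    resting_window: tuple[float, float] = (-1.5, -1.0),
    contraction_window: tuple[float, float] = (-1.0, 1.0),
) -> PhaseStats:
    """Resting-phase mean and contraction-phase max of the aligned dR/R0."""
    if aligned.dff is None:
        raise ValueError("aligned event carries no dR/R0 trace")
    g = aligned.grid
    rest_mask = (g >= resting_window[0]) & (g <= resting_window[1])
    con_mask = (g >= contraction_window[0]) & (g <= contraction_window[1])
    rest_vals = aligned.dff[rest_mask]
    con_vals = aligned.dff[con_mask]
    rest_ok = rest_vals.size > 0 and np.isfinite(rest_vals).all()
    con_ok = con_vals.size > 0 and np.isfinite(con_vals).all()
    return PhaseStats(
        cell_id=cell_id,
        resting_value=float(rest_vals.mean()) if rest_ok else None,
        contraction_value=float(con_vals.max()) if con_ok else None,
        resting_ok=rest_ok,
        contraction_ok=con_ok,
    )


def half_max_time(grid: np.ndarray, values: np.ndarray) -> float:
    """First rising crossing of 50% of the within-window maximum (A.U.).

    Activation timing is read off the rising edge; sub-sample linear
    interpolation between the bracketing grid points.  NaN when the maximum
    is not positive (no activation to time).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        return math.nan
    g, v = grid[ok], values[ok]
    peak = v.max()
    if peak <= 0:
        return math.nan
    half = 0.5 * peak
    above = np.flatnonzero(v >= half)
    i = above[0]
    if i == 0:
        return float(g[0])
    frac = (half - v[i - 1]) / (v[i] - v[i - 1])
    return float(g[i - 1] + frac * (g[i] - g[i - 1]))


def paired_lag_test(half_max_times_a, half_max_times_b) -> dict:
    """One-tailed paired t test that B activates later than A.

    ``a`` and ``b`` are half-maximum times paired within segment and event.
    Uses the exact t distribution with ``df = n - 1``; degenerate
    (zero-variance) differences are refused rather than reported as p = 0/1.
    """
    a = np.asarray(half_max_times_a, dtype=float)
    b = np.asarray(half_max_times_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = b - a
    sd = diff.std(ddof=1)
    if np.ptp(diff) == 0 or sd == 0:
        raise ValueError("degenerate variance: paired differences are constant")
    n = diff.size
    t = diff.mean() / (sd / math.sqrt(n))
    return {
        "mean_lag": float(diff.mean()),
        "t": float(t),
        "df": n - 1,
        "p": float(stats.t.sf(t, n - 1)),
        "n": n,
    }
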