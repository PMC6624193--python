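"""Ratiometric calcium activity extraction (green/red ratio, dR/R0).

For each tracked soma, mean green (indicator) and red (static fiducial)
intensities are taken over an axis-aligned box ROI that encompasses the cell
body.  After per-channel background subtraction the green/red ratio

    R(t) = (green - bg_g) / (red - bg_r)

cancels any intensity change common to both channels (motion through the
light sheet, occlusion), which is the point of the ratiometric design.  The
baseline R0 is the mean of the lowest 10% of ratio values over the track,
and activity is reported as dR/R0 = (R - R0) / R0.

Timepoints where the background-subtracted red signal is not positive leave
the ratio undefined there; they are excluded from the baseline and flagged,
never clamped (clamping would bias R0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatioTrace",
    "estimate_background",
    "extract_roi_means",
    "compute_ratio_trace",
    "static_marker_control",
    "extract_traces",
    "propagated_dff_noise_sd",
]


@dataclass
class RatioTrace:
    """Per-cell ratio time series: raw means, backgrounds, R, R0, dR/R0."""

    cell_id: str
    time: np.ndarray
    green_raw: np.ndarray
    red_raw: np.ndarray
    bg_green: np.ndarray
    bg_red: np.ndarray
    ratio: np.ndarray
    baseline: float
    dff: np.ndarray
    defined: np.ndarray
    clipped: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "cell_id": self.cell_id,
                "green_raw": self.green_raw,
                "red_raw": self.red_raw,
                "bg_green": self.bg_green,
                "bg_red": self.bg_red,
                "ratio": self.ratio,
                "baseline": self.baseline,
                "dRR0": self.dff,
                "defined_flag": self.defined,
            }
        )


def estimate_background(movie, channel: str, t: int, percentile: float = 5.0,
                        region: tuple[slice, slice, slice] | None = None) -> float:
    """Dark-floor background estimate for one channel at one timepoint.

    Default: mean intensity of voxels at or below the channel's 5th
    percentile.  Alternatively a user-supplied static box (z, y, x slices)
    is averaged instead.  A degenerate (constant) volume returns that
    constant with a warning.
    """
    vol = movie.channel(channel)[t]
    if region is not None:
        return float(vol[region].mean())
    lo, hi = float(vol.min()), float(vol.max())
    if lo == hi:
        warnings.warn("constant volume; background estimate equals that constant")
        return lo
    thresh = np.percentile(vol, percentile)
    return float(vol[vol <= thresh].mean())


def extract_roi_means(
    movie,
    track,
    cell_radius_um: float = 3.0,
    margin_um: float = 1.0,
) -> dict:
    """Mean green/red intensity over a box ROI centered on the tracked soma.

    The box half-width is ``cell_radius + margin`` per axis (the smallest box
    encompassing the whole cell body, with a safety margin).  ROIs clipped by
    the volume boundary are computed on the intersection and flagged.
    Returns arrays aligned with the movie time axis; NaN outside the track's
    valid range.
    """
    spacing = np.array(movie.spacing)  # (z, y, x)
    shape = movie.data.shape[2:]
    half = cell_radius_um + margin_um
    n_t = movie.n_timepoints
    green = np.full(n_t, np.nan)
    red = np.full(n_t, np.nan)
    clipped = np.zeros(n_t, dtype=bool)
    g_idx = movie.channel_index("green")
    r_idx = movie.channel_index("red")
    for t in range(track.valid_start, track.valid_end + 1):
        center = track.positions[t]  # (x, y, z) um
        if not np.isfinite(center).all():
            continue
        slices = []
        clip = False
        for dim, coord in ((0, center[2]), (1, center[1]), (2, center[0])):
            lo = int(math.ceil((coord - half) / spacing[dim] - 1e-9))
            hi = int(math.floor((coord + half) / spacing[dim] + 1e-9)) + 1
            if lo < 0 or hi > shape[dim]:
                clip = True
            slices.append(slice(max(lo, 0), min(hi, shape[dim])))
        box = movie.data[t][:, slices[0], slices[1], slices[2]]
        if box.size == 0:
            clipped[t] = True
            continue
        green[t] = box[g_idx].mean()
        red[t] = box[r_idx].mean()
        clipped[t] = clip
    return {"green_raw": green, "red_raw": red, "clipped": clipped}


def compute_ratio_trace(
    cell_id: str,
    time: np.ndarray,
    green_raw: np.ndarray,
    red_raw: np.ndarray,
    bg_green,
    bg_red,
    lowest_fraction: float = 0.10,
    clipped: np.ndarray | None = None,
) -> RatioTrace:
    """Background-subtracted ratio, lowest-fraction baseline, and dR/R0.

    R0 is the mean of the lowest ``ceil(lowest_fraction * N)`` defined ratio
    values (at least one sample).  Requires at least 10 defined samples.
    """
    time = np.asarray(time, dtype=float)
    green_raw = np.asarray(green_raw, dtype=float)
    red_raw = np.asarray(red_raw, dtype=float)
    bg_green = np.broadcast_to(np.asarray(bg_green, dtype=float), green_raw.shape).copy()
    bg_red = np.broadcast_to(np.asarray(bg_red, dtype=float), red_raw.shape).copy()

    num = green_raw - bg_green
    den = red_raw - bg_red
    defined = np.isfinite(num) & np.isfinite(den) & (den > 0)
    ratio = np.full_like(num, np.nan)
    ratio[defined] = num[defined] / den[defined]

    n_def = int(defined.sum())
    if n_def < 10:
        raise ValueError(f"need at least 10 defined ratio samples, have {n_def}")
    k = max(1, math.ceil(lowest_fraction * n_def))
    baseline = float(np.sort(ratio[defined])[:k].mean())
    if baseline <= 0:
        raise ValueError(f"non-positive baseline R0 = {baseline}")
    dff = (ratio - baseline) / baseline
    return RatioTrace(
        cell_id=cell_id,
        time=time,
        green_raw=green_raw,
        red_raw=red_raw,
        bg_green=bg_green,
        bg_red=bg_red,
        ratio=ratio,
        baseline=baseline,
        dff=dff,
        defined=defined,
        clipped=clipped,
    )


def static_marker_control(trace: RatioTrace) -> dict:
    """Magnitude summary validating a calcium-insensitive (GFP) marker.

    A static green marker processed through the full ratiometric pipeline
    should yield near-zero activity; returns the max |dR/R0| and its sd.
    """
    vals = trace.dff[trace.defined]
    return {
        "max_abs_dff": float(np.max(np.abs(vals))),
        "sd_dff": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    }


def propagated_dff_noise_sd(trace: RatioTrace, intensity_noise_sd: float,
                            n_roi_voxels: int) -> np.ndarray:
    """First-order propagation of voxel read noise into dR/R0.

    The ROI mean of ``n`` voxels carries noise ``sd / sqrt(n)`` per channel;
    propagating through the ratio quotient gives, per timepoint,

        sd_dff(t) = |R(t)| / R0 * sqrt((s/g)^2 + (s/r)^2)

    with g, r the background-subtracted channel means.  NaN where the ratio
    is undefined.
    """
    s = intensity_noise_sd / math.sqrt(n_roi_voxels)
    g = trace.green_raw - trace.bg_green
    r = trace.red_raw - trace.bg_red
    out = np.full_like(trace.ratio, np.nan)
    ok = trace.defined & (g != 0)
    out[ok] = (
        np.abs(trace.ratio[ok]) / trace.baseline
        * np.sqrt((s / g[ok]) ** 2 + (s / r[ok]) ** 2)
    )
    return out


def extract_traces(
    movie,
    tracks,
    cell_radius_um: float = 3.0,
    margin_um: float = 1.0,
    lowest_fraction: float = 0.10,
    background_percentile: float = 5.0,
    background_region: tuple[slice, slice, slice] | None = None,
) -> list[RatioTrace]:
    """Full extraction pipeline: per-frame backgrounds, ROI means, ratio traces."""
    n_t = movie.n_timepoints
    bg_g = np.array(
        [estimate_background(movie, "green", t, background_percentile, background_region)
         for t in range(n_t)]
    )
    bg_r = np.array(
        [estimate_background(movie, "red", t, background_percentile, background_region)
         for t in range(n_t)]
    )
    traces = []
    for track in tracks:
        roi = extract_roi_means(movie, track, cell_radius_um, margin_um)
        sl = slice(track.valid_start, track.valid_end + 1)
        traces.append(
            compute_ratio_trace(
                track.cell_id,
                movie.times[sl],
                roi["green_raw"][sl],
                roi["red_raw"][sl],
                bg_g[sl],
                bg_r[sl],
                lowest_fraction=lowest_fraction,
                clipped=roi["clipped"][sl],
            )
        )
    return traces
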