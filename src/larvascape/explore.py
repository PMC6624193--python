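"""Two-bar kinematic model of larval exploration and its linear decomposition.

During exploration the anterior larva turns (asymmetric) while retracting the
head (symmetric).  The model abstracts two body segments as rigid bars of
length 2p: the posterior bar is fixed with its midpoint at the origin, the
anterior bar sits at midpoint separation S(t) and is rotated rigidly by the
turning angle theta(t) about the posterior midpoint.  The left/right
inter-cell distances r_L, r_R between corresponding bar ends then decompose
the behavior:

    r_R - r_L  ~  2 p sin(theta)     (turning metric; retraction cancels)
    r_L + r_R  ~  2 S(t)             (retraction metric; turning cancels)

The linear forms ``r = S +/- p sin(theta)`` are an approximation; the exact
distances follow from the corner coordinates, and
``exact^2 = approx^2 + p^2 (1 - cos(theta))^2`` so the two agree closely for
physiological angles.  :func:`approximation_error` quantifies the worst-case
relative deviation over a parameter grid.

Sign convention: positive theta rotates the anterior bar counter-clockwise
(towards the larva's left side), which shortens r_L and lengthens r_R.  Pass
``positive_theta="right"`` to :func:`decompose_behavior` to flip the reported
angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TwoBarPose",
    "ExplorationMetrics",
    "pose_to_positions",
    "exact_distances",
    "approx_distances",
    "approximation_error",
    "decompose_behavior",
    "lagged_pearson",
    "metric_correlations",
]


@dataclass
class TwoBarPose:
    """Exploration geometry state: half-width, retraction, turning, corners."""

    p: float
    S: float
    theta: float
    D1L: np.ndarray
    D1R: np.ndarray
    D2L: np.ndarray
    D2R: np.ndarray


def pose_to_positions(p: float, S: float, theta: float) -> TwoBarPose:
    """Corner positions of the two-bar pose.

    The posterior bar spans (-p, 0)..(+p, 0); the anterior bar spans
    (-p, S)..(+p, S) before being rotated rigidly by ``theta`` about the
    origin (the posterior midpoint).
    """
    if p <= 0:
        raise ValueError("half-width p must be strictly positive")
    if S <= 0:
        raise ValueError("midpoint separation S must be strictly positive")
    if not abs(theta) < np.pi / 2:
        raise ValueError("turning angle must satisfy |theta| < pi/2")
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return TwoBarPose(
        p=float(p),
        S=float(S),
        theta=float(theta),
        D1L=rot @ np.array([-p, S], dtype=float),
        D1R=rot @ np.array([p, S], dtype=float),
        D2L=np.array([-p, 0.0]),
        D2R=np.array([p, 0.0]),
    )


def exact_distances(pose: TwoBarPose) -> tuple[float, float]:
    """Euclidean D1-D2 distances (r_L, r_R) from the corner coordinates."""
    r_l = float(np.linalg.norm(pose.D1L - pose.D2L))
    r_r = float(np.linalg.norm(pose.D1R - pose.D2R))
    return r_l, r_r


def approx_distances(p: float, S: float, theta: float) -> tuple[float, float]:
    """Linearized inter-cell distances ``r_L = S - p sin(theta)``, ``r_R = S + p sin(theta)``.

    With these forms the difference is exactly ``-2 p sin(theta)`` and the
    sum exactly ``2 S`` -- the common-mode-rejection identities.
    """
    ps = p * np.sin(theta)
    return float(S - ps), float(S + ps)


def approximation_error(
    p: float,
    S_values: np.ndarray,
    theta_values: np.ndarray,
) -> dict:
    """Worst-case relative deviation of the linear model from the exact one.

    Evaluates ``|exact - approx| / exact * 100`` for both sides over the
    Cartesian grid of ``S_values`` (um) and ``theta_values`` (radians), with
    the exact distance computed from the rotated-corner coordinates.

    Returns a dict with ``max_percent`` (over both sides), per-side maxima,
    and the (S, theta) gridpoint attaining the overall maximum.
    """
    S = np.asarray(S_values, dtype=float)
    th = np.asarray(theta_values, dtype=float)
    if S.size == 0 or th.size == 0:
        raise ValueError("S and theta grids must be nonempty")
    if p <= 0 or (S <= 0).any() or (np.abs(th) >= np.pi / 2).any():
        raise ValueError("grid contains invalid poses")

    Sg = S[:, None]
    c, s = np.cos(th)[None, :], np.sin(th)[None, :]
    # rotated anterior corners minus fixed posterior corners
    r_r = np.hypot(p * c - Sg * s - p, p * s + Sg * c)
    r_l = np.hypot(-p * c - Sg * s + p, -p * s + Sg * c)
    a_l = Sg - p * s
    a_r = Sg + p * s
    err_l = np.abs(r_l - a_l) / r_l * 100.0
    err_r = np.abs(r_r - a_r) / r_r * 100.0
    err = np.maximum(err_l, err_r)
    i, j = np.unravel_index(int(np.argmax(err)), err.shape)
    return {
        "max_percent": float(err[i, j]),
        "max_percent_left": float(err_l.max()),
        "max_percent_right": float(err_r.max()),
        "argmax_S_um": float(S[i]),
        "argmax_theta_rad": float(th[j]),
        "n_grid": int(err.size) * 2,
    }


@dataclass
class ExplorationMetrics:
    """Per-timepoint turning/retraction decomposition of four tracked corners."""

    time: np.ndarray
    r_L: np.ndarray
    r_R: np.ndarray
    turning_metric: np.ndarray      # r_L - r_R  (= -2p sin theta in the linear model)
    retraction_metric: np.ndarray   # r_L + r_R  (= 2S in the linear model)
    theta_est: np.ndarray           # radians
    clamped: np.ndarray
    p_hat: float
    ca_diff: dict = field(default_factory=dict)  # per cell type: left - right dR/R0
    ca_sum: dict = field(default_factory=dict)   # per cell type: left + right dR/R0

    @property
    def S_est(self) -> np.ndarray:
        return self.retraction_metric / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "time_s": self.time,
                "r_L_um": self.r_L,
                "r_R_um": self.r_R,
                "turning_metric_um": self.turning_metric,
                "retraction_metric_um": self.retraction_metric,
                "theta_est_deg": np.rad2deg(self.theta_est),
                "clamped": self.clamped,
            }
        )
        for name, vals in self.ca_diff.items():
            out[f"ca_diff_{name}"] = vals
        for name, vals in self.ca_sum.items():
            out[f"ca_sum_{name}"] = vals
        return out


CORNER_IDS = ("D1L", "D1R", "D2L", "D2R")


def _fit_plane_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a point cloud; returns (centroid, 2x3 basis)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[:2]


def decompose_behavior(
    tracks: dict,
    traces: dict | None = None,
    positive_theta: str = "left",
) -> ExplorationMetrics:
    """Turning/retraction decomposition of the four tracked corner cells.

    Parameters
    ----------
    tracks
        Mapping with keys ``D1L, D1R, D2L, D2R`` to tracks exposing
        ``positions`` (T, 3) in um, ``valid_start``/``valid_end`` and the
        movie ``times``-compatible attribute ``time`` (seconds).
    traces
        Optional mapping of the same keys to ratio traces exposing ``time``
        and ``dff``; per cell type (D1, D2) the left-right difference and sum
        of dR/R0 are added.
    positive_theta
        ``"left"`` (default, positive angle shortens r_L) or ``"right"``.

    The 3-D tracks are projected onto their joint least-squares plane before
    evaluating the planar model.  The bar half-width ``p_hat`` is estimated
    as half the mean D2L-D2R distance; ``theta_est`` is recovered by exact
    inversion of the linear turning identity with out-of-range values clamped
    and flagged.
    """
    missing = [k for k in CORNER_IDS if k not in tracks]
    if missing:
        raise ValueError(f"missing corner tracks: {missing}")
    if positive_theta not in ("left", "right"):
        raise ValueError("positive_theta must be 'left' or 'right'")

    t0 = max(tracks[k].valid_start for k in CORNER_IDS)
    t1 = min(tracks[k].valid_end for k in CORNER_IDS)
    if t1 < t0:
        raise ValueError("corner tracks share no common time range")
    idx = np.arange(t0, t1 + 1)
    time = tracks["D1L"].time[idx]

    pts = np.stack([tracks[k].positions[idx] for k in CORNER_IDS], axis=1)  # (T,4,3)
    centroid, basis = _fit_plane_basis(pts.reshape(-1, 3))
    flat = (pts - centroid) @ basis.T  # (T, 4, 2)
    d1l, d1r, d2l, d2r = (flat[:, i] for i in range(4))

    r_l = np.linalg.norm(d1l - d2l, axis=1)
    r_r = np.linalg.norm(d1r - d2r, axis=1)
    p_hat = float(np.linalg.norm(d2l - d2r, axis=1).mean()) / 2.0

    turning = r_l - r_r
    retraction = r_l + r_r
    ratio = turning / (-2.0 * p_hat)
    clamped = np.abs(ratio) > 1.0
    theta = np.arcsin(np.clip(ratio, -1.0, 1.0))
    if positive_theta == "right":
        theta = -theta

    ca_diff: dict = {}
    ca_sum: dict = {}
    if traces is not None:
        for ctype in ("D1", "D2"):
            left, right = f"{ctype}L", f"{ctype}R"
            if left in traces and right in traces:
                dl = np.interp(time, traces[left].time, traces[left].dff)
                dr = np.interp(time, traces[right].time, traces[right].dff)
                ca_diff[ctype] = dl - dr
                ca_sum[ctype] = dl + dr

    return ExplorationMetrics(
        time=time,
        r_L=r_l,
        r_R=r_r,
        turning_metric=turning,
        retraction_metric=retraction,
        theta_est=theta,
        clamped=clamped,
        p_hat=p_hat,
        ca_diff=ca_diff,
        ca_sum=ca_sum,
    )


def lagged_pearson(
    movement: np.ndarray,
    calcium: np.ndarray,
    max_lag_samples: int,
) -> dict:
    """Pearson correlation at lag 0 and at the best calcium-delayed lag.

    Calcium is assumed to lag movement (deformation causes the transient),
    so only non-negative delays of ``calcium`` relative to ``movement`` are
    searched: lag k correlates ``movement[:n-k]`` with ``calcium[k:]``.
    """
    x = np.asarray(movement, dtype=float)
    y = np.asarray(calcium, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r_lag0": np.nan, "best_r": np.nan, "best_lag": 0, "constant": True}

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    best_lag, best_r = 0, _r(x, y)
    r0 = best_r
    for k in range(1, max_lag_samples + 1):
        if k >= x.size - 1:
            break
        r = _r(x[:-k], y[k:])
        if np.isfinite(r) and (not np.isfinite(best_r) or abs(r) > abs(best_r)):
            best_lag, best_r = k, r
    return {"r_lag0": r0, "best_r": best_r, "best_lag": best_lag, "constant": False}


def metric_correlations(
    metrics: ExplorationMetrics,
    max_lag_s: float,
) -> pd.DataFrame:
    """Correlate ca_diff with the turning metric and ca_sum with retraction.

    The lag grid step is one volume period (inferred from the metric time
    axis); calcium may only be delayed relative to movement.
    """
    if metrics.time.size < 3:
        raise ValueError("series too short")
    dt = float(np.median(np.diff(metrics.time)))
    max_lag = int(round(max_lag_s / dt))
    rows = []
    for ctype, ca in metrics.ca_diff.items():
        res = lagged_pearson(metrics.turning_metric, ca, max_lag)
        rows.append(
            {
                "pair": f"ca_diff_{ctype}_vs_turning",
                "r_lag0": res["r_lag0"],
                "best_r": res["best_r"],
                "best_lag_s": res["best_lag"] * dt,
                "constant": res["constant"],
                "n": metrics.time.size,
            }
        )
    for ctype, ca in metrics.ca_sum.items():
        res = lagged_pearson(metrics.retraction_metric, ca, max_lag)
        rows.append(
            {
                "pair": f"ca_sum_{ctype}_vs_retraction",
                "r_lag0": res["r_lag0"],
                "best_r": res["best_r"],
                "best_lag_s": res["best_lag"] * dt,
                "constant": res["constant"],
                "n": metrics.time.size,
            }
        )
    return pd.DataFrame(rows)
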