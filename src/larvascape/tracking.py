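"""3-D soma tracking on the static red fiducial channel.

Somata are seeded manually (labelled 3-D points at the first frame) and then
followed frame to frame by iterated intensity-weighted centroiding inside a
search sphere: within the sphere around the previous position, voxels above
an adaptive threshold (half the window maximum) are centroided, the window
re-centred, and the step repeated until the estimate moves by less than a
tenth of a voxel.  The centroid of a symmetric soma profile is a fixed point
of this iteration, so a static noise-free cell does not drift.

When neighbouring cells converge within one cell radius their candidate
positions are re-assigned by minimal total displacement (optimal one-to-one
assignment over the conflicting cluster) and flagged low-confidence for
supervision; manual corrections overwrite a position and re-run the tracker
forward from there.  Lost tracks are truncated, never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .signals import estimate_background

__all__ = [
    "CellTrack",
    "seed_cells",
    "track_step",
    "resolve_conflicts",
    "track_movie",
    "apply_corrections",
    "tracks_to_dataframe",
    "tracks_from_dataframe",
]

CONF_AUTO = "auto"
CONF_CORRECTED = "corrected"
CONF_LOW = "low"

CELL_TYPES = ("vpda", "ddaD", "ddaE", "dbd", "vbd", "dmd1", "generic")


@dataclass
class CellTrack:
    """Per-cell time series of 3-D positions (um) with identity labels."""

    cell_id: str
    positions: np.ndarray            # (T, 3) um as (x, y, z); NaN outside valid range
    confidence: np.ndarray           # (T,) str flags; "" outside valid range
    valid_start: int
    valid_end: int
    time: np.ndarray                 # (T,) seconds
    cell_type: str = "generic"
    segment: str = ""
    side: str = ""
    meta: dict = field(default_factory=dict)

    def position(self, t: int) -> np.ndarray:
        if not self.valid_start <= t <= self.valid_end:
            raise IndexError(f"t={t} outside valid range [{self.valid_start}, {self.valid_end}]")
        return self.positions[t]


def _inside_volume(pos_xyz: np.ndarray, movie) -> bool:
    spacing = np.array(movie.spacing)  # (z, y, x)
    extent = (np.array(movie.data.shape[2:]) - 1) * spacing  # (z, y, x) um
    p = np.asarray(pos_xyz, dtype=float)[::-1]  # -> (z, y, x)
    return bool((p >= 0).all() and (p <= extent).all())


def seed_cells(movie, seeds: pd.DataFrame, t0: int = 0) -> list[CellTrack]:
    """Initialize one track per labelled seed point at frame ``t0``.

    ``seeds`` needs columns ``cell_id, x_um, y_um, z_um`` and may carry
    ``cell_type, segment, side``.  Duplicate labels and seeds sharing a voxel
    or lying outside the volume are rejected.
    """
    ids = list(seeds["cell_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id labels in seeds")
    spacing = np.array(movie.spacing)
    voxels = set()
    n_t = movie.n_timepoints
    tracks = []
    for _, row in seeds.iterrows():
        pos = np.array([row["x_um"], row["y_um"], row["z_um"]], dtype=float)
        if not _inside_volume(pos, movie):
            raise ValueError(f"seed {row['cell_id']} outside the volume: {pos}")
        vox = tuple(np.round(pos[::-1] / spacing).astype(int))
        if vox in voxels:
            raise ValueError(f"seed {row['cell_id']} duplicates another seed's position")
        voxels.add(vox)
        positions = np.full((n_t, 3), np.nan)
        positions[t0] = pos
        confidence = np.full(n_t, "", dtype=object)
        confidence[t0] = CONF_CORRECTED
        tracks.append(
            CellTrack(
                cell_id=str(row["cell_id"]),
                positions=positions,
                confidence=confidence,
                valid_start=t0,
                valid_end=t0,
                time=movie.times,
                cell_type=str(row.get("cell_type", "generic")),
                segment=str(row.get("segment", "")),
                side=str(row.get("side", "")),
            )
        )
    return tracks


def track_step(
    movie,
    position_um: np.ndarray,
    t_next: int,
    search_radius_um: float = 15.0,
    background: float | None = None,
    max_iter: int = 20,
    smooth_sigma_um: float = 2.0,
) -> tuple[np.ndarray | None, str]:
    """One tracking step: centroid iteration in the red channel at ``t_next``.

    The search window is denoised with a Gaussian matched filter
    (``smooth_sigma_um``, roughly the soma scale) before thresholding; the
    filter is linear and symmetric, so the centroid of a symmetric soma
    profile is unchanged while read-noise jitter roughly halves.

    Returns ``(position, confidence)``; position is ``None`` with confidence
    ``"lost"`` when the search window holds no signal above background.
    """
    red = movie.channel("red")[t_next]
    spacing = np.array(movie.spacing)  # (z, y, x)
    shape = np.array(red.shape)
    if background is None:
        background = estimate_background(movie, "red", t_next)
    start = np.asarray(position_um, dtype=float)  # (x, y, z)
    half = np.ceil(search_radius_um / spacing).astype(int)

    current = start.copy()
    window_max = -np.inf
    for _ in range(max_iter):
        center_vox = current[::-1] / spacing  # (z, y, x)
        lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
        hi = np.minimum(np.ceil(center_vox).astype(int) + half + 1, shape)
        if (hi <= lo).any():
            return None, "lost"
        window = red[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if smooth_sigma_um > 0:
            window = ndimage.gaussian_filter(
                window.astype(np.float64), smooth_sigma_um / spacing, mode="nearest"
            )
        grids = [np.arange(lo[d], hi[d]) * spacing[d] for d in range(3)]
        # sphere constraint around the position carried over from frame t
        dz = grids[0] - start[2]
        dy = grids[1] - start[1]
        dx = grids[2] - start[0]
        sphere = (
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
            <= search_radius_um**2
        )
        if not sphere.any():
            return None, "lost"
        vals = np.where(sphere, window, -np.inf)
        window_max = float(vals.max())
        if window_max <= background:
            return None, "lost"
        thr = 0.5 * window_max
        w = np.where(vals > thr, vals - thr, 0.0)
        total = w.sum()
        if total <= 0:
            break
        zc = (w.sum(axis=(1, 2)) * grids[0]).sum() / total
        yc = (w.sum(axis=(0, 2)) * grids[1]).sum() / total
        xc = (w.sum(axis=(0, 1)) * grids[2]).sum() / total
        new = np.array([xc, yc, zc])
        step = np.linalg.norm(new - current)
        current = new
        if step < 0.1 * spacing.min():
            break

    displacement = np.linalg.norm(current - start)
    conf = CONF_AUTO
    if window_max < 2.0 * background or displacement > search_radius_um:
        conf = CONF_LOW
    return current, conf


def resolve_conflicts(
    prev_positions: dict,
    candidates: dict,
    cell_radius_um: float,
) -> tuple[dict, set]:
    """Re-assign converging candidates by minimal total displacement.

    Candidates closer than one cell radius form a conflict cluster; within a
    cluster the candidate positions are re-distributed over the tracks by
    optimal one-to-one assignment against the previous positions (ties
    resolved deterministically by cell_id order).  All members of a cluster
    are flagged for supervision.
    """
    ids = sorted(candidates)
    assigned = dict(candidates)
    flagged: set = set()
    # connected components of the "closer than one cell radius" graph
    parent = {i: i for i in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i_pos, a in enumerate(ids):
        for b in ids[i_pos + 1:]:
            if np.linalg.norm(candidates[a] - candidates[b]) < cell_radius_um:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict = {}
    for a in ids:
        clusters.setdefault(find(a), []).append(a)
    for members in clusters.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        cost = np.array(
            [
                [np.linalg.norm(prev_positions[a] - candidates[b]) for b in members]
                for a in members
            ]
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            assigned[members[r]] = candidates[members[c]]
        flagged.update(members)
    return assigned, flagged


def track_movie(
    movie,
    seeds: pd.DataFrame,
    t0: int = 0,
    search_radius_um: float = 15.0,
    cell_radius_um: float = 3.0,
) -> list[CellTrack]:
    """Track all seeded cells across the movie (forward from ``t0``)."""
    tracks = seed_cells(movie, seeds, t0=t0)
    backgrounds = [
        estimate_background(movie, "red", t) for t in range(movie.n_timepoints)
    ]
    _run_forward(movie, tracks, t0, search_radius_um, cell_radius_um, backgrounds)
    return tracks


def _run_forward(movie, tracks, t_from, search_radius_um, cell_radius_um, backgrounds=None):
    for t in range(t_from, movie.n_timepoints - 1):
        bg = backgrounds[t + 1] if backgrounds else None
        active = [tr for tr in tracks if tr.valid_end == t]
        if not active:
            continue
        prev = {tr.cell_id: tr.positions[t] for tr in active}
        candidates = {}
        confs = {}
        for tr in active:
            pos, conf = track_step(
                movie, tr.positions[t], t + 1, search_radius_um, background=bg
            )
            if pos is None:
                tr.meta["lost_at"] = t + 1
            else:
                candidates[tr.cell_id] = pos
                confs[tr.cell_id] = conf
        assigned, flagged = resolve_conflicts(prev, candidates, cell_radius_um)
        for tr in active:
            if tr.cell_id not in assigned:
                continue  # lost: valid_end stays at t
            tr.positions[t + 1] = assigned[tr.cell_id]
            tr.confidence[t + 1] = CONF_LOW if tr.cell_id in flagged else confs[tr.cell_id]
            tr.valid_end = t + 1


def apply_corrections(
    movie,
    tracks: list[CellTrack],
    corrections,
    search_radius_um: float = 15.0,
    cell_radius_um: float = 3.0,
) -> list[CellTrack]:
    """Overwrite positions with manual corrections and re-track forward.

    ``corrections`` is an iterable of ``(cell_id, t, (x, y, z))``.  A
    correction outside a track's valid range extends the range only if
    adjacent to it.  Positions for ``t`` onward are recomputed; earlier
    timepoints are untouched.
    """
    by_id = {tr.cell_id: tr for tr in tracks}
    corrected = []
    for cell_id, t, pos in corrections:
        tr = by_id[cell_id]
        pos = np.asarray(pos, dtype=float)
        if not _inside_volume(pos, movie):
            raise ValueError(f"correction for {cell_id} at t={t} outside the volume")
        if not (tr.valid_start - 1 <= t <= tr.valid_end + 1):
            raise ValueError(
                f"correction for {cell_id} at t={t} not adjacent to valid range "
                f"[{tr.valid_start}, {tr.valid_end}]"
            )
        tr.positions[t] = pos
        tr.confidence[t] = CONF_CORRECTED
        tr.valid_start = min(tr.valid_start, t)
        tr.valid_end = max(tr.valid_end, t)
        corrected.append((tr, t))
    for tr, t in corrected:
        tr.valid_end = t  # retrack forward from the corrected frame
        _run_forward(movie, [tr], t, search_radius_um, cell_radius_um)
    return tracks


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t in range(tr.valid_start, tr.valid_end + 1):
            rows.append(
                {
                    "time_s": tr.time[t],
                    "frame": t,
                    "cell_id": tr.cell_id,
                    "cell_type": tr.cell_type,
                    "segment": tr.segment,
                    "side": tr.side,
                    "x_um": tr.positions[t, 0],
                    "y_um": tr.positions[t, 1],
                    "z_um": tr.positions[t, 2],
                    "confidence": tr.confidence[t],
                }
            )
    return pd.DataFrame(rows)


def tracks_from_dataframe(df: pd.DataFrame) -> list[CellTrack]:
    tracks = []
    n_t = int(df["frame"].max()) + 1
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        positions = np.full((n_t, 3), np.nan)
        confidence = np.full(n_t, "", dtype=object)
        time = np.full(n_t, np.nan)
        frames = sub["frame"].to_numpy(dtype=int)
        positions[frames] = sub[["x_um", "y_um", "z_um"]].to_numpy()
        confidence[frames] = sub["confidence"].to_numpy()
        time[frames] = sub["time_s"].to_numpy()
        if np.isnan(time).any():  # reconstruct a full clock from the sampled frames
            dt = np.nanmedian(np.diff(sub["time_s"].to_numpy()) / np.diff(frames))
            t0 = sub["time_s"].iloc[0] - frames[0] * dt
            time = t0 + np.arange(n_t) * dt
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                positions=positions,
                confidence=confidence,
                valid_start=int(frames.min()),
                valid_end=int(frames.max()),
                time=time,
                cell_type=str(sub["cell_type"].iloc[0]),
                segment=str(sub["segment"].iloc[0]),
                side=str(sub["side"].iloc[0]),
            )
        )
    return tracks
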