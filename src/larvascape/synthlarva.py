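"""Ground-truthed synthetic larvae: kinematics, calcium dynamics, rendering.

The generator emulates the statistical structure the analysis assumes in the
two behavioral regimes:

* **crawl** -- a segmented body with a posterior-to-anterior traveling
  contraction wave.  Each segment's length follows a Gaussian-in-time dip,
  ``L_i(t) = L0 (1 - A g_i(t))`` with per-segment onsets advancing at the
  wave speed; soma positions along the anterior-posterior (y) axis are
  cumulative sums of segment lengths (tail anchored), with homologous
  left/right cells at x = +/- p.
* **explore** -- head turning theta(t) plus head retraction S(t) driving the
  four corner cells of the two-bar model (module :mod:`larvascape.explore`).

Per-cell calcium follows first-order indicator kinetics
``dc/dt = gain * u - c / tau`` driven by the rectified fractional length
change of the cell's segment -- contraction-rectified for contraction-sensing
types (class I, dmd1, vbd analogs) and stretch-rectified for the dbd analog.
Optional per-type onset delays emulate sequential activation.

Rendering places each soma as an isotropic 3-D Gaussian: the red channel is
static (the fiducial), green is ``baseline * (1 + calcium)``; both channels
share a multiplicative slow sinusoidal intensity modulation (emulating
motion-induced intensity changes) before additive Gaussian read noise and
clipping at zero.  A single integer seed drives one root generator with
deterministic per-component substreams, so identical config + seed gives
bit-identical outputs.

Axis convention: y = anterior-posterior (anterior at larger y), x =
left-right, z = depth; physical position = voxel index x spacing, at voxel
centers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .explore import exact_distances, pose_to_positions
from .volio import TwoChannelMovie

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_crawl_kinematics",
    "simulate_explore_kinematics",
    "simulate_calcium",
    "render_movie",
    "run_simulation",
    "truth_to_seeds",
    "write_ground_truth",
]

#: cell types whose drive is rectified segment *contraction*
CONTRACTION_SENSING = frozenset({"vpda", "ddaD", "ddaE", "dmd1", "vbd", "generic"})
#: cell types whose drive is rectified segment *stretch*
STRETCH_SENSING = frozenset({"dbd"})

# spatial margins (um) keeping rendered somata well inside the volume
_EDGE_MARGIN_UM = 32.0
_Z_MID_UM = 20.0
#: anterior-posterior stagger between cell types sharing a segment boundary
_TYPE_Y_OFFSET_UM = 8.0


@dataclass
class SimulationConfig:
    """All simulator knobs.  Defaults are the study conditions emulated.

    Times are seconds, lengths micrometres, rates per second.  The 10
    volumes/s rate and the ~400 ms indicator decay follow the acquisition
    and indicator this pipeline targets; the wave shape (A = 0.35,
    sigma = 0.4 s) puts the contraction FWHM (~0.94 s) inside the 0.7-2.5 s
    range typical of crawling larvae.
    """

    mode: str = "crawl"
    n_segments: int = 4
    rest_segment_length: float = 80.0
    halfwidth: float = 25.0
    wave_amplitude: float = 0.35
    wave_sigma: float = 0.4
    wave_period: float = 6.0
    wave_speed: float = 1.0          # segments per second
    first_wave_onset: float = 1.0
    volume_rate: float = 10.0
    calcium_decay_tau: float = 0.4
    calcium_gain: float = 8.0
    cell_radius: float = 3.0
    red_brightness: float = 100.0
    green_baseline: float = 100.0
    noise_sd: float = 10.0
    intensity_modulation_amplitude: float = 0.1
    modulation_frequency: float = 0.5
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    duration: float = 6.0
    seed: int = 0
    cell_types: tuple[str, ...] = ("ddaE",)
    type_delays: dict = field(default_factory=dict)
    # explore-mode kinematics
    explore_s0: float = 100.0
    explore_s_amplitude: float = 12.0
    explore_theta_max_deg: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("crawl", "explore"):
            raise ValueError(f"mode must be 'crawl' or 'explore', got {self.mode!r}")
        if not 0.0 <= self.wave_amplitude < 1.0:
            raise ValueError("wave_amplitude must lie in [0, 1)")
        positive = (
            "rest_segment_length", "halfwidth", "wave_sigma", "wave_period",
            "wave_speed", "volume_rate", "calcium_decay_tau", "cell_radius",
            "red_brightness", "green_baseline", "duration", "explore_s0",
            "modulation_frequency",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.noise_sd < 0 or self.intensity_modulation_amplitude < 0:
            raise ValueError("noise_sd and intensity_modulation_amplitude must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing) or len(self.voxel_spacing) != 3:
            raise ValueError("voxel_spacing must be 3 strictly positive values")
        if self.explore_s_amplitude < 0:
            raise ValueError("explore_s_amplitude must be >= 0")
        unknown = set(self.cell_types) - (CONTRACTION_SENSING | STRETCH_SENSING)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component substream of the root seed."""
        components = ("kinematics", "calcium", "noise")
        children = np.random.SeedSequence(self.seed).spawn(len(components))
        return np.random.default_rng(children[components.index(component)])

    @property
    def times(self) -> np.ndarray:
        return np.arange(int(round(self.duration * self.volume_rate))) / self.volume_rate

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["voxel_spacing"] = list(d["voxel_spacing"])
        d["cell_types"] = list(d["cell_types"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Everything the analysis should recover, exactly known."""

    times: np.ndarray
    cells: pd.DataFrame          # cell_id, cell_type, segment, side
    positions: np.ndarray        # (n_cells, T, 3) um as (x, y, z)
    config: SimulationConfig
    segment_lengths: np.ndarray | None = None   # (n_segments, T) um, crawl only
    calcium: np.ndarray | None = None           # (n_cells, T), dimensionless
    pose_series: list | None = None             # explore only
    modulation: np.ndarray | None = None        # set by render_movie

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def theta(self) -> np.ndarray:
        if self.pose_series is None:
            raise ValueError("no pose series (crawl-mode ground truth)")
        return np.array([p.theta for p in self.pose_series])

    @property
    def S(self) -> np.ndarray:
        if self.pose_series is None:
            raise ValueError("no pose series (crawl-mode ground truth)")
        return np.array([p.S for p in self.pose_series])

    def cell_index(self, cell_id: str) -> int:
        hits = np.flatnonzero((self.cells["cell_id"] == cell_id).to_numpy())
        if hits.size != 1:
            raise KeyError(cell_id)
        return int(hits[0])


def _wave_envelope(config: SimulationConfig) -> np.ndarray:
    """Per-segment Gaussian wave envelope g_i(t), shape (n_segments, T)."""
    t = config.times
    seg = np.arange(config.n_segments)
    onsets = config.first_wave_onset + seg / config.wave_speed  # segment i's first wave
    n_before = int(math.ceil((onsets.max()) / config.wave_period)) + 1
    n_after = int(math.ceil(config.duration / config.wave_period)) + 1
    g = np.zeros((config.n_segments, t.size))
    for k in range(-n_before, n_after + 1):
        centers = onsets + k * config.wave_period
        g += np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2.0 * config.wave_sigma**2))
    return g


def simulate_crawl_kinematics(config: SimulationConfig) -> GroundTruth:
    """Segment lengths and soma positions for a peristaltic crawl."""
    if config.mode != "crawl":
        raise ValueError("config.mode must be 'crawl'")
    g = _wave_envelope(config)
    if config.wave_amplitude * g.max() >= 1.0:
        raise ValueError(
            "wave parameters drive segment length to zero or below "
            "(overlapping waves? reduce wave_amplitude or increase wave_period)"
        )
    lengths = config.rest_segment_length * (1.0 - config.wave_amplitude * g)

    # anterior boundary of segment i = tail anchor + cumulative length
    boundaries = _EDGE_MARGIN_UM + np.cumsum(lengths, axis=0)  # (n_segments, T)

    x_mid = _EDGE_MARGIN_UM + config.halfwidth
    rows = []
    pos = []
    for seg_i in range(config.n_segments):
        for type_i, ctype in enumerate(config.cell_types):
            for side, sgn in (("left", -1.0), ("right", 1.0)):
                rows.append(
                    {
                        "cell_id": f"{ctype}_s{seg_i}_{side[0].upper()}",
                        "cell_type": ctype,
                        "segment": seg_i,
                        "side": side,
                    }
                )
                y = boundaries[seg_i] - type_i * _TYPE_Y_OFFSET_UM
                x = np.full_like(y, x_mid + sgn * config.halfwidth)
                z = np.full_like(y, _Z_MID_UM)
                pos.append(np.stack([x, y, z], axis=-1))
    return GroundTruth(
        times=config.times,
        cells=pd.DataFrame(rows),
        positions=np.stack(pos, axis=0),
        segment_lengths=lengths,
        config=config,
    )


def simulate_explore_kinematics(config: SimulationConfig) -> GroundTruth:
    """Seeded smooth theta(t) and S(t) driving the four two-bar corner cells."""
    if config.mode != "explore":
        raise ValueError("config.mode must be 'explore'")
    if config.explore_s_amplitude >= config.explore_s0:
        raise ValueError("parameters drive S(t) to zero or below")
    t = config.times
    rng = config.rng("kinematics")
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    theta_max = math.radians(config.explore_theta_max_deg)
    theta = theta_max * (
        0.7 * np.sin(2 * np.pi * 0.20 * t + phases[0])
        + 0.3 * np.sin(2 * np.pi * 0.45 * t + phases[1])
    )
    S = config.explore_s0 + config.explore_s_amplitude * np.sin(
        2 * np.pi * 0.30 * t + phases[2]
    )

    poses = [pose_to_positions(config.halfwidth, S[k], theta[k]) for k in range(t.size)]
    corners = np.array([[po.D1L, po.D1R, po.D2L, po.D2R] for po in poses])  # (T,4,2)
    # shift model coordinates into the positive volume octant
    x_off = _EDGE_MARGIN_UM - corners[..., 0].min()
    y_off = _EDGE_MARGIN_UM - corners[..., 1].min()

    ids = ["D1L", "D1R", "D2L", "D2R"]
    rows = [
        {"cell_id": "D1L", "cell_type": "ddaD", "segment": "T3", "side": "left"},
        {"cell_id": "D1R", "cell_type": "ddaD", "segment": "T3", "side": "right"},
        {"cell_id": "D2L", "cell_type": "ddaD", "segment": "A1", "side": "left"},
        {"cell_id": "D2R", "cell_type": "ddaD", "segment": "A1", "side": "right"},
    ]
    pos = np.empty((len(ids), t.size, 3))
    for i in range(len(ids)):
        pos[i, :, 0] = corners[:, i, 0] + x_off
        pos[i, :, 1] = corners[:, i, 1] + y_off
        pos[i, :, 2] = _Z_MID_UM
    return GroundTruth(
        times=t,
        cells=pd.DataFrame(rows),
        positions=pos,
        pose_series=poses,
        config=config,
    )


def _cell_drives(truth: GroundTruth, config: SimulationConfig) -> np.ndarray:
    """Rectified fractional-deformation drive u(t) per cell."""
    u = np.zeros((truth.n_cells, truth.times.size))
    if truth.segment_lengths is not None:
        l_rest = config.rest_segment_length
        for i, row in truth.cells.iterrows():
            length = truth.segment_lengths[int(row["segment"])]
            strain = (l_rest - length) / l_rest
            if row["cell_type"] in STRETCH_SENSING:
                strain = -strain
            u[i] = np.clip(strain, 0.0, None)
    elif truth.pose_series is not None:
        dists = np.array([exact_distances(po) for po in truth.pose_series])  # (T, 2)
        l_rest = config.explore_s0
        for i, row in truth.cells.iterrows():
            length = dists[:, 0] if row["side"] == "left" else dists[:, 1]
            strain = (l_rest - length) / l_rest
            if row["cell_type"] in STRETCH_SENSING:
                strain = -strain
            u[i] = np.clip(strain, 0.0, None)
    else:
        raise ValueError("ground truth has no kinematics")
    return u


def simulate_calcium(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    initial: float = 0.0,
) -> GroundTruth:
    """First-order indicator kinetics dc/dt = gain*u - c/tau per cell.

    Integrated with the exact exponential step for piecewise-constant drive,
    so the closed-form solutions (pure decay, step response) are reproduced
    exactly at the sample times.  Per-type onset delays shift the drive in
    time before integration.
    """
    config = config or truth.config
    if truth.positions is None:
        raise ValueError("kinematics missing; simulate kinematics first")
    u = _cell_drives(truth, config)
    t = truth.times
    for i, row in truth.cells.iterrows():
        delay = float(config.type_delays.get(row["cell_type"], 0.0))
        if delay:
            u[i] = np.interp(t - delay, t, u[i])
    dt = 1.0 / config.volume_rate
    alpha = math.exp(-dt / config.calcium_decay_tau)
    drive_gain = config.calcium_gain * config.calcium_decay_tau * (1.0 - alpha)
    c = np.empty_like(u)
    c[:, 0] = initial
    for k in range(1, t.size):
        c[:, k] = c[:, k - 1] * alpha + drive_gain * u[:, k - 1]
    truth.calcium = c
    return truth


def render_movie(truth: GroundTruth, config: SimulationConfig | None = None) -> TwoChannelMovie:
    """Render somata as isotropic 3-D Gaussians into a two-channel movie.

    Red amplitude is static (``red_brightness``); green is
    ``green_baseline * (1 + calcium)``.  Both channels are multiplied by the
    common modulation ``m(t) = 1 + a sin(2 pi f t)``, then Gaussian read
    noise is added and intensities clipped at zero.
    """
    config = config or truth.config
    if truth.calcium is None:
        raise ValueError("calcium missing; run simulate_calcium first (gain=0 for a static marker)")
    spacing = np.array(config.voxel_spacing, dtype=float)  # (z, y, x)
    pos = truth.positions  # (n_cells, T, 3) as (x, y, z)
    margin = 4.0 * config.cell_radius + 2.0 * spacing.max()
    lo = pos.reshape(-1, 3).min(axis=0)
    if (lo < margin).any():
        raise ValueError("volume too small to contain positions with the rendering margin")
    hi = pos.reshape(-1, 3).max(axis=0)  # (x, y, z)
    shape_zyx = tuple(
        int(math.ceil((hi[ax] + margin) / spacing[dim])) + 1
        for dim, ax in ((0, 2), (1, 1), (2, 0))
    )

    t = truth.times
    modulation = 1.0 + config.intensity_modulation_amplitude * np.sin(
        2 * np.pi * config.modulation_frequency * t
    )
    truth.modulation = modulation

    half = np.ceil(4.0 * config.cell_radius / spacing).astype(int)  # (z, y, x) voxels
    rng = config.rng("noise")
    data = np.zeros((t.size, 2, *shape_zyx), dtype=np.float64)
    inv2r2 = 1.0 / (2.0 * config.cell_radius**2)
    for k in range(t.size):
        green = data[k, 0]
        red = data[k, 1]
        for i in range(truth.n_cells):
            x, y, z = pos[i, k]
            profile = []
            slices = []
            for dim, coord in ((0, z), (1, y), (2, x)):
                center = coord / spacing[dim]
                a = max(0, int(math.floor(center)) - half[dim])
                b = min(shape_zyx[dim], int(math.ceil(center)) + half[dim] + 1)
                grid = np.arange(a, b) * spacing[dim] - coord
                profile.append(np.exp(-(grid**2) * inv2r2))
                slices.append(slice(a, b))
            w = profile[0][:, None, None] * profile[1][None, :, None] * profile[2][None, None, :]
            red[tuple(slices)] += config.red_brightness * w
            green[tuple(slices)] += config.green_baseline * (1.0 + truth.calcium[i, k]) * w
        data[k] *= modulation[k]
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)
    return TwoChannelMovie(
        data,
        spacing=tuple(spacing),
        volume_rate=config.volume_rate,
        channel_names=("green", "red"),
    )


def run_simulation(config: SimulationConfig) -> tuple[GroundTruth, TwoChannelMovie]:
    """Kinematics -> calcium -> rendered movie for either mode."""
    if config.mode == "crawl":
        truth = simulate_crawl_kinematics(config)
    else:
        truth = simulate_explore_kinematics(config)
    simulate_calcium(truth, config)
    movie = render_movie(truth, config)
    return truth, movie


def truth_to_seeds(truth: GroundTruth, t0: int = 0) -> pd.DataFrame:
    """Seed table (labels + positions at t0) for the tracker."""
    df = truth.cells.copy()
    df["x_um"] = truth.positions[:, t0, 0]
    df["y_um"] = truth.positions[:, t0, 1]
    df["z_um"] = truth.positions[:, t0, 2]
    return df


def write_ground_truth(truth: GroundTruth, csv_path, config_json_path=None) -> None:
    """Long-format ground-truth CSV plus a JSON config echo sidecar."""
    frames = []
    for i, row in truth.cells.iterrows():
        df = pd.DataFrame(
            {
                "time_s": truth.times,
                "cell_id": row["cell_id"],
                "cell_type": row["cell_type"],
                "segment": row["segment"],
                "side": row["side"],
                "x_um": truth.positions[i, :, 0],
                "y_um": truth.positions[i, :, 1],
                "z_um": truth.positions[i, :, 2],
                "calcium": truth.calcium[i] if truth.calcium is not None else np.nan,
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if config_json_path is not None:
        with open(config_json_path, "w") as f:
            f.write(truth.config.to_json())
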