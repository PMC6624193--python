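"""Volumetric movie I/O and oblique-plane geometry.

The raw data object throughout the package is a two-channel (green dynamic,
red static) volumetric time series with physical voxel spacing.  Single-
objective oblique light-sheet systems acquire tilted y-z' planes stacked
along the scan (x) axis; :func:`deskew` applies the one geometric correction
such data need -- a shear along x proportional to depth -- and nothing else.

Formats: multi-page TIFF with a JSON description tag (page order TCZYX) and
HDF5 (dataset ``movie``, attrs ``spacing_um`` / ``volume_rate`` /
``channel_names``).  Readers never rescale intensities, and missing spacing
metadata is a hard error rather than a silent default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
from scipy import ndimage

AXES = "TCZYX"

__all__ = [
    "TwoChannelMovie",
    "ObliqueStack",
    "deskew",
    "read_movie",
    "write_movie",
]


@dataclass
class TwoChannelMovie:
    """A (time, channel, z, y, x) intensity volume with physical spacing.

    Parameters
    ----------
    data
        5-D array ordered ``(T, C, Z, Y, X)`` with exactly two channels.
    spacing
        Voxel spacing ``(z, y, x)`` in micrometres.
    volume_rate
        Acquisition rate in volumes per second.
    channel_names
        Names for the two channels, by convention ``("green", "red")``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    volume_rate: float
    channel_names: tuple[str, str] = ("green", "red")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected a 5-axis (T, C, Z, Y, X) array, got {self.data.ndim} axes"
            )
        if self.data.shape[1] != 2:
            raise ValueError(
                "expected exactly 2 channels on axis 1 (C), "
                f"got {self.data.shape[1]}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.volume_rate = float(self.volume_rate)
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be strictly positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != 2:
            raise ValueError("need exactly two channel names")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Volume acquisition times in seconds."""
        return np.arange(self.n_timepoints) / self.volume_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        """View of one channel as a (T, Z, Y, X) array."""
        return self.data[:, self.channel_index(name)]


@dataclass
class ObliqueStack:
    """Raw oblique-plane acquisition: y-z' planes stacked along the scan axis.

    ``planes`` is ordered ``(x_scan_step, channel, z', y)``.  ``sheet_angle``
    is the sheet's tilt from vertical in degrees; each z' level is displaced
    along x by ``z' * z_spacing * tan(sheet_angle)`` micrometres.
    """

    planes: np.ndarray
    sheet_angle: float
    x_step: float
    z_spacing: float
    y_spacing: float
    volume_rate: float = 1.0
    channel_names: tuple[str, str] = ("green", "red")

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 4:
            raise ValueError("planes must be a 4-axis (x, channel, z', y) array")
        if self.planes.size == 0:
            raise ValueError("empty stack")
        if self.planes.shape[1] != 2:
            raise ValueError(
                f"expected exactly 2 channels on axis 1, got {self.planes.shape[1]}"
            )
        if not 0.0 < self.sheet_angle < 90.0:
            raise ValueError("sheet_angle must lie in (0, 90) degrees from vertical")
        for name in ("x_step", "z_spacing", "y_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def deskew(stack: ObliqueStack) -> TwoChannelMovie:
    """Shear oblique planes onto a Cartesian grid (linear interpolation).

    Each y-z' plane is displaced along x by ``z' * z_spacing *
    tan(sheet_angle)``; no other reconstruction is applied.  Voxels sheared
    in from outside the acquired volume are filled with 0 and the amount of
    padding recorded in ``meta``.
    """
    shear_um_per_z = math.tan(math.radians(stack.sheet_angle)) * stack.z_spacing
    shear_vox_per_z = shear_um_per_z / stack.x_step

    vol = np.moveaxis(stack.planes.astype(np.float64), 0, -1)  # (C, Z', Y, X)
    n_c, n_z, n_y, n_x = vol.shape
    pad = int(math.ceil(shear_vox_per_z * (n_z - 1)))
    out = np.zeros((n_c, n_z, n_y, n_x + pad), dtype=np.float64)
    out[..., :n_x] = vol
    for z in range(n_z):
        shift = shear_vox_per_z * z
        if shift:
            out[:, z] = ndimage.shift(
                out[:, z], (0.0, 0.0, shift), order=1, mode="grid-constant", cval=0.0,
                prefilter=False,
            )
    np.clip(out, 0.0, None, out=out)
    return TwoChannelMovie(
        out[None],
        spacing=(stack.z_spacing, stack.y_spacing, stack.x_step),
        volume_rate=stack.volume_rate,
        channel_names=stack.channel_names,
        meta={
            "deskew_sheet_angle_deg": stack.sheet_angle,
            "deskew_fill": "zero",
            "deskew_pad_voxels": pad,
        },
    )


# ---------------------------------------------------------------------------
# readers / writers


def _movie_metadata(movie: TwoChannelMovie) -> dict:
    return {
        "axes": AXES,
        "shape": list(movie.data.shape),
        "spacing_um": list(movie.spacing),
        "volume_rate": movie.volume_rate,
        "channel_names": list(movie.channel_names),
    }


def write_movie(movie: TwoChannelMovie, path) -> None:
    """Write a movie as TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5) by suffix."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        _write_tiff(movie, path)
    elif path.endswith((".h5", ".hdf5")):
        _write_hdf5(movie, path)
    else:
        raise ValueError(f"unsupported movie format: {path}")


def read_movie(path) -> TwoChannelMovie:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        return _read_tiff(path)
    if path.endswith((".h5", ".hdf5")):
        return _read_hdf5(path)
    raise ValueError(f"unsupported movie format: {path}")


def _write_tiff(movie: TwoChannelMovie, path: str) -> None:
    t, c, z, y, x = movie.data.shape
    pages = np.ascontiguousarray(movie.data).reshape(t * c * z, y, x)
    tifffile.imwrite(path, pages, description=json.dumps(_movie_metadata(movie)))


def _read_tiff(path: str) -> TwoChannelMovie:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = None
        if not isinstance(meta, dict) or "spacing_um" not in meta:
            raise ValueError(f"{path}: missing spacing metadata in TIFF description tag")
        arr = tf.asarray()
    shape = tuple(meta["shape"])
    arr = arr.reshape(shape)
    return TwoChannelMovie(
        arr,
        spacing=tuple(meta["spacing_um"]),
        volume_rate=meta["volume_rate"],
        channel_names=tuple(meta.get("channel_names", ("green", "red"))),
    )


def _write_hdf5(movie: TwoChannelMovie, path: str) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("movie", data=movie.data)
        ds.attrs["axes"] = AXES
        ds.attrs["spacing_um"] = np.asarray(movie.spacing, dtype=np.float64)
        ds.attrs["volume_rate"] = movie.volume_rate
        ds.attrs["channel_names"] = [str(n) for n in movie.channel_names]


def _read_hdf5(path: str) -> TwoChannelMovie:
    with h5py.File(path, "r") as f:
        if "movie" not in f:
            raise ValueError(f"{path}: no 'movie' dataset")
        ds = f["movie"]
        if "spacing_um" not in ds.attrs or "volume_rate" not in ds.attrs:
            raise ValueError(f"{path}: missing spacing_um/volume_rate metadata")
        names = ds.attrs.get("channel_names", ["green", "red"])
        names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in names)
        return TwoChannelMovie(
            ds[()],
            spacing=tuple(ds.attrs["spacing_um"]),
            volume_rate=float(ds.attrs["volume_rate"]),
            channel_names=names,
        )
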