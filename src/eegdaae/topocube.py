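"""Scalp topomap rasterization and data-cube construction.

Each trial's channel time series become a stream of 32 x 32 topographic
frames: electrode positions on an ideal unit sphere are flattened by an
azimuthal equidistant projection centered at the vertex (planar radius
proportional to arc distance from Cz, azimuth preserved), voltages are
interpolated across the grid, and the time axis is compressed by
truncating 3000 raw samples to 2880 and taking the median of every 10
consecutive samples (robust to transient artifacts). The resulting
288 x 32 x 32 stream is partitioned into nine non-overlapping 32^3 data
cubes — the autoencoder's input/output unit.

Conventions (fixed here, since no single standard exists):

* Electrode positions are ideal-sphere 10-10 coordinates built by the
  textbook arc construction: the outer ring (Fp1/2, F7/8, T7/8, P7/8 ...)
  sits 72 deg from the vertex, midline electrodes at multiples of 18 deg,
  and intermediate electrodes (F3, FC5, CP1, ...) are placed by spherical
  linear interpolation along their row's great-circle arc. Positions are
  exactly midline-symmetric by construction.
* Head-disk radius 1 equals the outermost electrode arc plus a 5% margin;
  the 32 x 32 grid spans [-1.05, 1.05]^2; row 0 is anterior (nose-side),
  column 0 is left.
* Interpolation is piecewise-linear barycentric on the Delaunay
  triangulation of the projected electrodes, nearest-electrode fill
  between the convex hull and the disk boundary, zero outside the disk.
  Pixels that are an electrode's nearest grid point carry the electrode
  value exactly. The whole map is linear in the voltages.
* Per-trial amplitudes are NOT normalized before rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .synthdata import CHANNELS_24, RawTrial

__all__ = [
    "GRID_SIZE",
    "GRID_EXTENT",
    "N_KEEP",
    "DOWNSAMPLE_FACTOR",
    "N_FRAMES",
    "N_CUBES",
    "CUBE_SIZE",
    "ElectrodeLayout",
    "TopomapFrame",
    "CubeStream",
    "DataCube",
    "project_montage",
    "truncate_trial",
    "median_downsample",
    "rasterize",
    "build_stream",
    "partition_cubes",
]

GRID_SIZE = 32
GRID_EXTENT = 1.05  # grid spans [-1.05, 1.05]^2; head disk radius 1
N_KEEP = 2880
DOWNSAMPLE_FACTOR = 10
N_FRAMES = N_KEEP // DOWNSAMPLE_FACTOR  # 288
CUBE_SIZE = 32
N_CUBES = N_FRAMES // CUBE_SIZE  # 9

RING_ARC_DEG = 72.0  # arc from vertex of the circumferential 10-20 ring

# Ring electrodes: azimuth in degrees from anterior midline, positive -> right.
_RING_AZIMUTH = {
    "Fpz": 0.0, "Fp1": -18.0, "Fp2": 18.0,
    "AF7": -36.0, "AF8": 36.0,
    "F7": -54.0, "F8": 54.0,
    "FT7": -72.0, "FT8": 72.0,
    "T7": -90.0, "T8": 90.0,
    "TP7": -108.0, "TP8": 108.0,
    "P7": -126.0, "P8": 126.0,
    "PO7": -144.0, "PO8": 144.0,
    "O1": -162.0, "O2": 162.0, "Oz": 180.0,
}

# Midline electrodes: (arc from vertex in deg, azimuth 0 = anterior).
_MIDLINE = {
    "Fpz": (72.0, 0.0), "AFz": (54.0, 0.0), "Fz": (36.0, 0.0), "FCz": (18.0, 0.0),
    "Cz": (0.0, 0.0),
    "CPz": (18.0, 180.0), "Pz": (36.0, 180.0), "POz": (54.0, 180.0), "Oz": (72.0, 180.0),
}

# Intermediate electrodes: slerp fraction along the great-circle arc from the
# row's ring endpoint (position 7) to its midline point (position z).
# Positions 5, 3, 1 sit at 1/4, 1/2 (position 3 in 10-20 rows), 3/4.
_ROW_ARCS = {
    "F": ("F7", "Fz"), "FC": ("FT7", "FCz"), "C": ("T7", "Cz"),
    "CP": ("TP7", "CPz"), "P": ("P7", "Pz"),
}
_POSITION_FRACTION = {"7": 0.0, "5": 0.25, "3": 0.5, "1": 0.75, "z": 1.0}


def _sph_unit(arc_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector: x right, y anterior, z up; arc measured from vertex."""
    r, az = np.deg2rad(arc_deg), np.deg2rad(az_deg)
    return np.array([np.sin(r) * np.sin(az), np.sin(r) * np.cos(az), np.cos(r)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _electrode_pos3d(name: str) -> np.ndarray:
    if name in _MIDLINE:
        return _sph_unit(*_MIDLINE[name])
    if name in _RING_AZIMUTH:
        return _sph_unit(RING_ARC_DEG, _RING_AZIMUTH[name])
    # intermediate: row prefix + numeric position, e.g. FC5, P3, CP2
    row, pos = name[:-1], name[-1]
    if row not in _ROW_ARCS or not pos.isdigit() or not 1 <= int(pos) <= 8:
        raise ValueError(f"unknown electrode name {name!r}")
    left = int(pos) % 2 == 1  # odd = left hemisphere; mirror the left arc for even
    left_pos = pos if left else str(int(pos) - 1)
    ring_name, mid_name = _ROW_ARCS[row]
    p = _slerp(
        _electrode_pos3d(ring_name), _electrode_pos3d(mid_name),
        _POSITION_FRACTION[left_pos],
    )
    if not left:
        p = p * np.array([-1.0, 1.0, 1.0])  # mirror across the midline
    return p


@dataclass(frozen=True)
class ElectrodeLayout:
    """Projected electrode geometry shared by every topomap."""

    names: tuple[str, ...]
    pos3d: np.ndarray = field(repr=False)       # (n, 3) unit sphere
    pos2d: np.ndarray = field(repr=False)       # (n, 2) inside unit disk
    grid_index: np.ndarray = field(repr=False)  # (n, 2) nearest (row, col)


@dataclass(frozen=True)
class TopomapFrame:
    grid: np.ndarray = field(repr=False)  # (32, 32) uV
    mask: np.ndarray = field(repr=False)  # (32, 32) bool head disk


@dataclass(frozen=True)
class CubeStream:
    frames: np.ndarray = field(repr=False)  # (288, 32, 32)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape != (N_FRAMES, GRID_SIZE, GRID_SIZE):
            raise ValueError(f"stream must be {(N_FRAMES, GRID_SIZE, GRID_SIZE)}, "
                             f"got {self.frames.shape}")


@dataclass(frozen=True)
class DataCube:
    voxels: np.ndarray = field(repr=False)  # (32, 32, 32) time x row x col
    segment_index: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxels.shape != (CUBE_SIZE, GRID_SIZE, GRID_SIZE):
            raise ValueError(f"cube must be {(CUBE_SIZE, GRID_SIZE, GRID_SIZE)}, "
                             f"got {self.voxels.shape}")
        if not 0 <= self.segment_index < N_CUBES:
            raise ValueError(f"segment_index must be in [0, {N_CUBES}), "
                             f"got {self.segment_index}")


def _grid_coords() -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates: x per column (left->right), y per row (ant->post)."""
    xs = np.linspace(-GRID_EXTENT, GRID_EXTENT, GRID_SIZE)
    ys = np.linspace(GRID_EXTENT, -GRID_EXTENT, GRID_SIZE)
    return xs, ys


def head_mask() -> np.ndarray:
    xs, ys = _grid_coords()
    xx, yy = np.meshgrid(xs, ys)  # yy varies over rows
    return xx**2 + yy**2 <= 1.0


@lru_cache(maxsize=8)
def _project_montage_cached(names: tuple[str, ...]) -> ElectrodeLayout:
    if len(set(names)) != len(names):
        raise ValueError("electrode names must be unique")
    pos3d = np.array([_electrode_pos3d(n) for n in names])
    arcs = np.arccos(np.clip(pos3d[:, 2], -1.0, 1.0))
    max_arc = arcs.max()
    # disk radius 1 = outermost arc + 5% margin
    radius = arcs / (1.05 * max_arc)
    xy = pos3d[:, :2].copy()
    norms = np.linalg.norm(xy, axis=1)
    direction = np.zeros_like(xy)
    nz = norms > 1e-12
    direction[nz] = xy[nz] / norms[nz, None]
    pos2d = radius[:, None] * direction
    xs, ys = _grid_coords()
    rows = np.abs(ys[None, :] - pos2d[:, 1:2]).argmin(axis=1)
    cols = np.abs(xs[None, :] - pos2d[:, 0:1]).argmin(axis=1)
    grid_index = np.stack([rows, cols], axis=1)
    return ElectrodeLayout(names=names, pos3d=pos3d, pos2d=pos2d, grid_index=grid_index)


def project_montage(names=CHANNELS_24) -> ElectrodeLayout:
    """Vertex-centered azimuthal equidistant projection of named electrodes."""
    return _project_montage_cached(tuple(names))


@lru_cache(maxsize=8)
def _raster_weights(names: tuple[str, ...]) -> np.ndarray:
    """Precomputed (1024, n_electrodes) linear map: pixel values = W @ voltages."""
    layout = _project_montage_cached(names)
    n = len(names)
    xs, ys = _grid_coords()
    xx, yy = np.meshgrid(xs, ys)
    pixels = np.column_stack([xx.ravel(), yy.ravel()])
    mask = head_mask().ravel()

    tri = Delaunay(layout.pos2d)
    simplices = tri.find_simplex(pixels)
    tree = cKDTree(layout.pos2d)
    _, nearest = tree.query(pixels)

    W = np.zeros((pixels.shape[0], n))
    for p in range(pixels.shape[0]):
        if not mask[p]:
            continue
        s = simplices[p]
        if s >= 0:
            verts = tri.simplices[s]
            T = tri.transform[s]
            bary2 = T[:2] @ (pixels[p] - T[2])
            bary = np.append(bary2, 1.0 - bary2.sum())
            W[p, verts] = bary
        else:
            W[p, nearest[p]] = 1.0  # between hull and disk boundary
    # electrode-home pixels carry the measured value exactly
    for e, (r, c) in enumerate(layout.grid_index):
        p = r * GRID_SIZE + c
        W[p] = 0.0
        W[p, e] = 1.0
    return W


def rasterize(values: np.ndarray, layout: ElectrodeLayout) -> TopomapFrame:
    """Interpolate one time point's electrode voltages across the 32 x 32 grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(layout.names),):
        raise ValueError(f"expected {len(layout.names)} values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("electrode values must be finite")
    W = _raster_weights(layout.names)
    grid = (W @ values).reshape(GRID_SIZE, GRID_SIZE)
    return TopomapFrame(grid=grid, mask=head_mask())


def truncate_trial(data: np.ndarray | RawTrial, n_keep: int = N_KEEP) -> np.ndarray:
    """Keep the first ``n_keep`` samples per channel (deterministic head cut)."""
    arr = data.data if isinstance(data, RawTrial) else np.asarray(data)
    if arr.shape[-1] < n_keep:
        raise ValueError(f"need >= {n_keep} samples, got {arr.shape[-1]}")
    return arr[..., :n_keep]


def median_downsample(data: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Median of every ``factor`` consecutive samples: (C, T) -> (C, T/factor)."""
    data = np.asarray(data)
    c, t = data.shape
    if t % factor != 0:
        raise ValueError(f"sample count {t} not divisible by factor {factor}")
    return np.median(data.reshape(c, t // factor, factor), axis=2)


def build_stream(
    trial: RawTrial | np.ndarray, layout: ElectrodeLayout | None = None, provenance=None
) -> CubeStream:
    """Full chain trial -> 288 x 32 x 32 stream (truncate, downsample, rasterize)."""
    if layout is None:
        layout = project_montage()
    arr = trial.data if isinstance(trial, RawTrial) else np.asarray(trial)
    down = median_downsample(truncate_trial(arr))  # (C, 288)
    W = _raster_weights(layout.names)
    frames = (down.T @ W.T).reshape(N_FRAMES, GRID_SIZE, GRID_SIZE)
    if provenance is None and isinstance(trial, RawTrial):
        provenance = {
            "subject": trial.subject_id, "session": trial.session,
            "stimulus": trial.stimulus, "trial": trial.trial_index,
        }
    return CubeStream(frames=frames, provenance=provenance or {})


def partition_cubes(stream: CubeStream) -> list[DataCube]:
    """Split the stream into 9 contiguous 32^3 cubes; lossless in order."""
    frames = stream.frames
    return [
        DataCube(
            voxels=frames[CUBE_SIZE * k: CUBE_SIZE * (k + 1)],
            segment_index=k,
            provenance=dict(stream.provenance),
        )
        for k in range(N_CUBES)
    ]
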