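"""Nearest-voxel reconstruction of sparsely sampled Lissajous acquisitions.

Each enabled pulse sample is mapped to the voxel whose center is nearest
the predicted scan position.  Positions are *recomputed* from the frame's
synchronization metadata (the recorded phase delay plus the harmonic
closed forms), never trusted from stored coordinates — the same route the
real instrument uses, where only the TTL/pixel-enable timing is known.

Nearest-voxel mapping is implemented as half-open binning of the
continuous position (bin k covers [k*w, (k+1)*w) for voxel width w),
which is equivalent to a nearest-voxel-center search with edge ties going
to the lower bin.  Voxels that receive no sample are *missing*: their
value carries a NaN sentinel, they are excluded from statistics, and they
are only zero-filled at export time for visual parity with the black
missing pixels of raw instrument images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import RawStream, scan_position
from .scan_model import FrameMeta, ScanConfig

__all__ = [
    "Volume",
    "map_sample_to_voxel",
    "reconstruct_volume",
    "rebin_grid",
    "accumulate",
    "fill_ratio",
    "slice_fill_ratios",
]


@dataclass
class Volume:
    """A reconstructed voxel grid with per-voxel hit counts.

    ``values[ix, iy, iz]`` is the mean of all samples binned to the voxel
    (NaN where ``hits == 0``); ``hits`` counts the samples.  ``t_mid`` is
    the mid-acquisition timestamp, ``n_accumulated`` the number of raw
    volumes merged into this one.
    """

    values: np.ndarray
    hits: np.ndarray
    config: ScanConfig
    t_mid: float
    volume_index: int = 0
    n_accumulated: int = 1

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        return self.hits == 0

    def fill_ratio(self) -> float:
        return fill_ratio(self)

    def filled(self, fill_value: float = 0.0) -> np.ndarray:
        """Values with missing voxels replaced by ``fill_value`` (for export)."""
        out = self.values.copy()
        out[self.missing] = fill_value
        return out


def _grid_of(cfg: ScanConfig, grid) -> tuple[int, int, int]:
    if grid is None:
        return cfg.geometry.grid
    nx, ny, nz = (int(g) for g in grid)
    if min(nx, ny, nz) < 1:
        raise ValueError("grid counts must be >= 1")
    return nx, ny, nz


def _bin_index(pos: np.ndarray, fov: float, n: int) -> np.ndarray:
    """Half-open binning of a centered coordinate into n bins over [-fov/2, fov/2)."""
    idx = np.floor((pos + fov / 2) / fov * n).astype(np.int64)
    return np.clip(idx, 0, n - 1)


def map_sample_to_voxel(t, frame: FrameMeta, cfg: ScanConfig, grid=None):
    """Voxel indices (ix, iy, iz) of the sample(s) taken at time(s) ``t``.

    The position is predicted from the frame's phase delay and the
    harmonic closed forms; indices are 0-based with half-open bins (voxel
    centers at bin midpoints), clamped to the grid.  ``t`` must lie inside
    the frame's enable windows (checked against the frame span).
    """
    from .scan_model import enable_intervals

    nx, ny, nz = _grid_of(cfg, grid)
    t = np.asarray(t, dtype=float)
    eps = 0.5 / cfg.clocks.f_rep
    inside = np.zeros(t.shape, dtype=bool)
    for a, b in enable_intervals(cfg, frame.frame_index):
        inside |= (t >= a - eps) & (t <= b + eps)
    if not np.all(inside):
        raise ValueError("sample time outside the frame's enable windows")
    pos = scan_position(t, frame, cfg, from_meta=True)
    g = cfg.geometry
    ix = _bin_index(pos[..., 0], g.fov_x, nx)
    iz = _bin_index(pos[..., 2], g.fov_z, nz)
    iy = _bin_index(pos[..., 1], g.fov_y, ny)
    return ix, iy, iz


def reconstruct_volume(stream: RawStream, volume_index: int = 0, grid=None) -> Volume:
    """Assemble one volume from the stream by nearest-voxel binning.

    Every sample lands in exactly one voxel; the voxel value is the
    arithmetic mean of its samples (intensity independent of dwell
    density), and the per-voxel ``hits`` conserve the sample count.
    """
    cfg = stream.config
    nx, ny, nz = _grid_of(cfg, grid)
    n_vox = nx * ny * nz
    t_lo, t_hi = np.inf, -np.inf
    flat_parts, val_parts = [], []
    for local in stream.volume_frames(volume_index):
        meta = stream.frames[local]
        t, vals = stream.frame_samples(local)
        if t.size == 0:
            continue
        ix, iy, iz = map_sample_to_voxel(t, meta, cfg, grid=(nx, ny, nz))
        flat_parts.append((ix * ny + iy) * nz + iz)
        val_parts.append(vals)
        t_lo = min(t_lo, t[0])
        t_hi = max(t_hi, t[-1])
    if flat_parts:
        flat = np.concatenate(flat_parts)
        vals = np.concatenate(val_parts)
        sums = np.bincount(flat, weights=vals, minlength=n_vox)
        counts = np.bincount(flat, minlength=n_vox)
    else:
        sums = np.zeros(n_vox)
        counts = np.zeros(n_vox, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    t_mid = 0.5 * (t_lo + t_hi) if np.isfinite(t_lo) else float("nan")
    return Volume(
        values=values.reshape(nx, ny, nz),
        hits=counts.reshape(nx, ny, nz),
        config=cfg,
        t_mid=t_mid,
        volume_index=volume_index,
    )


def rebin_grid(stream: RawStream, n_x: int, n_y: int, n_z: int,
               volume_index: int = 0) -> Volume:
    """Map the same samples onto an alternate voxel grid.

    The acquisition (frames, enable windows, pulse times) is unchanged;
    only the binning grid differs, so coarser grids can only raise the
    fill ratio (pigeonhole) and finer ones lower it.
    """
    return reconstruct_volume(stream, volume_index, grid=(n_x, n_y, n_z))


def accumulate(volumes) -> Volume:
    """Merge consecutive volumes: hits summed, values hit-weighted means.

    All volumes must share the grid and configuration.  Because the
    Lissajous pattern drifts between volumes (incommensurate clocks), the
    union of hit voxels — the fill ratio — grows with each accumulation,
    at the cost of temporal resolution.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    base = volumes[0]
    sums = np.zeros_like(base.values, dtype=float)
    counts = np.zeros_like(base.hits, dtype=np.int64)
    n_acc = 0
    for v in volumes:
        if v.grid != base.grid:
            raise ValueError(f"grid mismatch: {v.grid} vs {base.grid}")
        vals = np.where(v.hits > 0, v.values, 0.0)
        sums += vals * v.hits
        counts += v.hits
        n_acc += v.n_accumulated
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Volume(
        values=values,
        hits=counts,
        config=base.config,
        t_mid=float(np.mean([v.t_mid for v in volumes])),
        volume_index=base.volume_index,
        n_accumulated=n_acc,
    )


def fill_ratio(volume: Volume) -> float:
    """Fraction of voxels that received at least one sample, in [0, 1]."""
    return float(np.count_nonzero(volume.hits) / volume.hits.size)


def slice_fill_ratios(volume: Volume) -> np.ndarray:
    """Per-z-slice (x-y plane) fill ratios, length n_z.

    The instrument's displayed "pixel ratio" refers to a 2D cross-section;
    this gives that figure for every z plane (the volume-wide
    :func:`fill_ratio` is the default reported metric).
    """
    nx, ny, _ = volume.grid
    return np.count_nonzero(volume.hits > 0, axis=(0, 1)) / (nx * ny)
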