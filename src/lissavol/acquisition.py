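"""Pulse-clocked acquisition: gate the pulse train, sample the phantom.

The laser emits pulses at ``t_k = k / f_rep`` exactly (the digitizer is
locked to the pulse train).  Pulses falling inside a frame's enable
windows are sampled: the phantom is evaluated at the instantaneous scan
position (mirror x, galvo y, TAG z) and a Poisson photon count is drawn.
The result is a :class:`RawStream` — the simulator's stand-in for the DMA
payload of the real instrument — holding the enabled samples plus the
per-frame synchronization metadata (``t_start``, ``delta_phi``) that
reconstruction needs to predict each frame's Lissajous pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom, intensity_at
from .scan_model import (
    TWO_PI,
    FrameMeta,
    ScanConfig,
    enable_intervals,
    frame_meta,
    rm_position,
    tag_phase,
    z_position,
)

__all__ = ["PulseSample", "RawStream", "simulate_acquisition", "scan_position", "enabled_pulse_indices"]


@dataclass(frozen=True)
class PulseSample:
    """One enabled laser pulse: global ordinal, time, measured photons."""

    pulse_index: int
    t: float
    value: float


@dataclass
class RawStream:
    """Ordered enabled samples plus per-frame synchronization metadata.

    Samples are stored as flat arrays (``pulse_index``, ``values``) with
    ``frame_bounds[i]:frame_bounds[i+1]`` delimiting frame ``i``'s slice.
    Sample times are implicit: ``t = pulse_index / f_rep``.
    """

    config: ScanConfig
    seed: int
    pulse_index: np.ndarray
    values: np.ndarray
    frame_bounds: np.ndarray
    frames: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_volumes(self) -> int:
        return self.n_frames // self.config.geometry.n_y

    @property
    def n_samples(self) -> int:
        return int(self.pulse_index.size)

    @property
    def times(self) -> np.ndarray:
        return self.pulse_index / self.config.clocks.f_rep

    def frame_samples(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(pulse times, values) of frame ``i`` (index into this stream)."""
        a, b = self.frame_bounds[i], self.frame_bounds[i + 1]
        return self.pulse_index[a:b] / self.config.clocks.f_rep, self.values[a:b]

    def sample(self, k: int) -> PulseSample:
        return PulseSample(
            pulse_index=int(self.pulse_index[k]),
            t=float(self.pulse_index[k] / self.config.clocks.f_rep),
            value=float(self.values[k]),
        )

    def volume_frames(self, volume_index: int) -> range:
        """Stream-local frame indices belonging to ``volume_index``."""
        n_y = self.config.geometry.n_y
        first_vol = self.frames[0].frame_index // n_y
        local = (volume_index - first_vol) * n_y
        if local < 0 or local + n_y > self.n_frames:
            raise IndexError(f"volume {volume_index} not contained in this stream")
        return range(local, local + n_y)


def enabled_pulse_indices(cfg: ScanConfig, frame_index: int) -> np.ndarray:
    """Global ordinals of the laser pulses enabled during one frame."""
    f_rep = cfg.clocks.f_rep
    parts = []
    for a, b in enable_intervals(cfg, frame_index):
        k0 = int(np.ceil(a * f_rep - 1e-9))
        k1 = int(np.floor(b * f_rep + 1e-9))
        if k1 >= k0:
            parts.append(np.arange(max(k0, 0), k1 + 1, dtype=np.int64))
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def scan_position(t, frame: FrameMeta, cfg: ScanConfig, from_meta: bool = False):
    """Instantaneous scan position (um) at pulse time(s) ``t`` within a frame.

    x follows the mirror closed form, z the TAG phase, and y is the
    galvo line held constant within the frame.  With ``from_meta=True``
    the TAG phase is re-derived from the frame's recorded phase delay
    (``delta_phi`` plus the elapsed time since ``t_start``) instead of the
    global clock — the route reconstruction uses, mirroring how the real
    instrument predicts the pattern from the measured TTL timing.
    """
    t = np.asarray(t, dtype=float)
    g = cfg.geometry
    x = rm_position(t, cfg)
    if from_meta:
        phi = np.mod(frame.delta_phi + TWO_PI * cfg.clocks.f_tag * (t - frame.t_start), TWO_PI)
    else:
        phi = tag_phase(t, cfg)
    z = z_position(phi, g.z_range)
    y = np.full_like(x, (frame.y_index + 0.5) / g.n_y * g.fov_y - g.fov_y / 2)
    return np.stack([x, y, z], axis=-1)


def simulate_acquisition(
    phantom: Phantom,
    cfg: ScanConfig,
    n_volumes: int = 1,
    seed: int = 0,
    noise: bool = True,
    start_volume: int = 0,
) -> RawStream:
    """Simulate ``n_volumes`` volumetric acquisitions of ``phantom``.

    Frames are mirror periods; volume ``v`` comprises frames
    ``v*n_y .. (v+1)*n_y - 1``.  ``start_volume`` offsets the absolute
    time axis so long acquisitions can be simulated volume by volume:
    the noise generator is seeded per frame from ``(seed, frame_index)``,
    making chunked simulation bit-identical to a single call.

    Raises ``ValueError`` if the configuration yields frames with no
    enabled pulses.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    n_y = cfg.geometry.n_y
    f_rep = cfg.clocks.f_rep
    first = start_volume * n_y
    frames: list[FrameMeta] = []
    idx_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []
    bounds = [0]
    for fi in range(first, first + n_volumes * n_y):
        meta = frame_meta(cfg, fi)
        k = enabled_pulse_indices(cfg, fi)
        if k.size == 0:
            raise ValueError(
                f"frame {fi} has no enabled pulses (duty {cfg.enable.duty:g} too small "
                f"for f_rep/f_rm = {f_rep / cfg.clocks.f_rm:g})"
            )
        t = k / f_rep
        pos = scan_position(t, meta, cfg)
        mean = intensity_at(phantom, pos, t) * phantom.photons_per_pulse
        if noise:
            rng = np.random.default_rng([seed, fi])
            vals = rng.poisson(mean).astype(np.float64)
        else:
            vals = np.asarray(mean, dtype=np.float64)
        frames.append(meta)
        idx_parts.append(k)
        val_parts.append(vals)
        bounds.append(bounds[-1] + k.size)
    return RawStream(
        config=cfg,
        seed=seed,
        pulse_index=np.concatenate(idx_parts),
        values=np.concatenate(val_parts),
        frame_bounds=np.asarray(bounds, dtype=np.int64),
        frames=frames,
    )
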