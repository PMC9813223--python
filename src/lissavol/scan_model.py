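"""Timing, geometry and trajectory model for dual-resonant volumetric scanning.

A pulsed laser (repetition rate ``f_rep``) clocks acquisition at one sample
per pulse while two resonant devices sweep the focus: a resonant mirror (RM,
frequency ``f_rm``) scans x sinusoidally and an ultrasound (TAG) lens
(frequency ``f_tag``) scans z sinusoidally.  A slow galvanometer steps y one
line per mirror period.  Because ``f_tag / f_rm`` is in general not an
integer, the x-z trajectory is a Lissajous figure whose pattern drifts from
frame to frame; the drift is fully described by the TAG phase ``delta_phi``
at the instant each frame's pixel-enable window opens.

This module holds the configuration types, the harmonic trajectory closed
forms, the enable-window geometry, and the analytic system-design
calculators (pulse/line budgets, rates, aperture coverage, resolution
degradation, alias folding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClockConfig",
    "Geometry",
    "EnableWindow",
    "ScanConfig",
    "FrameMeta",
    "rm_position",
    "tag_phase",
    "z_position",
    "enable_intervals",
    "phase_delay",
    "frame_meta",
    "pulses_per_frame",
    "tag_lines_per_frame",
    "frame_and_volume_rate",
    "aperture_coverage",
    "resolution_degradation",
    "alias_frequency",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ClockConfig:
    """The three clocks of the system, all in Hz.

    ``f_rep``
        laser repetition rate; one intensity sample is taken per pulse.
    ``f_rm``
        resonant-mirror frequency; one x-z frame per mirror period.
    ``f_tag``
        TAG-lens resonant frequency (axial scan).

    The sampling clock must outrun both scanners: ``f_rep > f_tag > f_rm``.
    """

    f_rep: float = 80e6
    f_rm: float = 7834.0
    f_tag: float = 456e3

    def __post_init__(self) -> None:
        if not (self.f_rep > 0 and self.f_rm > 0 and self.f_tag > 0):
            raise ValueError("all clock frequencies must be strictly positive")
        if not (self.f_rep > self.f_tag > self.f_rm):
            raise ValueError(
                f"clocks must satisfy f_rep > f_tag > f_rm, got "
                f"{self.f_rep:g} / {self.f_tag:g} / {self.f_rm:g}"
            )


@dataclass(frozen=True)
class Geometry:
    """Sample-space extents (um) and voxel grid of the reconstruction.

    ``rm_amplitude`` is the mirror half-swing in sample space.  When left
    ``None`` it is derived from the field of view and the enable-window duty
    so that the gated (near-linear) part of the sweep exactly spans
    ``fov_x`` — see :meth:`ScanConfig.rm_amplitude`.  ``z_range`` is the
    peak-to-peak axial scan range of the TAG lens and must equal ``fov_z``.
    """

    fov_x: float = 343.0
    fov_y: float = 343.0
    fov_z: float = 120.0
    n_x: int = 256
    n_y: int = 256
    n_z: int = 80
    rm_amplitude: float | None = None
    z_range: float | None = None

    def __post_init__(self) -> None:
        if min(self.fov_x, self.fov_y, self.fov_z) <= 0:
            raise ValueError("fields of view must be positive")
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ValueError("grid counts must be >= 1")
        if self.z_range is None:
            object.__setattr__(self, "z_range", self.fov_z)
        if self.z_range != self.fov_z:
            raise ValueError("z_range must equal fov_z (the axial FOV is the TAG scan range)")
        if self.rm_amplitude is not None and self.rm_amplitude < self.fov_x / 2:
            raise ValueError("rm_amplitude must be >= fov_x/2")

    @property
    def grid(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y * self.n_z


@dataclass(frozen=True)
class EnableWindow:
    """Pixel-enable gating of the resonant mirror sweep.

    ``duty`` is the enabled fraction of each mirror period; the windows are
    centered on the zero crossings of the swing, where the motion is
    fastest and most nearly linear.  ``bidirectional`` gates both
    half-sweeps of the period (two windows of length ``duty/2`` periods
    each); otherwise a single window of ``duty`` periods covers one sweep.
    """

    duty: float = 0.65
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.duty <= 1.0):
            raise ValueError("duty must lie in (0, 1]")


@dataclass(frozen=True)
class ScanConfig:
    """Full scan configuration: clocks + geometry + enable window + phase.

    ``tag_phase0`` is the TAG oscillation phase (rad) at t = 0, i.e. at the
    first laser pulse.  The TTL rising edge of the TAG driver defines phase
    zero; z = 0 at mid-range.
    """

    clocks: ClockConfig = field(default_factory=ClockConfig)
    geometry: Geometry = field(default_factory=Geometry)
    enable: EnableWindow = field(default_factory=EnableWindow)
    tag_phase0: float = 0.0

    # -- derived quantities ------------------------------------------------

    @property
    def frame_period(self) -> float:
        """Duration of one x-z frame (one mirror period), s."""
        return 1.0 / self.clocks.f_rm

    @property
    def window_half_phase(self) -> float:
        """Mirror phase half-width of one enable window, rad (capped at pi/2)."""
        d = self.enable.duty
        half = math.pi * d / 2 if self.enable.bidirectional else math.pi * d
        return min(half, math.pi / 2)

    @property
    def rm_amplitude(self) -> float:
        """Mirror half-swing A (um); gated sweep spans exactly fov_x."""
        if self.geometry.rm_amplitude is not None:
            return self.geometry.rm_amplitude
        return (self.geometry.fov_x / 2) / math.sin(self.window_half_phase)

    @property
    def pulses_per_frame(self) -> int:
        return pulses_per_frame(self.clocks.f_rep, self.clocks.f_rm)

    @property
    def tag_lines_per_frame(self) -> int:
        return tag_lines_per_frame(self.clocks.f_tag, self.clocks.f_rm)

    @property
    def frame_rate(self) -> float:
        return self.clocks.f_rm

    @property
    def volume_rate(self) -> float:
        return self.clocks.f_rm / self.geometry.n_y

    @property
    def volume_period(self) -> float:
        return self.geometry.n_y / self.clocks.f_rm

    def with_(self, **kw) -> "ScanConfig":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class FrameMeta:
    """Per-frame synchronization record.

    ``delta_phi`` is the TAG phase at ``t_start``, the opening of the
    frame's first enable window — the quantity the real instrument measures
    from the TTL/pixel-enable timing and from which each frame's Lissajous
    pattern is predicted.
    """

    frame_index: int
    y_index: int
    t_start: float
    delta_phi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_phi < TWO_PI):
            raise ValueError("delta_phi must lie in [0, 2*pi)")
        if self.frame_index < 0 or self.y_index < 0:
            raise ValueError("indices must be nonnegative")


# ---------------------------------------------------------------------------
# trajectory closed forms
# ---------------------------------------------------------------------------

def rm_position(t, cfg: ScanConfig):
    """Lateral mirror position x(t) = A sin(2 pi f_rm t), um."""
    t = np.asarray(t, dtype=float)
    return cfg.rm_amplitude * np.sin(TWO_PI * cfg.clocks.f_rm * t)


def tag_phase(t, cfg: ScanConfig):
    """TAG oscillation phase (2 pi f_tag t + tag_phase0) mod 2 pi, in [0, 2 pi)."""
    t = np.asarray(t, dtype=float)
    return np.mod(TWO_PI * cfg.clocks.f_tag * t + cfg.tag_phase0, TWO_PI)


def z_position(phi, z_range: float):
    """Axial focus position z = (Z/2) sin(phi), um, for peak-to-peak range Z."""
    if z_range <= 0:
        raise ValueError("z_range must be positive")
    return (z_range / 2.0) * np.sin(np.asarray(phi, dtype=float))


# ---------------------------------------------------------------------------
# enable windows and phase delay
# ---------------------------------------------------------------------------

def enable_intervals(cfg: ScanConfig, frame_index: int) -> list[tuple[float, float]]:
    """Enable windows (s) of frame ``frame_index``, as (start, end) pairs.

    Frame ``i`` spans one mirror period.  Bidirectional gating opens two
    windows of length ``duty * T / 2`` centered on the down-crossing at
    ``i*T + T/2`` and the up-crossing at ``(i+1)*T``; unidirectional gating
    opens one window of length ``duty * T`` centered on the down-crossing.
    All window times are nonnegative for ``frame_index >= 0`` and the total
    enabled time is exactly ``duty / f_rm``.
    """
    if frame_index < 0:
        raise ValueError("frame_index must be >= 0")
    T = cfg.frame_period
    d = cfg.enable.duty
    i = frame_index
    if cfg.enable.bidirectional:
        half = d * T / 4
        centers = (i * T + T / 2, (i + 1) * T)
    else:
        half = d * T / 2
        centers = (i * T + T / 2,)
    return [(c - half, c + half) for c in centers]


def frame_time_span(cfg: ScanConfig, frame_index: int) -> tuple[float, float]:
    """The mirror period [start, end) owning frame ``frame_index``'s windows."""
    T = cfg.frame_period
    if cfg.enable.bidirectional:
        return (frame_index * T + T / 4, (frame_index + 1) * T + T / 4)
    return (frame_index * T, (frame_index + 1) * T)


def phase_delay(t_start: float, cfg: ScanConfig) -> float:
    """Phase delay of the TAG oscillation at the enable-window opening.

    Constant across frames iff ``f_tag / f_rm`` is an integer; otherwise
    consecutive frames drift by ``2 pi frac(f_tag / f_rm)``, which is what
    makes the Lissajous pattern vary frame to frame.
    """
    return float(tag_phase(t_start, cfg))


def frame_meta(cfg: ScanConfig, frame_index: int) -> FrameMeta:
    """Synchronization metadata of frame ``frame_index``."""
    t_start = enable_intervals(cfg, frame_index)[0][0]
    return FrameMeta(
        frame_index=frame_index,
        y_index=frame_index % cfg.geometry.n_y,
        t_start=t_start,
        delta_phi=phase_delay(t_start, cfg),
    )


# ---------------------------------------------------------------------------
# design calculators
# ---------------------------------------------------------------------------

def pulses_per_frame(f_rep: float, f_rm: float) -> int:
    """Laser pulses available per x-z frame: round(f_rep / f_rm)."""
    if f_rep <= 0 or f_rm <= 0:
        raise ValueError("frequencies must be positive")
    if f_rm > f_rep:
        raise ValueError("mirror cannot outrun the laser (f_rm > f_rep)")
    return max(1, round(f_rep / f_rm))


def tag_lines_per_frame(f_tag: float, f_rm: float) -> int:
    """Complete TAG axial scan lines per frame: floor(f_tag / f_rm)."""
    if f_tag <= 0 or f_rm <= 0:
        raise ValueError("frequencies must be positive")
    return int(f_tag // f_rm)


def frame_and_volume_rate(cfg: ScanConfig) -> tuple[float, float]:
    """(frames/s, volumes/s): one frame per mirror period, n_y frames per volume."""
    return (cfg.frame_rate, cfg.volume_rate)


def aperture_coverage(d_eff: float, m_relay: float, d_back: float) -> float:
    """Fraction of the objective back aperture filled by the relayed beam.

    ``d_eff``: effective aperture of the TAG lens (mm); ``m_relay``: relay
    beam expansion; ``d_back``: objective back-aperture diameter (mm).
    Clipped at 1 when the expanded beam overfills the aperture.
    """
    if min(d_eff, m_relay, d_back) <= 0:
        raise ValueError("all optics parameters must be positive")
    return min(1.0, d_eff * m_relay / d_back)


def resolution_degradation(coverage: float) -> tuple[float, float]:
    """(lateral, axial) resolution degradation factors from underfilling.

    Underfilling the back aperture by a factor C reduces the effective NA
    by C, degrading lateral resolution by 1/C and axial by 1/C^2.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    return (1.0 / coverage, 1.0 / coverage**2)


def alias_frequency(f_signal: float, f_sample: float) -> float:
    """Apparent frequency of ``f_signal`` sampled at ``f_sample``.

    Folds the signal into the first Nyquist zone [0, f_sample/2]; signals
    below the Nyquist bound are returned unchanged.
    """
    if f_signal <= 0 or f_sample <= 0:
        raise ValueError("frequencies must be positive")
    r = math.fmod(f_signal, f_sample)
    return min(r, f_sample - r)
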