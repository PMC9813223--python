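"""Dynamic-imaging analytics and design-report assembly.

Centroid tracking turns a sequence of reconstructed volumes into a
displacement signal sampled at the volumetric rate; its discrete Fourier
spectrum reveals the apparent motion frequency, which for drives above
the Nyquist bound (half the volume rate) is the aliased fold-back.  The
axial-profile FWHM estimator re-measures the configured TAG scan range
from a simulated thin-film stage sweep, and ``design_report`` bundles the
analytic system calculators into one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconstruction import Volume
from .scan_model import (
    ScanConfig,
    aperture_coverage,
    frame_and_volume_rate,
    pulses_per_frame,
    resolution_degradation,
    tag_lines_per_frame,
)

__all__ = [
    "Track",
    "SpectrumResult",
    "track_centroid",
    "temporal_spectrum",
    "fit_harmonic_amplitude",
    "axial_profile_fwhm",
    "design_report",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Track:
    """Centroid positions (um, shape (n, 3)) vs mid-volume times (s).

    Entries from all-missing volumes are NaN and flagged in ``valid``.
    """

    times: np.ndarray
    positions: np.ndarray
    valid: np.ndarray

    def displacement(self, axis: str = "z") -> np.ndarray:
        return self.positions[:, _AXES[axis]]

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class SpectrumResult:
    """One-sided normalized magnitude spectrum of a displacement signal."""

    freqs: np.ndarray
    power: np.ndarray
    peak_freq: float


def _voxel_centers(cfg: ScanConfig, grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = cfg.geometry
    out = []
    for fov, n in ((g.fov_x, grid[0]), (g.fov_y, grid[1]), (g.fov_z, grid[2])):
        out.append((np.arange(n) + 0.5) / n * fov - fov / 2)
    return tuple(out)


def volume_centroid(volume: Volume) -> np.ndarray:
    """Signal-weighted centroid (um) over non-missing voxels; NaN if empty.

    The weight of a voxel is its total collected signal (mean value times
    hit count), so densely dwelled voxels do not dominate by dwell alone.
    """
    w = np.where(volume.hits > 0, volume.values * volume.hits, 0.0)
    total = w.sum()
    if total <= 0:
        return np.full(3, np.nan)
    cx, cy, cz = _voxel_centers(volume.config, volume.grid)
    return np.array(
        [
            (w.sum(axis=(1, 2)) * cx).sum() / total,
            (w.sum(axis=(0, 2)) * cy).sum() / total,
            (w.sum(axis=(0, 1)) * cz).sum() / total,
        ]
    )


def track_centroid(volumes) -> Track:
    """Track the signal-weighted centroid across an ordered volume sequence.

    Accepts any iterable of :class:`Volume` (including a lazily generated
    stream), so long acquisitions never need to be held in memory at once.
    """
    times, positions = [], []
    for v in volumes:
        times.append(v.t_mid)
        positions.append(volume_centroid(v))
    if not times:
        raise ValueError("need at least one volume")
    times = np.asarray(times)
    positions = np.asarray(positions)
    valid = ~np.isnan(positions).any(axis=1)
    return Track(times=times, positions=positions, valid=valid)


def temporal_spectrum(track: Track, axis: str = "z", window: str | None = None) -> SpectrumResult:
    """FFT magnitude spectrum of the mean-subtracted displacement.

    Requires >= 8 uniformly spaced time points; the spectrum is normalized
    to unit maximum and the peak is searched over non-DC bins only (the
    mean offset otherwise dominates).  ``window="hann"`` applies a Hann
    taper; by default no window is used (short records, leakage accepted).
    """
    if track.times.size < 8:
        raise ValueError("need at least 8 time points")
    dt = np.diff(track.times)
    if not np.allclose(dt, dt.mean(), rtol=1e-6, atol=1e-12):
        raise ValueError("time points must be uniformly spaced")
    y = track.displacement(axis)
    if np.isnan(y).any():
        raise ValueError("track contains invalid (all-missing) entries")
    y = y - y.mean()
    if window == "hann":
        y = y * np.hanning(y.size)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    rate = 1.0 / float(dt.mean())
    mag = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(y.size, d=1.0 / rate)
    peak = mag.max()
    power = mag / peak if peak > 0 else mag
    peak_freq = float(freqs[1:][np.argmax(power[1:])]) if freqs.size > 1 else 0.0
    return SpectrumResult(freqs=freqs, power=power, peak_freq=peak_freq)


def fit_harmonic_amplitude(track: Track, frequency: float, axis: str = "z") -> float:
    """Least-squares amplitude of a known-frequency sinusoid in the track."""
    t = track.times[track.valid]
    y = track.displacement(axis)[track.valid]
    design = np.column_stack(
        [np.sin(2 * np.pi * frequency * t), np.cos(2 * np.pi * frequency * t), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def axial_profile_fwhm(z: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum of an intensity-vs-z profile, um.

    Half-max crossings are located by linear interpolation on each side of
    the peak; raises if the profile never crosses half maximum on both
    sides (no measurable width).
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if z.size != y.size or z.size < 3:
        raise ValueError("need matching z/intensity arrays of length >= 3")
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    below_l = np.nonzero(y[: ipk + 1] < half)[0]
    below_r = np.nonzero(y[ipk:] < half)[0]
    if below_l.size == 0 or below_r.size == 0:
        raise ValueError("profile never crosses half maximum on both sides")
    i = below_l[-1]
    z_l = z[i] + (half - y[i]) / (y[i + 1] - y[i]) * (z[i + 1] - z[i])
    j = ipk + below_r[0]
    z_r = z[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (z[j] - z[j - 1])
    return float(z_r - z_l)


def design_report(cfg: ScanConfig, optics: dict | None = None) -> pd.DataFrame:
    """System-design summary: budgets, rates, Nyquist bound, optics coverage.

    ``optics`` rows are dicts with keys ``name``, ``d_eff`` (mm),
    ``m_relay`` and ``d_back`` (mm); each contributes beam size, aperture
    coverage and the resulting lateral/axial resolution degradation.
    """
    frame_rate, volume_rate = frame_and_volume_rate(cfg)
    rows = [
        ("pulses per frame", pulses_per_frame(cfg.clocks.f_rep, cfg.clocks.f_rm), ""),
        ("frame exposure time", 1.0 / cfg.clocks.f_rm * 1e3, "ms"),
        ("TAG lines per frame", tag_lines_per_frame(cfg.clocks.f_tag, cfg.clocks.f_rm), ""),
        ("frame rate", frame_rate, "fps"),
        ("volume rate", volume_rate, "vps"),
        ("Nyquist bound", volume_rate / 2.0, "Hz"),
        ("enabled pulses per frame", round(cfg.enable.duty * cfg.clocks.f_rep / cfg.clocks.f_rm), ""),
    ]
    if optics:
        for o in ([optics] if isinstance(optics, dict) else list(optics)):
            cov = aperture_coverage(o["d_eff"], o["m_relay"], o["d_back"])
            lat, ax = resolution_degradation(cov)
            name = o.get("name", "optics")
            rows += [
                (f"{name}: expanded beam", o["d_eff"] * o["m_relay"], "mm"),
                (f"{name}: back-aperture coverage", cov, ""),
                (f"{name}: lateral degradation", lat, "x"),
                (f"{name}: axial degradation", ax, "x"),
            ]
    return pd.DataFrame(rows, columns=["quantity", "value", "units"])
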