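"""End-to-end simulation pipelines (acquire -> reconstruct -> analyze).

These helpers run long acquisitions volume by volume so that only one
volume's raw stream is ever resident: per-frame noise seeding makes the
chunked simulation bit-identical to a single monolithic call.
"""

from __future__ import annotations

from typing import Iterator

from .acquisition import simulate_acquisition
from .metrics import Track, track_centroid
from .phantom import Phantom
from .reconstruction import Volume, reconstruct_volume
from .scan_model import ScanConfig

__all__ = ["iter_volumes", "simulate_volumes", "simulate_track"]


def iter_volumes(
    phantom: Phantom,
    cfg: ScanConfig,
    n_volumes: int,
    seed: int = 0,
    noise: bool = True,
    grid=None,
) -> Iterator[Volume]:
    """Lazily yield reconstructed volumes of a continuous acquisition."""
    for v in range(n_volumes):
        stream = simulate_acquisition(
            phantom, cfg, n_volumes=1, seed=seed, noise=noise, start_volume=v
        )
        yield reconstruct_volume(stream, volume_index=v, grid=grid)


def simulate_volumes(phantom, cfg, n_volumes, seed=0, noise=True, grid=None) -> list[Volume]:
    """Eager version of :func:`iter_volumes`."""
    return list(iter_volumes(phantom, cfg, n_volumes, seed=seed, noise=noise, grid=grid))


def simulate_track(
    phantom: Phantom,
    cfg: ScanConfig,
    n_volumes: int,
    seed: int = 0,
    noise: bool = True,
) -> Track:
    """Full-pipeline centroid track: simulate, reconstruct, and track a
    moving phantom over ``n_volumes`` consecutive volumes."""
    return track_centroid(iter_volumes(phantom, cfg, n_volumes, seed=seed, noise=noise))
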