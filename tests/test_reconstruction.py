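"""Nearest-voxel mapping, volume assembly, rebinning and accumulation."""

import numpy as np
import pytest

from lissavol import (
    ClockConfig,
    Geometry,
    RawStream,
    ScanConfig,
    accumulate,
    bead_10um,
    fill_ratio,
    map_sample_to_voxel,
    rebin_grid,
    reconstruct_volume,
    simulate_acquisition,
)
from lissavol.acquisition import enabled_pulse_indices, scan_position
from lissavol.reconstruction import Volume, slice_fill_ratios
from lissavol.scan_model import enable_intervals, frame_meta


def _single_sample_stream(cfg, t, value):
    """A stream holding one enabled pulse in frame 0 (n_y must be 1)."""
    k = int(round(t * cfg.clocks.f_rep))
    return RawStream(
        config=cfg,
        seed=0,
        pulse_index=np.array([k], dtype=np.int64),
        values=np.array([value]),
        frame_bounds=np.array([0, 1], dtype=np.int64),
        frames=[frame_meta(cfg, 0)],
    )


@pytest.fixture(scope="module")
def line_cfg():
    return ScanConfig(clocks=ClockConfig(f_rep=8e6), geometry=Geometry(n_y=1))


class TestVoxelMapping:
    def test_center_of_grid(self, default_cfg):
        """The mirror zero crossing with TAG phase ~0 maps to the central
        half-open bins (128, iy, 40) of the 256 x 256 x 80 grid."""
        c = 0.5 / default_cfg.clocks.f_rm  # down-sweep mirror zero crossing
        t_q = c - 1e-10  # a hair early: x is positive but far below one bin
        # phase the TAG lens so z is likewise tiny and positive at t_q
        cfg = default_cfg.with_(
            tag_phase0=(1e-4 - 2 * np.pi * default_cfg.clocks.f_tag * t_q) % (2 * np.pi)
        )
        meta = frame_meta(cfg, 0)
        ix, iy, iz = map_sample_to_voxel(t_q, meta, cfg)
        assert (int(ix), int(iy), int(iz)) == (128, meta.y_index, 40)

    def test_window_edge_maps_to_grid_edge(self, default_cfg):
        meta = frame_meta(default_cfg, 0)
        (a, b), _ = enable_intervals(default_cfg, 0)
        # down-sweep window: x = +fov/2 at opening, -fov/2 at closing
        ix_a, _, _ = map_sample_to_voxel(a, meta, default_cfg)
        ix_b, _, _ = map_sample_to_voxel(b, meta, default_cfg)
        assert {int(ix_a), int(ix_b)} == {0, 255}

    def test_halfopen_binning_arithmetic(self):
        # x = 100 um in a 343-um FOV of 256 bins: floor(271.5/343*256) = 202
        assert int(np.floor((100 + 343 / 2) / 343 * 256)) == 202

    def test_rejects_times_outside_enable_windows(self, default_cfg):
        meta = frame_meta(default_cfg, 0)
        (a, _), _ = enable_intervals(default_cfg, 0)
        with pytest.raises(ValueError, match="outside"):
            map_sample_to_voxel(a - 1e-6, meta, default_cfg)

    def test_matches_brute_force_nearest_center_search(self, default_cfg):
        """Half-open binning == nearest-voxel-center on 10^4 random samples."""
        rng = np.random.default_rng(2024)
        g = default_cfg.geometry
        centers = {
            "x": (np.arange(g.n_x) + 0.5) / g.n_x * g.fov_x - g.fov_x / 2,
            "y": (np.arange(g.n_y) + 0.5) / g.n_y * g.fov_y - g.fov_y / 2,
            "z": (np.arange(g.n_z) + 0.5) / g.n_z * g.fov_z - g.fov_z / 2,
        }
        n_checked = 0
        for fi in rng.integers(0, 512, size=5):
            meta = frame_meta(default_cfg, int(fi))
            k = enabled_pulse_indices(default_cfg, int(fi))
            k = rng.choice(k, size=2000, replace=False)
            t = np.sort(k) / default_cfg.clocks.f_rep
            ix, iy, iz = map_sample_to_voxel(t, meta, default_cfg)
            pos = scan_position(t, meta, default_cfg, from_meta=True)
            for axis, idx, key in ((0, ix, "x"), (1, iy, "y"), (2, iz, "z")):
                brute = np.argmin(
                    np.abs(pos[:, axis][:, None] - centers[key][None, :]), axis=1
                )
                assert np.array_equal(idx, brute)
            n_checked += t.size
        assert n_checked >= 10_000


class TestVolumeAssembly:
    def test_sample_count_conservation(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=1)
        vol = reconstruct_volume(stream, 0)
        assert vol.hits.sum() == stream.n_samples

    def test_single_sample_volume(self, line_cfg):
        (a, b), _ = enable_intervals(line_cfg, 0)
        stream = _single_sample_stream(line_cfg, (a + b) / 2, 3.5)
        vol = reconstruct_volume(stream, 0)
        assert np.count_nonzero(vol.hits) == 1
        assert vol.values[vol.hits > 0] == pytest.approx([3.5])
        assert np.isnan(vol.values[vol.hits == 0]).all()

    def test_empty_stream_gives_empty_volume(self, line_cfg):
        stream = RawStream(
            config=line_cfg,
            seed=0,
            pulse_index=np.empty(0, dtype=np.int64),
            values=np.empty(0),
            frame_bounds=np.array([0, 0], dtype=np.int64),
            frames=[frame_meta(line_cfg, 0)],
        )
        vol = reconstruct_volume(stream, 0)
        assert fill_ratio(vol) == 0.0
        assert np.isnan(vol.t_mid)

    def test_multi_hit_voxels_average_not_sum(self, line_cfg):
        (a, b), _ = enable_intervals(line_cfg, 0)
        c = (a + b) / 2
        dt = 1 / line_cfg.clocks.f_rep
        k = np.array([round(c / dt), round(c / dt) + 1], dtype=np.int64)
        stream = RawStream(
            config=line_cfg, seed=0, pulse_index=k, values=np.array([1.0, 3.0]),
            frame_bounds=np.array([0, 2], dtype=np.int64), frames=[frame_meta(line_cfg, 0)],
        )
        vol = reconstruct_volume(stream, 0, grid=(1, 1, 1))
        assert vol.values[0, 0, 0] == pytest.approx(2.0)  # mean, not 4.0
        assert vol.hits[0, 0, 0] == 2

    def test_static_bead_centroid_within_one_voxel(self, small_cfg):
        from lissavol.metrics import volume_centroid

        ph = bead_10um(center=(5.0, -4.0, 10.0))
        stream = simulate_acquisition(ph, small_cfg, 1, seed=0, noise=False)
        c = volume_centroid(reconstruct_volume(stream, 0))
        g = small_cfg.geometry
        voxel = np.array([g.fov_x / g.n_x, g.fov_y / g.n_y, g.fov_z / g.n_z])
        assert np.all(np.abs(c - [5.0, -4.0, 10.0]) <= voxel)


class TestRebinning:
    def test_single_voxel_grid_is_full(self, line_cfg):
        (a, b), _ = enable_intervals(line_cfg, 0)
        stream = _single_sample_stream(line_cfg, (a + b) / 2, 1.0)
        assert fill_ratio(rebin_grid(stream, 1, 1, 1)) == 1.0

    def test_coarser_grid_never_less_filled(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=0)
        fills = [
            fill_ratio(rebin_grid(stream, nx, nx, 80))
            for nx in (512, 256, 128, 64, 32)
        ]
        assert all(b >= a for a, b in zip(fills, fills[1:]))

    def test_rebin_conserves_samples(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=0)
        assert rebin_grid(stream, 64, 64, 20).hits.sum() == stream.n_samples


class TestAccumulation:
    def test_single_volume_identity(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=0)
        vol = reconstruct_volume(stream, 0)
        acc = accumulate([vol])
        assert np.array_equal(acc.hits, vol.hits)
        assert np.allclose(acc.values, vol.values, equal_nan=True)

    def test_disjoint_masks_add_fills(self):
        cfg = ScanConfig()
        mk = lambda sl: Volume(
            values=np.where(sl, 1.0, np.nan), hits=sl.astype(np.int64),
            config=cfg, t_mid=0.0,
        )
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[:2], b[2:] = True, True
        acc = accumulate([mk(a), mk(b)])
        assert fill_ratio(acc) == pytest.approx(fill_ratio(mk(a)) + fill_ratio(mk(b)))

    def test_values_are_hit_weighted_means(self):
        cfg = ScanConfig()
        v1 = Volume(values=np.full((1, 1, 1), 2.0), hits=np.full((1, 1, 1), 3), config=cfg, t_mid=0.0)
        v2 = Volume(values=np.full((1, 1, 1), 6.0), hits=np.full((1, 1, 1), 1), config=cfg, t_mid=1.0)
        acc = accumulate([v1, v2])
        assert acc.values[0, 0, 0] == pytest.approx(3.0)  # (2*3 + 6*1)/4
        assert acc.hits[0, 0, 0] == 4

    def test_fill_monotone_in_accumulated_volumes(self, small_cfg):
        from lissavol import simulate_volumes

        vols = simulate_volumes(bead_10um(), small_cfg, 3, seed=0)
        fills = [fill_ratio(accumulate(vols[: n + 1])) for n in range(3)]
        assert fills == sorted(fills)

    def test_mismatched_grids_rejected(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=0)
        v1 = reconstruct_volume(stream, 0)
        v2 = rebin_grid(stream, 64, 64, 80)
        with pytest.raises(ValueError, match="grid"):
            accumulate([v1, v2])


class TestFillRatio:
    def test_extremes_and_half(self):
        cfg = ScanConfig()
        hits = np.zeros((2, 2, 2), dtype=np.int64)
        vol = Volume(values=np.full((2, 2, 2), np.nan), hits=hits, config=cfg, t_mid=0.0)
        assert fill_ratio(vol) == 0.0
        hits[0] = 1
        assert fill_ratio(vol) == 0.5
        hits[:] = 2
        assert fill_ratio(vol) == 1.0

    def test_slice_ratios_bracket_volume_ratio(self, small_cfg):
        stream = simulate_acquisition(bead_10um(), small_cfg, 1, seed=0)
        vol = reconstruct_volume(stream, 0)
        per_slice = slice_fill_ratios(vol)
        assert per_slice.shape == (small_cfg.geometry.n_z,)
        assert per_slice.min() <= fill_ratio(vol) <= per_slice.max()

    def test_ten_volume_fill_stays_below_independence_bound(self, default_cfg):
        """Accumulated fill of N volumes cannot exceed the independent-pattern
        prediction 1-(1-p)^N by more than a small correlation slack; by ten
        volumes the drifting Lissajous patterns overlap strongly and the
        measured fill falls well short of the independent bound."""
        from lissavol import iter_volumes

        fills = []
        acc = None
        for vol in iter_volumes(bead_10um(), default_cfg, 10, seed=0, noise=False):
            acc = vol if acc is None else accumulate([acc, vol])
            fills.append(fill_ratio(acc))
        p1 = fills[0]
        for n, f in enumerate(fills, start=1):
            assert f <= 1 - (1 - p1) ** n + 0.02
        assert fills[-1] < 1 - (1 - p1) ** 10
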