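"""ROI grid, dF/F0 traces, and active-site calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nircat.roi import build_grid, call_active, extract_traces, site_density
from nircat.stack_io import FluorescenceStack
from nircat.synthetic import (
    AcquisitionProtocol,
    GroundTruthManifest,
    HotspotSpec,
    NoiseModel,
    manifest_for_density,
    simulate_movie,
)


@pytest.mark.parametrize(
    "fov_w, fov_h, tile, expected",
    [
        (178, 142, 7, 26 * 21),   # the standard field of view
        (70, 70, 7, 100),         # exact division, all full tiles
        (178, 142, 10, 18 * 15),  # ceiling arithmetic with edge remainders
        (178, 142, 4, 45 * 36),
        (5, 5, 7, 1),             # tile larger than FOV -> single tile
    ],
)
def test_grid_tile_counts(fov_w, fov_h, tile, expected):
    grid = build_grid(fov_w, fov_h, tile, 0.5)
    assert grid.n_tiles == expected
    assert grid.n_tiles == math.ceil(fov_w / tile) * math.ceil(fov_h / tile)


def test_grid_rejects_nonpositive():
    with pytest.raises(ValueError):
        build_grid(178, 142, 0, 0.5)
    with pytest.raises(ValueError):
        build_grid(-1, 142, 7, 0.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    fov_w=st.floats(min_value=4, max_value=80),
    fov_h=st.floats(min_value=4, max_value=80),
    tile=st.floats(min_value=1.0, max_value=25),
    umpp=st.sampled_from([0.5, 1.0]),
)
def test_grid_is_exact_partition(fov_w, fov_h, tile, umpp):
    """Every pixel belongs to exactly one tile; areas sum to the frame."""
    grid = build_grid(fov_w, fov_h, tile, umpp)
    cover = np.zeros((grid.n_rows_px, grid.n_cols_px), dtype=int)
    for t in grid.tiles:
        cover[t.row0 : t.row1, t.col0 : t.col1] += 1
    assert np.all(cover == 1)
    assert sum(t.n_pixels for t in grid.tiles) == grid.n_rows_px * grid.n_cols_px


def test_constant_stack_gives_zero_dff(small_protocol):
    data = np.full((small_protocol.n_frames, small_protocol.n_rows, small_protocol.n_cols), 321.0)
    stack = FluorescenceStack(data=data, protocol=small_protocol)
    grid = build_grid(30, 24, 7, 0.5)
    traces = extract_traces(stack, grid, small_protocol.stim_frame)
    for tr in traces:
        assert np.all(tr.dff == 0)
        assert tr.baseline_sd == 0
        assert tr.f0 == pytest.approx(321.0)


def test_traces_match_brute_force_pixel_loop(small_protocol):
    """Tile-mean traces equal an explicit per-pixel loop, to 1e-12."""
    m = GroundTruthManifest(
        hotspots=[HotspotSpec(center_um=(10.0, 10.0))],
        protocol=small_protocol,
        noise=NoiseModel(additive_sd=8.0),
        seed=5,
    )
    stack = simulate_movie(m)
    grid = build_grid(30, 24, 7, 0.5)
    stim = small_protocol.stim_frame
    traces = extract_traces(stack, grid, stim)
    for tr, tile in zip(traces, grid.tiles):
        pix = [
            stack.data[:, r, c]
            for r in range(tile.row0, tile.row1)
            for c in range(tile.col0, tile.col1)
        ]
        brute_raw = np.stack(pix).mean(axis=0)
        brute_f0 = brute_raw[:stim].mean()
        brute_dff = (brute_raw - brute_f0) / brute_f0
        assert np.max(np.abs(tr.raw - brute_raw)) < 1e-9  # counts-scale jitter only
        assert np.max(np.abs(tr.dff - brute_dff)) < 1e-12


def test_short_baseline_rejected(small_protocol):
    data = np.ones((small_protocol.n_frames, small_protocol.n_rows, small_protocol.n_cols))
    stack = FluorescenceStack(data=data, protocol=small_protocol)
    grid = build_grid(30, 24, 7, 0.5)
    with pytest.raises(ValueError, match="stim_frame"):
        extract_traces(stack, grid, 1)


def test_dff_gain_invariance(small_protocol):
    """Multiplying the whole stack by a gain leaves dF/F0 unchanged exactly."""
    m = GroundTruthManifest(
        hotspots=[HotspotSpec(center_um=(15.0, 12.0))],
        protocol=small_protocol,
        noise=NoiseModel(additive_sd=5.0),
        seed=1,
    )
    stack = simulate_movie(m)
    grid = build_grid(30, 24, 7, 0.5)
    t1 = extract_traces(stack, grid, small_protocol.stim_frame)
    scaled = FluorescenceStack(data=stack.data * 4.0, protocol=small_protocol)
    t2 = extract_traces(scaled, grid, small_protocol.stim_frame)
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a.dff, b.dff)


def test_noiseless_hotspot_tile_peak_matches_footprint_oracle(one_hotspot_manifest):
    """The tile peak equals the planted amplitude attenuated by averaging the
    Gaussian footprint over the tile, times the frame-sampled kinetic max."""
    m = one_hotspot_manifest
    p = m.protocol
    h = m.hotspots[0]
    stack = simulate_movie(m)
    grid = build_grid(p.fov_width_um, p.fov_height_um, 7.0, p.um_per_pixel)
    traces = extract_traces(stack, grid, p.stim_frame)
    peaks = [tr.dff[p.stim_frame :].max() for tr in traces]
    best = int(np.argmax(peaks))
    tile = grid.tiles[best]
    # oracle: footprint averaged over the tile's pixel centers
    xs = (np.arange(tile.col0, tile.col1) + 0.5) * p.um_per_pixel
    ys = (np.arange(tile.row0, tile.row1) + 0.5) * p.um_per_pixel
    gx = np.exp(-((xs - h.center_um[0]) ** 2) / (2 * h.footprint_sigma_um**2))
    gy = np.exp(-((ys - h.center_um[1]) ** 2) / (2 * h.footprint_sigma_um**2))
    atten = np.outer(gy, gx).mean()
    t_post = (np.arange(p.n_frames - p.stim_frame)) / p.frame_rate
    kin_max = ((1 - np.exp(-t_post / h.tau_on_s)) * np.exp(-t_post / h.tau_off_s)).max()
    expected = h.amplitude * kin_max * atten
    assert peaks[best] == pytest.approx(expected, rel=0.02)


class TestCallActive:
    def test_noiseless_no_hotspots_zero_active(self, small_protocol, quiet_noise):
        m = GroundTruthManifest(hotspots=[], protocol=small_protocol, noise=quiet_noise)
        stack = simulate_movie(m)
        grid = build_grid(30, 24, 7, 0.5)
        traces = extract_traces(stack, grid, small_protocol.stim_frame)
        calls = call_active(traces, small_protocol.stim_frame)
        assert sum(c.is_active for c in calls) == 0

    def test_monotone_in_k(self, small_protocol):
        m = manifest_for_density(
            40.0, seed=2, tile_um=7.0, protocol=small_protocol, noise=NoiseModel(additive_sd=10.0)
        )
        stack = simulate_movie(m)
        grid = build_grid(30, 24, 7, 0.5)
        traces = extract_traces(stack, grid, small_protocol.stim_frame)
        last = None
        for k in (1.0, 3.0, 10.0, 1e9):
            n_active = sum(c.is_active for c in call_active(traces, small_protocol.stim_frame, k=k))
            if last is not None:
                assert n_active <= last
            last = n_active
        assert last == 0  # k -> infinity kills every call

    def test_false_positive_rate_below_2pct(self):
        """No hotspots, default noise: expected active fraction < 2%.

        ~1000 tiles accumulated across seeds of a hotspot-free protocol."""
        protocol = AcquisitionProtocol(
            n_frames=150, stim_frame=50, fov_width_um=70.0, fov_height_um=70.0, um_per_pixel=0.5
        )
        grid = build_grid(70, 70, 7, 0.5)
        n_active = n_total = 0
        for seed in range(10):
            m = GroundTruthManifest(hotspots=[], protocol=protocol, noise=NoiseModel(), seed=seed)
            stack = simulate_movie(m)
            traces = extract_traces(stack, grid, protocol.stim_frame)
            calls = call_active(traces, protocol.stim_frame)
            n_active += sum(c.is_active for c in calls)
            n_total += len(calls)
        assert n_total == 1000
        assert n_active / n_total < 0.02


class TestSiteDensity:
    def _mock_calls(self, n_active, n_total):
        from nircat.roi import ActiveCall

        return [
            ActiveCall(roi_index=i, is_active=i < n_active, peak_dff=0.1, threshold=0.01)
            for i in range(n_total)
        ]

    def test_zero_and_half(self):
        grid = build_grid(178, 142, 7, 0.5)
        assert site_density(self._mock_calls(0, 546), grid) == 0.0
        assert site_density(self._mock_calls(273, 546), grid) == pytest.approx(50.0)

    def test_relabeling_invariance(self):
        import random

        grid = build_grid(178, 142, 7, 0.5)
        calls = self._mock_calls(100, 546)
        shuffled = calls[:]
        random.Random(0).shuffle(shuffled)
        assert site_density(calls, grid) == site_density(shuffled, grid)

    def test_call_count_mismatch(self):
        grid = build_grid(178, 142, 7, 0.5)
        with pytest.raises(ValueError):
            site_density(self._mock_calls(1, 10), grid)
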