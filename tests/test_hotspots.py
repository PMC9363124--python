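"""Hotspot segmentation: NNMF, clusters, centroids, widths, matching."""

import itertools

import numpy as np
import pytest

from dopafilm.errors import ConfigError, DataError
from dopafilm.baseline import BaselineParams, BaselineResult
from dopafilm.hotspots import (
    Hotspot,
    NnmfParams,
    _extract_cluster,
    _grid_adjacency,
    _nnmf_single,
    centroid,
    component_trace,
    deduplicate_hotspots,
    detect_varicosities,
    hotspot_spacing,
    match_hotspots,
    nnmf_decompose,
    nnmf_objective,
    spatial_fwhm,
    trace_snr,
)


def _blob(h, w, cx, cy, sigma):
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def _event_trace(t, onsets, tau=8.0):
    tr = np.zeros(t)
    for o in onsets:
        idx = np.arange(o, t)
        tr[idx] += np.exp(-(idx - o) / tau)
    return tr


def _stack_from_sources(maps, traces, noise=0.0, seed=0):
    x = np.einsum("kt,khw->thw", np.asarray(traces), np.asarray(maps))
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, x.shape)
    return x.astype(np.float32)


class TestNnmf:
    def test_rank1_noiseless_recovery(self):
        smap = _blob(24, 24, 12.0, 12.0, 2.5)
        trace = _event_trace(80, [10, 40])
        stack = _stack_from_sources([smap], [trace])
        hs = nnmf_decompose(stack, NnmfParams(k=1, center="none"))
        assert len(hs) == 1
        got = hs[0].spatial_map.ravel()
        want = smap.ravel()
        cos = got @ want / (np.linalg.norm(got) * np.linalg.norm(want))
        assert cos > 0.999

    def test_two_disjoint_sources_recovered(self):
        m1 = _blob(24, 48, 10.0, 12.0, 2.0)
        m2 = _blob(24, 48, 36.0, 12.0, 2.0)
        t1 = _event_trace(100, [10, 60])
        t2 = _event_trace(100, [30, 80])
        stack = _stack_from_sources([m1, m2], [t1, t2])
        hs = nnmf_decompose(stack, NnmfParams(k=2, center="none"))
        assert len(hs) == 2
        # match by spatial overlap, then check temporal recovery
        for true_map, true_tr in ((m1, t1), (m2, t2)):
            best = max(
                hs, key=lambda h: float((h.spatial_map * true_map).sum())
            )
            rho = np.corrcoef(best.loading, true_tr)[0, 1]
            assert rho > 0.99

    def test_objective_monotone_nonincreasing(self, rng):
        x = rng.uniform(0, 1, (30, 64)).astype(np.float32)  # pixels x T
        adj = _grid_adjacency(5, 6).astype(np.float32)
        deg = np.asarray(adj.sum(axis=1)).ravel().astype(np.float32)
        params = NnmfParams(k=3, alpha_sparsity=0.5, beta_contiguity=0.5, max_iter=80)
        _, _, objs, _ = _nnmf_single(
            x, 3, params, adj, deg, np.random.default_rng(0)
        )
        objs = np.asarray(objs)
        assert np.all(objs[1:] <= objs[:-1] * (1 + 1e-6) + 1e-9)

    @pytest.mark.parametrize("n_sources", [1, 2, 5, 10])
    def test_auto_rank_finds_all_sources(self, n_sources):
        # well-separated sources with independent event times at adequate
        # SNR: k="auto" returns exactly n hotspots
        h, w = 40, 110
        positions = [(12 + 10 * i, 12 + 16 * (i % 2)) for i in range(n_sources)]
        rng = np.random.default_rng(42)
        maps, traces = [], []
        for i, (cx, cy) in enumerate(positions):
            maps.append(_blob(h, w, cx, cy, 2.0))
            onsets = rng.choice(np.arange(5, 190), size=5, replace=False)
            traces.append(_event_trace(200, sorted(onsets)))
        stack = _stack_from_sources(maps, traces, noise=0.02, seed=1)
        hs = nnmf_decompose(stack, NnmfParams(center="none", seed=3))
        # one extra component may absorb the flat clipped-noise background;
        # it covers the whole field and is removed by the area criterion
        localized = [h for h in hs if h.pixel_cluster.mean() <= 0.2]
        assert len(localized) == n_sources

    def test_all_zero_stack_gives_no_components(self):
        assert nnmf_decompose(np.zeros((10, 8, 8), dtype=np.float32)) == []

    def test_sparsity_monotonicity(self):
        # increasing the L1 weight never increases the nonzero-pixel count
        m1 = _blob(20, 40, 10.0, 10.0, 2.0)
        m2 = _blob(20, 40, 30.0, 10.0, 2.0)
        stack = _stack_from_sources(
            [m1, m2], [_event_trace(60, [5, 35]), _event_trace(60, [20, 50])],
            noise=0.01, seed=2,
        )
        counts = []
        for alpha in (0.0, 2.0, 8.0):
            hs = nnmf_decompose(
                stack, NnmfParams(k=2, alpha_sparsity=alpha, center="none", seed=5)
            )
            nnz = sum(int((h.spatial_map > 1e-6).sum()) for h in hs)
            counts.append(nnz)
        assert counts[0] >= counts[1] >= counts[2]

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            nnmf_decompose(np.ones((4, 4)), NnmfParams())
        with pytest.raises(ConfigError):
            NnmfParams(cluster_frac=1.5)
        with pytest.raises(ConfigError):
            NnmfParams(k=0)


class TestClusterAndTrace:
    def test_cluster_threshold_and_largest_region(self):
        smap = np.zeros((10, 10))
        smap[1:4, 1:4] = 1.0  # 9-px blob at max
        smap[7:9, 7:9] = 0.5  # smaller secondary blob above threshold
        cluster = _extract_cluster(smap, 0.3)
        assert cluster[2, 2] and not cluster[7, 7]
        assert cluster.sum() == 9

    def test_component_trace_ratio_of_cluster_means(self):
        f0 = np.full((4, 5, 5), 100.0)
        dff = np.zeros((4, 5, 5))
        dff[:, 2, 2] = [0.0, 0.05, 0.02, 0.0]
        base = BaselineResult(F0=f0, dFF=dff, params_echo=BaselineParams())
        cluster = np.zeros((5, 5), dtype=bool)
        cluster[2, 2] = True
        hs = Hotspot(0, dff[1], np.zeros(4), cluster, 1.0)
        trace = component_trace(hs, base)
        np.testing.assert_allclose(trace, [0.0, 0.05, 0.02, 0.0])

    def test_component_trace_uniform_f0(self):
        # cluster mean dF = 5 counts on F0 = 100 -> 5%
        f0 = np.full((2, 4, 4), 100.0)
        dff = np.full((2, 4, 4), 0.05)
        base = BaselineResult(F0=f0, dFF=dff, params_echo=BaselineParams())
        cluster = np.ones((4, 4), dtype=bool)
        hs = Hotspot(0, dff[0], np.zeros(2), cluster, 1.0)
        np.testing.assert_allclose(component_trace(hs, base), 0.05)

    def test_empty_cluster_is_error(self):
        base = BaselineResult(
            F0=np.ones((2, 3, 3)), dFF=np.zeros((2, 3, 3)),
            params_echo=BaselineParams(),
        )
        hs = Hotspot(0, np.zeros((3, 3)), np.zeros(2), np.zeros((3, 3), bool), 1.0)
        with pytest.raises(DataError):
            component_trace(hs, base)


class TestCentroid:
    def _hotspot_for(self, frame, cluster=None):
        cluster = cluster if cluster is not None else frame > 0
        return Hotspot(0, frame, np.zeros(2), cluster, 1.0)

    def test_symmetric_blob_centered(self):
        frame = _blob(21, 21, 10.0, 10.0, 2.0)
        hs = self._hotspot_for(frame)
        assert centroid(hs, frame) == pytest.approx((10.0, 10.0), abs=1e-9)

    def test_two_pixel_hand_value(self):
        frame = np.zeros((3, 3))
        frame[1, 0] = 1.0
        frame[1, 1] = 3.0
        hs = self._hotspot_for(frame)
        cx, cy = centroid(hs, frame)
        assert cx == pytest.approx(0.75)
        assert cy == pytest.approx(1.0)

    def test_translation_equivariance(self):
        f1 = _blob(30, 30, 10.0, 8.0, 1.5)
        f2 = _blob(30, 30, 12.0, 11.0, 1.5)
        c1 = centroid(self._hotspot_for(f1 > 0.05), f1)
        c2 = centroid(self._hotspot_for(f2 > 0.05), f2)
        assert c2[0] - c1[0] == pytest.approx(2.0, abs=1e-6)
        assert c2[1] - c1[1] == pytest.approx(3.0, abs=1e-6)

    def test_zero_weights_fallback(self):
        frame = np.zeros((5, 5))
        cluster = np.zeros((5, 5), bool)
        cluster[1:4, 1:4] = True
        hs = self._hotspot_for(frame, cluster)
        cx, cy = centroid(hs, frame)
        assert (cx, cy) == pytest.approx((2.0, 2.0))
        assert "centroid_unweighted_fallback" in hs.flags


class TestSpatialFwhm:
    def _measure(self, sigma_px, px_um):
        n = int(max(41, 14 * sigma_px + 1)) | 1
        frame = _blob(n, n, n // 2, n // 2, sigma_px)
        cluster = frame >= 0.3
        hs = Hotspot(0, frame, np.zeros(2), cluster, px_um)
        hs.centroid_um = ((n // 2) * px_um, (n // 2) * px_um)
        return spatial_fwhm(frame, hs)

    def test_unit_sigma_closed_form(self):
        # sigma = 1 px at 1 um/px -> FWHM = 2.3548 um
        assert self._measure(1.0, 1.0) == pytest.approx(2.3548, rel=0.03)

    def test_four_pixel_sigma_at_camera_scale(self):
        # 2.3548 * 4 * 0.34 = 3.20 um
        assert self._measure(4.0, 0.34) == pytest.approx(3.20, rel=0.03)

    def test_scaling_homogeneity(self):
        a = self._measure(2.0, 1.0)
        b = self._measure(4.0, 1.0)
        assert b / a == pytest.approx(2.0, rel=0.06)


class TestVaricosities:
    def _process_image(self, plateau):
        img = np.full((10, 10), 100.0)
        img[4:6, 4:7] = plateau
        mask = np.ones((10, 10), bool)
        return img, mask

    def test_bright_punctum_detected(self):
        img, mask = self._process_image(plateau=350.0)
        img[4:6, 4:7] = 3.2 * img[mask].mean()  # safely above 3x the mean
        varic = detect_varicosities(img, mask, pixel_size_um=1.0, min_area_px=4)
        assert len(varic.centroids_um) == 1

    def test_dim_punctum_rejected(self):
        img, mask = self._process_image(plateau=250.0)
        varic = detect_varicosities(img, mask, pixel_size_um=1.0, min_area_px=4)
        assert len(varic.centroids_um) == 0

    def test_two_touching_puncta_with_subthreshold_gap(self):
        # hand-labeled toy image: two 2x2 plateaus separated by a dim column
        img = np.full((10, 10), 10.0)
        img[4:6, 2:4] = 1000.0
        img[4:6, 5:7] = 1000.0
        img[4:6, 4] = 50.0  # gap below threshold
        mask = np.ones((10, 10), bool)
        varic = detect_varicosities(img, mask, pixel_size_um=1.0, min_area_px=2)
        assert len(varic.centroids_um) == 2

    def test_empty_mask_is_error(self):
        with pytest.raises(DataError):
            detect_varicosities(np.ones((4, 4)), np.zeros((4, 4), bool), 1.0)


class TestMatching:
    def test_exact_match_zero_offset(self):
        res = match_hotspots([(3.0, 4.0)], [(3.0, 4.0)], max_radius_um=1.7)
        assert res["matches"][0]["offset_um"] == 0.0
        assert res["competent_fraction"] == 1.0

    def test_two_hotspots_one_varicosity_vs_bruteforce(self):
        hotspots = [(0.0, 0.0), (1.0, 0.0)]
        varic = [(0.4, 0.0)]
        res = match_hotspots(hotspots, varic, max_radius_um=1.7)
        # brute force over all assignments: best single pairing
        best = min(
            ((np.hypot(hx - vx, hy - vy), i)
             for i, (hx, hy) in enumerate(hotspots)
             for (vx, vy) in varic),
        )
        assert len(res["matches"]) == 1
        assert res["matches"][0]["hotspot"] == best[1]
        assert res["unmatched_hotspots"] == [1]

    def test_greedy_without_reuse(self):
        hotspots = [(0.0, 0.0), (1.0, 0.0)]
        varic = [(0.1, 0.0), (0.9, 0.0)]
        res = match_hotspots(hotspots, varic, max_radius_um=1.7)
        pairs = {(m["hotspot"], m["varicosity"]) for m in res["matches"]}
        assert pairs == {(0, 0), (1, 1)}

    def test_empty_inputs(self):
        res = match_hotspots([], [], max_radius_um=1.0)
        assert res["matches"] == []
        assert np.isnan(res["competent_fraction"])


class TestSpacing:
    def test_straight_path_hand_values(self):
        path = [(0.0, 0.0), (30.0, 0.0)]
        cents = [(5.0, 0.1), (12.5, -0.1), (20.0, 0.0)]
        res = hotspot_spacing(cents, path)
        np.testing.assert_allclose(res["spacings_um"], [7.5, 7.5])
        assert res["mean_um"] == pytest.approx(7.5)

    def test_quarter_circle_arclength(self):
        # centroids on a radius-20 quarter circle; polyline densely sampled
        r = 20.0
        theta = np.linspace(0, np.pi / 2, 400)
        path = [(r * np.cos(t), r * np.sin(t)) for t in theta]
        angles = [0.2, 0.5, 0.9]
        cents = [(r * np.cos(a), r * np.sin(a)) for a in angles]
        res = hotspot_spacing(cents, path)
        expected = [r * (angles[1] - angles[0]), r * (angles[2] - angles[1])]
        np.testing.assert_allclose(res["spacings_um"], expected, rtol=0.01)

    def test_off_path_centroids_excluded(self):
        path = [(0.0, 0.0), (30.0, 0.0)]
        cents = [(5.0, 0.0), (20.0, 0.0), (12.0, 10.0)]
        res = hotspot_spacing(cents, path, lateral_tol_um=3.0)
        assert len(res["arclengths_um"]) == 2

    def test_fewer_than_two_projectable(self):
        res = hotspot_spacing([(5.0, 0.0)], [(0.0, 0.0), (10.0, 0.0)])
        assert res["mean_um"] is None


class TestDedupAndSnr:
    def test_trace_snr_flat_vs_peaky(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.01, 300)
        assert trace_snr(noise) < 5
        sig = noise.copy()
        sig[100:120] += 0.2 * np.exp(-np.arange(20) / 8)
        assert trace_snr(sig) > 10

    def test_deduplicate_merges_fragments(self):
        rng = np.random.default_rng(1)
        base_trace = rng.normal(0, 0.01, 200)
        strong = base_trace + _event_trace(200, [50]) * 0.3
        weak = base_trace + _event_trace(200, [50]) * 0.1
        def mk(cix, cx, trace):
            h = Hotspot(cix, np.ones((4, 4)), trace, np.ones((4, 4), bool), 1.0)
            h.trace_dff = trace
            h.centroid_um = (cx, 0.0)
            return h
        a = mk(0, 0.0, strong)
        b = mk(1, 0.8, weak)  # within the localization bound of a
        c = mk(2, 10.0, base_trace + _event_trace(200, [120]) * 0.3)
        kept = deduplicate_hotspots([a, b, c])
        assert [h.component_index for h in kept] == [0, 2]
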