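"""Segmentation and feature extraction, each checked against an
independent brute-force oracle on small fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtscreen import synthdata as sd
from emtscreen.imaging import (
    ImagingConfig,
    calibrate_control_threshold,
    colony_contrasts,
    contrast_below_threshold_fraction,
    convex_hull_perimeter_ratio,
    extract_profile,
    glcm_texture,
    neighbor_distances,
    neighbor_min_dist,
    segment_colonies,
    segment_field,
    segment_nuclei,
    _mask_perimeter_points,
)
from emtscreen.parameters import PARAMETER_NAMES

from conftest import grid_centers, render_nuclei


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def nn_brute(points: np.ndarray) -> np.ndarray:
    """O(n^2) per-point nearest-neighbour distances."""
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def glcm_brute(image, mask, levels, offsets):
    """Pixel-pair double loop over every offset; entropy in nats."""
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        q = np.zeros(img.shape, dtype=int)
    else:
        q = (np.clip((img - lo) / (hi - lo), 0, 1 - 1e-12) * levels).astype(int)
    h, w = img.shape
    mats = []
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        seen = False
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
                    seen = True
        if seen:
            mats.append(counts / counts.sum())
    P = np.mean(mats, axis=0)
    nz = P[P > 0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    return float(-(nz * np.log(nz)).sum()), float((P * (i - j) ** 2).sum())


def hull_ratio_shapely(mask: np.ndarray) -> float:
    """Independent polygon-perimeter oracle on the same boundary convention."""
    from shapely.geometry import Polygon
    from shapely.ops import unary_union
    from skimage.measure import find_contours

    padded = np.pad(np.asarray(mask, float), 1)
    contours = find_contours(padded, 0.5)
    total = sum(Polygon(c).exterior.length for c in contours)
    pts = np.vstack(contours)
    from shapely.geometry import MultiPoint

    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return min(hull.length / total, 1.0)


# ---------------------------------------------------------------------------
# Nuclei segmentation
# ---------------------------------------------------------------------------

class TestSegmentNuclei:
    def test_recovers_nonoverlapping_grid_count(self):
        centers = grid_centers(10, 22.0)  # 100 well-separated nuclei
        img = render_nuclei(centers, (256, 256))
        seg = segment_nuclei(img)
        assert abs(seg.n_nuclei - 100) <= 2
        # every truth centre matched by a centroid within 2 px
        d = np.sqrt(((seg.nuclei_centroids[:, None] - centers[None]) ** 2
                     ).sum(-1)).min(axis=0)
        assert np.percentile(d, 95) < 2.0

    def test_blank_image_yields_zero_nuclei_and_invalid_well(self):
        blank = np.full((128, 128), 80.0)
        seg = segment_nuclei(blank)
        assert seg.n_nuclei == 0
        feats = extract_profile(blank, blank)
        assert feats["valid_field"] == 0.0
        assert feats["nuclei_count"] == 0.0

    def test_fused_dumbbell_is_split_in_two(self):
        img = render_nuclei([(64, 58), (64, 70)], (128, 128), sigma=3.0)
        seg = segment_nuclei(img)
        assert seg.n_nuclei == 2

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.full((64, 64), -1.0))


class TestSegmentColonies:
    def test_distant_nuclei_stay_separate(self):
        img = render_nuclei([(30, 30), (30, 90)], (128, 128))
        seg = segment_nuclei(img)
        labels, members = segment_colonies(seg.nuclei_labels, link_radius=3)
        assert len(set(members.values())) == 2

    def test_chain_merges_transitively(self):
        img = render_nuclei([(64, 30 + 12 * i) for i in range(5)], (128, 128))
        seg = segment_nuclei(img)
        labels, members = segment_colonies(seg.nuclei_labels, link_radius=5)
        assert len(set(members.values())) == 1

    def test_scattered_field_has_more_colonies_than_clustered(
            self, epithelial_field, mesenchymal_field):
        cfg = ImagingConfig()
        epi = segment_field(epithelial_field.nuclei_image, cfg)
        mes = segment_field(mesenchymal_field.nuclei_image, cfg)
        n_epi = len(set(epi.colony_of_nucleus.values()))
        n_mes = len(set(mes.colony_of_nucleus.values()))
        assert n_mes > n_epi

    def test_colony_mask_covers_member_nuclei(self, epithelial_field):
        seg = segment_field(epithelial_field.nuclei_image)
        for nid, cid in seg.colony_of_nucleus.items():
            nuc = seg.nuclei_labels == nid
            assert (seg.colony_labels[nuc] == cid).all()


# ---------------------------------------------------------------------------
# Neighbour distances
# ---------------------------------------------------------------------------

class TestNeighborMinDist:
    def test_three_four_five_triangle(self):
        assert neighbor_min_dist(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_regular_grid_returns_spacing(self):
        assert neighbor_min_dist(grid_centers(5, 13.0)) == pytest.approx(13.0)

    def test_fewer_than_two_nuclei_is_missing(self):
        assert np.isnan(neighbor_min_dist(np.array([[1.0, 1.0]])))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=40), st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 64, (n, 2))
        np.testing.assert_allclose(neighbor_distances(pts), nn_brute(pts),
                                   rtol=0, atol=1e-9)


# ---------------------------------------------------------------------------
# Convex hull / perimeter ratio
# ---------------------------------------------------------------------------

def disc_mask(radius=20, size=64):
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return (rr - size / 2) ** 2 + (cc - size / 2) ** 2 <= radius ** 2


class TestHullPerimeterRatio:
    def test_convex_shapes_score_near_one(self):
        assert convex_hull_perimeter_ratio(disc_mask()) > 0.93
        square = np.zeros((64, 64), bool)
        square[10:50, 10:50] = True
        assert convex_hull_perimeter_ratio(square) > 0.97

    def test_cross_is_less_convex_than_disc(self):
        cross = np.zeros((64, 64), bool)
        cross[10:54, 28:36] = True
        cross[28:36, 10:54] = True
        r = convex_hull_perimeter_ratio(cross)
        assert r < convex_hull_perimeter_ratio(disc_mask())
        assert r < 1.0

    def test_single_pixel_scores_one_by_convention(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        assert convex_hull_perimeter_ratio(mask) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_perimeter_ratio(np.zeros((8, 8), bool))

    def test_matches_shapely_polygon_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = np.zeros((48, 48), bool)
            # random blob: union of rectangles
            for _ in range(4):
                r, c = rng.integers(5, 30, 2)
                hh, ww = rng.integers(5, 15, 2)
                mask[r:r + hh, c:c + ww] = True
            mine = convex_hull_perimeter_ratio(mask)
            oracle = hull_ratio_shapely(mask)
            assert mine == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

class TestGlcmTexture:
    def test_constant_region_has_zero_entropy_and_contrast(self):
        img = np.full((32, 32), 7.0)
        e, c = glcm_texture(img, np.ones_like(img, bool), levels=8)
        assert e == 0.0 and c == 0.0

    def test_checkerboard_closed_form(self):
        levels = 32
        board = np.indices((16, 16)).sum(axis=0) % 2 * 100.0
        e, c = glcm_texture(board, np.ones_like(board, bool), levels=levels,
                            offsets=((0, 1),))
        # two quantisation bins a=0, b=levels-1 alternating at offset (0,1):
        # P mass 1/2 on (a,b) and (b,a)
        assert e == pytest.approx(np.log(2), abs=1e-12)
        assert c == pytest.approx((levels - 1) ** 2, abs=1e-9)

    def test_random_texture_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        img = rng.uniform(0, 1000, (24, 24))
        mask = rng.uniform(size=(24, 24)) > 0.3
        offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
        mine = glcm_texture(img, mask, 16, offsets)
        oracle = glcm_brute(img, mask, 16, offsets)
        np.testing.assert_allclose(mine, oracle, rtol=0, atol=1e-12)

    def test_invariant_to_adding_constant_intensity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 500, (20, 20))
        mask = np.ones((20, 20), bool)
        base = glcm_texture(img, mask, 16)
        shifted = glcm_texture(img + 12345.0, mask, 16)
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_tiny_mask_is_missing(self):
        img = np.random.default_rng(0).uniform(size=(16, 16))
        mask = np.zeros((16, 16), bool)
        mask[0, :3] = True
        e, c = glcm_texture(img, mask, 8)
        assert np.isnan(e) and np.isnan(c)


class TestContrastThreshold:
    def test_quantile_conventions(self):
        vals = np.arange(1, 101, dtype=float)
        assert calibrate_control_threshold(vals, q=0.0) == 1.0
        assert calibrate_control_threshold(vals, q=0.5) == 50.5
        with pytest.raises(ValueError):
            calibrate_control_threshold(vals[:10])

    def test_fraction_counts_strictly_below(self):
        contrasts = [1.0, 2.0, 3.0, 4.0]
        assert contrast_below_threshold_fraction(contrasts, np.inf) == 1.0
        assert contrast_below_threshold_fraction(contrasts, -np.inf) == 0.0
        assert contrast_below_threshold_fraction(contrasts, 3.0) == 0.5
        assert np.isnan(contrast_below_threshold_fraction([], 1.0))


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

class TestExtractProfile:
    def test_profile_has_all_18_parameters(self, mesenchymal_field):
        feats = extract_profile(mesenchymal_field.nuclei_image,
                                mesenchymal_field.fibronectin_image)
        assert set(feats) == set(PARAMETER_NAMES)

    def test_epithelial_vs_mesenchymal_direction(self, epithelial_field,
                                                 mesenchymal_field):
        cfg = ImagingConfig()
        epi = extract_profile(epithelial_field.nuclei_image,
                              epithelial_field.fibronectin_image, cfg)
        mes = extract_profile(mesenchymal_field.nuclei_image,
                              mesenchymal_field.fibronectin_image, cfg)
        assert epi["fn_texture_entropy"] < mes["fn_texture_entropy"]
        assert epi["nn_min_dist"] < mes["nn_min_dist"]
        assert epi["colony_count"] < mes["colony_count"]
        assert epi["fn_mean_intensity"] < mes["fn_mean_intensity"]

    def test_feature_monotonicity_in_severity_noise_free(self):
        cfg = ImagingConfig()
        series = {"fn_texture_entropy": [], "nn_min_dist": [], "colony_count": []}
        for sev in (0.0, 0.5, 1.0):
            spec = sd.PhenotypeSpec(label="partial" if 0 < sev < 1 else
                                    ("epithelial" if sev == 0 else "mesenchymal"),
                                    severity=sev, noise_sd=0.0)
            vals = {k: [] for k in series}
            for seed in (21, 22, 23):
                fld = sd.simulate_field(spec, (256, 256), seed=seed)
                feats = extract_profile(fld.nuclei_image, fld.fibronectin_image, cfg)
                for k in series:
                    vals[k].append(feats[k])
            for k in series:
                series[k].append(np.mean(vals[k]))
        # texture entropy and neighbour distance respond monotonically; the
        # colony count rises from compact islets to a dispersed field but may
        # peak mid-way as fragmenting clusters outnumber the final chains
        for k in ("fn_texture_entropy", "nn_min_dist"):
            seq = series[k]
            assert seq[0] < seq[1] < seq[2], (k, seq)
        assert series["colony_count"][0] < series["colony_count"][2]
        assert series["colony_count"][0] < series["colony_count"][1]

    def test_geometric_features_invariant_under_translation(self):
        centers = grid_centers(4, 18.0, origin=30.0)
        img = render_nuclei(centers, (160, 160))
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        f1 = extract_profile(img, img)
        f2 = extract_profile(shifted, shifted)
        for key in ("nn_min_dist", "nn_mean_dist", "colony_count",
                    "nucleus_area", "nuclei_count"):
            assert f1[key] == pytest.approx(f2[key], rel=1e-6), key

    def test_contrast_fraction_uses_control_threshold(self, mesenchymal_field):
        cfg = ImagingConfig()
        seg = segment_field(mesenchymal_field.nuclei_image, cfg)
        contrasts = colony_contrasts(mesenchymal_field.fibronectin_image, seg, cfg)
        thr = calibrate_control_threshold(contrasts[np.isfinite(contrasts)],
                                          cfg.contrast_quantile)
        feats = extract_profile(mesenchymal_field.nuclei_image,
                                mesenchymal_field.fibronectin_image, cfg,
                                control_contrast_threshold=thr)
        # by construction ~5% of the control population lies below its own
        # 5% quantile
        assert feats["fn_contrast_low_frac"] <= 0.15
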