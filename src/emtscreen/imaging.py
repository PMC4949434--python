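"""Segmentation and phenotype feature extraction from two-channel fields.

Two parallel routines mirror the screen's image analysis: *single nuclei*
(Otsu threshold, hole filling, distance-transform watershed, area filter)
and *colonies* (transitive merging of nuclei whose dilated masks touch).
From their outputs the 18-parameter profile is assembled, including the four
named screen parameters: fibronectin texture entropy within colonies,
the fraction of colonies whose co-occurrence contrast falls below a
control-derived threshold, the median minimum neighbour distance between
nuclei, and the colony convex-hull-perimeter to perimeter ratio.

Conventions (declared, configurable): pixel coordinates are 0-based
(row, col); connectivity is 8-neighbourhood; perimeters are measured on the
half-level marching-squares boundary polygon; distance features aggregate by
median over nuclei, intensity and texture features by mean over objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as sk_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .parameters import PARAMETER_NAMES

DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class ImagingConfig:
    """Tunable parameters of the two image-analysis routines."""

    min_nucleus_area: int = 10          # px^2
    max_nucleus_area: int = 400         # px^2
    watershed_min_distance: int = 4     # px between seed maxima
    link_radius: int = 4                # px, colony merging dilation
    colony_close_radius: int = 6        # px, smoothing of the colony outline
    glcm_levels: int = 32
    glcm_offsets: tuple = DEFAULT_GLCM_OFFSETS
    min_nuclei_valid: int = 10          # wells below are invalid (toxicity proxy)
    contrast_quantile: float = 0.05     # control-threshold quantile


@dataclass
class SegmentationResult:
    nuclei_labels: np.ndarray
    nuclei_centroids: np.ndarray                 # (n, 2) intensity-weighted
    colony_labels: np.ndarray | None = None
    colony_of_nucleus: dict[int, int] = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei_centroids)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(nuclei_image: np.ndarray, min_area: int = 10,
                   max_area: int = 400, min_distance: int = 4,
                   ) -> SegmentationResult:
    """Single-nuclei routine: Otsu -> fill holes -> watershed -> area filter.

    Touching nuclei are split on the watershed of the Euclidean distance
    transform seeded at its local maxima.  Centroids are intensity-weighted.
    An empty or constant image yields zero nuclei (never an exception).
    """
    img = np.asarray(nuclei_image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("expected a 2-D non-negative image")
    if img.max() == img.min():
        return SegmentationResult(np.zeros(img.shape, int), np.empty((0, 2)))
    mask = img > threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return SegmentationResult(np.zeros(img.shape, int), np.empty((0, 2)))
    distance = ndi.distance_transform_edt(mask)
    # Markers come from smoothed-intensity maxima: every nucleus is an
    # intensity peak even inside a confluent sheet, where the distance
    # transform plateaus and would under-seed.  The flood itself runs on the
    # distance relief so the split follows object geometry.
    smooth = ndi.gaussian_filter(img, 1.0)
    coords = peak_local_max(smooth, min_distance=min_distance, labels=mask,
                            exclude_border=False)
    markers = np.zeros(img.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=mask)
    # area filter and contiguous relabelling
    out = np.zeros_like(labels)
    centroids = []
    next_id = 1
    for prop in regionprops(labels, intensity_image=img):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = next_id
            centroids.append(prop.centroid_weighted)
            next_id += 1
    return SegmentationResult(out, np.asarray(centroids, dtype=float).reshape(-1, 2))


def segment_colonies(nuclei_labels: np.ndarray, link_radius: int = 4,
                     close_radius: int = 6,
                     ) -> tuple[np.ndarray, dict[int, int]]:
    """Colony routine: transitive merge of nuclei within ``link_radius``.

    Nuclei whose masks, dilated by ``link_radius``, overlap belong to one
    colony (connected components of the dilated union).  Each colony's mask
    is then smoothed by a morphological closing of ``close_radius`` — the
    drawn outline of a confluent cell group, filling the scallops between
    member nuclei — applied per component so distinct colonies never merge.
    Returns the colony label grid and the nucleus -> colony map.
    """
    mask = nuclei_labels > 0
    if not mask.any():
        return np.zeros_like(nuclei_labels), {}
    dil = ndi.binary_dilation(mask, structure=disk(link_radius))
    components = sk_label(dil, connectivity=2)
    colony_labels = np.zeros_like(components)
    if close_radius > 0:
        se = disk(close_radius)
        pad = close_radius + 1
        for prop in regionprops(components):
            r0, c0, r1, c1 = prop.bbox
            r0 = max(0, r0 - pad)
            c0 = max(0, c0 - pad)
            r1 = min(components.shape[0], r1 + pad)
            c1 = min(components.shape[1], c1 + pad)
            m = ndi.binary_closing(components[r0:r1, c0:c1] == prop.label,
                                   structure=se)
            sub = colony_labels[r0:r1, c0:c1]
            sub[m & (sub == 0)] = prop.label
    else:
        colony_labels = components
    membership: dict[int, int] = {}
    for nid in np.unique(nuclei_labels):
        if nid == 0:
            continue
        rr, cc = np.nonzero(nuclei_labels == nid)
        membership[int(nid)] = int(colony_labels[rr[0], cc[0]])
    return colony_labels, membership


def segment_field(nuclei_image: np.ndarray, config: ImagingConfig | None = None,
                  ) -> SegmentationResult:
    """Run both routines on one field."""
    cfg = config or ImagingConfig()
    seg = segment_nuclei(nuclei_image, cfg.min_nucleus_area, cfg.max_nucleus_area,
                         cfg.watershed_min_distance)
    seg.colony_labels, seg.colony_of_nucleus = segment_colonies(
        seg.nuclei_labels, cfg.link_radius, cfg.colony_close_radius)
    return seg


# ---------------------------------------------------------------------------
# Named features
# ---------------------------------------------------------------------------

def neighbor_distances(centroids: np.ndarray) -> np.ndarray:
    """Per-nucleus Euclidean distance to the nearest other centroid."""
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return np.full(len(pts), np.nan)
    dist, _ = cKDTree(pts).query(pts, k=2)
    return dist[:, 1]


def neighbor_min_dist(centroids: np.ndarray) -> float:
    """Well-level NeighborMinDist: median over nuclei of the NN distance.

    Undefined (NaN) below two nuclei; callers must treat that as an invalid
    well rather than a zero.
    """
    d = neighbor_distances(centroids)
    if len(d) < 2:
        return float("nan")
    return float(np.median(d))


def _mask_perimeter_points(mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Total marching-squares boundary length and the boundary vertices."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    length = 0.0
    pts = []
    for contour in contours:
        length += float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
        pts.append(contour)
    return length, np.vstack(pts) if pts else np.empty((0, 2))


def convex_hull_perimeter_ratio(mask: np.ndarray) -> float:
    """ObjectConvexHullPerimeterRatio of one colony mask, in (0, 1].

    Perimeter of the convex hull of the boundary polygon divided by the
    perimeter of the boundary polygon itself (holes included).  Convex
    colonies score ~1; ragged or branched colonies score lower.  Degenerate
    masks (single pixel, collinear) score 1 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("colony mask is empty")
    if mask.sum() == 1:
        return 1.0
    perim, pts = _mask_perimeter_points(mask)
    if perim == 0 or len(pts) < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 1.0
    # ConvexHull.area is the hull perimeter in 2-D
    return float(min(hull.area / perim, 1.0))


def glcm_texture(image: np.ndarray, mask: np.ndarray, levels: int = 32,
                 offsets=DEFAULT_GLCM_OFFSETS) -> tuple[float, float]:
    """Grey-level co-occurrence entropy (nats) and contrast within a mask.

    Intensities are quantised to ``levels`` bins over the image's robust
    range (1st-99th percentile, so texture is invariant to adding a constant
    to the whole image).  For each offset a symmetric, normalised
    co-occurrence matrix is built over pixel pairs lying inside the mask;
    matrices are averaged over offsets.  Entropy is ``-sum P ln P``,
    contrast is ``sum P(i,j) (i-j)^2``.  Returns NaN for masks under 4 px.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        return float("nan"), float("nan")
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        q = np.zeros(img.shape, dtype=int)
    else:
        q = np.clip((img - lo) / (hi - lo), 0.0, 1.0 - 1e-12)
        q = (q * levels).astype(int)
    mats = []
    for (dr, dc) in offsets:
        counts = np.zeros((levels, levels))
        h, w = img.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if not valid.any():
            continue
        np.add.at(counts, (a[valid], b[valid]), 1.0)
        counts = counts + counts.T  # symmetric
        mats.append(counts / counts.sum())
    if not mats:
        return float("nan"), float("nan")
    P = np.mean(mats, axis=0)
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(np.sum(P * (i - j) ** 2))
    return entropy, contrast


def calibrate_control_threshold(control_contrasts, q: float = 0.05) -> float:
    """Contrast threshold from a control (mesenchymal) colony population.

    The q-quantile (linear interpolation) of the TGF-beta-stimulated control
    colony contrast distribution; colonies falling below it count as having
    lost the textured mesenchymal fibronectin signal.
    """
    vals = np.asarray(control_contrasts, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 20:
        raise ValueError("need at least 20 control colonies to calibrate")
    return float(np.quantile(vals, q))


def contrast_below_threshold_fraction(colony_contrasts, threshold: float) -> float:
    """Fraction of colonies with contrast strictly below the control threshold."""
    vals = np.asarray(colony_contrasts, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.mean(vals < threshold))


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

def focus_score(image: np.ndarray) -> float:
    """Gradient-energy focus proxy (mean squared intensity gradient)."""
    gy, gx = np.gradient(np.asarray(image, dtype=float))
    return float(np.mean(gy ** 2 + gx ** 2))


def colony_contrasts(fibronectin_image: np.ndarray, seg: SegmentationResult,
                     config: ImagingConfig | None = None) -> np.ndarray:
    """GLCM contrast of every colony in a field (for threshold calibration)."""
    cfg = config or ImagingConfig()
    out = []
    for prop in regionprops(seg.colony_labels):
        m = seg.colony_labels == prop.label
        _, contrast = glcm_texture(fibronectin_image, m, cfg.glcm_levels,
                                   cfg.glcm_offsets)
        out.append(contrast)
    return np.asarray(out, dtype=float)


def extract_profile(nuclei_image: np.ndarray, fibronectin_image: np.ndarray,
                    config: ImagingConfig | None = None,
                    control_contrast_threshold: float | None = None,
                    ) -> dict[str, float]:
    """Assemble the 18-parameter profile of one field.

    Returns a dict keyed by the canonical parameter names; ``valid_field``
    is 0 when segmentation yields fewer than ``min_nuclei_valid`` nuclei, in
    which case object-level features may be NaN but are never silently
    replaced.  ``control_contrast_threshold`` comes from
    :func:`calibrate_control_threshold` on negative-control colonies; without
    one, ``fn_contrast_low_frac`` is NaN.
    """
    cfg = config or ImagingConfig()
    seg = segment_field(nuclei_image, cfg)
    n = seg.n_nuclei
    feats = {p: float("nan") for p in PARAMETER_NAMES}
    feats["nuclei_count"] = float(n)
    feats["focus_score"] = focus_score(nuclei_image)
    feats["valid_field"] = float(n >= cfg.min_nuclei_valid)

    nd = neighbor_distances(seg.nuclei_centroids)
    if n >= 2:
        feats["nn_min_dist"] = float(np.median(nd))
        feats["nn_mean_dist"] = float(np.mean(nd))
        area = float(np.prod(nuclei_image.shape))
        # Clark-Evans aggregation index: observed mean NN distance over the
        # expectation 0.5 / sqrt(density) for complete spatial randomness
        feats["nuclear_dispersion"] = float(np.mean(nd) * 2.0 * np.sqrt(n / area))

    if n >= 1:
        props = regionprops(seg.nuclei_labels, intensity_image=nuclei_image)
        feats["nucleus_area"] = float(np.mean([p.area for p in props]))
        feats["nucleus_eccentricity"] = float(np.mean([p.eccentricity for p in props]))
        means = [p.intensity_mean for p in props]
        feats["dna_mean_intensity"] = float(np.mean(means))
        feats["dna_intensity_sd"] = float(np.std(means))

    cprops = regionprops(seg.colony_labels)
    feats["colony_count"] = float(len(cprops))
    if cprops:
        feats["colony_area"] = float(np.mean([p.area for p in cprops]))
        sizes = np.bincount(list(seg.colony_of_nucleus.values()),
                            minlength=len(cprops) + 1)[1:]
        feats["nuclei_per_colony"] = float(np.mean(sizes)) if sizes.size else 0.0
        ratios, entropies, contrasts, fn_means = [], [], [], []
        fn_pixels = []
        for p in cprops:
            m = seg.colony_labels == p.label
            ratios.append(convex_hull_perimeter_ratio(m))
            e, c = glcm_texture(fibronectin_image, m, cfg.glcm_levels, cfg.glcm_offsets)
            entropies.append(e)
            contrasts.append(c)
            fn_means.append(float(np.mean(fibronectin_image[m])))
            fn_pixels.append(fibronectin_image[m])
        feats["colony_hull_perimeter_ratio"] = float(np.mean(ratios))
        with np.errstate(invalid="ignore"):
            feats["fn_texture_entropy"] = float(np.nanmean(entropies))
        feats["fn_mean_intensity"] = float(np.mean(fn_means))
        allpix = np.concatenate(fn_pixels)
        mu = float(np.mean(allpix))
        feats["fn_intensity_cv"] = float(np.std(allpix) / mu) if mu > 0 else float("nan")
        if control_contrast_threshold is not None:
            feats["fn_contrast_low_frac"] = contrast_below_threshold_fraction(
                contrasts, control_contrast_threshold)
    return feats
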