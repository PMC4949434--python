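"""The 18-parameter multi-parametric phenotype profile.

A well's phenotype is summarised by 18 scalar parameters produced by two
image-analysis routines (single-nuclei segmentation and colony segmentation)
and grouped into five blocks:

* **fibronectin** — texture and intensity of the mesenchymal marker channel
  within colonies,
* **colony morphology** — shape and size statistics of colonies,
* **nuclear distribution** — spatial statistics of nucleus centroids,
* **nuclear intensity/shape** — per-nucleus measurements of the DNA channel,
* **assay performance** — field validity and focus proxies.

Epithelial cultures form compact islets with low, smooth fibronectin;
TGF-beta-driven mesenchymal cultures scatter their nuclei and deposit bright,
textured fibronectin.  The anchor tables below encode those two phenotype
poles for the profile-level simulator: a partial phenotype of severity
``s`` (0 = fully epithelial/reverted, 1 = fully mesenchymal) has parameter
means interpolated linearly between the epithelial and mesenchymal anchors.
"""

from __future__ import annotations

import numpy as np

#: Canonical order of the 18 parameters; every profile table uses it.
PARAMETER_NAMES: tuple[str, ...] = (
    # fibronectin block
    "fn_texture_entropy",
    "fn_contrast_low_frac",
    "fn_mean_intensity",
    "fn_intensity_cv",
    # colony morphology block
    "colony_hull_perimeter_ratio",
    "colony_area",
    "nuclei_per_colony",
    "colony_count",
    # nuclear distribution block
    "nn_min_dist",
    "nn_mean_dist",
    "nuclear_dispersion",
    # nuclear intensity / shape block
    "nuclei_count",
    "nucleus_area",
    "nucleus_eccentricity",
    "dna_mean_intensity",
    "dna_intensity_sd",
    # assay performance block
    "valid_field",
    "focus_score",
)

N_PARAMETERS = len(PARAMETER_NAMES)

PARAMETER_BLOCKS: dict[str, tuple[str, ...]] = {
    "fibronectin": PARAMETER_NAMES[0:4],
    "colony_morphology": PARAMETER_NAMES[4:8],
    "nuclear_distribution": PARAMETER_NAMES[8:11],
    "nuclear_intensity_shape": PARAMETER_NAMES[11:16],
    "assay_performance": PARAMETER_NAMES[16:18],
}

# Anchor means for the fully epithelial (reverted) phenotype.  Units: texture
# entropy in nats, intensities in camera counts (a.u.), areas in px^2,
# distances in px, fractions dimensionless.
EPITHELIAL_ANCHOR: dict[str, float] = {
    "fn_texture_entropy": 0.8,
    "fn_contrast_low_frac": 0.60,
    "fn_mean_intensity": 300.0,
    "fn_intensity_cv": 0.15,
    "colony_hull_perimeter_ratio": 0.95,
    "colony_area": 6000.0,
    "nuclei_per_colony": 9.0,
    "colony_count": 8.0,
    "nn_min_dist": 9.0,
    "nn_mean_dist": 12.0,
    "nuclear_dispersion": 0.35,
    "nuclei_count": 110.0,
    "nucleus_area": 80.0,
    "nucleus_eccentricity": 0.55,
    "dna_mean_intensity": 2400.0,
    "dna_intensity_sd": 350.0,
    "valid_field": 1.0,
    "focus_score": 120.0,
}

# Anchor means for the fully mesenchymal (TGF-beta background) phenotype.
MESENCHYMAL_ANCHOR: dict[str, float] = {
    "fn_texture_entropy": 2.5,
    "fn_contrast_low_frac": 0.20,
    "fn_mean_intensity": 1800.0,
    "fn_intensity_cv": 0.55,
    "colony_hull_perimeter_ratio": 0.70,
    "colony_area": 2500.0,
    "nuclei_per_colony": 3.0,
    "colony_count": 45.0,
    "nn_min_dist": 28.0,
    "nn_mean_dist": 36.0,
    "nuclear_dispersion": 1.05,
    "nuclei_count": 120.0,
    "nucleus_area": 95.0,
    "nucleus_eccentricity": 0.75,
    "dna_mean_intensity": 2300.0,
    "dna_intensity_sd": 380.0,
    "valid_field": 1.0,
    "focus_score": 140.0,
}

# Anchor means for a toxic well (high-dose staurosporine): very few surviving
# nuclei, small fragmented colonies, residual fibronectin from the TGF-beta
# background.
TOXIC_ANCHOR: dict[str, float] = {
    "fn_texture_entropy": 1.6,
    "fn_contrast_low_frac": 0.40,
    "fn_mean_intensity": 800.0,
    "fn_intensity_cv": 0.45,
    "colony_hull_perimeter_ratio": 0.85,
    "colony_area": 300.0,
    "nuclei_per_colony": 1.2,
    "colony_count": 4.0,
    "nn_min_dist": 40.0,
    "nn_mean_dist": 55.0,
    "nuclear_dispersion": 1.0,
    "nuclei_count": 5.0,
    "nucleus_area": 60.0,
    "nucleus_eccentricity": 0.60,
    "dna_mean_intensity": 1800.0,
    "dna_intensity_sd": 500.0,
    "valid_field": 1.0,
    "focus_score": 110.0,
}

# Per-parameter biological + technical noise SD at noise scale 1.  Chosen so
# the full epithelial-to-mesenchymal swing of an informative parameter spans
# roughly six to seven SDs (the whole 18-parameter profile then separates by
# a Euclidean distance of ~24 reference-SD units), the regime of a screening
# assay whose multivariate Z-prime sits well above the 0.5 "excellent" bar.
# Anchors above additionally keep each parameter's epithelial:mesenchymal
# *ratio* moderate (within ~3x): percent-of-control normalisation divides by
# the plate's negative-control median, so a parameter whose reverted value is
# many times its control level amplifies control-median sampling noise into
# plate-to-plate jitter of exactly that ratio.
PARAMETER_SD: dict[str, float] = {
    "fn_texture_entropy": 0.25,
    "fn_contrast_low_frac": 0.06,
    "fn_mean_intensity": 228.0,
    "fn_intensity_cv": 0.06,
    "colony_hull_perimeter_ratio": 0.037,
    "colony_area": 530.0,
    "nuclei_per_colony": 0.9,
    "colony_count": 5.5,
    "nn_min_dist": 2.9,
    "nn_mean_dist": 3.6,
    "nuclear_dispersion": 0.11,
    "nuclei_count": 9.6,
    "nucleus_area": 6.0,
    "nucleus_eccentricity": 0.036,
    "dna_mean_intensity": 144.0,
    "dna_intensity_sd": 48.0,
    "valid_field": 0.0,
    "focus_score": 12.0,
}

# Toxic wells have their own nuclei-count noise: kept tight so that a
# staurosporine well is always far below the 10-nucleus validity floor.
TOXIC_SD_OVERRIDES: dict[str, float] = {
    "nuclei_count": 1.0,
    "nuclei_per_colony": 0.3,
    "colony_count": 1.5,
}

# Additive plate effects model batch shifts in staining, illumination and
# seeding geometry.  They act on intensity, texture, morphology and distance
# readouts; object *counts* are robust to intensity shifts, the validity
# flag is categorical, and the contrast-below-threshold fraction is computed
# against a threshold calibrated on the same plate's control colonies, which
# absorbs plate-level shifts by construction.  Values are multipliers of the
# assay SD per unit plate-effect scale.
PLATE_EFFECT_SUSCEPTIBILITY: dict[str, float] = {
    **{p: 1.0 for p in PARAMETER_NAMES},
    "fn_contrast_low_frac": 0.0,
    "nuclei_count": 0.0,
    "colony_count": 0.0,
    "nuclei_per_colony": 0.0,
    "valid_field": 0.0,
}

# Well-to-well noise is not independent across parameters: a common latent
# factor (local cell density and staining efficiency of the well) moves many
# readouts coherently — denser wells have more nuclei and colonies, shorter
# neighbour distances, more matrix signal.  Signed loadings below give the
# fraction of each parameter's noise SD carried by that factor (the residual
# is independent); marginal per-parameter SDs are unchanged.  The factor
# direction is essentially orthogonal to the epithelial-mesenchymal severity
# axis, as dense and sparse wells occur at every phenotype grade.
COMMON_FACTOR_LOADING: dict[str, float] = {
    "fn_texture_entropy": 0.3,
    "fn_contrast_low_frac": -0.3,
    "fn_mean_intensity": 0.5,
    "fn_intensity_cv": 0.3,
    "colony_hull_perimeter_ratio": -0.2,
    "colony_area": 0.45,
    "nuclei_per_colony": 0.45,
    "colony_count": 0.3,
    "nn_min_dist": -0.45,
    "nn_mean_dist": -0.45,
    "nuclear_dispersion": -0.3,
    "nuclei_count": 0.6,
    "nucleus_area": -0.2,
    "nucleus_eccentricity": 0.1,
    "dna_mean_intensity": 0.4,
    "dna_intensity_sd": 0.3,
    "valid_field": 0.0,
    "focus_score": 0.3,
}


def loading_vector() -> np.ndarray:
    return np.array([COMMON_FACTOR_LOADING[p] for p in PARAMETER_NAMES],
                    dtype=float)


def anchor_vector(anchor: dict[str, float]) -> np.ndarray:
    """Return an anchor table as a vector in canonical parameter order."""
    return np.array([anchor[p] for p in PARAMETER_NAMES], dtype=float)


def sd_vector(label: str = "default") -> np.ndarray:
    sds = dict(PARAMETER_SD)
    if label == "toxic":
        sds.update(TOXIC_SD_OVERRIDES)
    return np.array([sds[p] for p in PARAMETER_NAMES], dtype=float)
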