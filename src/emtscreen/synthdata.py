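"""Synthetic EMT-reversal screens with known ground truth.

This module generates everything the analysis side of the package consumes:
two-channel fluorescence fields (nuclei + fibronectin), profile-level
18-parameter feature tables, whole plates with control layouts and planted
active compounds, dose-response series, and three-compartment p-Smad2
translocation fields.  All generators are deterministic given their seed.

The phenotype model is one-dimensional: a *severity* in ``[0, 1]``
interpolates linearly between a fully epithelial/reverted culture
(severity 0: nuclei in compact Gaussian islets, low smooth fibronectin) and
a fully mesenchymal TGF-beta background (severity 1: scattered nuclei,
bright multiscale-textured fibronectin).  Toxic wells (high-dose
staurosporine) are modelled separately as near-empty fields.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .parameters import (
    EPITHELIAL_ANCHOR,
    MESENCHYMAL_ANCHOR,
    PARAMETER_NAMES,
    PLATE_EFFECT_SUSCEPTIBILITY,
    TOXIC_ANCHOR,
    anchor_vector,
    loading_vector,
    sd_vector,
)


class ConfigurationError(ValueError):
    """Raised when a generator is given an inconsistent configuration."""


# ---------------------------------------------------------------------------
# Phenotype specification
# ---------------------------------------------------------------------------

PHENOTYPE_LABELS = ("epithelial", "mesenchymal", "toxic", "partial")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters of one simulated well phenotype.

    ``severity`` runs from 0 (fully epithelial / fully reverted) to 1
    (fully mesenchymal).  ``noise_sd`` is a dimensionless scale applied to
    the per-parameter noise SDs (profiles) and to the additive pixel noise
    (images); 0 gives noise-free output.
    """

    label: str = "mesenchymal"
    severity: float = 1.0
    nuclei_count_mean: float = 120.0
    islet_count_mean: float = 8.0
    islet_spread_px: float = 36.0
    fibronectin_level: float = 1800.0
    fibronectin_texture_scale: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPE_LABELS:
            raise ConfigurationError(f"unknown phenotype label {self.label!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ConfigurationError("severity must lie in [0, 1]")
        if self.label != "toxic" and self.nuclei_count_mean <= 0:
            raise ConfigurationError("nuclei_count_mean must be positive")
        for name in ("islet_spread_px", "fibronectin_level",
                     "fibronectin_texture_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.islet_count_mean <= 0:
            raise ConfigurationError("islet_count_mean must be positive")


def epithelial_spec(**kw) -> PhenotypeSpec:
    return PhenotypeSpec(label="epithelial", severity=0.0,
                         fibronectin_level=EPITHELIAL_ANCHOR["fn_mean_intensity"], **kw)


def mesenchymal_spec(**kw) -> PhenotypeSpec:
    return PhenotypeSpec(label="mesenchymal", severity=1.0, **kw)


def partial_spec(severity: float, **kw) -> PhenotypeSpec:
    return PhenotypeSpec(label="partial", severity=float(severity), **kw)


def toxic_spec(**kw) -> PhenotypeSpec:
    return PhenotypeSpec(label="toxic", severity=1.0, **kw)


# ---------------------------------------------------------------------------
# Image-level field synthesis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticField:
    """A simulated two-channel acquisition with ground truth.

    Images are float arrays in 16-bit camera units (0..65535); ``truth_centers``
    is an ``(n, 2)`` array of (row, col) nucleus centres and
    ``truth_colony_ids`` the islet index of each nucleus.
    """

    nuclei_image: np.ndarray
    fibronectin_image: np.ndarray
    truth_centers: np.ndarray
    truth_colony_ids: np.ndarray
    phenotype: PhenotypeSpec
    seed: int


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


def _hex_sites(center: np.ndarray, radius: float, pitch: float) -> np.ndarray:
    """Hexagonal lattice sites within a disc around ``center``."""
    n_rings = int(np.ceil(radius / (pitch * np.sqrt(3) / 2))) + 1
    rows = np.arange(-n_rings, n_rings + 1)
    sites = []
    for i in rows:
        y = i * pitch * np.sqrt(3) / 2
        x_off = 0.5 * pitch if i % 2 else 0.0
        xs = np.arange(-n_rings, n_rings + 1) * pitch + x_off
        for x in xs:
            if x * x + y * y <= radius * radius:
                sites.append((center[0] + y, center[1] + x))
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def simulate_field(spec: PhenotypeSpec, image_shape: tuple[int, int] = (256, 256),
                   seed: int = 0) -> SyntheticField:
    """Render one two-channel field for the given phenotype.

    Severity 0 places nuclei in tight Gaussian islets over low uniform
    fibronectin; severity 1 scatters nuclei near-uniformly over bright,
    band-pass-textured fibronectin.  Intermediate severities interpolate
    islet spread, islet count, fibronectin level and texture amplitude
    monotonically.  A toxic spec emits at most 20% of the nominal nuclei
    count.  Deterministic given ``seed``.
    """
    from scipy import ndimage as ndi

    shape = tuple(int(s) for s in image_shape)
    if len(shape) != 2 or min(shape) < 64:
        raise ConfigurationError("image_shape must be 2-D and at least 64x64")
    rng = np.random.default_rng(seed)
    h, w = shape
    sev = spec.severity

    # --- nucleus placement -------------------------------------------------
    if spec.label == "toxic":
        cap = int(np.floor(0.2 * spec.nuclei_count_mean))
        n_nuclei = int(min(rng.poisson(0.15 * spec.nuclei_count_mean), cap))
        sev_place = 1.0
    else:
        n_nuclei = max(2, int(rng.poisson(spec.nuclei_count_mean)))
        sev_place = sev

    # Islet count interpolates geometrically from the epithelial islet count
    # to one islet per nucleus (fully dispersed); the islet radius likewise
    # from half the configured spread to the field scale, so intermediate
    # severities remain visibly graded instead of saturating early.
    base_islets = max(1.0, spec.islet_count_mean)
    n_islets = int(round(base_islets * (n_nuclei / base_islets) ** sev_place))
    n_islets = int(np.clip(n_islets, 1, n_nuclei))
    r_islet = 0.5 * spec.islet_spread_px
    r_max = 0.75 * min(h, w)
    radius = r_islet * (r_max / r_islet) ** sev_place if r_islet > 0 else r_max
    margin = 8.0
    # Islet centres repel each other (distinct epithelial patches): greedy
    # best-candidate sampling keeps centres ~2 islet radii apart while the
    # phenotype is compact; for dispersed fields the separation target is
    # negligible relative to the islet radius and placement is ~uniform.
    sep_target = min(2.2 * radius, 0.45 * min(h, w))
    islet_centers = np.empty((n_islets, 2))
    for k in range(n_islets):
        cand = np.column_stack([rng.uniform(margin, h - margin, 30),
                                rng.uniform(margin, w - margin, 30)])
        if k == 0:
            islet_centers[0] = cand[0]
            continue
        dists = np.sqrt(((cand[:, None, :] - islet_centers[None, :k, :]) ** 2
                         ).sum(-1)).min(1)
        far = np.nonzero(dists >= sep_target)[0]
        islet_centers[k] = cand[far[0]] if len(far) else cand[int(np.argmax(dists))]
    islet_of = rng.integers(0, n_islets, n_nuclei)
    # Cells cannot overlap: nuclei occupy sites of a jittered hexagonal
    # lattice (pitch ~ one cell diameter) inside each islet disc, drawn at
    # random.  Compact islets pack their sites densely; a dispersed field is
    # a sparse random occupancy of the lattice, approximating uniform
    # placement with a hard core.
    pitch = 8.5
    jitter = 1.0
    placed = []
    counts = np.bincount(islet_of, minlength=n_islets)

    def in_bounds(sites: np.ndarray) -> np.ndarray:
        keep = ((sites[:, 0] >= 3) & (sites[:, 0] <= h - 4)
                & (sites[:, 1] >= 3) & (sites[:, 1] <= w - 4))
        return sites[keep]

    for k in range(n_islets):
        n_k = int(counts[k])
        if n_k == 0:
            continue
        r_k = radius
        sites = in_bounds(_hex_sites(islet_centers[k], r_k, pitch))
        while len(sites) < n_k:
            r_k *= 1.3
            sites = in_bounds(_hex_sites(islet_centers[k], r_k, pitch))
        chosen = sites[rng.permutation(len(sites))[:n_k]]
        chosen = chosen + rng.uniform(-jitter, jitter, chosen.shape)
        for pt in chosen:
            placed.append((k, pt))
    islet_of = np.array([k for k, _ in placed], dtype=int)
    centers = np.array([pt for _, pt in placed], dtype=float)
    centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    # relabel islets contiguously in order of first appearance
    _, islet_ids = np.unique(islet_of, return_inverse=True)

    # --- nuclei channel ----------------------------------------------------
    nuc = np.zeros(shape)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    sigma_n = 2.2
    peak = 3000.0
    for (r, c) in centers:
        r0, r1 = int(max(0, r - 12)), int(min(h, r + 13))
        c0, c1 = int(max(0, c - 12)), int(min(w, c + 13))
        rr = rows[r0:r1] - r
        cc = cols[:, c0:c1] - c
        nuc[r0:r1, c0:c1] += peak * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma_n ** 2))
    nuc += 100.0  # camera offset

    # --- fibronectin channel ----------------------------------------------
    base = _lerp(EPITHELIAL_ANCHOR["fn_mean_intensity"], spec.fibronectin_level, sev)
    cell_density = ndi.gaussian_filter((nuc - 100.0), 16.0)
    if cell_density.max() > 0:
        cell_density = cell_density / cell_density.max()
    white = rng.normal(0.0, 1.0, shape)
    texture = ndi.gaussian_filter(white, 1.5) - ndi.gaussian_filter(white, 6.0)
    tstd = texture.std()
    if tstd > 0:
        texture = texture / tstd
    amp = 0.45 * base * sev * spec.fibronectin_texture_scale
    fib = 100.0 + base * (0.25 + 0.75 * cell_density) + amp * texture * (0.2 + 0.8 * cell_density)

    if spec.noise_sd > 0:
        nuc = nuc + rng.normal(0.0, 30.0 * spec.noise_sd, shape)
        fib = fib + rng.normal(0.0, 30.0 * spec.noise_sd, shape)
    nuc = np.clip(nuc, 0.0, 65535.0)
    fib = np.clip(fib, 0.0, 65535.0)

    return SyntheticField(nuclei_image=nuc, fibronectin_image=fib,
                          truth_centers=centers, truth_colony_ids=islet_ids,
                          phenotype=spec, seed=int(seed))


def save_field_tiffs(fld: SyntheticField, directory, plate: str, well: str) -> list[str]:
    """Write the two channels as 16-bit grayscale TIFFs; returns the paths."""
    import pathlib

    import tifffile

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, img in (("nuclei", fld.nuclei_image), ("fibronectin", fld.fibronectin_image)):
        p = directory / f"{plate}_{well}_{channel}.tif"
        tifffile.imwrite(p, np.clip(np.round(img), 0, 65535).astype(np.uint16))
        paths.append(str(p))
    return paths


# ---------------------------------------------------------------------------
# Profile-level synthesis
# ---------------------------------------------------------------------------

def profile_mean(spec: PhenotypeSpec) -> np.ndarray:
    """Anchor-interpolated mean 18-parameter vector for a phenotype."""
    if spec.label == "toxic":
        return anchor_vector(TOXIC_ANCHOR)
    epi = anchor_vector(EPITHELIAL_ANCHOR)
    mes = anchor_vector(MESENCHYMAL_ANCHOR)
    return epi + (mes - epi) * spec.severity


def simulate_profile(spec: PhenotypeSpec, seed: int = 0) -> np.ndarray:
    """Draw one 18-parameter profile from the Gaussian phenotype family.

    Parameter means interpolate linearly between the epithelial and
    mesenchymal anchors with severity.  The noise around the mean is a
    one-factor Gaussian model: a latent well factor (cell density/staining)
    contributes its signed loading fraction of each parameter's SD, the rest
    is independent, so marginal SDs equal the stored assay SDs scaled by
    ``spec.noise_sd``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    mean = profile_mean(spec)
    sd = sd_vector("toxic" if spec.label == "toxic" else "default")
    loading = loading_vector()
    u = rng.normal()
    resid = rng.normal(0.0, 1.0, mean.shape)
    noise = loading * u + np.sqrt(1.0 - loading ** 2) * resid
    return mean + noise * sd * spec.noise_sd


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------

WELL_ROLES = ("neg_dmso", "pos_control", "tox_control", "library", "empty")

PLATE_DIMS = {96: (8, 12), 384: (16, 24)}

#: Positive-control dose ladder (uM), strongest first; the top two
#: concentrations define the "strong" control wells used for the
#: EMT-cluster vote and the TPR denominator.
CONTROL_LADDER_UM = (10.0, 3.0, 1.0, 0.3, 0.1)

#: Reference receptor-kinase-inhibitor potencies used by the generator for
#: the positive-control severity ladder (uM).
CONTROL_IC50_UM = {"GW6604": 1.9, "LY-364947": 0.2}
#: Effective cooperativity of phenotype collapse along the control ladder.
#: EMT maintenance responds ultrasensitively to receptor-kinase inhibition,
#: so the top two ladder concentrations act as near-complete ("strong")
#: reversal standards while mid-ladder points are graded partial phenotypes.
CONTROL_HILL = 3.5
TOX_CONTROL_COMPOUND = "staurosporine"
TOX_CONTROL_CONC_UM = 0.1


def well_ids(plate_format: int) -> list[str]:
    nrow, ncol = PLATE_DIMS[plate_format]
    return [f"{r}{c:02d}" for r in string.ascii_uppercase[:nrow]
            for c in range(1, ncol + 1)]


def validate_well_id(well: str, plate_format: int) -> bool:
    nrow, ncol = PLATE_DIMS[plate_format]
    if len(well) != 3 or well[0] not in string.ascii_uppercase[:nrow]:
        return False
    try:
        col = int(well[1:])
    except ValueError:
        return False
    return 1 <= col <= ncol


@dataclass(frozen=True)
class WellSpec:
    role: str
    compound_id: str | None = None
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise ConfigurationError(f"unknown well role {self.role!r}")
        if self.compound_id is not None and self.concentration_uM is not None:
            if self.concentration_uM <= 0:
                raise ConfigurationError("concentration must be positive")


@dataclass
class PlateLayout:
    """Role, compound and concentration of every well on one plate."""

    plate_id: str
    plate_format: int
    wells: dict[str, WellSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_DIMS:
            raise ConfigurationError("plate_format must be 96 or 384")
        for wid in self.wells:
            if not validate_well_id(wid, self.plate_format):
                raise ConfigurationError(
                    f"well id {wid!r} invalid for a {self.plate_format}-well plate")

    def to_yaml(self, path) -> None:
        doc = {
            "plate_id": self.plate_id,
            "plate_format": self.plate_format,
            "wells": {
                wid: {"role": ws.role, "compound_id": ws.compound_id,
                      "concentration_uM": ws.concentration_uM}
                for wid, ws in self.wells.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        wells = {wid: WellSpec(role=w["role"], compound_id=w.get("compound_id"),
                               concentration_uM=w.get("concentration_uM"))
                 for wid, w in doc["wells"].items()}
        return cls(plate_id=doc["plate_id"], plate_format=int(doc["plate_format"]),
                   wells=wells)


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``active_compounds`` maps compound id to its true severity reduction in
    ``(0, 1]``; ``receptor_like`` marks which actives also block p-Smad2
    nuclear translocation (general receptor-kinase inhibitors rather than
    late-stage plasticity modulators).
    """

    active_compounds: dict[str, float] = field(default_factory=dict)
    toxic_compounds: set[str] = field(default_factory=set)
    inactive_compounds: set[str] = field(default_factory=set)
    receptor_like: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        act = set(self.active_compounds)
        if act & self.toxic_compounds or act & self.inactive_compounds \
                or self.toxic_compounds & self.inactive_compounds:
            raise ConfigurationError("truth classes must be disjoint")
        if not self.receptor_like <= act:
            raise ConfigurationError("receptor_like must be a subset of actives")

    def classify(self, compound_id: str) -> str:
        if compound_id in self.active_compounds:
            return "active"
        if compound_id in self.toxic_compounds:
            return "toxic"
        return "inactive"


def control_severity(compound_id: str, concentration_uM: float,
                     hill: float = CONTROL_HILL) -> float:
    """Residual EMT severity of a positive-control well.

    A receptor-kinase inhibitor at concentration ``c`` suppresses the
    TGF-beta phenotype with fractional inhibition ``c^h / (c^h + IC50^h)``;
    the residual severity is one minus that.
    """
    ic50 = CONTROL_IC50_UM[compound_id]
    c = float(concentration_uM)
    if c <= 0:
        raise ConfigurationError("concentration must be positive")
    inh = c ** hill / (c ** hill + ic50 ** hill)
    return 1.0 - inh


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------

ID_COLUMNS = ("plate", "well", "role", "compound_id", "concentration_uM", "severity")


def _spec_for_well(ws: WellSpec, truth: ScreenTruth, noise_sd: float) -> PhenotypeSpec:
    if ws.role == "neg_dmso":
        return PhenotypeSpec(label="mesenchymal", severity=1.0, noise_sd=noise_sd)
    if ws.role == "tox_control":
        return toxic_spec(noise_sd=noise_sd)
    if ws.role == "pos_control":
        sev = control_severity(ws.compound_id, ws.concentration_uM)
        return partial_spec(sev, noise_sd=noise_sd)
    if ws.role == "library":
        if ws.compound_id is None or (
                ws.compound_id not in truth.active_compounds
                and ws.compound_id not in truth.toxic_compounds
                and ws.compound_id not in truth.inactive_compounds):
            raise ConfigurationError(f"library compound {ws.compound_id!r} not in truth")
        if ws.compound_id in truth.toxic_compounds:
            return toxic_spec(noise_sd=noise_sd)
        reduction = truth.active_compounds.get(ws.compound_id, 0.0)
        return partial_spec(1.0 - reduction, noise_sd=noise_sd)
    raise ConfigurationError(f"role {ws.role!r} has no phenotype")


def simulate_plate(layout: PlateLayout, truth: ScreenTruth,
                   plate_effect: np.ndarray | float | None = None,
                   seed: int = 0, noise_sd: float = 1.0,
                   with_images: bool = False,
                   image_shape: tuple[int, int] = (192, 192)):
    """Simulate one plate at profile level (optionally with images).

    Returns a DataFrame of well records: identity columns followed by the 18
    raw parameter columns.  ``plate_effect`` is an additive per-parameter
    offset applied uniformly to every well of the plate (scalar or length-18
    vector).  With ``with_images=True`` a dict well-id -> SyntheticField is
    returned alongside; the profile row for those wells still comes from the
    profile family (image analysis is the consumer's job).
    """
    if plate_effect is None:
        offset = np.zeros(len(PARAMETER_NAMES))
    else:
        offset = np.broadcast_to(np.asarray(plate_effect, dtype=float),
                                 (len(PARAMETER_NAMES),)).copy()
    rng = np.random.default_rng(seed)
    rows = []
    fields = {}
    for wid in sorted(layout.wells):
        ws = layout.wells[wid]
        if ws.role == "empty":
            continue
        spec = _spec_for_well(ws, truth, noise_sd)
        sub = int(rng.integers(0, 2 ** 31 - 1))
        vec = simulate_profile(spec, seed=sub) + offset
        rows.append({
            "plate": layout.plate_id, "well": wid, "role": ws.role,
            "compound_id": ws.compound_id, "concentration_uM": ws.concentration_uM,
            "severity": spec.severity if spec.label != "toxic" else np.nan,
            **dict(zip(PARAMETER_NAMES, vec)),
        })
        if with_images:
            fields[wid] = simulate_field(spec, image_shape, seed=sub)
    df = pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(PARAMETER_NAMES))
    if with_images:
        return df, fields
    return df


def sample_plate_effect(seed: int, scale: float = 0.5) -> np.ndarray:
    """Draw an additive per-parameter plate effect.

    Offset SD = ``scale`` x assay SD x the parameter's plate-effect
    susceptibility (object counts, the validity flag and the plate-calibrated
    contrast fraction are insensitive to batch shifts).
    """
    rng = np.random.default_rng(seed)
    susceptibility = np.array([PLATE_EFFECT_SUSCEPTIBILITY[p]
                               for p in PARAMETER_NAMES])
    return rng.normal(0.0, 1.0, len(PARAMETER_NAMES)) * sd_vector() * scale * susceptibility


# ---------------------------------------------------------------------------
# Default desk-scale screen
# ---------------------------------------------------------------------------

def default_layout(plate_id: str, plate_format: int = 384,
                   library_ids: list[str] | None = None) -> PlateLayout:
    """Control layout of one screen plate.

    Columns 1 and 24 carry negative (DMSO + TGF-beta) and toxicity
    (staurosporine) controls; columns 2 and 23 carry the two positive-control
    dose ladders; the interior columns are library wells.
    """
    nrow, ncol = PLATE_DIMS[plate_format]
    rows_ = string.ascii_uppercase[:nrow]
    wells: dict[str, WellSpec] = {}
    for r in rows_:
        wells[f"{r}01"] = WellSpec("neg_dmso")
    half = nrow // 2
    for i, r in enumerate(rows_):
        wells[f"{r}{ncol:02d}"] = (WellSpec("neg_dmso") if i < half else
                                   WellSpec("tox_control", TOX_CONTROL_COMPOUND,
                                            TOX_CONTROL_CONC_UM))
    ladder_cols = {2: "GW6604", ncol - 1: "LY-364947"}
    # distribute the column's wells over the ladder, extra replicates to the
    # strongest concentrations (those anchor the Z' and the TPR)
    n_conc = len(CONTROL_LADDER_UM)
    base, rem = divmod(nrow, n_conc)
    counts = [base + 1] * rem + [base] * (n_conc - rem)
    conc_per_row = [CONTROL_LADDER_UM[i] for i, k in enumerate(counts) for _ in range(k)]
    for col, compound in ladder_cols.items():
        for r, conc in zip(rows_, conc_per_row):
            wells[f"{r}{col:02d}"] = WellSpec("pos_control", compound, conc)
    lib_cols = [c for c in range(1, ncol + 1) if c not in (1, 2, ncol - 1, ncol)]
    lib_iter = iter(library_ids or [])
    for c in lib_cols:
        for r in rows_:
            cid = next(lib_iter, None)
            if cid is None:
                wells[f"{r}{c:02d}"] = WellSpec("empty")
            else:
                wells[f"{r}{c:02d}"] = WellSpec("library", cid, 10.0)
    return PlateLayout(plate_id=plate_id, plate_format=plate_format, wells=wells)


def default_screen(n_plates: int = 4, plate_format: int = 384,
                   active_fraction: float = 0.01, n_toxic: int = 6,
                   receptor_like_fraction: float = 0.25,
                   min_reduction: float = 0.8, seed: int = 0,
                   ) -> tuple[list[PlateLayout], ScreenTruth]:
    """Build the default desk-scale screen: layouts plus ground truth.

    Defaults mirror the control structure of a 384-well receptor-inhibitor
    screen at desk scale: ``n_plates`` x 384 wells, 1% planted active
    compounds with true severity reductions drawn uniformly from
    ``[min_reduction, 1]``, a handful of planted toxic compounds, and a
    quarter of the actives flagged receptor-like for the counter-screen.
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = PLATE_DIMS[plate_format]
    per_plate = nrow * (ncol - 4)
    n_lib = n_plates * per_plate
    lib_ids = [f"CMP{idx:05d}" for idx in range(n_lib)]
    n_active = int(round(active_fraction * n_lib))
    special = rng.choice(n_lib, size=n_active + n_toxic, replace=False)
    active_idx = special[:n_active]
    toxic_idx = special[n_active:]
    reductions = rng.uniform(min_reduction, 1.0, n_active)
    active = {lib_ids[i]: float(r) for i, r in zip(active_idx, reductions)}
    toxic = {lib_ids[i] for i in toxic_idx}
    inactive = set(lib_ids) - set(active) - toxic
    n_rec = int(round(receptor_like_fraction * n_active))
    rec = ({str(c) for c in rng.choice(sorted(active), size=n_rec, replace=False)}
           if n_rec else set())
    truth = ScreenTruth(active_compounds=active, toxic_compounds=toxic,
                        inactive_compounds=inactive, receptor_like=rec)
    layouts = [default_layout(f"P{p + 1:03d}", plate_format,
                              lib_ids[p * per_plate:(p + 1) * per_plate])
               for p in range(n_plates)]
    return layouts, truth


def simulate_screen(layouts: list[PlateLayout], truth: ScreenTruth,
                    seed: int = 0, noise_sd: float = 1.0,
                    plate_effect_scale: float = 0.5) -> pd.DataFrame:
    """Simulate every plate of a screen with independent additive plate effects."""
    rng = np.random.default_rng(seed)
    frames = []
    for layout in layouts:
        eff_seed = int(rng.integers(0, 2 ** 31 - 1))
        plate_seed = int(rng.integers(0, 2 ** 31 - 1))
        eff = sample_plate_effect(eff_seed, plate_effect_scale)
        frames.append(simulate_plate(layout, truth, plate_effect=eff,
                                     seed=plate_seed, noise_sd=noise_sd))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Dose-response and dilution series
# ---------------------------------------------------------------------------

def make_dilution_grid(top_conc: float, n_points: int, factor: float) -> np.ndarray:
    """Descending geometric dilution series starting at ``top_conc``."""
    if top_conc <= 0 or n_points < 2 or factor <= 1:
        raise ConfigurationError("need top_conc > 0, n_points >= 2, factor > 1")
    return top_conc / factor ** np.arange(n_points, dtype=float)


def simulate_dose_series(ic50_true: float, hill: float, top: float, bottom: float,
                         concentrations, noise_sd: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Responses on a 4PL curve with additive Gaussian noise.

    ``response(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``, so the
    curve runs from ``top`` at c -> 0 to ``bottom`` at c -> infinity (for
    positive hill).
    """
    if ic50_true <= 0:
        raise ConfigurationError("ic50_true must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ConfigurationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    resp = bottom + (top - bottom) / (1.0 + (c / ic50_true) ** hill)
    resp = resp + rng.normal(0.0, noise_sd, c.shape)
    return pd.DataFrame({"concentration_uM": c, "response": resp})


# ---------------------------------------------------------------------------
# p-Smad2 translocation fields
# ---------------------------------------------------------------------------

#: Nuclear:cytoplasmic p-Smad2 ratio anchors.  TGF-beta stimulation drives
#: phosphorylated Smad2 into the nucleus within the hour; a saturating
#: receptor-kinase inhibitor returns the ratio to the unstimulated baseline.
RATIO_STIMULATED = 3.0
RATIO_UNSTIMULATED = 1.2


@dataclass
class TranslocationField:
    """Three-compartment counter-screen field with ground truth."""

    nuclei_image: np.ndarray
    psmad2_image: np.ndarray
    nuclei_labels: np.ndarray
    truth_ratio: float
    inhibition: float


def simulate_translocation_field(inhibition: float, n_cells: int = 64,
                                 seed: int = 0, noise_sd: float = 0.0,
                                 ) -> TranslocationField:
    """Render a p-Smad2 field at a given translocation inhibition.

    Cells are laid out on a jittered grid; each has a disk nucleus
    (radius 5 px) inside a cytoplasm annulus (outer radius 10 px).  The
    nuclear p-Smad2 intensity is ``ratio x cytoplasmic`` where the ratio
    interpolates linearly from the stimulated anchor (inhibition 0) to the
    unstimulated anchor (inhibition 1).  Deterministic given ``seed``.
    """
    if not 0.0 <= inhibition <= 1.0:
        raise ConfigurationError("inhibition must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ratio = RATIO_STIMULATED + inhibition * (RATIO_UNSTIMULATED - RATIO_STIMULATED)
    cyto_level = 1000.0
    nuc_level = ratio * cyto_level
    r_nuc, r_cyt, pitch = 5, 10, 26
    ncol = int(np.ceil(np.sqrt(n_cells)))
    nrow = int(np.ceil(n_cells / ncol))
    h = nrow * pitch + pitch
    w = ncol * pitch + pitch
    nuclei = np.zeros((h, w))
    psmad = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=int)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    k = 0
    for i in range(nrow):
        for j in range(ncol):
            if k >= n_cells:
                break
            k += 1
            cy = (i + 1) * pitch + rng.uniform(-2, 2)
            cx = (j + 1) * pitch + rng.uniform(-2, 2)
            d2 = (rows - cy) ** 2 + (cols - cx) ** 2
            nuc_mask = d2 <= r_nuc ** 2
            cyt_mask = (d2 <= r_cyt ** 2) & ~nuc_mask
            nuclei[nuc_mask] = 4000.0
            psmad[nuc_mask] = nuc_level
            psmad[cyt_mask] = cyto_level
            labels[nuc_mask] = k
    if noise_sd > 0:
        nuclei = np.clip(nuclei + rng.normal(0, noise_sd, nuclei.shape), 0, None)
        psmad = np.clip(psmad + rng.normal(0, noise_sd, psmad.shape), 0, None)
    return TranslocationField(nuclei_image=nuclei, psmad2_image=psmad,
                              nuclei_labels=labels, truth_ratio=float(ratio),
                              inhibition=float(inhibition))
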