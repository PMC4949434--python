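"""End-to-end orchestration of the screening pipeline.

``run_pipeline`` chains the stages on a synthetic screen: generation ->
normalisation -> QC -> hit calling -> dose-response of the control ladders
-> p-Smad2 counter-screen of the hit list, writing every intermediate as
CSV/YAML under a run directory together with the configuration and a
structured per-stage log.  Everything is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import countersmad, doseresp, hitcall, screenqc, synthdata
from .parameters import PARAMETER_NAMES
from .platenorm import Z_PREFIX, normalize_screen
from .synthdata import ConfigurationError

logger = logging.getLogger("emtscreen")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    n_plates: int = 4
    plate_format: int = 384
    active_fraction: float = 0.01
    n_toxic_compounds: int = 6
    min_reduction: float = 0.8
    receptor_like_fraction: float = 0.25
    noise_sd: float = 1.0
    plate_effect_scale: float = 0.5
    robust: bool = True
    per_plate_z: bool = False
    k: int = 5
    strength_threshold: float = 15.0
    n_init: int = 25
    min_nuclei: float = 10.0
    qc_pass_threshold: float = 0.5
    inhibition_cut: float = 0.5
    counter_wells_per_anchor: int = 8
    counter_cells_per_well: int = 49
    output_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    run_dir: pathlib.Path
    raw: pd.DataFrame
    normalized: pd.DataFrame
    norm_stats: object
    qc: screenqc.QcReport
    hits: hitcall.HitCallResult
    dose_fits: pd.DataFrame
    median_ic50: dict[str, float]
    counter_table: pd.DataFrame
    replicate_r_mean: float
    summary: dict = field(default_factory=dict)


def _derive_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def control_dose_fits(normalized: pd.DataFrame, z_params: list[str],
                      seed: int = 0) -> tuple[pd.DataFrame, dict[str, float]]:
    """4PL fits of every z-parameter along each positive-control ladder."""
    frames = []
    medians = {}
    pos = normalized[normalized["role"] == "pos_control"]
    for compound, grp in pos.groupby("compound_id"):
        tidy = pd.concat([
            pd.DataFrame({
                "parameter": p,
                "concentration_uM": grp["concentration_uM"].to_numpy(),
                "response": grp[Z_PREFIX + p].to_numpy(dtype=float),
            }) for p in z_params
        ], ignore_index=True)
        fits, med = doseresp.fit_compound(tidy, seed=seed)
        frame = doseresp.fits_to_frame(fits)
        frame.insert(0, "compound_id", compound)
        frames.append(frame)
        medians[str(compound)] = med
    return pd.concat(frames, ignore_index=True), medians


def run_counter_screen(hits: hitcall.HitCallResult, truth: synthdata.ScreenTruth,
                       config: RunConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate and quantify the p-Smad2 counter-screen for the hit list.

    Anchor wells (stimulated DMSO and a saturating reference receptor
    inhibitor) are simulated on the same run; each hit compound's true
    translocation inhibition is drawn from Beta(8, 2) for receptor-like
    truth and Beta(2, 8) otherwise, rendered as a field, and measured back
    through the ring-based nuclear:cytoplasmic ratio.
    """
    rng = np.random.default_rng(seed)
    cs_cfg = countersmad.CounterScreenConfig(
        inhibition_cut=config.inhibition_cut,
        strength_floor=config.strength_threshold)

    def well_ratio(inhibition: float) -> float:
        fld = synthdata.simulate_translocation_field(
            inhibition, n_cells=config.counter_cells_per_well,
            seed=int(rng.integers(0, 2 ** 31 - 1)), noise_sd=20.0 * config.noise_sd)
        _, med = countersmad.nc_ratio(fld.nuclei_labels, fld.psmad2_image,
                                      cs_cfg.ring_width, cs_cfg.background_quantile,
                                      cs_cfg.min_cells)
        return med

    n_anchor = config.counter_wells_per_anchor
    r_stim = float(np.median([well_ratio(0.0) for _ in range(n_anchor)]))
    r_inh = float(np.median([well_ratio(1.0) for _ in range(n_anchor)]))

    compounds = hits.hit_compounds["compound_id"].tolist()
    ratios, truths = {}, {}
    for cid in compounds:
        if cid in truth.receptor_like:
            true_inh = float(rng.beta(8, 2))
        else:
            true_inh = float(rng.beta(2, 8))
        truths[cid] = true_inh
        ratios[cid] = well_ratio(true_inh)
    strengths = hits.hit_compounds.set_index("compound_id")["max_strength"]
    table = countersmad.counter_screen_table(
        strengths, pd.Series(ratios, dtype=float).reindex(strengths.index),
        r_stim, r_inh, cs_cfg)
    table["true_inhibition"] = pd.Series(truths).reindex(table.index)
    table["true_receptor_like"] = [cid in truth.receptor_like for cid in table.index]
    table.index.name = "compound_id"
    return table.reset_index()


def run_pipeline(config: RunConfig, run_dir=None, truth=None,
                 layouts=None) -> PipelineResult:
    """Execute the full pipeline and persist every artifact.

    Supplying ``layouts``/``truth`` overrides the default generated screen
    (used for what-if runs); otherwise both come from the config seed.
    """
    base = config.seed
    if run_dir is None:
        run_dir = pathlib.Path(config.output_dir) / f"run_{config.digest()}"
    run_dir = pathlib.Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    if layouts is None or truth is None:
        layouts, truth = synthdata.default_screen(
            n_plates=config.n_plates, plate_format=config.plate_format,
            active_fraction=config.active_fraction,
            n_toxic=config.n_toxic_compounds,
            receptor_like_fraction=config.receptor_like_fraction,
            min_reduction=config.min_reduction,
            seed=_derive_seed(base, "screen"))
    for layout in layouts:
        layout.to_yaml(run_dir / f"layout_{layout.plate_id}.yaml")
    logger.info("stage=simulate plates=%d", len(layouts))

    raw = synthdata.simulate_screen(layouts, truth,
                                    seed=_derive_seed(base, "profiles"),
                                    noise_sd=config.noise_sd,
                                    plate_effect_scale=config.plate_effect_scale)
    raw.to_csv(run_dir / "features_raw.csv", index=False)
    logger.info("stage=features wells=%d", len(raw))

    normalized, stats = normalize_screen(raw, robust=config.robust,
                                         per_plate_z=config.per_plate_z)
    normalized.to_csv(run_dir / "features_normalized.csv", index=False)
    with open(run_dir / "normalization_stats.yaml", "w") as fh:
        yaml.safe_dump(stats.to_dict(), fh)
    logger.info("stage=normalize params=%d dropped=%s",
                len(stats.z_parameters), stats.dropped_parameters)

    qc = screenqc.qc_screen(normalized, stats.z_parameters, robust=config.robust,
                            pass_threshold=config.qc_pass_threshold)

    # replicate reproducibility: an independent noise realisation of the run
    raw2 = synthdata.simulate_screen(layouts, truth,
                                     seed=_derive_seed(base, "replicate"),
                                     noise_sd=config.noise_sd,
                                     plate_effect_scale=config.plate_effect_scale)
    norm2, stats2 = normalize_screen(raw2, robust=config.robust,
                                     per_plate_z=config.per_plate_z)
    shared = [p for p in stats.z_parameters if p in stats2.z_parameters]
    zcols = [Z_PREFIX + p for p in shared]
    key_cols = ["plate", "well"]
    r_series, r_mean = screenqc.replicate_correlation(
        normalized[key_cols + zcols], norm2[key_cols + zcols], zcols,
        keys=tuple(key_cols))
    qc.replicate_r = {c.removeprefix(Z_PREFIX): float(v)
                      for c, v in r_series.items()}
    qc.replicate_r_mean = r_mean
    with open(run_dir / "qc_report.yaml", "w") as fh:
        yaml.safe_dump(qc.to_dict(), fh)
    logger.info("stage=qc plates_pass=%d/%d replicate_r=%.3f",
                sum(qc.plate_pass.values()), len(qc.plate_pass), r_mean)

    hc_cfg = hitcall.HitCallConfig(
        k=config.k, strength_threshold=config.strength_threshold,
        n_init=config.n_init, min_nuclei=config.min_nuclei)
    if config.k == 1:
        logger.warning("k=1: cluster-based hit calling degenerates to a "
                       "pure strength threshold")
    hits = hitcall.run_hit_calling(normalized, stats.z_parameters, hc_cfg,
                                   seed=_derive_seed(base, "kmeans"), truth=truth)
    hits.records.to_csv(run_dir / "wells_scored.csv", index=False)
    hits.hit_compounds.to_csv(run_dir / "hit_list.csv", index=False)
    logger.info("stage=hits clean=%d toxic=%d hits=%d", len(hits.records),
                len(hits.toxic_records), len(hits.hit_compounds))

    dose_fits, medians = control_dose_fits(normalized, stats.z_parameters,
                                           seed=_derive_seed(base, "dose"))
    dose_fits.to_csv(run_dir / "dose_response_fits.csv", index=False)

    counter = run_counter_screen(hits, truth, config,
                                 seed=_derive_seed(base, "counter"))
    counter.to_csv(run_dir / "counter_screen.csv", index=False)
    logger.info("stage=counterscreen compounds=%d", len(counter))

    summary = {
        "config_digest": config.digest(),
        "n_wells": int(len(raw)),
        "n_hit_compounds": int(len(hits.hit_compounds)),
        "evaluation": hits.evaluation.to_dict(),
        "emt_cluster": {"id": hits.emt_cluster.cluster_id,
                        "control_fraction": hits.emt_cluster.control_fraction,
                        "needs_review": hits.emt_cluster.needs_review},
        "run_median_zprime": qc.run_median_zprime,
        "replicate_r_mean": float(r_mean),
        "median_ic50_uM": medians,
        "counter_classes": counter["class"].value_counts().to_dict(),
    }
    with open(run_dir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return PipelineResult(config=config, run_dir=run_dir, raw=raw,
                          normalized=normalized, norm_stats=stats, qc=qc,
                          hits=hits, dose_fits=dose_fits, median_ic50=medians,
                          counter_table=counter, replicate_r_mean=r_mean,
                          summary=summary)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

REQUIRED_FEATURE_COLUMNS = ("plate", "well", "role", "compound_id",
                            "concentration_uM") + tuple(PARAMETER_NAMES)


def validate_io(feature_csv=None, layout_yaml=None, tiff_paths=()) -> dict:
    """Pre-flight validation of user inputs; nothing is silently coerced.

    Returns ``{"ok": bool, "errors": [...]}`` listing every schema violation:
    missing feature columns, well ids inconsistent with the plate format,
    unreadable TIFFs.
    """
    errors = []
    if feature_csv is not None:
        df = pd.read_csv(feature_csv, nrows=5)
        missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
        if missing:
            errors.append(f"feature table missing columns: {missing}")
    if layout_yaml is not None:
        try:
            layout = synthdata.PlateLayout.from_yaml(layout_yaml)
        except (ConfigurationError, KeyError, yaml.YAMLError) as exc:
            errors.append(f"layout invalid: {exc}")
        else:
            for wid in layout.wells:
                if not synthdata.validate_well_id(wid, layout.plate_format):
                    errors.append(
                        f"well id {wid!r} invalid for {layout.plate_format}-well plate")
    for path in tiff_paths:
        try:
            import tifffile
            tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - report, never crash
            errors.append(f"unreadable TIFF {path}: {exc}")
    return {"ok": not errors, "errors": errors}
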