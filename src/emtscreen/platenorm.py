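"""Plate-wise robust percent-of-control and per-parameter z-scoring.

The screen's normalisation runs in two stages.  First, every parameter of
every well is expressed as a robust percent-of-control (POC): 100 times the
raw value divided by the *median* of the plate's negative-control wells
(DMSO vehicle on the TGF-beta-stimulated background), which removes additive
and multiplicative plate effects relative to the plate's own biology.
Second, each parameter's POC values are z-scored across the whole run
against a robust reference (median / 1.4826 x MAD of all valid library and
vehicle wells), putting all 18 parameters on a common dimensionless scale so
Euclidean distances between profiles are meaningful.

The z reference population is library + vehicle wells because library wells
are overwhelmingly inactive: hits then appear as outliers at z far from 0
while the reference itself sits at median 0, scaled-MAD 1.  Both robust and
classical moments, and per-run versus per-plate z, are exposed as switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for Gaussians

POC_PREFIX = "poc_"
Z_PREFIX = "z_"


class NormalizationError(ValueError):
    """Raised when a plate or run fails the normalisation preconditions."""


@dataclass
class NormalizationStats:
    """Audit trail of one normalisation run."""

    plate_neg_medians: dict[str, dict[str, float]] = field(default_factory=dict)
    screen_location: dict[str, float] = field(default_factory=dict)
    screen_scale: dict[str, float] = field(default_factory=dict)
    dropped_parameters: list[str] = field(default_factory=list)
    unusable_plate_parameters: dict[str, list[str]] = field(default_factory=dict)

    @property
    def z_parameters(self) -> list[str]:
        return [p for p in PARAMETER_NAMES if p not in self.dropped_parameters]

    def to_dict(self) -> dict:
        return {
            "plate_neg_medians": self.plate_neg_medians,
            "screen_location": self.screen_location,
            "screen_scale": self.screen_scale,
            "dropped_parameters": self.dropped_parameters,
            "unusable_plate_parameters": self.unusable_plate_parameters,
        }


def _valid_mask(df: pd.DataFrame) -> pd.Series:
    if "valid_field" in df.columns:
        return df["valid_field"] >= 0.5
    return pd.Series(True, index=df.index)


def robust_poc(records: pd.DataFrame, params=PARAMETER_NAMES,
               min_neg_wells: int = 8, stats: NormalizationStats | None = None,
               ) -> pd.DataFrame:
    """Robust percent-of-control normalisation, plate by plate.

    For each plate and parameter: ``poc = 100 * raw / median(raw over valid
    negative-control wells)``.  A plate with fewer than ``min_neg_wells``
    valid negatives fails QC (raises); a parameter whose negative median is
    zero is flagged unusable on that plate and its POC set to NaN.
    Returns a copy of ``records`` with ``poc_``-prefixed columns appended.
    """
    stats = stats if stats is not None else NormalizationStats()
    out = records.copy()
    for p in params:
        out[POC_PREFIX + p] = np.nan
    for plate, grp in records.groupby("plate", sort=False):
        neg = grp[(grp["role"] == "neg_dmso") & _valid_mask(grp)]
        if len(neg) < min_neg_wells:
            raise NormalizationError(
                f"plate {plate!r}: only {len(neg)} valid negative-control wells "
                f"(need {min_neg_wells})")
        medians = {}
        unusable = []
        for p in params:
            med = float(neg[p].median())
            medians[p] = med
            if med == 0 or not np.isfinite(med):
                unusable.append(p)
            else:
                out.loc[grp.index, POC_PREFIX + p] = 100.0 * grp[p] / med
        stats.plate_neg_medians[str(plate)] = medians
        if unusable:
            stats.unusable_plate_parameters[str(plate)] = unusable
    return out


def _location_scale(values: np.ndarray, robust: bool) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if robust:
        loc = float(np.median(values))
        scale = MAD_SCALE * float(np.median(np.abs(values - loc)))
    else:
        loc = float(np.mean(values))
        scale = float(np.std(values, ddof=1))
    return loc, scale


def zscore_per_parameter(poc_records: pd.DataFrame, params=PARAMETER_NAMES,
                         robust: bool = True, per_plate: bool = False,
                         reference_roles: tuple[str, ...] = ("library", "neg_dmso"),
                         min_reference: int = 100,
                         stats: NormalizationStats | None = None,
                         ) -> tuple[pd.DataFrame, NormalizationStats]:
    """Per-parameter z-scoring of POC values across the run.

    ``z = (poc - location) / scale`` with robust (median, 1.4826 x MAD) or
    classical (mean, SD) moments estimated on the reference population (all
    valid wells whose role is in ``reference_roles``; toxicity controls never
    enter).  A parameter with zero scale carries no information on this run
    and is dropped — recorded in the returned stats, and its ``z_`` column
    omitted so every downstream consumer sees a consistent dimension.
    """
    stats = stats if stats is not None else NormalizationStats()
    out = poc_records.copy()
    ref_mask = poc_records["role"].isin(reference_roles) & _valid_mask(poc_records)
    if per_plate:
        groups = [(plate, grp) for plate, grp in poc_records.groupby("plate", sort=False)]
    else:
        groups = [(None, poc_records)]
    n_ref = int(ref_mask.sum())
    if n_ref < min_reference:
        raise NormalizationError(
            f"only {n_ref} reference wells (need {min_reference})")
    dropped = set()
    for p in params:
        col = POC_PREFIX + p
        zcol = Z_PREFIX + p
        if per_plate:
            out[zcol] = np.nan
            for plate, grp in groups:
                vals = grp.loc[ref_mask.reindex(grp.index, fill_value=False), col].to_numpy()
                loc, scale = _location_scale(vals, robust)
                if scale == 0 or not np.isfinite(scale):
                    dropped.add(p)
                    continue
                out.loc[grp.index, zcol] = (grp[col] - loc) / scale
        else:
            vals = poc_records.loc[ref_mask, col].to_numpy()
            loc, scale = _location_scale(vals, robust)
            stats.screen_location[p] = loc
            stats.screen_scale[p] = scale
            if scale == 0 or not np.isfinite(scale):
                dropped.add(p)
                continue
            out[zcol] = (out[col] - loc) / scale
    stats.dropped_parameters = sorted(dropped)
    for p in dropped:
        if Z_PREFIX + p in out.columns:
            out = out.drop(columns=[Z_PREFIX + p])
    return out, stats


def normalize_screen(records: pd.DataFrame, params=PARAMETER_NAMES,
                     robust: bool = True, per_plate_z: bool = False,
                     min_neg_wells: int = 8,
                     ) -> tuple[pd.DataFrame, NormalizationStats]:
    """POC then z-score; the normalised profiles all statistics consume."""
    stats = NormalizationStats()
    poc = robust_poc(records, params, min_neg_wells=min_neg_wells, stats=stats)
    z, stats = zscore_per_parameter(poc, params, robust=robust,
                                    per_plate=per_plate_z, stats=stats)
    return z, stats


def z_matrix(df: pd.DataFrame, stats: NormalizationStats) -> np.ndarray:
    """The (wells x parameters) z-profile matrix in canonical order."""
    cols = [Z_PREFIX + p for p in stats.z_parameters]
    return df[cols].to_numpy(dtype=float)
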