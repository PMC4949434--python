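"""Assay-quality statistics: univariate and multivariate Z'-factor,
replicate reproducibility.

The Z'-factor, ``1 - 3 (s_pos + s_neg) / |m_pos - m_neg|``, measures how
cleanly a control population separates from the negative controls; values
above 0.5 are conventionally "excellent" for screening.  For a
multi-parametric assay the profiles are first scalarised as their Euclidean
distance to the negative-control centroid (the phenotypic strength axis)
and the univariate formula is applied to the two distance samples.  Robust
moments (median, 1.4826 x MAD) are the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .platenorm import MAD_SCALE


def _moments(values: np.ndarray, robust: bool) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if robust:
        m = float(np.median(values))
        s = MAD_SCALE * float(np.median(np.abs(values - m)))
    else:
        m = float(np.mean(values))
        s = float(np.std(values, ddof=1))
    return m, s


def zprime_univariate(positive, negative, robust: bool = True) -> float:
    """Z'-factor between two control populations of scalar readouts.

    Returns ``-inf`` when the locations coincide (no separation at all).
    Requires at least 4 values per group.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 4 or len(neg) < 4:
        raise ValueError("need at least 4 values per control group")
    m_p, s_p = _moments(pos, robust)
    m_n, s_n = _moments(neg, robust)
    if m_p == m_n:
        return float("-inf")
    return 1.0 - 3.0 * (s_p + s_n) / abs(m_p - m_n)


def profile_distance(profile: np.ndarray, reference_centroid: np.ndarray) -> float:
    """Euclidean distance of one profile to a reference centroid."""
    p = np.asarray(profile, dtype=float)
    c = np.asarray(reference_centroid, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {c.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(c))):
        raise ValueError("profiles must be finite")
    return float(np.linalg.norm(p - c))


def negative_centroid(negative_profiles: np.ndarray, robust: bool = True) -> np.ndarray:
    """Coordinate-wise median (or mean) of the negative-control profiles."""
    neg = np.asarray(negative_profiles, dtype=float)
    return np.median(neg, axis=0) if robust else np.mean(neg, axis=0)


def zprime_multivariate(positive_profiles, negative_profiles,
                        robust: bool = True,
                        scalarize: str = "neg_centroid") -> float:
    """Z'-factor of a multi-parametric assay via distance scalarisation.

    Every profile in both groups is reduced to its Euclidean distance to the
    negative-control centroid (``scalarize="neg_centroid"``, the phenotypic
    strength convention) or to its own group centroid
    (``scalarize="own_centroid"``); the univariate Z' of the two distance
    samples is returned.
    """
    pos = np.asarray(positive_profiles, dtype=float)
    neg = np.asarray(negative_profiles, dtype=float)
    if pos.ndim != 2 or neg.ndim != 2 or pos.shape[1] != neg.shape[1]:
        raise ValueError("profile groups must be 2-D with matching width")
    cn = negative_centroid(neg, robust)
    if scalarize == "neg_centroid":
        cp = cn
    elif scalarize == "own_centroid":
        cp = np.median(pos, axis=0) if robust else np.mean(pos, axis=0)
    else:
        raise ValueError(f"unknown scalarization {scalarize!r}")
    d_pos = np.linalg.norm(pos - cp, axis=1)
    d_neg = np.linalg.norm(neg - cn, axis=1)
    return zprime_univariate(d_pos, d_neg, robust=robust)


def replicate_correlation(run1: pd.DataFrame, run2: pd.DataFrame,
                          params: list[str],
                          keys: tuple[str, ...] = ("plate", "well"),
                          min_pairs: int = 10) -> tuple[pd.Series, float]:
    """Pearson r per parameter between two runs matched on ``keys``.

    Correlations are computed on the (already normalised) values so plate
    effects cannot inflate them.  Returns the per-parameter series and its
    mean.  Raises on unmatched keys, listing them.
    """
    k = list(keys)
    merged = run1.merge(run2, on=k, suffixes=("_1", "_2"), how="outer",
                        indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", k]
    if len(unmatched):
        raise ValueError(
            f"unmatched keys between runs: {unmatched.to_records(index=False).tolist()[:10]}")
    if len(merged) < min_pairs:
        raise ValueError(f"only {len(merged)} matched pairs (need {min_pairs})")
    rs = {}
    for p in params:
        a = merged[p + "_1"].to_numpy(dtype=float)
        b = merged[p + "_2"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        rs[p] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    series = pd.Series(rs)
    return series, float(series.mean())


@dataclass
class QcReport:
    """Per-plate and run-level assay-quality summary."""

    plate_zprime_univariate: dict[str, dict[str, float]] = field(default_factory=dict)
    plate_zprime_multivariate: dict[str, dict[str, float]] = field(default_factory=dict)
    run_median_zprime: dict[str, float] = field(default_factory=dict)
    replicate_r: dict[str, float] = field(default_factory=dict)
    replicate_r_mean: float = float("nan")
    plate_pass: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "plate_zprime_univariate": self.plate_zprime_univariate,
            "plate_zprime_multivariate": self.plate_zprime_multivariate,
            "run_median_zprime": self.run_median_zprime,
            "replicate_r": self.replicate_r,
            "replicate_r_mean": self.replicate_r_mean,
            "plate_pass": self.plate_pass,
        }


def qc_screen(normalized: pd.DataFrame, z_params: list[str],
              robust: bool = True, pass_threshold: float = 0.5) -> QcReport:
    """Per-plate multivariate Z' per control condition.

    The positive-control Z' is computed per compound at its top ladder
    concentration (the strongest, best-separated condition); the toxicity
    Z' uses all toxicity-control wells.  A plate passes QC when its
    strongest positive-control Z' and its toxicity Z' both reach
    ``pass_threshold``.  Run-level summaries are the medians over plates.
    """
    from .platenorm import Z_PREFIX

    report = QcReport()
    cols = [Z_PREFIX + p for p in z_params]

    def _profiles(sub: pd.DataFrame) -> np.ndarray:
        prof = sub[cols].to_numpy(dtype=float)
        return prof[np.all(np.isfinite(prof), axis=1)]

    per_condition: dict[str, list[float]] = {}
    for plate, grp in normalized.groupby("plate", sort=False):
        neg = _profiles(grp[grp["role"] == "neg_dmso"])
        entry: dict[str, float] = {}
        pos = grp[grp["role"] == "pos_control"]
        for compound, cgrp in pos.groupby("compound_id"):
            top = cgrp["concentration_uM"].max()
            prof = _profiles(cgrp[cgrp["concentration_uM"] == top])
            zp = (zprime_multivariate(prof, neg, robust=robust)
                  if len(prof) >= 4 and len(neg) >= 4 else float("nan"))
            entry[f"pos:{compound}"] = zp
        tox = _profiles(grp[grp["role"] == "tox_control"])
        entry["tox_control"] = (zprime_multivariate(tox, neg, robust=robust)
                                if len(tox) >= 4 and len(neg) >= 4 else float("nan"))
        report.plate_zprime_multivariate[str(plate)] = entry
        for cond, zp in entry.items():
            per_condition.setdefault(cond, []).append(zp)
        pos_vals = [v for k, v in entry.items()
                    if k.startswith("pos:") and np.isfinite(v)]
        report.plate_pass[str(plate)] = bool(
            pos_vals and max(pos_vals) >= pass_threshold
            and np.isfinite(entry["tox_control"])
            and entry["tox_control"] >= pass_threshold)
    for cond, vals in per_condition.items():
        finite = [v for v in vals if np.isfinite(v)]
        report.run_median_zprime[cond] = float(np.median(finite)) if finite else float("nan")
    return report
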