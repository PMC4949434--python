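"""Four-parameter logistic (4PL) dose-response fitting and median IC50.

Each measurement parameter of a control compound traces its own
dose-response curve; every curve is fitted with the 4PL model

    r(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

by least squares on log10 concentration, and the compound's potency is
summarised as the median IC50 over the successfully fitted parameters.
The Hill slope is box-constrained to [0.2, 5] (geometric 5-8 point ladders
cannot support steeper or shallower slopes meaningfully); curve direction is
absorbed by top/bottom, so relabelling the asymptotes leaves the IC50
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

HILL_BOUNDS = (0.2, 5.0)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    status: str                 # "fit" | "no fit"
    outside_range: bool = False  # IC50 outside the tested concentration span
    parameter: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "fit"


def four_pl(c: np.ndarray, bottom: float, top: float, ic50: float,
            hill: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _initial_guess(logc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(logc)
    lo_end = float(np.mean(resp[order[:2]]))    # response at low concentration -> top
    hi_end = float(np.mean(resp[order[-2:]]))   # response at high concentration -> bottom
    top0, bottom0 = lo_end, hi_end
    mid = 0.5 * (top0 + bottom0)
    # half-response crossing on the sorted curve
    idx = int(np.argmin(np.abs(resp[order] - mid)))
    logic50 = float(logc[order[idx]])
    return bottom0, top0, logic50, 1.0


def fit_4pl(concentrations, responses, parameter: str | None = None,
            noise_floor: float | None = None, n_restarts: int = 3,
            seed: int = 0) -> FourPLFit:
    """Least-squares 4PL fit of one parameter's dose-response.

    Requires >= 5 distinct concentrations spanning >= 2 log units.  Flat
    data — dynamic range under twice the noise estimate (default: residual
    SD around the mean) — gets status ``"no fit"``.  A deterministic
    initialiser from the data extremes and the half-response crossing plus
    ``n_restarts`` seeded jittered restarts guard against local minima; the
    best RSS wins, at a convergence tolerance of 1e-10 on relative RSS.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    ok = np.isfinite(c) & np.isfinite(r)
    c, r = c[ok], r[ok]
    if len(np.unique(c)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    logc = np.log10(c)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("concentrations must span at least 2 log units")

    dynamic = float(r.max() - r.min())
    if noise_floor is None:
        noise_floor = float(np.std(r - np.mean(r), ddof=1)) * 0.1 + 1e-12
    if dynamic < 2.0 * noise_floor or dynamic == 0.0:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.nan, "no fit",
                         parameter=parameter)

    def residuals(theta):
        bottom, top, logic50, hill = theta
        return four_pl(c, bottom, top, 10.0 ** logic50, hill) - r

    span = dynamic
    lo = [r.min() - 2 * span, r.min() - 2 * span, logc.min() - 2.0, HILL_BOUNDS[0]]
    hi = [r.max() + 2 * span, r.max() + 2 * span, logc.max() + 2.0, HILL_BOUNDS[1]]
    theta0 = np.clip(np.asarray(_initial_guess(logc, r)), lo, hi)
    rng = np.random.default_rng(seed)
    best = None
    starts = [theta0]
    for _ in range(n_restarts):
        jitter = theta0 + rng.normal(0, [0.1 * span + 1e-9, 0.1 * span + 1e-9, 0.5, 0.3])
        starts.append(np.clip(jitter, lo, hi))
    for start in starts:
        sol = least_squares(residuals, start, bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-10, gtol=1e-12, max_nfev=2000)
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    rss, (bottom, top, logic50, hill) = best
    ic50 = float(10.0 ** logic50)
    flat_rss = float(np.sum((r - r.mean()) ** 2))
    if rss > flat_rss:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, rss, "no fit",
                         parameter=parameter)
    outside = not (c.min() <= ic50 <= c.max())
    return FourPLFit(float(bottom), float(top), ic50, float(hill), rss, "fit",
                     outside_range=outside, parameter=parameter)


def median_ic50(fits: list[FourPLFit]) -> float:
    """Median IC50 over the successfully fitted parameters (NaN if none)."""
    vals = [f.ic50 for f in fits if f.ok]
    if not vals:
        return float("nan")
    return float(np.median(vals))


def fit_compound(tidy: pd.DataFrame, seed: int = 0) -> tuple[list[FourPLFit], float]:
    """Fit every measurement parameter of one compound from a tidy table.

    ``tidy`` columns: ``parameter``, ``concentration_uM``, ``response``.
    Returns the per-parameter fits and the median IC50.
    """
    fits = []
    for param, grp in tidy.groupby("parameter", sort=False):
        try:
            fits.append(fit_4pl(grp["concentration_uM"], grp["response"],
                                parameter=str(param), seed=seed))
        except ValueError:
            fits.append(FourPLFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                                  "no fit", parameter=str(param)))
    return fits, median_ic50(fits)


def fits_to_frame(fits: list[FourPLFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": f.parameter, "bottom": f.bottom, "top": f.top,
        "ic50_uM": f.ic50, "hill": f.hill, "rss": f.rss, "status": f.status,
        "outside_range": f.outside_range,
    } for f in fits])
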