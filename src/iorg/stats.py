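"""Cohort-level statistics for structure-function comparisons.

Demographic summaries, ordinary least-squares fits with 95% prediction
intervals (the dashed bands around structure-function regressions),
Spearman rank correlations against microperimetry, and nearest-
eccentricity pairing of iORG sampling locations with retinal
sensitivity measurements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "SensitivityRecord",
    "summarize_ages",
    "linear_fit_with_pi",
    "predict_with_pi",
    "spearman",
    "pair_sensitivity",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided test of zero slope
    x: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray  # pointwise prediction interval
    band_upper: np.ndarray
    level: float
    _model: object = None


@dataclass
class SensitivityRecord:
    """One microperimetry measurement: eccentricity (deg) and sensitivity (dB).

    Sensitivity spans 0-36 dB, 0 dB being the brightest stimulus the
    device can present and 36 dB the dimmest.
    """

    eccentricity: float
    sensitivity: float

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 36:
            raise ValueError("sensitivity must lie in [0, 36] dB")


def summarize_ages(ages) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of ages."""
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("age summary needs n >= 2")
    return float(ages.mean()), float(ages.std(ddof=1))


def linear_fit_with_pi(x, y, level: float = 0.95) -> RegressionResult:
    """OLS fit of y on x with pointwise prediction intervals.

    The prediction interval bounds the spread of a *new observation* at
    each x (wider than the confidence band for the mean response), which
    is the band used to flag individual measurements as outside the
    normative relationship.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linear fit needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is degenerate (all values equal)")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(X).summary_frame(alpha=1 - level)
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        x=x,
        fitted=pred["mean"].to_numpy(),
        band_lower=pred["obs_ci_lower"].to_numpy(),
        band_upper=pred["obs_ci_upper"].to_numpy(),
        level=level,
        _model=res,
    )


def predict_with_pi(fit: RegressionResult, x_new) -> pd.DataFrame:
    """Prediction and prediction interval of the fit at new x values."""
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    pred = fit._model.get_prediction(sm.add_constant(x_new, has_constant="add"))
    frame = pred.summary_frame(alpha=1 - fit.level)
    return pd.DataFrame(
        {
            "x": x_new,
            "predicted": frame["mean"].to_numpy(),
            "pi_lower": frame["obs_ci_lower"].to_numpy(),
            "pi_upper": frame["obs_ci_upper"].to_numpy(),
        }
    )


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks on ties
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x, y, exact_limit: int = 8, mc_limit: int = 20, n_resamples: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with a sample-size-adapted p-value.

    * n <= ``exact_limit``: exact permutation null (full enumeration);
    * n <= ``mc_limit``: seeded Monte-Carlo permutation null;
    * larger n: the usual t-approximation.

    Two-sided p throughout; ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    n = x.size
    rho = _spearman_rho(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if n <= exact_limit:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif n <= mc_limit:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_resamples, n)), axis=1)
        rhos = (ryc[perms] @ rxc) / denom
        hits = 1 + int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
        p = hits / (n_resamples + 1)
    else:
        _, p = sps.spearmanr(x, y)
        p = float(p)
    return rho, float(p)


def pair_sensitivity(
    iorg_locations, sensitivities: list[SensitivityRecord]
) -> pd.DataFrame:
    """Pair each iORG sampling location with the nearest-eccentricity sensitivity.

    Ties in |Δ eccentricity| resolve to the sensitivity measured at the
    smaller eccentricity.
    """
    locs = np.atleast_1d(np.asarray(iorg_locations, dtype=float))
    if locs.size == 0 or len(sensitivities) == 0:
        raise ValueError("both location and sensitivity lists must be non-empty")
    # sort by (eccentricity) so that argmin on ties picks the smaller one
    recs = sorted(sensitivities, key=lambda r: r.eccentricity)
    ecc = np.array([r.eccentricity for r in recs])
    sens = np.array([r.sensitivity for r in recs])
    rows = []
    for loc in locs:
        i = int(np.argmin(np.abs(ecc - loc)))  # first minimum = smaller ecc on tie
        rows.append(
            {
                "iorg_eccentricity_deg": float(loc),
                "sensitivity_eccentricity_deg": float(ecc[i]),
                "sensitivity_db": float(sens[i]),
                "pairing_distance_deg": float(abs(ecc[i] - loc)),
            }
        )
    return pd.DataFrame(rows)
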