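"""Box-Cox normal modeling of the global enrichment-score distribution.

The null model assumes that, absent enrichment, suitably transformed scores
are normally distributed. Raw score distributions are strongly right-skewed
(a large unenriched majority plus an enriched tail), so scores are passed
through the Box-Cox power family

    t = (y**lam - 1) / lam      (lam != 0)
    t = ln(y)                   (lam == 0)

with ``lam`` chosen by profile-likelihood maximization. Goodness of fit is
judged by the squared Pearson correlation of the normal Q-Q point set; when
the fit passes, a one-sided upper-tail critical value at the chosen alpha
yields significance calls and per-position p-values. When it fails, a
percentile-rank cutoff is the fallback (no p-values attached).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError

LAMBDA_BOUNDS = (-5.0, 5.0)
DEFAULT_R2_CUTOFF = 0.90
DEFAULT_ALPHA = 0.05
DEFAULT_PERCENTILE = 95.0


@dataclass
class NormalFit:
    """Fitted normal model of Box-Cox-transformed enrichment scores."""

    lam: float
    mu: float
    sigma: float
    r_squared: float
    alpha: float
    r2_cutoff: float
    critical_transformed: float
    critical_raw: float

    @property
    def passed_normality(self) -> bool:
        return self.r_squared >= self.r2_cutoff


def _as_positive_array(scores) -> np.ndarray:
    arr = np.asarray(scores, dtype=np.float64)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise DegenerateDataError("no scores supplied")
    if not np.all(arr > 0):
        raise ValueError("Box-Cox requires strictly positive scores")
    return arr


def boxcox_transform(scores, lam: float) -> np.ndarray:
    """Apply the Box-Cox transform at a fixed exponent ``lam``."""
    arr = _as_positive_array(scores)
    if lam == 0:
        return np.log(arr)
    return (np.power(arr, lam) - 1.0) / lam


def inverse_boxcox(values, lam: float):
    """Invert the Box-Cox transform.

    For ``lam > 0`` arguments below the transform's lower bound map to 0 (no
    positive score transforms there, so every score exceeds the threshold);
    for ``lam < 0`` arguments above the upper bound map to +inf.
    """
    vals = np.asarray(values, dtype=np.float64)
    scalar = vals.ndim == 0
    vals = np.atleast_1d(vals)
    if lam == 0:
        out = np.exp(vals)
    else:
        base = 1.0 + lam * vals
        out = np.empty_like(vals)
        ok = base > 0
        out[ok] = np.power(base[ok], 1.0 / lam)
        out[~ok] = 0.0 if lam > 0 else np.inf
    return float(out[0]) if scalar else out


def boxcox_mle(scores) -> float:
    """Maximum-likelihood Box-Cox exponent over a bounded search interval.

    Maximizes the profile log-likelihood on lam in [-5, 5] with a bounded
    scalar optimizer (absolute tolerance 1e-5).
    """
    arr = _as_positive_array(scores)
    if np.unique(arr).size < 10:
        raise DegenerateDataError(
            "need at least 10 distinct positive scores to estimate the "
            "Box-Cox exponent"
        )
    result = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, arr),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(result.x)


def qq_points(transformed) -> tuple[np.ndarray, np.ndarray]:
    """Ordered sample values paired with standard-normal quantiles.

    Plotting positions are (i - 0.5) / n.
    """
    arr = np.sort(np.asarray(transformed, dtype=np.float64))
    n = arr.size
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, arr


def qq_r_squared(transformed) -> float:
    """Squared Pearson correlation of the full normal Q-Q point set."""
    theoretical, ordered = qq_points(transformed)
    if np.std(ordered) == 0:
        raise DegenerateDataError("transformed scores have zero variance")
    r = np.corrcoef(theoretical, ordered)[0, 1]
    return float(r * r)


def qq_fit(
    transformed,
    lam: float,
    alpha: float = DEFAULT_ALPHA,
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
) -> NormalFit:
    """Fit the normal model to transformed scores and set critical values.

    ``mu`` and ``sigma`` are the sample mean and standard deviation;
    ``r_squared`` measures Q-Q linearity against the standard normal.
    """
    arr = np.asarray(transformed, dtype=np.float64)
    if arr.size < 10:
        raise DegenerateDataError("need at least 10 scores to fit the model")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    if sigma == 0:
        raise DegenerateDataError("transformed scores have zero variance")
    r2 = qq_r_squared(arr)
    fit = NormalFit(
        lam=lam,
        mu=mu,
        sigma=sigma,
        r_squared=r2,
        alpha=alpha,
        r2_cutoff=r2_cutoff,
        critical_transformed=math.nan,
        critical_raw=math.nan,
    )
    fit.critical_transformed, fit.critical_raw = critical_value(fit, alpha)
    return fit


def critical_value(fit: NormalFit, alpha: float) -> tuple[float, float]:
    """One-sided upper-tail critical value on the transformed and raw scales.

    ``critical_transformed = mu + sigma * z_{1-alpha}``; the raw-scale value
    is its inverse Box-Cox image. Enrichment is directional, so only the
    upper tail is ever tested.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    ct = fit.mu + fit.sigma * stats.norm.ppf(1.0 - alpha)
    return float(ct), float(inverse_boxcox(ct, fit.lam))


def position_pvalues(transformed, fit: NormalFit) -> np.ndarray:
    """Upper-tail p-values of transformed scores under the fitted normal."""
    arr = np.asarray(transformed, dtype=np.float64)
    return stats.norm.sf((arr - fit.mu) / fit.sigma)


def percentile_cutoff(
    scores, percentile: float = DEFAULT_PERCENTILE
) -> tuple[float, np.ndarray]:
    """Rank-based fallback: call the top (100 - percentile)% of scores.

    Returns the raw-score cutoff (the smallest called score) and a boolean
    mask of called positions; ties at the cutoff are all included. No
    p-values are attached to percentile calls.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    arr = _as_positive_array(scores)
    n = arr.size
    k = math.ceil(n * (100.0 - percentile) / 100.0)
    k = max(k, 1)
    cutoff = float(np.sort(arr)[n - k])
    called = arr >= cutoff
    if called.all() and np.unique(arr).size == 1:
        warnings.warn(
            "all scores identical: percentile cutoff degenerates to calling "
            "every position",
            stacklevel=2,
        )
    return cutoff, called
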