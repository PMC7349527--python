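"""Hill dose-response fits of hypocotyl growth and thermotolerance metrics.

Growth after a short heat treatment at temperature x follows

    growth(x) = max / (1 + (x / T50)**(-H))

with T50 the temperature of half-maximal growth (the thermotolerance
metric) and H the signed Hill slope (negative for growth decreasing with
temperature; its magnitude measures thermosensitivity).  From a fit, ECp is
the temperature producing a fractional growth *reduction* p, so EC10 < T50
< EC90 for decreasing curves, and the eustress range is the interval
(EC10, EC90) over which growth is modulated rather than abolished.  The
slope and the range are tied by the identity

    |H| * log10(EC90 / EC10) = log10(81).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def hill_growth(x, gmax, t50, hill):
    """Growth at temperature ``x`` under the Hill dose-response model."""
    x = np.asarray(x, dtype=float)
    return gmax / (1.0 + (x / t50) ** (-hill))


class FitError(RuntimeError):
    """Raised when the dose-response fit cannot be performed or fails."""


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with Jacobian-based standard errors."""

    max: float
    t50: float
    hill: float
    se_max: float
    se_t50: float
    se_hill: float
    rss: float
    n_obs: int
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.t50 <= 0:
            raise ValueError("t50 must be positive")

    def predict(self, x):
        return hill_growth(x, self.max, self.t50, self.hill)


def _check_fit_data(x: np.ndarray, y: np.ndarray) -> None:
    if len(np.unique(x)) < 4:
        raise FitError("need at least 4 distinct temperatures to fit")
    half = y.max() / 2.0
    if not ((y > half).any() and (y < half).any()):
        raise FitError(
            "degenerate data: no observations on both sides of half-maximal "
            "growth; the transition is outside the measured temperature range"
        )


def fit_hill(
    data: pd.DataFrame,
    genotype: str | None = None,
    normalized: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
) -> HillFit:
    """Least-squares fit of the Hill model to one genotype's growth data.

    Parameters
    ----------
    data
        Growth table with columns ``temperature_C`` and either
        ``growth_normalized`` (used when ``normalized``, the default) or
        ``growth_cm_per_day``; optionally pre-filtered to one genotype,
        otherwise pass ``genotype``.
    normalized
        Fit on the fraction-of-untreated scale (growth divided by the mean
        growth at the lowest temperature when no normalized column exists).

    All replicates are fit jointly.  Five jittered restarts around a
    data-driven initialization guard against local minima; the best
    residual sum of squares wins.  Standard errors come from the
    Jacobian-based covariance at the optimum.
    """
    df = data if genotype is None else data[data["genotype"] == genotype]
    if df.empty:
        raise FitError(f"no growth data for genotype {genotype!r}")
    x = df["temperature_C"].to_numpy(dtype=float)
    if normalized:
        if "growth_normalized" in df.columns:
            y = df["growth_normalized"].to_numpy(dtype=float)
        else:
            y = df["growth_cm_per_day"].to_numpy(dtype=float)
            base = y[x == x.min()].mean()
            if base <= 0:
                raise FitError("cannot normalize: zero growth at the lowest temperature")
            y = y / base
    else:
        y = df["growth_cm_per_day"].to_numpy(dtype=float)
    _check_fit_data(x, y)

    # sort for order invariance of the optimizer path
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    def residuals(theta):
        return hill_growth(x, *theta) - y

    gmax0 = float(y[x == x.min()].mean())
    half = gmax0 / 2.0
    t50_0 = float(x[np.argmin(np.abs(y - half))])
    t50_0 = min(max(t50_0, x.min()), x.max())
    inits = [(gmax0, t50_0, -10.0)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts - 1):
        inits.append(
            (
                gmax0 * rng.uniform(0.8, 1.2),
                t50_0 * rng.uniform(0.95, 1.05),
                -10.0 * rng.uniform(0.3, 3.0),
            )
        )

    best = None
    lo = (1e-9, x.min() * 0.5, -500.0)
    hi = (np.inf, x.max() * 1.5, -1e-3)
    for theta0 in inits:
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        except Exception:  # singular Jacobian etc.
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("Hill fit did not converge from any restart")

    rss = float(2.0 * best.cost)
    dof = max(len(y) - 3, 1)
    jac = best.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    gmax, t50, hill = best.x
    return HillFit(
        max=float(gmax),
        t50=float(t50),
        hill=float(hill),
        se_max=float(se[0]),
        se_t50=float(se[1]),
        se_hill=float(se[2]),
        rss=rss,
        n_obs=len(y),
        genotype=genotype,
    )


def ec(fit: HillFit, p: float) -> float:
    """Temperature of fractional growth reduction ``p`` (EC50 == T50).

    Solves growth(x) = (1 - p) * max for x, giving
    x = T50 * (p / (1 - p)) ** (-1 / H).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.hill == 0:
        raise ValueError("hill slope is zero; EC undefined")
    return float(fit.t50 * (p / (1.0 - p)) ** (-1.0 / fit.hill))


def eustress_range(fit: HillFit) -> tuple[float, float, float]:
    """(EC10, EC90, width): the responsive temperature zone of the genotype.

    Width shrinks as the slope magnitude grows; in the step-function limit
    (|H| -> inf) it vanishes.  For any fit,
    EC90 / EC10 = 81 ** (1 / |H|).
    """
    ec10 = ec(fit, 0.10)
    ec90 = ec(fit, 0.90)
    return ec10, ec90, ec90 - ec10


def hill_magnitude_from_ec(ec10: float, ec90: float) -> float:
    """|H| recovered from the EC ratio via |H| = log10(81)/log10(EC90/EC10)."""
    return math.log10(81.0) / abs(math.log10(ec90 / ec10))


def fit_all_genotypes(data: pd.DataFrame, normalized: bool = True, seed: int = 0) -> pd.DataFrame:
    """Fit every genotype in a growth table; one row per genotype.

    Columns: genotype, max, se_max, t50, se_t50, hill, se_hill, ec10, ec90,
    eustress_width, rss.
    """
    rows = []
    for g in pd.unique(data["genotype"]):
        fit = fit_hill(data, genotype=g, normalized=normalized, seed=seed)
        ec10, ec90, width = eustress_range(fit)
        rows.append(
            {
                "genotype": g,
                "max": fit.max,
                "se_max": fit.se_max,
                "t50": fit.t50,
                "se_t50": fit.se_t50,
                "hill": fit.hill,
                "se_hill": fit.se_hill,
                "ec10": ec10,
                "ec90": ec90,
                "eustress_width": width,
                "rss": fit.rss,
            }
        )
    return pd.DataFrame(rows)
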