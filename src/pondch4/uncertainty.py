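"""Sensitivity and uncertainty analysis for inventory totals.

Two complementary views of parameter uncertainty:

* a *spider* (one-at-a-time) analysis re-evaluating national totals with each
  parameter set to the bounds of its 95% confidence interval, the others held
  at their means — the flux at 15 °C (M15) and the water-surface error act
  multiplicatively on totals, while the activation energy E_M reweights warm
  vs cool pond-months and needs a re-evaluation;
* Monte-Carlo propagation drawing all parameters jointly (log-normal for M15
  and the multiplicative water-surface error, matching their asymmetric /
  positive-only CIs; normal for E_M) and reporting 2.5/50/97.5 percentiles of
  the total per financial year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pondch4.emissions import ArrheniusParams

__all__ = [
    "DEFAULT_SURFACE_ERROR_CV",
    "coefficient_of_variation",
    "sensitivity_spider",
    "propagate_ci",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054

#: Default coefficient of variation (fraction) of the multiplicative
#: water-surface prediction error used in sensitivity / Monte-Carlo runs.
DEFAULT_SURFACE_ERROR_CV = 0.42


def coefficient_of_variation(se: float, mean: float) -> float | None:
    """CV in percent: ``100 * se / |mean|``; ``None`` when the mean is zero."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if mean == 0:
        logger.warning("CV undefined for zero mean")
        return None
    return 100.0 * se / abs(mean)


def _surface_ci_from_cv(cv: float) -> tuple[float, float]:
    """95% CI of a mean-one log-normal multiplicative error with this CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(-_Z95 * sigma)), float(np.exp(_Z95 * sigma))


def _require_tier3(results) -> ArrheniusParams:
    if not isinstance(results.model, ArrheniusParams):
        raise TypeError(
            "sensitivity/uncertainty propagation applies to the tier-3 "
            "(Boltzmann–Arrhenius) inventory"
        )
    return results.model


def sensitivity_spider(
    results,
    surface_error_ci: tuple[float, float] | None = None,
    fy: int | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the national total over parameter CIs.

    Parameters
    ----------
    results : :class:`~pondch4.aggregation.InventoryResults` (tier 3).
    surface_error_ci : multiplicative (lower, upper) 95% bounds on predicted
        water surface; defaults to a log-normal error with
        :data:`DEFAULT_SURFACE_ERROR_CV`.
    fy : financial year to evaluate (default: final reported year).

    Returns a table with one row per parameter per bound
    (``2.5% | mean | 97.5%``): the re-evaluated national total (kt CH4) and
    its relative change versus the mean run. M15 and the surface error scale
    totals exactly linearly; E_M re-evaluates every pond-month flux.
    """
    params = _require_tier3(results)
    if fy is None:
        fy = results.years[1]
    if surface_error_ci is None:
        surface_error_ci = _surface_ci_from_cv(DEFAULT_SURFACE_ERROR_CV)

    baseline = results.total_emissions(fy)
    pm = results.pond_months
    pm_fy = pm[pm["fy"] == fy]
    g = 1.0 / params.t_ref - 1.0 / (pm_fy["temp_c"].to_numpy() + 273.15)
    area = pm_fy["area_ha"].to_numpy()

    def em_total(e_m: float) -> float:
        flux = params.m15 * np.exp((e_m / params.k_b) * g)
        return float(np.sum(flux * area / 12.0)) / 1e3

    rows = []
    bounds = ("2.5%", "mean", "97.5%")
    specs = {
        "M15": [
            baseline * b / params.m15
            for b in (params.m15_ci[0], params.m15, params.m15_ci[1])
        ],
        "E_M": [
            em_total(e)
            for e in (params.e_m_ci[0], params.e_m, params.e_m_ci[1])
        ],
        "water_surface": [
            baseline * f for f in (surface_error_ci[0], 1.0, surface_error_ci[1])
        ],
    }
    for name, totals in specs.items():
        mean_total = totals[1]
        for bound, total in zip(bounds, totals):
            rows.append(
                {
                    "parameter": name,
                    "bound": bound,
                    "total_emissions_kt": total,
                    "relative_change_pct": (total - mean_total)
                    / mean_total
                    * 100.0,
                }
            )
    return pd.DataFrame(rows)


def _lognormal_sigma(ci: tuple[float, float]) -> float:
    lo, hi = ci
    if lo <= 0 or hi <= 0:
        raise ValueError(
            f"log-normal CI bounds must be positive, got {ci}"
        )
    return (np.log(hi) - np.log(lo)) / (2.0 * _Z95)


def propagate_ci(
    results,
    n_draws: int = 1000,
    seed: int = 0,
    surface_error_cv: float = DEFAULT_SURFACE_ERROR_CV,
) -> pd.DataFrame:
    """Monte-Carlo 95% CI of national emissions per financial year.

    Draws, per replicate: M15 from a log-normal matched to its asymmetric 95%
    CI; E_M from a normal matched to its CI; a multiplicative water-surface
    error from a mean-one log-normal with coefficient of variation
    `surface_error_cv`. Each replicate re-evaluates every pond-month emission;
    the table reports the 2.5/50/97.5 percentiles per financial year.
    Reproducible given `seed`.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    params = _require_tier3(results)
    rng = np.random.default_rng(seed)

    sigma_m15 = _lognormal_sigma(params.m15_ci)
    sigma_em = (params.e_m_ci[1] - params.e_m_ci[0]) / (2.0 * _Z95)
    if surface_error_cv < 0:
        raise ValueError("surface_error_cv must be non-negative")
    sigma_s = np.sqrt(np.log1p(surface_error_cv**2))

    m15_draws = params.m15 * np.exp(rng.normal(0.0, 1.0, n_draws) * sigma_m15)
    em_draws = params.e_m + rng.normal(0.0, 1.0, n_draws) * sigma_em
    # mean-one multiplicative error
    surf_draws = np.exp(
        rng.normal(0.0, 1.0, n_draws) * sigma_s - 0.5 * sigma_s**2
    )

    pm = results.pond_months
    fy_values = np.sort(pm["fy"].unique())
    fy_codes = pd.Categorical(pm["fy"], categories=fy_values).codes
    g = 1.0 / params.t_ref - 1.0 / (pm["temp_c"].to_numpy() + 273.15)
    area = pm["area_ha"].to_numpy()

    totals = np.empty((n_draws, len(fy_values)))
    for i in range(n_draws):
        w = np.exp((em_draws[i] / params.k_b) * g) * area
        totals[i] = (
            np.bincount(fy_codes, weights=w, minlength=len(fy_values))
            * m15_draws[i]
            * surf_draws[i]
            / 12.0
            / 1e3
        )

    pct = np.percentile(totals, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "financial_year": fy_values,
            "emissions_kt_lower": pct[0],
            "emissions_kt_median": pct[1],
            "emissions_kt_upper": pct[2],
        }
    )
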