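"""Pond inventory filtering, establishment-year detection and accumulation.

A national pond census observes the *present* landscape; an inventory time
series needs to know when each pond appeared. Establishment years are read
off per-pond water-fraction series (first year water is consistently present
over a quarter of the pond's surface), small undetectable ponds are imputed by
assuming they accumulated at the same relative rate as detectable ones, and
regional accumulation rates drive backcasting/projection of pond counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionGrowth",
    "circularity",
    "filter_inventory",
    "detect_establishment_year",
    "accumulation_rates",
    "apply_national_fallback",
    "project_counts",
    "small_pond_extrapolation",
]

logger = logging.getLogger(__name__)

#: Smallest pond whose wetting history is resolvable at 30 m pixel size
#: (three Landsat pixels), in hectares.
MIN_DETECTABLE_AREA_HA = 0.27

#: Wet fraction of the maximum surface that counts as "established".
ESTABLISHMENT_THRESHOLD = 0.25

SQM_PER_HA = 10_000.0


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity ``4*pi*area / perimeter**2``.

    `area` and `perimeter` must use consistent length units (e.g. m² and m).
    Equals 1 for a circle and is < 1 for every other simple shape; low values
    flag complex, likely natural waterbodies.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    out = 4.0 * math.pi * area / perimeter**2
    return out if out.ndim else float(out)


def filter_inventory(
    ponds: pd.DataFrame,
    max_area_cap: float = 10.0,
    circ_min: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the size and shape filters that separate farm dams from natural
    waterbodies.

    Retains ponds with ``max_area_ha <= max_area_cap`` and circularity above
    `circ_min` (computed from ``max_area_ha`` and ``perimeter_m``; a pond with
    no recorded perimeter passes the shape filter with a logged warning).

    Returns ``(retained, rejections)`` where `rejections` has columns
    ``id`` and ``reason`` ("area" or "shape"); retained + rejected partition
    the input.
    """
    required = {"id", "max_area_ha"}
    missing = required - set(ponds.columns)
    if missing:
        raise ValueError(f"pond table missing columns: {sorted(missing)}")

    area_ok = ponds["max_area_ha"] <= max_area_cap
    if "perimeter_m" in ponds.columns:
        perim = ponds["perimeter_m"]
        has_perim = perim.notna() & (perim > 0)
        circ = pd.Series(np.nan, index=ponds.index)
        circ[has_perim] = (
            4.0
            * math.pi
            * ponds.loc[has_perim, "max_area_ha"]
            * SQM_PER_HA
            / perim[has_perim] ** 2
        )
        shape_ok = circ.gt(circ_min) | ~has_perim
        n_missing = int((~has_perim).sum())
        if n_missing:
            logger.warning(
                "%d ponds lack a perimeter; shape filter not applied to them",
                n_missing,
            )
    else:
        shape_ok = pd.Series(True, index=ponds.index)
        logger.warning("no perimeter column; shape filter skipped")

    reasons = np.where(~area_ok, "area", np.where(~shape_ok, "shape", ""))
    rejected = ponds.loc[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    retained = ponds.loc[reasons == ""].copy()
    return retained, rejected[["id", "reason"]].reset_index(drop=True)


def detect_establishment_year(
    series: pd.DataFrame,
    max_area: float,
    threshold: float = ESTABLISHMENT_THRESHOLD,
    min_detectable_area: float = MIN_DETECTABLE_AREA_HA,
) -> int | None:
    """First year water consistently covered >= `threshold` of the pond.

    `series` is a long table of monthly wet fractions with columns ``year``
    and ``fraction``. "Consistently" is taken as the within-year median of the
    monthly fractions. Ponds smaller than `min_detectable_area` (ha) are below
    the sensor's resolution and return ``None``, as does a series that never
    crosses the threshold.
    """
    if series.empty:
        raise ValueError("water-fraction series is empty")
    if max_area < min_detectable_area:
        return None
    medians = series.groupby("year")["fraction"].median().sort_index()
    hits = medians[medians >= threshold]
    return int(hits.index[0]) if len(hits) else None


@dataclass
class RegionGrowth:
    """Pond accumulation in one region over a window of years."""

    region: str
    yearly_counts: dict[int, int] = field(default_factory=dict)
    rel_rate: float = float("nan")
    abs_rate: float = float("nan")
    n_ponds: int = 0
    insufficient: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.rel_rate) and not 0 <= self.rel_rate <= 0.1:
            logger.warning(
                "region %s: relative accumulation rate %.3f/yr outside the "
                "plausible 0-10%% band",
                self.region,
                self.rel_rate,
            )


def _cumulative_counts(years: np.ndarray, window: tuple[int, int]) -> dict[int, int]:
    start, end = window
    axis = np.arange(start, end + 1)
    return {int(y): int((years <= y).sum()) for y in axis}


def accumulation_rates(
    established_years: Mapping[str, Iterable[int]] | pd.DataFrame,
    window: tuple[int, int],
) -> dict[str, RegionGrowth]:
    """Relative and absolute pond-accumulation rates per region.

    `established_years` maps region -> iterable of establishment years (or a
    DataFrame with ``region`` / ``established_year`` columns). Over `window`
    the cumulative count series is formed and summarised as

    * ``rel_rate`` — geometric-mean annual growth,
      ``(c_end / c_start) ** (1/years) - 1`` (compatible with compounding),
    * ``abs_rate`` — mean annual increment, ponds per year.

    A region with fewer than two window years of nonzero counts is flagged
    ``insufficient`` (rates NaN); see :func:`apply_national_fallback`.
    """
    if isinstance(established_years, pd.DataFrame):
        established_years = {
            str(r): g["established_year"].to_numpy()
            for r, g in established_years.groupby("region")
        }
    start, end = window
    if end <= start:
        raise ValueError("window must span at least one year")

    out: dict[str, RegionGrowth] = {}
    for region, years in established_years.items():
        years = np.asarray(list(years), dtype=int)
        counts = _cumulative_counts(years, window)
        vals = np.array([counts[y] for y in range(start, end + 1)], dtype=float)
        nonzero_years = int((vals > 0).sum())
        if nonzero_years < 2 or vals[0] <= 0:
            out[region] = RegionGrowth(
                region=region,
                yearly_counts=counts,
                n_ponds=len(years),
                insufficient=True,
            )
            continue
        span = end - start
        rel = (vals[-1] / vals[0]) ** (1.0 / span) - 1.0
        absr = (vals[-1] - vals[0]) / span
        out[region] = RegionGrowth(
            region=region,
            yearly_counts=counts,
            rel_rate=float(rel),
            abs_rate=float(absr),
            n_ponds=len(years),
        )
    return out


def apply_national_fallback(
    growths: Mapping[str, RegionGrowth],
    min_ponds: int = 50,
) -> dict[str, RegionGrowth]:
    """Substitute the national mean rate for data-poor regions.

    Regions flagged insufficient, or with fewer than `min_ponds` ponds, adopt
    the pooled national relative rate (cumulative counts summed over all
    regions). This mirrors inventory practice for sparsely observed regions
    such as the Northern Territory.
    """
    ok = [
        g
        for g in growths.values()
        if not g.insufficient and g.n_ponds >= min_ponds
    ]
    if not ok:
        raise ValueError("no region has sufficient data for a national rate")

    # pooled national cumulative counts -> geometric-mean rate
    years = sorted(ok[0].yearly_counts)
    national = np.zeros(len(years))
    for g in ok:
        national += np.array([g.yearly_counts.get(y, 0) for y in years], float)
    span = years[-1] - years[0]
    national_rate = float((national[-1] / national[0]) ** (1.0 / span) - 1.0)

    out = dict(growths)
    for region, g in growths.items():
        if g.insufficient or g.n_ponds < min_ponds:
            logger.info(
                "region %s: using national mean rate %.4f/yr", region, national_rate
            )
            out[region] = RegionGrowth(
                region=g.region,
                yearly_counts=g.yearly_counts,
                rel_rate=national_rate,
                abs_rate=g.abs_rate,
                n_ponds=g.n_ponds,
                insufficient=False,
            )
    return out


def project_counts(
    growth: RegionGrowth,
    from_year: int,
    to_year: int,
    fallback_window: tuple[int, int] = (2010, 2015),
) -> dict[int, float]:
    """Project (or backcast) pond counts by compounding a relative rate.

    The rate is the geometric-mean annual growth of the cumulative counts
    inside `fallback_window` when those years are available, otherwise
    ``growth.rel_rate``. Forward projection multiplies by ``(1 + rate)`` per
    year; backcasting divides, so a backcast followed by a forward projection
    is the identity. Counts stay fractional; round only on output.
    """
    w0, w1 = fallback_window
    if w1 <= w0:
        raise ValueError("fallback window must span at least one year")
    counts = growth.yearly_counts
    if w0 in counts and w1 in counts and counts[w0] > 0:
        rate = (counts[w1] / counts[w0]) ** (1.0 / (w1 - w0)) - 1.0
    else:
        rate = growth.rel_rate
    if not np.isfinite(rate):
        raise ValueError(
            f"region {growth.region}: no usable rate for projection"
        )
    if from_year not in counts:
        raise ValueError(f"no known count for {from_year}")
    base = counts[from_year]
    step = 1 if to_year >= from_year else -1
    out: dict[int, float] = {}
    for year in range(from_year, to_year + step, step):
        out[year] = base * (1.0 + rate) ** (year - from_year)
    return out


def small_pond_extrapolation(
    growth_large: RegionGrowth,
    n_small: int,
    years: tuple[int, int],
    seed: int | None = None,
) -> np.ndarray:
    """Impute establishment years for ponds too small to observe directly.

    Small ponds are assumed to accumulate at the same relative rate as the
    detectable ones, so the imputed cohort's cumulative count follows
    ``n_small * (1 + rel_rate) ** (year - end)``. Years are assigned by
    cumulative rounding (deterministic); `seed` only shuffles the order of the
    returned array.
    """
    if n_small == 0:
        return np.array([], dtype=int)
    rate = growth_large.rel_rate
    if not np.isfinite(rate):
        raise ValueError("growth_large has no relative rate")
    start, end = years
    axis = np.arange(start, end + 1)
    target = n_small * (1.0 + rate) ** (axis - end).astype(float)
    rounded = np.round(target).astype(int)
    rounded[-1] = n_small  # the present-day census count is exact
    increments = np.diff(rounded, prepend=0)
    increments[0] = rounded[0]  # ponds predating the window sit at `start`
    assigned = np.repeat(axis, np.maximum(increments, 0))
    # rounding can under-fill when the curve is very flat; pad at `start`
    if len(assigned) < n_small:
        assigned = np.concatenate(
            [np.full(n_small - len(assigned), start), assigned]
        )
    assigned = np.sort(assigned)[:n_small]
    if seed is not None:
        np.random.default_rng(seed).shuffle(assigned)
    return assigned
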