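"""Inventory aggregation: pond-months to per-region financial-year totals.

The reporting unit of a national greenhouse-gas inventory is the financial
year (1 July – 30 June, labelled by its ending calendar year). For every
pond-month the emission is ``annual_flux(T_month) * area_month / 12``; sums by
region and financial year give the inventory table: pond count, mean water
surface (kha), total emissions (kt CH4) and the implied mean flux
(t CH4 ha⁻¹ yr⁻¹, emissions divided by mean water surface).

:class:`MethaneInventory` is the model object binding ponds, water surfaces,
climate and an emission-factor tier; ``fit()`` returns
:class:`InventoryResults`, which carries the table, change statistics and the
sensitivity / Monte-Carlo machinery.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pondch4.emissions import (
    ArrheniusParams,
    Tier1Params,
    Tier2Params,
    tier1_flux,
    tier2_flux,
    tier3_flux,
)

__all__ = [
    "NATIONAL_LABEL",
    "MethaneInventory",
    "InventoryResults",
    "CorrelationReport",
    "financial_year",
    "change_statistics",
    "partition_emissions",
    "rainfall_anomaly_correlation",
]

logger = logging.getLogger(__name__)

NATIONAL_LABEL = "AUS"

_METRICS = ["count", "water_surface_kha", "emissions_kt", "mean_flux"]


def financial_year(date) -> int:
    """Financial-year label (ending calendar year) of a date.

    July–December of year Y fall in FY Y+1; January–June in FY Y. Accepts a
    ``datetime``/``date``/``Timestamp`` or a ``(year, month)`` pair.
    """
    if isinstance(date, tuple):
        year, month = date
    else:
        ts = pd.Timestamp(date)
        year, month = ts.year, ts.month
    return year + 1 if month >= 7 else year


def _fy_vector(year: pd.Series, month: pd.Series) -> pd.Series:
    return year + (month >= 7).astype(int)


EmissionParams = ArrheniusParams | Tier1Params | Tier2Params


def _annual_flux_column(frame: pd.DataFrame, model: EmissionParams) -> np.ndarray:
    """Per-row annual flux for whichever tier `model` belongs to."""
    if isinstance(model, ArrheniusParams):
        return np.asarray(tier3_flux(frame["temp_c"].to_numpy(), model))
    if isinstance(model, Tier1Params):
        return np.full(len(frame), tier1_flux(model))
    if isinstance(model, Tier2Params):
        return frame["zone"].map(lambda z: tier2_flux(z, model)).to_numpy()
    raise TypeError(f"unsupported emission model: {type(model).__name__}")


class MethaneInventory:
    """National methane inventory model for agricultural ponds.

    Parameters
    ----------
    ponds : table with ``id``, ``region``, ``max_area_ha``,
        ``established_year`` and, for tier 2, ``zone``.
    surfaces : long table of monthly water areas
        (``pond_id``, ``year``, ``month``, ``area_ha``).
    climate : long table of monthly climate per region
        (``region``, ``year``, ``month``, ``temp_c``, ``rain_mm``).
    model : emission-factor parameters; the class of the object selects the
        tier (:class:`ArrheniusParams` = tier 3, :class:`Tier1Params` = tier 1,
        :class:`Tier2Params` = tier 2).
    years : inclusive range of financial-year labels to report.
    """

    def __init__(
        self,
        ponds: pd.DataFrame,
        surfaces: pd.DataFrame,
        climate: pd.DataFrame,
        model: EmissionParams | None = None,
        years: tuple[int, int] | None = None,
    ) -> None:
        self.ponds = ponds.reset_index(drop=True)
        self.surfaces = surfaces
        self.climate = climate
        self.model = model or ArrheniusParams()
        if years is None:
            # default to financial years fully covered by the surface series
            months = surfaces[["year", "month"]].drop_duplicates()
            fy = _fy_vector(months["year"], months["month"])
            complete = fy.value_counts()
            complete = sorted(complete[complete >= 12].index)
            if not complete:
                raise ValueError(
                    "surface series covers no complete financial year"
                )
            years = (int(complete[0]), int(complete[-1]))
        self.years = years

    def fit(self) -> "InventoryResults":
        """Compute per-pond-month emissions and aggregate to the inventory."""
        start_fy, end_fy = self.years
        pond_cols = ["id", "region", "max_area_ha", "established_year"]
        if isinstance(self.model, Tier2Params):
            pond_cols.append("zone")
        pm = self.surfaces.merge(
            self.ponds[pond_cols], left_on="pond_id", right_on="id", how="inner"
        ).drop(columns="id")

        n_no_surface = self.ponds["id"].nunique() - pm["pond_id"].nunique()
        pm = pm.merge(
            self.climate[["region", "year", "month", "temp_c"]],
            on=["region", "year", "month"],
            how="left",
        )
        bad = pm["temp_c"].isna()
        n_bad = 0
        if bad.any():
            n_bad = pm.loc[bad, "pond_id"].nunique()
            logger.warning(
                "excluding %d ponds with missing climate months", n_bad
            )
            pm = pm.loc[~bad]
        if n_no_surface:
            logger.warning(
                "%d ponds have no water-surface series and are excluded",
                n_no_surface,
            )

        pm = pm.copy()
        pm["fy"] = _fy_vector(pm["year"], pm["month"])
        pm = pm[
            (pm["fy"] >= start_fy)
            & (pm["fy"] <= end_fy)
            & (pm["fy"] >= pm["established_year"])
        ].reset_index(drop=True)

        pm["annual_flux"] = _annual_flux_column(pm, self.model)
        pm["emission_t"] = pm["annual_flux"] * pm["area_ha"] / 12.0

        table = self._aggregate(pm)
        return InventoryResults(
            table=table,
            pond_months=pm,
            model=self.model,
            years=self.years,
            ponds=self.ponds,
            climate=self.climate,
            n_excluded_ponds=n_no_surface + n_bad,
        )

    def _aggregate(self, pm: pd.DataFrame) -> pd.DataFrame:
        start_fy, end_fy = self.years
        regions = sorted(self.ponds["region"].unique())
        fy_axis = range(start_fy, end_fy + 1)

        # monthly regional totals on a complete region x month grid, so a dry
        # month still counts as zero toward the FY mean water surface
        monthly = (
            pm.groupby(["region", "fy", "year", "month"], as_index=False)
            .agg(area_ha=("area_ha", "sum"), emission_t=("emission_t", "sum"))
        )
        rows = []
        for region in regions:
            est_years = self.ponds.loc[
                self.ponds["region"] == region, "established_year"
            ].to_numpy()
            sub = monthly[monthly["region"] == region]
            for fy in fy_axis:
                months = sub[sub["fy"] == fy]
                # every FY month contributes, wet or dry
                area_mean = months["area_ha"].sum() / 12.0
                emis = months["emission_t"].sum()
                count = int((est_years <= fy).sum())
                rows.append(
                    {
                        "region": region,
                        "financial_year": fy,
                        "count": count,
                        "water_surface_kha": area_mean / 1e3,
                        "emissions_kt": emis / 1e3,
                    }
                )
        table = pd.DataFrame(rows)
        national = (
            table.groupby("financial_year", as_index=False)[
                ["count", "water_surface_kha", "emissions_kt"]
            ]
            .sum()
            .assign(region=NATIONAL_LABEL)
        )
        table = pd.concat([table, national], ignore_index=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            table["mean_flux"] = np.where(
                table["water_surface_kha"] > 0,
                table["emissions_kt"] / table["water_surface_kha"],
                np.nan,
            )
        return table.sort_values(["region", "financial_year"]).reset_index(
            drop=True
        )


@dataclass
class InventoryResults:
    """Fitted inventory: per-region per-financial-year totals plus the
    pond-month detail needed for sensitivity and uncertainty analysis."""

    table: pd.DataFrame
    pond_months: pd.DataFrame
    model: EmissionParams
    years: tuple[int, int]
    ponds: pd.DataFrame
    climate: pd.DataFrame
    n_excluded_ponds: int = 0

    @property
    def national(self) -> pd.DataFrame:
        return self.table[self.table["region"] == NATIONAL_LABEL].reset_index(
            drop=True
        )

    def total_emissions(self, fy: int | None = None) -> float:
        """National emissions (kt CH4) in one FY, or summed over all."""
        nat = self.national
        if fy is not None:
            nat = nat[nat["financial_year"] == fy]
        return float(nat["emissions_kt"].sum())

    def change_statistics(self, base_year: int, end_year: int) -> pd.DataFrame:
        return change_statistics(self.table, base_year, end_year)

    def sensitivity(self, **kwargs) -> pd.DataFrame:
        from pondch4.uncertainty import sensitivity_spider

        return sensitivity_spider(self, **kwargs)

    def propagate_ci(self, **kwargs) -> pd.DataFrame:
        from pondch4.uncertainty import propagate_ci

        return propagate_ci(self, **kwargs)

    def relative_capacity(self) -> pd.Series:
        """National water surface ÷ active max capacity, per financial year."""
        nat = self.national.set_index("financial_year")
        est = self.ponds["established_year"].to_numpy()
        max_area = self.ponds["max_area_ha"].to_numpy()
        cap = pd.Series(
            {
                fy: max_area[est <= fy].sum() / 1e3
                for fy in nat.index
            }
        )
        return nat["water_surface_kha"] / cap

    def rainfall_anomaly(self) -> pd.Series:
        """FY mean-over-region total rainfall minus its long-term mean, mm."""
        cl = self.climate.copy()
        cl["fy"] = _fy_vector(cl["year"], cl["month"])
        start, end = self.years
        cl = cl[(cl["fy"] >= start) & (cl["fy"] <= end)]
        annual = (
            cl.groupby(["region", "fy"])["rain_mm"].sum().groupby("fy").mean()
        )
        return annual - annual.mean()

    def rainfall_correlation(self) -> "CorrelationReport":
        """Correlation between relative water capacity and rainfall anomaly."""
        cap = self.relative_capacity()
        anom = self.rainfall_anomaly()
        joined = pd.concat([cap.rename("cap"), anom.rename("anom")], axis=1)
        joined = joined.dropna()
        return rainfall_anomaly_correlation(
            joined["cap"].to_numpy(), joined["anom"].to_numpy()
        )

    def summary(self) -> str:
        start, end = self.years
        first = self.national[self.national["financial_year"] == start]
        last = self.national[self.national["financial_year"] == end]
        tier = {
            "ArrheniusParams": "tier 3 (Boltzmann–Arrhenius)",
            "Tier1Params": "tier 1 (fixed factor)",
            "Tier2Params": "tier 2 (climate zones)",
        }[type(self.model).__name__]
        lines = [
            f"Methane inventory, FY{start}–FY{end}, {tier}",
            f"  regions: {self.table['region'].nunique() - 1}, "
            f"ponds: {len(self.ponds)}, "
            f"excluded (missing data): {self.n_excluded_ponds}",
        ]
        for label, row in (("first", first), ("final", last)):
            if not row.empty:
                r = row.iloc[0]
                lines.append(
                    f"  {label} FY{int(r['financial_year'])}: "
                    f"{r['count']:.0f} ponds, "
                    f"{r['water_surface_kha']:.2f} kha, "
                    f"{r['emissions_kt']:.3f} kt CH4, "
                    f"mean flux {r['mean_flux']:.3f} t/ha/yr"
                )
        return "\n".join(lines)


def change_statistics(
    table: pd.DataFrame, base_year: int, end_year: int
) -> pd.DataFrame:
    """Relative (%) and absolute change of every metric between two FYs.

    Relative change is ``(end - base) / base * 100``; when the base value is
    zero the relative change is reported as missing. No rounding is applied —
    round at presentation time only.
    """
    for fy in (base_year, end_year):
        if fy not in set(table["financial_year"]):
            raise ValueError(f"financial year {fy} not in table")
    base = table[table["financial_year"] == base_year].set_index("region")
    end = table[table["financial_year"] == end_year].set_index("region")
    rows = []
    for region in base.index:
        for metric in _METRICS:
            b, e = base.loc[region, metric], end.loc[region, metric]
            rel = (e - b) / b * 100.0 if b != 0 else np.nan
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    "base": b,
                    "end": e,
                    "relative_change_pct": rel,
                    "absolute_change": e - b,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation with Fisher-z CI and the t-test bookkeeping."""

    r: float | None
    ci: tuple[float, float] | None
    t: float | None
    df: int
    p: float | None

    def __str__(self) -> str:
        if self.r is None:
            return "r undefined (zero variance)"
        ci = "" if self.ci is None else f" [{self.ci[0]:.2f}, {self.ci[1]:.2f}]"
        return (
            f"r = {self.r:.2f}{ci}, t = {self.t:.2f}, df = {self.df}, "
            f"p = {self.p:.2g}"
        )


def rainfall_anomaly_correlation(x, y) -> CorrelationReport:
    """Pearson correlation between two aligned annual series.

    Returns r with a Fisher-z 95% CI and the equivalent t statistic
    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2`` and a two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must be aligned")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    df = n - 2
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlation undefined: zero variance", stacklevel=2)
        return CorrelationReport(r=None, ci=None, t=None, df=df, p=None)
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return CorrelationReport(r=r, ci=None, t=float("inf"), df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    ci = None
    if n > 3:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationReport(r=r, ci=ci, t=float(t), df=df, p=float(p))


def partition_emissions(
    total: float, manure_fraction: float = 0.6
) -> tuple[float, float]:
    """Split a total into (manure, baseline) components.

    National reporting books 60% of constructed-waterbody methane under manure
    management and 40% as the baseline flooded-land component; the two always
    sum exactly to the input.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    if not 0 <= manure_fraction <= 1:
        raise ValueError("manure_fraction must be within [0, 1]")
    manure = total * manure_fraction
    return manure, total - manure
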