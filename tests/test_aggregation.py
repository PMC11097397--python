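"""Financial-year aggregation, change statistics, correlations, partitioning."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from pondch4.aggregation import (
    NATIONAL_LABEL,
    CorrelationReport,
    MethaneInventory,
    change_statistics,
    financial_year,
    partition_emissions,
    rainfall_anomaly_correlation,
)
from pondch4.emissions import ArrheniusParams, Tier1Params, tier3_flux


class TestFinancialYear:
    @pytest.mark.parametrize(
        "date, fy",
        [
            (dt.date(2021, 7, 1), 2022),
            (dt.date(2022, 6, 30), 2022),
            (dt.date(2022, 7, 1), 2023),
            ((2000, 1), 2000),
            ((2000, 12), 2001),
        ],
    )
    def test_boundaries(self, date, fy):
        assert financial_year(date) == fy

    def test_every_month_maps_to_exactly_one_fy(self):
        labels = {m: financial_year((2020, m)) for m in range(1, 13)}
        assert set(labels.values()) == {2020, 2021}
        assert sum(v == 2021 for v in labels.values()) == 6


def _single_pond_inputs(temp_c=15.0, area=1.0, years=(2000, 2002)):
    ponds = pd.DataFrame(
        {
            "id": ["p1"],
            "region": ["NSW"],
            "max_area_ha": [2.0],
            "established_year": [1990],
            "zone": ["temperate-warm"],
        }
    )
    months = pd.period_range(f"{years[0] - 1}-07", f"{years[1]}-06", freq="M")
    climate = pd.DataFrame(
        {
            "region": "NSW",
            "year": months.year,
            "month": months.month,
            "temp_c": temp_c,
            "rain_mm": 50.0,
        }
    )
    surfaces = pd.DataFrame(
        {
            "pond_id": "p1",
            "year": months.year,
            "month": months.month,
            "area_ha": area,
        }
    )
    return ponds, surfaces, climate


class TestComputeInventory:
    def test_constant_pond_at_15C_emits_m15_per_year(self):
        ponds, surfaces, climate = _single_pond_inputs()
        res = MethaneInventory(
            ponds, surfaces, climate, ArrheniusParams(), years=(2000, 2002)
        ).fit()
        nat = res.national
        assert np.allclose(nat["emissions_kt"], 0.204 / 1e3)
        assert np.allclose(nat["mean_flux"], 0.204)
        assert np.allclose(nat["water_surface_kha"], 1.0 / 1e3)

    def test_national_totals_are_region_sums(self, small_landscape):
        res = MethaneInventory(
            small_landscape["ponds"],
            small_landscape["surfaces"],
            small_landscape["climate"],
            years=(2001, 2006),
        ).fit()
        t = res.table
        nat = t[t["region"] == NATIONAL_LABEL].set_index("financial_year")
        reg = (
            t[t["region"] != NATIONAL_LABEL]
            .groupby("financial_year")[
                ["count", "water_surface_kha", "emissions_kt"]
            ]
            .sum()
        )
        for col in reg.columns:
            assert np.allclose(nat[col], reg[col])

    def test_matches_brute_force_pond_month_oracle(self, small_landscape):
        ponds = small_landscape["ponds"].head(50)
        surfaces = small_landscape["surfaces"]
        surfaces = surfaces[surfaces["pond_id"].isin(ponds["id"])]
        climate = small_landscape["climate"]
        params = ArrheniusParams()
        years = (2001, 2003)
        res = MethaneInventory(ponds, surfaces, climate, params, years).fit()

        # straight-loop oracle, independent of the pandas aggregation path
        temp = {
            (r.region, r.year, r.month): r.temp_c
            for r in climate.itertuples()
        }
        meta = ponds.set_index("id")[["region", "established_year"]]
        totals = {}
        areas = {}
        for row in surfaces.itertuples():
            fy = row.year + (1 if row.month >= 7 else 0)
            if not years[0] <= fy <= years[1]:
                continue
            region, est = meta.loc[row.pond_id]
            if fy < est:
                continue
            t = temp[(region, row.year, row.month)]
            flux = params.m15 * math.exp(
                (params.e_m / params.k_b) * (1 / 288.15 - 1 / (t + 273.15))
            )
            totals[fy] = totals.get(fy, 0.0) + flux * row.area_ha / 12.0
            areas[fy] = areas.get(fy, 0.0) + row.area_ha
        nat = res.national.set_index("financial_year")
        for fy in range(years[0], years[1] + 1):
            assert nat.loc[fy, "emissions_kt"] == pytest.approx(
                totals[fy] / 1e3, rel=1e-10
            )
            assert nat.loc[fy, "water_surface_kha"] == pytest.approx(
                areas[fy] / 12.0 / 1e3, rel=1e-10
            )

    def test_tier1_mean_flux_is_the_emission_factor_exactly(
        self, small_landscape
    ):
        res = MethaneInventory(
            small_landscape["ponds"],
            small_landscape["surfaces"],
            small_landscape["climate"],
            Tier1Params(),
            years=(2001, 2006),
        ).fit()
        flux = res.table["mean_flux"].dropna()
        assert np.allclose(flux, 0.183, rtol=1e-12)

    def test_emissions_scale_linearly_with_water_surface(self):
        ponds, surfaces, climate = _single_pond_inputs(temp_c=22.0)
        res1 = MethaneInventory(
            ponds, surfaces, climate, years=(2000, 2002)
        ).fit()
        scaled = surfaces.assign(area_ha=surfaces["area_ha"] * 1.7)
        res2 = MethaneInventory(
            ponds, scaled, climate, years=(2000, 2002)
        ).fit()
        assert np.allclose(
            res2.national["emissions_kt"],
            1.7 * res1.national["emissions_kt"],
        )

    def test_fy_totals_are_monthly_sums(self):
        ponds, surfaces, climate = _single_pond_inputs(temp_c=20.0)
        res = MethaneInventory(
            ponds, surfaces, climate, years=(2001, 2001)
        ).fit()
        pm = res.pond_months
        fy_sum = pm[pm["fy"] == 2001]["emission_t"].sum()
        assert res.total_emissions(2001) == pytest.approx(fy_sum / 1e3)
        assert len(pm[pm["fy"] == 2001]) == 12

    def test_pond_inactive_before_establishment(self):
        ponds, surfaces, climate = _single_pond_inputs()
        ponds["established_year"] = 2002
        res = MethaneInventory(
            ponds, surfaces, climate, years=(2000, 2002)
        ).fit()
        nat = res.national.set_index("financial_year")
        assert nat.loc[2000, "emissions_kt"] == 0
        assert nat.loc[2001, "emissions_kt"] == 0
        assert nat.loc[2002, "emissions_kt"] > 0
        assert nat.loc[2000, "count"] == 0 and nat.loc[2002, "count"] == 1


class TestChangeStatistics:
    def _table(self, base, end):
        rows = []
        for fy, vals in ((1990, base), (2022, end)):
            rows.append(
                {
                    "region": NATIONAL_LABEL,
                    "financial_year": fy,
                    "count": vals[0],
                    "water_surface_kha": vals[1],
                    "emissions_kt": vals[2],
                    "mean_flux": vals[3],
                }
            )
        return pd.DataFrame(rows)

    def test_relative_change_arithmetic(self):
        table = self._table((1227, 114.6, 26.03, 0.227), (1771, 172.8, 41.07, 0.238))
        ch = change_statistics(table, 1990, 2022).set_index("metric")
        assert round(ch.loc["emissions_kt", "relative_change_pct"]) == 58
        assert round(ch.loc["water_surface_kha", "relative_change_pct"]) == 51
        assert round(ch.loc["count", "relative_change_pct"]) == 44
        assert ch.loc["emissions_kt", "absolute_change"] == pytest.approx(15.04)

    def test_no_change_is_zero(self):
        table = self._table((10, 1.0, 2.0, 0.2), (10, 1.0, 2.0, 0.2))
        ch = change_statistics(table, 1990, 2022)
        assert (ch["relative_change_pct"] == 0).all()

    def test_zero_base_reported_absent(self):
        table = self._table((0, 1.0, 2.0, 0.2), (5, 1.0, 2.0, 0.2))
        ch = change_statistics(table, 1990, 2022).set_index("metric")
        assert np.isnan(ch.loc["count", "relative_change_pct"])

    def test_missing_year_rejected(self):
        table = self._table((1, 1, 1, 1), (2, 2, 2, 2))
        with pytest.raises(ValueError):
            change_statistics(table, 1990, 2030)


class TestCorrelation:
    def test_identical_series_r_one(self):
        x = np.arange(10, dtype=float)
        rep = rainfall_anomaly_correlation(x, x)
        assert rep.r == pytest.approx(1.0)

    def test_t_statistic_formula_at_printed_values(self):
        # t = r * sqrt(df / (1 - r^2)) gives ~3.9 for r=0.57, df=32
        t = 0.57 * np.sqrt(32 / (1 - 0.57**2))
        assert round(t, 1) == 3.9

    def test_five_point_manual_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        rep = rainfall_anomaly_correlation(x, y)
        r_manual = np.corrcoef(x, y)[0, 1]
        assert rep.r == pytest.approx(r_manual)
        assert rep.df == 3
        assert rep.t == pytest.approx(
            r_manual * np.sqrt(3 / (1 - r_manual**2))
        )

    def test_zero_variance_warns_and_is_absent(self):
        with pytest.warns(UserWarning):
            rep = rainfall_anomaly_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert rep.r is None

    def test_results_correlation_runs_on_landscape(self, small_landscape):
        res = MethaneInventory(
            small_landscape["ponds"],
            small_landscape["surfaces"],
            small_landscape["climate"],
            years=(2001, 2006),
        ).fit()
        rep = res.rainfall_correlation()
        assert isinstance(rep, CorrelationReport)
        assert rep.df == 4


class TestPartition:
    @pytest.mark.parametrize(
        "total, frac, expected",
        [(41.0, 0.6, (24.6, 16.4)), (0.0, 0.6, (0.0, 0.0)),
         (100.0, 0.6, (60.0, 40.0))],
    )
    def test_manure_baseline_split(self, total, frac, expected):
        manure, baseline = partition_emissions(total, frac)
        assert (manure, baseline) == pytest.approx(expected)
        assert manure + baseline == total

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            partition_emissions(10.0, 1.2)
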