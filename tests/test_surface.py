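"""Water-surface features, training protocol, prediction and validation."""

import numpy as np
import pandas as pd
import pytest

from pondch4.surface import (
    FEATURE_NAMES,
    SearchConfig,
    WaterSurfaceModel,
    WaterSurfaceResults,
    assemble_examples,
    build_features,
    validate,
)


def _climate(years, temp=None, rain=None):
    months = pd.period_range(f"{years[0]}-01", f"{years[1]}-12", freq="M")
    n = len(months)
    return pd.DataFrame(
        {
            "year": months.year,
            "month": months.month,
            "temp_c": np.full(n, 15.0) if temp is None else temp(n),
            "rain_mm": np.full(n, 50.0) if rain is None else rain(n),
        }
    )


class TestBuildFeatures:
    def test_constant_climate_gives_constant_lags(self):
        fv = build_features(0.4, _climate((2000, 2002)), 2002, 6)
        assert fv["max_area"] == 0.4
        assert all(fv[f"t_lag_{k}"] == 15.0 for k in range(13))
        assert all(fv[f"r_lag_{k}"] == 50.0 for k in range(13))

    def test_lag_k_is_k_months_back(self):
        cl = _climate((2000, 2002), temp=lambda n: np.arange(n, dtype=float))
        fv = build_features(1.0, cl, 2002, 12)  # last month, index n-1
        n = len(cl)
        for k in range(13):
            assert fv[f"t_lag_{k}"] == n - 1 - k

    def test_missing_history_names_the_months(self):
        with pytest.raises(ValueError, match="1999-07"):
            build_features(1.0, _climate((2000, 2001)), 2000, 7)


class TestValidate:
    def test_perfect_predictions(self):
        y = np.array([0.1, 0.2, 0.5, 0.9])
        rep = validate(y, y)
        assert rep.r == pytest.approx(1.0)
        assert rep.mae == 0.0 and rep.mape == 0.0

    def test_constant_predictor_reports_undefined_r(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = validate([0.1, 0.4, 0.8], [0.3, 0.3, 0.3])
        assert rep.r is None

    def test_five_point_manual_metrics(self):
        y = np.array([1.0, 2.0, 0.0, 4.0, 5.0])
        yhat = np.array([1.5, 1.5, 0.5, 5.0, 4.0])
        rep = validate(y, yhat)
        assert rep.mae == pytest.approx(np.mean([0.5, 0.5, 0.5, 1.0, 1.0]))
        # MAPE excludes the zero observation
        assert rep.mape == pytest.approx(
            100 * np.mean([0.5 / 1, 0.5 / 2, 1 / 4, 1 / 5])
        )
        assert rep.n == 5

    def test_empty_holdout_rejected(self):
        with pytest.raises(ValueError):
            validate([], [])


def _noiseless_examples(n=1500, seed=0):
    """Linear response of area to max_area and the rainfall window."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "max_area": rng.uniform(0.05, 1.5, n),
            **{f"t_lag_{k}": rng.uniform(5, 25, n) for k in range(13)},
            **{f"r_lag_{k}": rng.uniform(0, 120, n) for k in range(13)},
        }
    )
    rain13 = X[[f"r_lag_{k}" for k in range(13)]].sum(axis=1)
    y = X["max_area"] * np.clip(0.2 + 0.0005 * rain13, 0, 1)
    return X, y


TINY_SEARCH = SearchConfig(
    n_random=5, n_guided=5, ensemble_size=2,
    n_estimators_range=(10, 300),
)


class TestTraining:
    def test_recovers_noiseless_linear_response(self):
        X, y = _noiseless_examples()
        results = WaterSurfaceModel(X, y, config=TINY_SEARCH).fit(seed=3)
        assert results.validation.mae < 0.05 * y.mean()
        assert results.validation.r > 0.95

    def test_shuffled_labels_have_no_skill(self):
        X, y = _noiseless_examples(n=600, seed=1)
        y_shuffled = y.sample(frac=1.0, random_state=9).reset_index(drop=True)
        results = WaterSurfaceModel(X, y_shuffled, config=TINY_SEARCH).fit(
            seed=3
        )
        # score on an independent probe set: no signal, no skill
        X_probe, y_probe = _noiseless_examples(n=400, seed=77)
        y_probe = y_probe.sample(frac=1.0, random_state=8).reset_index(
            drop=True
        )
        rep = validate(y_probe, results.predict(X_probe))
        r, n = rep.r, rep.n
        t = r * np.sqrt((n - 2) / (1 - r**2))
        from scipy import stats

        assert stats.t.sf(t, n - 2) > 0.05

    def test_same_seed_reproduces_search_log_and_predictions(self):
        X, y = _noiseless_examples(n=300, seed=2)
        cfg = SearchConfig(n_random=3, n_guided=2, ensemble_size=2,
                           n_estimators_range=(10, 100))
        r1 = WaterSurfaceModel(X, y, config=cfg).fit(seed=5)
        r2 = WaterSurfaceModel(X, y, config=cfg).fit(seed=5)
        pd.testing.assert_frame_equal(r1.search_log, r2.search_log)
        assert np.array_equal(r1.predict(X), r2.predict(X))

    def test_large_ponds_excluded_and_minimum_enforced(self):
        X, y = _noiseless_examples(n=150)
        X.loc[:99, "max_area"] = 5.0  # over the 2 ha training cap
        with pytest.raises(ValueError, match="at least"):
            WaterSurfaceModel(X, y, config=TINY_SEARCH)

    def test_too_few_trials_for_ensemble_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(n_random=2, n_guided=2, ensemble_size=10)

    def test_hyperparameters_within_declared_ranges(self):
        X, y = _noiseless_examples(n=300, seed=4)
        results = WaterSurfaceModel(X, y, config=TINY_SEARCH).fit(seed=1)
        log = results.search_log
        assert log["learning_rate"].between(0.1, 0.5).all()
        assert log["n_estimators"].between(10, 300).all()
        assert log["max_depth"].between(1, 10).all()
        assert len(results.members) == TINY_SEARCH.ensemble_size


@pytest.fixture(scope="module")
def fitted():
    X, y = _noiseless_examples()
    return X, y, WaterSurfaceModel(X, y, config=TINY_SEARCH).fit(seed=3)


class TestPrediction:
    def test_predictions_clipped_to_capacity(self, fitted):
        X, _, results = fitted
        probe = X.head(20).copy()
        probe["max_area"] = 0.001  # force the upper clip
        pred = results.predict(probe)
        assert (pred <= 0.001 + 1e-12).all() and (pred >= 0).all()

    def test_ensemble_not_worse_than_worst_member(self, fitted):
        X, y, results = fitted
        member_preds = results.member_predictions(X)
        member_mae = np.abs(member_preds - y.to_numpy()).mean(axis=1)
        ens_mae = np.abs(results.predict(X) - y.to_numpy()).mean()
        assert ens_mae <= member_mae.max() + 1e-12

    def test_save_load_round_trip(self, fitted, tmp_path):
        X, _, results = fitted
        results.save(tmp_path / "bundle")
        loaded = WaterSurfaceResults.load(tmp_path / "bundle")
        assert np.allclose(loaded.predict(X), results.predict(X))
        assert loaded.validation.mae == pytest.approx(results.validation.mae)

    def test_unfitted_model_raises(self):
        empty = WaterSurfaceResults(
            members=[], search_log=pd.DataFrame(), config=SearchConfig(),
            seed=0,
        )
        with pytest.raises(RuntimeError):
            empty.predict(pd.DataFrame(columns=FEATURE_NAMES))


class TestAssembleExamples:
    def test_matches_hand_built_feature_vector(self, small_landscape):
        ponds = small_landscape["ponds"]
        climate = small_landscape["climate"]
        surfaces = small_landscape["surfaces"]
        ex = assemble_examples(ponds, climate, surfaces).iloc[42]
        pond = ponds.set_index("id").loc[ex["pond_id"]]
        region_climate = climate[climate["region"] == pond["region"]]
        fv = build_features(
            pond["max_area_ha"], region_climate,
            int(ex["year"]), int(ex["month"]),
        )
        assert np.allclose(ex[FEATURE_NAMES].astype(float), fv.to_numpy())

    def test_noise_reduction_improves_validation_mae(self, small_landscape):
        """Less observation noise in the generator: better median val MAE."""
        from pondch4.synthetic import (
            LandscapeConfig,
            SurfaceTruth,
            generate_climate,
            generate_ponds,
            generate_water_surface,
            ClimateConfig,
        )

        cfg = LandscapeConfig(n_ponds=250, years=(2001, 2004), seed=21)
        ponds = generate_ponds(cfg)
        climate = generate_climate(ClimateConfig(seed=21), 2000, 2004)
        maes = {}
        for label, noise in (("low", 0.05), ("high", 1.2)):
            vals = []
            for seed in (0, 1, 2):
                truth = SurfaceTruth(noise_sd=noise, pond_effect_sd=0.0)
                surf, _ = generate_water_surface(
                    ponds, climate, truth, years=(2001, 2004), seed=seed
                )
                ex = assemble_examples(ponds, climate, surf, sample=1500,
                                       seed=seed)
                res = WaterSurfaceModel.from_dataframe(
                    ex, config=SearchConfig(
                        n_random=4, n_guided=2, ensemble_size=2,
                        n_estimators_range=(10, 200),
                    )
                ).fit(seed=seed)
                vals.append(res.validation.mae)
            maes[label] = np.median(vals)
        assert maes["low"] < maes["high"]
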