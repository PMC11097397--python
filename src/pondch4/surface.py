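"""Monthly water-surface prediction from lagged climate.

Farm-dam water surfaces swing between wet and dry seasons, and the emitting
area in any month is what matters for the methane budget. This module predicts
a pond's monthly water surface area (ha) from its maximum fill area and 13
months of climate history (current month plus 12 lags of mean temperature and
cumulative rainfall — 27 features in all), using an ensemble of gradient
boosted tree regressors.

The training protocol is a statsmodels-style model/results pair:
``WaterSurfaceModel(X, y).fit(seed)`` runs a hyperparameter search of 15
random plus 30 surrogate-guided trials (Gaussian-process expected
improvement) over learning rate, number of estimators and tree depth, keeps
the 10 trials with the lowest validation MAE, and soft-votes them (unweighted
mean of member predictions). Ponds larger than 2 ha are excluded from
training; data are split 90:10 into train/validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.model_selection import train_test_split
import xgboost as xgb
from xgboost import XGBRegressor


def _member_predict(member, X: pd.DataFrame) -> np.ndarray:
    """Predict with either a sklearn-wrapped regressor or a raw Booster."""
    if isinstance(member, xgb.Booster):
        return member.inplace_predict(X.to_numpy())
    return member.predict(X)

__all__ = [
    "FEATURE_NAMES",
    "SearchConfig",
    "ValidationReport",
    "WaterSurfaceModel",
    "WaterSurfaceResults",
    "assemble_examples",
    "build_features",
    "validate",
]

logger = logging.getLogger(__name__)

N_LAGS = 13  # current month plus 12 back


def _period_index(year, month) -> pd.PeriodIndex:
    return pd.PeriodIndex(
        pd.to_datetime(
            {"year": year, "month": month, "day": 1}
        ),
        freq="M",
    )

FEATURE_NAMES: list[str] = (
    ["max_area"]
    + [f"t_lag_{k}" for k in range(N_LAGS)]
    + [f"r_lag_{k}" for k in range(N_LAGS)]
)


def build_features(
    max_area: float,
    climate: pd.DataFrame,
    year: int,
    month: int,
) -> pd.Series:
    """Assemble the 27-element feature vector for one pond-month.

    `climate` is a monthly table with columns ``year``, ``month``, ``temp_c``,
    ``rain_mm`` for the pond's location. Lag k is the value k months before
    (`year`, `month`); lag 0 is the current month. Raises if any of the 13
    required months is missing, naming the gaps.
    """
    idx = climate.set_index(_period_index(climate["year"], climate["month"]))
    ref = pd.Period(year=year, month=month, freq="M")
    wanted = [ref - k for k in range(N_LAGS)]
    missing = [str(p) for p in wanted if p not in idx.index]
    if missing:
        raise ValueError(f"climate series missing months: {missing}")
    temps = [float(idx.loc[p, "temp_c"]) for p in wanted]
    rains = [float(idx.loc[p, "rain_mm"]) for p in wanted]
    return pd.Series([max_area] + temps + rains, index=FEATURE_NAMES)


def assemble_examples(
    ponds: pd.DataFrame,
    climate: pd.DataFrame,
    surfaces: pd.DataFrame,
    sample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Join pond-months with their 13-month climate windows, vectorised.

    `surfaces` supplies the targets (``pond_id``, ``year``, ``month``,
    ``area_ha``); each row becomes one training example with the
    :data:`FEATURE_NAMES` features plus ``observed_area_ha`` and the
    identifying columns. Pond-months whose climate window is incomplete are
    dropped. `sample` optionally subsamples rows (seeded) to bound training
    cost.
    """
    out_frames = []
    pond_meta = ponds.set_index("id")[["region", "max_area_ha"]]
    sf = surfaces.join(pond_meta, on="pond_id", how="inner")
    for region, grp in sf.groupby("region"):
        cl = (
            climate[climate["region"] == region]
            .sort_values(["year", "month"])
            .reset_index(drop=True)
        )
        if cl.empty:
            continue
        periods = _period_index(cl["year"], cl["month"])
        pos_of = {p.ordinal: i for i, p in enumerate(periods)}
        row_periods = _period_index(grp["year"], grp["month"])
        pos = np.array([pos_of.get(p.ordinal, -1) for p in row_periods])
        ok = pos >= N_LAGS - 1
        # the window must also be contiguous; a gap-free monthly series is
        # assumed after sorting, so check span directly
        grp = grp.loc[ok]
        pos = pos[ok]
        if not len(grp):
            continue
        lag_idx = pos[:, None] - np.arange(N_LAGS)[None, :]
        temp = cl["temp_c"].to_numpy()[lag_idx]
        rain = cl["rain_mm"].to_numpy()[lag_idx]
        frame = pd.DataFrame(temp, columns=[f"t_lag_{k}" for k in range(N_LAGS)])
        for k in range(N_LAGS):
            frame[f"r_lag_{k}"] = rain[:, k]
        frame.insert(0, "max_area", grp["max_area_ha"].to_numpy())
        frame["observed_area_ha"] = grp["area_ha"].to_numpy()
        frame["pond_id"] = grp["pond_id"].to_numpy()
        frame["year"] = grp["year"].to_numpy()
        frame["month"] = grp["month"].to_numpy()
        out_frames.append(frame)
    if not out_frames:
        raise ValueError("no pond-months with complete climate windows")
    out = pd.concat(out_frames, ignore_index=True)
    if sample is not None and sample < len(out):
        out = out.sample(
            n=sample, random_state=seed % (2**32)
        ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class SearchConfig:
    """Hyperparameter-search protocol for the surface ensemble."""

    n_random: int = 15
    n_guided: int = 30
    ensemble_size: int = 10
    learning_rate_range: tuple[float, float] = (0.1, 0.5)
    n_estimators_range: tuple[int, int] = (10, 700)
    max_depth_range: tuple[int, int] = (1, 10)
    val_fraction: float = 0.1
    max_area_cap: float = 2.0
    min_examples: int = 100

    @property
    def n_trials(self) -> int:
        return self.n_random + self.n_guided

    def __post_init__(self) -> None:
        if self.n_trials < self.ensemble_size:
            raise ValueError(
                f"{self.n_trials} trials cannot fill an ensemble of "
                f"{self.ensemble_size}"
            )


@dataclass
class ValidationReport:
    """Hold-out metrics for a fitted surface model."""

    r: float | None
    r_ci: tuple[float, float] | None
    mae: float
    mape: float | None
    n: int

    def __str__(self) -> str:
        r_txt = "undefined" if self.r is None else f"{self.r:.3f}"
        mape_txt = "n/a" if self.mape is None else f"{self.mape:.1f}%"
        return (
            f"r={r_txt}, MAE={self.mae:.4f} ha, MAPE={mape_txt}, n={self.n}"
        )


def _pearson_with_ci(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float | None, tuple[float, float] | None]:
    """Pearson r with a Fisher-z 95% CI; None when either side is constant."""
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("correlation undefined: zero variance", stacklevel=3)
        return None, None
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    n = len(y_true)
    if n <= 3 or abs(r) >= 1.0:
        return r, None
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def validate(y_true, y_pred) -> ValidationReport:
    """Score predictions on a hold-out set.

    MAPE excludes observations with zero true area (a dry pond gives an
    undefined percentage error).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty hold-out set")
    r, r_ci = _pearson_with_ci(y_true, y_pred)
    mae = float(np.mean(np.abs(y_true - y_pred)))
    nz = y_true != 0
    mape = (
        float(np.mean(np.abs((y_true[nz] - y_pred[nz]) / y_true[nz])) * 100)
        if nz.any()
        else None
    )
    return ValidationReport(r=r, r_ci=r_ci, mae=mae, mape=mape, n=len(y_true))


def _sample_params(u: np.ndarray, config: SearchConfig) -> dict:
    """Map a point in the unit cube to XGBoost hyperparameters."""
    lo, hi = config.learning_rate_range
    lr = lo + u[0] * (hi - lo)
    n_lo, n_hi = config.n_estimators_range
    n_est = int(round(n_lo + u[1] * (n_hi - n_lo)))
    d_lo, d_hi = config.max_depth_range
    depth = int(round(d_lo + u[2] * (d_hi - d_lo)))
    return {"learning_rate": lr, "n_estimators": n_est, "max_depth": depth}


def _expected_improvement(
    gp: GaussianProcessRegressor, cand: np.ndarray, best: float
) -> np.ndarray:
    mu, sigma = gp.predict(cand, return_std=True)
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


class WaterSurfaceModel:
    """Gradient-boosted ensemble model of monthly pond water surface.

    Parameters
    ----------
    X : DataFrame with the :data:`FEATURE_NAMES` columns.
    y : observed water surface areas, ha.
    config : search protocol; defaults follow the standard training recipe.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        config: SearchConfig | None = None,
    ) -> None:
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.config = config or SearchConfig()
        X = X[FEATURE_NAMES].reset_index(drop=True)
        y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
        if X.isna().any().any() or y.isna().any():
            raise ValueError("features and targets must have no missing values")

        keep = X["max_area"] <= self.config.max_area_cap
        self.n_excluded = int((~keep).sum())
        if self.n_excluded:
            logger.info(
                "excluding %d training examples with max_area > %.1f ha",
                self.n_excluded,
                self.config.max_area_cap,
            )
        self.X = X.loc[keep].reset_index(drop=True)
        self.y = y.loc[keep].reset_index(drop=True)
        if len(self.X) < self.config.min_examples:
            raise ValueError(
                f"need at least {self.config.min_examples} examples after the "
                f"{self.config.max_area_cap} ha exclusion, got {len(self.X)}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str = "observed_area_ha",
        config: SearchConfig | None = None,
    ) -> "WaterSurfaceModel":
        return cls(df, df[target], config=config)

    def _make_member(self, params: dict, seed: int) -> XGBRegressor:
        return XGBRegressor(
            **params,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )

    def fit(self, seed: int = 0) -> "WaterSurfaceResults":
        """Run the hyperparameter search and return the fitted ensemble."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        X_tr, X_val, y_tr, y_val = train_test_split(
            self.X,
            self.y,
            test_size=cfg.val_fraction,
            random_state=seed % (2**32),
        )

        rows: list[dict] = []
        members: list[XGBRegressor] = []
        points: list[np.ndarray] = []
        maes: list[float] = []

        def run_trial(u: np.ndarray, stage: str) -> None:
            params = _sample_params(u, cfg)
            model = self._make_member(params, seed)
            model.fit(X_tr, y_tr)
            mae = float(np.mean(np.abs(model.predict(X_val) - y_val)))
            rows.append({"trial": len(rows), "stage": stage, **params,
                         "val_mae": mae})
            members.append(model)
            points.append(u)
            maes.append(mae)

        for _ in range(cfg.n_random):
            run_trial(rng.random(3), "random")

        kernel = Matern(nu=2.5, length_scale=[0.3] * 3) + WhiteKernel(1e-4)
        for _ in range(cfg.n_guided):
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(points), np.array(maes))
            cand = rng.random((512, 3))
            ei = _expected_improvement(gp, cand, min(maes))
            run_trial(cand[int(np.argmax(ei))], "guided")

        log = pd.DataFrame(rows)
        top = log.nsmallest(cfg.ensemble_size, "val_mae")["trial"].to_numpy()
        ensemble = [members[i] for i in top]

        results = WaterSurfaceResults(
            members=ensemble,
            search_log=log,
            config=cfg,
            seed=seed,
            n_excluded=self.n_excluded,
        )
        results.validation = validate(
            y_val.to_numpy(), results.predict(X_val)
        )
        results._val_index = X_val.index.to_numpy()
        return results


@dataclass
class WaterSurfaceResults:
    """Fitted soft-voting ensemble plus its search log and hold-out metrics."""

    members: list
    search_log: pd.DataFrame
    config: SearchConfig
    seed: int
    n_excluded: int = 0
    validation: ValidationReport | None = None
    _val_index: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Ensemble-mean water area, clipped to [0, max_area] per pond."""
        if not self.members:
            raise RuntimeError("model has no fitted members")
        X = X[FEATURE_NAMES]
        raw = np.mean([_member_predict(m, X) for m in self.members], axis=0)
        return np.clip(raw, 0.0, X["max_area"].to_numpy())

    def member_predictions(self, X: pd.DataFrame) -> np.ndarray:
        X = X[FEATURE_NAMES]
        return np.vstack([_member_predict(m, X) for m in self.members])

    def summary(self) -> str:
        lines = [
            "Water surface model (gradient-boosted ensemble, soft voting)",
            f"  members: {len(self.members)} of "
            f"{self.config.n_trials} trials "
            f"({self.config.n_random} random + {self.config.n_guided} guided)",
            f"  excluded from training (> {self.config.max_area_cap} ha): "
            f"{self.n_excluded}",
        ]
        if self.validation is not None:
            lines.append(f"  validation: {self.validation}")
        best = self.search_log.nsmallest(1, "val_mae").iloc[0]
        lines.append(
            f"  best trial: lr={best['learning_rate']:.3f}, "
            f"n_estimators={int(best['n_estimators'])}, "
            f"max_depth={int(best['max_depth'])}, "
            f"val MAE={best['val_mae']:.4f} ha"
        )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a versioned on-disk bundle (members + search log + config)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            booster = m if isinstance(m, xgb.Booster) else m.get_booster()
            booster.save_model(str(path / f"member_{i:02d}.json"))
        self.search_log.to_csv(path / "search_log.csv", index=False)
        meta = {
            "format_version": 1,
            "seed": self.seed,
            "n_members": len(self.members),
            "n_excluded": self.n_excluded,
            "config": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(self.config).items()
            },
            "validation": None
            if self.validation is None
            else {
                "r": self.validation.r,
                "r_ci": self.validation.r_ci,
                "mae": self.validation.mae,
                "mape": self.validation.mape,
                "n": self.validation.n,
            },
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WaterSurfaceResults":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        cfg_raw = meta["config"]
        cfg = SearchConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cfg_raw.items()
            }
        )
        members = []
        for i in range(meta["n_members"]):
            booster = xgb.Booster()
            booster.load_model(str(path / f"member_{i:02d}.json"))
            members.append(booster)
        val = meta.get("validation")
        report = None
        if val is not None:
            report = ValidationReport(
                r=val["r"],
                r_ci=tuple(val["r_ci"]) if val["r_ci"] else None,
                mae=val["mae"],
                mape=val["mape"],
                n=val["n"],
            )
        return cls(
            members=members,
            search_log=pd.read_csv(path / "search_log.csv"),
            config=cfg,
            seed=meta["seed"],
            n_excluded=meta["n_excluded"],
            validation=report,
        )
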