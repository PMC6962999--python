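"""Statistical layer: Lasso G-by-E prediction, variance partitioning, response fits.

The prediction model is y = mu + Z u + eps with an l1 penalty on u and the
penalty scale lambda chosen by internal cross-validation; Z holds standardized
environmental and reflectance covariates plus one-hot-encoded calendar and
genotype factors.  Accuracy is the Pearson correlation between predicted and
measured values after averaging within (genotype, day, hour) cells.  The
explained variance of individual factors is quantified by sequential (Type-I)
sums of squares, and dose-response relationships (efficiency vs temperature
or light) by per-group ordinary least squares on square-root / quadratic
transformed terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import ConfigurationError, SchemaError

DEFAULT_CONTINUOUS = [
    "ppfd", "temperature", "rh", "vpd", "reflectance_sum", "r685",
    "gndvi", "ndvi", "ndvi_ii", "pri", "mtci", "das", "hour_of_day",
]
DEFAULT_CATEGORICAL = ["species", "genotype", "week", "month"]

#: factor order of the temperature-led variance partition
FR2_PARTITION_ORDER = [
    "temperature", "month", "species", "hour_of_day", "date",
    "genotype", "plot_id", "das", "sqrt_temperature",
]
#: light/canopy-led order used for the PSII-efficiency response
FVFM_PARTITION_ORDER = [
    "ppfd", "sqrt_ppfd", "pri", "temperature", "month", "species",
    "hour_of_day", "date", "genotype", "plot_id", "das",
]
PARTITION_CATEGORICAL = {"month", "week", "hour_of_day", "date", "genotype",
                         "plot_id", "species"}


@dataclass
class DesignMatrix:
    """Standardized covariate matrix with stored transform constants."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    response: str
    continuous: list[str]
    categorical: list[str]
    means: pd.Series
    sds: pd.Series
    levels: dict
    n_dropped_rows: int = 0
    dropped_covariates: list[str] = field(default_factory=list)

    def transform(self, obs: pd.DataFrame) -> "DesignMatrix":
        """Encode new observations with the training constants."""
        return _encode(obs, self, fit=False)


def _encode(obs: pd.DataFrame, spec: DesignMatrix, fit: bool) -> DesignMatrix:
    used = spec.continuous + spec.categorical + [spec.response]
    data = obs[used].dropna()
    n_dropped = len(obs) - len(data)
    parts, columns = [], []
    for col in spec.continuous:
        parts.append((data[col].to_numpy(float) - spec.means[col]) / spec.sds[col])
        columns.append(col)
    for col in spec.categorical:
        levels = spec.levels[col]
        for lev in levels[1:]:  # reference level dropped
            parts.append((data[col] == lev).to_numpy(float))
            columns.append(f"{col}[{lev}]")
    X = np.column_stack(parts) if parts else np.empty((len(data), 0))
    return DesignMatrix(
        X=X, y=data[spec.response].to_numpy(float), columns=columns,
        response=spec.response, continuous=spec.continuous,
        categorical=spec.categorical, means=spec.means, sds=spec.sds,
        levels=spec.levels, n_dropped_rows=n_dropped,
        dropped_covariates=list(spec.dropped_covariates),
    )


def build_design_matrix(
    obs: pd.DataFrame,
    response: str,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> DesignMatrix:
    """Build the training design: standardize, one-hot encode, drop NaN rows.

    Zero-variance continuous covariates and single-level factors are dropped
    with a warning; their names are recorded on the result.
    """
    continuous = [c for c in continuous if c in obs.columns]
    categorical = [c for c in categorical if c in obs.columns]
    used = continuous + categorical + [response]
    data = obs[used].dropna()
    if data.empty:
        raise ConfigurationError("no complete observations for the design matrix")

    dropped = []
    keep_cont = []
    means, sds = {}, {}
    for col in continuous:
        sd = float(data[col].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            dropped.append(col)
            continue
        keep_cont.append(col)
        means[col] = float(data[col].mean())
        sds[col] = sd
    keep_cat, levels = [], {}
    for col in categorical:
        levs = sorted(data[col].astype(str).unique()) if data[col].dtype == object \
            else sorted(data[col].unique())
        if len(levs) < 2:
            dropped.append(col)
            continue
        keep_cat.append(col)
        levels[col] = list(levs)
    if dropped:
        warnings.warn(f"dropped zero-variance covariates: {dropped}", stacklevel=2)

    spec = DesignMatrix(
        X=np.empty((0, 0)), y=np.empty(0), columns=[], response=response,
        continuous=keep_cont, categorical=keep_cat,
        means=pd.Series(means), sds=pd.Series(sds), levels=levels,
        dropped_covariates=dropped,
    )
    return _encode(obs, spec, fit=True)


@dataclass
class LassoFit:
    mu: float
    u: pd.Series            # coefficient per design column (many exactly zero)
    lambda_: float
    cv_curve: pd.DataFrame  # (lambda, mean CV MSE)
    seed: int
    columns: list[str]

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.u.to_numpy() != 0.0))


def fit_lasso_cv(
    design: DesignMatrix,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    eps: float = 1e-4,
) -> LassoFit:
    """Coordinate-descent l1 path with lambda chosen at minimum mean CV error.

    The lambda grid is logarithmic over 4 decades down from the data-driven
    maximum; folds are assigned by a seeded shuffle at the observation level,
    and the final model is refit on the full training data at the chosen
    lambda.
    """
    n = len(design.y)
    if not (n > folds >= 2):
        raise ConfigurationError("need n > folds >= 2")
    if design.X.shape[1] == 0:
        raise ConfigurationError("empty design matrix")
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=n_lambdas, eps=eps, cv=cv, max_iter=50000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(design.X, design.y)
    curve = pd.DataFrame({
        "lambda": model.alphas_,
        "cv_mse": model.mse_path_.mean(axis=1),
    })
    return LassoFit(
        mu=float(model.intercept_),
        u=pd.Series(model.coef_, index=design.columns),
        lambda_=float(model.alpha_),
        cv_curve=curve,
        seed=seed,
        columns=list(design.columns),
    )


def fit_lasso(design: DesignMatrix, lambda_: float) -> LassoFit:
    """Single-lambda fit (no cross-validation)."""
    model = Lasso(alpha=lambda_, max_iter=50000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(design.X, design.y)
    return LassoFit(
        mu=float(model.intercept_),
        u=pd.Series(model.coef_, index=design.columns),
        lambda_=float(lambda_),
        cv_curve=pd.DataFrame(columns=["lambda", "cv_mse"]),
        seed=0,
        columns=list(design.columns),
    )


def predict(fit: LassoFit, design: DesignMatrix) -> np.ndarray:
    """y_hat = mu + Z u; the design must carry the training columns."""
    if list(design.columns) != fit.columns:
        raise SchemaError("design columns do not match the fitted model")
    return fit.mu + design.X @ fit.u.to_numpy()


def validate_accuracy(
    observed: np.ndarray,
    predicted: np.ndarray,
    groups: pd.DataFrame,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-genotype Pearson r after (genotype, day, hour) cell averaging.

    ``groups`` needs columns genotype, date, hour_of_day aligned with the
    value arrays.  Genotypes with fewer than ``min_cells`` cells or constant
    vectors get NaN with a flag.
    """
    df = groups[["genotype", "date", "hour_of_day"]].copy()
    df["observed"] = np.asarray(observed, float)
    df["predicted"] = np.asarray(predicted, float)
    cells = (
        df.groupby(["genotype", "date", "hour_of_day"], observed=True)[["observed", "predicted"]]
        .mean()
        .reset_index()
    )
    rows = []
    for genotype, g in cells.groupby("genotype", observed=True):
        flag = ""
        r = np.nan
        if len(g) < min_cells:
            flag = "too_few_cells"
        elif g["observed"].nunique() < 2 or g["predicted"].nunique() < 2:
            flag = "constant"
        else:
            r = float(pearsonr(g["observed"], g["predicted"])[0])
        rows.append({"genotype": genotype, "pearson_r": r,
                     "n_cells": len(g), "flag": flag})
    return pd.DataFrame(rows)


def split_train_validation(
    obs: pd.DataFrame,
    scheme: str = "half-days",
    seed: Optional[int] = None,
    season_col: str = "season",
    train_season=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/validation split.

    "half-days": alternate calendar days by date parity (even positions in
    the sorted day list train; a seed switches to a seeded-random alternation).
    "by-season": one labeled season trains, the rest validates.
    """
    if scheme == "half-days":
        days = np.sort(obs["date"].unique())
        if len(days) < 2:
            raise ConfigurationError("need at least 2 distinct days")
        if seed is not None:
            rng = np.random.default_rng(seed)
            days = rng.permutation(days)
        train_days = set(days[::2])
        mask = obs["date"].isin(train_days)
        return obs[mask].copy(), obs[~mask].copy()
    if scheme == "by-season":
        if season_col not in obs.columns or obs[season_col].nunique() < 2:
            raise ConfigurationError("by-season split needs >= 2 labeled seasons")
        if train_season is None:
            train_season = np.sort(obs[season_col].unique())[0]
        mask = obs[season_col] == train_season
        return obs[mask].copy(), obs[~mask].copy()
    raise ConfigurationError(f"unknown split scheme {scheme!r}")


def _factor_block(data: pd.DataFrame, factor: str) -> np.ndarray:
    """Design columns of one factor (dummies for categoricals, ref dropped)."""
    if factor in PARTITION_CATEGORICAL:
        d = pd.get_dummies(data[factor].astype(str), drop_first=True)
        return d.to_numpy(dtype=float)
    return data[[factor]].to_numpy(dtype=float)


def partition_variance(
    obs: pd.DataFrame,
    response: str,
    factors: Sequence[str] = FR2_PARTITION_ORDER,
) -> pd.DataFrame:
    """Sequential (Type-I) sum-of-squares decomposition.

    Factors enter the linear model strictly in the given order (each factor's
    SS is the drop in residual SS when its block is appended); each row
    reports df, sum of squares, mean square, F value against the full-model
    residual, and the share of the total SS in percent.  A residual row
    completes the total.  Derived columns ``sqrt_temperature`` / ``sqrt_ppfd``
    are added on the fly when requested.  Factors with a single level are
    skipped (0 df, recorded in ``attrs['skipped_factors']``); a factor block
    adding no rank is absorbed with 0 df.
    """
    data = obs.copy()
    if "sqrt_temperature" in factors and "sqrt_temperature" not in data.columns:
        data["sqrt_temperature"] = np.sqrt(np.clip(data["temperature"], 0.0, None))
    if "sqrt_ppfd" in factors and "sqrt_ppfd" not in data.columns:
        data["sqrt_ppfd"] = np.sqrt(np.clip(data["ppfd"], 0.0, None))
    present = [f for f in factors if f in data.columns]
    data = data[present + [response]].dropna()
    usable = [f for f in present if data[f].nunique(dropna=True) >= 2]
    skipped = [f for f in present if f not in usable]
    if not usable:
        raise ConfigurationError("no usable factors for the partition")

    y = data[response].to_numpy(dtype=float)
    n = len(y)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    X = np.ones((n, 1))
    rss_prev = total_ss
    rank_prev = 1
    rows = []
    for f in usable:
        X = np.column_stack([X, _factor_block(data, f)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        df = int(rank - rank_prev)
        rows.append({"factor": f, "df": float(df), "sum_sq": rss_prev - rss})
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    mse = rss_prev / df_resid if df_resid > 0 else np.nan
    for r in rows:
        r["mean_sq"] = r["sum_sq"] / r["df"] if r["df"] else np.nan
        r["f_value"] = r["mean_sq"] / mse if (r["df"] and df_resid > 0) else np.nan
        r["pct_explained"] = 100.0 * r["sum_sq"] / total_ss
    rows.append({"factor": "residual", "df": float(df_resid), "sum_sq": rss_prev,
                 "mean_sq": mse, "f_value": np.nan,
                 "pct_explained": 100.0 * rss_prev / total_ss})
    out = pd.DataFrame(rows)
    out.attrs["total_ss"] = total_ss
    out.attrs["skipped_factors"] = skipped
    return out


@dataclass(frozen=True)
class ResponseFit:
    """One per-group dose-response OLS fit."""

    response: str
    predictor: str
    terms: tuple
    group: object
    coefficients: dict
    r_squared: float
    n: int


def fit_response_curve(
    obs: pd.DataFrame,
    response: str,
    predictor: str,
    terms: Sequence[str] = ("linear", "sqrt"),
    group_by: Optional[str] = None,
    min_rows: int = 10,
) -> list[ResponseFit]:
    """Per-group OLS of ``response`` on transformed ``predictor`` terms.

    ``terms`` is any subset of {"linear", "sqrt", "square"}.  Groups with
    fewer than ``min_rows`` complete rows are skipped.
    """
    builders = {
        "linear": lambda x: x,
        "sqrt": lambda x: np.sqrt(np.clip(x, 0.0, None)),
        "square": lambda x: x ** 2,
    }
    unknown = set(terms) - set(builders)
    if unknown:
        raise ConfigurationError(f"unknown terms {sorted(unknown)}")
    data = obs[[c for c in (response, predictor, group_by) if c]].dropna()
    grouping = data.groupby(group_by, observed=True) if group_by else [(None, data)]
    fits = []
    for group, g in grouping:
        if len(g) < min_rows:
            continue
        x = g[predictor].to_numpy(float)
        X = np.column_stack([builders[t](x) for t in terms])
        X = sm.add_constant(X, has_constant="add")
        res = sm.OLS(g[response].to_numpy(float), X).fit()
        names = ["const"] + [f"{t}({predictor})" for t in terms]
        fits.append(ResponseFit(
            response=response, predictor=predictor, terms=tuple(terms),
            group=group, coefficients=dict(zip(names, res.params)),
            r_squared=float(res.rsquared), n=len(g),
        ))
    return fits
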