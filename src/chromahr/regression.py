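"""Statistical layer: maxHR%, stationarity testing, lag-1 multivariate
autoregression, pooled polynomial regression, and diagnostics.

Two model families relate the smoothed, min-max-normalized color channels
to exercise intensity expressed as percent of the age-predicted maximum
heart rate, maxHR% = HR·100/(220 − age):

* a personalized lag-1 autoregression per participant and color model,
  HR(t) = a1 + w1·HR(t−1) + Σ_n w_n·CR_n(t−1) + e(t),
  fit by ordinary least squares on the three lagged channels CR_n; and
* a universal (pooled across participants) polynomial regression of total
  degree 3 in the three channels, fit by ridge-regularized least squares
  (an epsilon-insensitive SVR loss is available by configuration).

Diagnostics follow the standard definitions: in-sample RMSE, R², the
overall F statistic, augmented Dickey-Fuller stationarity tests for the
channel series, and variance inflation factors VIF_j = 1/(1 − R²_j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "DesignTable",
    "ARFit",
    "ModelMetrics",
    "VIFEntry",
    "VIFReport",
    "ADFResult",
    "PolyFit",
    "max_hr_percent",
    "adf_stationarity",
    "fit_ar1",
    "predict_ar1",
    "fit_poly_global",
    "vif_report",
    "summarize_cohort",
]


def max_hr_percent(hr, age: float):
    """Percent of age-predicted maximum heart rate: HR·100/(220 − age)."""
    if age >= 220:
        raise ValueError("age must be below 220 years")
    hr = np.asarray(hr, dtype=np.float64)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive")
    out = hr * 100.0 / (220.0 - age)
    return float(out) if out.ndim == 0 else out


@dataclass
class DesignTable:
    """Aligned per-second regression rows for one participant and model.

    ``predictors`` holds the three min-max-normalized channel columns;
    ``y`` is maxHR% (or its normalized variant, by configuration).
    """

    t: np.ndarray
    y: np.ndarray
    predictors: pd.DataFrame
    participant_id: str = ""
    age: float = float("nan")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not isinstance(self.predictors, pd.DataFrame):
            self.predictors = pd.DataFrame(np.asarray(self.predictors))
        if self.predictors.shape[1] != 3:
            raise ValueError("design table needs exactly 3 predictor columns")
        n = len(self.y)
        if len(self.t) != n or len(self.predictors) != n:
            raise ValueError("t, y, predictors must have equal length")
        vals = self.predictors.to_numpy(dtype=np.float64)
        if np.isnan(vals).any() or np.isnan(self.y).any():
            raise ValueError("design table must not contain missing values")
        if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
            raise ValueError("predictor columns must be min-max normalized to [0, 1]")
        if self.y.min() < 0 or self.y.max() > 120:
            raise ValueError("y (maxHR%) must lie in [0, 120]")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(map(str, self.predictors.columns))

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class ARFit:
    """Lag-1 autoregression parameters and in-sample residuals."""

    a1: float
    w1: float
    wn: np.ndarray
    residuals: np.ndarray
    rmse: float
    se: np.ndarray  # standard errors, order (a1, w1, wn...)
    channel_names: tuple[str, ...]
    nobs: int

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.a1, self.w1], self.wn])


@dataclass
class ModelMetrics:
    rmse: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


@dataclass
class VIFEntry:
    name: str
    vif: float
    p_value: float


@dataclass
class VIFReport:
    entries: list[VIFEntry]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {e.name: {"vif": e.vif, "p_value": e.p_value} for e in self.entries}


@dataclass
class ADFResult:
    statistic: float
    p_value: float
    stationary: bool
    note: str = ""


def adf_stationarity(series, alpha: float = 0.05) -> ADFResult:
    """Augmented Dickey-Fuller unit-root test (constant term, lag order by
    AIC); ``stationary`` is rejection of the unit-root null at ``alpha``.

    A constant series has no unit root but degenerates the test regression;
    it is reported stationary with a note rather than an error.
    """
    v = np.asarray(series, dtype=np.float64)
    if len(v) < 10:
        raise ValueError("ADF test needs at least 10 observations")
    if np.ptp(v) == 0:
        return ADFResult(float("nan"), 0.0, True, note="degenerate constant series")
    stat, pvalue = adfuller(v, regression="c", autolag="AIC")[:2]
    return ADFResult(float(stat), float(pvalue), bool(pvalue < alpha))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        const = [
            names[j]
            for j in range(X.shape[1])
            if j > 0 and np.ptp(X[:, j]) == 0
        ]
        if const:
            raise ValueError(f"rank-deficient design: constant column(s) {const}")
        raise ValueError(f"rank-deficient design: collinear columns among {names[1:]}")


def fit_ar1(table: DesignTable) -> ARFit:
    """OLS fit of y(t) on [1, y(t−1), CR1(t−1), CR2(t−1), CR3(t−1)]."""
    n = len(table)
    if n < 10:
        raise ValueError("lag-1 autoregression needs at least 10 rows")
    P = table.predictors.to_numpy(dtype=np.float64)
    X = np.column_stack([np.ones(n - 1), table.y[:-1], P[:-1]])
    z = table.y[1:]
    names = ["intercept", "y_lag1", *table.channel_names]
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    rmse = float(np.sqrt(np.mean(resid**2)))
    dof = max(len(z) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return ARFit(
        a1=float(beta[0]),
        w1=float(beta[1]),
        wn=beta[2:].copy(),
        residuals=resid,
        rmse=rmse,
        se=se,
        channel_names=table.channel_names,
        nobs=n,
    )


def predict_ar1(fit: ARFit, table: DesignTable) -> tuple[np.ndarray, float]:
    """One-step-ahead predictions from observed lags, plus their RMSE."""
    if fit.channel_names != table.channel_names:
        raise ValueError(
            f"channel names {table.channel_names} do not match the fitted "
            f"model's {fit.channel_names}"
        )
    P = table.predictors.to_numpy(dtype=np.float64)
    pred = fit.a1 + fit.w1 * table.y[:-1] + P[:-1] @ fit.wn
    rmse = float(np.sqrt(np.mean((table.y[1:] - pred) ** 2)))
    return pred, rmse


@dataclass
class PolyFit:
    """Pooled polynomial regression model with its expansion attached."""

    expander: PolynomialFeatures
    model: object
    channel_names: tuple[str, ...]
    metrics: ModelMetrics = None  # type: ignore[assignment]
    coefficients: dict[str, float] = field(default_factory=dict)

    def predict(self, predictors) -> np.ndarray:
        P = (
            predictors.to_numpy(dtype=np.float64)
            if isinstance(predictors, pd.DataFrame)
            else np.asarray(predictors, dtype=np.float64)
        )
        return self.model.predict(self.expander.transform(P))


def fit_poly_global(
    tables: list[DesignTable],
    degree: int = 3,
    estimator: str = "ridge",
    alpha: float = 1e-6,
    epsilon: float = 0.1,
    C: float = 1.0,
) -> PolyFit:
    """Universal model: pool all participants' rows and regress y on all
    polynomial terms of the three channels up to total ``degree``.

    The default estimator is ridge-regularized least squares (deterministic,
    with a vanishing penalty); ``estimator="svr"`` uses an
    epsilon-insensitive loss with a polynomial kernel of the same degree.
    The overall F statistic uses df = (p_terms, n − p_terms − 1).
    """
    if not tables:
        raise ValueError("no design tables supplied")
    names = tables[0].channel_names
    for tb in tables:
        if tb.channel_names != names:
            raise ValueError("all design tables must share channel names")
    P = np.vstack([tb.predictors.to_numpy(dtype=np.float64) for tb in tables])
    y = np.concatenate([tb.y for tb in tables])
    expander = PolynomialFeatures(degree=degree, include_bias=False)
    Xp = expander.fit_transform(P)
    n, p = Xp.shape
    if n <= p + 1:
        raise ValueError(
            f"pooled n={n} insufficient for {p} polynomial terms"
        )
    if estimator == "ridge":
        model = Ridge(alpha=alpha)
    elif estimator == "svr":
        model = SVR(kernel="linear", C=C, epsilon=epsilon)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    model.fit(Xp, y)
    pred = model.predict(Xp)
    resid = y - pred
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    rmse = float(np.sqrt(sse / n))
    df = (p, n - p - 1)
    if sse > 0:
        f = (r2 / p) / ((1.0 - r2) / df[1]) if r2 < 1 else float("inf")
    else:
        f = float("inf")
    pval = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    term_names = expander.get_feature_names_out(names)
    if hasattr(model, "coef_"):
        coefs = {"intercept": float(np.atleast_1d(model.intercept_)[0])}
        coefs.update(
            {t: float(c) for t, c in zip(term_names, np.ravel(model.coef_))}
        )
    else:
        coefs = {}
    fit = PolyFit(expander=expander, model=model, channel_names=names)
    fit.metrics = ModelMetrics(rmse=rmse, r_squared=r2, f_stat=float(f), df=df, p_value=pval)
    fit.coefficients = coefs
    return fit


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float(resid @ resid) / sst


def vif_report(predictors, y=None) -> VIFReport:
    """Variance inflation factors, VIF_j = 1/(1 − R²_j), with R²_j from
    regressing predictor j on the remaining predictors (with intercept).

    The per-predictor p-value is the slope p-value of the univariate
    regression of ``y`` on that predictor when ``y`` is given, otherwise
    the F-test p-value of the auxiliary (collinearity) regression.
    Perfectly collinear columns yield an infinite VIF with a warning.
    """
    df = predictors if isinstance(predictors, pd.DataFrame) else pd.DataFrame(np.asarray(predictors))
    X = df.to_numpy(dtype=np.float64)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("too few rows for a VIF computation")
    entries = []
    for j, name in enumerate(map(str, df.columns)):
        others = np.delete(X, j, axis=1)
        r2 = _ols_r2(others, X[:, j])
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {name!r} is perfectly collinear; VIF infinite")
            vif = float("inf")
        else:
            vif = 1.0 / (1.0 - r2)
        if y is not None:
            res = stats.linregress(X[:, j], np.asarray(y, dtype=np.float64))
            pv = float(res.pvalue)
        else:
            p_aux = others.shape[1]
            if r2 >= 1.0 - 1e-12:
                pv = 0.0
            else:
                f = (r2 / p_aux) / ((1.0 - r2) / (n - p_aux - 1))
                pv = float(stats.f.sf(f, p_aux, n - p_aux - 1))
        entries.append(VIFEntry(name=name, vif=vif, p_value=pv))
    return VIFReport(entries)


def summarize_cohort(records) -> dict[str, dict[str, float]]:
    """Mean and sample (n−1) standard deviation of age, weight, height."""
    df = pd.DataFrame(records)
    if len(df) < 2:
        raise ValueError("cohort summary needs at least 2 records")
    out = {}
    for col in ("age", "weight", "height"):
        if col in df:
            out[col] = {
                "mean": float(df[col].mean()),
                "sd": float(df[col].std(ddof=1)),
            }
    return out
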