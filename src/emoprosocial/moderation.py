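"""Moderated multiple regression with simple-slopes inference.

The moderation model regresses a standardized outcome y (daily prosocial
score) on a standardized focal predictor x (a daily emotion score), a
standardized moderator m (daily newly confirmed cases) and their product:

    y = B0 + B1*x + B2*m + B3*x*m + e

x, m and y are z-scored (sample SD) *before* the product term is formed;
the product is not re-standardized.  B3 quantifies how the focal effect
changes with the moderator.  Inference is reported twice: analytic OLS
t/p with n − 4 residual degrees of freedom, and nonparametric
case-resampling bootstrap percentile 95% CIs.  The conditional ("simple")
slope of x at a moderator value with z-score z is B1 + B3*z, probed at
the high level M + 1SD and at a low level that substitutes the observed
minimum when M − 1SD falls below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

COEF_NAMES = ("intercept", "x", "m", "x:m")


class ModerationError(ValueError):
    pass


@dataclass
class StandardizedSeries:
    """A z-scored vector remembering its source moments (sample SD)."""

    values: np.ndarray
    source_mean: float
    source_sd: float


def standardize(x: Sequence[float]) -> StandardizedSeries:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ModerationError("standardize needs a 1-d vector of length >= 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ModerationError("zero variance: standardization undefined")
    return StandardizedSeries(values=(arr - mean) / sd, source_mean=mean, source_sd=sd)


def zscore_with(value: float, mean: float, sd: float) -> float:
    """z-score a raw value against externally supplied moments."""
    if sd <= 0:
        raise ModerationError("moderator SD must be positive")
    return (value - mean) / sd


@dataclass
class ModerationFit:
    """Standardized OLS fit of y ~ 1 + x + m + x*m with dual inference."""

    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    ci_analytic: dict[str, tuple[float, float]]
    ci_boot: dict[str, tuple[float, float]] | None
    cov: np.ndarray  # 4x4 coefficient covariance, COEF_NAMES order
    r2: float
    f: float
    f_p: float
    n: int
    n_boot: int
    seed: int | None
    x_moments: tuple[float, float]
    m_moments: tuple[float, float]
    y_moments: tuple[float, float]

    @property
    def df_resid(self) -> int:
        return self.n - 4


@dataclass
class SimpleSlope:
    """Conditional effect of x at one moderator level."""

    moderator_level_raw: float
    moderator_level_z: float
    slope: float
    se: float | None = None
    t: float | None = None
    p: float | None = None
    label: str = ""


def _design(zx: np.ndarray, zm: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(zx), zx, zm, zx * zm])


def fit_moderation(
    y: Sequence[float],
    x: Sequence[float],
    m: Sequence[float],
    n_boot: int = 5000,
    seed: int | None = None,
) -> ModerationFit:
    """Fit the moderation model on raw series.

    ``n_boot`` resamples of whole cases give percentile 95% CIs
    (``n_boot=0`` skips the bootstrap); ``seed`` makes them reproducible.
    """
    ys, xs, ms = standardize(y), standardize(x), standardize(m)
    n = ys.values.size
    if not (xs.values.size == n == ms.values.size):
        raise ModerationError("y, x, m must have equal length")
    if n < 5:
        raise ModerationError("need at least 5 observations for a 4-parameter model")
    X = _design(xs.values, ms.values)
    if np.linalg.matrix_rank(X) < 4:
        raise ModerationError("rank-deficient design (collinear predictors)")
    res = sm.OLS(ys.values, X).fit()
    ci = res.conf_int(alpha=0.05)

    ci_boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = np.empty((n_boot, 4))
        yv = ys.values
        for b in range(n_boot):
            rows = idx[b]
            boot[b], *_ = np.linalg.lstsq(X[rows], yv[rows], rcond=None)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        ci_boot = {name: (float(lo[k]), float(hi[k])) for k, name in enumerate(COEF_NAMES)}

    return ModerationFit(
        coef={name: float(res.params[k]) for k, name in enumerate(COEF_NAMES)},
        se={name: float(res.bse[k]) for k, name in enumerate(COEF_NAMES)},
        t={name: float(res.tvalues[k]) for k, name in enumerate(COEF_NAMES)},
        p={name: float(res.pvalues[k]) for k, name in enumerate(COEF_NAMES)},
        ci_analytic={name: (float(ci[k, 0]), float(ci[k, 1])) for k, name in enumerate(COEF_NAMES)},
        ci_boot=ci_boot,
        cov=np.asarray(res.cov_params()),
        r2=float(res.rsquared),
        f=float(res.fvalue),
        f_p=float(res.f_pvalue),
        n=int(n),
        n_boot=int(n_boot),
        seed=seed,
        x_moments=(xs.source_mean, xs.source_sd),
        m_moments=(ms.source_mean, ms.source_sd),
        y_moments=(ys.source_mean, ys.source_sd),
    )


def low_level_rule(m_raw: Sequence[float]) -> float:
    """Low moderator probe level: M − 1SD, floored at the observed minimum.

    When the moderator is strongly skewed (as epidemic case counts are),
    M − 1SD can fall below every observed value or even below zero; the
    observed minimum is substituted in that case.
    """
    arr = np.asarray(m_raw, dtype=float)
    if arr.size == 0:
        raise ModerationError("empty moderator series")
    if arr.size == 1:
        return float(arr[0])
    mean, sd, mn = arr.mean(), arr.std(ddof=1), arr.min()
    return float(max(mean - sd, mn))


def simple_slopes(
    fit: ModerationFit,
    m_levels_raw: Sequence[float],
    m_moments: tuple[float, float] | None = None,
    labels: Sequence[str] | None = None,
) -> list[SimpleSlope]:
    """Conditional slopes B1 + B3*z at raw moderator levels.

    SE comes from the analytic coefficient covariance,
    sqrt(Var(B1) + z^2 Var(B3) + 2z Cov(B1,B3)); t uses n − 4 df.
    """
    mean, sd = m_moments if m_moments is not None else fit.m_moments
    b1, b3 = fit.coef["x"], fit.coef["x:m"]
    v11, v33, v13 = fit.cov[1, 1], fit.cov[3, 3], fit.cov[1, 3]
    out = []
    for k, level in enumerate(m_levels_raw):
        z = zscore_with(float(level), mean, sd)
        slope = b1 + b3 * z
        var = v11 + z * z * v33 + 2.0 * z * v13
        se = float(np.sqrt(var)) if var >= 0 else float("nan")
        tval = slope / se if se and np.isfinite(se) and se > 0 else float("nan")
        pval = float(2.0 * sps.t.sf(abs(tval), df=fit.df_resid)) if np.isfinite(tval) else float("nan")
        out.append(
            SimpleSlope(
                moderator_level_raw=float(level),
                moderator_level_z=float(z),
                slope=float(slope),
                se=se,
                t=float(tval) if np.isfinite(tval) else None,
                p=pval if np.isfinite(tval) else None,
                label=labels[k] if labels is not None else "",
            )
        )
    return out


def probe_levels(m_raw: Sequence[float]) -> dict[str, float]:
    """The pick-a-point levels: high = M + 1SD, low via low_level_rule."""
    arr = np.asarray(m_raw, dtype=float)
    return {
        "high": float(arr.mean() + arr.std(ddof=1)),
        "low": low_level_rule(arr),
    }


@dataclass
class CorrelationReport:
    """Per-variable descriptives and the pairwise Pearson matrix."""

    means: pd.Series
    sds: pd.Series
    r: pd.DataFrame
    p: pd.DataFrame


def correlation_report(panel: pd.DataFrame, variables: Sequence[str] | None = None) -> CorrelationReport:
    """Descriptive statistics and correlations over the daily panel.

    Defaults to the eight analysis variables in the conventional order:
    severity first, then prosocial, then the six emotions.
    """
    if variables is None:
        variables = [
            "new_cases", "prosocial", "happiness", "anger",
            "sadness", "fear", "disgust", "surprise",
        ]
    missing = [v for v in variables if v not in panel.columns]
    if missing:
        raise ModerationError(f"panel lacks columns {missing}")
    df = panel[list(variables)].astype(float)
    n = len(df)
    if n < 3:
        raise ModerationError("need at least 3 rows for correlations")
    for v in variables:
        if df[v].std(ddof=1) == 0:
            raise ModerationError(f"column {v!r} is constant: correlation undefined")
    r = df.corr(method="pearson")
    rv = r.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.clip(1.0 - rv * rv, 1e-300, None))
    pmat = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pmat, 0.0)
    p = pd.DataFrame(pmat, index=r.index, columns=r.columns)
    return CorrelationReport(
        means=df.mean(), sds=df.std(ddof=1), r=r, p=p
    )
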