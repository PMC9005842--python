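"""Age-continuous percentile modelling (LMS / Box-Cox Cole-Green).

Per sex, the analyte y at age t follows a BCCG law:

    z = ((y / M(t))^L - 1) / (L * S(t))   (L != 0)
    z = ln(y / M(t)) / S(t)               (L  = 0)

with z standard normal, M(t) the median curve, S(t) the coefficient of
variation curve and L a constant skewness/power parameter.  M and S are
log-linked regression splines over age; models across a candidate grid
of degrees of freedom are compared by the generalized Akaike criterion
GAIC(k) = deviance + k * df, with k = ln(n) (SBC) as the default
selector.  Validation uses the fraction-outside-RI (FOR) statistic per
1-year age bin on a held-out split: with a one-sided interval
(0, C_95(t)) the mean FOR should sit near the nominal 5% and below 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

__all__ = [
    "AgeModel",
    "FORReport",
    "split_train_validation",
    "fit_age_model",
    "gaic",
    "sbc",
    "select_model",
    "percentile_table",
    "compute_for",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


def _basis(ages: np.ndarray, df: int, age_min: float, age_max: float) -> np.ndarray:
    """Design matrix with ``df`` columns (intercept included).

    df 1..3 use (orthogonalized) polynomial terms; df >= 4 uses a cubic
    B-spline basis with interior knots at age quantiles of a uniform
    grid.  Ages are scaled to [0, 1] for conditioning.
    """
    u = (np.asarray(ages, dtype=float) - age_min) / max(age_max - age_min, 1e-9)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df <= 3:
        cols = [u ** k for k in range(df)]
        return np.column_stack(cols)
    k = 3
    n_interior = df - k - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    t = np.concatenate([[0.0] * (k + 1), interior, [1.0] * (k + 1)])
    B = interpolate.BSpline.design_matrix(np.clip(u, 0, 1), t, k).toarray()
    return B


@dataclass
class AgeModel:
    """Fitted BCCG model for one sex: L constant, spline M(t) and S(t)."""

    sex: int
    lam: float                      # the constant L (skewness/power)
    beta_m: np.ndarray              # coefficients of ln M(t)
    beta_s: np.ndarray              # coefficients of ln S(t)
    df_m: int
    df_s: int
    age_min: float
    age_max: float
    deviance: float
    n_train: int
    n_outer_iter: int = 0

    @property
    def total_df(self) -> int:
        return self.df_m + self.df_s + 1

    def curves(self, ages) -> tuple[np.ndarray, np.ndarray]:
        """(M(t), S(t)) at the requested ages."""
        a = np.asarray(ages, dtype=float)
        Bm = _basis(a, self.df_m, self.age_min, self.age_max)
        Bs = _basis(a, self.df_s, self.age_min, self.age_max)
        return np.exp(Bm @ self.beta_m), np.exp(Bs @ self.beta_s)

    def to_dict(self) -> dict:
        return {"sex": self.sex, "L": self.lam,
                "beta_m": self.beta_m.tolist(), "beta_s": self.beta_s.tolist(),
                "df_m": self.df_m, "df_s": self.df_s,
                "age_min": self.age_min, "age_max": self.age_max,
                "deviance": self.deviance, "n_train": self.n_train}


@dataclass
class FORReport:
    """Per-1-year-bin fraction outside the reference interval (percent)."""

    bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_for: float = np.nan
    passes_below_10: bool = False
    around_5: bool = False

    def to_dict(self) -> dict:
        return {"mean_for_pct": self.mean_for,
                "passes_below_10": self.passes_below_10,
                "around_5": self.around_5,
                "bins": self.bins.to_dict(orient="records")}


def split_train_validation(df: pd.DataFrame, train_fraction: float = 0.7,
                           seed: int = 0, stratify: str | None = "sex",
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded, sex-stratified, disjoint and exhaustive 70/30-style split."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(df) < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    train_idx = []
    groups = df.groupby(stratify) if stratify else [(None, df)]
    for _, sub in groups:
        perm = rng.permutation(len(sub))
        n_train = int(round(train_fraction * len(sub)))
        train_idx.extend(sub.index[perm[:n_train]])
    mask = df.index.isin(train_idx)
    return df.loc[mask], df.loc[~mask]


def _bccg_nll(y, ln_y, Bm, Bs, beta_m, beta_s, lam):
    ln_M = Bm @ beta_m
    ln_S = Bs @ beta_s
    if np.any(ln_S > 5) or np.any(ln_S < -10):
        return 1e300
    S = np.exp(ln_S)
    r = ln_y - ln_M  # ln(y/M)
    if abs(lam) < 1e-8:
        z = r / S
        extra = -ln_y
    else:
        z = (np.exp(lam * r) - 1.0) / (lam * S)
        extra = (lam - 1.0) * ln_y - lam * ln_M
    nll = float(np.sum(0.5 * z * z + ln_S - extra)
                + 0.5 * y.size * math.log(2 * math.pi))
    if not np.isfinite(nll):
        return 1e300
    return nll


def fit_age_model(train: pd.DataFrame, sex: int,
                  candidate_dfs: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
                  df_s: int = 2, value_col: str = "hcy",
                  tol: float = 1e-4, max_outer: int = 200,
                  ) -> list[AgeModel]:
    """Blockwise maximum-likelihood BCCG fits over a df grid for M(t).

    For each candidate df, the optimizer alternates ("backfits") between
    the M-curve coefficients, the S-curve coefficients and the scalar L
    until the deviance changes by less than ``tol``.  Returns one fitted
    model per candidate; select among them with :func:`select_model`.
    """
    sub = train[train["sex"] == sex]
    if len(sub) < 200:
        raise ValueError(f"need >= 200 training records for sex={sex}")
    y = sub[value_col].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("analyte values must be > 0")
    ages = sub["age"].to_numpy(dtype=float)
    age_min, age_max = float(ages.min()), float(ages.max())
    ln_y = np.log(y)

    models = []
    for dfm in candidate_dfs:
        Bm = _basis(ages, dfm, age_min, age_max)
        Bs = _basis(ages, df_s, age_min, age_max)
        # init: ln M from OLS of ln y, ln S from log residual SD, L = 1
        beta_m, *_ = np.linalg.lstsq(Bm, ln_y, rcond=None)
        resid = ln_y - Bm @ beta_m
        beta_s = np.zeros(Bs.shape[1])
        beta_s[0] = math.log(max(resid.std(ddof=1), 1e-6))
        lam = 1.0
        prev_dev = math.inf
        converged = False
        for outer in range(1, max_outer + 1):
            res_m = optimize.minimize(
                lambda b: _bccg_nll(y, ln_y, Bm, Bs, b, beta_s, lam),
                beta_m, method="L-BFGS-B",
                options={"maxiter": 80, "ftol": 1e-10})
            beta_m = res_m.x
            res_s = optimize.minimize(
                lambda b: _bccg_nll(y, ln_y, Bm, Bs, beta_m, b, lam),
                beta_s, method="L-BFGS-B",
                options={"maxiter": 80, "ftol": 1e-10})
            beta_s = res_s.x
            res_l = optimize.minimize_scalar(
                lambda L: _bccg_nll(y, ln_y, Bm, Bs, beta_m, beta_s, L),
                bounds=(-3.0, 3.0), method="bounded",
                options={"xatol": 1e-6})
            lam = float(res_l.x)
            dev = 2.0 * res_l.fun
            if abs(prev_dev - dev) < tol:
                converged = True
                break
            prev_dev = dev
        if not converged:
            raise RuntimeError(
                f"BCCG backfitting did not converge within {max_outer} "
                f"outer iterations (df={dfm}, last deviance {dev:.6f})")
        models.append(AgeModel(
            sex=sex, lam=lam, beta_m=beta_m, beta_s=beta_s,
            df_m=dfm, df_s=df_s, age_min=age_min, age_max=age_max,
            deviance=float(dev), n_train=len(sub), n_outer_iter=outer))
    return models


def gaic(model: AgeModel, k: float) -> float:
    """Generalized AIC: deviance + k * total effective df."""
    if k <= 0:
        raise ValueError("penalty k must be > 0")
    return model.deviance + k * model.total_df


def sbc(model: AgeModel) -> float:
    """Schwarz criterion: the k = ln(n_train) case of the GAIC."""
    return gaic(model, math.log(model.n_train))


def select_model(models: Sequence[AgeModel], k: float | None = None) -> AgeModel:
    """Minimum-GAIC model; ``k=None`` uses ln(n) (SBC)."""
    if not models:
        raise ValueError("no models to select from")
    scores = [gaic(m, k) if k is not None else sbc(m) for m in models]
    return models[int(np.argmin(scores))]


def percentile_table(model: AgeModel, ages: Sequence[int] | None = None,
                     ps: Sequence[float] = DEFAULT_PERCENTILES) -> pd.DataFrame:
    """C_p(t) on a 1-year age grid.

    C_p(t) = M(t) (1 + L S(t) z_p)^(1/L) for L != 0, else
    M(t) exp(S(t) z_p).  Rows are ages; columns labelled 'p5'...'p95'.
    """
    if ages is None:
        ages = np.arange(int(math.ceil(model.age_min)),
                         int(math.floor(model.age_max)) + 1)
    ages = np.asarray(ages)
    if ages.min() < model.age_min or ages.max() > model.age_max:
        raise ValueError("requested ages outside the fitted range")
    M, S = model.curves(ages)
    out = {"age": ages}
    for p in sorted(ps):
        z = stats.norm.ppf(p)
        if abs(model.lam) < 1e-8:
            c = M * np.exp(S * z)
        else:
            base = 1.0 + model.lam * S * z
            if np.any(base <= 0):
                bad_age = int(ages[np.argmax(base <= 0)])
                raise ValueError(
                    f"percentile undefined at age {bad_age}, p={p}: "
                    f"1 + L*S*z_p <= 0")
            c = M * base ** (1.0 / model.lam)
        out[f"p{p * 100:g}"] = c
    table = pd.DataFrame(out)
    cols = [c for c in table.columns if c != "age"]
    vals = table[cols].to_numpy()
    if not np.all(np.diff(vals, axis=1) > 0):
        raise AssertionError("percentile curves cross on the age grid")
    return table


def upper_limit_curve(model: AgeModel, ages) -> np.ndarray:
    """Age-specific upper reference limit C_95(t) (lower limit is 0)."""
    tab = percentile_table(model, np.asarray(ages), ps=(0.95,))
    return tab["p95"].to_numpy()


def compute_for(model: AgeModel, validation: pd.DataFrame,
                value_col: str = "hcy") -> FORReport:
    """Fraction outside the one-sided RI per 1-year bin on held-out data.

    A subject is outside iff value > C_95(age); positive data can never
    violate the lower limit 0.  The mean FOR is the unweighted mean over
    non-empty bins; pass flags encode "< 10%" and "around 5%"
    (within 2.5 percentage points).
    """
    sub = validation[validation["sex"] == model.sex]
    if sub.empty:
        raise ValueError("validation set has no records for this sex")
    ages = np.clip(np.rint(sub["age"].to_numpy(dtype=float)).astype(int),
                   int(math.ceil(model.age_min)), int(math.floor(model.age_max)))
    vals = sub[value_col].to_numpy(dtype=float)
    limits = upper_limit_curve(model, ages)
    outside = vals > limits
    frame = pd.DataFrame({"age": ages, "outside": outside})
    grp = frame.groupby("age")["outside"].agg(["size", "sum"])
    grp["for_pct"] = 100.0 * grp["sum"] / grp["size"]
    bins = grp.reset_index().rename(columns={"size": "n", "sum": "n_outside"})
    mean_for = float(bins["for_pct"].mean())
    return FORReport(
        bins=bins, mean_for=mean_for,
        passes_below_10=bool(mean_for < 10.0),
        around_5=bool(abs(mean_for - 5.0) <= 2.5))
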