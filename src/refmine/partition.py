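"""Partitioning decision: should the reference interval be split by sex
and/or age?

Two classical tools are combined.  Standardized regression coefficients
from an OLS fit with dummy-coded age rank the factors; the larger factor
becomes level 1 of a two-level nested variance-components model.  The
standard-deviation ratio SDR_f = SD_f / SD_resid for each factor is then
compared against the conventional 0.375 threshold: a factor whose SDR
exceeds it warrants a partitioned reference interval.

Variance components come from the unbalanced nested ANOVA
(method-of-moments on expected mean squares); negative estimates are
truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cleaning import age_band, AGE_BAND_LABELS

__all__ = [
    "SDR_THRESHOLD",
    "build_design",
    "standardized_betas",
    "nested_sdr",
    "decide_partition",
    "PartitionDecision",
]

SDR_THRESHOLD = 0.375
AGE_DUMMIES = ("A1", "A2", "A3", "A4", "A5", "A6")


@dataclass
class PartitionDecision:
    """Betas, nested variance components, SDRs and the split verdicts."""

    betas: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    sd_level1: float = np.nan
    sd_level2: float = np.nan
    sd_resid: float = np.nan
    sdr_level1: float = np.nan
    sdr_level2: float = np.nan
    level1: str = "sex"
    level2: str = "age_group"
    threshold: float = SDR_THRESHOLD
    partition_by_sex: bool = False
    partition_by_age: bool = False

    @property
    def sdr_sex(self) -> float:
        return self.sdr_level1 if self.level1 == "sex" else self.sdr_level2

    @property
    def sdr_age(self) -> float:
        return self.sdr_level2 if self.level1 == "sex" else self.sdr_level1

    def to_dict(self) -> dict:
        return {
            "betas": self.betas, "p_values": self.p_values,
            "hierarchy": [self.level1, self.level2],
            "sd_level1": self.sd_level1, "sd_level2": self.sd_level2,
            "sd_resid": self.sd_resid,
            "sdr_sex": self.sdr_sex, "sdr_age": self.sdr_age,
            "threshold": self.threshold,
            "partition_by_sex": self.partition_by_sex,
            "partition_by_age": self.partition_by_age,
        }


def build_design(df: pd.DataFrame, value_col: str = "hcy") -> pd.DataFrame:
    """Response plus sex indicator and six age dummies A1..A6.

    Reference levels: female (sex=0) and ages 18–29 (all dummies zero);
    A1..A6 flag the bands 30–39 … 80+.
    """
    if (df["age"] < 18).any():
        raise ValueError("records with age < 18 present; clean first")
    bands = age_band(df["age"].to_numpy())
    out = pd.DataFrame({"y": df[value_col].to_numpy(),
                        "sex": df["sex"].to_numpy().astype(int)})
    for j, name in enumerate(AGE_DUMMIES, start=1):
        out[name] = (bands == j).astype(int)
    return out


def standardized_betas(design: pd.DataFrame) -> tuple[dict, dict]:
    """OLS betas rescaled to beta_j = b_j * SD(x_j) / SD(y), with p-values."""
    y = design["y"].to_numpy(dtype=float)
    X = design.drop(columns="y")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify offending columns by near-zero singular directions
        _, s, vt = np.linalg.svd(Xc)
        bad = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]
        names = ["const"] + list(X.columns)
        raise ValueError("rank-deficient design; collinear columns: "
                         + ", ".join(names[i] for i in bad))
    fit = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    betas, pvals = {}, {}
    for j, name in enumerate(X.columns, start=1):
        sd_x = X[name].to_numpy(dtype=float).std(ddof=1)
        betas[name] = float(fit.params[j] * sd_x / sd_y)
        pvals[name] = float(fit.pvalues[j])
    return betas, pvals


def _nested_anova_components(df: pd.DataFrame, level1: str, level2: str,
                             value_col: str) -> tuple[float, float, float]:
    """Unbalanced two-level nested ANOVA variance components.

    Expected mean squares (Sokal & Rohlf):
        E[MS_E]    = s2_e
        E[MS_B(A)] = s2_e + c1 * s2_b
        E[MS_A]    = s2_e + c2 * s2_b + c3 * s2_a
    with the standard unbalanced coefficients. Negative solutions are
    truncated at zero.
    """
    y = df[value_col].to_numpy(dtype=float)
    g1 = df[level1].to_numpy()
    g2 = df[level2].to_numpy()
    cells = df.groupby([level1, level2])[value_col]
    sizes = cells.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 records: {bad}")

    N = y.size
    grand = y.mean()
    a_levels = np.unique(g1)
    a = a_levels.size

    ss_a = 0.0
    ss_b = 0.0
    ss_e = 0.0
    df_b = 0
    sum_nij2_over_ni = 0.0
    sum_nij2 = 0.0
    sum_ni2 = 0.0
    for lev in a_levels:
        m = g1 == lev
        yi = y[m]
        ni = yi.size
        ss_a += ni * (yi.mean() - grand) ** 2
        sum_ni2 += ni ** 2
        sub2 = g2[m]
        b_levels = np.unique(sub2)
        df_b += b_levels.size - 1
        nij2 = 0.0
        for lev2 in b_levels:
            yij = yi[sub2 == lev2]
            nij = yij.size
            nij2 += nij ** 2
            ss_b += nij * (yij.mean() - yi.mean()) ** 2
            ss_e += ((yij - yij.mean()) ** 2).sum()
        sum_nij2_over_ni += nij2 / ni
        sum_nij2 += nij2

    df_a = a - 1
    df_e = N - df_a - df_b - 1
    ms_a = ss_a / df_a
    ms_b = ss_b / df_b if df_b > 0 else 0.0
    ms_e = ss_e / df_e

    c1 = (N - sum_nij2_over_ni) / df_b if df_b > 0 else 1.0
    c2 = (sum_nij2_over_ni - sum_nij2 / N) / df_a
    c3 = (N - sum_ni2 / N) / df_a

    s2_e = ms_e
    s2_b = max((ms_b - ms_e) / c1, 0.0) if df_b > 0 else 0.0
    s2_a = max((ms_a - ms_e - c2 * s2_b) / c3, 0.0)
    return s2_a, s2_b, s2_e


def nested_sdr(df: pd.DataFrame, level1: str = "sex",
               level2: str = "age_group", value_col: str = "hcy",
               threshold: float = SDR_THRESHOLD) -> PartitionDecision:
    """SDRs from the two-level nested model; verdicts use strict '>'."""
    work = df
    if level2 == "age_group" and "age_group" not in df.columns:
        work = df.copy()
        work["age_group"] = age_band(df["age"].to_numpy())
    s2_a, s2_b, s2_e = _nested_anova_components(work, level1, level2, value_col)
    sd_a, sd_b, sd_e = np.sqrt([s2_a, s2_b, s2_e])
    dec = PartitionDecision(
        sd_level1=float(sd_a), sd_level2=float(sd_b), sd_resid=float(sd_e),
        sdr_level1=float(sd_a / sd_e), sdr_level2=float(sd_b / sd_e),
        level1=level1, level2=level2, threshold=threshold)
    sdr_by_factor = {dec.level1: dec.sdr_level1, dec.level2: dec.sdr_level2}
    sex_key = level1 if level1 == "sex" else level2
    age_key = level2 if level1 == "sex" else level1
    dec.partition_by_sex = sdr_by_factor[sex_key] > threshold
    dec.partition_by_age = sdr_by_factor[age_key] > threshold
    return dec


def decide_partition(df: pd.DataFrame, value_col: str = "hcy",
                     threshold: float = SDR_THRESHOLD) -> PartitionDecision:
    """Full decision: betas rank the factors, nested SDRs give verdicts.

    The factor with the larger standardized coefficient magnitude (sex
    vs the largest age-dummy beta) is placed on level 1 of the nested
    model.
    """
    design = build_design(df, value_col)
    betas, pvals = standardized_betas(design)
    beta_sex = abs(betas["sex"])
    beta_age = max(abs(betas[d]) for d in AGE_DUMMIES)
    if beta_sex >= beta_age:
        level1, level2 = "sex", "age_group"
    else:
        level1, level2 = "age_group", "sex"
    work = df.copy()
    work["age_group"] = age_band(df["age"].to_numpy())
    dec = nested_sdr(work, level1, level2, value_col, threshold)
    dec.betas = betas
    dec.p_values = pvals
    return dec
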