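"""Record cleaning: filter cascade, deduplication, stratified subsampling,
and iterative Box-Cox/Tukey outlier removal.

The cascade mirrors a hospital data-mining waterfall: drop under-age
subjects, keep each subject's first visit, exclude records whose
covariates (folate, vitamin B12, liver/renal/thyroid panel) fall outside
their reference limits, then remove analyte outliers per subgroup with
Tukey fences on a Box-Cox-normalized scale, iterated to a fixed point.
Every step logs (n_before, n_excluded, n_after) so the waterfall is
auditable and conserves counts.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BoxCoxFit",
    "FilterRule",
    "CleaningReport",
    "fit_box_cox",
    "box_cox_transform",
    "tukey_fences",
    "iterative_tukey_filter",
    "apply_filter_cascade",
    "equal_weight_subsample",
    "default_filter_rules",
    "load_filter_rules",
    "age_band",
    "AGE_BAND_LABELS",
]

#: Seven decade bands used for stratification: 18–29, 30–39, …, 70–79, 80+.
AGE_BAND_LABELS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
_BAND_EDGES = (18, 30, 40, 50, 60, 70, 80)


def age_band(ages) -> np.ndarray:
    """Map integer ages (>= 18) to band indices 0..6."""
    a = np.asarray(ages)
    if np.any(a < 18):
        raise ValueError("ages below 18 have no band; filter them first")
    return np.clip(np.searchsorted(_BAND_EDGES, a, side="right") - 1, 0, 6)


# ---------------------------------------------------------------------------
# Box-Cox

@dataclass(frozen=True)
class BoxCoxFit:
    """Maximum-likelihood Box-Cox fit: exponent, log-likelihood, transform."""

    lam: float
    loglik: float
    transformed: np.ndarray


def box_cox_transform(values, lam: float) -> np.ndarray:
    return special.boxcox(np.asarray(values, dtype=float), lam)


def fit_box_cox(values, bounds: tuple[float, float] = (-5.0, 5.0)) -> BoxCoxFit:
    """Profile-likelihood Box-Cox exponent over a bounded interval.

    The profile log-likelihood is -(n/2) ln sigma_hat^2(lambda) +
    (lambda - 1) sum(ln x); its maximizer is found by bounded scalar
    minimization of the negative.
    """
    x = np.asarray(values, dtype=float)
    n_bad = int(np.sum(~(x > 0)))
    if n_bad:
        raise ValueError(f"Box-Cox requires positive values; {n_bad} are <= 0")
    if x.size < 10:
        raise ValueError(f"need at least 10 values, got {x.size}")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-6})
    lam = float(res.x)
    return BoxCoxFit(lam=lam, loglik=float(-res.fun),
                     transformed=box_cox_transform(x, lam))


# ---------------------------------------------------------------------------
# Tukey fences

def tukey_fences(values) -> tuple[float, float]:
    """(Q1 - 1.5 IQR, Q3 + 1.5 IQR) with linear-interpolation quartiles."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 values for fences, got {x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def iterative_tukey_filter(
    df: pd.DataFrame,
    group_keys: Sequence[str],
    value_col: str = "hcy",
    min_group: int = 10,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Per-group loop: Box-Cox fit -> fences on the transformed scale ->
    drop flagged; repeat until a pass removes nothing.

    The Box-Cox exponent is refitted at every iteration so the normality
    premise tracks the shrinking group.  Returns the retained records and
    a report fragment with per-group iteration counts and final lambdas.
    """
    if df.empty:
        raise ValueError("no records to filter")
    groups_info: dict[str, dict] = {}
    kept_parts = []
    for key, sub in df.groupby(list(group_keys), sort=True):
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        cur = sub
        n_removed_total = 0
        lam = math.nan
        for it in range(1, max_iter + 1):
            if len(cur) < min_group:
                raise ValueError(
                    f"group {label} shrank below {min_group} records")
            fit = fit_box_cox(cur[value_col].to_numpy())
            lam = fit.lam
            lo, hi = tukey_fences(fit.transformed)
            keep = (fit.transformed >= lo) & (fit.transformed <= hi)
            n_drop = int((~keep).sum())
            if n_drop == 0:
                break
            n_removed_total += n_drop
            cur = cur.loc[keep]
        groups_info[label] = {
            "iterations": it,
            "n_removed": n_removed_total,
            "lambda": lam,
            "n_final": len(cur),
        }
        kept_parts.append(cur)
    kept = pd.concat(kept_parts).sort_index()
    return kept, {"groups": groups_info,
                  "n_before": len(df), "n_after": len(kept)}


# ---------------------------------------------------------------------------
# Filter cascade

@dataclass(frozen=True)
class FilterRule:
    """Inclusive reference-range rule on one covariate.

    ``sex`` restricts the rule to one sex (0/1); ``None`` applies to all.
    Records failing the rule (value below ``lower`` or above ``upper``)
    are excluded.  Rules sharing a ``step`` label are reported as one
    waterfall row.
    """

    step: str
    covariate: str
    lower: float | None = None
    upper: float | None = None
    sex: int | None = None
    units: str = ""

    def __post_init__(self):
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"rule {self.step}: lower must be < upper")


@dataclass
class CleaningReport:
    """Ordered waterfall of (step, n_before, n_excluded, n_after)."""

    steps: list[dict] = field(default_factory=list)
    tukey: dict = field(default_factory=dict)

    def add(self, step: str, n_before: int, n_excluded: int) -> None:
        self.steps.append({
            "step": step, "n_before": n_before,
            "n_excluded": n_excluded, "n_after": n_before - n_excluded})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "n_before", "n_excluded", "n_after"])

    def validate(self) -> None:
        for i, row in enumerate(self.steps):
            if row["n_after"] != row["n_before"] - row["n_excluded"]:
                raise AssertionError(f"waterfall row {i} does not conserve counts")
            if i and row["n_before"] != self.steps[i - 1]["n_after"]:
                raise AssertionError(f"waterfall row {i} is discontinuous")


def default_filter_rules() -> list[FilterRule]:
    """The package's default covariate cascade (ships as a CSV)."""
    path = importlib.resources.files("refmine").joinpath(
        "data/default_filter_rules.csv")
    with importlib.resources.as_file(path) as p:
        return load_filter_rules(p)


def load_filter_rules(path) -> list[FilterRule]:
    df = pd.read_csv(path)
    rules = []
    for _, r in df.iterrows():
        rules.append(FilterRule(
            step=str(r["step"]),
            covariate=str(r["covariate"]),
            lower=None if pd.isna(r["lower"]) else float(r["lower"]),
            upper=None if pd.isna(r["upper"]) else float(r["upper"]),
            sex=None if pd.isna(r["sex"]) else int(r["sex"]),
            units="" if pd.isna(r.get("units", np.nan)) else str(r["units"]),
        ))
    return rules


def apply_filter_cascade(
    df: pd.DataFrame,
    rules: Iterable[FilterRule],
    dedupe: bool = True,
    min_age: int | None = 18,
    missing_policy: str = "drop",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the ordered cascade; returns retained records and the waterfall.

    Order: minimum-age rule, first-visit deduplication (minimum
    ``visit_index`` per ``id``), then covariate rules grouped by step
    label.  ``missing_policy`` governs records with a missing covariate
    ("drop" excludes them at that step, "error" raises).
    """
    if missing_policy not in ("drop", "error"):
        raise ValueError("missing_policy must be 'drop' or 'error'")
    report = CleaningReport()
    cur = df

    if min_age is not None:
        keep = cur["age"] >= min_age
        report.add(f"age >= {min_age}", len(cur), int((~keep).sum()))
        cur = cur.loc[keep]

    if dedupe:
        if "visit_index" in cur.columns:
            first = cur.sort_values("visit_index", kind="stable").groupby("id").head(1)
            keep_idx = first.index
        else:
            keep_idx = cur.groupby("id").head(1).index
        n_excl = len(cur) - len(keep_idx)
        report.add("first visit per subject", len(cur), n_excl)
        cur = cur.loc[cur.index.isin(keep_idx)].sort_index()

    # group rules by step label, preserving order
    step_order: list[str] = []
    by_step: dict[str, list[FilterRule]] = {}
    for rule in rules:
        if rule.covariate not in df.columns and rule.covariate not in ("age", "hcy"):
            raise KeyError(f"rule covariate '{rule.covariate}' not in records")
        if rule.step not in by_step:
            step_order.append(rule.step)
            by_step[rule.step] = []
        by_step[rule.step].append(rule)

    for step in step_order:
        keep = pd.Series(True, index=cur.index)
        for rule in by_step[step]:
            vals = cur[rule.covariate]
            missing = vals.isna()
            if missing.any() and missing_policy == "error":
                raise ValueError(
                    f"{int(missing.sum())} records missing '{rule.covariate}'")
            applies = pd.Series(True, index=cur.index)
            if rule.sex is not None:
                applies &= cur["sex"] == rule.sex
            ok = pd.Series(True, index=cur.index)
            if rule.lower is not None:
                ok &= vals >= rule.lower
            if rule.upper is not None:
                ok &= vals <= rule.upper
            ok &= ~missing
            keep &= ~applies | ok
        report.add(step, len(cur), int((~keep).sum()))
        cur = cur.loc[keep]

    report.validate()
    return cur, report


def equal_weight_subsample(
    df: pd.DataFrame,
    per_stratum_n: int | None = None,
    seed: int = 0,
    policy: str = "error",
) -> pd.DataFrame:
    """Equal-weighted random subsample over sex × age-band strata.

    ``per_stratum_n`` defaults to the smallest stratum size (the most
    balanced achievable design).  ``policy='take_all_smaller'`` lets
    under-sized strata contribute all their records instead of raising.
    """
    bands = age_band(df["age"].to_numpy())
    strata = df.groupby([df["sex"].to_numpy(), bands], sort=True)
    sizes = strata.size()
    expected = [(s, b) for s in (0, 1) for b in range(7)]
    missing = [f"sex={s}/band={AGE_BAND_LABELS[b]}"
               for (s, b) in expected if (s, b) not in sizes.index]
    if missing:
        raise ValueError("empty strata: " + ", ".join(missing))
    if per_stratum_n is None:
        per_stratum_n = int(sizes.min())
    rng = np.random.default_rng(seed)
    parts = []
    for key, sub in strata:
        if len(sub) < per_stratum_n:
            if policy == "take_all_smaller":
                parts.append(sub)
                continue
            raise ValueError(
                f"stratum {key} has {len(sub)} < {per_stratum_n} records")
        pick = rng.choice(len(sub), size=per_stratum_n, replace=False)
        parts.append(sub.iloc[np.sort(pick)])
    return pd.concat(parts).sort_index()
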