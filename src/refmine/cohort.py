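"""Synthetic mixed-cohort generator with known ground truth.

Routine laboratory databases mix a majority of non-pathological
("healthy") results with a pathological fraction.  For homocysteine the
pathological direction is upward (hyperhomocysteinemia), so the
contaminant component is right-shifted.  The healthy component is
Gaussian on a Box-Cox scale with sex-specific, smoothly age-dependent
location and scale; every generated record carries its true component
label so downstream estimators can be scored against exact quantiles.

Units: analyte values are in μmol/L; ages in integer years.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_mixture_sample",
    "generate_two_level_sample",
    "true_quantile",
    "write_cohort_csv",
    "write_truth_json",
    "COHORT_COLUMNS",
    "COVARIATE_NAMES",
    "DEFAULT_COVARIATE_SPECS",
]

#: CSV schema for cohorts (``component`` is the ground-truth label:
#: 1 = healthy, 0 = pathological).
COVARIATE_NAMES = (
    "folate", "vitb12", "alt", "ast", "cr", "urea", "tsh", "ft3", "ft4",
)
COHORT_COLUMNS = ("id", "sex", "age", "hcy") + COVARIATE_NAMES + ("component",)

_BOTH_SEXES = -1


@dataclass(frozen=True)
class CovariateSpec:
    """Sampling rule for one covariate.

    ``bounds`` maps sex (0 female, 1 male, -1 both) to an inclusive
    (lower, upper) reference range; either side may be ``None``.
    ``out_of_range_prob`` is the probability that a record's value is
    drawn outside the range (giving the filter cascade work to do).
    """

    name: str
    bounds: Mapping[int, tuple[float | None, float | None]]
    out_of_range_prob: float = 0.03
    units: str = ""

    def range_for(self, sex: int) -> tuple[float | None, float | None]:
        if sex in self.bounds:
            return self.bounds[sex]
        return self.bounds[_BOTH_SEXES]


# Reference limits mirror the package's default filter cascade; the
# out-of-range probabilities approximate exclusion fractions seen in a
# large physical-examination population.
DEFAULT_COVARIATE_SPECS: tuple[CovariateSpec, ...] = (
    CovariateSpec("folate", {_BOTH_SEXES: (4.0, None)}, 0.02, "ng/mL"),
    CovariateSpec("vitb12", {_BOTH_SEXES: (180.0, 914.0)}, 0.075, "pg/mL"),
    CovariateSpec("alt", {0: (7.0, 40.0), 1: (9.0, 50.0)}, 0.07, "U/L"),
    CovariateSpec("ast", {0: (13.0, 35.0), 1: (15.0, 40.0)}, 0.065, "U/L"),
    CovariateSpec("cr", {0: (45.0, 84.0), 1: (59.0, 104.0)}, 0.03, "μmol/L"),
    CovariateSpec("urea", {_BOTH_SEXES: (2.78, 7.14)}, 0.06, "mmol/L"),
    CovariateSpec("tsh", {_BOTH_SEXES: (0.380, 4.340)}, 0.09, "μIU/L"),
    CovariateSpec("ft3", {_BOTH_SEXES: (1.80, 4.10)}, 0.015, "pg/mL"),
    CovariateSpec("ft4", {_BOTH_SEXES: (0.81, 1.89)}, 0.002, "ng/dL"),
)

# Location/scale polynomials on the transformed (here: log) scale, in
# u = (age - 40) / 30.  Female median dips to a minimum at age 40 then
# rises; male median rises monotonically and sits above the female
# median at every age in [18, 95].
DEFAULT_MU_COEFFS: dict[int, tuple[float, ...]] = {
    0: (math.log(10.6), 0.012, 0.06),
    1: (math.log(10.6) + 0.165, 0.05),
}
DEFAULT_SIGMA_COEFFS: dict[int, tuple[float, ...]] = {
    0: (0.16,),
    1: (0.15,),
}


def _polyval(coeffs: Sequence[float], age, ) -> np.ndarray:
    u = (np.asarray(age, dtype=float) - 40.0) / 30.0
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a mixed healthy/pathological cohort."""

    n_total: int = 10_000
    healthy_fraction: float = 0.88
    lambda_h: float = 0.0
    mu_coeffs: Mapping[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MU_COEFFS))
    sigma_coeffs: Mapping[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_COEFFS))
    contaminant_shift: float = 0.5
    contaminant_sd: float = 0.35
    age_range: tuple[int, int] = (18, 95)
    sex_ratio: float = 0.5  # proportion male
    age_center: float = 47.0
    age_spread: float = 15.0
    #: multiplier on each covariate's out-of-range probability for
    #: pathological records: elevated homocysteine co-occurs with folate
    #: and B12 deficiency and impaired renal function, so the filter
    #: cascade preferentially removes the pathological component
    contaminant_covariate_boost: float = 4.0
    covariate_specs: tuple[CovariateSpec, ...] = DEFAULT_COVARIATE_SPECS
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0.0 < self.healthy_fraction <= 1.0):
            raise ValueError("healthy_fraction must lie in (0, 1]")
        if self.contaminant_shift <= 0:
            raise ValueError(
                "contaminant_shift must be > 0: pathology elevates the analyte")
        if self.contaminant_sd <= 0:
            raise ValueError("contaminant_sd must be > 0")
        if self.contaminant_covariate_boost < 1:
            raise ValueError("contaminant_covariate_boost must be >= 1")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ValueError("age_range must satisfy lo < hi")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must lie in [0, 1]")
        ages = np.arange(lo, hi + 1)
        for sex in (0, 1):
            sig = self.mu_sigma(sex, ages)[1]
            if np.any(sig <= 0):
                raise ValueError(f"sigma curve non-positive for sex={sex}")

    def mu_sigma(self, sex: int, age) -> tuple[np.ndarray, np.ndarray]:
        """Healthy-component location and scale on the transformed scale."""
        return (_polyval(self.mu_coeffs[sex], age),
                _polyval(self.sigma_coeffs[sex], age))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_specs"] = [
            {"name": s.name,
             "bounds": {str(k): list(v) for k, v in s.bounds.items()},
             "out_of_range_prob": s.out_of_range_prob,
             "units": s.units}
            for s in self.covariate_specs
        ]
        d["mu_coeffs"] = {str(k): list(v) for k, v in self.mu_coeffs.items()}
        d["sigma_coeffs"] = {str(k): list(v) for k, v in self.sigma_coeffs.items()}
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Realized config plus per-record component labels (1 = healthy)."""

    config: CohortConfig
    labels: np.ndarray

    def healthy_mask(self) -> np.ndarray:
        return self.labels.astype(bool)


def _inv_boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    return special.inv_boxcox(np.asarray(y, dtype=float), lam)


def _sample_ages(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = cfg.age_range
    a = (lo - cfg.age_center) / cfg.age_spread
    b = (hi - cfg.age_center) / cfg.age_spread
    raw = stats.truncnorm.rvs(a, b, loc=cfg.age_center, scale=cfg.age_spread,
                              size=n, random_state=rng)
    return np.clip(np.rint(raw).astype(int), lo, hi)


def _sample_covariate(spec: CovariateSpec, sexes: np.ndarray,
                      rng: np.random.Generator,
                      out_prob: np.ndarray) -> np.ndarray:
    n = sexes.size
    out = np.empty(n)
    is_out = rng.random(n) < out_prob
    for sex in (0, 1):
        m = sexes == sex
        if not m.any():
            continue
        lo, hi = spec.range_for(sex)
        lo_eff = lo if lo is not None else (hi / 5.0)
        hi_eff = hi if hi is not None else (lo * 5.0)
        k = int(m.sum())
        vals = lo_eff + (hi_eff - lo_eff) * rng.beta(2.5, 2.5, size=k)
        oor = is_out[m]
        if oor.any():
            j = int(oor.sum())
            side_low = rng.random(j) < 0.5
            if lo is None:
                side_low[:] = True  # only the high side exists... invert below
            if hi is None:
                side_low[:] = True
            low_vals = (lo if lo is not None else lo_eff) * rng.uniform(0.3, 0.95, j)
            high_vals = (hi if hi is not None else hi_eff) * rng.uniform(1.02, 1.6, j)
            bad = np.where(side_low & (lo is not None), low_vals, high_vals)
            vals[oor] = bad
        out[m] = vals
    return np.round(out, 3)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a mixed cohort; returns (records, ground truth).

    Deterministic for a fixed ``config.seed``.  Analyte values are
    strictly positive; back-transforms that would be non-positive (only
    possible for ``lambda_h`` != 0) are resampled a bounded number of
    times before the configuration is rejected.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total

    sexes = (rng.random(n) < config.sex_ratio).astype(int)
    ages = _sample_ages(config, rng, n)
    labels = (rng.random(n) < config.healthy_fraction).astype(int)

    mu = np.empty(n)
    sig = np.empty(n)
    for sex in (0, 1):
        m = sexes == sex
        mu[m], sig[m] = config.mu_sigma(sex, ages[m])
    shift = np.where(labels == 1, 0.0, config.contaminant_shift)
    scale = np.where(labels == 1, sig, config.contaminant_sd)

    t = mu + shift + scale * rng.standard_normal(n)
    hcy = _inv_boxcox(t, config.lambda_h)
    bad = ~np.isfinite(hcy) | (hcy <= 0)
    for _ in range(50):
        if not bad.any():
            break
        k = int(bad.sum())
        t_new = (mu[bad] + shift[bad]
                 + scale[bad] * rng.standard_normal(k))
        hcy[bad] = _inv_boxcox(t_new, config.lambda_h)
        bad = ~np.isfinite(hcy) | (hcy <= 0)
    if bad.any():
        raise ValueError(
            f"configuration yields non-positive analyte values for "
            f"{int(bad.sum())} records after bounded resampling")

    data = {
        "id": [f"S{i:07d}" for i in range(n)],
        "sex": sexes,
        "age": ages,
        "hcy": np.round(hcy, 2),
    }
    boost = config.contaminant_covariate_boost
    for spec in config.covariate_specs:
        p = np.where(labels == 1, spec.out_of_range_prob,
                     np.minimum(spec.out_of_range_prob * boost, 0.9))
        data[spec.name] = _sample_covariate(spec, sexes, rng, p)
    data["component"] = labels
    df = pd.DataFrame(data)
    df["visit_index"] = 1
    return df, GroundTruth(config=config, labels=labels)


def generate_mixture_sample(mu_h: float, sigma_h: float, mu_p: float,
                            sigma_p: float, w_h: float, n: int,
                            seed: int) -> np.ndarray:
    """Two-component Gaussian mixture draw: direct input for estimator tests.

    Component membership is Bernoulli(w_h) per value; the pathological
    component has parameters (mu_p, sigma_p).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma_h <= 0 or sigma_p <= 0:
        raise ValueError("sigmas must be > 0")
    if not (0.0 < w_h <= 1.0):
        raise ValueError("w_h must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    healthy = rng.random(n) < w_h
    z = rng.standard_normal(n)
    return np.where(healthy, mu_h + sigma_h * z, mu_p + sigma_p * z)


def generate_two_level_sample(sdr_level1: float, sdr_level2: float,
                              n_per_cell: int, sigma_resid: float = 1.0,
                              n_level2: int = 7, seed: int = 0,
                              grand_mean: float = 12.0) -> pd.DataFrame:
    """Two-level nested design with exactly realized group effects.

    Level 1 is a two-level factor ("sex"); level 2 has ``n_level2``
    groups ("age bands") nested within each level-1 group.  Effects are
    fixed so that the among-group standard deviations (with the usual
    df = a-1 denominator) equal ``sdr_level1 * sigma_resid`` and
    ``sdr_level2 * sigma_resid`` exactly; only residual noise is random.
    """
    rng = np.random.default_rng(seed)
    delta1 = sdr_level1 * sigma_resid * math.sqrt(2.0)  # two groups at ±delta/2
    # Level-2 effects: a fixed centered pattern scaled to the target SD.
    base = np.arange(n_level2) - (n_level2 - 1) / 2.0
    sd_base = base.std(ddof=1)
    eff2 = sdr_level2 * sigma_resid * base / sd_base if sd_base > 0 else base * 0.0
    rows = []
    for sex, off1 in ((0, -delta1 / 2), (1, +delta1 / 2)):
        for g in range(n_level2):
            noise = sigma_resid * rng.standard_normal(n_per_cell)
            noise -= noise.mean()  # cell means realize the effects exactly
            y = grand_mean + off1 + eff2[g] + noise
            rows.append(pd.DataFrame({
                "sex": sex, "age_group": g, "hcy": y}))
    return pd.concat(rows, ignore_index=True)


def true_quantile(truth: GroundTruth, sex: int, age: int, p: float) -> float:
    """Exact quantile of the healthy component at (sex, age)."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    lo, hi = truth.config.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    mu, sig = truth.config.mu_sigma(sex, age)
    z = stats.norm.ppf(p)
    return float(_inv_boxcox(np.asarray(mu + z * sig), truth.config.lambda_h))


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {"config": truth.config.to_dict(),
               "labels": truth.labels.astype(int).tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)
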