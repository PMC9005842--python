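"""Pipeline orchestration, cohort I/O and report assembly.

The full run follows a two-track design:

* track 1 — cleaned records are equal-weight subsampled over sex × age
  strata and de-outliered per subgroup; the partition decision is made;
  the five indirect estimators run on the pooled sample and (when the
  verdict says split by sex) per sex, with a consistency table against
  the bootstrap CI of the refineR-type estimator.
* track 2 — the cleaned records are de-outliered per sex, split 70/30,
  and the sex-specific age-continuous percentile model is fitted,
  selected by SBC and validated by the FOR statistic.

One master seed expands into per-stage seeds through a stable hash so
stages can be rerun in isolation; reports are written with deterministic
file names and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aging, cleaning, cohort, indirect, partition

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "RunReport",
    "derive_seed",
    "read_cohort_csv",
    "run_pipeline",
    "write_report",
]

ESTIMATORS = ("hoffmann", "bhattacharya", "em", "kosmic", "refiner")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, report: "RunReport", cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.report = report
        self.__cause__ = cause


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: low 31 bits of sha256(master||stage)."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    input_path: str | None = None        # None -> simulate
    rules_path: str | None = None        # None -> packaged defaults
    n_simulate: int = 20_000
    per_stratum_n: int | None = None
    subsample_policy: str = "take_all_smaller"
    estimators: tuple = ESTIMATORS
    n_boot: int = 200
    candidate_dfs: tuple = (2, 3, 4, 5, 6)
    train_fraction: float = 0.7
    seed: int = 0
    out_dir: str = "refmine_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("estimators", "candidate_dfs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.input_path, self.rules_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        bad = set(self.estimators) - set(ESTIMATORS)
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["estimators"] = list(self.estimators)
        d["candidate_dfs"] = list(self.candidate_dfs)
        return d


@dataclass
class RunReport:
    config: dict = field(default_factory=dict)
    version: str = ""
    cleaning: pd.DataFrame | None = None
    tukey: dict = field(default_factory=dict)
    partition: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)   # group -> {method: RIEstimate}
    consistency: dict = field(default_factory=dict)  # group -> DataFrame
    skipped: list = field(default_factory=list)
    percentiles: dict = field(default_factory=dict)  # sex -> DataFrame
    age_models: dict = field(default_factory=dict)   # sex -> AgeModel dict
    for_reports: dict = field(default_factory=dict)  # sex -> FORReport
    log: list = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(msg)


_REQUIRED_COLUMNS = ("id", "sex", "age", "hcy")


def read_cohort_csv(path, schema=cohort.COHORT_COLUMNS,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Typed cohort read; malformed rows go to a rejects frame with reasons.

    Mandatory columns: id, sex (0/1), age, hcy (> 0).  Extra columns are
    kept; a missing mandatory column raises.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    reasons = pd.Series("", index=df.index)

    sex_num = pd.to_numeric(df["sex"], errors="coerce")
    bad_sex = ~sex_num.isin([0, 1])
    reasons[bad_sex] += "sex not in {0,1};"
    age_num = pd.to_numeric(df["age"], errors="coerce")
    bad_age = age_num.isna() | (age_num < 0)
    reasons[bad_age] += "invalid age;"
    hcy_num = pd.to_numeric(df["hcy"], errors="coerce")
    bad_hcy = hcy_num.isna() | (hcy_num <= 0)
    reasons[bad_hcy] += "analyte not positive;"

    bad = reasons != ""
    rejects = df.loc[bad].copy()
    rejects["reason"] = reasons[bad]
    good = df.loc[~bad].copy()
    good["sex"] = sex_num[~bad].astype(int)
    good["age"] = age_num[~bad].astype(int)
    good["hcy"] = hcy_num[~bad]
    if "visit_index" not in good.columns:
        good["visit_index"] = 1
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def _run_estimators(values: np.ndarray, config: PipelineConfig,
                    group: str, report: RunReport) -> None:
    ests = {}
    for method in ESTIMATORS:
        if method not in config.estimators:
            report.skipped.append(f"{group}/{method}")
            continue
        seed = derive_seed(config.seed, f"{group}/{method}")
        report.note(f"estimator {group}/{method}")
        if method == "hoffmann":
            est = indirect.hoffmann_estimate(values)
        elif method == "bhattacharya":
            est = indirect.bhattacharya_estimate(values)
        elif method == "em":
            est, _ = indirect.em_mixture_estimate(values, seed=seed)
        elif method == "kosmic":
            est, _ = indirect.kosmic_estimate(values)
        else:
            est = indirect.refiner_estimate(values, n_boot=config.n_boot,
                                            seed=seed)
        ests[method] = est
        report.log[-1] = (f"{group}/{method}: P95={est.upper_limit:.2f} "
                          f"(n={values.size}, seed={seed})")
    report.estimates[group] = ests
    if "refiner" in ests and len(ests) > 1:
        others = [e for m, e in ests.items() if m != "refiner"]
        report.consistency[group] = indirect.consistency_check(
            others, ests["refiner"])


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute clean -> (partition + estimators) and (split -> age model).

    A failing stage aborts the run with a :class:`PipelineError` naming
    the stage and carrying the partial report assembled so far.
    """
    config.validate()
    report = RunReport(config=config.to_dict())
    from . import __version__
    report.version = __version__
    stage = "input"
    try:
        return _run_pipeline_stages(config, report)
    except PipelineError:
        raise
    except Exception as exc:
        last = report.log[-1] if report.log else stage
        raise PipelineError(last.split(":")[0].removeprefix("estimator "),
                            report, exc) from exc


def _run_pipeline_stages(config: PipelineConfig,
                         report: RunReport) -> RunReport:
    # --- input
    if config.input_path is None:
        cfg = cohort.CohortConfig(n_total=config.n_simulate,
                                  seed=derive_seed(config.seed, "simulate"))
        records, _ = cohort.generate_cohort(cfg)
        report.note(f"simulated cohort n={len(records)}")
    else:
        records, rejects = read_cohort_csv(config.input_path)
        report.note(f"read {len(records)} records, {len(rejects)} rejects")

    # --- cleaning cascade
    rules = (cleaning.default_filter_rules() if config.rules_path is None
             else cleaning.load_filter_rules(config.rules_path))
    cleaned, clean_report = cleaning.apply_filter_cascade(records, rules)
    report.cleaning = clean_report.to_frame()
    report.note(f"cascade: {len(records)} -> {len(cleaned)}")

    # --- track 1: subsample, per-subgroup Tukey, partition, estimators
    sub = cleaning.equal_weight_subsample(
        cleaned, per_stratum_n=config.per_stratum_n,
        seed=derive_seed(config.seed, "subsample"),
        policy=config.subsample_policy)
    sub = sub.copy()
    sub["age_group"] = cleaning.age_band(sub["age"].to_numpy())
    ds1, tukey1 = cleaning.iterative_tukey_filter(sub, ["sex", "age_group"])
    report.tukey["dataset1"] = tukey1
    report.note(f"data set 1: n={len(ds1)}")

    decision = partition.decide_partition(ds1)
    report.partition = decision.to_dict()
    report.note(f"SDR sex={decision.sdr_sex:.3f} age={decision.sdr_age:.3f} "
                f"(threshold {decision.threshold})")

    _run_estimators(ds1["hcy"].to_numpy(), config, "total", report)
    if decision.partition_by_sex:
        for sex, label in ((0, "female"), (1, "male")):
            vals = ds1.loc[ds1["sex"] == sex, "hcy"].to_numpy()
            _run_estimators(vals, config, label, report)

    # --- track 2: sex-grouped Tukey, split, age model, FOR
    ds2, tukey2 = cleaning.iterative_tukey_filter(cleaned, ["sex"])
    report.tukey["dataset2"] = tukey2
    train, valid = aging.split_train_validation(
        ds2, train_fraction=config.train_fraction,
        seed=derive_seed(config.seed, "split"))
    report.note(f"data set 2: n={len(ds2)} -> train {len(train)} / "
                f"validation {len(valid)}")
    for sex, label in ((0, "female"), (1, "male")):
        models = aging.fit_age_model(train, sex,
                                     candidate_dfs=config.candidate_dfs)
        best = aging.select_model(models)
        report.age_models[label] = {**best.to_dict(), "sbc": aging.sbc(best)}
        report.percentiles[label] = aging.percentile_table(best)
        fr = aging.compute_for(best, valid)
        report.for_reports[label] = fr
        report.note(f"{label} age model: df_m={best.df_m} "
                    f"SBC={aging.sbc(best):.2f} mean FOR={fr.mean_for:.2f}%")
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: RunReport, out_dir) -> dict:
    """Write all artifacts with deterministic names; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w_json(name: str, payload) -> None:
        p = out / name
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        written.append(p)

    def _w_csv(name: str, frame: pd.DataFrame) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)

    if report.cleaning is not None:
        _w_csv("cleaning_waterfall.csv", report.cleaning)
    if report.partition:
        _w_json("partition.json", report.partition)
    if report.estimates:
        rows = []
        for group, ests in report.estimates.items():
            for method, est in ests.items():
                row = {"group": group, "method": method,
                       "lower_limit": est.lower_limit,
                       "upper_limit": est.upper_limit}
                for p, v in sorted(est.quantiles.items()):
                    row[f"P{p * 100:g}"] = v
                rows.append(row)
        _w_csv("ri_table.csv", pd.DataFrame(rows))
        _w_json("ri_diagnostics.json", {
            g: {m: {"lam": e.lam, "mu": e.mu, "sigma": e.sigma,
                    "weight": e.weight, "ci": e.ci,
                    "diagnostics": e.diagnostics}
                for m, e in ests.items()}
            for g, ests in report.estimates.items()})
    if report.consistency:
        frames = []
        for group, tab in report.consistency.items():
            t = tab.copy()
            t.insert(0, "group", group)
            t.insert(1, "method", t.index)
            frames.append(t)
        _w_csv("consistency.csv", pd.concat(frames, ignore_index=True))
    if report.percentiles:
        frames = []
        for label, tab in report.percentiles.items():
            t = tab.copy()
            t.insert(0, "sex", label)
            frames.append(t)
        _w_csv("percentiles.csv", pd.concat(frames, ignore_index=True))
    if report.age_models:
        _w_json("age_models.json", report.age_models)
    if report.for_reports:
        frames = []
        for label, fr in report.for_reports.items():
            t = fr.bins.copy()
            t.insert(0, "sex", label)
            frames.append(t)
        _w_csv("for_report.csv", pd.concat(frames, ignore_index=True))
        _w_json("for_summary.json", {
            label: {"mean_for_pct": fr.mean_for,
                    "passes_below_10": fr.passes_below_10,
                    "around_5": fr.around_5}
            for label, fr in report.for_reports.items()})
    _w_json("run.json", {"config": report.config, "version": report.version,
                         "tukey": report.tukey, "skipped": report.skipped,
                         "log": report.log})
    manifest = {"artifacts": {p.name: _sha256(p) for p in sorted(written)},
                "skipped": report.skipped}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
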