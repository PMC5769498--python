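"""End-to-end orchestration: accuracy suite across dependence models and cut
points, prediction/reclassification comparison, and the exhaustive cut-point
scan.  Reports are plain dicts (JSON-serializable) plus pandas tables; every
report embeds the resolved configuration and seed so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from emtdx import cohort as cohort_mod
from emtdx import latent, reclassification as reclass, survival
from emtdx.cohort import CohortTable, MarkerDirection, pattern_counts
from emtdx.latent import DEPENDENCE_MODELS, build_priors, suite_table

logger = logging.getLogger("emtdx.pipeline")

__all__ = [
    "RunConfig",
    "run_accuracy_pipeline",
    "run_prediction_pipeline",
    "cutpoint_scan",
    "save_report",
]


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    cohort_path: str | None = None
    cores_path: str | None = None
    preset: str | None = None          # "cancors-like" to simulate inputs
    marker_direction: str = "epithelial"
    cut_points: tuple[float, ...] = (0.52, 0.60, 0.85)
    include_continuous: bool = True
    dependence_models: tuple[str, ...] = tuple(DEPENDENCE_MODELS)
    priors: dict = field(default_factory=dict)
    burn_in: int = 5000
    iterations: int = 50_000
    quadrature_order: int = 30
    risk_cuts: tuple[float, ...] = (0.20, 0.30, 0.40)
    horizon: float = 5.0
    bootstrap_B: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.cut_points = tuple(float(c) for c in self.cut_points)
        if not self.cut_points and not self.include_continuous:
            raise ValueError("at least one marker form must be requested")
        unknown = [m for m in self.dependence_models if m not in DEPENDENCE_MODELS]
        if unknown:
            raise ValueError(f"unknown dependence models: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cut_points"] = list(self.cut_points)
        d["dependence_models"] = list(self.dependence_models)
        d["risk_cuts"] = list(self.risk_cuts)
        return d

    def build_priors(self) -> latent.PriorSpec:
        return build_priors(
            test_intervals={
                k: tuple(v) for k, v in self.priors.items()
            }
            or None
        )


def resolve_cohort(config: RunConfig) -> CohortTable:
    """Load the cohort CSV or simulate from the named preset."""
    if config.cohort_path:
        return cohort_mod.read_cohort(
            config.cohort_path,
            cores_path=config.cores_path,
            marker_direction=config.marker_direction,
        )
    if config.preset == "cancors-like":
        from emtdx.synthetic import cancors_like_preset, generate_cohort

        synthetic = generate_cohort(cancors_like_preset(), seed=config.seed)
        return synthetic.cohort
    raise ValueError("config must provide cohort_path or preset='cancors-like'")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.start = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("%s finished in %.2fs", stage, time.perf_counter() - self.start)

    return _Timer()


def run_accuracy_pipeline(
    cohort: CohortTable, config: RunConfig
) -> dict:
    """Fit every dependence model at every cut point.

    Returns a report dict with one row per (cut point, model) carrying the
    marker (and established-test) Se/Sp posterior medians and 95% intervals
    as percentages.
    """
    priors = config.build_priors()
    rows = []
    for cut in config.cut_points:
        with _timed(f"accuracy cut={cut}"):
            counts = pattern_counts(cohort, cut)
            logger.info("cut %.2f: %d subjects", cut, counts.n)
            summaries = latent.dependence_model_suite(
                counts,
                priors=priors,
                burn_in=config.burn_in,
                iterations=config.iterations,
                seed=config.seed,
                order=config.quadrature_order,
                models=config.dependence_models,
            )
        table = suite_table(summaries)
        table.insert(0, "cut_point", cut)
        rows.append(table)
    full = pd.concat(rows, ignore_index=True)
    return {
        "kind": "accuracy",
        "config": config.to_dict(),
        "table": full.to_dict(orient="records"),
    }


def _marker_forms(config: RunConfig) -> list[tuple[str, float | None]]:
    forms: list[tuple[str, float | None]] = []
    if config.include_continuous:
        forms.append(("continuous", None))
    forms.extend((f"cut_{c:g}", c) for c in config.cut_points)
    return forms


def _design(cohort: CohortTable, cut: float | None) -> tuple[np.ndarray, list[str]]:
    tests = cohort.resolved_tests()
    if cut is None:
        marker = cohort.marker_scores()
        name = "marker_score"
    else:
        marker = cohort.marker_tests(cut)
        name = f"marker_pos_{cut:g}"
    X = np.column_stack([tests, marker])
    return X, ["ln", "ri", name]


def _fit_and_risks(
    X: np.ndarray, times: np.ndarray, events: np.ndarray, names, horizon: float
) -> np.ndarray:
    fit = survival.fit_cox(X, times, events, covariate_names=list(names))
    return np.atleast_1d(survival.predicted_risk(fit, X, horizon=horizon))


def run_prediction_pipeline(cohort: CohortTable, config: RunConfig) -> dict:
    """Base vs marker-augmented Cox models with reclassification metrics.

    For every marker form: predicted-risk distribution, c-indices, the
    stratification table, event/non-event NRI, IDI, the reclassification
    calibration statistic, and percentile-bootstrap intervals (both models
    refitted inside each replicate).
    """
    raw_times, raw_events = cohort.times(), cohort.deaths()
    times, events = survival.administrative_censor(
        raw_times, raw_events, config.horizon
    )
    tests = cohort.resolved_tests()
    cats = reclass.RiskCategories(config.risk_cuts)
    statuses = reclass.classify_status(times, events, config.horizon)

    base_X = tests.astype(float)
    base_risks = _fit_and_risks(
        base_X, times, events, ["ln", "ri"], config.horizon
    )
    report: dict = {
        "kind": "prediction",
        "config": config.to_dict(),
        "n": cohort.n,
        "n_events_5y": int(np.sum(statuses == reclass.EVENT)),
        "base_model": {
            "risk_summary": survival.risk_distribution_summary(base_risks),
            "c_index": survival.harrell_c_index(base_risks, times, events),
        },
        "models": {},
    }

    for label, cut in _marker_forms(config):
        with _timed(f"prediction {label}"):
            new_X, names = _design(cohort, cut)
            new_risks = _fit_and_risks(new_X, times, events, names, config.horizon)
            base_cats = cats.assign(base_risks)
            new_cats = cats.assign(new_risks)
            strat = reclass.stratification_table(base_risks, new_risks, statuses, cats)
            calib = reclass.reclassification_calibration(
                new_risks, times, events, cats, horizon=config.horizon
            )

            def metric_bundle(idx: np.ndarray) -> dict:
                b_risks = _fit_and_risks(
                    base_X[idx], times[idx], events[idx], ["ln", "ri"], config.horizon
                )
                n_risks = _fit_and_risks(
                    new_X[idx], times[idx], events[idx], names, config.horizon
                )
                st = reclass.classify_status(times[idx], events[idx], config.horizon)
                bc, nc = cats.assign(b_risks), cats.assign(n_risks)
                return {
                    "c_index_base": survival.harrell_c_index(
                        b_risks, times[idx], events[idx]
                    ),
                    "c_index_new": survival.harrell_c_index(
                        n_risks, times[idx], events[idx]
                    ),
                    "event_nri": reclass.event_nri(bc, nc, st),
                    "nonevent_nri": reclass.nonevent_nri(bc, nc, st),
                    "idi": reclass.idi(b_risks, n_risks, st),
                }

            boot = _bootstrap_bundle(
                metric_bundle, cohort.n, config.bootstrap_B, config.seed
            )
            entry = {
                "marker_form": label,
                "cut_point": cut,
                "risk_summary": survival.risk_distribution_summary(new_risks),
                "c_index": survival.harrell_c_index(new_risks, times, events),
                "stratification": {
                    "labels": strat.labels,
                    "overall": strat.overall.tolist(),
                    "events": strat.events.tolist(),
                    "nonevents": strat.nonevents.tolist(),
                    "moved_up": strat.moved_up,
                    "moved_down": strat.moved_down,
                    "total_reclassified": strat.total_reclassified,
                    **strat.percentages(),
                },
                "event_nri": reclass.event_nri(base_cats, new_cats, statuses),
                "nonevent_nri": reclass.nonevent_nri(base_cats, new_cats, statuses),
                "idi": reclass.idi(base_risks, new_risks, statuses),
                "calibration": calib,
                "bootstrap": boot,
            }
            report["models"][label] = entry
    return report


def _bootstrap_bundle(metric_bundle, n: int, B: int, seed: int) -> dict:
    """One resampling loop computing all metrics per replicate."""
    rng = np.random.default_rng(seed)
    names = None
    draws: dict[str, list[float]] = {}
    undefined = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values = metric_bundle(idx)
        except (ValueError, survival.CoxError):
            undefined += 1
            continue
        if names is None:
            names = list(values)
            draws = {k: [] for k in names}
        for k, v in values.items():
            draws[k].append(v)
    if undefined > 0.10 * B:
        raise reclass.BootstrapError(
            f"metrics undefined in {undefined}/{B} bootstrap replicates"
        )
    out = {"B": B, "seed": seed, "n_undefined": undefined}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        lo, hi = np.percentile(arr, [2.5, 97.5])
        out[k] = {
            "lo95": float(lo),
            "hi95": float(hi),
            "p_value": float(
                min(1.0, 2.0 * min(np.mean(arr <= 0), np.mean(arr >= 0)))
            ),
        }
    return out


def cutpoint_scan(
    cohort: CohortTable,
    config: RunConfig,
    grid: Sequence[float] | None = None,
    dependence_model: str = "fully_independent",
    include_accuracy: bool = True,
) -> dict:
    """Per-cut-point accuracy and prediction-increment metrics.

    ``grid`` defaults to every distinct observed marker value (every
    achievable dichotomization).  Accuracy columns use a single dependence
    model; prediction metrics are computed without bootstrap intervals.
    """
    if grid is None:
        grid = sorted(set(np.round(cohort.marker_scores(), 10)))
        grid = [g for g in grid if 0 < g <= 3]
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("cut-point grid is empty")
    if any(not (0 < g <= 3) for g in grid):
        raise ValueError("cut points must lie in (0, 3]")

    times, events = survival.administrative_censor(
        cohort.times(), cohort.deaths(), config.horizon
    )
    cats = reclass.RiskCategories(config.risk_cuts)
    statuses = reclass.classify_status(times, events, config.horizon)
    tests = cohort.resolved_tests().astype(float)
    base_risks = _fit_and_risks(tests, times, events, ["ln", "ri"], config.horizon)
    base_cats = cats.assign(base_risks)
    priors = config.build_priors()

    rows = []
    for cut in grid:
        with _timed(f"scan cut={cut:g}"):
            row: dict = {"cut_point": cut}
            marker = cohort.marker_tests(cut)
            row["n_positive"] = int(marker.sum())
            if include_accuracy:
                counts = pattern_counts(cohort, cut)
                summary = latent.fit_latent_class(
                    counts,
                    DEPENDENCE_MODELS[dependence_model],
                    priors=priors,
                    burn_in=config.burn_in,
                    iterations=config.iterations,
                    seed=config.seed,
                    order=config.quadrature_order,
                )
                row["emt_se"] = summary.tests["emt"]["se"]["median"] * 100
                row["emt_sp"] = summary.tests["emt"]["sp"]["median"] * 100
            new_X, names = _design(cohort, cut)
            new_risks = _fit_and_risks(new_X, times, events, names, config.horizon)
            new_cats_arr = cats.assign(new_risks)
            row["c_index"] = survival.harrell_c_index(new_risks, times, events)
            row["event_nri"] = reclass.event_nri(base_cats, new_cats_arr, statuses)
            row["nonevent_nri"] = reclass.nonevent_nri(
                base_cats, new_cats_arr, statuses
            )
            row["idi"] = reclass.idi(base_risks, new_risks, statuses)
            try:
                row["calibration_p"] = reclass.reclassification_calibration(
                    new_risks, times, events, cats, horizon=config.horizon
                )["p_value"]
            except ValueError:
                row["calibration_p"] = float("nan")
            rows.append(row)
    return {
        "kind": "cutpoint_scan",
        "config": config.to_dict(),
        "dependence_model": dependence_model,
        "table": rows,
    }


def save_report(report: dict, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a report as a JSON bundle plus CSV table(s); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    json_path = out_dir / f"{stem}.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["json"] = json_path
    if "table" in report:
        csv_path = out_dir / f"{stem}.csv"
        pd.DataFrame(report["table"]).to_csv(csv_path, index=False)
        paths["csv"] = csv_path
    if report.get("kind") == "prediction":
        rows = []
        for label, entry in report["models"].items():
            rows.append(
                {
                    "marker_form": label,
                    "c_index": entry["c_index"],
                    "event_nri": entry["event_nri"],
                    "nonevent_nri": entry["nonevent_nri"],
                    "idi": entry["idi"],
                    "calibration_p": entry["calibration"]["p_value"],
                    "moved_up": entry["stratification"]["moved_up"],
                    "moved_down": entry["stratification"]["moved_down"],
                }
            )
        csv_path = out_dir / f"{stem}.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        paths["csv"] = csv_path
    return paths
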