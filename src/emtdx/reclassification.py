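"""Risk categories, stratification tables, NRI/IDI, reclassification
calibration, and bootstrap confidence intervals.

Five-year outcome status: subjects who died at or before the horizon are
events; subjects followed alive to the horizon are non-events; subjects
censored earlier are excluded from the category-based metrics (the simplest
transparent rule; a Kaplan-Meier-weighted variant is used only inside the
calibration statistic, where censoring must be accounted for cell-wise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "RiskCategories",
    "StratificationTable",
    "classify_status",
    "assign_risk_category",
    "stratification_table",
    "event_nri",
    "nonevent_nri",
    "idi",
    "reclassification_calibration",
    "bootstrap_intervals",
    "BootstrapError",
]

EVENT, NONEVENT, CENSORED = 1, 0, -1


@dataclass(frozen=True)
class RiskCategories:
    """Ordered probability cut points defining half-open risk categories.

    The default (0.20, 0.30, 0.40) yields categories [0, 20%), [20%, 30%),
    [30%, 40%) and >= 40%; a probability equal to a cut point falls in the
    upper category.
    """

    cuts: tuple[float, ...] = (0.20, 0.30, 0.40)

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if not cuts or any(not (0 < c < 1) for c in cuts):
            raise ValueError("cut points must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_categories(self) -> int:
        return len(self.cuts) + 1

    @property
    def labels(self) -> list[str]:
        pct = [0.0, *[100 * c for c in self.cuts]]
        out = [
            f"{lo:g}–{hi:g}%" for lo, hi in zip(pct[:-1], pct[1:])
        ]
        out.append(f">{pct[-1]:g}%")
        return out

    def assign(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        idx = np.searchsorted(self.cuts, p, side="right")
        return idx if idx.shape else int(idx)


def assign_risk_category(p: float, cats: RiskCategories) -> int:
    """Category index of one predicted probability (0 = lowest risk)."""
    return int(cats.assign(p))


def classify_status(times, events, horizon: float = 5.0) -> np.ndarray:
    """Per-subject 5-year status: EVENT, NONEVENT, or CENSORED (pre-horizon)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    status = np.full(times.shape, CENSORED, dtype=int)
    status[(events == 1) & (times <= horizon)] = EVENT
    status[(events == 0) & (times >= horizon)] = NONEVENT
    return status


@dataclass
class StratificationTable:
    """Cross-classification of base- vs new-model risk categories."""

    labels: list[str]
    overall: np.ndarray           # (K, K) counts, rows = base category
    events: np.ndarray            # same shape, events only
    nonevents: np.ndarray         # same shape, non-events only
    n: int
    moved_up: int
    moved_down: int

    @property
    def total_reclassified(self) -> int:
        return self.moved_up + self.moved_down

    def percentages(self) -> dict:
        return {
            "moved_up_pct": 100.0 * self.moved_up / self.n if self.n else 0.0,
            "moved_down_pct": 100.0 * self.moved_down / self.n if self.n else 0.0,
            "total_reclassified_pct": (
                100.0 * self.total_reclassified / self.n if self.n else 0.0
            ),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.overall, index=self.labels, columns=self.labels)


def stratification_table(
    base_risks,
    new_risks,
    statuses,
    cats: RiskCategories | None = None,
) -> StratificationTable:
    """Cross-tabulate risk categories under the two models.

    ``statuses`` comes from :func:`classify_status`; subjects censored before
    the horizon appear in the overall table but in neither outcome stratum.
    """
    cats = cats or RiskCategories()
    base_risks = np.asarray(base_risks, dtype=float)
    new_risks = np.asarray(new_risks, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    if not (base_risks.shape == new_risks.shape == statuses.shape):
        raise ValueError("inputs must have equal length")
    b = cats.assign(base_risks)
    m = cats.assign(new_risks)
    K = cats.n_categories
    overall = np.zeros((K, K), dtype=int)
    ev = np.zeros((K, K), dtype=int)
    ne = np.zeros((K, K), dtype=int)
    np.add.at(overall, (b, m), 1)
    np.add.at(ev, (b[statuses == EVENT], m[statuses == EVENT]), 1)
    np.add.at(ne, (b[statuses == NONEVENT], m[statuses == NONEVENT]), 1)
    return StratificationTable(
        labels=cats.labels,
        overall=overall,
        events=ev,
        nonevents=ne,
        n=int(base_risks.size),
        moved_up=int(np.sum(m > b)),
        moved_down=int(np.sum(m < b)),
    )


def _nri(base_cats, new_cats, statuses, which: int) -> float:
    base_cats = np.asarray(base_cats, dtype=int)
    new_cats = np.asarray(new_cats, dtype=int)
    statuses = np.asarray(statuses, dtype=int)
    mask = statuses == which
    n = int(mask.sum())
    if n == 0:
        label = "events" if which == EVENT else "non-events"
        raise ValueError(f"no {label} among subjects with known 5-year status")
    up = int(np.sum(new_cats[mask] > base_cats[mask]))
    down = int(np.sum(new_cats[mask] < base_cats[mask]))
    signed = (up - down) if which == EVENT else (down - up)
    return 100.0 * signed / n


def event_nri(base_cats, new_cats, statuses) -> float:
    """100 * [P(up | event) - P(down | event)]."""
    return _nri(base_cats, new_cats, statuses, EVENT)


def nonevent_nri(base_cats, new_cats, statuses) -> float:
    """100 * [P(down | non-event) - P(up | non-event)]."""
    return _nri(base_cats, new_cats, statuses, NONEVENT)


def idi(base_risks, new_risks, statuses) -> float:
    """Difference in discrimination slopes between models, in percent.

    The discrimination slope of a model is the mean predicted risk among
    events minus the mean among non-events.
    """
    base_risks = np.asarray(base_risks, dtype=float)
    new_risks = np.asarray(new_risks, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    ev = statuses == EVENT
    ne = statuses == NONEVENT
    if not ev.any() or not ne.any():
        raise ValueError("IDI requires at least one event and one non-event")
    slope_new = new_risks[ev].mean() - new_risks[ne].mean()
    slope_base = base_risks[ev].mean() - base_risks[ne].mean()
    return 100.0 * (slope_new - slope_base)


def _km_event_probability(times, events, horizon: float) -> float:
    """1 - S(horizon) by Kaplan-Meier (complement at the horizon)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    return float(1.0 - km.predict(horizon))


def reclassification_calibration(
    risks,
    times,
    events,
    cats: RiskCategories | None = None,
    horizon: float = 5.0,
    cell_labels=None,
    min_cell: int = 5,
) -> dict:
    """Hosmer-Lemeshow-type chi-square over cells of the risk table.

    Cells default to the categories of ``risks`` but may be supplied
    explicitly (e.g. cells of the base-by-new cross-classified table) via
    ``cell_labels``.  Cells smaller than ``min_cell`` are merged into the
    cell with the nearest mean predicted risk.  Observed 5-year deaths use
    the Kaplan-Meier complement at the horizon whenever a cell contains
    subjects censored before it.  The statistic is referred to chi-square
    with (number of included cells - 2) degrees of freedom.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cats = cats or RiskCategories()
    labels = (
        np.asarray(cell_labels) if cell_labels is not None else cats.assign(risks)
    )
    cells: list[dict] = []
    for value in np.unique(labels):
        mask = labels == value
        cells.append(
            {
                "n": int(mask.sum()),
                "mean_risk": float(risks[mask].mean()),
                "times": times[mask],
                "events": events[mask],
            }
        )
    # merge small cells into the nearest by mean predicted risk
    while len(cells) > 1 and min(c["n"] for c in cells) < min_cell:
        k = min(range(len(cells)), key=lambda i: cells[i]["n"])
        small = cells.pop(k)
        j = min(
            range(len(cells)),
            key=lambda i: abs(cells[i]["mean_risk"] - small["mean_risk"]),
        )
        merged_times = np.concatenate([cells[j]["times"], small["times"]])
        merged_events = np.concatenate([cells[j]["events"], small["events"]])
        n_total = cells[j]["n"] + small["n"]
        cells[j] = {
            "n": n_total,
            "mean_risk": (
                cells[j]["mean_risk"] * cells[j]["n"]
                + small["mean_risk"] * small["n"]
            )
            / n_total,
            "times": merged_times,
            "events": merged_events,
        }
    if len(cells) < 3:
        raise ValueError(
            f"calibration needs at least 3 cells after merging, got {len(cells)}"
        )
    statistic = 0.0
    for cell in cells:
        censored_early = np.any((cell["events"] == 0) & (cell["times"] < horizon))
        if censored_early:
            observed_prop = _km_event_probability(
                cell["times"], cell["events"], horizon
            )
        else:
            observed_prop = float(
                np.mean((cell["events"] == 1) & (cell["times"] <= horizon))
            )
        n_k = cell["n"]
        o_k = observed_prop * n_k
        p_k = min(max(cell["mean_risk"], 1e-12), 1 - 1e-12)
        statistic += (o_k - n_k * p_k) ** 2 / (n_k * p_k * (1 - p_k))
    df = len(cells) - 2
    return {
        "statistic": float(statistic),
        "df": int(df),
        "p_value": float(chi2.sf(statistic, df)),
        "n_cells": len(cells),
    }


class BootstrapError(RuntimeError):
    """Raised when too many bootstrap replicates leave the metric undefined."""


def bootstrap_intervals(
    metric_function: Callable[[np.ndarray], float],
    n: int,
    B: int = 1000,
    seed: int = 0,
    max_undefined_frac: float = 0.10,
) -> dict:
    """Percentile bootstrap over subject resamples.

    ``metric_function`` receives an index array into the cohort (the identity
    permutation gives the point estimate) and may return NaN or raise
    ValueError for degenerate resamples; more than ``max_undefined_frac`` of
    such replicates aborts.  The two-sided p-value tests the metric against 0.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    point = float(metric_function(np.arange(n)))
    values = np.empty(B)
    undefined = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = metric_function(idx)
        except (ValueError, ZeroDivisionError):
            values[b] = np.nan
        if not np.isfinite(values[b]):
            undefined += 1
    if undefined > max_undefined_frac * B:
        raise BootstrapError(
            f"metric undefined in {undefined}/{B} bootstrap replicates"
        )
    valid = values[np.isfinite(values)]
    lo, hi = np.percentile(valid, [2.5, 97.5])
    frac_le = np.mean(valid <= 0)
    frac_ge = np.mean(valid >= 0)
    return {
        "point": point,
        "lo95": float(lo),
        "hi95": float(hi),
        "p_value": float(min(1.0, 2.0 * min(frac_le, frac_ge))),
        "B": B,
        "n_undefined": undefined,
        "seed": seed,
    }
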