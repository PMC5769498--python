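"""Cox proportional-hazards fitting with a Breslow baseline, 5-year absolute
risk prediction, censored-outcome concordance, and predicted-risk summaries.

The partial likelihood uses the Breslow approximation for tied event times,
which is consistent with the Breslow step-function estimator used to convert
linear predictors into absolute risks at a horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoxFit",
    "CoxError",
    "administrative_censor",
    "fit_cox",
    "predicted_risk",
    "harrell_c_index",
    "risk_distribution_summary",
]


class CoxError(RuntimeError):
    """Raised on non-convergence or degenerate survival inputs."""


def administrative_censor(
    times: np.ndarray, events: np.ndarray, horizon: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Censor follow-up at the horizon: events after it become censored at it."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    capped = np.minimum(times, horizon)
    kept = events.copy()
    kept[times > horizon] = 0
    return capped, kept


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients plus Breslow cumulative baseline hazard."""

    beta: np.ndarray
    covariate_names: list[str]
    baseline_times: np.ndarray       # distinct event times, ascending
    baseline_cumhaz: np.ndarray      # H0 at those times
    n: int
    n_events: int
    log_likelihood: float
    score_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def cumulative_baseline_hazard(self, t: float) -> float:
        """H0(t): right-continuous step function, 0 before the first event."""
        idx = np.searchsorted(self.baseline_times, t, side="right")
        if idx == 0:
            return 0.0
        return float(self.baseline_cumhaz[idx - 1])


def _partial_loglik_score_info(beta, X, times, events):
    """Breslow-ties log partial likelihood with score vector and information."""
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(bool)
    Xs = X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix sums: risk set for time t_i is everyone from the first index with
    # that time onward
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    firsts = np.searchsorted(t, t, side="left")
    ei = np.flatnonzero(e)
    fi = firsts[ei]
    s0e = s0[fi]
    loglik = float(np.sum(eta[ei] - np.log(s0e)))
    mean = s1[fi] / s0e[:, None]
    score = Xs[ei].sum(axis=0) - mean.sum(axis=0)
    info = (s2[fi] / s0e[:, None, None]).sum(axis=0) - mean.T @ mean
    return loglik, score, info


def fit_cox(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    covariate_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Zero-variance covariates get a coefficient of exactly 0 and a
    ``zero_information`` flag; runaway coefficients (monotone likelihood /
    perfect separation) are flagged as ``possible_separation``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if times.shape != (n,) or events.shape != (n,):
        raise CoxError("times/events length must match the covariate rows")
    if np.any(times <= 0):
        raise CoxError("survival times must be positive")
    names = covariate_names or [f"x{j}" for j in range(p)]

    flags: list[str] = []
    active = np.std(X, axis=0) > 0
    for j in np.flatnonzero(~active):
        flags.append(f"zero_information:{names[j]}")

    beta = np.zeros(p)
    Xa = X[:, active]
    converged = False
    loglik = -np.inf
    score_norm = np.inf
    if Xa.shape[1] > 0 and events.sum() > 0:
        b = np.zeros(Xa.shape[1])
        # center for numerical stability; score/information are shift-invariant
        Xc = Xa - Xa.mean(axis=0)
        loglik, score, info = _partial_loglik_score_info(b, Xc, times, events)
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
                flags.append("singular_information")
            new_b = b + step
            new_ll, new_score, new_info = _partial_loglik_score_info(
                new_b, Xc, times, events
            )
            halvings = 0
            # tolerance guards against float-noise rejections near the optimum
            while new_ll < loglik - 1e-10 and halvings < 30:
                step *= 0.5
                new_b = b + step
                new_ll, new_score, new_info = _partial_loglik_score_info(
                    new_b, Xc, times, events
                )
                halvings += 1
            b, loglik, score, info = new_b, new_ll, new_score, new_info
            score_norm = float(np.max(np.abs(score)))
            if score_norm < max(tol, 1e-9):
                converged = True
                break
        if np.any(np.abs(b) > 20):
            flags.append("possible_separation")
        if not converged and score_norm < 1e-6:
            converged = True
        if not converged and "possible_separation" not in flags:
            raise CoxError(
                f"Newton-Raphson failed to converge (score sup-norm {score_norm:.3g})"
            )
        beta[active] = b
    else:
        # no informative covariates: the null model, score identically zero
        converged = True
        loglik, _, _ = (
            _partial_loglik_score_info(np.zeros(1), np.zeros((n, 1)), times, events)
            if events.sum() > 0
            else (0.0, None, None)
        )
        score_norm = 0.0

    # Breslow baseline on the original (uncentered) covariates
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(bool)
    ws = w[order]
    s0 = np.cumsum(ws[::-1])[::-1]
    uniq = np.unique(t[e])
    increments = []
    for u in uniq:
        d_u = int(np.sum(e & (t == u)))
        s0_u = s0[np.searchsorted(t, u, side="left")]
        increments.append(d_u / s0_u)
    cumhaz = np.cumsum(increments) if increments else np.array([])

    return CoxFit(
        beta=beta,
        covariate_names=names,
        baseline_times=uniq,
        baseline_cumhaz=np.asarray(cumhaz, dtype=float),
        n=n,
        n_events=int(events.sum()),
        log_likelihood=float(loglik),
        score_norm=float(score_norm),
        converged=converged,
        flags=flags,
    )


def predicted_risk(fit: CoxFit, x: np.ndarray, horizon: float = 5.0) -> np.ndarray:
    """Absolute risk by the horizon: 1 - exp(-H0(horizon) exp(x . beta)).

    ``x`` may be a single covariate vector or an (n, p) matrix.  A horizon
    beyond the last event time reuses the final baseline step with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if fit.baseline_times.size and horizon > fit.baseline_times[-1]:
        warnings.warn(
            "horizon beyond last event time; using final baseline hazard step",
            stacklevel=2,
        )
    h0 = fit.cumulative_baseline_hazard(horizon)
    risks = 1.0 - np.exp(-h0 * np.exp(x @ fit.beta))
    return risks if risks.size > 1 else float(risks[0])


def harrell_c_index(risks, times, events) -> float:
    """Concordance for censored outcomes, as a percentage.

    A pair is usable iff its times differ and the subject with the shorter
    time had an event; concordant when the higher predicted risk accompanies
    the shorter survival, with risk ties counting one half.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (risks.shape == times.shape == events.shape):
        raise ValueError("risks, times, events must have equal length")
    # vectorized over all ordered pairs (i shorter, j longer)
    dt = times[:, None] - times[None, :]
    usable = (dt < 0) & (events[:, None] == 1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    dr = risks[:, None] - risks[None, :]
    concordant = float(np.sum(usable & (dr > 0)) + 0.5 * np.sum(usable & (dr == 0)))
    return 100.0 * concordant / n_usable


def _nearest_rank_percentile(sorted_values: np.ndarray, q: float) -> float:
    n = sorted_values.size
    rank = int(np.ceil(q / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(sorted_values[rank - 1])


def risk_distribution_summary(risks) -> dict:
    """Summary of predicted risks on the percentage scale.

    Percentiles use the nearest-rank definition on the empirical
    distribution; SD is the sample standard deviation.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.size == 0:
        raise ValueError("empty risk vector")
    s = np.sort(risks) * 100.0
    return {
        "min": float(s[0]),
        "max": float(s[-1]),
        "p10": _nearest_rank_percentile(s, 10),
        "p25": _nearest_rank_percentile(s, 25),
        "p50": _nearest_rank_percentile(s, 50),
        "p75": _nearest_rank_percentile(s, 75),
        "p90": _nearest_rank_percentile(s, 90),
        "mean": float(np.mean(s)),
        "sd": float(np.std(s, ddof=1)) if s.size > 1 else 0.0,
    }
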