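"""Bayesian 3-test latent-class accuracy model without a gold standard.

The binary latent state D splits subjects into two classes.  Given D = d and
a shared standard-normal random effect Z, test j is positive with probability
Phi(a_dj + c_dj * Z); the loadings c_dj induce conditional dependence between
test errors within a class.  Marginally over Z the accuracy of test j is
Phi(a_dj / sqrt(1 + c_dj^2)) — sensitivity for class 1, one minus specificity
for class 0.

Sampling is parameterized directly on (prevalence, Se_j, Sp_j, free c_dj) so
the stated uniform priors apply to the marginal accuracies; the probit
intercepts are recovered as a_dj = Phi^{-1}(marginal) * sqrt(1 + c_dj^2).
Eight conditional-dependence structures are supported, from fully independent
(all six c zero) to fully dependent (none constrained), with six partial
structures in between.

The 8-cell pattern likelihood is evaluated by deterministic Gauss-Hermite
quadrature, and the posterior is explored with a seeded random-walk
Metropolis-within-Gibbs sampler (one chain, reflective proposals, step sizes
adapted during burn-in only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from emtdx.cohort import PATTERNS, PatternCounts

__all__ = [
    "TESTS",
    "DependenceSpec",
    "DEPENDENCE_MODELS",
    "PriorSpec",
    "build_priors",
    "LatentClassParams",
    "conditional_positive_prob",
    "marginal_accuracy",
    "intercept_from_marginal",
    "pattern_likelihood",
    "pattern_prob_table",
    "log_likelihood",
    "fit_latent_class",
    "dependence_model_suite",
    "suite_table",
    "PosteriorSummary",
]

TESTS: tuple[str, str, str] = ("emt", "ln", "ri")
_PATTERN_ARRAY = np.array(PATTERNS, dtype=bool)  # (8, 3)


# --------------------------------------------------------------------------
# Dependence structures


@dataclass(frozen=True)
class DependenceSpec:
    """Which dependence loadings c_dj are constrained to zero.

    Constraints are (class, test-index) pairs; class 1 corresponds to the
    sensitivity side of a test and class 0 to the specificity side.
    """

    name: str
    zero_constraints: frozenset

    def c_free_mask(self) -> np.ndarray:
        """(2, 3) boolean mask: True where c_dj is a free parameter."""
        mask = np.ones((2, 3), dtype=bool)
        for d, j in self.zero_constraints:
            mask[d, j] = False
        return mask


def _spec(name: str, constrained_tests: Sequence[int]) -> DependenceSpec:
    pairs = {(d, j) for j in constrained_tests for d in (0, 1)}
    return DependenceSpec(name=name, zero_constraints=frozenset(pairs))


#: The eight structures, keyed by name, in canonical reporting order.
DEPENDENCE_MODELS: dict[str, DependenceSpec] = {
    "fully_independent": _spec("fully_independent", [0, 1, 2]),
    "fully_dependent": _spec("fully_dependent", []),
    "PDM1": _spec("PDM1", [0]),        # marker Se/Sp loadings zeroed
    "PDM2": _spec("PDM2", [1]),        # LN
    "PDM3": _spec("PDM3", [2]),        # RI
    "PDM4": _spec("PDM4", [0, 1]),     # marker + LN
    "PDM5": _spec("PDM5", [0, 2]),     # marker + RI
    "PDM6": _spec("PDM6", [1, 2]),     # LN + RI
}


# --------------------------------------------------------------------------
# Priors


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior supports on the marginal-accuracy scale.

    ``se`` / ``sp`` give (lo, hi) per test in the order (emt, ln, ri);
    ``c`` is the common support for every unconstrained loading and
    ``prevalence`` the support for the class-1 probability.
    """

    se: tuple[tuple[float, float], ...]
    sp: tuple[tuple[float, float], ...]
    c: tuple[float, float] = (0.0, 3.0)
    prevalence: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name, intervals in (("se", self.se), ("sp", self.sp)):
            for lo, hi in intervals:
                if not (0 <= lo < hi <= 1):
                    raise ValueError(
                        f"invalid {name} prior interval ({lo}, {hi}): "
                        "need 0 <= lo < hi <= 1"
                    )
        if not (self.c[0] >= 0 and self.c[0] < self.c[1]):
            raise ValueError(f"invalid c prior interval {self.c}")
        lo, hi = self.prevalence
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"invalid prevalence prior interval {self.prevalence}")


def build_priors(
    test_intervals: Mapping[str, tuple[float, float]] | None = None,
    marker_uninformative: bool = True,
    c_interval: tuple[float, float] = (0.0, 3.0),
    prevalence_interval: tuple[float, float] = (0.0, 1.0),
) -> PriorSpec:
    """Assemble the prior specification.

    Defaults follow the informative literature-based priors for the two
    established tests — Se uniform(0.60, 0.70) and Sp uniform(0.95, 0.99)
    for both LN and RI — with a flat uniform(0, 1) prior on the marker's
    Se and Sp.  ``test_intervals`` overrides individual entries with keys
    like ``"ln_se"`` or ``"emt_sp"``.
    """
    defaults = {
        "emt_se": (0.0, 1.0),
        "emt_sp": (0.0, 1.0),
        "ln_se": (0.60, 0.70),
        "ln_sp": (0.95, 0.99),
        "ri_se": (0.60, 0.70),
        "ri_sp": (0.95, 0.99),
    }
    if test_intervals:
        unknown = set(test_intervals) - set(defaults)
        if unknown:
            raise ValueError(f"unknown prior keys: {sorted(unknown)}")
        defaults.update({k: tuple(v) for k, v in test_intervals.items()})
    if not marker_uninformative and not (
        test_intervals and {"emt_se", "emt_sp"} <= set(test_intervals)
    ):
        raise ValueError(
            "marker_uninformative=False requires explicit emt_se and emt_sp intervals"
        )
    se = tuple(defaults[f"{t}_se"] for t in TESTS)
    sp = tuple(defaults[f"{t}_sp"] for t in TESTS)
    return PriorSpec(
        se=se, sp=sp, c=tuple(c_interval), prevalence=tuple(prevalence_interval)
    )


# --------------------------------------------------------------------------
# Parameters and likelihood


@dataclass
class LatentClassParams:
    """Prevalence plus the 2x3 probit intercepts and dependence loadings."""

    prevalence: float
    a: np.ndarray  # (2, 3), row d = class
    c: np.ndarray  # (2, 3), nonnegative

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != (2, 3) or self.c.shape != (2, 3):
            raise ValueError("a and c must have shape (2, 3)")
        if not (0 < self.prevalence < 1):
            raise ValueError(f"prevalence {self.prevalence} outside (0, 1)")
        if np.any(self.c < 0):
            raise ValueError("dependence loadings must be nonnegative")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.c))):
            raise ValueError("parameters must be finite")

    @classmethod
    def from_accuracy(
        cls,
        prevalence: float,
        se: Sequence[float],
        sp: Sequence[float],
        c1: Sequence[float] = (0.0, 0.0, 0.0),
        c0: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "LatentClassParams":
        """Build from marginal accuracies; intercepts absorb the loadings."""
        se = np.asarray(se, dtype=float)
        sp = np.asarray(sp, dtype=float)
        c = np.vstack([np.asarray(c0, float), np.asarray(c1, float)])
        a = np.vstack(
            [
                intercept_from_marginal(1.0 - sp, c[0]),
                intercept_from_marginal(se, c[1]),
            ]
        )
        return cls(prevalence=prevalence, a=a, c=c)

    def se(self) -> np.ndarray:
        return marginal_accuracy(self.a[1], self.c[1])

    def sp(self) -> np.ndarray:
        return 1.0 - marginal_accuracy(self.a[0], self.c[0])


def conditional_positive_prob(a: float, c: float, z: float):
    """P(test positive | class, Z=z) = Phi(a + c z)."""
    return ndtr(np.asarray(a) + np.asarray(c) * np.asarray(z))


def marginal_accuracy(a, c):
    """Positive probability marginal over Z ~ N(0,1): Phi(a / sqrt(1 + c^2))."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("dependence loading must be nonnegative")
    result = ndtr(a / np.sqrt(1.0 + c * c))
    return result if result.shape else float(result)


def intercept_from_marginal(p, c):
    """Inverse of :func:`marginal_accuracy`: a = Phi^{-1}(p) sqrt(1 + c^2)."""
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    return ndtri(p) * np.sqrt(1.0 + c * c)


def _gauss_hermite(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for integrating against the standard normal density."""
    if order < 2:
        raise ValueError("quadrature order must be at least 2")
    x, w = np.polynomial.hermite.hermgauss(order)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def pattern_prob_table(params: LatentClassParams, order: int = 30) -> np.ndarray:
    """Probabilities of the 8 patterns in :data:`~emtdx.cohort.PATTERNS` order."""
    z, w = _gauss_hermite(order)
    probs = np.empty((2, 8))
    for d in (0, 1):
        p = ndtr(params.a[d][:, None] + params.c[d][:, None] * z[None, :])  # (3, Q)
        terms = np.ones((8, z.size))
        for j in range(3):
            pj = p[j]
            terms *= np.where(_PATTERN_ARRAY[:, j : j + 1], pj, 1.0 - pj)
        probs[d] = terms @ w
    pi = params.prevalence
    return pi * probs[1] + (1.0 - pi) * probs[0]


def pattern_likelihood(
    pattern: Sequence[int], params: LatentClassParams, order: int = 30
) -> float:
    """Probability of one joint (emt, ln, ri) result under the model.

    The mixture over latent class of the Z-integral of the conditional
    Bernoulli products, evaluated by Gauss-Hermite quadrature.
    """
    pattern = tuple(int(v) for v in pattern)
    if pattern not in PATTERNS:
        raise ValueError(f"invalid pattern {pattern}")
    return float(pattern_prob_table(params, order=order)[PATTERNS.index(pattern)])


def log_likelihood(
    counts: PatternCounts, params: LatentClassParams, order: int = 30
) -> float:
    """Multinomial log-likelihood of the 8-cell counts."""
    arr = counts.to_array()
    probs = pattern_prob_table(params, order=order)
    positive = arr > 0
    if np.any(probs[positive] <= 0.0):
        return -np.inf
    return float(arr[positive] @ np.log(probs[positive]))


# --------------------------------------------------------------------------
# Posterior sampling


@dataclass
class PosteriorSummary:
    """Point estimates and 95% credible intervals for one dependence model."""

    model: str
    seed: int
    n: int
    prevalence: dict
    tests: dict  # test name -> {"se": summary, "sp": summary}
    c_loadings: dict  # "c_{d}_{test}" -> summary for free loadings
    acceptance: dict
    burn_in: int
    iterations: int
    quadrature_order: int

    def to_row(self, as_percent: bool = True) -> dict:
        scale = 100.0 if as_percent else 1.0
        row: dict = {"model": self.model}
        for test in TESTS:
            for metric in ("se", "sp"):
                s = self.tests[test][metric]
                row[f"{test}_{metric}"] = s["median"] * scale
                row[f"{test}_{metric}_lo"] = s["lo"] * scale
                row[f"{test}_{metric}_hi"] = s["hi"] * scale
        row["prevalence"] = self.prevalence["median"]
        return row


def _summarize(draws: np.ndarray) -> dict:
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return {
        "median": float(med),
        "lo": float(lo),
        "hi": float(hi),
        "ess": _effective_sample_size(draws),
    }


def _effective_sample_size(draws: np.ndarray) -> float:
    """ESS via arviz's bulk estimator (warn-only diagnostic)."""
    try:
        import arviz as az

        return float(az.ess(draws[None, :]))
    except Exception:  # pragma: no cover - diagnostic only
        return float("nan")


def _make_loglik(counts_arr: np.ndarray, order: int):
    z, w = _gauss_hermite(order)
    pats = _PATTERN_ARRAY
    positive = counts_arr > 0
    counts_pos = counts_arr[positive]

    def loglik(pi, se, sp, c1, c0):
        a1 = ndtri(se) * np.sqrt(1.0 + c1 * c1)
        a0 = ndtri(1.0 - sp) * np.sqrt(1.0 + c0 * c0)
        p1 = ndtr(a1[:, None] + c1[:, None] * z[None, :])
        p0 = ndtr(a0[:, None] + c0[:, None] * z[None, :])
        t1 = np.ones((8, z.size))
        t0 = np.ones((8, z.size))
        for j in range(3):
            col = pats[:, j : j + 1]
            t1 *= np.where(col, p1[j], 1.0 - p1[j])
            t0 *= np.where(col, p0[j], 1.0 - p0[j])
        probs = pi * (t1 @ w) + (1.0 - pi) * (t0 @ w)
        probs = probs[positive]
        if np.any(probs <= 0.0):
            return -np.inf
        return float(counts_pos @ np.log(probs))

    return loglik


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal into [lo, hi] (preserves detailed balance)."""
    width = hi - lo
    x = (x - lo) % (2.0 * width)
    if x > width:
        x = 2.0 * width - x
    return lo + x


def fit_latent_class(
    counts: PatternCounts,
    spec: DependenceSpec,
    priors: PriorSpec | None = None,
    burn_in: int = 5000,
    iterations: int = 50_000,
    seed: int = 0,
    order: int = 30,
    return_draws: bool = False,
):
    """Sample the posterior for one dependence structure.

    A single seeded chain of random-walk Metropolis updates, one coordinate
    at a time, on (prevalence, Se_j, Sp_j, free c_dj).  Proposal scales are
    tuned toward 44% acceptance during burn-in and frozen afterwards, so
    identical seeds yield identical summaries.
    """
    if priors is None:
        priors = build_priors()
    if counts.n <= 0:
        raise ValueError("pattern counts must sum to a positive cohort size")
    if burn_in < 0 or iterations <= 0:
        raise ValueError("burn_in must be >= 0 and iterations positive")

    counts_arr = counts.to_array()
    loglik = _make_loglik(counts_arr, order)
    rng = np.random.default_rng(seed)
    c_free = spec.c_free_mask()

    # Coordinate bookkeeping: (kind, index) with bounds.
    coords: list[tuple] = [("pi", None, priors.prevalence)]
    for j in range(3):
        coords.append(("se", j, priors.se[j]))
    for j in range(3):
        coords.append(("sp", j, priors.sp[j]))
    for d in (0, 1):
        for j in range(3):
            if c_free[d, j]:
                coords.append(("c", (d, j), priors.c))

    def midpoint(bounds):
        return 0.5 * (bounds[0] + bounds[1])

    pi = midpoint(priors.prevalence)
    se = np.array([midpoint(b) for b in priors.se])
    sp = np.array([midpoint(b) for b in priors.sp])
    c = np.zeros((2, 3))
    for d in (0, 1):
        for j in range(3):
            if c_free[d, j]:
                c[d, j] = 0.25 * (priors.c[0] + priors.c[1])

    current = loglik(pi, se, sp, c[1], c[0])
    scales = np.array([0.1 * (b[1] - b[0]) for *_, b in coords])
    accepted = np.zeros(len(coords))
    proposed = np.zeros(len(coords))

    n_kept = iterations
    draws_pi = np.empty(n_kept)
    draws_se = np.empty((n_kept, 3))
    draws_sp = np.empty((n_kept, 3))
    free_idx = [(d, j) for d in (0, 1) for j in range(3) if c_free[d, j]]
    draws_c = np.empty((n_kept, len(free_idx)))

    total = burn_in + iterations
    adapt_window = 50
    window_accept = np.zeros(len(coords))
    window_count = np.zeros(len(coords))

    for it in range(total):
        for k, (kind, idx, bounds) in enumerate(coords):
            if kind == "pi":
                old = pi
            elif kind == "se":
                old = se[idx]
            elif kind == "sp":
                old = sp[idx]
            else:
                old = c[idx]
            prop = _reflect(old + scales[k] * rng.standard_normal(), *bounds)
            if kind == "pi":
                pi = prop
            elif kind == "se":
                se[idx] = prop
            elif kind == "sp":
                sp[idx] = prop
            else:
                c[idx] = prop
            candidate = loglik(pi, se, sp, c[1], c[0])
            proposed[k] += 1
            window_count[k] += 1
            if math.log(rng.random()) < candidate - current:
                current = candidate
                accepted[k] += 1
                window_accept[k] += 1
            else:
                if kind == "pi":
                    pi = old
                elif kind == "se":
                    se[idx] = old
                elif kind == "sp":
                    sp[idx] = old
                else:
                    c[idx] = old

        if it < burn_in and (it + 1) % adapt_window == 0:
            rate = np.divide(
                window_accept,
                np.maximum(window_count, 1),
            )
            scales *= np.exp(0.5 * (rate - 0.44))
            window_accept[:] = 0
            window_count[:] = 0

        if it >= burn_in:
            keep = it - burn_in
            draws_pi[keep] = pi
            draws_se[keep] = se
            draws_sp[keep] = sp
            for m, dj in enumerate(free_idx):
                draws_c[keep, m] = c[dj]

    tests = {}
    for j, test in enumerate(TESTS):
        tests[test] = {
            "se": _summarize(draws_se[:, j]),
            "sp": _summarize(draws_sp[:, j]),
        }
    c_summaries = {
        f"c_{d}_{TESTS[j]}": _summarize(draws_c[:, m])
        for m, (d, j) in enumerate(free_idx)
    }
    acceptance = {
        f"{kind}" + (f"_{idx}" if idx is not None else ""): float(a / max(p, 1))
        for (kind, idx, _), a, p in zip(coords, accepted, proposed)
    }
    summary = PosteriorSummary(
        model=spec.name,
        seed=seed,
        n=int(counts.n),
        prevalence=_summarize(draws_pi),
        tests=tests,
        c_loadings=c_summaries,
        acceptance=acceptance,
        burn_in=burn_in,
        iterations=iterations,
        quadrature_order=order,
    )
    if return_draws:
        draws = {
            "prevalence": draws_pi,
            "se": draws_se,
            "sp": draws_sp,
            "c": draws_c,
            "c_index": free_idx,
        }
        return summary, draws
    return summary


def dependence_model_suite(
    counts: PatternCounts,
    priors: PriorSpec | None = None,
    burn_in: int = 5000,
    iterations: int = 50_000,
    seed: int = 0,
    order: int = 30,
    models: Sequence[str] | None = None,
) -> list[PosteriorSummary]:
    """Fit every requested dependence structure (all eight by default)."""
    names = list(models) if models is not None else list(DEPENDENCE_MODELS)
    unknown = [m for m in names if m not in DEPENDENCE_MODELS]
    if unknown:
        raise ValueError(f"unknown dependence models: {unknown}")
    return [
        fit_latent_class(
            counts,
            DEPENDENCE_MODELS[name],
            priors=priors,
            burn_in=burn_in,
            iterations=iterations,
            seed=seed,
            order=order,
        )
        for name in names
    ]


def suite_table(summaries: Sequence[PosteriorSummary], as_percent: bool = True):
    """Wide table (one row per dependence model) of Se/Sp estimates."""
    import pandas as pd

    return pd.DataFrame([s.to_row(as_percent=as_percent) for s in summaries])
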