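"""Synthetic cohorts with known latent truth.

Each subject gets a latent binary state D ~ Bernoulli(prevalence) and a
shared random effect Z ~ N(0, 1); the three binary tests are positive with
probability Phi(a_Dj + c_Dj Z).  The continuous marker is drawn from a
class-conditional truncated normal on the 0-3 scale, restricted to the side
of the configured cut point implied by the subject's marker-test result so
score and test are consistent by construction.  Survival is exponential with
a class-specific hazard, with independent exponential censoring and
administrative censoring at the horizon.

A single seed drives everything through a SeedSequence-spawned generator per
block (latent state, tests, marker, survival, censoring), so modules can be
tested independently and identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from emtdx.cohort import CohortTable, MarkerDirection, SubjectRecord
from emtdx.latent import LatentClassParams, pattern_prob_table

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "theoretical_pattern_probs",
    "cancors_like_preset",
    "emission_mean_for_accuracy",
]


@dataclass
class SyntheticConfig:
    """Generative truth for one synthetic cohort.

    Tests are ordered (marker, ln, ri).  ``se``/``sp`` are the marginal
    accuracies; ``c1``/``c0`` the dependence loadings within the latent
    positive/negative class.  ``marker_mean`` maps latent class to the
    emission mean of the truncated normal on [0, 3].
    """

    n: int = 188
    prevalence: float = 0.5
    se: tuple[float, float, float] = (0.55, 0.65, 0.65)
    sp: tuple[float, float, float] = (0.60, 0.97, 0.97)
    c1: tuple[float, float, float] = (0.0, 0.0, 0.0)
    c0: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cut_point: float = 0.85
    marker_direction: MarkerDirection = MarkerDirection.EPITHELIAL
    marker_mean: tuple[float, float] = (1.8, 0.6)   # (class 0, class 1)
    marker_sd: float = 0.6
    hazard: tuple[float, float] = (0.03, 0.13)      # (class 0, class 1)
    censor_hazard: float = 0.02
    horizon: float = 5.0
    seed: int = 0
    emission_tolerance: float = 0.20

    def __post_init__(self):
        self.marker_direction = MarkerDirection.parse(self.marker_direction)
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if any(h <= 0 for h in self.hazard) or self.censor_hazard < 0:
            raise ValueError("hazards must be positive")
        if not (0 < self.cut_point <= 3):
            raise ValueError("cut_point must lie in (0, 3]")
        if self.marker_sd <= 0:
            raise ValueError("marker_sd must be positive")
        self._check_emission_consistency()

    def params(self) -> LatentClassParams:
        return LatentClassParams.from_accuracy(
            self.prevalence, self.se, self.sp, c1=self.c1, c0=self.c0
        )

    def emission_positive_prob(self, d: int) -> float:
        """P(marker test positive | class d) implied by the emission alone."""
        dist = _truncated(self.marker_mean[d], self.marker_sd)
        below = dist.cdf(self.cut_point)
        if self.marker_direction is MarkerDirection.EPITHELIAL:
            return float(below)
        return float(1.0 - below)

    def _check_emission_consistency(self):
        """The emission-implied positive rates must approximate the configured
        marginal accuracies of the marker test."""
        probit = [1.0 - self.sp[0], self.se[0]]
        for d in (0, 1):
            gap = abs(self.emission_positive_prob(d) - probit[d])
            if gap > self.emission_tolerance:
                raise ValueError(
                    f"marker emission inconsistent with cut point for class {d}: "
                    f"emission positive-rate differs from configured accuracy by "
                    f"{gap:.3f} (> {self.emission_tolerance})"
                )


def _truncated(mean: float, sd: float, lo: float = 0.0, hi: float = 3.0):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def emission_mean_for_accuracy(
    target_positive_prob: float,
    cut_point: float,
    sd: float,
    direction: MarkerDirection | str = MarkerDirection.EPITHELIAL,
) -> float:
    """Emission mean whose truncated normal puts the target mass on the
    positive side of the cut point.  Solved by root finding over the mean."""
    direction = MarkerDirection.parse(direction)
    if not (0 < target_positive_prob < 1):
        raise ValueError("target probability must lie in (0, 1)")

    def objective(mean):
        below = _truncated(mean, sd).cdf(cut_point)
        positive = below if direction is MarkerDirection.EPITHELIAL else 1 - below
        return positive - target_positive_prob

    return float(brentq(objective, -5.0, 8.0, xtol=1e-10))


@dataclass
class SyntheticCohort:
    """Observable cohort plus hidden truth columns (latent state, random effect)."""

    cohort: CohortTable
    truth: pd.DataFrame  # subject_id, d, z, plus per-test error indicators
    config: SyntheticConfig

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, index=False)


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> SyntheticCohort:
    """Draw one cohort from the configured generative model."""
    seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(5)
    rng_latent = np.random.default_rng(children[0])
    rng_tests = np.random.default_rng(children[1])
    rng_marker = np.random.default_rng(children[2])
    rng_surv = np.random.default_rng(children[3])
    rng_cens = np.random.default_rng(children[4])

    n = config.n
    params = config.params()
    d = (rng_latent.random(n) < config.prevalence).astype(int)
    z = rng_latent.standard_normal(n)

    a = params.a[d]            # (n, 3)
    c = params.c[d]
    p_pos = _phi(a + c * z[:, None])
    tests = (rng_tests.random((n, 3)) < p_pos).astype(int)

    # marker score consistent with its test result: draw from the class
    # emission truncated to the matching side of the cut point (inverse-CDF
    # sampling, vectorized over the four class x side groups)
    scores = np.empty(n)
    u = rng_marker.random(n)
    eps = 1e-9
    positive = tests[:, 0] == 1
    want_below = (
        positive
        if config.marker_direction is MarkerDirection.EPITHELIAL
        else ~positive
    )
    for klass in (0, 1):
        dist = _truncated(config.marker_mean[klass], config.marker_sd)
        below = float(dist.cdf(config.cut_point))
        for side in (True, False):
            mask = (d == klass) & (want_below == side)
            if not mask.any():
                continue
            if side:
                q = u[mask] * max(below, eps)
            else:
                q = below + u[mask] * max(1.0 - below, eps)
            scores[mask] = dist.ppf(np.clip(q, eps, 1 - eps))
    scores = np.round(scores, 6)
    # keep the rounded score strictly on the drawn side of the cut
    scores[want_below & (scores >= config.cut_point)] = config.cut_point - 1e-6
    scores[~want_below & (scores < config.cut_point)] = config.cut_point
    scores = np.clip(scores, 0.0, 3.0)

    death_time = rng_surv.exponential(1.0, size=n) / np.array(config.hazard)[d]
    if config.censor_hazard > 0:
        censor_time = rng_cens.exponential(1.0 / config.censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    followup = np.minimum(np.minimum(death_time, censor_time), config.horizon)
    death = (death_time <= np.minimum(censor_time, config.horizon)).astype(int)
    followup = np.maximum(followup, 1e-6)  # guard against zero times

    records = []
    for i in range(n):
        stage, n_stage = _stage_consistent_with_tests(tests[i, 1], tests[i, 2])
        records.append(
            SubjectRecord(
                subject_id=f"s{i + 1:05d}",
                stage=stage,
                n_stage=n_stage,
                marker_score=float(scores[i]),
                ln_test=int(tests[i, 1]),
                ri_test=int(tests[i, 2]),
                followup_time=float(followup[i]),
                death=int(death[i]),
            )
        )
    cohort = CohortTable(records=records, marker_direction=config.marker_direction)
    truth = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "d": d,
            "z": z,
            "emt_test": tests[:, 0],
            "ln_test": tests[:, 1],
            "ri_test": tests[:, 2],
            "death_time": death_time,
        }
    )
    return SyntheticCohort(cohort=cohort, truth=truth, config=config)


def _phi(x):
    from scipy.special import ndtr

    return ndtr(x)


def _stage_consistent_with_tests(ln: int, ri: int) -> tuple[str, str]:
    """A stage/N-stage assignment whose imputation reproduces (ln, ri)."""
    if ri == 1:
        return ("distant", "N1orN2" if ln == 1 else "N0")
    if ln == 1:
        return ("regional", "not_applicable")
    return ("local", "not_applicable")


def theoretical_pattern_probs(config: SyntheticConfig, order: int = 60) -> np.ndarray:
    """Exact 8-pattern probabilities implied by the config, by quadrature."""
    return pattern_prob_table(config.params(), order=order)


def expected_death_fraction(config: SyntheticConfig) -> float:
    """Closed-form P(death observed by the horizon) under the config."""
    total = 0.0
    weights = (1.0 - config.prevalence, config.prevalence)
    for d in (0, 1):
        lam = config.hazard[d]
        rate = lam + config.censor_hazard
        total += weights[d] * (lam / rate) * (1.0 - math.exp(-rate * config.horizon))
    return total


def cancors_like_preset() -> SyntheticConfig:
    """A 188-subject configuration calibrated so the expected positive-test
    margins are about 86 (nodes) and 23 (imaging) and expected 5-year deaths
    about 62.

    Marker accuracies are derived from the emission (class-1 mean 0.6,
    class-0 mean 1.8, common SD 0.6, cut point 0.85) so score and test are
    exactly consistent.
    """
    prevalence = 0.62
    cut = 0.85
    sd = 0.6
    mean1, mean0 = 0.6, 1.8
    p_pos_1 = float(_truncated(mean1, sd).cdf(cut))      # Se of the marker test
    p_pos_0 = float(_truncated(mean0, sd).cdf(cut))      # 1 - Sp
    return SyntheticConfig(
        n=188,
        prevalence=prevalence,
        se=(p_pos_1, 0.70, 0.185),
        sp=(1.0 - p_pos_0, 0.95, 0.98),
        c1=(0.0, 0.0, 0.0),
        c0=(0.0, 0.0, 0.0),
        cut_point=cut,
        marker_mean=(mean0, mean1),
        marker_sd=sd,
        hazard=(0.0306, 0.127),
        censor_hazard=0.02,
        horizon=5.0,
        seed=0,
    )
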