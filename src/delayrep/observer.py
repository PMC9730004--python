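"""Bayesian-observer simulator for delayed interval reproduction.

The generative model has three stages, all operating on log10 duration:

1. *Measurement.*  The sample interval ``s`` yields a noisy internal
   measurement ``m ~ Normal(log10 s, sigma_eff(d))`` whose SD widens with
   the retention period ``d`` through diffusion of the memory trace:
   ``sigma_eff(d) = sqrt(sigma_m**2 + eta2 * d)``.  Additive log-space
   noise gives the scalar property (SD proportional to duration).
2. *Inference.*  The observer combines ``m`` with a prior over log
   durations (the reference memory acquired over trials).  With a
   Gaussian log prior the posterior mean is the precision-weighted
   average ``w*m + (1-w)*prior_mu`` with
   ``w = prior_sigma**2 / (prior_sigma**2 + sigma_eff**2)``, so the
   expected log-log reproduction slope equals ``w`` exactly — slopes
   below 1 are the central (Vierordt) bias, and ``eta2 > 0`` makes the
   bias stronger at longer retention.  A discrete empirical prior over
   the presented interval set is also available (BLS-style observer).
3. *Production.*  The estimate is reproduced with multiplicative motor
   noise: ``log10 r = log10 e + Normal(0, sigma_prod)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .design import DesignSpec, IntervalSet, generate_schedule

__all__ = [
    "ObserverParams",
    "PopulationSpec",
    "effective_sd",
    "posterior_weight",
    "estimate",
    "simulate_trial",
    "simulate_dataset",
    "DEFAULT_PRIOR_MU",
]

#: Prior mean at the log of the standard 640 ms central interval.
DEFAULT_PRIOR_MU = math.log10(640.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one observer.

    sigma_m : measurement noise SD at zero delay (log10 units).
    eta2 : memory diffusion rate (log10 units**2 per second); the
        measurement variance grows linearly with the retention period.
    sigma_prod : production noise SD (log10 units).
    prior_kind : ``"gaussian_log"`` (conjugate Gaussian prior on log
        duration) or ``"empirical_discrete"`` (uniform prior on the
        presented interval set).
    prior_mu, prior_sigma : mean (log10 ms) and SD (log10 units) of the
        Gaussian log prior.
    estimator : ``"posterior_mean_log"`` or ``"posterior_mean_linear"``
        (the latter only differs for the discrete prior).
    """

    sigma_m: float = 0.115
    eta2: float = 0.0013
    sigma_prod: float = 0.05
    prior_kind: str = "gaussian_log"
    prior_mu: float = DEFAULT_PRIOR_MU
    prior_sigma: float = 0.2
    estimator: str = "posterior_mean_log"

    def __post_init__(self) -> None:
        if self.sigma_m < 0 or self.eta2 < 0 or self.sigma_prod < 0:
            raise ValueError("noise SDs and eta2 must be non-negative")
        if self.prior_kind not in ("gaussian_log", "empirical_discrete"):
            raise ValueError(f"unknown prior_kind {self.prior_kind!r}")
        if self.prior_kind == "gaussian_log" and not self.prior_sigma > 0:
            raise ValueError("prior_sigma must be positive for gaussian_log")
        if self.estimator not in ("posterior_mean_log", "posterior_mean_linear"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def effective_sd(params: ObserverParams, retention_s: float) -> float:
    """Measurement SD after a retention period, in log10 units.

    Diffusion noise accumulates linearly in variance:
    ``sqrt(sigma_m**2 + eta2 * d)``; non-decreasing in ``d``.
    """
    if retention_s < 0:
        raise ValueError(f"retention_s must be >= 0, got {retention_s}")
    return math.sqrt(params.sigma_m**2 + params.eta2 * retention_s)


def posterior_weight(params: ObserverParams, retention_s: float) -> float:
    """Weight on the measurement in the conjugate posterior mean, in [0, 1].

    ``w = prior_sigma**2 / (prior_sigma**2 + sigma_eff**2)``.  This is
    also the expected log-log reproduction slope of the observer.
    """
    if params.prior_kind != "gaussian_log":
        raise ValueError("posterior_weight requires the gaussian_log prior")
    s2 = params.prior_sigma**2
    return s2 / (s2 + effective_sd(params, retention_s) ** 2)


def estimate(
    params: ObserverParams,
    measurement_log10: float,
    retention_s: float,
    interval_set: IntervalSet | None = None,
) -> float:
    """Posterior-mean duration estimate (ms) from a log10 measurement."""
    if not np.isfinite(measurement_log10):
        raise ValueError("measurement must be finite")
    if params.prior_kind == "gaussian_log":
        w = posterior_weight(params, retention_s)
        return 10.0 ** (w * measurement_log10 + (1.0 - w) * params.prior_mu)
    # empirical_discrete: uniform prior over the interval set, Gaussian
    # likelihood in log space.
    if interval_set is None or len(interval_set) == 0:
        raise ValueError("empirical_discrete prior requires a non-empty interval set")
    sd = effective_sd(params, retention_s)
    logs = np.log10(np.asarray(interval_set.values_ms, dtype=float))
    if sd == 0:
        # Degenerate likelihood: posterior mass on nearest set member.
        post = np.zeros_like(logs)
        post[np.argmin(np.abs(logs - measurement_log10))] = 1.0
    else:
        loglik = -0.5 * ((measurement_log10 - logs) / sd) ** 2
        loglik -= loglik.max()
        post = np.exp(loglik)
        post /= post.sum()
    if params.estimator == "posterior_mean_linear":
        return float(post @ (10.0**logs))
    return float(10.0 ** (post @ logs))


def simulate_trial(
    params: ObserverParams,
    sample_ms: float,
    retention_s: float,
    rng: np.random.Generator,
    interval_set: IntervalSet | None = None,
) -> float:
    """Simulate one reproduced duration (ms) through the three stages."""
    m = rng.normal(math.log10(sample_ms), effective_sd(params, retention_s))
    e = estimate(params, m, retention_s, interval_set)
    return 10.0 ** (math.log10(e) + rng.normal(0.0, params.sigma_prod))


@dataclass
class PopulationSpec:
    """Between-participant heterogeneity around mean observer parameters.

    ``sigma_m``, ``eta2`` and ``sigma_prod`` vary log-normally across
    participants (SD given on the natural-log scale, keeping them
    non-negative); ``prior_mu`` varies normally.  Zero SDs give a
    homogeneous population.  These random effects mirror the participant
    random intercept of the analysis models.
    """

    mean: ObserverParams = field(default_factory=ObserverParams)
    cv_sigma_m: float = 0.2
    cv_eta2: float = 0.2
    cv_sigma_prod: float = 0.2
    sd_prior_mu: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_sigma_m, self.cv_eta2, self.cv_sigma_prod, self.sd_prior_mu) < 0:
            raise ValueError("heterogeneity SDs must be non-negative")

    def sample_params(self, rng: np.random.Generator) -> ObserverParams:
        """Draw one participant's parameters."""
        def lognorm(mu: float, cv: float) -> float:
            if mu == 0 or cv == 0:
                return mu
            return mu * math.exp(rng.normal(0.0, cv))

        return replace(
            self.mean,
            sigma_m=lognorm(self.mean.sigma_m, self.cv_sigma_m),
            eta2=lognorm(self.mean.eta2, self.cv_eta2),
            sigma_prod=lognorm(self.mean.sigma_prod, self.cv_sigma_prod),
            prior_mu=self.mean.prior_mu + rng.normal(0.0, self.sd_prior_mu)
            if self.sd_prior_mu > 0
            else self.mean.prior_mu,
        )


def simulate_dataset(
    spec: DesignSpec,
    pop: PopulationSpec | None = None,
    interval_set: IntervalSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full reproduction dataset for one experiment design.

    Returns ``(data, truth)``: the trial table with a ``reproduced_ms``
    column appended to the schedule schema, and a sidecar table of the
    true per-participant observer parameters (for recovery tests).
    Fully determined by ``spec.seed`` and ``pop.seed``.
    """
    if pop is None:
        pop = PopulationSpec()
    if interval_set is None:
        interval_set = spec.interval_set()
    schedule = generate_schedule(spec, interval_set)
    rng = np.random.default_rng(pop.seed)

    truth_rows = []
    participants = schedule["participant"].unique() if len(schedule) else []
    params_by_p: dict[str, ObserverParams] = {}
    for p in participants:
        params = pop.sample_params(rng)
        params_by_p[p] = params
        truth_rows.append({"participant": p, **asdict(params)})

    reproduced = np.empty(len(schedule))
    for j, row in enumerate(schedule.itertuples(index=False)):
        reproduced[j] = simulate_trial(
            params_by_p[row.participant], row.sample_ms, row.retention_s, rng, interval_set
        )
    data = schedule.copy()
    data["reproduced_ms"] = reproduced
    truth = pd.DataFrame(truth_rows)
    return data, truth
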