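"""Restless four-armed bandit task: payoff process and session harness.

The latent mean payoff of every arm follows a mean-reverting (decaying)
Gaussian random walk,

    mu[i, t+1] = lambda * mu[i, t] + (1 - lambda) * theta + nu,

with decay ``lambda``, decay center ``theta`` and diffusion noise
``nu ~ N(0, sigma_d^2)``.  The payoff actually shown on a trial is a Gaussian
draw around the current latent mean (SD ``sigma_o``), rounded to the nearest
integer and kept inside the 1..100 point range.  Because the best arm drifts,
continued exploration stays rational throughout a session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .records import MISSED, SessionRecord

__all__ = [
    "TaskConfig",
    "PayoffSchedule",
    "step_means",
    "stationary_moments",
    "generate_schedule",
    "play_session",
]


@dataclass
class TaskConfig:
    """Generating-process parameters of the restless bandit task.

    Defaults are the published task settings: 300 trials in 4 runs of 75,
    decay ``lambda_gen`` = 0.9836 toward center 50, diffusion SD 2.8,
    observation SD 4, integer payoffs in [1, 100], and a 1.5 s response
    window.
    """

    n_arms: int = 4
    n_trials: int = 300
    n_runs: int = 4
    lambda_gen: float = 0.9836
    theta_gen: float = 50.0
    sigma_d_gen: float = 2.8
    sigma_o_gen: float = 4.0
    payoff_min: int = 1
    payoff_max: int = 100
    boundary_mode: str = "reflect"
    choice_window: float = 1.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        if self.n_runs < 1 or self.n_trials % self.n_runs:
            raise ValueError("n_trials must be a multiple of n_runs")
        if not 0.0 < self.lambda_gen <= 1.0:
            raise ValueError("lambda_gen must be in (0, 1]")
        if self.sigma_d_gen < 0 or self.sigma_o_gen < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.payoff_min >= self.payoff_max:
            raise ValueError("payoff_min must be < payoff_max")
        if self.boundary_mode not in ("reflect", "clamp"):
            raise ValueError("boundary_mode must be 'reflect' or 'clamp'")
        if self.choice_window <= 0:
            raise ValueError("choice_window must be positive")

    @property
    def trials_per_run(self) -> int:
        return self.n_trials // self.n_runs

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        return cls(**json.loads(text))


@dataclass
class PayoffSchedule:
    """Realized latent means and integer payoffs for every trial x arm."""

    means: np.ndarray  # (n_trials, n_arms) latent means, points
    payoffs: np.ndarray  # (n_trials, n_arms) integer payoffs, points
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: Optional[int] = None

    @property
    def n_trials(self) -> int:
        return self.means.shape[0]

    @property
    def n_arms(self) -> int:
        return self.means.shape[1]


def step_means(mu: np.ndarray, config: TaskConfig, noise: np.ndarray) -> np.ndarray:
    """Advance the latent means one step of the decaying random walk.

    ``noise`` is the realized diffusion draw ``nu`` (supplied explicitly so
    the deterministic part of the recursion can be tested in isolation).
    Latent means are unbounded; only realized payoffs are range-limited.
    """
    mu = np.asarray(mu, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if mu.shape[-1] != config.n_arms or noise.shape != mu.shape:
        raise ValueError("mu and noise must both have n_arms entries")
    lam = config.lambda_gen
    return lam * mu + (1.0 - lam) * config.theta_gen + noise


def stationary_moments(config: TaskConfig) -> tuple[float, float]:
    """Long-run mean and variance of the latent AR(1) mean process.

    Only defined for ``lambda_gen`` < 1 (the mean-reverting regime):
    mean = theta, variance = sigma_d^2 / (1 - lambda^2).
    """
    lam = config.lambda_gen
    if lam >= 1.0:
        raise ValueError("stationary distribution requires lambda_gen < 1")
    return config.theta_gen, config.sigma_d_gen**2 / (1.0 - lam**2)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by repeated reflection at the bounds."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def generate_schedule(
    config: TaskConfig,
    init_means: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> PayoffSchedule:
    """Simulate the full payoff process for one session.

    The initial latent means default to independent draws from the
    stationary distribution of the walk, so that early trials are
    statistically indistinguishable from late ones; explicit values can be
    supplied instead.  Payoffs are Gaussian draws around the latent means,
    folded into the payoff range (``boundary_mode='reflect'``, the default)
    or clipped to it (``'clamp'``), then rounded to the nearest integer.
    """
    rng_seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(rng_seed)
    n_t, n_a = config.n_trials, config.n_arms
    lam, theta = config.lambda_gen, config.theta_gen

    if init_means is not None:
        mu = np.asarray(init_means, dtype=float).copy()
        if mu.shape != (n_a,):
            raise ValueError("init_means must have n_arms entries")
    elif lam < 1.0:
        _, svar = stationary_moments(config)
        mu = rng.normal(theta, np.sqrt(svar), size=n_a)
    else:
        mu = np.full(n_a, theta, dtype=float)  # pure random walk: start at center

    means = np.empty((n_t, n_a))
    for t in range(n_t):
        means[t] = mu
        nu = rng.normal(0.0, config.sigma_d_gen, size=n_a)
        mu = lam * mu + (1.0 - lam) * theta + nu

    raw = rng.normal(means, config.sigma_o_gen)
    lo, hi = float(config.payoff_min), float(config.payoff_max)
    if config.boundary_mode == "reflect":
        bounded = _reflect(raw, lo, hi)
    else:
        bounded = np.clip(raw, lo, hi)
    payoffs = np.clip(np.rint(bounded), lo, hi).astype(int)
    return PayoffSchedule(means=means, payoffs=payoffs, config=config, seed=rng_seed)


def play_session(
    schedule: PayoffSchedule,
    policy,
    rt_sampler: Callable[[np.random.Generator], float],
    miss_rate: float = 0.0,
    seed: Optional[int] = None,
    subject: str = "sim",
    group: str = "",
) -> SessionRecord:
    """Play an agent through a payoff schedule and log the session.

    ``policy`` is either a stateful agent exposing ``probabilities()``,
    ``observe(arm, reward)`` and ``advance()`` (see
    :class:`~explorebandit.model.KalmanSoftmaxAgent`), or a plain callable
    ``policy(t) -> probability vector`` for stateless policies.  Each trial
    is missed with probability ``miss_rate`` (no choice, zero reward, no RT);
    otherwise an arm is sampled from the policy's probabilities, the reward
    is read off the schedule, and an RT is drawn from ``rt_sampler``
    truncated to (0, choice_window].
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = schedule.config
    n_t, n_a = schedule.n_trials, schedule.n_arms

    stateful = hasattr(policy, "probabilities")
    choice = np.full(n_t, MISSED, dtype=int)
    reward = np.zeros(n_t)
    rt = np.full(n_t, np.nan)
    for t in range(n_t):
        if rng.random() < miss_rate:
            if stateful:
                policy.advance()
            continue
        probs = np.asarray(policy.probabilities() if stateful else policy(t), dtype=float)
        if probs.shape != (n_a,) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ArithmeticError(f"policy returned non-normalized probabilities at trial {t}")
        arm = int(rng.choice(n_a, p=probs / probs.sum()))
        choice[t] = arm
        reward[t] = schedule.payoffs[t, arm]
        x = float(rt_sampler(rng))
        for _ in range(1000):
            if 0.0 < x <= cfg.choice_window:
                break
            x = float(rt_sampler(rng))
        rt[t] = min(max(x, np.finfo(float).tiny), cfg.choice_window)
        if stateful:
            policy.observe(arm, reward[t])

    trials = np.arange(1, n_t + 1)
    runs = (trials - 1) // cfg.trials_per_run + 1
    return SessionRecord(
        subject=subject, group=group, run=runs, trial=trials,
        choice=choice, reward=reward, rt=rt,
    )
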