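"""Kalman-filter belief tracking with a softmax choice rule.

Each arm's value is tracked as a Gaussian belief (mean, variance).  Before a
choice the agent holds *prior* ("pre-choice") beliefs; observing the chosen
arm's reward produces a posterior for that arm only, and all arms then
diffuse through the same decaying random walk the task uses:

    gain       kappa  = pre_var_c / (pre_var_c + sigma_o^2)
    posterior  mean_c = pre_mean_c + kappa * (reward - pre_mean_c)
               var_c  = (1 - kappa) * pre_var_c
    diffusion  pre_mean' = lambda * post_mean + (1 - lambda) * theta
               pre_var'  = lambda^2 * post_var + sigma_d^2

Choice probabilities are softmax in the pre-choice means,
P(i) proportional to exp(beta * pre_mean_i); the inverse temperature beta
(units 1/points) is the exploration parameter: beta = 0 chooses uniformly,
large beta is greedy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
from scipy.special import log_softmax, softmax

from .records import SessionRecord

__all__ = [
    "ModelParams",
    "BeliefState",
    "init_beliefs",
    "kalman_update",
    "diffuse",
    "choice_probabilities",
    "session_nll",
    "KalmanSoftmaxAgent",
]

#: variance floor inside the gain computation; when both the prior variance
#: and sigma_o are 0 the gain is taken to be 1 (the observation is exact).
VAR_FLOOR = 1e-12


@dataclass
class ModelParams:
    """Learning and choice parameters of the Kalman + softmax model.

    Defaults are the best-fitting values reported for this task family:
    lam = 0.8941, theta = 54.77, sigma_d = 6.32, sigma_o = 0,
    mu0 = 67.78 points and var0 = 8.18 points^2 shared by all arms.  ``beta``
    defaults to 0.18 (1/points), the scale of the observed group means.
    """

    lam: float = 0.8941
    theta: float = 54.77
    sigma_d: float = 6.32
    sigma_o: float = 0.0
    mu0: float = 67.78
    var0: float = 8.18
    beta: float = 0.18

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must be in (0, 1]")
        if self.sigma_d < 0 or self.sigma_o < 0:
            raise ValueError("sigma_d and sigma_o must be >= 0")
        if self.var0 < 0:
            raise ValueError("var0 must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def with_beta(self, beta: float) -> "ModelParams":
        return replace(self, beta=beta)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls(**json.loads(text))


@dataclass
class BeliefState:
    """Pre-choice Gaussian beliefs over all arms at one trial."""

    pre_mean: np.ndarray  # points
    pre_var: np.ndarray  # points^2
    t: int = 0

    def __post_init__(self) -> None:
        self.pre_mean = np.asarray(self.pre_mean, dtype=float)
        self.pre_var = np.asarray(self.pre_var, dtype=float)
        if np.any(self.pre_var < 0):
            raise ValueError("pre_var must be >= 0 elementwise")


def init_beliefs(params: ModelParams, n_arms: int = 4) -> BeliefState:
    """Initial beliefs: the same prior mean and variance for every arm."""
    if n_arms < 2:
        raise ValueError("n_arms must be >= 2")
    return BeliefState(
        pre_mean=np.full(n_arms, params.mu0),
        pre_var=np.full(n_arms, params.var0),
        t=0,
    )


def kalman_update(
    belief: BeliefState, chosen: int, reward: float, params: ModelParams
) -> BeliefState:
    """Observe one reward on the chosen arm and diffuse to the next trial.

    Only the chosen arm's belief moves toward the reward; unchosen arms'
    posteriors equal their priors, and every arm then undergoes the decay /
    diffusion step.
    """
    if not 0 <= chosen < len(belief.pre_mean):
        raise ValueError(f"chosen arm {chosen} out of range")
    if not np.isfinite(reward):
        raise ValueError("reward must be finite")
    post_mean = belief.pre_mean.copy()
    post_var = belief.pre_var.copy()
    pv = post_var[chosen]
    denom = pv + params.sigma_o**2
    kappa = 1.0 if denom < VAR_FLOOR else pv / denom
    post_mean[chosen] += kappa * (reward - post_mean[chosen])
    post_var[chosen] *= 1.0 - kappa
    return _diffused(post_mean, post_var, belief.t, params)


def diffuse(belief: BeliefState, params: ModelParams) -> BeliefState:
    """Advance beliefs one trial with no observation (e.g. a missed trial)."""
    return _diffused(belief.pre_mean.copy(), belief.pre_var.copy(), belief.t, params)


def _diffused(mean: np.ndarray, var: np.ndarray, t: int, params: ModelParams) -> BeliefState:
    lam = params.lam
    return BeliefState(
        pre_mean=lam * mean + (1.0 - lam) * params.theta,
        pre_var=lam**2 * var + params.sigma_d**2,
        t=t + 1,
    )


def choice_probabilities(belief: BeliefState, beta: float) -> np.ndarray:
    """Softmax choice probabilities over the pre-choice means.

    Computed with max-subtraction so large beta * mean products cannot
    overflow; the result is positive and sums to 1 to machine precision.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return softmax(beta * belief.pre_mean)


def session_nll(session: SessionRecord, params: ModelParams) -> float:
    """Negative log-likelihood (nats) of a session under the model.

    Beliefs start from the shared prior and are advanced trial by trial:
    responded trials contribute -log P(chosen arm | pre-choice beliefs) and
    update the filter with the observed reward; missed trials contribute no
    likelihood term but still undergo the diffusion step (time passes
    without an observation).
    """
    n_arms = max(4, int(session.choice.max()) + 1)
    belief = init_beliefs(params, n_arms=n_arms)
    nll = 0.0
    for t in range(session.n_trials):
        if session.missed[t]:
            belief = diffuse(belief, params)
            continue
        arm = int(session.choice[t])
        logp = log_softmax(params.beta * belief.pre_mean)[arm]
        nll -= logp
        if not np.isfinite(nll):
            raise ArithmeticError(f"non-finite likelihood at trial index {t}")
        belief = kalman_update(belief, arm, float(session.reward[t]), params)
    return float(nll)


class KalmanSoftmaxAgent:
    """Stateful agent for :func:`~explorebandit.task.play_session`.

    Maintains a Kalman belief state and chooses with softmax(beta * mean).
    ``beta = 0`` is a uniform-random agent.
    """

    def __init__(self, params: ModelParams, n_arms: int = 4):
        self.params = params
        self.belief = init_beliefs(params, n_arms)

    def probabilities(self) -> np.ndarray:
        return choice_probabilities(self.belief, self.params.beta)

    def observe(self, arm: int, reward: float) -> None:
        self.belief = kalman_update(self.belief, arm, reward, self.params)

    def advance(self) -> None:
        self.belief = diffuse(self.belief, self.params)
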