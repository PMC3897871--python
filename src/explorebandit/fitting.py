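"""Maximum-likelihood fitting of the Kalman + softmax model.

The model is fit hierarchically in the simplest sense: one set of learning
parameters (lam, theta, sigma_d, sigma_o, mu0, var0) is shared by every
subject in the cohort, while each subject gets their own softmax inverse
temperature beta.  The beta dimension is profiled out exactly: for fixed
learning parameters the belief trajectory — and hence the matrix of
pre-choice means — does not depend on beta, so each subject's likelihood is
a smooth convex function of beta alone and is minimized by a damped Newton
iteration.  The outer search over the shared parameters is a bounded
quasi-Newton (L-BFGS-B) run from several seeded starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .model import ModelParams, VAR_FLOOR
from .records import SessionRecord

__all__ = ["FitResult", "fit", "compare_group_betas", "DEFAULT_BOUNDS"]

PARAM_NAMES: Tuple[str, ...] = ("lam", "theta", "sigma_d", "sigma_o", "mu0", "var0")

#: default box constraints for the shared learning parameters
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "lam": (1e-3, 1.0),
    "theta": (0.0, 100.0),
    "sigma_d": (0.0, 30.0),
    "sigma_o": (0.0, 30.0),  # lower bound exactly 0: the optimum may sit there
    "mu0": (0.0, 100.0),
    "var0": (0.0, 200.0),
}

BETA_MAX = 5.0


@dataclass
class FitResult:
    """Shared learning parameters, per-subject betas and fit diagnostics."""

    params: ModelParams
    betas: Dict[str, float]
    per_subject_nll: Dict[str, float]
    nll_total: float
    nll_by_group: Dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0
    n_restarts: int = 1
    restart_nlls: Sequence[float] = field(default_factory=list)

    def params_for(self, subject: str) -> ModelParams:
        """The shared learning parameters with this subject's fitted beta."""
        return replace(self.params, beta=self.betas[subject])


def _stack(sessions: Sequence[SessionRecord]):
    n_t = sessions[0].n_trials
    if any(s.n_trials != n_t for s in sessions):
        raise ValueError("all sessions must have the same number of trials")
    choices = np.stack([s.choice for s in sessions])
    rewards = np.stack([s.reward for s in sessions])
    n_arms = max(4, int(choices.max()) + 1)
    return choices, rewards, n_arms


def _premeans(choices, rewards, x, n_arms):
    """Pre-choice mean matrix (subjects x trials x arms) for shared params x.

    Runs all subjects' Kalman filters in lock-step; missed trials (choice
    < 0) receive the diffusion-only step.
    """
    lam, theta, sigma_d, sigma_o, mu0, var0 = x
    S, T = choices.shape
    m = np.full((S, n_arms), mu0, dtype=float)
    v = np.full((S, n_arms), var0, dtype=float)
    so2 = sigma_o**2
    sd2 = sigma_d**2
    out = np.empty((S, T, n_arms))
    rows = np.arange(S)
    for t in range(T):
        out[:, t, :] = m
        resp = choices[:, t] >= 0
        if resp.any():
            r_idx = rows[resp]
            c = choices[resp, t]
            pv = v[r_idx, c]
            denom = pv + so2
            kappa = np.where(denom < VAR_FLOOR, 1.0, pv / np.maximum(denom, VAR_FLOOR))
            m[r_idx, c] += kappa * (rewards[resp, t] - m[r_idx, c])
            v[r_idx, c] = (1.0 - kappa) * pv
        m = lam * m + (1.0 - lam) * theta
        v = lam**2 * v + sd2
    return out


def _profile_betas(premeans, choices, beta0=0.1, tol=1e-9, max_iter=60):
    """Per-subject beta minimizing the session NLL, by damped Newton.

    The NLL is convex in beta (log-sum-exp of linear functions), so Newton
    with step clamping to [0, BETA_MAX] converges; flat likelihoods (all
    pre-choice means equal) leave beta at its current value.
    Returns (betas, per-subject NLLs).
    """
    S, T, A = premeans.shape
    resp = choices >= 0
    rows, cols = np.where(resp)
    m_c = np.zeros((S, T))
    m_c[rows, cols] = premeans[rows, cols, choices[rows, cols]]
    beta = np.full(S, float(beta0))
    for _ in range(max_iter):
        z = beta[:, None, None] * premeans
        zmax = z.max(axis=2, keepdims=True)
        ez = np.exp(z - zmax)
        sez = ez.sum(axis=2)
        p = ez / sez[:, :, None]
        em = np.einsum("sta,sta->st", p, premeans)
        em2 = np.einsum("sta,sta,sta->st", p, premeans, premeans)
        grad = ((em - m_c) * resp).sum(axis=1)
        hess = ((em2 - em**2) * resp).sum(axis=1)
        step = np.where(hess > 1e-12, grad / np.maximum(hess, 1e-12), 0.0)
        step = np.clip(step, -1.0, 1.0)  # damping
        new = np.clip(beta - step, 0.0, BETA_MAX)
        moved = np.abs(new - beta)
        beta = new
        if np.all((np.abs(grad) < tol) | (moved < 1e-12)):
            break
    z = beta[:, None, None] * premeans
    lse = logsumexp(z, axis=2)
    nll = ((lse - beta[:, None] * m_c) * resp).sum(axis=1)
    return beta, nll


def _objective(x_free, free_idx, x_full, choices, rewards, n_arms):
    x = x_full.copy()
    x[free_idx] = x_free
    pm = _premeans(choices, rewards, x, n_arms)
    _, nll = _profile_betas(pm, choices)
    return float(nll.sum())


def fit(
    sessions: Sequence[SessionRecord],
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    restarts: int = 5,
    seed: Optional[int] = None,
    init: Optional[ModelParams] = None,
    free: Optional[Iterable[str]] = None,
) -> FitResult:
    """Fit shared learning parameters and per-subject betas by ML.

    Parameters
    ----------
    sessions : sequence of SessionRecord
        One session per subject; all must have the same trial count.
    bounds : dict, optional
        Box constraints per parameter name; defaults to
        :data:`DEFAULT_BOUNDS`.
    restarts : int
        Number of starting points: the first is ``init`` (or the model
        defaults), the rest are drawn uniformly inside the bounds from
        ``seed``.  The best local optimum is returned.
    init : ModelParams, optional
        First starting point and the values at which non-free parameters
        are held fixed.
    free : iterable of str, optional
        Which of ``lam, theta, sigma_d, sigma_o, mu0, var0`` are optimized;
        all six by default.

    The fit is deterministic given ``seed``.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    init = init or ModelParams()
    free_names = tuple(free) if free is not None else PARAM_NAMES
    for name in free_names:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    free_idx = np.array([PARAM_NAMES.index(n) for n in free_names], dtype=int)

    choices, rewards, n_arms = _stack(sessions)
    x_full = np.array([getattr(init, n) for n in PARAM_NAMES], dtype=float)
    box = [bounds[n] for n in free_names]
    rng = np.random.default_rng(seed)

    starts = [x_full[free_idx]]
    for _ in range(restarts - 1):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in box]))

    best = None
    restart_nlls = []
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            _objective,
            x0,
            args=(free_idx, x_full, choices, rewards, n_arms),
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": 300},
        )
        restart_nlls.append(float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok:
        raise RuntimeError(
            f"no optimizer restart converged; restart NLLs: {restart_nlls}")

    x = x_full.copy()
    x[free_idx] = best.x
    pm = _premeans(choices, rewards, x, n_arms)
    betas, nlls = _profile_betas(pm, choices)

    params = ModelParams(**dict(zip(PARAM_NAMES, x)), beta=float(np.mean(betas)))
    subjects = [s.subject for s in sessions]
    per_subject = dict(zip(subjects, nlls.astype(float).tolist()))
    by_group: Dict[str, float] = {}
    for s, nl in zip(sessions, nlls):
        if s.group:
            by_group[s.group] = by_group.get(s.group, 0.0) + float(nl)
    return FitResult(
        params=params,
        betas=dict(zip(subjects, betas.astype(float).tolist())),
        per_subject_nll=per_subject,
        nll_total=float(nlls.sum()),
        nll_by_group=by_group,
        converged=bool(best.success),
        n_iterations=int(best.nit),
        n_restarts=restarts,
        restart_nlls=restart_nlls,
    )


def compare_group_betas(fit_result: FitResult, groups: Dict[str, str]) -> dict:
    """Pooled-variance two-sample t-test on fitted betas between two groups.

    Returns ``{"t": ..., "df": n1 + n2 - 2, "p": ...}`` (two-sided).
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = [b for s, b in fit_result.betas.items() if groups.get(s) == names[0]]
    b = [b for s, b in fit_result.betas.items() if groups.get(s) == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": len(a) + len(b) - 2, "p": float(p),
            "groups": names, "means": [float(np.mean(a)), float(np.mean(b))]}
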