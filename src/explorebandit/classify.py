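"""Model-based explore/exploit labelling of bandit choices.

A responded trial is *exploitative* when the chosen arm is the one currently
believed to have the highest value (within a tiny tie tolerance), and
*explorative* when any other arm was chosen.  Beliefs are reconstructed with
a fixed parameter set — typically the cohort-level maximum-likelihood fit —
by replaying the session through the Kalman filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, diffuse, init_beliefs, kalman_update
from .records import SessionRecord

__all__ = ["TrialLabels", "label_trials", "TIE_TOL"]

#: ties in believed value within this many points count as exploit — choosing
#: an arm *other than* the believed best implies strict inferiority.
TIE_TOL = 1e-9

EXPLOIT, EXPLORE, MISSED_LABEL = "exploit", "explore", "missed"


@dataclass
class TrialLabels:
    """Per-trial explore/exploit/missed labels for one session."""

    subject: str
    labels: np.ndarray  # array of str, aligned with the session's trials

    @property
    def counts(self) -> dict:
        vals, cts = np.unique(self.labels, return_counts=True)
        out = {EXPLOIT: 0, EXPLORE: 0, MISSED_LABEL: 0}
        out.update(dict(zip(vals, cts.astype(int).tolist())))
        return out

    @property
    def proportions(self) -> dict:
        """Explore/exploit proportions over responded trials (sum to 1)."""
        c = self.counts
        n = c[EXPLOIT] + c[EXPLORE]
        if n == 0:
            return {EXPLOIT: float("nan"), EXPLORE: float("nan")}
        return {EXPLOIT: c[EXPLOIT] / n, EXPLORE: c[EXPLORE] / n}


def label_trials(session: SessionRecord, params: ModelParams) -> TrialLabels:
    """Label every trial of a session as exploit, explore or missed.

    The belief walk is exactly the one used for the session likelihood:
    Kalman update after each responded trial, diffusion-only step after each
    missed trial.  Because all arms share the same initial prior, trial 1 is
    a tie and is labelled exploit by the tie rule (this affects counts by at
    most one trial).
    """
    n_arms = max(4, int(session.choice.max()) + 1)
    belief = init_beliefs(params, n_arms=n_arms)
    labels = np.empty(session.n_trials, dtype=object)
    for t in range(session.n_trials):
        if session.missed[t]:
            labels[t] = MISSED_LABEL
            belief = diffuse(belief, params)
            continue
        arm = int(session.choice[t])
        best = float(belief.pre_mean.max())
        labels[t] = EXPLOIT if belief.pre_mean[arm] >= best - TIE_TOL else EXPLORE
        belief = kalman_update(belief, arm, float(session.reward[t]), params)
    return TrialLabels(subject=session.subject, labels=np.asarray(labels, dtype=str))
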