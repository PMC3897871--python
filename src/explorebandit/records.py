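"""Trial-level session records shared by the simulator, model and statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSED = -1  # sentinel arm index for trials with no response


@dataclass
class SessionRecord:
    """One subject's log of a full bandit session.

    Arrays are aligned by trial (length ``n_trials``). On a missed trial
    ``choice`` is :data:`MISSED`, ``reward`` is 0 (no points are awarded when
    the response window lapses) and ``rt`` is NaN.

    Parameters
    ----------
    subject : str
        Subject identifier.
    group : str
        Group label (e.g. ``"entrepreneur"`` or ``"manager"``).
    run : ndarray of int
        1-based scanner-run index per trial.
    trial : ndarray of int
        1-based global trial index.
    choice : ndarray of int
        0-based chosen arm, or :data:`MISSED`.
    reward : ndarray of float
        Points obtained on the trial.
    rt : ndarray of float
        Response time in seconds; NaN when missed.
    missed : ndarray of bool
        True where no response was registered.
    """

    subject: str
    group: str
    run: np.ndarray
    trial: np.ndarray
    choice: np.ndarray
    reward: np.ndarray
    rt: np.ndarray
    missed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.run = np.asarray(self.run, dtype=int)
        self.trial = np.asarray(self.trial, dtype=int)
        self.choice = np.asarray(self.choice, dtype=int)
        self.reward = np.asarray(self.reward, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.missed is None:
            self.missed = self.choice == MISSED
        self.missed = np.asarray(self.missed, dtype=bool)
        n = len(self.trial)
        for name in ("run", "choice", "reward", "rt", "missed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has length != n_trials")

    @property
    def n_trials(self) -> int:
        return len(self.trial)

    @property
    def responded(self) -> np.ndarray:
        """Boolean mask of trials on which a choice was registered."""
        return ~self.missed

    @property
    def n_responded(self) -> int:
        return int(self.responded.sum())

    @property
    def total_payoff(self) -> float:
        return float(self.reward[self.responded].sum())

    @property
    def mean_rt(self) -> float:
        """Mean response time over responded trials, seconds."""
        if self.n_responded == 0:
            return float("nan")
        return float(np.nanmean(self.rt[self.responded]))
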