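"""Plain-text readers and writers for every pipeline artifact.

Sessions, payoff schedules, trial labels and ROI tables travel as CSV;
configurations and fit reports as JSON.  All writers round-trip through the
matching reader without loss.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .classify import TrialLabels
from .fitting import FitResult
from .model import ModelParams
from .records import SessionRecord
from .roi import ROIBetaTable
from .task import PayoffSchedule, TaskConfig

__all__ = [
    "write_sessions", "read_sessions",
    "write_schedule", "read_schedule",
    "write_labels", "read_labels",
    "write_roi_table", "read_roi_table",
    "write_fit_result", "read_fit_result",
]


def write_sessions(sessions: Sequence[SessionRecord], path) -> None:
    """Write trial logs as one CSV: subject, group, run, trial, choice,
    reward, rt, missed.  Missed trials carry choice -1 and an empty RT."""
    frames = []
    for s in sessions:
        frames.append(pd.DataFrame({
            "subject": s.subject, "group": s.group, "run": s.run,
            "trial": s.trial, "choice": s.choice, "reward": s.reward,
            "rt": s.rt, "missed": s.missed.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_sessions(path) -> List[SessionRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    sessions = []
    for (subject, group), sub in df.groupby(["subject", "group"], sort=False):
        sub = sub.sort_values("trial")
        sessions.append(SessionRecord(
            subject=str(subject), group=str(group),
            run=sub["run"].to_numpy(), trial=sub["trial"].to_numpy(),
            choice=sub["choice"].to_numpy(), reward=sub["reward"].to_numpy(),
            rt=sub["rt"].to_numpy(), missed=sub["missed"].to_numpy().astype(bool),
        ))
    return sessions


def write_schedule(schedule: PayoffSchedule, path) -> None:
    """Long-format schedule CSV (trial, arm, latent_mean, payoff) plus a JSON
    sidecar (<path>.json) echoing the generating configuration and seed."""
    n_t, n_a = schedule.means.shape
    trial, arm = np.meshgrid(np.arange(1, n_t + 1), np.arange(1, n_a + 1), indexing="ij")
    pd.DataFrame({
        "trial": trial.ravel(), "arm": arm.ravel(),
        "latent_mean": schedule.means.ravel(), "payoff": schedule.payoffs.ravel(),
    }).to_csv(path, index=False, float_format="%.17g")
    sidecar = {"config": json.loads(schedule.config.to_json()), "seed": schedule.seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_schedule(path) -> PayoffSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    n_t = int(df["trial"].max())
    n_a = int(df["arm"].max())
    means = np.empty((n_t, n_a))
    payoffs = np.empty((n_t, n_a), dtype=int)
    means[df["trial"] - 1, df["arm"] - 1] = df["latent_mean"]
    payoffs[df["trial"] - 1, df["arm"] - 1] = df["payoff"]
    sidecar_path = Path(str(path) + ".json")
    config, seed = TaskConfig(), None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        config = TaskConfig(**sidecar["config"])
        seed = sidecar.get("seed")
    return PayoffSchedule(means=means, payoffs=payoffs, config=config, seed=seed)


def write_labels(labels: Dict[str, TrialLabels], path) -> None:
    rows = []
    for subject in labels:
        lab = labels[subject]
        for t, value in enumerate(lab.labels, start=1):
            rows.append({"subject": subject, "trial": t, "label": value})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path) -> Dict[str, TrialLabels]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for subject, sub in df.groupby("subject", sort=False):
        sub = sub.sort_values("trial")
        out[str(subject)] = TrialLabels(subject=str(subject),
                                        labels=sub["label"].to_numpy(dtype=str))
    return out


def write_roi_table(table: ROIBetaTable, path) -> None:
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_roi_table(path) -> ROIBetaTable:
    return ROIBetaTable(data=pd.read_csv(path, float_precision="round_trip"))


def write_fit_result(fit: FitResult, path) -> None:
    payload = {
        "params": json.loads(fit.params.to_json()),
        "betas": fit.betas,
        "per_subject_nll": fit.per_subject_nll,
        "nll_total": fit.nll_total,
        "nll_by_group": fit.nll_by_group,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "n_restarts": fit.n_restarts,
        "restart_nlls": list(fit.restart_nlls),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_result(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    return FitResult(
        params=ModelParams(**payload["params"]),
        betas=payload["betas"],
        per_subject_nll=payload["per_subject_nll"],
        nll_total=payload["nll_total"],
        nll_by_group=payload.get("nll_by_group", {}),
        converged=payload.get("converged", True),
        n_iterations=payload.get("n_iterations", 0),
        n_restarts=payload.get("n_restarts", 1),
        restart_nlls=payload.get("restart_nlls", []),
    )
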