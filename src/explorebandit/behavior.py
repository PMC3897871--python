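"""Decision-efficiency measures and the 2 x 2 mixed-design ANOVA.

Decision-making efficiency is performance divided by decision time: a
subject's total payoff (points) over responded trials divided by their mean
response time (seconds).  Efficiency, payoff and RT are each analysed in a
two-way mixed ANOVA with choice type (explore vs exploit) as the within-
subject factor and group as the between-subject factor.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import EXPLOIT, EXPLORE, TrialLabels
from .records import SessionRecord

__all__ = [
    "subject_efficiency",
    "efficiency_by_type",
    "efficiency_table",
    "mixed_anova",
    "cohort_summary",
]


def subject_efficiency(session: SessionRecord) -> float:
    """Overall efficiency: total payoff / mean RT, points per second."""
    if session.n_responded == 0:
        raise ValueError(f"subject {session.subject}: no responded trials")
    return session.total_payoff / session.mean_rt


def efficiency_by_type(
    session: SessionRecord, labels: TrialLabels, cell: str = "total"
) -> Dict[str, float]:
    """Efficiency for the explore and exploit trial subsets.

    Two cell definitions are supported.  ``"total"`` (default) is the
    literal reading of payoff-over-time: the cell's total payoff divided by
    its mean RT, so cells with more trials carry proportionally larger
    totals.  ``"per_trial"`` divides the cell's mean payoff per trial by its
    mean RT, removing the trial-count dependence.  A cell with no trials is
    returned as NaN.
    """
    if cell not in ("total", "per_trial"):
        raise ValueError("cell must be 'total' or 'per_trial'")
    out = {}
    for lab in (EXPLORE, EXPLOIT):
        mask = (labels.labels == lab) & session.responded
        if not mask.any():
            out[lab] = float("nan")
            continue
        pay = session.reward[mask]
        mean_rt = float(np.mean(session.rt[mask]))
        num = float(pay.sum()) if cell == "total" else float(pay.mean())
        out[lab] = num / mean_rt
    return out


def efficiency_table(
    sessions: Sequence[SessionRecord],
    labels: Dict[str, TrialLabels],
    cell: str = "total",
) -> pd.DataFrame:
    """Per-subject efficiency table with explore/exploit cells.

    One row per subject with group, total payoff, mean RT, overall
    efficiency, and — under both cell definitions — explore and exploit
    cell payoff, mean RT and efficiency.  The ``cell`` argument selects
    which definition downstream ANOVAs use via the plain
    ``explore_efficiency`` / ``exploit_efficiency`` columns.
    """
    rows = []
    for s in sessions:
        lab = labels[s.subject]
        row = {
            "subject": s.subject,
            "group": s.group,
            "payoff": s.total_payoff,
            "mean_rt": s.mean_rt,
            "efficiency": subject_efficiency(s),
        }
        for variant in ("total", "per_trial"):
            eff = efficiency_by_type(s, lab, cell=variant)
            suffix = "" if variant == cell else f"_{variant}"
            for cond in (EXPLORE, EXPLOIT):
                row[f"{cond}_efficiency{suffix}"] = eff[cond]
        for cond in (EXPLORE, EXPLOIT):
            mask = (lab.labels == cond) & s.responded
            row[f"{cond}_payoff"] = float(s.reward[mask].sum())
            row[f"{cond}_mean_rt"] = float(np.mean(s.rt[mask])) if mask.any() else float("nan")
            row[f"{cond}_n"] = int(mask.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_anova(data: pd.DataFrame, value: str = "value") -> list[dict]:
    """Two-way mixed ANOVA: one within factor (2 levels), one between factor.

    ``data`` is long format with columns ``subject``, ``group``,
    ``condition`` and the value column.  Every subject must have exactly one
    value per condition; unbalanced group sizes are allowed and handled with
    unweighted (Type-III style) cell means.  With n subjects all three
    effects are F(1, n-2) tests:

    * group — between-subject, tested against between-subject error
      (equivalent to a pooled t-test on subject means across conditions);
    * condition — within-subject, tested against the subject-by-condition
      error on difference scores;
    * interaction — group difference of the within-subject difference.

    Returns a list of records ``{"effect", "F", "df1", "df2", "p"}``.
    """
    required = {"subject", "group", "condition", value}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    conds = sorted(data["condition"].unique())
    if len(conds) != 2:
        raise ValueError("exactly two within-subject conditions required")
    wide = data.pivot_table(index=["subject", "group"], columns="condition",
                            values=value, aggfunc="first")
    bad = wide.index[wide.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"subject {bad[0][0]!r} is missing a condition value")
    wide = wide.reset_index()
    groups = sorted(wide["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    n = len(wide)
    if n < 4:
        raise ValueError("need at least 2 subjects per group")
    df2 = n - 2

    # between effect: pooled t on per-subject condition means
    m = wide[conds].mean(axis=1).to_numpy()
    g0 = m[wide["group"] == groups[0]]
    g1 = m[wide["group"] == groups[1]]
    t_b, p_b = stats.ttest_ind(g0, g1, equal_var=True)
    results = [{"effect": "group", "F": float(t_b**2), "df1": 1, "df2": df2,
                "p": float(p_b)}]

    # within + interaction: OLS of difference scores on effect-coded group
    d = (wide[conds[0]] - wide[conds[1]]).to_numpy()
    g = np.where(wide["group"] == groups[0], 1.0, -1.0)
    X = np.column_stack([np.ones(n), g])
    coef, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ coef
    sigma2 = float(resid @ resid) / df2
    cov = sigma2 * np.linalg.inv(X.T @ X)
    for name, j in (("condition", 0), ("interaction", 1)):
        if cov[j, j] == 0.0:  # degenerate: no subject-by-condition variance
            F = 0.0 if coef[j] == 0.0 else float("inf")
        else:
            F = float(coef[j] ** 2 / cov[j, j])
        results.append({"effect": name, "F": F, "df1": 1, "df2": df2,
                        "p": float(stats.f.sf(F, 1, df2))})
    return results


def cohort_summary(table: pd.DataFrame,
                   variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Descriptive summary (N, mean, SD, min, max) overall and per group.

    SD uses the n-1 denominator and is NaN for a single subject.
    """
    if variables is None:
        variables = ["efficiency", "payoff", "mean_rt"]
    rows = []
    scopes = [("all", table)] + [
        (g, table[table["group"] == g]) for g in sorted(table["group"].unique())
    ]
    for var in variables:
        for scope, sub in scopes:
            x = sub[var].dropna().to_numpy()
            if len(x) == 0:
                continue
            rows.append({
                "variable": var, "scope": scope, "N": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
                "min": float(np.min(x)), "max": float(np.max(x)),
            })
    return pd.DataFrame(rows)
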