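"""Second-level statistics on ROI activity tables.

All operations start from tabular per-subject, per-condition activity
estimates (BOLD parameter-estimate units) extracted upstream from 8 mm
spheres at fixed MNI coordinates; image handling is out of scope here.
Three analyses are provided: the explore-vs-exploit contrast per ROI, the
choice-type x group mixed ANOVA on one ROI, and an ordinary least squares
regression of per-subject decision efficiency on group membership plus the
explore and exploit estimates of the analysis ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .behavior import mixed_anova
from .classify import EXPLOIT, EXPLORE

__all__ = [
    "ROIDef",
    "ROI_REGISTRY",
    "REGRESSION_ROIS",
    "ROIBetaTable",
    "roi_contrast",
    "roi_mixed_anova",
    "efficiency_regression",
]


@dataclass(frozen=True)
class ROIDef:
    """A spherical region of interest in MNI space."""

    name: str
    center: Tuple[int, int, int]  # MNI mm
    source: str
    radius: float = 8.0


#: The ROI set used by the second-level analyses: ventromedial prefrontal
#: cortex, bilateral frontopolar cortex and intraparietal sulcus from a
#: value-tracking bandit study; a second right-FPC sphere from a study of
#: switching between alternatives; dorsal anterior cingulate from a foraging
#: study; and bilateral locus coeruleus from a neuromelanin-based anatomical
#: localization.
ROI_REGISTRY: Dict[str, ROIDef] = {
    r.name: r
    for r in [
        ROIDef("vmPFC", (-3, 33, -6), "value-tracking study"),
        ROIDef("lFPC", (-27, 48, 4), "value-tracking study"),
        ROIDef("rFPC", (27, 57, 6), "value-tracking study"),
        ROIDef("lIPS", (-29, -33, 45), "value-tracking study"),
        ROIDef("rIPS", (39, -36, 42), "value-tracking study"),
        ROIDef("rFPC_switch", (36, 54, 0), "switch-tracking study"),
        ROIDef("dACC", (-2, 21, 34), "foraging study"),
        ROIDef("lLC", (-4, -37, -23), "neuromelanin atlas"),
        ROIDef("rLC", (5, -37, -23), "neuromelanin atlas"),
    ]
}

#: ROIs entering the efficiency regression (those with reliable
#: explore/exploit differences; the locus coeruleus spheres are excluded).
REGRESSION_ROIS: Tuple[str, ...] = (
    "rFPC_switch", "lFPC", "rFPC", "dACC", "vmPFC", "lIPS", "rIPS",
)


@dataclass
class ROIBetaTable:
    """Long-format table of activity estimates: subject x ROI x condition.

    ``data`` columns: subject, group, roi, condition (explore/exploit),
    estimate.  Validation requires both condition entries for every
    subject x ROI pair present in the table.
    """

    data: pd.DataFrame
    registry: Dict[str, ROIDef] = field(default_factory=lambda: dict(ROI_REGISTRY))

    def __post_init__(self) -> None:
        required = {"subject", "group", "roi", "condition", "estimate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"ROI table must have columns {sorted(required)}")
        counts = self.data.groupby(["subject", "roi"])["condition"].nunique()
        if (counts < 2).any():
            subj, roi = counts[counts < 2].index[0]
            raise ValueError(f"subject {subj!r} lacks both conditions for ROI {roi!r}")

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject"].unique())

    @property
    def rois(self) -> list:
        return sorted(self.data["roi"].unique())

    def condition_values(self, roi: str) -> pd.DataFrame:
        """Wide subject x condition estimates for one ROI."""
        sub = self.data[self.data["roi"] == roi]
        if sub.empty:
            raise ValueError(f"no entries for ROI {roi!r}")
        return sub.pivot_table(index=["subject", "group"], columns="condition",
                               values="estimate", aggfunc="first").reset_index()


def roi_contrast(table: ROIBetaTable, roi: str, paired: bool = False) -> dict:
    """Explore-vs-exploit contrast of activity in one ROI.

    Default is the unpaired pooled-variance t across the 2n condition
    estimates (df = 2n - 2), treating the explore and exploit sets as
    independent samples; ``paired=True`` gives the within-subject paired t
    (df = n - 1).  The reported direction names the larger condition, and
    p is two-sided.
    """
    wide = table.condition_values(roi)
    x = wide[EXPLORE].to_numpy(dtype=float)
    y = wide[EXPLOIT].to_numpy(dtype=float)
    n = len(x)
    if paired:
        t, p = stats.ttest_rel(x, y)
        df = n - 1
    else:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df = 2 * n - 2
    direction = "explore > exploit" if t >= 0 else "exploit > explore"
    return {"roi": roi, "t": float(t), "df": df, "p": float(p),
            "direction": direction, "n_subjects": n}


def roi_mixed_anova(table: ROIBetaTable, roi: str) -> list[dict]:
    """Choice-type x group mixed ANOVA on one ROI's condition estimates."""
    sub = table.data[table.data["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no entries for ROI {roi!r}")
    long = sub.rename(columns={"estimate": "value"})[
        ["subject", "group", "condition", "value"]
    ]
    return mixed_anova(long)


def efficiency_regression(
    table: ROIBetaTable,
    efficiency: Dict[str, float],
    group_indicator: Optional[Dict[str, int]] = None,
    rois: Sequence[str] = REGRESSION_ROIS,
    standardize: bool = False,
) -> dict:
    """OLS of per-subject efficiency on group + ROI condition estimates.

    The design has an intercept, a 0/1 group-membership indicator and one
    regressor per (ROI, condition) pair — 15 regressors for the default
    7-ROI set, giving overall F degrees of freedom (k, n - k - 1).
    Estimates enter the design raw by default; ``standardize=True``
    z-scores the ROI columns first.

    ``group_indicator`` maps subject to 0/1; if omitted, the
    lexicographically *later* group label is coded 1.

    Returns a dict with the coefficient table (estimate, se, t, p), R^2,
    adjusted R^2 and the overall F test.
    """
    subjects = table.subjects
    missing = [s for s in subjects if s not in efficiency]
    if missing:
        raise ValueError(f"efficiency missing for subjects {missing[:3]}")
    if group_indicator is None:
        glab = table.data.drop_duplicates("subject").set_index("subject")["group"]
        hi = sorted(glab.unique())[-1]
        group_indicator = {s: int(glab[s] == hi) for s in subjects}

    cols = {"group": [float(group_indicator[s]) for s in subjects]}
    for roi in rois:
        wide = table.condition_values(roi).set_index("subject")
        for cond in (EXPLORE, EXPLOIT):
            cols[f"{roi}_{cond}"] = [float(wide.loc[s, cond]) for s in subjects]
    X = pd.DataFrame(cols, index=subjects)
    if standardize:
        roi_cols = [c for c in X.columns if c != "group"]
        X[roi_cols] = (X[roi_cols] - X[roi_cols].mean()) / X[roi_cols].std(ddof=1)
    y = pd.Series([efficiency[s] for s in subjects], index=subjects)

    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        _, r = np.linalg.qr(Xc.to_numpy())
        dep = [Xc.columns[j] for j in range(Xc.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {dep}")
    res = sm.OLS(y, Xc).fit()
    coefs = pd.DataFrame({
        "estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    k = X.shape[1]
    n = len(y)
    return {
        "coefficients": coefs,
        "r2": float(res.rsquared),
        "adj_r2": float(res.rsquared_adj),
        "F": float(res.fvalue),
        "df1": k,
        "df2": n - k - 1,
        "f_pvalue": float(res.f_pvalue),
        "n": n,
    }
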