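"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain loops and textbook
formulas, sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_session_nll(choices, rewards, missed, lam, theta, sigma_d, sigma_o,
                      mu0, var0, beta, n_arms=4):
    """Stepwise likelihood walk with explicit per-arm loops."""
    mean = [mu0] * n_arms
    var = [var0] * n_arms
    nll = 0.0
    for t in range(len(choices)):
        if missed[t]:
            mean = [lam * m + (1 - lam) * theta for m in mean]
            var = [lam**2 * v + sigma_d**2 for v in var]
            continue
        c = int(choices[t])
        mx = max(beta * m for m in mean)
        z = [math.exp(beta * m - mx) for m in mean]
        nll -= math.log(z[c] / sum(z))
        denom = var[c] + sigma_o**2
        kappa = 1.0 if denom < 1e-12 else var[c] / denom
        mean[c] = mean[c] + kappa * (rewards[t] - mean[c])
        var[c] = (1 - kappa) * var[c]
        mean = [lam * m + (1 - lam) * theta for m in mean]
        var = [lam**2 * v + sigma_d**2 for v in var]
    return nll


def glm_mixed_anova(values, groups):
    """Mixed 2x2 ANOVA by design-matrix projection (model comparison).

    ``values``: (n, 2) array of per-subject condition values;
    ``groups``: length-n array of 0/1 between-group codes.
    Returns dict effect -> (F, df1, df2).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)

    # between: one-way ANOVA on per-subject means across conditions
    m = values.mean(axis=1)
    grand = m.mean()
    ss_between = sum(
        len(m[groups == g]) * (m[groups == g].mean() - grand) ** 2
        for g in np.unique(groups)
    )
    ss_within = sum(((m[groups == g] - m[groups == g].mean()) ** 2).sum()
                    for g in np.unique(groups))
    F_group = (ss_between / 1) / (ss_within / (n - 2))

    # within + interaction: full GLM with subject dummies, effect-coded
    # condition, and condition x group; partial F by model comparison
    y = values.ravel()  # subject-major: (s0c0, s0c1, s1c0, ...)
    cond = np.tile([1.0, -1.0], n)
    g = np.repeat(np.where(groups == np.unique(groups)[0], 1.0, -1.0), 2)
    subj = np.kron(np.eye(n), np.ones((2, 1)))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.column_stack([subj, cond, cond * g])
    rss_full = rss(X_full)
    df_err = 2 * n - (n + 2)
    out = {"group": (float(F_group), 1, n - 2)}
    for name, drop in (("condition", n), ("interaction", n + 1)):
        X_red = np.delete(X_full, drop, axis=1)
        F = (rss(X_red) - rss_full) / (rss_full / df_err)
        out[name] = (float(F), 1, df_err)
    return out


def normal_equations_ols(X, y):
    """OLS estimates, SEs, R2, adjusted R2 and overall F from X'X directly.

    ``X`` must already contain the intercept column (first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    k = p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    F = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return {"beta": beta, "se": se, "r2": r2, "adj_r2": adj, "F": F,
            "df": (k, n - k - 1)}


def pooled_t(x, y):
    """Textbook pooled-variance two-sample t statistic and df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, nx + ny - 2
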