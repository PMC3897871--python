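"""Second-level ROI statistics: contrasts, interaction ANOVA, regression."""

import numpy as np
import pandas as pd
import pytest

from explorebandit import (
    ROI_REGISTRY,
    REGRESSION_ROIS,
    ROIBetaTable,
    efficiency_regression,
    roi_contrast,
    roi_mixed_anova,
)
from helpers_oracles import normal_equations_ols, pooled_t


def _make_table(rng, n=50, rois=("vmPFC", "rFPC"), effects=None, groups=None):
    effects = effects or {}
    rows = []
    for i in range(n):
        g = groups[i] if groups is not None else ("ent" if i < n // 2 else "man")
        for roi in rois:
            d = effects.get(roi, 0.0)
            for cond, sign in (("explore", 0.5), ("exploit", -0.5)):
                rows.append({"subject": f"s{i:02d}", "group": g, "roi": roi,
                             "condition": cond,
                             "estimate": float(sign * 2 * d * 0.5 + rng.normal(0, 1))})
    return ROIBetaTable(data=pd.DataFrame(rows))


class TestRegistry:
    def test_contains_all_analysis_rois(self):
        expected = {"vmPFC", "lFPC", "rFPC", "lIPS", "rIPS", "rFPC_switch",
                    "dACC", "lLC", "rLC"}
        assert expected == set(ROI_REGISTRY)
        assert all(r.radius == 8.0 for r in ROI_REGISTRY.values())
        assert ROI_REGISTRY["vmPFC"].center == (-3, 33, -6)
        assert ROI_REGISTRY["dACC"].center == (-2, 21, 34)
        assert ROI_REGISTRY["rFPC_switch"].center == (36, 54, 0)


class TestContrast:
    def test_df_is_2n_minus_2(self, rng):
        table = _make_table(rng, n=50)
        out = roi_contrast(table, "vmPFC")
        assert out["df"] == 98
        paired = roi_contrast(table, "vmPFC", paired=True)
        assert paired["df"] == 49

    def test_identical_conditions_t_zero(self):
        rows = []
        for i in range(10):
            for cond in ("explore", "exploit"):
                rows.append({"subject": f"s{i}", "group": "g", "roi": "dACC",
                             "condition": cond, "estimate": float(i)})
        out = roi_contrast(ROIBetaTable(data=pd.DataFrame(rows)), "dACC")
        assert out["t"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_effect_matches_pooled_formula(self, rng):
        table = _make_table(rng, n=50, effects={"rFPC": 1.0})
        out = roi_contrast(table, "rFPC")
        wide = table.condition_values("rFPC")
        t_ref, df_ref = pooled_t(wide["explore"], wide["exploit"])
        assert out["t"] == pytest.approx(t_ref, abs=1e-9)
        assert out["df"] == df_ref
        assert out["direction"] == "explore > exploit"

    def test_subject_order_invariance(self, rng):
        table = _make_table(rng, n=20, effects={"vmPFC": -0.8})
        shuffled = ROIBetaTable(
            data=table.data.sample(frac=1.0, random_state=3).reset_index(drop=True))
        assert roi_contrast(table, "vmPFC")["t"] == pytest.approx(
            roi_contrast(shuffled, "vmPFC")["t"], abs=1e-12)

    def test_missing_condition_rejected(self):
        rows = [{"subject": "s0", "group": "g", "roi": "vmPFC",
                 "condition": "explore", "estimate": 1.0}]
        with pytest.raises(ValueError):
            ROIBetaTable(data=pd.DataFrame(rows))


class TestInteractionAnova:
    def test_df_and_delegation(self, rng):
        table = _make_table(rng, n=50, rois=("rFPC_switch",))
        recs = {r["effect"]: r for r in roi_mixed_anova(table, "rFPC_switch")}
        assert (recs["interaction"]["df1"], recs["interaction"]["df2"]) == (1, 48)

    def test_interaction_f_grows_with_planted_effect(self):
        """The choice-by-group interaction F increases, in expectation, with
        the planted group difference in explore-exploit activity."""
        mean_f = []
        for delta in (0.0, 0.8, 1.6):
            fs = []
            for rep in range(30):
                rng = np.random.default_rng(1000 * rep + int(delta * 10))
                rows = []
                for i in range(50):
                    g = "ent" if i < 24 else "man"
                    d = rng.normal(delta if g == "ent" else 0.0, 1.0)
                    for cond, sign in (("explore", 0.5), ("exploit", -0.5)):
                        rows.append({"subject": f"s{i}", "group": g,
                                     "roi": "rFPC_switch", "condition": cond,
                                     "estimate": float(sign * d + rng.normal(0, 1))})
                table = ROIBetaTable(data=pd.DataFrame(rows))
                recs = {r["effect"]: r for r in roi_mixed_anova(table, "rFPC_switch")}
                fs.append(recs["interaction"]["F"])
            mean_f.append(np.mean(fs))
        assert mean_f[0] < mean_f[1] < mean_f[2]


class TestEfficiencyRegression:
    def _full_table(self, rng, n=50):
        return _make_table(rng, n=n, rois=tuple(ROI_REGISTRY))

    def test_study_sized_df(self, rng):
        table = self._full_table(rng)
        eff = {s: float(rng.normal(44000, 9000)) for s in table.subjects}
        out = efficiency_regression(table, eff)
        assert (out["df1"], out["df2"]) == (15, 34)
        assert len(out["coefficients"]) == 16  # intercept + group + 14 ROI terms

    def test_exact_linear_relation_r2_one(self, rng):
        table = self._full_table(rng)
        wide = {}
        for roi in REGRESSION_ROIS:
            w = table.condition_values(roi).set_index("subject")
            wide[f"{roi}_explore"] = w["explore"]
            wide[f"{roi}_exploit"] = w["exploit"]
        eff = {s: 3.0 + 2.0 * wide["rFPC_explore"][s] - 1.5 * wide["vmPFC_exploit"][s]
               for s in table.subjects}
        out = efficiency_regression(table, eff)
        assert out["r2"] == pytest.approx(1.0)
        assert out["adj_r2"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(60):
            table = _make_table(rng, n=int(rng.integers(12, 25)),
                                rois=("vmPFC", "rFPC", "dACC"))
            eff = {s: float(rng.normal(0, 1)) for s in table.subjects}
            out = efficiency_regression(table, eff, rois=("vmPFC", "rFPC", "dACC"))
            subjects = table.subjects
            X = [np.ones(len(subjects))]
            glab = table.data.drop_duplicates("subject").set_index("subject")["group"]
            hi = sorted(glab.unique())[-1]
            X.append(np.array([float(glab[s] == hi) for s in subjects]))
            for roi in ("vmPFC", "rFPC", "dACC"):
                w = table.condition_values(roi).set_index("subject")
                X.append(w.loc[subjects, "explore"].to_numpy())
                X.append(w.loc[subjects, "exploit"].to_numpy())
            ref = normal_equations_ols(np.column_stack(X), [eff[s] for s in subjects])
            assert np.allclose(out["coefficients"]["estimate"].to_numpy(), ref["beta"],
                               atol=1e-8)
            assert np.allclose(out["coefficients"]["se"].to_numpy(), ref["se"], atol=1e-8)
            assert out["r2"] == pytest.approx(ref["r2"], abs=1e-10)
            assert out["F"] == pytest.approx(ref["F"], rel=1e-8)

    def test_adjusted_r2_identity(self, rng):
        table = _make_table(rng, n=30, rois=("vmPFC", "rFPC"))
        eff = {s: float(rng.normal(0, 1)) for s in table.subjects}
        out = efficiency_regression(table, eff, rois=("vmPFC", "rFPC"))
        n, k = out["n"], out["df1"]
        assert out["adj_r2"] == pytest.approx(
            1 - (1 - out["r2"]) * (n - 1) / (n - k - 1), abs=1e-12)

    def test_rank_deficient_design_names_columns(self, rng):
        table = _make_table(rng, n=20, rois=("vmPFC", "rFPC"))
        dup = table.data.copy()
        # make dACC an exact copy of vmPFC -> collinear columns
        extra = dup[dup.roi == "vmPFC"].assign(roi="dACC")
        table2 = ROIBetaTable(data=pd.concat([dup, extra], ignore_index=True))
        eff = {s: float(rng.normal(0, 1)) for s in table2.subjects}
        with pytest.raises(ValueError, match="collinear"):
            efficiency_regression(table2, eff, rois=("vmPFC", "rFPC", "dACC"))

    def test_planted_signs_recovered_in_most_replicates(self):
        """With effects planted at the observed sign pattern and noise at the
        default calibration, the group and rFPC-exploit coefficients keep
        their signs in >= 90% of replicate tables."""
        from explorebandit import (CohortConfig, generate_cohort,
                                   generate_roi_table, subject_efficiency)
        sessions, groups = generate_cohort(CohortConfig(), seed=3)
        eff = {s.subject: subject_efficiency(s) for s in sessions}
        ent = {s: int(groups[s] == "entrepreneur") for s in groups}
        eff_hits = group_hits = 0
        reps = 100
        for rep in range(reps):
            table = generate_roi_table(sessions, groups, seed=rep)
            out = efficiency_regression(table, eff, group_indicator=ent)
            coefs = out["coefficients"]
            group_hits += coefs.loc["group", "estimate"] > 0
            eff_hits += coefs.loc["rFPC_exploit", "estimate"] > 0
        assert group_hits >= 0.9 * reps
        assert eff_hits >= 0.9 * reps
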