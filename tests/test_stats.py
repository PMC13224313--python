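"""Delta features, rmcorr, permutation ANOVA, Friedman/Wilcoxon, screening."""

import numpy as np
import pandas as pd
import pytest

from avbci.stats import (
    ParamScreenRow,
    RmcorrResult,
    delta_features,
    friedman_learning,
    hit_miss_compare,
    permutation_anova,
    rmcorr,
    screen_rmcorr,
    select_correlated_params,
    wilcoxon_condition,
    _two_way_f,
)


def _features(rows):
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "condition", "theta_k", "min_dur_ms",
                 "lambda_av_ms", "alpha_av"],
    )


class TestDeltas:
    def _tab(self):
        return _features([
            ("a", 1, "MI", 3.0, 50.0, 14.0, 5.0),
            ("a", 1, "Rest", 3.0, 50.0, 10.0, 4.0),
        ])

    def test_mi_minus_rest_default(self):
        out = delta_features(self._tab())
        assert out["d_lambda_ms"].iloc[0] == pytest.approx(4.0)
        assert out["d_alpha"].iloc[0] == pytest.approx(1.0)
        assert out.attrs["convention"] == "mi_minus_rest"

    def test_printed_orientation_flag(self):
        out = delta_features(self._tab(), convention="rest_minus_mi")
        assert out["d_lambda_ms"].iloc[0] == pytest.approx(-4.0)

    def test_identical_conditions_zero(self):
        tab = _features([
            ("a", 1, "MI", 3.0, 50.0, 10.0, 4.0),
            ("a", 1, "Rest", 3.0, 50.0, 10.0, 4.0),
        ])
        out = delta_features(tab)
        assert out["d_lambda_ms"].iloc[0] == 0.0

    def test_missing_condition_errors(self):
        tab = _features([
            ("a", 1, "MI", 3.0, 50.0, 10.0, 4.0),
            ("b", 1, "MI", 3.0, 50.0, 11.0, 4.0),
            ("b", 1, "Rest", 3.0, 50.0, 9.0, 4.0),
        ])
        with pytest.raises(ValueError, match="Rest"):
            delta_features(tab)


def _rmcorr_oracle(x, y, subjects):
    """Dummy-coded least-squares ANCOVA fit, solved with lstsq."""
    subs = pd.get_dummies(pd.Series(subjects)).to_numpy(dtype=float)
    design_full = np.column_stack([subs, x])
    beta_full, *_ = np.linalg.lstsq(design_full, y, rcond=None)
    resid_full = y - design_full @ beta_full
    beta_red, *_ = np.linalg.lstsq(subs, y, rcond=None)
    resid_red = y - subs @ beta_red
    ss_full = resid_full @ resid_full
    ss_red = resid_red @ resid_red
    slope = beta_full[-1]
    if ss_red == 0:
        return 0.0, 0.0
    r = np.sign(slope) * np.sqrt((ss_red - ss_full) / ss_red)
    return float(r), float(slope)


class TestRmcorr:
    def test_perfect_within_subject_slope(self):
        x = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        y = np.array([2, 4, 6, 12, 14, 16], dtype=float)
        subs = np.array(["A"] * 3 + ["B"] * 3)
        res = rmcorr(x, y, subs)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_matches_lstsq_oracle(self, rng):
        for _ in range(100):
            n_sub = int(rng.integers(3, 8))
            n_ses = int(rng.integers(2, 6))
            subs = np.repeat([f"s{i}" for i in range(n_sub)], n_ses)
            x = rng.standard_normal(n_sub * n_ses)
            y = rng.standard_normal(n_sub * n_ses)
            res = rmcorr(x, y, subs)
            r_oracle, slope_oracle = _rmcorr_oracle(x, y, subs)
            assert res.r == pytest.approx(r_oracle, abs=1e-10)
            assert res.slope == pytest.approx(slope_oracle, abs=1e-10)
            assert res.df == len(x) - n_sub - 1

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        subs = np.repeat([f"s{i}" for i in range(6)], 4)
        x = rng.standard_normal(24)
        y = 0.5 * x + rng.standard_normal(24)
        df = pd.DataFrame({"x": x, "y": y, "subject": subs})
        res = rmcorr(x, y, subs)
        pg = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(pg["pval"].iloc[0]), abs=1e-8)
        assert res.df == int(pg["dof"].iloc[0])

    def test_constant_y_within_subject(self):
        x = np.array([1.0, 2.0, 1.0, 3.0])
        y = np.array([5.0, 5.0, 7.0, 7.0])
        res = rmcorr(x, y, np.array(["a", "a", "b", "b"]))
        assert res.r == 0.0
        assert res.p == pytest.approx(1.0)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rmcorr(
                np.array([1.0, 1.0, 2.0, 2.0]),
                np.array([1.0, 2.0, 3.0, 4.0]),
                np.array(["a", "a", "b", "b"]),
            )

    def test_single_observation_subject_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            rmcorr(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                   np.array(["a", "a", "b"]))

    def test_affine_invariance(self, rng):
        subs = np.repeat(["a", "b", "c", "d"], 4)
        x = rng.standard_normal(16)
        y = rng.standard_normal(16)
        r1 = rmcorr(x, y, subs)
        r2 = rmcorr(3.5 * x + 11.0, y, subs)
        assert r1.r == pytest.approx(r2.r, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)


def _cube_to_features(cube):
    """(n_subjects, 2, n_sessions) -> long feature table (conditions Rest, MI)."""
    n, _, s = cube.shape
    rows = []
    for i in range(n):
        for ci, cond in enumerate(("Rest", "MI")):
            for ses in range(s):
                rows.append(
                    {"subject": f"s{i:02d}", "session": ses + 1, "condition": cond,
                     "lambda_av_ms": cube[i, ci, ses], "alpha_av": 0.0}
                )
    return pd.DataFrame(rows)


class TestPermutationAnova:
    def test_all_identical_gives_f0_p1(self):
        cube = np.full((6, 2, 4), 3.14)
        res = permutation_anova(_cube_to_features(cube), n_perm=200, seed=0)
        assert res.f_condition == 0.0 and res.f_session == 0.0
        assert res.p_condition == 1.0 and res.p_interaction == 1.0

    def test_planted_condition_shift_significant(self, rng):
        cube = rng.standard_normal((20, 2, 4))
        cube[:, 1, :] += 3.0  # 3 pooled-SD MI shift
        res = permutation_anova(_cube_to_features(cube), n_perm=10_000, seed=1)
        assert res.p_condition <= 0.001
        assert res.p_session > 0.05

    def test_seed_determinism(self, rng):
        feats = _cube_to_features(rng.standard_normal((8, 2, 3)))
        r1 = permutation_anova(feats, n_perm=300, seed=5)
        r2 = permutation_anova(feats, n_perm=300, seed=5)
        assert r1 == r2

    def test_observed_f_independent_of_n_perm(self, rng):
        feats = _cube_to_features(rng.standard_normal((8, 2, 3)))
        r1 = permutation_anova(feats, n_perm=100, seed=5)
        r2 = permutation_anova(feats, n_perm=1000, seed=9)
        assert r1.f_condition == pytest.approx(r2.f_condition)
        assert r1.f_session == pytest.approx(r2.f_session)
        assert r1.f_interaction == pytest.approx(r2.f_interaction)

    def test_f_matches_textbook_decomposition(self, rng):
        # cross-check against statsmodels OLS two-way ANOVA on one dataset
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        cube = rng.standard_normal((10, 2, 4))
        feats = _cube_to_features(cube)
        model = ols("lambda_av_ms ~ C(condition) * C(session)", data=feats).fit()
        table = sm.stats.anova_lm(model, typ=2)
        fa, fb, fab = _two_way_f(cube)
        assert fa == pytest.approx(table.loc["C(condition)", "F"], rel=1e-8)
        assert fb == pytest.approx(table.loc["C(session)", "F"], rel=1e-8)
        assert fab == pytest.approx(table.loc["C(condition):C(session)", "F"], rel=1e-8)

    def test_unbalanced_errors(self, rng):
        feats = _cube_to_features(rng.standard_normal((4, 2, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            permutation_anova(feats, n_perm=10, seed=0)

    def test_affine_invariance_of_p(self, rng):
        feats = _cube_to_features(rng.standard_normal((8, 2, 3)))
        r1 = permutation_anova(feats, n_perm=500, seed=3)
        feats2 = feats.copy()
        feats2["lambda_av_ms"] = 2.5 * feats2["lambda_av_ms"] + 7.0
        r2 = permutation_anova(feats2, n_perm=500, seed=3)
        assert r1.p_condition == r2.p_condition
        assert r1.p_session == r2.p_session
        assert r1.p_interaction == r2.p_interaction


class TestFriedmanWilcoxon:
    def test_friedman_hand_example(self):
        rows = []
        for i in range(3):
            for s, v in enumerate((1.0, 2.0, 3.0), start=1):
                rows.append({"subject": f"s{i}", "session": s, "condition": "MI",
                             "lambda_av_ms": v})
        stat, p = friedman_learning(pd.DataFrame(rows), "MI")
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.049787, abs=1e-5)

    def test_friedman_all_tied(self):
        rows = [
            {"subject": f"s{i}", "session": s, "condition": "MI", "lambda_av_ms": 2.0}
            for i in range(4) for s in (1, 2, 3)
        ]
        stat, p = friedman_learning(pd.DataFrame(rows), "MI")
        assert stat == 0.0 and p == 1.0

    def test_wilcoxon_all_positive_exact(self):
        rows = []
        for i in range(20):
            rows.append({"subject": f"s{i}", "session": 4, "condition": "MI",
                         "lambda_av_ms": 10.0 + i * 0.1})
            rows.append({"subject": f"s{i}", "session": 4, "condition": "Rest",
                         "lambda_av_ms": 5.0 + i * 0.05})
        stat, p = wilcoxon_condition(pd.DataFrame(rows), session=4)
        assert p == pytest.approx(2 * 2.0 ** -20, rel=1e-9)

    def test_wilcoxon_matches_enumeration_oracle(self, rng):
        from itertools import product

        diffs = rng.standard_normal(7)
        rows = []
        for i, d in enumerate(diffs):
            rows.append({"subject": f"s{i}", "session": 1, "condition": "MI",
                         "lambda_av_ms": d})
            rows.append({"subject": f"s{i}", "session": 1, "condition": "Rest",
                         "lambda_av_ms": 0.0})
        stat, p = wilcoxon_condition(pd.DataFrame(rows), session=1)
        # exact null: enumerate all sign assignments of the ranks
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        w_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in product([0, 1], repeat=7)
        ]
        w_all = np.array(w_all)
        n = len(w_all)
        p_exact = min(1.0, 2 * min((w_all <= w_obs).sum(), (w_all >= w_obs).sum()) / n)
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_wilcoxon_identical_errors(self):
        rows = []
        for i in range(5):
            for cond in ("MI", "Rest"):
                rows.append({"subject": f"s{i}", "session": 1, "condition": cond,
                             "lambda_av_ms": 4.0})
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_condition(pd.DataFrame(rows), session=1)


class TestSelection:
    def _row(self, k, d, feat, r, p):
        return ParamScreenRow(k, d, feat, RmcorrResult(r=r, df=10, p=p, slope=r))

    def test_no_significant_empty(self):
        screen = [self._row(1, 5, "d_lambda_ms", 0.1, 0.5)]
        assert select_correlated_params(screen) == []

    def test_significant_sorted_by_r(self):
        screen = [
            self._row(1, 5, "d_lambda_ms", 0.4, 0.01),
            self._row(2, 50, "d_alpha", 0.8, 0.001),
            self._row(3, 80, "d_lambda_ms", 0.2, 0.2),
        ]
        assert select_correlated_params(screen) == [(2, 50), (1, 5)]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_correlated_params([])

    def test_screen_restricts_sessions(self, rng):
        deltas = pd.DataFrame(
            {
                "subject": np.repeat(["a", "b", "c"], 4),
                "session": list(range(1, 5)) * 3,
                "theta_k": 3.0, "min_dur_ms": 50.0,
                "d_lambda_ms": rng.standard_normal(12),
                "d_alpha": rng.standard_normal(12),
            }
        )
        scores = pd.DataFrame(
            {"subject": np.repeat(["a", "b", "c"], 4),
             "session": list(range(1, 5)) * 3,
             "score": rng.uniform(40, 70, 12)}
        )
        full = screen_rmcorr(deltas, scores)
        train = screen_rmcorr(deltas, scores, sessions=[1, 2, 3])
        assert full[0].result.df == 12 - 3 - 1
        assert train[0].result.df == 9 - 3 - 1


class TestHitMiss:
    def _data(self, rng, shift=0.0):
        rows, outs = [], []
        for cond in ("MI", "Rest"):
            for t in range(1, 13):
                hit = t <= 6
                lam = rng.standard_normal() + (shift if (hit and cond == "MI") else 0)
                rows.append({"subject": "a", "session": 4, "condition": cond,
                             "trial": t, "lambda_av_ms": lam,
                             "alpha_av": rng.standard_normal()})
                outs.append({"subject": "a", "session": 4, "condition": cond,
                             "trial": t, "outcome": "Hit" if hit else "Miss"})
        return pd.DataFrame(rows), pd.DataFrame(outs)

    def test_planted_shift_detected(self, rng):
        ps = []
        for _ in range(10):
            trials, outcomes = self._data(rng, shift=3.0)
            tab = hit_miss_compare(trials, outcomes, session=4)
            row = tab[(tab["contrast"] == "MI-Hit vs MI-Miss")
                      & (tab["feature"] == "lambda_av_ms")]
            ps.append(float(row["p"].iloc[0]))
        assert np.median(ps) < 0.05

    def test_all_hit_errors(self, rng):
        trials, outcomes = self._data(rng)
        outcomes["outcome"] = "Hit"
        with pytest.raises(ValueError, match="empty group"):
            hit_miss_compare(trials, outcomes, session=4)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(40):
            trials, outcomes = self._data(rng, shift=0.0)
            tab = hit_miss_compare(trials, outcomes, session=4)
            ps.append(float(tab["p"].iloc[0]))
        # under the null, p-values should not pile up near 0
        assert (np.array(ps) < 0.05).mean() < 0.25
        assert np.median(ps) > 0.2
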