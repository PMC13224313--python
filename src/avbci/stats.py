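"""Statistical analyses: condition deltas, repeated-measures correlation,
permutation factorial ANOVA, Friedman/Wilcoxon effect tests, parameter
screening, and Hit/Miss trial comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Condition deltas
# ---------------------------------------------------------------------------

def delta_features(features: pd.DataFrame, convention: str = "mi_minus_rest") -> pd.DataFrame:
    """Per-(subject, session, params) MI/Rest differences of both features.

    ``convention`` is ``"mi_minus_rest"`` (default; positive when MI exceeds
    Rest) or ``"rest_minus_mi"``. The chosen convention is recorded in
    ``DataFrame.attrs["convention"]``.
    """
    if convention not in ("mi_minus_rest", "rest_minus_mi"):
        raise ValueError(f"unknown sign convention {convention!r}")
    keys = ["subject", "session", "theta_k", "min_dur_ms"]
    pivot = features.pivot_table(
        index=keys, columns="condition", values=["lambda_av_ms", "alpha_av"], aggfunc="first"
    )
    for cond in ("MI", "Rest"):
        if ("lambda_av_ms", cond) not in pivot.columns:
            raise ValueError(f"no {cond} rows at all")
        missing = pivot.index[pivot[("lambda_av_ms", cond)].isna()]
        if len(missing):
            raise ValueError(f"missing {cond} rows for keys: {list(missing[:5])}")
    sign = 1.0 if convention == "mi_minus_rest" else -1.0
    out = pd.DataFrame(
        {
            "d_lambda_ms": sign
            * (pivot[("lambda_av_ms", "MI")] - pivot[("lambda_av_ms", "Rest")]),
            "d_alpha": sign * (pivot[("alpha_av", "MI")] - pivot[("alpha_av", "Rest")]),
        }
    ).reset_index()
    out.attrs["convention"] = convention
    return out


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmcorrResult:
    """Common within-subject correlation from the subject-intercept ANCOVA."""

    r: float
    df: int
    p: float
    slope: float


def rmcorr(x: np.ndarray, y: np.ndarray, subjects: np.ndarray) -> RmcorrResult:
    """Repeated-measures correlation of paired longitudinal observations.

    Fits ``y ~ subject intercepts + common slope * x`` by least squares;
    r = sign(slope) * sqrt(SS_x / (SS_x + SS_err)) where SS_x is the sum of
    squares the common slope explains beyond the subject means. The p-value
    comes from the t distribution with ``df = n_obs - n_subjects - 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if x.shape != y.shape or x.shape != subjects.shape:
        raise ValueError("x, y and subjects must have identical shapes")
    uniq, idx = np.unique(subjects, return_inverse=True)
    n_obs, n_sub = x.size, uniq.size
    counts = np.bincount(idx)
    if (counts < 2).any():
        raise ValueError("every subject needs >= 2 paired observations")
    # within-subject centering == projecting out the subject dummies
    xc = x - np.bincount(idx, weights=x)[idx] / counts[idx]
    yc = y - np.bincount(idx, weights=y)[idx] / counts[idx]
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant within every subject; rmcorr undefined")
    slope = float(xc @ yc) / sxx
    ss_total = float(yc @ yc)          # residual SS of the intercepts-only fit
    ss_err = ss_total - slope**2 * sxx  # residual SS of the full fit
    ss_x = ss_total - ss_err
    df = n_obs - n_sub - 1
    if df <= 0:
        raise ValueError("not enough observations for the rmcorr df")
    if ss_total == 0.0:
        return RmcorrResult(r=0.0, df=df, p=1.0, slope=0.0)
    r = float(np.sign(slope) * np.sqrt(ss_x / ss_total)) if slope != 0 else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrResult(r=r, df=df, p=p, slope=slope)


# ---------------------------------------------------------------------------
# Permutation two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermAnovaResult:
    """Observed F and empirical p per effect from response-shuffle permutations."""

    f_condition: float
    f_session: float
    f_interaction: float
    p_condition: float
    p_session: float
    p_interaction: float
    n_perm: int
    seed: int


def _two_way_f(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced two-factor fixed-effects F statistics.

    ``y`` has shape (..., n_subjects, n_a, n_b): subjects are replicates
    within each (condition, session) cell. Degenerate 0/0 ratios are 0.
    """
    n, a, b = y.shape[-3:]
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    cell = y.mean(axis=-3, keepdims=True)                    # (..., 1, a, b)
    am = y.mean(axis=(-3, -1), keepdims=True)                # (..., 1, a, 1)
    bm = y.mean(axis=(-3, -2), keepdims=True)                # (..., 1, 1, b)
    ss_a = n * b * ((am - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = n * a * ((bm - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = n * ((cell - am - bm + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_err = ((y - cell) ** 2).sum(axis=(-3, -2, -1))
    df_a, df_b, df_ab, df_err = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_err = ss_err / df_err

    def _f(ss, dof):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / dof) / ms_err
        return np.where(ss == 0, 0.0, np.where(ms_err == 0, np.inf, f))

    return _f(ss_a, df_a), _f(ss_b, df_b), _f(ss_ab, df_ab)


def permutation_anova(
    features: pd.DataFrame,
    value: str = "lambda_av_ms",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermAnovaResult:
    """Permutation-based two-way (condition x session) ANOVA.

    The observed F statistics come from the balanced fixed-effects
    decomposition with subjects as within-cell replicates. The null is built
    by shuffling the full response vector across all (subject, condition,
    session) rows and recomputing all three effects from the same permuted
    vector. Empirical p uses the add-one estimator, so p is in (0, 1].
    """
    y = _layout_cube(features, value)
    f_obs = tuple(float(v) for v in _two_way_f(y))
    rng = np.random.default_rng(seed)
    flat = y.ravel()
    exceed = np.zeros(3, dtype=int)
    batch = 500
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        perms = np.empty((nb, flat.size))
        for i in range(nb):
            perms[i] = flat[rng.permutation(flat.size)]
        fp = _two_way_f(perms.reshape(nb, *y.shape))
        for j in range(3):
            exceed[j] += int((fp[j] >= f_obs[j]).sum())
        done += nb
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermAnovaResult(
        f_condition=f_obs[0], f_session=f_obs[1], f_interaction=f_obs[2],
        p_condition=float(p[0]), p_session=float(p[1]), p_interaction=float(p[2]),
        n_perm=n_perm, seed=seed,
    )


def _layout_cube(features: pd.DataFrame, value: str) -> np.ndarray:
    """Pivot a one-value-per-cell table to (n_subjects, n_cond, n_sessions)."""
    subjects = np.sort(features["subject"].unique())
    sessions = np.sort(features["session"].unique())
    conds = ["Rest", "MI"]
    pivot = features.pivot_table(
        index="subject", columns=["condition", "session"], values=value, aggfunc="first"
    )
    try:
        cube = np.stack(
            [pivot[c][sessions].loc[subjects].to_numpy() for c in conds], axis=1
        )
    except KeyError as exc:
        raise ValueError(f"unbalanced layout: missing cell {exc}") from exc
    if np.isnan(cube).any():
        raise ValueError("unbalanced layout: missing (subject, condition, session) cells")
    return cube


# ---------------------------------------------------------------------------
# Local effect tests
# ---------------------------------------------------------------------------

def friedman_learning(
    features: pd.DataFrame, condition: str, value: str = "lambda_av_ms"
) -> tuple[float, float]:
    """Friedman test of a session (learning) effect within one condition."""
    sub = features[features["condition"] == condition]
    pivot = sub.pivot_table(index="subject", columns="session", values=value, aggfunc="first")
    if pivot.isna().any().any():
        raise ValueError("missing (subject, session) cells for the Friedman test")
    if pivot.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 sessions")
    cols = [pivot[c].to_numpy() for c in pivot.columns]
    if all((c == cols[0]).all() for c in cols[1:]):
        return 0.0, 1.0  # fully tied layout: no session effect by definition
    stat, p = sps.friedmanchisquare(*cols)
    return float(stat), float(p)


def wilcoxon_condition(
    features: pd.DataFrame, session: int, value: str = "lambda_av_ms"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank MI-vs-Rest test for one session.

    Zero differences are dropped (classic Wilcoxon rule); the p-value is
    two-sided and exact for small tie-free samples.
    """
    sub = features[features["session"] == session]
    pivot = sub.pivot_table(index="subject", columns="condition", values=value, aggfunc="first")
    if "MI" not in pivot.columns or "Rest" not in pivot.columns or pivot.isna().any().any():
        raise ValueError(f"missing paired MI/Rest values for session {session}")
    diff = pivot["MI"].to_numpy() - pivot["Rest"].to_numpy()
    if (diff == 0).all():
        raise ValueError("all MI-Rest differences are zero; Wilcoxon undefined")
    stat, p = sps.wilcoxon(diff, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Parameter screening by repeated correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamScreenRow:
    theta_k: float
    min_dur_ms: float
    feature: str
    result: RmcorrResult


def screen_rmcorr(
    deltas: pd.DataFrame, scores: pd.DataFrame, *, sessions: Sequence[int] | None = None
) -> list[ParamScreenRow]:
    """rmcorr of each delta feature against BCI score for every parameter pair.

    ``sessions`` restricts the correlation to a subset (leakage-safe mode:
    training sessions only).
    """
    merged = deltas.merge(scores, on=["subject", "session"], how="left")
    if merged["score"].isna().any():
        missing = merged.loc[merged["score"].isna(), ["subject", "session"]]
        raise ValueError(f"missing score rows: {missing.values.tolist()[:5]}")
    if sessions is not None:
        merged = merged[merged["session"].isin(sessions)]
    rows: list[ParamScreenRow] = []
    for (k, d), g in merged.groupby(["theta_k", "min_dur_ms"], sort=True):
        for feat in ("d_lambda_ms", "d_alpha"):
            x = g[feat].to_numpy()
            try:
                res = rmcorr(x, g["score"].to_numpy(), g["subject"].to_numpy())
            except ValueError:
                # degenerate pair (delta constant within every subject, e.g.
                # whole-epoch avalanches at k=1): uninformative, never selected
                n_sub = g["subject"].nunique()
                res = RmcorrResult(r=0.0, df=max(len(g) - n_sub - 1, 0), p=1.0,
                                   slope=0.0)
            rows.append(ParamScreenRow(float(k), float(d), feat, res))
    return rows


def select_correlated_params(
    screen: Sequence[ParamScreenRow], alpha: float = 0.05
) -> list[tuple[float, float]]:
    """Parameter pairs significant for either delta feature, by descending |r|."""
    if not screen:
        raise ValueError("empty screening input")
    best: dict[tuple[float, float], float] = {}
    for row in screen:
        if row.result.p < alpha:
            key = (row.theta_k, row.min_dur_ms)
            best[key] = max(best.get(key, 0.0), abs(row.result.r))
    return sorted(best, key=lambda k: -best[k])


# ---------------------------------------------------------------------------
# Hit/Miss trial comparison
# ---------------------------------------------------------------------------

def hit_miss_compare(
    trial_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    session: int,
    values: Sequence[str] = ("lambda_av_ms", "alpha_av"),
) -> pd.DataFrame:
    """Rank-sum comparisons of trial features between Hit and Miss trials.

    Contrasts: MI-Hit vs MI-Miss, Rest-Hit vs Rest-Miss, MI-Hit vs Rest-Hit.
    ``outcomes`` has columns (subject, session, condition, trial, outcome)
    with outcome in {"Hit", "Miss"}.
    """
    merged = trial_table.merge(
        outcomes, on=["subject", "session", "condition", "trial"], how="inner"
    )
    merged = merged[merged["session"] == session]
    contrasts = [
        ("MI", "Hit", "MI", "Miss"),
        ("Rest", "Hit", "Rest", "Miss"),
        ("MI", "Hit", "Rest", "Hit"),
    ]
    rows = []
    for c1, o1, c2, o2 in contrasts:
        g1 = merged[(merged["condition"] == c1) & (merged["outcome"] == o1)]
        g2 = merged[(merged["condition"] == c2) & (merged["outcome"] == o2)]
        name = f"{c1}-{o1} vs {c2}-{o2}"
        if g1.empty or g2.empty:
            raise ValueError(f"empty group in contrast {name}")
        for v in values:
            stat, p = sps.mannwhitneyu(
                g1[v].to_numpy(), g2[v].to_numpy(), alternative="two-sided"
            )
            rows.append({"contrast": name, "feature": v, "statistic": float(stat),
                         "p": float(p), "n1": len(g1), "n2": len(g2)})
    return pd.DataFrame(rows)
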