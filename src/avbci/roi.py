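"""ROI-level activation features and group-level ROI selection.

Each trial yields a per-ROI, duration-weighted activation vector (the
per-ROI analogue of the trial's weighted mean activation count). Activations
are normalized within subject to a percentage of the maximum activation seen
in that subject's first Rest session, preserving relative spatial patterns
while removing between-subject amplitude offsets. Per-(subject, session)
paired t statistics contrasting MI and Rest trials form a t-map tensor; a
per-ROI two-way analysis (session fixed factor, subject as block) then picks
ROIs whose condition contrast is robust across individuals and sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .avalanche import Avalanche, trial_features


def roi_trial_activation(avalanches: Sequence[Avalanche], n_rois: int, fs: float) -> np.ndarray:
    """Length-weighted per-ROI activation for one trial (zeros if empty).

    Sums to the trial's weighted mean activation count exactly.
    """
    return trial_features(avalanches, n_rois=n_rois, fs=fs).per_roi_weighted


def activation_table(
    trial_table: pd.DataFrame, roi_names: Sequence[str], *, share: bool = False
) -> pd.DataFrame:
    """Explode per-trial ``per_roi_weighted`` vectors into a long table.

    Input rows must carry a ``per_roi_weighted`` array column (from
    ``extract_trial_table(..., per_roi=True)`` at a single parameter pair).

    ``share=True`` divides each vector by its trial total (the trial's
    weighted mean activation count), yielding each ROI's *share* of the
    trial's activation. Global avalanche-duration changes — e.g. a
    condition-wide lengthening of cascades — cancel exactly in the share,
    which is what makes ROI-level condition contrasts selective rather than
    cortex-wide.
    """
    if "per_roi_weighted" not in trial_table.columns:
        raise ValueError("trial table lacks per_roi_weighted; re-extract with per_roi=True")
    n_rois = len(roi_names)
    base = trial_table[["subject", "session", "condition", "trial"]].to_numpy()
    mat = np.stack(trial_table["per_roi_weighted"].to_numpy())
    if mat.shape[1] != n_rois:
        raise ValueError(f"vectors have {mat.shape[1]} ROIs, expected {n_rois}")
    if share:
        totals = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, totals, out=np.zeros_like(mat), where=totals > 0)
    reps = np.repeat(base, n_rois, axis=0)
    out = pd.DataFrame(reps, columns=["subject", "session", "condition", "trial"])
    out["session"] = out["session"].astype(int)
    out["trial"] = out["trial"].astype(int)
    out["roi"] = np.tile(np.asarray(roi_names), len(trial_table))
    out["activation"] = mat.ravel()
    return out


def normalize_roi(table: pd.DataFrame) -> pd.DataFrame:
    """Scale activations to % of each subject's Rest-session-1 per-ROI maximum.

    The reference for (subject, ROI) is the maximum over that subject's
    Rest-session-1 trials; a zero reference is an error (that ROI never
    activated in the baseline session).
    """
    rest1 = table[(table["condition"] == "Rest") & (table["session"] == 1)]
    if rest1.empty:
        raise ValueError("no Rest session-1 trials to normalize against")
    ref = rest1.groupby(["subject", "roi"])["activation"].max().rename("reference")
    merged = table.merge(ref, on=["subject", "roi"], how="left")
    if merged["reference"].isna().any():
        bad = merged.loc[merged["reference"].isna(), ["subject", "roi"]].drop_duplicates()
        raise ValueError(f"no Rest-session-1 reference for: {bad.values.tolist()[:5]}")
    zero = merged["reference"] == 0
    if zero.any():
        bad = merged.loc[zero, ["subject", "roi"]].drop_duplicates()
        raise ValueError(f"zero Rest-session-1 reference for: {bad.values.tolist()[:5]}")
    merged["activation_norm"] = 100.0 * merged["activation"] / merged["reference"]
    return merged.drop(columns="reference")


def condition_tmaps(
    table: pd.DataFrame, roi_names: Sequence[str], *, mode: str = "paired"
) -> np.ndarray:
    """Per-(subject, session, ROI) t statistic contrasting MI vs Rest trials.

    Trials carry no natural MI/Rest pairing, so ``paired`` mode matches them
    by sorted trial index after truncation to the common count; ``welch``
    computes an unequal-variance two-sample t instead. Cells with fewer than
    two trials per condition are NaN (flagged missing).
    """
    if mode not in ("paired", "welch"):
        raise ValueError(f"unknown t-map mode {mode!r}")
    value = "activation_norm" if "activation_norm" in table.columns else "activation"
    subjects = np.sort(table["subject"].unique())
    sessions = np.sort(table["session"].unique())
    roi_index = {r: j for j, r in enumerate(roi_names)}
    out = np.full((len(subjects), len(sessions), len(roi_names)), np.nan)
    grouped = table.groupby(["subject", "session", "roi", "condition"])[value]
    arrays = {key: g.to_numpy() for key, g in grouped}
    for i, sid in enumerate(subjects):
        for s_i, ses in enumerate(sessions):
            for roi, j in roi_index.items():
                mi = arrays.get((sid, ses, roi, "MI"))
                rest = arrays.get((sid, ses, roi, "Rest"))
                if mi is None or rest is None or len(mi) < 2 or len(rest) < 2:
                    continue
                if mode == "paired":
                    m = min(len(mi), len(rest))
                    d = np.sort(mi)[:m] - np.sort(rest)[:m]
                    sd = d.std(ddof=1)
                    if sd == 0:
                        out[i, s_i, j] = 0.0
                    else:
                        out[i, s_i, j] = d.mean() / (sd / np.sqrt(m))
                else:
                    out[i, s_i, j] = sps.ttest_ind(mi, rest, equal_var=False).statistic
    return out


@dataclass
class RoiSelection:
    """Outcome of the group-level ROI screen (possibly empty)."""

    params: tuple[float, float] | None
    roi_names: list[str]
    selected: list[str]
    p_condition: np.ndarray
    p_session: np.ndarray
    tmaps: np.ndarray

    def indices(self) -> list[int]:
        lookup = {r: j for j, r in enumerate(self.roi_names)}
        return [lookup[r] for r in self.selected]


def select_rois(
    tmaps: np.ndarray,
    roi_names: Sequence[str],
    alpha: float = 0.05,
    rule: str = "condition",
    tail: str = "greater",
    params: tuple[float, float] | None = None,
) -> RoiSelection:
    """Group-level ROI screen from the t-map tensor.

    Per ROI, a randomized-block two-way view of the t-values (session fixed,
    subject blocking, no interaction term — one observation per cell):

    * condition effect — does the mean t differ from 0 across subjects?
      (intercept test against between-subject variation);
    * session effect — block-design F test of session differences.

    ``tail`` applies to the condition effect: ``"greater"`` (default) keeps
    only ROIs *more* engaged in MI than Rest — with share-based activations
    the competing ROIs' shares necessarily dip, and a two-sided rule would
    flag that dilution; ``"two-sided"`` is available.

    ``rule`` combines the effects: ``"condition"`` (default; session effect
    is still recorded), ``"session"``, ``"and"``, ``"or"``. An empty
    selection is a valid outcome.
    """
    tmaps = np.asarray(tmaps, dtype=float)
    if tmaps.ndim != 3 or tmaps.shape[0] < 2 or tmaps.shape[1] < 2:
        raise ValueError("t tensor must be (subjects >= 2, sessions >= 2, rois)")
    if rule not in ("condition", "session", "and", "or"):
        raise ValueError(f"unknown selection rule {rule!r}")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    n, s, r = tmaps.shape
    if np.isnan(tmaps).all(axis=(0, 1)).any():
        raise ValueError("degenerate tensor: some ROI has no valid cells")
    p_cond = np.ones(r)
    p_sess = np.ones(r)
    for j in range(r):
        tj = tmaps[:, :, j]
        valid = ~np.isnan(tj).any(axis=1)
        tj = tj[valid]
        if tj.shape[0] < 2:
            continue
        # intercept test: one-sample t on subject-mean t-values
        subj_means = tj.mean(axis=1)
        if subj_means.std(ddof=1) == 0:
            if tail == "greater":
                p_cond[j] = 0.0 if subj_means.mean() > 0 else 1.0
            else:
                p_cond[j] = 0.0 if subj_means.mean() != 0 else 1.0
        else:
            res = sps.ttest_1samp(
                subj_means, 0.0,
                alternative="greater" if tail == "greater" else "two-sided",
            )
            p_cond[j] = float(res.pvalue)
        # session effect: randomized-block F (subjects are blocks)
        grand = tj.mean()
        sess_means = tj.mean(axis=0)
        ss_sess = tj.shape[0] * ((sess_means - grand) ** 2).sum()
        ss_block = s * ((subj_means - grand) ** 2).sum()
        ss_err = ((tj - subj_means[:, None] - sess_means[None, :] + grand) ** 2).sum()
        df_sess, df_err = s - 1, (tj.shape[0] - 1) * (s - 1)
        if ss_err == 0:
            p_sess[j] = 1.0 if ss_sess == 0 else 0.0
        else:
            f = (ss_sess / df_sess) / (ss_err / df_err)
            p_sess[j] = float(sps.f.sf(f, df_sess, df_err))
    masks = {
        "condition": p_cond < alpha,
        "session": p_sess < alpha,
        "and": (p_cond < alpha) & (p_sess < alpha),
        "or": (p_cond < alpha) | (p_sess < alpha),
    }
    selected = [roi_names[j] for j in np.flatnonzero(masks[rule])]
    return RoiSelection(
        params=params, roi_names=list(roi_names), selected=selected,
        p_condition=p_cond, p_session=p_sess, tmaps=tmaps,
    )


def mask_rois(epoch, selection: RoiSelection):
    """Restrict an epoch to the selected ROI rows (re-detect downstream).

    Avalanche boundaries may change on the reduced raster, so features must
    be recomputed, not subset.
    """
    if not selection.selected:
        raise ValueError("empty ROI selection: run in full-ROI mode instead")
    from .io import RoiEpoch

    idx = selection.indices()
    return RoiEpoch(
        subject_id=epoch.subject_id, session=epoch.session, condition=epoch.condition,
        trial=epoch.trial, data=epoch.data[idx], fs=epoch.fs,
        roi_names=[epoch.roi_names[j] for j in idx],
    )
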