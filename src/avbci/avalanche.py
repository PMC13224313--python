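"""Neuronal-avalanche detection and trial-level feature extraction.

A neuronal avalanche is a spatiotemporal cascade of supra-threshold activity:
it begins at the first frame in which at least one region of interest (ROI)
exceeds a z-score threshold and ends when every ROI has returned below it.
Two parameters govern detection:

``theta_k``
    The z-threshold expressed as mu + k*sigma of the standardized signal;
    because signals are z-scored first, the threshold is numerically ``k``.
``min_dur_ms``
    The minimum avalanche duration (in milliseconds) for a cascade to be
    retained, excluding transients too short to be physiologically meaningful.

Two features summarize each trial: the mean avalanche length ``lambda_av``
(ms) and the duration-weighted mean activation count ``alpha_av``,

    alpha_av = sum_av(alpha_av_i * lambda_i) / sum_av(lambda_i)

with per-avalanche ``alpha`` the number of supra-threshold (ROI, time) cells
and ``lambda`` the duration in samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Candidate (theta_k, min_dur_ms) grid screened before analysis: z-thresholds
#: mu + k*sigma for k = 1..5 crossed with minimum durations 5/50/80 ms.
DEFAULT_GRID: tuple[tuple[int, float], ...] = tuple(
    (k, d) for k in (1, 2, 3, 4, 5) for d in (5.0, 50.0, 80.0)
)


@dataclass(frozen=True)
class AvalancheParams:
    """Detection parameter pair (z-threshold multiplier, minimum duration)."""

    theta_k: float
    min_dur_ms: float
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.theta_k < 0:
            raise ValueError(f"theta_k must be >= 0, got {self.theta_k}")
        if self.min_dur_ms <= 0:
            raise ValueError(f"min_dur_ms must be > 0, got {self.min_dur_ms}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def min_dur_samples(self) -> int:
        # ceiling so the retained duration is never shorter than min_dur_ms
        # (5 ms @ 250 Hz -> 2 samples, since 1 sample = 4 ms < 5 ms)
        return max(1, math.ceil(self.min_dur_ms * self.fs / 1000.0))


@dataclass(frozen=True)
class Avalanche:
    """One detected cascade over ``[start, end)`` sample indices."""

    start: int
    end: int
    fs: float
    per_roi_alpha: np.ndarray = field(repr=False)

    @property
    def duration_samples(self) -> int:
        return self.end - self.start

    @property
    def lambda_ms(self) -> float:
        return self.duration_samples * 1000.0 / self.fs

    @property
    def alpha(self) -> int:
        return int(self.per_roi_alpha.sum())


@dataclass(frozen=True)
class TrialFeatures:
    """Per-trial avalanche summary (zeros and ``empty`` flag if none found)."""

    lambda_av_ms: float
    alpha_av: float
    n_avalanches: int
    per_roi_weighted: np.ndarray = field(repr=False)

    @property
    def empty(self) -> bool:
        return self.n_avalanches == 0


def zscore_epoch(data: np.ndarray) -> np.ndarray:
    """Standardize each ROI row to zero mean and unit population SD.

    Raises
    ------
    ValueError
        If any row is constant (zero variance), naming the offending row.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"expected 2-D [n_rois, n_samples] array, got ndim={data.ndim}")
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        raise ValueError(f"constant signal (zero variance) in ROI rows {flat.tolist()}")
    return (data - mu) / sd


def binarize(z_data: np.ndarray, params: AvalancheParams, two_sided: bool = True) -> np.ndarray:
    """Mark supra-threshold cells: ``|z| > theta_k`` (or ``z > theta_k`` one-sided).

    The inequality is strict, so ``theta_k = 0`` activates every nonzero cell.
    """
    z_data = np.asarray(z_data, dtype=float)
    if two_sided:
        return np.abs(z_data) > params.theta_k
    return z_data > params.theta_k


def detect_avalanches(raster: np.ndarray, params: AvalancheParams) -> list[Avalanche]:
    """Segment a binary raster into avalanches.

    Avalanches are maximal runs of consecutive frames with at least one active
    ROI, truncated at epoch edges, retained iff their duration reaches
    ``params.min_dur_samples``. Returned in temporal order.
    """
    raster = np.asarray(raster, dtype=bool)
    starts, ends = _active_runs(raster.any(axis=0))
    min_len = params.min_dur_samples
    out: list[Avalanche] = []
    # cumulative per-ROI counts let each run's alpha be read off in O(n_rois)
    csum = np.concatenate(
        [np.zeros((raster.shape[0], 1), dtype=np.int64), np.cumsum(raster, axis=1)], axis=1
    )
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        per_roi = csum[:, e] - csum[:, s]
        out.append(Avalanche(start=int(s), end=int(e), fs=params.fs, per_roi_alpha=per_roi))
    return out


def _active_runs(frame_active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) indices of maximal True runs in a 1-D bool array."""
    padded = np.diff(np.concatenate([[0], frame_active.astype(np.int8), [0]]))
    return np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)


def trial_features(
    avalanches: Sequence[Avalanche], n_rois: int, fs: float
) -> TrialFeatures:
    """Duration-weighted trial summary of a list of avalanches.

    ``alpha_av`` weights each avalanche's activation count by its duration in
    samples; ``per_roi_weighted`` applies the same weighting to the per-ROI
    counts, so it sums exactly to ``alpha_av``.
    """
    if not avalanches:
        return TrialFeatures(0.0, 0.0, 0, np.zeros(n_rois))
    lam = np.array([a.duration_samples for a in avalanches], dtype=float)
    alpha = np.array([a.alpha for a in avalanches], dtype=float)
    per_roi = np.stack([a.per_roi_alpha for a in avalanches]).astype(float)
    wsum = lam.sum()
    return TrialFeatures(
        lambda_av_ms=float(np.mean(lam * 1000.0 / fs)),
        alpha_av=float((alpha * lam).sum() / wsum),
        n_avalanches=len(avalanches),
        per_roi_weighted=(per_roi * lam[:, None]).sum(axis=0) / wsum,
    )


def epoch_features(
    data: np.ndarray,
    fs: float,
    params: AvalancheParams,
    *,
    two_sided: bool = True,
    prezscored: bool = False,
) -> TrialFeatures:
    """z-score, binarize and summarize one epoch in a single call."""
    z = np.asarray(data, dtype=float) if prezscored else zscore_epoch(data)
    raster = binarize(z, params, two_sided=two_sided)
    av = detect_avalanches(raster, params)
    return trial_features(av, n_rois=z.shape[0], fs=fs)


def extract_trial_table(
    epochs: Iterable,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    *,
    two_sided: bool = True,
    per_roi: bool = False,
) -> pd.DataFrame:
    """Per-trial features for every epoch x parameter pair.

    Parameters
    ----------
    epochs : iterable of RoiEpoch
        Each epoch is z-scored once; thresholds sharing ``theta_k`` reuse the
        same raster segmentation and differ only in the duration filter.
    grid : sequence of (theta_k, min_dur_ms)
    per_roi : bool
        If True, add a ``per_roi_weighted`` object column (needed for ROI
        selection); omitted by default to keep the table light.

    Returns
    -------
    DataFrame with columns subject, session, condition, trial, theta_k,
    min_dur_ms, lambda_av_ms, alpha_av, n_avalanches (+ per_roi_weighted).
    """
    grid = list(grid)
    by_k: dict[float, list[float]] = {}
    for k, d in grid:
        by_k.setdefault(k, []).append(d)
    rows = []
    for ep in epochs:
        z = zscore_epoch(ep.data)
        for k, durs in by_k.items():
            p0 = AvalancheParams(theta_k=k, min_dur_ms=min(durs), fs=ep.fs)
            raster = binarize(z, p0, two_sided=two_sided)
            av_all = detect_avalanches(
                raster, AvalancheParams(theta_k=k, min_dur_ms=1e-9, fs=ep.fs)
            )
            for d in durs:
                p = AvalancheParams(theta_k=k, min_dur_ms=d, fs=ep.fs)
                kept = [a for a in av_all if a.duration_samples >= p.min_dur_samples]
                tf = trial_features(kept, n_rois=z.shape[0], fs=ep.fs)
                row = {
                    "subject": ep.subject_id,
                    "session": ep.session,
                    "condition": ep.condition,
                    "trial": ep.trial,
                    "theta_k": k,
                    "min_dur_ms": d,
                    "lambda_av_ms": tf.lambda_av_ms,
                    "alpha_av": tf.alpha_av,
                    "n_avalanches": tf.n_avalanches,
                }
                if per_roi:
                    row["per_roi_weighted"] = tf.per_roi_weighted
                rows.append(row)
    return pd.DataFrame(rows)


def subject_features(
    trial_table: pd.DataFrame, *, include_empty_trials: bool = False
) -> pd.DataFrame:
    """Aggregate per-trial features to one row per (subject, session, condition, params).

    Trials without avalanches are excluded from the means by default (a
    zero-length avalanche is undefined, not observed); a cell whose trials are
    all empty yields a flagged row with zeros and ``n_avalanches = 0``.
    """
    keys = ["subject", "session", "condition", "theta_k", "min_dur_ms"]
    if trial_table.empty:
        raise ValueError("trial table is empty: no cells to aggregate")

    def _agg(g: pd.DataFrame) -> pd.Series:
        nonempty = g if include_empty_trials else g[g["n_avalanches"] > 0]
        if nonempty.empty:
            return pd.Series(
                {"lambda_av_ms": 0.0, "alpha_av": 0.0, "n_avalanches": 0, "n_trials": len(g)}
            )
        return pd.Series(
            {
                "lambda_av_ms": nonempty["lambda_av_ms"].mean(),
                "alpha_av": nonempty["alpha_av"].mean(),
                "n_avalanches": int(g["n_avalanches"].sum()),
                "n_trials": len(g),
            }
        )

    out = trial_table.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_avalanches"] = out["n_avalanches"].astype(int)
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def screen_parameter_grid(
    features: pd.DataFrame,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    *,
    min_mean_duration_ms: float = 5.0,
) -> list[tuple[float, float]]:
    """Keep parameter pairs that are physiologically usable.

    A pair is valid iff every (subject, session, condition) cell yields at
    least one avalanche and the grand-mean avalanche duration over cells
    exceeds ``min_mean_duration_ms``. Pairs are returned in grid order.
    """
    valid = []
    for k, d in grid:
        sub = features[(features["theta_k"] == k) & (features["min_dur_ms"] == d)]
        if sub.empty:
            continue
        if (sub["n_avalanches"] == 0).any():
            continue
        if sub["lambda_av_ms"].mean() <= min_mean_duration_ms:
            continue
        valid.append((k, d))
    return valid
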