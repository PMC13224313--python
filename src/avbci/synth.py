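"""Synthetic BCI-training cohorts with planted avalanche dynamics.

The generator emulates the statistical structure the analysis pipeline
assumes, at study scale (20 subjects x 4 sessions x 2 conditions x 32 trials
of 68-ROI, 7-s, 250-Hz source time series):

* per-ROI background = unit-variance AR(1) noise (phi = 0.95), so z-scored
  signals have realistic autocorrelation and non-degenerate avalanche
  durations;
* multi-ROI burst events arriving as a Poisson process, each with a
  log-normal duration, a random ROI subset, and a smooth positive Tukey
  envelope of a few background standard deviations;
* a "learner" subset of subjects whose motor-imagery (MI) burst-duration
  median grows linearly with session number, on top of session-level jitter
  of the MI gap shared by all subjects (day-to-day fluctuation of task
  engagement); Rest dynamics stay session-invariant;
* in MI, each burst additionally recruits a small planted set of task ROIs
  with some probability, leaving the uniform recruitment of all other ROIs
  untouched (so non-task ROIs are condition-null);
* BCI scores generatively linked to the planted MI-Rest duration-scale gap
  (not to detected features, so downstream feature-score correlations remain
  an emergent, testable property).

Everything is deterministic under the configured seed; each epoch draws from
an RNG keyed by (seed, subject, session, condition, trial), so any subset of
the cohort reproduces the exact epochs of a full generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

from .io import CONDITIONS, DK_ROI_NAMES, BciScores, RoiEpoch, write_epoch_store

import pandas as pd


@dataclass
class SynthConfig:
    """Cohort-generation parameters (defaults are the study conditions)."""

    n_subjects: int = 20
    n_sessions: int = 4
    trials_per_condition: int = 32
    n_rois: int = 68
    fs: float = 250.0
    epoch_seconds: float = 7.0
    ar_coef: float = 0.95           # background AR(1) coefficient
    burst_rate: float = 1.5         # events / s
    burst_roi_mean: float = 5.0     # mean ROIs recruited per burst
    burst_dur_median_ms: float = 60.0
    burst_dur_sigma_log: float = 0.5
    burst_amplitude: float = 4.0    # z units above background
    n_planted_rois: int = 5
    planted_task_prob: float = 0.4  # per-burst chance each planted ROI joins in MI
    learner_fraction: float = 0.6
    learning_gain: float = 0.25     # fractional MI duration increase / session
    scale_noise_sd: float = 0.15    # session-level jitter of the MI gap
    score_base: float = 50.0        # %, non-learner level just below chance
    score_gain: float = 25.0        # % per unit duration-scale gap
    score_noise_sd: float = 5.0     # % measurement noise on top of the gap link
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.learner_fraction <= 1:
            raise ValueError("learner_fraction must be in [0, 1]")
        for name in ("burst_rate", "burst_dur_median_ms", "burst_dur_sigma_log", "fs",
                     "epoch_seconds", "burst_roi_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be >= 0")
        # epoch must host the longest plausible burst (3 log-sigmas at the
        # steepest session scaling)
        max_scale = (
            1.0 + self.learning_gain * (self.n_sessions - 1) + 3 * self.scale_noise_sd
        )
        max_dur_ms = (
            self.burst_dur_median_ms * max_scale * float(np.exp(3 * self.burst_dur_sigma_log))
        )
        if max_dur_ms >= self.epoch_seconds * 1000.0:
            raise ValueError("epoch too short to host the maximum burst duration")

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.epoch_seconds)


@dataclass
class GroundTruth:
    """Planted cohort structure used by parameter-recovery tests."""

    learners: dict[str, bool]
    mi_duration_scale: dict[str, list[float]]   # per subject, one scale per session
    planted_rois: list[int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def subject_ids(config: SynthConfig) -> list[str]:
    return [f"{i + 1:02d}" for i in range(config.n_subjects)]


def make_ground_truth(config: SynthConfig) -> GroundTruth:
    """Draw learner flags, per-session MI duration scales and planted ROIs."""
    rng = np.random.default_rng([config.seed, 101])
    ids = subject_ids(config)
    n_learners = int(round(config.learner_fraction * config.n_subjects))
    learner_idx = set(rng.choice(config.n_subjects, size=n_learners, replace=False).tolist())
    learners = {sid: (i in learner_idx) for i, sid in enumerate(ids)}
    # MI duration scale = deterministic learning trend plus session-level
    # jitter (day-to-day fluctuation of MI engagement, also for non-learners)
    scales = {}
    for sid in ids:
        per_session = []
        for s in range(config.n_sessions):
            trend = config.learning_gain * s if learners[sid] else 0.0
            jitter = config.scale_noise_sd * rng.standard_normal()
            per_session.append(float(max(0.3, 1.0 + trend + jitter)))
        scales[sid] = per_session
    planted = rng.choice(config.n_rois, size=config.n_planted_rois, replace=False)
    return GroundTruth(
        learners=learners,
        mi_duration_scale=scales,
        planted_rois=sorted(int(r) for r in planted),
    )


def _ar1_background(rng: np.random.Generator, n_rois: int, n_samples: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows (short burn-in discarded)."""
    burn = 200
    innov = rng.standard_normal((n_rois, n_samples + burn)) * np.sqrt(1.0 - phi**2)
    x = signal.lfilter([1.0], [1.0, -phi], innov, axis=1)
    return x[:, burn:]


def _synth_epoch(
    rng: np.random.Generator, config: SynthConfig, dur_scale: float, planted: Sequence[int],
    biased: bool,
) -> np.ndarray:
    n, t = config.n_rois, config.n_samples
    data = _ar1_background(rng, n, t, config.ar_coef)
    if config.burst_amplitude == 0:
        return data
    n_bursts = rng.poisson(config.burst_rate * config.epoch_seconds)
    for _ in range(n_bursts):
        dur_ms = config.burst_dur_median_ms * dur_scale * float(
            np.exp(config.burst_dur_sigma_log * rng.standard_normal())
        )
        dur = int(round(dur_ms * config.fs / 1000.0))
        dur = max(2, min(dur, t - 1))
        onset = int(rng.integers(0, t - dur))
        m = 1 + rng.poisson(config.burst_roi_mean - 1.0)
        m = min(m, n)
        rois = rng.choice(n, size=m, replace=False)
        if biased and len(planted):
            # task bursts additionally recruit planted ROIs, leaving the
            # uniform recruitment of the remaining cortex untouched
            extra = [r for r in planted
                     if rng.random() < config.planted_task_prob]
            rois = np.union1d(rois, np.asarray(extra, dtype=int))
        envelope = signal.windows.tukey(dur, alpha=0.5) * config.burst_amplitude
        data[np.ix_(rois, np.arange(onset, onset + dur))] += envelope
    return data


def iter_epochs(
    config: SynthConfig,
    truth: GroundTruth,
    subjects: Sequence[str] | None = None,
    sessions: Sequence[int] | None = None,
    conditions: Sequence[str] | None = None,
) -> Iterator[RoiEpoch]:
    """Generate epochs lazily; any subset reproduces the full cohort's draws."""
    roi_names = (
        DK_ROI_NAMES if config.n_rois == len(DK_ROI_NAMES)
        else tuple(f"roi{j:02d}" for j in range(config.n_rois))
    )
    ids = subject_ids(config)
    for sid in subjects if subjects is not None else ids:
        si = ids.index(sid)
        for ses in sessions if sessions is not None else range(1, config.n_sessions + 1):
            for cond in conditions if conditions is not None else CONDITIONS:
                is_mi = cond == "MI"
                scale = truth.mi_duration_scale[sid][ses - 1] if is_mi else 1.0
                for trial in range(1, config.trials_per_condition + 1):
                    rng = np.random.default_rng(
                        [config.seed, si, ses, int(is_mi), trial]
                    )
                    data = _synth_epoch(rng, config, scale, truth.planted_rois, biased=is_mi)
                    yield RoiEpoch(
                        subject_id=sid, session=ses, condition=cond, trial=trial,
                        data=data, fs=config.fs, roi_names=roi_names,
                    )


def generate_scores(
    truth: GroundTruth, config: SynthConfig, seed: int | None = None
) -> BciScores:
    """BCI scores linked to the planted MI-Rest duration-scale gap.

    score(i, s) = base + gain * (MI scale - Rest scale) + N(0, noise_sd),
    clipped to [0, 100]. Learners trend upward with session; non-learners
    hover near base.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 202])
    rows = []
    for sid, scales in sorted(truth.mi_duration_scale.items()):
        if len(scales) != config.n_sessions:
            raise ValueError(
                f"cohort mismatch: subject {sid} has {len(scales)} sessions, "
                f"config says {config.n_sessions}"
            )
        for s in range(1, config.n_sessions + 1):
            gap = scales[s - 1] - 1.0
            noise = rng.standard_normal() * config.score_noise_sd
            score = float(np.clip(config.score_base + config.score_gain * gap + noise, 0, 100))
            rows.append({"subject": sid, "session": s, "score": score})
    return BciScores(pd.DataFrame(rows))


def generate_dataset(
    config: SynthConfig, path: str | Path | None = None
) -> tuple[object, GroundTruth, BciScores]:
    """Generate a full cohort; optionally persist it as an epoch store.

    Returns ``(epochs, truth, scores)`` where ``epochs`` is a lazy iterator
    when ``path`` is None, else an :class:`~avbci.io.EpochStore` over the
    written directory (alongside ``scores.csv`` and ``truth.json``).
    """
    truth = make_ground_truth(config)
    scores = generate_scores(truth, config)
    if path is None:
        return iter_epochs(config, truth), truth, scores
    from .io import load_epoch_store, save_table

    path = Path(path)
    write_epoch_store(path, iter_epochs(config, truth))
    save_table(scores.table, path / "scores.csv", "scores")
    truth.to_json(path / "truth.json")
    return load_epoch_store(path), truth, scores
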