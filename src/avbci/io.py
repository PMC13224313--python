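"""Data model, on-disk formats and pipeline configuration.

The epoch store holds source-level ROI time series: one HDF5 file per subject
(``sub-<id>.h5``) with groups ``/ses-<s>/<condition>/trial-<k>`` and a
``manifest.json`` describing the cohort layout (subjects, sessions,
conditions, trial counts per cell, ROI labels, sampling rate). Tabular
results travel as CSV with fixed schemas.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("Rest", "MI")

#: Desikan-Killiany-style default: 34 bilateral cortical labels.
_DK_BASE = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]
DK_ROI_NAMES: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_BASE
)


@dataclass
class RoiEpoch:
    """One trial's ROI x time amplitude matrix with identifying labels."""

    subject_id: str
    session: int
    condition: str
    trial: int
    data: np.ndarray
    fs: float = 250.0
    roi_names: Sequence[str] = DK_ROI_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.session < 1:
            raise ValueError("sessions are 1-based")
        if self.trial < 1:
            raise ValueError("trials are 1-based")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [n_rois, n_samples]")
        if self.data.shape[0] != len(self.roi_names):
            raise ValueError(
                f"n_rois mismatch: data has {self.data.shape[0]} rows, "
                f"{len(self.roi_names)} roi_names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class BciScores:
    """Per-(subject, session) BCI performance scores in percent.

    Wraps a DataFrame with columns (subject, session, score); enforces exactly
    one score per cell and a complete session grid per subject.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"subject", "session", "score"}
        if not required.issubset(table.columns):
            raise ValueError(f"scores table needs columns {sorted(required)}")
        table = table.copy()
        table["subject"] = table["subject"].astype(str)
        dup = table.duplicated(["subject", "session"])
        if dup.any():
            raise ValueError(
                f"duplicate (subject, session) rows: "
                f"{table.loc[dup, ['subject', 'session']].values.tolist()}"
            )
        sessions = sorted(table["session"].unique())
        counts = table.groupby("subject")["session"].nunique()
        bad = counts[counts != len(sessions)]
        if len(bad):
            raise ValueError(f"subjects missing sessions: {bad.index.tolist()}")
        if ((table["score"] < 0) | (table["score"] > 100)).any():
            raise ValueError("scores must lie in [0, 100]")
        self.table = table.sort_values(["subject", "session"]).reset_index(drop=True)
        self.sessions = sessions

    def score(self, subject: str, session: int) -> float:
        row = self.table[
            (self.table["subject"] == str(subject)) & (self.table["session"] == session)
        ]
        if row.empty:
            raise KeyError(f"no score for subject {subject!r} session {session}")
        return float(row["score"].iloc[0])

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, with study-scale defaults."""

    seed: int
    grid: list[tuple[float, float]] = field(
        default_factory=lambda: [(k, d) for k in (1, 2, 3, 4, 5) for d in (5.0, 50.0, 80.0)]
    )
    n_permutations: int = 10_000
    alpha: float = 0.05
    control_threshold: float = 57.0
    C: float = 10.0
    epsilon: float = 1.0
    ridge: float = 1e-3
    tol: float = 1e-6
    max_iter: int = 100
    n_shuffles: int = 20
    train_sessions: int = 3
    store_path: str | None = None
    out_dir: str = "avbci-out"
    simulate: bool = True
    synth_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.control_threshold < 100:
            raise ValueError("control threshold must be in (0, 100)")
        if not self.grid:
            raise ValueError("no parameter pairs: grid is empty")
        self.grid = [(float(k), float(d)) for k, d in self.grid]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Epoch store (HDF5 + manifest)
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def write_epoch_store(
    path: str | Path, epochs: Iterator[RoiEpoch] | Sequence[RoiEpoch]
) -> Path:
    """Write epochs to a directory store, building the manifest on the fly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    layout: dict = {}
    meta: dict = {}
    handles: dict[str, h5py.File] = {}
    try:
        for ep in epochs:
            if not meta:
                meta = {
                    "fs": ep.fs,
                    "n_rois": ep.n_rois,
                    "n_samples": ep.n_samples,
                    "roi_names": list(ep.roi_names),
                }
            sid = str(ep.subject_id)
            if sid not in handles:
                handles[sid] = h5py.File(path / f"sub-{sid}.h5", "w")
                handles[sid].attrs["fs"] = ep.fs
                handles[sid].attrs["roi_names"] = list(ep.roi_names)
            g = handles[sid].require_group(f"ses-{ep.session}/{ep.condition}")
            g.create_dataset(f"trial-{ep.trial}", data=ep.data, dtype="f4")
            cell = layout.setdefault(sid, {}).setdefault(str(ep.session), {})
            cell[ep.condition] = cell.get(ep.condition, 0) + 1
    finally:
        for fh in handles.values():
            fh.close()
    manifest = {"subjects": sorted(layout), "layout": layout, **meta}
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


class EpochStore:
    """Lazy handle over an on-disk epoch collection.

    Validates each epoch against the manifest on access; raises on schema
    mismatch naming the offending file/dataset.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        mpath = self.path / MANIFEST_NAME
        if not mpath.exists():
            raise FileNotFoundError(f"no manifest at {mpath}")
        with open(mpath) as fh:
            self.manifest = json.load(fh)
        self.subjects: list[str] = self.manifest["subjects"]
        self.fs: float = self.manifest["fs"]
        self.roi_names: list[str] = self.manifest["roi_names"]

    @property
    def sessions(self) -> list[int]:
        out: set[int] = set()
        for cells in self.manifest["layout"].values():
            out.update(int(s) for s in cells)
        return sorted(out)

    def n_trials(self, subject: str, session: int, condition: str) -> int:
        return self.manifest["layout"][str(subject)][str(session)].get(condition, 0)

    def iter_epochs(
        self,
        subjects: Sequence[str] | None = None,
        sessions: Sequence[int] | None = None,
        conditions: Sequence[str] | None = None,
    ) -> Iterator[RoiEpoch]:
        n_rois = self.manifest["n_rois"]
        n_samples = self.manifest["n_samples"]
        for sid in subjects if subjects is not None else self.subjects:
            fpath = self.path / f"sub-{sid}.h5"
            if not fpath.exists():
                raise FileNotFoundError(f"manifest lists subject {sid} but {fpath} is missing")
            with h5py.File(fpath, "r") as fh:
                cells = self.manifest["layout"][str(sid)]
                for ses in sessions if sessions is not None else sorted(map(int, cells)):
                    for cond in conditions if conditions is not None else CONDITIONS:
                        n = cells.get(str(ses), {}).get(cond, 0)
                        for t in range(1, n + 1):
                            dset = fh[f"ses-{ses}/{cond}/trial-{t}"]
                            data = dset[()]
                            if data.shape != (n_rois, n_samples):
                                raise ValueError(
                                    f"schema mismatch in {fpath.name}:"
                                    f"/ses-{ses}/{cond}/trial-{t}: shape {data.shape}, "
                                    f"manifest says ({n_rois}, {n_samples})"
                                )
                            yield RoiEpoch(
                                subject_id=sid,
                                session=ses,
                                condition=cond,
                                trial=t,
                                data=data.astype(float),
                                fs=self.fs,
                                roi_names=self.roi_names,
                            )


def load_epoch_store(path: str | Path) -> EpochStore:
    return EpochStore(path)


# ---------------------------------------------------------------------------
# CSV table schemas
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, dict] = {
    "scores": {
        "columns": ["subject", "session", "score"],
        "key": ["subject", "session"],
    },
    "features": {
        "columns": [
            "subject", "session", "condition", "theta_k", "min_dur_ms",
            "lambda_av_ms", "alpha_av", "n_avalanches",
        ],
        "key": ["subject", "session", "condition", "theta_k", "min_dur_ms"],
    },
    "deltas": {
        "columns": [
            "subject", "session", "theta_k", "min_dur_ms", "d_lambda_ms", "d_alpha",
        ],
        "key": ["subject", "session", "theta_k", "min_dur_ms"],
    },
    "rois": {
        "columns": ["theta_k", "min_dur_ms", "roi_name"],
        "key": ["theta_k", "min_dur_ms", "roi_name"],
    },
    "predictions": {
        "columns": [
            "subject", "model", "predicted_score", "predicted_label",
            "true_score", "true_label",
        ],
        "key": ["subject", "model"],
    },
}


def save_table(table: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a known-schema CSV; floats keep >= 15 significant digits."""
    spec = TABLE_SCHEMAS.get(schema)
    if spec is None:
        raise ValueError(f"unknown table schema {schema!r}")
    missing = [c for c in spec["columns"] if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing} for schema {schema!r}")
    dup = table.duplicated(spec["key"])
    if dup.any():
        raise ValueError(
            f"duplicate key rows for schema {schema!r}: "
            f"{table.loc[dup, spec['key']].values.tolist()[:5]}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[spec["columns"]].to_csv(path, index=False, float_format="%.17g")
    return path


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    spec = TABLE_SCHEMAS.get(schema)
    if spec is None:
        raise ValueError(f"unknown table schema {schema!r}")
    table = pd.read_csv(path)
    missing = [c for c in spec["columns"] if c not in table.columns]
    if missing:
        raise ValueError(f"file {path} missing columns {missing} for schema {schema!r}")
    if "subject" in table.columns:
        table["subject"] = table["subject"].astype(str)
    dup = table.duplicated(spec["key"])
    if dup.any():
        raise ValueError(f"duplicate key rows in {path} for schema {schema!r}")
    return table
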