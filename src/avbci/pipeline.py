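"""End-to-end pipeline: simulate -> features -> stats/screening -> ROI
selection -> longitudinal prediction -> report.

Every stage draws randomness from the root seed through fixed per-stage
offsets, so a rerun with the same config reproduces all outputs byte-wise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import avalanche as av
from . import roi as roimod
from . import stats as st
from .io import PipelineConfig, load_epoch_store, save_table
from .models import build_longitudinal_dataset, loo_evaluate
from .synth import SynthConfig, make_ground_truth, iter_epochs, generate_scores

log = logging.getLogger("avbci")

# fixed per-stage seed offsets keep stage RNG streams independent
_SEED_SIM, _SEED_PERM, _SEED_SHUFFLE = 11, 13, 17


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _json_safe(asdict(config)), "stages": []}
    try:
        epochs_factory, scores, truth = _stage_data(config)
        report["stages"].append("data")
        trial_tab, features = _stage_features(config, epochs_factory, out)
        report["stages"].append("features")
        stats_report, deltas, selected_pairs = _stage_stats(config, features, scores, out)
        report["stages"].append("stats")
        report["stats"] = stats_report
        if not selected_pairs:
            raise RuntimeError("screening selected no parameter pairs")
        best_pair = selected_pairs[0]
        report["best_pair"] = {"theta_k": best_pair[0], "min_dur_ms": best_pair[1]}
        selection = _stage_rois(config, epochs_factory, best_pair, out)
        report["stages"].append("select-rois")
        report["rois"] = {"selected": selection.selected if selection else []}
        model_report, predictions = _stage_predict(config, deltas, scores, best_pair, out)
        report["stages"].append("predict")
        report["models"] = model_report
        if truth is not None:
            report["truth"] = {
                "learners": truth.learners,
                "planted_rois": truth.planted_rois,
            }
    except Exception as exc:
        stage = report["stages"][-1] if report["stages"] else "init"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    with open(out / "report.json", "w") as fh:
        json.dump(_json_safe(report), fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", out / "report.json")
    return report


def _stage_data(config: PipelineConfig):
    """Return (epochs_factory, scores table, truth-or-None)."""
    if config.simulate:
        synth = SynthConfig(seed=config.seed + _SEED_SIM, **config.synth_overrides)
        truth = make_ground_truth(synth)
        scores = generate_scores(truth, synth).table
        log.info("simulate: %d subjects x %d sessions, %d trials/condition",
                 synth.n_subjects, synth.n_sessions, synth.trials_per_condition)

        def factory(**kw):
            return iter_epochs(synth, truth, **kw)

        return factory, scores, truth
    if not config.store_path:
        raise ValueError("simulate disabled and no store_path configured")
    store = load_epoch_store(config.store_path)
    from .io import load_table

    scores = load_table(Path(config.store_path) / "scores.csv", "scores")

    def factory(**kw):
        return store.iter_epochs(**kw)

    return factory, scores, None


def _stage_features(config: PipelineConfig, epochs_factory, out: Path):
    log.info("features: grid of %d parameter pairs", len(config.grid))
    trial_tab = av.extract_trial_table(epochs_factory(), config.grid)
    features = av.subject_features(trial_tab)
    save_table(features, out / "features.csv", "features")
    return trial_tab, features


def _stage_stats(config: PipelineConfig, features, scores, out: Path):
    valid = av.screen_parameter_grid(features, config.grid)
    log.info("screening: %d/%d pairs physiologically valid", len(valid), len(config.grid))
    if not valid:
        raise RuntimeError("no parameter pairs survive avalanche screening")
    features_valid = features.merge(
        pd.DataFrame(valid, columns=["theta_k", "min_dur_ms"]), on=["theta_k", "min_dur_ms"]
    )
    deltas = st.delta_features(features_valid)
    save_table(deltas, out / "deltas.csv", "deltas")
    train_sessions = list(range(1, config.train_sessions + 1))
    screen = st.screen_rmcorr(deltas, scores, sessions=train_sessions)
    selected = st.select_correlated_params(screen, alpha=config.alpha)
    stats_report = {
        "valid_pairs": valid,
        "selected_pairs": selected,
        "rmcorr": [
            {"theta_k": r.theta_k, "min_dur_ms": r.min_dur_ms, "feature": r.feature,
             "r": r.result.r, "p": r.result.p, "df": r.result.df}
            for r in screen
        ],
    }
    if selected:
        k, d = selected[0]
        sub = features_valid[
            (features_valid["theta_k"] == k) & (features_valid["min_dur_ms"] == d)
        ]
        perm = st.permutation_anova(
            sub, n_perm=config.n_permutations, seed=config.seed + _SEED_PERM
        )
        fried_mi = st.friedman_learning(sub, "MI")
        fried_rest = st.friedman_learning(sub, "Rest")
        wilcox = {
            int(s): st.wilcoxon_condition(sub, s) for s in sorted(sub["session"].unique())
        }
        stats_report["best_pair_tests"] = {
            "permutation_anova": asdict(perm),
            "friedman_mi": fried_mi,
            "friedman_rest": fried_rest,
            "wilcoxon_by_session": wilcox,
        }
    with open(out / "stats_report.json", "w") as fh:
        json.dump(_json_safe(stats_report), fh, indent=1, sort_keys=True)
    return stats_report, deltas, selected


def _stage_rois(config: PipelineConfig, epochs_factory, pair, out: Path):
    k, d = pair
    log.info("select-rois: t-maps at pair (k=%g, %g ms)", k, d)
    tab = av.extract_trial_table(epochs_factory(), [(k, d)], per_roi=True)
    roi_names = None
    for ep in epochs_factory():
        roi_names = list(ep.roi_names)
        break
    act = roimod.activation_table(tab, roi_names, share=True)
    try:
        act = roimod.normalize_roi(act)
    except ValueError as exc:
        log.warning("ROI normalization skipped (%s); using raw activations", exc)
    tmaps = roimod.condition_tmaps(act, roi_names)
    selection = roimod.select_rois(tmaps, roi_names, alpha=config.alpha, params=pair)
    rois_df = pd.DataFrame(
        [{"theta_k": k, "min_dur_ms": d, "roi_name": r} for r in selection.selected]
    )
    if rois_df.empty:
        rois_df = pd.DataFrame(columns=["theta_k", "min_dur_ms", "roi_name"])
    save_table(rois_df, out / "rois.csv", "rois")
    return selection


def _stage_predict(config: PipelineConfig, deltas, scores, pair, out: Path):
    dataset = build_longitudinal_dataset(
        deltas, scores, pair,
        train_sessions=config.train_sessions, target_session=config.train_sessions + 1,
        threshold=config.control_threshold,
    )
    common = dict(C=config.C, ridge=config.ridge, tol=config.tol, max_iter=config.max_iter)
    reports = {
        "lsvr": loo_evaluate(dataset, "lsvr", epsilon=config.epsilon, **common),
        "svr": loo_evaluate(dataset, "svr", epsilon=config.epsilon, **common),
        "lsvc": loo_evaluate(dataset, "lsvc", **common),
        "svc": loo_evaluate(dataset, "svc", **common),
    }
    shuffled_acc, shuffled_rmse = [], []
    for j in range(config.n_shuffles):
        seed = config.seed + _SEED_SHUFFLE + j
        shuffled_acc.append(
            loo_evaluate(dataset, "lsvc", shuffle_seed=seed, **common).accuracy
        )
        shuffled_rmse.append(
            loo_evaluate(dataset, "lsvr", epsilon=config.epsilon,
                         shuffle_seed=seed, **common).rmse
        )
    rows = []
    for name, rep in reports.items():
        regression = name.endswith("vr")
        for i, sid in enumerate(rep.subjects):
            rows.append({
                "subject": sid, "model": name,
                "predicted_score": rep.predictions[i] if regression else np.nan,
                "predicted_label": (
                    int(rep.predictions[i]) if not regression
                    else int(rep.predictions[i] > config.control_threshold)
                ),
                "true_score": dataset.scores[i],
                "true_label": int(dataset.labels[i]),
            })
    predictions = pd.DataFrame(rows)
    save_table(predictions, out / "predictions.csv", "predictions")
    model_report = {
        "pair": {"theta_k": pair[0], "min_dur_ms": pair[1]},
        "lsvr_rmse": reports["lsvr"].rmse,
        "svr_rmse": reports["svr"].rmse,
        "lsvc_accuracy": reports["lsvc"].accuracy,
        "svc_accuracy": reports["svc"].accuracy,
        "lsvc_confusion": reports["lsvc"].confusion,
        "shuffled_lsvc_accuracy_mean": float(np.mean(shuffled_acc)),
        "shuffled_lsvr_rmse_mean": float(np.mean(shuffled_rmse)),
        "lsvr_beta_cosine": reports["lsvr"].beta_cosine(),
        "lsvc_beta_cosine": reports["lsvc"].beta_cosine(),
        "lsvc_beta_delta": reports["lsvc"].beta_delta(),
        "lsvr_betas": reports["lsvr"].betas.tolist(),
        "lsvc_betas": reports["lsvc"].betas.tolist(),
        "lsvc_converged": reports["lsvc"].converged,
        "lsvr_converged": reports["lsvr"].converged,
    }
    with open(out / "model_report.json", "w") as fh:
        json.dump(_json_safe(model_report), fh, indent=1, sort_keys=True)
    log.info(
        "predict: LSVC acc=%.2f (SVC %.2f, shuffled %.2f) | LSVR rmse=%.2f (SVR %.2f)",
        model_report["lsvc_accuracy"], model_report["svc_accuracy"],
        model_report["shuffled_lsvc_accuracy_mean"],
        model_report["lsvr_rmse"], model_report["svr_rmse"],
    )
    return model_report, predictions


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
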