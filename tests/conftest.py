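import numpy as np
import pytest

from avbci.avalanche import Avalanche


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_avalanches(raster: np.ndarray, min_dur_samples: int, fs: float):
    """Independent frame-scan oracle: walk columns, accumulate runs.

    Deliberately naive (per-frame python loop) and structurally unlike the
    vectorized detector it checks.
    """
    raster = np.asarray(raster, dtype=bool)
    n_rois, n_samples = raster.shape
    events = []
    current = None
    for t in range(n_samples):
        active = bool(raster[:, t].any())
        if active and current is None:
            current = t
        elif not active and current is not None:
            events.append((current, t))
            current = None
    if current is not None:
        events.append((current, n_samples))
    out = []
    for s, e in events:
        if e - s < min_dur_samples:
            continue
        per_roi = np.array([int(raster[r, s:e].sum()) for r in range(n_rois)])
        out.append(Avalanche(start=s, end=e, fs=fs, per_roi_alpha=per_roi))
    return out


@pytest.fixture
def tiny_cohort():
    """A small but complete synthetic cohort (fast to generate)."""
    from avbci.synth import SynthConfig, make_ground_truth, iter_epochs, generate_scores

    cfg = SynthConfig(seed=77, n_subjects=6, trials_per_condition=4)
    truth = make_ground_truth(cfg)
    scores = generate_scores(truth, cfg)
    return cfg, truth, list(iter_epochs(cfg, truth)), scores
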