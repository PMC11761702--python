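import numpy as np
import pytest

import reachmetrics as rm


@pytest.fixture
def base_waveform() -> np.ndarray:
    from reachmetrics.simulate import default_grab_waveform

    return default_grab_waveform()


@pytest.fixture
def noiseless_tracks():
    """Three noiseless, fully stereotyped trials with ground-truth grabs."""
    cfg = rm.TrajectorySimConfig(
        n_trials=3, stereotypy_level=1.0, baseline_noise_sd=0.0, seed=11
    )
    tracks, truth = rm.gen_pose_trials(cfg)
    return cfg, tracks, truth


def brute_force_sliding_correlation(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Independent oracle: per-window Pearson correlation at every offset.

    Computes, one window at a time with np.corrcoef, the mean over the 10
    coordinates of the correlation between trial window [s, s+50) and the
    template; the value is stored at the window centre s + 25. Edges stay
    NaN. Zero-variance coordinates contribute 0.
    """
    n, k = len(X), len(T)
    out = np.full(n, np.nan)
    for s in range(n - k + 1):
        rs = []
        for j in range(T.shape[1]):
            w = X[s : s + k, j]
            t = T[:, j]
            if w.std() == 0.0 or t.std() == 0.0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(w, t)[0, 1]))
        out[s + k // 2] = float(np.mean(rs))
    return out
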