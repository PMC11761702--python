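"""Synthetic data generators with known ground truth.

Every input kind the pipeline consumes can be simulated here with the
statistical structure the downstream analyses assume:

* pose-tracked reaching trials with embedded grab events at known frames and
  a tunable stereotypy level,
* animal × day learning tables following a linear-in-log-day mixed model,
* EMG sweeps with sigmoidal MEP recruitment and analytic window means,
* 4-contact lattice potentials under sinusoidal transcranial current with a
  known field gain.

All generators are deterministic for a fixed seed. Per-unit random
sub-streams are derived from the global seed with ``np.random.SeedSequence``
so that growing ``n_trials`` (or ``n_animals``) never perturbs the draws of
earlier units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from .pose import DEFAULT_FRAME_RATE, POINT_LABELS, PoseTrack

TEMPLATE_LEN = 50  # samples per grab waveform (150 ms at 309 fps)
HALF_WIN = TEMPLATE_LEN // 2

# Resting geometry of the simulated scene, pixels (2032x1086 image frame).
_REST_WRIST = np.array([950.0, 720.0])
_PELLET_POS = np.array([1130.0, 640.0])
_DIGIT_SPREAD_X = np.array([-30.0, -15.0, 0.0, 15.0, 30.0])
_DIGIT_OFFSET_Y = np.array([-42.0, -50.0, -54.0, -50.0, -42.0])


def default_grab_waveform() -> np.ndarray:
    """Canonical 50-sample × 10-coordinate reach-advance-close arc.

    Columns follow :meth:`PoseTrack.digit_matrix` order (digit1 x, digit1 y,
    ..., digit5 y), absolute pixel coordinates. The arc starts and ends at
    the digits' resting positions so a grab splices continuously into a
    resting baseline: each digit advances toward the pellet with a
    raised-cosine profile, lifts, splays and closes with per-digit phase
    lags so the ten coordinate series are mutually distinct.
    """
    t = np.linspace(0.0, 1.0, TEMPLATE_LEN)
    w = np.empty((TEMPLATE_LEN, 10))
    for d in range(5):
        lag = 0.03 * (d - 2)  # digit-specific timing
        phase = np.clip(t - lag, 0.0, 1.0)
        adv = np.sin(np.pi * phase) ** 2           # advance toward pellet
        lift = np.sin(np.pi * phase) ** 4          # vertical arc, sharper
        close = np.sin(2 * np.pi * phase) ** 2     # splay then close
        rest_x = _REST_WRIST[0] + _DIGIT_SPREAD_X[d]
        rest_y = _REST_WRIST[1] + _DIGIT_OFFSET_Y[d]
        w[:, 2 * d] = (
            rest_x
            + (150.0 + 6.0 * d) * adv
            + _DIGIT_SPREAD_X[d] * 0.6 * close
        )
        w[:, 2 * d + 1] = rest_y - (70.0 + 4.0 * d) * lift + 8.0 * close
    return w


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream keyed on (seed, *key)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySimConfig:
    """Conditions for simulated pose-tracked reaching trials.

    ``stereotypy_level`` in [0, 1] controls trial-to-trial waveform
    fidelity: 1 reproduces the base grab waveform exactly, 0 applies the
    full shape noise (``grab_jitter_sd``) and time warp (``time_warp_sd``),
    both scaled by ``1 - stereotypy_level``.
    """

    n_trials: int = 100
    frame_rate: float = DEFAULT_FRAME_RATE
    trial_len: int = 400
    grab_waveform: np.ndarray = field(default_factory=default_grab_waveform)
    grabs_per_trial: int = 3
    grab_jitter_sd: float = 25.0
    time_warp_sd: float = 0.08
    baseline_noise_sd: float = 1.5
    stereotypy_level: float = 0.8
    min_grab_separation: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.grab_waveform = np.asarray(self.grab_waveform, dtype=float)
        if self.grab_waveform.shape != (TEMPLATE_LEN, 10):
            raise ValueError(
                f"grab_waveform must be {TEMPLATE_LEN}x10, got {self.grab_waveform.shape}"
            )
        if not np.all(np.isfinite(self.grab_waveform)):
            raise ValueError("grab_waveform must be finite")
        if not 0.0 <= self.stereotypy_level <= 1.0:
            raise ValueError("stereotypy_level must lie in [0, 1]")
        if self.trial_len < TEMPLATE_LEN:
            raise ValueError(f"trial_len must be >= {TEMPLATE_LEN}")
        for name in ("grab_jitter_sd", "time_warp_sd", "baseline_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trials < 1 or self.grabs_per_trial < 1:
            raise ValueError("n_trials and grabs_per_trial must be >= 1")


@dataclass
class LearningSimConfig:
    """Generating coefficients for an animal × day learning table.

    Expected successes for animal *i* on day *d* in group *G* (anodal = 1):
    ``beta0 + beta_day*log(d) + beta_tdcs*G + beta_interaction*G*log(d) + b_i``
    with ``b_i ~ N(0, animal_sd²)`` and residual ``N(0, resid_sd²)``; counts
    are rounded and floored at 0. ``round_counts=False`` emits the latent
    continuous response instead — rounding is a ±0.5 quantisation the linear
    model absorbs as noise, but exact noiseless coefficient recovery is only
    possible on the un-rounded response.
    """

    n_animals: int = 24
    n_days: int = 10
    beta0: float = 5.0
    beta_day: float = 8.0
    beta_tdcs: float = 0.0
    beta_interaction: float = 2.0
    animal_sd: float = 3.0
    resid_sd: float = 4.0
    extra_attempt_mean: float = 15.0
    p_right: float = 13.0 / 24.0
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2 or self.n_animals % 2:
            raise ValueError("n_animals must be even and >= 2 (balanced groups)")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("animal_sd", "resid_sd", "extra_attempt_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_right <= 1.0:
            raise ValueError("p_right must lie in [0, 1]")


@dataclass
class MEPSimConfig:
    """Conditions for simulated MEP sweeps.

    The per-trial burst is a positive half-cosine envelope filling the
    [10, 30) ms post-stimulus window, with amplitude following a logistic
    recruitment curve in stimulation intensity (% of motor threshold)
    times lognormal trial-to-trial jitter, plus Gaussian noise at the
    noise-floor scale.
    """

    n_trials_per_intensity: int = 20
    intensities: tuple[float, ...] = (90.0, 100.0, 120.0, 140.0, 200.0)
    noise_floor_sd: float = 0.01
    recruitment_midpoint: float = 115.0
    recruitment_slope: float = 0.06
    max_amplitude: float = 1.2
    amplitude_jitter_sd: float = 0.2
    response_latency: float = 10.0
    response_duration: float = 20.0
    sample_rate: float = 10_000.0
    sweep_duration: float = 0.06
    stim_onset: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_intensity < 1:
            raise ValueError("n_trials_per_intensity must be >= 1")
        if self.max_amplitude < 0 or self.noise_floor_sd < 0:
            raise ValueError("amplitudes and noise SDs must be >= 0")
        if self.response_latency < 10.0 or (
            self.response_latency + self.response_duration > 30.0
        ):
            raise ValueError("response window must lie within [10, 30] ms post pulse")
        end = self.stim_onset + (self.response_latency + self.response_duration) / 1e3
        if end > self.sweep_duration:
            raise ValueError("response window exceeds sweep duration")


@dataclass
class FieldSimConfig:
    """Conditions for simulated 4-contact lattice field recordings."""

    true_gain_x: float = 0.010
    true_gain_y: float = 0.010
    currents: tuple[float, ...] = (10.0, 20.0, 40.0)
    frequencies: tuple[float, ...] = (10.0, 100.0, 1000.0)
    duration: float = 1.0
    sample_rate: float = 20_000.0
    noise_sd: float = 1e-5
    contact_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_spacing != 1.0:
            raise ValueError("contact_spacing is fixed at 1.0 mm (square planar lattice)")
        if any(c <= 0 for c in self.currents):
            raise ValueError("currents must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be > 0")


# ---------------------------------------------------------------------------
# Pose trials
# ---------------------------------------------------------------------------

class PoseSim(NamedTuple):
    tracks: list[PoseTrack]
    grab_frames: list[list[int]]


def _place_grab_centers(
    rng: np.random.Generator, trial_len: int, n_grabs: int, sep: int
) -> np.ndarray:
    """Random ordered grab centers with pairwise separation >= sep."""
    lo, hi = HALF_WIN, trial_len - HALF_WIN  # window must fit
    slack = (hi - lo) - (n_grabs - 1) * sep
    if slack < 0:
        raise ValueError(
            f"trial_len={trial_len} too short for {n_grabs} grabs "
            f"separated by >= {sep} samples"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n_grabs))
    return (lo + np.floor(u) + np.arange(n_grabs) * sep).astype(int)


def _distort_waveform(
    base: np.ndarray, rng: np.random.Generator, level: float, cfg: TrajectorySimConfig
) -> np.ndarray:
    """One grab realisation: time-warped, shape-noised copy of the base."""
    noise_scale = 1.0 - level
    if noise_scale == 0.0:
        return base.copy()
    # time warp about the window centre
    warp = 1.0 + noise_scale * cfg.time_warp_sd * rng.standard_normal()
    warp = float(np.clip(warp, 0.7, 1.3))
    k = np.arange(TEMPLATE_LEN, dtype=float)
    src = np.clip(HALF_WIN + (k - HALF_WIN) * warp, 0, TEMPLATE_LEN - 1)
    warped = np.empty_like(base)
    for j in range(base.shape[1]):
        warped[:, j] = np.interp(src, k, base[:, j])
    # smooth additive shape noise (correlated across samples, like a
    # trajectory deviation, not per-frame jitter)
    white = rng.standard_normal(base.shape)
    smooth = gaussian_filter1d(white, sigma=4.0, axis=0, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return warped + noise_scale * cfg.grab_jitter_sd * smooth


def gen_pose_trials(cfg: TrajectorySimConfig) -> PoseSim:
    """Simulate pose-tracked reaching trials with known grab times.

    Returns the tracks together with the ground-truth grab centre frames
    per trial. Each trial holds ``grabs_per_trial`` grab events: the base
    waveform distorted by noise scaled by ``1 - stereotypy_level``, spliced
    into a resting baseline, plus per-frame tracking noise everywhere.
    """
    rest = np.empty((1, 7, 2))
    rest[0, :5, 0] = _REST_WRIST[0] + _DIGIT_SPREAD_X
    rest[0, :5, 1] = _REST_WRIST[1] + _DIGIT_OFFSET_Y
    rest[0, 5] = _REST_WRIST
    rest[0, 6] = _PELLET_POS

    tracks: list[PoseTrack] = []
    truth: list[list[int]] = []
    for i in range(cfg.n_trials):
        rng = _rng_for(cfg.seed, i)
        centers = _place_grab_centers(
            rng, cfg.trial_len, cfg.grabs_per_trial, cfg.min_grab_separation
        )
        xy = np.broadcast_to(rest, (cfg.trial_len, 7, 2)).copy()
        for c in centers:
            seg = _distort_waveform(cfg.grab_waveform, rng, cfg.stereotypy_level, cfg)
            sl = slice(c - HALF_WIN, c + HALF_WIN)
            xy[sl, :5, 0] = seg[:, 0::2]
            xy[sl, :5, 1] = seg[:, 1::2]
            # wrist trails the digit centroid
            xy[sl, 5, 0] = seg[:, 0::2].mean(axis=1) - _DIGIT_SPREAD_X.mean()
            xy[sl, 5, 1] = seg[:, 1::2].mean(axis=1) - _DIGIT_OFFSET_Y.mean()
        if cfg.baseline_noise_sd > 0:
            xy += rng.normal(0.0, cfg.baseline_noise_sd, size=xy.shape)
        lk = rng.uniform(0.9, 1.0, size=(cfg.trial_len, 7))
        tracks.append(
            PoseTrack(
                x=xy[:, :, 0],
                y=xy[:, :, 1],
                likelihood=lk,
                frame_rate=cfg.frame_rate,
                labels=POINT_LABELS,
                trial_id=f"trial{i:04d}",
            )
        )
        truth.append([int(c) for c in centers])
    return PoseSim(tracks, truth)


# ---------------------------------------------------------------------------
# Learning table
# ---------------------------------------------------------------------------

def gen_learning_table(cfg: LearningSimConfig) -> pd.DataFrame:
    """Simulate an animal × day learning table.

    One row per animal per day with columns ``animal_id, day, group, paw,
    successes, attempts``. The first half of the animals are anodal, the
    rest control. Success counts follow the Gaussian linear-in-log-day
    model of :class:`LearningSimConfig`, rounded and floored at 0; attempts
    add a Poisson count of unsuccessful reaches on top.
    """
    rows = []
    for i in range(cfg.n_animals):
        rng = _rng_for(cfg.seed, 1, i)
        g = 1 if i < cfg.n_animals // 2 else 0
        b_i = rng.normal(0.0, cfg.animal_sd) if cfg.animal_sd > 0 else 0.0
        paw = "right" if rng.uniform() < cfg.p_right else "left"
        for day in range(1, cfg.n_days + 1):
            ld = np.log(day)
            mu = (
                cfg.beta0
                + cfg.beta_day * ld
                + cfg.beta_tdcs * g
                + cfg.beta_interaction * g * ld
                + b_i
            )
            eps = rng.normal(0.0, cfg.resid_sd) if cfg.resid_sd > 0 else 0.0
            if cfg.round_counts:
                succ = max(0, int(round(mu + eps)))
            else:  # latent continuous response, for exact-recovery validation
                succ = max(0.0, mu + eps)
            extra = int(rng.poisson(cfg.extra_attempt_mean)) if cfg.extra_attempt_mean else 0
            rows.append(
                {
                    "animal_id": f"rat{i:02d}",
                    "day": day,
                    "group": "anodal" if g else "control",
                    "paw": paw,
                    "successes": succ,
                    "attempts": succ + extra,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MEP sweeps
# ---------------------------------------------------------------------------

class MEPSim(NamedTuple):
    sweeps: list
    truth: pd.DataFrame


def recruitment_sigmoid(intensity: np.ndarray | float, cfg: MEPSimConfig) -> np.ndarray | float:
    """Expected MEP amplitude (mV) at an intensity in % of motor threshold."""
    z = cfg.recruitment_slope * (np.asarray(intensity, dtype=float) - cfg.recruitment_midpoint)
    return cfg.max_amplitude / (1.0 + np.exp(-z))


def gen_mep_sweeps(
    cfg: MEPSimConfig,
    *,
    animal_id: str = "rat00",
    hemisphere: str = "contra",
    paw: str = "trained",
) -> MEPSim:
    """Simulate EMG sweeps with sigmoidal recruitment and known window means.

    Returns the sweeps plus a ground-truth table with one row per sweep:
    the trial's noise-free burst amplitude and the analytic mean of the
    rectified signal over the [10, 30) ms post-pulse window.
    """
    from .mep import MEPSweep  # local import avoids a cycle

    n_samp = int(round(cfg.sweep_duration * cfg.sample_rate))
    onset_idx = int(round(cfg.stim_onset * cfg.sample_rate))
    win_lo = onset_idx + int(round(10e-3 * cfg.sample_rate))
    win_hi = onset_idx + int(round(30e-3 * cfg.sample_rate))
    b_lo = onset_idx + int(round(cfg.response_latency * 1e-3 * cfg.sample_rate))
    b_n = int(round(cfg.response_duration * 1e-3 * cfg.sample_rate))
    envelope = np.sin(np.pi * np.arange(b_n) / b_n) ** 2  # positive half-cosine^2

    # analytic rectified window mean per unit amplitude: the burst is the only
    # non-zero signal in the window and its envelope is non-negative
    env_in_win = np.zeros(win_hi - win_lo)
    env_in_win[b_lo - win_lo : b_lo - win_lo + b_n] = envelope
    unit_mean = float(env_in_win.mean())

    # EMG-like carrier: sign alternation leaves |signal| = amplitude * envelope
    carrier = np.sign(
        np.sin(2 * np.pi * 400.0 * np.arange(b_n) / cfg.sample_rate) + 1e-12
    )

    sweeps: list = []
    rows = []
    for j, inten in enumerate(cfg.intensities):
        mean_amp = float(recruitment_sigmoid(inten, cfg))
        for t in range(cfg.n_trials_per_intensity):
            rng = _rng_for(cfg.seed, 2, j, t)
            amp = mean_amp * float(np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd)))
            sig = np.zeros(n_samp)
            sig[b_lo : b_lo + b_n] = amp * envelope * carrier
            if cfg.noise_floor_sd > 0:
                sig += rng.normal(0.0, cfg.noise_floor_sd, size=n_samp)
            sweeps.append(
                MEPSweep(
                    samples=sig,
                    sample_rate=cfg.sample_rate,
                    stim_onset=cfg.stim_onset,
                    intensity=float(inten),
                    hemisphere=hemisphere,
                    paw=paw,
                    animal_id=animal_id,
                    trial_index=t + 1,
                )
            )
            rows.append(
                {
                    "intensity": float(inten),
                    "trial_index": t + 1,
                    "true_amplitude": amp,
                    "true_window_mean": amp * unit_mean,
                }
            )
    return MEPSim(sweeps, pd.DataFrame(rows))


def gen_threshold_ladder(
    currents: list[float],
    frac_above: list[float],
    *,
    n_trials: int = 20,
    noise_floor: float = 0.05,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Construct per-current window-mean ladders with known above-floor counts.

    For each current, exactly ``round(frac_above * n_trials)`` trials get a
    window mean above ``noise_floor`` and the rest below — a fixture for
    exercising the motor-threshold rule with a known answer.
    """
    rng = _rng_for(seed, 3)
    out: dict[float, np.ndarray] = {}
    for c, f in zip(currents, frac_above):
        n_above = int(round(f * n_trials))
        vals = np.concatenate(
            [
                noise_floor * (1.5 + rng.uniform(0, 1, n_above)),
                noise_floor * rng.uniform(0.1, 0.9, n_trials - n_above),
            ]
        )
        rng.shuffle(vals)
        out[float(c)] = vals
    return out


# ---------------------------------------------------------------------------
# Field recordings
# ---------------------------------------------------------------------------

def gen_field_recording(cfg: FieldSimConfig) -> list:
    """Simulate 4-contact lattice potentials for every frequency × current.

    The potential at contact position r is the uniform-field value
    ``V(r, t) = -E(t) · r`` with ``E(t) = gain * current * sin(2π f t)``
    per component (positions in mm converted to metres), plus white noise.
    """
    from .efield import UNIT_SQUARE_MM, FieldRecording  # local import avoids a cycle

    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    pos_m = UNIT_SQUARE_MM * 1e-3
    recs = []
    for fi, f in enumerate(cfg.frequencies):
        for ci, cur in enumerate(cfg.currents):
            rng = _rng_for(cfg.seed, 4, fi, ci)
            ex = cfg.true_gain_x * cur
            ey = cfg.true_gain_y * cur
            carrier = np.sin(2 * np.pi * f * t)
            pots = np.empty((4, n))
            for k in range(4):
                pots[k] = -(ex * pos_m[k, 0] + ey * pos_m[k, 1]) * carrier
            if cfg.noise_sd > 0:
                pots += rng.normal(0.0, cfg.noise_sd, size=pots.shape)
            recs.append(
                FieldRecording(
                    potentials=pots,
                    stim_frequency=float(f),
                    stim_current=float(cur),
                    sample_rate=cfg.sample_rate,
                )
            )
    return recs


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_SECTIONS = {
    "trajectory": TrajectorySimConfig,
    "learning": LearningSimConfig,
    "mep": MEPSimConfig,
    "field": FieldSimConfig,
}


def load_sim_configs(path) -> dict:
    """Load simulation configs from a YAML file.

    The file is a mapping with any of the sections ``trajectory``,
    ``learning``, ``mep``, ``field``; each holds keyword overrides for the
    corresponding config dataclass. List-valued fields (intensities,
    currents, frequencies) are accepted as YAML lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    out = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs = dict(raw[name] or {})
            for key, val in kwargs.items():
                if isinstance(val, list):
                    kwargs[key] = tuple(val)
            out[name] = cls(**kwargs)
    return out
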