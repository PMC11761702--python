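"""Motor-evoked potential (MEP) quantification.

MEPs are muscle responses to epidural motor-cortex microstimulation (trains
of three 0.2 ms pulses at 300 Hz) recorded as EMG sweeps sampled at 10 kHz.
Each sweep is reduced to the mean of the rectified signal over the
[10, 30) ms window after the first stimulation pulse; the median across the
20 trials of one condition is the condition's MEP amplitude, analysed on a
natural-log scale so amplitude differences read as ratios.

The motor threshold is the smallest tested current (0.5–4 mA range) that
evokes a window mean above the 0.05 mV noise floor in at least 90% of
trials (>= 18 of 20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

DEFAULT_WINDOW_MS = (10.0, 30.0)
DEFAULT_NOISE_FLOOR_MV = 0.05
STANDARD_INTENSITIES = (90.0, 100.0, 120.0, 140.0, 200.0)


@dataclass
class MEPSweep:
    """One EMG sweep with its stimulation metadata.

    samples are in mV at ``sample_rate``; ``stim_onset`` is the time of the
    first stimulation pulse in seconds from sweep start; ``intensity`` is
    the stimulation current as % of motor threshold; ``hemisphere`` is
    contra/ipsi relative to the recorded paw.
    """

    samples: np.ndarray
    sample_rate: float = 10_000.0
    stim_onset: float = 0.0
    intensity: float = 100.0
    hemisphere: str = "contra"
    paw: str = "trained"
    animal_id: str = ""
    trial_index: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not 0.0 <= self.stim_onset <= self.samples.size / self.sample_rate:
            raise ValueError("stim_onset must lie within the sweep")
        if self.hemisphere not in ("contra", "ipsi"):
            raise ValueError("hemisphere must be 'contra' or 'ipsi'")
        if self.paw not in ("trained", "untrained"):
            raise ValueError("paw must be 'trained' or 'untrained'")


@dataclass
class MEPAmplitude:
    """Condition-level MEP amplitude: median of per-trial window means."""

    per_trial_means: np.ndarray
    median_mV: float
    log_value: float
    condition: tuple = ()
    n_trials: int = 0
    flags: list[str] = field(default_factory=list)


def mep_window_mean(
    sweep: MEPSweep, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    *, blank_ms: tuple[float, float] | None = None,
) -> float:
    """Mean rectified amplitude over a post-pulse window, in mV.

    The window is half-open, ``[stim_onset + lo, stim_onset + hi)`` in ms
    after the first pulse, default [10, 30). ``blank_ms`` optionally zeroes
    a post-pulse interval (stimulation-artifact blanking, e.g. ``(0, 8)``);
    sweeps are normally artifact-truncated upstream, so it is off by
    default and only matters if the blank overlaps the analysis window.
    """
    lo_ms, hi_ms = window_ms
    if hi_ms <= lo_ms:
        raise ValueError("window must have hi > lo")
    fs = sweep.sample_rate
    i0 = int(round((sweep.stim_onset + lo_ms / 1e3) * fs))
    i1 = int(round((sweep.stim_onset + hi_ms / 1e3) * fs))
    if i0 < 0 or i1 > sweep.samples.size:
        raise ValueError(
            f"window [{lo_ms}, {hi_ms}) ms exceeds sweep of "
            f"{sweep.samples.size / fs * 1e3:.1f} ms"
        )
    seg = np.abs(sweep.samples[i0:i1])
    if blank_ms is not None:
        b0 = int(round((sweep.stim_onset + blank_ms[0] / 1e3) * fs))
        b1 = int(round((sweep.stim_onset + blank_ms[1] / 1e3) * fs))
        ov0, ov1 = max(b0, i0), min(b1, i1)
        if ov1 > ov0:
            seg = seg.copy()
            seg[ov0 - i0 : ov1 - i0] = 0.0
    return float(seg.mean())


def mep_amplitude(
    sweeps: list[MEPSweep], window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> MEPAmplitude:
    """Median-of-trials MEP amplitude for one condition.

    Computes each trial's rectified window mean and takes the median
    (mean of the middle two for even counts), then the natural log. A zero
    median leaves ``log_value`` NaN and flags the condition instead of
    raising, so bookkeeping survives silent muscles.
    """
    if len(sweeps) < 2:
        raise ValueError(f"need >= 2 trials for a median amplitude, got {len(sweeps)}")
    means = np.array([mep_window_mean(s, window_ms) for s in sweeps])
    med = float(np.median(means))
    flags = []
    if med > 0:
        logv = math.log(med)
    else:
        logv = math.nan
        flags.append("zero_median")
    s0 = sweeps[0]
    return MEPAmplitude(
        per_trial_means=means,
        median_mV=med,
        log_value=logv,
        condition=(s0.animal_id, s0.paw, s0.hemisphere, s0.intensity),
        n_trials=len(sweeps),
        flags=flags,
    )


def estimate_threshold(
    trials_by_current: dict[float, np.ndarray],
    noise_floor: float = DEFAULT_NOISE_FLOOR_MV,
) -> float | None:
    """Motor threshold: smallest current evoking supra-floor MEPs in 90% of trials.

    ``trials_by_current`` maps tested current (mA) to that current's
    per-trial rectified window means (mV). A current qualifies when at
    least ``ceil(0.9 * n)`` of its n trials exceed the noise floor
    (>= 18 of 20). Returns the smallest qualifying current, or None when no
    tested current qualifies.
    """
    if not trials_by_current:
        raise ValueError("no currents supplied")
    for current in sorted(trials_by_current):
        means = np.asarray(trials_by_current[current], dtype=float)
        if means.size == 0:
            continue
        need = math.ceil(0.9 * means.size)
        if int((means > noise_floor).sum()) >= need:
            return float(current)
    return None


def recruitment_curve(
    amplitudes: dict[float, MEPAmplitude] | list[MEPAmplitude],
) -> pd.DataFrame:
    """Intensity-sorted recruitment curve from per-intensity amplitudes.

    Returns a DataFrame (intensity, median_mV, log_value, n_trials,
    missing) sorted by intensity; standard intensities absent from the
    input appear as flagged missing rows.
    """
    if isinstance(amplitudes, list):
        amplitudes = {a.condition[3]: a for a in amplitudes}
    rows = []
    for inten in sorted(set(amplitudes) | set(STANDARD_INTENSITIES)):
        if inten in amplitudes:
            a = amplitudes[inten]
            rows.append(
                {
                    "intensity": float(inten),
                    "median_mV": a.median_mV,
                    "log_value": a.log_value,
                    "n_trials": a.n_trials,
                    "missing": False,
                }
            )
        else:
            rows.append(
                {
                    "intensity": float(inten),
                    "median_mV": np.nan,
                    "log_value": np.nan,
                    "n_trials": 0,
                    "missing": True,
                }
            )
    return pd.DataFrame(rows)


def contra_ipsi_log_contrast(contra: MEPAmplitude, ipsi: MEPAmplitude) -> float:
    """Log-amplitude difference between contra- and ipsilateral stimulation.

    Equals the natural log of the amplitude ratio; using the same recording
    electrode for both sides, it controls for EMG-strength differences
    across animals.
    """
    if contra.median_mV <= 0 or ipsi.median_mV <= 0:
        raise ValueError("log contrast undefined for non-positive median amplitudes")
    return math.log(contra.median_mV) - math.log(ipsi.median_mV)


# ---------------------------------------------------------------------------
# Sweep container (HDF5) and flat export
# ---------------------------------------------------------------------------

def write_sweeps(sweeps: list[MEPSweep], path: str | Path) -> None:
    """Write sweeps to HDF5, one dataset per sweep with metadata attributes."""
    with h5py.File(path, "w") as fh:
        for i, s in enumerate(sweeps):
            ds = fh.create_dataset(f"sweep{i:05d}", data=s.samples)
            ds.attrs.update(
                {
                    "sample_rate": s.sample_rate,
                    "stim_onset": s.stim_onset,
                    "intensity": s.intensity,
                    "hemisphere": s.hemisphere,
                    "paw": s.paw,
                    "animal_id": s.animal_id,
                    "trial_index": s.trial_index,
                }
            )


def read_sweeps(path: str | Path) -> list[MEPSweep]:
    """Read an HDF5 sweep container written by :func:`write_sweeps`."""
    out: list[MEPSweep] = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            ds = fh[name]
            out.append(
                MEPSweep(
                    samples=ds[()],
                    sample_rate=float(ds.attrs["sample_rate"]),
                    stim_onset=float(ds.attrs["stim_onset"]),
                    intensity=float(ds.attrs["intensity"]),
                    hemisphere=str(ds.attrs["hemisphere"]),
                    paw=str(ds.attrs["paw"]),
                    animal_id=str(ds.attrs["animal_id"]),
                    trial_index=int(ds.attrs["trial_index"]),
                )
            )
    return out


def amplitude_table(amplitudes: list[MEPAmplitude]) -> pd.DataFrame:
    """Flatten MEPAmplitude records for CSV export / model fitting."""
    return pd.DataFrame(
        {
            "animal_id": [a.condition[0] for a in amplitudes],
            "paw": [a.condition[1] for a in amplitudes],
            "hemisphere": [a.condition[2] for a in amplitudes],
            "intensity": [a.condition[3] for a in amplitudes],
            "median_mV": [a.median_mV for a in amplitudes],
            "log_value": [a.log_value for a in amplitudes],
            "n_trials": [a.n_trials for a in amplitudes],
        }
    )


def sweeps_to_amplitudes(
    sweeps: list[MEPSweep], window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> list[MEPAmplitude]:
    """Group sweeps by (animal, paw, hemisphere, intensity) and reduce each."""
    groups: dict[tuple, list[MEPSweep]] = {}
    for s in sweeps:
        groups.setdefault((s.animal_id, s.paw, s.hemisphere, s.intensity), []).append(s)
    return [mep_amplitude(v, window_ms) for _, v in sorted(groups.items())]
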