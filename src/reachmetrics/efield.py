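"""Intracranial electric-field dosimetry for transcranial stimulation.

Sinusoidal transcranial current at known amplitudes (μA) and frequencies
(Hz) is applied while potentials are recorded on 4 intracortical contacts
arranged as a 1 mm square planar lattice. Assuming a locally uniform field,
the potential differences across the lattice divided by the 1 mm spacing
give the 2D field vector (sign convention E = −∇V); the field magnitude
grows linearly with current, and the slope — the montage gain in
(V/m)/μA — calibrates the current needed for a target field (e.g. 2 V/m at
motor cortex).

Gain is estimated per frequency; DC (0 Hz) is excluded because electrode
impedance dominates constant-current measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Contact positions on the 1 mm square lattice, mm:
#: channel order (0,0), (1,0), (0,1), (1,1).
UNIT_SQUARE_MM = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


@dataclass
class FieldRecording:
    """4-channel potential recording under sinusoidal stimulation."""

    potentials: np.ndarray  # (4, n) volts
    stim_frequency: float  # Hz
    stim_current: float  # μA
    sample_rate: float  # samples/s
    contact_positions: np.ndarray = field(
        default_factory=lambda: UNIT_SQUARE_MM.copy()
    )

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.contact_positions = np.asarray(self.contact_positions, dtype=float)
        if self.potentials.ndim != 2 or self.potentials.shape[0] != 4:
            raise ValueError(
                f"potentials must be (4, n), got {self.potentials.shape}"
            )
        if self.contact_positions.shape != (4, 2):
            raise ValueError("contact_positions must be (4, 2) mm coordinates")
        side = np.linalg.norm(
            self.contact_positions - self.contact_positions[0], axis=1
        )
        if not np.allclose(sorted(side), [0.0, 1.0, 1.0, np.sqrt(2.0)], atol=1e-9):
            raise ValueError("contacts must form a 1 mm square lattice")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class FieldEstimate:
    """2D uniform-field estimate at one (frequency, current) condition."""

    Ex: float  # V/m
    Ey: float  # V/m
    magnitude: float  # V/m
    frequency: float  # Hz
    current: float  # μA

    def __post_init__(self) -> None:
        expected = float(np.hypot(self.Ex, self.Ey))
        if not np.isclose(self.magnitude, expected, rtol=1e-9, atol=1e-12):
            raise ValueError("magnitude must equal sqrt(Ex^2 + Ey^2)")


@dataclass
class GainFit:
    """Current→field gain at one frequency, from a through-origin fit."""

    gain: float  # (V/m)/μA
    per_current_estimates: list[tuple[float, float]]  # (current μA, |E| V/m)
    frequency: float
    fit_residual: float  # RMS residual, V/m
    intercept_diagnostic: float | None = None  # slope offset from an ordinary fit


# ---------------------------------------------------------------------------
# Sinusoid demodulation
# ---------------------------------------------------------------------------

def sinusoid_phasor(
    channel: np.ndarray, freq: float, sample_rate: float
) -> complex:
    """Complex amplitude of the component at ``freq`` by least squares.

    Fits ``a·sin(2πft) + b·cos(2πft) + c`` over an integer number of cycles
    (the record is truncated to whole cycles so the offset and spectral
    leakage do not bias the estimate) and returns ``a + i·b``; its modulus
    is the amplitude, its angle the phase.
    """
    channel = np.asarray(channel, dtype=float)
    if freq <= 0:
        raise ValueError("freq must be > 0 (DC gain is out of scope)")
    n_per_cycle = sample_rate / freq
    n_cycles = int(np.floor(channel.size / n_per_cycle))
    if n_cycles < 1:
        raise ValueError(
            f"record of {channel.size} samples shorter than one cycle "
            f"({n_per_cycle:.0f} samples) at {freq} Hz"
        )
    n = int(round(n_cycles * n_per_cycle))
    t = np.arange(n) / sample_rate
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t), np.ones(n)]
    )
    coef, *_ = np.linalg.lstsq(design, channel[:n], rcond=None)
    return complex(coef[0], coef[1])


def sinusoid_amplitude(
    channel: np.ndarray, freq: float, sample_rate: float
) -> float:
    """Amplitude (same units as the record) of the component at ``freq``."""
    return abs(sinusoid_phasor(channel, freq, sample_rate))


# ---------------------------------------------------------------------------
# Field estimation
# ---------------------------------------------------------------------------

def field_from_potentials(
    amplitudes: np.ndarray,
    positions: np.ndarray = UNIT_SQUARE_MM,
    *,
    frequency: float = np.nan,
    current: float = np.nan,
) -> FieldEstimate:
    """Uniform-field estimate from 4 contact potentials.

    ``amplitudes`` are the 4 channels' (possibly complex, phase-coherent)
    potential amplitudes in volts, ordered as ``positions`` (mm). The field
    is the least-squares gradient fit ``V = c − E·r`` — on the 1 mm square
    lattice this equals the mean of the two x-direction pair differences
    divided by the 1 mm spacing (and likewise for y), with the sign
    convention E = −∇V. Complex inputs are rotated to the common phase
    before taking real parts, so magnitude is phase-invariant.
    """
    amps = np.asarray(amplitudes)
    if amps.shape != (4,):
        raise ValueError(f"expected 4 channel amplitudes, got shape {amps.shape}")
    pos_m = np.asarray(positions, dtype=float) * 1e-3  # mm -> m
    design = np.column_stack([-pos_m, np.ones(4)])  # [-x, -y, 1] => coefs [Ex, Ey, c]
    if np.iscomplexobj(amps):
        coef, *_ = np.linalg.lstsq(design, amps, rcond=None)
        ex_c, ey_c = coef[0], coef[1]
        # rotate the field phasor to its principal phase; for in-phase
        # components this recovers signed real Ex, Ey
        ref = ex_c if abs(ex_c) >= abs(ey_c) else ey_c
        phase = np.exp(-1j * np.angle(ref)) if abs(ref) > 0 else 1.0
        ex, ey = (ex_c * phase).real, (ey_c * phase).real
        # the quadrature remainder after phase rotation is measurement noise
        mag = float(np.hypot(ex, ey))
    else:
        coef, *_ = np.linalg.lstsq(design, amps.astype(float), rcond=None)
        ex, ey = float(coef[0]), float(coef[1])
        mag = float(np.hypot(ex, ey))
    return FieldEstimate(
        Ex=float(ex), Ey=float(ey), magnitude=mag,
        frequency=float(frequency), current=float(current),
    )


def estimate_field(recording: FieldRecording) -> FieldEstimate:
    """Demodulate a recording at its stimulation frequency and fit the field."""
    phasors = np.array(
        [
            sinusoid_phasor(ch, recording.stim_frequency, recording.sample_rate)
            for ch in recording.potentials
        ]
    )
    return field_from_potentials(
        phasors,
        recording.contact_positions,
        frequency=recording.stim_frequency,
        current=recording.stim_current,
    )


# ---------------------------------------------------------------------------
# Gain fitting and calibration
# ---------------------------------------------------------------------------

def fit_gain(estimates: list[FieldEstimate], frequency: float | None = None) -> GainFit:
    """Through-origin fit of field magnitude against current at one frequency.

    Physically zero current produces zero field, so the regression is
    through the origin: gain = Σ(current·|E|) / Σ(current²). An ordinary
    (intercept) fit's slope is retained as a diagnostic when >= 2 currents
    are available. RMS residual is reported in V/m.
    """
    if frequency is not None:
        estimates = [e for e in estimates if e.frequency == frequency]
    if not estimates:
        raise ValueError("no field estimates at the requested frequency")
    cur = np.array([e.current for e in estimates], dtype=float)
    mag = np.array([e.magnitude for e in estimates], dtype=float)
    if np.any(cur <= 0):
        raise ValueError("currents must be > 0")
    gain = float(np.sum(cur * mag) / np.sum(cur**2))
    resid = mag - gain * cur
    ordinary = None
    if len(np.unique(cur)) >= 2:
        ordinary = float(np.polyfit(cur, mag, 1)[0])
    return GainFit(
        gain=gain,
        per_current_estimates=[(float(c), float(m)) for c, m in zip(cur, mag)],
        frequency=float(estimates[0].frequency),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
        intercept_diagnostic=ordinary,
    )


def calibrate_current(target_field: float, gain: float) -> float:
    """Current (μA) needed for a target field (V/m) given a montage gain."""
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    if target_field < 0:
        raise ValueError("target_field must be >= 0")
    return target_field / gain


def outlier_flag(
    estimates: list[FieldEstimate],
    *,
    mad_multiple: float = 3.0,
) -> np.ndarray:
    """Flag estimates inconsistent with the through-origin current→field line.

    The reference line uses the robust through-origin slope — the median of
    the per-point magnitude/current ratios — so a gross outlier cannot drag
    the line toward itself and implicate clean points. Residuals from that
    line beyond ``mad_multiple`` median absolute deviations (MAD) of the
    median residual are flagged. A degenerate MAD of 0 (e.g. a perfect
    line) flags nothing unless a residual departs by more than a
    magnitude-relative epsilon. Flagged points are only excluded from a
    refit when the caller chooses to.
    """
    cur = np.array([e.current for e in estimates], dtype=float)
    mag = np.array([e.magnitude for e in estimates], dtype=float)
    if np.any(cur <= 0):
        raise ValueError("currents must be > 0")
    robust_gain = float(np.median(mag / cur))
    resid = mag - robust_gain * cur
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    eps = 1e-9 * max(1.0, float(np.max(np.abs(mag))))
    thresh = max(mad_multiple * mad, eps)
    return np.abs(resid - med) > thresh


def gain_report(estimates: list[FieldEstimate]) -> pd.DataFrame:
    """Per-frequency gain table (frequency, gain, rms_residual, n)."""
    rows = []
    for f in sorted({e.frequency for e in estimates}):
        fit = fit_gain(estimates, frequency=f)
        rows.append(
            {
                "frequency_Hz": f,
                "gain_Vpm_per_uA": fit.gain,
                "rms_residual_Vpm": fit.fit_residual,
                "n_conditions": len(fit.per_current_estimates),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recording container (HDF5)
# ---------------------------------------------------------------------------

def write_recordings(recordings: list[FieldRecording], path: str | Path) -> None:
    """Write recordings to HDF5, one group per (frequency, current)."""
    with h5py.File(path, "w") as fh:
        for i, r in enumerate(recordings):
            grp = fh.create_group(f"rec{i:04d}")
            grp.create_dataset("potentials", data=r.potentials)
            grp.create_dataset("contact_positions", data=r.contact_positions)
            grp.attrs["stim_frequency"] = r.stim_frequency
            grp.attrs["stim_current"] = r.stim_current
            grp.attrs["sample_rate"] = r.sample_rate


def read_recordings(path: str | Path) -> list[FieldRecording]:
    """Read an HDF5 recording container written by :func:`write_recordings`."""
    out: list[FieldRecording] = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            grp = fh[name]
            out.append(
                FieldRecording(
                    potentials=grp["potentials"][()],
                    contact_positions=grp["contact_positions"][()],
                    stim_frequency=float(grp.attrs["stim_frequency"]),
                    stim_current=float(grp.attrs["stim_current"]),
                    sample_rate=float(grp.attrs["sample_rate"]),
                )
            )
    return out
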