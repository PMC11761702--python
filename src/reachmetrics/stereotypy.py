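"""Movement-stereotypy scoring by trajectory template matching.

A grab is a single reach-and-close event; trials usually contain several.
Stereotypy — the trial-to-trial similarity of the movement — is scored by
cross-correlating each trial's digit trajectories against a canonical
50-sample (150 ms at 309 frames/s) grab template built per animal and
session, detecting grabs as correlation peaks, and taking the correlation
at the final grab of the trial as the trial's stereotypy score.

"Correlation" throughout is the Pearson correlation coefficient computed
per coordinate over the 50-sample window and averaged across the 10 digit
coordinates (5 digits × {x, y}), i.e. normalised cross-correlation: the
score is bounded in [-1, 1] and invariant to uniform translation and
positive scaling of the coordinate frame.

Window alignment is causal-centred: the score at frame f correlates the
template against trial frames [f - 25, f + 25). Alignments whose window
overruns the trial edges are undefined (NaN), never zero-filled, so the
"last peak" cannot be an edge artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .pose import PoseTrack

logger = logging.getLogger(__name__)

TEMPLATE_LEN = 50
HALF_WIN = TEMPLATE_LEN // 2

DEFAULT_MIN_SEPARATION = 50  # one template length
DEFAULT_MIN_SCORE = 0.3


@dataclass
class GrabTemplate:
    """Canonical grab trajectory: a 50-sample × 10-coordinate matrix.

    Built by averaging the digit-coordinate windows of three grabs from one
    animal's training session.
    """

    values: np.ndarray
    animal_id: str = ""
    day: int = 1
    source_trials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TEMPLATE_LEN, 10):
            raise ValueError(
                f"template must be {TEMPLATE_LEN}x10, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template values must be finite")


@dataclass(frozen=True)
class GrabEvent:
    """A detected grab: correlation peak frame, its score, finality flag."""

    frame: int
    score: float
    is_final: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError(f"score must lie in [-1, 1], got {self.score}")


@dataclass(frozen=True)
class StereotypyRecord:
    """Per-trial stereotypy: the correlation score at the final grab."""

    trial_id: str
    animal_id: str
    day: int
    frame: int | None
    score: float | None
    success: bool | None = None


# ---------------------------------------------------------------------------
# Windows and templates
# ---------------------------------------------------------------------------

def extract_grab_window(track: PoseTrack, center_frame: int) -> np.ndarray:
    """Digit-coordinate window of 50 samples centred on a frame.

    Returns trial frames ``[center - 25, center + 25)`` of the (n, 10)
    digit matrix. Raises if the window overruns the trial.
    """
    lo = center_frame - HALF_WIN
    hi = center_frame + HALF_WIN
    if lo < 0 or hi > track.n_frames:
        raise ValueError(
            f"window [{lo}, {hi}) out of bounds for trial of {track.n_frames} frames"
        )
    return track.digit_matrix()[lo:hi]


def build_template(
    tracks: list[PoseTrack], grab_frames: list[int]
) -> GrabTemplate:
    """Average the grab windows of three trials into a session template."""
    if len(tracks) < 3 or len(grab_frames) < 3:
        raise ValueError(
            f"template needs 3 grabs, got {min(len(tracks), len(grab_frames))}"
        )
    wins = [
        extract_grab_window(tr, f) for tr, f in zip(tracks[:3], grab_frames[:3])
    ]
    first = tracks[0]
    return GrabTemplate(
        values=np.mean(wins, axis=0),
        animal_id=first.animal_id,
        day=first.day,
        source_trials=tuple(tr.trial_id for tr in tracks[:3]),
    )


# ---------------------------------------------------------------------------
# Sliding correlation
# ---------------------------------------------------------------------------

def sliding_correlation(track: PoseTrack, template: GrabTemplate) -> np.ndarray:
    """Averaged windowed Pearson correlation of a trial against a template.

    At every frame f whose 50-sample window fits the trial, the Pearson
    correlation between the window and the template is computed separately
    for each of the 10 digit coordinates and the 10 values averaged.
    Returns a length-``n_frames`` series; alignments whose window overruns
    the edges are NaN. A zero-variance window or template coordinate
    contributes a correlation of 0 at that alignment (logged).
    """
    n = track.n_frames
    if n < TEMPLATE_LEN:
        raise ValueError(f"trial length {n} shorter than template ({TEMPLATE_LEN})")
    X = track.digit_matrix()  # (n, 10)
    T = template.values  # (50, 10)

    # windows: (n - 49, 10, 50); windows[s, j] = X[s:s+50, j]
    W = sliding_window_view(X, TEMPLATE_LEN, axis=0)
    Wc = W - W.mean(axis=2, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)  # (50, 10)
    num = np.einsum("sjk,kj->sj", Wc, Tc)
    w_ss = np.einsum("sjk,sjk->sj", Wc, Wc)
    t_ss = np.einsum("kj,kj->j", Tc, Tc)
    denom = np.sqrt(w_ss * t_ss[None, :])
    zero = denom <= 0
    if np.any(zero):
        logger.info(
            "zero-variance coordinate in %d window/coordinate pairs; "
            "correlation set to 0 there",
            int(zero.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(zero, 0.0, num / np.where(zero, 1.0, denom))
    series = np.full(n, np.nan)
    # window starting at s is centred at frame s + 25
    series[HALF_WIN : HALF_WIN + r.shape[0]] = np.clip(r.mean(axis=1), -1.0, 1.0)
    return series


# ---------------------------------------------------------------------------
# Grab detection and scoring
# ---------------------------------------------------------------------------

def detect_grabs(
    corr: np.ndarray,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[GrabEvent]:
    """Detect grabs as separated local maxima of the correlation series.

    Local maxima above ``min_score`` are kept greedily in descending score
    order subject to a ``min_separation`` exclusion zone; the last
    surviving peak in time is flagged ``is_final``. NaN alignments
    (edges) never host a peak. Returns events sorted by frame.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.size < 3:
        return []
    v = np.where(np.isnan(corr), -np.inf, corr)
    interior = (v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:]) & np.isfinite(v[1:-1])
    cand = np.flatnonzero(interior) + 1
    cand = cand[v[cand] > min_score]
    if cand.size == 0:
        return []
    # plateaus: collapse runs of equal neighbouring values to their first frame
    keep_mask = np.ones(cand.size, dtype=bool)
    keep_mask[1:] = ~((np.diff(cand) == 1) & (np.diff(v[cand]) == 0))
    cand = cand[keep_mask]

    order = cand[np.argsort(v[cand], kind="stable")[::-1]]
    kept: list[int] = []
    for f in order:
        if all(abs(f - k) >= min_separation for k in kept):
            kept.append(int(f))
    kept.sort()
    return [
        GrabEvent(frame=f, score=float(corr[f]), is_final=(i == len(kept) - 1))
        for i, f in enumerate(kept)
    ]


def stereotypy_score(
    track: PoseTrack,
    template: GrabTemplate,
    *,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_score: float = DEFAULT_MIN_SCORE,
) -> StereotypyRecord:
    """Score one trial: the correlation at its final detected grab.

    Trials with no detected grab return a record with ``score=None`` and
    are excluded from downstream statistics (the caller counts them).
    """
    corr = sliding_correlation(track, template)
    events = detect_grabs(corr, min_separation=min_separation, min_score=min_score)
    if not events:
        return StereotypyRecord(
            trial_id=track.trial_id, animal_id=track.animal_id, day=track.day,
            frame=None, score=None, success=track.success,
        )
    final = events[-1]
    return StereotypyRecord(
        trial_id=track.trial_id, animal_id=track.animal_id, day=track.day,
        frame=final.frame, score=final.score, success=track.success,
    )


# ---------------------------------------------------------------------------
# Session-level template selection
# ---------------------------------------------------------------------------

def motion_energy_center(track: PoseTrack) -> int:
    """Frame of peak digit motion energy, clipped so a window fits.

    Motion energy is the summed squared frame-to-frame displacement of the
    10 digit coordinates, smoothed over one template length — a template-free
    proxy for "a grab happens here", used only to bootstrap a seed template.
    """
    X = track.digit_matrix()
    speed2 = np.sum(np.diff(X, axis=0) ** 2, axis=1)
    kernel = np.ones(TEMPLATE_LEN) / TEMPLATE_LEN
    energy = np.convolve(speed2, kernel, mode="same")
    c = int(np.argmax(energy))
    return int(np.clip(c, HALF_WIN, track.n_frames - HALF_WIN))


def build_session_template(
    tracks: list[PoseTrack],
    *,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_score: float = DEFAULT_MIN_SCORE,
) -> GrabTemplate:
    """Build one animal/session template from that session's trials.

    The three grabs to average are not hand-picked: a seed template is
    bootstrapped as the cross-trial average of the windows at each trial's
    peak motion energy; the seed is slid along the first trials and, from
    each of the first three trials with a detected grab, the
    highest-scoring grab is taken. The final template averages those three
    windows. The selection is logged per session.
    """
    if len(tracks) < 3:
        raise ValueError(f"session template needs >= 3 trials, got {len(tracks)}")
    seed_wins = [extract_grab_window(tr, motion_energy_center(tr)) for tr in tracks]
    seed = GrabTemplate(
        values=np.mean(seed_wins, axis=0),
        animal_id=tracks[0].animal_id,
        day=tracks[0].day,
    )
    chosen_tracks: list[PoseTrack] = []
    chosen_frames: list[int] = []
    for tr in tracks:
        corr = sliding_correlation(tr, seed)
        events = detect_grabs(corr, min_separation=min_separation, min_score=min_score)
        if not events:
            continue
        best = max(events, key=lambda e: e.score)
        chosen_tracks.append(tr)
        chosen_frames.append(best.frame)
        if len(chosen_tracks) == 3:
            break
    if len(chosen_tracks) < 3:
        raise ValueError(
            f"only {len(chosen_tracks)} of {len(tracks)} trials had a detectable "
            "grab against the seed template; cannot build a session template"
        )
    logger.info(
        "session template %s/day%s from trials %s at frames %s",
        tracks[0].animal_id, tracks[0].day,
        [t.trial_id for t in chosen_tracks], chosen_frames,
    )
    return build_template(chosen_tracks, chosen_frames)


def score_session(
    tracks: list[PoseTrack],
    template: GrabTemplate | None = None,
    *,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_score: float = DEFAULT_MIN_SCORE,
) -> pd.DataFrame:
    """Score every trial of a session; build the template if not supplied.

    Returns a DataFrame with columns trial_id, animal_id, day, frame,
    score, success (frame/score NaN where no grab was detected; the count
    of such trials is logged).
    """
    if template is None:
        template = build_session_template(
            tracks, min_separation=min_separation, min_score=min_score
        )
    recs = [
        stereotypy_score(
            tr, template, min_separation=min_separation, min_score=min_score
        )
        for tr in tracks
    ]
    n_missing = sum(r.score is None for r in recs)
    if n_missing:
        logger.info("%d/%d trials had no detected grab", n_missing, len(recs))
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in recs],
            "animal_id": [r.animal_id for r in recs],
            "day": [r.day for r in recs],
            "frame": [np.nan if r.frame is None else r.frame for r in recs],
            "score": [np.nan if r.score is None else r.score for r in recs],
            "success": [r.success for r in recs],
        }
    )


# ---------------------------------------------------------------------------
# Template archive (HDF5)
# ---------------------------------------------------------------------------

def save_templates(templates: list[GrabTemplate], path: str | Path) -> None:
    """Write templates to an HDF5 archive, one dataset per animal/day."""
    with h5py.File(path, "w") as fh:
        for tpl in templates:
            ds = fh.create_dataset(f"{tpl.animal_id}/day{tpl.day}", data=tpl.values)
            ds.attrs["animal_id"] = tpl.animal_id
            ds.attrs["day"] = tpl.day
            ds.attrs["source_trials"] = list(tpl.source_trials)


def load_templates(path: str | Path) -> list[GrabTemplate]:
    """Read an HDF5 template archive written by :func:`save_templates`."""
    out: list[GrabTemplate] = []

    with h5py.File(path, "r") as fh:
        def _visit(name: str, obj) -> None:
            if isinstance(obj, h5py.Dataset):
                out.append(
                    GrabTemplate(
                        values=obj[()],
                        animal_id=str(obj.attrs["animal_id"]),
                        day=int(obj.attrs["day"]),
                        source_trials=tuple(
                            str(s) for s in obj.attrs.get("source_trials", [])
                        ),
                    )
                )

        fh.visititems(_visit)
    return out
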