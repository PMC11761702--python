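"""Pose-track containers, markerless-tracking CSV I/O and preprocessing.

Trials are short high-speed videos (~309 frames/s) of a rat reaching for a
food pellet. A markerless tracker labels six points of interest — the five
digits, the wrist and the pellet — and emits one (x, y, likelihood) column
triplet per body part under a three-row header (scorer / bodyparts /
coords). This module reads and writes that dialect, median-filters the
traces, mirrors left-pawed animals into the right-pawed frame, and applies
the 6-of-10 paw-preference rule used during shaping.

Conventions: pixel coordinates with the image origin at the top-left
(x rightward, y downward), 0-based frame indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical body-part order: five digits (thumb-side to pinky-side),
#: wrist, pellet.
POINT_LABELS: tuple[str, ...] = (
    "digit1",
    "digit2",
    "digit3",
    "digit4",
    "digit5",
    "wrist",
    "pellet",
)

DIGIT_LABELS: tuple[str, ...] = POINT_LABELS[:5]

#: Default acquisition frame rate, frames per second.
DEFAULT_FRAME_RATE = 309.0


class PoseIOError(ValueError):
    """Raised for malformed pose CSV files."""


@dataclass
class PoseTrack:
    """Per-trial time series of labelled 2D points with confidence.

    Parameters
    ----------
    x, y : ndarray, shape (n_frames, n_points)
        Pixel coordinates per frame per body part, ordered as
        :data:`POINT_LABELS`.
    likelihood : ndarray, shape (n_frames, n_points)
        Tracker confidence in [0, 1].
    frame_rate : float
        Frames per second (> 0).
    trial_id, animal_id : str
    day : int
        Training day, 1-based.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    labels: tuple[str, ...] = POINT_LABELS
    trial_id: str = ""
    animal_id: str = ""
    day: int = 1
    success: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValueError(
                "x, y and likelihood must share one shape; got "
                f"{self.x.shape}, {self.y.shape}, {self.likelihood.shape}"
            )
        if self.x.ndim != 2 or self.x.shape[1] != len(self.labels):
            raise ValueError(
                f"expected (n_frames, {len(self.labels)}) arrays, got {self.x.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        lk = self.likelihood
        if lk.size and (np.nanmin(lk) < 0 or np.nanmax(lk) > 1):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_points(self) -> int:
        return self.x.shape[1]

    def point_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown body part {label!r}") from None

    def digit_matrix(self) -> np.ndarray:
        """Stack the five digits' coordinates as an (n_frames, 10) matrix.

        Column order is (digit1 x, digit1 y, digit2 x, ..., digit5 y) — the
        ten coordinate series the stereotypy statistic correlates.
        """
        cols = [self.point_index(lab) for lab in DIGIT_LABELS]
        out = np.empty((self.n_frames, 10), dtype=float)
        out[:, 0::2] = self.x[:, cols]
        out[:, 1::2] = self.y[:, cols]
        return out


@dataclass(frozen=True)
class ReachOutcome:
    """Outcome bookkeeping for one trial."""

    trial_id: str
    success: bool
    attempt_count: int

    def __post_init__(self) -> None:
        if self.attempt_count < 0:
            raise ValueError("attempt_count must be >= 0")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_pose_csv(
    path: str | Path,
    *,
    frame_rate: float = DEFAULT_FRAME_RATE,
    trial_id: str = "",
    animal_id: str = "",
    day: int = 1,
) -> PoseTrack:
    """Read a pose CSV in the three-header-row tracking dialect.

    The file must carry the header rows ``scorer`` / ``bodyparts`` /
    ``coords`` with one x/y/likelihood column triplet per body part. A
    missing likelihood column is tolerated and filled with 1.0. Body parts
    are mapped onto the canonical 7-point order regardless of file order.

    Raises
    ------
    PoseIOError
        On unknown or missing body-part labels, or ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise PoseIOError(f"{path.name}: malformed pose CSV: {exc}") from exc

    parts = list(dict.fromkeys(df.columns.get_level_values(1)))
    unknown = [p for p in parts if p not in POINT_LABELS]
    if unknown:
        raise PoseIOError(
            f"{path.name}: unknown body-part label(s): {', '.join(unknown)}"
        )
    missing = [p for p in POINT_LABELS if p not in parts]
    if missing:
        raise PoseIOError(
            f"{path.name}: missing body-part label(s): {', '.join(missing)}"
        )

    n = len(df)
    x = np.empty((n, len(POINT_LABELS)))
    y = np.empty_like(x)
    lk = np.ones_like(x)
    scorer = df.columns.get_level_values(0)[0]
    for j, part in enumerate(POINT_LABELS):
        sub = df[scorer][part]
        for coord in ("x", "y"):
            if coord not in sub.columns:
                raise PoseIOError(f"{path.name}: {part} lacks a {coord!r} column")
        x[:, j] = sub["x"].to_numpy(dtype=float)
        y[:, j] = sub["y"].to_numpy(dtype=float)
        if "likelihood" in sub.columns:
            lk[:, j] = sub["likelihood"].to_numpy(dtype=float)

    meta = trial_id or path.stem
    return PoseTrack(
        x=x, y=y, likelihood=np.clip(lk, 0.0, 1.0), frame_rate=frame_rate,
        trial_id=meta, animal_id=animal_id, day=day,
    )


def write_pose_csv(track: PoseTrack, path: str | Path, *, scorer: str = "reachmetrics") -> None:
    """Write a :class:`PoseTrack` in the same dialect :func:`read_pose_csv` reads.

    Coordinates are written at full float precision so read∘write is the
    identity.
    """
    cols = pd.MultiIndex.from_tuples(
        [
            (scorer, part, coord)
            for part in track.labels
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((track.n_frames, 3 * track.n_points))
    data[:, 0::3] = track.x
    data[:, 1::3] = track.y
    data[:, 2::3] = track.likelihood
    df = pd.DataFrame(data, columns=cols)
    df.index.name = None
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def median_filter_track(track: PoseTrack, window: int = 5) -> PoseTrack:
    """Running-median filter of every coordinate series.

    The default 5-sample window is ~15 ms at 309 frames/s and removes
    single-frame tracker glitches. Edges are handled by shrinking the
    window (the half-windows overhanging the trial are dropped), so series
    length is preserved. Likelihood is left untouched.

    Parameters
    ----------
    window : int
        Odd window length in samples, >= 1. ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if window == 1:
        return replace(track, x=track.x.copy(), y=track.y.copy())

    def _run(a: np.ndarray) -> np.ndarray:
        return (
            pd.DataFrame(a)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )

    return replace(track, x=_run(track.x), y=_run(track.y))


def mirror_if_left(track: PoseTrack, paw: str, image_width: int) -> PoseTrack:
    """Horizontally flip a left-pawed animal's track into the right-pawed frame.

    Left-pawed videos are mirrored so one analysis template applies to all
    animals: ``x -> image_width - 1 - x`` (0-based pixel convention), y
    unchanged. Right-pawed tracks pass through untouched.
    """
    if paw not in ("left", "right"):
        raise ValueError(f"paw must be 'left' or 'right', got {paw!r}")
    if paw == "right":
        return track
    return replace(track, x=(image_width - 1) - track.x, y=track.y.copy())


def paw_preference(reach_sides: list[str]) -> str:
    """Determine the preferred paw from the first 10 shaping reaches.

    The preferred paw is the one used at least 6 of the first 10 times; a
    5–5 split returns ``"undetermined"`` and the caller should extend
    shaping.

    Raises
    ------
    ValueError
        With fewer than 10 observed reaches.
    """
    if len(reach_sides) < 10:
        raise ValueError(
            f"paw preference needs >= 10 shaping reaches, got {len(reach_sides)}"
        )
    first = reach_sides[:10]
    bad = sorted({s for s in first if s not in ("left", "right")})
    if bad:
        raise ValueError(f"unknown side label(s): {', '.join(map(str, bad))}")
    n_right = sum(s == "right" for s in first)
    if n_right >= 6:
        return "right"
    if n_right <= 4:
        return "left"
    return "undetermined"
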