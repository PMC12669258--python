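"""The closed-loop feedback engine.

Every iteration (default cadence 250 ms of simulated time) the engine takes
the last 3 s of the stream, applies the online cleaning chain (drop mastoids,
band-pass + notch, stored-ICA cleanup, bad-channel interpolation, average
reference), backfits the templates without smoothing, and computes the target
state's time coverage. Raw coverages are smoothed by a linearly time-weighted
average of the last 10 values and scaled against the calibration thresholds:

    feedback = 1 - 2 * (max - score) / (max - min)

which maps score = min to -1, score = max to +1 and the midpoint to 0
(clipped to [-1, +1] by default — a gauge cannot over-fill). The up/down
session direction never changes the computed value, only how the display
interprets it: participants are blind to the computation.

Time is simulated sample count over the sampling rate, decoupling behaviour
from wall-clock speed; a deterministic stream yields a bit-identical trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .layout import MASTOIDS
from .microstates import TemplateSet, backfit
from .preprocess import ICASolution, apply_ica, average_reference, bandpass, interpolate_bads, notch
from .recording import EEGRecording

__all__ = [
    "EngineConfig",
    "FeedbackSample",
    "FeedbackTrace",
    "Stream",
    "ReplayStream",
    "score_window",
    "smooth_score",
    "feedback_value",
    "run_session",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EngineConfig:
    """Loop and session parameters.

    Defaults are the full protocol: 3 s windows every 250 ms, 10-score
    smoothing, 10 blocks of 3 min separated by 20 s breaks.
    """

    window_s: float = 3.0
    step_s: float = 0.25
    n_smooth: int = 10
    target_state: int | str = "D"
    direction: str = "up"
    n_blocks: int = 10
    block_s: float = 180.0
    break_s: float = 20.0
    clip: bool = True
    apply_filters: bool = True
    bandpass_hz: tuple[float, float] = (1.0, 30.0)
    notch_hz: tuple[float, float] = (49.0, 51.0)
    reset_history_at_block: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if self.n_smooth < 1:
            raise ValueError("n_smooth must be >= 1")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass(frozen=True)
class FeedbackSample:
    """One loop iteration: raw coverage, smoothed score, scaled feedback."""

    t: float
    raw_coverage: float
    smoothed_score: float
    feedback: float
    block: int


@dataclass
class FeedbackTrace:
    """Ordered feedback samples plus block markers."""

    samples: list[FeedbackSample] = field(default_factory=list)
    direction: str = "up"

    def append(self, sample: FeedbackSample) -> None:
        if self.samples and sample.t <= self.samples[-1].t:
            raise ValueError("timestamps must be strictly increasing")
        self.samples.append(sample)

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.t, s.raw_coverage, s.smoothed_score, s.feedback, s.block)
                for s in self.samples
            ],
            columns=["t", "raw_coverage", "smoothed_score", "feedback", "block"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def block_means(self, column: str = "raw_coverage") -> pd.Series:
        """Per-block mean of a trace column (index = block number)."""
        df = self.to_frame()
        return df.groupby("block")[column].mean()


# ----------------------------------------------------------------------
# streams
# ----------------------------------------------------------------------

@runtime_checkable
class Stream(Protocol):
    """Pull-based sample source for the engine.

    ``read(n)`` returns a ``(n_channels, m)`` chunk with ``m <= n``
    (``m < n`` signals exhaustion). Streams may implement ``on_feedback`` to
    observe emitted feedback values (closed-loop virtual subjects do).
    """

    sfreq: float

    def read(self, n_samples: int) -> np.ndarray: ...


class ReplayStream:
    """Replay a recorded file / in-memory recording sample by sample."""

    def __init__(self, recording: EEGRecording):
        self.recording = recording
        self.sfreq = recording.sfreq
        self.layout = recording.layout
        self._pos = 0

    def read(self, n_samples: int) -> np.ndarray:
        chunk = self.recording.data[:, self._pos:self._pos + n_samples]
        self._pos += chunk.shape[1]
        return chunk


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def score_window(window: EEGRecording, templates: TemplateSet, target_state) -> float:
    """Target-state time coverage of a raw window (no smoothing)."""
    target = templates.state_index(target_state)
    return backfit(window, templates).coverage(target)


def smooth_score(history, n_smooth: int = 10) -> float:
    """Linearly time-weighted mean of the most recent raw coverages.

    The last ``m = min(len(history), n_smooth)`` values get weights
    ``1..m`` (most recent highest), normalised by their sum. With a single
    value the score is that value.
    """
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    recent = np.asarray(history[-n_smooth:], float)
    w = np.arange(1, recent.size + 1, dtype=float)
    return float((w * recent).sum() / w.sum())


def feedback_value(score: float, calib: CalibrationResult, clip: bool = True) -> float:
    """Scale a smoothed score to the gauge range via the calibration thresholds."""
    lo, hi = calib.min_threshold, calib.max_threshold
    if hi <= lo:
        raise ValueError("degenerate calibration: max_threshold <= min_threshold")
    value = 1.0 - 2.0 * (hi - score) / (hi - lo)
    if clip:
        value = float(np.clip(value, -1.0, 1.0))
    return value


# ----------------------------------------------------------------------
# session loop
# ----------------------------------------------------------------------

def _clean_window(
    window: EEGRecording, config: EngineConfig, ica: ICASolution | None
) -> EEGRecording:
    out = window
    if any(m in out.ch_names for m in MASTOIDS):
        out = out.drop_channels(MASTOIDS)
    if config.apply_filters:
        out = bandpass(out, *config.bandpass_hz)
        out = notch(out, *config.notch_hz)
    if ica is not None:
        out = apply_ica(out, ica)
    if out.layout.bads:
        out = interpolate_bads(out)
    return average_reference(out)


def run_session(
    stream: Stream,
    calib: CalibrationResult,
    config: EngineConfig,
    templates: TemplateSet,
    ica: ICASolution | None = None,
) -> FeedbackTrace:
    """Run the block/break session structure over a stream.

    Scores are only emitted once a full window of samples exists (warm-up);
    smoothing uses however many scores have accumulated, and its history is
    reset at each block start so a block never leaks pre-break data. During
    breaks the stream keeps advancing but no score is computed. A stream
    underrun ends the session early (logged).
    """
    fs = stream.sfreq
    win = int(round(config.window_s * fs))
    step = int(round(config.step_s * fs))
    break_n = int(round(config.break_s * fs))
    block_n = int(round(config.block_s * fs))
    buffer: np.ndarray | None = None
    trace = FeedbackTrace(direction=config.direction)
    t_samples = 0
    history: list[float] = []
    notify = getattr(stream, "on_feedback", None)

    def _push(chunk: np.ndarray) -> None:
        nonlocal buffer, t_samples
        t_samples += chunk.shape[1]
        if buffer is None:
            buffer = chunk
        else:
            buffer = np.concatenate([buffer, chunk], axis=1)
        if buffer.shape[1] > win:
            buffer = buffer[:, -win:]

    for block in range(config.n_blocks):
        if config.reset_history_at_block:
            history = []
        consumed = 0
        underrun = False
        while consumed < block_n:
            chunk = stream.read(min(step, block_n - consumed))
            if chunk.shape[1] == 0:
                underrun = True
                break
            consumed += chunk.shape[1]
            _push(chunk)
            if buffer.shape[1] < win:
                continue  # warm-up: window not yet full, iteration skipped
            window = EEGRecording(
                data=buffer.copy(), sfreq=fs, layout=getattr(stream, "layout")
            )
            cleaned = _clean_window(window, config, ica)
            raw = score_window(cleaned, templates, config.target_state)
            history.append(raw)
            history = history[-config.n_smooth:]
            score = smooth_score(history, config.n_smooth)
            fb = feedback_value(score, calib, clip=config.clip)
            trace.append(
                FeedbackSample(
                    t=t_samples / fs, raw_coverage=raw, smoothed_score=score,
                    feedback=fb, block=block,
                )
            )
            if notify is not None:
                notify(fb)
        if underrun:
            logger.warning("stream underrun in block %d; session ended early", block)
            break
        if block < config.n_blocks - 1 and break_n > 0:
            chunk = stream.read(break_n)
            if chunk.shape[1]:
                _push(chunk)
    return trace
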