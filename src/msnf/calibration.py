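"""Per-participant feedback calibration.

A resting-state recording (already filtered, ICA-cleaned and
average-referenced) is split into overlapping epochs that mimic the real-time
processing cadence; each epoch is backfitted without smoothing and the target
state's time coverage collected. The feedback gauge range is then set to one
standard deviation around the mean of that coverage distribution:

    min = mu - sigma,   max = mu + sigma.

Calibration is deterministic: no randomness is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .microstates import TemplateSet, backfit
from .preprocess import epoch
from .recording import EEGRecording

__all__ = ["CalibrationError", "DegenerateCalibrationError", "CalibrationResult", "calibrate"]


class CalibrationError(ValueError):
    """Recording unsuitable for calibration (e.g. too short)."""


class DegenerateCalibrationError(CalibrationError):
    """All epochs had identical coverage: sigma = 0, thresholds collapse."""


@dataclass(frozen=True)
class CalibrationResult:
    """Epoch-wise coverage distribution and the derived feedback thresholds."""

    coverages: np.ndarray
    mu: float
    sigma: float
    min_threshold: float
    max_threshold: float
    target_state: int
    epoch_length_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coverages", np.asarray(self.coverages, float))
        if not np.isclose(self.min_threshold, self.mu - self.sigma):
            raise ValueError("min_threshold must equal mu - sigma")
        if not np.isclose(self.max_threshold, self.mu + self.sigma):
            raise ValueError("max_threshold must equal mu + sigma")

    def to_json(self, path=None) -> str:
        obj = {
            "coverages": [float(c) for c in self.coverages],
            "mu": self.mu,
            "sigma": self.sigma,
            "min_threshold": self.min_threshold,
            "max_threshold": self.max_threshold,
            "target_state": self.target_state,
            "epoch_length_s": self.epoch_length_s,
            "overlap_s": self.overlap_s,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        obj = json.loads(Path(path).read_text())
        return cls(
            coverages=np.asarray(obj["coverages"], float),
            mu=obj["mu"], sigma=obj["sigma"],
            min_threshold=obj["min_threshold"],
            max_threshold=obj["max_threshold"],
            target_state=obj["target_state"],
            epoch_length_s=obj["epoch_length_s"],
            overlap_s=obj["overlap_s"],
        )


def thresholds_from_coverages(
    coverages: np.ndarray,
    target_state: int,
    epoch_length_s: float,
    overlap_s: float,
    ddof: int = 0,
) -> CalibrationResult:
    """Build a CalibrationResult from an epoch-coverage distribution.

    The standard deviation is the population SD by default (``ddof=0``): the
    calibration epochs are the full population the gauge is scaled to, not a
    sample from a larger one.
    """
    coverages = np.asarray(coverages, float)
    if coverages.size < 2:
        raise CalibrationError("need at least 2 epochs (sigma undefined otherwise)")
    mu = float(coverages.mean())
    sigma = float(coverages.std(ddof=ddof))
    if sigma < 1e-12:
        raise DegenerateCalibrationError(
            "all calibration epochs have identical coverage; thresholds collapse"
        )
    return CalibrationResult(
        coverages=coverages, mu=mu, sigma=sigma,
        min_threshold=mu - sigma, max_threshold=mu + sigma,
        target_state=target_state, epoch_length_s=epoch_length_s,
        overlap_s=overlap_s,
    )


def calibrate(
    recording: EEGRecording,
    templates: TemplateSet,
    target_state="D",
    epoch_length_s: float = 3.0,
    overlap_s: float = 0.5,
    ddof: int = 0,
) -> CalibrationResult:
    """Derive feedback thresholds from a resting recording.

    The recording is epoched (epochs overlapping annotated bad segments are
    dropped), each epoch backfitted *without* smoothing, and the target
    state's per-epoch coverage summarised into ``mu +/- sigma`` thresholds.
    """
    target = templates.state_index(target_state)
    epochs = epoch(recording, length_s=epoch_length_s, overlap_s=overlap_s,
                   drop_annotated=True)
    if len(epochs) < 2:
        raise CalibrationError(
            f"only {len(epochs)} usable epoch(s); calibration needs >= 2"
        )
    coverages = np.array(
        [backfit(ep, templates).coverage(target) for ep in epochs]
    )
    return thresholds_from_coverages(
        coverages, target, epoch_length_s, overlap_s, ddof=ddof
    )
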