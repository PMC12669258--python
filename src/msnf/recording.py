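"""The in-memory EEG container used throughout the package.

``EEGRecording`` is a thin channels-by-samples array with a sampling rate, a
:class:`~msnf.layout.ChannelLayout` and bad-segment annotations. Conversion to
and from :class:`mne.io.Raw` is provided for interchange (FIF on disk); the
processing code itself stays on plain numpy arrays so that the 250 ms
real-time loop has no container overhead.

Units are microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelLayout, make_layout

__all__ = ["Annotation", "EEGRecording", "load_fif", "read_labels_csv", "write_labels_csv"]


@dataclass(frozen=True)
class Annotation:
    """A labelled bad segment: ``[onset_s, onset_s + duration_s)``."""

    onset_s: float
    duration_s: float
    label: str = "bad"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is ``(n_channels, n_samples)`` in microvolts."""

    data: np.ndarray
    sfreq: float
    layout: ChannelLayout
    annotations: tuple[Annotation, ...] = ()
    t0: float = 0.0  # seconds; offset of first sample (set by epoching)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, layout has "
                f"{self.layout.n_channels}"
            )
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        self.annotations = tuple(self.annotations)

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def ch_names(self) -> tuple[str, ...]:
        return self.layout.names

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def copy(self, data: np.ndarray | None = None) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq,
            layout=self.layout,
            annotations=self.annotations,
            t0=self.t0,
        )

    def drop_channels(self, names) -> "EEGRecording":
        """Remove channels by name; unknown names are ignored."""
        drop = set(names)
        keep = [i for i, n in enumerate(self.ch_names) if n not in drop]
        return EEGRecording(
            data=self.data[keep],
            sfreq=self.sfreq,
            layout=self.layout.subset([self.ch_names[i] for i in keep]),
            annotations=self.annotations,
            t0=self.t0,
        )

    # -- mne interchange -------------------------------------------------
    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (volts, as mne expects)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.sfreq, ch_types="eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        montage = mne.channels.make_dig_montage(
            ch_pos={n: p for n, p in zip(self.ch_names, self.layout.positions)},
            coord_frame="head",
        )
        raw.set_montage(montage, verbose="error")
        raw.info["bads"] = sorted(self.layout.bads)
        if self.annotations:
            raw.set_annotations(
                mne.Annotations(
                    onset=[a.onset_s for a in self.annotations],
                    duration=[a.duration_s for a in self.annotations],
                    description=[a.label for a in self.annotations],
                )
            )
        return raw

    @classmethod
    def from_mne(cls, raw) -> "EEGRecording":
        picks = [raw.ch_names[i] for i in range(len(raw.ch_names))]
        pos = np.array(
            [raw.info["chs"][i]["loc"][:3] for i in range(len(picks))], dtype=float
        )
        norms = np.linalg.norm(pos, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        layout = ChannelLayout(
            names=tuple(picks), positions=pos / norms, bads=frozenset(raw.info["bads"])
        )
        ann = tuple(
            Annotation(float(o), float(d), str(l))
            for o, d, l in zip(
                raw.annotations.onset, raw.annotations.duration,
                raw.annotations.description,
            )
        )
        return cls(
            data=raw.get_data() * 1e6, sfreq=float(raw.info["sfreq"]),
            layout=layout, annotations=ann,
        )

    def save_fif(self, path) -> None:
        self.to_mne().save(str(path), overwrite=True, verbose="error")


def load_fif(path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    return EEGRecording.from_mne(raw)


def write_labels_csv(path, labels: np.ndarray) -> None:
    """Ground-truth / backfitted labels as ``sample_index,label``."""
    pd.DataFrame(
        {"sample_index": np.arange(len(labels)), "label": np.asarray(labels, int)}
    ).to_csv(path, index=False)


def read_labels_csv(path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=int)
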