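"""Deterministic signal conditioning.

All steps are stateless functions ``EEGRecording -> EEGRecording``, matching
the offline cleaning chain and the per-iteration online chain:

band-pass 1-30 Hz (Butterworth, two-pass zero-phase) -> 49-51 Hz notch ->
bridged-electrode handling (intrinsic Hjorth electrical distance, virtual
midpoint channel) -> spherical-spline interpolation of bad channels
(Perrin-style Legendre spline) -> average reference -> stored-ICA cleanup.

The Butterworth default order is 8 per pass, i.e. an effective order of 16
after forward-backward filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .layout import ChannelLayout
from .recording import EEGRecording

__all__ = [
    "ICASolution",
    "bandpass",
    "notch",
    "detect_bridges",
    "virtual_midpoint",
    "add_virtual_midpoint",
    "interpolation_matrix",
    "interpolate_bads",
    "average_reference",
    "apply_ica",
    "epoch",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def _check_band(low: float, high: float, sfreq: float) -> None:
    nyq = sfreq / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq})"
        )


def bandpass(
    recording: EEGRecording, low_hz: float = 1.0, high_hz: float = 30.0, order: int = 8
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (two-pass forward and reverse).

    ``order`` is per pass; the effective order after the forward-backward
    application is ``2 * order``.
    """
    _check_band(low_hz, high_hz, recording.sfreq)
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.sfreq, output="sos"
    )
    return recording.copy(data=signal.sosfiltfilt(sos, recording.data, axis=1))


def notch(
    recording: EEGRecording,
    low_hz: float = 49.0,
    high_hz: float = 51.0,
    order: int = 4,
    method: str = "iir",
    transition_hz: float = 0.5,
) -> EEGRecording:
    """Band-stop filter around the power-line frequency.

    ``method="iir"`` (online dialect): zero-phase two-pass Butterworth
    band-stop. ``method="fir"``: Hamming-window linear-phase design with
    ``transition_hz`` transition bands, applied centred so the net filter is
    zero phase; the tap count follows the standard Hamming transition-width
    rule and is logged.
    """
    _check_band(low_hz, high_hz, recording.sfreq)
    if method == "iir":
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandstop", fs=recording.sfreq, output="sos"
        )
        return recording.copy(data=signal.sosfiltfilt(sos, recording.data, axis=1))
    if method == "fir":
        numtaps = int(np.ceil(3.3 * recording.sfreq / transition_hz))
        numtaps += 1 - numtaps % 2  # force odd -> exactly linear phase
        logger.info("FIR notch length: %d samples (%.3f s)",
                    numtaps, numtaps / recording.sfreq)
        taps = signal.firwin(
            numtaps, [low_hz, high_hz], fs=recording.sfreq,
            pass_zero="bandstop", window="hamming",
        )
        pad = numtaps // 2
        padded = np.pad(recording.data, [(0, 0), (pad, pad)], mode="reflect")
        out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
        return recording.copy(data=out[:, pad:-pad])
    raise ValueError(f"unknown notch method {method!r}")


def average_reference(recording: EEGRecording) -> EEGRecording:
    """Re-reference every sample to the instantaneous channel mean."""
    return recording.copy(data=recording.data - recording.data.mean(axis=0))


# ----------------------------------------------------------------------
# bridged electrodes
# ----------------------------------------------------------------------

def electrical_distances(recording: EEGRecording) -> np.ndarray:
    """Pairwise electrical distance: variance over time of channel differences."""
    x = recording.data
    n = x.shape[0]
    ed = np.full((n, n), np.nan)
    for i in range(n):
        d = x[i + 1:] - x[i]
        if d.size:
            ed[i, i + 1:] = d.var(axis=1)
    return ed


def detect_bridges(
    recording: EEGRecording, cutoff: float | None = None
) -> list[tuple[str, str]]:
    """Flag electrode pairs shorted by gel (intrinsic Hjorth algorithm).

    A bridged pair carries nearly identical signals, so the temporal variance
    of its difference collapses by orders of magnitude relative to ordinary
    pairs. With ``cutoff=None`` an adaptive threshold is used: the widest gap
    in the log electrical-distance distribution below the median, falling back
    to ``median / 16`` when the distribution shows no separated low cluster.
    """
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if recording.duration_s < 2.0:
        raise ValueError("need at least 2 s of data for stable variances")
    ed = electrical_distances(recording)
    iu = np.triu_indices(recording.n_channels, k=1)
    vals = ed[iu]
    if cutoff is None:
        med = np.median(vals)
        logv = np.log10(np.maximum(vals, 1e-300))
        below = np.sort(logv[logv < np.log10(med)])
        cutoff = med / 16.0
        if below.size >= 2:
            gaps = np.diff(below)
            k = int(np.argmax(gaps))
            # a real bridged cluster sits >= 1 decade below the rest
            if gaps[k] > 1.0:
                cutoff = min(cutoff, 10 ** ((below[k] + below[k + 1]) / 2.0))
    pairs = []
    names = recording.ch_names
    for i, j in zip(*iu):
        if ed[i, j] < cutoff:
            pairs.append((names[i], names[j]))
    return pairs


def virtual_midpoint(layout: ChannelLayout, pair: tuple[str, str]) -> ChannelLayout:
    """Insert a virtual channel at the spherical midpoint of a bridged pair.

    The midpoint is the normalised chord midpoint; both original electrodes
    are marked bad. Antipodal pairs have no defined midpoint and raise.
    """
    a, b = pair
    pa = layout.positions[layout.index(a)]
    pb = layout.positions[layout.index(b)]
    mid = pa + pb
    norm = np.linalg.norm(mid)
    if norm < 1e-8:
        raise ValueError(f"channels {a}/{b} are antipodal; midpoint undefined")
    mid = mid / norm
    name = f"{a}-{b}"
    if name in layout.names:
        raise ValueError(f"virtual channel {name} already exists")
    return ChannelLayout(
        names=layout.names + (name,),
        positions=np.vstack([layout.positions, mid]),
        bads=layout.bads | {a, b},
        bridged_pairs=layout.bridged_pairs + ((a, b),),
    )


def add_virtual_midpoint(
    recording: EEGRecording, pair: tuple[str, str]
) -> EEGRecording:
    """Recording-level counterpart of :func:`virtual_midpoint`.

    The virtual channel starts as the mean of the (near-identical) bridged
    signals; the originals become bad and are meant to be spline-interpolated
    afterwards.
    """
    new_layout = virtual_midpoint(recording.layout, pair)
    ia, ib = recording.layout.index(pair[0]), recording.layout.index(pair[1])
    vdata = recording.data[[ia, ib]].mean(axis=0, keepdims=True)
    return EEGRecording(
        data=np.vstack([recording.data, vdata]),
        sfreq=recording.sfreq,
        layout=new_layout,
        annotations=recording.annotations,
        t0=recording.t0,
    )


# ----------------------------------------------------------------------
# spherical spline interpolation (Perrin-style)
# ----------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Legendre series g(cos angle) = sum (2l+1) / (l(l+1))^m P_l / (4 pi)."""
    g = np.zeros_like(cosang, dtype=float)
    for ell in range(1, n_terms + 1):
        g += (2 * ell + 1) / (ell * (ell + 1)) ** m * eval_legendre(ell, cosang)
    return g / (4.0 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Spline operator mapping good-channel values to bad-channel estimates.

    Solves the bordered system (spline coefficients constrained to sum to
    zero, plus a free constant) on the good electrodes and evaluates the
    spline at the bad positions. Rows sum to one: constant topographies are
    reproduced exactly.
    """
    ng = good_pos.shape[0]
    G = _g_matrix(good_pos @ good_pos.T, m, n_terms) + reg * np.eye(ng)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    Gb = _g_matrix(bad_pos @ good_pos.T, m, n_terms)
    B = np.hstack([Gb, np.ones((bad_pos.shape[0], 1))])
    return (B @ np.linalg.solve(A, np.eye(ng + 1)))[:, :ng]


def interpolate_bads(
    recording: EEGRecording, m: int = 4, n_terms: int = 50, reg: float = 1e-5
) -> EEGRecording:
    """Replace channels flagged bad in the layout by their spline estimate."""
    layout = recording.layout
    bad_idx = layout.bad_indices()
    if bad_idx.size == 0:
        return recording.copy()
    good_idx = layout.good_indices()
    if good_idx.size < 4:
        raise ValueError("spherical spline interpolation needs >= 4 good channels")
    W = interpolation_matrix(
        layout.positions[good_idx], layout.positions[bad_idx], m=m,
        n_terms=n_terms, reg=reg,
    )
    data = recording.data.copy()
    data[bad_idx] = W @ data[good_idx]
    return recording.copy(data=data)


# ----------------------------------------------------------------------
# stored-ICA application
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ICASolution:
    """A precomputed ICA decomposition with components marked for rejection.

    ``mixing`` is channels x components, ``unmixing`` components x channels;
    on the modelled subspace ``unmixing @ mixing`` is the identity. Computing
    the decomposition is out of scope here — this type only *applies* a
    stored solution.
    """

    mixing: np.ndarray
    unmixing: np.ndarray
    rejected: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mixing", np.asarray(self.mixing, float))
        object.__setattr__(self, "unmixing", np.asarray(self.unmixing, float))
        c, n = self.mixing.shape
        if self.unmixing.shape != (n, c):
            raise ValueError("unmixing must be components x channels")
        eye = self.unmixing @ self.mixing
        if not np.allclose(eye, np.eye(n), atol=1e-6):
            raise ValueError("unmixing @ mixing is not the identity on components")
        rej = frozenset(int(i) for i in self.rejected)
        if any(i < 0 or i >= n for i in rej):
            raise ValueError("rejected component index out of range")
        object.__setattr__(self, "rejected", rej)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def save(self, npz_path, json_path=None) -> None:
        import json
        from pathlib import Path

        np.savez(npz_path, mixing=self.mixing, unmixing=self.unmixing)
        if json_path is not None:
            Path(json_path).write_text(json.dumps({"rejected": sorted(self.rejected)}))

    @classmethod
    def load(cls, npz_path, json_path=None) -> "ICASolution":
        import json
        from pathlib import Path

        arch = np.load(npz_path)
        rejected: frozenset[int] = frozenset()
        if json_path is not None:
            rejected = frozenset(json.loads(Path(json_path).read_text())["rejected"])
        return cls(arch["mixing"], arch["unmixing"], rejected)


def apply_ica(recording: EEGRecording, solution: ICASolution) -> EEGRecording:
    """Remove rejected components; signal outside the modelled subspace is kept."""
    rej = sorted(solution.rejected)
    if not rej:
        return recording.copy()
    sources = solution.unmixing[rej] @ recording.data
    cleaned = recording.data - solution.mixing[:, rej] @ sources
    return recording.copy(data=cleaned)


# ----------------------------------------------------------------------
# epoching
# ----------------------------------------------------------------------

def epoch(
    recording: EEGRecording,
    length_s: float = 3.0,
    overlap_s: float = 0.5,
    drop_annotated: bool = True,
) -> list[EEGRecording]:
    """Slice into fixed windows of ``length_s`` stepping ``length_s - overlap_s``.

    Windows are half-open sample ranges; a trailing partial window is
    discarded. With ``drop_annotated`` any window overlapping a bad-segment
    annotation is dropped (and logged).
    """
    if not (length_s > overlap_s >= 0):
        raise ValueError("need length_s > overlap_s >= 0")
    win = int(round(length_s * recording.sfreq))
    step = int(round((length_s - overlap_s) * recording.sfreq))
    if win <= 0 or step <= 0:
        raise ValueError("window and step must span at least one sample")
    out = []
    n_dropped = 0
    for start in range(0, recording.n_samples - win + 1, step):
        t_start = recording.t0 + start / recording.sfreq
        t_end = t_start + win / recording.sfreq
        if drop_annotated and any(
            a.onset_s < t_end and a.end_s > t_start for a in recording.annotations
        ):
            n_dropped += 1
            continue
        out.append(
            EEGRecording(
                data=recording.data[:, start:start + win],
                sfreq=recording.sfreq,
                layout=recording.layout,
                t0=t_start,
            )
        )
    if n_dropped:
        logger.info("epoch: dropped %d window(s) overlapping bad segments", n_dropped)
    return out
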