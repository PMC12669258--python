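"""Microstate backfitting and spatio-temporal metrics.

EEG microstate analysis models multichannel EEG as a sequence of K
quasi-stable scalp topographies. Given a fixed set of template maps (here:
five canonical states named A, B, C, D, F), *backfitting* assigns every
sample to the template with the highest absolute spatial correlation —
absolute, because the generating topography is polarity-invariant.

From a label sequence three metrics are computed per state:

* global explained variance (GEV): fraction of GFP^2-weighted variance
  explained by the assigned templates,
* time coverage: fraction of samples assigned to the state,
* mean duration: average uninterrupted run length in milliseconds.

Offline label sequences are additionally regularised by a windowed smoothing
pass and by splitting segments shorter than a minimum duration. The online
(real-time) path applies neither — windows are scored raw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelLayout
from .recording import EEGRecording

__all__ = [
    "UNASSIGNED",
    "TemplateSet",
    "LabelSequence",
    "MicrostateMetrics",
    "gfp",
    "spatial_correlation",
    "backfit",
    "smooth_labels",
    "reject_short_segments",
    "compute_metrics",
    "segment",
]

logger = logging.getLogger(__name__)

#: Label for samples that cannot be assigned (zero spatial variance).
UNASSIGNED = -1

DEFAULT_STATE_NAMES = ("A", "B", "C", "D", "F")


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSet:
    """K microstate template topographies over C channels.

    Each map is average-referenced (zero channel mean) and unit L2 norm;
    maps are defined up to sign.
    """

    maps: np.ndarray  # (K, C)
    state_names: tuple[str, ...]
    layout: ChannelLayout

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, float)
        if maps.ndim != 2 or maps.shape[0] < 1:
            raise ValueError("maps must be (K, C) with K >= 1")
        if maps.shape[1] != self.layout.n_channels:
            raise ValueError("template channel count does not match layout")
        if len(self.state_names) != maps.shape[0]:
            raise ValueError("need one state name per map")
        if not np.allclose(maps.mean(axis=1), 0.0, atol=1e-9):
            raise ValueError("template maps must have zero channel mean")
        if not np.allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-9):
            raise ValueError("template maps must have unit norm")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "state_names", tuple(self.state_names))

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]

    def state_index(self, state) -> int:
        """Resolve a state given by name or integer index."""
        if isinstance(state, str):
            return self.state_names.index(state)
        idx = int(state)
        if not 0 <= idx < self.n_states:
            raise ValueError(f"state index {idx} out of range")
        return idx

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.maps, index=list(self.state_names),
                          columns=list(self.layout.names))
        df.to_csv(path, sep="\t", index_label="state")

    @classmethod
    def from_tsv(cls, path, layout: ChannelLayout | None = None) -> "TemplateSet":
        df = pd.read_csv(path, sep="\t", index_col="state")
        names = tuple(df.columns)
        if layout is None:
            # positions unknown from the file alone: place on a generic cap
            from .layout import make_layout

            base = make_layout(len(names))
            layout = ChannelLayout(names=names, positions=base.positions)
        maps = df.to_numpy(float)
        # renormalise against round-tripping error
        maps = maps - maps.mean(axis=1, keepdims=True)
        maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        return cls(maps=maps, state_names=tuple(df.index), layout=layout)


@dataclass
class LabelSequence:
    """Per-sample state assignment aligned to a recording."""

    labels: np.ndarray  # int, UNASSIGNED allowed
    sfreq: float
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.labels.max(initial=UNASSIGNED) >= self.n_states:
            raise ValueError("label exceeds n_states")
        if self.labels.min(initial=0) < UNASSIGNED:
            raise ValueError("negative label other than UNASSIGNED")

    def __len__(self) -> int:
        return self.labels.size

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal constant runs as ``(start, end, label)`` half-open."""
        lab = self.labels
        edges = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [lab.size]])
        return [(int(s), int(e), int(lab[s])) for s, e in zip(starts, ends)]

    def coverage(self, state: int, denominator: str = "assigned") -> float:
        assigned = self.labels != UNASSIGNED
        denom = assigned.sum() if denominator == "assigned" else self.labels.size
        if denom == 0:
            return float("nan")
        return float((self.labels == state).sum() / denom)


@dataclass
class MicrostateMetrics:
    """Per-state GEV, time coverage and mean duration."""

    gev: np.ndarray
    time_coverage: np.ndarray
    mean_duration_ms: np.ndarray
    state_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (state, metric)."""
        rows = []
        for i, name in enumerate(self.state_names):
            rows += [
                (name, "gev", self.gev[i]),
                (name, "time_coverage", self.time_coverage[i]),
                (name, "mean_duration_ms", self.mean_duration_ms[i]),
            ]
        return pd.DataFrame(rows, columns=["state", "metric", "value"])

    def to_json(self, path) -> None:
        import json

        obj = {
            name: {
                "gev": float(self.gev[i]),
                "time_coverage": float(self.time_coverage[i]),
                "mean_duration_ms": float(self.mean_duration_ms[i]),
            }
            for i, name in enumerate(self.state_names)
        }
        Path(path).write_text(json.dumps(obj, indent=2))


# ----------------------------------------------------------------------
# core computations
# ----------------------------------------------------------------------

def gfp(recording: EEGRecording) -> np.ndarray:
    """Global field power: per-sample SD across channels (population SD)."""
    return recording.data.std(axis=0)


def spatial_correlation(
    recording: EEGRecording, templates: TemplateSet
) -> np.ndarray:
    """Signed Pearson correlation across channels, shape ``(K, n_samples)``.

    Samples and maps are average-referenced before correlating; zero-variance
    samples get correlation 0 with every map.
    """
    x = recording.data - recording.data.mean(axis=0)
    norms = np.linalg.norm(x, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return (templates.maps @ x) / safe


def backfit(recording: EEGRecording, templates: TemplateSet) -> LabelSequence:
    """Assign each sample to the template with highest absolute correlation.

    Ties resolve to the lowest state index; samples with zero spatial
    variance are UNASSIGNED (logged).
    """
    if recording.n_channels != templates.layout.n_channels:
        raise ValueError("recording/template channel counts differ")
    corr = np.abs(spatial_correlation(recording, templates))
    labels = corr.argmax(axis=0)
    dead = recording.data.std(axis=0) == 0
    if dead.any():
        logger.info("backfit: %d zero-variance sample(s) left unassigned",
                    int(dead.sum()))
        labels[dead] = UNASSIGNED
    return LabelSequence(labels=labels, sfreq=recording.sfreq,
                         n_states=templates.n_states)


def _fit_terms(recording: EEGRecording, templates: TemplateSet):
    x = recording.data - recording.data.mean(axis=0)
    act = templates.maps @ x            # (K, n); template "activation"
    ssum = (x**2).sum(axis=0)           # per-sample power
    return act, ssum


def smooth_labels(
    recording: EEGRecording,
    templates: TemplateSet,
    labels: LabelSequence,
    window_samples: int = 24,
    factor: float = 10.0,
    max_iter: int = 1000,
) -> LabelSequence:
    """Windowed label smoothing enforcing temporal continuity.

    Classical iterative relabeling: each sample's misfit (residual power not
    explained by a template, noise-normalised) is offset by ``factor`` times
    the number of samples sharing that label inside a window of
    ``+/- window_samples // 2`` around it; samples are reassigned to the
    minimum-cost state. Updates sweep left to right in place (iterated
    conditional modes on a Potts-coupled chain, so each sweep monotonically
    lowers the global cost and the procedure converges) and repeat until a
    full sweep changes nothing. ``factor=0`` leaves the input unchanged;
    unassigned samples stay unassigned and never count as neighbours.
    """
    if factor == 0:
        return LabelSequence(labels.labels.copy(), labels.sfreq, labels.n_states)
    half = max(1, int(window_samples) // 2)
    act, ssum = _fit_terms(recording, templates)
    K, n = act.shape
    lab = labels.labels.copy()
    valid = lab != UNASSIGNED
    nch = recording.n_channels
    # noise-variance estimate from the initial fit
    resid = ssum[valid] - act[lab[valid], np.arange(n)[valid]] ** 2
    e = max(float(resid.sum()) / max(1, valid.sum() * (nch - 1)), 1e-12)
    misfit = (ssum[None, :] - act**2) / (2.0 * e * (nch - 1))

    todo = np.flatnonzero(valid)
    for _ in range(max_iter):
        changed = 0
        for t in todo:
            lo = max(0, t - half)
            hi = min(n, t + half + 1)
            counts = np.bincount(lab[lo:hi] + 1, minlength=K + 1)[1:]
            counts[lab[t]] -= 1  # exclude the sample itself
            new = int(np.argmin(misfit[:, t] - factor * counts))
            if new != lab[t]:
                lab[t] = new
                changed += 1
        if changed == 0:
            break
    else:
        warnings.warn(
            f"smooth_labels did not converge in {max_iter} sweeps; "
            "returning last iterate", RuntimeWarning,
        )
    return LabelSequence(labels=lab, sfreq=labels.sfreq, n_states=labels.n_states)


def reject_short_segments(
    recording: EEGRecording,
    templates: TemplateSet,
    labels: LabelSequence,
    min_samples: int = 3,
) -> LabelSequence:
    """Split label runs shorter than ``min_samples`` between their neighbours.

    Each interior short run is cut at its midpoint: the left part takes the
    left neighbour's label, the right part the right neighbour's; the middle
    sample of an odd-length run joins the side whose template correlates
    higher with it. Runs touching the sequence boundary keep their label (no
    neighbour on that side); the pass repeats until no short interior run
    remains.
    """
    corr = np.abs(spatial_correlation(recording, templates))
    lab = labels.labels.copy()
    n = lab.size
    # Fix one run at a time and re-derive the run list: every fix merges the
    # short run into its neighbours, so the run count strictly decreases and
    # the loop terminates without ever acting on stale boundaries.
    for _ in range(n):
        runs = LabelSequence(lab, labels.sfreq, labels.n_states).runs()
        fixed = False
        for idx, (start, end, value) in enumerate(runs):
            if value == UNASSIGNED or end - start >= min_samples:
                continue
            if idx == 0 or idx == len(runs) - 1:
                continue  # edge run: no neighbour on one side
            left_label = runs[idx - 1][2]
            right_label = runs[idx + 1][2]
            if left_label == UNASSIGNED or right_label == UNASSIGNED:
                continue
            length = end - start
            mid = start + length // 2
            lab[start:mid] = left_label
            lab[mid:end] = right_label
            if length % 2 == 1:
                # odd run: midpoint sample joins the better-correlated side
                lab[mid] = (
                    left_label
                    if corr[left_label, mid] >= corr[right_label, mid]
                    else right_label
                )
            fixed = True
            break
        if not fixed:
            break
    return LabelSequence(labels=lab, sfreq=labels.sfreq, n_states=labels.n_states)


def compute_metrics(
    recording: EEGRecording,
    labels: LabelSequence,
    templates: TemplateSet,
    coverage_denominator: str = "assigned",
) -> MicrostateMetrics:
    """GEV, time coverage and mean duration per state.

    GEV_k sums squared spatial correlation weighted by GFP^2 over samples
    assigned to k, normalised by total GFP^2 over all samples; coverage
    divides by assigned samples by default (``coverage_denominator="all"``
    for the strict convention); durations are mean run lengths in ms.
    """
    if coverage_denominator not in ("assigned", "all"):
        raise ValueError("coverage_denominator must be 'assigned' or 'all'")
    corr = spatial_correlation(recording, templates)
    g = gfp(recording)
    g2 = g**2
    total = g2.sum()
    K = templates.n_states
    lab = labels.labels
    gev = np.zeros(K)
    cov = np.zeros(K)
    dur = np.full(K, np.nan)
    assigned = lab != UNASSIGNED
    denom = assigned.sum() if coverage_denominator == "assigned" else lab.size
    run_lengths: dict[int, list[int]] = {k: [] for k in range(K)}
    for start, end, value in labels.runs():
        if value != UNASSIGNED:
            run_lengths[value].append(end - start)
    for k in range(K):
        mask = lab == k
        if total > 0:
            gev[k] = (g2[mask] * corr[k, mask] ** 2).sum() / total
        cov[k] = mask.sum() / denom if denom else np.nan
        if run_lengths[k]:
            dur[k] = float(np.mean(run_lengths[k])) * 1000.0 / labels.sfreq
    return MicrostateMetrics(
        gev=gev, time_coverage=cov, mean_duration_ms=dur,
        state_names=templates.state_names,
    )


def segment(
    recording: EEGRecording,
    templates: TemplateSet,
    mode: str = "offline",
    window_samples: int = 24,
    factor: float = 10.0,
    min_samples: int = 3,
) -> LabelSequence:
    """Full labeling pipeline.

    ``mode="offline"`` runs backfit -> smoothing -> short-segment rejection;
    ``mode="online"`` runs backfit only (the real-time loop scores raw
    windows).
    """
    labels = backfit(recording, templates)
    if mode == "online":
        return labels
    if mode != "offline":
        raise ValueError("mode must be 'offline' or 'online'")
    labels = smooth_labels(recording, templates, labels,
                           window_samples=window_samples, factor=factor)
    return reject_short_segments(recording, templates, labels,
                                 min_samples=min_samples)
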