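"""Synthetic EEG with known microstate ground truth.

The generator is a first-order Markov chain over K states rendered through
template topographies:

    x(t) = s(t) * a(t) * sqrt(C) * T[L(t)] + eps(t)

where L(t) is the sampled label sequence, a(t) a per-segment log-normal
amplitude (so the noiseless GFP equals the segment amplitude), s(t) a
per-segment random polarity (microstate topographies are sign-invariant),
and eps(t) i.i.d. Gaussian sensor noise. The chain's self-transition
probability p_kk sets the mean dwell time: 1 / ((1 - p_kk) * rate) seconds.

A *responsive virtual subject* couples the chain to the feedback loop: after
every emitted feedback value the target state's self-transition probability
is nudged by ``learning_gain * feedback`` (sign flipped for down-regulation),
clamped between a floor at the resting baseline and a ceiling below one.
The floor encodes that a participant attempting regulation does not drop
below their own resting dynamics; it also makes up-regulation a ratchet
(successful excursions are reinforced, unsuccessful ones bounded), the
learning effect the closed-loop tests probe.

No claim of physiological realism is made: spectra, volume conduction and
artifacts are out of scope. The generator exists to give every downstream
stage a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layout import ChannelLayout, make_layout
from .microstates import DEFAULT_STATE_NAMES, LabelSequence, TemplateSet
from .recording import EEGRecording

__all__ = [
    "MarkovMicrostateModel",
    "ResponsiveSubjectModel",
    "uniform_chain",
    "make_template_set",
    "sample_labels",
    "render_eeg",
    "VirtualSubjectStream",
    "SimulationResult",
    "run_virtual_subject",
]


# ----------------------------------------------------------------------
# models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovMicrostateModel:
    """First-order Markov microstate dynamics plus rendering amplitudes.

    Parameters
    ----------
    transition_matrix
        K x K row-stochastic matrix (rows sum to 1 within 1e-12).
    gfp_mean
        Mean segment amplitude = mean noiseless GFP, microvolts.
    gfp_cv
        Coefficient of variation of the per-segment log-normal amplitude.
    noise_sigma
        Per-channel Gaussian sensor noise SD, microvolts. The per-channel
        signal-to-noise power ratio is (gfp_mean / noise_sigma)^2.
    """

    transition_matrix: np.ndarray
    gfp_mean: float = 10.0
    gfp_cv: float = 0.3
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition_matrix must be square")
        if (P < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        if self.gfp_mean <= 0 or self.gfp_cv < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude parameters out of range")
        object.__setattr__(self, "transition_matrix", P)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Stationary probabilities via the unit left eigenvector."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def expected_dwell_s(self, sampling_rate: float) -> np.ndarray:
        """Mean dwell time per state in seconds at the given rate."""
        p_stay = np.diag(self.transition_matrix)
        return 1.0 / ((1.0 - p_stay) * sampling_rate)


def uniform_chain(
    n_states: int = 5, p_stay: float = 0.94, **amplitude_kwargs
) -> MarkovMicrostateModel:
    """Symmetric chain: equal self-transitions, uniform off-diagonals.

    ``p_stay=0.94`` at 250 Hz gives a ~67 ms mean dwell, a typical resting
    microstate duration.
    """
    if not 0.0 <= p_stay < 1.0:
        raise ValueError("p_stay must be in [0, 1)")
    P = np.full((n_states, n_states), (1.0 - p_stay) / (n_states - 1))
    np.fill_diagonal(P, p_stay)
    return MarkovMicrostateModel(P, **amplitude_kwargs)


@dataclass(frozen=True)
class ResponsiveSubjectModel:
    """A virtual participant whose target-state dwell responds to feedback.

    After each feedback emission the target state's self-transition
    probability moves by ``learning_gain * feedback`` (negated for
    direction="down"), clamped to ``[p_floor, p_ceil]``. ``p_floor=None``
    defaults to the baseline self-transition (the resting level).
    ``learning_gain=0`` gives an unresponsive control subject.
    """

    base_model: MarkovMicrostateModel
    target_state: int = 3  # microstate D in the A,B,C,D,F ordering
    learning_gain: float = 0.002
    direction: str = "up"
    p_floor: float | None = None
    p_ceil: float = 0.995

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not 0 <= self.target_state < self.base_model.n_states:
            raise ValueError("target_state out of range")
        base = float(
            self.base_model.transition_matrix[self.target_state, self.target_state]
        )
        floor = base if self.p_floor is None else float(self.p_floor)
        if not (0.0 < floor <= self.p_ceil < 1.0):
            raise ValueError("need 0 < p_floor <= p_ceil < 1")
        object.__setattr__(self, "p_floor", floor)


# ----------------------------------------------------------------------
# templates
# ----------------------------------------------------------------------

def _harmonic_basis(pos: np.ndarray) -> np.ndarray:
    """Low-order polynomial (real spherical-harmonic) basis at unit positions."""
    x, y, z = pos.T
    return np.column_stack(
        [x, y, z, x * y, x * z, y * z, x**2 - y**2, 3 * z**2 - 1]
    )


def make_template_set(
    layout: ChannelLayout | None = None, n_states: int = 5, seed: int = 0
) -> TemplateSet:
    """Random smooth, mutually orthogonal template topographies.

    Maps are random combinations of low-order spherical harmonics evaluated
    at the electrode positions, demeaned, then orthonormalised — smooth
    dipolar/quadrupolar fields standing in for published grand-average maps.
    Five states are named A, B, C, D, F.
    """
    if layout is None:
        layout = make_layout()
    rng = np.random.default_rng(seed)
    basis = _harmonic_basis(layout.positions)
    if n_states > basis.shape[1]:
        raise ValueError(f"at most {basis.shape[1]} orthogonal smooth maps")
    raw = basis @ rng.standard_normal((basis.shape[1], n_states))
    raw = raw - raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    maps = (q - q.mean(axis=0)).T
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    names = (
        DEFAULT_STATE_NAMES
        if n_states == len(DEFAULT_STATE_NAMES)
        else tuple(f"S{i}" for i in range(n_states))
    )
    return TemplateSet(maps=maps, state_names=names, layout=layout)


# ----------------------------------------------------------------------
# sampling and rendering
# ----------------------------------------------------------------------

def sample_labels(
    model: MarkovMicrostateModel,
    n_samples: int,
    sampling_rate: float,
    seed: int | np.random.Generator = 0,
) -> LabelSequence:
    """Sample a label sequence from the chain (initial state ~ stationary)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    pi = model.stationary_distribution()
    cum = np.cumsum(model.transition_matrix, axis=1)
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.choice(model.n_states, p=pi))
    u = rng.random(n_samples)
    for t in range(n_samples):
        labels[t] = state
        state = int(np.searchsorted(cum[state], u[t], side="right"))
    return LabelSequence(labels=labels, sfreq=sampling_rate,
                         n_states=model.n_states)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def render_eeg(
    labels: LabelSequence,
    templates: TemplateSet,
    gfp_mean: float = 10.0,
    gfp_cv: float = 0.3,
    noise_sigma: float = 5.0,
    polarity_flips: bool = True,
    seed: int | np.random.Generator = 0,
) -> EEGRecording:
    """Render a label sequence through templates into an EEG recording.

    Amplitude and polarity are drawn once per segment (constant within), so
    segments stay spatially coherent; the noiseless GFP of a segment equals
    its amplitude. Channel count follows the template layout.
    """
    if labels.labels.max() >= templates.n_states:
        raise ValueError("label index outside template range")
    if labels.labels.min() < 0:
        raise ValueError("cannot render UNASSIGNED samples")
    rng = np.random.default_rng(seed)
    C = templates.layout.n_channels
    mu, sg = _lognormal_params(gfp_mean, gfp_cv)
    amp = np.empty(len(labels))
    sign = np.ones(len(labels))
    for start, end, _ in labels.runs():
        a = float(np.exp(rng.normal(mu, sg))) if gfp_cv > 0 else gfp_mean
        amp[start:end] = a
        if polarity_flips:
            sign[start:end] = 1.0 if rng.random() < 0.5 else -1.0
    data = (templates.maps[labels.labels] * (sign * amp * np.sqrt(C))[:, None]).T
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return EEGRecording(data=data, sfreq=labels.sfreq, layout=templates.layout)


# ----------------------------------------------------------------------
# the closed-loop virtual subject
# ----------------------------------------------------------------------

class VirtualSubjectStream:
    """Feedback-responsive sample source for the engine.

    Generates chain samples on demand, rendering them like
    :func:`render_eeg`; ``on_feedback`` nudges the target state's
    self-transition probability, rescaling the off-diagonal row entries to
    keep the row stochastic. The full emitted label/EEG history is retained
    so a completed run can be analysed against its ground truth.
    """

    def __init__(
        self,
        subject: ResponsiveSubjectModel,
        templates: TemplateSet,
        sfreq: float,
        seed: int | np.random.Generator = 0,
    ):
        self.subject = subject
        self.templates = templates
        self.sfreq = float(sfreq)
        self.layout = templates.layout
        self.rng = np.random.default_rng(seed)
        self.P = subject.base_model.transition_matrix.copy()
        base = subject.base_model
        self._amp_params = _lognormal_params(base.gfp_mean, base.gfp_cv)
        self._noise = base.noise_sigma
        self._state = int(
            self.rng.choice(base.n_states, p=base.stationary_distribution())
        )
        self._amp, self._sign = self._draw_segment()
        self._labels: list[np.ndarray] = []
        self._chunks: list[np.ndarray] = []
        self.p_stay_history: list[float] = [self._p_stay]

    @property
    def _p_stay(self) -> float:
        k = self.subject.target_state
        return float(self.P[k, k])

    def _draw_segment(self) -> tuple[float, float]:
        mu, sg = self._amp_params
        amp = float(np.exp(self.rng.normal(mu, sg))) if sg > 0 else np.exp(mu)
        sign = 1.0 if self.rng.random() < 0.5 else -1.0
        return amp, sign

    def read(self, n_samples: int) -> np.ndarray:
        K = self.P.shape[0]
        C = self.layout.n_channels
        labels = np.empty(n_samples, dtype=int)
        amps = np.empty(n_samples)
        signs = np.empty(n_samples)
        cum = np.cumsum(self.P, axis=1)
        u = self.rng.random(n_samples)
        for t in range(n_samples):
            labels[t] = self._state
            amps[t] = self._amp
            signs[t] = self._sign
            nxt = int(np.searchsorted(cum[self._state], u[t], side="right"))
            nxt = min(nxt, K - 1)
            if nxt != self._state:
                self._amp, self._sign = self._draw_segment()
            self._state = nxt
        data = (self.templates.maps[labels] * (signs * amps * np.sqrt(C))[:, None]).T
        if self._noise > 0:
            data = data + self.rng.normal(0.0, self._noise, size=data.shape)
        self._labels.append(labels)
        self._chunks.append(data)
        return data

    def on_feedback(self, value: float) -> None:
        k = self.subject.target_state
        delta = self.subject.learning_gain * value
        if self.subject.direction == "down":
            delta = -delta
        p_new = float(np.clip(self._p_stay + delta, self.subject.p_floor,
                              self.subject.p_ceil))
        row = self.P[k].copy()
        off = row.sum() - row[k]
        row[k] = p_new
        scale = (1.0 - p_new) / off if off > 0 else 0.0
        for j in range(len(row)):
            if j != k:
                row[j] *= scale
        self.P[k] = row
        self.p_stay_history.append(p_new)

    # -- post-run accessors ---------------------------------------------
    def emitted_labels(self) -> LabelSequence:
        return LabelSequence(
            labels=np.concatenate(self._labels), sfreq=self.sfreq,
            n_states=self.P.shape[0],
        )

    def emitted_recording(self) -> EEGRecording:
        return EEGRecording(
            data=np.concatenate(self._chunks, axis=1), sfreq=self.sfreq,
            layout=self.layout,
        )


@dataclass
class SimulationResult:
    """Everything a closed-loop virtual-subject run produces."""

    recording: EEGRecording
    trace: "FeedbackTrace"
    labels: LabelSequence
    calibration: "CalibrationResult"
    p_stay_history: list[float]


def run_virtual_subject(
    subject: ResponsiveSubjectModel,
    templates: TemplateSet,
    engine_config,
    sfreq: float = 250.0,
    calibration=None,
    calibration_duration_s: float = 60.0,
    seed: int = 0,
) -> SimulationResult:
    """Closed-loop simulation: calibrate (if needed), run a session, collect.

    With ``calibration=None`` a resting recording of the base chain is
    rendered and calibrated with the session's window/step cadence. The
    engine then drives a :class:`VirtualSubjectStream`; the returned result
    carries the emitted EEG, the feedback trace, the ground-truth labels and
    the self-transition trajectory.
    """
    from .calibration import calibrate
    from .engine import run_session

    rng = np.random.default_rng(seed)
    base = subject.base_model
    if calibration is None:
        n_rest = int(round(calibration_duration_s * sfreq))
        rest_labels = sample_labels(base, n_rest, sfreq,
                                    seed=rng.integers(2**31 - 1))
        rest = render_eeg(
            rest_labels, templates, gfp_mean=base.gfp_mean, gfp_cv=base.gfp_cv,
            noise_sigma=base.noise_sigma, polarity_flips=True,
            seed=rng.integers(2**31 - 1),
        )
        calibration = calibrate(
            rest, templates, target_state=subject.target_state,
            epoch_length_s=engine_config.window_s, overlap_s=0.5,
        )
    stream = VirtualSubjectStream(
        subject, templates, sfreq, seed=rng.integers(2**31 - 1)
    )
    trace = run_session(stream, calibration, engine_config, templates)
    return SimulationResult(
        recording=stream.emitted_recording(),
        trace=trace,
        labels=stream.emitted_labels(),
        calibration=calibration,
        p_stay_history=stream.p_stay_history,
    )
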