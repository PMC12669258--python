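"""Backfitting, label smoothing, short-segment rejection and metrics,
checked against brute-force oracles and the generator's ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from msnf.microstates import (
    UNASSIGNED,
    LabelSequence,
    TemplateSet,
    backfit,
    compute_metrics,
    gfp,
    reject_short_segments,
    segment,
    smooth_labels,
    spatial_correlation,
)
from msnf.recording import EEGRecording
from msnf.simulate import render_eeg, sample_labels, uniform_chain


def _rec_from_labels(labels, templates, **kw):
    kw.setdefault("noise_sigma", 0.0)
    kw.setdefault("polarity_flips", False)
    seq = LabelSequence(np.asarray(labels), 250.0, templates.n_states)
    return render_eeg(seq, templates, **kw), seq


# ----------------------------------------------------------------------
# GFP and backfitting
# ----------------------------------------------------------------------

def test_gfp_constant_sample_is_zero(templates20):
    rec = EEGRecording(np.full((20, 10), 4.2), 250.0, templates20.layout)
    assert np.allclose(gfp(rec), 0.0)


def test_gfp_of_scaled_map_and_brute_force(templates20, rng):
    a = 7.5
    x = (a * templates20.maps[2])[:, None]
    rec = EEGRecording(x, 250.0, templates20.layout)
    assert gfp(rec)[0] == pytest.approx(a / np.sqrt(20))
    noisy = rng.normal(size=(20, 50))
    rec = EEGRecording(noisy, 250.0, templates20.layout)
    brute = np.array([np.std(noisy[:, t]) for t in range(50)])
    assert np.allclose(gfp(rec), brute)


@pytest.mark.parametrize("sign", [+1.0, -1.0])
def test_backfit_assigns_signed_template(templates20, sign):
    d_idx = templates20.state_index("D")
    x = sign * 12.0 * templates20.maps[d_idx][:, None]
    rec = EEGRecording(x, 250.0, templates20.layout)
    assert backfit(rec, templates20).labels[0] == d_idx


def test_backfit_zero_variance_sample_unassigned(templates20):
    data = np.hstack(
        [templates20.maps[0][:, None], np.full((20, 1), 1.0)]
    )
    labels = backfit(EEGRecording(data, 250.0, templates20.layout), templates20)
    assert labels.labels[0] == 0
    assert labels.labels[1] == UNASSIGNED


@settings(max_examples=30, derandomize=True)
@given(scale=hst.floats(0.01, 100.0), sign=hst.sampled_from([-1.0, 1.0]),
       offset=hst.floats(-5.0, 5.0))
def test_backfit_invariant_to_scaling_sign_and_reference(scale, sign, offset):
    rng = np.random.default_rng(99)
    from msnf.layout import make_layout
    from msnf.simulate import make_template_set

    templates = make_template_set(make_layout(12), seed=2)
    base = rng.normal(size=(12, 40))
    a = backfit(EEGRecording(base, 250.0, templates.layout), templates)
    b = backfit(
        EEGRecording(sign * scale * base + offset, 250.0, templates.layout),
        templates,
    )
    assert np.array_equal(a.labels, b.labels)


def test_backfit_recovers_ground_truth_degrading_with_noise(templates20, chain5):
    labels = sample_labels(chain5, 5000, 250.0, seed=21)
    agreements = []
    for sigma in (0.0, 20.0, 60.0):
        rec = render_eeg(labels, templates20, gfp_mean=10.0, noise_sigma=sigma,
                         seed=22)
        fit = backfit(rec, templates20)
        agreements.append((fit.labels == labels.labels).mean())
    assert agreements[0] >= 0.99
    assert agreements[0] >= agreements[1] > agreements[2]
    assert agreements[2] < 0.95


# ----------------------------------------------------------------------
# smoothing
# ----------------------------------------------------------------------

def _smooth_oracle(rec, templates, labels, window_samples, factor):
    """Direct, unoptimised reimplementation of the sequential update rule."""
    x = rec.data - rec.data.mean(axis=0)
    act = templates.maps @ x
    ssum = (x**2).sum(axis=0)
    K, n = act.shape
    nch = rec.n_channels
    lab = labels.labels.copy()
    valid = lab != UNASSIGNED
    resid = sum(
        ssum[t] - act[lab[t], t] ** 2 for t in range(n) if valid[t]
    )
    e = max(resid / max(1, valid.sum() * (nch - 1)), 1e-12)
    half = max(1, window_samples // 2)
    while True:
        changed = False
        for t in range(n):
            if not valid[t]:
                continue
            counts = [0] * K
            for s in range(max(0, t - half), min(n, t + half + 1)):
                if s != t and lab[s] >= 0:
                    counts[lab[s]] += 1
            costs = [
                (ssum[t] - act[k, t] ** 2) / (2 * e * (nch - 1))
                - factor * counts[k]
                for k in range(K)
            ]
            new = int(np.argmin(costs))
            if new != lab[t]:
                lab[t] = new
                changed = True
        if not changed:
            return lab


def test_smoothing_factor_zero_is_identity(templates20, chain5):
    labels = sample_labels(chain5, 300, 250.0, seed=30)
    rec = render_eeg(labels, templates20, noise_sigma=5.0, seed=31)
    fit = backfit(rec, templates20)
    out = smooth_labels(rec, templates20, fit, factor=0.0)
    assert np.array_equal(out.labels, fit.labels)


def test_smoothing_removes_isolated_flip(templates20):
    lab = [3] * 30 + [0] + [3] * 30
    rec, seq = _rec_from_labels(lab, templates20, noise_sigma=1.0, seed=5)
    out = smooth_labels(rec, templates20, backfit(rec, templates20),
                        window_samples=24, factor=10.0)
    assert (out.labels == 3).all()


def test_smoothing_equals_brute_force_oracle(templates20, chain5):
    """200-sample noisy sequence: optimised path == direct reimplementation."""
    labels = sample_labels(chain5, 200, 250.0, seed=33)
    rec = render_eeg(labels, templates20, gfp_mean=10.0, noise_sigma=8.0,
                     seed=34)
    fit = backfit(rec, templates20)
    fast = smooth_labels(rec, templates20, fit, window_samples=24, factor=10.0)
    slow = _smooth_oracle(rec, templates20, fit, 24, 10.0)
    assert np.array_equal(fast.labels, slow)


def test_smoothing_never_invents_states_absent_from_data(templates20):
    lab = [0] * 50 + [1] * 50
    rec, seq = _rec_from_labels(lab, templates20)
    out = smooth_labels(rec, templates20, seq, factor=10.0)
    assert set(np.unique(out.labels)) <= {0, 1}


# ----------------------------------------------------------------------
# short-segment rejection
# ----------------------------------------------------------------------

def test_short_run_between_identical_neighbours_absorbed(templates20):
    lab = [3, 3, 3, 0, 3, 3, 3]
    rec, seq = _rec_from_labels(lab, templates20)
    out = reject_short_segments(rec, templates20, seq, min_samples=3)
    assert (out.labels == 3).all()


def test_short_run_joins_better_correlated_neighbour(templates20):
    """Oracle: direct correlation comparison on constructed data."""
    lab = [0, 0, 0, 1, 2, 2, 2]
    rec, seq = _rec_from_labels(lab, templates20)
    out = reject_short_segments(rec, templates20, seq, min_samples=3)
    corr = np.abs(spatial_correlation(rec, templates20))
    expected = 0 if corr[0, 3] >= corr[2, 3] else 2
    assert out.labels[3] == expected
    assert out.labels.tolist() == [0, 0, 0, expected, 2, 2, 2]


def test_even_short_run_splits_between_neighbours(templates20):
    lab = [0] * 4 + [1, 1] + [2] * 4
    rec, seq = _rec_from_labels(lab, templates20)
    out = reject_short_segments(rec, templates20, seq, min_samples=3)
    assert out.labels.tolist() == [0] * 5 + [2] * 5


def test_sequences_without_short_runs_unchanged(templates20, chain5):
    labels = sample_labels(chain5, 500, 250.0, seed=40)
    rec = render_eeg(labels, templates20, seed=41)
    out = reject_short_segments(rec, templates20, labels, min_samples=2)
    lengths = [e - s for s, e, _ in labels.runs()]
    if min(lengths) >= 2:
        assert np.array_equal(out.labels, labels.labels)


def test_single_short_run_left_unchanged(templates20):
    lab = [2, 2]
    rec, seq = _rec_from_labels(lab, templates20)
    out = reject_short_segments(rec, templates20, seq, min_samples=3)
    assert out.labels.tolist() == lab


def test_no_interior_short_runs_after_rejection(templates20, chain5):
    labels = sample_labels(uniform_chain(5, p_stay=0.7), 2000, 250.0, seed=42)
    rec = render_eeg(labels, templates20, noise_sigma=5.0, seed=43)
    out = reject_short_segments(rec, templates20, backfit(rec, templates20),
                                min_samples=3)
    runs = out.runs()
    for (s, e, v) in runs[1:-1]:
        assert e - s >= 3


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def test_coverage_counting_example(templates20):
    lab = [0, 0, 1, 3, 3, 3, 3, 3]
    rec, seq = _rec_from_labels(lab, templates20)
    m = compute_metrics(rec, seq, templates20)
    assert m.time_coverage[3] == pytest.approx(0.625)


def test_mean_duration_from_run_lengths(templates20):
    # D runs of 2 and 4 samples at 500 Hz -> (2+4)/2 samples = 6 ms
    lab = [0, 3, 3, 1, 3, 3, 3, 3, 0]
    seq = LabelSequence(np.array(lab), 500.0, 5)
    rec = render_eeg(seq, templates20, noise_sigma=0.0, polarity_flips=False,
                     seed=0)
    m = compute_metrics(rec, seq, templates20)
    assert m.mean_duration_ms[3] == pytest.approx(6.0)


def test_gev_partitions_unity_at_zero_noise(templates20, chain5):
    labels = sample_labels(chain5, 2000, 250.0, seed=44)
    rec = render_eeg(labels, templates20, noise_sigma=0.0, seed=45)
    m = compute_metrics(rec, backfit(rec, templates20), templates20)
    assert m.gev.sum() == pytest.approx(1.0, abs=1e-9)
    assert m.time_coverage.sum() == pytest.approx(1.0)
    assert (m.gev >= 0).all() and (m.gev <= 1).all()


def test_coverage_denominator_conventions(templates20):
    data = np.hstack(
        [np.tile(templates20.maps[0][:, None], (1, 3)), np.ones((20, 1))]
    )
    rec = EEGRecording(data, 250.0, templates20.layout)
    fit = backfit(rec, templates20)
    m_assigned = compute_metrics(rec, fit, templates20)
    m_all = compute_metrics(rec, fit, templates20, coverage_denominator="all")
    assert m_assigned.time_coverage[0] == pytest.approx(1.0)
    assert m_all.time_coverage[0] == pytest.approx(0.75)


def test_offline_pipeline_recovers_coverage_at_snr_4(templates20, chain5):
    """backfit -> smooth -> reject on SNR 4:1 data: coverage within 0.05."""
    labels = sample_labels(chain5, 15_000, 250.0, seed=46)  # 60 s at 250 Hz
    rec = render_eeg(labels, templates20, gfp_mean=10.0, noise_sigma=5.0,
                     seed=47)
    fitted = segment(rec, templates20, mode="offline")
    truth = np.bincount(labels.labels, minlength=5) / len(labels)
    m = compute_metrics(rec, fitted, templates20)
    assert np.abs(m.time_coverage - truth).max() <= 0.05


def test_template_tsv_round_trip(tmp_path, templates20):
    path = tmp_path / "maps.tsv"
    templates20.to_tsv(path)
    back = TemplateSet.from_tsv(path)
    assert back.state_names == templates20.state_names
    assert np.allclose(back.maps, templates20.maps, atol=1e-9)
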