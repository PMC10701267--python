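import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chd_phonoscreen.pcg_io import PCGRecord
from chd_phonoscreen.segment import (
    CycleNotFoundError, DurationHMM, EcgLabelRule, SegmentMap,
    TRANSITION_MATRIX, INITIAL_DISTRIBUTION, autocorrelation,
    envelope_observations, estimate_cycle_length, fit_dhmm, hilbert_envelope,
    label_from_ecg, segment_record, viterbi_segment,
)
from chd_phonoscreen.synth import SynthSpec, gen_heart_sound

from oracles import autocorr_brute, viterbi_brute


# -- autocorrelation --------------------------------------------------------

def test_autocorrelation_closed_form():
    # constant input: r(l) = (N - l)/N
    assert np.allclose(autocorrelation([1, 1, 1, 1]), [1, 0.75, 0.5, 0.25])
    assert np.all(autocorrelation(np.zeros(8)) == 0)
    with pytest.raises(ValueError):
        autocorrelation([])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(-10, 10), min_size=1, max_size=16))
def test_autocorrelation_matches_double_sum(xs):
    assert np.allclose(autocorrelation(xs), autocorr_brute(xs), atol=1e-12)


# -- Hilbert envelope -------------------------------------------------------

def test_envelope_of_unit_sine_is_one():
    t = np.arange(2000) / 1000.0
    env = hilbert_envelope(np.sin(2 * np.pi * 50 * t))
    core = env[100:-100]
    assert np.all(np.abs(core - 1.0) < 0.02)


def test_envelope_is_sign_invariant():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(256)
    assert np.allclose(hilbert_envelope(x), hilbert_envelope(-x))


def test_envelope_peak_at_gaussian_burst_centre():
    t = np.arange(4000) / 2000.0
    centre = 1.0
    x = np.exp(-0.5 * ((t - centre) / 0.03) ** 2) * np.sin(2 * np.pi * 60 * t)
    peak = np.argmax(hilbert_envelope(x))
    assert abs(peak - 2000) <= 1


# -- cycle-length estimation ------------------------------------------------

def test_cycle_length_recovered_on_jitter_free_record():
    rec, _ = gen_heart_sound(SynthSpec(duration=8.0, cycle_jitter_sd=0.0, seed=1))
    lag = estimate_cycle_length(rec)
    assert lag == pytest.approx(1600, abs=32)  # 0.8 s at 2 kHz, +-2%


def test_strictly_periodic_envelope_gives_exact_period():
    sr = 2000.0
    period = 900
    t = np.arange(period) / sr
    template = np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2) * np.sin(2 * np.pi * 60 * t)
    rec = PCGRecord(samples=np.tile(template, 10), sampling_rate=sr)
    assert estimate_cycle_length(rec) == period


def test_white_noise_has_no_cycle():
    rng = np.random.default_rng(3)
    rec = PCGRecord(samples=rng.uniform(-0.5, 0.5, 8000), sampling_rate=2000.0)
    with pytest.raises(CycleNotFoundError):
        estimate_cycle_length(rec)


def test_too_short_record_rejected():
    rec = PCGRecord(samples=np.zeros(1000), sampling_rate=2000.0)
    with pytest.raises(ValueError):
        estimate_cycle_length(rec)


# -- ECG-guided labelling ---------------------------------------------------

def test_ecg_labels_agree_with_ground_truth(short_record):
    rec, gt = short_record
    segmap = label_from_ecg(rec)
    decoded = segmap.to_samples(len(gt.state_sequence))
    assert np.mean(decoded == gt.state_sequence) >= 0.95
    assert segmap.check_cyclic()


def test_single_r_peak_is_degenerate(short_record):
    rec, _ = short_record
    solo = PCGRecord(samples=rec.samples, sampling_rate=rec.sampling_rate,
                     r_peaks=rec.r_peaks[:1], t_ends=rec.t_ends[:1])
    with pytest.raises(ValueError):
        label_from_ecg(solo)


def test_missing_fiducials_rejected(short_record):
    rec, _ = short_record
    bare = PCGRecord(samples=rec.samples, sampling_rate=rec.sampling_rate)
    with pytest.raises(ValueError):
        label_from_ecg(bare)


def test_explicit_rule_controls_s1_width(short_record):
    rec, _ = short_record
    segmap = label_from_ecg(rec, EcgLabelRule(s1_mean=0.2, s2_mean=0.2))
    runs = [b - a for s, a, b in segmap.boundaries if s == 0][1:-1]
    hop_s = segmap.hop / rec.sampling_rate
    assert np.mean(runs) * hop_s == pytest.approx(0.2, abs=0.02)


# -- DHMM fitting -----------------------------------------------------------

def _tiled_segmap(dwells, n_cycles, hop=20, frame_length=50):
    states = []
    for _ in range(n_cycles):
        for j, d in enumerate(dwells):
            states.extend([j] * d)
    return SegmentMap(states=np.asarray(states), frame_length=frame_length,
                      hop=hop, sampling_rate=2000.0)


def test_constant_dwell_gives_degenerate_duration_model():
    sm = _tiled_segmap([20, 12, 20, 28], n_cycles=5)
    obs = np.zeros(sm.n_frames)
    hmm = fit_dhmm([(obs, sm)])
    assert hmm.duration_mean[0] == 20
    assert hmm.duration_var[0] == 0
    d, logp = hmm.duration_log_pmf(0)
    assert list(d) == [20] and np.allclose(np.exp(logp), [1.0])


def test_fitted_duration_pmfs_normalize(fitted_hmm):
    for j in range(4):
        _, logp = fitted_hmm.duration_log_pmf(j)
        assert np.exp(logp).sum() == pytest.approx(1.0)


def test_transition_and_initial_distributions_are_fixed(fitted_hmm):
    assert np.array_equal(fitted_hmm.A, TRANSITION_MATRIX)
    assert np.array_equal(fitted_hmm.pi, INITIAL_DISTRIBUTION)
    assert np.all(fitted_hmm.A.sum(axis=1) == 1)
    assert np.all((fitted_hmm.A == 0) | (fitted_hmm.A == 1))


def test_gaussian_dwells_recovered_within_two_se():
    rng = np.random.default_rng(5)
    mu, sd, n = 24.0, 3.0, 120
    segmaps = []
    draws = []
    states = []
    for _ in range(n):
        for j in range(4):
            d = max(1, int(round(rng.normal(mu, sd))))
            if j == 0:
                draws.append(d)
            states.extend([j] * d)
    sm = SegmentMap(states=np.asarray(states), frame_length=50, hop=20,
                    sampling_rate=2000.0)
    hmm = fit_dhmm([(np.zeros(sm.n_frames), sm)])
    se = sd / np.sqrt(n)
    assert abs(hmm.duration_mean[0] - np.mean(draws[1:])) <= 2 * se + 1e-9


def test_missing_state_is_reported_by_name():
    sm = SegmentMap(states=np.asarray(([0] * 10 + [1] * 10) * 3),
                    frame_length=50, hop=20, sampling_rate=2000.0)
    with pytest.raises(ValueError, match="S2"):
        fit_dhmm([(np.zeros(sm.n_frames), sm)])


# -- Viterbi decoding -------------------------------------------------------

def _random_model(rng):
    return DurationHMM(
        duration_mean=np.full(4, 4.0),
        duration_var=np.full(4, 1.0 / 9.0),   # support exactly {3, 4, 5}
        emission_mean=rng.normal(0, 2, 4),
        emission_var=rng.uniform(0.3, 2.0, 4),
    )


def test_viterbi_matches_exhaustive_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(10):
        model = _random_model(rng)
        obs = rng.normal(0, 2, 16)
        decoded = viterbi_segment(obs, model)
        best_score, best_states = viterbi_brute(obs, model)
        assert np.array_equal(decoded.states, best_states)


def test_viterbi_respects_cyclic_transitions(small_cohort, fitted_hmm):
    rec, _ = small_cohort[0]
    segmap = segment_record(rec, fitted_hmm)
    assert segmap.check_cyclic()


def test_viterbi_raises_when_no_tiling_exists():
    model = DurationHMM(duration_mean=np.full(4, 5.0), duration_var=np.zeros(4),
                        emission_mean=np.zeros(4), emission_var=np.ones(4))
    from chd_phonoscreen.segment import NoAdmissiblePathError
    with pytest.raises(NoAdmissiblePathError):
        viterbi_segment(np.zeros(7), model)  # only multiples of 5 are tileable


def test_segmentation_is_amplitude_invariant(small_cohort, fitted_hmm):
    rec, _ = small_cohort[1]
    scaled = PCGRecord(samples=rec.samples * 0.2, sampling_rate=rec.sampling_rate)
    a = segment_record(rec, fitted_hmm)
    b = segment_record(scaled, fitted_hmm)
    assert np.array_equal(a.states, b.states)


def test_dhmm_pipeline_recovers_ground_truth(small_cohort, fitted_hmm):
    agree = total = 0
    for rec, gt in small_cohort:
        decoded = segment_record(rec, fitted_hmm).to_samples(len(gt.state_sequence))
        agree += np.sum(decoded == gt.state_sequence)
        total += len(gt.state_sequence)
    assert agree / total >= 0.90
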