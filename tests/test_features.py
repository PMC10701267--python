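import numpy as np
import pytest

from chd_phonoscreen.pcg_io import PCGRecord, frame_signal
from chd_phonoscreen.features import (
    ENERGY_FLOOR, build_envelope_matrix, build_mel_bank, homomorphic_envelope,
    max_pool_1d, mfsc, power_spectrum, resize_map,
)
from chd_phonoscreen.segment import label_from_ecg

from oracles import dft_power_brute, mfsc_brute


def _frames(signal, sr=2000.0, frame_length=50, hop=20, window="rect"):
    return frame_signal(PCGRecord(samples=signal, sampling_rate=sr),
                        frame_length, hop, window)


# -- power spectrum ---------------------------------------------------------

def test_dc_frame_energy_lands_in_bin_zero():
    fs = _frames(np.ones(64), frame_length=64, hop=64)
    P = power_spectrum(fs, 64)
    assert P[0, 0] == pytest.approx(64.0 ** 2)
    assert np.allclose(P[0, 1:], 0, atol=1e-18)


def test_bin_centre_tone_is_a_single_peak():
    n = 64
    x = np.cos(2 * np.pi * 8 * np.arange(n) / n)
    P = power_spectrum(_frames(x, frame_length=n, hop=n), n)[0]
    assert np.argmax(P) == 8
    assert P[8] > 100 * np.sort(P)[-2]


def test_power_spectrum_matches_naive_dft():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(40)
    P = power_spectrum(_frames(x, frame_length=40, hop=40), 64)[0]
    brute = dft_power_brute(x, 64)
    assert np.max(np.abs(P - brute) / np.maximum(np.abs(brute), 1e-30)) < 1e-9


def test_fft_size_below_frame_length_rejected():
    with pytest.raises(ValueError):
        power_spectrum(_frames(np.ones(100), frame_length=100, hop=100), 64)


# -- Mel filter bank --------------------------------------------------------

@pytest.fixture(scope="module")
def bank():
    return build_mel_bank(40, 256, 2000.0, 25.0, 1000.0)


def test_filters_peak_at_their_own_centre(bank):
    for n in range(bank.n_filters):
        assert bank.H[n, int(bank.centers[n])] == 1.0


def test_filters_vanish_outside_their_support(bank):
    for n in range(bank.n_filters):
        left, right = bank.edges[n], bank.edges[n + 2]
        assert np.all(bank.H[n, :left] == 0)
        assert np.all(bank.H[n, right + 1:] == 0)


def test_adjacent_filters_sum_to_one_between_centres(bank):
    for n in range(bank.n_filters - 1):
        c0, c1 = int(bank.centers[n]), int(bank.centers[n + 1])
        ks = np.arange(c0 + 1, c1 + 1)
        assert np.allclose(bank.H[n, ks] + bank.H[n + 1, ks], 1.0)


def test_overfull_bank_is_rejected():
    with pytest.raises(ValueError):
        build_mel_bank(200, 64, 2000.0, 25.0, 1000.0)


# -- MFSC -------------------------------------------------------------------

def test_unit_filter_energy_gives_zero_log(bank):
    # craft a frame whose weighted energy in filter 0 is exactly 1
    c = int(bank.centers[0])
    fs = _frames(np.ones(256), frame_length=256, hop=256)
    P = np.zeros_like(power_spectrum(fs, 256))
    P[:, c] = 1.0
    s = np.log(np.maximum(P @ bank.H.T, ENERGY_FLOOR))
    assert s[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_amplitude_scaling_shifts_mfsc_additively(bank):
    rng = np.random.default_rng(2)
    x = rng.standard_normal(400) * 0.1
    c = 3.0
    m1 = mfsc(_frames(x), bank).M
    m2 = mfsc(_frames(c * x), bank).M
    unfloored = m1 > np.log(ENERGY_FLOOR) + 1e-9
    assert np.allclose((m2 - m1)[unfloored], 2 * np.log(c))


def test_mfsc_matches_per_filter_dot_product_oracle(bank):
    rng = np.random.default_rng(3)
    x = rng.standard_normal(200) * 0.2
    fs = _frames(x)
    M = mfsc(fs, bank).M
    brute = mfsc_brute(power_spectrum(fs, bank.fft_size), bank.H, ENERGY_FLOOR)
    rel = np.abs(M - brute) / np.maximum(np.abs(brute), 1e-30)
    assert rel.max() < 1e-9


# -- homomorphic envelope ---------------------------------------------------

def test_envelope_tracks_constant_tone_amplitude():
    sr = 2000.0
    t = np.arange(int(6 * sr)) / sr
    x = 0.4 * np.sin(2 * np.pi * 80 * t)
    he = homomorphic_envelope(x, sr)
    core = he[int(0.1 * sr):-int(0.1 * sr)]
    assert np.all(he > 0)
    assert np.all(np.abs(core - 0.4) / 0.4 < 0.05)


def test_envelope_tracks_slow_modulator():
    sr = 2000.0
    t = np.arange(int(6 * sr)) / sr
    mod = 0.55 + 0.45 * np.sin(2 * np.pi * 2 * t)
    x = mod * np.sin(2 * np.pi * 100 * t)
    he = homomorphic_envelope(x, sr)
    core = slice(int(0.2 * sr), -int(0.2 * sr))
    r = np.corrcoef(he[core], mod[core])[0, 1]
    assert r >= 0.98


def test_envelope_is_amplitude_equivariant():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(4000) * 0.1
    he1 = homomorphic_envelope(x, 2000.0)
    he5 = homomorphic_envelope(5 * x, 2000.0)
    assert np.allclose(he5, 5 * he1, rtol=1e-6)


def test_envelope_rejects_low_sample_rate():
    with pytest.raises(ValueError):
        homomorphic_envelope(np.ones(1000), 500.0)


# -- envelope matrix --------------------------------------------------------

def test_max_pool_windowed_maximum():
    assert np.array_equal(max_pool_1d([1, 5, 2, 4, 4, 4, 0, 0, 9], 3), [5, 4, 9])
    assert len(max_pool_1d(np.arange(10), 3)) == 4  # ceil(10/3)


def test_max_pool_never_underestimates():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(100)
    pooled = max_pool_1d(x, 3)
    for i, v in enumerate(pooled):
        assert v == x[3 * i:3 * (i + 1)].max()


def test_envelope_matrix_is_centred_and_normalized(short_record):
    rec, _ = short_record
    segmap = label_from_ecg(rec)
    env = build_envelope_matrix(rec, segmap, pool_region=3)
    assert env.Q.shape[0] == env.n_cycles >= 2
    assert env.G.mean() == pytest.approx(0.0, abs=1e-9)
    assert np.max(np.abs(env.G)) == pytest.approx(1.0)
    assert np.all(env.He > 0)


def test_envelope_matrix_requires_a_cycle(short_record):
    rec, _ = short_record
    from chd_phonoscreen.segment import SegmentMap
    empty = SegmentMap(states=np.full(100, 3), frame_length=50, hop=20,
                       sampling_rate=2000.0)
    with pytest.raises(ValueError, match="no cycle"):
        build_envelope_matrix(rec, empty)
    with pytest.raises(ValueError):
        build_envelope_matrix(rec, empty, pool_region=2)


def test_resize_map_preserves_constant_and_corners():
    a = np.full((7, 11), 2.5)
    assert np.allclose(resize_map(a, (4, 4)), 2.5)
    b = np.arange(20.0).reshape(4, 5)
    out = resize_map(b, (8, 10))
    assert out[0, 0] == b[0, 0] and out[-1, -1] == b[-1, -1]
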