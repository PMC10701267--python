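"""Per-record feature maps: MFSC and the normalized envelope matrix.

MFSC (Mel-frequency spectral coefficients) are the log energies of a
triangular Mel filter bank applied to each frame's one-sided power
spectrum -- MFCC without the DCT.  The envelope matrix stacks, one row
per cardiac cycle, the max-pooled log homomorphic envelope, resampled to
a common column count and jointly centred and amplitude-normalized so the
two maps can be fused on a shared time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from chd_phonoscreen.pcg_io import FrameSet, PCGRecord

#: energy floor applied before the log in the MFSC computation
ENERGY_FLOOR = 1e-10

# default homomorphic-envelope filters: band-pass covering S1/S2 energy,
# then a zero-phase low-pass on the log magnitude for sub-10 Hz dynamics
BP_BAND = (25.0, 400.0)
BP_ORDER = 2
LP_CUTOFF = 8.0
LP_ORDER = 1

# default Mel bank: sized to give a square-ish map at 2 kHz / 10 ms hop
N_MEL = 64
FFT_SIZE = 256
F_LO = 25.0
F_HI = 1000.0


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def power_spectrum(frames: FrameSet, fft_size: int = FFT_SIZE) -> np.ndarray:
    """One-sided magnitude-squared spectrum |X(k)|^2 per frame.

    Returns a (n_frames, fft_size//2 + 1) matrix; frames shorter than
    ``fft_size`` are zero-padded.
    """
    if fft_size < frames.frame_length:
        raise ValueError(f"fft_size {fft_size} < frame_length {frames.frame_length}")
    if fft_size & (fft_size - 1):
        warnings.warn(f"fft_size {fft_size} is not a power of two; zero-padding anyway")
    X = np.fft.rfft(frames.frames, n=fft_size, axis=1)
    return np.abs(X) ** 2


@dataclass
class MelFilterBank:
    """Triangular filters with centres equally spaced on the Mel scale."""

    H: np.ndarray            # (n_filters, K) weights
    centers: np.ndarray      # (n_filters,) centre bin indices
    edges: np.ndarray        # (n_filters + 2,) bin indices incl. outer edges
    fft_size: int
    sample_rate: float

    @property
    def n_filters(self) -> int:
        return self.H.shape[0]

    def center_freqs(self) -> np.ndarray:
        return self.centers * self.sample_rate / self.fft_size


def build_mel_bank(n_filters: int = N_MEL, fft_size: int = FFT_SIZE,
                   sample_rate: float = 2000.0, f_lo: float = F_LO,
                   f_hi: float = F_HI) -> MelFilterBank:
    """Build the triangular Mel bank on FFT-bin indices.

    Each filter is 0 below its left neighbour's centre, rises linearly to
    1 at its own centre bin, falls to 0 at its right neighbour's centre,
    so adjacent filters sum to 1 between consecutive centres.
    """
    if not (0 <= f_lo < f_hi <= sample_rate / 2):
        raise ValueError(f"need 0 <= f_lo < f_hi <= Nyquist, got ({f_lo}, {f_hi})")
    if n_filters < 2:
        raise ValueError("need at least 2 filters")
    K = fft_size // 2 + 1
    mel_pts = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_filters + 2)
    edges = np.round(mel_to_hz(mel_pts) * fft_size / sample_rate).astype(int)
    if np.any(np.diff(edges) < 1):
        raise ValueError(
            f"{n_filters} filters collapse onto duplicate FFT bins at fft_size "
            f"{fft_size}; reduce n_filters or raise fft_size")
    H = np.zeros((n_filters, K))
    k = np.arange(K)
    for n in range(n_filters):
        left, centre, right = edges[n], edges[n + 1], edges[n + 2]
        rise = (k >= left) & (k <= centre)
        fall = (k > centre) & (k <= right)
        H[n, rise] = (k[rise] - left) / (centre - left)
        H[n, fall] = (right - k[fall]) / (right - centre)
    return MelFilterBank(H=H, centers=edges[1:-1].astype(float), edges=edges,
                         fft_size=fft_size, sample_rate=sample_rate)


@dataclass
class MfscMatrix:
    """Frames x filters matrix of log filter-bank energies (units: dB-like
    natural-log energy)."""

    M: np.ndarray
    frame_times: np.ndarray
    center_freqs: np.ndarray
    hop: int
    frame_length: int
    sampling_rate: float


def mfsc(frames: FrameSet, bank: MelFilterBank) -> MfscMatrix:
    """s_n = ln(max(eps, sum_k |X(k)|^2 H_n(k))) per frame and filter."""
    P = power_spectrum(frames, bank.fft_size)
    E = P @ bank.H.T
    M = np.log(np.maximum(E, ENERGY_FLOOR))
    return MfscMatrix(M=M, frame_times=frames.frame_times(),
                      center_freqs=bank.center_freqs(), hop=frames.hop,
                      frame_length=frames.frame_length,
                      sampling_rate=frames.sampling_rate)


def homomorphic_envelope(x, sample_rate: float, band: tuple[float, float] = BP_BAND,
                         lp_cutoff: float = LP_CUTOFF) -> np.ndarray:
    """Homomorphic amplitude envelope, strictly positive, same length as x.

    Chain: Butterworth band-pass -> analytic-signal magnitude -> log ->
    zero-phase low-pass -> exp.  Acting on the log magnitude makes the
    result amplitude-equivariant: scaling the input by c scales the
    envelope by c.
    """
    x = np.asarray(x, dtype=np.float64)
    if sample_rate / 2 <= band[1]:
        raise ValueError(f"sample_rate {sample_rate} too low for band-pass edge {band[1]} Hz")
    if x.size < 64:
        raise ValueError("signal too short for envelope extraction")
    b, a = butter(BP_ORDER, np.asarray(band) / (sample_rate / 2), btype="bandpass")
    y = filtfilt(b, a, x)
    mag = np.abs(hilbert(y))
    lg = np.log(np.maximum(mag, 1e-12))
    b2, a2 = butter(LP_ORDER, lp_cutoff / (sample_rate / 2), btype="low")
    return np.exp(filtfilt(b2, a2, lg))


def max_pool_1d(x, region: int) -> np.ndarray:
    """Non-overlapping windowed maximum; a final partial window is kept,
    so the output length is ceil(len(x)/region)."""
    x = np.asarray(x, dtype=np.float64)
    if region < 1:
        raise ValueError("pool region must be >= 1")
    n_out = -(-len(x) // region)
    pad = np.full(n_out * region - len(x), -np.inf)
    return np.concatenate([x, pad]).reshape(n_out, region).max(axis=1)


@dataclass
class EnvelopeMatrix:
    """Cycle-stacked, pooled, log, centred and amplitude-normalized envelopes."""

    He: np.ndarray            # full-record homomorphic envelope
    Q: np.ndarray             # (n_cycles, n_columns) log pooled envelopes
    G: np.ndarray             # centred / normalized Q, in [-1, 1]
    pool_region: int
    cycle_start_frames: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.Q.shape[0]


def build_envelope_matrix(record: PCGRecord, segmap, pool_region: int = 3,
                          n_columns: int | None = None) -> EnvelopeMatrix:
    """Build the normalized envelope matrix G from the record's cycles.

    Cycles are the spans between consecutive S1 onsets in ``segmap``.
    Each cycle's homomorphic envelope is max-pooled over ``pool_region``
    samples, log-transformed, linearly resampled to ``n_columns`` (default:
    frame count of the median cycle) and stacked; the stack is centred by
    its global mean and scaled by its max absolute deviation.
    """
    if pool_region < 3:
        raise ValueError("pool_region must be >= 3 (minimum sampling region)")
    starts_f = segmap.cycle_start_frames()
    if len(starts_f) < 2:
        raise ValueError("no cycle: segment map contains fewer than two S1 onsets")
    He = homomorphic_envelope(record.samples, record.sampling_rate)
    hop = segmap.hop
    starts_s = starts_f * hop
    cycle_frames = np.diff(starts_f)
    if n_columns is None:
        n_columns = int(np.median(cycle_frames))
    rows = []
    for a, b in zip(starts_s[:-1], starts_s[1:]):
        pooled = max_pool_1d(He[a:b], pool_region)
        q = np.log(np.maximum(pooled, 1e-12))
        xs = np.linspace(0, 1, len(q))
        rows.append(np.interp(np.linspace(0, 1, n_columns), xs, q))
    Q = np.vstack(rows)
    centred = Q - Q.mean()
    denom = np.max(np.abs(centred))
    G = centred / denom if denom > 0 else np.zeros_like(centred)
    return EnvelopeMatrix(He=He, Q=Q, G=G, pool_region=pool_region,
                          cycle_start_frames=starts_f)


def align_envelope_to_frames(env: EnvelopeMatrix, n_frames: int) -> np.ndarray:
    """Map G back onto the analysis-frame axis as one value per frame.

    Frame f inside cycle i at relative position phi takes
    ``G[i, floor(phi * n_columns)]``; frames outside any complete cycle
    take 0 (the global mean of G).
    """
    g = np.zeros(n_frames)
    starts = env.cycle_start_frames
    ncol = env.G.shape[1]
    for i, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
        a2, b2 = min(a, n_frames), min(b, n_frames)
        if b2 <= a2:
            continue
        phi = (np.arange(a2, b2) - a) / (b - a)
        g[a2:b2] = env.G[i, np.minimum((phi * ncol).astype(int), ncol - 1)]
    return g


def resize_map(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D map (separable linear interpolation)."""
    a = np.asarray(a, dtype=np.float64)
    h, w = a.shape
    out_h, out_w = shape
    yi = np.linspace(0, h - 1, out_h)
    xi = np.linspace(0, w - 1, out_w)
    tmp = np.empty((out_h, w))
    rows = np.arange(h, dtype=float)
    for j in range(w):
        tmp[:, j] = np.interp(yi, rows, a[:, j])
    cols = np.arange(w, dtype=float)
    out = np.empty((out_h, out_w))
    for i in range(out_h):
        out[i] = np.interp(xi, cols, tmp[i])
    return out
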