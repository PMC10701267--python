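"""Heart-sound segmentation into S1 / systole / S2 / diastole.

Three stages:

1. cardiac-cycle length from the autocorrelation of the Hilbert envelope;
2. supervised labelling from synchronized ECG fiducials (R peak = S1
   onset; the largest envelope peak after the T-wave end centres S2);
3. a duration-constrained HMM (hidden semi-Markov model): the transition
   matrix is the fixed cyclic permutation over the four states, the
   initial distribution is uniform (the probe lands anywhere in the
   cycle), per-state dwell times follow a truncated discretized Gaussian
   fit to labelled data, and a duration-explicit Viterbi pass decodes the
   maximum-probability segmentation.

Observations for the HMM are the per-frame homomorphic-envelope values,
z-scored per record, which makes decoding invariant to overall amplitude
scaling of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from chd_phonoscreen.pcg_io import PCGRecord, FrameSet, frame_signal
from chd_phonoscreen.synth import S1, SYSTOLE, S2, DIASTOLE, STATE_NAMES

N_STATES = 4

# fixed cyclic transition structure: S1 -> systole -> S2 -> diastole -> S1
TRANSITION_MATRIX = np.array([
    [0, 1, 0, 0],
    [0, 0, 1, 0],
    [0, 0, 0, 1],
    [1, 0, 0, 0],
], dtype=float)

INITIAL_DISTRIBUTION = np.full(N_STATES, 0.25)

#: physiologic cardiac-cycle search band, seconds (30-160 bpm)
CYCLE_BAND = (0.375, 2.0)


class CycleNotFoundError(RuntimeError):
    """No credible periodicity peak inside the physiologic band."""


class NoAdmissiblePathError(RuntimeError):
    """No state path satisfies the duration constraints."""


def autocorrelation(x) -> np.ndarray:
    """Biased autocorrelation r(l) = (1/N) sum_n x(n+l) x(n), l = 0..N-1."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("autocorrelation needs a non-empty 1-D input")
    n = x.size
    return np.correlate(x, x, mode="full")[n - 1:] / n


def hilbert_envelope(x) -> np.ndarray:
    """Magnitude of the analytic signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("hilbert_envelope needs at least 2 samples")
    return np.abs(hilbert(x))


def estimate_cycle_length(record: PCGRecord, band: tuple[float, float] = CYCLE_BAND,
                          min_peak_ratio: float = 0.1) -> int:
    """Cardiac-cycle length in samples, from the envelope autocorrelation.

    The highest autocorrelation peak of the mean-removed Hilbert envelope
    inside ``band`` (seconds) is taken; it must be a local maximum and
    reach ``min_peak_ratio`` of the zero-lag value, otherwise
    :class:`CycleNotFoundError` is raised.
    """
    if record.duration < 2.0:
        raise ValueError("record must be at least 2 s long for cycle estimation")
    env = hilbert_envelope(record.samples)
    env = env - env.mean()
    r = autocorrelation(env)
    sr = record.sampling_rate
    lo = int(np.ceil(band[0] * sr))
    hi = min(int(np.floor(band[1] * sr)), len(r) - 2)
    if lo >= hi:
        raise CycleNotFoundError("cycle not found: search band empty for this record")
    lag = lo + int(np.argmax(r[lo:hi + 1]))
    is_local_max = r[lag] >= r[lag - 1] and r[lag] >= r[lag + 1]
    if r[0] <= 0 or r[lag] < min_peak_ratio * r[0] or not is_local_max:
        raise CycleNotFoundError("cycle not found: no prominent periodicity peak in band")
    return lag


@dataclass
class SegmentMap:
    """Per-frame state sequence with framing metadata.

    ``states`` holds one integer code per analysis frame (see
    ``synth.STATE_NAMES``); frame ``i`` covers samples
    ``[i*hop, i*hop + frame_length)``.
    """

    states: np.ndarray
    frame_length: int
    hop: int
    sampling_rate: float

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def boundaries(self) -> list[tuple[int, int, int]]:
        """Maximal runs as (state, start_frame, end_frame), half-open."""
        out = []
        s = self.states
        start = 0
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[i - 1]:
                out.append((int(s[start]), start, i))
                start = i
        return out

    def check_cyclic(self) -> bool:
        """True when consecutive distinct states follow the cardiac order."""
        b = self.boundaries
        return all((b[i + 1][0] - b[i][0]) % N_STATES == 1 for i in range(len(b) - 1))

    def to_samples(self, n_samples: int) -> np.ndarray:
        """Expand frame labels to per-sample labels via frame centres."""
        centre_off = self.frame_length / 2
        idx = np.round((np.arange(n_samples) - centre_off) / self.hop).astype(int)
        return self.states[np.clip(idx, 0, self.n_frames - 1)]

    def cycle_start_frames(self) -> np.ndarray:
        """Frames where an S1 run begins (cycle onsets)."""
        return np.asarray([b[1] for b in self.boundaries if b[0] == S1], dtype=int)

    @classmethod
    def from_sample_states(cls, sample_states: np.ndarray, frame_length: int,
                           hop: int, sampling_rate: float, n_frames: int) -> "SegmentMap":
        centre = (np.arange(n_frames) * hop + frame_length // 2).clip(0, len(sample_states) - 1)
        return cls(states=np.asarray(sample_states)[centre], frame_length=frame_length,
                   hop=hop, sampling_rate=sampling_rate)


@dataclass
class EcgLabelRule:
    """Mean/SD of S1 and S2 dwell times (seconds) for ECG-guided labelling.

    Unset means are estimated from the record's envelope (second-moment
    width of the burst after each fiducial).  The SDs are retained as QC
    tolerances only; boundary placement uses the means.
    """

    s1_mean: float | None = None
    s1_sd: float = 0.0
    s2_mean: float | None = None
    s2_sd: float = 0.0

    def __post_init__(self):
        for name in ("s1_mean", "s2_mean"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"EcgLabelRule.{name} must be positive")
        if self.s1_sd < 0 or self.s2_sd < 0:
            raise ValueError("EcgLabelRule SDs must be >= 0")


def _burst_width(env: np.ndarray, lo: int, hi: int, sr: float) -> float:
    """Burst duration inside env[lo:hi] as 6x the envelope's second-moment
    width (a Gaussian-enveloped burst of nominal duration d has envelope
    SD d/6)."""
    seg = env[lo:hi].astype(float)
    if seg.size < 3:
        return 0.0
    w = np.clip(seg - np.percentile(seg, 10), 0, None) ** 2
    if w.sum() <= 0:
        return 0.0
    t = np.arange(seg.size)
    mu = (w * t).sum() / w.sum()
    var = (w * (t - mu) ** 2).sum() / w.sum()
    # env^2 of a Gaussian envelope has SD sigma/sqrt(2)
    sigma = np.sqrt(2.0 * var)
    return 6.0 * sigma / sr


def label_from_ecg(record: PCGRecord, rule: EcgLabelRule | None = None,
                   frame_length: int | None = None, hop: int | None = None) -> SegmentMap:
    """Frame-level state labels from R-peak / T-wave-end fiducials.

    S1 occupies ``s1_mean`` seconds from each R peak; S2 is centred on the
    largest envelope peak after the T-wave end with width ``s2_mean``;
    systole and diastole fill the gaps.
    """
    from chd_phonoscreen.features import homomorphic_envelope

    if not record.has_fiducials:
        raise ValueError("record has no ECG fiducials")
    r_peaks = record.r_peaks
    if len(r_peaks) < 2:
        raise ValueError("need at least one complete R-R interval")
    rule = rule or EcgLabelRule()
    sr = record.sampling_rate
    n = len(record.samples)
    env = homomorphic_envelope(record.samples, sr)

    rr = float(np.median(np.diff(r_peaks)))

    s1_mean = rule.s1_mean
    if s1_mean is None:
        widths = [_burst_width(env, r, min(n, r + int(0.3 * rr)), sr)
                  for r in r_peaks[:-1]]
        widths = [w for w in widths if w > 0]
        s1_mean = float(np.clip(np.mean(widths), 0.04, 0.35 * rr / sr)) if widths else 0.1

    s2_mean = rule.s2_mean
    t_ends = record.t_ends if record.t_ends is not None else np.asarray([], dtype=int)

    sample_states = np.full(n, DIASTOLE, dtype=np.int8)
    s2_widths = []
    s1_len = int(round(s1_mean * sr))

    # complete R-R cycles, plus a virtual final cycle covering the tail
    pairs = [(int(a), int(b)) for a, b in zip(r_peaks[:-1], r_peaks[1:])]
    tail_end = min(n, int(r_peaks[-1] + rr))
    if tail_end - int(r_peaks[-1]) > s1_len:
        pairs.append((int(r_peaks[-1]), tail_end))

    cycles = []
    for r0, r1 in pairs:
        te_cand = t_ends[(t_ends > r0) & (t_ends < r1)]
        if te_cand.size == 0:
            continue  # cycle skipped: no T-wave end inside
        te = int(te_cand[0])
        lo = max(te, r0 + s1_len)
        hi = r1 - int(0.05 * (r1 - r0))
        if hi <= lo + 2:
            continue  # S2 search window empty
        peak = lo + int(np.argmax(env[lo:hi]))
        if s2_mean is None:
            w = _burst_width(env, max(lo, peak - int(0.15 * rr)),
                             min(hi, peak + int(0.15 * rr)), sr)
            if w > 0:
                s2_widths.append(w)
        cycles.append((r0, r1, peak))

    if not cycles:
        raise ValueError("no labellable cycle (fiducials never bracket an S2 window)")
    if s2_mean is None:
        s2_mean = float(np.clip(np.mean(s2_widths), 0.04, 0.3)) if s2_widths else 0.1
    s2_half = int(round(s2_mean * sr / 2))

    for r0, r1, peak in cycles:
        s1_end = min(r0 + s1_len, r1)
        s2_start = max(peak - s2_half, s1_end)
        s2_end = min(peak + s2_half, r1)
        sample_states[r0:s1_end] = S1
        sample_states[s1_end:s2_start] = SYSTOLE
        sample_states[s2_start:s2_end] = S2
        sample_states[s2_end:r1] = DIASTOLE

    fs = frame_signal(record, frame_length, hop)
    return SegmentMap.from_sample_states(sample_states, fs.frame_length, fs.hop,
                                         sr, fs.n_frames)


@dataclass
class DurationHMM:
    """Duration-constrained HMM over the four heart-sound states.

    ``A`` and ``pi`` are fixed by the cardiac cycle's deterministic order
    and the arbitrary probe-placement time; they are never re-estimated.
    Dwell times (frames) follow a discretized Gaussian truncated to
    [max(1, mu-3sd), mu+3sd]; emissions are per-state Gaussians over a
    scalar observation (z-scored homomorphic envelope per frame).
    """

    duration_mean: np.ndarray        # (4,) frames
    duration_var: np.ndarray         # (4,)
    emission_mean: np.ndarray        # (4,)
    emission_var: np.ndarray         # (4,)
    A: np.ndarray = field(default_factory=lambda: TRANSITION_MATRIX.copy())
    pi: np.ndarray = field(default_factory=lambda: INITIAL_DISTRIBUTION.copy())

    def duration_support(self, j: int) -> np.ndarray:
        mu = self.duration_mean[j]
        sd = np.sqrt(self.duration_var[j])
        lo = max(1, int(round(mu - 3 * sd)))
        hi = max(lo, int(round(mu + 3 * sd)))
        return np.arange(lo, hi + 1)

    def duration_log_pmf(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(support, log p_j(d)); a zero-variance state is a point mass."""
        d = self.duration_support(j)
        sd = np.sqrt(self.duration_var[j])
        if sd == 0 or len(d) == 1:
            d = np.asarray([max(1, int(round(self.duration_mean[j])))])
            return d, np.zeros(1)
        logw = -0.5 * ((d - self.duration_mean[j]) / sd) ** 2
        logw -= np.log(np.exp(logw).sum())
        return d, logw

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(), "pi": self.pi.tolist(),
            "duration_mean": self.duration_mean.tolist(),
            "duration_var": self.duration_var.tolist(),
            "emission_mean": self.emission_mean.tolist(),
            "emission_var": self.emission_var.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DurationHMM":
        return cls(duration_mean=np.asarray(d["duration_mean"], float),
                   duration_var=np.asarray(d["duration_var"], float),
                   emission_mean=np.asarray(d["emission_mean"], float),
                   emission_var=np.asarray(d["emission_var"], float),
                   A=np.asarray(d["A"], float), pi=np.asarray(d["pi"], float))


def envelope_observations(record: PCGRecord, frame_length: int | None = None,
                          hop: int | None = None) -> np.ndarray:
    """Per-frame scalar observation: mean homomorphic envelope, z-scored."""
    from chd_phonoscreen.features import homomorphic_envelope

    env = homomorphic_envelope(record.samples, record.sampling_rate)
    env_rec = PCGRecord(samples=env, sampling_rate=record.sampling_rate)
    fs = frame_signal(env_rec, frame_length, hop, window_fn="rect")
    obs = fs.frames.mean(axis=1)
    sd = obs.std()
    return (obs - obs.mean()) / (sd if sd > 0 else 1.0)


def fit_dhmm(labeled: list[tuple[np.ndarray, SegmentMap]]) -> DurationHMM:
    """Fit duration and emission statistics from labelled recordings.

    ``labeled`` pairs a per-frame observation vector with its frame-level
    :class:`SegmentMap`.  The first and last run of each record are
    excluded from the duration statistics (they are truncated dwells).
    """
    if not labeled:
        raise ValueError("need at least one labelled recording")
    dwell = {j: [] for j in range(N_STATES)}
    obs_by_state = {j: [] for j in range(N_STATES)}
    for obs, segmap in labeled:
        obs = np.asarray(obs, float)
        if len(obs) != segmap.n_frames:
            raise ValueError("observation length does not match segment map")
        runs = segmap.boundaries
        for k, (state, a, b) in enumerate(runs):
            obs_by_state[state].append(obs[a:b])
            if 0 < k < len(runs) - 1:
                dwell[state].append(b - a)
    for j in range(N_STATES):
        if not dwell[j] or not obs_by_state[j]:
            raise ValueError(f"state {STATE_NAMES[j]} absent from the labelled data")
    dmu = np.array([np.mean(dwell[j]) for j in range(N_STATES)])
    dvar = np.array([np.var(dwell[j]) for j in range(N_STATES)])
    emu = np.array([np.mean(np.concatenate(obs_by_state[j])) for j in range(N_STATES)])
    evar = np.array([max(np.var(np.concatenate(obs_by_state[j])), 1e-6)
                     for j in range(N_STATES)])
    return DurationHMM(duration_mean=dmu, duration_var=dvar,
                       emission_mean=emu, emission_var=evar)


def viterbi_segment(observations: np.ndarray, model: DurationHMM,
                    frame_length: int = 0, hop: int = 1,
                    sampling_rate: float = 0.0) -> SegmentMap:
    """Duration-explicit Viterbi decoding.

    A path is a tiling of the frame axis by segments whose states follow
    the cyclic order; its score is ``log pi`` at the first segment plus,
    per segment, ``log p_j(d)`` and the summed Gaussian log-emissions.
    Raises :class:`NoAdmissiblePathError` when no tiling satisfies the
    duration supports.  Ties are broken deterministically: shorter final
    segments and lower state indices win.
    """
    obs = np.asarray(observations, float)
    t_total = len(obs)
    if t_total < 1:
        raise ValueError("need at least one observation frame")

    log_b = np.empty((N_STATES, t_total))
    for j in range(N_STATES):
        v = model.emission_var[j]
        log_b[j] = -0.5 * (np.log(2 * np.pi * v) + (obs - model.emission_mean[j]) ** 2 / v)
    cum = np.concatenate([np.zeros((N_STATES, 1)), np.cumsum(log_b, axis=1)], axis=1)

    supports = [model.duration_log_pmf(j) for j in range(N_STATES)]
    log_pi = np.log(model.pi)

    delta = np.full((t_total, N_STATES), -np.inf)
    back = np.zeros((t_total, N_STATES), dtype=int)  # chosen duration, 0 = none
    for t in range(t_total):
        for j in range(N_STATES):
            prev = (j - 1) % N_STATES
            ds, logp = supports[j]
            k = int(np.searchsorted(ds, t + 1, side="right"))
            if k == 0:
                continue
            d = ds[:k]
            base = np.where(d == t + 1, log_pi[j],
                            delta[np.maximum(t - d, 0), prev])
            score = base + logp[:k] + (cum[j, t + 1] - cum[j, t + 1 - d])
            best = int(np.argmax(score))  # first max: shortest duration wins ties
            if np.isfinite(score[best]):
                delta[t, j] = score[best]
                back[t, j] = int(d[best])

    j = int(np.argmax(delta[t_total - 1]))
    if not np.isfinite(delta[t_total - 1, j]):
        raise NoAdmissiblePathError("no admissible path under the duration constraints")
    states = np.empty(t_total, dtype=np.int8)
    t = t_total - 1
    while t >= 0:
        d = back[t, j]
        states[t - d + 1: t + 1] = j
        t -= d
        j = (j - 1) % N_STATES
    return SegmentMap(states=states, frame_length=frame_length, hop=hop,
                      sampling_rate=sampling_rate)


def segment_record(record: PCGRecord, model: DurationHMM,
                   frame_length: int | None = None, hop: int | None = None) -> SegmentMap:
    """Decode a recording with a fitted model (envelope observations)."""
    obs = envelope_observations(record, frame_length, hop)
    fs = frame_signal(record, frame_length, hop)
    return viterbi_segment(obs, model, frame_length=fs.frame_length, hop=fs.hop,
                           sampling_rate=record.sampling_rate)
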