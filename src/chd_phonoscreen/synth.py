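"""Synthetic phonocardiogram generator.

Emulates quasi-periodic heart sounds: each cardiac cycle (~0.8 s) carries
an S1 and an S2 burst (~0.2 s each) modelled as Gaussian-enveloped
sinusoids, an optional murmur (band-limited 100-400 Hz noise gated to the
systolic interval or the whole cycle, mimicking VSD/PDA-type murmurs
qualitatively), and additive white noise.  Per-sample ground-truth states,
ECG fiducials (R peak at S1 onset, T-wave end just before S2 onset) and a
class label accompany every record, so the whole downstream pipeline is
testable without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from chd_phonoscreen.pcg_io import PCGRecord, write_wav, write_fiducials, write_manifest

# state codes, cyclic order S1 -> systole -> S2 -> diastole
S1, SYSTOLE, S2, DIASTOLE = 0, 1, 2, 3
STATE_NAMES = ("S1", "systole", "S2", "diastole")

MURMUR_KINDS = ("none", "systolic", "continuous")
MURMUR_BAND = (100.0, 400.0)  # Hz


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording.

    Durations in seconds, frequencies in Hz, SNRs in dB (clean heart-sound
    power over the component's power).  Identical specs (including seed)
    yield bit-identical output.
    """

    sampling_rate: float = 2000.0
    duration: float = 20.0
    cycle_mean: float = 0.8
    cycle_jitter_sd: float = 0.02
    s1_duration: float = 0.2
    s2_duration: float = 0.2
    s1_freq: float = 50.0
    s2_freq: float = 70.0
    murmur_kind: str = "none"
    murmur_snr: float = 6.0
    noise_snr: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sampling_rate", "duration", "cycle_mean", "s1_duration",
                     "s2_duration", "s1_freq", "s2_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SynthSpec.{name} must be positive, got {getattr(self, name)}")
        if self.cycle_jitter_sd < 0:
            raise ValueError(f"SynthSpec.cycle_jitter_sd must be >= 0, got {self.cycle_jitter_sd}")
        if self.cycle_mean <= self.s1_duration + self.s2_duration:
            raise ValueError("SynthSpec.cycle_mean must exceed s1_duration + s2_duration")
        if self.murmur_kind not in MURMUR_KINDS:
            raise ValueError(f"SynthSpec.murmur_kind must be one of {MURMUR_KINDS}, "
                             f"got {self.murmur_kind!r}")


@dataclass
class GroundTruth:
    """Per-sample truth for a synthetic record."""

    state_sequence: np.ndarray      # int codes, see STATE_NAMES
    r_peaks: np.ndarray             # S1-onset sample indices
    t_ends: np.ndarray              # T-wave-end sample indices
    class_label: str                # "normal" | "chd"
    cycle_starts: np.ndarray = field(default=None)  # complete-cycle onsets

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_starts)


def _gauss_burst(t: np.ndarray, centre: float, dur: float, freq: float,
                 amp: float, phase: float) -> np.ndarray:
    # +-3 sigma of the Gaussian envelope spans the nominal burst duration
    sigma = dur / 6.0
    env = np.exp(-0.5 * ((t - centre) / sigma) ** 2)
    return amp * env * np.sin(2 * np.pi * freq * (t - centre) + phase)


def gen_heart_sound(spec: SynthSpec) -> tuple[PCGRecord, GroundTruth]:
    """Generate one synthetic PCG with per-sample ground truth."""
    spec.validate()
    sr = spec.sampling_rate
    n = int(round(spec.duration * sr))
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / sr

    # --- cycle timing: jittered lengths, truncated at +-3 SD
    starts, lengths = [], []
    pos = 0.0
    min_len = spec.s1_duration + spec.s2_duration + 0.05
    while pos * sr < n:
        jit = float(np.clip(rng.normal(0.0, spec.cycle_jitter_sd),
                            -3 * spec.cycle_jitter_sd, 3 * spec.cycle_jitter_sd))
        length = max(min_len, spec.cycle_mean + jit)
        starts.append(pos)
        lengths.append(length)
        pos += length

    heart = np.zeros(n)
    states = np.full(n, DIASTOLE, dtype=np.int8)
    r_peaks, t_ends, cycle_starts = [], [], []
    systole_gate = np.zeros(n)

    for start, length in zip(starts, lengths):
        i0 = int(round(start * sr))
        i_end = int(round((start + length) * sr))
        s1_off = start + spec.s1_duration
        # systole ends ~40% into the cycle; never overlap S1
        s2_on = start + max(0.4 * length, spec.s1_duration + 0.02)
        s2_off = s2_on + spec.s2_duration
        j1 = int(round(s1_off * sr))
        j2 = int(round(s2_on * sr))
        j3 = int(round(s2_off * sr))
        states[i0:min(j1, n)] = S1
        states[min(j1, n):min(j2, n)] = SYSTOLE
        states[min(j2, n):min(j3, n)] = S2
        states[min(j3, n):min(i_end, n)] = DIASTOLE

        heart += _gauss_burst(t, start + spec.s1_duration / 2, spec.s1_duration,
                              spec.s1_freq, 1.0, rng.uniform(0, 2 * np.pi))
        heart += _gauss_burst(t, s2_on + spec.s2_duration / 2, spec.s2_duration,
                              spec.s2_freq, 0.8, rng.uniform(0, 2 * np.pi))
        lo, hi = min(j1, n), min(j2, n)
        systole_gate[lo:hi] = 1.0

        if i0 < n:
            r_peaks.append(i0)
        te = int(round((s2_on - 0.02) * sr))   # T-wave end 20 ms before S2 onset
        if te < n:
            t_ends.append(te)
        if i_end <= n:
            cycle_starts.append(i0)

    clean = heart.copy()
    heart_rms = np.sqrt(np.mean(heart ** 2)) or 1.0

    if spec.murmur_kind != "none":
        raw = rng.standard_normal(n)
        b, a = butter(4, np.array(MURMUR_BAND) / (sr / 2), btype="bandpass")
        murmur = filtfilt(b, a, raw)
        gate = systole_gate if spec.murmur_kind == "systolic" else np.ones(n)
        murmur = murmur * gate
        m_rms = np.sqrt(np.mean(murmur[gate > 0] ** 2)) if np.any(gate > 0) else 0.0
        if m_rms > 0:
            murmur *= heart_rms * 10 ** (-spec.murmur_snr / 20) / m_rms
        clean = clean + murmur

    clean_rms = np.sqrt(np.mean(clean ** 2)) or 1.0
    noise = rng.standard_normal(n) * clean_rms * 10 ** (-spec.noise_snr / 20)
    x = clean + noise
    x *= 0.95 / np.max(np.abs(x))

    rec = PCGRecord(samples=x, sampling_rate=sr,
                    record_id=f"synth_{spec.seed}",
                    label="chd" if spec.murmur_kind != "none" else "normal",
                    r_peaks=np.asarray(r_peaks), t_ends=np.asarray(t_ends))
    gt = GroundTruth(state_sequence=states,
                     r_peaks=np.asarray(r_peaks),
                     t_ends=np.asarray(t_ends),
                     class_label=rec.label,
                     cycle_starts=np.asarray(cycle_starts))
    return rec, gt


def derive_seeds(seed: int, n: int) -> list[int]:
    """Counter-based per-record seed derivation (stable under n)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2 ** 31) for c in ss.spawn(n)]


def gen_dataset(n_normal: int, n_chd: int, spec_template: SynthSpec,
                seed: int, outdir) -> Path:
    """Write a labelled synthetic dataset: WAVs, fiducial CSVs, manifest.

    CHD records carry the template's murmur kind (``systolic`` if the
    template says ``none``); normal records carry no murmur.  Returns the
    manifest path.
    """
    if n_normal < 0 or n_chd < 0:
        raise ValueError("record counts must be >= 0")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

    chd_murmur = spec_template.murmur_kind if spec_template.murmur_kind != "none" else "systolic"
    labels = ["normal"] * n_normal + ["chd"] * n_chd
    seeds = derive_seeds(seed, len(labels))

    rows = []
    for i, (label, rec_seed) in enumerate(zip(labels, seeds)):
        spec = replace(spec_template, seed=rec_seed,
                       murmur_kind=chd_murmur if label == "chd" else "none")
        rec, gt = gen_heart_sound(spec)
        stem = f"rec_{i:04d}_{label}"
        write_wav(outdir / f"{stem}.wav", rec)
        write_fiducials(outdir / f"{stem}_fiducials.csv", gt.r_peaks, gt.t_ends)
        rows.append((f"{stem}.wav", label))

    manifest = outdir / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest
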