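"""Reading, writing, resampling and framing of PCG recordings.

Recordings are mono WAV files (PCM 16-bit); amplitudes are kept as floats
in [-1, 1] in memory.  Optional ECG fiducials (R-peak and T-wave-end
sample indices) ride along on the record and drive the supervised
segmentation labelling.  All sample indexing is 0-based and half-open.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

#: canonical internal sampling rate (Hz); heart-sound energy sits well below 1 kHz
CANONICAL_RATE = 2000

#: default spectral-analysis framing
FRAME_MS = 25.0
HOP_MS = 10.0
DEFAULT_WINDOW = "hamming"


@dataclass
class PCGRecord:
    """One phonocardiogram recording.

    Parameters
    ----------
    samples : float array, amplitudes in [-1, 1]
    sampling_rate : Hz
    record_id : identifier string
    label : optional class label, ``"normal"`` or ``"chd"``
    r_peaks, t_ends : optional ECG fiducial sample indices (0-based)
    """

    samples: np.ndarray
    sampling_rate: float
    record_id: str = ""
    label: str | None = None
    r_peaks: np.ndarray | None = None
    t_ends: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        for name in ("r_peaks", "t_ends"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.size and (np.any(np.diff(v) <= 0) or v[0] < 0 or v[-1] >= len(self.samples)):
                    raise ValueError(f"{name} must be strictly increasing and within the record")
                setattr(self, name, v)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def has_fiducials(self) -> bool:
        return self.r_peaks is not None and self.t_ends is not None


@dataclass
class FrameSet:
    """Equal-length windowed frames of a signal; frame i starts at i*hop."""

    frames: np.ndarray  # (n_frames, frame_length)
    frame_length: int
    hop: int
    window_fn: str
    sampling_rate: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times(self) -> np.ndarray:
        """Centre time (s) of each frame."""
        starts = np.arange(self.n_frames) * self.hop
        return (starts + self.frame_length / 2) / self.sampling_rate


def read_wav(path) -> PCGRecord:
    """Read a mono PCM WAV into a :class:`PCGRecord` with samples in [-1, 1]."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multi-channel WAV, using channel 0")
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = data.astype(np.float64)
    return PCGRecord(samples=samples, sampling_rate=float(rate), record_id=path.stem)


def write_wav(path, record: PCGRecord) -> None:
    """Write a record as PCM 16-bit mono WAV (amplitudes clipped to [-1, 1])."""
    x = np.clip(record.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(record.sampling_rate), pcm)


def resample(record: PCGRecord, target_rate: float) -> PCGRecord:
    """Polyphase resampling with anti-aliasing; fiducials are rescaled."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == record.sampling_rate:
        return record
    frac = Fraction(int(round(target_rate)), int(round(record.sampling_rate))).limit_denominator(10000)
    y = resample_poly(record.samples, frac.numerator, frac.denominator)
    scale = target_rate / record.sampling_rate

    def _rescale(idx):
        if idx is None:
            return None
        out = np.round(idx * scale).astype(np.int64)
        return np.clip(out, 0, len(y) - 1)

    return replace(
        record,
        samples=np.clip(y, -1.0, 1.0),
        sampling_rate=float(target_rate),
        r_peaks=_rescale(record.r_peaks),
        t_ends=_rescale(record.t_ends),
    )


def frame_signal(record: PCGRecord, frame_length: int | None = None,
                 hop: int | None = None, window_fn: str = DEFAULT_WINDOW) -> FrameSet:
    """Slice a record into overlapping windowed frames.

    Defaults to 25 ms frames with a 10 ms hop and a Hamming window.  The
    last partial frame is dropped, so the frame count is
    ``floor((N - frame_length)/hop) + 1``.
    """
    sr = record.sampling_rate
    if frame_length is None:
        frame_length = int(round(FRAME_MS * 1e-3 * sr))
    if hop is None:
        hop = int(round(HOP_MS * 1e-3 * sr))
    n = len(record.samples)
    if not (0 < hop <= frame_length):
        raise ValueError(f"need 0 < hop <= frame_length, got hop={hop}, frame_length={frame_length}")
    if frame_length > n:
        raise ValueError(f"frame_length {frame_length} exceeds signal length {n}")
    n_frames = (n - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    win = (np.ones(frame_length) if window_fn in (None, "rect", "rectangular", "boxcar")
           else get_window(window_fn, frame_length, fftbins=True))
    frames = record.samples[idx] * win
    return FrameSet(frames=frames, frame_length=frame_length, hop=hop,
                    window_fn=window_fn or "rect", sampling_rate=sr)


# ---------------------------------------------------------------------------
# manifest / fiducial CSV plumbing

def write_fiducials(path, r_peaks, t_ends) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_index", "kind"])
        marks = sorted([(int(i), "R") for i in r_peaks] + [(int(i), "Tend") for i in t_ends])
        w.writerows(marks)


def read_fiducials(path) -> tuple[np.ndarray, np.ndarray]:
    r, t = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            (r if row["kind"] == "R" else t).append(int(row["sample_index"]))
    return np.asarray(r, dtype=np.int64), np.asarray(t, dtype=np.int64)


def write_manifest(path, rows) -> None:
    """rows: iterable of (path, label) pairs."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label"])
        w.writerows(rows)


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_record(manifest_row: dict, manifest_path=None) -> PCGRecord:
    """Load a WAV named in a manifest row, attaching label and any sibling
    ``<stem>_fiducials.csv``."""
    wav = Path(manifest_row["path"])
    if not wav.is_absolute() and manifest_path is not None:
        wav = Path(manifest_path).parent / wav
    rec = read_wav(wav)
    rec.label = manifest_row.get("label") or None
    fid = wav.with_name(wav.stem + "_fiducials.csv")
    if fid.exists():
        rec.r_peaks, rec.t_ends = read_fiducials(fid)
    return rec
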