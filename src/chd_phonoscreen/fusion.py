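"""Energy-gated local overlay fusion of the MFSC and envelope maps.

High-energy intervals (S1/S2) are found by sliding a 0.2 s window over
the per-frame mean MFSC energy; a window whose mean strictly exceeds the
mean energy of its cardiac cycle flags all of its frames.  On flagged
frames the maps are summed (overlay); elsewhere they are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: sliding-window length for high-energy detection, seconds
DEFAULT_WINDOW_S = 0.2

FUSION_MODES = ("overlay", "mfsc-only", "envelope-only")


@dataclass
class FusedMap:
    """Fused feature map W with its gating mask."""

    W: np.ndarray                 # (frames, channels)
    high_energy_mask: np.ndarray  # (frames,) bool
    window_s: float = DEFAULT_WINDOW_S


def frame_energy(M: np.ndarray) -> np.ndarray:
    """Per-frame energy: channel mean of the (log-energy) MFSC matrix."""
    return np.asarray(M, float).mean(axis=1)


def detect_high_energy(M: np.ndarray, cycle_start_frames, window_frames: int) -> np.ndarray:
    """Boolean per-frame mask of elevated-energy (S1/S2) intervals.

    The threshold is the mean frame energy of each cardiac cycle (cycles
    are spans between consecutive entries of ``cycle_start_frames``;
    leading/trailing frames join the nearest cycle).  A length-
    ``window_frames`` window slides with stride 1; windows are compared
    against the threshold of the cycle containing their centre frame, and
    the mask is the union of all strictly-exceeding windows.
    """
    M = np.asarray(M, float)
    energy = frame_energy(M)
    t = len(energy)
    if window_frames < 1:
        raise ValueError("window must cover at least one frame")
    starts = np.asarray(cycle_start_frames, dtype=int)
    if len(starts) < 1:
        raise ValueError("need at least one cycle start")
    # cycle id per frame; frames before the first start fold into cycle 0
    cyc = np.clip(np.searchsorted(starts, np.arange(t), side="right") - 1, 0, None)
    n_cyc = cyc.max() + 1
    thresholds = np.array([energy[cyc == c].mean() for c in range(n_cyc)])
    cycle_lengths = np.bincount(cyc)
    if window_frames > cycle_lengths.max():
        raise ValueError(f"window of {window_frames} frames exceeds the longest "
                         f"cycle ({cycle_lengths.max()} frames)")
    if window_frames > t:
        raise ValueError("window longer than the record")

    csum = np.concatenate([[0.0], np.cumsum(energy)])
    win_mean = (csum[window_frames:] - csum[:-window_frames]) / window_frames
    centres = np.arange(len(win_mean)) + window_frames // 2
    thr = thresholds[cyc[centres]]
    # strict inequality, guarded against cumulative-sum round-off so a
    # constant map never self-flags
    exceeding = win_mean - thr > 1e-9 * np.maximum(1.0, np.abs(thr))
    mask = np.zeros(t, dtype=bool)
    for p in np.flatnonzero(exceeding):
        mask[p:p + window_frames] = True
    return mask


def local_overlay(M: np.ndarray, G: np.ndarray, mask: np.ndarray,
                  window_s: float = DEFAULT_WINDOW_S) -> FusedMap:
    """W = M + G on masked frames, (M + G)/2 elsewhere.

    ``G`` may be a per-frame vector; it is then broadcast across M's
    channel axis.
    """
    M = np.asarray(M, float)
    G = np.asarray(G, float)
    if G.ndim == 1:
        G = np.broadcast_to(G[:, None], M.shape)
    if G.shape != M.shape:
        raise ValueError(f"shape mismatch: M is {M.shape}, G is {G.shape}")
    mask = np.asarray(mask, bool)
    if mask.shape != (M.shape[0],):
        raise ValueError(f"mask length {mask.shape} does not match {M.shape[0]} frames")
    S = M + G
    W = np.where(mask[:, None], S, S / 2.0)
    return FusedMap(W=W, high_energy_mask=mask, window_s=window_s)
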