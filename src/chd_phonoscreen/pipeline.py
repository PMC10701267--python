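"""End-to-end orchestration: records -> segmentation -> fused maps -> classifier.

Mirrors the screening procedure: ECG-guided labels supervise the
duration-constrained HMM, the HMM segments every recording, the MFSC and
envelope maps are fused by energy-gated local overlay, and the LCACNN is
trained on the fused maps with a stratified 70/20/10
train/test/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chd_phonoscreen import pcg_io
from chd_phonoscreen.pcg_io import PCGRecord, frame_signal, CANONICAL_RATE
from chd_phonoscreen.synth import SynthSpec, gen_heart_sound, derive_seeds
from chd_phonoscreen import segment as seg
from chd_phonoscreen import features as feat
from chd_phonoscreen import fusion as fus
from chd_phonoscreen import lcacnn
from chd_phonoscreen.metrics import evaluate, EvalReport

#: default stratified split fractions (train, test, validation)
SPLIT_FRACTIONS = (0.7, 0.2, 0.1)


@dataclass
class FeatureConfig:
    n_mel: int = feat.N_MEL
    fft_size: int = feat.FFT_SIZE
    f_lo: float = feat.F_LO
    f_hi: float = feat.F_HI
    pool_region: int = 3
    window_s: float = fus.DEFAULT_WINDOW_S
    fusion_mode: str = "overlay"
    input_shape: tuple = (32, 32)

    def validate(self) -> None:
        if self.fusion_mode not in fus.FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {fus.FUSION_MODES}")


def canonicalize(record: PCGRecord) -> PCGRecord:
    """Resample to the canonical internal rate (2 kHz)."""
    return pcg_io.resample(record, CANONICAL_RATE)


def fit_segmenter(records: list[PCGRecord]) -> seg.DurationHMM:
    """Fit the duration-constrained HMM from ECG-labelled recordings."""
    labeled = []
    for rec in records:
        if not rec.has_fiducials:
            continue
        segmap = seg.label_from_ecg(rec)
        obs = seg.envelope_observations(rec)
        labeled.append((obs, segmap))
    if not labeled:
        raise ValueError("no record carries ECG fiducials; cannot fit the segmenter")
    return seg.fit_dhmm(labeled)


def featurize_record(record: PCGRecord, segmap: seg.SegmentMap,
                     config: FeatureConfig | None = None) -> np.ndarray:
    """Fused (or single-feature) map for one record, resized and z-scored
    to the classifier's fixed input shape."""
    config = config or FeatureConfig()
    config.validate()
    frames = frame_signal(record)
    bank = feat.build_mel_bank(config.n_mel, config.fft_size, record.sampling_rate,
                               config.f_lo, min(config.f_hi, record.sampling_rate / 2))
    M = feat.mfsc(frames, bank)
    env = feat.build_envelope_matrix(record, segmap, config.pool_region)
    g = feat.align_envelope_to_frames(env, frames.n_frames)
    hop_s = frames.hop / record.sampling_rate
    window_frames = max(1, int(round(config.window_s / hop_s)))
    mask = fus.detect_high_energy(M.M, segmap.cycle_start_frames(), window_frames)
    if config.fusion_mode == "overlay":
        fmap = fus.local_overlay(M.M, g, mask, config.window_s).W
    elif config.fusion_mode == "mfsc-only":
        fmap = M.M
    else:  # envelope-only
        fmap = np.broadcast_to(g[:, None], M.M.shape).copy()
    out = feat.resize_map(fmap, config.input_shape)
    sd = out.std()
    return (out - out.mean()) / (sd if sd > 0 else 1.0)


def stratified_split(labels: np.ndarray, seed: int,
                     fractions: tuple = SPLIT_FRACTIONS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class shuffled 70/20/10 split -> (train_idx, test_idx, val_idx)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_test = int(round(fractions[1] * n))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:n_train + n_test])
        val.extend(idx[n_train + n_test:])
    return (np.sort(np.asarray(train, int)), np.sort(np.asarray(test, int)),
            np.sort(np.asarray(val, int)))


@dataclass
class ExperimentResult:
    report: EvalReport
    history: dict
    segmentation_accuracy: float     # frame-state agreement vs ground truth
    n_records: int
    split_sizes: tuple
    probabilities: np.ndarray
    test_labels: np.ndarray


def run_experiment(n_normal: int = 100, n_chd: int = 100, seed: int = 0,
                   epochs: int = 25, spec: SynthSpec | None = None,
                   feature_config: FeatureConfig | None = None,
                   model_config: "lcacnn.LcacnnConfig | None" = None) -> ExperimentResult:
    """Full in-memory surrogate experiment on synthetic records.

    Generates the dataset, fits the DHMM segmenter from the ECG labels,
    segments every record with it, extracts fused maps, trains the
    LCACNN on the stratified 70% split and evaluates on the held-out 20%
    test split.
    """
    spec = spec or SynthSpec()
    feature_config = feature_config or FeatureConfig()

    labels_str = ["normal"] * n_normal + ["chd"] * n_chd
    seeds = derive_seeds(seed, len(labels_str))
    records, truths = [], []
    from dataclasses import replace
    for label, s in zip(labels_str, seeds):
        sp = replace(spec, seed=s,
                     murmur_kind="none" if label == "normal"
                     else (spec.murmur_kind if spec.murmur_kind != "none" else "systolic"))
        rec, gt = gen_heart_sound(sp)
        records.append(rec)
        truths.append(gt)

    hmm = fit_segmenter(records)

    maps, agree, total = [], 0, 0
    for rec, gt in zip(records, truths):
        segmap = seg.segment_record(rec, hmm)
        decoded = segmap.to_samples(len(gt.state_sequence))
        agree += int(np.sum(decoded == gt.state_sequence))
        total += len(gt.state_sequence)
        maps.append(featurize_record(rec, segmap, feature_config))
    seg_acc = agree / total

    X = np.stack(maps)[:, None, :, :]
    y = np.asarray([1 if l == "chd" else 0 for l in labels_str], dtype=float)
    tr, te, va = stratified_split(y, seed)

    cfg = model_config or lcacnn.LcacnnConfig(seed=seed, epochs=epochs,
                                              input_shape=feature_config.input_shape)
    model = lcacnn.build_model(cfg)
    history = lcacnn.train(model, X[tr], y[tr], cfg, epochs=epochs)
    probs = lcacnn.predict(model, X[te])
    rep = evaluate(y[te], probs)
    return ExperimentResult(report=rep, history=history,
                            segmentation_accuracy=seg_acc,
                            n_records=len(records),
                            split_sizes=(len(tr), len(te), len(va)),
                            probabilities=probs, test_labels=y[te])
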