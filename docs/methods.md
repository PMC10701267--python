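# Methods

This note records the models implemented by `chd_phonoscreen`, the
parameter choices that matter, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and conventions

Recordings are mono PCG waveforms, held as float64 in [−1, 1]. All
internal analysis runs at a canonical 2 kHz (heart-sound energy lies far
below 1 kHz; the resampler is polyphase with anti-aliasing, so 5 kHz
clinical recordings and 2 kHz archive recordings meet on one grid).
Spectral framing uses 25 ms frames, 10 ms hop, Hamming window — standard
short-time analysis values for signals whose stationarity horizon is the
~0.2 s heart sound. Indexing is 0-based and half-open everywhere.

## Segmentation

The cardiac cycle visits S1 → systole → S2 → diastole deterministically,
so the four-state transition matrix is the cyclic permutation and is
never re-estimated; the initial distribution is uniform because the
recording may begin at any phase. What distinguishes the model from a
plain HMM is the explicit dwell-time distribution p_j(d): a Gaussian
N(d̄μ_j, dΣ_j) discretized on frames and truncated to
[max(1, μ−3σ), μ+3σ]. A zero-variance state degenerates to a point mass,
which the decoder handles exactly.

Supervision comes from synchronized ECG fiducials. S1 begins at each R
peak and lasts the mean S1 width; S2 is centred on the tallest envelope
peak after the T-wave end. When the rule's widths are not supplied they
are estimated per record from the envelope's second moment: a
Gaussian-enveloped burst of nominal duration d has envelope SD d/6, so
width = 6·√(2·Var) of the squared envelope inside the search window.
The partial cycle after the last R peak is labelled too (using the
median R–R as a virtual cycle end); leaving it unlabelled costs several
percent of frame agreement on 8–20 s records. The "±σ" halves of the
clinical rule are kept as QC tolerances only; boundary placement uses
the means, since using a dispersion to place a boundary is not
well-defined.

Emissions are deliberately minimal: one homomorphic-envelope value per
frame, z-scored per record. This makes decoding invariant to overall
gain — recording level varies with probe pressure and skin contact —
and is sufficient because the duration model carries most of the
structure. Decoding is duration-explicit Viterbi in log space,
O(T · states · max-dwell) with cumulative-sum emission totals. A path
must tile the frame axis exactly; if the supports admit no tiling the
decoder raises rather than silently truncating. Ties break
deterministically toward the shorter final dwell and lower state index.

Cycle-length estimation searches the envelope autocorrelation in
0.375–2.0 s (30–160 bpm, a physiologic band); the peak must be a local
maximum reaching 10% of the zero-lag value, otherwise the record is
reported as having no credible periodicity (white noise fails here by
design).

## Features and fusion

MFSC uses a 64-filter triangular Mel bank from 25 to 1000 Hz on a
256-point FFT. At 2 kHz this is the smallest power-of-two FFT whose bin
spacing keeps all 64 Mel centres on distinct bins; the bank constructor
rejects configurations where centres collide. Filter-bank energies are
floored at 1e−10 before the log so silent frames yield finite values.

The homomorphic envelope is band-pass (Butterworth order 2, 25–400 Hz,
covering S1/S2 energy) → analytic magnitude → log → zero-phase low-pass
(order 1, 8 Hz, forward–backward) → exp. Operating on the log magnitude
makes the chain amplitude-equivariant, which the tests assert. The
printed form He = exp(log a(t)) is an identity on its own; the
three-step description above is the operative definition.

The per-cycle envelope rows are max-pooled over 3-sample regions (the
minimum region that still smooths sampling jitter without blurring
murmur morphology), logged, resampled to the median cycle's frame count
so the rows align, and normalized as G = (Q − Q̄)/max|Q − Q̄| with a
global scalar mean. The denominator is read as the max *absolute*
deviation so G spans [−1, 1] symmetrically; a literal signed max would
leave negative excursions unbounded below −1.

Fusion gates on energy: frame energy is the channel mean of M (log
units), the threshold is each cycle's mean frame energy, and a 0.2 s
window slides at 1-frame stride with union semantics. The inequality is
strict (with a 1e−9 relative guard against cumulative-sum round-off) so
a constant map flags nothing. Flagged frames get W = M + G, others
(M + G)/2, exactly; M (log energy) and G (dimensionless, [−1, 1]) are
combined as-is, with the scale difference documented rather than
rescaled away. G enters as a per-frame column broadcast across M's
channels, mapped from its cycle row by relative phase.

## Classifier

Architecture: n_groups ∈ [1, 5] blocks of convolution → batch norm →
ReLU → mixed pooling (2×2, stride 2, replicate-padded when odd) →
coordinate attention, then global average pooling and a sigmoid unit.
Groups 1–2 use standard 3×3 convolutions, later groups
depthwise-separable ones (c·k² + c·o parameters versus c·o·k²). Widths
are 8/16/32/64 on 32×32 single-channel input maps: the network runs on
the package's own numpy autodiff engine on one CPU core, and this is
the smallest configuration that cleanly separates the synthetic classes
while keeping a full training run in tens of seconds; all architectural
relations (parameter-count ordering, the group-count sweep, attention
gating bounds) are width-independent and tested as such. Coordinate
attention uses reduction 8 (capped at the channel count); its gates are
sigmoids, so the block can only attenuate, never amplify — asserted as
an invariant.

Mixed pooling samples λ ∈ {0, 1} per pooling layer per training batch
(the reference behaviour specifies only "a random value"; per-layer
per-batch is the coarsest choice that still randomizes). At inference λ
is fixed to 0.5: stochastic inference would make predictions
irreproducible, so the equal blend is used and documented as a
deliberate divergence between train- and test-time behaviour.

Training: Adam at 0.001, batch 64, binary cross-entropy with
probabilities clipped at 1e−7 inside the graph (1e−12 in the reference
loss function). One integer seed drives weight init, shuffling and the
λ streams; runs are bit-reproducible single-threaded.

## Synthetic data

The generator emulates what the pipeline assumes about real PCG:
quasi-periodic cycles of mean 0.8 s with Gaussian per-cycle jitter
(SD 0.02 s, truncated at ±3σ), S1 and S2 bursts of 0.2 s each as
Gaussian-enveloped sinusoids at 50 and 70 Hz (S2 at 0.8 relative
amplitude), S2 onset at 40% of the cycle, murmurs as 100–400 Hz
band-limited noise gated to systole (or the whole cycle) at 6 dB below
the heart-sound RMS, and white noise at 20 dB SNR. R peaks sit at S1
onsets and T-wave ends 20 ms before S2 onsets. Defaults are 20 s at
2 kHz. Where the underlying literature fixes a value (cycle and sound
durations) the default is that value; the murmur and noise levels are
free choices set once at levels a clinician would call an obvious
murmur in a quiet room.

What passing tests show: the segmentation, feature, fusion and
classification code paths are correct, consistent with their
closed-form oracles, and able to recover structure they are designed
for. What they do not show: performance on clinical recordings. Real
murmurs vary in grade and timing, S2 splits, sensors and environments
add structured (not white) noise, and class balance is far from 50/50 —
none of which the generator models. Published accuracies on clinical
databases are therefore not claimed or reproduced here.

## Problem sizes

The standard benchmark configuration, chosen as the package's own
convention: 200 records (100/100) for the end-to-end experiment with a
stratified 70/20/10 train/test/validation split and 25 training epochs;
20 records for the segmentation-recovery measurement; 100 random
instances per numeric-kernel oracle check; 50 exhaustive 16-frame
instances (dwells restricted to {3,4,5}) for Viterbi optimality.

## Known limitations

* The ECG labelling rule assumes fiducials are trustworthy; it does not
  detect R/T from raw ECG.
* The duration model is unimodal Gaussian per state; arrhythmic rhythms
  (bigeminy, fibrillation) violate it.
* The F-measure follows the screening convention F_β(Sp, Se) — the
  harmonic mean of sensitivity and specificity at β = 1 — not the
  precision-based textbook F-score.
* Feature maps are resized to a fixed input shape, so very long records
  are summarized rather than scanned.
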