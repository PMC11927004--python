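# Methods

This note documents the models implemented by `cwcst`, the choices made
where the method left room, and what the synthetic benchmark does and does
not demonstrate.

## Signal model

Multichannel surface EMG is treated as a convolutive mixture

```
X(t) = H * S(t) + w(t)
```

where `X(t)` stacks the M recording channels, `S(t)` the N motor-unit (MU)
spike trains, `w(t)` additive noise, and `H` holds each unit's action
potential (MUAP) as an L-sample response per channel. The physiological
fact the whole method leans on is spatial: a MUAP conducts along the muscle
fibres with little attenuation and decays rapidly across them, so each
discharge produces a local spatial peak at the electrode nearest its source.

## Channel-wise cumulative spike-train decomposition

Decomposition parameters are fitted once, on a single calibration trial,
then applied unchanged to every other trial (emulating prospective/online
use).

1. **ZCA whitening.** `W = Σ^(-1/2) = U Λ^(-1/2) Uᵀ` from the
   eigendecomposition of the channel covariance of the calibration signal
   (channel means removed). ZCA is chosen over PCA-style whitening because
   it keeps whitened channels aligned with the physical electrodes — the
   spatial detection step below depends on that correspondence.
   Eigenvalues below `1e-12 * λ_max` are floored with a warning; a
   rank-deficient covariance (e.g. silent or zeroed channels) otherwise has
   no inverse square root.
2. **Energy envelope.** `e_i(t) = Σ_{r=1..R} z_i(t-r+1)²`, the sliding sum
   of squares over the R most recent whitened samples — equivalently the
   squared norm of the R-fold delay-extended signal. Default `R = 10`
   samples (~5 ms at 2,048 Hz): the integration window is tied to the MUAP
   time scale, matching the temporal detection window. The first `R-1`
   samples use zero-padded delays; they underestimate the energy but are
   never detection candidates of interest in multi-second trials.
3. **Threshold calibration.** Per channel, candidate peaks are the temporal
   local maxima of `e_i(t)` above the channel's median energy (the median
   floor keeps the two clusters balanced). Exact 1-D 2-means (enumerating
   all split points of the sorted peak values — for scalars the optimal
   partition is contiguous, so this is the global optimum) splits peaks
   into inactivated/activated groups, and the threshold is the centroid
   mean `λ_i = (e_low + e_high)/2`. The silhouette coefficient of that
   split, computed exactly in O(n log n) with prefix sums, is recorded as
   channel quality. We read the published silhouette value 0.7 as a
   quality-acceptance cut-off, not an optimisation target: channels whose
   silhouette falls below it (or with fewer than 10 peaks, or a degenerate
   split) fall back to a near-maximal percentile (default 99.9) of their
   peak values and are flagged low-quality. The fallback is deliberately
   conservative: a channel with no separable activated cluster carries no
   detectable motor-unit activity, and a mid-range percentile would make it
   fire on a fixed fraction of its noise peaks by construction (several
   spurious spikes per second per silent channel at 2,048 Hz). Channels
   with essentially zero energy get a threshold at the global energy
   ceiling and never fire.
4. **Spatial spike detection.** Sample `t` is a discharge of channel `i`
   iff (a) `e_i(t) > λ_i` and (b) `e_i(t)` is the strict maximum over the
   3×3 electrode neighbourhood and a centred 5-ms temporal window. The
   neighbourhood is truncated at grid edges; an optional `circular` montage
   flag wraps it across columns (the arrays encircle the forearm), off by
   default. The statistic maximised in (b) is the energy — the same
   quantity condition (a) thresholds; a config switch
   (`candidate_stat="amplitude"`) substitutes the absolute whitened
   amplitude instead. Exact ties are resolved deterministically: lowest
   channel index, then earliest time. Excluded channels neither fire nor
   suppress neighbours.

The result `Ŝ(t)` is a binary channel × time matrix of cumulative
discharges. No attempt is made to attribute discharges to individual motor
units — the cumulative, channel-wise pooling *is* the representation.

### Scoring recovery against ground truth

Detection marks the energy maximum, which trails the planted discharge time
by a constant, template-dependent offset. Recovery metrics therefore remove
a single global lag (rounded median of nearest-detection deltas) before
greedy one-to-one matching at ±2 samples, the standard alignment convention
when comparing decomposed firings to a reference. Per motor unit, truth is
its centre-channel discharge train and detections are pooled over the
centre's 3×3 neighbourhood; recall and precision aggregate over units.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass, 20–450 Hz,
followed by a zero-phase cascade of second-order IIR notches (Q = 30) at
50 Hz and all harmonics up to the band edge. Zero-phase filtering is
essential here: group delay would shift energy peaks and corrupt spike
timing. Edges use reflect padding. Channel screening flags channels whose
whole-trial RMS lies outside median ± 5·MAD across channels, or is exactly
zero; flagging more than half the channels raises a data-quality error.
Screened channels are excluded from decomposition and filled with the mean
of their available grid neighbours during imaging so image shape is fixed.

## Feature imaging

Both feature streams use a 200-ms window advanced by 50 ms
(`floor((T - window)/step) + 1` frames). Per channel and frame:

* **Discharge rate** — spike count / window length, clamped at
  `rate_cap = 100` firings/s. The cap suppresses paradoxical bursts;
  100 /s is far above single-unit rates but reachable by a cumulative
  train, and the exact value is configurable because the published cap is
  not stated. Rates are fed to the classifier clamped but otherwise raw.
* **RMS** — windowed RMS divided per channel by its maximum over the
  *training* trials (so normalisation is refitted for every train/test
  split; the training maximum maps to 1.0).

Frames are labelled by the gesture covering the window centre; frames not
fully contained in a single labelled interval (transition straddlers,
uncovered gaps) are dropped — a convention that keeps supervision clean.
Each frame's 192 values are placed at their electrode positions to form an
8×24 single-channel image.

## Classifiers

**Cascade CNN.** A rest-detection network (trained on normalised RMS
images, rest vs non-rest) gates a 9-class gesture network (trained on
discharge-rate images; on RMS images for the RMS-CNN comparator). Both
share the trunk: two modules of [3×3 conv, stride 1, same padding, 32 then
16 filters → batch normalisation → ReLU → 2×2 average pooling, stride 1,
zero-padded]. Stride-1 pooling does not downsample; it is implemented
exactly as specified rather than "corrected" to stride 2, so the trunk
preserves the 8×24 resolution throughout. Heads: flatten → 128 → 9
(gesture) and flatten → 64 → 2 (rest), each ending in log-softmax. The
hidden widths are the package's choice, sized to the 8×24 input; the
original widths are not published. Training: Adam at initial rate 0.01
(its per-parameter adaptation is the only scheduling), minibatches of
1,000, NLL loss, up to 100 epochs, with a stratified 10% validation split
of the training frames; the earliest parameter state with the best
validation accuracy is kept. Because ties keep the earliest best state,
training can stop as soon as validation accuracy reaches 1.0 without
changing the selected model — this exact-equivalence early exit is on by
default and makes the easy synthetic runs fast. The networks are
implemented directly in NumPy (im2col convolutions, explicit backward
passes, gradient-checked against finite differences); at 8×24 resolution
this is fully adequate on one CPU core.

**LDA comparators.** Multiclass linear discriminant analysis on the flat
192-dimensional feature vector (all ten classes directly, no cascade):
class-conditional Gaussians with a shared pooled covariance under
Ledoit–Wolf shrinkage (192-dimensional features from limited frames are
otherwise near-singular), discriminant
`δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c`.

## Evaluation

Accuracy is correct frames / total frames; confusion matrices are truth ×
prediction over the canonical M1..M10 order. The k-trial sweep trains on
the first k non-calibration trials and tests on the rest, k = 1..6.

The separability index (SI) and repeatability index (RI) are Mahalanobis
centroid distances relative to the pooled within-class covariance S of the
training features (classic `/(n − k)` pooled estimator; Ledoit–Wolf
shrinkage only when S is ill-conditioned, preserving SI's exact affine
invariance on healthy data):

* `SI_c = ½ · min_{c'≠c} sqrt((μ_c − μ_c')ᵀ S⁻¹ (μ_c − μ_c'))`, averaged
  over classes — half the nearest-centroid distance.
* `RI_c = ½ · sqrt((μ_c,train − μ_c,test)ᵀ S⁻¹ (μ_c,train − μ_c,test))`,
  averaged over classes.

The ½ factor and the nearest-class (rather than all-pairs) convention
follow the standard myoelectric-control formulation; both are configurable
readings since the primary description cites them without formulas. SI and
RI are computed on the raw feature vectors (clamped rates; normalised RMS),
not on network activations.

## Synthetic HD-sEMG generator

The generator exists to make every stage testable with known ground truth;
it implements the convolutive mixture directly.

* **MUAP template**: first derivative of a Gaussian (biphasic), 10 ms long,
  peak amplitude drawn from U(0.8, 1.2). Spatial gains
  `decay_along^|Δrow| · decay_across^|Δcol|` with defaults 0.85 along
  fibres (grid rows) and 0.5 across — the qualitative anisotropy the
  spatial detector exploits. Footprints are truncated at 5% of peak gain
  and clipped at the grid boundary (with a warning).
* **Spike trains**: truncated-Gaussian renewal process — ISI mean
  `1/rate`, SD `cv/rate`, floored at twice the template length as an
  absolute refractory period. Rates 8–15 Hz, CV 0.15. Simple, controllable,
  guarantees refractoriness.
* **Gesture pools**: the 24 grid columns are split into nine contiguous
  bands; each active gesture recruits 10 motor units at distinct cells of
  its band. Disjoint spatial pools are what make gestures separable in the
  rate images, mirroring the distinct per-gesture activation maps seen in
  recordings.
* **Protocol**: 10 gestures (M10 = rest, recruiting nothing), 10-s motions,
  5-s inter-motion rests, randomised M1–M9 order with rest last, 150-s
  trials, 8 trials per session, 2,048 Hz, one randomly chosen calibration
  trial. Additive white Gaussian noise, SD 0.1 against unit MUAP
  amplitudes (a moderate, ~5 dB active-segment SNR).
* **Inter-trial variability**: each trial draws a global lognormal gain
  (SD 0.1) and per-unit rate scales (±15%). Real sessions drift between
  repetitions — electrode–skin coupling and activation level change — and
  this drift is why accuracy grows with the number of training trials; a
  generator without it would make the k-sweep flat and unrealistic.

What the generator deliberately does **not** model: motoneuron-pool
recruitment/rate-coding structure, force feedback, fatigue, MUAP shape
change, electrode shift, or correlated physiological noise. Passing the
synthetic benchmark therefore shows the pipeline is implemented correctly
and behaves as designed under the stated assumptions — not that the
recorded-data accuracies would be reproduced. Synthetic sessions with
cleanly disjoint activation pools are considerably easier than real
recordings; near-ceiling synthetic accuracies should be read accordingly.

## Numerical choices and degenerate inputs

* Whitening: symmetric eigendecomposition (`eigh`), relative eigenvalue
  floor `1e-12`, channel means removed before covariance.
* Energy: accumulated in float64 (chunked cumulative sums), stored float32.
* Detection: vectorised 3-axis maximum filter proposes candidates; each
  candidate is then verified exactly, including the deterministic
  (channel, time) tie-break. Bit-identical to exhaustive enumeration.
* 2-means/silhouette: exact, deterministic, no iterative clustering.
* Degenerate cases: empty spike trains are valid; trials shorter than one
  window produce empty frame sets; zero RMS normalisers are replaced by 1
  with a warning; a single-class training set raises.
* Problem sizes: the test suite runs the full default-protocol session
  (8 × 150 s × 192 channels) once with the epoch budget reduced to 30, and
  uses shorter sessions (3-s motions, 1.5-s rests) for the multi-seed
  trend check; both are stated choices balancing coverage against desk-
  scale runtime, with every protocol constant unchanged. The trend check
  additionally raises the noise level (SD 0.25 instead of 0.1) because the
  growth of accuracy with training trials is only measurable below the
  accuracy ceiling, and the short low-noise sessions are already solved
  from a single training trial. It also scores every k on the same
  held-out final trial so the trend is not confounded by the shrinking
  test remainder.

## Known limitations

* The decomposition is channel-wise and cumulative by design; it neither
  identifies individual motor units nor estimates MUAP templates.
* The silhouette-0.7 reading (acceptance cut-off vs clustering objective)
  and the within-array electrode numbering are documented conventions, not
  claims about the original hardware or code.
* SI/RI normalisation (the ½ factor, nearest-class minimum) follows the
  field's common formulation and is configurable.
* Stride-1 average pooling keeps full resolution, so the flatten layer is
  comparatively wide (3,072 units); this matches the printed architecture
  at the cost of some parameters.
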