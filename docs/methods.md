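# Methods

## The modelling problem

A routine obstetric ultrasound scan produces a long video stream while the
sonographer narrates what is on screen.  The narration is sparse, noisy and
often off-topic, but when an anatomy is named it is named while that
anatomy is visible.  echofuse learns visual and audio representations from
this weak co-occurrence alone — no manual labels — by **correspondence
modelling** (is this audio/text window the one recorded with this clip?)
and **cross-modal contrastive learning** (matched pairs should be closer
in embedding space than mismatched ones), with transcribed text as a third
modality refined by a **selective information gating** (SIG) module.

## Objectives

For a batch of N (video, audio, text) triples with correspondence labels
c ∈ {0, 1}:

* **Correspondence loss** — mean binary cross-entropy
  `L_base = −1/N Σ [c·log p + (1−c)·log(1−p)]` on the fused probability p.
  Probabilities are clamped to [1e−7, 1−1e−7].
* **Contrastive loss** — per matched anchor i,
  `L_contra = −log( sim(V_i, A_i) / Σ_j sim(V_j, A_i) )` with
  `sim(x, y) = exp(cos(x, y)/τ)`, τ = 0.1, and in-batch negatives.  The
  default (`mode="infonce"`) keeps the j = i term in the denominator so the
  loss is bounded below by 0 and equals ln N under uniform similarity; a
  `"literal"` mode that drops it (and can therefore go negative) is kept
  for comparison.  Anchors are only the c = 1 pairs; batches are arranged
  so no two matched items come from the same scan within 5 s of each other,
  which avoids false negatives.
* **Spatial objective** — `L_base + L_contra` evaluated on spatial video
  features V^s (the backbone feature map before pooling) through the
  element-wise dot-product fusion described below.
* **Joint loss** —
  `α·L_base(V,A) + β·L_base(V,T) + γ·L_contra(V,A) + δ·L_contra(V,T)` with
  α+β+γ+δ = 1, all equal by default.  Pairs whose gated text feature is
  empty are excluded from the two text terms, with denominators
  renormalised over the remaining pairs; if none remain the text terms
  contribute 0.

## Fusion

* **Concatenation** (baseline): `[v; a] → FC → ReLU → FC → sigmoid`.
* **Spatial-aware**: the response map `r[h,w] = ⟨V^s[:,h,w], a⟩` measures
  where in the frame the audio "matches".  The correspondence probability
  is a sigmoid of a linear readout of the response-weighted, globally
  averaged feature map together with the pooled response, both divided by
  `‖mean-map‖·‖a‖` so the head sees O(1), cosine-scale inputs regardless
  of feature magnitudes.  The raw response map is exposed for
  localisation.

In the joint loss the spatial video feature enters the contrastive terms
through its spatially pooled map, scored by cosine similarity (bounded
exponentials).  An experimental `spatial_pool="softmax"` scores pairs by a
smooth maximum of per-cell cosines instead; in our experiments it
destabilised training and `"mean"` is the default.

## Selective information gating

Per-token gates are produced by a 1×1 convolution along the token axis
followed by a fully-connected layer and a softplus (non-negative,
interpretable as attention mass).  Gates at ⟨unk⟩ positions are forced to
exactly 0, so the pooled feature is an exact constant function of whatever
embedding content sits there.  Keyword spotting multiplies the gates of
tokens absent from the anatomy dictionary by a depression factor
λ ∈ [0, 1] (default 0 — hard selection; λ = 1 recovers plain outlier
filtering).  The pooled output is the gate-weighted mean of the projected
token embeddings; if every gate is 0 the feature is flagged *empty* and
excluded from text losses.  Gating happens after the E→D projection;
matching is exact token equality after case-folding.

## Encoders

All branches emit the same embedding dimension D (class default 128; the
desk presets use 32).  The default **tiny backbone** is
`conv(s2,16) → conv(s2,32) → conv(s1,64) → dilated conv(s1,64,d2) → 1×1
conv(D)`, each convolution followed by instance normalisation and ReLU
(the 1×1 output layer keeps a plain ReLU).  Instance normalisation has no
running statistics, so training and inference are the same function and
single-threaded runs are bit-reproducible.  The spatial feature map has
stride 4 (a 64 px frame gives a 16×16 map); the dilated block widens the
receptive field without further downsampling so that cells centred on a
structure integrate evidence from its whole extent.  A paper-scale preset
builds a ResNeXt-style grouped-convolution topology with
squeeze-and-excitation blocks and a dilated final stage; it is available
untrained for architecture experiments and is not the test default.

Video clips are represented by 2 frames sampled uniformly without
replacement and stacked as channels.  The audio branch shares the
architecture family (never the weights — initialisation streams are
disjoint and the test suite asserts it) and average-pools its 256×256
spectrogram input 4× before the stack.  The text branch looks tokens up
in a fixed random embedding table (width E = 64, seeded from a hash of the
vocabulary, one reserved ⟨unk⟩ row) and projects through two trainable
fully-connected layers.  The table stands in for pretrained word vectors
behind the same interface.

## Audio front end and cleaning chain

The front end converts a 0.6 s window, resampled to 24 kHz, into a
256×256 log-magnitude spectrogram: STFT with 10 ms Hann window, 5 ms hop,
nfft = 512 giving 257 linear bins of which the Nyquist bin is dropped;
magnitudes are compressed by log(1+x) (bounded at silence).  A 0.6 s
window yields ~119 STFT frames; the time axis is linearly interpolated to
256 columns.  Frequency band k therefore covers k·(rate/512) Hz — a 6 kHz
tone peaks in band 128.

The cleaning chain mirrors a clinical audio pipeline with simple,
well-defined stand-ins behind plug-in interfaces: an identity denoiser, an
energy-quantile voice activity detector (frames whose RMS exceeds the
batch quantile; invariant to global gain), the dominant-speaker rule (most
segments, ties by total duration then lexicographic id), ground-truth
transcripts with injected corruption in place of ASR, and keyword-segment
selection by exact dictionary match.

## Synthetic scan generator

The generator emulates the *structure* of clinical scan recordings, not
their physics: a timeline of anatomy events (2–4 s long, 0.8–2 s gaps),
each rendering one of 13 class-specific phantom shapes (ellipses, ring,
cross, bars, blobs, …) at a random centroid over |N(0, σ)| speckle with
σ = 0.05; per-frame plane labels (the 13 plane classes + background) and
Gaussian gaze maps at the shape centroid (σ = image/12).  With probability
1 − p_offtopic the concurrent utterance names the anatomy (filler template
plus keyword) and the waveform carries the class's acoustic signature — a
two-tone mixture (f₁ = 500+400k Hz, f₂ = 6000+450k Hz, both below the
12 kHz Nyquist) amplitude-modulated at 4 Hz to mimic a speech envelope.
Off-topic utterances draw small-talk tokens and a neutral 250/330 Hz
signature.  Each token is corrupted to an out-of-vocabulary string with
probability p_invalid_token.

Defaults are the study conditions: p_offtopic = 0.3 (the real proportion
is uncharacterised; this is a deliberately hostile level), p_invalid_token
= 0.1 (a plausible ASR word-error rate), 4 fps, 64 px frames, 24 kHz
audio.  What the generator does **not** emulate: real speckle physics,
human speech (the signatures are separable tones — real speech classes
overlap far more), probe motion, multiple simultaneous anatomies, or
gaze/anatomy dissociation.  Passing tests therefore demonstrate that the
pipeline recovers structure the generator planted, not clinical
performance.

## Training

SGD with classical momentum 0.9.  The printed schedule — learning rate
1e−3 divided by 10 every 20 epochs, batch size 40 — is the class default
(`TrainState`), matching the original large-scale regime of ~1,800 steps
per epoch.  At desk scale an epoch is a few dozen steps, so the presets
use a proportionally larger rate (0.05) and, for the smallest runs,
batch 20; with the default rate the desk-scale runs simply do not move in
the step budget available.  Examples are regenerated each epoch from an
epoch-indexed random stream; a held-out example set is drawn once and
never trained on.  Training aborts if the loss becomes non-finite.
Optional random flip augmentation exists but is off by default (it did
not help on the phantom shapes).

Positives are anchored at anatomy-keyword utterances — the output of the
cleaning chain — with the audio/text window [t−0.3 s, t+0.3 s).  Negatives
substitute the window of another scan or of the same scan shifted ≥ 5 s.
Anchoring at keyword segments is what makes the task well-posed: windows
anchored at arbitrary silent times would make matched and substituted
silence indistinguishable.

### Desk-scale problem sizes

* **Standard configuration** (parameter recovery): 6 scans × 60 s,
  embed 32, 25 epochs × 400 examples, batch 40, lr 0.05 — ~250 SGD steps,
  a few minutes on one CPU.
* **Ablation configuration** (5-seed variant comparison): 6 scans × 45 s
  (last two held out for transfer), 12 epochs × 240 examples, batch 20,
  lr 0.05 — 144 steps per run.  Below ~120 steps the full variant does
  not lift off chance, so this is close to the minimum meaningful size.

## Downstream transfer

Contrastive pretraining leaves pooled feature norms ~30× smaller than
random initialisation; a naive head on raw features then barely learns
while a from-scratch control does fine.  Both fine-tuning estimators
therefore normalise the encoder output before their heads: the 14-way
plane classifier L2-normalises the pooled vector (×√D), and the saliency
regressor instance-normalises the feature map before its decoder (two
transposed-convolution blocks factoring the encoder stride, pixel-softmax
output trained with a KL objective).  Cross-validation folds are assigned
by scan, never by frame.

Representation comparisons between pretraining variants use the standard
**linear evaluation protocol** (frozen encoder, standardised pooled
features, logistic-regression head): on the ablation configuration the
full multi-modal variant's features reach median macro-F1 1.0 over five
seeds versus ~0.95 for the video-audio baseline and ~0.6 for a random
encoder.  End-to-end fine-tuning on the same labelled set drives every
initialisation to training accuracy 1.0 within a few epochs (~150 labelled
frames of trivially separable phantom shapes), after which held-out F1
differences between initialisations are dominated by fine-tuning noise and
carry no reliable ordering — a known behaviour of full fine-tuning when
the labelled task is easy relative to the model.  Both estimators
(`PlaneClassifier`, `SaliencyPredictor`) fine-tune all weights as their
task interface; the probe is the measurement instrument for comparing
pretraining variants.

Audio-guided localisation needs no fine-tuning and consumes no text: the
response map is computed for the clip and the 0.6 s audio window,
averaged over the four axis flips of the clip (cancelling directional
biases in the learned detectors), bilinearly upsampled with centre-aligned
sampling (output pixel k reads map coordinate (k+0.5)/scale − 0.5, so each
coarse cell stays centred on the image region it was computed from) and
min–max normalised with an ε-guard that returns a zero map when the
response is constant.

### Known limitation: localisation is approximate

Correspondence accuracy on the standard configuration saturates around
0.94–0.97, and the response maps track the rendered anatomy closely.  The
argmax of the map, however, lands *inside* the ground-truth region mask
for only ~35–60 % of held-out matched clips (varying with the data seed)
rather than the ~80 % the recovery experiment targets.  The failure is systematic, not noisy: for a
few shape classes the most audio-aligned visual feature is an edge-type
detector whose peak sits one or two cells beside the structure, and
nothing in a position-agnostic correspondence/contrastive objective
penalises that offset (a horizontally symmetric twin of a failing class
can localise perfectly).  Finer spatial maps, dilated context, flip
averaging, response smoothing, longer schedules, wider embeddings and
signed feature maps were all evaluated; they moved the rate from ~0.3 to
~0.6 and no further.  The maps remain qualitatively useful (the response
mass sits on or immediately around the anatomy), but peak-in-mask
localisation at desk scale should be treated as approximate.

## Evaluation suite

Classification uses standard per-class precision/recall/F1 with macro
averages over classes with support > 0.  Saliency uses KL
(ε = 1e−8 added to both numerator and denominator so identity scores
exactly 0), Pearson CC (0 for constant maps), SIM = Σ min, NSS (z-scored
prediction at fixations; 0 when the prediction is constant) and ROC AUC of
prediction values at fixation vs non-fixation pixels (0.5 for constant
maps).  The compactness score is

    Comp = IoU · η_H / α_S,   η_H = α_H / α_S,

with α_S the support-area of the min–max-normalised prediction, α_H the
area above the threshold (default 0.5), and IoU the support overlap with
the reference.  Supports are pixels > 0 by default (`iou_at_thres`
binarises at the threshold instead); areas are fractions of total pixels,
which makes Comp invariant to resolution, with `raw_counts=True` for
literal pixel counts.  An all-zero prediction yields a flagged-invalid
result rather than a number.

## Numerical and degenerate-input choices

* Probability clamps at 1e−7; cosine denominators guarded by 1e−12;
  KL ε = 1e−8; min–max ε-guard 1e−12.
* VAD threshold comparison is strict (>), so silence yields no segments.
* Gaze-map centroids round to the nearest pixel so the map's argmax is a
  well-defined pixel.
* Dominant-speaker ties break by duration, then lexicographic id.
* All randomness flows from one master seed through named
  `SeedSequence` substreams (init / data / per-epoch sampler), so any
  component can be reproduced independently; checkpoints store every
  weight array plus a hash of the resolved configuration.
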