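# Methods

`msmilestone` implements a multimodal deep network that predicts whether a
multiple-sclerosis patient will exceed an EDSS milestone (4.0, 6.0 or 7.0)
a fixed horizon (default three years) after an index clinic visit, from
three modality groups — longitudinal structured EHR tables, per-sequence
brain MRI volumes, and free-text clinical notes — plus a demographics
vector. Because cohorts of this kind are private, the package ships a
synthetic-cohort generator with controllable, known class signal in every
modality; all quantitative claims the test-suite and the acceptance script
make are about recovery of that planted signal.

## Labels

EDSS is recorded per visit. For a patient whose follow-up spans at least
the horizon, the index visit is the *latest* visit that still has a
qualifying visit at least one horizon later, and the target is the last
such later visit; shorter histories fall back to first visit → last visit.
The label is strict: `EDSS(target) > θ`. The "latest qualifying index"
choice maximizes usable history; the prediction origin is configurable
(`index_policy`), since either convention is defensible. Milestones are
treated as strict inequalities throughout.

## Structured EHR

Observations arrive as long-format events `(patient, encounter, time,
feature, value)`. They are averaged within 4-hour windows anchored at clock
midnight (00:00, 04:00, …) and intersected with encounter spans, so a
window never mixes encounters; midnight anchoring is the only convention
under which a 13:15–18:00 encounter plus a 09:12–13:00 encounter yield
four rows, the behaviour the binning test pins down. Bins with no
observation of any schema feature are dropped; unobserved features within a
kept bin are zero. Features observed in fewer than 10% of training-split
patients are discarded cohort-wide. Continuous values are min–max scaled to
[0, 1] with ranges learned on the training split only; out-of-range values
are clipped *before* bin averaging, and binary medication indicators pass
through. History is truncated at the end of the encounter containing the
index visit — the index visit's own observations are part of the history.

Each table kind has an attention channel: every bin's feature vector runs
through a stack of 1-D convolutions over the feature axis (lab: 1→8 k7 s2,
8→8 k4 s2, 8→1 k3 s2; vitals and medications: 1→8 k3 s2, 8→1 k2 s2; ReLU
after every convolution past the first; dropout 0.3), is average-pooled to
a scalar, and the per-bin scalars are softmax-normalized over time. The
table embedding is `e_k = α_kᵀ D_k` (length `f_k`). Softmax normalization
is a deliberate choice: raw weights would make the embedding scale with
visit count and break cross-patient comparability; a config flag restores
raw weights. Convolutions use same-padding so short feature vectors
survive the stride pyramid. An empty table yields the zero embedding, the
same convention used for missing modalities.

## MRI channels

Each sequence (T1-pre, T1-post, T2, FLAIR, PD) has an independent residual
3-D CNN: stem conv (stride 2), residual blocks, a stride-2 down-stage, more
blocks, global average pooling and a linear head, so the embedding length
is independent of the input extents. Channels are metric-trained with a
fixed-anchor triplet margin loss, `Σ max(d(a,p) − d(a,n) + margin, 0)`,
Euclidean distance, margin 1.5, sum reduction; the anchor is the origin of
the embedding space (configurable — only "a fixed point" is prescribed).
Milestone-positive patients are pulled toward the anchor, negatives pushed
beyond the margin. Augmentation during training: intensity min–max
normalization, horizontal/vertical flips each with probability 0.5,
rotation with probability 0.5 by per-axis angles uniform in ±0.02° (the
stated tiny angle is implemented literally; larger angles are a config
knob), and a random zoom-out followed by a resize. When a patient has
several scan sessions, the chronologically last is used. Paper-scale
training defaults are learning rate 1e-5, batch 10, 500 epochs, patience
50.

Saliency is gradient-weighted class activation mapping on the last
convolutional stage. The attribution target is the distance to the anchor
— the quantity the metric objective separates classes by. Because the
head is metric rather than classification, the gradient's sign per channel
is an arbitrary consequence of initialization; channel weights are
therefore spatially averaged gradient *magnitudes*, and the weighted
activation sum is rectified and trilinearly upsampled to the input grid.

## Clinical-note channel

A note is lowercased, split on non-word characters, and turned into a
weighted directed word co-occurrence graph: within every stride-1 window of
10 tokens, each ordered pair of distinct words increments the earlier→later
edge; overlapping windows intentionally up-weight near pairs. A document
node is connected to every word node with unit weights in both directions.
Node states (width 64, trainable embeddings; a pre-trained word2vec text
table can be loaded) are refined for T = 2 passes of
`H' = GRU(H, MLP(D⁻¹AH))`, with out-degree row normalization and per-pass
parameters. The document vector is a softmax self-attention readout over
the word nodes only. The channel is metric-trained with the same
fixed-anchor triplet loss (batch 128, learning rate 1e-3, 500 epochs,
patience 50 at paper scale). By default all notes up to the index visit are
concatenated (`notes.mode = last` uses only the most recent).

## Fusion and decoder

Modality embeddings are stacked into `E` (K×d, d = max embedding length,
zero right-padding, all-zero rows for missing modalities) in a causal
order: vitals, labs, T1-pre, T1-post, T2, FLAIR, PD, note, medications —
observations first, the note standing in the diagnosis slot, medications
last. The decoder runs a stacked bidirectional GRU over the K rows
(paper-scale: 4 layers, hidden 512 ⇒ h = 1024), derives per-state
attention vectors γ_k of length g (default 8) with a 1-D convolution over
the state axis, forms `O = BᵀC`, and maps `Flatten(O)` concatenated with
the demographics vector through a fully connected sigmoid head to the
milestone probability. Demographics enter only at the head, not as a
fusion row. The decoder stage trains with binary cross-entropy.

## Training protocol

Training is staged per cross-validation fold: metric-train the image and
note channels, then train the EHR channels and decoder jointly with the
encoders frozen (a flag allows joint fine-tuning). Minority-class examples
are duplicated 10× in training pools (`resample.target` can force the
negative or positive class instead); evaluation folds are never resampled.
Stratified 5-fold CV refits every preprocessing statistic on each training
split. Metrics: AUROC, AUPRC, sensitivity/specificity/accuracy at
threshold 0.5, reported as mean ± sd over folds. Early stopping restores
the best-validation checkpoint after `patience` non-improving epochs, on a
10% stratified validation split within each training fold.

Two model-selection details matter and are easy to get wrong:

* Minority resampling shifts the effective training prior toward 0.5, so
  validation *cross-entropy* degrades through mis-calibration even while
  discrimination improves. Decoder model selection therefore uses
  validation AUROC with a small (0.01×) class-balanced cross-entropy
  tiebreak — ranking-first, calibration as tie-break.
* On weak-signal cohorts the validation objective dips for tens of epochs
  before the planted feature is found; the weak-signal reference protocol
  therefore runs its decoder schedule to completion (patience = epochs)
  and relies on best-checkpoint selection alone.

Epoch accounting: an epoch draws one original-training-set's worth of
batches from the resampled pool, so the resampling factor re-weights
classes without inflating wall time.

## Explainability

Per-timestamp attention α carries no per-feature resolution, so per-feature
importance is gradient-weighted attention: importance of feature j in table
k is the mean over evaluation patients and bins of
`α_k[m]·|∂o/∂D_k[m,j]|`, normalized to sum to one per table (uniform
fallback when all gradients vanish). Image explainability is the Grad-CAM
map above.

## Synthetic cohorts

The generator plants signal with known ground truth: visit counts are
`1 + Poisson(mean − 1)` (guaranteeing ≥ 1 visit, matching a ~3.4 ± 1.6
visits/patient shape), follow-up spans are exponential (mean 5.14 y),
encounter durations uniform in [1 h, 8 h] with observation times uniform
within the encounter so 4-hour binning is nontrivially exercised. EDSS
trajectories are linear-plus-noise paths whose endpoint is placed strictly
above or below the milestone according to the latent label, so derived
labels reproduce the generating labels exactly. Designated lab features are
mean-shifted (in standardized units) for positives; medications are
Bernoulli with class-dependent rates; volumes are Gaussian background plus
a Poisson number of hyperintense ellipsoidal blobs at recorded locations;
notes are class-conditional unigram draws with up-weighted signal tokens.
Missing-modality masks are sampled independently per patient (default 10%
of patients lack imaging and 10% lack notes). Setting all class-conditional
parameters equal yields a null cohort on which held-out discrimination
concentrates near 0.5.

What the generator does *not* emulate: anatomical templates or realistic
lesion morphology, pharmacokinetics, correlated lab panels, note syntax
(unigram text only), scanner effects. Passing tests therefore demonstrate
that the architecture recovers class signal routed through each modality's
encoding path — not clinical performance on real data.

## Desk-scale reference protocols

End-to-end checks run on one CPU at deliberately reduced problem sizes,
frozen in `msmilestone.protocols`:

* **Strong-signal cohort** — 300 patients, prevalence 0.25, lab shift 2.0
  on 3 features, lesion-count means 6 vs 1 on 32³ volumes, note-token
  multiplier 5 on three tokens, one FLAIR-like MRI channel generated.
* **Matched null cohort** — identical with all class-conditional
  parameters equalized.
* **Single-feature cohort** — 200 patients, EHR only, exactly one lab
  feature shifted 2.0, for importance recovery.
* Backbones: image width 2/embedding 8, note width 16, decoder hidden
  8/1 layer/g = 2; epoch caps of 8 (image), 12 (text) and 36 or 120
  (decoder) with the early-stopping rule above; weight decay 1e-2 on the
  decoder stage.

The full-scale defaults (`TrainConfig()`, `ImageEncoderConfig()`) remain
the paper-scale hyperparameters listed in the sections above.

## Numerical and engineering notes

* All layers run on a purpose-built numpy reverse-mode autodiff engine
  (`autodiff.py`): conv1d/conv3d via strided windows with exact manual
  backward rules, GRU/attention/losses by composition. Every backward rule
  is finite-difference-checked in the tests. Float64 throughout.
* Softmax and sigmoid use max-shift / branch-stable forms; the triplet
  distance adds 1e-12 under the square root to stay differentiable at
  zero; BCE clamps probabilities away from {0, 1} by 1e-7.
* Constant features scale to 0; empty tables embed to zero vectors;
  all-zero-gradient importance falls back to uniform; an all-missing
  patient is rejected rather than silently imputed.
* Checkpoints are flat `.npz` state dicts with a JSON sidecar (row order,
  sequences, feature schema).

## Known limitations

* The attention-based handling of irregular sampling is the only missing-
  data mechanism; no imputation is provided.
* The 2-D slice mode for volumes is not implemented; the 3-D backbone at
  small extents is already CPU-feasible.
* Metric training uses balanced anchor-positive/negative pair draws; other
  triplet-mining schemes are out of scope.
* Real-data performance is out of scope by construction; the private study
  cohort is not reproducible.
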