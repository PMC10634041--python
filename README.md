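# msmilestone

Multimodal deep learning for predicting disability milestones in multiple
sclerosis (MS).

Clinicians grade MS disability with the Expanded Disability Status Scale
(EDSS); the milestones EDSS 4 (limited walking without aid), 6 (unilateral
assistance) and 7 (essentially wheelchair-bound) mark stage transitions.
`msmilestone` implements a neural architecture that predicts, from a
patient's records up to an index clinic visit, whether they will exceed a
milestone θ ∈ {4, 6, 7} three years ahead, using three modality groups:

* **longitudinal structured EHR** — lab tests, vital signs and medication
  events, averaged into 4-hour clock-aligned bins per encounter into
  matrices `D_k` (t_k bins × f_k features), pooled by per-bin attention
  weights computed with stacked 1-D CNNs: `e_k = α_kᵀ D_k`;
* **brain MRI** — one residual 3-D CNN per sequence (T1-pre, T1-post, T2,
  FLAIR, PD), metric-trained with a fixed-anchor triplet margin loss
  `Σ max(d(a,p) − d(a,n) + margin, 0)` (margin 1.5), with Grad-CAM
  saliency maps;
* **clinical notes** — a word co-occurrence graph with a document node,
  message passing `H' = GRU(H, MLP(D⁻¹AH))` (window 10, 2 passes), and a
  self-attention readout `u = Σᵢ βᵢ Ĥᵢ`.

The embeddings are stacked in causal order into a zero-padded matrix `E`
(K×d), decoded by a bidirectional GRU with convolutional attention
(`O = BᵀC`), and mapped — together with the demographics vector — through a
fully connected head to the milestone probability
`o = σ(FC(Concat(Flatten(O), dem)))`. Missing modalities contribute
all-zero rows. Training is staged (metric-learn the image/text channels,
then the decoder with binary cross-entropy), with 10× minority resampling
and stratified 5-fold cross-validation reporting AUROC, AUPRC,
sensitivity, specificity and accuracy.

Since cohorts of this kind are private, the package includes a synthetic
multimodal cohort generator (`msmilestone.synthetic`) that plants known
class signal in every modality — shifted lab features, class-dependent
medication rates, lesion-like hyperintense blobs at recorded locations,
class-discriminative note tokens — so every stage, and the end-to-end
model, is verifiable. See `docs/methods.md` for the model, assumptions and
limitations.

## Worked example

Generate the 300-patient reference cohort with planted signal in every
modality (lab shift 2.0 σ on three features, lesion-count means 6 vs 1,
note tokens up-weighted 5×), run 3-fold CV with the desk-scale training
configuration, and report metrics:

```python
import dataclasses

import msmilestone as mm
from msmilestone.protocols import desk_scale_config, strong_signal_spec

cohort = mm.generate_cohort(strong_signal_spec(seed=7))
cfg = dataclasses.replace(desk_scale_config(seed=1), folds=3)
report = mm.cross_validate(cohort, cfg)
for metric in ("auroc", "auprc", "accuracy"):
    mean, sd = report.mean_sd(metric)
    print(f"{metric}: {mean:.3f} +/- {sd:.3f}")
```

prints (about five minutes on one CPU)

```
auroc: 0.972 +/- 0.004
auprc: 0.866 +/- 0.021
accuracy: 0.863 +/- 0.057
```

— the model recovers the planted multimodal signal far above chance,
while an identically configured null cohort (`null_spec_matched`) scores
≈ 0.5 AUROC. The mean ± sd is over the three folds; numbers shift
slightly with the seed.

The same pipeline is scriptable from the shell:

```bash
msmilestone simulate --config cohort.yaml --out data/ --seed 7
msmilestone train --data data/ --milestone 4.0 --folds 5 --seed 7 --out run/
msmilestone evaluate --run run/ --out report.json
msmilestone explain --data data/ --out explain/   # importance TSVs + saliency NIfTIs
```

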