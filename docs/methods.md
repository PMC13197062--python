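# Methods

`cplp` implements contrastive patient-level pretraining for fusing
longitudinal chest-CT imaging with cross-sectional clinical variables, and
the downstream classifiers and evaluation protocol used to measure its
value for 2-year lung-cancer risk prediction. This note records the model,
the default parameters and why they are set as they are, what the
synthetic cohort generator does and does not emulate, and the numerical
choices a maintainer would want to know.

## The model

**Inputs.** Each patient contributes (a) up to three screening chest CTs,
already reduced to fixed-dimension feature vectors (default D = 256) by a
frozen upstream CT encoder, each with an absolute acquisition day; and (b)
twelve tabular clinical variables (age, sex, race, BMI, smoking quit time,
smoking duration, pack-years, COPD, emphysema, personal cancer history,
family lung-cancer history, smoking status), any of which may be missing,
plus the binary 2-year outcome, follow-up length and a detected-nodule
flag. The frozen CT encoder and the frozen text representation model are
*inputs* to this package — pluggable providers, never trained here.

**Image head.** A time-distance transformer: the patient's latest-3 scan
window is padded to length 3, sinusoidal encodings of the days elapsed
since the earliest retained scan are added to the real tokens, and a
pre-norm transformer encoder runs under a key-padding mask so absent scans
are never attended to. The output token at the chronologically latest
*real* position (not slot 3) is linearly projected to the shared space and
L2-normalized, giving the image embedding I^i. Padded tokens are zeroed at
entry and masked as keys at every layer, which makes the embedding exactly
(bit-for-bit) independent of padded-slot contents.

Time encodings use position = days / `day_scale` with `day_scale` = 30, so
annual screens sit ~12 positions apart; layout is [sin block | cos block]
with the standard geometric frequency ladder (base 10⁴). The encoder
default is 1 layer, 4 heads, feed-forward width 256, model width = D.
Additive time encodings are the encoder's only temporal mechanism;
distance-weighted attention variants are deliberately out of scope.

**Text head.** Clinical variables are serialized to a natural-language
paragraph (below), embedded by the frozen text provider, and passed
through an MLP (one hidden layer of 256) with a linear projection to the
shared space and L2 normalization, giving T^i. The same head class serves
the tabular ablations, with the imputed tabular vector as input.

**Serialization.** One sentence template per variable, emitted in the
fixed schema order; numeric values carry units (years, kg/m², pack years);
integers print as integers, reals to one decimal; a missing variable
produces no sentence. In the pretraining phase the paragraph ends with the
follow-up sentence ("The patient was followed for {n} days without lung
cancer.") and the true outcome sentence ("The patient [developed/did not
develop] lung cancer after 2 years."); in the finetune phase both are
omitted; in zero-shot scoring the outcome sentence for the queried class
replaces the true one. Templates are YAML-serializable so wording can be
changed without code.

**Shipped text provider.** A deterministic hashed bag-of-tokens embedder:
each lowercase word or number token is md5-hashed (salt-free, so stable
across processes) to a bucket and a sign; numeric tokens additionally emit
a decade-binned token (64 → "~60") so nearby magnitudes share mass and
small cohorts can generalize over numbers. It has no learned weights and
makes no claim to sentence-transformer geometry — it exists so alignment,
finetuning and evaluation are testable offline; any embedder with an
`embed(text) -> vector` surface can replace it.

**Contrastive objective.** Within a batch of n patients, image and text
embeddings of the same patient are the positive pair; all n² − n
cross-patient image–text combinations are negatives (pairs are always
cross-modal). The loss is the symmetric cross entropy over the n×n matrix
of cosine similarities scaled by a learnable temperature (initialized at
0.07, parameterized on the log scale so it stays positive): the mean of
the row-wise (image→text) and column-wise (text→image) cross entropies
with the diagonal as target. Optimization is Adam under a cosine-annealed
learning rate with warm restarts (base 10⁻³, first cycle 100 epochs, cycle
multiplier 2). Early stopping monitors the training loss with a patience
of 1000 epochs; epochs shuffle the patients into batches, keeping the
final partial batch (a 1-patient tail batch is skipped — it has no
negatives — but never occurs with the default sizes).

**Checkpoint probing.** Pretraining can snapshot its weights every
`checkpoint_every` epochs. The `clip_finetune` variant then finetunes from
*each* snapshot and keeps the model with the best validation AUC.
Downstream performance is not monotone in pretraining length, so
checkpoint selection is part of the method; selection here uses the
validation split only, never the test set. At desk scale we pretrain for
30 epochs with snapshots every 10: on synthetic cohorts we observe that
much longer contrastive training over-specializes the encoder to patient
identification (a linear probe of the label on the image embedding
degrades steadily after the first few dozen epochs) — the small-cohort
analogue of non-monotone finetune performance over pretraining epochs.
Dropout (0.3) inside the transformer during pretraining passes slows this
degradation and is on by default; supervised passes run without dropout.

**Finetune fusion classifier.** The pre-normalization projections of the
two heads are concatenated and fed through an MLP (hidden width 128) with
a sigmoid output, trained with binary cross entropy. Encoder parameter
groups use one tenth of the classifier learning rate. Training holds out
a label-stratified 10% of the training patients; early stopping monitors
the validation loss with a patience of 40 epochs and restores the
best-validation-loss weights. Paragraphs exclude the outcome and
follow-up sentences in this phase. We concatenate the projected,
pre-normalization embeddings; the unit-norm embeddings are used only where
cosine geometry is the point (the contrastive loss and zero-shot scoring).

**Zero-shot scoring.** For each patient the paragraph is rebuilt twice
with the two candidate outcome sentences, both are embedded and encoded,
and the continuous score is cos(I, T₊) − cos(I, T₋); a positive score
predicts a case and a tie predicts the negative class. The difference (not
just the argmax) is kept so the score supports AUC.

**Baselines/ablations.** `mm_lang` is the identical fusion architecture
trained from random weights; `mm_tabular` and `clip_tabular` replace the
text pathway with an imputed tabular vector (z-scored numerics + one-hot
categoricals), the latter with its own contrastive pretraining stage;
`sybil_tdvit` is the image head + classifier alone; `sybil_cs` is an MLP
on the latest scan's raw features. All variants share splits and seeds so
comparisons are paired. Supervised variants use the same patience-40
early stopping.

**Imputation.** "Multiple linear imputation" is implemented as
deterministic chained linear regression (scikit-learn's iterative imputer
with plain least-squares estimators, ≤20 rounds, tolerance 10⁻³):
categorical variables are one-hot encoded for the regressions and decoded
by argmax, numeric imputations are clamped to the observed per-variable
range. A single completed dataset is produced (seeded); pooling over
multiple imputations was judged unnecessary for the ablation's purpose.

**Evaluation.** AUC (ties counted ½) on the full withheld test set
("screening") and on its detected-nodule subset. Uncertainty comes from
1000 bootstrap resamples of the test patients; resamples that draw a
single class are redrawn so the count stays fixed (this matters at 4%
prevalence). Intervals are 2.5/97.5 percentiles of the bootstrap AUCs
(percentile, not normal-approximation). Methods are compared with a
two-sided Wilcoxon signed-rank test on the per-resample AUC differences;
the resample indices are drawn once per cohort and shared across variants,
which is what makes the signed-rank pairing valid. Identical prediction
vectors return p = 1 by convention.

## The synthetic cohort generator

The generator exists so the whole pipeline — alignment, transfer,
ordering of variants, bootstrap reporting — can be exercised end to end
with a known ground truth. Each patient has a latent risk vector
z ~ N(0, I₄). The outcome is Bernoulli(sigmoid(a·z + b)) with
a = (1.25, 1.05, 0.95, 0.85) and the intercept b calibrated by root
finding so the realized prevalence matches the target of 4%; ‖a‖ ≈ 2.07
puts the Bayes-optimal AUC near 0.90, high enough for models to order
themselves and low enough not to saturate. The true log-odds is stored in
a separate latent record that training code never reads; `bayes_auc` is
the ceiling oracle.

Imaging expresses only the first three latent coordinates (a random
D×4 loading with its last column zeroed) plus isotropic noise
(σ = 0.5) and, for cases, a per-day drift of 2×10⁻⁴ along a fixed
direction so longitudinal change is informative. Clinical variables are
fixed monotone maps of z (pack-years and smoking duration rise with z₁,
COPD/emphysema odds with z₀ + z₁, BMI with z₂); the personal/family
cancer-history flags are driven by the image-invisible z₃, so fusion has
signal that imaging alone cannot reach. Missingness is independent
Bernoulli(5%) per variable, independent of the outcome by construction.
Patients receive 1–3 scans (probabilities 0.1/0.1/0.8, matching an
average of ~2.7 CTs per patient in screening programs) at intervals
uniform on [330, 400] days. The detected-nodule flag fires at 0.886 for
controls and 0.99 for cases, reproducing a nodule-subset fraction of
~0.89 of the test split. Splits are 70/30 train/test, stratified by
label, fixed by the seed; generation is byte-identical for a fixed config
and seed.

What the generator does **not** emulate: real CT texture or any property
of real frozen-encoder features beyond linear latent structure; the
geometry of a real sentence-embedding model; informative missingness;
temporal confounding between scan timing and risk; covariate shift
between cohorts; label noise. Passing tests therefore demonstrate that
the machinery is correct and that the method behaves as designed when its
core assumption (a shared cross-modal latent) holds — they say nothing
about absolute performance on real screening data.

## Numerical choices

* All training arithmetic is single precision (float32); the
  `mixed_precision` flag additionally stores the frozen input features at
  half precision. Gradients come from the package's own minimal
  reverse-mode autodiff over numpy, finite-difference-checked in the test
  suite.
* Attention masking adds −10⁹ to masked key logits; combined with zeroing
  padded tokens at entry this makes embeddings exactly independent of
  padding content.
* Layer norm uses ε = 10⁻⁵; L2 normalization ε = 10⁻¹²; binary cross
  entropy is computed from logits via a stable softplus form.
* Early-stopping ties break toward the earlier epoch (strict improvement
  required); a diverged (NaN) loss aborts with a diagnostic rather than
  continuing.
* Zero-shot ties (score exactly 0) predict the negative class.
* Desk-scale problem sizes used by the shipped experiments: cohorts of
  600–2000 patients, 30-epoch pretraining with snapshots every 10 for
  transfer experiments, 300-epoch runs for alignment-dynamics
  measurements, finetuning ≤50 epochs with patience 40, bootstrap B =
  1000.
* All randomness flows from explicit integer seeds; the CLI derives
  independent named streams (data/init/batching/bootstrap) from one
  master seed by hashing.

## Known limitations

* At small cohort sizes the contrastive task is partially solvable by
  memorizing training patients; dropout and short pretraining with
  checkpoint probing mitigate but do not remove this. With realistic
  training-set sizes (tens of thousands of patients) this regime recedes.
* The validation split at 4% prevalence contains very few cases, so
  validation-based selection (early stopping, checkpoint probing) is
  noisy; results are reported as means over seeds for this reason.
* The hashed bag-of-tokens provider makes paragraph embeddings sensitive
  to token identity, not meaning; zero-shot numbers with it measure the
  pipeline, not language understanding.
* `CLIP_ZEROSHOT` is not a trainable variant; requesting it from
  `train_variant` is an error by design.
* The single-imputation implementation understates imputation
  uncertainty; it is used only to feed the tabular ablations.
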