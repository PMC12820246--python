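# Methods

## The model

`neurofuse` classifies subjects into Alzheimer's disease (AD),
Parkinson's disease (PD) and healthy controls (HC) from three
modalities: a structural volume (MRI), a multichannel recording (EEG)
and a genotype vector (SNPs). Each modality has its own encoder branch,
the branches meet in a cross-modality attention block, and a shared
head produces class probabilities with Monte-Carlo-dropout uncertainty.

**Encoders.** The scaled SNP feature vector S' is embedded by a dense
affine map `Z_S = W_S S' + b_S` (embedding dim `m`, default 64; desk
scale 32), chunked into fixed-width tokens and passed through a
bidirectional LSTM, giving per-token features of width `2 x hidden`.
Volumes are normalised to [0, 1], bias-corrected, cut into patches, and
each patch runs through a stack of 3-D convolution blocks
(conv -> ReLU -> max-pool -> dropout); the spatially pooled channel
vector of each patch is one token. Recordings are band-pass filtered
(0.5-40 Hz, zero-phase Butterworth of order 4), split into 2-s windows,
and each window's log band powers (delta/theta/alpha/beta per channel,
Welch estimate with 2-s Hann segments at 50% overlap, z-scored across
training subjects) form a feature sequence consumed by a 1-D
convolution stack. All branches end in a linear projection to the
shared fusion dimension.

**Fusion.** Per modality, queries/keys/values are bias-free linear maps
of the token set and self-attention is the row-softmax of
`Q K^T / sqrt(d_k)` applied to the values. Cross-modality attention
runs in three directions — SNP->MRI (`C_SM`), SNP->EEG (`C_SE`),
MRI->EEG (`C_ME`) — and the per-modality fused vectors are the additive
combinations

    F_S  = O_S + C_SM + C_SE
    F_M' = O_M + C_SM + C_ME
    F_E' = O_E + C_SE + C_ME

computed on mean-pooled, linearly projected attended outputs (the
cross outputs have their querying modality's token count, so pooling
before the sums is the only reading under which the combination is
well-typed; the same pooled `C_SM` enters both sums). The fused vectors
are concatenated, projected through a dense layer with dropout, refined
by a LayerNorm -> gated-linear-unit -> residual block, and mapped to
three logits. The no-attention ablation replaces the whole block by
plain concatenation of the masked, mean-pooled encoder outputs into the
same head.

Missing modalities contribute zero: every term involving an absent
modality is dropped, without rescaling the remaining sum. We considered
compensating the masked sums by the number of live terms, but plain
zeroing is the only rule under which masking a modality and zeroing its
tokens coincide, which is the invariant the tests pin down.

Two optimisation details matter at small scale. The value projections
start at the identity, the pooled self-term projections at the
identity, and the pooled cross-term projections at zero — a
residual-style initialisation under which the fused vectors begin as
clean per-modality features and cross-attention grows in as it earns
its gradient. Without it the randomly-initialised cross terms act as
input noise and the attention model converges measurably worse than
the concatenation baseline.

## Uncertainty

At test time dropout stays active and `T = 30` stochastic passes (each
seeded from the MC seed plus the pass index, so runs replay exactly)
yield per-pass probability vectors `y_t`. The predictive mean is their
average, the per-class epistemic variance is the population variance
over passes, and the scalar epistemic summary is its mean over classes.
Aleatoric uncertainty — noise the model attributes to the data — has no
single canonical estimator in this setting; we use the mean over passes
of the per-pass predictive variance `sum_c y_tc (1 - y_tc)`, the
standard partner of the MC variance, which makes the additive identity
`U_final = epistemic + aleatoric` exact by construction. With all
dropout rates zero the passes coincide and the epistemic part is
exactly zero (a guard removes the 1-ulp artefact of averaging
bit-identical floats).

## The objective

    L_final = L_CE + U + lambda ||W||_2^2 + alpha |W|_1 + D_KL + L_focal

* `L_CE`: cross-entropy on the MC-averaged calibrated softmax of a
  small number of in-graph stochastic passes (5 by default; the 30-pass
  inference estimate is not itself trainable).
* `U`: the batch-mean total uncertainty of those same passes, computed
  inside the graph so it is differentiable.
* `lambda = 1e-5` (squared-L2, matching the optimiser's weight decay),
  `alpha = 1e-6` (L1).
* `D_KL`: the MC-dropout variational KL surrogate — a dropout-scaled
  squared-weight penalty `kl_coeff (1 - rate)/2 ||W||^2`,
  `kl_coeff = 1e-5`; always nonnegative.
* `L_focal`: `-w_c (1 - p_c)^gamma log p_c` on the true class with
  `gamma = 2` and inverse-class-frequency weights; with `gamma = 0` and
  unit weights it reduces exactly to the cross-entropy.

Every term is logged separately per epoch; zeroing a coefficient
removes exactly that term. Training uses Adam (weight decay 1e-5),
global gradient-norm clipping at 1.0, a staged schedule (learning rate
annealed 1e-3 -> 1e-5, batch 32 -> 16, dropout 0.5 -> 0.2 in the
ten-stage reference schedule; a three-stage compression is the desk
default), and early stopping on validation loss (patience 5, min-delta
1e-4) with best-weight restoration. The printed reference schedule also
varies filter/LSTM/FC capacity across stages; since weights are carried
across stages the realised architecture is fixed by the model config
and those columns are kept as stage metadata only.

Probability calibration is post-hoc temperature scaling: a 1-D bounded
search on log-temperature minimising validation NLL, constrained never
to exceed the NLL at temperature 1.

## Evaluation protocol

Splitting is stratified at the subject level (70/15/15 train/val/test;
all of a subject's scans share one partition) with a stratified k-fold
plan (k = 5) over the non-test pool; every preprocessing statistic
(imputation modes, PCA basis, clip bounds, min-max ranges, PSD
z-scores) is estimated on training subjects only and applied unchanged
elsewhere. Subject predictions are arithmetic means of per-sample
calibrated probabilities, arg-max decided with ties broken in class
order (AD, PD, HC). Metrics are one-vs-rest sensitivity, specificity,
F1, NPV, AUROC and AUPRC per class plus macro averages and the 3x3
confusion matrix. Paired model comparisons use McNemar's test
(continuity-corrected chi-square; exact binomial below 25 discordant
pairs) and a paired t-test on fold-wise metrics.

## The synthetic cohort generator

The generator is the package's test bed: it plants class signal whose
ground truth is known, so recovery, saliency and uncertainty behaviour
can be asserted.

* **Volumes** (default 32^3, configurable): a plateau "tissue" region
  with mild fixed texture inside a smooth boundary. AD subjects lose
  intensity in a fixed ellipsoid (a stand-in for hippocampal atrophy),
  PD subjects in a second ellipsoid ("motor" region); per-subject
  severity is jittered (40% sd) to mimic disease heterogeneity. A
  smooth quadratic multiplicative bias field (mean 1, configurable
  amplitude) emulates scanner inhomogeneity. The plateau (rather than
  a smooth blob) is essential: a Gaussian blob's log-intensity is
  itself quadratic, which would make a planted quadratic bias
  unidentifiable for any low-order polynomial correction.
* **Recordings**: band-limited sinusoid mixtures plus pink noise;
  per-class dB offsets raise delta/theta power for AD and alpha/beta
  for PD (defaults +3 dB), with 2 dB per-subject band jitter.
* **Genotypes**: independent biallelic loci (background minor-allele
  frequencies uniform on [0.05, 0.5]); six AD-associated and six
  PD-associated risk loci drawn at 0.45 vs 0.15 allele frequency.
* **Missingness**: a configurable fraction of subjects (default 0.6,
  i.e. 600 of 1000) carries all three modalities; the rest drop
  modalities uniformly with at least one retained.
* **Cross-modal interaction channel** (off by default): a dedicated
  SNP bit (homozygous-alt vs -ref) and an EEG bit realised as two 2-s
  episodic alpha bursts (+10 dB). The bits agree for AD, disagree for
  PD, and are independent for HC, so each is marginally uninformative
  (present with probability 1/2 in every class) while their parity
  separates AD from PD.

Class counts follow largest-remainder rounding with ties broken in
class order; identical spec + seed reproduces the cohort bit-exactly.

What the generator does **not** emulate: anatomy, scanner physics,
linkage disequilibrium, EEG artefacts, nonstationarity, or any
correlation structure beyond the planted effects. Passing recovery
tests therefore demonstrates that the pipeline's machinery works as
specified on data with known ground truth — not clinical performance.

## The planted-signal recovery study

The study conditions (frozen in `interaction_cohort_spec` and
`recovery_study_config`): 300 subjects, complete tri-modal data, 16^3
volumes, 64-s recordings at 128 Hz with 4 channels, 120 SNPs, moderate
marginal class effects in every modality (each branch informative but
insufficient: band shifts 2.5 dB on the class-typical bands, volume
effects 0.12, risk-allele enrichment 0.40 vs 0.15) plus the interaction
channel. Five configurations are trained per seed — each single
modality, trimodal concatenation, trimodal attention — on identical
splits and features, for ten seeds. Trimodal fits are restart-sensitive
at this scale, so both fusion variants train from three initialisations
and keep the best by validation loss. Problem sizes were chosen so the
full study runs in minutes on one CPU core.

At the frozen conditions the study reproduces the qualitative ablation
shape: trimodal attention ranks above trimodal concatenation and above
every single modality in mean test accuracy, and misclassified test
subjects carry significantly higher total uncertainty than correct ones
(one-sided Mann-Whitney on the pooled test sets). The
`scripts/acceptance.py` run recomputes these numbers from scratch.

## Numerical and degenerate-input conventions

* Min-max scaling maps a constant column to zeros (the 0/0 case);
  held-out data transformed with training parameters is clipped into
  [0, 1].
* Outlier clipping truncates at mean +- 3 sd per column; zero-variance
  columns pass through. (With the outlier included in the statistics, a
  five-point column can never exceed 3 sd — the maximum z-score of an
  n-sample is (n-1)/sqrt(n) — so clipping demonstrations need n >= 11.)
* Missing genotypes impute to the per-locus training mode before
  one-hot encoding; one-hot column order is (AA, AG, GG) = counts
  (0, 1, 2) of the alternate allele.
* PCA keeps the smallest component count reaching 95% cumulative
  explained variance, capped at 200 components.
* The bias-correction stand-in fits a quadratic to the log-intensity of
  eroded tissue voxels (above half the maximum, eroded 3 voxels to shed
  the partial-volume shell) and divides out the exponentiated,
  mean-centred fit, rescaled to preserve the volume mean. It assumes
  roughly homogeneous tissue intensity; it is not an N4 implementation,
  and a hook for an external implementation is the natural extension.
* Patch extraction uses half-open strided windows with the final window
  clamped to the volume end, so the last voxel is always covered.
* Zero-phase filtering has edge transients; steady-state attenuation
  (>= 36 dB at twice the cut-off) is measured away from the edges.
* Attention over an empty key set is undefined and rejected; a single
  token attends to itself with weight 1.
* Subject-prediction ties break in class order (AD, PD, HC).

## Known limitations

* The NN core is a compact numpy autograd implementation; it is exact
  but not fast, which is why desk-scale configurations (16-32^3
  volumes, 4-8 filters) are the defaults and the printed full-scale
  settings (64^3 patches, 64-256 filters) are configuration options.
* The attention-vs-concatenation margin at desk scale is a mean effect
  over seeds, not a per-seed guarantee; single small-cohort fits are
  noisy and early stopping on a 45-subject validation set is itself a
  noise source.
* Temperature scaling calibrates globally, not per class.
* The variational KL surrogate is a heuristic stand-in for an explicit
  posterior; only its sign and additivity are load-bearing.
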