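# neurofuse

Attention-based tri-modal classification of Alzheimer's disease (AD),
Parkinson's disease (PD) and healthy controls (HC) from structural MRI,
EEG and SNP genotypes, with Monte-Carlo-dropout uncertainty estimation.

Neurodegenerative diseases are hard to separate early: structural,
functional and genetic markers are individually weak and unevenly
available across patients. `neurofuse` implements a multimodal
classifier for researchers who want to study *how* such markers
combine: three encoder branches (3-D CNN for volumes, 1-D CNN over
band power-spectral-density sequences for EEG, dense embedding +
Bi-LSTM for genotypes), fused by per-modality self-attention and
cross-modality attention

    A = softmax(Q K^T / sqrt(d_k)),   C_SM = softmax(Q_S K_M^T / sqrt(d_k)) V_M
    F_S = O_S + C_SM + C_SE,  F_M' = O_M + C_SM + C_ME,  F_E' = O_E + C_SE + C_ME

followed by a dense head with a LayerNorm/GLU/residual refinement.
Prediction uncertainty comes from Monte-Carlo dropout: T = 30
stochastic passes give a posterior mean mu = (1/T) sum_t y_t, an
epistemic variance sigma^2 = (1/T) sum_t (y_t - mu)^2, and a total
U_final = sigma^2 + U_aleatoric. Training minimises the composite
objective

    L_final = L_CE + U_final + lambda ||W||_2^2 + alpha |W|_1 + D_KL + L_focal

with Adam (weight decay 1e-5), gradient clipping at norm 1.0, a staged
learning-rate/dropout schedule, subject-level 70/15/15 splits with
five-fold cross-validation support, and post-hoc temperature scaling.

Because real multimodal cohorts cannot ship with a package, a
first-class synthetic cohort generator plants class-dependent signal in
every modality — regional volume loss, band-power shifts, risk-allele
enrichment, partial-modality patterns, scanner-style intensity bias,
and (optionally) a cross-modal SNP x EEG interaction that no single
modality carries — so every pipeline stage is testable against known
ground truth. The neural-network layer (autograd, 3-D/1-D convolution,
Bi-LSTM, attention, Adam) is a compact numpy implementation.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from neurofuse.synthetic import CohortSpec, generate_cohort
from neurofuse.train_eval import run_experiment

spec = CohortSpec(n_subjects=150, volume_shape=(16, 16, 16),
                  frac_complete=0.8, seed=7)
cohort = generate_cohort(spec)                  # 150 subjects, 80% tri-modal
res = run_experiment(cohort, spec.sample_rate, seed=7)

rep = res["metrics"]
print(f"test accuracy: {rep.accuracy:.3f}   temperature: {res['temperature']:.2f}")
print(rep.confusion)
print(rep.per_class.round(3))
```

prints (desk-scale model, one split, 23 held-out subjects):

```
test accuracy: 0.714   temperature: 1.36
[[4 1 2]
 [0 7 0]
 [2 1 4]]
    sensitivity  specificity     f1  npv  auroc  auprc
AD        0.571        0.857  0.615  0.8  0.816  0.639
PD        1.000        0.857  0.875  1.0  1.000  1.000
HC        0.571        0.857  0.615  0.8  0.786  0.724
```

The confusion matrix rows are the true classes (AD, PD, HC); here all
seven PD test subjects are recovered while AD and HC — whose planted
effects overlap more after the per-subject severity jitter — trade a
few subjects. `res["subjects"]` carries per-subject probabilities and
epistemic/aleatoric/total uncertainties; on this run misclassified
subjects average U_final 0.576 vs 0.514 for correct ones.

The command-line interface wraps the same calls:

```bash
neurofuse simulate --n-subjects 20 --out-dir cohort/   # NIfTI+EDF+VCF+manifest
neurofuse fit --n-subjects 150 --seed 7 --out-dir run/ # train + evaluate
neurofuse ablate --n-subjects 150 --seed 7             # modality ablation
neurofuse explain --model run/model.npz --out-dir maps/
neurofuse show-config ; neurofuse describe-model
```

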