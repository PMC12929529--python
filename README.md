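# prommf

Multimodal MSI/MSS classification from histopathology and gene expression.

Microsatellite instability (MSI) marks tumors with defective DNA mismatch
repair, high mutational burden and abundant neoantigens — patients whose
cancers are MSI respond far better to immune-checkpoint inhibition, but in
stomach adenocarcinoma only about 22% of patients carry the subtype and
laboratory MSI testing (PCR/IHC) is slow and costly. `prommf` implements a
computational alternative for researchers working with paired
histopathology and RNA-seq data: a deep multimodal classifier that fuses a
patient's H&E tile embeddings with their expression profile, together with
the full training protocol, a synthetic-cohort generator, and the paired
statistics needed to compare two classifiers honestly on the same test set.

## The model

A patient is a *bag* of tile embeddings (one 2048-d vector per tile from a
pretrained CNN's global-average-pool layer) plus a gene-expression vector.

**Image branch — gated attention MIL.** Tiles are projected to
h_m ∈ R^512 and pooled with learned gated attention,

    a_m = softmax_m ( wᵀ ( tanh(V h_m) ⊙ σ(U h_m) ) ),
    h_patient = Σ_m a_m h_m,

so the model decides which tiles matter without tile-level labels.

**Expression branch.** Counts → TPM → log2(x+1) → per-gene z-score (moments
from training patients only), restricted to genes passing a
differential-expression screen (|logFC| > 2 strictly, p < 0.05, fitted on
the training split), then a small MLP.

**Fusion.** Both branches are reduced to 32-d vectors, augmented with a
trailing 1, and fused by the Kronecker (outer) product

    h_fusion = vec( [h_histology; 1] [h_omic; 1]ᵀ ) ∈ R^1089,

whose last row/column preserve the unimodal vectors exactly while the rest
captures all pairwise cross-modal interactions (plain concatenation is the
alternative operator). *Progressive fusion* (the ProMMF models) projects the
fused vector back into each unimodal space, adds the result to the original
unimodal features, and re-fuses — unrolled for T refinement cycles
(default 2). With zeroed back-projection weights ProMMF reduces exactly to
single-pass MMF. Unimodal baselines (AMIL, DMLP) and decision-level late
fusion are included; the registry covers
`{AMIL, DMLP, LateFusion, MMF_Kron, MMF_Con, ProMMF_Kron, ProMMF_Con}`.

**Comparison statistics.** Two models scored on the same patients are
compared with a paired bootstrap of the AUCs (identical resample indices
for both models; percentile 95% CIs), a paired sign-flip permutation test
on score differences, paired Cohen's d, and parametric Monte-Carlo power at
α = 0.05.

The networks run on a compact reverse-mode autodiff core written on NumPy
(`prommf._tensor` / `prommf.nn`) — the models are small enough that no
deep-learning framework is needed.

## Worked example

```python
import numpy as np
from prommf import (SyntheticSpec, generate_cohort, patient_level_split,
                    train_model, TrainConfig, compare_models)

# a synthetic cohort with class signal planted in both modalities
spec = SyntheticSpec(n_patients=300, prevalence=0.22, n_genes=2000,
                     n_de_up=4, n_de_down=4, de_logfc=2.3, nb_dispersion=3.0,
                     informative_fraction=0.3, image_effect=4.0,
                     signal_dim=8, embedding_dim=128, bag_size_range=(6, 16),
                     seed=101)
cohort = generate_cohort(spec)
split = patient_level_split(cohort.patient_ids, seed=2024,
                            stratify_labels=cohort.labels)

cfg = TrainConfig(epochs=20, seed=1)   # Adam 1e-4, wd 5e-3, batch size 1
runs = {name: train_model(cohort, split, name, cfg)
        for name in ("DMLP", "AMIL", "ProMMF_Kron")}
for name, run in runs.items():
    print(name, {k: round(v, 3) for k, v in run.metrics("test").items()})

report = compare_models(runs["ProMMF_Kron"].predictions["test"],
                        runs["DMLP"].predictions["test"], seed=1)
print("delta =", round(report.delta_observed, 3),
      "p =", round(report.p_permutation, 4),
      "d =", round(report.cohen_d, 2))
```

Output from this exact script:

```
DMLP {'auc': 0.912, 'precision': 0.714, 'recall': 0.714, 'f1': 0.714}
AMIL {'auc': 0.866, 'precision': 0.9, 'recall': 0.643, 'f1': 0.75}
ProMMF_Kron {'auc': 0.86, 'precision': 0.75, 'recall': 0.643, 'f1': 0.692}
delta = -0.061 p = 0.0306 d = -0.28
```

On a single seed the three test AUCs (60 held-out patients) are noisy and
any ordering can occur, which is exactly why the comparison machinery and
multi-seed means exist: averaged over five seeds of this design the fusion
model overtakes both unimodal baselines (see below). `run.predictions`
holds patient-aligned scores for each split; `evalstat.group_metrics`
computes stage/treatment subgroup tables; `cross_validate` runs
patient-level k-fold CV with mean ± SD reporting.

The same study is available from the shell:

```bash
prommf synthesize --out data/ --n-patients 300 --seed 101
prommf train --data data/ --model ProMMF_Kron --out runs/prommf --epochs 20
prommf compare --scores-a runs/prommf/scores_test.csv --scores-b runs/dmlp/scores_test.csv
prommf run --profile fast --out runs/full    # whole pipeline, one config
```

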