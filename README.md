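# mbehrt

Multimodal BERT-style modelling of breast-cancer patient trajectories from
electronic health records (EHRs).

Clinicians and ML researchers working with longitudinal oncology EHRs face
two heterogeneous signals: structured visit data (lab values, departments,
procedures, therapies, tumor features) and free-text reports.  `mbehrt`
turns both into transformer-ready sequences and predicts 3-year disease-free
survival (DFS):

* **Tabular trajectories** — each visit is tokenized into at most 17 feature
  tokens (binarized markers `1`/`2`, marker deltas `round(Δ/10)`, department,
  procedure, therapy, subtherapy, age, dynamic Nottingham Prognostic Index
  prognostic group, molecular subtype) on four aligned layers: token,
  modality (feature type — this is what lets missing values simply be
  skipped), inter-visit delay bucket (W0–W3 / M1–M12 / LT) and position,
  truncated to the first 512 tokens.  The NPI is
  `0.2 × size(cm) + grade + node stage` with node stage 1/2/3 for
  0 / 1–3 / >3 nodes, banded into Blamey's six prognostic groups.
* **Masked-language-model pretraining** — 15% of eligible tokens masked, 2%
  swapped at random; precision (top-1 accuracy at masked positions) is
  benchmarked against a within-sequence-shuffled baseline; final token
  embeddings ensemble five seeded runs after per-dimension standardization.
* **Text trajectories** — each report is preprocessed and embedded as the
  sum of its token embeddings (pluggable embedder; a deterministic hash stub
  ships), giving a chronological sequence of report vectors with delay
  buckets for a second transformer.
* **Cross-attention fusion** — the text representation queries the tabular
  encoder's hidden sequence (keys/values); submodels stay frozen and only
  the projection, attention and head are trained.
* **Interpretation** — integrated gradients (with the completeness gap
  reported), high-attribution report selection, frequent 3–9-word phrase
  mining between DFS groups, and Kaplan–Meier / log-rank validation of the
  extracted phrases.

A seeded synthetic-cohort generator reproduces the statistical structure the
pipeline assumes (6.2% event prevalence by default, department–procedure
co-occurrence, marker missingness, censoring, plantable tabular and textual
signal), so every stage is testable without any private clinical data.  The
transformer stack runs on a small NumPy autodiff core — no GPU or deep
learning framework required.

## Worked example

```python
import numpy as np
import mbehrt as mb
from mbehrt.cohort import Vocabulary, apply_cohort_filters, build_trajectory, \
    token_modality_stream
from mbehrt.classifiers import TabularTrajectoryClassifier, TrainConfig
from mbehrt.mlm import EncoderConfig
from mbehrt.evaluate import roc_auc_ci

cfg = mb.SimConfig(n_patients=400, seed=5, visits_per_month=0.25,
                   prevalence=0.30, beta_npi=2.5, censor_fraction=0.0)
records = mb.generate_cohort(cfg)
kept, excluded = apply_cohort_filters(records)      # 3-year DFS labels
vocab = Vocabulary.build([token_modality_stream(r, kept) for r in kept])
trajs = [build_trajectory(r, vocab, kept) for r in kept]
labels = np.array([r.dfs_event for r in kept])

n = int(0.7 * len(kept))
enc = EncoderConfig(n_layers=2, n_heads=4, hidden_size=32, intermediate_size=64)
clf = TabularTrajectoryClassifier(trajs[:n], labels[:n], vocab, enc,
                                  TrainConfig(1e-3, 32, 4, seed=0)).fit()
print(clf.summary())
rep = roc_auc_ci(labels[n:], clf.predict_proba(trajs[n:]), seed=0)
print(rep)
```

prints

```
Tabular trajectory classifier (fine-tuned encoder)
==================================================
hidden size          32
layers/heads         2/4
epochs               4
final balanced loss  0.4766
auc_roc [all] = 0.759 [0.581 - 0.901] (n=102)
```

— the held-out AUC of a small encoder fine-tuned on a 338-patient synthetic
cohort with a strong planted dNPI effect: well above chance, with a
bootstrap 95% CI excluding 0.5, exactly what the planted signal warrants.
(The reference full-scale configuration — 5 layers, hidden 144, intermediate
133, 12 heads — ships as `EncoderConfig()`.)

The same workflow is scriptable from the shell:

```bash
mbehrt simulate --n 400 --seed 5 --out data/
mbehrt tokenize --data data/ --out traj.jsonl --vocab vocab.json
mbehrt pretrain --trajectories traj.jsonl --vocab vocab.json --out mlm/ --seeds 5
mbehrt finetune-tabular --trajectories traj.jsonl --pretrained mlm/ --out tab/
mbehrt embed-reports --data data/ --out reports
mbehrt train-text --reports reports --out text/
mbehrt fuse --tabular tab/ --text text/ --trajectories traj.jsonl \
            --reports reports --out fusion/
mbehrt attribute --tabular tab/ --trajectories traj.jsonl --out attr.jsonl
mbehrt evaluate --predictions fusion/predictions.csv --data data/ \
                --npi-baseline --out metrics.json
```

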