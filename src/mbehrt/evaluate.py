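"""Evaluation: AUC-ROC with stratified bootstrap CIs, average precision,
DeLong's paired AUC test, the NPI clinical baseline, subgroup-stratified
scoring, and a learning-curve harness for the pretraining advantage.

AUC and average precision are computed with scikit-learn; confidence
intervals are percentile bootstrap stratified by class (2000 resamples by
default).  DeLong's test is the standard placement-value construction for
paired ROC curves on identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvalReport:
    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    subgroup: str = "all"
    note: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must contain the point estimate")

    def __str__(self):
        return (f"{self.metric} [{self.subgroup}] = {self.estimate:.3f} "
                f"[{self.ci_low:.3f} - {self.ci_high:.3f}] (n={self.n})")


def _check_two_classes(labels):
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def roc_auc_ci(labels, scores, n_boot: int = 2000, seed: int = 0,
               alpha: float = 0.05) -> EvalReport:
    """AUC-ROC with a percentile bootstrap CI, resampling within each class
    so every replicate keeps both classes."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(labels, scores))
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        boots[b] = _rank_auc(labels[idx], scores[idx])
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return EvalReport("auc_roc", auc, min(float(lo), auc), max(float(hi), auc), len(labels))


def _rank_auc(labels, scores) -> float:
    """Mann–Whitney AUC via midranks (fast bootstrap inner loop)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def average_precision(labels, scores) -> float:
    """Average precision score (area under the precision-recall steps)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _placements(pos_scores, neg_scores):
    """DeLong placement values via midranks."""
    m, n = len(pos_scores), len(neg_scores)
    combined = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(combined)
    rank_pos, rank_neg = ranks[:m], ranks[m:]
    v_pos = (rank_pos - stats.rankdata(pos_scores)) / n
    v_neg = 1.0 - (rank_neg - stats.rankdata(neg_scores)) / m
    return v_pos, v_neg


def delong_test(labels, scores_a, scores_b) -> tuple:
    """Two-sided DeLong test for the difference of two correlated AUCs
    evaluated on the same samples.  Returns (z statistic, p-value)."""
    labels = _check_two_classes(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not len(labels) == len(scores_a) == len(scores_b):
        raise ValueError("predictions must be paired on identical samples")
    pos, neg = labels, ~labels
    va_pos, va_neg = _placements(scores_a[pos], scores_a[neg])
    vb_pos, vb_neg = _placements(scores_b[pos], scores_b[neg])
    auc_a, auc_b = va_pos.mean(), vb_pos.mean()
    m, n = int(pos.sum()), int(neg.sum())
    s_pos = np.cov(np.stack([va_pos, vb_pos]))
    s_neg = np.cov(np.stack([va_neg, vb_neg]))
    var = (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m \
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    if auc_a == auc_b:
        return 0.0, 1.0
    if var <= 0:
        raise ValueError(
            f"degenerate DeLong variance ({var:.3g}); scores may be constant "
            f"or identical within classes (AUCs {auc_a:.3f} vs {auc_b:.3f})")
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def npi_baseline_scores(records) -> np.ndarray:
    """Clinical baseline: risk score = NPI at diagnosis (higher = riskier),
    after the standard imputations."""
    from .cohort import compute_npi, impute_for_dnpi
    scores = []
    for r in records:
        completed = impute_for_dnpi(r, records)
        if completed is None:
            raise ValueError(f"{r.patient_id}: dNPI unavailable even after imputation")
        scores.append(compute_npi(*completed).npi)
    return np.asarray(scores)


def stratified_eval(labels, scores, strata, n_boot: int = 2000, seed: int = 0,
                    min_per_class: int = 5) -> dict:
    """Per-stratum AUC reports (age band, grade, subtype, node status, ...).
    Strata with fewer than `min_per_class` members of either class are
    flagged as insufficient rather than scored."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    strata = np.asarray(strata)
    out = {}
    for key in np.unique(strata):
        sel = strata == key
        n_pos = int(labels[sel].sum())
        n_neg = int((~labels[sel]).sum())
        if min(n_pos, n_neg) < min_per_class:
            out[str(key)] = EvalReport("auc_roc", 0.5, 0.0, 1.0, int(sel.sum()),
                                       subgroup=str(key),
                                       note=f"insufficient ({n_pos} pos / {n_neg} neg)")
        else:
            rep = roc_auc_ci(labels[sel], scores[sel], n_boot=n_boot, seed=seed)
            out[str(key)] = EvalReport(rep.metric, rep.estimate, rep.ci_low,
                                       rep.ci_high, rep.n, subgroup=str(key))
    return out


def pretraining_advantage(trajectories, labels, vocab, enc_config, train_config,
                          labelled_sizes, seeds, pretrained, holdout_trajectories,
                          holdout_labels):
    """Learning-curve harness: held-out AUC of the fine-tuned classifier with
    and without MLM initialization across labelled-set sizes.  Returns a list
    of dicts (size, seed, auc_pretrained, auc_scratch)."""
    from .classifiers import TabularTrajectoryClassifier, TrainConfig
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for size in labelled_sizes:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            pos = np.flatnonzero(labels)
            neg = np.flatnonzero(~labels)
            n_pos = max(2, int(round(size * labels.mean())))
            idx = np.concatenate([
                rng.choice(pos, min(n_pos, len(pos)), replace=False),
                rng.choice(neg, min(size - n_pos, len(neg)), replace=False)])
            sub = [trajectories[i] for i in idx]
            sub_labels = labels[idx]
            aucs = {}
            for tag, init in (("pretrained", pretrained), ("scratch", None)):
                clf = TabularTrajectoryClassifier(
                    sub, sub_labels, vocab, enc_config, train_config, init).fit(seed=seed)
                probs = clf.predict_proba(holdout_trajectories)
                aucs[tag] = float(roc_auc_score(holdout_labels, probs))
            rows.append({"size": int(size), "seed": int(seed),
                         "auc_pretrained": aucs["pretrained"],
                         "auc_scratch": aucs["scratch"]})
    return rows
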