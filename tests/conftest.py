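"""Shared fixtures: synthetic cohorts and trained models.

Heavy objects (trained encoders/classifiers) are session-scoped and reused by
the unit, property and acceptance suites.  All randomness is seeded; problem
sizes are deliberately small (hundreds of patients, 2-layer/32-unit
encoders) so the whole suite runs on one CPU core.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import mbehrt as mb
from mbehrt.classifiers import (CrossAttentionFusion, FusionConfig,
                                ReportSequenceClassifier, TabularTrajectoryClassifier,
                                TextModelConfig, TrainConfig)
from mbehrt.cohort import (Vocabulary, apply_cohort_filters, build_trajectory,
                           token_modality_stream)
from mbehrt.mlm import EncoderConfig
from mbehrt.text import HashingTokenEmbedder, build_text_trajectory, n_reports_in_window

TINY_ENCODER = EncoderConfig(n_layers=2, n_heads=4, hidden_size=32,
                             intermediate_size=64, epochs=3, batch_size=32,
                             learning_rate=1e-3)


def make_visit(date, **kw):
    kw.setdefault("department", "oncologie medicale")
    return mb.VisitEvent(date=date, **kw)


def make_record(patient_id="P0", n_visits=4, dfs_event=False, followup_days=1300,
                **kw):
    diagnosis = dt.date(2016, 3, 1)
    surgery = dt.date(2016, 4, 1)
    visits = [make_visit(diagnosis + dt.timedelta(days=30 * k)) for k in range(n_visits)]
    defaults = dict(birth_date=dt.date(1960, 1, 1), diagnosis_date=diagnosis,
                    surgery_date=surgery, visits=visits, molecular_subtype="Luminal",
                    tumor_grade=2, n_nodes=1, tnm_stage="T2",
                    dfs_event=dfs_event, followup_days=followup_days)
    defaults.update(kw)
    return mb.PatientRecord(patient_id=patient_id, **defaults)


def prepare_cohort(config):
    """Generate → attach reports → filter/label → tokenize both modalities."""
    records = mb.generate_cohort(config)
    for r in records:
        mb.generate_reports(r, config)
    kept, _ = apply_cohort_filters(records)
    kept = [r for r in kept if n_reports_in_window(r) > 0]
    labels = np.array([r.dfs_event for r in kept])
    vocab = Vocabulary.build([token_modality_stream(r, kept) for r in kept])
    trajs = [build_trajectory(r, vocab, kept) for r in kept]
    embedder = HashingTokenEmbedder(dim=64, seed=0)
    texts = [build_text_trajectory(r, embedder) for r in kept]
    return {"records": kept, "labels": labels, "vocab": vocab,
            "trajectories": trajs, "text_trajectories": texts}


def synthetic_vocab(n_content: int = 50) -> Vocabulary:
    stream = [(f"DEPT:d{i}", "department") for i in range(n_content)]
    return Vocabulary.build([stream])


def synthetic_trajectories(vocab, n_seqs: int, n_eligible: int, seed: int = 0):
    """Plain content-token sequences (CLS + content) for corruption tests."""
    rng = np.random.default_rng(seed)
    content = np.asarray(vocab.content_ids)
    cls_id = 1
    out = []
    for k in range(n_seqs):
        toks = [cls_id] + list(rng.choice(content, n_eligible))
        n = len(toks)
        out.append(mb.TokenizedTrajectory(
            f"S{k}", toks, [0] * n, [0] * n, list(range(n))))
    return out


@pytest.fixture(scope="session")
def signal_cohort():
    """Planted-signal cohort: strong dNPI effect in the event model and
    signal phrases injected into relapse-bound reports; elevated prevalence
    and no censoring so desk-scale splits keep enough positives."""
    config = mb.SimConfig(
        n_patients=400, seed=5, visits_per_month=0.25, bio_visit_fraction=0.3,
        prevalence=0.30, beta_npi=2.5, beta_abnormal_ca153=0.5,
        censor_fraction=0.0, signal_phrase_prob_event=0.8,
        signal_phrase_prob_noevent=0.05, mean_report_words=25)
    data = prepare_cohort(config)
    n_train = int(0.7 * len(data["records"]))
    data["n_train"] = n_train
    data["config"] = config
    return data


@pytest.fixture(scope="session")
def trained_tabular(signal_cohort):
    sc = signal_cohort
    n = sc["n_train"]
    model = TabularTrajectoryClassifier(
        sc["trajectories"][:n], sc["labels"][:n], sc["vocab"], TINY_ENCODER,
        TrainConfig(learning_rate=1e-3, batch_size=32, epochs=4, seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def trained_text(signal_cohort):
    sc = signal_cohort
    n = sc["n_train"]
    cfg = TextModelConfig(d_text=64, hidden_size=32, n_heads=4, n_layers=2,
                          intermediate_size=64, max_reports=32)
    model = ReportSequenceClassifier(
        sc["text_trajectories"][:n], sc["labels"][:n], cfg,
        TrainConfig(learning_rate=1e-3, batch_size=32, epochs=6, seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def trained_fusion(signal_cohort, trained_tabular, trained_text):
    sc = signal_cohort
    n = sc["n_train"]
    model = CrossAttentionFusion(
        trained_tabular, trained_text, sc["trajectories"][:n],
        sc["text_trajectories"][:n], sc["labels"][:n],
        FusionConfig(d_model=32, text_dim=32),
        TrainConfig(learning_rate=1e-3, batch_size=32, epochs=30, seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def dnpi_cohort():
    """Cohort where the dNPI is the only outcome driver (no marker or
    subtype effects, no lab tokens), for attribution and monotonicity
    checks."""
    config = mb.SimConfig(
        n_patients=300, seed=5, visits_per_month=0.25, bio_visit_fraction=0.0,
        prevalence=0.30, beta_npi=2.5, beta_abnormal_ca153=0.0,
        beta_subtype={}, censor_fraction=0.0,
        missing_grade_frac=0.0, missing_nodes_frac=0.0, missing_size_frac=0.0)
    records = mb.generate_cohort(config)
    kept, _ = apply_cohort_filters(records)
    labels = np.array([r.dfs_event for r in kept])
    vocab = Vocabulary.build([token_modality_stream(r, kept) for r in kept])
    trajs = [build_trajectory(r, vocab, kept) for r in kept]
    return {"records": kept, "labels": labels, "vocab": vocab,
            "trajectories": trajs}


@pytest.fixture(scope="session")
def dnpi_classifier(dnpi_cohort):
    dc = dnpi_cohort
    model = TabularTrajectoryClassifier(
        dc["trajectories"], dc["labels"], dc["vocab"], TINY_ENCODER,
        TrainConfig(learning_rate=1e-3, batch_size=32, epochs=6, seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def complementary_cohort():
    """Two merged half-cohorts with disjoint planted signals: in one half the
    event is driven by the dNPI only (no report phrases), in the other by
    report phrases only (no tabular effect).  Each submodel can recover at
    most half the signal; fusion can use both."""
    import dataclasses

    def half(seed, beta_npi, p_event, p_noevent, prefix):
        cfg = mb.SimConfig(
            n_patients=220, seed=seed, visits_per_month=0.25, bio_visit_fraction=0.0,
            prevalence=0.35, beta_npi=beta_npi, beta_abnormal_ca153=0.0,
            beta_subtype={}, censor_fraction=0.0,
            signal_phrase_prob_event=p_event, signal_phrase_prob_noevent=p_noevent,
            mean_report_words=20, missing_grade_frac=0.0, missing_nodes_frac=0.0,
            missing_size_frac=0.0)
        records = mb.generate_cohort(cfg)
        for r in records:
            mb.generate_reports(r, cfg)
        return [dataclasses.replace(r, patient_id=prefix + r.patient_id)
                for r in records]

    records = half(5, 4.0, 0.0, 0.0, "A") + half(6, 0.0, 1.0, 0.0, "B")
    order = np.random.default_rng(0).permutation(len(records))
    records = [records[i] for i in order]
    kept, _ = apply_cohort_filters(records)
    kept = [r for r in kept if n_reports_in_window(r) > 0]
    labels = np.array([r.dfs_event for r in kept])
    vocab = Vocabulary.build([token_modality_stream(r, kept) for r in kept])
    trajs = [build_trajectory(r, vocab, kept) for r in kept]
    embedder = HashingTokenEmbedder(dim=64, seed=0)
    texts = [build_text_trajectory(r, embedder) for r in kept]
    return {"records": kept, "labels": labels, "vocab": vocab,
            "trajectories": trajs, "text_trajectories": texts,
            "n_train": int(0.7 * len(kept))}


@pytest.fixture(scope="session")
def mlm_cohort():
    """Cohort with department→procedure co-occurrence for MLM structure
    tests."""
    config = mb.SimConfig(n_patients=250, seed=11, visits_per_month=0.5,
                          bio_visit_fraction=0.3, censor_fraction=0.0)
    records = mb.generate_cohort(config)
    kept, _ = apply_cohort_filters(records)
    vocab = Vocabulary.build([token_modality_stream(r, kept) for r in kept])
    trajs = [build_trajectory(r, vocab, kept) for r in kept]
    return {"records": kept, "vocab": vocab, "trajectories": trajs}


@pytest.fixture(scope="session")
def trained_mlm(mlm_cohort):
    from mbehrt.mlm import MaskedLanguageModel
    trajs = mlm_cohort["trajectories"]
    n = int(0.9 * len(trajs))
    return MaskedLanguageModel(trajs[:n], mlm_cohort["vocab"], TINY_ENCODER).fit(seed=0)
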