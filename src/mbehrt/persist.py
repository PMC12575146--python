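"""Save/load fitted models: weights as .npz, configuration as JSON (with the
vocabulary and a hash of it for audit)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .classifiers import (
    FusionConfig, FusionResults, TabularClassifierResults, TextClassifierResults,
    TextModelConfig, TrainConfig, _FusionNetwork, _TabularNetwork, _TextNetwork,
)
from .cohort import Vocabulary
from .mlm import EncoderConfig, MLMResults, _MLMNetwork

WEIGHTS = "weights.npz"
CONFIG = "config.json"


def _vocab_hash(vocab: Vocabulary) -> str:
    return hashlib.sha256(vocab.to_json().encode()).hexdigest()[:16]


def _write(out_dir, network, payload):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / WEIGHTS, **network.state_dict())
    with open(out / CONFIG, "w") as fh:
        json.dump(payload, fh, ensure_ascii=False)


def _read(in_dir):
    path = Path(in_dir)
    with open(path / CONFIG) as fh:
        payload = json.load(fh)
    state = dict(np.load(path / WEIGHTS))
    return payload, state


def save_mlm(results: MLMResults, out_dir) -> None:
    _write(out_dir, results.network, {
        "kind": "mlm",
        "config": dataclasses.asdict(results.config),
        "vocab": results.vocab.to_json(),
        "vocab_hash": _vocab_hash(results.vocab),
        "loss_history": results.loss_history,
        "val_loss_history": results.val_loss_history,
        "n_train": results.n_train, "n_val": results.n_val,
    })


def load_mlm(in_dir) -> MLMResults:
    payload, state = _read(in_dir)
    vocab = Vocabulary.from_json(payload["vocab"])
    config = EncoderConfig(**payload["config"])
    network = _MLMNetwork(vocab, config, np.random.default_rng(0))
    network.load_state_dict(state)
    return MLMResults(network, vocab, config, payload["loss_history"],
                      payload["val_loss_history"], payload["n_train"], payload["n_val"])


def save_tabular(results: TabularClassifierResults, out_dir) -> None:
    _write(out_dir, results.network, {
        "kind": "tabular",
        "enc_config": dataclasses.asdict(results.enc_config),
        "train_config": dataclasses.asdict(results.train_config),
        "vocab": results.vocab.to_json(),
        "vocab_hash": _vocab_hash(results.vocab),
        "loss_history": results.loss_history,
    })


def load_tabular(in_dir) -> TabularClassifierResults:
    payload, state = _read(in_dir)
    vocab = Vocabulary.from_json(payload["vocab"])
    enc = EncoderConfig(**payload["enc_config"])
    network = _TabularNetwork(vocab, enc, np.random.default_rng(0))
    network.load_state_dict(state)
    return TabularClassifierResults(network, vocab, enc,
                                    TrainConfig(**payload["train_config"]),
                                    payload["loss_history"])


def save_text(results: TextClassifierResults, out_dir, n_delays: int = 17) -> None:
    _write(out_dir, results.network, {
        "kind": "text",
        "model_config": dataclasses.asdict(results.model_config),
        "train_config": dataclasses.asdict(results.train_config),
        "n_delays": n_delays,
        "loss_history": results.loss_history,
    })


def load_text(in_dir) -> TextClassifierResults:
    payload, state = _read(in_dir)
    cfg = TextModelConfig(**payload["model_config"])
    network = _TextNetwork(cfg, payload["n_delays"], np.random.default_rng(0))
    network.load_state_dict(state)
    return TextClassifierResults(network, cfg, TrainConfig(**payload["train_config"]),
                                 payload["loss_history"])


def save_fusion(results: FusionResults, out_dir) -> None:
    _write(out_dir, results.network, {
        "kind": "fusion",
        "config": dataclasses.asdict(results.config),
        "loss_history": results.loss_history,
    })


def load_fusion(in_dir, tab_results: TabularClassifierResults,
                text_results: TextClassifierResults) -> FusionResults:
    payload, state = _read(in_dir)
    cfg = FusionConfig(**payload["config"])
    network = _FusionNetwork(cfg, np.random.default_rng(0))
    network.load_state_dict(state)
    return FusionResults(network, cfg, tab_results, text_results, payload["loss_history"])
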