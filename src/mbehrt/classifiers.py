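"""Supervised trajectory classifiers and multimodal fusion.

Three models predict the 3-year disease-free-survival label:

* a tabular trajectory classifier — the pretrained MLM encoder with its
  output layer replaced by a single feed-forward layer + sigmoid on the CLS
  representation;
* a report-sequence classifier — a transformer over pooled report vectors
  (with learned CLS/SEP vectors and delay embeddings), same head;
* a cross-attention fusion meta-model — the text model's representation acts
  as the query against the tabular encoder's hidden sequence as keys/values;
  both submodels stay frozen and only the projection, attention and a fresh
  head are trained.

Because positive events are rare (~6%), every model trains on class-balanced
batches: each batch holds exactly half positives and half negatives, the
majority class sampled without replacement per epoch and the minority with
replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .autograd import Tensor, concat, gather_rows, no_grad
from .cohort import Vocabulary
from .mlm import EncoderConfig, MLMResults, pad_trajectories

# ---------------------------------------------------------------------------
# balanced sampling


def balanced_batches(labels, batch_size: int, seed: int):
    """Index lists for one epoch of class-balanced batches: exactly
    batch_size/2 positives and negatives each.  The majority class is sampled
    without replacement (shuffled, chunked; a short final chunk is topped up
    with replacement), the minority with replacement.  With perfectly
    balanced classes both are enumerated without replacement."""
    labels = np.asarray(labels, dtype=bool)
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even")
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    half = batch_size // 2
    maj, mino = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    n_batches = max(1, math.ceil(len(maj) / half))

    maj_order = rng.permutation(maj)
    deficit = n_batches * half - len(maj_order)
    if deficit > 0:
        maj_order = np.concatenate([maj_order, rng.choice(maj, deficit, replace=True)])
    if len(mino) == len(maj):
        mino_order = rng.permutation(mino)
        deficit = n_batches * half - len(mino_order)
        if deficit > 0:
            mino_order = np.concatenate([mino_order, rng.choice(mino, deficit, replace=True)])
    else:
        mino_order = rng.choice(mino, n_batches * half, replace=True)

    batches = []
    for b in range(n_batches):
        sl = slice(b * half, (b + 1) * half)
        idx = np.concatenate([maj_order[sl], mino_order[sl]])
        batches.append(rng.permutation(idx))
    return batches


# ---------------------------------------------------------------------------
# configs


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0


#: reference fine-tuning hyperparameters of the full-scale models
TABULAR_REFERENCE = TrainConfig(learning_rate=1e-4, batch_size=16, epochs=5)
TEXT_REFERENCE = TrainConfig(learning_rate=5e-4, batch_size=32, epochs=99)


@dataclass
class TextModelConfig:
    """Architecture of the report-sequence transformer."""

    d_text: int = 768            # report-vector dimension fed in
    hidden_size: int = 768       # transformer width (= text "logits" dim)
    n_heads: int = 12
    intermediate_size: int = 256
    n_layers: int = 2
    max_reports: int = 128

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")


@dataclass
class FusionConfig:
    """Cross-attention fusion: text representation (dim `text_dim`, reference
    768) is projected to `d_model` (the tabular dimension, reference 144) and
    used as the query; tabular keys/values.  `logit_mode` picks what "logits"
    means: the CLS-representation vectors (default) or the scalar pre-sigmoid
    scores."""

    d_model: int = 144
    text_dim: int = 768
    n_heads: int = 1
    freeze_submodels: bool = True
    logit_mode: str = "representation"   # or "scalar"

    def __post_init__(self):
        if self.logit_mode not in ("representation", "scalar"):
            raise ValueError("logit_mode must be 'representation' or 'scalar'")


# ---------------------------------------------------------------------------
# shared head / training loop


class ClassifierHead(nn.Module):
    """Single feed-forward layer; sigmoid applied at prediction time."""

    def __init__(self, d_in: int, rng: np.random.Generator):
        self.fc = nn.Linear(d_in, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x).reshape(x.shape[0])


def _train_binary(network_logit_fn, params, labels, cfg: TrainConfig):
    """Generic balanced-batch BCE loop; `network_logit_fn(idx)` returns logits
    for the given example indices."""
    opt = nn.Adam(params, lr=cfg.learning_rate)
    labels = np.asarray(labels, dtype=bool)
    history = []
    for epoch in range(cfg.epochs):
        batches = balanced_batches(labels, cfg.batch_size, cfg.seed + 1000 * epoch)
        total, count = 0.0, 0
        for idx in batches:
            logits = network_logit_fn(idx)
            loss = nn.bce_with_logits(logits, labels[idx].astype(np.float32))
            if not np.isfinite(loss.item()):
                raise RuntimeError("classifier training diverged (NaN/inf loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            count += len(idx)
        history.append(total / max(count, 1))
    return history


# ---------------------------------------------------------------------------
# tabular classifier


class TabularClassifierResults:
    def __init__(self, network, vocab, enc_config, train_config, loss_history):
        self.network = network
        self.vocab = vocab
        self.enc_config = enc_config
        self.train_config = train_config
        self.loss_history = loss_history

    def _cls_hidden(self, trajectories) -> Tensor:
        tok, mod, dly, pos, mask = pad_trajectories(trajectories, self.enc_config.max_len)
        hidden = self.network.encoder(tok, mod, dly, pos, mask)
        b, t, d = hidden.shape
        return gather_rows(hidden.reshape(b * t, d), np.arange(b) * t), (hidden, mask)

    def logits(self, trajectories) -> np.ndarray:
        with no_grad():
            cls, _ = self._cls_hidden(trajectories)
            return self.network.head(cls).data.copy()

    def predict_proba(self, trajectories, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, len(trajectories), batch_size):
            out.append(1.0 / (1.0 + np.exp(-self.logits(trajectories[start:start + batch_size]))))
        return np.concatenate(out)

    def encode(self, trajectories):
        """Frozen features for fusion: (CLS representation (N, d), full hidden
        sequence (N, T, d), attention mask (N, T))."""
        with no_grad():
            cls, (hidden, mask) = self._cls_hidden(trajectories)
            return cls.data.copy(), hidden.data.copy(), mask

    def summary(self) -> str:
        return "\n".join([
            "Tabular trajectory classifier (fine-tuned encoder)",
            "=" * 50,
            f"hidden size          {self.enc_config.hidden_size}",
            f"layers/heads         {self.enc_config.n_layers}/{self.enc_config.n_heads}",
            f"epochs               {len(self.loss_history)}",
            f"final balanced loss  {self.loss_history[-1]:.4f}",
        ])


class _TabularNetwork(nn.Module):
    def __init__(self, vocab, enc_config, rng):
        self.encoder = nn.TrajectoryEncoder(
            len(vocab), vocab.n_modalities, vocab.n_delays, enc_config.max_len,
            enc_config.hidden_size, enc_config.n_heads, enc_config.intermediate_size,
            enc_config.n_layers, rng)
        self.head = ClassifierHead(enc_config.hidden_size, rng)


class TabularTrajectoryClassifier:
    """Fine-tune the (optionally pretrained) trajectory encoder for binary
    DFS classification: CLS representation → single feed-forward layer →
    sigmoid, trained with BCE on balanced batches."""

    def __init__(self, trajectories, labels, vocab: Vocabulary,
                 enc_config: EncoderConfig | None = None,
                 train_config: TrainConfig | None = None,
                 pretrained: MLMResults | None = None):
        if len(trajectories) != len(labels):
            raise ValueError("one label per trajectory required")
        self.trajectories = list(trajectories)
        self.labels = np.asarray(labels, dtype=bool)
        self.vocab = vocab
        self.enc_config = enc_config or (pretrained.config if pretrained else EncoderConfig())
        self.train_config = train_config or TABULAR_REFERENCE
        self.pretrained = pretrained
        if pretrained is not None and len(pretrained.vocab) != len(vocab):
            raise ValueError("pretrained encoder vocabulary does not match")

    def fit(self, seed: int | None = None) -> TabularClassifierResults:
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        network = _TabularNetwork(self.vocab, self.enc_config, np.random.default_rng(cfg.seed))
        if self.pretrained is not None:
            network.encoder.load_state_dict(self.pretrained.encoder.state_dict())

        def logit_fn(idx):
            chunk = [self.trajectories[i] for i in idx]
            tok, mod, dly, pos, mask = pad_trajectories(chunk, self.enc_config.max_len)
            hidden = network.encoder(tok, mod, dly, pos, mask)
            b, t, d = hidden.shape
            cls = gather_rows(hidden.reshape(b * t, d), np.arange(b) * t)
            return network.head(cls)

        history = _train_binary(logit_fn, network.parameters(), self.labels, cfg)
        return TabularClassifierResults(network, self.vocab, self.enc_config, cfg, history)


# ---------------------------------------------------------------------------
# text classifier


def _pad_reports(report_trajectories, max_reports):
    n = len(report_trajectories)
    r = min(max(len(t) for t in report_trajectories), max_reports)
    d = report_trajectories[0].dim
    vecs = np.zeros((n, r, d), dtype=np.float32)
    delays = np.zeros((n, r), dtype=np.int64)
    mask = np.zeros((n, r), dtype=np.int64)
    for i, t in enumerate(report_trajectories):
        k = min(len(t), r)
        vecs[i, :k] = t.vectors[:k]
        delays[i, :k] = t.delay_ids[:k]
        mask[i, :k] = 1
    return vecs, delays, mask


class _TextNetwork(nn.Module):
    """Transformer over report vectors.  Input sequence: learned CLS vector,
    then for each report its projected vector followed by a learned SEP
    vector; delay embeddings ride on the report and its SEP, positions are
    token-indexed."""

    def __init__(self, cfg: TextModelConfig, n_delays: int, rng):
        d = cfg.hidden_size
        self.proj = nn.Linear(cfg.d_text, d, rng)
        self.cls_vec = Tensor(rng.normal(0.0, nn.INIT_STD, (1, 1, d)), requires_grad=True)
        self.sep_vec = Tensor(rng.normal(0.0, nn.INIT_STD, (1, 1, d)), requires_grad=True)
        self.delay = nn.Embedding(n_delays, d, rng)
        self.pos = nn.Embedding(2 * cfg.max_reports + 1, d, rng)
        self.stack = nn.TransformerStack(cfg.n_layers, d, cfg.n_heads,
                                         cfg.intermediate_size, rng)
        self.head = ClassifierHead(d, rng)
        self.cfg = cfg

    def _assemble(self, vecs, delays, mask):
        n, r, _ = vecs.shape
        d = self.cfg.hidden_size
        proj = self.proj(Tensor(vecs))                       # (N, R, d)
        zeros = Tensor(np.zeros((n, 1, d), dtype=np.float32))
        pieces = [self.cls_vec + zeros]
        seq_delay = [np.zeros((n, 1), dtype=np.int64)]
        seq_mask = [np.ones((n, 1), dtype=np.int64)]
        flat = proj.reshape(n * r, d)
        for j in range(r):
            rep = gather_rows(flat, np.arange(n) * r + j).reshape(n, 1, d)
            pieces.extend([rep, self.sep_vec + zeros])
            dj = delays[:, j:j + 1]
            seq_delay.extend([dj, dj])
            mj = mask[:, j:j + 1]
            seq_mask.extend([mj, mj])
        x = concat(pieces, axis=1)                           # (N, 1+2R, d)
        delay_ids = np.concatenate(seq_delay, axis=1)
        attn_mask = np.concatenate(seq_mask, axis=1)
        t = x.shape[1]
        positions = np.broadcast_to(np.arange(t), (n, t))
        x = x + self.delay(delay_ids) + self.pos(positions)
        return x, attn_mask

    def cls_hidden(self, vecs, delays, mask) -> Tensor:
        x, attn_mask = self._assemble(vecs, delays, mask)
        hidden = self.stack(x, attn_mask)
        n, t, d = hidden.shape
        return gather_rows(hidden.reshape(n * t, d), np.arange(n) * t)


class TextClassifierResults:
    def __init__(self, network, model_config, train_config, loss_history):
        self.network = network
        self.model_config = model_config
        self.train_config = train_config
        self.loss_history = loss_history

    def _cls(self, report_trajectories) -> Tensor:
        vecs, delays, mask = _pad_reports(report_trajectories, self.model_config.max_reports)
        return self.network.cls_hidden(vecs, delays, mask)

    def logits(self, report_trajectories) -> np.ndarray:
        with no_grad():
            return self.network.head(self._cls(report_trajectories)).data.copy()

    def predict_proba(self, report_trajectories, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, len(report_trajectories), batch_size):
            chunk = report_trajectories[start:start + batch_size]
            out.append(1.0 / (1.0 + np.exp(-self.logits(chunk))))
        return np.concatenate(out)

    def encode(self, report_trajectories) -> np.ndarray:
        """Frozen CLS representation (N, hidden) for fusion."""
        with no_grad():
            return self._cls(report_trajectories).data.copy()

    def summary(self) -> str:
        return "\n".join([
            "Report-sequence classifier",
            "=" * 40,
            f"hidden size          {self.model_config.hidden_size}",
            f"layers/heads         {self.model_config.n_layers}/{self.model_config.n_heads}",
            f"epochs               {len(self.loss_history)}",
            f"final balanced loss  {self.loss_history[-1]:.4f}",
        ])


class ReportSequenceClassifier:
    """Transformer over a patient's chronological report vectors (+ delay
    embeddings); CLS representation → feed-forward head, balanced batches."""

    def __init__(self, report_trajectories, labels, model_config: TextModelConfig | None = None,
                 train_config: TrainConfig | None = None, n_delays: int = 17):
        if len(report_trajectories) != len(labels):
            raise ValueError("one label per trajectory required")
        dims = {t.dim for t in report_trajectories}
        if len(dims) != 1:
            raise ValueError(f"inconsistent report-vector dimensions: {sorted(dims)}")
        d_text = dims.pop()
        self.trajectories = list(report_trajectories)
        self.labels = np.asarray(labels, dtype=bool)
        self.model_config = model_config or TextModelConfig(d_text=d_text)
        if self.model_config.d_text != d_text:
            raise ValueError("model d_text does not match the report vectors")
        self.train_config = train_config or TEXT_REFERENCE
        self.n_delays = n_delays

    def fit(self, seed: int | None = None) -> TextClassifierResults:
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        network = _TextNetwork(self.model_config, self.n_delays, np.random.default_rng(cfg.seed))

        def logit_fn(idx):
            chunk = [self.trajectories[i] for i in idx]
            vecs, delays, mask = _pad_reports(chunk, self.model_config.max_reports)
            return network.head(network.cls_hidden(vecs, delays, mask))

        history = _train_binary(logit_fn, network.parameters(), self.labels, cfg)
        return TextClassifierResults(network, self.model_config, cfg, history)


# ---------------------------------------------------------------------------
# cross-attention fusion


class _FusionNetwork(nn.Module):
    def __init__(self, cfg: FusionConfig, rng):
        if cfg.logit_mode == "scalar":
            d, dq = 1, 1
            self.attn = nn.Attention(1, 1, rng, d_query=1)
            self.proj = nn.Linear(1, 1, rng)
        else:
            d, dq = cfg.d_model, cfg.text_dim
            self.attn = nn.Attention(d, cfg.n_heads, rng)
            self.proj = nn.Linear(dq, d, rng)
        self.head = ClassifierHead(3 * d, rng)

    def logit(self, text_feat: Tensor, tab_keys: Tensor, key_mask) -> Tensor:
        q = self.proj(text_feat).reshape(text_feat.shape[0], 1, -1)
        out = self.attn(q, tab_keys, key_mask)
        # residual paths: the head sees the attention output plus both
        # modalities' representations (query and the tabular CLS position),
        # so the fused model can always fall back on either submodel
        tab_cls = gather_rows(tab_keys.reshape(-1, tab_keys.shape[2]),
                              np.arange(tab_keys.shape[0]) * tab_keys.shape[1])
        fused = concat([out.reshape(out.shape[0], out.shape[2]),
                        q.reshape(q.shape[0], q.shape[2]), tab_cls], axis=1)
        return self.head(fused)


class FusionResults:
    def __init__(self, network, config, tab_results, text_results, loss_history):
        self.network = network
        self.config = config
        self.tab_results = tab_results
        self.text_results = text_results
        self.loss_history = loss_history

    def _features(self, tab_trajectories, text_trajectories):
        if self.config.logit_mode == "scalar":
            text_feat = self.text_results.logits(text_trajectories)[:, None]
            tab_keys = self.tab_results.logits(tab_trajectories)[:, None, None]
            mask = np.ones(tab_keys.shape[:2], dtype=np.int64)
        else:
            text_feat = self.text_results.encode(text_trajectories)
            _, tab_keys, mask = self.tab_results.encode(tab_trajectories)
        return Tensor(text_feat), Tensor(tab_keys), mask

    def predict_proba(self, tab_trajectories, text_trajectories) -> np.ndarray:
        text_feat, tab_keys, mask = self._features(tab_trajectories, text_trajectories)
        with no_grad():
            logit = self.network.logit(text_feat, tab_keys, mask)
        return 1.0 / (1.0 + np.exp(-logit.data))

    def summary(self) -> str:
        return "\n".join([
            "Cross-attention fusion (text query, tabular keys/values)",
            "=" * 55,
            f"d_model / text_dim   {self.config.d_model}/{self.config.text_dim}",
            f"attention heads      {self.config.n_heads}",
            f"submodels frozen     {self.config.freeze_submodels}",
            f"final balanced loss  {self.loss_history[-1]:.4f}",
        ])


class CrossAttentionFusion:
    """Meta-model fusing the two trained submodels.  The text representation
    (projected to the tabular dimension) queries the tabular hidden sequence;
    the attention output, concatenated with the query, feeds a fresh head.
    With ``freeze_submodels`` (default) the submodel outputs are precomputed
    constants — their weights are untouched by fusion training."""

    def __init__(self, tab_results: TabularClassifierResults,
                 text_results: TextClassifierResults,
                 tab_trajectories, text_trajectories, labels,
                 config: FusionConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not (len(tab_trajectories) == len(text_trajectories) == len(labels)):
            raise ValueError("tabular/text trajectories and labels must align per patient")
        self.tab_results = tab_results
        self.text_results = text_results
        self.tab_trajectories = list(tab_trajectories)
        self.text_trajectories = list(text_trajectories)
        self.labels = np.asarray(labels, dtype=bool)
        if config is None:
            config = FusionConfig(d_model=tab_results.enc_config.hidden_size,
                                  text_dim=text_results.model_config.hidden_size)
        if config.logit_mode == "representation":
            if config.d_model != tab_results.enc_config.hidden_size:
                raise ValueError("fusion d_model must equal the tabular hidden size")
            if config.text_dim != text_results.model_config.hidden_size:
                raise ValueError("fusion text_dim must equal the text hidden size")
        if not config.freeze_submodels:
            raise NotImplementedError(
                "joint fine-tuning of submodels during fusion is not supported; "
                "submodels are frozen as in the reference training protocol")
        self.config = config
        self.train_config = train_config or TrainConfig(learning_rate=1e-3, batch_size=16, epochs=30)

    def fit(self, seed: int | None = None) -> FusionResults:
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        network = _FusionNetwork(self.config, np.random.default_rng(cfg.seed))
        results = FusionResults(network, self.config, self.tab_results,
                                self.text_results, [])
        text_feat, tab_keys, mask = results._features(self.tab_trajectories,
                                                      self.text_trajectories)

        def logit_fn(idx):
            return network.logit(Tensor(text_feat.data[idx]), Tensor(tab_keys.data[idx]),
                                 mask[idx])

        results.loss_history = _train_binary(logit_fn, network.parameters(),
                                             self.labels, cfg)
        return results


def cross_attention_fuse(tab_results, text_results, tab_trajectories,
                         text_trajectories, labels, config=None,
                         train_config=None, seed=None) -> FusionResults:
    """Functional wrapper over :class:`CrossAttentionFusion`."""
    return CrossAttentionFusion(tab_results, text_results, tab_trajectories,
                                text_trajectories, labels, config, train_config).fit(seed)


def finetune_tabular(pretrained: MLMResults, trajectories, labels,
                     train_config: TrainConfig | None = None,
                     seed: int | None = None) -> TabularClassifierResults:
    """Functional wrapper: fine-tune a pretrained encoder for classification."""
    model = TabularTrajectoryClassifier(trajectories, labels, pretrained.vocab,
                                        pretrained.config, train_config, pretrained)
    return model.fit(seed)


def train_text_classifier(report_trajectories, labels, model_config=None,
                          train_config=None, seed=None) -> TextClassifierResults:
    """Functional wrapper over :class:`ReportSequenceClassifier`."""
    return ReportSequenceClassifier(report_trajectories, labels, model_config,
                                    train_config).fit(seed)


def predict_proba(results, *inputs) -> np.ndarray:
    """Dispatch to the results object's prediction method; output strictly in
    (0, 1) and invariant to batch composition."""
    return results.predict_proba(*inputs)
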