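"""Masked-language-model pretraining of the tabular trajectory encoder.

The self-supervised objective corrupts each trajectory — every eligible
(non-CLS/SEP/PAD) position is independently replaced by MASK with probability
0.15 or swapped for a random other content token with probability 0.02 — and
trains the encoder to recover the original tokens from bidirectional context
(cross-entropy at corrupted positions only, softmax over the vocabulary).
The corpus is split 90/10 into training and validation; embedding quality is
read out as *precision*, the fraction of masked tokens whose argmax
prediction is correct, and compared against a within-sequence shuffled
baseline that destroys contextual structure while preserving token content.

For downstream use, the model is run several times with different seeds and
the final token-embedding table is the mean of the per-run tables after
per-dimension standardization across the vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .autograd import Tensor, gather_rows, no_grad
from .cohort import SPECIAL_TOKENS, TokenizedTrajectory, Vocabulary

IGNORE_INDEX = -100
_STRUCTURAL_IDS = (SPECIAL_TOKENS["PAD"], SPECIAL_TOKENS["CLS"], SPECIAL_TOKENS["SEP"])

MASK_RATE = 0.15
SWAP_RATE = 0.02


@dataclass
class EncoderConfig:
    """Trajectory-encoder and training hyperparameters.  The defaults are the
    reference configuration of the full-scale model; tests use far smaller
    instances."""

    n_layers: int = 5
    n_heads: int = 12
    hidden_size: int = 144
    intermediate_size: int = 133
    max_len: int = 512
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 120
    optimizer: str = "adam"
    seed: int = 0
    mask_rate: float = MASK_RATE
    swap_rate: float = SWAP_RATE
    swap_in_loss: bool = True   # swapped positions carry prediction targets
    val_fraction: float = 0.10

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.max_len > 512:
            raise ValueError("max_len must be at most 512")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class MaskedBatch:
    """Corrupted token layer plus aligned targets for one or more sequences.

    ``corruption_mask``: 0 untouched, 1 masked, 2 swapped.  ``targets`` holds
    the original id at corrupted positions and IGNORE_INDEX elsewhere."""

    token_ids: np.ndarray
    modality_ids: np.ndarray
    delay_ids: np.ndarray
    positions: np.ndarray
    targets: np.ndarray
    corruption_mask: np.ndarray
    attn_mask: np.ndarray = None

    def __post_init__(self):
        shapes = {a.shape for a in (self.token_ids, self.modality_ids, self.delay_ids,
                                    self.positions, self.targets, self.corruption_mask)}
        if len(shapes) != 1:
            raise ValueError("layers must be aligned")
        if self.attn_mask is None:
            self.attn_mask = np.ones_like(self.token_ids)


def _corrupt_arrays(token_ids: np.ndarray, rng: np.random.Generator,
                    mask_rate: float, swap_rate: float, content_ids: np.ndarray,
                    eligible: np.ndarray, swap_in_loss: bool):
    """Per-position Bernoulli corruption (disjoint mask/swap events)."""
    u = rng.random(token_ids.shape)
    masked = eligible & (u < mask_rate)
    swapped = eligible & (u >= mask_rate) & (u < mask_rate + swap_rate)
    corrupted = token_ids.copy()
    corrupted[masked] = SPECIAL_TOKENS["MASK"]
    if swapped.any():
        draws = content_ids[rng.integers(0, len(content_ids), int(swapped.sum()))]
        originals = token_ids[swapped]
        clash = draws == originals
        while clash.any():  # resample until replacement differs from original
            draws[clash] = content_ids[rng.integers(0, len(content_ids), int(clash.sum()))]
            clash = draws == originals
        corrupted[swapped] = draws
    targets = np.full_like(token_ids, IGNORE_INDEX)
    targets[masked] = token_ids[masked]
    if swap_in_loss:
        targets[swapped] = token_ids[swapped]
    cmask = np.zeros_like(token_ids)
    cmask[masked] = 1
    cmask[swapped] = 2
    return corrupted, targets, cmask


def corrupt_sequence(traj: TokenizedTrajectory, seed: int, vocab: Vocabulary,
                     mask_rate: float = MASK_RATE, swap_rate: float = SWAP_RATE,
                     swap_in_loss: bool = True) -> MaskedBatch:
    """Corrupt one trajectory: each eligible position is masked with
    probability `mask_rate` or swapped for a uniformly random other content
    token with probability `swap_rate` (disjoint events)."""
    for name, rate in (("mask_rate", mask_rate), ("swap_rate", swap_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if mask_rate + swap_rate > 1.0:
        raise ValueError("mask_rate + swap_rate must not exceed 1")
    rng = np.random.default_rng(seed)
    tok = np.asarray(traj.token_ids)
    eligible = ~np.isin(tok, _STRUCTURAL_IDS)
    corrupted, targets, cmask = _corrupt_arrays(
        tok, rng, mask_rate, swap_rate, np.asarray(vocab.content_ids), eligible,
        swap_in_loss)
    return MaskedBatch(corrupted, np.asarray(traj.modality_ids),
                       np.asarray(traj.delay_ids), np.asarray(traj.positions),
                       targets, cmask)


def shuffle_tokens_within_sequence(traj: TokenizedTrajectory, seed: int) -> TokenizedTrajectory:
    """Permute the content (token, modality) pairs uniformly within the
    sequence, destroying contextual order.  CLS and SEP stay put, and the
    delay and position layers keep their original values (they describe visit
    timing, not token identity)."""
    rng = np.random.default_rng(seed)
    tok = np.asarray(traj.token_ids).copy()
    mod = np.asarray(traj.modality_ids).copy()
    content = np.flatnonzero(~np.isin(tok, _STRUCTURAL_IDS))
    perm = rng.permutation(len(content))
    tok[content] = tok[content][perm]
    mod[content] = mod[content][perm]
    return TokenizedTrajectory(traj.patient_id, tok.tolist(), mod.tolist(),
                               list(traj.delay_ids), list(traj.positions), traj.label)


def ensemble_token_embeddings(tables) -> np.ndarray:
    """Final token embeddings from multiple pretraining runs: standardize each
    run's table per dimension (zero mean, unit variance across the vocabulary)
    and average elementwise."""
    tables = [np.asarray(t, dtype=float) for t in tables]
    if len(tables) < 2:
        raise ValueError("need at least two runs to ensemble")
    shape = tables[0].shape
    if any(t.shape != shape for t in tables):
        raise ValueError("embedding tables must share one shape")
    standardized = []
    for t in tables:
        mu = t.mean(axis=0, keepdims=True)
        sd = t.std(axis=0, keepdims=True)
        standardized.append((t - mu) / np.maximum(sd, 1e-12))
    return np.mean(standardized, axis=0)


# ---------------------------------------------------------------------------
# batching

def pad_trajectories(trajectories, max_len: int):
    """Stack variable-length trajectories into padded (B, T) id arrays plus an
    attention mask (1 = real token)."""
    lengths = [min(len(t), max_len) for t in trajectories]
    width = max(lengths)
    b = len(trajectories)
    tok = np.zeros((b, width), dtype=np.int64)
    mod = np.zeros_like(tok)
    dly = np.zeros_like(tok)
    pos = np.zeros_like(tok)
    mask = np.zeros_like(tok)
    for i, (t, n) in enumerate(zip(trajectories, lengths)):
        tok[i, :n] = t.token_ids[:n]
        mod[i, :n] = t.modality_ids[:n]
        dly[i, :n] = t.delay_ids[:n]
        pos[i, :n] = t.positions[:n]
        mask[i, :n] = 1
    return tok, mod, dly, pos, mask


class _MLMNetwork(nn.Module):
    def __init__(self, vocab: Vocabulary, config: EncoderConfig, rng: np.random.Generator):
        self.encoder = nn.TrajectoryEncoder(
            len(vocab), vocab.n_modalities, vocab.n_delays, config.max_len,
            config.hidden_size, config.n_heads, config.intermediate_size,
            config.n_layers, rng)
        self.out = nn.Linear(config.hidden_size, len(vocab), rng)

    def target_logits(self, batch: MaskedBatch):
        hidden = self.encoder(batch.token_ids, batch.modality_ids, batch.delay_ids,
                              batch.positions, batch.attn_mask)
        b, t, d = hidden.shape
        flat_targets = batch.targets.reshape(-1)
        keep = np.flatnonzero(flat_targets != IGNORE_INDEX)
        picked = gather_rows(hidden.reshape(b * t, d), keep)
        return self.out(picked), flat_targets[keep]

    def all_logits(self, batch: MaskedBatch):
        hidden = self.encoder(batch.token_ids, batch.modality_ids, batch.delay_ids,
                              batch.positions, batch.attn_mask)
        return self.out(hidden)


class MLMResults:
    """Fitted masked-language model: loss history, the trained encoder, the
    token-embedding table and precision evaluation."""

    def __init__(self, network, vocab, config, loss_history, val_loss_history, n_train, n_val):
        self.network = network
        self.vocab = vocab
        self.config = config
        self.loss_history = loss_history
        self.val_loss_history = val_loss_history
        self.n_train = n_train
        self.n_val = n_val

    @property
    def encoder(self):
        return self.network.encoder

    @property
    def token_embeddings(self) -> np.ndarray:
        return self.network.encoder.tok.weight.data.copy()

    def precision(self, trajectories, seed: int,
                  mask_rate: float = MASK_RATE, swap_rate: float = SWAP_RATE) -> float:
        """Top-1 accuracy over masked positions of freshly corrupted copies of
        `trajectories` (fixed masking seed so the metric is stable)."""
        rng = np.random.default_rng(seed)
        correct = total = 0
        bs = max(1, self.config.batch_size)
        for start in range(0, len(trajectories), bs):
            chunk = trajectories[start:start + bs]
            tok, mod, dly, pos, mask = pad_trajectories(chunk, self.config.max_len)
            eligible = mask.astype(bool) & ~np.isin(tok, _STRUCTURAL_IDS)
            corrupted, targets, cmask = _corrupt_arrays(
                tok, rng, mask_rate, swap_rate,
                np.asarray(self.vocab.content_ids), eligible, swap_in_loss=False)
            batch = MaskedBatch(corrupted, mod, dly, pos, targets, cmask, mask)
            with no_grad():
                logits = self.network.all_logits(batch)
            pred = logits.data.argmax(axis=-1)
            masked = cmask == 1
            correct += int((pred[masked] == tok[masked]).sum())
            total += int(masked.sum())
        if total == 0:
            raise ValueError("no masked positions: cannot compute precision")
        return correct / total

    def summary(self) -> str:
        lines = [
            "Masked-language-model pretraining",
            "=" * 40,
            f"vocabulary size        {len(self.vocab)}",
            f"encoder layers/heads   {self.config.n_layers}/{self.config.n_heads}",
            f"hidden/intermediate    {self.config.hidden_size}/{self.config.intermediate_size}",
            f"train/val sequences    {self.n_train}/{self.n_val}",
            f"epochs                 {len(self.loss_history)}",
            f"final train loss       {self.loss_history[-1]:.4f}",
            f"final val loss         {self.val_loss_history[-1]:.4f}",
        ]
        return "\n".join(lines)


class MaskedLanguageModel:
    """Model object: corpus of tokenized trajectories + encoder configuration.

    ``fit`` runs MLM pretraining and returns :class:`MLMResults`."""

    def __init__(self, trajectories, vocab: Vocabulary, config: EncoderConfig | None = None):
        if not trajectories:
            raise ValueError("at least one trajectory required")
        self.trajectories = list(trajectories)
        self.vocab = vocab
        self.config = config or EncoderConfig()

    def fit(self, seed: int | None = None, verbose: bool = False) -> MLMResults:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        rng_init = np.random.default_rng(cfg.seed)
        rng_corrupt = np.random.default_rng(cfg.seed + 1)
        rng_order = np.random.default_rng(cfg.seed + 2)

        n = len(self.trajectories)
        order = np.random.default_rng(cfg.seed + 3).permutation(n)
        n_val = int(round(cfg.val_fraction * n)) if n > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        train = [self.trajectories[i] for i in train_idx]
        val = [self.trajectories[i] for i in val_idx]

        network = _MLMNetwork(self.vocab, cfg, rng_init)
        opt = nn.Adam(network.parameters(), lr=cfg.learning_rate)
        content_ids = np.asarray(self.vocab.content_ids)

        def epoch_loss(seqs, rng, train_mode):
            total, count = 0.0, 0
            idx = rng_order.permutation(len(seqs)) if train_mode else np.arange(len(seqs))
            for start in range(0, len(seqs), cfg.batch_size):
                chunk = [seqs[i] for i in idx[start:start + cfg.batch_size]]
                tok, mod, dly, pos, mask = pad_trajectories(chunk, cfg.max_len)
                eligible = mask.astype(bool) & ~np.isin(tok, _STRUCTURAL_IDS)
                corrupted, targets, cmask = _corrupt_arrays(
                    tok, rng, cfg.mask_rate, cfg.swap_rate, content_ids, eligible,
                    cfg.swap_in_loss)
                if (targets != IGNORE_INDEX).sum() == 0:
                    continue
                batch = MaskedBatch(corrupted, mod, dly, pos, targets, cmask, mask)
                if train_mode:
                    logits, tgt = network.target_logits(batch)
                    loss = nn.cross_entropy(logits, tgt)
                    if not np.isfinite(loss.item()):
                        raise RuntimeError(
                            f"MLM training diverged (NaN/inf loss) at step with "
                            f"batch of {len(chunk)} sequences; lr={cfg.learning_rate}")
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                else:
                    with no_grad():
                        logits, tgt = network.target_logits(batch)
                        loss = nn.cross_entropy(logits, tgt)
                total += loss.item() * len(tgt)
                count += len(tgt)
            return total / max(count, 1)

        val_rng_seed = cfg.seed + 7  # fixed masking for a stable validation metric
        loss_history, val_history = [], []
        val_history.append(epoch_loss(val or train, np.random.default_rng(val_rng_seed), False))
        for _ in range(cfg.epochs):
            loss_history.append(epoch_loss(train, rng_corrupt, True))
            val_history.append(epoch_loss(val or train, np.random.default_rng(val_rng_seed), False))
            if verbose:
                print(f"epoch {len(loss_history)}: train {loss_history[-1]:.4f} "
                      f"val {val_history[-1]:.4f}")
        return MLMResults(network, self.vocab, cfg, loss_history, val_history,
                          len(train), len(val))


def train_mlm(trajectories, vocab: Vocabulary, config: EncoderConfig | None = None,
              seed: int | None = None) -> MLMResults:
    """Functional wrapper over :class:`MaskedLanguageModel`."""
    return MaskedLanguageModel(trajectories, vocab, config).fit(seed=seed)


def mlm_precision(results: MLMResults, trajectories, seed: int) -> float:
    """Fraction of masked tokens predicted correctly on held-out data."""
    return results.precision(trajectories, seed)
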