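"""Training and constrained generation for the trajectory language model.

The model is a decoder-only transformer over sub-token ids (see
:mod:`storeflow.transformer`). Training uses the asymmetric loss: only
positions whose label sub-token belongs to a focal (``S``) word — including
the end-of-trajectory word — contribute to the cross-entropy, so neighbour
context conditions the model but never supervises it.

Generation is constrained by a prefix trie over the sub-token spellings of
every admissible next word (an ``S`` + cell-code word or the
end-of-trajectory word), so sampled output is valid by construction. A
rejection-resampling mode is kept as an option for fidelity experiments.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .bpe import SubTokenCodec
from .corpus import CorpusConfig, MaskedExample
from .geometry import GridSpec, all_codes
from .transformer import (
    AdamW,
    DegenerateBatchError,
    IncrementalDecoder,
    ModelConfig,
    forward,
    init_params,
    loss_and_grads,
    masked_cross_entropy,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SamplerConfig",
    "Checkpoint",
    "masked_loss",
    "train",
    "next_focal_token",
    "generate_focal",
    "TokenTrie",
    "DegenerateBatchError",
]

#: The spec-level masked loss operation (mean CE over masked-in positions).
masked_loss = masked_cross_entropy


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (AdamW with linear warmup–decay and early stop)."""

    learning_rate: float = 3e-4
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 3
    val_fraction: float = 0.1
    weight_decay: float = 0.01
    warmup_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")

    @classmethod
    def full(cls, **over) -> "TrainConfig":
        """Full-scale preset: lr 3e-4, batch 32."""
        return cls(**{"learning_rate": 3e-4, "batch_size": 32, **over})

    @classmethod
    def desk(cls, **over) -> "TrainConfig":
        """CPU-scale preset: smaller batches, short patience."""
        return cls(**{"learning_rate": 3e-4, "batch_size": 16,
                      "max_epochs": 8, "patience": 2, **over})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling controls for generation. ``temperature == 0`` is greedy."""

    temperature: float = 1.0
    top_k: int = 0
    seed: Optional[int] = None


@dataclass
class Checkpoint:
    """Trained parameters plus everything needed to generate from them."""

    params: Dict[str, np.ndarray]
    model_config: ModelConfig
    codec: SubTokenCodec
    corpus_config: CorpusConfig
    grid: GridSpec
    history: List[dict] = field(default_factory=list)
    _trie: Optional["TokenTrie"] = field(default=None, repr=False, compare=False)

    def trie(self) -> "TokenTrie":
        if self._trie is None:
            self._trie = TokenTrie(self.codec, self.grid, self.corpus_config)
        return self._trie

    def decoder(self) -> IncrementalDecoder:
        return IncrementalDecoder(self.params, self.model_config)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "params.npz"), **self.params)
        self.codec.save(os.path.join(directory, "codec.json"))
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(
                {
                    "model": self.model_config.to_dict(),
                    "corpus": self.corpus_config.to_dict(),
                    "grid": self.grid.to_dict(),
                },
                fh,
                indent=1,
            )
        with open(os.path.join(directory, "history.json"), "w") as fh:
            json.dump(self.history, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "Checkpoint":
        with open(os.path.join(directory, "config.json")) as fh:
            cfgs = json.load(fh)
        with np.load(os.path.join(directory, "params.npz")) as npz:
            params = {k: npz[k].copy() for k in npz.files}
        with open(os.path.join(directory, "history.json")) as fh:
            history = json.load(fh)
        return cls(
            params=params,
            model_config=ModelConfig.from_dict(cfgs["model"]),
            codec=SubTokenCodec.load(os.path.join(directory, "codec.json")),
            corpus_config=CorpusConfig.from_dict(cfgs["corpus"]),
            grid=GridSpec.from_dict(cfgs["grid"]),
            history=history,
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def truncate_example(ex: MaskedExample, context_length: int) -> MaskedExample:
    """Head-truncate an over-long example in whole frames (keep the tail)."""
    n = len(ex.ids)
    if n <= context_length:
        return ex
    keep_from = None
    for fs in ex.frame_starts:
        if n - fs <= context_length:
            keep_from = int(fs)
            break
    if keep_from is None:
        raise ValueError(
            f"no whole-frame suffix of length ≤ {context_length}; "
            "a single frame exceeds the context window"
        )
    return MaskedExample(
        ids=ex.ids[keep_from:],
        target_mask=ex.target_mask[keep_from:],
        frame_starts=ex.frame_starts[ex.frame_starts >= keep_from] - keep_from,
    )


def _pad_batch(examples: Sequence[MaskedExample]):
    B = len(examples)
    T = max(len(e.ids) for e in examples)
    ids = np.zeros((B, T), np.int64)
    labels = np.zeros((B, T), np.int64)
    mask = np.zeros((B, T), bool)
    for b, e in enumerate(examples):
        n = len(e.ids)
        ids[b, :n] = e.ids
        labels[b, : n - 1] = e.ids[1:]
        mask[b, :n] = e.target_mask
    return ids, labels, mask


def _epoch_batches(order: np.ndarray, examples, batch_size: int,
                   rng: np.random.Generator):
    # bucket by length to limit padding, then shuffle batch order
    order = sorted(order, key=lambda i: -len(examples[i].ids))
    batches = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    rng.shuffle(batches)
    return batches


def _eval_loss(params, mc, examples, batch_size) -> float:
    total = 0.0
    count = 0
    for i in range(0, len(examples), batch_size):
        ids, labels, mask = _pad_batch(examples[i:i + batch_size])
        logits, _ = forward(params, mc, ids)
        n_in = int(mask.sum())
        if n_in == 0:
            continue
        total += masked_cross_entropy(logits, labels, mask) * n_in
        count += n_in
    if count == 0:
        raise DegenerateBatchError("validation set has no masked-in positions")
    return total / count


def train(
    examples: Sequence[MaskedExample],
    mc: ModelConfig,
    tc: TrainConfig,
    codec: SubTokenCodec,
    corpus_config: CorpusConfig,
    grid: GridSpec,
    verbose: bool = False,
) -> Checkpoint:
    """Train from scratch and return the best-validation-loss checkpoint.

    The corpus is split into train/validation *by document* using
    ``tc.seed``; examples longer than the context window are head-truncated
    in whole frames so the most recent context is kept.
    """
    if len(examples) == 0:
        raise ValueError("empty corpus")
    examples = [truncate_example(e, mc.context_length) for e in examples]

    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(examples))
    n_val = max(1, int(round(tc.val_fraction * len(examples))))
    if n_val >= len(examples):
        raise ValueError("corpus too small for the validation split")
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    val_examples = [examples[i] for i in val_idx]

    params = init_params(mc, rng)
    opt = AdamW(params, lr=tc.learning_rate, weight_decay=tc.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / tc.batch_size)))
    total_steps = steps_per_epoch * tc.max_epochs
    warmup = max(1, int(tc.warmup_frac * total_steps))

    def lr_at(step: int) -> float:
        if step < warmup:
            return tc.learning_rate * (step + 1) / warmup
        frac = (step - warmup) / max(1, total_steps - warmup)
        return tc.learning_rate * max(0.1, 1.0 - 0.9 * frac)

    history: List[dict] = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0
    step = 0
    for epoch in range(1, tc.max_epochs + 1):
        batches = _epoch_batches(train_idx, examples, tc.batch_size, rng)
        train_total = 0.0
        train_count = 0
        for batch in batches:
            ids, labels, mask = _pad_batch([examples[i] for i in batch])
            n_in = int(mask.sum())
            if n_in == 0:
                continue
            loss, grads = loss_and_grads(params, mc, ids, labels, mask)
            opt.step(params, grads, lr=lr_at(step))
            step += 1
            train_total += loss * n_in
            train_count += n_in
        train_loss = train_total / max(1, train_count)
        val_loss = _eval_loss(params, mc, val_examples, tc.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tc.patience:
                break

    return Checkpoint(
        params=best_params,
        model_config=mc,
        codec=codec,
        corpus_config=corpus_config,
        grid=grid,
        history=history,
    )


# ---------------------------------------------------------------------------
# constrained generation
# ---------------------------------------------------------------------------

class TokenTrie:
    """Prefix trie over the sub-token spellings of every admissible word.

    Admissible words are ``"S" + code`` for every cell of the grid, plus the
    end-of-trajectory word. Because all focal words have equal character
    length and the end word is atomic, no spelling is a strict prefix of
    another: trie terminals are leaves, so constrained sampling can never
    dead-end.
    """

    def __init__(self, codec: SubTokenCodec, grid: GridSpec, cfg: CorpusConfig):
        self.codec = codec
        self.eos_id_seq: Tuple[int, ...] = tuple(
            codec.token_to_id[p] for p in codec.encode_word(cfg.eos_token)
        )
        children: Dict[Tuple[int, ...], set] = {}
        words: Dict[Tuple[int, ...], str] = {}
        self.max_len = 0
        for code in all_codes(grid):
            word = "S" + code
            seq = tuple(codec.token_to_id[p] for p in codec.encode_word(word))
            self._insert(children, seq)
            words[seq] = word
            self.max_len = max(self.max_len, len(seq))
        self._insert(children, self.eos_id_seq)
        words[self.eos_id_seq] = cfg.eos_token
        self.max_len = max(self.max_len, len(self.eos_id_seq))
        self.children = {k: np.array(sorted(v), np.int64) for k, v in children.items()}
        self.words = words
        self.eos_token = cfg.eos_token

    @staticmethod
    def _insert(children: Dict[Tuple[int, ...], set], seq: Tuple[int, ...]):
        for i in range(len(seq)):
            children.setdefault(seq[:i], set()).add(seq[i])

    def allowed(self, prefix: Tuple[int, ...]) -> Optional[np.ndarray]:
        """Allowed next ids after ``prefix``; None when prefix is a full word."""
        return self.children.get(prefix)


def _sample_from(logits: np.ndarray, allowed: np.ndarray, sampler: SamplerConfig,
                 rng: np.random.Generator) -> int:
    sub = logits[allowed].astype(np.float64)
    if sampler.temperature <= 0:
        return int(allowed[int(np.argmax(sub))])
    sub = sub / sampler.temperature
    if sampler.top_k and sampler.top_k < len(sub):
        cutoff = np.sort(sub)[-sampler.top_k]
        sub = np.where(sub >= cutoff, sub, -np.inf)
    sub -= sub.max()
    p = np.exp(sub)
    p /= p.sum()
    return int(allowed[rng.choice(len(allowed), p=p)])


def generate_focal(
    ckpt: Checkpoint,
    decoder: IncrementalDecoder,
    sampler: SamplerConfig,
    rng: np.random.Generator,
) -> Tuple[Optional[str], List[int]]:
    """Sample one focal word from a primed decoder.

    The decoder must already hold a context ending at a frame boundary.
    Returns ``(code, sampled_ids)`` where ``code`` is the cell code of the
    sampled ``S`` word, or ``(None, ids)`` when the end-of-trajectory word
    was produced. The sampled sub-tokens are appended into the decoder.
    """
    trie = ckpt.trie()
    prefix: Tuple[int, ...] = ()
    sampled: List[int] = []
    logits = decoder.append([])  # logits after the current context
    while True:
        allowed = trie.allowed(prefix)
        if allowed is None:
            break  # complete word (terminals are leaves)
        nxt = _sample_from(logits, allowed, sampler, rng)
        sampled.append(nxt)
        prefix = prefix + (nxt,)
        if trie.allowed(prefix) is not None:
            logits = decoder.append([nxt])
        else:
            decoder.append([nxt])  # keep cache consistent; no logits needed
    word = trie.words[prefix]
    if word == trie.eos_token:
        return None, sampled
    return word[1:], sampled


def frame_starts_from_ids(
    ids: Sequence[int], codec: SubTokenCodec, cfg: CorpusConfig
) -> List[int]:
    """Recover frame start positions from a sub-token id sequence."""
    word_starts: List[int] = []
    for i, tid in enumerate(ids):
        piece = codec.vocab[tid]
        if piece in codec.atomic_words or (piece and piece[0] in codec.word_initial_chars):
            word_starts.append(i)
    return word_starts[:: cfg.frame_words]


def next_focal_token(
    ckpt: Checkpoint,
    context: Sequence[int],
    sampler: SamplerConfig = SamplerConfig(),
    grid: Optional[GridSpec] = None,
    cfg: Optional[CorpusConfig] = None,
    rng: Optional[np.random.Generator] = None,
    mode: str = "trie",
) -> Optional[str]:
    """Sample the focal agent's next location code (or None for trajectory end).

    ``context`` is a sub-token id sequence ending at a frame boundary. When it
    is too long for the model's window it is head-truncated in whole frames.
    With ``mode="trie"`` (default) sampling is constrained so output is valid
    by construction; ``mode="rejection"`` samples the raw model and resamples
    malformed words, for fidelity experiments.
    """
    cfg = cfg or ckpt.corpus_config
    grid = grid or ckpt.grid
    if rng is None:
        rng = np.random.default_rng(sampler.seed)
    trie = ckpt.trie()
    context = list(context)
    budget = ckpt.model_config.context_length - trie.max_len
    if len(context) > budget:
        starts = frame_starts_from_ids(context, ckpt.codec, cfg)
        keep_from = next(
            (s for s in starts if len(context) - s <= budget), None
        )
        if keep_from is None:
            raise ValueError("context cannot be truncated to fit the window")
        context = context[keep_from:]
    decoder = ckpt.decoder()
    decoder.reset(np.asarray(context, np.int64))
    if mode == "trie":
        code, _ = generate_focal(ckpt, decoder, sampler, rng)
        return code
    if mode == "rejection":
        return _rejection_sample(ckpt, context, sampler, rng)
    raise ValueError(f"unknown generation mode {mode!r}")


def _rejection_sample(ckpt, context, sampler, rng, max_tries: int = 64):
    trie = ckpt.trie()
    vocab_ids = np.arange(len(ckpt.codec.vocab), dtype=np.int64)
    for _ in range(max_tries):
        decoder = ckpt.decoder()
        decoder.reset(np.asarray(context, np.int64))
        logits = decoder.append([])
        seq: Tuple[int, ...] = ()
        for _ in range(trie.max_len):
            nxt = _sample_from(logits, vocab_ids, sampler, rng)
            seq = seq + (nxt,)
            if seq in trie.words:
                word = trie.words[seq]
                return None if word == trie.eos_token else word[1:]
            logits = decoder.append([nxt])
    raise RuntimeError(f"rejection sampling failed after {max_tries} tries")
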