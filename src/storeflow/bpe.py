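"""Deterministic byte-pair-encoding codec for symbolic trajectory corpora.

The corpus language is closed: whitespace-separated "words" that are either a
role prefix glued to a location code (``Sagimrx``), an atomic placeholder
(``Onone``), or the end-of-trajectory marker. The codec therefore uses a
character-level base alphabet, merges that never cross word boundaries, and a
small explicit list of atomic words that are seeded into the vocabulary as
single symbols and never split.

Training is the classic frequency-greedy pair-merge procedure: count adjacent
symbol pairs over word types (weighted by word frequency), merge the most
frequent pair, repeat until the vocabulary budget is reached. Ties are broken
lexicographically on the pair, which makes training a pure function of the
corpus and the budget.

A deliberately small budget (the full-scale configuration uses 200) forces
each role+code word to decompose into a few reusable sub-tokens, so the
downstream sequence model can generalise across locations that share quadtree
prefixes instead of memorising whole cell names.
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = ["SubTokenCodec", "CodecError"]


class CodecError(ValueError):
    """Raised for untrainable budgets or unencodable input."""


def _word_frequencies(corpus: Iterable[str]) -> Counter:
    freqs: Counter = Counter()
    for doc in corpus:
        freqs.update(doc.split())
    return freqs


class SubTokenCodec:
    """Sub-token vocabulary + ordered merge rules (lossless round trip)."""

    def __init__(
        self,
        vocab: Sequence[str],
        merges: Sequence[Tuple[str, str]],
        atomic_words: Sequence[str] = (),
        word_initial_chars: Sequence[str] = (),
    ) -> None:
        self.vocab: List[str] = list(vocab)
        self.merges: List[Tuple[str, str]] = [tuple(m) for m in merges]
        self.atomic_words = frozenset(atomic_words)
        # Characters that can only appear word-initially (role prefixes);
        # together with the atomic words they make word boundaries
        # recoverable from the sub-token stream alone.
        self.word_initial_chars = frozenset(word_initial_chars)
        self.token_to_id: Dict[str, int] = {t: i for i, t in enumerate(self.vocab)}
        if len(self.token_to_id) != len(self.vocab):
            raise CodecError("duplicate entries in vocabulary")
        self._merge_rank = {pair: r for r, pair in enumerate(self.merges)}
        self._word_cache: Dict[str, Tuple[str, ...]] = {}

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    @classmethod
    def train(
        cls,
        corpus: Iterable[str],
        vocab_budget: int,
        atomic_words: Sequence[str] = (),
        word_initial_chars: Sequence[str] = (),
        alphabet: Sequence[str] = (),
        seed: int | None = None,
    ) -> "SubTokenCodec":
        """Train on an iterable of documents (one string per document).

        ``alphabet`` chars are seeded into the base vocabulary even when the
        corpus never uses them, so any well-formed word stays encodable
        (constrained generation must be able to spell every grid cell).
        ``seed`` is accepted for interface uniformity; training is fully
        deterministic and does not consume randomness.
        """
        del seed
        freqs = _word_frequencies(corpus)
        if not freqs:
            raise CodecError("cannot train a codec on an empty corpus")

        atomic = set(atomic_words)
        base_chars = sorted(
            {ch for w in freqs if w not in atomic for ch in w} | set(alphabet)
        )
        vocab: List[str] = list(base_chars) + sorted(atomic)
        if vocab_budget < len(vocab):
            raise CodecError(
                f"vocab budget {vocab_budget} smaller than base alphabet + "
                f"atomic seeds ({len(vocab)})"
            )

        # word types as symbol tuples; atomic words are single symbols
        pieces: Dict[Tuple[str, ...], int] = {}
        for w, f in freqs.items():
            key = (w,) if w in atomic else tuple(w)
            pieces[key] = pieces.get(key, 0) + f

        merges: List[Tuple[str, str]] = []
        while len(vocab) < vocab_budget:
            pair_counts: Counter = Counter()
            for sym, f in pieces.items():
                for a, b in zip(sym, sym[1:]):
                    pair_counts[(a, b)] += f
            if not pair_counts:
                break
            best = max(pair_counts, key=lambda p: (pair_counts[p], _neg_lex(p)))
            merges.append(best)
            vocab.append(best[0] + best[1])
            pieces = {_apply_merge(sym, best): f for sym, f in pieces.items()}

        return cls(vocab, merges, sorted(atomic), sorted(word_initial_chars))

    # ------------------------------------------------------------------
    # encoding / decoding
    # ------------------------------------------------------------------
    def encode_word(self, word: str) -> Tuple[str, ...]:
        """Sub-token strings of one word (merges applied in training order)."""
        cached = self._word_cache.get(word)
        if cached is not None:
            return cached
        if word in self.atomic_words:
            pieces: Tuple[str, ...] = (word,)
        else:
            sym = tuple(word)
            for ch in sym:
                if ch not in self.token_to_id:
                    raise CodecError(f"character {ch!r} not in codec alphabet")
            while len(sym) > 1:
                ranked = [
                    (self._merge_rank[p], i)
                    for i, p in enumerate(zip(sym, sym[1:]))
                    if p in self._merge_rank
                ]
                if not ranked:
                    break
                rank, i = min(ranked)
                pair = self.merges[rank]
                sym = _apply_merge_at(sym, i, pair)
            pieces = sym
        self._word_cache[word] = pieces
        return pieces

    def encode(self, text: str) -> List[int]:
        """Sub-token ids of a whitespace-separated document."""
        ids: List[int] = []
        for w in text.split():
            for piece in self.encode_word(w):
                ids.append(self.token_to_id[piece])
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        """Inverse of :meth:`encode` (single-space separated words)."""
        words: List[str] = []
        current = ""
        for i in ids:
            piece = self.vocab[i]
            starts_word = piece in self.atomic_words or (
                piece and piece[0] in self.word_initial_chars
            )
            if starts_word:
                if current:
                    words.append(current)
                current = piece
            else:
                current += piece
        if current:
            words.append(current)
        return " ".join(words)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "vocab": self.vocab,
            "merges": [list(m) for m in self.merges],
            "atomic_words": sorted(self.atomic_words),
            "word_initial_chars": sorted(self.word_initial_chars),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubTokenCodec":
        return cls(
            d["vocab"],
            [tuple(m) for m in d["merges"]],
            d.get("atomic_words", ()),
            d.get("word_initial_chars", ()),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SubTokenCodec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def __len__(self) -> int:
        return len(self.vocab)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubTokenCodec)
            and self.vocab == other.vocab
            and self.merges == other.merges
            and self.atomic_words == other.atomic_words
        )


def _neg_lex(pair: Tuple[str, str]) -> Tuple:
    # max() key helper: among equal counts prefer lexicographically smallest
    a, b = pair
    return tuple(-ord(c) for c in a + "\x00" + b)


def _apply_merge(sym: Tuple[str, ...], pair: Tuple[str, str]) -> Tuple[str, ...]:
    out: List[str] = []
    i = 0
    n = len(sym)
    merged = pair[0] + pair[1]
    while i < n:
        if i + 1 < n and sym[i] == pair[0] and sym[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(sym[i])
            i += 1
    return tuple(out)


def _apply_merge_at(
    sym: Tuple[str, ...], i: int, pair: Tuple[str, str]
) -> Tuple[str, ...]:
    return sym[:i] + (pair[0] + pair[1],) + sym[i + 2 :]
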