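"""Unigram-language-model subword tokenizer shared by all neural components.

Chemical text is an open-vocabulary domain: systematic nomenclature composes
morphemes ("3-cyano-4-((1-methylethyl)oxy)benzoic acid"), so word-level
vocabularies cannot cover it.  The tokenizer learned here segments text into
variable-length pieces from a fixed-size vocabulary chosen to maximize the
unigram likelihood of the training corpus, with the usual conventions:

* words are marked with a leading "▁" so detokenization is unambiguous;
* encoding picks the highest-likelihood segmentation by Viterbi search;
* characters outside the vocabulary fall back to raw UTF-8 byte pieces, so
  no input is unrepresentable and decode(encode(s)) == s holds for any
  single-spaced text;
* with ``split_digits=False`` (the default) a segmentation boundary is never
  placed inside a run of digits when a whole-run segmentation exists, so
  numbers like "374" stay within one piece instead of per-digit fragments.

One model is trained on the concatenation of source sentences and structured
targets, giving the shared source/target vocabulary that permits tied
embeddings in the sequence-to-sequence models.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError, CorpusTooSmall, InvalidId, VocabTooLarge

__all__ = ["SubwordModel", "train_subword"]

WS = "▁"
PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3
SPECIALS = ("<pad>", "<s>", "</s>", "<unk>")
N_BYTES = 256
FIRST_BYTE_ID = len(SPECIALS)
FIRST_PIECE_ID = FIRST_BYTE_ID + N_BYTES
_BYTE_SCORE = -20.0  # per-byte fallback log-score, below any learned piece
_DIGIT_RUN_RE = re.compile(rf"{WS}?\d+")


def _byte_piece(b: int) -> str:
    return f"<0x{b:02X}>"


def _digit_runs(word: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ch in enumerate(word):
        if ch.isdigit():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(word)))
    return runs


def _interior_digit_positions(word: str) -> set[int]:
    banned = set()
    for start, end in _digit_runs(word):
        banned.update(range(start + 1, end))
    return banned


@dataclass
class SubwordModel:
    """A trained unigram segmentation model with a fixed vocabulary."""

    pieces: list[str]
    scores: list[float]
    vocab_size: int
    split_digits: bool = False
    _piece_ids: dict = field(default_factory=dict, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)
    _max_piece_len: int = 1

    def __post_init__(self):
        if len(self.pieces) != self.vocab_size:
            raise ConfigError("piece list length must equal vocab_size")
        self._piece_ids = {p: i for i, p in enumerate(self.pieces)}
        learned = self.pieces[FIRST_PIECE_ID:]
        self._max_piece_len = max((len(p) for p in learned), default=1)

    # -- encoding ----------------------------------------------------------

    def _viterbi(self, word: str, ban_digit_interior: bool) -> list[int] | None:
        n = len(word)
        banned = _interior_digit_positions(word) if ban_digit_interior else set()
        best = [-math.inf] * (n + 1)
        back: list[tuple[int, list[int]] | None] = [None] * (n + 1)
        best[0] = 0.0
        for i in range(n):
            if best[i] == -math.inf:
                continue
            limit = min(n, i + self._max_piece_len)
            for j in range(i + 1, limit + 1):
                if j < n and j in banned:
                    continue
                pid = self._piece_ids.get(word[i:j])
                if pid is None or pid < FIRST_PIECE_ID:
                    continue
                score = best[i] + self.scores[pid]
                if score > best[j]:
                    best[j] = score
                    back[j] = (i, [pid])
            # byte fallback for a single character
            j = i + 1
            if j == n or j not in banned:
                ids = [self._piece_ids[_byte_piece(b)]
                       for b in word[i].encode("utf-8")]
                score = best[i] + _BYTE_SCORE * len(ids)
                if score > best[j]:
                    best[j] = score
                    back[j] = (i, ids)
        if best[n] == -math.inf:
            return None
        out: list[int] = []
        pos = n
        while pos > 0:
            prev, ids = back[pos]  # type: ignore[misc]
            out[:0] = ids
            pos = prev
        return out

    def _encode_word(self, word: str) -> list[int]:
        cached = self._cache.get(word)
        if cached is None:
            ids = None
            if not self.split_digits:
                ids = self._viterbi(word, ban_digit_interior=True)
            if ids is None:
                ids = self._viterbi(word, ban_digit_interior=False)
            cached = ids
            self._cache[word] = cached
        return list(cached)

    def encode(self, text: str, add_bos: bool = False,
               add_eos: bool = False) -> list[int]:
        ids: list[int] = [BOS_ID] if add_bos else []
        if self.split_digits:
            text = self._isolate_digits(text)
        for word in text.split():
            ids.extend(self._encode_word(WS + word))
        if add_eos:
            ids.append(EOS_ID)
        return ids

    @staticmethod
    def _isolate_digits(text: str) -> str:
        return text  # digits are handled piece-wise during training

    def encode_pieces(self, text: str) -> list[str]:
        return [self.pieces[i] for i in self.encode(text)]

    # -- decoding ----------------------------------------------------------

    def decode(self, ids: Sequence[int]) -> str:
        chunks: list[str] = []
        byte_buffer = bytearray()

        def flush():
            if byte_buffer:
                chunks.append(byte_buffer.decode("utf-8", errors="replace"))
                byte_buffer.clear()

        for i in ids:
            if not 0 <= i < self.vocab_size:
                raise InvalidId(f"id {i} outside vocabulary of {self.vocab_size}")
            if i in (PAD_ID, BOS_ID, EOS_ID):
                continue
            if FIRST_BYTE_ID <= i < FIRST_PIECE_ID:
                byte_buffer.append(i - FIRST_BYTE_ID)
                continue
            flush()
            chunks.append(self.pieces[i] if i != UNK_ID else "")
        flush()
        return "".join(chunks).replace(WS, " ").lstrip(" ")

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "vocab_size": self.vocab_size,
            "split_digits": self.split_digits,
            "pieces": self.pieces,
            "scores": self.scores,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False)

    def save_piece_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for piece, score in zip(self.pieces, self.scores):
                fh.write(f"{piece}\t{score:.6f}\n")

    @classmethod
    def load(cls, path) -> "SubwordModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            pieces=payload["pieces"], scores=payload["scores"],
            vocab_size=payload["vocab_size"],
            split_digits=payload["split_digits"],
        )

    def mean_pieces_per_word(self, lines: Iterable[str]) -> float:
        pieces = words = 0
        for line in lines:
            toks = line.split()
            words += len(toks)
            pieces += len(self.encode(line))
        return pieces / max(words, 1)


def _word_counts(corpus: Iterable[str], split_digits: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for line in corpus:
        for word in line.split():
            marked = WS + word
            counts[marked] = counts.get(marked, 0) + 1
    return counts


def _candidate_counts(
    words: dict[str, int], max_len: int, split_digits: bool
) -> dict[str, int]:
    cand: dict[str, int] = {}
    for word, freq in words.items():
        n = len(word)
        # without digit splitting, pieces may not start or end strictly
        # inside a run of digits, so runs stay whole
        banned = set() if split_digits else _interior_digit_positions(word)
        for i in range(n):
            if i in banned:
                continue
            for j in range(i + 1, min(n, i + max_len) + 1):
                if j in banned:
                    continue
                piece = word[i:j]
                if split_digits and len(piece) > 1 and any(
                        c.isdigit() for c in piece):
                    continue
                if WS in piece[1:]:
                    continue
                cand[piece] = cand.get(piece, 0) + freq
    return cand


def _viterbi_counts(
    words: dict[str, int], scores: dict[str, float], max_len: int
) -> tuple[dict[str, float], float]:
    """Hard-EM expectation step: best-path piece counts over unique words."""
    counts: dict[str, float] = {}
    loglik = 0.0
    for word, freq in words.items():
        n = len(word)
        best = [-math.inf] * (n + 1)
        back = [0] * (n + 1)
        best[0] = 0.0
        for i in range(n):
            if best[i] == -math.inf:
                continue
            for j in range(i + 1, min(n, i + max_len) + 1):
                s = scores.get(word[i:j])
                if s is None:
                    continue
                if best[i] + s > best[j]:
                    best[j] = best[i] + s
                    back[j] = i
        if best[n] == -math.inf:
            continue  # unreachable only if a char was dropped; bytes at encode
        loglik += best[n] * freq
        pos = n
        while pos > 0:
            prev = back[pos]
            piece = word[prev:pos]
            counts[piece] = counts.get(piece, 0.0) + freq
            pos = prev
    return counts, loglik


def train_subword(
    corpus: Iterable[str],
    vocab_size: int,
    split_digits: bool = False,
    max_piece_len: int = 10,
    em_iterations: int = 3,
    prune_fraction: float = 0.25,
    seed_factor: int = 6,
) -> SubwordModel:
    """Train a unigram subword model of exactly ``vocab_size`` pieces.

    The vocabulary budget includes 4 control pieces and 256 byte-fallback
    pieces.  Training is deterministic for a fixed corpus and settings:
    seed candidates are frequent substrings, expectation steps use Viterbi
    counts, and the piece inventory is pruned by likelihood contribution
    until the budget is met.
    """
    lines = list(corpus)
    total_chars = sum(len(l) for l in lines)
    if total_chars < 1000:
        raise CorpusTooSmall(
            f"corpus has {total_chars} characters; at least 1000 required")
    if vocab_size < 100:
        raise ConfigError("vocab_size must be >= 100")
    budget = vocab_size - FIRST_PIECE_ID
    if budget < 1:
        raise ConfigError(
            f"vocab_size must exceed {FIRST_PIECE_ID} reserved pieces")

    words = _word_counts(lines, split_digits)
    cand = _candidate_counts(words, max_piece_len, split_digits)
    single_chars = {p for p in cand if len(p) == 1}
    # complete digit runs are kept whole (never pruned) unless digit
    # splitting was requested; candidate generation guarantees any piece
    # matching ▁?\d+ covers a full run
    protected = set() if split_digits else {
        p for p in cand if len(p) > 1 and _DIGIT_RUN_RE.fullmatch(p)}
    if len(single_chars) + len(protected) > budget:
        raise VocabTooLarge(
            f"corpus alphabet plus digit runs "
            f"({len(single_chars) + len(protected)}) exceeds piece budget "
            f"({budget}); increase vocab_size")
    if len(cand) < budget:
        raise VocabTooLarge(
            f"only {len(cand)} candidate pieces attainable, "
            f"{budget} requested")

    # seed inventory: all single chars + most frequent multi-char substrings,
    # ranked by count * length (likelihood-saving proxy)
    multis = sorted(
        (p for p in cand if len(p) > 1 and p not in protected),
        key=lambda p: (-cand[p] * len(p), p),
    )[: max(budget * seed_factor, budget) - len(single_chars) - len(protected)]
    inventory = dict.fromkeys(sorted(single_chars) + sorted(protected) + multis)
    total = sum(cand[p] for p in inventory)
    scores = {p: math.log(cand[p] / total) for p in inventory}

    while True:
        for _ in range(em_iterations):
            counts, _ = _viterbi_counts(words, scores, max_piece_len)
            # keep chars and whole digit runs alive with a floor count
            for p in single_chars | protected:
                counts[p] = counts.get(p, 0.0) + 0.1
            kept = {p: c for p, c in counts.items() if p in scores and c > 0}
            total = sum(kept.values())
            scores = {p: math.log(c / total) for p, c in kept.items()}
        n_current = len(scores)
        if n_current <= budget:
            break
        # prune lowest-count multi-char pieces
        counts, _ = _viterbi_counts(words, scores, max_piece_len)
        multi = [p for p in scores if len(p) > 1 and p not in protected]
        multi.sort(key=lambda p: (counts.get(p, 0.0), p))
        n_drop = min(
            max(1, int(len(multi) * prune_fraction)),
            n_current - budget,
        )
        for p in multi[:n_drop]:
            del scores[p]

    # top up with unused candidates if pruning overshot below budget
    if len(scores) < budget:
        fill = sorted(
            (p for p in cand if p not in scores),
            key=lambda p: (-cand[p] * len(p), p),
        )
        floor = min(scores.values()) - 1.0
        for p in fill[: budget - len(scores)]:
            scores[p] = floor
    if len(scores) != budget:
        raise VocabTooLarge(
            f"attainable pieces ({len(scores)}) below requested budget "
            f"({budget})")

    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    pieces = list(SPECIALS) + [_byte_piece(b) for b in range(N_BYTES)]
    piece_scores = [0.0] * len(pieces)
    for p, s in ordered:
        pieces.append(p)
        piece_scores.append(s)
    return SubwordModel(
        pieces=pieces, scores=piece_scores, vocab_size=vocab_size,
        split_digits=split_digits,
    )
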