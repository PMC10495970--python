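"""Evaluation formulas: baselines, classification metrics, BLEU, ROUGE-L.

Conventions used throughout:

* the random baseline is the accuracy of a label-frequency-matched random
  labeler, ``sum_i P(y_i)^2``; the majority baseline is ``max_i P(y_i)``;
* classification metrics treat class 1 as positive and return 0 (with a
  flag in :class:`ClassificationReport`) when a denominator is zero;
* BLEU is corpus-level: modified (clipped) n-gram counts up to N=4 are
  pooled over all segments, combined by a uniform-weight geometric mean and
  multiplied by the brevity penalty ``e^(1 - r/c)`` for ``c <= r`` where r
  and c are corpus-total reference/hypothesis token counts.  No smoothing by
  default: any zero precision gives BLEU 0;
* ROUGE-L uses the longest common subsequence with beta = 1; the corpus
  score is the arithmetic mean of per-pair scores;
* exact-match accuracy compares strings after surface normalization
  (collapsed whitespace, '; ' separators, single trailing period).

Tokenization for the text metrics is whitespace splitting on the normalized
strings; the structured action language is whitespace-friendly by design.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .actionlang import normalize
from .errors import EmptyCorpus, EmptyLabels, EmptyText, LengthMismatch

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "BleuReport",
    "random_baseline",
    "majority_baseline",
    "confusion_counts",
    "classification_metrics",
    "corpus_bleu",
    "rouge_l",
    "rouge_l_corpus",
    "exact_match_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    undefined: tuple[str, ...] = ()  # metrics whose denominator was zero


@dataclass(frozen=True)
class BleuReport:
    precisions: tuple[float, float, float, float]
    brevity_penalty: float
    bleu: float
    ref_len: int
    hyp_len: int


def _class_probs(labels: Sequence) -> dict:
    if len(labels) == 0:
        raise EmptyLabels("labels must be non-empty")
    counts = Counter(labels)
    n = len(labels)
    return {k: v / n for k, v in counts.items()}


def random_baseline(labels: Sequence) -> float:
    """Accuracy of a class-frequency-matched random labeler: sum of P(y)^2."""
    return sum(p * p for p in _class_probs(labels).values())


def majority_baseline(labels: Sequence) -> float:
    """Accuracy of always predicting the most frequent class: max P(y)."""
    return max(_class_probs(labels).values())


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise LengthMismatch(f"{len(y_true)} labels vs {len(y_pred)} predictions")
    for y in (*y_true, *y_pred):
        if y not in (0, 1):
            raise ValueError(f"labels must be binary, got {y!r}")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ClassificationReport:
    """Accuracy, precision, recall and F1 for binary labels (positive = 1)."""
    c = confusion_counts(y_true, y_pred)
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        counts=c, undefined=tuple(undefined),
    )


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def corpus_bleu(
    references: Sequence[str],
    hypotheses: Sequence[str],
    max_n: int = 4,
    smooth_eps: float = 0.0,
) -> BleuReport:
    """Corpus-level BLEU with clipped n-gram precisions and brevity penalty.

    One reference per hypothesis.  ``smooth_eps`` (off by default) floors the
    matched counts to keep log(p_n) finite; the default policy scores 0 when
    any pooled precision is 0.
    """
    if len(references) != len(hypotheses):
        raise LengthMismatch(
            f"{len(references)} references vs {len(hypotheses)} hypotheses")
    if len(references) == 0:
        raise EmptyCorpus("no segments to score")
    matched = [0] * max_n
    total = [0] * max_n
    ref_len = hyp_len = 0
    for ref, hyp in zip(references, hypotheses):
        ref_tokens = ref.split()
        hyp_tokens = hyp.split()
        ref_len += len(ref_tokens)
        hyp_len += len(hyp_tokens)
        for n in range(1, max_n + 1):
            hyp_counts = _ngrams(hyp_tokens, n)
            if not hyp_counts:
                continue
            ref_counts = _ngrams(ref_tokens, n)
            total[n - 1] += sum(hyp_counts.values())
            matched[n - 1] += sum(
                min(c, ref_counts.get(g, 0)) for g, c in hyp_counts.items())
    precisions = []
    for n in range(max_n):
        if total[n] == 0:
            precisions.append(0.0)
        else:
            num = matched[n] if matched[n] > 0 else smooth_eps
            precisions.append(num / total[n])
    if hyp_len == 0 or any(p == 0.0 for p in precisions):
        bp = 0.0 if hyp_len == 0 else _brevity_penalty(ref_len, hyp_len)
        return BleuReport(tuple(precisions), bp, 0.0, ref_len, hyp_len)
    bp = _brevity_penalty(ref_len, hyp_len)
    geo = math.exp(sum(math.log(p) for p in precisions) / max_n)
    return BleuReport(tuple(precisions), bp, bp * geo, ref_len, hyp_len)


def _brevity_penalty(ref_len: int, hyp_len: int) -> float:
    if hyp_len > ref_len:
        return 1.0
    return math.exp(1.0 - ref_len / hyp_len)


def _lcs_length(a: list[str], b: list[str]) -> int:
    # O(len(a) * len(b)) dynamic program, one rolling row
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            if x == y:
                cur.append(prev[j - 1] + 1)
            else:
                cur.append(max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_l(reference: str, hypothesis: str, beta: float = 1.0) -> float:
    """ROUGE-L: LCS-based F-measure of one (reference, hypothesis) pair."""
    ref_tokens = reference.split()
    hyp_tokens = hypothesis.split()
    if not ref_tokens or not hyp_tokens:
        raise EmptyText("both texts must contain at least one token")
    lcs = _lcs_length(ref_tokens, hyp_tokens)
    if lcs == 0:
        return 0.0
    precision = lcs / len(hyp_tokens)
    recall = lcs / len(ref_tokens)
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def rouge_l_corpus(
    references: Sequence[str], hypotheses: Sequence[str], beta: float = 1.0
) -> float:
    """Arithmetic mean of per-pair ROUGE-L scores."""
    if len(references) != len(hypotheses):
        raise LengthMismatch(
            f"{len(references)} references vs {len(hypotheses)} hypotheses")
    if len(references) == 0:
        raise EmptyCorpus("no segments to score")
    return sum(rouge_l(r, h, beta) for r, h in zip(references, hypotheses)) / len(
        references)


def exact_match_accuracy(
    references: Sequence[str], hypotheses: Sequence[str]
) -> float:
    """Fraction of hypothesis strings identical to references after
    surface normalization (whitespace collapse, trailing period)."""
    if len(references) != len(hypotheses):
        raise LengthMismatch(
            f"{len(references)} references vs {len(hypotheses)} hypotheses")
    if len(references) == 0:
        raise EmptyCorpus("no segments to score")
    matches = sum(
        1 for r, h in zip(references, hypotheses)
        if normalize(r) == normalize(h))
    return matches / len(references)
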