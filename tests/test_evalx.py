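"""Evaluation formulas against hand counts and independent oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from synthaction import evalx
from synthaction.errors import (EmptyCorpus, EmptyLabels, EmptyText,
                                LengthMismatch)


# --------------------------------------------------------------------------
# Independent oracles, written against the metric definitions only (never
# calling the package implementation).


def oracle_bleu(references, hypotheses, max_n=4):
    """Corpus BLEU re-derived from the definition: pooled clipped n-gram
    counts, uniform-weight geometric mean, brevity penalty on corpus totals."""
    clipped = Counter()
    totals = Counter()
    r = c = 0
    for ref, hyp in zip(references, hypotheses):
        ref_t, hyp_t = ref.split(), hyp.split()
        r += len(ref_t)
        c += len(hyp_t)
        for n in range(1, max_n + 1):
            hyp_ngrams = Counter(
                tuple(hyp_t[i:i + n]) for i in range(len(hyp_t) - n + 1))
            ref_ngrams = Counter(
                tuple(ref_t[i:i + n]) for i in range(len(ref_t) - n + 1))
            totals[n] += sum(hyp_ngrams.values())
            clipped[n] += sum((hyp_ngrams & ref_ngrams).values())
    precisions = [clipped[n] / totals[n] if totals[n] else 0.0
                  for n in range(1, max_n + 1)]
    if c == 0 or any(p == 0 for p in precisions):
        return 0.0
    bp = 1.0 if c > r else math.exp(1 - r / c)
    return bp * math.exp(sum(math.log(p) for p in precisions) / max_n)


def oracle_lcs(a, b):
    """Longest common subsequence by exhaustive subsequence enumeration."""
    best = 0
    for k in range(len(a), best, -1):
        for combo in itertools.combinations(a, k):
            sub = list(combo)
            it = iter(b)
            if all(tok in it for tok in sub):
                return k
    return 0


def _random_corpus(rng, n_segments, vocab=8, max_len=12):
    alphabet = [f"w{i}" for i in range(vocab)]
    refs, hyps = [], []
    for _ in range(n_segments):
        ref = [alphabet[rng.integers(vocab)]
               for _ in range(rng.integers(1, max_len))]
        # hypothesis: a noisy copy so n-gram overlap is nontrivial
        hyp = [t if rng.random() > 0.3 else alphabet[rng.integers(vocab)]
               for t in ref]
        if rng.random() < 0.3 and len(hyp) > 1:
            hyp = hyp[:-1]
        refs.append(" ".join(ref))
        hyps.append(" ".join(hyp))
    return refs, hyps


class TestBaselines:
    def test_imbalanced_two_class(self):
        labels = [1] * 336 + [0] * 664
        random = evalx.random_baseline(labels)
        assert math.floor(random * 1000) / 1000 == 0.553
        assert evalx.majority_baseline(labels) == pytest.approx(0.664)

    def test_balanced_binary(self):
        labels = [0, 1] * 50
        assert evalx.random_baseline(labels) == pytest.approx(0.5)
        assert evalx.majority_baseline(labels) == pytest.approx(0.5)

    def test_single_class(self):
        assert evalx.random_baseline([1, 1, 1]) == 1.0
        assert evalx.majority_baseline([0, 0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyLabels):
            evalx.random_baseline([])

    def test_random_never_exceeds_majority(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            labels = list(rng.integers(0, k, size=int(rng.integers(1, 60))))
            assert evalx.random_baseline(labels) <= evalx.majority_baseline(
                labels) + 1e-12


class TestClassificationMetrics:
    def test_hand_counted_confusion(self):
        rep = evalx.classification_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.counts.tp == 1 and rep.counts.fn == 1

    def test_perfect_and_inverted(self):
        y = [1, 0, 1, 0, 1]
        perfect = evalx.classification_metrics(y, y)
        assert (perfect.accuracy, perfect.precision, perfect.recall,
                perfect.f1) == (1.0, 1.0, 1.0, 1.0)
        inverted = evalx.classification_metrics(y, [1 - v for v in y])
        assert inverted.accuracy == inverted.precision == inverted.recall == 0.0
        assert "f1" in inverted.undefined

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            evalx.classification_metrics([1, 0], [1])


class TestBleu:
    def test_identity_scores_one(self):
        refs = ["ADD water ; STIR at 25 °C", "FILTER keep precipitate ."]
        report = evalx.corpus_bleu(refs, refs)
        assert report.bleu == pytest.approx(1.0)
        assert report.brevity_penalty == 1.0

    def test_hand_computed_brevity_penalty(self):
        report = evalx.corpus_bleu(["a b c d e"], ["a b c d"])
        assert report.precisions == (1.0, 1.0, 1.0, 1.0)
        assert report.brevity_penalty == pytest.approx(math.exp(1 - 5 / 4))
        assert report.bleu == pytest.approx(math.exp(1 - 5 / 4))

    def test_disjoint_tokens_score_zero(self):
        assert evalx.corpus_bleu(["a b c d"], ["e f g h"]).bleu == 0.0

    def test_zero_precision_policy_without_smoothing(self):
        # unigram overlap but no common 4-gram -> BLEU 0
        report = evalx.corpus_bleu(["a b c d e"], ["a x b y c"])
        assert report.bleu == 0.0

    def test_matches_independent_oracle_on_200_corpora(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            refs, hyps = _random_corpus(rng, int(rng.integers(1, 12)))
            ours = evalx.corpus_bleu(refs, hyps).bleu
            theirs = oracle_bleu(refs, hyps)
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_errors(self):
        with pytest.raises(EmptyCorpus):
            evalx.corpus_bleu([], [])
        with pytest.raises(LengthMismatch):
            evalx.corpus_bleu(["a"], ["a", "b"])


class TestRougeL:
    def test_identity(self):
        assert evalx.rouge_l("A B C", "A B C") == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # LCS("A B C D", "A C D E") = "A C D" (3); P = R = 0.75
        assert evalx.rouge_l("A B C D", "A C D E") == pytest.approx(0.75)

    def test_disjoint(self):
        assert evalx.rouge_l("A B", "C D") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyText):
            evalx.rouge_l("", "A")

    def test_dp_matches_bruteforce_enumeration(self):
        alphabet = ["x", "y", "z"]
        # exhaustive on short strings, seeded sample up to length 8
        short = [list(t) for n in range(1, 4)
                 for t in itertools.product(alphabet, repeat=n)]
        for a in short:
            for b in short:
                lcs = oracle_lcs(a, b)
                expected = (0.0 if lcs == 0 else
                            2 * (lcs / len(a)) * (lcs / len(b))
                            / (lcs / len(a) + lcs / len(b)))
                got = evalx.rouge_l(" ".join(a), " ".join(b))
                assert got == pytest.approx(expected)
        rng = np.random.default_rng(8)
        for _ in range(2000):
            a = [alphabet[rng.integers(3)]
                 for _ in range(rng.integers(1, 9))]
            b = [alphabet[rng.integers(3)]
                 for _ in range(rng.integers(1, 9))]
            lcs = oracle_lcs(a, b)
            expected = (0.0 if lcs == 0 else
                        2 * (lcs / len(a)) * (lcs / len(b))
                        / (lcs / len(a) + lcs / len(b)))
            assert evalx.rouge_l(" ".join(a), " ".join(b)) == pytest.approx(
                expected)

    def test_corpus_mean(self):
        score = evalx.rouge_l_corpus(["a b", "c d"], ["a b", "x y"])
        assert score == pytest.approx(0.5)


class TestExactMatch:
    def test_identity_and_mismatch(self):
        assert evalx.exact_match_accuracy(["ADD water."], ["ADD water."]) == 1.0
        assert evalx.exact_match_accuracy(
            ["ADD water.", "FILTER."], ["ADD water.", "STIR."]) == 0.5

    def test_missing_final_period_counts_as_match(self):
        assert evalx.exact_match_accuracy(["ADD water."], ["ADD water"]) == 1.0

    def test_whitespace_normalized(self):
        assert evalx.exact_match_accuracy(
            ["ADD  water ;  STIR."], ["ADD water; STIR."]) == 1.0
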