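"""Classifier and seq2seq training: early stopping, importance weighting,
decoding contracts.  Networks here are deliberately tiny."""

import numpy as np
import pytest

from synthaction import evalx, nn, synthcorpus as sc
from synthaction.errors import (ConfigError, DataError, EmptyInput,
                                TokenizerMismatch)
from synthaction.models import (ClassifierConfig, Seq2SeqConfig,
                                PAPER_CLASSIFIER_PRESETS,
                                PAPER_TRANSFORMER_CLF_PRESETS,
                                PAPER_SEQ2SEQ_PRESETS,
                                PAPER_TRANSFORMER_S2S_PRESET,
                                desk_classifier_config, desk_seq2seq_config,
                                paper_classifier_config, paper_seq2seq_config,
                                predict_label, predict_proba,
                                train_classifier, train_seq2seq, translate,
                                translate_batch)
from synthaction.tokenize import train_subword


@pytest.fixture(scope="module")
def clf_data():
    records = sc.generate_classification_set(400, seed=88)
    corpus = [r.text for r in records]
    tok = train_subword(corpus, 600)
    train, val, test = sc.split(records, seed=88)
    return train, val, test, tok


@pytest.fixture(scope="module")
def tiny_clf_cfg():
    return desk_classifier_config(
        vocab_size=600, seed=0, arch="gru", recurrent_size=8, max_epochs=6,
        max_len=32, batch_size=32, dropout=0.0)


@pytest.fixture(scope="module")
def trained_classifier(clf_data, tiny_clf_cfg):
    train, val, _, tok = clf_data
    return train_classifier(train, val, tok, tiny_clf_cfg)


@pytest.fixture(scope="module")
def s2s_setup(small_pairs, small_tokenizer):
    pairs = small_pairs[:64]
    cfg = desk_seq2seq_config(
        vocab_size=600, seed=0, embedding_dim=64, ff_size=128, batch_size=16,
        max_epochs=40, patience=40, learning_rate=2e-3)
    model = train_seq2seq(pairs, pairs, small_tokenizer, cfg)
    return pairs, model


class TestConfigs:
    def test_paper_recurrent_presets_load_and_validate(self):
        for row in PAPER_CLASSIFIER_PRESETS:
            cfg = paper_classifier_config(row)
            assert cfg.importance > 0 and 0 <= cfg.dropout < 1
            assert cfg.batch_size == 64 and cfg.patience == 7
        bilstm16k = paper_classifier_config(PAPER_CLASSIFIER_PRESETS[15])
        assert (bilstm16k.arch, bilstm16k.vocab_size) == ("bilstm", 16000)
        assert bilstm16k.embedding_dim == 8
        assert bilstm16k.dropout == pytest.approx(0.639)
        assert bilstm16k.recurrent_size == 16 and bilstm16k.ff_size == 8
        assert bilstm16k.importance == pytest.approx(2.493)
        assert bilstm16k.optimizer == "rmsprop"

    def test_paper_transformer_clf_presets_validate(self):
        for vocab, emb, batch, heads, layers, imp, opt in \
                PAPER_TRANSFORMER_CLF_PRESETS:
            cfg = ClassifierConfig(
                arch="transformer_encoder", vocab_size=vocab,
                embedding_dim=emb, batch_size=batch, heads=heads,
                attention_layers=layers, importance=imp, optimizer=opt)
            assert cfg.embedding_dim % cfg.heads == 0

    def test_paper_seq2seq_presets_validate(self):
        for row in PAPER_SEQ2SEQ_PRESETS:
            cfg = paper_seq2seq_config(row)
            assert cfg.vocab_size in (8000, 16000, 32000)
        full = Seq2SeqConfig(vocab_size=32000, **PAPER_TRANSFORMER_S2S_PRESET)
        assert full.stacks == 6 and full.heads == 8 and full.ff_size == 2048
        assert full.lr == pytest.approx(0.005)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierConfig(dropout=1.0)
        with pytest.raises(ConfigError):
            ClassifierConfig(importance=0.0)
        with pytest.raises(ConfigError):
            ClassifierConfig(arch="cnn")
        with pytest.raises(ConfigError):
            Seq2SeqConfig(beam_width=0)
        with pytest.raises(ConfigError):
            Seq2SeqConfig(max_tgt_len=0)


class TestClassifierTraining:
    def test_beats_majority_on_validation(self, clf_data, trained_classifier):
        _, _, test, _ = clf_data
        labels = [r.label for r in test]
        probs = predict_proba(trained_classifier, [r.text for r in test])
        acc = float(((probs >= 0.5).astype(int) == np.array(labels)).mean())
        assert acc > evalx.majority_baseline(labels)

    def test_single_class_training_rejected(self, clf_data, tiny_clf_cfg):
        train, val, _, tok = clf_data
        ones = [r for r in train if r.label == 1]
        with pytest.raises(DataError):
            train_classifier(ones, val, tok, tiny_clf_cfg)

    def test_empty_split_rejected(self, clf_data, tiny_clf_cfg):
        train, _, _, tok = clf_data
        with pytest.raises(DataError):
            train_classifier(train, [], tok, tiny_clf_cfg)

    def test_tokenizer_mismatch_rejected(self, clf_data):
        train, val, _, tok = clf_data
        cfg = desk_classifier_config(vocab_size=999)
        with pytest.raises(TokenizerMismatch):
            train_classifier(train, val, tok, cfg)

    def test_history_length_matches_stopped_epoch(self, trained_classifier):
        assert len(trained_classifier.history) == trained_classifier.stopped_epoch

    def test_predict_label_contract(self, trained_classifier):
        prob, label = predict_label(trained_classifier,
                                    "Water was added to the mixture.")
        assert 0.0 <= prob <= 1.0 and label in (0, 1)
        prob2, label2 = predict_label(
            trained_classifier, "Water was added to the mixture.",
            threshold=1.0)
        assert label2 == (1 if prob2 == 1.0 else 0)

    def test_training_reproducible_for_fixed_seed(self, clf_data,
                                                  tiny_clf_cfg):
        train, val, _, tok = clf_data
        a = train_classifier(train[:80], val[:40], tok, tiny_clf_cfg)
        b = train_classifier(train[:80], val[:40], tok, tiny_clf_cfg)
        assert a.history == b.history

    def test_importance_increases_positive_recall(self, clf_data):
        """On an imbalanced set, recall of the positive class is
        non-decreasing in the importance factor (averaged over 5 seeds)."""
        train, val, test, tok = clf_data
        labels = np.array([r.label for r in test])
        mean_recall = {}
        for importance in (0.5, 3.0):
            recalls = []
            for seed in range(5):
                cfg = desk_classifier_config(
                    vocab_size=600, seed=seed, arch="gru", recurrent_size=8,
                    max_epochs=2, max_len=32, batch_size=32, dropout=0.0,
                    importance=importance)
                model = train_classifier(train, val, tok, cfg)
                probs = predict_proba(model, [r.text for r in test])
                rep = evalx.classification_metrics(
                    list(labels), list((probs >= 0.5).astype(int)))
                recalls.append(rep.recall)
            mean_recall[importance] = float(np.mean(recalls))
        assert mean_recall[3.0] >= mean_recall[0.5]


class TestEarlyStopping:
    def test_stops_patience_epochs_after_best(self, clf_data):
        train, val, _, tok = clf_data
        cfg = desk_classifier_config(
            vocab_size=600, seed=1, arch="gru", recurrent_size=8,
            max_epochs=40, max_len=32, batch_size=32, dropout=0.0, patience=3)
        model = train_classifier(train, val, tok, cfg)
        if model.stopped_epoch < cfg.max_epochs:  # stopped early
            assert model.stopped_epoch - model.best_epoch == cfg.patience
        metrics = [h["val_metric"] for h in model.history]
        # restored weights correspond to the best epoch
        assert metrics[model.best_epoch - 1] == max(metrics)


class TestGradientSanity:
    @pytest.mark.parametrize("arch", ["gru", "lstm", "bilstm",
                                      "transformer_encoder"])
    def test_classifier_loss_decreases_after_one_epoch(self, clf_data, arch):
        train, val, _, tok = clf_data
        cfg = desk_classifier_config(
            vocab_size=600, seed=3, arch=arch, recurrent_size=8,
            embedding_dim=8, max_epochs=1, max_len=24, batch_size=32,
            dropout=0.0)
        model = train_classifier(train[:128], val[:64], tok, cfg)
        first_loss = model.history[0]["train_loss"]
        # loss at initialization for balanced-ish binary data is ~log(2)
        assert first_loss < np.log(2) * 1.6

    @pytest.mark.parametrize("arch", ["rnn", "birnn", "transformer"])
    def test_seq2seq_loss_decreases(self, small_pairs, small_tokenizer, arch):
        cfg = desk_seq2seq_config(
            vocab_size=600, seed=3, arch=arch, embedding_dim=32, ff_size=64,
            encoder_size=32, decoder_size=32, batch_size=16, max_epochs=2,
            patience=2)
        model = train_seq2seq(small_pairs[:64], small_pairs[:16],
                              small_tokenizer, cfg)
        losses = [h["train_loss"] for h in model.history]
        assert losses[-1] < losses[0]
        assert losses[0] < np.log(cfg.vocab_size) * 1.5  # sane initialization


class TestSeq2Seq:
    def test_memorizes_small_training_set(self, s2s_setup):
        pairs, model = s2s_setup
        hyps = translate_batch(model, [p.sentence for p in pairs])
        exact = sum(h == p.structured for h, p in zip(hyps, pairs))
        assert exact >= 0.95 * len(pairs)

    def test_greedy_decoding_deterministic(self, s2s_setup):
        pairs, model = s2s_setup
        a = translate(model, pairs[0].sentence)
        b = translate(model, pairs[0].sentence)
        assert a == b

    def test_beam_returns_wellformed_output(self, s2s_setup):
        pairs, model = s2s_setup
        out = translate(model, pairs[0].sentence, decoding="beam")
        assert isinstance(out, str) and out

    def test_empty_sentence_rejected(self, s2s_setup):
        _, model = s2s_setup
        with pytest.raises(EmptyInput):
            translate(model, "   ")

    def test_empty_pairs_rejected(self, small_pairs, small_tokenizer):
        cfg = desk_seq2seq_config(vocab_size=600)
        with pytest.raises(DataError):
            train_seq2seq([], small_pairs[:4], small_tokenizer, cfg)

    def test_checkpoint_save(self, s2s_setup, tmp_path):
        _, model = s2s_setup
        model.save(tmp_path / "ckpt")
        assert (tmp_path / "ckpt" / "config.json").exists()
        assert (tmp_path / "ckpt" / "weights.npz").exists()
        assert (tmp_path / "ckpt" / "history.json").exists()
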