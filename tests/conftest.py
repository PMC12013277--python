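"""Shared fixtures.

The expensive artifact — a test-profile classifier trained on the default
synthetic corpus (2,000 windows per class, motif strength 0.8) — is built
once per session and shared between the learning-performance tests and the
end-to-end pipeline tests, which specify the same study conditions.
Pretraining is label-free, so the label-shuffled control fine-tunes a clone
of the same pretrained encoder.
"""

from __future__ import annotations

import numpy as np
import pytest

from selenoscan.fixtures import SimConfig, generate_synthetic_corpus
from selenoscan.model import (
    ModelConfig,
    evaluate_classifier,
    finetune_classifier,
    pretrain_mlm,
    score_windows,
)
from selenoscan.encode import build_vocab

SESSION_SEED = 20240901


def split_corpus(pos, neg, seed):
    """Shuffle and split a two-class window corpus 50/25/25."""
    rng = np.random.default_rng(seed)
    seqs = list(pos) + list(neg)
    labels = np.array([1] * len(pos) + [0] * len(neg))
    order = rng.permutation(len(seqs))
    seqs = [seqs[i] for i in order]
    labels = labels[order]
    n_tr, n_va = int(0.5 * len(seqs)), int(0.25 * len(seqs))
    return (
        (seqs[:n_tr], labels[:n_tr]),
        (seqs[n_tr : n_tr + n_va], labels[n_tr : n_tr + n_va]),
        (seqs[n_tr + n_va :], labels[n_tr + n_va :]),
    )


def run_learning_experiment(seed):
    """Pretrain + fine-tune on the default synthetic corpus, plus a
    label-shuffled control; returns classifier and held-out metrics."""
    sim = SimConfig(seed=seed)
    pos, neg = generate_synthetic_corpus(sim)
    (tr_s, tr_y), (va_s, va_y), (te_s, te_y) = split_corpus(pos, neg, seed)
    cfg = ModelConfig.test_profile(seed=seed)
    vocab = build_vocab(cfg.k)
    pretrain_log: list[dict] = []
    encoder = pretrain_mlm(tr_s, cfg, vocab, log=pretrain_log)

    clf = finetune_classifier(encoder.clone(), tr_s, tr_y, va_s, va_y, cfg, vocab)
    metrics = evaluate_classifier(score_windows(clf, te_s), te_y)

    rng = np.random.default_rng(seed + 1)
    tr_y_shuf = tr_y[rng.permutation(len(tr_y))]
    va_y_shuf = va_y[rng.permutation(len(va_y))]
    clf_shuf = finetune_classifier(
        encoder.clone(), tr_s, tr_y_shuf, va_s, va_y_shuf, cfg, vocab
    )
    shuffled = evaluate_classifier(score_windows(clf_shuf, te_s), te_y)

    return {
        "sim": sim,
        "classifier": clf,
        "metrics": metrics,
        "shuffled_metrics": shuffled,
        "pretrain_log": pretrain_log,
        "splits": ((tr_s, tr_y), (va_s, va_y), (te_s, te_y)),
    }


@pytest.fixture(scope="session")
def learning_run():
    return run_learning_experiment(SESSION_SEED)


@pytest.fixture(scope="session")
def trained_classifier(learning_run):
    return learning_run["classifier"]


@pytest.fixture(scope="session")
def tiny_arch():
    """A miniature encoder architecture for unit tests of the nn module."""
    from selenoscan.nn import ArchConfig

    return ArchConfig(
        vocab_size=21, max_len=12, embed_dim=16, n_layers=2, n_heads=2,
        intermediate_dim=32, dropout=0.0, attn_dropout=0.0,
    )
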