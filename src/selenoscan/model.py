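"""Training and evaluation of the Sec-TGA window classifier.

The classifier distinguishes windows downstream of a selenocysteine-encoding
TGA (positive) from windows downstream of a genuine stop-TGA (negative).  It
is a BERT-style encoder over overlapping k-mer tokens, pretrained with a
masked-token objective on the unlabeled training windows and then fine-tuned
with a CLS softmax head; the epoch with the highest validation accuracy is
retained.

Two scale profiles are provided.  ``paper`` is the published architecture
(768-dim embeddings, 6 layers, 6 heads, 2048-unit intermediate layers,
dropout 0.2; pretraining batch 32 for 3 epochs; fine-tuning 10 epochs with
AdamW, batch 128, learning rate 1e-6).  ``test`` is a scaled-down profile
(2 layers, 64 dims, 4 heads, intermediate 256, learning rate 1e-3, 5
fine-tuning epochs) for CI-scale corpora; it changes sizes and the learning
rate only, never the contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .encode import MASK_ID, Vocab, build_vocab, encode_batch, max_len_for
from .nn import AdamW, ArchConfig, BertEncoder, make_mlm_batch


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + training hyperparameters for one (L, k) model."""

    window_len: int = 300
    k: int = 3
    embed_dim: int = 768
    n_layers: int = 6
    n_heads: int = 6
    intermediate_dim: int = 2048
    dropout: float = 0.2
    attn_dropout: float = 0.2
    pretrain_epochs: int = 3
    pretrain_batch: int = 32
    pretrain_lr: float = 1e-4
    finetune_epochs: int = 10
    finetune_batch: int = 128
    learning_rate: float = 1e-6
    weight_decay: float = 0.01
    seed: int = 0
    profile: str = "paper"

    def __post_init__(self) -> None:
        for name in ("embed_dim", "n_layers", "n_heads", "intermediate_dim",
                     "pretrain_epochs", "pretrain_batch", "finetune_epochs",
                     "finetune_batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def max_len(self) -> int:
        return max_len_for(self.window_len, self.k)

    @classmethod
    def paper_profile(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def test_profile(cls, **overrides) -> "ModelConfig":
        """Scaled-down profile for small synthetic corpora on one CPU."""
        defaults = dict(
            embed_dim=64,
            n_layers=2,
            n_heads=4,
            intermediate_dim=256,
            attn_dropout=0.0,
            pretrain_epochs=2,
            pretrain_batch=32,
            pretrain_lr=1e-3,
            finetune_epochs=5,
            finetune_batch=64,
            learning_rate=1e-3,
            profile="test",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float


class Classifier:
    """A trained Sec-TGA scorer: encoder state + head + vocabulary."""

    def __init__(self, cfg: ModelConfig, vocab: Vocab, encoder: BertEncoder):
        if vocab.k != cfg.k:
            raise ValueError("vocab k does not match config k")
        self.cfg = cfg
        self.vocab = vocab
        self.encoder = encoder
        self.training_log: list[dict] = []

    # -- persistence: directory of {weights.npz, config.json, vocab.txt} --

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.encoder.state_dict())
        (out / "config.json").write_text(json.dumps(asdict(self.cfg), indent=1))
        self.vocab.save(out / "vocab.txt")
        if self.training_log:
            lines = ["epoch\tsplit\tloss\taccuracy"]
            for row in self.training_log:
                lines.append(
                    f"{row['epoch']}\t{row['split']}\t{row.get('loss', '')}\t{row.get('accuracy', '')}"
                )
            (out / "training_log.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, model_dir) -> "Classifier":
        d = Path(model_dir)
        cfg = ModelConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocab.load(d / "vocab.txt")
        enc = _build_encoder(cfg, vocab)
        with np.load(d / "weights.npz") as z:
            enc.load_state_dict({k: z[k] for k in z.files})
        return cls(cfg, vocab, enc)


def _build_encoder(cfg: ModelConfig, vocab: Vocab, rng=None) -> BertEncoder:
    arch = ArchConfig(
        vocab_size=len(vocab),
        max_len=cfg.max_len,
        embed_dim=cfg.embed_dim,
        n_layers=cfg.n_layers,
        n_heads=cfg.n_heads,
        intermediate_dim=cfg.intermediate_dim,
        dropout=cfg.dropout,
        attn_dropout=cfg.attn_dropout,
    )
    return BertEncoder(arch, rng or np.random.default_rng(cfg.seed))


def _batches(n, batch_size, rng=None):
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    for i in range(0, n, batch_size):
        yield idx[i : i + batch_size]


def pretrain_mlm(
    seqs: list[str], cfg: ModelConfig, vocab: Vocab | None = None, log=None
) -> BertEncoder:
    """Masked-token pretraining on unlabeled windows.

    Returns the pretrained encoder; per-epoch mean masked losses (and the
    loss at initialization) are appended to ``log`` when given.
    """
    if not seqs:
        raise ValueError("pretraining corpus is empty")
    vocab = vocab or build_vocab(cfg.k)
    rng = np.random.default_rng(cfg.seed)
    enc = _build_encoder(cfg, vocab, rng)
    ids, mask = encode_batch(seqs, vocab, cfg.max_len)
    opt = AdamW(lr=cfg.pretrain_lr, weight_decay=cfg.weight_decay)

    if log is not None:
        eval_rng = np.random.default_rng(cfg.seed + 1)
        c_ids, c_labels = make_mlm_batch(ids, mask, len(vocab), eval_rng, mask_id=MASK_ID)
        # batched evaluation: a whole-corpus forward would not fit in memory
        losses, weights = [], []
        for i in range(0, len(seqs), 64):
            sl = slice(i, i + 64)
            losses.append(enc.mlm_loss(c_ids[sl], mask[sl], c_labels[sl]))
            weights.append(int((c_labels[sl] >= 0).sum()))
        init_loss = float(np.average(losses, weights=weights))
        log.append({"epoch": 0, "split": "pretrain", "loss": init_loss})

    for epoch in range(1, cfg.pretrain_epochs + 1):
        losses = []
        for sel in _batches(len(seqs), cfg.pretrain_batch, rng):
            b_ids, b_labels = make_mlm_batch(
                ids[sel], mask[sel], len(vocab), rng, mask_id=MASK_ID
            )
            loss, grads = enc.mlm_loss_and_grads(b_ids, mask[sel], b_labels, train=True, rng=rng)
            opt.step(enc.params, grads)
            losses.append(loss)
        if log is not None:
            log.append({"epoch": epoch, "split": "pretrain", "loss": float(np.mean(losses))})
    return enc


def finetune_classifier(
    encoder: BertEncoder,
    train_seqs: list[str],
    train_labels: np.ndarray,
    val_seqs: list[str],
    val_labels: np.ndarray,
    cfg: ModelConfig,
    vocab: Vocab | None = None,
) -> Classifier:
    """Fine-tune the CLS head + encoder; keep the best-validation-accuracy
    epoch (ties broken toward the earliest epoch)."""
    train_labels = np.asarray(train_labels, dtype=np.int64)
    val_labels = np.asarray(val_labels, dtype=np.int64)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("fine-tuning requires both classes in the training set")
    vocab = vocab or build_vocab(cfg.k)
    rng = np.random.default_rng(cfg.seed + 1000)
    ids, mask = encode_batch(train_seqs, vocab, cfg.max_len)
    v_ids, v_mask = encode_batch(val_seqs, vocab, cfg.max_len)
    opt = AdamW(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    clf = Classifier(cfg, vocab, encoder)
    best_acc, best_state = -1.0, None
    for epoch in range(1, cfg.finetune_epochs + 1):
        losses = []
        for sel in _batches(len(train_seqs), cfg.finetune_batch, rng):
            loss, grads = encoder.cls_loss_and_grads(
                ids[sel], mask[sel], train_labels[sel], train=True, rng=rng
            )
            opt.step(encoder.params, grads)
            losses.append(loss)
        val_probs = _score_ids(encoder, v_ids, v_mask)
        val_acc = float(accuracy_score(val_labels, (val_probs >= 0.5).astype(int)))
        clf.training_log.append(
            {"epoch": epoch, "split": "train", "loss": float(np.mean(losses))}
        )
        clf.training_log.append({"epoch": epoch, "split": "val", "accuracy": val_acc})
        if val_acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc = val_acc
            best_state = encoder.state_dict()
    encoder.load_state_dict(best_state)
    return clf


def _score_ids(encoder: BertEncoder, ids, mask, batch_size: int = 64) -> np.ndarray:
    out = np.empty(len(ids), dtype=np.float64)
    for i in range(0, len(ids), batch_size):
        out[i : i + batch_size] = encoder.cls_probs(ids[i : i + batch_size], mask[i : i + batch_size])[:, 1]
    return out


def score_windows(clf: Classifier, seqs: list[str], batch_size: int = 64) -> np.ndarray:
    """P(Sec-TGA) per window, order-preserving and batch-size invariant."""
    if not seqs:
        return np.empty(0)
    if any(len(s) != clf.cfg.window_len for s in seqs):
        raise ValueError(f"all windows must have length {clf.cfg.window_len}")
    ids, mask = encode_batch(seqs, clf.vocab, clf.cfg.max_len)
    return _score_ids(clf.encoder, ids, mask, batch_size)


def evaluate_classifier(scores, labels, threshold: float = 0.5) -> Metrics:
    """Accuracy, precision, recall, F1 at ``threshold`` plus rank-based AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels) or len(scores) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    return Metrics(
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        auroc=float(roc_auc_score(labels, scores)),
    )


def run_grid(
    make_corpus,
    window_lens=(100, 200, 300),
    ks=(3, 4, 5),
    profile="test",
    seed: int = 0,
) -> dict[tuple[int, int], Metrics]:
    """Train and evaluate one model per (window length, k) combination.

    ``make_corpus(L)`` must return ((train_seqs, train_labels),
    (val_seqs, val_labels), (test_seqs, test_labels)) with windows of
    length L.  Returns held-out metrics per combination; the caller picks
    the best row (the production choice is 300 nt / 3-mer).
    """
    maker = ModelConfig.test_profile if profile == "test" else ModelConfig.paper_profile
    results: dict[tuple[int, int], Metrics] = {}
    for L in window_lens:
        (tr_s, tr_y), (va_s, va_y), (te_s, te_y) = make_corpus(L)
        for k in ks:
            cfg = maker(window_len=L, k=k, seed=seed)
            clf = train_classifier(tr_s, tr_y, va_s, va_y, cfg)
            results[(L, k)] = evaluate_classifier(score_windows(clf, te_s), te_y)
    return results


def train_classifier(
    train_seqs, train_labels, val_seqs, val_labels, cfg: ModelConfig
) -> Classifier:
    """Pretrain (unlabeled training windows) then fine-tune, end to end."""
    vocab = build_vocab(cfg.k)
    log: list[dict] = []
    enc = pretrain_mlm(list(train_seqs), cfg, vocab, log=log)
    clf = finetune_classifier(enc, train_seqs, train_labels, val_seqs, val_labels, cfg, vocab)
    clf.training_log = log + clf.training_log
    return clf
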