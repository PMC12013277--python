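"""Overlapping k-mer tokenization of nucleotide windows.

Windows are represented as stride-1 overlapping k-mers (k = 3, 4 or 5), the
convention of k-mer BERT models for DNA, then mapped to dense integer ids:
five reserved specials followed by the 4^k ACGT k-mers in lexicographic
order.  Any k-mer containing a non-ACGT character (N padding, IUPAC
ambiguity codes) becomes UNK so that positions stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIALS = (PAD, UNK, CLS, SEP, MASK)
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)

VALID_K = (3, 4, 5)


@dataclass(frozen=True)
class Vocab:
    k: int
    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def save(self, path) -> None:
        """One token per line; the id is the line number."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.id_to_token) + "\n")

    @classmethod
    def load(cls, path) -> "Vocab":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.strip()]
        if tuple(tokens[:5]) != SPECIALS:
            raise ValueError("vocab file does not start with the reserved specials")
        k = len(tokens[5])
        return cls(k=k, token_to_id={t: i for i, t in enumerate(tokens)}, id_to_token=tuple(tokens))


@dataclass(frozen=True)
class EncodedWindow:
    ids: np.ndarray  # (max_len,) int32
    attention_mask: np.ndarray  # (max_len,) int8, 1 for CLS/tokens/SEP


def build_vocab(k: int) -> Vocab:
    if k not in VALID_K:
        raise ValueError(f"k must be one of {VALID_K}, got {k}")
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    tokens = list(SPECIALS) + kmers
    return Vocab(k=k, token_to_id={t: i for i, t in enumerate(tokens)}, id_to_token=tuple(tokens))


def kmerize(seq: str, k: int) -> list[str]:
    """Stride-1 overlapping k-mers; degenerate k-mers become UNK."""
    if k not in VALID_K:
        raise ValueError(f"k must be one of {VALID_K}, got {k}")
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    acgt = set("ACGT")
    return [
        seq[i : i + k] if set(seq[i : i + k]) <= acgt else UNK
        for i in range(len(seq) - k + 1)
    ]


def max_len_for(window_len: int, k: int) -> int:
    """Model sequence length for a (window length, k) pair: tokens + CLS + SEP."""
    return (window_len - k + 1) + 2


def encode_window(tokens: list[str], vocab: Vocab, max_len: int) -> EncodedWindow:
    """[CLS] ids [SEP] PAD... with an attention mask over non-PAD positions."""
    if len(tokens) > max_len - 2:
        raise ValueError(f"{len(tokens)} tokens overflow max_len={max_len} (need CLS+SEP)")
    ids = np.full(max_len, PAD_ID, dtype=np.int32)
    ids[0] = CLS_ID
    for i, tok in enumerate(tokens, start=1):
        ids[i] = vocab[tok]
    ids[len(tokens) + 1] = SEP_ID
    mask = np.zeros(max_len, dtype=np.int8)
    mask[: len(tokens) + 2] = 1
    return EncodedWindow(ids=ids, attention_mask=mask)


def decode_ids(ids: np.ndarray, vocab: Vocab) -> list[str]:
    """Inverse of encode_window on the non-special token span."""
    out = []
    for i in ids:
        tok = vocab.id_to_token[int(i)]
        if tok in (CLS, SEP, PAD):
            continue
        out.append(tok)
    return out


def encode_batch(seqs: list[str], vocab: Vocab, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized encoding of many windows → (ids, mask) arrays of shape (n, max_len)."""
    ids = np.empty((len(seqs), max_len), dtype=np.int32)
    mask = np.empty((len(seqs), max_len), dtype=np.int8)
    for r, s in enumerate(seqs):
        ew = encode_window(kmerize(s, vocab.k), vocab, max_len)
        ids[r] = ew.ids
        mask[r] = ew.attention_mask
    return ids, mask
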