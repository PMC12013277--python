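"""Construction of labeled window corpora and leakage-controlled splits.

Positive windows are the 100/200/300 nt immediately downstream of known
selenocysteine-encoding TGA codons; negative windows are the same lengths
downstream of annotated genes that genuinely terminate with TGA in
non-Sec-utilizing organisms.  Splits follow the family-aware recipe used for
the published corpus: 90% of sequences from 40 randomly chosen selenoprotein
families train, 50% of sequences from 30 further families validate, and the
remainder tests after removing any sequence with >= 70% identity to a
train/validation member.  Negatives are subsampled to match positive split
sizes.  Negative sequence diversity is controlled by greedy clustering at
50% identity / 80% bidirectional coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from . import scan


@dataclass(frozen=True)
class LabeledWindow:
    seq: str
    label: int  # 1 = Sec-TGA (positive), 0 = stop-TGA (negative)
    family: str | None = None
    organism: str | None = None


@dataclass(frozen=True)
class SplitSpec:
    n_train_families: int = 40
    train_frac: float = 0.9
    n_val_families: int = 30
    val_frac: float = 0.5
    test_identity_cap: float = 0.70
    cluster_id: float = 0.50
    cluster_cov: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac):
            if not (0.0 < f <= 1.0):
                raise ValueError("fractions must be in (0, 1]")
        for c in (self.test_identity_cap, self.cluster_id, self.cluster_cov):
            if not (0.0 < c < 1.0):
                raise ValueError("identity/coverage caps must be in (0, 1)")


# ---------------- window extraction ----------------


def _window_for_tga(genomes, contig, strand, tga_pos, L) -> str:
    by_id = {g.id: g for g in genomes}
    if contig not in by_id:
        raise ValueError(f"unknown contig {contig!r}")
    g = by_id[contig]
    site = scan.TgaSite(contig=contig, strand=strand, pos=tga_pos)
    s = g.seq if strand == "+" else scan.reverse_complement(g.seq)
    if tga_pos < 0 or tga_pos + 3 > len(s):
        raise ValueError(f"tga_pos {tga_pos} off contig {contig}")
    if s[tga_pos : tga_pos + 3] != "TGA":
        raise ValueError(
            f"annotated triplet at {contig}:{strand}:{tga_pos} is "
            f"{s[tga_pos:tga_pos+3]!r}, not TGA"
        )
    params = scan.ScanParams(window_len=L, pad_short_windows=True)
    return scan.extract_downstream_window(g, site, params).seq


def extract_positive_windows(
    annotations: Sequence[dict], genomes: Sequence[scan.GenomeRecord], L: int = 300
) -> list[LabeledWindow]:
    """Windows downstream of annotated Sec-TGA codons; exact duplicates removed.

    Each annotation is a mapping with contig, strand, tga_pos (strand-local,
    0-based), family and optionally organism.
    """
    out, seen = [], set()
    for a in annotations:
        seq = _window_for_tga(genomes, a["contig"], a["strand"], a["tga_pos"], L)
        key = (seq, a.get("family"))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            LabeledWindow(seq=seq, label=1, family=a.get("family"), organism=a.get("organism"))
        )
    return out


def extract_negative_windows(
    gene_annotations: Sequence[dict], genomes: Sequence[scan.GenomeRecord], L: int = 300
) -> list[LabeledWindow]:
    """Windows downstream of the terminal TGA of annotated stop-TGA genes.

    Each annotation carries the strand-local 0-based position of the
    terminal TGA (``tga_pos``); source organisms must be non-Sec-utilizing
    (the caller's responsibility, recorded in the organism tag).
    """
    out, seen = [], set()
    for a in gene_annotations:
        seq = _window_for_tga(genomes, a["contig"], a["strand"], a["tga_pos"], L)
        if seq in seen:
            continue
        seen.add(seq)
        out.append(LabeledWindow(seq=seq, label=0, organism=a.get("organism")))
    return out


# ---------------- pairwise identity / clustering ----------------


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def pairwise_identity(a: str, b: str) -> tuple[float, float, float]:
    """Local-alignment identity and per-sequence coverage.

    identity = matches / aligned columns (gap columns included);
    coverage_a, coverage_b = aligned span / sequence length.
    Returns (0, 0, 0) when no positive-score local alignment exists.
    """
    aligner = _nt_aligner()
    if not a or not b:
        return 0.0, 0.0, 0.0
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0, 0.0
    ident = counts.identities / columns
    coords = aln.coordinates
    span_a = coords[0, -1] - coords[0, 0]
    span_b = coords[1, -1] - coords[1, 0]
    return ident, span_a / len(a), span_b / len(b)


def sequence_identity(a: str, b: str) -> float:
    """Identity normalized by the shorter sequence (CD-HIT convention):
    matches in the best local alignment / min(|a|, |b|).  Used for the
    >= 70% test-set leakage cap, where the raw per-column identity of a
    short local alignment would over-exclude unrelated sequences."""
    if not a or not b:
        return 0.0
    aligner = _nt_aligner()
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0
    counts = alns[0].counts()
    return counts.identities / min(len(a), len(b))


def greedy_cluster(
    seqs: Sequence[str], id_threshold: float = 0.50, cov_threshold: float = 0.80,
    identity_fn=None,
) -> tuple[list[int], list[int]]:
    """Greedy incremental clustering in the CD-HIT/linclust style.

    Sequences are processed longest-first (ties lexicographic); each joins
    the earliest-founded cluster whose representative aligns with identity
    >= id_threshold and coverage >= cov_threshold on both sequences,
    otherwise founds a new cluster.

    Returns (assignment, representatives): ``assignment[i]`` is the cluster
    index of input sequence i; ``representatives[c]`` the input index of
    cluster c's founder.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    identity_fn = identity_fn or pairwise_identity  # hook for external backends
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    assignment = [-1] * len(seqs)
    reps: list[int] = []
    for i in order:
        placed = False
        for c, r in enumerate(reps):
            ident, cov_a, cov_b = identity_fn(seqs[r], seqs[i])
            if ident >= id_threshold and cov_a >= cov_threshold and cov_b >= cov_threshold:
                assignment[i] = c
                placed = True
                break
        if not placed:
            assignment[i] = len(reps)
            reps.append(i)
    return assignment, reps


# ---------------- splits ----------------


@dataclass
class Splits:
    train: list[LabeledWindow] = field(default_factory=list)
    val: list[LabeledWindow] = field(default_factory=list)
    test: list[LabeledWindow] = field(default_factory=list)

    def counts(self) -> dict[str, tuple[int, int]]:
        def c(ws):
            return (sum(w.label == 1 for w in ws), sum(w.label == 0 for w in ws))

        return {"train": c(self.train), "val": c(self.val), "test": c(self.test)}


def _sample_frac(items, frac, rng):
    n = len(items)
    k = int(round(n * frac))
    k = min(max(k, 1), n)
    chosen = set(rng.choice(n, size=k, replace=False).tolist())
    picked = [x for i, x in enumerate(items) if i in chosen]
    rest = [x for i, x in enumerate(items) if i not in chosen]
    return picked, rest


def make_splits(
    positives: Sequence[LabeledWindow],
    negatives: Sequence[LabeledWindow],
    spec: SplitSpec = SplitSpec(),
) -> Splits:
    """Family-aware train/val/test splits with identity-capped test set.

    Training takes ``train_frac`` of sequences from ``n_train_families``
    seeded-random families (sampled per family so family proportions are
    preserved); validation takes ``val_frac`` from ``n_val_families`` further
    families; everything else is a test candidate.  Test candidates with
    local-alignment identity >= ``test_identity_cap`` to any train or
    validation sequence are excluded, as are exact duplicates across splits.
    Negatives are shuffled and subsampled so each split has as many
    negatives as positives.
    """
    rng = np.random.default_rng(spec.seed)
    families = sorted({w.family for w in positives if w.family is not None})
    need = spec.n_train_families + spec.n_val_families
    if len(families) < need:
        raise ValueError(f"need >= {need} families, got {len(families)}")

    fam_perm = [families[i] for i in rng.permutation(len(families))]
    train_fams = set(fam_perm[: spec.n_train_families])
    val_fams = set(fam_perm[spec.n_train_families : need])

    by_family: dict[str, list[LabeledWindow]] = {}
    for w in positives:
        by_family.setdefault(w.family, []).append(w)
    for fam in by_family:
        by_family[fam].sort(key=lambda w: w.seq)

    splits = Splits()
    test_candidates: list[LabeledWindow] = []
    for fam in sorted(by_family):
        ws = by_family[fam]
        if fam in train_fams:
            picked, rest = _sample_frac(ws, spec.train_frac, rng)
            splits.train.extend(picked)
            test_candidates.extend(rest)
        elif fam in val_fams:
            picked, rest = _sample_frac(ws, spec.val_frac, rng)
            splits.val.extend(picked)
            test_candidates.extend(rest)
        else:
            test_candidates.extend(ws)

    ref_seqs = [w.seq for w in splits.train] + [w.seq for w in splits.val]
    ref_set = set(ref_seqs)
    for w in test_candidates:
        if w.seq in ref_set:
            continue
        if any(sequence_identity(w.seq, r) >= spec.test_identity_cap for r in ref_seqs):
            continue
        splits.test.append(w)

    # negatives: shuffle once, deal matching counts to each split
    neg = list(negatives)
    neg_order = rng.permutation(len(neg))
    neg = [neg[i] for i in neg_order]
    need_n = len(splits.train) + len(splits.val) + len(splits.test)
    if len(neg) < need_n:
        raise ValueError(f"need {need_n} negatives, got {len(neg)}")
    i = 0
    for part in (splits.train, splits.val, splits.test):
        k = len(part)
        part.extend(neg[i : i + k])
        i += k
    return splits


# ---------------- manifests ----------------


def write_split_manifest(splits: Splits, out_dir) -> None:
    """Per-split FASTA plus a combined manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["seq_id\tlabel\tfamily\torganism\tsplit"]
    for split_name, ws in (("train", splits.train), ("val", splits.val), ("test", splits.test)):
        with open(out / f"{split_name}.fasta", "w") as fh:
            for i, w in enumerate(ws):
                sid = f"{split_name}_{i:06d}"
                fh.write(f">{sid}\n{w.seq}\n")
                rows.append(
                    f"{sid}\t{'pos' if w.label else 'neg'}\t{w.family or '.'}\t{w.organism or '.'}\t{split_name}"
                )
    (out / "manifest.tsv").write_text("\n".join(rows) + "\n")
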