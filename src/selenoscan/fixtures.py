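"""Seeded synthetic data with known ground truth.

Real selenoprotein corpora require genome downloads and curated homolog
databases; every other module is therefore exercised against synthetic
inputs built here.  The recoding signal downstream of a Sec-TGA is emulated
by a position weight matrix (PWM) emitted immediately after the TGA — a
learnable stand-in for the SECIS region, not a folded stem-loop; the
classifier contract only requires a localized downstream signal.

Three generators share one ``SimConfig``:

* ``generate_synthetic_corpus`` — labeled positive/negative windows for
  classifier training (positives carry the PWM emission, negatives are
  i.i.d. background).
* ``generate_synthetic_genome`` — a contig with planted selenoprotein genes
  (valid ORFs with an in-frame TGA and the PWM downstream), decoy genes that
  genuinely stop at TGA, and random background; returns a truth table.
* ``generate_fixture_db`` — a protein database with Cys-variant homologs
  (85-95% identity, distinct organism tags) for each planted gene, plus
  unrelated decoy proteins; decoy genes get no homologs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .filter import DbEntry
from .scan import GenomeRecord, reverse_complement

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in _STOPS
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# 24-nt consensus for the downstream signal; its in-frame codons contain no
# stop, so it can sit directly after the Sec-TGA inside a coding region
DEFAULT_MOTIF_CONSENSUS = "GGTCAGCGGTTCCGCGAAGCCTGC"


def pwm_from_consensus(consensus: str) -> np.ndarray:
    pwm = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        pwm[i, BASES.index(b)] = 1.0
    return pwm


@dataclass
class SimConfig:
    genome_len: int = 100_000
    n_selenogenes: int = 10
    n_decoy_genes: int = 50
    motif: np.ndarray = field(default_factory=lambda: pwm_from_consensus(DEFAULT_MOTIF_CONSENSUS))
    motif_strength: float = 0.8
    gc_content: float = 0.5
    window_len: int = 300
    n_windows: int = 2000  # per class, for corpus generation
    n_homologs_per_gene: int = 3
    n_db_decoys: int = 20
    add_known_sec: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must be in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.motif.shape[0] > self.window_len:
            raise ValueError("motif longer than window")
        if not np.allclose(self.motif.sum(axis=1), 1.0):
            raise ValueError("motif rows must be probability distributions")

    @property
    def background(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass(frozen=True)
class TruthEntry:
    """One planted gene, strand-local 0-based coordinates like CandidateOrf."""

    contig: str
    strand: str
    start: int
    tga_pos: int
    stop_pos: int
    family: str
    is_selenogene: bool
    has_db_homolog: bool
    protein: str


def _random_seq(n: int, bg: np.ndarray, rng) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=bg)])


def _emit_motif(cfg: SimConfig, rng) -> str:
    """One PWM emission mixed with background at motif_strength."""
    p = cfg.motif_strength * cfg.motif + (1 - cfg.motif_strength) * cfg.background[None, :]
    return "".join(BASES[rng.choice(4, p=row / row.sum())] for row in p)


def _positive_window(cfg: SimConfig, rng) -> str:
    w = list(_random_seq(cfg.window_len, cfg.background, rng))
    m = _emit_motif(cfg, rng)
    w[: len(m)] = m
    return "".join(w)


def generate_synthetic_corpus(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """(positive windows, negative windows), equal class sizes, seeded."""
    rng = np.random.default_rng(cfg.seed)
    pos = [_positive_window(cfg, rng) for _ in range(cfg.n_windows)]
    neg = [_random_seq(cfg.window_len, cfg.background, rng) for _ in range(cfg.n_windows)]
    return pos, neg


def _sense_codons(n: int, rng, exclude_tga_only: bool = True) -> list[str]:
    return [ _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n) ]


def _frame_safe(seq: str, rng, bg) -> str:
    """Resample any in-frame stop codon (keeps a planted coding region open)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for j, c in enumerate(codons):
        while codons[j] in _STOPS:
            codons[j] = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
    return "".join(codons)


_TABLE11_FWD = None


def _translate_cassette(coding: str) -> str:
    """Protein of a planted coding region: leading M, U at internal TGA."""
    global _TABLE11_FWD
    if _TABLE11_FWD is None:
        from Bio.Data import CodonTable

        _TABLE11_FWD = CodonTable.unambiguous_dna_by_id[11].forward_table
    aa = ["M"]
    for i in range(3, len(coding), 3):
        codon = coding[i : i + 3]
        aa.append("U" if codon == "TGA" else _TABLE11_FWD[codon])
    return "".join(aa)


def _selenogene_cassette(cfg: SimConfig, rng) -> tuple[str, int, int, int, str]:
    """Returns (cassette, start_off, tga_off, stop_off, protein).

    Layout: TAA guard | ATG | 15-30 sense codons | TGA | window_len nt of
    frame-safe downstream carrying the PWM emission at offset 0 | TAA.
    The guard pins the ORF start the scanner reconstructs to the planted ATG.
    """
    n_up = int(rng.integers(15, 31))
    upstream = "".join(_sense_codons(n_up, rng))
    down = list(_random_seq(cfg.window_len, cfg.background, rng))
    m = _emit_motif(cfg, rng)
    down[: len(m)] = m
    downstream = _frame_safe("".join(down), rng, cfg.background)
    cassette = "TAA" + "ATG" + upstream + "TGA" + downstream + "TAA"
    start_off = 3
    tga_off = 3 + 3 + len(upstream)
    stop_off = tga_off + 3 + len(downstream)
    coding = cassette[start_off:stop_off]
    return cassette, start_off, tga_off, stop_off, _translate_cassette(coding)


def _decoy_cassette(cfg: SimConfig, rng) -> tuple[str, int, int, str]:
    """A gene that genuinely terminates at TGA: TAA guard | ATG | codons | TGA."""
    n = int(rng.integers(30, 61))
    body = "".join(_sense_codons(n, rng))
    cassette = "TAA" + "ATG" + body + "TGA"
    start_off, tga_off = 3, 3 + 3 + len(body)
    protein = _translate_cassette(cassette[start_off:tga_off])
    return cassette, start_off, tga_off, protein


def generate_synthetic_genome(
    cfg: SimConfig, contig_id: str = "synth_contig"
) -> tuple[GenomeRecord, list[TruthEntry]]:
    """A contig with planted selenogenes and decoys at non-overlapping loci."""
    rng = np.random.default_rng(cfg.seed + 7)
    seq = list(_random_seq(cfg.genome_len, cfg.background, rng))
    L = cfg.genome_len

    placed: list[tuple[int, int]] = []  # forward-coordinate intervals
    entries: list[TruthEntry] = []
    margin = cfg.window_len + 30  # keep downstream windows on-contig

    def try_place(cassette_len: int) -> Optional[int]:
        for _ in range(200):
            a = int(rng.integers(margin, L - cassette_len - margin))
            b = a + cassette_len
            if all(b + 20 <= s or a >= e + 20 for s, e in placed):
                placed.append((a, b))
                return a
        return None

    for g in range(cfg.n_selenogenes):
        cassette, s_off, t_off, p_off, protein = _selenogene_cassette(cfg, rng)
        a = try_place(len(cassette))
        if a is None:
            raise RuntimeError("could not place all selenogenes; genome too small")
        strand = "+" if rng.random() < 0.5 else "-"
        ins = cassette if strand == "+" else reverse_complement(cassette)
        seq[a : a + len(cassette)] = ins
        base = a if strand == "+" else L - (a + len(cassette))
        entries.append(
            TruthEntry(
                contig=contig_id, strand=strand, start=base + s_off,
                tga_pos=base + t_off, stop_pos=base + p_off,
                family=f"fam{g:02d}", is_selenogene=True,
                has_db_homolog=True, protein=protein,
            )
        )

    for d in range(cfg.n_decoy_genes):
        cassette, s_off, t_off, protein = _decoy_cassette(cfg, rng)
        a = try_place(len(cassette))
        if a is None:
            raise RuntimeError("could not place all decoys; genome too small")
        strand = "+" if rng.random() < 0.5 else "-"
        ins = cassette if strand == "+" else reverse_complement(cassette)
        seq[a : a + len(cassette)] = ins
        base = a if strand == "+" else L - (a + len(cassette))
        entries.append(
            TruthEntry(
                contig=contig_id, strand=strand, start=base + s_off,
                tga_pos=base + t_off, stop_pos=base + t_off,
                family=f"decoy{d:02d}", is_selenogene=False,
                has_db_homolog=False, protein=protein,
            )
        )

    return GenomeRecord(id=contig_id, seq="".join(seq)), entries


def _mutate_protein(protein: str, keep_pos: int, rng, rate: float) -> str:
    """Point-substitute ``rate`` of residues, never touching keep_pos."""
    aa = list(protein)
    candidates = [i for i in range(1, len(aa)) if i != keep_pos]
    k = max(1, int(round(rate * len(aa))))
    for i in rng.choice(len(candidates), size=min(k, len(candidates)), replace=False):
        p = candidates[int(i)]
        choices = [c for c in _AA20 if c != aa[p]]
        aa[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(aa)


def generate_fixture_db(
    truth: list[TruthEntry], cfg: SimConfig, only_families: Optional[set[str]] = None
) -> list[DbEntry]:
    """Protein database with Cys-variant homologs for planted selenogenes.

    Each selenogene with ``has_db_homolog`` receives
    ``cfg.n_homologs_per_gene`` homologs: U→C at the Sec position plus 5-15%
    random substitutions elsewhere, each under a distinct organism tag.  With
    ``cfg.add_known_sec`` a Sec-retaining entry flagged as a curated known
    selenoprotein is added per family.  ``only_families`` restricts which
    planted families get homologs (for negative-control runs).
    """
    rng = np.random.default_rng(cfg.seed + 99)
    db: list[DbEntry] = []
    for e in truth:
        if not (e.is_selenogene and e.has_db_homolog):
            continue
        if only_families is not None and e.family not in only_families:
            continue
        sec_pos = e.protein.index("U")
        cys_protein = e.protein[:sec_pos] + "C" + e.protein[sec_pos + 1 :]
        for j in range(cfg.n_homologs_per_gene):
            rate = rng.uniform(0.05, 0.15)
            hom = _mutate_protein(cys_protein, sec_pos, rng, rate)
            db.append(
                DbEntry(
                    id=f"{e.family}_h{j}", organism=f"{e.family}_org{j}",
                    family=e.family, seq=hom, is_known_selenoprotein=False,
                )
            )
        if cfg.add_known_sec:
            db.append(
                DbEntry(
                    id=f"{e.family}_known", organism=f"{e.family}_orgK",
                    family=e.family, seq=e.protein, is_known_selenoprotein=True,
                )
            )
    for j in range(cfg.n_db_decoys):
        n = int(rng.integers(80, 200))
        seq = "M" + "".join(_AA20[i] for i in rng.integers(0, 20, size=n))
        db.append(DbEntry(id=f"dbdecoy{j}", organism=f"dorg{j}", family=None, seq=seq))
    return db


def write_db_fasta(db: list[DbEntry], path) -> None:
    with open(path, "w") as fh:
        for e in db:
            known = "|known" if e.is_known_selenoprotein else ""
            fh.write(f">{e.id}|{e.organism}|{e.family or '.'}{known}\n{e.seq}\n")


def write_truth_tsv(truth: list[TruthEntry], path) -> None:
    rows = ["contig\tstrand\tstart\ttga_pos\tstop_pos\tfamily\tis_selenogene\thas_db_homolog"]
    for e in truth:
        rows.append(
            f"{e.contig}\t{e.strand}\t{e.start}\t{e.tga_pos}\t{e.stop_pos}\t"
            f"{e.family}\t{int(e.is_selenogene)}\t{int(e.has_db_homolog)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
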