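"""Six-frame TGA scanning and candidate-ORF reconstruction.

In Sec-utilizing bacteria an in-frame TGA codon can encode selenocysteine
(Sec) instead of terminating translation.  The first stage of selenoprotein
gene prediction is therefore purely geometric: enumerate every TGA triplet on
both strands of a genome, try to build a valid open reading frame around it
(ATG/CTG/GTG start, no premature in-frame terminator, a terminator after the
TGA), and cut out the fixed-length nucleotide window immediately downstream
of the TGA — the region that carries the recoding signal and that the
classifier scores.

Coordinates are 0-based, half-open and strand-local throughout: a position on
the minus strand indexes into the reverse complement of the contig.
Conversion to 1-based genomic coordinates happens only when writing GFF3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq

START_CODONS = frozenset({"ATG", "CTG", "GTG"})
DEFAULT_TERMINATORS = frozenset({"TAA", "TAG"})

_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)
_IUPAC_RE = re.compile(r"^[ACGTRYSWKMBDHVN]*$")


class AlphabetError(ValueError):
    """Sequence contains a character outside the IUPAC nucleotide alphabet."""


class ContractError(ValueError):
    """A precondition of an operation was violated by the caller."""


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: identifier plus upper-cased nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class TgaSite:
    """A TGA triplet occurrence.

    ``pos`` is the 0-based offset of the T of the triplet in strand-forward
    orientation (i.e. an index into the reverse complement for '-' sites).
    ``frame`` is ``pos % 3`` on that strand.
    """

    contig: str
    strand: str  # '+' or '-'
    pos: int

    @property
    def frame(self) -> int:
        return self.pos % 3


@dataclass(frozen=True)
class CandidateOrf:
    """A TGA-anchored open reading frame in strand-local coordinates.

    ``stop_pos`` is the first nucleotide of the terminator codon, or ``None``
    with ``partial3=True`` when the ORF runs off the contig end.
    """

    contig: str
    strand: str
    start_pos: int
    tga_pos: int
    stop_pos: Optional[int]
    partial3: bool = False

    @property
    def sec_codon_index(self) -> int:
        return (self.tga_pos - self.start_pos) // 3

    @property
    def n_codons(self) -> int:
        """Codon count excluding the terminator."""
        if self.stop_pos is not None:
            return (self.stop_pos - self.start_pos) // 3
        raise ValueError("3'-partial ORF has no defined codon count")


@dataclass(frozen=True)
class Window:
    """Fixed-length sequence immediately downstream of a candidate TGA."""

    site: TgaSite
    seq: str
    n_padded: int = 0


@dataclass(frozen=True)
class ScanParams:
    """Scanner thresholds.

    window_len
        Length of the downstream window handed to the classifier (100, 200
        or 300 nt).
    min_upstream_codons
        Minimum number of codons between the start codon and the candidate
        TGA; suppresses spurious micro-ORFs.
    min_orf_len
        Minimum total ORF length in nt, terminator excluded.
    terminator_set
        Codons treated as genuine terminators when walking the frame.  TGA
        is excluded by default because a downstream in-frame TGA could
        itself be a Sec codon; add it via ``tga_terminates=True`` semantics
        by passing ``frozenset({"TAA", "TAG", "TGA"})``.
    longest_orf
        Start-codon choice: farthest reachable in-frame start (the
        longest-ORF convention of standard gene callers) when True,
        nearest start when False.
    """

    window_len: int = 300
    min_upstream_codons: int = 10
    min_orf_len: int = 90
    terminator_set: frozenset[str] = DEFAULT_TERMINATORS
    pad_short_windows: bool = True
    longest_orf: bool = True

    def __post_init__(self) -> None:
        if self.window_len not in (100, 200, 300):
            raise ValueError("window_len must be one of 100, 200, 300")
        if self.min_orf_len % 3:
            raise ValueError("min_orf_len must be a multiple of 3")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (N maps to N)."""
    seq = seq.upper()
    if not _IUPAC_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTRYSWKMBDHVN"))
        raise AlphabetError(f"non-IUPAC nucleotide characters: {bad}")
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def read_genome(path) -> list[GenomeRecord]:
    """Read a multi-record nucleotide FASTA (wrapped or single-line)."""
    return [
        GenomeRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def _strand_seq(genome: GenomeRecord, strand: str) -> str:
    return genome.seq if strand == "+" else reverse_complement(genome.seq)


def enumerate_tga_sites(genome: GenomeRecord) -> list[TgaSite]:
    """All TGA triplets on both strands, sorted by (strand, pos).

    Equivalent to collecting TGA occurrences in all six reading frames:
    every occurrence lies in exactly one frame per strand.  Ambiguous IUPAC
    bases never match.
    """
    sites: list[TgaSite] = []
    for strand in "+-":
        s = _strand_seq(genome, strand)
        start = 0
        while True:
            i = s.find("TGA", start)
            if i == -1:
                break
            sites.append(TgaSite(contig=genome.id, strand=strand, pos=i))
            start = i + 1
    sites.sort(key=lambda t: (t.strand, t.pos))
    return sites


def find_candidate_orf(
    genome: GenomeRecord, site: TgaSite, params: ScanParams = ScanParams()
) -> Optional[CandidateOrf]:
    """Reconstruct a valid ORF around an in-frame TGA, or ``None``.

    Walks codons upstream of the TGA in frame until a terminator codon or
    the contig edge, remembering start codons seen; walks downstream until
    the first terminator (3'-partial if the contig ends first).  Applies the
    minimum-length thresholds from ``params``.
    """
    s = _strand_seq(genome, site.strand)
    p = site.pos
    if s[p : p + 3] != "TGA":
        raise ContractError(f"triplet at {site} is {s[p:p+3]!r}, not TGA")

    starts: list[int] = []
    q = p - 3
    while q >= 0:
        codon = s[q : q + 3]
        if codon in params.terminator_set:
            break
        if codon in START_CODONS:
            starts.append(q)
        q -= 3
    if not starts:
        return None
    start_pos = min(starts) if params.longest_orf else max(starts)

    stop_pos: Optional[int] = None
    q = p + 3
    while q + 3 <= len(s):
        codon = s[q : q + 3]
        if codon in params.terminator_set:
            stop_pos = q
            break
        q += 3
    partial3 = stop_pos is None

    upstream_codons = (p - start_pos) // 3
    if upstream_codons < params.min_upstream_codons:
        return None
    end = stop_pos if stop_pos is not None else (len(s) - (len(s) - start_pos) % 3)
    if end - start_pos < params.min_orf_len:
        return None
    return CandidateOrf(
        contig=site.contig,
        strand=site.strand,
        start_pos=start_pos,
        tga_pos=p,
        stop_pos=stop_pos,
        partial3=partial3,
    )


def extract_downstream_window(
    genome: GenomeRecord, site: TgaSite, params: ScanParams = ScanParams()
) -> Optional[Window]:
    """The ``window_len`` nt immediately after the TGA, strand-forward.

    Windows truncated by the contig end are 3'-padded with N when
    ``pad_short_windows`` is set, otherwise dropped.
    """
    s = _strand_seq(genome, site.strand)
    start = site.pos + 3
    raw = s[start : start + params.window_len]
    n_pad = params.window_len - len(raw)
    if n_pad > 0 and not params.pad_short_windows:
        return None
    return Window(site=site, seq=raw + "N" * n_pad, n_padded=n_pad)


def orf_nucleotide_seq(genome: GenomeRecord, orf: CandidateOrf) -> str:
    """Strand-forward coding sequence of the ORF, terminator excluded."""
    s = _strand_seq(genome, orf.strand)
    end = orf.stop_pos if orf.stop_pos is not None else len(s) - (len(s) - orf.start_pos) % 3
    return s[orf.start_pos : end]


def to_forward_coords(orf: CandidateOrf, contig_len: int) -> tuple[int, int]:
    """Map strand-local [start, end) (incl. terminator if present) to
    forward-strand 0-based half-open coordinates."""
    end_local = (orf.stop_pos + 3) if orf.stop_pos is not None else contig_len - (contig_len - orf.start_pos) % 3
    if orf.strand == "+":
        return orf.start_pos, end_local
    return contig_len - end_local, contig_len - orf.start_pos


def sites_to_table(sites: Iterator[TgaSite]):
    """Site list as a pandas DataFrame (TSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        [{"contig": t.contig, "strand": t.strand, "pos": t.pos, "frame": t.frame} for t in sites]
    )
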