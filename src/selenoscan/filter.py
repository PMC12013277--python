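"""Homology-based validation of candidate selenoprotein ORFs.

A window classifier alone cannot distinguish a genuine selenoprotein from a
fortuitous high-scoring window, so each model-positive candidate is
translated (with U at the recoded TGA), searched against a microbial protein
database, and retained only if the alignments support Sec recoding:

(i)  at least one Sec-containing homolog (a subject with U, or a curated
     known selenoprotein, aligned at the query's Sec position), or
(ii) at least two of the top ten hits place cysteine at the Sec position and
     come from different organisms.

Hits are pre-filtered at e-value <= 0.01 and sequence identity >= 20%.
Retained candidates are labeled *known* when a supporting Sec-homolog
belongs to the curated known-selenoprotein set, otherwise *new*.

Three interchangeable search backends implement a single tabular contract
(the 12-column BLAST dialect plus aligned query/subject strings and an
organism tag): precomputed hit tables, an external ``blastp`` run, and a
built-in Smith-Waterman backend (BLOSUM62, affine gaps, U scored as C) whose
e-values are deterministic but not calibrated — adequate for fixtures, not
for production screens.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .scan import CandidateOrf, ContractError, GenomeRecord, orf_nucleotide_seq

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
START_TO_MET = {"ATG", "CTG", "GTG"}

HIT_COLUMNS = (
    "qseqid sseqid pident evalue bitscore qstart qend sstart send qseq sseq organism"
).split()


@dataclass(frozen=True)
class SelenoCandidate:
    """A translated candidate: ORF + protein with U at the Sec position."""

    orf: CandidateOrf
    protein: str
    score: float = float("nan")

    @property
    def sec_index(self) -> int:
        return self.orf.sec_codon_index


@dataclass(frozen=True)
class Hit:
    """One parsed homology alignment against a database subject."""

    subject_id: str
    organism: str
    evalue: float
    pident: float
    bitscore: float
    qstart: int  # 1-based, inclusive, on the query protein
    qend: int
    sstart: int
    send: int
    qseq_aln: str  # aligned query string with '-' gaps
    sseq_aln: str
    subject_is_known_selenoprotein: bool = False
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError("pident must be in [0, 100]")

    def subject_residue_at(self, query_pos: int) -> Optional[str]:
        """Subject residue aligned to 0-based query position, '-' for a gap,
        None when the position lies outside the aligned span."""
        q = self.qstart - 1
        for qc, sc in zip(self.qseq_aln, self.sseq_aln):
            if qc != "-":
                if q == query_pos:
                    return sc
                q += 1
        return None


@dataclass(frozen=True)
class Decision:
    keep: bool
    reason: Literal["sec_homolog", "cys_rule", "rejected"]
    supporting: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.keep != (self.reason != "rejected"):
            raise ValueError("keep flag inconsistent with reason")


def translate_orf(orf: CandidateOrf, genome: GenomeRecord) -> SelenoCandidate:
    """Translate with bacterial code (table 11), U at every internal TGA.

    The initial codon (ATG/CTG/GTG) becomes M regardless of its table-11
    sense; the terminator is excluded.  An internal TAA/TAG violates the ORF
    invariant and raises.
    """
    nt = orf_nucleotide_seq(genome, orf)
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if i == 0:
            if codon not in START_TO_MET:
                raise ContractError(f"ORF does not begin with a start codon: {codon}")
            aa.append("M")
        elif codon == "TGA":
            aa.append("U")
        elif codon in ("TAA", "TAG"):
            raise ContractError(f"internal terminator {codon} at codon {i // 3}")
        else:
            aa.append(_TABLE11.forward_table.get(codon, "X"))
    protein = "".join(aa)
    if protein[orf.sec_codon_index] != "U":
        raise ContractError("Sec codon index does not map to U after translation")
    return SelenoCandidate(orf=orf, protein=protein)


# ---------------- backends ----------------


class BackendError(RuntimeError):
    """A homology-search backend failed; message carries diagnostics."""


@dataclass(frozen=True)
class DbEntry:
    """One protein database record (fixture dialect: ``id|organism|family``)."""

    id: str
    organism: str
    family: Optional[str]
    seq: str
    is_known_selenoprotein: bool = False


def parse_protein_db(path) -> list[DbEntry]:
    """Protein FASTA whose headers follow ``id|organism|family[|known]``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(_entry_from_header(rec.description.split()[0], str(rec.seq)))
    return entries


def _entry_from_header(header: str, seq: str) -> DbEntry:
    parts = header.split("|")
    sid = parts[0]
    org = parts[1] if len(parts) > 1 else sid
    fam = parts[2] if len(parts) > 2 and parts[2] != "." else None
    known = len(parts) > 3 and parts[3] == "known"
    return DbEntry(id=sid, organism=org, family=fam, seq=seq.upper(), is_known_selenoprotein=known)


class LocalAlignmentBackend:
    """Built-in Smith-Waterman search over an in-memory protein database.

    BLOSUM62 with affine gaps (open -11, extend -1); selenocysteine is
    scored as cysteine on both sides but reported with its original letter.
    E-values follow the Karlin-Altschul form E = m*n*2^(-bits) with gapped
    BLOSUM62 constants — deterministic and monotone in score, but NOT
    calibrated against BLAST/DIAMOND statistics.
    """

    _LAMBDA = 0.267
    _K = 0.041

    def __init__(self, db: Sequence[DbEntry]):
        if not db:
            raise BackendError("empty protein database")
        self.db = list(db)
        self._total_len = sum(len(e.seq) for e in self.db)
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self.aligner.open_gap_score = -11
        self.aligner.extend_gap_score = -1

    def search(self, query_id: str, query: str) -> list[Hit]:
        hits = []
        q_sub = query.replace("U", "C").replace("J", "L")
        for e in self.db:
            s_sub = e.seq.replace("U", "C").replace("J", "L")
            try:
                alns = self.aligner.align(q_sub, s_sub)
                if len(alns) == 0:
                    continue
                aln = alns[0]
            except Exception as exc:  # alphabet problems etc.
                raise BackendError(f"alignment of {query_id} vs {e.id} failed: {exc}") from exc
            score = aln.score
            if score <= 0:
                continue
            bits = (self._LAMBDA * score - math.log(self._K)) / math.log(2.0)
            evalue = len(query) * self._total_len * 2.0 ** (-bits)
            qa, sa, (qs, qe, ss, se) = _aligned_strings(aln, query, e.seq)
            columns = len(qa)
            matches = sum(a == b and a != "-" for a, b in zip(qa.replace("U", "C"), sa.replace("U", "C")))
            pident = 100.0 * matches / columns if columns else 0.0
            hits.append(
                Hit(
                    subject_id=e.id,
                    organism=e.organism,
                    evalue=evalue,
                    pident=pident,
                    bitscore=bits,
                    qstart=qs + 1,
                    qend=qe,
                    sstart=ss + 1,
                    send=se,
                    qseq_aln=qa,
                    sseq_aln=sa,
                    subject_is_known_selenoprotein=e.is_known_selenoprotein,
                    family=e.family,
                )
            )
        return hits


def _aligned_strings(aln, query: str, subject: str):
    """Rebuild aligned strings (with original residues, e.g. U) from an
    alignment's coordinate blocks."""
    coords = aln.coordinates
    qa, sa = [], []
    for i in range(coords.shape[1] - 1):
        q0, q1 = coords[0, i], coords[0, i + 1]
        s0, s1 = coords[1, i], coords[1, i + 1]
        if q1 > q0 and s1 > s0:
            qa.append(query[q0:q1])
            sa.append(subject[s0:s1])
        elif q1 > q0:
            qa.append(query[q0:q1])
            sa.append("-" * (q1 - q0))
        else:
            qa.append("-" * (s1 - s0))
            sa.append(subject[s0:s1])
    span = (int(coords[0, 0]), int(coords[0, -1]), int(coords[1, 0]), int(coords[1, -1]))
    return "".join(qa), "".join(sa), span


class PrecomputedHitsBackend:
    """Hits read from a 12-column TSV (qseqid..send, qseq, sseq, organism)."""

    def __init__(self, path, known_subject_ids: Optional[set[str]] = None,
                 subject_families: Optional[dict[str, str]] = None):
        self.by_query: dict[str, list[Hit]] = {}
        known = known_subject_ids or set()
        fams = subject_families or {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != len(HIT_COLUMNS):
                    raise BackendError(
                        f"expected {len(HIT_COLUMNS)} columns, got {len(f)}: {line[:80]}"
                    )
                hit = Hit(
                    subject_id=f[1],
                    organism=f[11],
                    evalue=float(f[3]),
                    pident=float(f[2]),
                    bitscore=float(f[4]),
                    qstart=int(f[5]),
                    qend=int(f[6]),
                    sstart=int(f[7]),
                    send=int(f[8]),
                    qseq_aln=f[9],
                    sseq_aln=f[10],
                    subject_is_known_selenoprotein=f[1] in known or "U" in f[10],
                    family=fams.get(f[1]),
                )
                self.by_query.setdefault(f[0], []).append(hit)

    def search(self, query_id: str, query: str) -> list[Hit]:
        return list(self.by_query.get(query_id, []))


class BlastBackend:
    """External ``blastp`` run emitting the same tabular contract.

    Requires the BLAST+ suite on PATH; subject headers must follow the
    ``id|organism|family`` dialect so organism tags can be recovered.
    """

    def __init__(self, db_fasta):
        if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
            raise BackendError("blastp/makeblastdb not found on PATH")
        self.db_fasta = Path(db_fasta)
        self.entries = {e.id: e for e in parse_protein_db(db_fasta)}

    def search(self, query_id: str, query: str) -> list[Hit]:
        with tempfile.TemporaryDirectory() as td:
            qf = Path(td) / "q.fasta"
            qf.write_text(f">{query_id}\n{query.replace('U', 'C')}\n")
            dbf = Path(td) / "db.fasta"
            dbf.write_text(
                "".join(f">{e.id}\n{e.seq.replace('U', 'C')}\n" for e in self.entries.values())
            )
            subprocess.run(
                ["makeblastdb", "-in", str(dbf), "-dbtype", "prot"],
                check=True, capture_output=True,
            )
            out = subprocess.run(
                [
                    "blastp", "-query", str(qf), "-db", str(dbf),
                    "-outfmt", "6 qseqid sseqid pident evalue bitscore qstart qend sstart send qseq sseq",
                ],
                check=True, capture_output=True, text=True,
            )
        hits = []
        for line in out.stdout.splitlines():
            f = line.split("\t")
            e = self.entries[f[1]]
            # restore U residues masked as C for the aligner
            sseq = _restore_u(f[10], int(f[7]), e.seq)
            hits.append(
                Hit(
                    subject_id=f[1], organism=e.organism, evalue=float(f[3]),
                    pident=float(f[2]), bitscore=float(f[4]), qstart=int(f[5]),
                    qend=int(f[6]), sstart=int(f[7]), send=int(f[8]),
                    qseq_aln=f[9], sseq_aln=sseq,
                    subject_is_known_selenoprotein=e.is_known_selenoprotein,
                    family=e.family,
                )
            )
        return hits


def _restore_u(sseq_aln: str, sstart: int, original: str) -> str:
    pos = sstart - 1
    out = []
    for ch in sseq_aln:
        if ch == "-":
            out.append(ch)
        else:
            out.append(original[pos] if original[pos] == "U" else ch)
            pos += 1
    return "".join(out)


# ---------------- search + retention ----------------


def search_homologs(
    candidate: SelenoCandidate,
    backend,
    query_id: str = "query",
    max_evalue: float = 0.01,
    min_identity: float = 20.0,
) -> list[Hit]:
    """Run a backend, filter by e-value/identity, sort deterministically.

    The query is submitted with U replaced by C (aligners have no Sec
    scores); the Sec index travels out-of-band on the candidate.
    """
    hits = backend.search(query_id, candidate.protein)
    kept = [h for h in hits if h.evalue <= max_evalue and h.pident >= min_identity]
    kept.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return kept


def classify_hit(hit: Hit, sec_query_pos: int) -> str:
    """Class of one hit w.r.t. the query's Sec position.

    sec_homolog: subject has U aligned there (or is a flagged known
    selenoprotein whose aligned residue is its annotated Sec, conventionally
    written U); cys_homolog: subject has C aligned there; other: any other
    residue, a gap, or the position outside the aligned span.
    """
    res = hit.subject_residue_at(sec_query_pos)
    if res == "U":
        return "sec_homolog"
    if res == "C":
        return "cys_homolog"
    if res is not None and hit.subject_is_known_selenoprotein and res == "X":
        # curated known selenoproteins sometimes mask Sec as X
        return "sec_homolog"
    return "other"


def decide(classes: Sequence[str], organisms: Sequence[str], top_n: int = 10,
           min_cys: int = 2) -> tuple[bool, str, list[int]]:
    """Retention decision from per-hit classes and organism tags (in the
    backend's sorted order).  Pure function used by apply_retention_rule."""
    sec_idx = [i for i, c in enumerate(classes) if c == "sec_homolog"]
    if sec_idx:
        return True, "sec_homolog", sec_idx
    cys_idx = [i for i, c in enumerate(classes[:top_n]) if c == "cys_homolog"]
    orgs = {organisms[i] for i in cys_idx}
    if len(orgs) >= min_cys:
        return True, "cys_rule", cys_idx
    return False, "rejected", []


def apply_retention_rule(hits: Sequence[Hit], sec_query_pos: int) -> Decision:
    """Keep a candidate if (i) any Sec-containing homolog is present, or
    (ii) >= 2 of the top 10 hits are Cys-homologs from different organisms."""
    classes = [classify_hit(h, sec_query_pos) for h in hits]
    organisms = [h.organism for h in hits]
    keep, reason, idx = decide(classes, organisms)
    return Decision(keep=keep, reason=reason, supporting=tuple(hits[i].subject_id for i in idx))


def label_known_or_new(
    candidate: SelenoCandidate,
    hits: Sequence[Hit],
    decision: Decision,
    known_selenoprotein_ids: set[str],
) -> tuple[str, Optional[str]]:
    """('known', family) when a supporting Sec-homolog belongs to the curated
    set (best e-value wins), else ('new', None)."""
    if not decision.keep:
        raise ContractError("label_known_or_new called on a rejected candidate")
    if decision.reason != "sec_homolog":
        return "new", None
    supporting = [h for h in hits if h.subject_id in decision.supporting
                  and h.subject_id in known_selenoprotein_ids]
    if not supporting:
        return "new", None
    best = min(supporting, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return "known", best.family
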