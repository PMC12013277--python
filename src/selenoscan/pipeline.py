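"""End-to-end selenoprotein gene prediction.

Stage order mirrors the two-module design: (1) enumerate every TGA triplet
on both strands, (2) reconstruct valid TGA-anchored ORFs, (3) score the
fixed-length downstream window of each candidate with the trained
classifier, (4) pass model-positive candidates through the homology filter,
(5) label retained candidates known/new and write GFF3 + protein FASTA +
TSV.  Stage counts are non-increasing and logged in the report metadata.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import filter as flt
from . import scan
from .model import Classifier, score_windows


@dataclass(frozen=True)
class PipelineConfig:
    scan_params: scan.ScanParams = scan.ScanParams()
    score_threshold: float = 0.5
    max_evalue: float = 0.01
    min_identity: float = 20.0
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(
            {
                "window_len": self.scan_params.window_len,
                "min_upstream_codons": self.scan_params.min_upstream_codons,
                "min_orf_len": self.scan_params.min_orf_len,
                "terminators": sorted(self.scan_params.terminator_set),
                "longest_orf": self.scan_params.longest_orf,
                "score_threshold": self.score_threshold,
                "max_evalue": self.max_evalue,
                "min_identity": self.min_identity,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CandidateRow:
    contig: str
    strand: str
    start: int  # strand-local, 0-based
    tga_pos: int
    stop_pos: Optional[int]
    sec_codon_index: int
    score: float
    keep: bool
    reason: str
    label: str  # known / new / rejected
    family: Optional[str]
    supporting: tuple[str, ...]
    protein: str


@dataclass
class PredictionReport:
    rows: list[CandidateRow]
    counts: dict[str, int]
    metadata: dict

    def retained(self) -> list[CandidateRow]:
        return [r for r in self.rows if r.keep]


def run_pipeline(
    genomes: Sequence[scan.GenomeRecord],
    classifier: Classifier,
    backend,
    config: PipelineConfig = PipelineConfig(),
    known_selenoprotein_ids: Optional[set[str]] = None,
    log=print,
) -> PredictionReport:
    """Scan genomes, score downstream windows, homology-filter positives."""
    params = config.scan_params
    if params.window_len != classifier.cfg.window_len:
        raise ValueError(
            f"scan window_len {params.window_len} != classifier window_len "
            f"{classifier.cfg.window_len}"
        )
    known = known_selenoprotein_ids or set()

    n_sites = 0
    candidates: list[tuple[scan.GenomeRecord, scan.TgaSite, scan.CandidateOrf, str]] = []
    seen: set[tuple[str, str, int]] = set()
    for g in genomes:
        sites = scan.enumerate_tga_sites(g)
        n_sites += len(sites)
        for site in sites:
            orf = scan.find_candidate_orf(g, site, params)
            if orf is None:
                continue
            key = (orf.contig, orf.strand, orf.tga_pos)
            if key in seen:
                continue
            seen.add(key)
            win = scan.extract_downstream_window(g, site, params)
            if win is None:
                continue
            candidates.append((g, site, orf, win.seq))

    candidates.sort(key=lambda c: (c[2].contig, c[2].strand, c[2].tga_pos))
    scores = (
        score_windows(classifier, [c[3] for c in candidates])
        if candidates
        else np.empty(0)
    )

    rows: list[CandidateRow] = []
    n_positive = 0
    n_retained = 0
    for (g, site, orf, _win), score in zip(candidates, scores):
        if score < config.score_threshold:
            continue
        n_positive += 1
        if orf.partial3:
            continue  # cannot translate a 3'-partial candidate for homology
        cand = flt.translate_orf(orf, g)
        qid = f"{orf.contig}:{orf.strand}:{orf.tga_pos}"
        hits = flt.search_homologs(
            cand, backend, query_id=qid,
            max_evalue=config.max_evalue, min_identity=config.min_identity,
        )
        decision = flt.apply_retention_rule(hits, cand.sec_index)
        if decision.keep:
            n_retained += 1
            label, family = flt.label_known_or_new(cand, hits, decision, known)
        else:
            label, family = "rejected", None
        rows.append(
            CandidateRow(
                contig=orf.contig, strand=orf.strand, start=orf.start_pos,
                tga_pos=orf.tga_pos, stop_pos=orf.stop_pos,
                sec_codon_index=orf.sec_codon_index, score=float(score),
                keep=decision.keep, reason=decision.reason, label=label,
                family=family, supporting=decision.supporting, protein=cand.protein,
            )
        )

    counts = {
        "tga_sites": n_sites,
        "valid_orfs": len(candidates),
        "model_positive": n_positive,
        "retained": n_retained,
    }
    if log:
        log(f"[selenoscan] stages: {counts}", file=sys.stderr)
    metadata = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "model_profile": classifier.cfg.profile,
        "window_len": classifier.cfg.window_len,
        "k": classifier.cfg.k,
        "score_threshold": config.score_threshold,
        "counts": counts,
    }
    return PredictionReport(rows=rows, counts=counts, metadata=metadata)


# ---------------- output writers ----------------


def write_outputs(report: PredictionReport, genomes: Sequence[scan.GenomeRecord], out_dir) -> dict[str, Path]:
    """GFF3 (1-based inclusive CDS features), protein FASTA, TSV report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lens = {g.id: g.length for g in genomes}

    gff = ["##gff-version 3"]
    fasta: list[str] = []
    tsv = [
        "contig\tstrand\tstart\ttga_pos\tstop_pos\tsec_codon_index\tscore\t"
        "keep\treason\tlabel\tfamily\tsupporting"
    ]
    for i, r in enumerate(sorted(report.retained(), key=lambda r: (r.contig, r.strand, r.tga_pos))):
        cid = f"seleno_{i:04d}"
        orf = scan.CandidateOrf(
            contig=r.contig, strand=r.strand, start_pos=r.start,
            tga_pos=r.tga_pos, stop_pos=r.stop_pos,
        )
        f0, f1 = scan.to_forward_coords(orf, lens[r.contig])
        attrs = (
            f"ID={cid};sec_codon_position={r.sec_codon_index + 1};"
            f"score={r.score:.4f};label={r.label}"
            + (f";family={r.family}" if r.family else "")
        )
        gff.append(
            f"{r.contig}\tselenoscan\tCDS\t{f0 + 1}\t{f1}\t{r.score:.4f}\t"
            f"{r.strand}\t0\t{attrs}"
        )
        fasta.append(f">{cid} {r.contig}:{r.strand}:{r.tga_pos}\n{r.protein}")
    for r in sorted(report.rows, key=lambda r: (r.contig, r.strand, r.tga_pos)):
        tsv.append(
            f"{r.contig}\t{r.strand}\t{r.start}\t{r.tga_pos}\t"
            f"{r.stop_pos if r.stop_pos is not None else '.'}\t{r.sec_codon_index}\t"
            f"{r.score:.6f}\t{int(r.keep)}\t{r.reason}\t{r.label}\t"
            f"{r.family or '.'}\t{','.join(r.supporting) or '.'}"
        )

    paths = {
        "gff3": out / "predictions.gff3",
        "proteins": out / "proteins.fasta",
        "report": out / "report.tsv",
        "metadata": out / "run_metadata.json",
    }
    paths["gff3"].write_text("\n".join(gff) + "\n")
    paths["proteins"].write_text("\n".join(fasta) + ("\n" if fasta else ""))
    paths["report"].write_text("\n".join(tsv) + "\n")
    paths["metadata"].write_text(json.dumps(report.metadata, indent=1, sort_keys=True))
    return paths
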