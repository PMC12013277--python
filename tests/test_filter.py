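"""Translation, homology search, hit classification and the retention rule."""

import itertools

import numpy as np
import pytest

from selenoscan import filter as flt
from selenoscan import scan
from selenoscan.filter import DbEntry, Decision, Hit
from selenoscan.scan import CandidateOrf, ContractError, GenomeRecord


def make_hit(cls="other", org="orgA", sid="s1", evalue=1e-5, pident=50.0, bitscore=50.0,
             qlen=10, sec_pos=4):
    """A hit whose subject residue at sec_pos realizes the requested class."""
    q = "M" + "A" * (qlen - 1)
    s = list("M" + "G" * (qlen - 1))
    s[sec_pos] = {"sec_homolog": "U", "cys_homolog": "C", "other": "G"}[cls]
    return Hit(
        subject_id=sid, organism=org, evalue=evalue, pident=pident, bitscore=bitscore,
        qstart=1, qend=qlen, sstart=1, send=qlen, qseq_aln=q, sseq_aln="".join(s),
    )


# ---- translation ----


def test_translation_of_worked_example():
    g = GenomeRecord("c", "ATGTGTTGAGCCTAA")
    orf = CandidateOrf("c", "+", 0, 6, 12)
    cand = flt.translate_orf(orf, g)
    assert cand.protein == "MCUA"
    assert cand.sec_index == 2


def test_alternative_start_codons_become_met():
    for start in ("GTG", "CTG"):
        g = GenomeRecord("c", start + "TGAGCCTAA")
        cand = flt.translate_orf(CandidateOrf("c", "+", 0, 3, 9), g)
        assert cand.protein.startswith("MU")


def test_internal_terminator_is_contract_error():
    g = GenomeRecord("c", "ATGTAATGAGCCTAA")
    with pytest.raises(ContractError):
        flt.translate_orf(CandidateOrf("c", "+", 0, 6, 12), g)


def test_translation_matches_codon_table_oracle():
    """Random valid ORFs vs an independent per-codon table lookup."""
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    rng = np.random.default_rng(8)
    sense = [c for c in map("".join, itertools.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    for _ in range(50):
        n = int(rng.integers(5, 40))
        codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), n)]
        sec_idx = int(rng.integers(1, len(codons)))
        codons[sec_idx] = "TGA"
        seq = "".join(codons) + "TAA"
        g = GenomeRecord("c", seq)
        orf = CandidateOrf("c", "+", 0, sec_idx * 3, len(seq) - 3)
        got = flt.translate_orf(orf, g).protein
        exp = "".join(
            "M" if i == 0 else ("U" if c == "TGA" else fwd[c])
            for i, c in enumerate(codons)
        )
        assert got == exp


# ---- search + thresholds ----


def make_candidate(protein="MAAAUAAAAA"):
    # a synthetic candidate wrapper; coordinates are irrelevant to search
    orf = CandidateOrf("c", "+", 0, 3 * protein.index("U"), 3 * len(protein))
    return flt.SelenoCandidate(orf=orf, protein=protein)


def test_exact_cys_variant_is_top_hit_at_full_identity():
    cand = make_candidate("MAEKLCGHIRWQPTVNDSYF" * 3 + "UAEKLCGHIRWQPTVNDSYF")
    c_variant = cand.protein.replace("U", "C")
    backend = flt.LocalAlignmentBackend(
        [DbEntry("exact", "orgX", None, c_variant)]
        + [DbEntry(f"junk{i}", f"o{i}", None, "MWYFHKNDE" * 10) for i in range(3)]
    )
    hits = flt.search_homologs(cand, backend)
    assert hits and hits[0].subject_id == "exact"
    assert hits[0].pident == pytest.approx(100.0)


def test_evalue_and_identity_thresholds():
    h_bad_e = make_hit(evalue=0.5)
    h_bad_id = make_hit(pident=15.0, sid="s2")
    h_ok = make_hit(evalue=1e-4, sid="s3")

    class Fake:
        def search(self, qid, q):
            return [h_bad_e, h_bad_id, h_ok]

    hits = flt.search_homologs(make_candidate(), Fake())
    assert [h.subject_id for h in hits] == ["s3"]


def test_hit_ordering_deterministic():
    hits = [
        make_hit(sid="b", evalue=1e-5, bitscore=40),
        make_hit(sid="a", evalue=1e-5, bitscore=40),
        make_hit(sid="c", evalue=1e-5, bitscore=60),
        make_hit(sid="d", evalue=1e-7, bitscore=10),
    ]

    class Fake:
        def search(self, qid, q):
            return hits

    got = [h.subject_id for h in flt.search_homologs(make_candidate(), Fake())]
    assert got == ["d", "c", "a", "b"]


# ---- hit classification ----


def test_classify_hit_residue_cases():
    assert flt.classify_hit(make_hit("sec_homolog"), 4) == "sec_homolog"
    assert flt.classify_hit(make_hit("cys_homolog"), 4) == "cys_homolog"
    assert flt.classify_hit(make_hit("other"), 4) == "other"


def test_sec_position_in_gap_or_outside_span_is_other():
    gap = Hit(
        subject_id="s", organism="o", evalue=1e-5, pident=40, bitscore=30,
        qstart=1, qend=8, sstart=1, send=7,
        qseq_aln="MAAAXAAA", sseq_aln="MAAA-AAA",
    )
    assert flt.classify_hit(gap, 4) == "other"
    outside = make_hit(qlen=4, sec_pos=1)
    assert outside.subject_residue_at(9) is None
    assert flt.classify_hit(outside, 9) == "other"


# ---- retention rule ----


def brute_force_decision(classes, organisms):
    """Literal reading: (i) at least one Sec-containing homolog anywhere, or
    (ii) at least two of the top ten hits are Cys-containing homologs in
    different organisms."""
    if any(c == "sec_homolog" for c in classes):
        return True
    top = list(zip(classes, organisms))[:10]
    cys_orgs = {o for c, o in top if c == "cys_homolog"}
    return len(cys_orgs) >= 2


def test_single_sec_homolog_keeps():
    d = flt.apply_retention_rule([make_hit("sec_homolog")], 4)
    assert d.keep and d.reason == "sec_homolog"


def test_two_cys_homologs_different_organisms_keep():
    hits = [make_hit("cys_homolog", org="orgA", sid="a"),
            make_hit("cys_homolog", org="orgB", sid="b")]
    d = flt.apply_retention_rule(hits, 4)
    assert d.keep and d.reason == "cys_rule"
    assert set(d.supporting) == {"a", "b"}


def test_two_cys_homologs_same_organism_reject():
    hits = [make_hit("cys_homolog", org="orgA", sid="a"),
            make_hit("cys_homolog", org="orgA", sid="b")]
    assert not flt.apply_retention_rule(hits, 4).keep


def test_cys_rule_counts_only_top_ten():
    hits = [make_hit("other", org=f"o{i}", sid=f"s{i}") for i in range(10)]
    hits += [make_hit("cys_homolog", org="oA", sid="cA"),
             make_hit("cys_homolog", org="oB", sid="cB")]
    assert not flt.apply_retention_rule(hits, 4).keep


def test_empty_hit_list_rejects():
    d = flt.apply_retention_rule([], 4)
    assert not d.keep and d.reason == "rejected"


def test_decision_matches_bruteforce_over_configurations():
    """Exhaustive through length 6, seeded random configurations to 12."""
    classes3 = ["sec_homolog", "cys_homolog", "other"]
    orgs3 = ["o1", "o2", "o3"]
    combos = list(itertools.product(classes3, orgs3))
    # exhaustive short configurations
    for n in range(0, 7):
        for cfg in itertools.product(range(len(combos)), repeat=n):
            classes = [combos[i][0] for i in cfg]
            organisms = [combos[i][1] for i in cfg]
            keep, _, _ = flt.decide(classes, organisms)
            assert keep == brute_force_decision(classes, organisms)
    # sampled long configurations
    rng = np.random.default_rng(9)
    for _ in range(4000):
        n = int(rng.integers(7, 13))
        idx = rng.integers(0, len(combos), size=n)
        classes = [combos[i][0] for i in idx]
        organisms = [combos[i][1] for i in idx]
        keep, _, _ = flt.decide(classes, organisms)
        assert keep == brute_force_decision(classes, organisms)


def test_retention_monotone_in_sec_evidence():
    """Adding a sec homolog never flips keep->reject; removing hits never
    flips reject->keep."""
    rng = np.random.default_rng(10)
    classes3 = ["sec_homolog", "cys_homolog", "other"]
    for _ in range(300):
        n = int(rng.integers(0, 12))
        classes = [classes3[i] for i in rng.integers(0, 3, n)]
        orgs = [f"o{i}" for i in rng.integers(0, 3, n)]
        base, _, _ = flt.decide(classes, orgs)
        kept_with_sec, _, _ = flt.decide(classes + ["sec_homolog"], orgs + ["oX"])
        assert kept_with_sec  # criterion (i) always satisfiable by addition
        if not base:
            for k in range(n):
                sub_keep, _, _ = flt.decide(classes[:k], orgs[:k])
                assert not sub_keep or brute_force_decision(classes[:k], orgs[:k])


def test_decision_ignores_payload_fields():
    """Metamorphic: evalue/bitscore/id changes that preserve order, classes
    and organisms leave the decision unchanged."""
    hits = [make_hit("cys_homolog", org="oA", sid="a", evalue=1e-9),
            make_hit("other", org="oB", sid="b", evalue=1e-8),
            make_hit("cys_homolog", org="oC", sid="c", evalue=1e-7)]
    d1 = flt.apply_retention_rule(hits, 4)
    relabeled = [
        Hit(subject_id=h.subject_id + "_x", organism=h.organism,
            evalue=h.evalue * 0.1, pident=min(h.pident + 9, 100.0), bitscore=h.bitscore + 5,
            qstart=h.qstart, qend=h.qend, sstart=h.sstart, send=h.send,
            qseq_aln=h.qseq_aln, sseq_aln=h.sseq_aln)
        for h in hits
    ]
    d2 = flt.apply_retention_rule(relabeled, 4)
    assert d1.keep == d2.keep and d1.reason == d2.reason


# ---- known/new labeling ----


def test_known_label_uses_best_evalue_family():
    cand = make_candidate()
    h1 = Hit(subject_id="k1", organism="o1", evalue=1e-10, pident=60, bitscore=80,
             qstart=1, qend=10, sstart=1, send=10, qseq_aln="MAAAUAAAAA",
             sseq_aln="MAAAUAAAAA", subject_is_known_selenoprotein=True, family="famA")
    h2 = Hit(subject_id="k2", organism="o2", evalue=1e-5, pident=60, bitscore=40,
             qstart=1, qend=10, sstart=1, send=10, qseq_aln="MAAAUAAAAA",
             sseq_aln="MAAAUAAAAA", subject_is_known_selenoprotein=True, family="famB")
    hits = [h1, h2]
    d = flt.apply_retention_rule(hits, 4)
    label, family = flt.label_known_or_new(cand, hits, d, {"k1", "k2"})
    assert (label, family) == ("known", "famA")


def test_cys_rule_only_candidates_are_new():
    cand = make_candidate()
    hits = [make_hit("cys_homolog", org="oA", sid="a"),
            make_hit("cys_homolog", org="oB", sid="b")]
    d = flt.apply_retention_rule(hits, 4)
    assert flt.label_known_or_new(cand, hits, d, {"a"}) == ("new", None)


def test_labeling_rejected_candidate_is_contract_error():
    cand = make_candidate()
    d = Decision(keep=False, reason="rejected")
    with pytest.raises(ContractError):
        flt.label_known_or_new(cand, [], d, set())


# ---- hits TSV round trip ----


def test_precomputed_backend_roundtrip(tmp_path):
    line = "\t".join(["q1", "subj", "55.0", "1e-06", "80.2", "1", "10", "1", "10",
                      "MAAAUAAAAA", "MAAACAAAAA", "orgZ"])
    f = tmp_path / "hits.tsv"
    f.write_text(line + "\n")
    backend = flt.PrecomputedHitsBackend(f)
    hits = backend.search("q1", "MAAAUAAAAA")
    assert len(hits) == 1
    assert hits[0].organism == "orgZ"
    assert flt.classify_hit(hits[0], 4) == "cys_homolog"
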