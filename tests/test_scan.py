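"""Scanner: TGA enumeration, ORF reconstruction, window extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selenoscan import scan

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


# ---- brute-force oracles ----


def oracle_tga_sites(genome):
    """Position-by-position scan of both strands."""
    out = []
    for strand in "+-":
        s = genome.seq if strand == "+" else scan.reverse_complement(genome.seq)
        for i in range(len(s) - 2):
            if s[i : i + 3] == "TGA":
                out.append((strand, i))
    return sorted(out)


def oracle_orf(genome, site, params):
    """Enumerate every in-frame codon explicitly, then apply the rules."""
    s = genome.seq if site.strand == "+" else scan.reverse_complement(genome.seq)
    p = site.pos
    codons_up = [(q, s[q : q + 3]) for q in range(p - 3, -1, -3)]
    starts = []
    for q, c in codons_up:
        if c in params.terminator_set:
            break
        if c in scan.START_CODONS:
            starts.append(q)
    if not starts:
        return None
    start = min(starts) if params.longest_orf else max(starts)
    stop = None
    for q in range(p + 3, len(s) - 2, 3):
        if s[q : q + 3] in params.terminator_set:
            stop = q
            break
    if (p - start) // 3 < params.min_upstream_codons:
        return None
    end = stop if stop is not None else len(s) - (len(s) - start) % 3
    if end - start < params.min_orf_len:
        return None
    return (start, p, stop)


# ---- reverse complement ----


def test_reverse_complement_definition():
    assert scan.reverse_complement("ATGC") == "GCAT"
    assert scan.reverse_complement("TGA") == "TCA"
    assert scan.reverse_complement("ANRY") == "RYNT"


def test_reverse_complement_rejects_non_iupac():
    with pytest.raises(scan.AlphabetError):
        scan.reverse_complement("ATGZ")


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_reverse_complement_involution(seed):
    rng = np.random.default_rng(seed)
    s = random_seq(rng, 1000)
    assert scan.reverse_complement(scan.reverse_complement(s)) == s


# ---- TGA enumeration ----


def test_single_tga_plus_strand():
    sites = scan.enumerate_tga_sites(scan.GenomeRecord("c", "TGA"))
    assert [(s.strand, s.pos) for s in sites] == [("+", 0)]


def test_single_tga_minus_strand():
    sites = scan.enumerate_tga_sites(scan.GenomeRecord("c", "TCA"))
    assert [(s.strand, s.pos) for s in sites] == [("-", 0)]


def test_enumerate_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        g = scan.GenomeRecord("c", random_seq(rng, 2000))
        got = [(s.strand, s.pos) for s in scan.enumerate_tga_sites(g)]
        assert got == oracle_tga_sites(g)


def test_site_count_equals_substring_counts():
    rng = np.random.default_rng(12)
    for _ in range(20):
        seq = random_seq(rng, 3000)
        g = scan.GenomeRecord("c", seq)
        n = len(scan.enumerate_tga_sites(g))
        expected = sum(
            seq[i : i + 3] == "TGA" or seq[i : i + 3] == "TCA" for i in range(len(seq) - 2)
        )
        assert n == expected


def test_strand_symmetry_under_reverse_complement():
    rng = np.random.default_rng(13)
    seq = random_seq(rng, 1500)
    g = scan.GenomeRecord("c", seq)
    g_rc = scan.GenomeRecord("c", scan.reverse_complement(seq))
    swap = {"+": "-", "-": "+"}
    fwd = sorted((s.strand, s.pos) for s in scan.enumerate_tga_sites(g))
    rc = sorted((swap[s.strand], s.pos) for s in scan.enumerate_tga_sites(g_rc))
    assert fwd == rc


def test_ambiguous_bases_never_match():
    g = scan.GenomeRecord("c", "TGNTGRNNN")
    assert scan.enumerate_tga_sites(g) == []


# ---- ORF reconstruction ----

RELAXED = scan.ScanParams(min_upstream_codons=0, min_orf_len=0)


def test_worked_orf_example():
    g = scan.GenomeRecord("c", "ATGAAATGAGGGTAA")
    site = scan.TgaSite("c", "+", 6)
    orf = scan.find_candidate_orf(g, site, RELAXED)
    assert (orf.start_pos, orf.stop_pos, orf.sec_codon_index) == (0, 12, 2)
    assert not orf.partial3


def test_interrupted_upstream_returns_none():
    # in-frame TAA separates every start from the TGA
    g = scan.GenomeRecord("c", "ATGTAATGAGGGTAA")
    site = scan.TgaSite("c", "+", 6)
    assert scan.find_candidate_orf(g, site, RELAXED) is None


def test_non_tga_site_is_contract_violation():
    g = scan.GenomeRecord("c", "ATGAAATGAGGGTAA")
    with pytest.raises(scan.ContractError):
        scan.find_candidate_orf(g, scan.TgaSite("c", "+", 0), RELAXED)


@pytest.mark.parametrize("longest", [True, False])
def test_orf_matches_bruteforce_oracle(longest):
    rng = np.random.default_rng(21 if longest else 22)
    params = scan.ScanParams(min_upstream_codons=0, min_orf_len=0, longest_orf=longest)
    checked = 0
    for _ in range(200):
        g = scan.GenomeRecord("c", random_seq(rng, 600))
        for site in scan.enumerate_tga_sites(g):
            got = scan.find_candidate_orf(g, site, params)
            exp = oracle_orf(g, site, params)
            if exp is None:
                assert got is None
            else:
                assert (got.start_pos, got.tga_pos, got.stop_pos) == exp
                checked += 1
    assert checked > 100


def test_orf_thresholds_filter_short_orfs():
    g = scan.GenomeRecord("c", "ATGAAATGAGGGTAA")
    site = scan.TgaSite("c", "+", 6)
    assert scan.find_candidate_orf(g, site, scan.ScanParams()) is None  # 10-codon floor
    assert (
        scan.find_candidate_orf(g, site, scan.ScanParams(min_upstream_codons=1, min_orf_len=90))
        is None
    )


def test_orf_invariants_on_random_genomes():
    rng = np.random.default_rng(23)
    params = scan.ScanParams(min_upstream_codons=1, min_orf_len=9)
    for _ in range(30):
        g = scan.GenomeRecord("c", random_seq(rng, 1500))
        for site in scan.enumerate_tga_sites(g):
            orf = scan.find_candidate_orf(g, site, params)
            if orf is None:
                continue
            s = g.seq if orf.strand == "+" else scan.reverse_complement(g.seq)
            assert (orf.tga_pos - orf.start_pos) % 3 == 0
            assert s[orf.start_pos : orf.start_pos + 3] in scan.START_CODONS
            for q in range(orf.start_pos, orf.tga_pos, 3):
                assert s[q : q + 3] not in params.terminator_set
            if orf.stop_pos is not None:
                assert s[orf.stop_pos : orf.stop_pos + 3] in params.terminator_set


def test_tga_can_be_configured_as_terminator():
    # with TGA in the terminator set the downstream walk stops at the next TGA
    g = scan.GenomeRecord("c", "ATG" + "AAA" * 4 + "TGA" + "AAA" + "TGA" + "AAATAA")
    site = scan.TgaSite("c", "+", 15)
    params = scan.ScanParams(
        min_upstream_codons=0, min_orf_len=0,
        terminator_set=frozenset({"TAA", "TAG", "TGA"}),
    )
    orf = scan.find_candidate_orf(g, site, params)
    assert orf.stop_pos == 21


# ---- window extraction ----


def test_plus_strand_window_is_forward_substring():
    rng = np.random.default_rng(31)
    seq = random_seq(rng, 400)
    g = scan.GenomeRecord("c", seq)
    site = scan.TgaSite("c", "+", 50)
    w = scan.extract_downstream_window(g, site, scan.ScanParams(window_len=300))
    assert w.seq == seq[53:353]
    assert w.n_padded == 0


def test_short_window_padding_policy():
    g = scan.GenomeRecord("c", "TGA" + "ACGTACGTAC")
    w = scan.extract_downstream_window(g, scan.TgaSite("c", "+", 0), scan.ScanParams())
    assert len(w.seq) == 300 and w.n_padded == 290
    assert w.seq.startswith("ACGTACGTAC") and set(w.seq[10:]) == {"N"}
    none = scan.extract_downstream_window(
        g, scan.TgaSite("c", "+", 0), scan.ScanParams(pad_short_windows=False)
    )
    assert none is None


def test_minus_strand_window_matches_whole_contig_rc_oracle():
    rng = np.random.default_rng(32)
    params = scan.ScanParams(window_len=100)
    for _ in range(50):
        seq = random_seq(rng, 800)
        g = scan.GenomeRecord("c", seq)
        g_rc = scan.GenomeRecord("c", scan.reverse_complement(seq))
        for site in scan.enumerate_tga_sites(g):
            if site.strand != "-":
                continue
            w = scan.extract_downstream_window(g, site, params)
            # oracle: apply the + strand rule on the reverse-complemented contig
            w_oracle = scan.extract_downstream_window(
                g_rc, scan.TgaSite("c", "+", site.pos), params
            )
            assert w.seq == w_oracle.seq and w.n_padded == w_oracle.n_padded


def test_windows_are_deterministic():
    rng = np.random.default_rng(33)
    seq = random_seq(rng, 2000)
    g = scan.GenomeRecord("c", seq)
    params = scan.ScanParams()

    def all_windows():
        return [
            scan.extract_downstream_window(g, s, params).seq
            for s in scan.enumerate_tga_sites(g)
        ]

    assert all_windows() == all_windows()
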