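"""Seed-and-extend local alignment, alignment statistics and translation."""

import math

import numpy as np
import pytest
from Bio import Align

from seedasm.seqio import ReadStore, SeqRecord
from seedasm.search import (
    NUCLEOTIDE_SCHEME,
    align_local,
    bitscore_evalue,
    revcomp,
    search_store,
    six_frame_translate,
)
from .conftest import mutate_copy, random_seq


def sw_oracle():
    """Independent optimal local-alignment scorer (full Smith-Waterman)."""
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=NUCLEOTIDE_SCHEME.match,
        mismatch_score=NUCLEOTIDE_SCHEME.mismatch,
        open_gap_score=-(NUCLEOTIDE_SCHEME.gap_open + NUCLEOTIDE_SCHEME.gap_extend),
        extend_gap_score=-NUCLEOTIDE_SCHEME.gap_extend,
    )
    return aligner


def test_self_alignment_is_perfect(rng):
    seq = random_seq(rng, 100)
    hits = align_local(SeqRecord("q", seq), SeqRecord("s", seq))
    assert hits[0].identity == 1.0
    assert hits[0].align_len == 100
    assert hits[0].strand == "+"
    assert (hits[0].q_start, hits[0].q_end) == (0, 100)


def test_reverse_complement_hit_reports_minus_strand(rng):
    core = random_seq(rng, 120)
    subject = random_seq(rng, 60) + core + random_seq(rng, 60)
    hits = align_local(SeqRecord("q", revcomp(core)), SeqRecord("s", subject))
    top = hits[0]
    assert top.strand == "-"
    assert top.identity == 1.0
    assert (top.s_start, top.s_end) == (60, 180)


def test_strand_symmetry_of_coordinates(rng):
    q = random_seq(rng, 150)
    s = random_seq(rng, 40) + mutate_copy(rng, q, n_subs=4) + random_seq(rng, 40)
    fwd = align_local(SeqRecord("q", q), SeqRecord("s", s))[0]
    rev = align_local(SeqRecord("q", revcomp(q)), SeqRecord("s", s))[0]
    # same subject interval, reflected query interval, flipped strand
    assert (fwd.s_start, fwd.s_end) == (rev.s_start, rev.s_end)
    assert (fwd.q_start, fwd.q_end) == (len(q) - rev.q_end, len(q) - rev.q_start)
    assert {fwd.strand, rev.strand} == {"+", "-"}


def test_optimal_score_matches_smith_waterman_oracle(rng):
    """Banded seed-and-extend must find the optimum on homologous pairs."""
    aligner = sw_oracle()
    for _ in range(60):
        n = int(rng.integers(80, 400))
        a = random_seq(rng, n)
        b = mutate_copy(rng, a, n_subs=max(1, n // 40), n_indels=int(rng.integers(0, 3)))
        if rng.random() < 0.3:
            b = random_seq(rng, 30) + b + random_seq(rng, 30)
        if rng.random() < 0.3:
            b = revcomp(b)
        hits = align_local(SeqRecord("a", a), SeqRecord("b", b))
        mine = hits[0].raw_score if hits else 0
        oracle = max(int(aligner.score(a, b)), int(aligner.score(revcomp(a), b)))
        assert mine == oracle


def test_empty_sequences_rejected_and_short_subject_yields_nothing(rng):
    with pytest.raises(ValueError, match="empty"):
        SeqRecord("q", "")  # empty queries cannot even be constructed
    # subject shorter than the seed length yields no hits
    assert align_local(SeqRecord("q", random_seq(rng, 50)), SeqRecord("s", "ACGTA")) == []


def test_bitscore_evalue_closed_forms():
    scheme = NUCLEOTIDE_SCHEME
    # S' = 0 implies E = m*n
    s0 = math.log(scheme.K) / scheme.lam  # raw score giving zero bits
    bits, ev = bitscore_evalue(0, 100, 1000, scheme)
    assert ev == pytest.approx(100 * 1000 * 2 ** (-bits))
    # doubling n doubles E at fixed score
    _, e1 = bitscore_evalue(30, 100, 1000, scheme)
    _, e2 = bitscore_evalue(30, 100, 2000, scheme)
    assert e2 == pytest.approx(2 * e1)
    # one extra bit halves E
    b1, ea = bitscore_evalue(30, 100, 1000, scheme)
    s_plus = 30 + math.log(2) / scheme.lam
    eb = 100 * 1000 * 2 ** (-(b1 + 1))
    assert eb == pytest.approx(ea / 2)


def test_evalue_monotone_in_score():
    evs = [bitscore_evalue(s, 200, 10_000, NUCLEOTIDE_SCHEME)[1] for s in range(0, 200, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


def test_tighter_cutoff_returns_subset(rng):
    store = ReadStore()
    src = random_seq(rng, 2000)
    for i in range(40):
        start = int(rng.integers(0, 1800))
        store.add(SeqRecord(f"r{i}", mutate_copy(rng, src[start : start + 200], n_subs=3)))
    query = [SeqRecord("q", src[500:1500])]
    loose = {h.subject_id for h in search_store(query, store, 1e-10)}
    tight = {h.subject_id for h in search_store(query, store, 1e-20)}
    assert tight <= loose


def test_search_store_ranks_exact_read_first_and_respects_cutoff(rng):
    store = ReadStore()
    target = random_seq(rng, 300)
    store.add(SeqRecord("exact", target))
    for i in range(20):
        store.add(SeqRecord(f"noise{i}", random_seq(rng, 300)))
    hits = search_store([SeqRecord("q", target)], store, 1e-5)
    assert hits[0].subject_id == "exact"
    assert search_store([SeqRecord("q", target)], store, 1e-300) == []


def test_search_store_recovers_planted_motif_exactly(rng):
    """Reads carrying the motif are exactly the ones recovered (oracle sweep)."""
    motif = random_seq(rng, 80)
    store = ReadStore()
    planted = set()
    for i in range(100):
        seq = random_seq(rng, 200)
        if i % 5 == 0:
            pos = int(rng.integers(0, 120))
            seq = seq[:pos] + motif + seq[pos + 80 :]
            planted.add(f"r{i}")
        store.add(SeqRecord(f"r{i}", seq))
    hits = search_store([SeqRecord("m", motif)], store, 1e-20)
    assert {h.subject_id for h in hits} == planted
    aligner = sw_oracle()
    for h in hits:
        assert h.raw_score == int(aligner.score(motif, store[h.subject_id].sequence))


def test_max_hits_truncates_ranking(rng):
    store = ReadStore()
    src = random_seq(rng, 500)
    for i in range(30):
        store.add(SeqRecord(f"r{i:02d}", mutate_copy(rng, src, n_subs=i)))
    hits = search_store([SeqRecord("q", src)], store, 10.0, max_hits=7)
    assert len(hits) == 7
    scores = [h.bitscore for h in hits]
    assert scores == sorted(scores, reverse=True)


@pytest.mark.parametrize(
    "seq, frame_index, expected",
    [
        ("ATGAAA", 0, "MK"),  # frame +1
        ("TTTCAT", 3, "MK"),  # frame -1 reads the reverse complement
        ("ATGAAAC", 1, "*N"),  # frame +2 drops the trailing partial codon
    ],
)
def test_six_frame_translation(seq, frame_index, expected):
    assert six_frame_translate(seq)[frame_index] == expected


def test_six_frame_lengths_follow_truncation_rule():
    frames = six_frame_translate("ATGAAAC")  # length 7
    assert [len(f) for f in frames] == [2, 2, 1, 2, 2, 1]


def test_protein_query_finds_encoding_read(rng):
    from seedasm.search import PROTEIN_SCHEME

    protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    codons = {
        "M": "ATG", "K": "AAA", "T": "ACT", "A": "GCT", "Y": "TAT", "I": "ATT",
        "Q": "CAA", "R": "CGT", "S": "TCT", "F": "TTT", "V": "GTT", "H": "CAT",
        "L": "CTT", "E": "GAA", "G": "GGT",
    }
    nt = "".join(codons[a] for a in protein)
    subject = SeqRecord("s", random_seq(rng, 50) + nt + random_seq(rng, 50))
    hits = align_local(SeqRecord("p", protein), subject, scheme=PROTEIN_SCHEME)
    top = hits[0]
    assert top.frame == 1 or top.frame == 2 or top.frame == 3
    assert top.identity == 1.0
    assert top.s_start >= 50 and top.s_end <= 50 + len(nt) + 2
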