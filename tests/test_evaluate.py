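"""Accuracy records, trajectories, locus calling, anchors and closed forms."""

import numpy as np
import pytest

from seedasm.assemble import Contig
from seedasm.evaluate import (
    alignment_identity,
    call_loci,
    classify_trajectory,
    contig_accuracy,
    contig_loci_ratio,
    coverage_fold,
    lengthening_bins,
    primer_match_prob,
    region_span_sum,
    snp_anchor_scan,
    trajectory_stats,
)
from seedasm.pipeline import CycleReport
from seedasm.seqio import SeqRecord
from .conftest import mutate_copy, random_seq


def as_contig(cid, seq):
    return Contig(id=cid, sequence=seq, depth=np.ones(len(seq), np.int32))


# -- contig accuracy ---------------------------------------------------------

def test_exact_substring_contig_has_identity_one(rng):
    ref = SeqRecord("ref", random_seq(rng, 2000))
    contig = as_contig("c1", ref.sequence[400:1300])
    rec = contig_accuracy([contig], ref)[0]
    assert rec.identity == 1.0
    assert rec.align_len == 900
    assert rec.mismatches_terminal == 0 and rec.mismatches_middle == 0


def test_terminal_and_middle_mismatch_rates(rng):
    ref = SeqRecord("ref", random_seq(rng, 1000))
    seq = list(ref.sequence[200:600])  # 400-nt contig
    # plant 2 mismatches in the first 100 bases, 1 in the middle 200
    for pos in (10, 50, 200):
        seq[pos] = "A" if seq[pos] != "A" else "C"
    rec = contig_accuracy([as_contig("c1", "".join(seq))], ref)[0]
    assert rec.len_terminal == 200 and rec.len_middle == 200
    assert rec.mismatches_terminal == 2 and rec.mismatches_middle == 1
    assert rec.terminal_rate == pytest.approx(0.01)
    assert rec.middle_rate == pytest.approx(0.005)


def test_unalignable_contig_flagged(rng):
    ref = SeqRecord("ref", random_seq(rng, 500))
    rec = contig_accuracy([as_contig("c1", random_seq(rng, 300))], ref)[0]
    assert not rec.aligned and rec.identity == 0.0


# -- trajectories ------------------------------------------------------------

def test_trajectory_table_schema():
    reports = [CycleReport(cycle=i, longest_matching=100 * i) for i in (1, 2, 3)]
    df = trajectory_stats(reports)
    assert list(df.columns) == [
        "cycle", "n_reads_selected", "n_contigs_all", "n_contigs_matching",
        "longest_all", "longest_matching", "mean_len_all", "mean_len_matching",
    ]
    assert len(df) == 3


@pytest.mark.parametrize(
    "lengths, label",
    [
        ([10, 20, 30], "monotone"),
        ([10, 20, 20, 30], "stepwise"),
        ([10, 30, 10, 30], "alternating"),
        ([10, 30, 20], "peaked"),
    ],
)
def test_trajectory_classification(lengths, label):
    assert classify_trajectory(lengths) == label


def test_lengthening_bins_boundaries_and_counts():
    assert lengthening_bins([1.39]) == [1, 0, 0, 0, 0, 0]
    assert lengthening_bins([1.40]) == [0, 1, 0, 0, 0, 0]
    assert lengthening_bins([1.0, 2.0, 3.5]) == [1, 0, 1, 0, 0, 1]
    assert sum(lengthening_bins([1.0 + 0.1 * i for i in range(30)])) == 30


# -- locus calling -----------------------------------------------------------

def test_overlapping_hits_merge_into_one_locus():
    calls = call_loci([("chr1", 100, 500), ("chr1", 450, 900)])
    assert len(calls) == 1
    assert (calls[0].start, calls[0].end, calls[0].n_hits) == (100, 900, 1)


def test_gap_over_threshold_opens_new_locus():
    calls = call_loci(
        [("chr1", 100, 500), ("chr1", 600, 900), ("chr1", 15000, 15400)]
    )
    assert len(calls) == 2
    assert calls[0].n_hits == 2  # 600 > 500 counts a distinct hit
    assert (calls[1].start, calls[1].end) == (15000, 15400)


def test_call_loci_invariant_to_input_order(rng):
    hits = []
    for _ in range(50):
        s = int(rng.integers(1, 10**6))
        hits.append(("chr2", s, s + int(rng.integers(100, 2000))))
    a = call_loci(hits)
    shuffled = list(hits)
    rng.shuffle(shuffled)
    assert call_loci(shuffled) == a


def test_call_loci_empty_and_ratio():
    assert call_loci([]) == []
    assert contig_loci_ratio(10, 10) == 1.0
    assert contig_loci_ratio(25.5, 34.9) == pytest.approx(0.73, abs=0.005)
    assert contig_loci_ratio(0, 0) == 0.0
    with pytest.raises(ValueError):
        contig_loci_ratio(5, 0)


# -- SNP anchors -------------------------------------------------------------

def test_identical_contigs_have_no_anchor_sites(rng):
    seq = random_seq(rng, 1200)
    sites = snp_anchor_scan([as_contig("a", seq), as_contig("b", seq)])
    assert sites == []


def test_two_snps_form_one_anchor_pair(rng):
    seq = random_seq(rng, 1200)
    other = list(seq)
    for pos in (199, 899):  # 0-based; 1-based 200 and 900
        other[pos] = "A" if other[pos] != "A" else "C"
    sites = snp_anchor_scan(
        [as_contig("a", seq), as_contig("b", "".join(other))],
        min_product=600,
        max_product=1100,
    )
    a_sites = {s.position: s for s in sites if s.contig_id == "a"}
    assert set(a_sites) == {200, 900}
    assert a_sites[200].paired_with == 900


def test_position_shared_with_any_contig_is_not_specific(rng):
    seq = random_seq(rng, 900)
    b = list(seq)
    b[450] = "A" if b[450] != "A" else "C"  # B differs from A and C at 450
    sites = snp_anchor_scan(
        [as_contig("a", seq), as_contig("b", "".join(b)), as_contig("c", seq)]
    )
    # position 451 is specific for b (differs from both), not for a or c
    assert {s.contig_id for s in sites} == {"b"}


def test_anchor_scan_symmetric_under_relabeling(rng):
    seq = random_seq(rng, 800)
    other = mutate_copy(rng, seq, n_subs=4)
    s1 = snp_anchor_scan([as_contig("a", seq), as_contig("b", other)])
    s2 = snp_anchor_scan([as_contig("b", other), as_contig("a", seq)])
    key = lambda sites: sorted((s.contig_id, s.position) for s in sites)
    assert key(s1) == key(s2)


# -- closed forms ------------------------------------------------------------

def test_primer_match_probability_worked_values():
    assert round(primer_match_prob(0.990, 20, 20), 3) == 0.669
    assert round(primer_match_prob(0.995, 20, 20), 3) == 0.818
    assert primer_match_prob(1.0, 25, 31) == 1.0


def test_coverage_fold_values():
    assert round(coverage_fold(87.4e9, 2.4e9), 1) == 36.4
    assert round(coverage_fold(178.5e9, 17e9), 1) == 10.5
    assert coverage_fold(123.0, 123.0) == 1.0


def test_region_span_sum_values():
    assert region_span_sum([(1, 10)]) == 10
    assert region_span_sum([]) == 0
    ranges = [
        (559066659, 596637530),
        (627849254, 696738616),
        (454010413, 496939616),
    ]
    assert region_span_sum(ranges) == 149_389_439


def test_alignment_identity_basics(rng):
    seq = random_seq(rng, 400)
    assert alignment_identity(seq, seq) == 1.0
    noisy = mutate_copy(rng, seq, n_subs=40)
    assert 0.85 < alignment_identity(seq, noisy) < 0.95
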