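"""Overlap detection, greedy OLC assembly and consensus calling."""

import numpy as np
import pytest

from seedasm.assemble import (
    AssemblerParams,
    ExternalAssembler,
    consensus,
    external_adapter,
    find_overlaps,
    greedy_assemble,
    parse_contig_fasta,
)
from seedasm.search import revcomp
from seedasm.seqio import SeqRecord
from .conftest import mutate_copy, random_seq


def test_exact_dovetail_overlap_detected(rng):
    shared = random_seq(rng, 50)
    x = SeqRecord("X", random_seq(rng, 80) + shared)
    y = SeqRecord("Y", shared + random_seq(rng, 70))
    ov = find_overlaps([x, y])[0]
    assert (ov.length, ov.identity, ov.orientation) == (50, 1.0, "same")
    assert (ov.a_start, ov.a_end, ov.b_start, ov.b_end) == (80, 130, 0, 50)


def test_one_mismatch_overlap_identity(rng):
    shared = random_seq(rng, 50)
    noisy = mutate_copy(rng, shared, n_subs=1)
    x = SeqRecord("X", random_seq(rng, 80) + shared)
    y = SeqRecord("Y", noisy + random_seq(rng, 70))
    ov = find_overlaps([x, y])[0]
    assert ov.identity == pytest.approx(49 / 50)


def test_reverse_orientation_overlap(rng):
    shared = random_seq(rng, 60)
    x = SeqRecord("X", random_seq(rng, 90) + shared)
    y = SeqRecord("Y", revcomp(shared + random_seq(rng, 90)))
    ov = find_overlaps([x, y])[0]
    assert ov.orientation == "reverse"
    assert ov.length == 60 and ov.identity == 1.0


def test_overlaps_match_exhaustive_pair_oracle(rng):
    """Accepted pairs equal a brute-force all-pairs check on a small set."""
    params = AssemblerParams(min_overlap=40, min_identity=0.9)
    src = random_seq(rng, 900)
    reads = [SeqRecord(f"r{i}", src[120 * i : 120 * i + 240]) for i in range(6)]
    reads.append(SeqRecord("far", random_seq(rng, 240)))
    found = {(o.read_a, o.read_b) for o in find_overlaps(reads, params)}
    # oracle: adjacent tiles overlap by 120, one-apart tiles touch at 0
    expected = {(f"r{i}", f"r{i+1}") for i in range(5)}
    assert found == expected


def test_greedy_reconstructs_tiled_source(rng):
    src = random_seq(rng, 2500)
    reads = [SeqRecord(f"t{i}", src[i : i + 250]) for i in range(0, 2251, 125)]
    contigs = greedy_assemble(reads)
    assert len(contigs) == 1
    assert contigs[0].sequence == src
    assert contigs[0].n_reads == len(reads)


def test_reconstruction_with_reverse_complemented_reads(rng):
    src = random_seq(rng, 1200)
    reads = []
    for i, start in enumerate(range(0, 1001, 100)):
        piece = src[start : start + 200]
        reads.append(SeqRecord(f"t{i}", revcomp(piece) if i % 3 == 1 else piece))
    contigs = greedy_assemble(reads)
    assert len(contigs) == 1
    assert contigs[0].sequence in (src, revcomp(src))


def test_disjoint_sources_produce_separate_contigs(rng):
    a, b = random_seq(rng, 600), random_seq(rng, 600)
    reads = [SeqRecord(f"a{i}", a[i : i + 200]) for i in range(0, 401, 100)]
    reads += [SeqRecord(f"b{i}", b[i : i + 200]) for i in range(0, 401, 100)]
    contigs = greedy_assemble(reads)
    assert len(contigs) == 2
    assert {contigs[0].sequence, contigs[1].sequence} == {a, b}


def test_short_overlaps_leave_only_singletons(rng):
    params = AssemblerParams(min_overlap=40)
    reads = [SeqRecord(f"s{i}", random_seq(rng, 120)) for i in range(5)]
    assert greedy_assemble(reads, params) == []
    kept = greedy_assemble(reads, AssemblerParams(min_overlap=40, keep_singletons=True))
    assert len(kept) == 5


def test_depth_counts_reads_spanning_each_column(rng):
    src = random_seq(rng, 300)
    reads = [SeqRecord(f"r{i}", src[i : i + 100]) for i in range(0, 201, 50)]
    contig = greedy_assemble(reads)[0]
    depth = contig.depth
    assert len(depth) == 300
    assert depth.min() >= 1
    # interior columns are covered by two tiles, the very ends by one
    assert depth[0] == 1 and depth[150] == 2


def test_contigs_sorted_by_length_and_named_sequentially(rng):
    a, b = random_seq(rng, 900), random_seq(rng, 500)
    reads = [SeqRecord(f"a{i}", a[i : i + 300]) for i in range(0, 601, 150)]
    reads += [SeqRecord(f"b{i}", b[i : i + 200]) for i in range(0, 301, 100)]
    contigs = greedy_assemble(reads)
    assert [c.id for c in contigs] == ["c1", "c2"]
    assert len(contigs[0]) >= len(contigs[1])


@pytest.mark.parametrize(
    "column, expected",
    [
        ([("A", 1), ("A", 1), ("G", 1)], "A"),  # simple majority
        ([("A", 1), ("G", 1)], "A"),  # tie broken by base order
        ([("A", 10), ("G", 40)], "G"),  # quality-weighted
        ([("T", 1), ("-", 1)], "T"),  # deletion loses ties to bases
    ],
)
def test_consensus_majority_and_tie_break(column, expected):
    assert consensus(column) == expected


def test_external_adapter_missing_tool_is_descriptive(rng):
    tool = ExternalAssembler(name="cap3", command="definitely_not_installed_xyz {reads}")
    with pytest.raises(FileNotFoundError, match="built-in"):
        external_adapter([SeqRecord("r", random_seq(rng, 100))], tool)


def test_external_contig_fasta_parses_into_contigs(tmp_path):
    (tmp_path / "out.fasta").write_text(">Contig1\nACGTACGT\n>Contig2\nTTTT\n")
    contigs = parse_contig_fasta(tmp_path / "out.fasta")
    assert [c.id for c in contigs] == ["Contig1", "Contig2"]
    assert contigs[0].sequence == "ACGTACGT"
    assert contigs[0].layout == []
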