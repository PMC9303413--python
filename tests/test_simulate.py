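"""Founder/allele generation, read drawing and the four-channel error model."""

import numpy as np
import pytest

from seedasm.simulate import (
    DIRIGENT_LIKE_FREQS,
    ErrorModel,
    LONG_ERRORS,
    LocusModel,
    ReadProfile,
    SHORT_ERRORS,
    apply_errors,
    draw_reads,
    make_alleles,
    make_founder,
    simulate_readset,
)
from seedasm.seqio import SeqRecord


def test_founder_length_and_determinism():
    model = LocusModel()
    a = make_founder(model, np.random.default_rng(5))
    b = make_founder(model, np.random.default_rng(5))
    assert len(a) == 7000
    assert a == b


def test_degenerate_base_frequencies():
    model = LocusModel(founder_len=500, core_len=100, base_freqs=(1.0, 0.0, 0.0, 0.0))
    assert make_founder(model, np.random.default_rng(0)) == "A" * 500


def test_preset_frequencies_sum_to_one():
    assert sum(DIRIGENT_LIKE_FREQS) == pytest.approx(1.0)
    LocusModel(base_freqs=DIRIGENT_LIKE_FREQS)  # validates


def test_zero_mutation_rates_reproduce_founder(rng):
    model = LocusModel(p_mut_core=0.0, p_mut_flank=0.0, n_alleles=3)
    founder = make_founder(model, rng)
    assert make_alleles(founder, model, rng) == [founder] * 3


def test_allele_snp_count_matches_binomial_expectation(rng):
    """Mean SNPs/allele ~ core_len*p_core + flank_len*p_flank, within 3 sigma."""
    model = LocusModel(n_alleles=100)
    founder = make_founder(model, rng)
    alleles = make_alleles(founder, model, rng)
    counts = [sum(x != y for x, y in zip(founder, a)) for a in alleles]
    mean = 1800 * 0.005 + 5200 * 0.02  # = 113
    var = 1800 * 0.005 * 0.995 + 5200 * 0.02 * 0.98
    sigma_of_mean = np.sqrt(var / len(alleles))
    assert abs(np.mean(counts) - mean) < 3 * sigma_of_mean


def test_core_snp_density_below_flank_density(rng):
    model = LocusModel(n_alleles=50)
    founder = make_founder(model, rng)
    cs = model.resolved_core_start
    core_mut = flank_mut = 0
    for allele in make_alleles(founder, model, rng):
        diffs = [i for i, (x, y) in enumerate(zip(founder, allele)) if x != y]
        core_mut += sum(cs <= i < cs + 1800 for i in diffs)
        flank_mut += sum(not (cs <= i < cs + 1800) for i in diffs)
    assert core_mut / 1800 < flank_mut / 5200


def test_read_count_tracks_coverage(rng):
    src = make_founder(LocusModel(founder_len=10000, core_len=100), rng)
    reads = draw_reads(src, ReadProfile(kind="length_file", lengths=[500]), 5.0, rng)
    assert abs(sum(len(r) for r in reads) - 50000) <= 500  # within one read


def test_paired_reads_conventions(rng):
    src = make_founder(LocusModel(founder_len=20000, core_len=100), rng)
    reads = draw_reads(src, ReadProfile(kind="paired_short"), 1.0, rng)
    r1, r2 = reads[0], reads[1]
    assert r1.id.endswith("/1") and r2.id.endswith("/2")
    assert r1.mate_of == r2.id and r2.mate_of == r1.id
    assert len(r1) == 150 and len(r2) == 150


def test_long_reads_within_length_bounds(rng):
    src = make_founder(LocusModel(founder_len=50000, core_len=100), rng)
    reads = draw_reads(src, ReadProfile(kind="long"), 2.0, rng)
    assert all(7000 <= len(r) <= 14000 for r in reads)


def test_truth_ids_encode_placement(rng):
    src = make_founder(LocusModel(founder_len=10000, core_len=100), rng)
    reads = draw_reads(src, ReadProfile(kind="length_file", lengths=[400]), 2.0, rng)
    from seedasm.search import revcomp

    for read in reads[:20]:
        _, source, start, strand = read.id.rsplit("_", 3)
        seq = src[int(start) : int(start) + len(read)]
        assert read.sequence == (seq if strand == "+" else revcomp(seq))


def test_zero_error_model_is_identity(rng):
    read = SeqRecord("r", make_founder(LocusModel(founder_len=2000, core_len=100), rng))
    assert apply_errors(read, ErrorModel(), rng).sequence == read.sequence


def test_forced_substitution_changes_every_base(rng):
    read = SeqRecord("r", "ACGT" * 100)
    out = apply_errors(read, ErrorModel(p_sub=1.0), rng)
    assert len(out.sequence) == 400
    assert all(a != b for a, b in zip(read.sequence, out.sequence))


def test_event_log_matches_sequence_edit_distance(rng):
    import edlib

    src = make_founder(LocusModel(founder_len=5000, core_len=100), rng)
    read = SeqRecord("r", src)
    log = []
    out = apply_errors(read, SHORT_ERRORS, rng, log=log)
    dist = edlib.align(out.sequence, src)["editDistance"]
    # each logged event changes at most one base
    assert dist <= len(log)
    assert dist >= len(log) // 3  # events rarely cancel


def test_realized_substitution_rate_within_3_sigma(rng):
    em = ErrorModel(p_sub=0.01)
    n = 200_000
    src = make_founder(LocusModel(founder_len=n, core_len=100), rng)
    log = []
    apply_errors(SeqRecord("r", src), em, rng, log=log)
    subs = sum(e.kind == "sub" for e in log)
    sigma = np.sqrt(n * 0.01 * 0.99)
    assert abs(subs - n * 0.01) < 3 * sigma


def test_determinism_of_full_readset(rng):
    src = make_founder(LocusModel(founder_len=8000, core_len=100), np.random.default_rng(3))
    out1 = simulate_readset(src, ReadProfile(kind="paired_short"), 2.0, SHORT_ERRORS, np.random.default_rng(9))
    out2 = simulate_readset(src, ReadProfile(kind="paired_short"), 2.0, SHORT_ERRORS, np.random.default_rng(9))
    assert [r.sequence for r in out1[1]] == [r.sequence for r in out2[1]]
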