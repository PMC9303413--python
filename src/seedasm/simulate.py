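"""Synthetic locus, allele and read simulation.

Generates the study conditions every other module is exercised on: a random
founder locus (7 kb with an 1800-nt relatively conserved core) mutated into
nine alleles, accurate 2x150 paired-end reads, and noisy 7-14 kb long reads.
Sequencing errors come from four channels - substitutions, single-base
deletions, single-base insertions, and homopolymer run-length shifts -
emulating Illumina-like and nanopore-like profiles respectively.

Every operation is deterministic under a fixed ``numpy.random.Generator``.
Error events are logged per read so evaluation can compare realized error
rates against the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .search import revcomp
from .seqio import SeqRecord

BASES = "ACGT"

#: Approximate composition of an AT-rich plant defence-gene locus, usable as
#: an alternative to uniform base frequencies for the founder sequence.
DIRIGENT_LIKE_FREQS = (0.31, 0.19, 0.20, 0.30)


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error channels.

    ``p_sub``/``p_del``/``p_ins`` apply independently per base.
    ``p_runshift`` applies once per maximal homopolymer run of at least
    ``min_run_len`` bases and shifts the run length by +/-1 (equiprobable).
    ``min_run_len`` is a calibration choice: with the long-read preset it is
    what brings overall alignment identity to the intended ~90%.
    """

    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0
    p_runshift: float = 0.0
    min_run_len: int = 4

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_del, self.p_ins, self.p_runshift):
            if not (0.0 <= p <= 1.0):
                raise ValueError("error probabilities must be in [0, 1]")


#: Illumina-like accurate short-read profile.
SHORT_ERRORS = ErrorModel(p_sub=0.005, p_del=0.001, p_ins=0.001, p_runshift=0.01)
#: Nanopore-like noisy long-read profile (~90% identity to source).
LONG_ERRORS = ErrorModel(p_sub=0.07, p_del=0.01, p_ins=0.01, p_runshift=0.80)


@dataclass(frozen=True)
class LocusModel:
    """A founder locus with a conserved core and variable flanks."""

    founder_len: int = 7000
    core_len: int = 1800
    core_start: Optional[int] = None  # default: centered
    p_mut_core: float = 0.005
    p_mut_flank: float = 0.02
    n_alleles: int = 9
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.core_len > self.founder_len:
            raise ValueError("core longer than founder")
        start = self.resolved_core_start
        if not (0 <= start and start + self.core_len <= self.founder_len):
            raise ValueError("core interval outside founder")
        if not math.isclose(sum(self.base_freqs), 1.0, abs_tol=1e-6):
            raise ValueError("base frequencies must sum to 1")

    @property
    def resolved_core_start(self) -> int:
        if self.core_start is not None:
            return self.core_start
        return (self.founder_len - self.core_len) // 2


@dataclass(frozen=True)
class ReadProfile:
    """How reads are drawn: paired short, long single, or empirical lengths."""

    kind: str = "paired_short"  # paired_short | long | length_file
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    long_min: int = 7000
    long_max: int = 14000
    lengths: Optional[Sequence[int]] = None  # empirical length distribution

    def __post_init__(self) -> None:
        if self.kind not in ("paired_short", "long", "length_file"):
            raise ValueError(f"unknown read profile kind {self.kind!r}")
        if self.read_len < 1 or self.long_min > self.long_max:
            raise ValueError("bad read length settings")


#: Surrogate for a pyrosequencing-style medium-read length distribution.
MEDIUM_PROFILE = ReadProfile(kind="length_file", lengths=None)


@dataclass
class ErrorEvent:
    read_id: str
    kind: str  # sub | del | ins | runshift
    position: int  # 0-based on the clean read
    detail: str = ""


def make_founder(model: LocusModel, rng: np.random.Generator) -> str:
    """Random founder sequence with the model's base frequencies."""
    draws = rng.choice(4, size=model.founder_len, p=list(model.base_freqs))
    return "".join(BASES[i] for i in draws)


def mutate(seq: str, positions_p: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each position i with probability positions_p[i]."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < positions_p
    idx = np.nonzero(hit)[0]
    lut = {ord(b): [ord(c) for c in BASES if c != b] for b in BASES}
    for i in idx:
        choices = lut.get(arr[i])
        if choices:
            arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def make_alleles(founder: str, model: LocusModel, rng: np.random.Generator) -> list[str]:
    """Derive alleles by region-dependent random substitution.

    Core positions mutate at ``p_mut_core``, flanks at ``p_mut_flank``;
    every substitution goes to a uniformly chosen different base.
    """
    p = np.full(len(founder), model.p_mut_flank)
    cs = model.resolved_core_start
    p[cs : cs + model.core_len] = model.p_mut_core
    return [mutate(founder, p, rng) for _ in range(model.n_alleles)]


def _as_sources(genome: Union[str, dict[str, str], Sequence[str]]) -> list[tuple[str, str]]:
    if isinstance(genome, str):
        return [("src", genome)]
    if isinstance(genome, dict):
        return list(genome.items())
    return [(f"src{i+1}", s) for i, s in enumerate(genome)]


def draw_reads(
    genome: Union[str, dict[str, str], Sequence[str]],
    profile: ReadProfile,
    coverage: float,
    rng: np.random.Generator,
) -> list[SeqRecord]:
    """Draw error-free reads at ~coverage-fold depth, uniformly placed.

    Read ids encode source, start and strand (``<kind><n>_<src>_<start>_<+|->``)
    so downstream evaluation can recover the truth.  Long/medium reads longer
    than their template are truncated.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    sources = _as_sources(genome)
    total_len = sum(len(s) for _, s in sources)
    weights = np.array([len(s) for _, s in sources], dtype=float)
    weights /= weights.sum()
    reads: list[SeqRecord] = []
    target_bases = coverage * total_len
    emitted = 0.0
    i = 0
    while emitted < target_bases:
        i += 1
        si = rng.choice(len(sources), p=weights)
        name, src = sources[si]
        if profile.kind == "paired_short":
            rl = profile.read_len
            insert = int(round(rng.normal(profile.insert_mean, profile.insert_sd)))
            insert = max(2 * rl, min(insert, len(src)))
            if len(src) < insert:
                insert = len(src)
            start = int(rng.integers(0, max(len(src) - insert, 0) + 1))
            fwd = src[start : start + rl]
            rev = revcomp(src[start + insert - rl : start + insert])
            base_id = f"pr{i}_{name}_{start}_+"
            r1 = SeqRecord(f"{base_id}/1", fwd, mate_of=f"{base_id}/2")
            r2 = SeqRecord(f"{base_id}/2", rev, mate_of=f"{base_id}/1")
            reads.extend((r1, r2))
            emitted += len(fwd) + len(rev)
        else:
            if profile.kind == "long":
                length = int(rng.integers(profile.long_min, profile.long_max + 1))
                tag = "lr"
            else:
                if profile.lengths:
                    length = int(profile.lengths[rng.integers(len(profile.lengths))])
                else:  # surrogate for a medium-read length profile
                    length = int(rng.integers(300, 901))
                tag = "mr"
            if length > len(src):
                length = len(src)
            start = int(rng.integers(0, len(src) - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = src[start : start + length]
            if strand == "-":
                seq = revcomp(seq)
            reads.append(SeqRecord(f"{tag}{i}_{name}_{start}_{strand}", seq))
            emitted += length
    return reads


def _maximal_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of maximal homopolymer runs with length >= min_len."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def apply_errors(
    read: SeqRecord,
    em: ErrorModel,
    rng: np.random.Generator,
    log: Optional[list[ErrorEvent]] = None,
) -> SeqRecord:
    """Inject sequencing errors into one read.

    Per-base channels scan left to right (substitution to a different base,
    single-base deletion, single-base insertion before the position); run
    shifts lengthen or shorten qualifying homopolymer runs by one base.
    Events append to ``log`` when given.
    """
    seq = read.sequence
    n = len(seq)
    run_del: set[int] = set()
    run_ins: dict[int, str] = {}
    if em.p_runshift > 0:
        for start, length in _maximal_runs(seq, em.min_run_len):
            if rng.random() < em.p_runshift:
                if rng.random() < 0.5:
                    run_del.add(start)
                    if log is not None:
                        log.append(ErrorEvent(read.id, "runshift", start, "-1"))
                else:
                    run_ins[start] = seq[start]
                    if log is not None:
                        log.append(ErrorEvent(read.id, "runshift", start, "+1"))
    draws = rng.random((n, 3))
    out: list[str] = []
    for i, c in enumerate(seq):
        if i in run_ins:
            out.append(run_ins[i])
        if draws[i, 0] < em.p_del:
            if log is not None:
                log.append(ErrorEvent(read.id, "del", i, c))
            continue
        if draws[i, 1] < em.p_ins:
            ins = BASES[rng.integers(4)]
            out.append(ins)
            if log is not None:
                log.append(ErrorEvent(read.id, "ins", i, ins))
        if i in run_del:
            continue
        if draws[i, 2] < em.p_sub:
            sub = BASES[(BASES.index(c) + 1 + rng.integers(3)) % 4] if c in BASES else BASES[rng.integers(4)]
            out.append(sub)
            if log is not None:
                log.append(ErrorEvent(read.id, "sub", i, f"{c}>{sub}"))
        else:
            out.append(c)
    errored = "".join(out)
    if not errored:  # pathological all-deleted read
        errored = seq[:1]
    return SeqRecord(read.id, errored, mate_of=read.mate_of)


def simulate_readset(
    genome: Union[str, dict[str, str], Sequence[str]],
    profile: ReadProfile,
    coverage: float,
    em: ErrorModel,
    rng: np.random.Generator,
) -> tuple[list[SeqRecord], list[SeqRecord], list[ErrorEvent]]:
    """Draw reads and inject errors; returns (clean, errored, event log)."""
    clean = draw_reads(genome, profile, coverage, rng)
    log: list[ErrorEvent] = []
    errored = [apply_errors(r, em, rng, log) for r in clean]
    return clean, errored, log


def write_truth(
    reads: Iterable[SeqRecord], log: Iterable[ErrorEvent], path: str
) -> None:
    """Truth TSV: one row per read (source, start, strand) plus the events."""
    events: dict[str, list[ErrorEvent]] = {}
    for ev in log:
        events.setdefault(ev.read_id, []).append(ev)
    with open(path, "w") as fh:
        fh.write("read\tsource\tstart\tstrand\tn_events\tevents\n")
        for read in reads:
            parts = read.id.rsplit("_", 3)
            src, start, strand = (parts[1], parts[2], parts[3]) if len(parts) == 4 else ("?", "?", "?")
            evs = events.get(read.id, [])
            desc = ";".join(f"{e.kind}@{e.position}{':' + e.detail if e.detail else ''}" for e in evs)
            fh.write(f"{read.id}\t{src}\t{start}\t{strand}\t{len(evs)}\t{desc}\n")
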