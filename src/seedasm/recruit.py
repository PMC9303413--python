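"""Read selection and long-read fragmentation.

Each cycle, ranked search hits become the read set actually assembled.
Five selection modes limit how many ranked reads go in; long reads can be
broken into non-overlapping pieces of one length (single fragmentation) or
of two lengths combined (double fragmentation), which doubles the apparent
depth for an overlap assembler without adding information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqio import SeqRecord

logger = logging.getLogger("seedasm")

SELECTION_MODES = ("all", "bitscore", "increment", "population", "manual")


class ManualCountsExhausted(Exception):
    """Manual mode has no count for this cycle: a stopping condition."""


@dataclass
class SelectionPolicy:
    mode: str = "increment"
    bitscore_min: float = 0.0
    increment: int = 10
    manual_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.increment < 1:
            raise ValueError("increment must be >= 1")
        if any(c < 0 for c in self.manual_counts):
            raise ValueError("manual counts must be >= 0")


def select_reads(
    ranked: Sequence[tuple[str, float]],
    policy: SelectionPolicy,
    cycle: int = 1,
    previous_ids: Optional[set[str]] = None,
) -> list[str]:
    """Choose which ranked reads to assemble this cycle.

    ``ranked`` must be sorted by bitscore descending (ties by id).  Modes:

    - ``all``: every ranked read.
    - ``bitscore``: reads scoring at least ``bitscore_min``.
    - ``increment``: the top ``increment * cycle`` reads.
    - ``population``: the shortest prefix, extended whole bitscore-tie
      groups at a time, containing every previous-cycle read still ranked.
    - ``manual``: the top ``manual_counts[cycle-1]`` reads; running out of
      counts raises :class:`ManualCountsExhausted`.
    """
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    ids = [rid for rid, _ in ranked]
    if policy.mode == "all":
        return ids
    if policy.mode == "bitscore":
        return [rid for rid, bs in ranked if bs >= policy.bitscore_min]
    if policy.mode == "increment":
        return ids[: policy.increment * cycle]
    if policy.mode == "manual":
        if cycle > len(policy.manual_counts):
            raise ManualCountsExhausted(
                f"no manual read count for cycle {cycle} "
                f"({len(policy.manual_counts)} provided)"
            )
        return ids[: policy.manual_counts[cycle - 1]]
    # population mode
    previous = set(previous_ids or ())
    still_ranked = previous & set(ids)
    for missing in sorted(previous - still_ranked):
        logger.warning("population mode: previous read %s no longer ranked", missing)
    if not still_ranked:
        return []
    chosen: list[str] = []
    remaining = set(still_ranked)
    i = 0
    while i < len(ranked) and remaining:
        # advance one whole bitscore-tie group at a time
        score = ranked[i][1]
        j = i
        while j < len(ranked) and ranked[j][1] == score:
            remaining.discard(ranked[j][0])
            chosen.append(ranked[j][0])
            j += 1
        i = j
    return chosen


@dataclass
class Fragment:
    """A non-overlapping piece of a parent read, with provenance."""

    id: str
    parent_id: str
    offset: int
    sequence: str
    scheme: str  # single | lenA | lenB

    def to_record(self) -> SeqRecord:
        return SeqRecord(id=self.id, sequence=self.sequence)


def fragment_single(read: SeqRecord, L: int, scheme: str = "single") -> list[Fragment]:
    """Break a read into consecutive pieces of length L, keeping the remainder.

    The concatenation of the fragments reconstructs the read exactly; a read
    shorter than L passes through as one fragment.
    """
    if L < 1:
        raise ValueError("fragment length must be >= 1")
    frags = []
    for ordinal, off in enumerate(range(0, len(read.sequence), L), start=1):
        piece = read.sequence[off : off + L]
        frags.append(
            Fragment(
                id=f"{read.id}_{scheme}_{ordinal}",
                parent_id=read.id,
                offset=off,
                sequence=piece,
                scheme=scheme,
            )
        )
    return frags


def fragment_double(read: SeqRecord, L1: int = 610, L2: int = 490) -> list[Fragment]:
    """Fragment at two distinct lengths and pool the pieces.

    Total fragment bases equal twice the read length: apparent depth doubles
    with no new information, letting an overlap assembler span 1-2x regions.
    """
    if L1 == L2:
        raise ValueError("the two fragment lengths must differ")
    return fragment_single(read, L1, scheme="lenA") + fragment_single(read, L2, scheme="lenB")


def fragment_reads(
    reads: Sequence[SeqRecord],
    mode: str = "off",
    frag_len: int = 600,
    frag_len2: int = 490,
) -> list[SeqRecord]:
    """Apply the configured fragmentation to already-selected reads."""
    if mode == "off":
        return list(reads)
    out: list[SeqRecord] = []
    for read in reads:
        if mode == "single":
            frags = fragment_single(read, frag_len)
        elif mode == "double":
            frags = fragment_double(read, frag_len, frag_len2)
        else:
            raise ValueError(f"unknown fragmentation mode {mode!r}")
        out.extend(f.to_record() for f in frags)
    return out
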