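"""Pileup-majority contig polishing.

Plays the racon role with an internal aligner: polishing reads are locally
aligned to the contig, a per-column pileup (with deletions as a fifth
voting symbol and explicit insertion records) is built, and each
sufficiently covered column is replaced by the weighted majority call.
Useful when a draft contig comes from noisy long reads and accurate short
reads from the same locus are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .assemble import Contig
from .search import (
    NUCLEOTIDE_SCHEME,
    ScoringScheme,
    _align_oriented,
    encode_nt,
    revcomp,
)
from .seqio import ReadStore, SeqRecord

logger = logging.getLogger("seedasm")

_ORDER = {c: i for i, c in enumerate("ACGTN-")}


@dataclass
class Pileup:
    """Per-position evidence from read alignments to one contig.

    ``columns[i]`` lists (symbol, weight, read_id) with symbol a base or
    ``-`` for a read deletion; ``insertions[i]`` lists (inserted-string,
    weight, read_id) for material between columns i-1 and i.
    """

    contig_id: str
    columns: list[list[tuple[str, float, str]]]
    insertions: dict[int, list[tuple[str, float, str]]] = field(default_factory=dict)

    @property
    def depth(self) -> list[int]:
        return [len(col) for col in self.columns]


def _best_oriented_alignment(
    read: SeqRecord, s_enc, scheme: ScoringScheme, mat
) -> Optional[tuple[str, int, int, object]]:
    """(oriented sequence, q_start, s_start, ops) of the best local alignment."""
    best = None
    for oriented in (read.sequence, revcomp(read.sequence)):
        q_enc = encode_nt(oriented)
        for score, qs, qe, ss, se, ops in _align_oriented(q_enc, s_enc, scheme, mat):
            if best is None or score > best[0]:
                best = (score, oriented, qs, ss, ops)
    if best is None:
        return None
    _, oriented, qs, ss, ops = best
    return oriented, qs, ss, ops


def build_pileup(
    contig: Contig,
    reads: Iterable[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> Pileup:
    """Align reads to the contig and stack the evidence column by column."""
    s_enc = encode_nt(contig.sequence)
    mat = scheme.score_matrix()
    columns: list[list[tuple[str, float, str]]] = [[] for _ in contig.sequence]
    insertions: dict[int, list[tuple[str, float, str]]] = {}
    n_aligned = 0
    for read in reads:
        hit = _best_oriented_alignment(read, s_enc, scheme, mat)
        if hit is None:
            continue
        n_aligned += 1
        oriented, qi, sj, ops = hit
        quals = read.qualities
        if quals is not None and oriented != read.sequence:
            quals = quals[::-1]
        pending_ins = ""
        pending_w = 0.0
        for op in ops:
            if op == 2:  # query-only: insertion relative to the contig
                pending_ins += oriented[qi]
                pending_w += quals[qi] if quals else 1.0
                qi += 1
                continue
            if pending_ins:
                insertions.setdefault(sj, []).append(
                    (pending_ins, pending_w / len(pending_ins), read.id)
                )
                pending_ins, pending_w = "", 0.0
            if op == 0:  # aligned pair
                w = float(quals[qi]) if quals else 1.0
                columns[sj].append((oriented[qi], w, read.id))
                qi += 1
                sj += 1
            else:  # op == 1, contig-only: the read votes for a deletion
                w = float(quals[qi]) if quals and qi < len(quals) else 1.0
                columns[sj].append(("-", w, read.id))
                sj += 1
    if n_aligned == 0:
        logger.warning("polish: no reads aligned to contig %s", contig.id)
    return Pileup(contig_id=contig.id, columns=columns, insertions=insertions)


def _majority(votes: list[tuple[str, float, str]]) -> str:
    weights: dict[str, float] = {}
    for sym, w, _ in votes:
        weights[sym] = weights.get(sym, 0.0) + w
    return min(weights, key=lambda s: (-weights[s], _ORDER.get(s, 9)))


def polish_once(
    contig: Contig,
    reads: Iterable[SeqRecord],
    min_depth: int = 2,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> str:
    """One polishing pass; returns the corrected consensus sequence.

    Columns with pileup depth below ``min_depth`` are left untouched.  An
    insertion is applied where its total weight exceeds half the weight of
    the flanking column's voters (majority among covering reads).
    """
    pileup = build_pileup(contig, reads, scheme)
    out: list[str] = []
    for j, base in enumerate(contig.sequence):
        votes = pileup.columns[j]
        ins = pileup.insertions.get(j, ())
        if len(votes) >= min_depth and votes:
            col_weight = sum(w for _, w, _ in votes)
            if ins:
                by_seq: dict[str, float] = {}
                for s, w, _ in ins:
                    by_seq[s] = by_seq.get(s, 0.0) + w
                top = min(by_seq, key=lambda s: (-by_seq[s], s))
                if by_seq[top] > col_weight / 2:
                    out.append(top)
            call = _majority(votes)
            if call != "-":
                out.append(call)
        else:
            out.append(base)
    return "".join(out)


def polish(
    contig: Contig,
    reads: ReadStore | Iterable[SeqRecord],
    iterations: int = 1,
    min_depth: int = 2,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> Contig:
    """Polish a contig for a set number of iterations (default cap is 5
    in the pipeline configuration).

    Iteration 0 returns the input unchanged.  The polished contig keeps the
    original layout bookkeeping and gains an id suffix ``.polN``.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return contig
    read_list = list(reads)
    seq = contig.sequence
    done = 0
    for _ in range(iterations):
        draft = Contig(id=contig.id, sequence=seq, layout=contig.layout,
                       depth=contig.depth, n_reads=contig.n_reads)
        new_seq = polish_once(draft, read_list, min_depth=min_depth, scheme=scheme)
        done += 1
        if new_seq == seq:
            break
        seq = new_seq
    return Contig(
        id=f"{contig.id}.pol{done}",
        sequence=seq,
        layout=contig.layout,
        depth=contig.depth,
        n_reads=contig.n_reads,
    )
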