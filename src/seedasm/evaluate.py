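"""Measurement procedures for assemblies and pipeline runs.

Covers contig accuracy against a reference (with a terminal-vs-middle
mismatch split), per-cycle trajectory statistics and their qualitative
classification, lengthening-ratio bins, locus calling from reference hits,
contig-specific SNP scanning for primer anchors, and small closed-form
helpers (primer match probability, coverage fold, region span sums).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .assemble import Contig, _cigar_counts
from .search import Hit, NUCLEOTIDE_SCHEME, ScoringScheme, align_local, revcomp
from .seqio import SeqRecord

TERMINAL_LEN = 100  # bases at each contig end treated as "terminal"


def alignment_identity(a: str, b: str) -> float:
    """Global alignment identity (matches / alignment columns) via edlib."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    eq, mm, gap = _cigar_counts(res["cigar"])
    cols = eq + mm + gap
    return eq / cols if cols else 0.0


# ---------------------------------------------------------------------------
# Contig accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyRecord:
    contig_id: str
    ref_id: Optional[str]
    identity: float
    align_len: int
    mismatches_terminal: int
    mismatches_middle: int
    len_terminal: int
    len_middle: int
    aligned: bool = True

    @property
    def terminal_rate(self) -> float:
        return self.mismatches_terminal / self.len_terminal if self.len_terminal else 0.0

    @property
    def middle_rate(self) -> float:
        return self.mismatches_middle / self.len_middle if self.len_middle else 0.0


def _terminal_middle_split(hit: Hit, contig: Contig, reference: SeqRecord) -> tuple[int, int, int, int]:
    """Mismatch counts and segment lengths for terminal vs middle columns.

    Terminal means within the first or last TERMINAL_LEN contig bases of the
    alignment; every non-match column (mismatch or gap) counts as a mismatch
    for the rate.
    """
    q = contig.sequence if hit.strand == "+" else revcomp(contig.sequence)
    s = reference.sequence
    qs = hit.q_start if hit.strand == "+" else len(q) - hit.q_end
    qe = hit.q_end if hit.strand == "+" else len(q) - hit.q_start
    res = edlib.align(q[qs:qe], s[hit.s_start : hit.s_end], mode="NW", task="path")
    mm_t = mm_m = len_t = len_m = 0
    qi = qs
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n, op = int(num), ch
        num = ""
        for _ in range(n):
            # classify by contig coordinate relative to the aligned segment
            terminal = (qi - qs) < TERMINAL_LEN or (qe - qi) <= TERMINAL_LEN
            if op == "=":
                if terminal:
                    len_t += 1
                else:
                    len_m += 1
            elif op == "X":
                if terminal:
                    len_t += 1
                    mm_t += 1
                else:
                    len_m += 1
                    mm_m += 1
            elif op == "D":  # reference-only column: a contig deletion
                if terminal:
                    mm_t += 1
                else:
                    mm_m += 1
            if op in "=XI":
                qi += 1
                if op == "I":  # contig-only column: insertion error
                    if terminal:
                        len_t += 1
                        mm_t += 1
                    else:
                        len_m += 1
                        mm_m += 1
    return mm_t, mm_m, len_t, len_m


def contig_accuracy(
    contigs: Sequence[Contig],
    reference: SeqRecord | Sequence[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> list[AccuracyRecord]:
    """Best-local-alignment identity of each contig against the reference.

    Contigs with no hit are reported with identity 0 and ``aligned=False``.
    """
    refs = [reference] if isinstance(reference, SeqRecord) else list(reference)
    if not refs:
        raise ValueError("empty reference")
    out = []
    for contig in contigs:
        best: Optional[Hit] = None
        best_ref: Optional[SeqRecord] = None
        for ref in refs:
            hits = align_local(contig.to_record(), ref, scheme=scheme)
            if hits and (best is None or hits[0].bitscore > best.bitscore):
                best, best_ref = hits[0], ref
        if best is None:
            out.append(AccuracyRecord(contig.id, None, 0.0, 0, 0, 0, 0, 0, aligned=False))
            continue
        mm_t, mm_m, len_t, len_m = _terminal_middle_split(best, contig, best_ref)
        out.append(
            AccuracyRecord(
                contig.id, best_ref.id, best.identity, best.align_len,
                mm_t, mm_m, len_t, len_m,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def trajectory_stats(reports: Sequence) -> pd.DataFrame:
    """Per-cycle table of the quantities the cycle engine records."""
    if not reports:
        raise ValueError("no cycle reports")
    rows = []
    for r in reports:
        rows.append(
            {
                "cycle": r.cycle,
                "n_reads_selected": r.n_reads_selected,
                "n_contigs_all": r.n_contigs_all,
                "n_contigs_matching": r.n_contigs_matching,
                "longest_all": r.longest_all,
                "longest_matching": r.longest_matching,
                "mean_len_all": r.mean_len_all,
                "mean_len_matching": r.mean_len_matching,
            }
        )
    return pd.DataFrame(rows)


def classify_trajectory(lengths: Sequence[float], tol: float = 0.0) -> str:
    """Heuristic label for a longest-contig trajectory.

    monotone: never decreases; stepwise: monotone with at least one flat
    stretch; peaked: one rise-then-fall; alternating: two or more direction
    changes.  Documented, deliberately simple rules.
    """
    if len(lengths) < 2:
        return "monotone"
    diffs = [b - a for a, b in zip(lengths, lengths[1:])]
    signs = [0 if abs(d) <= tol else (1 if d > 0 else -1) for d in diffs]
    changes = sum(
        1 for a, b in zip(signs, signs[1:]) if a != 0 and b != 0 and a != b
    )
    if all(s >= 0 for s in signs):
        return "stepwise" if 0 in signs else "monotone"
    if changes >= 2:
        return "alternating"
    return "peaked"


def plot_trajectory(reports: Sequence, path: str) -> None:
    """Longest/mean/count trajectory plot (matching vs all contigs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trajectory_stats(reports)
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(df.cycle, df.longest_matching, "b-", label="longest (matching)")
    ax1.plot(df.cycle, df.mean_len_matching, "b--", label="mean (matching)")
    ax1.plot(df.cycle, df.longest_all, "r-", alpha=0.4, label="longest (all)")
    ax1.set_xlabel("cycle")
    ax1.set_ylabel("contig length (nt)")
    ax2 = ax1.twinx()
    ax2.plot(df.cycle, df.n_contigs_matching, "b:", label="count (matching)")
    ax2.set_ylabel("contig count")
    ax1.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


LENGTHENING_BIN_EDGES = (1.0, 1.4, 1.8, 2.2, 2.6, 3.0)


def lengthening_bins(ratios: Sequence[float]) -> list[int]:
    """Bin lengthening ratios (max longest over cycles / cycle-1 longest).

    Six bins in 0.4 increments: [1.0,1.4), [1.4,1.8), [1.8,2.2), [2.2,2.6),
    [2.6,3.0), [3.0,inf).  Ratios below 1 cannot arise when the maximum
    includes cycle 1; they are counted in the first bin with a warning.
    """
    import logging

    counts = [0] * 6
    for r in ratios:
        if r < 1.0:
            logging.getLogger("seedasm").warning("lengthening ratio %.3f < 1", r)
            counts[0] += 1
            continue
        idx = int(math.floor((r - 1.0) / 0.4 + 1e-9))
        counts[min(idx, 5)] += 1
    return counts


# ---------------------------------------------------------------------------
# Locus calling
# ---------------------------------------------------------------------------

@dataclass
class LocusCall:
    ref_id: str
    start: int  # 1-based inclusive
    end: int
    n_hits: int


def call_loci(
    hits: Iterable[tuple[str, int, int]], gap: int = 10000
) -> list[LocusCall]:
    """Cluster reference hits into loci.

    Hits are (ref_id, start, end), 1-based inclusive, any order.  Per
    reference, hits are sorted by start; a distinct hit is counted wherever
    a start exceeds the previous maximum end, and a new locus opens where
    that gap exceeds ``gap`` bases.
    """
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for ref, s, e in hits:
        if s > e:
            raise ValueError(f"hit start {s} > end {e}")
        by_ref.setdefault(ref, []).append((s, e))
    calls: list[LocusCall] = []
    for ref in sorted(by_ref):
        spans = sorted(by_ref[ref])
        cur_start, cur_end = spans[0]
        n_hits = 1
        for s, e in spans[1:]:
            if s - cur_end > gap:
                calls.append(LocusCall(ref, cur_start, cur_end, n_hits))
                cur_start, cur_end, n_hits = s, e, 1
                continue
            if s > cur_end:
                n_hits += 1
            cur_end = max(cur_end, e)
        calls.append(LocusCall(ref, cur_start, cur_end, n_hits))
    return calls


def contig_loci_ratio(n_contigs: int, n_loci: int) -> float:
    """Contigs per called locus; diagnostic for off-target assembly."""
    if n_loci == 0:
        if n_contigs == 0:
            return 0.0
        raise ValueError("undefined ratio: no loci called")
    return n_contigs / n_loci


# ---------------------------------------------------------------------------
# SNP anchor scanning
# ---------------------------------------------------------------------------

@dataclass
class AnchorSite:
    contig_id: str
    position: int  # 1-based
    kind: str = "contig-specific-SNP"
    paired_with: Optional[int] = None


def _pairwise_base_map(
    query: SeqRecord, subject: SeqRecord, evalue: float
) -> dict[int, list[str]]:
    """query position (0-based, forward) -> bases aligned from subject."""
    out: dict[int, list[str]] = {}
    for hit in align_local(query, subject, keep_ops=True):
        if hit.evalue > evalue or hit.ops is None:
            continue
        m = len(query.sequence)
        if hit.strand == "+":
            q_seq, qi = query.sequence, hit.q_start
        else:
            q_seq, qi = revcomp(query.sequence), m - hit.q_end
        sj = hit.s_start
        s_seq = subject.sequence
        for op in hit.ops:
            if op == 0:
                pos = qi if hit.strand == "+" else m - 1 - qi
                base = s_seq[sj]
                if hit.strand == "-":
                    base = revcomp(base)
                out.setdefault(pos, []).append(base)
                qi += 1
                sj += 1
            elif op == 1:
                sj += 1
            else:
                qi += 1
    return out


def snp_anchor_scan(
    contigs: Sequence[Contig],
    evalue: float = 1e-8,
    min_depth: int = 1,
    min_product: int = 100,
    max_product: int = 2000,
    strict_no_coverage: bool = False,
) -> list[AnchorSite]:
    """Find contig-specific SNP positions usable as primer anchors.

    All-vs-all local alignment (self excluded) gives each contig a per-base
    nonself coverage depth.  Within the interval from the first to the last
    position with depth >= min_depth, a position is contig-specific when its
    base differs from every aligned nonself base (or, with
    ``strict_no_coverage``, when no nonself contig aligns there at all).
    Pairs of such positions separated by [min_product, max_product] bases are
    reported as anchor pairs for a discriminating PCR product.
    """
    if len(contigs) < 2:
        raise ValueError("need at least two contigs")
    sites: list[AnchorSite] = []
    for contig in contigs:
        cover: dict[int, list[str]] = {}
        for other in contigs:
            if other.id == contig.id:
                continue
            for pos, bases in _pairwise_base_map(
                contig.to_record(), other.to_record(), evalue
            ).items():
                cover.setdefault(pos, []).extend(bases)
        covered = [p for p, b in cover.items() if len(b) >= min_depth]
        if not covered:
            continue
        lo, hi = min(covered), max(covered)
        specific: list[int] = []
        for p in range(lo, hi + 1):
            bases = cover.get(p, [])
            if strict_no_coverage:
                if not bases:
                    specific.append(p)
            elif bases and all(b != contig.sequence[p] for b in bases):
                specific.append(p)
        paired: dict[int, int] = {}
        for i, p in enumerate(specific):
            for q in specific[i + 1 :]:
                if min_product <= q - p <= max_product and p not in paired:
                    paired[p] = q
                    break
        for p in specific:
            sites.append(
                AnchorSite(contig.id, p + 1, paired_with=paired.get(p, None) and paired[p] + 1)
            )
    return sites


# ---------------------------------------------------------------------------
# Closed-form helpers
# ---------------------------------------------------------------------------

def primer_match_prob(x: float, m: int, n: int) -> float:
    """Probability that two primers of lengths m and n both match exactly,
    given per-base accuracy x: x**(m + n)."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("accuracy must be in [0, 1]")
    if m < 1 or n < 1:
        raise ValueError("primer lengths must be >= 1")
    return x ** (m + n)


def coverage_fold(total_bases: float, genome_size: float) -> float:
    """Sequencing depth: total bases over genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return total_bases / genome_size


def region_span_sum(ranges: Sequence[tuple[int, int]]) -> int:
    """Total bases in 1-based inclusive ranges."""
    total = 0
    for s, e in ranges:
        if s > e:
            raise ValueError(f"range start {s} > end {e}")
        total += e - s + 1
    return total


def paired_t_statistic(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired t statistic and p-value (scipy), for matched measurements."""
    from scipy import stats

    t, p = stats.ttest_rel(list(a), list(b))
    return float(t), float(p)


def accuracy_table(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [r.contig_id for r in records],
            "reference": [r.ref_id for r in records],
            "identity": [r.identity for r in records],
            "align_len": [r.align_len for r in records],
            "terminal_mismatch_rate": [r.terminal_rate for r in records],
            "middle_mismatch_rate": [r.middle_rate for r in records],
        }
    )
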