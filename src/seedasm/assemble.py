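"""Built-in greedy overlap-layout-consensus assembler.

Replaces an external cap3/phrap call with the same knobs those tools expose:
minimum overlap length, minimum percent identity at the junction, and
match/mismatch/gap scores that rank competing overlaps.  Assembly proceeds
greedily: the best-scoring dovetail (or containment) overlap between any two
current assemblies is merged, the consensus of the junction is recomputed
from per-column read depth, and the process repeats until no overlap passes
the thresholds.  An adapter contract for external assemblers is provided but
never required.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib
import numpy as np

from .seqio import SeqRecord, read_fasta, write_fasta
from .search import revcomp

BASE_ORDER = "ACGTN-"  # deterministic tie-break order for consensus calls


@dataclass(frozen=True)
class AssemblerParams:
    """cap3/phrap-style tunables for the built-in assembler.

    ``min_identity`` 0.83 mirrors a permissive cap3 ``-p 83``; 0.93/0.97 are
    the documented stricter alternatives for separating close paralogs.
    """

    min_overlap: int = 40
    min_identity: float = 0.83
    match: int = 2
    mismatch: int = -4
    gap: int = -5
    keep_singletons: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap < 10:
            raise ValueError("min_overlap must be >= 10")


@dataclass
class Overlap:
    """A dovetail or containment overlap between two reads/assemblies."""

    read_a: str
    read_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # same | reverse
    length: int
    identity: float
    score: float


@dataclass
class Contig:
    """Assembled consensus with per-column support and contributing layout.

    ``layout`` rows are (read_id, contig_start, orientation, read_length);
    starts are approximate to within alignment indels.  ``depth[i]`` counts
    the reads whose placement spans column i.
    """

    id: str
    sequence: str
    layout: list[tuple[str, int, str, int]] = field(default_factory=list)
    depth: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    n_reads: int = 1

    def __len__(self) -> int:
        return len(self.sequence)

    def to_record(self) -> SeqRecord:
        return SeqRecord(id=self.id, sequence=self.sequence)


def consensus(column_bases: Sequence[tuple[str, float]]) -> str:
    """Weighted-majority base call for one column.

    Weights are qualities when available, else 1.  Ties break by the fixed
    base order A < C < G < T < N (then '-').
    """
    if not column_bases:
        raise ValueError("empty column")
    weights: dict[str, float] = {}
    for base, w in column_bases:
        weights[base] = weights.get(base, 0.0) + float(w)
    order = {c: i for i, c in enumerate(BASE_ORDER)}
    return min(weights, key=lambda b: (-weights[b], order.get(b, len(order))))


# ---------------------------------------------------------------------------
# Overlap detection
# ---------------------------------------------------------------------------

def _cigar_walk(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _cigar_counts(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap columns) from an edlib extended CIGAR."""
    eq = mm = gap = 0
    for n, op in _cigar_walk(cigar):
        if op == "=":
            eq += n
        elif op == "X":
            mm += n
        else:
            gap += n
    return eq, mm, gap


_CODE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _kmer_ints(seq: str, k: int) -> np.ndarray:
    """Base-4 packed k-mers per position; -1 where the window contains N."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    km = win @ powers
    bad = np.lib.stride_tricks.sliding_window_view(codes == 4, k).any(axis=1)
    km[bad] = -1
    return km


def _kmer_arrays(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted k-mer ints, their positions), N-containing windows dropped."""
    km = _kmer_ints(seq, k)
    pos = np.nonzero(km >= 0)[0]
    km = km[pos]
    order = np.argsort(km, kind="stable")
    return km[order], pos[order]


def _diagonals(
    skm: np.ndarray,
    spos: np.ndarray,
    b_km: np.ndarray,
    max_candidates: int = 2,
    sample_step: int = 3,
) -> list[int]:
    """Candidate offsets of b[0] on a, from shared k-mers (vectorized join).

    Only every ``sample_step``-th b position is queried (a dovetail overlap
    of min_overlap bases still contributes several seeds).  Diagonals within
    +/-16 of one another are clustered; each cluster is represented by its
    modal diagonal, ranked by total seed count.
    """
    valid = np.nonzero(b_km >= 0)[0]
    if sample_step > 1 and len(valid) > 64:
        valid = valid[::sample_step]
    if len(valid) == 0 or len(skm) == 0:
        return []
    bk = b_km[valid]
    lo = np.searchsorted(skm, bk, side="left")
    hi = np.searchsorted(skm, bk, side="right")
    counts = hi - lo
    hit = counts > 0
    if not hit.any():
        return []
    lo, counts, j_idx = lo[hit], counts[hit], valid[hit]
    # expand [lo, lo+counts) ranges into flat indices into spos
    total = int(counts.sum())
    starts = np.repeat(lo, counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    i_pos = spos[starts + offsets]
    j_pos = np.repeat(j_idx, counts)
    d = i_pos - j_pos
    ud, uc = np.unique(d, return_counts=True)
    breaks = np.nonzero(np.diff(ud) > 16)[0] + 1
    reps: list[tuple[int, int]] = []
    for group in np.split(np.arange(len(ud)), breaks):
        weight = int(uc[group].sum())
        rep = int(ud[group[np.argmax(uc[group])]])
        reps.append((weight, rep))
    reps.sort(key=lambda t: (-t[0], t[1]))
    return [rep for _, rep in reps[:max_candidates]]


def _candidate_diagonals(a: str, b: str, k: int, max_candidates: int = 4) -> list[int]:
    """Offsets of b[0] on a implied by shared k-mers, clustered."""
    skm, spos = _kmer_arrays(a, k)
    return _diagonals(skm, spos, _kmer_ints(b, k), max_candidates)


def _overlap_at(a: str, b: str, d: int, params: AssemblerParams) -> Optional[dict]:
    """Verify the overlap implied by b starting at offset d on a.

    Returns coordinates on a and b (forward of the given strings), identity,
    length and score, or None when the implied overlap fails the thresholds.
    """
    la, lb = len(a), len(b)
    if d >= 0:
        if lb <= la - d:  # b contained in a
            res = edlib.align(b, a, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                return None
            s, e = res["locations"][0]
            coords = (s, e + 1, 0, lb)
            cigar = _swap_cigar(res["cigar"])  # edlib query was b
        else:  # a left of b: suffix of a vs prefix of b
            res = edlib.align(a[d:], b, mode="SHW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                return None
            e = res["locations"][0][1]
            coords = (d, la, 0, e + 1)
            cigar = res["cigar"]
    else:
        dd = -d
        if la <= lb - dd:  # a contained in b
            res = edlib.align(a, b, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                return None
            s, e = res["locations"][0]
            coords = (0, la, s, e + 1)
            cigar = res["cigar"]
        else:  # b left of a: suffix of b vs prefix of a
            res = edlib.align(b[dd:], a, mode="SHW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                return None
            e = res["locations"][0][1]
            coords = (0, e + 1, dd, lb)
            cigar = _swap_cigar(res["cigar"])  # edlib query was b
    eq, mm, gap = _cigar_counts(cigar)
    cols = eq + mm + gap
    if cols == 0:
        return None
    identity = eq / cols
    length = coords[1] - coords[0]
    if length < params.min_overlap or identity < params.min_identity:
        return None
    score = params.match * eq + params.mismatch * mm + params.gap * gap
    return {
        "coords": coords,
        "identity": identity,
        "length": length,
        "score": float(score),
        "cigar": cigar,
    }


def _best_overlap(a: str, b: str, params: AssemblerParams) -> Optional[dict]:
    """Best-scoring overlap between sequences a and b in either orientation."""
    k = min(12, params.min_overlap)
    best: Optional[dict] = None
    for orientation, b_seq in (("same", b), ("reverse", revcomp(b))):
        for d in _candidate_diagonals(a, b_seq, k):
            cand = _overlap_at(a, b_seq, d, params)
            if cand is None:
                continue
            if orientation == "reverse":
                bs, be = cand["coords"][2], cand["coords"][3]
                cand["coords"] = (
                    cand["coords"][0],
                    cand["coords"][1],
                    len(b) - be,
                    len(b) - bs,
                )
            cand["orientation"] = orientation
            if best is None or cand["score"] > best["score"]:
                best = cand
    return best


def find_overlaps(reads: Sequence[SeqRecord], params: Optional[AssemblerParams] = None) -> list[Overlap]:
    """All accepted dovetail/containment overlaps between read pairs.

    Both orientations are tried; only the best overlap per pair is kept.
    Output order is deterministic: score descending, then the id pair.
    """
    params = params or AssemblerParams()
    if len(reads) < 2:
        raise ValueError("need at least two reads")
    out: list[Overlap] = []
    for ra, rb in itertools.combinations(reads, 2):
        cand = _best_overlap(ra.sequence, rb.sequence, params)
        if cand is None:
            continue
        a_s, a_e, b_s, b_e = cand["coords"]
        out.append(
            Overlap(
                ra.id, rb.id, a_s, a_e, b_s, b_e, cand["orientation"],
                cand["length"], cand["identity"], cand["score"],
            )
        )
    out.sort(key=lambda o: (-o.score, o.read_a, o.read_b))
    return out


# ---------------------------------------------------------------------------
# Greedy assembly
# ---------------------------------------------------------------------------

class _Asm:
    """Mutable assembly state: consensus, depth, layout and a k-mer index."""

    __slots__ = (
        "key", "seq", "depth", "layout", "k",
        "skm", "spos", "kms_fwd", "kms_rc", "kmer_set",
    )

    def __init__(self, key: int, seq: str, depth: list[int], layout: list, k: int = 12):
        self.key = key
        self.seq = seq
        self.depth = depth
        self.layout = layout
        self.k = k
        self.skm, self.spos = _kmer_arrays(seq, k)
        self.kms_fwd = _kmer_ints(seq, k)
        self.kms_rc = _kmer_ints(revcomp(seq), k)
        self.kmer_set = set(self.skm.tolist()) | {
            int(km) for km in self.kms_rc.tolist() if km >= 0
        }

    @classmethod
    def from_read(cls, key: int, read: SeqRecord, k: int = 12) -> "_Asm":
        n = len(read.sequence)
        return cls(key, read.sequence, [1] * n, [(read.id, 0, "+", n)], k)


def _flip(asm: _Asm) -> _Asm:
    n = len(asm.seq)
    layout = [
        (rid, n - (start + length), "-" if orient == "+" else "+", length)
        for rid, start, orient, length in asm.layout
    ]
    return _Asm(asm.key, revcomp(asm.seq), asm.depth[::-1], layout, asm.k)


def _column_merge(
    a: _Asm, b: _Asm, a_s: int, a_e: int, b_s: int, b_e: int, cigar: str
) -> tuple[str, list[int]]:
    """Depth-weighted consensus of the junction columns of two assemblies."""
    seq: list[str] = []
    depth: list[int] = []
    i, j = a_s, b_s
    order = {c: k for k, c in enumerate(BASE_ORDER)}
    for n, op in _cigar_walk(cigar):
        for _ in range(n):
            if op in "=X":
                wa, wb = a.depth[i], b.depth[j]
                if op == "=":
                    base = a.seq[i]
                elif wa > wb:
                    base = a.seq[i]
                elif wb > wa:
                    base = b.seq[j]
                else:
                    base = min(a.seq[i], b.seq[j], key=lambda c: order.get(c, 9))
                seq.append(base)
                depth.append(wa + wb)
                i += 1
                j += 1
            elif op == "I":  # column present only in a
                wa = a.depth[i]
                wb = b.depth[min(j, len(b.depth) - 1)]
                if wa >= wb:
                    seq.append(a.seq[i])
                    depth.append(wa)
                i += 1
            else:  # 'D': column present only in b
                wb = b.depth[j]
                wa = a.depth[min(i, len(a.depth) - 1)]
                if wb > wa:
                    seq.append(b.seq[j])
                    depth.append(wb)
                j += 1
    return "".join(seq), depth


def _merge(a: _Asm, b: _Asm, cand: dict, new_key: int) -> _Asm:
    """Merge two assemblies at an accepted overlap (b already oriented)."""
    a_s, a_e, b_s, b_e = cand["coords"]
    cigar = cand["cigar"]
    la, lb = len(a.seq), len(b.seq)
    if b_s == 0 and b_e == lb and not (a_s == 0 and a_e == la and lb > la):
        # b contained in a: consensus stays a's, b's support folds in
        mid, mdep = _column_merge(a, b, a_s, a_e, b_s, b_e, cigar)
        seq = a.seq[:a_s] + mid + a.seq[a_e:]
        depth = a.depth[:a_s] + mdep + a.depth[a_e:]
        shift = a_s - b_s
        layout = a.layout + [
            (rid, start + shift, orient, ln) for rid, start, orient, ln in b.layout
        ]
        return _Asm(new_key, seq, depth, layout, a.k)
    if a_s == 0 and a_e == la and (b_s > 0 or b_e < lb):
        # a contained in b: swap roles (cigar is a-vs-b, so swap via recursion)
        swapped = {
            "coords": (b_s, b_e, a_s, a_e),
            "cigar": _swap_cigar(cigar),
        }
        return _merge(b, a, swapped, new_key)
    if a_e == la and b_s == 0:
        mid, mdep = _column_merge(a, b, a_s, a_e, b_s, b_e, cigar)
        seq = a.seq[:a_s] + mid + b.seq[b_e:]
        depth = a.depth[:a_s] + mdep + b.depth[b_e:]
        shift = a_s - b_s
        layout = a.layout + [
            (rid, start + shift, orient, ln) for rid, start, orient, ln in b.layout
        ]
        return _Asm(new_key, seq, depth, layout, a.k)
    # b left of a
    mid, mdep = _column_merge(a, b, a_s, a_e, b_s, b_e, cigar)
    seq = b.seq[:b_s] + mid + a.seq[a_e:]
    depth = b.depth[:b_s] + mdep + a.depth[a_e:]
    shift = b_s - a_s
    layout = b.layout + [
        (rid, start + shift, orient, ln) for rid, start, orient, ln in a.layout
    ]
    return _Asm(new_key, seq, depth, layout, a.k)


def _swap_cigar(cigar: str) -> str:
    return "".join(
        f"{n}{'D' if op == 'I' else 'I' if op == 'D' else op}"
        for n, op in _cigar_walk(cigar)
    )


def _oriented_candidate(a: _Asm, b: _Asm, params: AssemblerParams) -> Optional[dict]:
    """Best overlap of a vs b with b's orientation resolved; coords on b as oriented."""
    best: Optional[dict] = None
    for orientation, b_seq, b_kms in (
        ("same", b.seq, b.kms_fwd),
        ("reverse", revcomp(b.seq), b.kms_rc),
    ):
        for d in _diagonals(a.skm, a.spos, b_kms):
            cand = _overlap_at(a.seq, b_seq, d, params)
            if cand is None:
                continue
            cand["orientation"] = orientation
            if best is None or cand["score"] > best["score"]:
                best = cand
    return best


def greedy_assemble(
    reads: Sequence[SeqRecord], params: Optional[AssemblerParams] = None
) -> list[Contig]:
    """Assemble reads by repeated best-overlap merging.

    Contigs are named c1..cN in decreasing length; singletons are dropped
    unless ``params.keep_singletons``.  Deterministic for a fixed input
    order: ties in overlap score break on the participating keys.
    """
    params = params or AssemblerParams()
    if not reads:
        raise ValueError("no reads to assemble")
    k = min(12, params.min_overlap)
    items: dict[int, _Asm] = {}
    for key, read in enumerate(reads):
        items[key] = _Asm.from_read(key, read, k)
    next_key = len(reads)

    # candidate pairs: items sharing at least one k-mer in either orientation
    buckets: dict[int, list[int]] = {}
    for key in sorted(items):
        for kmer in items[key].kmer_set:
            buckets.setdefault(kmer, []).append(key)
    neighbors: dict[int, set[int]] = {key: set() for key in items}
    for bucket in buckets.values():
        for ka, kb in itertools.combinations(sorted(set(bucket)), 2):
            neighbors[ka].add(kb)
            neighbors[kb].add(ka)

    cache: dict[tuple[int, int], Optional[dict]] = {}
    for ka in sorted(neighbors):
        for kb in sorted(neighbors[ka]):
            if ka < kb:
                cache[(ka, kb)] = _oriented_candidate(items[ka], items[kb], params)

    while True:
        best_pair: Optional[tuple[int, int]] = None
        best_cand: Optional[dict] = None
        for (ka, kb), cand in cache.items():
            if cand is None or ka not in items or kb not in items:
                continue
            if (
                best_cand is None
                or cand["score"] > best_cand["score"]
                or (cand["score"] == best_cand["score"] and (ka, kb) < best_pair)
            ):
                best_pair, best_cand = (ka, kb), cand
        if best_cand is None:
            break
        ka, kb = best_pair
        a, b = items.pop(ka), items.pop(kb)
        if best_cand["orientation"] == "reverse":
            b = _flip(b)
        merged = _merge(a, b, best_cand, next_key)
        cache = {
            pk: pv
            for pk, pv in cache.items()
            if ka not in pk and kb not in pk
        }
        items[next_key] = merged
        inherited = (neighbors.pop(ka, set()) | neighbors.pop(kb, set())) & set(items)
        inherited.discard(next_key)
        neighbors[next_key] = inherited
        for other in inherited:
            neighbors[other].add(next_key)
            lo, hi = min(other, next_key), max(other, next_key)
            cache[(lo, hi)] = _oriented_candidate(items[lo], items[hi], params)
        next_key += 1

    finished = [asm for asm in items.values() if len(asm.layout) >= 2 or params.keep_singletons]
    finished.sort(key=lambda s: (-len(s.seq), s.key))
    contigs = []
    for i, asm in enumerate(finished, start=1):
        contigs.append(
            Contig(
                id=f"c{i}",
                sequence=asm.seq,
                layout=list(asm.layout),
                depth=np.array(asm.depth, dtype=np.int32),
                n_reads=len(asm.layout),
            )
        )
    return contigs


def write_layout(contigs: Sequence[Contig], path: str) -> None:
    """TSV layout report: read, contig, start, orientation."""
    with open(path, "w") as fh:
        fh.write("read\tcontig\tstart\torientation\n")
        for contig in contigs:
            for rid, start, orient, _ in contig.layout:
                fh.write(f"{rid}\t{contig.id}\t{start}\t{orient}\n")


# ---------------------------------------------------------------------------
# External assembler adapter (contract only)
# ---------------------------------------------------------------------------

@dataclass
class ExternalAssembler:
    """Adapter contract for an external assembler executable.

    ``command`` is a template with ``{reads}`` and ``{outdir}`` slots; the
    tool's contig FASTA (``contigs_glob`` within outdir) is parsed into
    :class:`Contig` records with empty layout/depth.  Interchangeable with
    the built-in assembler behind :func:`assemble_with`.
    """

    name: str
    command: str
    contigs_glob: str = "*.fasta"


def parse_contig_fasta(path: str | Path) -> list[Contig]:
    """Parse an external assembler's contig FASTA (layout/depth unknown)."""
    contigs = []
    for rec in read_fasta(path):
        contigs.append(
            Contig(id=rec.id, sequence=rec.sequence, layout=[], depth=np.zeros(0, np.int32), n_reads=1)
        )
    return contigs


def external_adapter(reads: Sequence[SeqRecord], tool: ExternalAssembler) -> list[Contig]:
    """Run an external assembler; raises a descriptive error if absent."""
    exe = tool.command.split()[0]
    if shutil.which(exe) is None:
        raise FileNotFoundError(
            f"external assembler {tool.name!r} ({exe}) is not on PATH; "
            "use the built-in greedy assembler (assembler: builtin)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        reads_path = Path(tmp) / "reads.fasta"
        write_fasta(reads, reads_path)
        outdir = Path(tmp) / "out"
        outdir.mkdir()
        cmd = tool.command.format(reads=reads_path, outdir=outdir)
        subprocess.run(cmd, shell=True, check=True, capture_output=True)
        contigs: list[Contig] = []
        for fasta in sorted(outdir.glob(tool.contigs_glob)):
            contigs.extend(parse_contig_fasta(fasta))
        return contigs


def assemble_with(
    reads: Sequence[SeqRecord],
    params: Optional[AssemblerParams] = None,
    external: Optional[ExternalAssembler] = None,
) -> list[Contig]:
    """One entry point for built-in and adapter assembly."""
    if external is not None:
        return external_adapter(reads, external)
    return greedy_assemble(reads, params)
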