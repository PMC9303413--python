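"""BLAST-like local alignment search.

Nucleotide query vs nucleotide subjects (blastn role) and protein query vs
six-frame-translated subjects (tblastn role).  The engine is seed-and-extend:
exact k-mer matches define diagonals, diagonal clusters define a band, and a
banded affine-gap Smith-Waterman (numba-compiled) scores and tracebacks the
extension.  Bitscores and e-values follow the Karlin-Altschul formulae with
published gapped parameters for the default scoring schemes.

Coordinates in :class:`Hit` are 0-based half-open on the forward strand of
both sequences; the tabular writer converts to 1-based BLAST convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import ReadStore, SeqRecord, looks_nucleotide

# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------

_PROT_ALPHA = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_INDEX = {c: i for i, c in enumerate(_PROT_ALPHA)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores plus the Karlin-Altschul statistics that go with them.

    ``lam``/``K`` are the gapped Karlin-Altschul parameters for the chosen
    scores (published values for the defaults); they convert raw scores to
    bitscores and e-values.  Gap of length L costs ``gap_open + L*gap_extend``.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.28
    K: float = 0.46
    protein_matrix: Optional[str] = None  # e.g. "BLOSUM62"
    kmer: int = 11
    min_raw_score: int = 18

    def __post_init__(self) -> None:
        if self.protein_matrix is None and not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def is_protein(self) -> bool:
        return self.protein_matrix is not None

    def score_matrix(self) -> np.ndarray:
        if self.protein_matrix is not None:
            blo = substitution_matrices.load(self.protein_matrix)
            mat = np.zeros((len(_PROT_ALPHA), len(_PROT_ALPHA)), dtype=np.int16)
            for i, a in enumerate(_PROT_ALPHA):
                for j, b in enumerate(_PROT_ALPHA):
                    mat[i, j] = int(blo[a][b])
            return mat
        mat = np.full((5, 5), self.mismatch, dtype=np.int16)
        for i in range(4):
            mat[i, i] = self.match
        mat[4, :] = self.mismatch  # N scores as mismatch
        mat[:, 4] = self.mismatch
        return mat


#: blastn-style defaults: +1/-2, gap 5/2, gapped Karlin-Altschul lambda/K
NUCLEOTIDE_SCHEME = ScoringScheme()
#: tblastn-style defaults: BLOSUM62, gap 11/1, gapped lambda/K
PROTEIN_SCHEME = ScoringScheme(
    match=1,
    mismatch=-2,
    gap_open=11,
    gap_extend=1,
    lam=0.267,
    K=0.041,
    protein_matrix="BLOSUM62",
    kmer=4,
    min_raw_score=35,
)


@dataclass
class Hit:
    """One local alignment of a query against a subject.

    Coordinates are 0-based half-open on the forward strand of each
    sequence.  ``frame`` is 0 for nucleotide-nucleotide, else the subject
    reading frame in {-3..-1, +1..+3}.
    """

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    identity: float
    align_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    frame: int = 0
    raw_score: int = 0
    n_matches: int = 0
    ops: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# Sequence encoding and translation
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_nt(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode("ascii").translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    ).astype(np.int8)


def encode_prot(seq: str) -> np.ndarray:
    return np.array([_PROT_INDEX.get(c, _PROT_INDEX["X"]) for c in seq], dtype=np.int8)


def six_frame_translate(seq: str) -> list[str]:
    """Translate all six reading frames (standard code, '*' for stop).

    Frames are returned in order [+1, +2, +3, -1, -2, -3]; trailing partial
    codons are dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    rc = revcomp(seq)
    for src in (seq, rc):
        for off in range(3):
            sub = src[off : off + 3 * ((len(src) - off) // 3)]
            out.append(str(Seq(sub).translate()))
    return out


# ---------------------------------------------------------------------------
# Banded affine Smith-Waterman kernel
# ---------------------------------------------------------------------------

NEG = -(10**8)


@njit(cache=True)
def _banded_sw(q, s, mat, gap_open, gap_ext, dlo, dhi):  # pragma: no cover - numba
    """Banded local DP over cells (i,j) with dlo <= j-i <= dhi.

    Returns (score, qe, se, ptr, klo) where ptr encodes traceback state.
    Band storage: column k = j - i - dlo.
    """
    m = q.shape[0]
    n = s.shape[0]
    w = dhi - dlo + 1
    H = np.full((m + 1, w), NEG, dtype=np.int32)
    E = np.full((m + 1, w), NEG, dtype=np.int32)
    F = np.full((m + 1, w), NEG, dtype=np.int32)
    # ptr bits: 0-1 H-source (0 stop, 1 diag, 2 E, 3 F); bit2 E-ext; bit3 F-ext
    ptr = np.zeros((m + 1, w), dtype=np.uint8)
    go = gap_open + gap_ext
    best = 0
    bi = -1
    bk = -1
    for i in range(m + 1):
        jmin = i + dlo
        jmax = i + dhi
        if jmin < 0:
            jmin = 0
        if jmax > n:
            jmax = n
        for j in range(jmin, jmax + 1):
            k = j - i - dlo
            if i == 0 or j == 0:
                H[i, k] = 0
                continue
            # E: gap in query (move left, consume subject)
            e = NEG
            eext = 0
            if k - 1 >= 0:
                open_e = H[i, k - 1] - go
                ext_e = E[i, k - 1] - gap_ext
                if ext_e > open_e:
                    e = ext_e
                    eext = 1
                else:
                    e = open_e
            # F: gap in subject (move up, consume query)
            f = NEG
            fext = 0
            if k + 1 < w:
                open_f = H[i - 1, k + 1] - go
                ext_f = F[i - 1, k + 1] - gap_ext
                if ext_f > open_f:
                    f = ext_f
                    fext = 1
                else:
                    f = open_f
            d = H[i - 1, k] + mat[q[i - 1], s[j - 1]]
            h = 0
            src = 0
            if d > h:
                h = d
                src = 1
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            H[i, k] = h
            E[i, k] = e
            F[i, k] = f
            ptr[i, k] = src | (eext << 2) | (fext << 3)
            if h > best:
                best = h
                bi = i
                bk = k
    return best, bi, bk, ptr


@njit(cache=True)
def _traceback(q, s, ptr, dlo, bi, bk, gap_open, gap_ext):  # pragma: no cover
    """Walk pointers from the best cell; ops: 0=M, 1=subject-only, 2=query-only."""
    ops = np.empty(ptr.shape[0] + ptr.shape[1] + 8, dtype=np.uint8)
    nops = 0
    i = bi
    k = bk
    state = 0  # 0 in H, 1 in E, 2 in F
    while i >= 0:
        p = ptr[i, k]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                ops[nops] = 0
                nops += 1
                i -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E: came from (i, k-1)
            ops[nops] = 1
            nops += 1
            ext = (p >> 2) & 1
            k -= 1
            if ext == 0:
                state = 0
        else:  # F: came from (i-1, k+1)
            ops[nops] = 2
            nops += 1
            ext = (p >> 3) & 1
            i -= 1
            k += 1
            if ext == 0:
                state = 0
        if nops >= ops.shape[0] - 1:
            tmp = np.empty(ops.shape[0] * 2, dtype=np.uint8)
            tmp[: nops] = ops[: nops]
            ops = tmp
    j = i + k + dlo
    return ops[:nops][::-1].copy(), i, j


def banded_align(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    mat: np.ndarray,
    gap_open: int,
    gap_extend: int,
    dlo: int,
    dhi: int,
) -> Optional[tuple[int, int, int, int, int, np.ndarray]]:
    """Best local alignment in the band; returns (score, qs, qe, ss, se, ops)."""
    score, bi, bk, ptr = _banded_sw(
        q_enc, s_enc, mat, np.int32(gap_open), np.int32(gap_extend),
        np.int64(dlo), np.int64(dhi),
    )
    if bi < 0 or score <= 0:
        return None
    ops, qs, ss = _traceback(
        q_enc, s_enc, ptr, np.int64(dlo), np.int64(bi), np.int64(bk),
        np.int32(gap_open), np.int32(gap_extend),
    )
    qe = bi
    se = bi + bk + dlo
    return int(score), qs, qe, ss, se, ops


def ops_stats(q_enc: np.ndarray, s_enc: np.ndarray, qs: int, ss: int, ops: np.ndarray) -> tuple[int, int]:
    """(matches, alignment columns) for an ops path starting at (qs, ss)."""
    i, j, matches = qs, ss, 0
    for op in ops:
        if op == 0:
            if q_enc[i] == s_enc[j]:
                matches += 1
            i += 1
            j += 1
        elif op == 1:
            j += 1
        else:
            i += 1
    return matches, len(ops)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def bitscore_evalue(
    raw_score: int, m: int, n: int, scheme: ScoringScheme
) -> tuple[float, float]:
    """Normalised bitscore S' = (lambda*S - ln K)/ln 2 and e-value E = m*n*2^-S'."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    bits = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)
    evalue = float(m) * float(n) * math.pow(2.0, -bits)
    return bits, evalue


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_positions(seq_enc: np.ndarray, k: int) -> dict[bytes, list[int]]:
    return _kmer_positions_cached(seq_enc.tobytes(), k)


@lru_cache(maxsize=256)
def _kmer_positions_cached(buf: bytes, k: int) -> dict[bytes, list[int]]:
    table: dict[bytes, list[int]] = {}
    for i in range(len(buf) - k + 1):
        table.setdefault(buf[i : i + k], []).append(i)
    return table


def _seed_clusters(
    q_enc: np.ndarray, s_enc: np.ndarray, k: int, band_pad: int, max_gap: int
) -> list[tuple[int, int, int, int]]:
    """Cluster exact k-mer matches into candidate bands.

    Returns (dlo, dhi, s_min, s_max) per cluster, diagonals d = spos - qpos.
    """
    if len(s_enc) < k or len(q_enc) < k:
        return []
    table = _kmer_positions(q_enc, k)
    sbuf = s_enc.tobytes()
    seeds: list[tuple[int, int]] = []  # (diag, spos)
    for j in range(len(sbuf) - k + 1):
        hits = table.get(sbuf[j : j + k])
        if hits:
            for qpos in hits:
                seeds.append((j - qpos, j))
    if not seeds:
        return []
    seeds.sort()
    clusters: list[tuple[int, int, int, int]] = []
    cur = [seeds[0]]
    for d, j in seeds[1:]:
        if d - cur[-1][0] <= band_pad:
            cur.append((d, j))
        else:
            clusters.append(_cluster_extent(cur))
            cur = [(d, j)]
    clusters.append(_cluster_extent(cur))
    # merge clusters whose diagonal bands touch after padding
    merged: list[tuple[int, int, int, int]] = []
    for c in clusters:
        if merged and c[0] <= merged[-1][1]:
            p = merged[-1]
            merged[-1] = (p[0], max(p[1], c[1]), min(p[2], c[2]), max(p[3], c[3]))
        else:
            merged.append(c)
    return merged


def _cluster_extent(seeds: list[tuple[int, int]]) -> tuple[int, int, int, int]:
    ds = [d for d, _ in seeds]
    js = [j for _, j in seeds]
    return min(ds), max(ds), min(js), max(js)


# ---------------------------------------------------------------------------
# align_local and friends
# ---------------------------------------------------------------------------

BAND_PAD = 48


def _align_oriented(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    scheme: ScoringScheme,
    mat: np.ndarray,
) -> list[tuple[int, int, int, int, int, np.ndarray]]:
    """All band-cluster alignments of encoded query vs encoded subject."""
    m, n = len(q_enc), len(s_enc)
    clusters = _seed_clusters(q_enc, s_enc, scheme.kmer, BAND_PAD, m)
    results = []
    for dlo_c, dhi_c, smin, smax in clusters:
        dlo = dlo_c - BAND_PAD
        dhi = dhi_c + BAND_PAD
        dlo = max(dlo, -m)
        dhi = min(dhi, n)
        res = banded_align(q_enc, s_enc, mat, scheme.gap_open, scheme.gap_extend, dlo, dhi)
        if res is not None and res[0] >= scheme.min_raw_score:
            results.append(res)
    return results


def _dedupe(hits: list[Hit]) -> list[Hit]:
    """Drop hits mostly contained in a better hit on the same subject region."""
    hits.sort(key=lambda h: (-h.raw_score, h.s_start, h.q_start, h.strand))
    kept: list[Hit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.strand != h.strand or g.frame != h.frame:
                continue
            ov_s = min(h.s_end, g.s_end) - max(h.s_start, g.s_start)
            ov_q = min(h.q_end, g.q_end) - max(h.q_start, g.q_start)
            if ov_s > 0.5 * (h.s_end - h.s_start) and ov_q > 0.5 * (h.q_end - h.q_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def align_local(
    query: SeqRecord,
    subject: SeqRecord,
    scheme: Optional[ScoringScheme] = None,
    db_len: Optional[int] = None,
    keep_ops: bool = False,
) -> list[Hit]:
    """Local alignments of query against subject, sorted by bitscore.

    Nucleotide queries are searched on both strands; protein queries are
    searched against all six reading frames of the subject (tblastn role).
    ``db_len`` is the effective database length for e-values (defaults to
    the subject length).
    """
    if not query.sequence:
        raise ValueError("empty query")
    if scheme is None:
        scheme = (
            NUCLEOTIDE_SCHEME if looks_nucleotide(query.sequence) else PROTEIN_SCHEME
        )
    n_db = db_len if db_len is not None else len(subject.sequence)
    mat = scheme.score_matrix()
    hits: list[Hit] = []
    if not scheme.is_protein:
        q_fwd = encode_nt(query.sequence)
        s_enc = encode_nt(subject.sequence)
        m = len(q_fwd)
        for strand, q_enc in (("+", q_fwd), ("-", encode_nt(revcomp(query.sequence)))):
            for score, qs, qe, ss, se, ops in _align_oriented(q_enc, s_enc, scheme, mat):
                matches, cols = ops_stats(q_enc, s_enc, qs, ss, ops)
                if strand == "-":
                    qs, qe = m - qe, m - qs
                bits, ev = bitscore_evalue(score, m, n_db, scheme)
                hits.append(
                    Hit(
                        query.id, subject.id, bits, ev, matches / cols, cols,
                        qs, qe, ss, se, strand, 0, score, matches,
                        ops if keep_ops else None,
                    )
                )
    else:
        q_enc = encode_prot(query.sequence)
        m = len(q_enc)
        n_nt = len(subject.sequence)
        frames = six_frame_translate(subject.sequence)
        frame_ids = (1, 2, 3, -1, -2, -3)
        for frame, prot in zip(frame_ids, frames):
            if len(prot) < scheme.kmer:
                continue
            s_enc = encode_prot(prot)
            for score, qs, qe, ss, se, ops in _align_oriented(q_enc, s_enc, scheme, mat):
                matches, cols = ops_stats(q_enc, s_enc, qs, ss, ops)
                off = abs(frame) - 1
                if frame > 0:
                    nt_s, nt_e = off + 3 * ss, off + 3 * se
                    strand = "+"
                else:
                    nt_s, nt_e = n_nt - (off + 3 * se), n_nt - (off + 3 * ss)
                    strand = "-"
                bits, ev = bitscore_evalue(score, m, n_db, scheme)
                hits.append(
                    Hit(
                        query.id, subject.id, bits, ev, matches / cols, cols,
                        qs, qe, nt_s, nt_e, strand, frame, score, matches,
                        ops if keep_ops else None,
                    )
                )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.bitscore, h.subject_id, h.s_start))
    return hits


def search_store(
    queries: Sequence[SeqRecord],
    store: ReadStore,
    evalue_cutoff: float = 1e-10,
    max_hits: int = 10000,
    scheme: Optional[ScoringScheme] = None,
) -> list[Hit]:
    """Union of per-query hits with E <= cutoff, ranked per subject read.

    A read's rank is its best hit across all queries; at most ``max_hits``
    distinct reads are returned, in decreasing bitscore order with
    deterministic tie-break by subject id.  E-values use the total stored
    bases as the database length.
    """
    if not queries:
        raise ValueError("at least one query required")
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    n_db = max(store.total_bases, 1)
    best: dict[str, Hit] = {}
    for query in queries:
        for rec in store:
            for hit in align_local(query, rec, scheme=scheme, db_len=n_db):
                if hit.evalue > evalue_cutoff:
                    continue
                prev = best.get(rec.id)
                if prev is None or hit.bitscore > prev.bitscore:
                    best[rec.id] = hit
    ranked = sorted(best.values(), key=lambda h: (-h.bitscore, h.subject_id))
    return ranked[:max_hits]


def write_tabular(hits: Iterable[Hit], path: str) -> None:
    """BLAST outfmt-6-style TSV (1-based inclusive coordinates)."""
    cols = (
        "qseqid sseqid pident length mismatch gapopen "
        "qstart qend sstart send evalue bitscore"
    ).split()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for h in hits:
            mism = h.align_len - h.n_matches
            qs, qe = h.q_start + 1, h.q_end
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100*h.identity:.2f}\t{h.align_len}"
                f"\t{mism}\t0\t{qs}\t{qe}\t{ss}\t{se}\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )
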