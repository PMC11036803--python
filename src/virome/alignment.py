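"""Nucleotide alignment layer.

Pairs of sequences are screened with exact k-mer anchors (strand-canonical,
value-sampled sketches) and, when they share anchors, aligned with edlib.
Identity is counted from the extended CIGAR (``=``/``X``/``I``/``D``), so
ANI is matches / alignment columns and the alignment fraction (AF) of each
sequence is the aligned span divided by its length — the bookkeeping the
95%-ANI / 75%-AF vOTU clustering rule needs.

At test scale the same quantities are recomputed by a full
dynamic-programming aligner (Biopython) as an independent oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from virome.sequtils import encode, kmer_codes, revcomp

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

#: anchor k-mer length for the similarity screen
ANCHOR_K = 15
#: value-sampling modulus for sketches (keeps ~1/SKETCH_MOD of k-mers)
SKETCH_MOD = 16


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one pairwise alignment (a = query role, b = target role)."""

    matches: int
    columns: int
    span_a: int        # aligned bases on a
    span_b: int        # aligned bases on b
    strand: int        # +1 forward, -1 b was reverse-complemented

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """Extended CIGAR -> (eq, x, ins, dele) op counts."""
    eq = x = ins = dele = 0
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op == "=":
            eq += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
        else:  # 'M' should not appear with task="path"; treat as mismatchless
            eq += n
    return eq, x, ins, dele


def canonical_codes(seq: str, k: int = ANCHOR_K) -> np.ndarray:
    """Per-window strand-canonical k-mer codes (min of fwd / revcomp code)."""
    fwd = kmer_codes(seq, k)
    if fwd.size == 0:
        return fwd
    rev = kmer_codes(revcomp(seq), k)[::-1]
    if rev.size != fwd.size:  # N characters dropped asymmetrically
        m = min(rev.size, fwd.size)
        fwd, rev = fwd[:m], rev[:m]
    return np.minimum(fwd, rev)


def sketch(seq: str, k: int = ANCHOR_K, mod: int = SKETCH_MOD) -> np.ndarray:
    """Deterministic value-sampled sketch of canonical k-mers.

    Sampling by ``code % mod == 0`` is position- and strand-independent, so
    two homologous sequences retain the same surviving anchors regardless of
    orientation or offset.
    """
    codes = canonical_codes(seq, k)
    return np.unique(codes[codes % np.uint64(mod) == 0])


def shared_anchor_count(sk_a: np.ndarray, sk_b: np.ndarray) -> int:
    return int(np.intersect1d(sk_a, sk_b, assume_unique=True).size)


def n_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (encode(seq) == 255).mean()


def align_pair(
    a: str,
    b: str,
    min_anchors: int = 2,
    k: int = ANCHOR_K,
) -> AlignmentStats | None:
    """Align two contigs, trying both orientations of ``b``.

    The shorter sequence is aligned as an infix of the longer (edlib HW
    mode: free end gaps on the longer sequence), which handles both the
    full-length-homolog case and a fragment embedded in a larger genome.
    Returns ``None`` when the pair shares no k-mer anchors in either
    orientation (no alignment block exists).
    """
    if n_fraction(a) > 0.5 or n_fraction(b) > 0.5:
        raise ValueError("sequence is >50% N; refusing to align")
    sk_a = sketch(a, k)
    # canonical sketches are strand symmetric, one comparison covers both
    if shared_anchor_count(sk_a, sketch(b, k)) < min_anchors:
        return None
    # decide orientation with full (unsampled) forward k-mer sets
    ka = np.unique(kmer_codes(a, k))
    fwd_shared = np.intersect1d(ka, np.unique(kmer_codes(b, k)),
                                assume_unique=True).size
    rev_shared = np.intersect1d(ka, np.unique(kmer_codes(revcomp(b), k)),
                                assume_unique=True).size
    strand = 1 if fwd_shared >= rev_shared else -1
    b_or = b if strand == 1 else revcomp(b)

    if len(a) <= len(b_or):
        query, target, a_is_query = a, b_or, True
    else:
        query, target, a_is_query = b_or, a, False
    res = edlib.align(query, target, mode="HW", task="path")
    eq, x, ins, dele = _parse_cigar(res["cigar"])
    span_q = eq + x + ins
    span_t = eq + x + dele
    columns = eq + x + ins + dele
    if a_is_query:
        span_a, span_b = span_q, span_t
    else:
        span_a, span_b = span_t, span_q
    return AlignmentStats(matches=eq, columns=columns,
                          span_a=span_a, span_b=span_b, strand=strand)


def _anchor_positions(query: str, target: str, k: int) -> np.ndarray:
    """(qpos, tpos) pairs of exact shared k-mers (forward strands)."""
    tq = kmer_codes(query, k)
    tt = kmer_codes(target, k)
    if tq.size == 0 or tt.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(tt, kind="stable")
    tt_sorted = tt[order]
    idx = np.searchsorted(tt_sorted, tq)
    idx = np.clip(idx, 0, tt_sorted.size - 1)
    hit = tt_sorted[idx] == tq
    qpos = np.nonzero(hit)[0]
    tpos = order[idx[hit]]
    return np.column_stack([qpos, tpos])


def local_blocks(
    query: str,
    target: str,
    k: int = 21,
    band: int = 200,
    min_block: int = 300,
) -> list[tuple[int, int, int, int, float, int]]:
    """Find colinear local alignment blocks of ``query`` inside ``target``.

    Exact shared k-mers are grouped by diagonal (within ``band``); each
    diagonal cluster's spanned region is realigned with edlib to get an
    identity.  Both strands are searched.  Returns tuples
    ``(qstart, qend, tstart, tend, identity, columns)`` with query
    coordinates on the forward strand of ``query``.
    """
    out: list[tuple[int, int, int, int, float, int]] = []
    for strand, qseq in ((1, query), (-1, revcomp(query))):
        anchors = _anchor_positions(qseq, target, k)
        if anchors.shape[0] == 0:
            continue
        diag = anchors[:, 1] - anchors[:, 0]
        order = np.argsort(diag, kind="stable")
        anchors = anchors[order]
        diag = diag[order]
        splits = np.nonzero(np.diff(diag) > band)[0] + 1
        for grp in np.split(anchors, splits):
            q0, t0 = grp.min(axis=0)
            q1, t1 = grp.max(axis=0) + k
            if q1 - q0 < min_block:
                continue
            sub_q = qseq[q0:q1]
            sub_t = target[t0:t1]
            res = edlib.align(sub_q, sub_t, mode="NW", task="path")
            eq, x, ins, dele = _parse_cigar(res["cigar"])
            cols = eq + x + ins + dele
            if cols == 0:
                continue
            ident = eq / cols
            if strand == 1:
                out.append((q0, q1, t0, t1, ident, cols))
            else:
                n = len(query)
                out.append((n - q1, n - q0, t0, t1, ident, cols))
    return out
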