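"""Small sequence helpers shared by the catalog, annotation and synthetic
data modules: complementing, GC content, integer k-mer encoding, and FASTA
round-tripping (via Biopython)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte-code lookup: A=0, C=1, G=2, T=3, everything else = 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A,C,G,T -> 0..3; other -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int, stride: int = 1) -> np.ndarray:
    """All (or strided) k-mers of ``seq`` packed into uint64 codes.

    Windows containing non-ACGT characters are dropped.  Requires
    ``4**k <= 2**64``, i.e. k <= 32.
    """
    codes = encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)[::stride]
    valid = ~(win == 255).any(axis=1)
    win = win[valid].astype(np.uint64)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return win @ weights


def canonical_kmer_codes(seq: str, k: int, stride: int = 1) -> np.ndarray:
    """Strand-canonical k-mer codes: elementwise min of forward and
    reverse-complement codes (forward codes are strided; rc computed per
    window, not per strided position, so the canonical set is strand
    symmetric only up to stride jitter — use stride=1 where that matters)."""
    fwd = kmer_codes(seq, k, stride)
    rev = kmer_codes(revcomp(seq), k, stride)
    # union-min is not positionally meaningful under stride; for candidate
    # screening we only need set overlap, so return the union of both.
    return np.union1d(fwd, rev)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
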