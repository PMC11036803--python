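"""vOTU annotation: family-level taxonomy by protein-hit voting, host
prediction by CRISPR-spacer matching and prophage alignment, and per-protein
function (KO) assignment by best database hit.

Taxonomy follows a quarter-vote: a family is assigned when strictly more
than 25% of a vOTU's proteins have their best hit in that family (the
denominator includes proteins with no hit).  Host links are called when a
bacterial CRISPR spacer matches the viral sequence nearly exactly (at most
one mismatch over the spacer's full length, either strand) or when a local
alignment of at least 1 kb at >= 90% identity places the virus inside a
bacterial genome (a prophage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from virome import alignment
from virome.sequtils import revcomp

log = logging.getLogger(__name__)

SPACER_MAX_MISMATCH = 1
SPACER_MIN_LEN = 20
PROPHAGE_MIN_LEN = 1_000
PROPHAGE_MIN_IDENTITY = 0.90
FAMILY_VOTE_FRACTION = 0.25


@dataclass(frozen=True)
class HostLink:
    votu_id: str
    host_id: str
    mechanism: str        # "crispr" | "prophage"
    support: int          # matching spacers, or aligned bp


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per protein: highest bitscore, ties broken by the
    lexicographically smallest (family, ko) target."""
    h = hits.copy()
    h["hit_family"] = h["hit_family"].fillna("")
    h["hit_ko"] = h["hit_ko"].fillna("")
    h = h.sort_values(
        ["protein_id", "bitscore", "hit_family", "hit_ko"],
        ascending=[True, False, True, True], kind="stable")
    return h.drop_duplicates("protein_id", keep="first")


def assign_family(
    hits: pd.DataFrame, vote_fraction: float = FAMILY_VOTE_FRACTION
) -> str:
    """Family call for one vOTU's protein-hit table.

    The table must contain one row per predicted protein (rows with an
    empty ``hit_family`` count in the denominator).  A family qualifies if
    its best-hit share strictly exceeds ``vote_fraction``; among qualifying
    families the largest share wins, and an exact tie is unclassified.
    """
    if hits.empty:
        log.warning("vOTU with zero predicted proteins: unclassified")
        return "unclassified"
    bh = best_hits(hits)
    n_proteins = bh["protein_id"].nunique()
    fam_counts = (bh.loc[bh["hit_family"] != "", "hit_family"]
                  .value_counts())
    qualifying = fam_counts[fam_counts / n_proteins > vote_fraction]
    if qualifying.empty:
        return "unclassified"
    top = qualifying.max()
    winners = sorted(qualifying[qualifying == top].index)
    return winners[0] if len(winners) == 1 else "unclassified"


def assign_families(
    hits: pd.DataFrame, votu_of_contig: dict[str, str]
) -> dict[str, str]:
    """Family call per vOTU, pooling the protein tables of all member
    contigs mapped through ``votu_of_contig``."""
    h = hits.copy()
    h["votu_id"] = h["contig_id"].map(votu_of_contig)
    h = h.dropna(subset=["votu_id"])
    return {votu: assign_family(grp)
            for votu, grp in h.groupby("votu_id", sort=True)}


# ---------------------------------------------------------------------------
# CRISPR-spacer host prediction
# ---------------------------------------------------------------------------

def _near_exact_positions(spacer: str, target: str, max_mm: int) -> int:
    """Count positions where ``spacer`` matches ``target`` with at most
    ``max_mm`` mismatches, via pigeonhole seeding: any window with <= 1
    mismatch contains one exact half, so exact half-matches are extended
    and verified."""
    L = len(spacer)
    if len(target) < L:
        return 0
    hits: set[int] = set()
    half = L // 2
    seeds = ((spacer[:half], 0), (spacer[half:], half))
    tarr = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    sarr = np.frombuffer(spacer.encode("ascii"), dtype=np.uint8)
    for seed, offset in seeds:
        start = target.find(seed)
        while start != -1:
            w0 = start - offset
            if 0 <= w0 <= len(target) - L and w0 not in hits:
                mm = int((tarr[w0:w0 + L] != sarr).sum())
                if mm <= max_mm:
                    hits.add(w0)
            start = target.find(seed, start + 1)
    return len(hits)


def spacer_matches(spacer: str, virus_seq: str,
                   max_mm: int = SPACER_MAX_MISMATCH) -> int:
    """Number of near-exact placements of ``spacer`` on either strand of
    the viral sequence."""
    return (_near_exact_positions(spacer, virus_seq, max_mm)
            + _near_exact_positions(revcomp(spacer), virus_seq, max_mm))


def crispr_host(
    spacers: pd.DataFrame,
    votu_seqs: dict[str, str],
    max_mismatch: int = SPACER_MAX_MISMATCH,
    min_spacer_len: int = SPACER_MIN_LEN,
) -> list[HostLink]:
    """Link vOTUs to hosts whose CRISPR spacers match them.

    ``spacers`` columns: host_id, spacer_id, sequence.  A link is created
    when at least one spacer of the host matches the vOTU with at most
    ``max_mismatch`` mismatches over the spacer's full length (either
    strand); support counts the matching spacers.
    """
    counts: dict[tuple[str, str], int] = {}
    for row in spacers.itertuples(index=False):
        seq = str(row.sequence).upper()
        if len(seq) < min_spacer_len:
            log.warning("spacer %s shorter than %d bp: skipped",
                        row.spacer_id, min_spacer_len)
            continue
        if set(seq) - set("ACGT"):
            log.warning("spacer %s contains non-ACGT characters: skipped",
                        row.spacer_id)
            continue
        for votu, vseq in votu_seqs.items():
            if spacer_matches(seq, vseq, max_mismatch) > 0:
                key = (votu, str(row.host_id))
                counts[key] = counts.get(key, 0) + 1
    return [HostLink(v, h, "crispr", n)
            for (v, h), n in sorted(counts.items())]


# ---------------------------------------------------------------------------
# prophage host prediction
# ---------------------------------------------------------------------------

def prophage_host(
    host_seqs: dict[str, str],
    votu_seqs: dict[str, str],
    min_len: int = PROPHAGE_MIN_LEN,
    min_identity: float = PROPHAGE_MIN_IDENTITY,
) -> list[HostLink]:
    """Link vOTUs to hosts containing a prophage copy of them: a local
    alignment block covering >= ``min_len`` bp at >= ``min_identity``.
    Candidate pairs are screened by shared 21-mers before alignment, so
    unrelated virus/host pairs cost only a set intersection."""
    k = 21
    host_codes = {h: np.unique(alignment.canonical_codes(s, k))
                  for h, s in host_seqs.items()}
    links: list[HostLink] = []
    for votu in sorted(votu_seqs):
        vseq = votu_seqs[votu]
        vcodes = np.unique(alignment.canonical_codes(vseq, k))
        for host in sorted(host_seqs):
            shared = np.intersect1d(vcodes, host_codes[host],
                                    assume_unique=True).size
            if shared < 5:
                continue
            blocks = alignment.local_blocks(
                vseq, host_seqs[host], k=k, min_block=min_len // 2)
            support = sum(
                cols for *_, ident, cols in blocks
                if cols >= min_len and ident >= min_identity)
            if support > 0:
                links.append(HostLink(votu, host, "prophage", support))
    return links


def predict_hosts(
    spacers: pd.DataFrame,
    host_seqs: dict[str, str],
    votu_seqs: dict[str, str],
    **kwargs,
) -> list[HostLink]:
    """Both mechanisms combined; a vOTU may carry multiple links."""
    return (crispr_host(spacers, votu_seqs)
            + prophage_host(host_seqs, votu_seqs, **kwargs))


# ---------------------------------------------------------------------------
# function
# ---------------------------------------------------------------------------

def assign_ko(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-protein KO of the best-scoring hit (empty when no hit carries a
    KO).  Returns columns contig_id, protein_id, ko."""
    bh = best_hits(hits)
    out = bh[["contig_id", "protein_id", "hit_ko"]].rename(
        columns={"hit_ko": "ko"})
    return out.sort_values(["contig_id", "protein_id"],
                           kind="stable").reset_index(drop=True)


def links_to_frame(links: list[HostLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.votu_id, l.host_id, l.mechanism, l.support) for l in links],
        columns=["votu_id", "host_id", "mechanism", "support"])
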