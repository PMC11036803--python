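"""Nonredundant vOTU catalog construction.

Candidate contigs are triaged by a three-criterion rule that pools evidence
from gene-content comparison, a machine-learning virus predictor, and an
annotation-based flag; contigs whose BUSCO ratio (bacterial universal
single-copy orthologs over total genes) exceeds 5% are removed as likely
bacterial contamination; the survivors are compared all-against-all
(k-mer-screened ANI/AF) and clustered greedily at >=95% ANI over >=75% of
both sequences, longest contig first, the centroid becoming the vOTU
representative.  Quality tiers follow completeness bands: Complete (flag),
High (>90), Medium (50-90 inclusive), Low (<50), Undetermined (missing).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from virome import alignment
from virome.sequtils import gc_content

log = logging.getLogger(__name__)

MIN_CONTIG_LEN = 5_000
ANI_THRESHOLD = 0.95
AF_THRESHOLD = 0.75
BUSCO_MAX_RATIO = 0.05

TIERS = ("Complete", "High", "Medium", "Low", "Undetermined")

EVIDENCE_COLUMNS = [
    "contig_id", "length", "gc", "viral_genes", "microbial_genes",
    "total_genes", "predictor_score", "predictor_p", "keyword_flag",
    "busco_count", "completeness", "complete_flag",
]


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str | None
    length: int
    gc: float
    viral_genes: int
    microbial_genes: int
    total_genes: int
    predictor_score: float
    predictor_p: float
    keyword_flag: bool
    busco_count: int
    completeness: float | None = None
    complete_flag: bool = False

    @classmethod
    def from_sequence(cls, contig_id: str, sequence: str, **evidence):
        return cls(contig_id=contig_id, sequence=sequence,
                   length=len(sequence), gc=gc_content(sequence), **evidence)


@dataclass(frozen=True)
class PairwiseSimilarity:
    query_id: str
    target_id: str
    ani: float | None
    af_query: float
    af_target: float

    def swapped(self) -> "PairwiseSimilarity":
        return PairwiseSimilarity(self.target_id, self.query_id, self.ani,
                                  self.af_target, self.af_query)


@dataclass
class VOTUCluster:
    votu_id: str
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    quality_tier: str = "Undetermined"


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read the per-contig evidence TSV, reporting the 1-based line number
    of the first malformed row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence TSV {path}: missing columns {missing}")
    numeric = {
        "length": int, "viral_genes": int, "microbial_genes": int,
        "total_genes": int, "busco_count": int,
        "gc": float, "predictor_score": float, "predictor_p": float,
    }
    for col, typ in numeric.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +header +1-based
            raise ValueError(
                f"evidence TSV {path}: bad value in column '{col}' "
                f"at line {line}") from None
    for col in ("keyword_flag", "complete_flag"):
        df[col] = df[col].str.lower().isin(("true", "1", "yes"))
    df["completeness"] = pd.to_numeric(df["completeness"], errors="coerce")
    return df


def records_from_evidence(
    df: pd.DataFrame, sequences: dict[str, str] | None = None
) -> list[ContigRecord]:
    records = []
    for row in df.itertuples(index=False):
        comp = None if pd.isna(row.completeness) else float(row.completeness)
        records.append(ContigRecord(
            contig_id=row.contig_id,
            sequence=None if sequences is None else sequences.get(row.contig_id),
            length=int(row.length), gc=float(row.gc),
            viral_genes=int(row.viral_genes),
            microbial_genes=int(row.microbial_genes),
            total_genes=int(row.total_genes),
            predictor_score=float(row.predictor_score),
            predictor_p=float(row.predictor_p),
            keyword_flag=bool(row.keyword_flag),
            busco_count=int(row.busco_count),
            completeness=comp,
            complete_flag=bool(row.complete_flag),
        ))
    return records


# ---------------------------------------------------------------------------
# triage and decontamination
# ---------------------------------------------------------------------------

def passes_triage(rec: ContigRecord, mode: str = "union") -> bool:
    c1 = rec.viral_genes > rec.microbial_genes
    c2 = rec.predictor_p < 0.01 and rec.predictor_score > 0.90
    c3 = rec.keyword_flag
    if mode == "union":
        return c1 or c2 or c3
    if mode == "intersection":
        return c1 and c2 and c3
    raise ValueError(f"unknown triage mode {mode!r}")


def triage(records: list[ContigRecord], mode: str = "union") -> list[str]:
    """Retain contigs passing any of the three viral-evidence criteria:
    (i) viral gene count strictly above microbial, (ii) predictor p < 0.01
    and score > 0.90, (iii) annotation flag set."""
    retained = []
    for rec in records:
        try:
            if passes_triage(rec, mode):
                retained.append(rec.contig_id)
        except TypeError:
            log.warning("contig %s: missing evidence, skipped", rec.contig_id)
    return retained


def busco_ratio(rec: ContigRecord) -> float | None:
    if rec.total_genes == 0:
        return None
    return rec.busco_count / rec.total_genes


def busco_filter(
    records: list[ContigRecord], max_ratio: float = BUSCO_MAX_RATIO
) -> list[str]:
    """Eliminate contigs whose BUSCO ratio is strictly greater than
    ``max_ratio``; contigs with zero annotated genes are retained with a
    warning (ratio undefined)."""
    retained = []
    for rec in records:
        ratio = busco_ratio(rec)
        if ratio is None:
            log.warning("contig %s: 0 annotated genes, BUSCO ratio "
                        "undefined; retained", rec.contig_id)
            retained.append(rec.contig_id)
        elif ratio <= max_ratio:
            retained.append(rec.contig_id)
    return retained


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------

def pairwise_ani(a_id: str, a_seq: str, b_id: str, b_seq: str
                 ) -> PairwiseSimilarity:
    stats = alignment.align_pair(a_seq, b_seq)
    if stats is None:
        return PairwiseSimilarity(a_id, b_id, None, 0.0, 0.0)
    return PairwiseSimilarity(
        a_id, b_id, stats.identity,
        stats.span_a / len(a_seq), stats.span_b / len(b_seq))


def candidate_pairs(
    seqs: dict[str, str], min_shared: int = 4
) -> list[tuple[str, str]]:
    """Pairs of contigs sharing at least ``min_shared`` sketch anchors.

    Sketches are strand-canonical value-sampled k-mers, so unrelated contigs
    essentially never collide while 95%-identical homologs share hundreds.
    """
    sketches = {cid: alignment.sketch(s) for cid, s in seqs.items()}
    owners: dict[int, list[str]] = defaultdict(list)
    for cid, sk in sketches.items():
        for code in sk.tolist():
            owners[code].append(cid)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for ids in owners.values():
        if len(ids) < 2:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                counts[(a, b) if a < b else (b, a)] += 1
    return [pair for pair, n in counts.items() if n >= min_shared]


def all_pairwise(
    seqs: dict[str, str], pairs: list[tuple[str, str]] | None = None
) -> list[PairwiseSimilarity]:
    if pairs is None:
        pairs = candidate_pairs(seqs)
    sims = []
    for a, b in pairs:
        sims.append(pairwise_ani(a, seqs[a], b, seqs[b]))
    return sims


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def greedy_cluster(
    similarities: list[PairwiseSimilarity],
    lengths: dict[str, int],
    ani_threshold: float = ANI_THRESHOLD,
    af_threshold: float = AF_THRESHOLD,
) -> list[VOTUCluster]:
    """Greedy centroid clustering, longest sequence first.

    The longest unassigned contig seeds a cluster and recruits every
    unassigned contig whose ANI >= ``ani_threshold`` and whose alignment
    fraction >= ``af_threshold`` on BOTH sequences.  Deterministic given the
    similarity table: ordering is by length descending, ties by id.
    """
    neighbours: dict[str, set[str]] = defaultdict(set)
    for sim in similarities:
        if sim.query_id not in lengths or sim.target_id not in lengths:
            raise KeyError(
                f"similarity references unknown contig "
                f"{sim.query_id!r}/{sim.target_id!r}")
        if sim.ani is None:
            continue
        if (sim.ani >= ani_threshold and sim.af_query >= af_threshold
                and sim.af_target >= af_threshold):
            neighbours[sim.query_id].add(sim.target_id)
            neighbours[sim.target_id].add(sim.query_id)
    order = sorted(lengths, key=lambda c: (-lengths[c], c))
    assigned: set[str] = set()
    clusters: list[VOTUCluster] = []
    for centroid in order:
        if centroid in assigned:
            continue
        members = [centroid] + sorted(
            m for m in neighbours[centroid] if m not in assigned)
        assigned.update(members)
        clusters.append(VOTUCluster(
            votu_id=f"vOTU{len(clusters) + 1:05d}",
            representative_id=centroid,
            member_ids=members))
    return clusters


# ---------------------------------------------------------------------------
# quality tiers
# ---------------------------------------------------------------------------

def quality_tier(rec: ContigRecord) -> str:
    if rec.completeness is not None and not 0 <= rec.completeness <= 100:
        raise ValueError(
            f"contig {rec.contig_id}: completeness {rec.completeness} "
            "outside [0, 100]")
    if rec.complete_flag:
        return "Complete"
    if rec.completeness is None:
        return "Undetermined"
    if rec.completeness > 90:
        return "High"
    if rec.completeness >= 50:
        return "Medium"
    return "Low"


# ---------------------------------------------------------------------------
# end-to-end catalog build
# ---------------------------------------------------------------------------

@dataclass
class CatalogResult:
    clusters: list[VOTUCluster]
    retained_ids: list[str]          # survivors of triage + BUSCO filter
    triaged_ids: list[str]
    representatives: dict[str, str]  # votu_id -> representative sequence

    @property
    def votu_of_contig(self) -> dict[str, str]:
        return {m: c.votu_id for c in self.clusters for m in c.member_ids}


def build_catalog(
    sequences: dict[str, str],
    records: list[ContigRecord],
    min_len: int = MIN_CONTIG_LEN,
    ani_threshold: float = ANI_THRESHOLD,
    af_threshold: float = AF_THRESHOLD,
    busco_max: float = BUSCO_MAX_RATIO,
    triage_mode: str = "union",
) -> CatalogResult:
    by_id = {r.contig_id: r for r in records}
    long_enough = [r for r in records
                   if r.contig_id in sequences
                   and len(sequences[r.contig_id]) >= min_len]
    triaged = triage(long_enough, mode=triage_mode)
    triaged_recs = [by_id[c] for c in triaged]
    retained = busco_filter(triaged_recs, max_ratio=busco_max)
    seqs = {c: sequences[c] for c in retained}
    sims = all_pairwise(seqs)
    lengths = {c: len(s) for c, s in seqs.items()}
    clusters = greedy_cluster(sims, lengths, ani_threshold, af_threshold)
    for cl in clusters:
        cl.quality_tier = quality_tier(by_id[cl.representative_id])
    reps = {cl.votu_id: seqs[cl.representative_id] for cl in clusters}
    log.info("catalog: %d contigs -> %d triaged -> %d retained -> %d vOTUs",
             len(records), len(triaged), len(retained), len(clusters))
    return CatalogResult(clusters=clusters, retained_ids=retained,
                         triaged_ids=triaged, representatives=reps)


def clusters_to_frame(clusters: list[VOTUCluster]) -> pd.DataFrame:
    return pd.DataFrame({
        "votu_id": [c.votu_id for c in clusters],
        "representative": [c.representative_id for c in clusters],
        "n_members": [len(c.member_ids) for c in clusters],
        "members": [",".join(c.member_ids) for c in clusters],
        "quality_tier": [c.quality_tier for c in clusters],
    })
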