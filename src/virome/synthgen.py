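"""Synthetic gut-virome study generator with planted ground truth.

Emulates the inputs of a two-group (case vs control) virome cohort: viral
contigs organised into species (an ancestor plus diverged copies inside the
95%-ANI species boundary), non-viral decoy contigs, bacterial host genomes
carrying planted CRISPR spacers and prophage insertions, per-contig evidence
tables (gene counts, predictor score/p, annotation flag, BUSCO counts,
completeness), per-contig protein hit tables, per-sample mapped-read count
matrices with planted differentially abundant features and planted
virus-bacterium correlations, and sample metadata.  Every planted signal is
recorded in a :class:`TruthSet` so downstream stages can be scored.

Default scale mirrors the emulated study design: 40 case and 37 control
samples, 200 viral species with log-normal abundances, and a per-sample
depth of 200,000 mapped reads standing in for the study's 4 million.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from virome.sequtils import kmer_codes, write_fasta, gc_content

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae",
            "crAss-like", "Quimbyviridae")
#: fixed CRISPR direct-repeat used when rendering arrays into host genomes
CRISPR_REPEAT = "GTTTTAGAGCTATGCTGTTTTGAATGGTCCCA"
#: shared-latent-factor loading for planted virus-bacterium correlations;
#: with unit log-normal noise this yields a Pearson (and hence Spearman)
#: correlation of lam^2/(lam^2+1) ~ 0.86 within each group
CORRELATION_LOADING = 2.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 200
    members_per_species: int = 3
    mutant_divergence: float = 0.02
    n_decoys: int = 100
    n_hosts: int = 20
    n_samples_group_a: int = 40
    n_samples_group_b: int = 37
    depth: int = 200_000
    n_diff: int = 40
    effect_log2fc: float = 2.0
    n_planted_edges: int = 10
    genome_length_range: tuple[int, int] = (5_000, 20_000)
    # fields beyond the core design, needed by the host / evidence stages
    n_crispr_links: int = 30
    n_prophage_links: int = 10
    n_bacteria: int = 74
    n_decoy_spacers: int = 20
    prophage_length: int = 2_000
    prophage_divergence: float = 0.03
    host_length_range: tuple[int, int] = (30_000, 60_000)
    busco_contam_fraction: float = 0.05

    def __post_init__(self):
        if self.genome_length_range[0] < 5_000:
            raise ValueError(
                "genome_length_range lower bound below the 5 kb contig "
                "floor; contigs of >= 5 kb are required")
        if not 0 <= self.mutant_divergence < 0.05:
            raise ValueError(
                "mutant_divergence must be in [0, 0.05) so planted species "
                "members stay above the 95% ANI threshold")
        if self.n_diff > self.n_species:
            raise ValueError("n_diff cannot exceed n_species")
        if self.n_crispr_links + self.n_prophage_links > 0 and self.n_hosts < 1:
            raise ValueError("planted host links require n_hosts >= 1")


@dataclass
class TruthSet:
    """Planted ground truth for one simulated study."""

    species_assignment: dict[str, str] = field(default_factory=dict)
    species_family: dict[str, str | None] = field(default_factory=dict)
    differential: list[tuple[str, int]] = field(default_factory=list)
    host_links: list[tuple[str, str, str]] = field(default_factory=list)
    planted_edges: list[tuple[str, str, int]] = field(default_factory=list)
    busco_contaminated: set[str] = field(default_factory=set)

    @property
    def differential_ids(self) -> set[str]:
        return {f for f, _ in self.differential}


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation at per-base rate ``rate`` (no indels)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # map current base to one of the three other bases
        cur = np.searchsorted(BASES, arr[hits])
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = BASES[(cur + shift) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def generate_genomes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], TruthSet]:
    """Viral species (ancestor + diverged members) and decoy contigs.

    Members are full-length substitution mutants of their ancestor, so
    planted within-species pairs have an expected ANI of
    ``1 - mutant_divergence`` (pairs of members: ``(1 - d)^2`` plus back
    mutations) at 100% mutual overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.genome_length_range
    seqs: dict[str, str] = {}
    truth = TruthSet()
    for i in range(config.n_species):
        sp = f"sp{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        seqs[f"{sp}_c0"] = ancestor
        truth.species_assignment[f"{sp}_c0"] = sp
        for m in range(config.members_per_species):
            cid = f"{sp}_c{m + 1}"
            seqs[cid] = _mutate(rng, ancestor, config.mutant_divergence)
            truth.species_assignment[cid] = sp
    for j in range(config.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        seqs[f"decoy{j + 1:04d}"] = _random_seq(rng, length)
    return seqs, truth


# ---------------------------------------------------------------------------
# hosts, spacers, prophages
# ---------------------------------------------------------------------------

def _shares_long_kmer(host: str, virus_codes: np.ndarray, k: int = 21) -> bool:
    hc = np.unique(kmer_codes(host, k))
    return bool(np.intersect1d(hc, virus_codes, assume_unique=True).size)


def generate_hosts(
    config: SimulationConfig,
    viral_seqs: dict[str, str],
    truth: TruthSet,
    rng: np.random.Generator | None = None,
    candidate_ids: list[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Bacterial genomes with planted CRISPR-spacer and prophage links.

    Non-linked hosts are verified (and resampled if needed) to share no
    21-mer with any viral genome, so the only virus-host homology present
    is the planted one.  Returns host sequences and the spacer table
    (host_id, spacer_id, sequence); planted links are appended to ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    virus_ids = sorted(candidate_ids if candidate_ids is not None
                       else viral_seqs)
    lo, hi = config.host_length_range
    k = 21
    virus_codes = np.unique(np.concatenate(
        [kmer_codes(s, k) for s in viral_seqs.values()]
        or [np.empty(0, dtype=np.uint64)]))

    hosts: dict[str, str] = {}
    for h in range(config.n_hosts):
        hid = f"host{h + 1:03d}"
        for _ in range(50):
            g = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if not _shares_long_kmer(g, virus_codes, k):
                break
        hosts[hid] = g

    host_ids = sorted(hosts)
    n_links = config.n_crispr_links + config.n_prophage_links
    if n_links > len(virus_ids):
        raise ValueError("more planted host links than viral genomes")
    linked_viruses = [str(v) for v in
                      rng.choice(virus_ids, size=n_links, replace=False)]
    crispr_viruses = linked_viruses[: config.n_crispr_links]
    prophage_viruses = linked_viruses[config.n_crispr_links:]

    spacer_rows: list[dict] = []
    arrays: dict[str, list[str]] = {h: [] for h in host_ids}
    sp_counter = 0
    for v in crispr_viruses:
        hid = str(rng.choice(host_ids))
        vseq = viral_seqs[v]
        length = int(rng.integers(25, 41))
        if len(vseq) < length:
            warnings.warn(f"virus {v} shorter than requested spacer; skipped")
            continue
        start = int(rng.integers(0, len(vseq) - length + 1))
        spacer = vseq[start:start + length]
        sp_counter += 1
        spacer_rows.append({"host_id": hid,
                            "spacer_id": f"spacer{sp_counter:04d}",
                            "sequence": spacer})
        arrays[hid].append(spacer)
        truth.host_links.append((v, hid, "crispr"))

    occupied: dict[str, list[tuple[int, int]]] = {h: [] for h in host_ids}
    for v in prophage_viruses:
        hid = str(rng.choice(host_ids))
        vseq = viral_seqs[v]
        plen = min(config.prophage_length, len(vseq))
        start = int(rng.integers(0, len(vseq) - plen + 1))
        insert = _mutate(rng, vseq[start:start + plen],
                         config.prophage_divergence)
        g = hosts[hid]
        # inserts into one host must not overwrite each other, or the
        # planted homology would fall below the link length floor
        for _ in range(100):
            pos = int(rng.integers(0, max(1, len(g) - plen)))
            if all(pos + plen <= a or pos >= b
                   for a, b in occupied[hid]):
                break
        else:
            raise RuntimeError(f"cannot place prophage in host {hid}")
        occupied[hid].append((pos, pos + plen))
        hosts[hid] = g[:pos] + insert + g[pos + plen:]
        truth.host_links.append((v, hid, "prophage"))

    for _ in range(config.n_decoy_spacers):
        hid = str(rng.choice(host_ids))
        sp_counter += 1
        spacer = _random_seq(rng, int(rng.integers(25, 41)))
        spacer_rows.append({"host_id": hid,
                            "spacer_id": f"spacer{sp_counter:04d}",
                            "sequence": spacer})
        arrays[hid].append(spacer)

    # render CRISPR arrays (repeat-spacer-...-repeat) onto genome ends
    for hid, spacers in arrays.items():
        if spacers:
            hosts[hid] += "".join(
                CRISPR_REPEAT + sp for sp in spacers) + CRISPR_REPEAT

    # construction check: hosts without any planted link share no 21-mer
    # with any virus (CRISPR spacers are < k-proof only for k > 40; the
    # check therefore only covers hosts with neither spacers nor prophages)
    linked_hosts = {h for _, h, _ in truth.host_links} | {
        r["host_id"] for r in spacer_rows}
    for hid in host_ids:
        if hid not in linked_hosts:
            assert not _shares_long_kmer(hosts[hid], virus_codes, k), \
                f"non-linked host {hid} shares a {k}-mer with a virus"

    spacers_df = pd.DataFrame(
        spacer_rows, columns=["host_id", "spacer_id", "sequence"])
    return hosts, spacers_df


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

_TIER_PROBS = {  # completeness-tier mix observed in real gut-virome catalogs
    "Complete": 0.051, "High": 0.065, "Medium": 0.143,
    "Low": 0.430, "Undetermined": 0.311,
}


def generate_evidence(
    config: SimulationConfig,
    seqs: dict[str, str],
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-contig evidence rows.

    True viral contigs pass at least one of the three triage criteria
    (gene-content, predictor score/p, annotation flag); decoys fail all
    three.  A ``busco_contam_fraction`` of the true virals receive BUSCO
    ratios above the 5% decontamination cutoff and are recorded as planted
    contaminants in ``truth``.  Completeness values populate all five
    quality tiers.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tiers = list(_TIER_PROBS)
    tier_p = np.array([_TIER_PROBS[t] for t in tiers])
    tier_p = tier_p / tier_p.sum()

    rows = []
    for cid in sorted(seqs):
        seq = seqs[cid]
        is_viral = cid in truth.species_assignment
        total_genes = int(max(5, rng.poisson(len(seq) / 1000) + 3))
        if is_viral:
            c1, c2, c3 = (rng.random(3) < [0.7, 0.5, 0.6])
            if not (c1 or c2 or c3):
                c1 = True
            if c1:
                viral = int(rng.integers(5, 21))
                microbial = int(rng.integers(0, viral))
            else:
                viral = int(rng.integers(0, 4))
                microbial = int(viral + rng.integers(0, 4))
            if c2:
                score = float(rng.uniform(0.905, 1.0))
                p = float(rng.uniform(0.0, 0.009))
            else:
                score = float(rng.uniform(0.2, 0.95))
                p = (float(rng.uniform(0.02, 1.0)) if score > 0.90
                     else float(rng.uniform(0.0, 1.0)))
            flag = bool(c3)
            if rng.random() < config.busco_contam_fraction:
                busco = int(np.floor(0.05 * total_genes)) + int(
                    rng.integers(1, max(2, total_genes // 4)))
                busco = min(busco, total_genes)
                truth.busco_contaminated.add(cid)
            else:
                busco = int(rng.integers(0, int(0.05 * total_genes) + 1))
        else:
            viral = int(rng.integers(0, 3))
            microbial = int(viral + rng.integers(0, 5))
            score = float(rng.uniform(0.2, 0.95))
            p = (float(rng.uniform(0.02, 1.0)) if score > 0.90
                 else float(rng.uniform(0.0, 1.0)))
            flag = False
            busco = int(rng.integers(0, int(0.05 * total_genes) + 1))

        tier = str(rng.choice(tiers, p=tier_p))
        complete_flag = tier == "Complete"
        if tier == "Complete":
            completeness = 100.0
        elif tier == "High":
            completeness = float(rng.uniform(90.5, 100.0))
        elif tier == "Medium":
            completeness = float(rng.uniform(50.0, 90.0))
        elif tier == "Low":
            completeness = float(rng.uniform(1.0, 49.9))
        else:
            completeness = np.nan

        rows.append({
            "contig_id": cid, "length": len(seq),
            "gc": round(gc_content(seq), 6),
            "viral_genes": viral, "microbial_genes": microbial,
            "total_genes": total_genes,
            "predictor_score": round(score, 6),
            "predictor_p": round(p, 6),
            "keyword_flag": flag, "busco_count": busco,
            "completeness": (np.nan if np.isnan(completeness)
                             else round(completeness, 3)),
            "complete_flag": complete_flag,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein hits (taxonomy + function inputs)
# ---------------------------------------------------------------------------

def generate_protein_hits(
    config: SimulationConfig,
    seqs: dict[str, str],
    truth: TruthSet,
    rng: np.random.Generator | None = None,
    family_fraction: float = 0.7,
) -> pd.DataFrame:
    """Per-contig protein best-hit table (protein_id, hit_family, hit_ko,
    bitscore).  Species drawn a true family (``family_fraction`` of them)
    get >25% of their proteins hitting it; unclassified species never let
    any single family exceed the quarter-vote threshold."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    species = sorted(set(truth.species_assignment.values()))
    for sp in species:
        if rng.random() < family_fraction:
            truth.species_family[sp] = str(rng.choice(FAMILIES))
        else:
            truth.species_family[sp] = None

    rows = []
    for cid in sorted(truth.species_assignment):
        sp = truth.species_assignment[cid]
        fam = truth.species_family[sp]
        n_prot = int(max(4, rng.poisson(len(seqs[cid]) / 1500)))
        fam_hits = np.zeros(n_prot, dtype=bool)
        if fam is not None:
            k = int(np.floor(rng.uniform(0.30, 0.60) * n_prot))
            if k / n_prot <= 0.25:
                k = int(np.floor(0.25 * n_prot)) + 1
            fam_hits[rng.choice(n_prot, size=min(k, n_prot), replace=False)] \
                = True
        # background hits to random other families, capped below the
        # quarter-vote so they can never flip the call
        cap = max(0, int(np.floor(0.25 * n_prot)) - 1)
        bg_counts: dict[str, int] = {}
        for i in range(n_prot):
            pid = f"{cid}_p{i + 1}"
            if fam_hits[i]:
                hit_fam = fam
            elif rng.random() < 0.10:
                hit_fam = str(rng.choice(FAMILIES))
                if hit_fam == fam or bg_counts.get(hit_fam, 0) >= cap:
                    hit_fam = None
                else:
                    bg_counts[hit_fam] = bg_counts.get(hit_fam, 0) + 1
            else:
                hit_fam = None
            if hit_fam is not None or rng.random() < 0.3:
                ko = f"K{int(rng.integers(0, 26000)):05d}" \
                    if rng.random() < 0.5 else ""
                rows.append({
                    "contig_id": cid, "protein_id": pid,
                    "hit_family": hit_fam or "",
                    "hit_ko": ko,
                    "bitscore": round(float(rng.uniform(50, 500)), 1)})
                if rng.random() < 0.2:  # a weaker secondary hit
                    rows.append({
                        "contig_id": cid, "protein_id": pid,
                        "hit_family": hit_fam or "",
                        "hit_ko": f"K{int(rng.integers(0, 26000)):05d}",
                        "bitscore": round(float(rng.uniform(20, 49)), 1)})
            else:  # protein with no database hit still appears in the table
                rows.append({
                    "contig_id": cid, "protein_id": pid,
                    "hit_family": "", "hit_ko": "", "bitscore": np.nan})
    return pd.DataFrame(
        rows, columns=["contig_id", "protein_id", "hit_family", "hit_ko",
                       "bitscore"])


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def generate_abundances(
    config: SimulationConfig,
    virus_ids: list[str],
    bacteria_ids: list[str] | None,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted two-group abundance study.

    Base per-sample log-abundances are Gaussian around feature means drawn
    once (log-normal abundances after exponentiation, sigma = 1).  ``n_diff``
    viral features get group means separated by ``effect_log2fc`` log2
    units; each planted virus-bacterium pair shares a per-sample latent
    factor inducing strong monotone correlation within both groups.  Viral
    counts are multinomial draws at ``depth`` per sample.

    Returns (viral count matrix [samples x features], bacterial relative
    abundances [samples x features], metadata).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    if bacteria_ids is None:
        bacteria_ids = [f"bact{i + 1:03d}" for i in range(config.n_bacteria)]
    n_v, n_b = len(virus_ids), len(bacteria_ids)
    n_a, n_b_samp = config.n_samples_group_a, config.n_samples_group_b
    n = n_a + n_b_samp
    if config.depth < 10 * n_v:
        warnings.warn("depth < 10 x n_features: sparse counts make rank "
                      "tests unstable")

    samples = ([f"case{i + 1:02d}" for i in range(n_a)]
               + [f"ctrl{i + 1:02d}" for i in range(n_b_samp)])
    group = np.array(["case"] * n_a + ["control"] * n_b_samp)

    mu_v = rng.normal(0.0, 1.5, size=n_v)
    mu_b = rng.normal(0.0, 1.5, size=n_b)

    diff_idx = rng.choice(n_v, size=config.n_diff, replace=False)
    directions = rng.choice([1, -1], size=config.n_diff)
    truth.differential = [
        (virus_ids[i], int(d)) for i, d in zip(diff_idx, directions)]

    # planted correlated pairs on viruses not used as differential features
    free = np.setdiff1d(np.arange(n_v), diff_idx)
    if config.n_planted_edges > min(free.size, n_b):
        raise ValueError("not enough free features for planted edges")
    edge_v = rng.choice(free, size=config.n_planted_edges, replace=False)
    edge_b = rng.choice(n_b, size=config.n_planted_edges, replace=False)
    edge_signs = rng.choice([1, -1], size=config.n_planted_edges)
    truth.planted_edges = [
        (virus_ids[i], bacteria_ids[j], int(s))
        for i, j, s in zip(edge_v, edge_b, edge_signs)]

    logv = mu_v[None, :] + rng.normal(0.0, 1.0, size=(n, n_v))
    logb = mu_b[None, :] + rng.normal(0.0, 1.0, size=(n, n_b))
    shift = 0.5 * config.effect_log2fc * np.log(2.0)
    for i, d in zip(diff_idx, directions):
        logv[group == "case", i] += d * shift
        logv[group == "control", i] -= d * shift
    lam = CORRELATION_LOADING
    for i, j, s in zip(edge_v, edge_b, edge_signs):
        z = rng.normal(0.0, 1.0, size=n)
        logv[:, i] += lam * z
        logb[:, j] += s * lam * z

    pv = np.exp(logv)
    pv /= pv.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(config.depth, pv[s]) for s in range(n)])
    pb = np.exp(logb)
    pb /= pb.sum(axis=1, keepdims=True)

    counts_df = pd.DataFrame(counts, index=samples, columns=virus_ids)
    bact_df = pd.DataFrame(pb, index=samples, columns=bacteria_ids)
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": group,
        "age": np.round(rng.normal(30.0, 4.0, size=n), 1),
        "bmi": np.round(rng.normal(22.0, 3.0, size=n), 1),
    }).set_index("sample_id")
    return counts_df, bact_df, meta


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    contigs: dict[str, str]
    hosts: dict[str, str]
    spacers: pd.DataFrame
    evidence: pd.DataFrame
    protein_hits: pd.DataFrame
    counts: pd.DataFrame          # samples x viral features
    bacteria: pd.DataFrame        # samples x bacterial features
    metadata: pd.DataFrame
    truth: TruthSet


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete synthetic study from a single seed.

    Stage seeds are fanned out deterministically from ``config.seed`` so the
    whole study is byte-reproducible.
    """
    r_gen, r_host, r_evi, r_prot, r_abund = _rng_children(config.seed, 5)
    contigs, truth = generate_genomes(config, r_gen)
    viral = {c: s for c, s in contigs.items()
             if c in truth.species_assignment}
    evidence = generate_evidence(config, contigs, truth, r_evi)
    # links are planted against species ancestors that survive the BUSCO
    # decontamination: the eventual vOTU representatives, against which
    # the annotation stage matches
    ancestors = sorted(c for c in viral if c.endswith("_c0")
                       and c not in truth.busco_contaminated)
    hosts, spacers = generate_hosts(config, viral, truth, r_host,
                                    candidate_ids=ancestors)
    hits = generate_protein_hits(config, contigs, truth, r_prot)
    # abundance features are the species ancestors (the eventual vOTU
    # representatives: members are equal-length mutants and ties break
    # lexicographically, so _c0 always represents its cluster)
    virus_features = [f"sp{i + 1:04d}_c0" for i in range(config.n_species)]
    counts, bacteria, meta = generate_abundances(
        config, virus_features, None, truth, r_abund)
    return SimulatedStudy(config=config, contigs=contigs, hosts=hosts,
                          spacers=spacers, evidence=evidence,
                          protein_hits=hits, counts=counts,
                          bacteria=bacteria, metadata=meta, truth=truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study file (FASTA/TSV, feature-by-sample orientation for
    count tables) plus truth tables under ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    paths = {
        "contigs": out / "contigs.fasta",
        "hosts": out / "hosts.fasta",
        "spacers": out / "spacers.tsv",
        "evidence": out / "evidence.tsv",
        "protein_hits": out / "protein_hits.tsv",
        "counts": out / "counts.tsv",
        "bacteria": out / "bacteria_abundance.tsv",
        "metadata": out / "metadata.tsv",
        "config": out / "config.json",
    }
    write_fasta(study.contigs, paths["contigs"])
    write_fasta(study.hosts, paths["hosts"])
    study.spacers.to_csv(paths["spacers"], sep="\t", index=False)
    study.evidence.to_csv(paths["evidence"], sep="\t", index=False)
    study.protein_hits.to_csv(paths["protein_hits"], sep="\t", index=False)
    study.counts.T.to_csv(paths["counts"], sep="\t",
                          index_label="feature_id")
    study.bacteria.T.to_csv(paths["bacteria"], sep="\t",
                            index_label="feature_id")
    study.metadata.to_csv(paths["metadata"], sep="\t")
    import json
    cfg = asdict(study.config)
    cfg["genome_length_range"] = list(cfg["genome_length_range"])
    cfg["host_length_range"] = list(cfg["host_length_range"])
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")

    t = study.truth
    pd.DataFrame(sorted(t.species_assignment.items()),
                 columns=["contig_id", "species_id"]).to_csv(
        tdir / "species.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.species_family.items()),
                 columns=["species_id", "family"]).to_csv(
        tdir / "taxonomy.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.differential),
                 columns=["feature_id", "direction"]).to_csv(
        tdir / "markers.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.host_links),
                 columns=["virus_id", "host_id", "mechanism"]).to_csv(
        tdir / "host_links.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.planted_edges),
                 columns=["virus_id", "bacterium_id", "sign"]).to_csv(
        tdir / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.busco_contaminated),
                 columns=["contig_id"]).to_csv(
        tdir / "busco_contaminated.tsv", sep="\t", index=False)
    paths["truth"] = tdir
    return paths
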