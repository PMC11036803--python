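"""End-to-end orchestration: catalog -> annotate -> profile -> ecology ->
markers -> netassoc -> classify, driven by one config and one global seed.

Each stage reads only the declared output files of earlier stages, writes
its outputs under the run directory, and drops a ``<stage>.done`` marker so
interrupted runs resume from completed stages.  A manifest (JSON, no
timestamps) records the package version, the config hash, the fanned-out
per-stage seeds, and every stage's output files, so two runs with the same
config and seed produce byte-identical run directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from virome import (annotate, catalog, classify, ecology, markers, netassoc,
                    profile, synthgen)
from virome.sequtils import read_fasta, write_fasta

log = logging.getLogger(__name__)

STAGES = ("catalog", "annotate", "profile", "ecology", "markers",
          "netassoc", "classify")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    simulate: bool = False
    demo: bool = False
    input_dir: str | None = None
    sim_overrides: dict = field(default_factory=dict)
    # catalog
    min_len: int = 5_000
    ani_threshold: float = 0.95
    af_threshold: float = 0.75
    busco_max: float = 0.05
    triage_mode: str = "union"
    # profile
    target_depth: int | None = None   # None -> minimum sample total
    # ecology
    n_permutations: int = 1000
    # markers
    q_threshold: float = 0.05
    fc_threshold: float = 1.2
    # netassoc
    rho_threshold: float = 0.6
    # classify
    n_repeats: int = 5
    n_folds: int = 5
    n_trees: int = 500
    sweep: bool = True
    sweep_repetitions: int = 10

    def validate(self) -> None:
        checks = [
            (0 < self.ani_threshold <= 1, "ani_threshold in (0, 1]"),
            (0 < self.af_threshold <= 1, "af_threshold in (0, 1]"),
            (0 <= self.busco_max <= 1, "busco_max in [0, 1]"),
            (0 < self.q_threshold < 1, "q_threshold in (0, 1)"),
            (self.fc_threshold >= 1, "fc_threshold >= 1"),
            (0 < self.rho_threshold < 1, "rho_threshold in (0, 1)"),
            (self.min_len >= 0, "min_len >= 0"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.n_folds >= 2 and self.n_repeats >= 1, "CV layout"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config: {what} violated")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: demo-scale generator overrides for the one-command synthetic smoke run
DEMO_SIM = dict(n_species=50, members_per_species=2, n_decoys=20,
                n_hosts=10, n_samples_group_a=15, n_samples_group_b=15,
                depth=30_000, n_diff=10, n_planted_edges=5,
                n_crispr_links=8, n_prophage_links=4, n_bacteria=20,
                n_decoy_spacers=8, genome_length_range=(5_000, 12_000))
DEMO_RUN = dict(n_permutations=199, n_trees=200, sweep_repetitions=5)


def stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES) + 1)
    names = ("simulate",) + STAGES
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    config.validate()
    if config.demo:
        for k, v in DEMO_RUN.items():
            setattr(config, k, v)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "package": "virome",
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "stages": {},
    }

    def done(stage: str) -> Path:
        return out / f"{stage}.done"

    def stage_files(d: Path) -> list[str]:
        return sorted(str(f.relative_to(out)) for f in d.rglob("*")
                      if f.is_file())

    def finish(stage: str, d: Path) -> None:
        manifest["stages"][stage] = stage_files(d)
        done(stage).write_text("")
        log.info("stage %s: %d output files", stage,
                 len(manifest["stages"][stage]))

    # ------------------------------------------------------------------ data
    if config.simulate:
        sdir = out / "simulated"
        if not done("simulate").exists():
            overrides = dict(DEMO_SIM) if config.demo else {}
            overrides.update(config.sim_overrides)
            sim_cfg = synthgen.SimulationConfig(
                seed=seeds["simulate"], **overrides)
            study = synthgen.simulate(sim_cfg)
            synthgen.write_study(study, sdir)
            finish("simulate", sdir)
        indir = sdir
    elif config.input_dir:
        indir = Path(config.input_dir)
    else:
        raise StageError("catalog", "no input directory and --simulate "
                         "not set")

    def need(name: str) -> Path:
        p = indir / name
        if not p.exists():
            raise StageError("catalog", f"missing input {p}")
        return p

    # --------------------------------------------------------------- catalog
    cdir = out / "catalog"
    if not done("catalog").exists():
        cdir.mkdir(exist_ok=True)
        try:
            seqs = read_fasta(need("contigs.fasta"))
            evidence = catalog.read_evidence(need("evidence.tsv"))
            records = catalog.records_from_evidence(evidence, seqs)
            result = catalog.build_catalog(
                seqs, records, min_len=config.min_len,
                ani_threshold=config.ani_threshold,
                af_threshold=config.af_threshold,
                busco_max=config.busco_max,
                triage_mode=config.triage_mode)
        except (ValueError, KeyError) as exc:
            raise StageError("catalog", str(exc)) from exc
        catalog.clusters_to_frame(result.clusters).to_csv(
            cdir / "clusters.tsv", sep="\t", index=False)
        write_fasta(result.representatives, cdir / "representatives.fasta")
        finish("catalog", cdir)

    clusters = pd.read_csv(cdir / "clusters.tsv", sep="\t")
    votu_of_contig = {
        m: row.votu_id
        for row in clusters.itertuples(index=False)
        for m in row.members.split(",")}
    # representatives.fasta is keyed by vOTU id
    votu_seqs = read_fasta(cdir / "representatives.fasta")

    # -------------------------------------------------------------- annotate
    adir = out / "annotate"
    if not done("annotate").exists():
        adir.mkdir(exist_ok=True)
        try:
            hits = pd.read_csv(need("protein_hits.tsv"), sep="\t")
            spacers = pd.read_csv(need("spacers.tsv"), sep="\t")
            hosts = read_fasta(need("hosts.fasta"))
            fams = annotate.assign_families(hits, votu_of_contig)
            links = annotate.predict_hosts(spacers, hosts, votu_seqs)
            kos = annotate.assign_ko(hits)
        except (ValueError, KeyError) as exc:
            raise StageError("annotate", str(exc)) from exc
        pd.DataFrame(sorted(fams.items()),
                     columns=["votu_id", "family"]).to_csv(
            adir / "taxonomy.tsv", sep="\t", index=False)
        annotate.links_to_frame(links).to_csv(
            adir / "host_links.tsv", sep="\t", index=False)
        kos.to_csv(adir / "ko.tsv", sep="\t", index=False)
        finish("annotate", adir)

    # --------------------------------------------------------------- profile
    pdir = out / "profile"
    if not done("profile").exists():
        pdir.mkdir(exist_ok=True)
        try:
            counts = profile.read_feature_table(need("counts.tsv"))
            counts.columns = [votu_of_contig.get(c, c)
                              for c in counts.columns]
            target = config.target_depth or int(counts.sum(axis=1).min())
            sub = profile.subsample(counts, target, seeds["profile"])
            ab = profile.relative_abundance(sub)
            taxonomy = pd.read_csv(adir / "taxonomy.tsv", sep="\t")
            fam_map = dict(zip(taxonomy["votu_id"], taxonomy["family"]))
            fam = profile.family_rollup(ab, fam_map)
        except ValueError as exc:
            raise StageError("profile", str(exc)) from exc
        profile.write_feature_table(sub, pdir / "counts_subsampled.tsv")
        profile.write_feature_table(ab, pdir / "abundance_votu.tsv")
        profile.write_feature_table(fam, pdir / "abundance_family.tsv")
        finish("profile", pdir)

    ab = profile.read_feature_table(pdir / "abundance_votu.tsv")
    meta = pd.read_csv(need("metadata.tsv"), sep="\t", index_col=0)
    meta = meta.loc[ab.index]

    # --------------------------------------------------------------- ecology
    edir = out / "ecology"
    if not done("ecology").exists():
        edir.mkdir(exist_ok=True)
        try:
            div = ecology.alpha_diversity(ab)
            dist = ecology.bray_curtis(ab)
            ords = ecology.pcoa(dist, n_axes=10)
            acc = ecology.accumulation_curve(
                ab, meta["group"], seed=seeds["ecology"])
            perm = ecology.permanova_table(
                dist, meta, n_permutations=config.n_permutations,
                seed=seeds["ecology"])
        except ValueError as exc:
            raise StageError("ecology", str(exc)) from exc
        div.to_csv(edir / "diversity.tsv", sep="\t")
        dist.to_csv(edir / "distance.tsv", sep="\t")
        coords = ords.coordinates.copy()
        coords.to_csv(edir / "pcoa.tsv", sep="\t")
        pd.DataFrame({"axis": coords.columns,
                      "variance_ratio": ords.variance_ratio
                      [:coords.shape[1]]}).to_csv(
            edir / "pcoa_variance.tsv", sep="\t", index=False)
        acc.to_csv(edir / "accumulation.tsv", sep="\t", index=False)
        perm.to_csv(edir / "permanova.tsv", sep="\t", index=False)
        finish("ecology", edir)

    # --------------------------------------------------------------- markers
    mdir = out / "markers"
    if not done("markers").exists():
        mdir.mkdir(exist_ok=True)
        try:
            table = markers.call_markers(
                ab, meta["group"], q_threshold=config.q_threshold,
                fc_threshold=config.fc_threshold)
        except ValueError as exc:
            raise StageError("markers", str(exc)) from exc
        table.to_csv(mdir / "markers.tsv", sep="\t", index=False)
        finish("markers", mdir)

    marker_table = pd.read_csv(mdir / "markers.tsv", sep="\t",
                               keep_default_na=False)
    marker_ids = [f for f in marker_table.loc[
        marker_table["enriched_in"] != "", "feature_id"]]

    # -------------------------------------------------------------- netassoc
    ndir = out / "netassoc"
    if not done("netassoc").exists():
        ndir.mkdir(exist_ok=True)
        try:
            bact = profile.read_feature_table(need("bacteria_abundance.tsv"))
            bact = bact.loc[ab.index]
            ga, gb = sorted(meta["group"].unique())
            virus_feats = ab[marker_ids] if len(marker_ids) >= 2 else ab
            ea = netassoc.spearman_edges(
                virus_feats, bact, meta["group"] == ga, ga,
                threshold=config.rho_threshold)
            eb = netassoc.spearman_edges(
                virus_feats, bact, meta["group"] == gb, gb,
                threshold=config.rho_threshold)
            rep = netassoc.share_networks(ea, eb)
        except ValueError as exc:
            raise StageError("netassoc", str(exc)) from exc
        ea.edges.to_csv(ndir / f"edges_{ea.group}.tsv", sep="\t",
                        index=False)
        eb.edges.to_csv(ndir / f"edges_{eb.group}.tsv", sep="\t",
                        index=False)
        sharing = pd.DataFrame(
            sorted([(v, b, "shared") for v, b in rep.shared]
                   + [(v, b, f"{ea.group}_specific") for v, b in rep.only_a]
                   + [(v, b, f"{eb.group}_specific") for v, b in rep.only_b]),
            columns=["virus_id", "bacterium_id", "status"])
        sharing.to_csv(ndir / "sharing.tsv", sep="\t", index=False)
        if rep.shared:
            dv, db = netassoc.degree_ranking(rep.shared, top_k=20)
            dv.to_csv(ndir / "degree_virus.tsv", sep="\t", index=False)
            db.to_csv(ndir / "degree_bacterium.tsv", sep="\t", index=False)
        else:
            for f in ("degree_virus.tsv", "degree_bacterium.tsv"):
                pd.DataFrame(columns=["node", "degree"]).to_csv(
                    ndir / f, sep="\t", index=False)
        finish("netassoc", ndir)

    # -------------------------------------------------------------- classify
    kdir = out / "classify"
    if not done("classify").exists():
        kdir.mkdir(exist_ok=True)
        feats = ab[marker_ids] if len(marker_ids) >= 2 else ab
        try:
            report = classify.cv_auc(
                feats, meta["group"], n_repeats=config.n_repeats,
                n_folds=config.n_folds, seed=seeds["classify"],
                n_trees=config.n_trees)
            order = classify.importance_ranking(report)
            sweep = None
            if config.sweep and len(order) >= 2:
                grid = [k for k in range(5, min(50, len(order)) + 1, 5)]
                if not grid:
                    grid = [len(order)]
                sweep = classify.panel_sweep(
                    feats, meta["group"], order, k_grid=grid,
                    n_repetitions=config.sweep_repetitions,
                    n_folds=config.n_folds, seed=seeds["classify"],
                    n_trees=config.n_trees)
        except ValueError as exc:
            raise StageError("classify", str(exc)) from exc
        (kdir / "report.json").write_text(json.dumps({
            "auc": report.auc, "ci_low": report.ci_low,
            "ci_high": report.ci_high,
            "per_repeat_auc": report.per_repeat_auc,
            "scheme": report.scheme,
            "n_features": int(feats.shape[1]),
        }, indent=2, sort_keys=True) + "\n")
        report.importance.rename_axis("feature_id").reset_index().to_csv(
            kdir / "importance.tsv", sep="\t", index=False)
        if sweep is not None:
            sweep.table.assign(best_k=sweep.best_k).to_csv(
                kdir / "sweep.tsv", sep="	", index=False)
        finish("classify", kdir)

    # stages skipped on resume: backfill their file lists from disk
    dirs = {"simulate": "simulated", "catalog": "catalog",
            "annotate": "annotate", "profile": "profile",
            "ecology": "ecology", "markers": "markers",
            "netassoc": "netassoc", "classify": "classify"}
    for stage, dname in dirs.items():
        if (stage not in manifest["stages"] and done(stage).exists()
                and (out / dname).exists()):
            manifest["stages"][stage] = stage_files(out / dname)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
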