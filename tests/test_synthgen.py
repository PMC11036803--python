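"""Generator contracts: determinism, counting, planted homology levels,
truth coverage, and the abundance model's planted signals."""

import numpy as np
import pandas as pd
import pytest

from helpers import dp_identity
from virome import synthgen
from virome.synthgen import SimulationConfig, TruthSet


def tiny_cfg(**kw) -> SimulationConfig:
    base = dict(seed=1, n_species=5, members_per_species=1, n_decoys=3,
                n_hosts=4, n_samples_group_a=6, n_samples_group_b=6,
                depth=10_000, n_diff=2, n_planted_edges=1,
                n_crispr_links=2, n_prophage_links=1, n_bacteria=6,
                n_decoy_spacers=2, genome_length_range=(5_000, 7_000))
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_contigs_below_5kb_floor(self):
        with pytest.raises(ValueError, match="5 kb"):
            tiny_cfg(genome_length_range=(2_000, 7_000))

    def test_rejects_divergence_breaking_species_boundary(self):
        with pytest.raises(ValueError, match="ANI"):
            tiny_cfg(mutant_divergence=0.06)

    def test_rejects_more_differentials_than_species(self):
        with pytest.raises(ValueError, match="n_diff"):
            tiny_cfg(n_diff=99)


class TestGenomes:
    def test_seeded_runs_are_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            study = synthgen.simulate(tiny_cfg())
            synthgen.write_study(study, tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_contig_count_without_members(self):
        cfg = tiny_cfg(members_per_species=0)
        seqs, truth = synthgen.generate_genomes(cfg)
        assert len(seqs) == cfg.n_species + cfg.n_decoys
        assert len(truth.species_assignment) == cfg.n_species

    def test_member_divergence_matches_requested_rate(self, rng):
        cfg = tiny_cfg(mutant_divergence=0.02,
                       genome_length_range=(5_000, 5_000))
        seqs, truth = synthgen.generate_genomes(
            cfg, np.random.default_rng(5))
        ident = dp_identity(seqs["sp0001_c0"], seqs["sp0001_c1"])
        # substitutions at rate 2% over L=5000: binomial sd ~ 0.2 pp
        assert ident == pytest.approx(0.98, abs=0.01)

    def test_every_contig_appears_in_exactly_one_truth_record(self):
        study = synthgen.simulate(tiny_cfg())
        viral = [c for c in study.contigs if not c.startswith("decoy")]
        assert sorted(study.truth.species_assignment) == sorted(viral)


class TestHosts:
    def test_planted_spacer_is_exact_substring_of_its_virus(self, small_study):
        spacers = small_study.spacers.set_index("spacer_id")
        by_host = small_study.spacers.groupby("host_id")
        crispr = [(v, h) for v, h, m in small_study.truth.host_links
                  if m == "crispr"]
        assert crispr
        for virus, host in crispr:
            host_spacers = by_host.get_group(host)["sequence"]
            assert any(s in small_study.contigs[virus]
                       for s in host_spacers)

    def test_planted_prophage_aligns_long_and_high_identity(self, small_study):
        from virome.alignment import local_blocks
        pro = [(v, h) for v, h, m in small_study.truth.host_links
               if m == "prophage"]
        assert pro
        for virus, host in pro:
            blocks = local_blocks(small_study.contigs[virus],
                                  small_study.hosts[host], min_block=500)
            assert any(cols >= 1_000 and ident >= 0.95
                       for *_, ident, cols in blocks)

    def test_zero_planted_links_gives_empty_spacer_table(self):
        cfg = tiny_cfg(n_crispr_links=0, n_prophage_links=0,
                       n_decoy_spacers=0)
        seqs, truth = synthgen.generate_genomes(cfg)
        hosts, spacers = synthgen.generate_hosts(cfg, seqs, truth)
        assert spacers.empty
        assert truth.host_links == []


class TestEvidence:
    def test_decoys_fail_all_three_triage_criteria(self, small_study):
        ev = small_study.evidence.set_index("contig_id")
        decoys = ev.loc[[c for c in ev.index if c.startswith("decoy")]]
        assert (decoys["viral_genes"] <= decoys["microbial_genes"]).all()
        assert ((decoys["predictor_score"] <= 0.90)
                | (decoys["predictor_p"] >= 0.01)).all()
        assert (~decoys["keyword_flag"]).all()

    def test_planted_contaminants_exceed_busco_cutoff(self, small_study):
        ev = small_study.evidence.set_index("contig_id")
        for cid in small_study.truth.busco_contaminated:
            row = ev.loc[cid]
            assert row["busco_count"] / row["total_genes"] > 0.05
        clean = ev.drop(index=list(small_study.truth.busco_contaminated))
        assert (clean["busco_count"] / clean["total_genes"] <= 0.05).all()

    def test_all_five_quality_tiers_are_populated(self):
        study = synthgen.simulate(tiny_cfg(n_species=80, n_decoys=0,
                                           members_per_species=0))
        ev = study.evidence
        assert ev["complete_flag"].any()
        comp = ev["completeness"].dropna()
        assert (comp > 90).any() and comp.isin(comp[(comp >= 50)
                                                    & (comp <= 90)]).any()
        assert (comp < 50).any()
        assert ev["completeness"].isna().any()


class TestAbundances:
    def test_sample_totals_equal_depth(self, small_study):
        totals = small_study.counts.sum(axis=1)
        assert (totals == small_study.config.depth).all()

    def test_null_configuration_leaves_groups_exchangeable(self):
        """With no planted effect the two group means agree to sampling
        noise; marker behaviour under the null is covered in the marker
        suite."""
        cfg = tiny_cfg(n_diff=0, n_planted_edges=0, n_species=50,
                       n_samples_group_a=20, n_samples_group_b=20,
                       depth=100_000)
        truth = TruthSet()
        counts, _, meta = synthgen.generate_abundances(
            cfg, [f"v{i}" for i in range(50)], None, truth,
            np.random.default_rng(0))
        a = counts[meta["group"] == "case"].mean()
        b = counts[meta["group"] == "control"].mean()
        # pooled over features, relative difference is small under the null
        assert abs(a.sum() - b.sum()) / a.sum() < 0.01
        assert truth.differential == [] and truth.planted_edges == []

    def test_planted_pair_correlates_in_most_seeds(self):
        """The planted latent factor induces within-group Spearman rho
        above 0.6 in nearly all seeds."""
        from scipy.stats import spearmanr
        hits = trials = 0
        for seed in range(15):
            cfg = tiny_cfg(seed=seed, n_species=40, n_planted_edges=3,
                           n_diff=0, n_samples_group_a=40,
                           n_samples_group_b=40, n_bacteria=15,
                           depth=100_000)
            truth = TruthSet()
            vids = [f"v{i}" for i in range(40)]
            counts, bact, meta = synthgen.generate_abundances(
                cfg, vids, None, truth, np.random.default_rng(seed))
            rel = counts.div(counts.sum(axis=1), axis=0)
            for v, b, sign in truth.planted_edges:
                for g in ("case", "control"):
                    m = meta["group"] == g
                    rho = spearmanr(rel.loc[m.values, v],
                                    bact.loc[m.values, b]).statistic
                    trials += 1
                    hits += abs(rho) > 0.6 and np.sign(rho) == sign
        assert hits / trials >= 0.95

    def test_shallow_depth_warns_about_sparse_counts(self):
        cfg = tiny_cfg(n_species=50, depth=100)
        truth = TruthSet()
        with pytest.warns(UserWarning, match="sparse"):
            synthgen.generate_abundances(
                cfg, [f"v{i}" for i in range(50)], None, truth,
                np.random.default_rng(0))
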