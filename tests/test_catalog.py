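"""Catalog construction: triage rule boundaries, BUSCO decontamination,
ANI/AF bookkeeping against a dynamic-programming oracle, greedy clustering
determinism, and quality tiers."""

import numpy as np
import pandas as pd
import pytest

from helpers import dp_identity, mutate_exact, random_seq
from virome import catalog
from virome.catalog import ContigRecord, PairwiseSimilarity
from virome.sequtils import revcomp


def rec(cid="c1", viral=0, microbial=0, score=0.0, p=1.0, flag=False,
        busco=0, total=10, completeness=None, complete=False, length=6000):
    return ContigRecord(
        contig_id=cid, sequence=None, length=length, gc=0.5,
        viral_genes=viral, microbial_genes=microbial, total_genes=total,
        predictor_score=score, predictor_p=p, keyword_flag=flag,
        busco_count=busco, completeness=completeness, complete_flag=complete)


class TestTriage:
    @pytest.mark.parametrize("kw,expected", [
        # gene-content criterion alone retains
        (dict(viral=5, microbial=2, score=0.1, p=1.0), True),
        # predictor criterion at its open boundary retains
        (dict(viral=0, microbial=3, score=0.91, p=0.005), True),
        # strict inequalities: score exactly 0.90 and equal gene counts fail
        (dict(viral=2, microbial=2, score=0.90, p=0.005), False),
        # annotation flag alone retains
        (dict(viral=0, microbial=5, flag=True), True),
        # p exactly 0.01 fails the predictor criterion
        (dict(viral=0, microbial=0, score=0.99, p=0.01), False),
    ])
    def test_union_rule_boundaries(self, kw, expected):
        assert (catalog.triage([rec(**kw)]) == ["c1"]) is expected

    def test_intersection_mode_requires_all_three(self):
        r = rec(viral=5, microbial=2, score=0.95, p=0.001, flag=True)
        assert catalog.triage([r], mode="intersection") == ["c1"]
        r2 = rec(viral=5, microbial=2, score=0.95, p=0.001, flag=False)
        assert catalog.triage([r2], mode="intersection") == []


class TestBuscoFilter:
    @pytest.mark.parametrize("busco,total,kept", [
        (6, 100, False),   # 6% > 5% eliminated
        (5, 100, True),    # exactly 5% retained (not strictly greater)
        (0, 100, True),
    ])
    def test_ratio_boundary(self, busco, total, kept):
        out = catalog.busco_filter([rec(busco=busco, total=total)])
        assert (out == ["c1"]) is kept

    def test_zero_genes_retained_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = catalog.busco_filter([rec(busco=0, total=0)])
        assert out == ["c1"]
        assert "BUSCO ratio" in caplog.text


class TestPairwiseANI:
    def test_identical_sequences_full_identity(self, rng):
        s = random_seq(rng, 1_000)
        sim = catalog.pairwise_ani("a", s, "b", s)
        assert sim.ani == 1.0
        assert sim.af_query == 1.0 and sim.af_target == 1.0

    def test_exactly_fifty_substitutions_gives_ani_095(self, rng):
        s = random_seq(rng, 1_000)
        t = mutate_exact(rng, s, 50)
        sim = catalog.pairwise_ani("a", s, "b", t)
        assert sim.ani == pytest.approx(0.95, abs=0.001)
        assert sim.af_query == pytest.approx(1.0, abs=0.01)

    def test_unrelated_sequences_have_no_alignment(self, rng):
        a, b = random_seq(rng, 5_000), random_seq(rng, 5_000)
        sim = catalog.pairwise_ani("a", a, "b", b)
        assert sim.ani is None and sim.af_query == 0.0

    def test_reverse_complement_gives_same_ani(self, rng):
        s = random_seq(rng, 2_000)
        t = mutate_exact(rng, s, 40)
        fwd = catalog.pairwise_ani("a", s, "b", t)
        rev = catalog.pairwise_ani("a", s, "b", revcomp(t))
        assert rev.ani == pytest.approx(fwd.ani, abs=0.002)

    def test_agrees_with_dp_oracle_on_short_pairs(self, rng):
        """k-mer-screened edlib ANI tracks a full DP alignment within
        0.5 percentage points on <= 2 kb pairs."""
        for _ in range(10):
            n = int(rng.integers(500, 2_000))
            a = random_seq(rng, n)
            b = mutate_exact(rng, a, int(rng.integers(5, n // 12)))
            got = catalog.pairwise_ani("a", a, "b", b).ani
            assert abs(got - dp_identity(a, b)) < 0.005

    def test_refuses_mostly_n_sequence(self):
        with pytest.raises(ValueError, match="N"):
            catalog.pairwise_ani("a", "N" * 900 + "ACGT" * 25, "b",
                                 "ACGT" * 250)


class TestGreedyCluster:
    def test_three_identical_sequences_one_cluster(self, rng):
        s = random_seq(rng, 6_000)
        seqs = {"a": s, "b": s, "c": s}
        sims = catalog.all_pairwise(seqs)
        out = catalog.greedy_cluster(sims, {k: len(v)
                                            for k, v in seqs.items()})
        assert len(out) == 1
        assert sorted(out[0].member_ids) == ["a", "b", "c"]
        assert out[0].representative_id == "a"  # ties break lexicographically

    def test_high_ani_low_overlap_stays_separate(self, rng):
        """A half-length fragment at 97% identity fails the 75% AF gate on
        the longer sequence and must not be absorbed."""
        s = random_seq(rng, 8_000)
        frag = mutate_exact(rng, s[:4_000], 120)
        seqs = {"long": s, "frag": frag}
        sims = catalog.all_pairwise(seqs)
        sim = sims[0]
        assert sim.ani > 0.95
        assert min(sim.af_query, sim.af_target) < 0.75
        out = catalog.greedy_cluster(sims, {k: len(v)
                                            for k, v in seqs.items()})
        assert len(out) == 2

    def test_planted_species_recovered_exactly(self, rng):
        """10 species x 4 members at 2% divergence cluster to exactly the
        planted partition (oracle: member-vs-centroid DP identity)."""
        from sklearn.metrics import adjusted_rand_score
        from virome import synthgen
        cfg = synthgen.SimulationConfig(
            seed=9, n_species=10, members_per_species=3, n_decoys=0,
            n_diff=0, genome_length_range=(5_000, 8_000))
        seqs, truth = synthgen.generate_genomes(cfg)
        sims = catalog.all_pairwise(seqs)
        clusters = catalog.greedy_cluster(
            sims, {k: len(v) for k, v in seqs.items()})
        assert len(clusters) == 10
        label_of = {m: i for i, c in enumerate(clusters)
                    for m in c.member_ids}
        contigs = sorted(seqs)
        ari = adjusted_rand_score(
            [truth.species_assignment[c] for c in contigs],
            [label_of[c] for c in contigs])
        assert ari == 1.0
        for c in clusters[:2]:  # spot-check members against the centroid
            for m in c.member_ids:  # with the DP oracle (full sweep is slow)
                if m != c.representative_id:
                    ident = dp_identity(seqs[c.representative_id], seqs[m])
                    assert ident >= 0.95

    def test_result_independent_of_similarity_order(self, rng):
        s = random_seq(rng, 6_000)
        seqs = {"a": s, "b": mutate_exact(rng, s, 60),
                "c": random_seq(rng, 7_000)}
        sims = catalog.all_pairwise(seqs)
        lengths = {k: len(v) for k, v in seqs.items()}
        out1 = catalog.greedy_cluster(sims, lengths)
        out2 = catalog.greedy_cluster(list(reversed(sims)), lengths)
        assert ([sorted(c.member_ids) for c in out1]
                == [sorted(c.member_ids) for c in out2])

    def test_unknown_id_in_similarity_table_fails(self):
        sims = [PairwiseSimilarity("x", "y", 1.0, 1.0, 1.0)]
        with pytest.raises(KeyError):
            catalog.greedy_cluster(sims, {"x": 5_000})


class TestQualityTier:
    @pytest.mark.parametrize("completeness,complete,expected", [
        (95.0, False, "High"),
        (100.0, True, "Complete"),
        (90.0, False, "Medium"),   # inclusive upper bound of the band
        (50.0, False, "Medium"),   # inclusive lower bound
        (49.9, False, "Low"),
        (None, False, "Undetermined"),
    ])
    def test_tier_bands(self, completeness, complete, expected):
        assert catalog.quality_tier(
            rec(completeness=completeness, complete=complete)) == expected

    def test_out_of_range_completeness_fails(self):
        with pytest.raises(ValueError, match="completeness"):
            catalog.quality_tier(rec(completeness=140.0))


class TestEvidenceIO:
    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        header = "\t".join(catalog.EVIDENCE_COLUMNS)
        good = "c1\t6000\t0.5\t5\t1\t10\t0.5\t0.5\tfalse\t0\t80\tfalse"
        bad = "c2\toops\t0.5\t5\t1\t10\t0.5\t0.5\tfalse\t0\t80\tfalse"
        path.write_text("\n".join([header, good, bad]) + "\n")
        with pytest.raises(ValueError, match="line 3"):
            catalog.read_evidence(path)

    def test_roundtrip_through_records(self, small_study):
        df = small_study.evidence
        records = catalog.records_from_evidence(df, small_study.contigs)
        assert len(records) == len(df)
        assert all(r.sequence is not None for r in records)
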