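"""16S curation, tiered rank assignment, and community profiling."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phyllotig as pt
from phyllotig.align import pairwise_identity
from phyllotig.ssu import (
    CommunityProfile,
    MissingDepthForGene,
    RankTiers,
    SSUGene,
    SSURecord,
    assign_rank,
    clustering_identity,
    compare_profiles,
    curate_reference_db,
    profile_community,
    search_top_hit,
)

from .oracles import oracle_greedy_cluster, oracle_profile, random_dna

LINEAGE = ("P", "C", "O", "F", "G", "S")


def _rec(ref_id, seq):
    return SSURecord(ref_id=ref_id, lineage=LINEAGE, sequence=seq)


class TestCuration:
    def test_length_filter_is_inclusive_drop(self):
        rng = random.Random(0)
        short = _rec("short", random_dna(rng, 1400))
        long = _rec("long", random_dna(rng, 1500))
        assert curate_reference_db([short, long]) == [long]

    def test_identical_pair_collapses(self):
        rng = random.Random(1)
        a = random_dna(rng, 1500)
        b = random_dna(rng, 1500)
        reps = curate_reference_db([_rec("a1", a), _rec("a2", a), _rec("b", b)])
        assert {r.ref_id for r in reps} == {"a1", "b"}

    def test_matches_all_pairs_greedy_oracle(self):
        rng = random.Random(2)
        records = []
        for i in range(10):
            base = random_dna(rng, rng.randint(1450, 1600))
            records.append(_rec(f"r{i:02d}", base))
            # plant a 98%-identity partner for some records
            if i % 3 == 0:
                twin = pt.mutate_to_identity(base, 98.0, seed=i)
                records.append(_rec(f"r{i:02d}t", twin))
        reps = curate_reference_db(records)
        expected = oracle_greedy_cluster(records, 1400, 97.0, pairwise_identity)
        assert [r.ref_id for r in reps] == [r.ref_id for r in expected]
        # and no two representatives remain at >= 97% coverage-gated identity
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert clustering_identity(a.sequence, b.sequence) < 97.0

    def test_all_filtered_returns_empty(self):
        assert curate_reference_db([_rec("x", random_dna(random.Random(3), 1200))]) == []


class TestTopHit:
    def test_exact_member_is_top_hit(self, curated_db):
        ref = curated_db[0]
        gene = SSUGene("g", "ctg", ref.sequence)
        hit = search_top_hit(gene, curated_db)
        assert hit.ref_id == ref.ref_id
        assert hit.identity == 100.0

    def test_low_coverage_hit_removed(self):
        rng = random.Random(4)
        gene_seq = random_dna(rng, 1500)
        partial_ref = _rec("partial", gene_seq[45:1455])  # covers 94% of the gene
        hit = search_top_hit(SSUGene("g", "ctg", gene_seq), [partial_ref], min_coverage=95.0)
        assert hit is None

    def test_short_gene_rejected(self, curated_db):
        with pytest.raises(ValueError):
            search_top_hit(SSUGene("g", "ctg", "ACGT" * 300), curated_db)

    def test_planted_identities_recovered(self, curated_db):
        rng = np.random.default_rng(5)
        for target in (99.0, 95.5, 88.0, 80.5):
            ref = curated_db[int(rng.integers(len(curated_db)))]
            mutated = pt.mutate_to_identity(ref.sequence, target, seed=int(rng.integers(2**31)))
            hit = search_top_hit(SSUGene("g", "ctg", mutated), curated_db)
            assert hit.ref_id == ref.ref_id
            assert hit.identity == pytest.approx(target, abs=0.5)


class TestRankTiers:
    @pytest.mark.parametrize(
        "identity,rank,flag",
        [
            (98.2, "species", "known_species"),
            (100.0, "species", "known_species"),
            (97.0, "species", "known_species"),
            (96.9, "genus", "novel_species"),
            (94.5, "genus", "novel_species"),
            (87.4, "family", "novel_genus"),
            (86.5, "family", "novel_genus"),
            (82.0, "order", "novel_family"),
            (78.0, "class", "novel_order"),
            (77.0, "unresolved", "novel_class"),
        ],
    )
    def test_boundaries_are_lower_inclusive(self, identity, rank, flag):
        assert assign_rank(identity) == (rank, flag)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 100.5])
    def test_out_of_range_identity_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_rank(bad)

    @given(st.floats(min_value=1e-6, max_value=100.0))
    def test_exactly_one_tier_fires(self, identity):
        rank, flag = assign_rank(identity)
        assert (flag == "known_species") == (identity >= 97.0)

    def test_tiers_must_strictly_decrease(self):
        with pytest.raises(ValueError):
            RankTiers(species=97, genus=97, family=86.5, order=82, class_=78)


def _profile_fixture():
    genes = [
        SSUGene("g1", "c1", "A" * 1500, contig_depth=10.0),
        SSUGene("g2", "c2", "A" * 1500, contig_depth=30.0),
    ]
    assignments = [
        pt.RankAssignment("g1", "r1", (*LINEAGE[:-1], "X"), 99.0, 100.0, "species", "known_species"),
        pt.RankAssignment("g2", "r2", (*LINEAGE[:-1], "Y"), 99.0, 100.0, "species", "known_species"),
    ]
    return genes, assignments


class TestProfile:
    def test_depth_weighted_arithmetic(self):
        genes, assignments = _profile_fixture()
        profile = profile_community(assignments, genes)
        assert profile.abundance("X") == pytest.approx(25.0)
        assert profile.abundance("Y") == pytest.approx(75.0)

    def test_multi_copy_contig_counts_once_per_contig(self):
        genes = [SSUGene(f"g{i}", "c1", "A" * 1500, contig_depth=10.0) for i in range(3)]
        genes.append(SSUGene("g9", "c2", "A" * 1500, contig_depth=10.0))
        assignments = [
            pt.RankAssignment(g.gene_id, "r", (*LINEAGE[:-1], "X" if g.contig_id == "c1" else "Y"),
                              99.0, 100.0, "species", "known_species")
            for g in genes
        ]
        per_contig = profile_community(assignments, genes, weighting="per_contig")
        assert per_contig.abundance("X") == pytest.approx(50.0)
        row = per_contig.table.loc["X"]
        assert (row["n_genes"], row["n_contigs"]) == (3, 1)
        per_gene = profile_community(assignments, genes, weighting="per_gene")
        assert per_gene.abundance("X") == pytest.approx(75.0)

    def test_abundances_sum_to_100_and_scale_invariant(self):
        rng = np.random.default_rng(6)
        genes = [
            SSUGene(f"g{i}", f"c{i % 12}", "A" * 1500, contig_depth=float(d))
            for i, d in enumerate(rng.lognormal(2, 1, 30))
        ]
        assignments = [
            pt.RankAssignment(g.gene_id, "r", (*LINEAGE[:-1], f"sp{int(g.contig_id[1:]) % 5}"),
                              99.0, 100.0, "species", "known_species")
            for g in genes
        ]
        for weighting in ("per_contig", "per_gene"):
            profile = profile_community(assignments, genes, weighting=weighting)
            assert profile.table["relative_abundance"].sum() == pytest.approx(100.0, abs=1e-6)
            expected = oracle_profile(assignments, genes, weighting)
            for taxon, ab in expected.items():
                assert profile.abundance(taxon) == pytest.approx(ab, abs=1e-9)
            scaled = [
                SSUGene(g.gene_id, g.contig_id, g.sequence, contig_depth=g.contig_depth * 37.5)
                for g in genes
            ]
            rescaled = profile_community(assignments, scaled, weighting=weighting)
            pd.testing.assert_series_equal(
                rescaled.table["relative_abundance"], profile.table["relative_abundance"]
            )

    def test_missing_depth_raises(self):
        genes = [SSUGene("g1", "c1", "A" * 1500, contig_depth=None)]
        assignments = [
            pt.RankAssignment("g1", "r", LINEAGE, 99.0, 100.0, "species", "known_species")
        ]
        with pytest.raises(MissingDepthForGene):
            profile_community(assignments, genes)


def _profile_from(abundances: dict[str, float]) -> CommunityProfile:
    table = pd.DataFrame(
        {"relative_abundance": pd.Series(abundances), "n_genes": 1, "n_contigs": 1}
    ).rename_axis("taxon")
    return CommunityProfile(table=table, weighting="per_contig")


class TestCompareProfiles:
    def test_identical_profiles_fully_overlap(self):
        p = _profile_from({"X": 60.0, "Y": 39.5, "Z": 0.5})
        cmp = compare_profiles(p, p, threshold=1.0)
        assert set(cmp.above_threshold_in_b) == {"X", "Y"}
        assert cmp.n_present_in_a == 2
        assert cmp.combined_abundance_a == cmp.combined_abundance_b == pytest.approx(99.5)

    def test_hand_example(self):
        a = _profile_from({"X": 10.0})
        b = _profile_from({"X": 2.0, "Y": 0.5})
        cmp = compare_profiles(a, b)
        assert cmp.above_threshold_in_b == ("X",)
        assert cmp.n_present_in_a == 1
        assert cmp.combined_abundance_a == pytest.approx(10.0)
        assert cmp.combined_abundance_b == pytest.approx(2.0)

    def test_disjoint_profiles_share_nothing(self):
        a = _profile_from({"X": 100.0})
        b = _profile_from({"Q": 70.0, "R": 30.0})
        cmp = compare_profiles(a, b)
        assert cmp.n_present_in_a == 0
        assert cmp.combined_abundance_a == 0.0
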