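"""Replicon decision list, contig taxonomy rule, and T4SS scoring."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pytest

from phyllotig.classify import (
    T4SS_COMPONENTS,
    AnnotationSchemaError,
    FeatureVector,
    arrangement_compare,
    assign_contig_taxonomy,
    build_features,
    classify_replicon,
    score_t4ss,
)
from phyllotig.qc import Contig
from phyllotig.synthetic import ANNOTATION_COLUMNS

from .oracles import oracle_rotated_subsequence, random_dna


def _ann(rows):
    full = []
    for i, row in enumerate(rows):
        base = {
            "contig_id": "ctg",
            "gene_id": f"g{i:03d}",
            "start": 1 + 2000 * i,
            "end": 1500 + 2000 * i,
            "strand": "+",
            "label": "OTHER",
            "hit_species": None,
            "hit_genus": None,
            "hit_phylum": None,
            "hit_identity": np.nan,
            "hit_coverage": np.nan,
        }
        base.update(row)
        full.append(base)
    return pd.DataFrame(full, columns=ANNOTATION_COLUMNS)


def _fv(**kwargs) -> FeatureVector:
    defaults = dict(contig_id="ctg", length=50_000, circular=False)
    defaults.update(kwargs)
    return FeatureVector(**defaults)


class TestBuildFeatures:
    def test_marker_booleans_from_labels(self):
        contig = Contig("ctg", random_dna(random.Random(0), 5000))
        fv = build_features(_ann([{"label": "REPC"}, {"label": "OTHER"}]), contig)
        assert fv.has_repC
        assert not any([fv.has_dnaA, fv.has_repA, fv.has_repAB, fv.has_traY, fv.has_par,
                        fv.has_phage_structural, fv.has_virD4])
        assert fv.n_virB_components == 0

    def test_full_t4ss_component_count(self):
        contig = Contig("ctg", random_dna(random.Random(1), 5000))
        fv = build_features(_ann([{"label": c} for c in T4SS_COMPONENTS]), contig)
        assert fv.n_virB_components == 11
        assert fv.has_virD4

    def test_empty_annotations_give_all_false_vector(self):
        contig = Contig("ctg", random_dna(random.Random(2), 5000))
        fv = build_features(_ann([]), contig)
        assert fv.n_virB_components == 0
        assert not fv.has_dnaA and fv.phage_score is None

    def test_unknown_label_names_the_row(self):
        contig = Contig("ctg", random_dna(random.Random(3), 5000))
        with pytest.raises(AnnotationSchemaError, match="g001"):
            build_features(_ann([{"label": "OTHER"}, {"label": "BOGUS"}]), contig)

    def test_external_scores_pass_through(self):
        contig = Contig("ctg", random_dna(random.Random(4), 5000))
        fv = build_features(_ann([]), contig, {"phage_score": 0.93, "genome_completeness": np.nan})
        assert fv.phage_score == 0.93
        assert fv.genome_completeness is None


class TestDecisionList:
    def test_large_circular_with_dnaa_is_chromosome(self):
        call = classify_replicon(_fv(length=4_300_000, circular=True, has_dnaA=True,
                                     genome_completeness=95.0))
        assert call.klass == "chromosome"
        assert "has_dnaA" in call.evidence

    def test_large_circular_with_plasmid_replication_is_megaplasmid(self):
        call = classify_replicon(_fv(length=1_500_000, circular=True, has_repA=True))
        assert call.klass == "megaplasmid"

    def test_high_phage_score_is_bacteriophage(self):
        call = classify_replicon(_fv(length=45_000, phage_score=0.92))
        assert call.klass == "bacteriophage"
        # at the cutoff the rule must NOT fire (strictly greater)
        assert classify_replicon(_fv(length=45_000, phage_score=0.8)).klass == "unclassified"

    def test_repc_is_repabc_plasmid(self):
        call = classify_replicon(_fv(length=120_000, circular=True, has_repC=True))
        assert call.klass == "repABC_plasmid"

    def test_bare_small_circular_contig_is_unclassified(self):
        call = classify_replicon(_fv(length=30_000, circular=True))
        assert call.klass == "unclassified"
        assert call.evidence == ()

    def test_megaplasmid_precedence_over_phage(self):
        """When the size/replication rule and the phage-score rule both fire,
        the earlier megaplasmid rule wins."""
        call = classify_replicon(_fv(length=1_200_000, circular=True, has_repC=True,
                                     phage_score=0.95))
        assert call.klass == "megaplasmid"

    def test_dnaa_on_small_contig_does_not_force_chromosome(self):
        assert classify_replicon(_fv(length=40_000, circular=True, has_dnaA=True)).klass == "unclassified"

    def test_par_with_phage_genes_does_not_mark_plasmid(self):
        call = classify_replicon(_fv(length=40_000, has_par=True, has_phage_structural=True))
        assert call.klass == "unclassified"

    def test_every_vector_gets_exactly_one_class(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            fv = _fv(
                length=int(rng.integers(8_000, 5_000_000)),
                circular=bool(rng.integers(2)),
                has_dnaA=bool(rng.integers(2)),
                has_repA=bool(rng.integers(2)),
                has_repC=bool(rng.integers(2)),
                has_repAB=bool(rng.integers(2)),
                has_traY=bool(rng.integers(2)),
                has_par=bool(rng.integers(2)),
                has_phage_structural=bool(rng.integers(2)),
                n_virB_components=int(rng.integers(0, 12)),
                has_virD4=bool(rng.integers(2)),
                phage_score=float(rng.random()) if rng.integers(2) else None,
                genome_completeness=float(rng.uniform(0, 100)) if rng.integers(2) else None,
            )
            call = classify_replicon(fv)
            assert call.klass in {"chromosome", "megaplasmid", "repABC_plasmid",
                                  "putative_plasmid", "bacteriophage", "unclassified"}
            assert call.evidence or call.klass == "unclassified"


def _taxonomy_table(n_total, hits):
    """hits: list of (n, genus, phylum) qualifying gene groups."""
    rows = []
    for n, genus, phylum in hits:
        rows += [{"hit_species": f"{genus} sp", "hit_genus": genus, "hit_phylum": phylum,
                  "hit_identity": 95.0, "hit_coverage": 95.0}] * n
    rows += [{}] * (n_total - len(rows))
    return _ann(rows)


class TestContigTaxonomy:
    def test_thirty_percent_single_phylum_assigns_genus(self):
        call = assign_contig_taxonomy(_taxonomy_table(100, [(30, "G", "P")]))
        assert call is not None and call.name == "G" and call.rank == "genus"

    def test_exact_quarter_is_not_exceeding(self):
        assert assign_contig_taxonomy(_taxonomy_table(100, [(25, "G", "P")])) is None

    def test_one_above_quarter_assigns(self):
        call = assign_contig_taxonomy(_taxonomy_table(100, [(26, "G", "P")]))
        assert call is not None and call.name == "G"

    def test_two_phyla_block_assignment(self):
        table = _taxonomy_table(100, [(20, "G", "P1"), (20, "G", "P2")])
        assert assign_contig_taxonomy(table) is None

    def test_weak_hits_do_not_qualify_but_still_count_in_denominator(self):
        table = _taxonomy_table(100, [(30, "G", "P")])
        table.loc[table.index[:10], "hit_identity"] = 70.0  # 10 hits fall below threshold
        assert assign_contig_taxonomy(table) is None  # 20/100 no longer exceeds 1/4

    def test_row_order_invariance(self):
        table = _taxonomy_table(40, [(15, "G", "P")])
        shuffled = table.sample(frac=1.0, random_state=0)
        a = assign_contig_taxonomy(table)
        b = assign_contig_taxonomy(shuffled)
        assert a == b and a.name == "G"

    def test_empty_contig_rejected(self):
        with pytest.raises(ValueError):
            assign_contig_taxonomy(_ann([]))


class TestT4SS:
    def test_all_twelve_components_complete(self):
        call = score_t4ss(_ann([{"label": c} for c in T4SS_COMPONENTS]))
        assert call.status == "complete"
        assert call.missing == ()
        assert call.order_diff.reference_order_conserved

    @pytest.mark.parametrize("n_drop,status", [(1, "nearly_complete"), (2, "nearly_complete"), (5, "partial")])
    def test_partial_systems(self, n_drop, status):
        comps = list(T4SS_COMPONENTS)[: 12 - n_drop]
        call = score_t4ss(_ann([{"label": c} for c in comps]))
        assert call.status == status
        assert set(call.missing) == set(T4SS_COMPONENTS[12 - n_drop :])

    def test_absent_system(self):
        call = score_t4ss(_ann([{"label": "OTHER"}, {"label": "REPC"}]))
        assert call.status == "absent"
        assert len(call.missing) == 12

    def test_duplicated_component_reported(self):
        call = score_t4ss(_ann([{"label": "VIRB1"}, {"label": "VIRB1"}, {"label": "VIRD4"}]))
        assert call.duplicated == {"VIRB1": 2}
        assert call.status == "partial"


class TestArrangement:
    def test_exact_reference_order(self):
        diff = arrangement_compare(list(T4SS_COMPONENTS))
        assert diff.duplicated == {} and diff.missing == () and diff.reference_order_conserved

    def test_reference_order_missing_one_component(self):
        observed = [c for c in T4SS_COMPONENTS if c != "VIRB5"]
        diff = arrangement_compare(observed)
        assert diff.missing == ("VIRB5",)
        assert diff.reference_order_conserved

    def test_rotated_reference_order_is_conserved(self):
        observed = list(T4SS_COMPONENTS[4:]) + list(T4SS_COMPONENTS[:4])
        assert arrangement_compare(observed).reference_order_conserved

    def test_swap_and_duplication_break_order(self):
        observed = ["VIRB1", "VIRB9", "VIRB2", "VIRB3", "VIRB3", "VIRB4", "VIRD4"]
        diff = arrangement_compare(observed)
        assert diff.duplicated == {"VIRB3": 2}
        assert not diff.reference_order_conserved
        assert oracle_rotated_subsequence(observed, T4SS_COMPONENTS) is False

    def test_matches_rotation_oracle_on_random_orders(self):
        rng = random.Random(11)
        for _ in range(50):
            k = rng.randint(1, 12)
            observed = rng.sample(list(T4SS_COMPONENTS), k)
            if rng.random() < 0.5:
                observed.append(rng.choice(observed))
            diff = arrangement_compare(observed)
            assert diff.reference_order_conserved == oracle_rotated_subsequence(observed, T4SS_COMPONENTS)
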