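"""15-class scheme tests: exhaustive enumeration, symmetry, concordance oracle."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from thermoclass.classify import (
    CLASS_TABLE,
    STATUSES,
    TAGS,
    assign_class,
    classify_genotype,
    common_sets,
    concordance,
)

ALL_TRIPLES = list(product(STATUSES, repeat=3))


class TestAssignClass:
    def test_partition_of_all_27_triples(self):
        classes = {assign_class(t) for t in ALL_TRIPLES}
        assert classes == set(range(1, 16))
        # total function: every triple maps, no triple maps to two classes
        assert len(CLASS_TABLE) == 27

    def test_block_structure_follows_39v25_status(self):
        for t in ALL_TRIPLES:
            cls = assign_class(t)
            if t[0] == "up":
                assert 1 <= cls <= 5
            elif t[0] == "down":
                assert 6 <= cls <= 10
            else:
                assert 11 <= cls <= 15

    def test_textual_anchors(self):
        # no alteration -> class 13; up at both 39 and 45 -> classes 1-3;
        # down at 39 only -> class 7
        assert assign_class(("ns", "ns", "ns")) == 13
        for third in STATUSES:
            assert assign_class(("up", "up", third)) in {1, 2, 3}
            assert assign_class(("down", "ns", third)) == 7

    def test_up_down_relabel_symmetry(self):
        # swapping up<->down everywhere maps block 1-5 onto 6-10 and fixes 13
        flip = {"up": "down", "down": "up", "ns": "ns"}
        for t in ALL_TRIPLES:
            a = assign_class(t)
            b = assign_class(tuple(flip[s] for s in t))
            if a == 13:
                assert b == 13
            if 1 <= a <= 5:
                assert 6 <= b <= 10
            if 6 <= a <= 10:
                assert 1 <= b <= 5

    def test_invalid_triples_rejected(self):
        with pytest.raises(ValueError):
            assign_class(("up", "up"))
        with pytest.raises(ValueError):
            assign_class(("up", "sideways", "ns"))


def assignments_from_statuses(status_table: dict) -> dict:
    """Build per-genotype assignment frames from gene -> genotype -> triple."""
    genotypes = sorted({g for v in status_table.values() for g in v})
    out = {}
    for g in genotypes:
        rows = {}
        for gene, per_g in status_table.items():
            if g in per_g:
                t = per_g[g]
                rows[gene] = {
                    "class": assign_class(t),
                    "status_39v25": t[0],
                    "status_45v25": t[1],
                    "status_45v39": t[2],
                }
        out[g] = pd.DataFrame.from_dict(rows, orient="index")
    return out


def oracle_levels(status_table, genotypes):
    """Straight-from-text re-implementation of the level definitions."""
    levels = {}
    for gene, per_g in status_table.items():
        if set(per_g) != set(genotypes):
            continue
        triples = [per_g[g] for g in genotypes]
        if len(set(triples)) == 1:
            levels[gene] = "1"
        elif len({t[0] for t in triples}) == 1 or len({t[1] for t in triples}) == 1:
            levels[gene] = "2"
        else:
            levels[gene] = "none"
    return levels


class TestConcordance:
    GENOTYPES = ["G1", "G2", "G3", "G4"]

    def test_identical_class_everywhere_is_level1_with_both_tags(self):
        table = {"geneA": {g: ("up", "up", "up") for g in self.GENOTYPES}}
        res = concordance(assignments_from_statuses(table))
        row = res.records.loc["geneA"]
        assert row["level"] == "1"
        assert row["common_up_39"] and row["common_up_45"]
        assert not row["common_down_39"] and not row["common_down_45"]

    def test_shared_39_status_without_class_identity_is_level2(self):
        table = {
            "geneA": {
                "G1": ("up", "up", "up"),
                "G2": ("up", "up", "ns"),
                "G3": ("up", "ns", "down"),
                "G4": ("up", "down", "down"),
            }
        }
        res = concordance(assignments_from_statuses(table))
        row = res.records.loc["geneA"]
        assert row["level"] == "2"
        assert row["common_up_39"] and not row["common_up_45"]

    def test_levels_mutually_exclusive(self):
        rng = np.random.default_rng(0)
        table = {
            f"g{i}": {
                g: tuple(rng.choice(STATUSES, 3)) for g in self.GENOTYPES
            }
            for i in range(500)
        }
        res = concordance(assignments_from_statuses(table))
        assert set(res.records["level"]) <= {"1", "2", "none"}
        # a level-1 gene never carries level 2
        assert (res.records["level"] != "1").sum() + (res.records["level"] == "1").sum() == len(
            res.records
        )

    def test_matches_straight_from_text_oracle_on_random_tables(self):
        # 10^4 random per-genotype status triples: implementation and an
        # independent reading of the level definitions agree everywhere
        rng = np.random.default_rng(1)
        table = {
            f"g{i}": {g: tuple(rng.choice(STATUSES, 3)) for g in self.GENOTYPES}
            for i in range(10_000)
        }
        res = concordance(assignments_from_statuses(table))
        oracle = oracle_levels(table, self.GENOTYPES)
        mine = res.records["level"].to_dict()
        assert mine == oracle

    def test_missing_genotype_excluded_with_reason(self):
        table = {
            "geneA": {g: ("ns", "ns", "ns") for g in self.GENOTYPES},
            "geneB": {g: ("ns", "ns", "ns") for g in self.GENOTYPES[:3]},
        }
        res = concordance(assignments_from_statuses(table))
        assert "geneB" not in res.records.index
        assert list(res.excluded["gene_id"]) == ["geneB"]


class TestCommonSets:
    GENOTYPES = ["G1", "G2", "G3", "G4"]

    def test_empty_when_nothing_shared(self):
        # all four genotypes disagree on both control-vs-HS statuses
        table = {
            "geneA": {
                "G1": ("up", "up", "up"),
                "G2": ("down", "down", "down"),
                "G3": ("ns", "ns", "ns"),
                "G4": ("up", "down", "down"),
            }
        }
        counts = common_sets(concordance(assignments_from_statuses(table)))
        assert (counts[["level1", "level2", "total"]] == 0).all().all()

    def test_planted_bookkeeping_accumulates_levels(self):
        # 50 planted level-1 common-up-39 genes + 30 level-2 -> total 80
        table = {}
        for i in range(50):
            table[f"l1_{i}"] = {g: ("up", "up", "ns") for g in self.GENOTYPES}
        for i in range(30):
            table[f"l2_{i}"] = {
                "G1": ("up", "up", "up"),
                "G2": ("up", "up", "up"),
                "G3": ("up", "up", "up"),
                "G4": ("up", "ns", "down"),
            }
        counts = common_sets(concordance(assignments_from_statuses(table)))
        assert counts.loc["common_up_39", "level1"] == 50
        assert counts.loc["common_up_39", "level2"] == 30
        assert counts.loc["common_up_39", "total"] == 80

    def test_gene_with_both_tags_counts_once_per_tag(self):
        table = {"geneA": {g: ("up", "up", "ns") for g in self.GENOTYPES}}
        counts = common_sets(concordance(assignments_from_statuses(table)))
        assert counts.loc["common_up_39", "total"] == 1
        assert counts.loc["common_up_45", "total"] == 1
        assert counts.loc["common_down_39", "total"] == 0


class TestClassifyGenotype:
    def test_untested_genes_excluded(self):
        idx = pd.Index(["g0", "g1"], name="gene_id")
        frame = pd.DataFrame(
            {"status": ["up", "ns"], "tested": [True, False]}, index=idx
        )
        res = classify_genotype({"39v25": frame, "45v25": frame, "45v39": frame})
        assert list(res.index) == ["g0"]
        assert res.loc["g0", "class"] == 1

    def test_missing_contrast_rejected(self):
        idx = pd.Index(["g0"], name="gene_id")
        frame = pd.DataFrame({"status": ["up"], "tested": [True]}, index=idx)
        with pytest.raises(ValueError, match="missing contrasts"):
            classify_genotype({"39v25": frame, "45v25": frame})
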