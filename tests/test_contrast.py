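"""Genotype-contrast selection rules: truth tables, invariants, null rate."""

import numpy as np
import pandas as pd
import pytest

from conftest import nb_draw
from thermoclass import simulate
from thermoclass.contrast import (
    ContrastSelection,
    SelectionRuleConfig,
    rule_i,
    rule_ii,
    rule_iii,
    rule_iii_selects,
    select_genotype_specific,
    summarize_selection,
)
from thermoclass.expression import ExpressionMatrix, sample_name
from thermoclass.quant import tpm_no_length


def contrast_frame(entries):
    """entries: gene -> (log2fc, pvalue)."""
    idx = pd.Index(list(entries), name="gene_id")
    lfc = [v[0] for v in entries.values()]
    p = [v[1] for v in entries.values()]
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "padj": p, "tested": True}, index=idx
    )


class TestRuleI:
    def test_same_direction_selected_with_direction(self):
        vs = {
            "T1": contrast_frame({"g0": (2.0, 0.001), "g1": (-1.5, 0.01)}),
            "T2": contrast_frame({"g0": (1.0, 0.02), "g1": (-2.0, 0.001)}),
        }
        out = rule_i(vs)
        assert out.loc["g0", "direction"] == "higher"
        assert out.loc["g1", "direction"] == "lower"

    def test_opposite_directions_rejected(self):
        vs = {
            "T1": contrast_frame({"g0": (2.0, 0.001)}),
            "T2": contrast_frame({"g0": (-2.0, 0.001)}),
        }
        assert rule_i(vs).empty

    def test_significance_needed_against_both(self):
        vs = {
            "T1": contrast_frame({"g0": (2.0, 0.001)}),
            "T2": contrast_frame({"g0": (2.0, 0.2)}),
        }
        assert rule_i(vs).empty

    def test_invariant_to_tolerant_order(self):
        rng = np.random.default_rng(0)
        entries1 = {f"g{i}": (rng.normal(), rng.uniform()) for i in range(50)}
        entries2 = {f"g{i}": (rng.normal(), rng.uniform()) for i in range(50)}
        vs = {"T1": contrast_frame(entries1), "T2": contrast_frame(entries2)}
        sw = {"T2": vs["T2"], "T1": vs["T1"]}
        assert set(rule_i(vs).index) == set(rule_i(sw).index)

    def test_single_contrast_rejected(self):
        with pytest.raises(ValueError):
            rule_i({"T1": contrast_frame({"g0": (1.0, 0.01)})})


class TestRuleII:
    def test_truth_table_matches_hand_oracle(self):
        # exhaustive {sig, ns} x {same, opposite} per tolerant genotype:
        # kept iff significant against both AND same direction as focal vs both
        focal_dir = 1.0
        cases = []
        for sig1 in (True, False):
            for sig2 in (True, False):
                for dir1 in (1.0, -1.0):
                    for dir2 in (1.0, -1.0):
                        cases.append((sig1, sig2, dir1, dir2))
        for sig1, sig2, dir1, dir2 in cases:
            r1 = contrast_frame({"g0": (focal_dir * 2.0, 0.001)})
            r1 = rule_i({"T1": r1, "T2": contrast_frame({"g0": (focal_dir * 2.0, 0.001)})})
            inter = {
                "T1": contrast_frame({"g0": (dir1 * 1.0, 0.01 if sig1 else 0.5)}),
                "T2": contrast_frame({"g0": (dir2 * 1.0, 0.01 if sig2 else 0.5)}),
            }
            out = rule_ii(r1, inter, 25.0)
            expected = sig1 and sig2 and dir1 == dir2 == focal_dir
            assert ("g0" in out.index) == expected, (sig1, sig2, dir1, dir2)

    def test_rejected_at_45(self):
        r1 = rule_i(
            {
                "T1": contrast_frame({"g0": (1.0, 0.01)}),
                "T2": contrast_frame({"g0": (1.0, 0.01)}),
            }
        )
        with pytest.raises(ValueError, match="25 or 39"):
            rule_ii(r1, {"T1": contrast_frame({}), "T2": contrast_frame({})}, 45.0)

    def test_subset_of_rule_i(self):
        rng = np.random.default_rng(1)
        e = lambda: {f"g{i}": (rng.normal(), rng.uniform()) for i in range(100)}
        r1 = rule_i({"T1": contrast_frame(e()), "T2": contrast_frame(e())})
        out = rule_ii(r1, {"T1": contrast_frame(e()), "T2": contrast_frame(e())}, 39.0)
        assert set(out.index) <= set(r1.index)


class TestRuleIII:
    @pytest.mark.parametrize(
        "r_focal,r_inter,expected",
        [
            (2.0, 0.5, True),  # up in focal, separated by 1.5
            (2.0, 1.5, False),  # difference 0.5 below the bar
            (-1.5, 0.0, True),  # down branch, separation 1.5
            (0.0, -5.0, False),  # zero response satisfies neither branch
            (1.0, 0.0, False),  # boundary: difference exactly 1 not selected
        ],
    )
    def test_worked_examples(self, r_focal, r_inter, expected):
        assert rule_iii_selects(r_focal, r_inter) is expected

    def test_frame_version_matches_scalar_rule(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        r1 = contrast_frame({g: (1.0, 0.001) for g in genes})
        r1["direction"] = "higher"
        pc = 1.0
        tf = pd.DataFrame(
            {"25": rng.uniform(0, 100, 200), "45": rng.uniform(0, 100, 200)}, index=genes
        )
        ti = pd.DataFrame(
            {"25": rng.uniform(0, 100, 200), "45": rng.uniform(0, 100, 200)}, index=genes
        )
        out = rule_iii(r1, tf, ti, pseudocount=pc)
        for g in genes:
            rf = np.log2((tf.loc[g, "45"] + pc) / (tf.loc[g, "25"] + pc))
            ri = np.log2((ti.loc[g, "45"] + pc) / (ti.loc[g, "25"] + pc))
            assert (g in out.index) == rule_iii_selects(rf, ri)
        assert set(out.index) <= set(r1.index)


class TestEndToEndSelection:
    def test_planted_contrast_genes_recovered(self, small_truth, small_counts, small_tpm):
        selection = select_genotype_specific(small_counts, small_tpm)
        planted = {
            role: {
                p.gene_id for p in small_truth.planted if p.contrast_role == role
            }
            for role in ("focal_25", "focal_39", "focal_45", "sensitive_25", "sensitive_39")
        }
        # focal-only genes satisfy rule (i); at 25/39 the reported per-condition
        # set additionally passes rule (ii) (sensitive genes), at 45 rule (iii)
        sel45 = set(selection.per_condition["45"].index)
        assert len(planted["focal_45"] & sel45) >= 0.5 * len(planted["focal_45"])
        sel25 = set(selection.per_condition["25"].index)
        sel39 = set(selection.per_condition["39"].index)
        assert len(planted["sensitive_25"] & sel25) >= 0.5 * len(planted["sensitive_25"])
        assert len(planted["sensitive_39"] & sel39) >= 0.5 * len(planted["sensitive_39"])
        # rule-(ii) conditions must not pick up unplanted genes en masse
        unplanted = sel25 - planted["sensitive_25"] - planted["focal_25"]
        assert len(unplanted) <= 0.01 * small_truth.n_genes

    def test_null_selection_rate_small(self):
        # no genotype effects planted: the both-tolerant same-direction
        # conjunction at p<0.05 selects far below 5% of genes.  The two
        # contrasts share the focal genotype's samples, so their z scores
        # correlate (~0.5) and the exact calibrated rate is 0.0092, not the
        # 0.0025/2 an independence argument would give; finite-sample
        # dispersion noise at n=2 adds a little more, hence the 0.02 bound.
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = np.exp(rng.normal(5, 1.5, 1000))
            cols = [sample_name(g, 25.0, r) for g in ("T1", "T2", "F") for r in (1, 2)]
            y = nb_draw(rng, mu, 0.05, 6)
            em = ExpressionMatrix(
                pd.DataFrame(y, index=[f"g{i}" for i in range(1000)], columns=cols)
            )
            from thermoclass.diffexp import genotype_contrast

            vs = {
                t: genotype_contrast(em, t, "F", 25.0) for t in ("T1", "T2")
            }
            rates.append(len(rule_i(vs)) / 1000)
        assert np.mean(rates) < 0.02

    def test_config_validation(self):
        with pytest.raises(ValueError, match="focal"):
            SelectionRuleConfig(focal="LA1994")
        with pytest.raises(ValueError, match="thresholds"):
            SelectionRuleConfig(p_threshold=-1)


class TestSummary:
    def test_empty_selection_all_zero(self):
        empty = pd.DataFrame(columns=["direction"])
        sel = ContrastSelection(per_condition={"25": empty, "39": empty, "45": empty})
        summary = summarize_selection(sel).set_index("entry")
        assert (summary["count"] == 0).all()

    def test_overlaps_match_set_algebra_oracle(self):
        rng = np.random.default_rng(3)
        conds = {}
        for cond in ("25", "39", "45"):
            genes = rng.choice([f"g{i}" for i in range(40)], size=15, replace=False)
            df = pd.DataFrame(
                {"direction": rng.choice(["higher", "lower"], size=15)},
                index=pd.Index(genes, name="gene_id"),
            )
            conds[cond] = df
        summary = summarize_selection(ContrastSelection(per_condition=conds)).set_index("entry")
        sets = {k: set(v.index) for k, v in conds.items()}
        assert summary.loc["overlap@25&39", "count"] == len(sets["25"] & sets["39"])
        assert summary.loc["overlap@25&39&45", "count"] == len(
            sets["25"] & sets["39"] & sets["45"]
        )
        for cond, df in conds.items():
            assert summary.loc[f"selected@{cond}", "higher_in_focal"] == (
                df["direction"] == "higher"
            ).sum()
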