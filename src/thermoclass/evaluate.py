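"""Scoring of pipeline output against planted simulation truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from thermoclass.simulate import SimulationTruth, expected_mean_matrix


def strong_effect_genes(
    truth: SimulationTruth,
    min_abs_lfc: float = 2.0,
    min_mean: float = 200.0,
) -> pd.DataFrame:
    """Planted (gene, genotype) pairs whose class should be unambiguous.

    A pair qualifies when every non-zero component of its planted contrast
    triple has |lfc| >= ``min_abs_lfc`` and the expected baseline count at
    25 degC is at least ``min_mean``.  Returns columns gene_id, genotype,
    true_class.
    """
    expected = expected_mean_matrix(truth)
    rows = []
    for p in truth.planted:
        for g in truth.genotype_names:
            comps = (
                p.lfc_39v25.get(g, 0.0),
                p.lfc_45v25.get(g, 0.0),
                p.lfc_45v39(g),
            )
            if any(c != 0 and abs(c) < min_abs_lfc for c in comps):
                continue
            base_cols = [c for c in expected.columns if c.startswith(f"{g}_25_")]
            if expected.loc[p.gene_id, base_cols].mean() < min_mean:
                continue
            rows.append(
                {"gene_id": p.gene_id, "genotype": g, "true_class": p.true_class(g)}
            )
    return pd.DataFrame(rows)


def class_recovery_accuracy(
    truth: SimulationTruth,
    assignments: dict[str, pd.DataFrame],
    min_abs_lfc: float = 2.0,
    min_mean: float = 200.0,
) -> float:
    """Fraction of strong-effect planted (gene, genotype) pairs classified
    into their planted class by the pipeline."""
    strong = strong_effect_genes(truth, min_abs_lfc, min_mean)
    if strong.empty:
        return float("nan")
    hits = 0
    for _, row in strong.iterrows():
        assigned = assignments[row["genotype"]]
        if (
            row["gene_id"] in assigned.index
            and assigned.loc[row["gene_id"], "class"] == row["true_class"]
        ):
            hits += 1
    return hits / len(strong)
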