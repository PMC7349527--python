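"""Functional-category composition and Fisher's-exact enrichment.

Gene sets (e.g. the commonly upregulated genes, or the PCA-selected genes)
are tested category by category against the gene universe with a two-sided
Fisher's exact test on the 2x2 table (in set / not in set) x (in category /
not in category).  Both enrichment and depletion are flagged, at p < 0.01
and p < 0.05.  No multiple-testing correction is applied by default (an
optional BH column can be emitted); the category vocabulary is a flat
two-level MapMan-style map supplied as input, with an optional merge table
collapsing related bins (e.g. the carbon-fixation bins into one category).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from thermoclass.diffexp import bh_adjust

#: bin merges used for the published category roster
DEFAULT_MERGES: dict[str, list[int]] = {
    "C-fixation": [2, 3, 4, 5, 6, 7, 8, 25],
    "cell and development": [31, 33],
    "metabolism": list(range(12, 20)) + [22, 23, 24],
    "signaling and redox": [20, 30],
}

#: categories hidden from the default report (kept in the data)
DEFAULT_HIDDEN: tuple[str, ...] = ("misc", "not assigned", "unknown", "DNA")


def merge_categories(
    category_map: pd.DataFrame, merges: dict[str, list[int]] | None = None
) -> pd.Series:
    """Collapse bin codes into merged category labels; returns gene -> category.

    ``category_map`` needs columns gene_id, bin_code, level1_category.  A
    bin referenced by two merge targets is an error; unmapped genes keep
    their level-1 name.  Merging is idempotent: re-applying the same merge
    table leaves the labels unchanged.
    """
    merges = DEFAULT_MERGES if merges is None else merges
    code_to_target: dict[int, str] = {}
    for target, codes in merges.items():
        for code in codes:
            if code in code_to_target and code_to_target[code] != target:
                raise ValueError(f"bin code {code} mapped to two merge targets")
            code_to_target[code] = target
    labels = [
        code_to_target.get(int(code), level1)
        for code, level1 in zip(category_map["bin_code"], category_map["level1_category"])
    ]
    return pd.Series(labels, index=pd.Index(category_map["gene_id"], name="gene_id"), name="category")


def enrich(
    gene_set,
    categories: pd.Series,
    background,
    alternative: str = "two-sided",
    with_bh: bool = False,
    hidden: tuple[str, ...] = DEFAULT_HIDDEN,
) -> pd.DataFrame:
    """Fisher's exact enrichment of ``gene_set`` against ``background``.

    ``categories`` maps gene id to category label; unmapped genes count as
    'unknown'.  Returns one row per category with the 2x2 margins (k of n
    set genes, K of N background genes), the set and background
    percentages, the Fisher p and significance flags; categories in
    ``hidden`` are dropped from the report (pass ``hidden=()`` to keep).
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")
    cats = categories.reindex(pd.Index(sorted(background))).fillna("unknown")
    n, N = len(gene_set), len(background)
    rows = []
    for cat, members in cats.groupby(cats).groups.items():
        members = set(members)
        K = len(members)
        k = len(gene_set & members)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        p = float(stats.fisher_exact(table, alternative=alternative).pvalue)
        rows.append(
            {
                "category": cat,
                "set_count": k,
                "set_size": n,
                "background_count": K,
                "background_size": N,
                "set_pct": 100.0 * k / n,
                "background_pct": 100.0 * K / N,
                "pvalue": p,
                "sig_01": p < 0.01,
                "sig_05": p < 0.05,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    if with_bh:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    if hidden:
        out = out[~out.index.isin(hidden)]
    return out.sort_values("pvalue")
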