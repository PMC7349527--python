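"""PCA on mean-TPM profiles with gene-contribution selection and Venn overlap.

Genes are the individuals of the PCA and the replicate-mean expression
columns are the variables (columns centered, unscaled by default).  The
contribution of gene g to component c is its share of the squared
principal-component scores, 100 * score_gc^2 / sum_g score_gc^2, so
contributions per component sum to 100%.  If every one of N expressed genes
contributed equally the share would be 100/N percent; genes contributing at
least tenfold that equal-share baseline to PC1 or PC2 are selected.  With
the 25,478 expressed genes of the original dataset the baseline is
0.003925% and the selection threshold 0.03925%.

Two scopes mirror the two published analyses: one PCA per genotype over its
three temperature mean-columns, and one PCA per temperature over the
genotype mean-columns; selections are intersected across scopes via an
exhaustive Venn table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from thermoclass.expression import ExpressionMatrix


@dataclass
class PCContribution:
    """Per-gene percentage contributions to each principal component."""

    contributions: pd.DataFrame  # genes x PC1..PCk, percentages
    explained_variance_ratio: pd.Series  # per component
    scores: pd.DataFrame  # genes x components
    n_genes: int


def run_pca(matrix: pd.DataFrame, log_scale: bool = False) -> PCContribution:
    """PCA over a genes x mean-columns matrix; genes are the individuals.

    Columns are mean expression profiles (the variables); they are centered
    and left unscaled.  ``log_scale`` applies log2(x + 1) first.  Raises on
    fewer than two variables or an all-constant column set.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 variables (mean columns) for PCA")
    X = matrix.to_numpy(dtype=float)
    if log_scale:
        X = np.log2(X + 1.0)
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0.0):
        raise ValueError("all columns are constant; PCA undefined")
    # SVD of the centered matrix: scores = U * S
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(Xc.shape) if min(Xc.shape) < Xc.shape[1] else Xc.shape[1]
    comps = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.index, columns=comps)
    ss = S**2
    evr = pd.Series(ss / ss.sum() if ss.sum() > 0 else ss, index=comps)
    denom = (scores**2).sum(axis=0)
    denom = denom.replace(0.0, np.nan)
    contrib = 100.0 * (scores**2) / denom
    contrib = contrib.fillna(0.0)
    return PCContribution(
        contributions=contrib,
        explained_variance_ratio=evr,
        scores=scores,
        n_genes=matrix.shape[0],
    )


@dataclass
class SelectionResult:
    """Genes whose PC1/PC2 contribution clears the tenfold equal-share bar."""

    scope: str
    selected: set[str]
    baseline_pct: float  # 100 / n_expressed
    threshold_pct: float  # tenfold_factor * baseline
    n_expressed: int


def equal_share_baseline(n_expressed: int) -> float:
    """Equal-share contribution baseline in percent: 100 / N."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    return 100.0 / n_expressed


def select_contributors(
    contribs: PCContribution,
    n_expressed: int,
    components: tuple[str, ...] = ("PC1", "PC2"),
    tenfold_factor: float = 10.0,
    scope: str = "",
) -> SelectionResult:
    """Select genes with contribution >= tenfold the equal-share baseline.

    A gene qualifies through PC1 *or* PC2 (any listed component); boundary
    genes exactly at the threshold are included.
    """
    baseline = equal_share_baseline(n_expressed)
    threshold = tenfold_factor * baseline
    present = [c for c in components if c in contribs.contributions.columns]
    if not present:
        raise ValueError(f"none of {components} present in the contribution table")
    mask = (contribs.contributions[present] >= threshold).any(axis=1)
    return SelectionResult(
        scope=scope,
        selected=set(contribs.contributions.index[mask]),
        baseline_pct=baseline,
        threshold_pct=threshold,
        n_expressed=n_expressed,
    )


def expressed_genes(tpm: ExpressionMatrix, samples: list[str], min_samples: int = 1) -> pd.Index:
    """Genes with TPM > 0 in at least ``min_samples`` samples of the scope."""
    nonzero = (tpm.values[samples] > 0).sum(axis=1)
    return tpm.genes[nonzero >= min_samples]


def per_genotype_selections(
    tpm: ExpressionMatrix, log_scale: bool = False, tenfold_factor: float = 10.0
) -> dict[str, SelectionResult]:
    """One PCA per genotype over its temperature mean-columns; select per scope."""
    out = {}
    for g in tpm.genotypes:
        samples = tpm.select_samples(genotype=g)
        genes = expressed_genes(tpm, samples)
        sub = tpm.subset(samples)
        means = sub.mean_by(("temperature_C",)).loc[genes]
        pc = run_pca(means, log_scale=log_scale)
        out[g] = select_contributors(
            pc, n_expressed=len(genes), tenfold_factor=tenfold_factor, scope=g
        )
    return out


def per_temperature_selections(
    tpm: ExpressionMatrix, log_scale: bool = False, tenfold_factor: float = 10.0
) -> dict[str, SelectionResult]:
    """One PCA per temperature over the genotype mean-columns."""
    out = {}
    for t in tpm.temperatures:
        samples = tpm.select_samples(temperature=t)
        genes = expressed_genes(tpm, samples)
        sub = tpm.subset(samples)
        means = sub.mean_by(("genotype",)).loc[genes]
        pc = run_pca(means, log_scale=log_scale)
        label = f"{t:g}C"
        out[label] = select_contributors(
            pc, n_expressed=len(genes), tenfold_factor=tenfold_factor, scope=label
        )
    return out


def overlap(selections: dict[str, set[str] | SelectionResult]) -> pd.DataFrame:
    """Exhaustive Venn table over the selection scopes.

    One row per non-empty scope combination with the *exclusive* cell count
    (genes in exactly those scopes) and the member list; cells partition the
    union of all selections.
    """
    sets = {
        k: (v.selected if isinstance(v, SelectionResult) else set(v))
        for k, v in selections.items()
    }
    if len(sets) < 2:
        raise ValueError("need at least 2 scopes for an overlap table")
    labels = list(sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in labels if c not in combo), set())
            cell = inside - outside
            rows.append(
                {
                    "scopes": "&".join(combo),
                    "n_scopes": r,
                    "count": len(cell),
                    "genes": ";".join(sorted(cell)),
                }
            )
    return pd.DataFrame(rows)
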