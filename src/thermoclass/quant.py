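"""Length-free TPM normalization and cross-genotype relative abundance.

With 3'-tag sequencing one read represents one transcript, so transcript
abundance is the tag count scaled to library size with no transcript-length
term:  TPM_gs = count_gs / sum_g(count_gs) * 1e6.

For the cross-genotype comparison at one temperature, A(x) is the
replicate-mean TPM of gene x per genotype and X(x) = A(x) / sum_i A(x) its
share across genotypes (0.25 everywhere means equal expression in four
genotypes).  A min-max rescaled display value in [0, 1] feeds the treemap
color scale.  Per-category distribution tests (Kruskal-Wallis across
genotypes, Shapiro-Wilk normality per genotype, Tukey all-pairs) flag
categories whose abundance shares differ between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from thermoclass.expression import ExpressionMatrix


def tpm_no_length(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample's counts to transcripts-per-million (no length term)."""
    if counts.unit != "counts":
        raise ValueError("input matrix must contain raw counts")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    tpm = counts.values / totals * 1e6
    return ExpressionMatrix(tpm, counts.design.copy(), unit="tpm")


@dataclass
class RelativeAbundanceTable:
    """Per-gene genotype shares of mean TPM at one temperature.

    ``abundance`` (A): genes x genotypes replicate-mean TPM;
    ``share`` (X): rows of A normalized to sum 1;
    ``display``: X min-max rescaled to [0, 1] over the whole table.
    Genes unexpressed in every genotype (sum A = 0, where the share is
    undefined) are excluded and listed in ``excluded``.
    """

    temperature: float
    abundance: pd.DataFrame
    share: pd.DataFrame
    display: pd.DataFrame
    excluded: pd.Index


def relative_abundance(tpm: ExpressionMatrix, temperature: float) -> RelativeAbundanceTable:
    """Compute A, X and the display rescaling for one temperature."""
    if tpm.unit != "tpm":
        raise ValueError("input matrix must be TPM")
    if temperature not in tpm.design["temperature_C"].values:
        raise ValueError(f"temperature {temperature} absent from design")
    genotypes = tpm.genotypes
    if len(genotypes) < 2:
        raise ValueError("need at least 2 genotypes for relative abundance")
    cols = {}
    for g in genotypes:
        samples = tpm.select_samples(genotype=g, temperature=temperature)
        cols[g] = tpm.values[samples].mean(axis=1)
    A = pd.DataFrame(cols)
    totals = A.sum(axis=1)
    expressed = totals > 0
    excluded = A.index[~expressed]
    A = A.loc[expressed]
    X = A.div(A.sum(axis=1), axis=0)
    lo, hi = X.to_numpy().min(), X.to_numpy().max()
    display = (X - lo) / (hi - lo) if hi > lo else X * 0.0
    return RelativeAbundanceTable(
        temperature=float(temperature),
        abundance=A,
        share=X,
        display=display,
        excluded=excluded,
    )


def category_distribution_tests(
    table: RelativeAbundanceTable,
    categories: pd.Series,
    method: str = "kruskal",
    alpha_main: float = 0.005,
    alpha_shapiro: float = 0.05,
    alpha_tukey: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-category genotype-difference tests on the abundance shares X.

    For each category with at least ``min_genes`` genes, the genotype groups
    of X values are compared with Kruskal-Wallis (default, flag at
    ``alpha_main``) or one-way ANOVA, normality is screened per genotype
    with Shapiro-Wilk, and all genotype pairs are compared with Tukey's HSD.
    Returns one row per category: n_genes, statistic, pvalue, significant,
    min_shapiro_p, any_non_normal, significant_pairs (';'-joined).
    """
    if method not in ("kruskal", "anova"):
        raise ValueError("method must be 'kruskal' or 'anova'")
    X = table.share
    cats = categories.reindex(X.index).dropna()
    rows = []
    for cat, genes in cats.groupby(cats).groups.items():
        sub = X.loc[genes]
        if len(sub) < min_genes:
            continue
        groups = [sub[g].to_numpy() for g in sub.columns]
        flat = np.concatenate(groups)
        if np.allclose(flat, flat[0]):
            raise ValueError(f"category {cat!r} has all-identical values")
        if method == "kruskal":
            stat, p = stats.kruskal(*groups)
        else:
            stat, p = stats.f_oneway(*groups)
        shapiro_ps = []
        for arr in groups:
            if len(np.unique(arr)) < 3:
                shapiro_ps.append(np.nan)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapiro_ps.append(stats.shapiro(arr).pvalue)
        tuk = stats.tukey_hsd(*groups)
        names = list(sub.columns)
        sig_pairs = [
            f"{names[i]}|{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if tuk.pvalue[i, j] < alpha_tukey
        ]
        rows.append(
            {
                "category": cat,
                "n_genes": len(sub),
                "statistic": float(stat),
                "pvalue": float(p),
                "significant": bool(p < alpha_main),
                "min_shapiro_p": float(np.nanmin(shapiro_ps)) if not all(np.isnan(shapiro_ps)) else np.nan,
                "any_non_normal": bool(np.nanmin(shapiro_ps) < alpha_shapiro)
                if not all(np.isnan(shapiro_ps))
                else False,
                "significant_pairs": ";".join(sig_pairs),
            }
        )
    return pd.DataFrame(rows)
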