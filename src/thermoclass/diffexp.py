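"""Negative-binomial Wald tests for two-group contrasts on tag counts.

Per gene, a NB generalized linear model with a log link, library-size
offsets and a two-level group factor is fit by iteratively reweighted least
squares; the Wald z statistic on the group coefficient gives a two-sided p,
and Benjamini-Hochberg adjustment controls the false discovery rate across
genes.  With only two replicates per group, per-gene method-of-moments
dispersion estimates are shrunk toward a mean-dispersion trend fitted over
all genes -- a deliberately simple stand-in for the heavier empirical-Bayes
machinery of dedicated DE packages, adequate for the planted-effect sizes
this pipeline is scored on.

Status calls: ``up``/``down`` when the (adjusted) p is below the threshold
with the corresponding fold-change sign, else ``ns``.  Temperature
contrasts within a genotype use adjusted p < 0.01 by default; genotype
contrasts within a temperature use raw p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from thermoclass.expression import ExpressionMatrix

_LN2 = np.log(2.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moment_dispersions(q: np.ndarray, n_a: int, mean_inv_sf: float) -> np.ndarray:
    """Method-of-moments NB dispersion from normalized counts, per gene.

    ``q`` is genes x samples normalized counts with the first ``n_a``
    columns group A.  Within-group variance pooled over both groups;
    phi = (s2 - mu * E[1/sf]) / mu^2, clipped to [1e-8, 10].
    """
    qa, qb = q[:, :n_a], q[:, n_a:]
    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    dof = q.shape[1] - 2
    s2 = ((qa - ma[:, None]) ** 2).sum(axis=1) + ((qb - mb[:, None]) ** 2).sum(axis=1)
    s2 = s2 / max(dof, 1)
    mu = (ma + mb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (s2 - mu * mean_inv_sf) / mu**2
    phi[~np.isfinite(phi)] = 0.0
    return np.clip(phi, 1e-8, 10.0)


def _trend_dispersion(phi_hat: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit phi(mu) = a0 + a1/mu by least squares over well-expressed genes."""
    use = mu > 1.0
    if use.sum() < 10:
        return np.full_like(phi_hat, max(np.median(phi_hat), 1e-8))
    A = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(A, phi_hat[use], rcond=None)
    a0 = max(coef[0], 1e-8)
    a1 = max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        tr = a0 + a1 / np.maximum(mu, 1e-8)
    return np.clip(tr, 1e-8, 10.0)


def _irls_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: np.ndarray,
             n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2-parameter NB GLM fit (intercept + group) per gene.

    Returns (beta1, se_beta1) in natural-log units.  ``y``: genes x samples,
    ``x``: 0/1 group indicator per sample, ``offset``: log size factors.
    """
    sf = np.exp(offset)
    qa = (y[:, x == 0] / sf[x == 0]).mean(axis=1)
    qb = (y[:, x == 1] / sf[x == 1]).mean(axis=1)
    b0 = np.log(np.maximum(qa, 1e-8))
    b1 = np.log(np.maximum(qb, 1e-8)) - b0
    phi_col = phi[:, None]
    for _ in range(n_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -50.0, 50.0))
        W = mu / (1.0 + phi_col * mu)
        t = (eta - offset[None, :]) + (y - mu) / mu
        sw = W.sum(axis=1)
        swx = (W * x).sum(axis=1)  # x binary: sum W over group B
        b_0 = (W * t).sum(axis=1)
        b_1 = (W * x * t).sum(axis=1)
        det = sw * swx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (swx * b_0 - swx * b_1) / det
        new_b1 = (sw * b_1 - swx * b_0) / det
        step0 = np.where(np.isfinite(new_b0), new_b0 - b0, 0.0)
        step1 = np.where(np.isfinite(new_b1), new_b1 - b1, 0.0)
        step0 = np.clip(step0, -5.0, 5.0)
        step1 = np.clip(step1, -5.0, 5.0)
        b0 = b0 + step0
        b1 = b1 + step1
        if max(np.abs(step0).max(initial=0.0), np.abs(step1).max(initial=0.0)) < 1e-12:
            break
    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -50.0, 50.0))
    W = mu / (1.0 + phi_col * mu)
    sw = W.sum(axis=1)
    swx = (W * x).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sw / det)
    return b1, se


def nb_wald_test(
    counts: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    dispersion: float | np.ndarray | None = None,
    shrink_weight: float = 0.2,
    padj_threshold: float = 0.01,
    use_adjusted: bool = True,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B versus group A.

    Positive log2 fold changes mean higher expression in ``group_b``.
    Genes with zero counts in every sample of both groups are reported
    untested (NaN statistics, status ``ns``).  Genes where one group is all
    zero are tested on counts with a half-count added to every sample so the
    GLM stays finite; their fold change uses the same floor.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc,
    lfc_se, pvalue, padj, status, tested and attrs ``label``, ``contrast``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    samples = list(group_a) + list(group_b)
    y = counts.values[samples].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib[: len(group_a)].sum() == 0) or (lib[len(group_a):].sum() == 0):
        raise ValueError("a group has zero total library size")
    sf = lib / np.exp(np.mean(np.log(lib)))
    offset = np.log(sf)
    x = np.array([0.0] * len(group_a) + [1.0] * len(group_b))

    q = y / sf
    n_a = len(group_a)
    tested = y.sum(axis=1) > 0
    base_mean = q.mean(axis=1)

    if dispersion is None:
        phi_hat = _moment_dispersions(q, n_a, float(np.mean(1.0 / sf)))
        phi_tr = _trend_dispersion(phi_hat[tested], base_mean[tested])
        phi = np.full(y.shape[0], 1e-8)
        phi[tested] = shrink_weight * phi_hat[tested] + (1.0 - shrink_weight) * phi_tr
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
        phi = np.clip(phi, 1e-12, None)

    # floor genes with an all-zero group by a half count on every sample
    ma = q[:, :n_a].mean(axis=1)
    mb = q[:, n_a:].mean(axis=1)
    zero_group = tested & ((ma == 0) | (mb == 0))
    y_fit = y.copy()
    y_fit[zero_group] += 0.5

    b1 = np.full(y.shape[0], np.nan)
    se = np.full(y.shape[0], np.nan)
    if tested.any():
        b1_t, se_t = _irls_nb(y_fit[tested], x, offset, phi[tested])
        b1[tested] = b1_t
        se[tested] = se_t

    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se
    pvalue = np.full(y.shape[0], np.nan)
    pvalue[tested] = 2.0 * stats.norm.sf(np.abs(z[tested]))
    # exact nulls (identical groups) can give z = 0/0; call them p = 1
    pvalue[tested & ~np.isfinite(pvalue)] = 1.0
    pvalue = np.clip(pvalue, 0.0, 1.0)

    log2fc = b1 / _LN2
    padj = np.full(y.shape[0], np.nan)
    padj[tested] = bh_adjust(pvalue[tested])

    crit = padj if use_adjusted else pvalue
    status = np.where(
        tested & (crit < padj_threshold) & (log2fc > 0),
        "up",
        np.where(tested & (crit < padj_threshold) & (log2fc < 0), "down", "ns"),
    )

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "lfc_se": se / _LN2,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
            "tested": tested,
        },
        index=counts.genes,
    )
    out.attrs["label"] = label or "B_vs_A"
    out.attrs["group_a"] = list(group_a)
    out.attrs["group_b"] = list(group_b)
    return out


def temperature_contrasts(
    counts: ExpressionMatrix,
    genotype: str,
    baseline: float = 25.0,
    mid: float = 39.0,
    severe: float = 45.0,
    padj_threshold: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """The three within-genotype temperature contrasts feeding classification."""
    s25 = counts.select_samples(genotype=genotype, temperature=baseline)
    s39 = counts.select_samples(genotype=genotype, temperature=mid)
    s45 = counts.select_samples(genotype=genotype, temperature=severe)
    return {
        "39v25": nb_wald_test(counts, s25, s39, padj_threshold=padj_threshold,
                              label=f"39v25@{genotype}"),
        "45v25": nb_wald_test(counts, s25, s45, padj_threshold=padj_threshold,
                              label=f"45v25@{genotype}"),
        "45v39": nb_wald_test(counts, s39, s45, padj_threshold=padj_threshold,
                              label=f"45v39@{genotype}"),
    }


def genotype_contrast(
    counts: ExpressionMatrix,
    genotype_a: str,
    genotype_b: str,
    temperature: float,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Between-genotype contrast at one temperature (B vs A); raw p by default."""
    sa = counts.select_samples(genotype=genotype_a, temperature=temperature)
    sb = counts.select_samples(genotype=genotype_b, temperature=temperature)
    return nb_wald_test(
        counts,
        sa,
        sb,
        padj_threshold=p_threshold,
        use_adjusted=use_adjusted,
        label=f"{genotype_b}_vs_{genotype_a}@{temperature:g}",
    )
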