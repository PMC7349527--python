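"""qRT-PCR-style concordance checks between two quantification platforms.

Relative transcript levels from Ct values follow the ddCt method:
dCt = Ct_target - Ct_reference per condition (replicate-averaged, with the
reference gene cancelling plate offsets), ddCt = dCt_condition - dCt_control
and the relative level is 2**(-ddCt).

Platform concordance: per-gene Pearson correlations between matched
expression profiles are summarized by a Gaussian fitted to their histogram
(10 equal bins over [-1, 1], least squares); the one-sided 95% bound is the
fitted 5th percentile, mean - 1.6449 * sd.  A histogram-free moment fit is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z_95_ONE_SIDED = 1.6449


def delta_delta_ct(ct: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative levels 2**(-ddCt) per gene and condition.

    ``ct`` columns: gene_id, condition, replicate, ct_target, ct_reference.
    Replicate Ct values are averaged before dCt; the replicate SD of dCt is
    propagated into a ``dct_sd`` column but not used in the point estimate.
    """
    required = {"gene_id", "condition", "replicate", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    work = ct.copy()
    work["dct"] = work["ct_target"] - work["ct_reference"]
    agg = work.groupby(["gene_id", "condition"])["dct"].agg(["mean", "std"]).reset_index()
    rows = []
    for gene, sub in agg.groupby("gene_id"):
        ctrl = sub[sub["condition"] == control_condition]
        if ctrl.empty:
            raise ValueError(f"control condition missing for gene {gene!r}")
        dct_ctrl = float(ctrl["mean"].iloc[0])
        for _, r in sub.iterrows():
            ddct = r["mean"] - dct_ctrl
            rows.append(
                {
                    "gene_id": gene,
                    "condition": r["condition"],
                    "ddct": float(ddct),
                    "relative_level": float(2.0 ** (-ddct)),
                    "dct_sd": float(r["std"]) if np.isfinite(r["std"]) else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceStats:
    """Correlation set, fitted Gaussian and its one-sided 95% lower bound."""

    correlations: pd.Series
    mean: float
    sd: float
    bound: float  # mean - 1.6449 * sd
    fit_r2: float
    method: str
    excluded: list[str]


def _gaussian_histogram_fit(r: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def model(x, amp, m, s):
        return amp * np.exp(-((x - m) ** 2) / (2.0 * s**2))

    p0 = (counts.max() or 1.0, float(np.mean(r)), max(float(np.std(r)), 1e-3))
    popt, _ = optimize.curve_fit(model, centers, counts, p0=p0, maxfev=10000)
    pred = model(centers, *popt)
    ss_res = float(((counts - pred) ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(popt[1]), abs(float(popt[2])), r2


def concordance_bound(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    method: str = "histogram",
) -> ConcordanceStats:
    """Gaussian-summarized per-gene correlation between two platforms.

    ``profiles_a``/``profiles_b``: genes x matched conditions.  Genes with a
    zero-variance profile on either platform are excluded with a reason.
    ``method``: 'histogram' (least-squares Gaussian on 10 bins over [-1, 1])
    or 'moments' (sample mean and sd).
    """
    common = profiles_a.index.intersection(profiles_b.index)
    if len(common) < 5:
        raise ValueError("need at least 5 genes with matched profiles")
    if profiles_a.shape[1] < 3:
        raise ValueError("need condition vectors of length >= 3")
    cors, excluded = {}, []
    for gene in common:
        a = profiles_a.loc[gene].to_numpy(dtype=float)
        b = profiles_b.loc[gene].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            excluded.append(gene)
            continue
        cors[gene] = float(stats.pearsonr(a, b).statistic)
    r = pd.Series(cors, name="pcc")
    if r.empty:
        raise ValueError("all profiles have zero variance")
    vals = r.to_numpy()
    if np.allclose(vals, vals[0]):
        m, s, r2 = float(vals[0]), 0.0, 1.0
    elif method == "histogram":
        # a near-degenerate histogram (few genes, one dominant bin) makes the
        # least-squares Gaussian ill-posed; fall back to moment estimates
        try:
            m, s, r2 = _gaussian_histogram_fit(vals)
        except RuntimeError:
            m, s, r2 = float(vals.mean()), float(vals.std(ddof=1)), float("nan")
    elif method == "moments":
        m, s, r2 = float(vals.mean()), float(vals.std(ddof=1)), 1.0
    else:
        raise ValueError("method must be 'histogram' or 'moments'")
    return ConcordanceStats(
        correlations=r,
        mean=m,
        sd=s,
        bound=m - Z_95_ONE_SIDED * s,
        fit_r2=r2,
        method=method,
        excluded=excluded,
    )
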