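"""Hypothesis-driven selection of genes separating tolerant from sensitive lines.

The hypothesis: the two tolerant accessions (LA1994, LA2661) differ from
the thermosensitive Red Setter, with Moneymaker behaving like Red Setter at
25 and 39 degC but tolerating heat better at 45 degC.  Three rules pick
genes whose transcript abundance tracks that pattern:

(i)   at a given temperature, Red Setter differs significantly (p < 0.05)
      from *both* tolerant genotypes, in the same direction against both;
(ii)  rule-(i) genes at 25 or 39 degC where Moneymaker is likewise
      significantly different from both tolerant genotypes in the same
      direction as Red Setter ("tolerant vs sensitive" at 25/39 degC);
(iii) rule-(i) genes at 45 degC whose heat response (log2 TPM ratio
      45 vs 25 degC, pseudo-count guarded) separates Red Setter from
      Moneymaker by more than one log2 unit, on the side of Red Setter's
      own response sign ("tolerant vs sensitive" at 45 degC).

Significance comes from the NB Wald genotype contrasts on counts; the
response ratio of rule (iii) is computed on replicate-mean TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from thermoclass.diffexp import genotype_contrast
from thermoclass.expression import ExpressionMatrix


@dataclass
class SelectionRuleConfig:
    focal: str = "RedSetter"
    tolerant: tuple[str, str] = ("LA1994", "LA2661")
    intermediate: str = "Moneymaker"
    p_threshold: float = 0.05
    use_adjusted: bool = False
    lfc_diff_threshold: float = 1.0
    pseudocount: float = 1.0
    temperatures: tuple[float, float, float] = (25.0, 39.0, 45.0)

    def __post_init__(self) -> None:
        if self.focal in self.tolerant:
            raise ValueError("focal genotype must not be in the tolerant set")
        if self.p_threshold <= 0 or self.lfc_diff_threshold <= 0:
            raise ValueError("thresholds must be positive")


def rule_i(
    vs_tolerant: dict[str, pd.DataFrame],
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Rule (i): significant same-direction change against both tolerant genotypes.

    ``vs_tolerant`` maps each tolerant genotype to the focal-vs-that-genotype
    contrast frame (positive log2fc = higher in focal).  Returns a frame of
    the selected genes with a ``direction`` column ('higher'/'lower' in
    focal) and the per-contrast fold changes.
    """
    if len(vs_tolerant) < 2:
        raise ValueError("need contrasts against both tolerant genotypes")
    names = list(vs_tolerant)
    crit = "padj" if use_adjusted else "pvalue"
    sig = None
    for name in names:
        df = vs_tolerant[name]
        s = df["tested"] & (df[crit] < p_threshold)
        sig = s if sig is None else (sig & s)
    lfc = pd.DataFrame({n: vs_tolerant[n]["log2fc"] for n in names})
    same_dir = (lfc.gt(0).all(axis=1)) | (lfc.lt(0).all(axis=1))
    selected = sig & same_dir
    out = lfc.loc[selected].copy()
    out.columns = [f"log2fc_vs_{n}" for n in names]
    out["direction"] = np.where(lfc.loc[selected, names[0]] > 0, "higher", "lower")
    return out


def rule_ii(
    rule_i_genes: pd.DataFrame,
    intermediate_vs_tolerant: dict[str, pd.DataFrame],
    temperature: float,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Rule (ii): the intermediate genotype mirrors the focal pattern (25/39 degC only)."""
    if temperature not in (25.0, 39.0):
        raise ValueError("rule (ii) applies only at 25 or 39 degC")
    inter = rule_i(intermediate_vs_tolerant, p_threshold, use_adjusted)
    keep = rule_i_genes.index.intersection(inter.index)
    same = rule_i_genes.loc[keep, "direction"] == inter.loc[keep, "direction"]
    out = rule_i_genes.loc[keep[same.to_numpy()]].copy()
    out["label"] = f"tolerant-vs-sensitive at {temperature:g} degC"
    return out


def rule_iii(
    rule_i_genes_45: pd.DataFrame,
    mean_tpm_focal: pd.DataFrame,
    mean_tpm_intermediate: pd.DataFrame,
    pseudocount: float = 1.0,
    lfc_diff_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rule (iii): heat-response separation of focal vs intermediate at 45 degC.

    ``mean_tpm_*`` are frames with columns '25' and '45' of replicate-mean
    TPM.  With r_G = log2((TPM45 + pc) / (TPM25 + pc)): selected iff
    (r_focal > 0 and r_focal - r_inter > threshold) or
    (r_focal < 0 and r_inter - r_focal > threshold).
    A gene with r_focal exactly 0 satisfies neither branch.
    """
    genes = rule_i_genes_45.index

    def response(df: pd.DataFrame) -> pd.Series:
        return np.log2((df["45"] + pseudocount) / (df["25"] + pseudocount))

    r_f = response(mean_tpm_focal).reindex(genes)
    r_i = response(mean_tpm_intermediate).reindex(genes)
    pos = (r_f > 0) & ((r_f - r_i) > lfc_diff_threshold)
    neg = (r_f < 0) & ((r_i - r_f) > lfc_diff_threshold)
    out = rule_i_genes_45.loc[pos | neg].copy()
    out["r_focal"] = r_f.loc[out.index]
    out["r_intermediate"] = r_i.loc[out.index]
    out["label"] = "tolerant-vs-sensitive at 45 degC"
    return out


def rule_iii_selects(r_focal: float, r_intermediate: float, threshold: float = 1.0) -> bool:
    """Scalar form of the rule-(iii) predicate (used for worked examples)."""
    if r_focal > 0:
        return (r_focal - r_intermediate) > threshold
    if r_focal < 0:
        return (r_intermediate - r_focal) > threshold
    return False


@dataclass
class ContrastSelection:
    """Per-condition rule outputs and the cross-condition summary."""

    per_condition: dict[str, pd.DataFrame]  # "25"/"39"/"45" -> selected genes
    rule_ii_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: SelectionRuleConfig = field(default_factory=SelectionRuleConfig)


def mean_tpm_at(tpm: ExpressionMatrix, genotype: str, temperatures=(25.0, 45.0)) -> pd.DataFrame:
    cols = {}
    for t in temperatures:
        samples = tpm.select_samples(genotype=genotype, temperature=t)
        cols[f"{t:g}"] = tpm.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def select_genotype_specific(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    config: SelectionRuleConfig | None = None,
) -> ContrastSelection:
    """Run rules (i)-(iii) over all three conditions from a count matrix."""
    cfg = config or SelectionRuleConfig()
    per_condition: dict[str, pd.DataFrame] = {}
    rule2: dict[str, pd.DataFrame] = {}
    for t in cfg.temperatures:
        focal_vs = {
            tol: genotype_contrast(
                counts, tol, cfg.focal, t, cfg.p_threshold, cfg.use_adjusted
            )
            for tol in cfg.tolerant
        }
        r1 = rule_i(focal_vs, cfg.p_threshold, cfg.use_adjusted)
        key = f"{t:g}"
        if t == 45.0:
            r3 = rule_iii(
                r1,
                mean_tpm_at(tpm, cfg.focal),
                mean_tpm_at(tpm, cfg.intermediate),
                cfg.pseudocount,
                cfg.lfc_diff_threshold,
            )
            r3["rules_passed"] = "i+iii"
            per_condition[key] = r3
        else:
            inter_vs = {
                tol: genotype_contrast(
                    counts, tol, cfg.intermediate, t, cfg.p_threshold, cfg.use_adjusted
                )
                for tol in cfg.tolerant
            }
            r2 = rule_ii(r1, inter_vs, t, cfg.p_threshold, cfg.use_adjusted)
            r2["rules_passed"] = "i+ii"
            per_condition[key] = r2
            rule2[key] = r2
    return ContrastSelection(per_condition=per_condition, rule_ii_sets=rule2, config=cfg)


def summarize_selection(selection: ContrastSelection) -> pd.DataFrame:
    """Condition counts, direction splits and exhaustive condition overlaps."""
    sets = {k: set(v.index) for k, v in selection.per_condition.items()}
    rows = []
    for cond, df in selection.per_condition.items():
        rows.append(
            {
                "entry": f"selected@{cond}",
                "count": len(df),
                "higher_in_focal": int((df["direction"] == "higher").sum()),
                "lower_in_focal": int((df["direction"] == "lower").sum()),
            }
        )
    labels = list(sets)
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set.intersection(*(sets[c] for c in combo))
            rows.append(
                {
                    "entry": "overlap@" + "&".join(combo),
                    "count": len(inter),
                    "higher_in_focal": np.nan,
                    "lower_in_focal": np.nan,
                }
            )
    return pd.DataFrame(rows)
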