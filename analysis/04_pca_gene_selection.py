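"""PCA gene-contribution selection per genotype and per temperature.

Selects genes contributing at least tenfold the equal-share baseline
(100/N percent of a component) to PC1 or PC2, in each scope, and tabulates
the cross-scope Venn overlap -- the gene sets that drive the common
temperature response versus genotype identity.
"""

from pathlib import Path

from thermoclass import pca_select, quant
from thermoclass.expression import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    counts = ExpressionMatrix.from_tsv(ROOT / "data" / "counts.tsv")
    tpm = quant.tpm_no_length(counts)

    by_geno = pca_select.per_genotype_selections(tpm)
    venn = pca_select.overlap(by_geno)
    venn.to_csv(ROOT / "pca_overlap_genotypes.tsv", sep="\t", index=False)

    for r in by_geno.values():
        print(f"{r.scope}: {len(r.selected)} of {r.n_expressed} expressed genes "
              f">= {r.threshold_pct:.4g}% (baseline {r.baseline_pct:.4g}%)")
    full = venn.loc[venn["n_scopes"] == len(by_geno), "count"].iloc[0]
    print(f"selected in all four genotypes: {full} genes")

    by_temp = pca_select.per_temperature_selections(tpm)
    for r in by_temp.values():
        print(f"{r.scope}: {len(r.selected)} selected of {r.n_expressed}")
    print(f"Venn table -> {ROOT / 'pca_overlap_genotypes.tsv'}")
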