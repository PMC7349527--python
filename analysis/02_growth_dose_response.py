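"""Fit the Hill dose-response per genotype and rank thermotolerance.

Reads results/data/growth.csv, fits T50%, Hill slope and the EC10-EC90
eustress range for each genotype, and prints the thermotolerance ordering
the growth assay supports.
"""

from pathlib import Path

import pandas as pd

from thermoclass.growth import fit_all_genotypes

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    growth = pd.read_csv(ROOT / "data" / "growth.csv")
    fits = fit_all_genotypes(growth, seed=20)
    out = ROOT / "growth_fits.tsv"
    fits.to_csv(out, sep="\t", index=False)

    ranked = fits.sort_values("t50", ascending=False)
    print(ranked[["genotype", "t50", "se_t50", "hill", "ec10", "ec90",
                  "eustress_width"]].round(2).to_string(index=False))
    print(f"\nT50 ranking: {' > '.join(ranked['genotype'])}")
    widest = fits.loc[fits["eustress_width"].idxmax(), "genotype"]
    print(f"widest eustress range (shallowest Hill slope): {widest}")
    print(f"table -> {out}")
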