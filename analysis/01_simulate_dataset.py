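"""Generate the synthetic study dataset: growth assay, counts, categories.

Emulates the experimental design (4 tomato genotypes x 3 temperatures x 2
replicates of 3'-tag counts; hypocotyl growth over a 25-50 degC series)
with planted expression classes, genotype-contrast genes and a planted
category enrichment.  Writes everything under results/data/.
"""

from pathlib import Path

from thermoclass import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    truth = simulate.default_truth(seed=SEED, n_genes=2000)
    counts = simulate.simulate_counts(truth)
    growth = simulate.simulate_growth(truth.genotypes, seed=SEED)
    categories = simulate.category_map_frame(truth)

    truth.to_json(OUT / "truth.json")
    counts.to_tsv(OUT / "counts.tsv")
    growth.to_csv(OUT / "growth.csv", index=False)
    categories.to_csv(OUT / "category_map.tsv", sep="\t", index=False)

    print(f"simulated {truth.n_genes} genes, {len(truth.planted)} planted "
          f"({sum(1 for p in truth.planted if p.contrast_role and p.contrast_role.startswith('class'))} class genes), "
          f"{counts.values.shape[1]} samples; library ~{int(truth.library_size):,} reads")
    print(f"growth assay: {growth['genotype'].nunique()} genotypes x "
          f"{growth['temperature_C'].nunique()} temperatures x 8 replicates")
    print(f"outputs in {OUT}")
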