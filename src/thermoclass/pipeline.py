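"""End-to-end orchestration: simulate/load -> growth -> quant -> DE -> classify
-> PCA selection -> contrast rules -> enrichment (-> qPCR concordance).

A single :class:`PipelineConfig` (YAML-serializable) drives every stage.
Outputs are plain TSV/CSV/JSON under the configured output directory, and a
run manifest records the config hash, seed, per-stage row counts and
content checksums; identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from thermoclass import classify as classify_mod
from thermoclass import contrast as contrast_mod
from thermoclass import diffexp, enrich, pca_select, quant, simulate
from thermoclass.expression import ExpressionMatrix, checksum_frame, read_design_csv
from thermoclass.growth import fit_all_genotypes


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All inputs, thresholds and switches of one pipeline run."""

    # inputs; when counts_tsv is None the simulation block is used
    counts_tsv: str | None = None
    design_csv: str | None = None
    growth_csv: str | None = None
    category_map_tsv: str | None = None
    ct_table_csv: str | None = None

    # simulation block
    n_genes: int = 2000
    effect_size: float = 2.0
    genes_per_class: int = 10
    contrast_genes_per_condition: int = 8
    library_size: float = 2e5
    dispersion: float = 0.05

    # thresholds (defaults follow the published procedure)
    de_padj: float = 0.01
    genotype_p: float = 0.05
    lfc_diff: float = 1.0
    tenfold_factor: float = 10.0
    category_alpha: float = 0.005
    category_method: str = "kruskal"
    pca_log_scale: bool = False

    seed: int = 0
    outdir: str = "results/pipeline"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str, name: str,
           index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={manifest['config_hash']}\n")
        df.to_csv(fh, sep="\t", index=index)
    manifest["stages"].setdefault(stage, {})[name] = {
        "path": str(path),
        "rows": int(len(df)),
        "sha256": checksum_frame(df),
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "status": "running",
    }
    t_start = time.time()
    try:
        # -- inputs / simulation ------------------------------------------
        stage = "simulate"
        if config.counts_tsv is None:
            truth = simulate.default_truth(
                seed=config.seed,
                n_genes=config.n_genes,
                effect_size=config.effect_size,
                genes_per_class=config.genes_per_class,
                contrast_genes_per_condition=config.contrast_genes_per_condition,
                library_size=config.library_size,
                dispersion=config.dispersion,
            )
            counts = simulate.simulate_counts(truth)
            growth = simulate.simulate_growth(truth.genotypes, seed=config.seed)
            cat_frame = simulate.category_map_frame(truth)
            truth.to_json(out / "truth.json")
            counts.to_tsv(out / "counts.tsv")
            growth.to_csv(out / "growth.csv", index=False)
            cat_frame.to_csv(out / "category_map.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_genes": truth.n_genes,
                "n_planted": len(truth.planted),
            }
        else:
            design = read_design_csv(config.design_csv) if config.design_csv else None
            counts = ExpressionMatrix.from_tsv(config.counts_tsv, design)
            growth = pd.read_csv(config.growth_csv) if config.growth_csv else None
            cat_frame = (
                pd.read_csv(config.category_map_tsv, sep="\t")
                if config.category_map_tsv
                else None
            )

        # -- growth --------------------------------------------------------
        stage = "growth"
        if growth is not None:
            fits = fit_all_genotypes(growth, seed=config.seed)
            _write(fits, out / "growth_fits.tsv", manifest, stage, "fits", index=False)

        # -- quant ---------------------------------------------------------
        stage = "quant"
        tpm = quant.tpm_no_length(counts)
        tpm.to_tsv(out / "tpm.tsv")
        manifest["stages"][stage] = {"tpm_sha256": checksum_frame(tpm.values)}
        categories = None
        if cat_frame is not None:
            categories = enrich.merge_categories(cat_frame)
            for t in tpm.temperatures:
                table = quant.relative_abundance(tpm, t)
                _write(table.share, out / f"relative_abundance_{t:g}.tsv",
                       manifest, stage, f"share_{t:g}")
                report = quant.category_distribution_tests(
                    table, categories, method=config.category_method,
                    alpha_main=config.category_alpha,
                )
                _write(report, out / f"category_tests_{t:g}.tsv",
                       manifest, stage, f"cat_tests_{t:g}", index=False)

        # -- diffexp + classify ---------------------------------------------
        stage = "diffexp"
        assignments: dict[str, pd.DataFrame] = {}
        for g in counts.genotypes:
            contrasts = diffexp.temperature_contrasts(
                counts, g, padj_threshold=config.de_padj
            )
            for key, df in contrasts.items():
                _write(
                    df.drop(columns=["tested"]),
                    out / f"de_{key}_{g}.tsv",
                    manifest,
                    stage,
                    f"{key}@{g}",
                )
            assignments[g] = classify_mod.classify_genotype(contrasts)

        stage = "classify"
        for g, df in assignments.items():
            _write(df, out / f"classes_{g}.tsv", manifest, stage, f"classes@{g}")
        conc = classify_mod.concordance(assignments)
        _write(conc.records, out / "concordance.tsv", manifest, stage, "concordance")
        common = classify_mod.common_sets(conc)
        _write(common, out / "common_sets.tsv", manifest, stage, "common_sets")
        summary = classify_mod.class_level_summary(assignments, conc)
        _write(summary, out / "class_level_summary.tsv", manifest, stage, "summary")

        # -- pca selection ---------------------------------------------------
        stage = "pca_select"
        by_geno = pca_select.per_genotype_selections(
            tpm, log_scale=config.pca_log_scale, tenfold_factor=config.tenfold_factor
        )
        venn = pca_select.overlap(by_geno)
        _write(venn, out / "pca_overlap_genotypes.tsv", manifest, stage, "venn",
               index=False)
        by_temp = pca_select.per_temperature_selections(
            tpm, log_scale=config.pca_log_scale, tenfold_factor=config.tenfold_factor
        )
        sel_rows = [
            {
                "scope": r.scope,
                "n_selected": len(r.selected),
                "n_expressed": r.n_expressed,
                "baseline_pct": r.baseline_pct,
                "threshold_pct": r.threshold_pct,
            }
            for r in list(by_geno.values()) + list(by_temp.values())
        ]
        _write(pd.DataFrame(sel_rows), out / "pca_selections.tsv", manifest, stage,
               "selections", index=False)

        # -- contrast rules --------------------------------------------------
        stage = "contrast"
        cfg = contrast_mod.SelectionRuleConfig(
            p_threshold=config.genotype_p, lfc_diff_threshold=config.lfc_diff
        )
        selection = contrast_mod.select_genotype_specific(counts, tpm, cfg)
        for cond, df in selection.per_condition.items():
            _write(df, out / f"contrast_selected_{cond}.tsv", manifest, stage,
                   f"selected@{cond}")
        _write(contrast_mod.summarize_selection(selection),
               out / "contrast_summary.tsv", manifest, stage, "summary", index=False)

        # -- enrichment ------------------------------------------------------
        stage = "enrich"
        if categories is not None:
            background = set(
                pca_select.expressed_genes(tpm, tpm.samples)
            )
            up39 = set(common.loc["common_up_39", "level1_genes"].split(";")) | set(
                common.loc["common_up_39", "level2_genes"].split(";")
            )
            up39.discard("")
            if up39:
                report = enrich.enrich(up39 & background, categories, background)
                _write(report, out / "enrichment_common_up_39.tsv", manifest, stage,
                       "common_up_39")

        # -- qPCR concordance -----------------------------------------------
        stage = "validate"
        if config.ct_table_csv is not None:
            from thermoclass.validate import delta_delta_ct

            ct = pd.read_csv(config.ct_table_csv)
            rel = delta_delta_ct(ct, control_condition="25")
            _write(rel, out / "qpcr_relative_levels.tsv", manifest, stage,
                   "relative_levels", index=False)

        manifest["status"] = "ok"
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise StageError(stage, type(exc).__name__, str(exc)) from exc

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
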