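"""Synthetic growth assays and MACE-like 3'-tag count matrices with planted truth.

The generator emulates the study design of the seedling experiment: four
tomato genotypes with contrasting thermotolerance, hypocotyl growth measured
over a temperature series, and per-sample transcript tag counts for a
4 genotypes x 3 temperatures (25/39/45 degC) x 2 replicates design.

Counts are negative-binomially distributed with a lognormal gene-to-gene
dispersion scatter.  One tag represents one transcript, so expected counts
are proportional to relative transcript abundance times library size with
no transcript-length term.  Ground truth (genotype dose-response parameters,
planted per-class log2 fold changes, planted genotype-contrast genes and
planted category enrichments) is carried alongside every dataset so that
each downstream stage can be scored against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from thermoclass.expression import ExpressionMatrix, sample_name

TEMPERATURES = (25.0, 39.0, 45.0)
#: temperature series of the growth assay (degC)
GROWTH_TEMPERATURES = (25.0, 40.0, 42.5, 45.0, 45.7, 50.0)

FOCAL = "RedSetter"
TOLERANT = ("LA1994", "LA2661")
INTERMEDIATE = "Moneymaker"


@dataclass(frozen=True)
class GenotypeSpec:
    """Dose-response and expression-offset parameters of one genotype.

    ``t50`` is the temperature of half-maximal growth (degC), ``hill`` the
    signed Hill slope (negative for growth decreasing with temperature) and
    ``baseline_log_mean_shift`` a global log2 offset applied to every gene's
    expected expression in this genotype.
    """

    name: str
    growth_max: float  # cm/day
    t50: float  # degC
    hill: float  # dimensionless, signed
    baseline_log_mean_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_max <= 0:
            raise ValueError("growth_max must be positive")
        if self.hill == 0:
            raise ValueError("hill must be non-zero")


# Defaults follow the qualitative ordering of the four genotypes: the two
# accessions are most tolerant (highest t50), Moneymaker intermediate with a
# shallower slope (widest eustress range) and Red Setter most sensitive.
DEFAULT_GENOTYPES: tuple[GenotypeSpec, ...] = (
    GenotypeSpec("LA2661", growth_max=0.92, t50=45.6, hill=-26.0),
    GenotypeSpec("LA1994", growth_max=0.88, t50=45.4, hill=-25.0),
    GenotypeSpec("Moneymaker", growth_max=1.00, t50=45.0, hill=-13.0),
    GenotypeSpec("RedSetter", growth_max=0.95, t50=43.8, hill=-24.0),
)


@dataclass
class PlantedGene:
    """Ground truth for one gene: per-genotype log2 fold changes and offsets.

    ``lfc_39v25`` / ``lfc_45v25`` map genotype name to the planted log2 fold
    change of the 39-vs-25 and 45-vs-25 temperature responses (genotypes not
    listed respond with 0).  ``genotype_offset`` is a temperature-independent
    log2 offset (used to plant baseline differences between genotypes).
    The 45-vs-39 fold change is always the difference of the two, so planted
    triples are internally consistent by construction.
    """

    gene_id: str
    lfc_39v25: dict[str, float] = field(default_factory=dict)
    lfc_45v25: dict[str, float] = field(default_factory=dict)
    genotype_offset: dict[str, float] = field(default_factory=dict)
    category: tuple[str, str] | None = None
    contrast_role: str | None = None

    def lfc(self, genotype: str, temperature: float) -> float:
        """Planted log2 offset of this gene at (genotype, temperature) vs 25 degC baseline."""
        off = self.genotype_offset.get(genotype, 0.0)
        if temperature == 39.0:
            return off + self.lfc_39v25.get(genotype, 0.0)
        if temperature == 45.0:
            return off + self.lfc_45v25.get(genotype, 0.0)
        return off

    def lfc_45v39(self, genotype: str) -> float:
        return self.lfc_45v25.get(genotype, 0.0) - self.lfc_39v25.get(genotype, 0.0)

    def status_triple(self, genotype: str) -> tuple[str, str, str]:
        """Truth status (up/down/ns) of the three contrasts, by sign of the planted lfc."""

        def s(x: float) -> str:
            return "up" if x > 0 else ("down" if x < 0 else "ns")

        return (
            s(self.lfc_39v25.get(genotype, 0.0)),
            s(self.lfc_45v25.get(genotype, 0.0)),
            s(self.lfc_45v39(genotype)),
        )

    def true_class(self, genotype: str) -> int:
        from thermoclass.classify import assign_class

        return assign_class(self.status_triple(genotype))


@dataclass
class SimulationTruth:
    """Everything needed to regenerate a dataset bit-identically.

    ``dispersion`` is the median NB dispersion phi (var = mu + phi*mu^2);
    per-gene values scatter lognormally around it with log-sd
    ``dispersion_sigma``.  ``library_size`` is reads per sample, scaled down
    from the 5-10 M of a real MACE library so simulations run in seconds.
    """

    genotypes: tuple[GenotypeSpec, ...] = DEFAULT_GENOTYPES
    planted: tuple[PlantedGene, ...] = ()
    n_genes: int = 2000
    dispersion: float = 0.05
    dispersion_sigma: float = 0.3
    library_size: float = 2e5
    zero_fraction: float = 0.15
    baseline_log2_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < len(self.planted):
            raise ValueError("n_genes smaller than number of planted genes")

    @property
    def genotype_names(self) -> list[str]:
        return [g.name for g in self.genotypes]

    def planted_by_id(self) -> dict[str, PlantedGene]:
        return {p.gene_id: p for p in self.planted}

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = asdict(self)
        for p in payload["planted"]:
            if p["category"] is not None:
                p["category"] = list(p["category"])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["genotypes"] = tuple(GenotypeSpec(**g) for g in payload["genotypes"])
        planted = []
        for p in payload["planted"]:
            if p["category"] is not None:
                p["category"] = tuple(p["category"])
            planted.append(PlantedGene(**p))
        payload["planted"] = tuple(planted)
        return cls(**payload)


# ---------------------------------------------------------------------------
# growth assay
# ---------------------------------------------------------------------------


def simulate_growth(
    specs=DEFAULT_GENOTYPES,
    temperatures=GROWTH_TEMPERATURES,
    n_reps: int = 8,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicated hypocotyl growth rates along a temperature series.

    Each observation is the Hill dose-response value plus Gaussian noise with
    standard deviation ``noise_sd * growth_max``, floored at zero.  A
    normalized column (fraction of the genotype's maximal growth, the scale
    on which curves are usually fit) is emitted alongside the raw rates.
    """
    from thermoclass.growth import hill_growth

    if len(temperatures) == 0:
        raise ValueError("temperature list is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x67726F77]))
    rows = []
    for spec in specs:
        for x in temperatures:
            mu = hill_growth(x, spec.growth_max, spec.t50, spec.hill)
            noise = rng.normal(0.0, noise_sd * spec.growth_max, size=n_reps)
            vals = np.maximum(mu + noise, 0.0)
            for rep, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "genotype": spec.name,
                        "temperature_C": float(x),
                        "replicate": rep,
                        "growth_cm_per_day": float(v),
                        "growth_normalized": float(v / spec.growth_max),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _design_frame(genotype_names: list[str], temperatures=TEMPERATURES, n_reps: int = 2) -> pd.DataFrame:
    rows = []
    for g in genotype_names:
        for t in temperatures:
            for r in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample": sample_name(g, t, r),
                        "genotype": g,
                        "temperature_C": float(t),
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(truth: SimulationTruth, n_reps: int = 2) -> ExpressionMatrix:
    """Draw an NB tag-count matrix for the full design encoded in ``truth``.

    Expected counts: per sample, each gene's lognormal baseline weight is
    multiplied by 2**(genotype shift + planted offsets/fold changes); the
    column is then scaled so the expected library size matches
    ``truth.library_size``, and counts are drawn NB(mean, phi_gene) via the
    gamma-Poisson mixture.  A configurable fraction of genes is unexpressed
    (weight zero) to emulate the silent part of the genome.
    """
    ss = np.random.SeedSequence([int(truth.seed), 0x636E7473])
    rng_base, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))

    n = truth.n_genes
    planted = truth.planted
    if n < len(planted):
        raise ValueError("n_genes smaller than number of planted genes")

    gene_ids = [f"gene{i:05d}" for i in range(n)]
    planted_map: dict[int, PlantedGene] = {}
    for j, p in enumerate(planted):
        # planted genes occupy the first slots under their own ids
        gene_ids[j] = p.gene_id
        planted_map[j] = p

    # lognormal baseline expression weights; a fraction of the *unplanted*
    # genes is silenced so planted effects are always observable
    log2_w = rng_base.normal(loc=5.0, scale=truth.baseline_log2_sd, size=n)
    weights = np.power(2.0, log2_w)
    n_zero = int(round(truth.zero_fraction * n))
    unplanted = np.arange(len(planted), n)
    if n_zero > len(unplanted):
        n_zero = len(unplanted)
    silent = rng_base.choice(unplanted, size=n_zero, replace=False)
    weights[silent] = 0.0

    phi = truth.dispersion * np.exp(
        rng_base.normal(0.0, truth.dispersion_sigma, size=n) - truth.dispersion_sigma**2 / 2
    )

    design = _design_frame(truth.genotype_names, TEMPERATURES, n_reps)
    spec_by_name = {g.name: g for g in truth.genotypes}

    counts = np.zeros((n, len(design)), dtype=np.int64)
    for s_idx, (sample, row) in enumerate(design.iterrows()):
        g, t = row["genotype"], row["temperature_C"]
        shift = np.zeros(n)
        for j, p in planted_map.items():
            shift[j] = p.lfc(g, t)
        a = weights * np.power(2.0, spec_by_name[g].baseline_log_mean_shift + shift)
        total = a.sum()
        mu = a / total * truth.library_size
        lam = np.where(
            mu > 0,
            rng_counts.gamma(shape=1.0 / phi, scale=np.maximum(mu, 1e-300) * phi),
            0.0,
        )
        counts[:, s_idx] = rng_counts.poisson(lam)

    values = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=design.index)
    return ExpressionMatrix(values, design, unit="counts")


def expected_mean_matrix(truth: SimulationTruth, n_reps: int = 2) -> pd.DataFrame:
    """Expected NB means per gene and sample (the truth the sampler targets)."""
    ss = np.random.SeedSequence([int(truth.seed), 0x636E7473])
    rng_base = np.random.default_rng(ss.spawn(2)[0])
    n = truth.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    planted_map: dict[int, PlantedGene] = {}
    for j, p in enumerate(truth.planted):
        gene_ids[j] = p.gene_id
        planted_map[j] = p
    log2_w = rng_base.normal(loc=5.0, scale=truth.baseline_log2_sd, size=n)
    weights = np.power(2.0, log2_w)
    n_zero = int(round(truth.zero_fraction * n))
    unplanted = np.arange(len(truth.planted), n)
    if n_zero > len(unplanted):
        n_zero = len(unplanted)
    silent = rng_base.choice(unplanted, size=n_zero, replace=False)
    weights[silent] = 0.0

    design = _design_frame(truth.genotype_names, TEMPERATURES, n_reps)
    spec_by_name = {g.name: g for g in truth.genotypes}
    out = np.zeros((n, len(design)))
    for s_idx, (_, row) in enumerate(design.iterrows()):
        g, t = row["genotype"], row["temperature_C"]
        shift = np.zeros(n)
        for j, p in planted_map.items():
            shift[j] = p.lfc(g, t)
        a = weights * np.power(2.0, spec_by_name[g].baseline_log_mean_shift + shift)
        out[:, s_idx] = a / a.sum() * truth.library_size
    return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene_id"), columns=design.index)


# ---------------------------------------------------------------------------
# default planted truth
# ---------------------------------------------------------------------------

# canonical (lfc_39v25, lfc_45v25) pairs, in units of the effect size e,
# realizing each plantable expression class by the signs of the contrast
# triple.  Classes 12 and 14 (no 39v25/45v25 change but a significant
# 45-vs-39 shift) cannot be realized by exact sign-consistent truth and are
# only produced by threshold effects in noisy data, so they are not planted.
CLASS_LFC_PAIRS: dict[int, tuple[float, float]] = {
    1: (1.0, 2.0),
    2: (1.0, 1.0),
    3: (2.0, 1.0),
    4: (1.0, 0.0),
    5: (1.0, -1.0),
    6: (-1.0, -2.0),
    7: (-1.0, 0.0),
    8: (-1.0, -1.0),
    9: (-2.0, -1.0),
    10: (-1.0, 1.0),
    11: (0.0, 1.0),
    13: (0.0, 0.0),
    15: (0.0, -1.0),
}

#: MapMan-style synthetic bin roster (codes loosely echo the real numbering)
SYNTHETIC_BINS: dict[int, str] = {
    1: "photosynthesis",
    **{c: f"carbon fixation.{c}" for c in range(2, 9)},
    9: "mitochondrial energy",
    10: "cell wall",
    11: "lipid metabolism",
    **{c: f"metabolism.{c}" for c in range(12, 20)},
    20: "redox",
    21: "stress",
    22: "metabolism.22",
    23: "metabolism.23",
    24: "metabolism.24",
    25: "C1-metabolism",
    26: "misc",
    27: "RNA",
    28: "DNA",
    29: "protein",
    30: "signaling",
    31: "cell",
    33: "development",
    34: "transport",
    35: "not assigned",
}


def default_truth(
    seed: int = 0,
    n_genes: int = 2000,
    effect_size: float = 2.0,
    genes_per_class: int = 10,
    contrast_genes_per_condition: int = 8,
    contrast_effect: float = 2.0,
    enriched_category: str = "stress",
    enrichment_prob: float = 0.5,
    **truth_kwargs,
) -> SimulationTruth:
    """Assemble the default planted truth: class genes, contrast genes, categories.

    Per plantable class, ``genes_per_class`` genes receive the canonical lfc
    pair scaled by ``effect_size`` in every genotype (level-1 concordant) --
    except a fraction planted in only a subset of genotypes to populate
    level 2.  Genotype-contrast genes are planted per condition for the
    focal (Red Setter) and sensitive (Red Setter + Moneymaker) selection
    rules, half higher and half lower in the focal genotype(s).  Upregulated
    class genes carry the ``enriched_category`` label with probability
    ``enrichment_prob`` against a uniform background, planting a category
    enrichment in the common-up set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x74727574]))
    genotypes = truth_kwargs.pop("genotypes", DEFAULT_GENOTYPES)
    names = [g.name for g in genotypes]
    codes = sorted(SYNTHETIC_BINS)

    def draw_category(upregulated: bool) -> tuple[str, str]:
        if upregulated and rng.random() < enrichment_prob:
            name = enriched_category
            code = next(c for c, v in SYNTHETIC_BINS.items() if v == name)
        else:
            code = int(rng.choice(codes))
            name = SYNTHETIC_BINS[code]
        return (str(code), name)

    planted: list[PlantedGene] = []
    idx = 0
    for cls, (a, b) in CLASS_LFC_PAIRS.items():
        for k in range(genes_per_class):
            l39, l45 = a * effect_size, b * effect_size
            # last fifth planted in only three genotypes -> level-2 material
            gset = names if k < genes_per_class - max(1, genes_per_class // 5) else names[:-1]
            upreg = cls in (1, 2, 3)
            planted.append(
                PlantedGene(
                    gene_id=f"class{cls:02d}_{k:02d}",
                    lfc_39v25={g: l39 for g in gset} if l39 else {},
                    lfc_45v25={g: l45 for g in gset} if l45 else {},
                    category=draw_category(upreg),
                    contrast_role=f"class{cls}",
                )
            )
            idx += 1

    def plant_contrast(role: str, members: list[str], temp: float, k: int, sign: float):
        e = sign * contrast_effect
        if temp == 25.0:
            off = {g: e for g in members}
            l39 = {g: -e for g in members}
            l45 = {g: -e for g in members}
        elif temp == 39.0:
            off, l39, l45 = {}, {g: e for g in members}, {}
        else:
            off, l39, l45 = {}, {}, {g: e for g in members}
        return PlantedGene(
            gene_id=f"{role}_{k:02d}",
            lfc_39v25=l39,
            lfc_45v25=l45,
            genotype_offset=off,
            category=draw_category(False),
            contrast_role=role,
        )

    for temp, tag in ((25.0, "focal_25"), (39.0, "focal_39"), (45.0, "focal_45")):
        for k in range(contrast_genes_per_condition):
            sign = 1.0 if k % 2 == 0 else -1.0
            planted.append(plant_contrast(tag, [FOCAL], temp, k, sign))
    for temp, tag in ((25.0, "sensitive_25"), (39.0, "sensitive_39")):
        for k in range(contrast_genes_per_condition):
            sign = 1.0 if k % 2 == 0 else -1.0
            planted.append(plant_contrast(tag, [FOCAL, INTERMEDIATE], temp, k, sign))

    return SimulationTruth(
        genotypes=tuple(genotypes),
        planted=tuple(planted),
        n_genes=n_genes,
        seed=seed,
        **truth_kwargs,
    )


def category_map_frame(truth: SimulationTruth, rng_seed: int | None = None) -> pd.DataFrame:
    """Two-level gene-to-category map covering every simulated gene.

    Planted genes keep their planted category; the rest are assigned
    uniformly over the synthetic MapMan-style bins.  Columns:
    gene_id, bin_code, level1_category, level2_category.
    """
    seed = truth.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x63617467]))
    codes = sorted(SYNTHETIC_BINS)
    planted = truth.planted_by_id()
    rows = []
    for i in range(truth.n_genes):
        gid = f"gene{i:05d}"
        if i < len(truth.planted):
            gid = truth.planted[i].gene_id
        p = planted.get(gid)
        if p is not None and p.category is not None:
            code = int(p.category[0])
        else:
            code = int(rng.choice(codes))
        name = SYNTHETIC_BINS[code]
        rows.append(
            {
                "gene_id": gid,
                "bin_code": code,
                "level1_category": name.split(".")[0],
                "level2_category": name,
            }
        )
    return pd.DataFrame(rows)
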