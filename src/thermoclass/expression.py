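"""Gene-by-sample expression container with an attached sample design.

The design records, per sample, the genotype, the heat-stress temperature
(by default one of 25, 39 or 45 degC) and the biological replicate.  Sample
names follow the convention ``<genotype>_<temperature>_r<replicate>``, which
is also parsed back when a matrix is read from disk without a design file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SAMPLE_RE = re.compile(r"^(?P<genotype>.+)_(?P<temp>[0-9]+(?:\.[0-9]+)?)_r(?P<rep>[0-9]+)$")


def sample_name(genotype: str, temperature: float, replicate: int) -> str:
    return f"{genotype}_{temperature:g}_r{replicate}"


def parse_sample_names(names: list[str]) -> pd.DataFrame:
    """Recover the (genotype, temperature, replicate) design from sample names."""
    rows = []
    for name in names:
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(f"sample name {name!r} does not follow <genotype>_<temp>_r<rep>")
        rows.append(
            {
                "sample": name,
                "genotype": m["genotype"],
                "temperature_C": float(m["temp"]),
                "replicate": int(m["rep"]),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative counts or TPM plus sample design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    design
        DataFrame indexed by sample name with columns ``genotype``,
        ``temperature_C`` and ``replicate``; must cover exactly the columns
        of ``values``.
    unit
        Either ``"counts"`` (raw tag counts) or ``"tpm"``.
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = parse_sample_names(list(self.values.columns))
        if self.unit not in ("counts", "tpm"):
            raise ValueError(f"unit must be 'counts' or 'tpm', got {self.unit!r}")
        if set(self.values.columns) != set(self.design.index):
            raise ValueError("design samples do not match matrix columns")
        if self.design.index.duplicated().any():
            raise ValueError("duplicate sample names in design")
        # align design row order to matrix column order
        self.design = self.design.loc[list(self.values.columns)]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.design["genotype"]))

    @property
    def temperatures(self) -> list[float]:
        return sorted(pd.unique(self.design["temperature_C"]))

    def select_samples(
        self, genotype: str | None = None, temperature: float | None = None
    ) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if genotype is not None:
            mask &= self.design["genotype"] == genotype
        if temperature is not None:
            mask &= self.design["temperature_C"] == temperature
        return list(self.design.index[mask])

    def subset(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[samples].copy(), self.design.loc[samples].copy(), self.unit
        )

    def mean_by(self, by: tuple[str, ...] = ("genotype", "temperature_C")) -> pd.DataFrame:
        """Replicate-mean matrix; one column per design group, named g@t."""
        groups = self.design.groupby(list(by), sort=True).groups
        cols = {}
        for key, samples in groups.items():
            key = key if isinstance(key, tuple) else (key,)
            label = "@".join(f"{k:g}" if isinstance(k, float) else str(k) for k in key)
            cols[label] = self.values[list(samples)].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, design: pd.DataFrame | None = None, unit: str = "counts"):
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(values, design, unit)


def read_design_csv(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    required = {"sample", "genotype", "temperature_C", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design CSV missing columns: {sorted(missing)}")
    return design.set_index("sample")


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.reset_index().rename(columns={"index": "sample"}).to_csv(path, index=False)


def checksum_frame(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame (used for determinism checks)."""
    import hashlib

    h = hashlib.sha256()
    h.update(df.to_csv().encode())
    return h.hexdigest()


def as_float_array(values) -> np.ndarray:
    return np.asarray(values, dtype=float)
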