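"""The pipeline's central exchange object: a samples × species concentration
matrix (nM) paired with per-sample metadata."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ConcentrationTable", "META_COLUMNS"]

#: leading metadata columns of the on-disk CSV, in order
META_COLUMNS = ["group", "age", "sex", "batch", "injection_order"]


@dataclass
class ConcentrationTable:
    """Samples × species plasma concentrations in nM.

    ``samples`` is indexed by sample_id and carries at least the
    ``META_COLUMNS`` (extra clinical columns are preserved);
    ``concentrations`` shares the same index, one column per canonical
    species name.  Missing cells are NaN; non-missing cells are ≥ 0.
    """

    samples: pd.DataFrame
    concentrations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.concentrations.index):
            raise ValueError("samples and concentrations must share the same sample index")
        neg = (self.concentrations < 0).any().any()
        if bool(neg):
            raise ValueError("concentrations must be non-negative (or NaN for missing)")

    @property
    def species(self) -> list[str]:
        return list(self.concentrations.columns)

    def group_mask(self, group: str) -> pd.Series:
        return self.samples["group"] == group

    def subset_species(self, names: list[str]) -> "ConcentrationTable":
        missing = set(names) - set(self.concentrations.columns)
        if missing:
            raise KeyError(f"species not in table: {sorted(missing)}")
        return ConcentrationTable(self.samples, self.concentrations[list(names)])

    def to_csv(self, path) -> None:
        meta = self.samples.copy()
        extra = [c for c in meta.columns if c not in META_COLUMNS]
        meta = meta[[c for c in META_COLUMNS if c in meta.columns] + extra]
        out = pd.concat([meta, self.concentrations], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        from .nomenclature import NameParseError, parse_species_name

        df = pd.read_csv(path, index_col="sample_id")
        meta_cols, species_cols = [], []
        for c in df.columns:
            try:
                parse_species_name(c)
            except (NameParseError, ValueError):
                meta_cols.append(c)
            else:
                species_cols.append(c)
        return cls(df[meta_cols], df[species_cols].astype(float))
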