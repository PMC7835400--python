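"""Trait schemas and the mixed-type phenotype table container.

A germplasm phenotype table is a rectangular accession x trait grid in
which each trait is declared either *quantitative* (a finite real number,
e.g. plant height in cm) or *qualitative* (a categorical level drawn from
a declared vocabulary, e.g. hypocotyl coloration in {green, purple}).
Missing cells are explicit and first-class: quantitative missingness is
NaN, qualitative missingness is a null object cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"

#: tokens read as missing in delimited input (configurable per call)
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", ".")


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of a single trait.

    Parameters
    ----------
    name
        Unique, non-empty trait name (column header in tables).
    kind
        ``"quantitative"`` or ``"qualitative"``.
    units
        Optional measurement units for quantitative traits (e.g. ``"cm"``).
    levels
        Ordered level vocabulary for qualitative traits. May be empty at
        construction time, in which case levels are inferred from data on
        first read.
    """

    name: str
    kind: str
    units: str | None = None
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("trait name must be non-empty")
        if self.kind not in (QUANTITATIVE, QUALITATIVE):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_quantitative(self) -> bool:
        return self.kind == QUANTITATIVE

    @property
    def is_qualitative(self) -> bool:
        return self.kind == QUALITATIVE


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of :class:`TraitSpec` declarations."""

    traits: tuple[TraitSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        if not self.traits:
            raise ValueError("schema must declare at least one trait")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique")

    def __len__(self) -> int:
        return len(self.traits)

    def __iter__(self):
        return iter(self.traits)

    def __getitem__(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(t.name == name for t in self.traits)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def quantitative(self) -> list[str]:
        return [t.name for t in self.traits if t.is_quantitative]

    @property
    def qualitative(self) -> list[str]:
        return [t.name for t in self.traits if t.is_qualitative]

    def subset(self, names: Iterable[str]) -> "TraitSchema":
        keep = set(names)
        return TraitSchema(tuple(t for t in self.traits if t.name in keep))

    def with_levels(self, trait: str, levels: Sequence[str]) -> "TraitSchema":
        """Return a schema with the level vocabulary of one trait replaced."""
        out = []
        for t in self.traits:
            if t.name == trait:
                t = TraitSpec(t.name, t.kind, t.units, tuple(levels))
            out.append(t)
        return TraitSchema(tuple(out))

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "traits": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    **({"units": t.units} if t.units else {}),
                    **({"levels": list(t.levels)} if t.levels else {}),
                }
                for t in self.traits
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSchema":
        return cls(
            tuple(
                TraitSpec(
                    name=t["name"],
                    kind=t["kind"],
                    units=t.get("units"),
                    levels=tuple(t.get("levels", ())),
                )
                for t in d["traits"]
            )
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TraitSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PhenotypeTable:
    """Accession x trait grid of mixed-type values with explicit missingness.

    Backed by a :class:`pandas.DataFrame` indexed by accession id.
    Quantitative columns are float64 (NaN marks a missing cell);
    qualitative columns hold level strings with ``None``/NaN for missing.
    """

    data: pd.DataFrame
    schema: TraitSchema = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.schema.names:
            # tolerate supersets/reordering by realigning to the schema
            self.data = self.data[self.schema.names]
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate accession ids: {dups}")
        if len(self.data) < 1:
            raise ValueError("table must contain at least one accession")
        for name in self.schema.quantitative:
            self.data[name] = pd.to_numeric(self.data[name], errors="raise")
            col = self.data[name]
            if np.isinf(col.to_numpy(dtype=float, na_value=np.nan)).any():
                raise ValueError(f"non-finite value in quantitative trait {name!r}")
        for name in self.schema.qualitative:
            self.data[name] = self.data[name].astype(object).where(
                self.data[name].notna(), None
            )

    # -- basic properties --------------------------------------------------

    @property
    def accession_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def m(self) -> int:
        return len(self.schema)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def missing_rate(self, trait: str) -> float:
        return float(self.data[trait].isna().mean())

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy(), self.schema)

    def subset_accessions(self, ids: Sequence[str]) -> "PhenotypeTable":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"unknown accession ids: {missing}")
        return PhenotypeTable(self.data.loc[list(ids)].copy(), self.schema)

    def subset_traits(self, names: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data[list(names)].copy(), self.schema.subset(names)
        )

    def equals(self, other: "PhenotypeTable") -> bool:
        """Cell-exact equality including the missingness pattern."""
        if self.schema.names != other.schema.names:
            return False
        if self.accession_ids != other.accession_ids:
            return False
        for name in self.schema.names:
            a, b = self.data[name], other.data[name]
            if not ((a.isna() == b.isna()).all() and (a.dropna() == b.dropna()).all()):
                return False
        return True
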