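"""Reading, writing and cleaning germplasm phenotype tables.

Cleaning covers the three standard curation steps for a raw germplasm
phenotype dump: unstacking long-format records into a rectangular table,
collapsing identically redundant accessions (duplicated passport entries
whose value vectors agree exactly on every trait, missingness included),
and dropping traits whose missing rate is too high to impute reliably.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import (
    DEFAULT_MISSING_TOKENS,
    PhenotypeTable,
    TraitSchema,
)

MISSING = None  # sentinel used in record-level interfaces


@dataclass
class CleaningLog:
    """Audit trail of destructive cleaning steps.

    ``removed_redundant`` lists, per redundancy group, the retained id and
    the ids dropped in its favour. ``dropped_traits`` lists each removed
    trait with its observed missing rate.
    """

    removed_redundant: list[tuple[str, list[str]]] = field(default_factory=list)
    dropped_traits: list[tuple[str, float]] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_redundant": [
                {"kept": k, "removed": r} for k, r in self.removed_redundant
            ],
            "dropped_traits": [
                {"trait": t, "missing_rate": mr} for t, mr in self.dropped_traits
            ],
            "n_before": self.n_before,
            "n_after": self.n_after,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def read_table(
    path,
    schema: TraitSchema,
    *,
    id_column: str = "accession",
    sep: str = ",",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> PhenotypeTable:
    """Read a delimited phenotype table and validate it against a schema.

    The file must have a header row containing ``id_column`` and one column
    per schema trait. Cells equal to one of ``missing_tokens`` become
    missing. Unparseable quantitative cells and qualitative labels outside
    the declared vocabulary raise ``ValueError`` naming the offending row
    and trait. A qualitative trait with an empty declared vocabulary has
    its levels inferred from the observed data (in order of appearance).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise ValueError(f"missing accession-id column {id_column!r}")
    for t in schema.names:
        if t not in raw.columns:
            raise ValueError(f"schema trait {t!r} not found in file columns")
    ids = raw[id_column].tolist()
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate accession id(s): {dups}")

    tokens = set(missing_tokens)
    data: dict[str, list] = {}
    new_schema = schema
    for spec in schema:
        col = []
        for acc, cell in zip(ids, raw[spec.name]):
            cell = cell.strip()
            if cell in tokens:
                col.append(np.nan if spec.is_quantitative else None)
            elif spec.is_quantitative:
                try:
                    col.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"accession {acc!r}, trait {spec.name!r}: "
                        f"unparseable quantitative value {cell!r}"
                    ) from None
            else:
                if spec.levels and cell not in spec.levels:
                    raise ValueError(
                        f"accession {acc!r}, trait {spec.name!r}: "
                        f"level {cell!r} not in declared vocabulary"
                    )
                col.append(cell)
        data[spec.name] = col
        if spec.is_qualitative and not spec.levels:
            seen = list(dict.fromkeys(v for v in col if v is not None))
            new_schema = new_schema.with_levels(spec.name, seen)

    frame = pd.DataFrame(data, index=pd.Index(ids, name=id_column))
    return PhenotypeTable(frame, new_schema)


def write_table(
    table: PhenotypeTable,
    path,
    *,
    id_column: str = "accession",
    sep: str = ",",
    missing_token: str = "NA",
    float_format: str = "%g",
) -> None:
    """Write a phenotype table as delimited text (RFC-4180 quoting for CSV)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow([id_column, *table.schema.names])
        for acc in table.accession_ids:
            row = [acc]
            for spec in table.schema:
                v = table.data.at[acc, spec.name]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    row.append(missing_token)
                elif spec.is_quantitative:
                    row.append(float_format % v)
                else:
                    row.append(v)
            writer.writerow(row)


def unstack_records(
    records: Iterable[tuple[str, str, object]],
    schema: TraitSchema,
) -> PhenotypeTable:
    """Pivot long-format (accession, trait, value) records into a table.

    Absent (accession, trait) pairs become missing cells; two records for
    the same pair with conflicting values raise ``ValueError``.
    """
    cells: dict[tuple[str, str], object] = {}
    ids: list[str] = []
    for acc, trait, value in records:
        if trait not in schema:
            raise ValueError(f"record references unknown trait {trait!r}")
        key = (acc, trait)
        if key in cells:
            if cells[key] != value:
                raise ValueError(
                    f"conflicting duplicate record for accession {acc!r}, "
                    f"trait {trait!r}: {cells[key]!r} vs {value!r}"
                )
            continue
        cells[key] = value
        if acc not in ids:
            ids.append(acc)
    if not ids:
        raise ValueError("no records given")
    data = {
        spec.name: [
            cells.get((acc, spec.name), np.nan if spec.is_quantitative else None)
            for acc in ids
        ]
        for spec in schema
    }
    frame = pd.DataFrame(data, index=pd.Index(ids, name="accession"))
    return PhenotypeTable(frame, schema)


def _row_key(table: PhenotypeTable, acc: str) -> tuple:
    """Hashable exact-value signature of one accession (missingness included)."""
    key = []
    for spec in table.schema:
        v = table.data.at[acc, spec.name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            key.append(("NA",))
        else:
            key.append(v)
    return tuple(key)


def remove_redundant_accessions(
    table: PhenotypeTable, seed: int = 0
) -> tuple[PhenotypeTable, CleaningLog]:
    """Collapse groups of identically redundant accessions to one member.

    Accessions whose value vectors are exactly equal across *all* traits
    (including the pattern of missing cells) form a redundancy group; one
    member per group is retained, chosen by a seeded uniform draw so the
    operation is reproducible. Idempotent: a table without identical rows
    is returned unchanged with an empty log.
    """
    groups: dict[tuple, list[str]] = {}
    for acc in table.accession_ids:
        groups.setdefault(_row_key(table, acc), []).append(acc)

    rng = np.random.default_rng(seed)
    log = CleaningLog(n_before=table.n)
    keep: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            keep.add(members[0])
            continue
        kept = members[int(rng.integers(len(members)))]
        keep.add(kept)
        log.removed_redundant.append(
            (kept, [m for m in members if m != kept])
        )
    retained = [a for a in table.accession_ids if a in keep]
    log.n_after = len(retained)
    return table.subset_accessions(retained), log


def filter_traits_by_missing_rate(
    table: PhenotypeTable, threshold: float = 0.30
) -> tuple[PhenotypeTable, CleaningLog]:
    """Drop traits whose missing fraction reaches ``threshold``.

    The comparison is strict: a trait is retained iff its missing rate is
    < threshold, so at the default 0.30 a trait missing exactly 30% of its
    cells is dropped while one at 26.5% survives.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    log = CleaningLog(n_before=table.n, n_after=table.n)
    survivors = []
    for spec in table.schema:
        rate = table.missing_rate(spec.name)
        if rate < threshold:
            survivors.append(spec.name)
        else:
            log.dropped_traits.append((spec.name, rate))
    if not survivors:
        raise ValueError("all traits exceed the missing-rate threshold")
    return table.subset_traits(survivors), log
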