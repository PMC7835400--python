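"""Modified Roger's distance for mixed quantitative-qualitative phenotypes.

The squared distance between accessions i and i* decomposes into a
quantitative and a qualitative part,

    d^2 = d^2_Eul + d^2_mR,

where d^2_Eul sums (x_ij - x_i*j)^2 over quantitative traits j, and the
qualitative part contributes, per trait, 0 when the two accessions share
the level and (ln f_ij - ln f_i*j)^2 when they differ, with f the relative
level frequency over the whole collection. Traits where either accession
is missing are skipped (pairwise-complete). Quantitative traits are
z-standardised by default so that traits on large measurement scales do
not swamp the log-frequency term; ``scaling="raw"`` evaluates the literal
formula.

Note an inherent quirk of the formula: two different levels that happen to
have equal frequency contribute 0 for that trait, exactly as two equal
levels do. It is implemented literally, not corrected.

On complete cases sqrt(d^2) is a pseudometric (each per-trait term is, and
the Euclidean combination preserves it). Pairwise deletion of missing
cells can break the triangle inequality, since different pairs may be
compared on different trait subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import PhenotypeTable


@dataclass(frozen=True)
class FrequencyTable:
    """Per qualitative trait: level -> relative frequency among observed."""

    freqs: dict[str, dict[str, float]]

    def __getitem__(self, trait: str) -> dict[str, float]:
        return self.freqs[trait]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of squared modified Roger's distances."""

    ids: list[str]
    d2: np.ndarray
    scaling: str = "zscore"

    def __post_init__(self) -> None:
        self.d2 = np.asarray(self.d2, dtype=float)
        n = len(self.ids)
        if self.d2.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d2[i, j])

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(a) for a in ids]
        return DistanceMatrix(list(ids), self.d2[np.ix_(idx, idx)], self.scaling)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d2, index=self.ids, columns=self.ids)


def level_frequencies(table: PhenotypeTable) -> FrequencyTable:
    """Relative level frequencies per qualitative trait over observed cells."""
    freqs: dict[str, dict[str, float]] = {}
    for name in table.schema.qualitative:
        observed = table.data[name].dropna()
        if observed.empty:
            raise ValueError(f"qualitative trait {name!r} has no observed values")
        counts = observed.value_counts()
        total = int(counts.sum())
        freqs[name] = {lv: c / total for lv, c in counts.items()}
    return FrequencyTable(freqs)


def _scaled_quant(table: PhenotypeTable, scaling: str) -> pd.DataFrame:
    quants = table.data[table.schema.quantitative].astype(float)
    if scaling == "raw":
        return quants
    if scaling != "zscore":
        raise ValueError(f"unknown scaling {scaling!r}")
    mu = quants.mean()
    sd = quants.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant trait contributes 0 everywhere
    return (quants - mu) / sd


def pair_distance(
    i: str,
    i_star: str,
    table: PhenotypeTable,
    freqs: FrequencyTable | None = None,
    scaling: str = "zscore",
) -> float:
    """Squared modified Roger's distance between two accessions."""
    if freqs is None:
        freqs = level_frequencies(table)
    quants = _scaled_quant(table, scaling)
    d2 = 0.0
    for name in table.schema.quantitative:
        a, b = quants.at[i, name], quants.at[i_star, name]
        if np.isnan(a) or np.isnan(b):
            continue
        d2 += (a - b) ** 2
    for name in table.schema.qualitative:
        a, b = table.data.at[i, name], table.data.at[i_star, name]
        if a is None or b is None:
            continue
        if a != b:
            f = freqs[name]
            d2 += (np.log(f[a]) - np.log(f[b])) ** 2
    return float(d2)


def distance_matrix(
    table: PhenotypeTable, scaling: str = "zscore"
) -> DistanceMatrix:
    """Full symmetric matrix of pairwise squared distances.

    Level frequencies are computed once over the whole collection;
    missing cells are skipped pairwise. Vectorised per trait.
    """
    if table.n < 2:
        raise ValueError("need at least two accessions")
    n = table.n
    d2 = np.zeros((n, n))
    freqs = level_frequencies(table)

    quants = _scaled_quant(table, scaling)
    for name in table.schema.quantitative:
        x = quants[name].to_numpy()
        diff2 = (x[:, None] - x[None, :]) ** 2
        d2 += np.nan_to_num(diff2, nan=0.0)

    for name in table.schema.qualitative:
        col = table.data[name]
        observed = col.notna().to_numpy()
        lf = np.array(
            [np.log(freqs[name][v]) if v is not None else np.nan for v in col]
        )
        levels = col.where(col.notna(), "\0MISSING").to_numpy(dtype=object)
        differ = (levels[:, None] != levels[None, :]) & np.outer(observed, observed)
        contrib = (lf[:, None] - lf[None, :]) ** 2
        d2 += np.where(differ, np.nan_to_num(contrib, nan=0.0), 0.0)

    return DistanceMatrix(table.accession_ids, d2, scaling)


def write_matrix(dist: DistanceMatrix, path, fmt: str = "csv") -> None:
    """Write a square matrix as CSV (header = accession ids) or PHYLIP."""
    if fmt == "csv":
        dist.to_frame().to_csv(path, index_label="accession")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{dist.n}\n")
            for i, acc in enumerate(dist.ids):
                row = " ".join(f"{v:.6f}" for v in np.sqrt(dist.d2[i]))
                fh.write(f"{acc[:10]:<10} {row}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
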