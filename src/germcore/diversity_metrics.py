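"""Shannon-Weaver and Nei diversity indices over trait classes.

Both indices score how evenly the accessions of a collection spread over
the classes of a trait — the observed levels of a qualitative trait, or
the occupancy of per-trait clusters for a quantitative one. The
Shannon-Weaver index used here is the entropy of the class proportions
normalised by ln S, so it lies in [0, 1] with 1 for a perfectly even
spread; Nei's index is the gene-diversity analogue 1 - sum(p_i^2), bounded
by 1 - 1/S. Only classes actually present in the scored collection count
toward S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import PhenotypeTable


@dataclass(frozen=True)
class DiversityRecord:
    trait: str
    collection: str  # "EC" or "CC"
    S: int
    class_counts: tuple[int, ...]
    H_prime: float
    nei: float


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    return c / c.sum()


def shannon(counts) -> float:
    """Normalised Shannon-Weaver index H' = -sum(p ln p) / ln S in [0, 1].

    S is the number of classes with nonzero count; a single occupied class
    gives 0 by the defined limit.
    """
    p = _proportions(counts)
    if p.size == 1:
        return 0.0
    return float(-(p * np.log(p)).sum() / np.log(p.size))


def nei(counts) -> float:
    """Nei's diversity index 1 - sum(p_i^2), in [0, 1 - 1/S]."""
    p = _proportions(counts)
    return float(1.0 - (p**2).sum())


def trait_class_counts(
    table: PhenotypeTable,
    trait: str,
    clustering=None,
) -> list[int]:
    """Class occupancy counts for one trait in one collection.

    Qualitative traits count observed levels (missing cells excluded);
    quantitative traits need a fitted per-trait clustering (see
    :func:`germcore.mixed_kmeans.cluster_single_trait`) and count
    accessions per cluster. Zero-count classes are dropped.
    """
    if trait not in table.schema:
        raise KeyError(trait)
    spec = table.schema[trait]
    if spec.is_qualitative:
        observed = table.data[trait].dropna()
        if observed.empty:
            raise ValueError(f"trait {trait!r} fully missing in this collection")
        order = list(spec.levels) or list(dict.fromkeys(observed))
        counts = observed.value_counts()
        return [int(counts[lv]) for lv in order if counts.get(lv, 0) > 0]
    if clustering is None:
        raise ValueError(
            f"quantitative trait {trait!r} needs a per-trait clustering"
        )
    assign = clustering.assign(table, trait)
    counts = pd.Series(assign).value_counts()
    return [int(v) for v in counts.sort_index().values if v > 0]


def diversity_record(
    table: PhenotypeTable, trait: str, collection: str, clustering=None
) -> DiversityRecord:
    counts = trait_class_counts(table, trait, clustering)
    return DiversityRecord(
        trait=trait,
        collection=collection,
        S=len(counts),
        class_counts=tuple(counts),
        H_prime=shannon(counts),
        nei=nei(counts),
    )


def diversity_table(
    ec: PhenotypeTable,
    cc: PhenotypeTable,
    clusterings: dict | None = None,
) -> pd.DataFrame:
    """Per-trait EC/CC class counts and indices, one row per trait.

    ``clusterings`` maps quantitative trait name -> fitted per-trait
    cluster model (fit on the EC; CC members are assigned to the EC
    clusters so the two collections are scored on the same partition).
    Columns mirror the usual diversity-comparison report: k_EC, H'_EC,
    Nei_EC, k_CC, H'_CC, Nei_CC.
    """
    clusterings = clusterings or {}
    rows = []
    for spec in ec.schema:
        model = clusterings.get(spec.name)
        if spec.is_quantitative and model is None:
            continue
        r_ec = diversity_record(ec, spec.name, "EC", model)
        r_cc = diversity_record(cc, spec.name, "CC", model)
        rows.append(
            {
                "trait": spec.name,
                "kind": spec.kind,
                "k_EC": r_ec.S,
                "H_EC": round(r_ec.H_prime, 2),
                "Nei_EC": round(r_ec.nei, 2),
                "k_CC": r_cc.S,
                "H_CC": round(r_cc.H_prime, 2),
                "Nei_CC": round(r_cc.nei, 2),
            }
        )
    return pd.DataFrame(rows)
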