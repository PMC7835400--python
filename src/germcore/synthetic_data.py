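"""Seeded generator of mixed-type germplasm phenotype tables.

Emulates the structure of a curated vegetable-soybean style germplasm
collection: a couple of hundred accessions scored on a mix of quantitative
traits (lengths, weights, rates on disparate scales, several of them
skewed) and qualitative traits (2-5 level categorical descriptors), with
a planted cluster structure, a handful of byte-identical duplicated
passport entries, and up to 30% missing cells under an MCAR or MAR
mechanism. Ground truth (labels, duplicate pairs, masked values) is
returned alongside so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import (
    QUALITATIVE,
    QUANTITATIVE,
    PhenotypeTable,
    TraitSchema,
    TraitSpec,
)

_LEVEL_ALPHABET = "ABCDEFGH"

#: hard validity bound on the missing rate; chained-equation imputation is
#: only trusted up to slight-to-mild missingness
MAX_MISSING_RATE = 0.30


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror a raw collection of 213 accessions scored on
    15 quantitative + 14 qualitative traits with 9 latent clusters and
    13 duplicated accession pairs; per-trait missing rates in the source
    material ranged from none to mild, so the default overall rate is 0.15.
    ``cluster_separation`` is the between-cluster mean shift expressed in
    within-cluster standard deviation units.
    """

    n_accessions: int = 213
    n_quant: int = 15
    n_qual: int = 14
    n_clusters: int = 9
    cluster_separation: float = 3.0
    level_counts: Sequence[int] | None = None
    skewness: Sequence[bool] | None = None
    missing_rate: float = 0.15
    missing_mechanism: str = "MCAR"
    n_redundant_pairs: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_redundant_pairs > self.n_accessions // 2:
            raise ValueError("n_redundant_pairs exceeds floor(n_accessions/2)")
        if not (0 <= self.missing_rate <= MAX_MISSING_RATE):
            raise ValueError(f"missing_rate must be in [0, {MAX_MISSING_RATE}]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be MCAR or MAR")
        n_unique = self.n_accessions - self.n_redundant_pairs
        if self.n_clusters > n_unique:
            raise ValueError("more clusters than unique accessions")
        if self.n_clusters < 1 or self.n_quant + self.n_qual < 1:
            raise ValueError("need at least one cluster and one trait")
        if self.level_counts is None:
            # 2-5 levels, cycled, like typical categorical descriptors
            self.level_counts = [2 + i % 4 for i in range(self.n_qual)]
        if len(self.level_counts) != self.n_qual:
            raise ValueError("level_counts length must equal n_qual")
        if self.skewness is None:
            # roughly a third of quantitative traits skewed
            self.skewness = [i % 3 == 0 for i in range(self.n_quant)]
        if len(list(self.skewness)) != self.n_quant:
            raise ValueError("skewness length must equal n_quant")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    cluster_labels: dict[str, int] = field(default_factory=dict)
    true_centroids: dict = field(default_factory=dict)
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)
    masked_cells: list[tuple[str, str, object]] = field(default_factory=list)


def _make_schema(config: SimulationConfig) -> TraitSchema:
    traits = [
        TraitSpec(f"q{j + 1:02d}", QUANTITATIVE, units="au")
        for j in range(config.n_quant)
    ]
    traits += [
        TraitSpec(
            f"c{j + 1:02d}",
            QUALITATIVE,
            levels=tuple(_LEVEL_ALPHABET[:k]),
        )
        for j, k in enumerate(config.level_counts)
    ]
    return TraitSchema(tuple(traits))


def generate_germplasm(
    config: SimulationConfig,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw a fully observed mixed-type table with planted structure.

    Quantitative traits are drawn per cluster from a normal (or, for
    skew-flagged traits, a mirrored log-normal with most values high and a
    tail of extreme low values) whose cluster means are separated by
    ``cluster_separation`` within-cluster SDs. Each qualitative trait gives
    every cluster a preferred level carrying probability ~0.6, with the
    remainder spread by Dirichlet noise. Redundant pairs are appended as
    byte-identical copies of existing accessions. Apply
    :func:`inject_missing` afterwards to mask cells.
    """
    rng = np.random.default_rng(config.seed)
    schema = _make_schema(config)
    n_unique = config.n_accessions - config.n_redundant_pairs
    k = config.n_clusters

    labels = rng.integers(k, size=n_unique)
    # guarantee every cluster non-empty
    labels[rng.permutation(n_unique)[:k]] = np.arange(k)

    truth = GroundTruth()
    data: dict[str, np.ndarray | list] = {}
    centroids: dict[str, object] = {}

    for j in range(config.n_quant):
        name = f"q{j + 1:02d}"
        # equally spaced, randomly permuted centers: adjacent clusters are
        # cluster_separation within-SD units apart in every trait
        centers = (rng.permutation(k) - (k - 1) / 2) * config.cluster_separation
        base = rng.normal(centers[labels], 1.0)
        if list(config.skewness)[j]:
            # mirrored log-normal: bulk high, few extreme low values
            base = centers[labels] - (rng.lognormal(0.0, 0.7, size=n_unique) - 1.0)
        scale = 10.0 ** rng.integers(0, 3)  # disparate measurement scales
        offset = rng.uniform(5, 50)
        data[name] = np.round(base * scale + offset * scale, 4)
        centroids[name] = (centers * scale + offset * scale).tolist()

    for j, n_levels in enumerate(config.level_counts):
        name = f"c{j + 1:02d}"
        levels = list(_LEVEL_ALPHABET[:n_levels])
        probs = np.empty((k, n_levels))
        for c in range(k):
            preferred = int(rng.integers(n_levels))
            p = rng.dirichlet(np.ones(n_levels)) * 0.4
            p[preferred] += 0.6
            probs[c] = p / p.sum()
        draws = [
            levels[rng.choice(n_levels, p=probs[labels[i]])]
            for i in range(n_unique)
        ]
        data[name] = draws
        centroids[name] = {
            f"cluster_{c + 1}": dict(zip(levels, probs[c].round(6).tolist()))
            for c in range(k)
        }

    ids = [f"ACC{i + 1:04d}" for i in range(n_unique)]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="accession"))

    unique_table = PhenotypeTable(frame, schema)
    if config.missing_rate > 0:
        # mask the unique accessions first so that duplicated passport
        # records share the missingness pattern of their source and stay
        # byte-identical, as real duplicated records do
        unique_table, mask_truth = inject_missing(
            unique_table,
            config.missing_rate,
            config.missing_mechanism,
            seed=int(rng.integers(2**31)),
        )
        truth.masked_cells = mask_truth.masked_cells
    frame = unique_table.data

    # append byte-identical duplicates of distinct source accessions
    sources = rng.choice(n_unique, size=config.n_redundant_pairs, replace=False)
    for d, src in enumerate(sources):
        dup_id = f"DUP{d + 1:04d}"
        frame.loc[dup_id] = frame.iloc[src]
        truth.redundant_pairs.append((ids[src], dup_id))
        truth.cluster_labels[dup_id] = int(labels[src]) + 1
        for acc, trait, value in list(truth.masked_cells):
            if acc == ids[src]:
                truth.masked_cells.append((dup_id, trait, value))

    truth.cluster_labels.update(
        {acc: int(lab) + 1 for acc, lab in zip(ids, labels)}
    )
    truth.true_centroids = centroids
    return PhenotypeTable(frame, schema), truth


def inject_missing(
    table: PhenotypeTable,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Mask cells of a fully observed table at a target per-trait rate.

    MCAR masks uniformly at random within each trait. MAR ties the masking
    probability to the quartile of a designated fully observed covariate
    (the first quantitative trait, which is never masked): accessions in
    higher quartiles are progressively more likely to have other traits
    missing, with quartile weights 0.4/0.8/1.2/1.6 x ``rate`` so the
    overall per-trait rate is preserved in expectation.
    """
    if not (0 <= rate <= MAX_MISSING_RATE):
        raise ValueError(
            f"missing rate {rate} outside the validity bound "
            f"[0, {MAX_MISSING_RATE}]"
        )
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be MCAR or MAR")
    out = table.copy()
    truth = GroundTruth()
    if rate == 0:
        return out, truth
    rng = np.random.default_rng(seed)

    covariate = None
    maskable = list(table.schema.names)
    if mechanism == "MAR":
        quants = table.schema.quantitative
        if not quants:
            raise ValueError("MAR mechanism needs a quantitative covariate")
        covariate = quants[0]
        maskable.remove(covariate)
        ranks = table.data[covariate].rank(method="first")
        quartile = pd.qcut(ranks, 4, labels=False).to_numpy()
        probs = rate * np.array([0.4, 0.8, 1.2, 1.6])[quartile]
    else:
        probs = np.full(table.n, rate)

    for spec in table.schema:
        if spec.name == covariate:
            continue
        if np.asarray(table.data[spec.name].isna()).any():
            raise ValueError(
                f"trait {spec.name!r} already has missing cells at masked "
                "positions; inject_missing expects a fully observed table"
            )
        mask = rng.random(table.n) < probs
        for acc, hit in zip(table.accession_ids, mask):
            if hit:
                truth.masked_cells.append(
                    (acc, spec.name, table.data.at[acc, spec.name])
                )
                out.data.at[acc, spec.name] = (
                    np.nan if spec.is_quantitative else None
                )
    return PhenotypeTable(out.data, out.schema), truth
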