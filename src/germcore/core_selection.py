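"""Core-subset selection: maximal-distance samplers plus SRS/SPS comparators.

The core collection is the subset of accessions with maximal pairwise
distance. Exact subset maximisation is NP-hard, so the default sampler is
the standard greedy maximin (farthest-point) traversal: start from the
globally farthest pair, then repeatedly add the accession whose minimum
distance to the already-selected set is largest. A greedy max-sum variant
and the two classical comparison samplers — simple random sampling (SRS)
and stratified proportional sampling (SPS, largest-remainder quotas per
cluster) — are provided for benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mixed_kmeans import ClusterModel
from .mrd_distance import DistanceMatrix
from .schema import PhenotypeTable

DEFAULT_FRACTION = 0.15  # core size as a fraction of the collection


@dataclass
class CoreSet:
    """An ordered core subset with its per-step selection trace."""

    selected_ids: list[str]
    method: str
    k: int
    seed: int = 0
    trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.selected_ids) != self.k:
            raise ValueError("|selected_ids| must equal k")
        if len(set(self.selected_ids)) != self.k:
            raise ValueError("selected ids must be unique")


def default_core_size(n: int, fraction: float = DEFAULT_FRACTION) -> int:
    """Core size as ceil(fraction * n); 15% by default (30 of 200)."""
    return math.ceil(fraction * n)


def _id_ranks(ids: list[str]) -> np.ndarray:
    order = np.argsort(ids, kind="stable")
    rank = np.empty(len(ids), dtype=int)
    rank[order] = np.arange(len(ids))
    return rank


def _greedy_maximin(
    d: np.ndarray, rank: np.ndarray, k: int, start: tuple[int, int]
) -> list[int]:
    """Farthest-point traversal from a given starting pair."""
    n = d.shape[0]
    selected = list(start)
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < k:
        sub = d[np.ix_(remaining, selected)]
        min_d = sub.min(axis=1)
        sum_d = sub.sum(axis=1)
        keys = list(zip(min_d, sum_d, [-rank[i] for i in remaining]))
        pick = max(range(len(remaining)), key=lambda t: keys[t])
        selected.append(remaining.pop(pick))
    return selected


def _subset_key(d: np.ndarray, sel: list[int]) -> tuple[float, float]:
    sub = d[np.ix_(sel, sel)]
    iu = np.triu_indices(len(sel), 1)
    return float(sub[iu].min()), float(sub[iu].sum())


def _swap_refine(d: np.ndarray, sel: list[int], rank: np.ndarray) -> list[int]:
    """Deterministic local exchange maximising (min, sum) pairwise distance."""
    sel = list(sel)
    k = len(sel)
    n = d.shape[0]
    while True:
        rest = [i for i in range(n) if i not in sel]
        if not rest:
            return sel
        cur = _subset_key(d, sel)
        sub = d[np.ix_(sel, sel)]
        np.fill_diagonal(sub, np.inf)
        pair_sum_total = (sub[sub != np.inf]).sum() / 2
        M = d[np.ix_(rest, sel)]  # |rest| x k
        best_swap, best_key = None, cur
        for o in range(k):
            keep = [q for q in range(k) if q != o]
            inner = sub[np.ix_(keep, keep)]
            m1 = float(inner.min()) if k > 2 else np.inf
            s1 = pair_sum_total - float(np.where(np.isfinite(sub[o]), sub[o], 0).sum())
            m2 = M[:, keep].min(axis=1)
            s2 = M[:, keep].sum(axis=1)
            new_min = np.minimum(m1, m2)
            for r_idx, r in enumerate(rest):
                key = (float(new_min[r_idx]), s1 + float(s2[r_idx]))
                if key > best_key or (
                    key == best_key
                    and best_swap is not None
                    and rank[r] < rank[best_swap[1]]
                ):
                    if key > cur:
                        best_key, best_swap = key, (o, r)
        if best_swap is None:
            return sel
        o, r = best_swap
        sel = [s for q, s in enumerate(sel) if q != o] + [r]


def _farthest_point_trace(
    d: np.ndarray, rank: np.ndarray, sel: list[int], ids: list[str]
) -> tuple[list[int], list[tuple[str, float]]]:
    """Order a fixed subset by farthest-point traversal; insertion values
    are non-increasing after the seed pair."""
    sub_rank = rank[sel]
    sub = d[np.ix_(sel, sel)]
    kk = len(sel)
    best_pair, best_key = None, None
    for i in range(kk):
        for j in range(i + 1, kk):
            a, b = sorted((i, j), key=lambda t: sub_rank[t])
            key = (sub[i, j], sub[i].sum() + sub[j].sum(), -sub_rank[a], -sub_rank[b])
            if best_key is None or key > best_key:
                best_key, best_pair = key, (a, b)
    order = list(best_pair)
    trace = [
        (ids[sel[best_pair[0]]], float(best_key[0])),
        (ids[sel[best_pair[1]]], float(best_key[0])),
    ]
    remaining = [i for i in range(kk) if i not in order]
    while remaining:
        msub = sub[np.ix_(remaining, order)]
        min_d = msub.min(axis=1)
        sum_d = msub.sum(axis=1)
        keys = list(zip(min_d, sum_d, [-sub_rank[i] for i in remaining]))
        pick = max(range(len(remaining)), key=lambda t: keys[t])
        chosen = remaining.pop(pick)
        order.append(chosen)
        trace.append((ids[sel[chosen]], float(min_d[pick])))
    return [sel[i] for i in order], trace


def select_maximin(
    dist: DistanceMatrix,
    k: int,
    seed: int = 0,
    n_starts: int | None = None,
    refine: bool = True,
) -> CoreSet:
    """Maximally distant core: maximise the minimum pairwise distance.

    Deterministic farthest-point traversal — start from the globally
    farthest pair (ties by larger distance sum, then id order), then
    repeatedly add the accession with the largest minimum distance to the
    selected set (ties by larger distance sum, then id order). Because a
    single greedy pass can land well short of the best subset, the
    traversal is restarted from the ``n_starts`` farthest pairs (all
    pairs when n <= 40) and each candidate set is polished by a
    deterministic local exchange that swaps a member for an outsider
    whenever that raises the (min, sum) pairwise-distance pair. The
    reported trace re-orders the winning subset by farthest-point
    insertion, so its criterion values are non-increasing after step 2.
    """
    n = dist.n
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    d = dist.d2
    rank = _id_ranks(dist.ids)

    # rank all pairs by (distance, distance sums, id order)
    iu = np.triu_indices(n, 1)
    pair_keys = sorted(
        (
            (
                d[i, j],
                d[i].sum() + d[j].sum(),
                -min(rank[i], rank[j]),
                -max(rank[i], rank[j]),
                (i, j),
            )
            for i, j in zip(*iu)
        ),
        reverse=True,
    )
    if n_starts is None:
        n_starts = len(pair_keys) if n <= 40 else 20
    starts = [pk[-1] for pk in pair_keys[: max(1, n_starts)]]

    best_sel, best_key = None, None
    for start in starts:
        sel = _greedy_maximin(d, rank, k, start)
        if refine and k < n:
            sel = _swap_refine(d, sel, rank)
        key = _subset_key(d, sel)
        if best_key is None or key > best_key:
            best_key, best_sel = key, sel

    ordered, trace = _farthest_point_trace(d, rank, best_sel, dist.ids)
    return CoreSet(
        selected_ids=[dist.ids[i] for i in ordered],
        method="maximin",
        k=k,
        seed=seed,
        trace=trace,
    )


def select_maxsum(dist: DistanceMatrix, k: int, seed: int = 0) -> CoreSet:
    """Greedy variant maximising the sum of distances to the selected set."""
    n = dist.n
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    d = dist.d2
    order = np.argsort(dist.ids, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    best_pair, best_key = None, None
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((i, j), key=lambda t: rank[t])
            key = (d[i, j], -rank[a], -rank[b])
            if best_key is None or key > best_key:
                best_key, best_pair = key, (a, b)
    selected = list(best_pair)
    trace = [
        (dist.ids[best_pair[0]], float(best_key[0])),
        (dist.ids[best_pair[1]], float(best_key[0])),
    ]
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < k:
        sub = d[np.ix_(remaining, selected)]
        sum_d = sub.sum(axis=1)
        keys = list(zip(sum_d, [-rank[i] for i in remaining]))
        pick = max(range(len(remaining)), key=lambda t: keys[t])
        chosen = remaining.pop(pick)
        selected.append(chosen)
        trace.append((dist.ids[chosen], float(sum_d[pick])))
    return CoreSet(
        selected_ids=[dist.ids[i] for i in selected],
        method="maxsum",
        k=k,
        seed=seed,
        trace=trace,
    )


def select_srs(table: PhenotypeTable, k: int, seed: int = 0) -> CoreSet:
    """Simple random sample of k accessions without replacement."""
    if k > table.n:
        raise ValueError("k exceeds collection size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n, size=k, replace=False)
    ids = [table.accession_ids[i] for i in sorted(idx)]
    return CoreSet(
        selected_ids=ids,
        method="srs",
        k=k,
        seed=seed,
        trace=[(a, float("nan")) for a in ids],
    )


def largest_remainder_quotas(sizes, k: int) -> list[int]:
    """Apportion k slots over strata proportionally (largest remainder).

    Leftover slots go to the strata with the largest fractional
    remainders; exact remainder ties favour the smaller stratum (so a
    150/50 split of k=30, remainders 0.5/0.5, yields quotas 22/8).
    """
    sizes = np.asarray(sizes, dtype=float)
    exact = k * sizes / sizes.sum()
    quotas = np.floor(exact).astype(int)
    remainders = exact - quotas
    order = sorted(
        range(len(sizes)), key=lambda i: (-remainders[i], sizes[i], i)
    )
    for i in order[: k - quotas.sum()]:
        quotas[i] += 1
    return quotas.tolist()


def select_sps(
    table: PhenotypeTable, clusters: ClusterModel, k: int, seed: int = 0
) -> CoreSet:
    """Stratified proportional sampling: per-cluster quotas, SRS within.

    Quotas follow largest-remainder apportionment of k by cluster size;
    with many small clusters some may receive quota 0.
    """
    if k > table.n:
        raise ValueError("k exceeds collection size")
    if set(clusters.ids) < set(table.accession_ids):
        raise ValueError("cluster model does not cover all accessions")
    labels = {acc: lab for acc, lab in zip(clusters.ids, clusters.labels)}
    strata: dict[int, list[str]] = {}
    for acc in table.accession_ids:
        strata.setdefault(int(labels[acc]), []).append(acc)
    keys = sorted(strata)
    quotas = largest_remainder_quotas([len(strata[c]) for c in keys], k)
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    for c, q in zip(keys, quotas):
        members = strata[c]
        take = rng.choice(len(members), size=q, replace=False)
        ids.extend(members[i] for i in sorted(take))
    return CoreSet(
        selected_ids=ids,
        method="sps",
        k=k,
        seed=seed,
        trace=[(a, float("nan")) for a in ids],
    )
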