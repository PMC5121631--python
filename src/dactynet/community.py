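"""Community dissimilarity, NMDS ordination and PERMANOVA.

Mycorrhizal communities are compared between orchid species (or samples)
with Bray–Curtis or Jaccard dissimilarities, visualised by non-metric
multidimensional scaling (Kruskal stress-1, isotonic regression of fitted
distances on observed dissimilarity ranks), and tested for group structure
with a permutational multivariate analysis of variance on the distance
matrix (pseudo-F, label-permutation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .data_model import DataValidationError, DistanceMatrix, OtuTable, SampleMetadata

__all__ = [
    "NmdsResult",
    "PermanovaResult",
    "aggregate_by_group",
    "aggregate_by_species",
    "dissimilarity",
    "kruskal_stress",
    "nmds",
    "permanova",
]


@dataclass
class NmdsResult:
    """Best-of-restarts NMDS embedding with its Kruskal stress-1."""

    ids: list[str]
    coordinates: np.ndarray  # (n, k), centered at the origin
    stress: float
    n_restarts_used: int
    converged: bool


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int


def aggregate_by_group(
    table: OtuTable,
    meta: Sequence[SampleMetadata],
    attr: str = "species",
    mode: str = "presence",
) -> OtuTable:
    """Collapse samples to one row per group (``species`` or ``population_id``).

    ``presence`` yields 0/1 incidence; ``summed_counts`` sums the reads of
    the group's samples. Group order follows first appearance in metadata.
    """
    if mode not in ("presence", "summed_counts"):
        raise ValueError("mode must be 'presence' or 'summed_counts'")
    if attr not in ("species", "population_id"):
        raise ValueError("attr must be 'species' or 'population_id'")
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for m in meta:
        if m.sample_id in pos:
            g = getattr(m, attr)
            if g not in members:
                members[g] = []
                order.append(g)
            members[g].append(pos[m.sample_id])
    rows = np.zeros((len(order), table.n_otus), dtype=np.int64)
    for i, g in enumerate(order):
        summed = table.counts[members[g], :].sum(axis=0)
        rows[i] = (summed >= 1).astype(np.int64) if mode == "presence" else summed
    return OtuTable(order, list(table.otu_ids), rows)


def aggregate_by_species(
    table: OtuTable, meta: Sequence[SampleMetadata], mode: str = "presence"
) -> OtuTable:
    return aggregate_by_group(table, meta, attr="species", mode=mode)


def dissimilarity(table: OtuTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray–Curtis (on counts) or Jaccard (on presence) dissimilarity.

    Bray–Curtis d = 1 − 2·Σ min(x, y) / (Σx + Σy); Jaccard d = 1 − |A∩B|/|A∪B|.
    """
    if metric not in ("bray_curtis", "jaccard"):
        raise ValueError("metric must be 'bray_curtis' or 'jaccard'")
    if table.n_samples < 2:
        raise DataValidationError("need at least two rows for dissimilarity")
    totals = table.counts.sum(axis=1)
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise DataValidationError(f"all-zero rows: {empty[:5]}")
    if metric == "bray_curtis":
        cond = pdist(table.counts.astype(float), metric="braycurtis")
    else:
        cond = pdist(table.counts > 0, metric="jaccard")
    return DistanceMatrix(list(table.sample_ids), squareform(cond))


def kruskal_stress(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against observed dissimilarities.

    Disparities are the isotonic (weakly monotone) regression of embedded
    distances on dissimilarity ranks, primary treatment of ties: tied
    dissimilarities are pre-sorted by embedded distance so they may take
    distinct disparities.
    """
    dist = pdist(coords)
    order = np.lexsort((dist, dissim))
    iso = IsotonicRegression(increasing=True)
    dhat_sorted = iso.fit_transform(np.arange(len(dist)), dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = dhat_sorted
    denom = float(np.sum(dist**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS: minimise Kruskal stress-1, best of random restarts.

    Each restart runs non-metric SMACOF (majorisation with isotonic
    regression) from a random configuration; restarts use seeds spawned
    deterministically from ``seed``, so enlarging ``n_restarts`` only adds
    candidate solutions and the achieved stress is non-increasing.
    """
    n = d.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        raise ValueError(f"k={k} too large for n={n} points")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    dissim_cond = d.condensed()
    best = None
    ss = np.random.SeedSequence(0 if seed is None else seed)
    for r in range(n_restarts):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(r,))
        rs = np.random.RandomState(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        coords, _, n_iter = smacof(
            d.values,
            metric=False,
            n_components=k,
            init=None,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            random_state=rs,
            return_n_iter=True,
            normalized_stress=True,
        )
        stress = kruskal_stress(dissim_cond, coords)
        if best is None or stress < best[0] - 1e-15:
            best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    coords = coords - coords.mean(axis=0, keepdims=True)
    return NmdsResult(
        ids=list(d.ids),
        coordinates=coords,
        stress=stress,
        n_restarts_used=n_restarts,
        converged=n_iter < max_iter,
    )


def _ss_within_batch(D2: np.ndarray, labels: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """SS_within for each row of a (B, n) int label matrix."""
    ssw = np.zeros(labels.shape[0])
    for g in codes:
        mask = (labels == g).astype(float)
        n_g = mask.sum(axis=1)
        ssw += np.einsum("bi,ij,bj->b", mask, D2, mask) / (2.0 * n_g)
    return ssw


def permanova(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/n)·Σ_{i<j} d²_ij; SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij;
    pseudo-F = (SS_between/df_between)/(SS_within/df_within). The p-value is
    the add-one permutation tail (1 + #{F_perm ≥ F_obs})/(1 + B) under
    uniform relabelling.
    """
    missing = [i for i in d.ids if i not in groups]
    if missing:
        raise DataValidationError(f"no group for ids {missing[:5]}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    label_names = [groups[i] for i in d.ids]
    uniq = sorted(set(label_names))
    k = len(uniq)
    n = d.n
    if k < 2:
        raise DataValidationError("need at least two groups")
    if n <= k:
        raise DataValidationError("need more observations than groups")
    code = {g: c for c, g in enumerate(uniq)}
    labels = np.array([code[g] for g in label_names], dtype=np.int64)
    codes = np.arange(k)
    D2 = d.values**2
    ss_total = float(D2[np.triu_indices(n, k=1)].sum()) / n
    df_b, df_w = k - 1, n - k

    def f_of(lab: np.ndarray) -> np.ndarray:
        ssw = _ss_within_batch(D2, lab, codes)
        ssb = ss_total - ssw
        return (ssb / df_b) / (ssw / df_w)

    ssw_obs = _ss_within_batch(D2, labels[None, :], codes)[0]
    if ssw_obs <= 0.0:
        raise DataValidationError("SS_within is zero; pseudo-F undefined")
    f_obs = float((ss_total - ssw_obs) / df_b / (ssw_obs / df_w))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=np.int64)
    for b in range(n_permutations):
        perms[b] = labels[rng.permutation(n)]
    f_perm = f_of(perms)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        df_between=df_b,
        df_within=df_w,
        p_value=float(p),
        n_permutations=n_permutations,
    )
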