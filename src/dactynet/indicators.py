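"""Indicator-species analysis: IndVal over habitats and habitat combinations.

For a target site group g (a single habitat or a union of habitats) and one
OTU, the indicator value is IndVal = sqrt(A·B) with

* A (specificity): mean abundance of the OTU over the sites of g divided by
  the sum of group-mean abundances over the partition {g} ∪ {each habitat
  outside g}, following the group-combination extension of IndVal;
* B (fidelity): fraction of the sites of g where the OTU is present.

Each OTU is assigned the habitat combination maximising IndVal, and
significance is assessed by permuting site→habitat labels and recomputing
the per-OTU maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .data_model import DataValidationError, OtuTable

__all__ = [
    "IndicatorResult",
    "indval_components",
    "best_combination",
    "indicator_test",
    "benjamini_hochberg",
]


@dataclass
class IndicatorResult:
    otu_id: str
    best_group: frozenset[str]
    A: float
    B: float
    ind_val: float
    p_value: float | None = None

    @property
    def applicable(self) -> bool:
        return not np.isnan(self.A)


def _prepare(table: OtuTable, groups: Mapping[str, str], relative: bool):
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise DataValidationError(f"no habitat for sites {missing[:5]}")
    habitats = sorted({groups[s] for s in table.sample_ids})
    code = {h: c for c, h in enumerate(habitats)}
    labels = np.array([code[groups[s]] for s in table.sample_ids], dtype=np.int64)
    X = table.counts.astype(float)
    if relative:
        row_tot = X.sum(axis=1, keepdims=True)
        np.divide(X, row_tot, out=X, where=row_tot > 0)
    P = (table.counts > 0).astype(float)
    return habitats, labels, X, P


def _group_stats(labels: np.ndarray, k: int, X: np.ndarray, P: np.ndarray):
    """Per-habitat site counts, abundance sums and presence counts."""
    onehot = np.zeros((k, labels.shape[0]))
    onehot[labels, np.arange(labels.shape[0])] = 1.0
    n_g = onehot.sum(axis=1)  # (k,)
    sum_g = onehot @ X  # (k, O)
    pres_g = onehot @ P  # (k, O)
    return n_g, sum_g, pres_g


def _combo_indvals(
    n_g: np.ndarray,
    sum_g: np.ndarray,
    pres_g: np.ndarray,
    combos: Sequence[tuple[int, ...]],
):
    """(n_combos, O) arrays of A, B and IndVal for every habitat union."""
    k = n_g.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = sum_g / n_g[:, None]  # (k, O)
    total_mean = mean_g.sum(axis=0)  # (O,)
    A = np.empty((len(combos), sum_g.shape[1]))
    B = np.empty_like(A)
    for ci, combo in enumerate(combos):
        idx = list(combo)
        n_c = n_g[idx].sum()
        mean_c = sum_g[idx].sum(axis=0) / n_c
        out_idx = [g for g in range(k) if g not in combo]
        denom = mean_c + (mean_g[out_idx].sum(axis=0) if out_idx else 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            A[ci] = np.where(denom > 0, mean_c / denom, np.nan)
        B[ci] = pres_g[idx].sum(axis=0) / n_c
    ind = np.sqrt(np.where(np.isnan(A), 0.0, A) * B)
    ind = np.where(np.isnan(A), np.nan, ind)
    return A, B, ind


def _all_combos(k: int, max_order: int) -> list[tuple[int, ...]]:
    return [c for r in range(1, max_order + 1) for c in combinations(range(k), r)]


def indval_components(
    table: OtuTable,
    groups: Mapping[str, str],
    target: frozenset[str] | set[str],
    relative_abundance: bool = True,
) -> dict[str, tuple[float, float]]:
    """Per-OTU (A, B) for one target habitat (or union of habitats).

    OTUs absent from every site get ``A = nan`` (not applicable rather
    than zero).
    """
    habitats, labels, X, P = _prepare(table, groups, relative_abundance)
    target = frozenset(target)
    if not target:
        raise ValueError("target must be non-empty")
    if not target.issubset(habitats):
        raise ValueError(f"target {sorted(target)} not among habitats {habitats}")
    if target == set(habitats):
        raise ValueError("target must be a proper subset of the habitats")
    code = {h: c for c, h in enumerate(habitats)}
    combo = tuple(sorted(code[h] for h in target))
    n_g, sum_g, pres_g = _group_stats(labels, len(habitats), X, P)
    A, B, _ = _combo_indvals(n_g, sum_g, pres_g, [combo])
    return {o: (float(A[0, j]), float(B[0, j])) for j, o in enumerate(table.otu_ids)}


def best_combination(
    table: OtuTable,
    groups: Mapping[str, str],
    max_order: int | None = None,
    relative_abundance: bool = True,
) -> list[IndicatorResult]:
    """Per-OTU habitat union maximising IndVal (p-values unset).

    Unions of up to ``max_order`` habitats are scanned (default: all proper
    unions, k−1); ties are broken towards the smallest union, then
    lexicographically.
    """
    habitats, labels, X, P = _prepare(table, groups, relative_abundance)
    k = len(habitats)
    if k < 2:
        raise DataValidationError("need at least two habitats")
    if max_order is None:
        max_order = k - 1
    if not (1 <= max_order < k):
        raise ValueError("max_order must be in [1, n_habitats)")
    combos = _all_combos(k, max_order)
    n_g, sum_g, pres_g = _group_stats(labels, k, X, P)
    A, B, ind = _combo_indvals(n_g, sum_g, pres_g, combos)
    results = []
    for j, otu in enumerate(table.otu_ids):
        col = ind[:, j]
        if np.all(np.isnan(col)):
            results.append(
                IndicatorResult(otu, frozenset(), np.nan, np.nan, np.nan)
            )
            continue
        best_val = np.nanmax(col)
        cands = [
            ci for ci in range(len(combos)) if not np.isnan(col[ci])
            and col[ci] >= best_val - 1e-12
        ]
        ci = min(
            cands,
            key=lambda c: (len(combos[c]), tuple(sorted(habitats[g] for g in combos[c]))),
        )
        results.append(
            IndicatorResult(
                otu_id=otu,
                best_group=frozenset(habitats[g] for g in combos[ci]),
                A=float(A[ci, j]),
                B=float(B[ci, j]),
                ind_val=float(ind[ci, j]),
            )
        )
    return results


def indicator_test(
    table: OtuTable,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    max_order: int | None = None,
    relative_abundance: bool = True,
) -> list[IndicatorResult]:
    """Permutation test of the per-OTU best-combination IndVal.

    Site→habitat labels are permuted uniformly; for each permutation the
    per-OTU maximum IndVal over all habitat unions is recomputed, and
    p = (1 + #{IndVal_perm ≥ IndVal_obs}) / (1 + n_perm). OTUs with
    p ≤ alpha form the significant set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    habitats, labels, X, P = _prepare(table, groups, relative_abundance)
    k = len(habitats)
    if max_order is None:
        max_order = k - 1
    combos = _all_combos(k, max_order)
    observed = best_combination(
        table, groups, max_order=max_order, relative_abundance=relative_abundance
    )
    obs_val = np.array([r.ind_val for r in observed])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(table.n_otus)
    for _ in range(n_perm):
        perm = labels[rng.permutation(labels.shape[0])]
        n_g, sum_g, pres_g = _group_stats(perm, k, X, P)
        _, _, ind = _combo_indvals(n_g, sum_g, pres_g, combos)
        perm_max = np.nanmax(np.where(np.isnan(ind), -np.inf, ind), axis=0)
        exceed += perm_max >= obs_val - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    out = []
    for r, pj in zip(observed, p):
        pv = float(pj) if r.applicable else None
        out.append(
            IndicatorResult(r.otu_id, r.best_group, r.A, r.B, r.ind_val, p_value=pv)
        )
    return out


def benjamini_hochberg(results: Sequence[IndicatorResult]) -> dict[str, float]:
    """BH-adjusted p-values (optional; raw p-values are the default output)."""
    items = [(r.otu_id, r.p_value) for r in results if r.p_value is not None]
    if not items:
        return {}
    ids, ps = zip(*sorted(items, key=lambda kv: kv[1]))
    m = len(ps)
    adj = np.minimum.accumulate((np.array(ps) * m / np.arange(1, m + 1))[::-1])[::-1]
    return {i: float(min(a, 1.0)) for i, a in zip(ids, adj)}
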