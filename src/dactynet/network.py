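"""Bipartite orchid–fungus network: modularity, module detection, null model.

The network links orchid species (rows) to the fungal OTUs detected in their
roots (columns). Modules — groups of species *and* OTUs holding most of
their links inside the group — are found by maximising the modularity index

    M = Σ_s [ l_s / L − (d_s / 2L)² ]

over joint partitions of all nodes, where L is the number of links in the
network, l_s the number of links with both endpoints in module s, and d_s
the summed degree of module s. Maximisation uses simulated annealing
(single-node reassignments plus module merges and splits, worse moves
accepted with probability exp(ΔM/T)). Significance is assessed against
random networks with both degree sequences preserved exactly (checkerboard
swaps of 2×2 submatrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Set

import numpy as np
from numba import njit

from .data_model import DataValidationError

__all__ = [
    "BipartiteNetwork",
    "ModulePartition",
    "ModularitySignificance",
    "SASchedule",
    "build_network",
    "modularity",
    "detect_modules",
    "randomize",
    "significance",
]


def child_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 derived from (seed, key)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class BipartiteNetwork:
    """Binary species × OTU incidence with degree bookkeeping."""

    species_ids: list[str]
    otu_ids: list[str]
    incidence: np.ndarray  # (S, O) of 0/1

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2 or inc.shape != (len(self.species_ids), len(self.otu_ids)):
            raise DataValidationError("incidence shape does not match id lists")
        if not np.isin(inc, (0, 1)).all():
            raise DataValidationError("incidence must be binary")
        if set(self.species_ids) & set(self.otu_ids):
            raise DataValidationError("species and OTU ids must be disjoint")
        self.incidence = inc.astype(np.int8)

    @property
    def L(self) -> int:
        """Total number of links."""
        return int(self.incidence.sum())

    @property
    def node_ids(self) -> list[str]:
        """Joint node order: species first, then OTUs."""
        return list(self.species_ids) + list(self.otu_ids)

    @property
    def degrees(self) -> dict[str, int]:
        sp = self.incidence.sum(axis=1)
        ot = self.incidence.sum(axis=0)
        out = {s: int(k) for s, k in zip(self.species_ids, sp)}
        out.update({o: int(k) for o, k in zip(self.otu_ids, ot)})
        return out

    def degree_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.incidence.sum(axis=1), self.incidence.sum(axis=0)

    def to_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Adjacency of the joint node set in CSR form (indptr, indices, deg)."""
        S, O = self.incidence.shape
        n = S + O
        deg = np.concatenate(self.degree_arrays()).astype(np.int64)
        indptr = np.zeros(n + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(deg)
        indices = np.empty(indptr[-1], dtype=np.int64)
        fill = indptr[:-1].copy()
        rows, cols = np.nonzero(self.incidence)
        for r, c in zip(rows, cols):
            u, v = r, S + c
            indices[fill[u]] = v
            fill[u] += 1
            indices[fill[v]] = u
            fill[v] += 1
        return indptr, indices, deg


def build_network(prevalence: Mapping[str, Set[str]]) -> BipartiteNetwork:
    """Build the binary species × OTU network from per-species OTU sets.

    Species with no OTUs are pruned with a warning; OTU order is
    lexicographic for determinism.
    """
    if not prevalence:
        raise DataValidationError("empty prevalence mapping")
    species = [sp for sp in prevalence if prevalence[sp]]
    dropped = [sp for sp in prevalence if not prevalence[sp]]
    if dropped:
        warnings.warn(f"pruning {len(dropped)} species with no OTUs: {dropped}")
    if not species:
        raise DataValidationError("no species with any OTU")
    otus = sorted(set().union(*(prevalence[sp] for sp in species)))
    col = {o: j for j, o in enumerate(otus)}
    inc = np.zeros((len(species), len(otus)), dtype=np.int8)
    for i, sp in enumerate(species):
        for o in prevalence[sp]:
            inc[i, col[o]] = 1
    return BipartiteNetwork(species, otus, inc)


@dataclass
class ModulePartition:
    """A joint node→module assignment with its modularity bookkeeping."""

    assignment: dict[str, int]
    n_modules: int
    l_s: list[int]  # links internal to each module
    d_s: list[int]  # summed degree of each module
    M: float

    def module_members(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_modules)]
        for node, m in self.assignment.items():
            out[m].append(node)
        return out


@dataclass
class ModularitySignificance:
    """Observed modularity against a degree-preserving null ensemble."""

    M_obs: float
    null_Ms: list[float]
    null_mean: float
    null_sd: float
    p_value: float
    n_modules_obs: int = 0

    @classmethod
    def from_nulls(
        cls, M_obs: float, null_Ms: Sequence[float], n_modules_obs: int = 0
    ) -> "ModularitySignificance":
        arr = np.asarray(null_Ms, dtype=float)
        p = (1.0 + np.sum(arr >= M_obs - 1e-12)) / (1.0 + len(arr))
        return cls(
            M_obs=float(M_obs),
            null_Ms=[float(x) for x in arr],
            null_mean=float(arr.mean()),
            null_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            p_value=float(p),
            n_modules_obs=n_modules_obs,
        )


@dataclass
class SASchedule:
    """Simulated-annealing schedule for module detection.

    ``t0=None`` picks the starting temperature so that roughly 97% of
    sampled downhill moves would initially be accepted. Each temperature
    performs ``f·n²`` single-node moves and ``f·n`` collective (merge/split)
    moves; the run stops after ``stall_max`` consecutive temperatures
    without improvement of the best partition, or at ``max_temps``.
    """

    t0: float | None = None
    cooling: float = 0.95
    f: float = 1.0
    stall_max: int = 10
    split_sweeps: int = 2
    max_temps: int = 5000

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.stall_max < 1 or self.max_temps < 1:
            raise ValueError("stall_max and max_temps must be >= 1")


def _stats_for(
    net: BipartiteNetwork, assign: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """(l_s, d_s, M) for an integer assignment over the joint node order."""
    S, _ = net.incidence.shape
    L = net.L
    n_mod = int(assign.max()) + 1 if assign.size else 0
    l = np.zeros(n_mod, dtype=np.int64)
    d = np.zeros(n_mod, dtype=np.int64)
    deg = np.concatenate(net.degree_arrays())
    np.add.at(d, assign, deg)
    rows, cols = np.nonzero(net.incidence)
    same = assign[rows] == assign[S + cols]
    np.add.at(l, assign[rows][same], 1)
    M = float(np.sum(l / L - (d / (2.0 * L)) ** 2))
    return l, d, M


def modularity(net: BipartiteNetwork, assignment: Mapping[str, int]) -> float:
    """Evaluate M = Σ_s [l_s/L − (d_s/2L)²] for a given joint partition.

    Links whose endpoints sit in different modules contribute to no l_s.
    """
    nodes = net.node_ids
    missing = [u for u in nodes if u not in assignment]
    if missing:
        raise DataValidationError(f"nodes missing from assignment: {missing[:5]}")
    labels = sorted({assignment[u] for u in nodes})
    remap = {lab: i for i, lab in enumerate(labels)}
    assign = np.array([remap[assignment[u]] for u in nodes], dtype=np.int64)
    _, _, M = _stats_for(net, assign)
    return M


def _canonical_partition(net: BipartiteNetwork, assign: np.ndarray) -> ModulePartition:
    """Relabel modules (size-descending, then smallest member id) and pack."""
    nodes = net.node_ids
    members: dict[int, list[str]] = {}
    for u, m in zip(nodes, assign):
        members.setdefault(int(m), []).append(u)
    ordered = sorted(members.values(), key=lambda ms: (-len(ms), min(ms)))
    relabel: dict[str, int] = {}
    for new, ms in enumerate(ordered):
        for u in ms:
            relabel[u] = new
    canon = np.array([relabel[u] for u in nodes], dtype=np.int64)
    l, d, M = _stats_for(net, canon)
    return ModulePartition(
        assignment=relabel,
        n_modules=len(ordered),
        l_s=[int(x) for x in l],
        d_s=[int(x) for x in d],
        M=M,
    )


# ---------------------------------------------------------------------------
# Simulated-annealing kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _links_to(indptr, indices, assign, i, m):
    c = 0
    for p in range(indptr[i], indptr[i + 1]):
        if assign[indices[p]] == m:
            c += 1
    return c


@njit(cache=True)
def _sa_kernel(
    indptr,
    indices,
    deg,
    L,
    t0,
    cooling,
    f,
    stall_max,
    split_sweeps,
    max_temps,
    seed,
):
    np.random.seed(seed)
    n = deg.shape[0]
    Lf = float(L)
    assign = np.arange(n)
    l = np.zeros(n)
    d = deg.astype(np.float64).copy()
    M = 0.0
    for s in range(n):
        M += l[s] / Lf - (d[s] / (2.0 * Lf)) ** 2
    best_M = M
    best_assign = assign.copy()

    # auto temperature: mean |ΔM| of sampled downhill single-node moves,
    # scaled so the initial acceptance probability is about 0.97
    T = t0
    if T <= 0.0:
        acc = 0.0
        cnt = 0
        for _ in range(200):
            i = np.random.randint(n)
            b = np.random.randint(n)
            a = assign[i]
            if a == b:
                continue
            lia = _links_to(indptr, indices, assign, i, a)
            lib = _links_to(indptr, indices, assign, i, b)
            ki = float(deg[i])
            dM = (lib - lia) / Lf - (
                (d[b] + ki) ** 2 + (d[a] - ki) ** 2 - d[a] ** 2 - d[b] ** 2
            ) / (4.0 * Lf * Lf)
            if dM < 0.0:
                acc += -dM
                cnt += 1
        T = (acc / cnt) / 0.030459 if cnt > 0 else 1.0 / Lf

    n_single = max(1, int(f * n * n))
    n_coll = max(1, int(f * n))
    stall = 0
    member_buf = np.empty(n, dtype=np.int64)
    t_floor = T * 1e-7

    for _temp in range(max_temps):
        improved = False
        n_down_acc = 0

        # --- single-node reassignments ---
        for _ in range(n_single):
            i = np.random.randint(n)
            b = np.random.randint(n)
            a = assign[i]
            if a == b:
                continue
            lia = _links_to(indptr, indices, assign, i, a)
            lib = _links_to(indptr, indices, assign, i, b)
            ki = float(deg[i])
            dM = (lib - lia) / Lf - (
                (d[b] + ki) ** 2 + (d[a] - ki) ** 2 - d[a] ** 2 - d[b] ** 2
            ) / (4.0 * Lf * Lf)
            if dM >= 0.0 or np.random.random() < np.exp(dM / T):
                assign[i] = b
                l[a] -= lia
                l[b] += lib
                d[a] -= ki
                d[b] += ki
                M += dM
                if dM < 0.0:
                    n_down_acc += 1
                if M > best_M + 1e-12:
                    best_M = M
                    best_assign[:] = assign
                    improved = True

        # --- collective moves: merges and splits ---
        for _ in range(n_coll):
            if np.random.random() < 0.5:
                # merge the modules of two random nodes
                a = assign[np.random.randint(n)]
                b = assign[np.random.randint(n)]
                if a == b:
                    continue
                lab = 0
                for u in range(n):
                    if assign[u] == a:
                        for p in range(indptr[u], indptr[u + 1]):
                            if assign[indices[p]] == b:
                                lab += 1
                dM = lab / Lf - (d[a] * d[b]) / (2.0 * Lf * Lf)
                if dM >= 0.0 or np.random.random() < np.exp(dM / T):
                    for u in range(n):
                        if assign[u] == b:
                            assign[u] = a
                    l[a] += l[b] + lab
                    l[b] = 0.0
                    d[a] += d[b]
                    d[b] = 0.0
                    M += dM
                    if M > best_M + 1e-12:
                        best_M = M
                        best_assign[:] = assign
                        improved = True
            else:
                # split a random module: random bipartition refined by a few
                # annealed sweeps, accepted or reverted as a whole
                a = assign[np.random.randint(n)]
                size = 0
                for u in range(n):
                    if assign[u] == a:
                        member_buf[size] = u
                        size += 1
                if size < 2:
                    continue
                e = -1
                for s in range(n):
                    if d[s] == 0.0:
                        e = s
                        break
                if e < 0:
                    continue
                l_a0 = l[a]
                d_a0 = d[a]
                M0 = M
                # random bipartition via unconditional moves a -> e
                for j in range(size):
                    if np.random.random() < 0.5:
                        u = member_buf[j]
                        lua = _links_to(indptr, indices, assign, u, a)
                        lue = _links_to(indptr, indices, assign, u, e)
                        ku = float(deg[u])
                        dM = (lue - lua) / Lf - (
                            (d[e] + ku) ** 2 + (d[a] - ku) ** 2 - d[a] ** 2 - d[e] ** 2
                        ) / (4.0 * Lf * Lf)
                        assign[u] = e
                        l[a] -= lua
                        l[e] += lue
                        d[a] -= ku
                        d[e] += ku
                        M += dM
                # refine within {a, e}
                for _sw in range(split_sweeps):
                    for j in range(size):
                        u = member_buf[j]
                        src = assign[u]
                        dst = e if src == a else a
                        lus = _links_to(indptr, indices, assign, u, src)
                        lud = _links_to(indptr, indices, assign, u, dst)
                        ku = float(deg[u])
                        dM = (lud - lus) / Lf - (
                            (d[dst] + ku) ** 2
                            + (d[src] - ku) ** 2
                            - d[src] ** 2
                            - d[dst] ** 2
                        ) / (4.0 * Lf * Lf)
                        if dM >= 0.0 or np.random.random() < np.exp(dM / T):
                            assign[u] = dst
                            l[src] -= lus
                            l[dst] += lud
                            d[src] -= ku
                            d[dst] += ku
                            M += dM
                dM_total = M - M0
                if dM_total >= 0.0 or np.random.random() < np.exp(dM_total / T):
                    if M > best_M + 1e-12:
                        best_M = M
                        best_assign[:] = assign
                        improved = True
                else:
                    for j in range(size):
                        assign[member_buf[j]] = a
                    l[a] = l_a0
                    d[a] = d_a0
                    l[e] = 0.0
                    d[e] = 0.0
                    M = M0

        # a temperature counts towards the stall limit only once the chain
        # is effectively frozen: best unimproved and almost no accepted
        # downhill moves (uphill/neutral moves are always accepted)
        frozen = n_down_acc * 100 < n_single
        if improved:
            stall = 0
        elif frozen:
            stall += 1
            if stall >= stall_max:
                break
        if T < t_floor:
            break
        T *= cooling

    return best_assign, best_M


def detect_modules(
    net: BipartiteNetwork,
    seed: int | None = None,
    schedule: SASchedule | None = None,
) -> ModulePartition:
    """Maximise modularity by simulated annealing over joint partitions.

    Species and OTU nodes are partitioned together using bipartite links
    only. Deterministic given ``seed``; the best partition visited is
    returned with canonical module labels (size-descending, ties by
    smallest member id).
    """
    schedule = schedule or SASchedule()
    indptr, indices, deg = net.to_csr()
    if (deg == 0).any():
        raise DataValidationError("network has isolated nodes; prune before detection")
    kernel_seed = child_seed(0 if seed is None else seed, 0) % (2**32)
    assign, best_M = _sa_kernel(
        indptr,
        indices,
        deg,
        net.L,
        -1.0 if schedule.t0 is None else float(schedule.t0),
        float(schedule.cooling),
        float(schedule.f),
        int(schedule.stall_max),
        int(schedule.split_sweeps),
        int(schedule.max_temps),
        np.uint32(kernel_seed),
    )
    part = _canonical_partition(net, assign)
    # stored M is recomputed exactly from the returned assignment; the
    # kernel's incrementally tracked optimum may carry float drift
    if abs(part.M - best_M) > 1e-6:
        raise RuntimeError("annealing bookkeeping drifted from exact modularity")
    return part


def randomize(
    net: BipartiteNetwork, n_swaps: int | None = None, seed: int | None = None
) -> BipartiteNetwork:
    """Degree-preserving randomisation by checkerboard (2×2) swaps.

    Runs ``n_swaps`` *trial* swaps (default 10·L): each trial samples two
    rows and two columns uniformly and exchanges the 2×2 submatrix when it
    is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]). Failed trials leave
    the matrix unchanged, which makes the chain symmetric and its stationary
    distribution uniform over all fillings with the observed margins. Both
    the species and the OTU degree sequences are preserved exactly.
    """
    inc = net.incidence.copy()
    S, O = inc.shape
    L = int(inc.sum())
    if n_swaps is None:
        n_swaps = 10 * L
    if S < 2 or O < 2:
        warnings.warn("network too small to randomize; returning copy")
        return BipartiteNetwork(list(net.species_ids), list(net.otu_ids), inc)
    rng = np.random.default_rng(seed)
    rr = rng.integers(0, S, size=(n_swaps, 2))
    cc = rng.integers(0, O, size=(n_swaps, 2))
    successes = 0
    for t in range(n_swaps):
        r1, r2 = rr[t]
        c1, c2 = cc[t]
        if r1 == r2 or c1 == c2:
            continue
        a, b = inc[r1, c1], inc[r1, c2]
        c, d = inc[r2, c1], inc[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            inc[r1, c1] = inc[r2, c2] = 0
            inc[r1, c2] = inc[r2, c1] = 1
            successes += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            inc[r1, c1] = inc[r2, c2] = 1
            inc[r1, c2] = inc[r2, c1] = 0
            successes += 1
    if successes == 0:
        warnings.warn("no swappable checkerboard found; returning identical copy")
    return BipartiteNetwork(list(net.species_ids), list(net.otu_ids), inc)


def significance(
    net: BipartiteNetwork,
    n_null: int = 999,
    seed: int | None = None,
    schedule: SASchedule | None = None,
    n_swaps: int | None = None,
) -> ModularitySignificance:
    """Compare observed modularity with a degree-preserving null ensemble.

    Each of ``n_null`` random networks is an independent randomisation of
    the observed incidence, re-optimised with the same annealing schedule;
    p = (1 + #{M_null ≥ M_obs}) / (1 + n_null).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    base = 0 if seed is None else int(seed)
    obs = detect_modules(net, seed=child_seed(base, 1), schedule=schedule)
    null_Ms = []
    for b in range(n_null):
        rnd = randomize(net, n_swaps=n_swaps, seed=child_seed(base, 2, b))
        part = detect_modules(rnd, seed=child_seed(base, 3, b), schedule=schedule)
        null_Ms.append(part.M)
    return ModularitySignificance.from_nulls(obs.M, null_Ms, n_modules_obs=obs.n_modules)
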