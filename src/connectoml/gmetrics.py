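"""Graph metrics on binary undirected networks.

Implements the global metrics (clustering coefficient Cp, characteristic path
length Lp, normalized gamma/lambda/sigma against degree-preserving rewired
nulls, global efficiency, modularity Q), the seven nodal metrics, module-level
connection densities, and mean + 2 SD hub detection.

Conventions on degenerate inputs (documented and unit-tested): within-module
degree is 0 when the module's degree SD is 0; participation coefficient is 0
for isolated nodes; path-length averages run over reachable pairs only and
unreachable pairs contribute 0 to efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from connectoml.errors import ConfigurationError, DataError

NODAL_METRIC_NAMES = (
    "betweenness_centrality",
    "degree_centrality",
    "clustering_coefficient",
    "local_efficiency",
    "shortest_path_length",
    "participation_coefficient",
    "within_module_degree",
)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "E_global", "Q")


@dataclass(frozen=True)
class ModularPartition:
    """Node -> module assignment with 1-based contiguous module ids."""

    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        mods = sorted(set(self.assignment))
        if mods != list(range(1, len(mods) + 1)):
            raise ConfigurationError(
                f"module ids must be contiguous from 1, got {mods}"
            )

    @property
    def n_modules(self) -> int:
        return max(self.assignment)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise DataError("adjacency must be symmetric")
    if not np.all((A == 0) | (A == 1)):
        raise DataError("adjacency must be binary")
    if np.any(np.diag(A) != 0):
        raise DataError("adjacency must have a zero diagonal")
    return A.astype(np.int8)


def degrees(A: np.ndarray) -> np.ndarray:
    return np.asarray(A).sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# modularity and module structure


def modularity_q(A: np.ndarray, P: ModularPartition) -> float:
    """Q = sum over modules of [l_i / L - (d_i / 2L)^2]."""
    A = _check_adjacency(A)
    part = P.as_array()
    if len(part) != A.shape[0]:
        raise ConfigurationError("partition length must match node count")
    L = int(A.sum()) // 2
    if L == 0:
        raise DataError("modularity undefined for an edgeless graph")
    q = 0.0
    deg = degrees(A)
    for m in range(1, P.n_modules + 1):
        idx = part == m
        l_i = int(A[np.ix_(idx, idx)].sum()) // 2
        d_i = int(deg[idx].sum())
        q += l_i / L - (d_i / (2 * L)) ** 2
    return q


def greedy_modules(A: np.ndarray) -> ModularPartition:
    """Agglomerative greedy Q maximization.

    Starts from singleton modules and repeatedly merges the pair with the
    largest positive modularity gain; ties break by the smallest module-id
    pair.  Stops when no merge increases Q.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    L = int(A.sum()) // 2
    if L == 0:
        raise DataError("module detection undefined for an edgeless graph")
    # B[u, v]: edges between modules u and v; d[u]: degree mass of module u
    B = A.astype(float)
    d = degrees(A).astype(float)
    active = np.ones(n, dtype=bool)
    labels = np.arange(n)  # node -> current module id (singleton index)

    while True:
        act = np.flatnonzero(active)
        if act.size < 2:
            break
        # gain(u, v) = B[u,v]/L - 2 * (d_u/2L)(d_v/2L)
        sub_B = B[np.ix_(act, act)]
        a = d[act] / (2.0 * L)
        gain = sub_B / L - 2.0 * np.outer(a, a)
        iu = np.triu_indices(act.size, k=1)
        if iu[0].size == 0:
            break
        vals = gain[iu]
        best = np.argmax(vals)
        if vals[best] <= 1e-15:
            break
        # ties: argmax returns the first occurrence, and triu_indices walks
        # pairs in lexicographic order -> smallest (u, v) wins
        u, v = int(act[iu[0][best]]), int(act[iu[1][best]])
        B[u, :] += B[v, :]
        B[:, u] += B[:, v]
        B[u, u] += 0.0  # within-module mass handled via B[u,u] below
        d[u] += d[v]
        active[v] = False
        labels[labels == v] = u
    # relabel contiguously by first appearance
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out.append(seen[lab])
    return ModularPartition(tuple(out))


def module_densities(A: np.ndarray, P: ModularPartition) -> dict:
    """Intra-module densities D_s and inter-module densities D_{s,t}.

    Modules with fewer than two nodes get D_s = 0 with a flag.
    """
    A = _check_adjacency(A)
    part = P.as_array()
    n_mod = P.n_modules
    intra = np.zeros(n_mod)
    flagged: list[int] = []
    for m in range(1, n_mod + 1):
        idx = part == m
        n_s = int(idx.sum())
        if n_s < 2:
            flagged.append(m)
            continue
        e_s = int(A[np.ix_(idx, idx)].sum()) // 2
        intra[m - 1] = 2.0 * e_s / (n_s * (n_s - 1))
    inter: dict[tuple[int, int], float] = {}
    for s in range(1, n_mod + 1):
        for t in range(s + 1, n_mod + 1):
            si = part == s
            ti = part == t
            e_st = int(A[np.ix_(si, ti)].sum())
            inter[(s, t)] = e_st / (int(si.sum()) * int(ti.sum()))
    return {"intra": intra, "inter": inter, "undefined_modules": flagged}


def within_module_degree(
    A: np.ndarray, P: ModularPartition, sample_sd: bool = False
) -> np.ndarray:
    """WD_i = (e_i - mean_s) / sd_s over node i's module; sd_s = 0 -> 0.

    Population SD by default; ``sample_sd`` switches to the n-1 denominator.
    """
    A = _check_adjacency(A)
    part = P.as_array()
    wd = np.zeros(A.shape[0])
    ddof = 1 if sample_sd else 0
    for m in range(1, P.n_modules + 1):
        idx = part == m
        e = A[np.ix_(idx, idx)].sum(axis=1).astype(float)
        sd = e.std(ddof=ddof) if e.size > ddof else 0.0
        if sd > 0:
            wd[idx] = (e - e.mean()) / sd
    return wd


def participation_coefficient(A: np.ndarray, P: ModularPartition) -> np.ndarray:
    """PC_i = 1 - sum_s (k_{i,s} / k_i)^2; isolated nodes get 0."""
    A = _check_adjacency(A)
    part = P.as_array()
    k = degrees(A).astype(float)
    pc = np.zeros(A.shape[0])
    nz = k > 0
    acc = np.zeros(A.shape[0])
    for m in range(1, P.n_modules + 1):
        k_is = A[:, part == m].sum(axis=1).astype(float)
        acc[nz] += (k_is[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - acc[nz]
    return pc


# ---------------------------------------------------------------------------
# nodal metrics


def _distances(A: np.ndarray) -> np.ndarray:
    """All-pairs geodesic distances by level-synchronous BFS (dense, small n)."""
    n = A.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    Ab = np.asarray(A, dtype=np.uint8)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    frontier = Ab != 0
    known = frontier | np.eye(n, dtype=bool)
    D[frontier] = 1.0
    d = 1
    while frontier.any():
        nxt = ((frontier.astype(np.uint8) @ Ab) > 0) & ~known
        d += 1
        D[nxt] = d
        known |= nxt
        frontier = nxt
    return D


def _global_efficiency_from_dist(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficients(A: np.ndarray) -> np.ndarray:
    A = _check_adjacency(A)
    Af = A.astype(float)
    tri = np.diag(Af @ Af @ Af) / 2.0
    k = degrees(A).astype(float)
    denom = k * (k - 1) / 2.0
    out = np.zeros(A.shape[0])
    nz = denom > 0
    out[nz] = tri[nz] / denom[nz]
    return out


def betweenness_centrality(A: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness on the unweighted graph (pair counts, not normalized)."""
    A = _check_adjacency(A)
    n = A.shape[0]
    neighbors = [np.flatnonzero(A[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # undirected: each pair counted twice
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def nodal_metrics(A: np.ndarray, P: ModularPartition | None = None) -> dict[str, np.ndarray]:
    """All seven per-node metrics; WD/PC need a partition (else omitted)."""
    A = _check_adjacency(A)
    n = A.shape[0]
    D = _distances(A)
    k = degrees(A)
    spl = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(D[i]) & (np.arange(n) != i)
        if finite.any():
            spl[i] = D[i, finite].mean()
    leff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size >= 2:
            sub = A[np.ix_(nbrs, nbrs)]
            leff[i] = _global_efficiency_from_dist(_distances(sub))
    out = {
        "betweenness_centrality": betweenness_centrality(A),
        "degree_centrality": k.astype(float),
        "clustering_coefficient": clustering_coefficients(A),
        "local_efficiency": leff,
        "shortest_path_length": spl,
    }
    if P is not None:
        out["participation_coefficient"] = participation_coefficient(A, P)
        out["within_module_degree"] = within_module_degree(A, P)
    return out


# ---------------------------------------------------------------------------
# global metrics and the rewired null model


def rewire_degree_preserving(
    A: np.ndarray, rng: np.random.Generator, attempts_per_edge: int = 10
) -> np.ndarray:
    """Double-edge-swap rewiring; preserves the exact degree sequence."""
    A = _check_adjacency(A)
    ii, jj = np.nonzero(np.triu(A, k=1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    m = len(edges)
    if m < 2:
        return A.copy()
    edge_set = set(edges)
    n_attempts = attempts_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    out = np.zeros_like(A)
    for a, b in edge_set:
        out[a, b] = out[b, a] = 1
    return out


def characteristic_path_length(A: np.ndarray) -> float:
    D = _distances(_check_adjacency(A))
    mask = np.isfinite(D) & ~np.eye(D.shape[0], dtype=bool)
    if not mask.any():
        return 0.0
    return float(D[mask].mean())


def global_efficiency(A: np.ndarray) -> float:
    return _global_efficiency_from_dist(_distances(_check_adjacency(A)))


def global_metrics(
    A: np.ndarray,
    n_random: int = 100,
    seed: int | None = None,
    partition: ModularPartition | None = None,
    null_networks: list[np.ndarray] | None = None,
) -> dict[str, float]:
    """Global record: Cp, Lp, gamma, lambda, sigma, E_global, Q.

    gamma = Cp / <Cp over degree-preserving rewired nulls>, lambda likewise
    for Lp, sigma = gamma / lambda.  ``null_networks`` overrides the rewiring
    (used for identity tests).  Q uses ``partition`` or a greedy one.
    """
    A = _check_adjacency(A)
    if A.shape[0] < 2:
        raise DataError("global metrics require >= 2 nodes")
    cp = float(clustering_coefficients(A).mean())
    lp = characteristic_path_length(A)
    eg = global_efficiency(A)
    if int(A.sum()) > 0:
        part = partition if partition is not None else greedy_modules(A)
        q = modularity_q(A, part)
    else:
        q = np.nan
    if null_networks is None:
        if n_random < 1:
            raise ConfigurationError("n_random must be >= 1")
        rng = np.random.default_rng(seed)
        null_networks = [rewire_degree_preserving(A, rng) for _ in range(n_random)]
    cp_rand = float(np.mean([clustering_coefficients(R).mean() for R in null_networks]))
    lp_rand = float(np.mean([characteristic_path_length(R) for R in null_networks]))
    gamma = cp / cp_rand if cp_rand > 0 else np.nan
    lam = lp / lp_rand if lp_rand > 0 else np.nan
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam > 0 else np.nan
    return {
        "Cp": cp,
        "Lp": lp,
        "gamma": gamma,
        "lambda": lam,
        "sigma": sigma,
        "E_global": eg,
        "Q": q,
    }


def detect_hubs(node_degrees: np.ndarray, sample_sd: bool = False) -> set[int]:
    """Nodes whose degree exceeds mean + 2 SDs (population SD by default)."""
    d = np.asarray(node_degrees, dtype=float)
    if d.size < 2:
        raise DataError("hub detection requires >= 2 nodes")
    threshold = d.mean() + 2.0 * d.std(ddof=1 if sample_sd else 0)
    return set(np.flatnonzero(d > threshold).tolist())
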