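"""Communication topologies and their spectral/matrix views.

Agents communicate on an undirected, unweighted graph.  The default
generator places ``n`` nodes uniformly at random in the unit square and
connects pairs closer than a radius ``delta`` (a random geometric graph,
the standard abstraction for spatially embedded animal groups).  The
module also provides the matrix objects the consensus analysis needs: the
adjacency matrix, the graph Laplacian ``L = D - A``, Metropolis–Hastings
doubly stochastic weights, and spectral radii with dominant eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "generate_rgg",
    "generate_connected_rgg",
    "generate_erdos_renyi",
    "generate_ring_lattice",
    "radius_for_target_degree",
    "is_connected",
    "metropolis_hastings_weights",
    "safe_epsilon",
    "spectral_radius",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class Topology:
    """An undirected communication graph over agents ``0 .. n-1``.

    Parameters
    ----------
    n
        Number of agents (nodes).
    edges
        Frozen set of unordered index pairs ``(i, j)`` with ``i < j``;
        no self-loops.
    positions
        Optional ``(n, 2)`` array of node coordinates in the unit square,
        retained for reproducibility when the graph is geometric.
    """

    n: int
    edges: frozenset[tuple[int, int]]
    positions: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one agent, got n={self.n}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            if not (0 <= i < j < self.n):
                raise ValueError(f"edge ({i},{j}) out of range for n={self.n}")

    @classmethod
    def from_pairs(cls, n: int, pairs, positions: np.ndarray | None = None) -> "Topology":
        """Build from any iterable of (i, j) pairs, normalizing order."""
        edges = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        return cls(n=n, edges=edges, positions=positions)

    @classmethod
    def complete(cls, n: int) -> "Topology":
        return cls.from_pairs(n, ((i, j) for i in range(n) for j in range(i + 1, n)))

    def adjacency(self) -> np.ndarray:
        """0/1 symmetric adjacency matrix with zero diagonal."""
        a = np.zeros((self.n, self.n))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = D - A; rows sum to zero."""
        a = self.adjacency()
        return np.diag(a.sum(axis=1)) - a

    def neighbours(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def neighbour_lists(self) -> list[list[int]]:
        """Neighbour sets of every agent, as sorted lists."""
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            out[i].append(j)
            out[j].append(i)
        return [sorted(m) for m in out]

    @property
    def mean_degree(self) -> float:
        return 2.0 * len(self.edges) / self.n

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


def generate_rgg(n: int, delta: float, seed: int) -> Topology:
    """Random geometric graph in the unit square.

    Nodes are placed uniformly at random in ``[0, 1]^2`` and two nodes are
    connected when their Euclidean distance is smaller than ``delta``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n, 2))
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    ii, jj = np.nonzero(np.triu(dist < delta, k=1))
    return Topology.from_pairs(n, zip(ii.tolist(), jj.tolist()), positions=pos)


def generate_connected_rgg(
    n: int, delta: float, seed: int, max_attempts: int = 1000
) -> tuple[Topology, int]:
    """Rejection-sample RGG instances until one is connected.

    Returns the topology and the number of rejected (disconnected) draws.
    Seeds for successive attempts are spawned deterministically from
    ``seed`` so the procedure is reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(max_attempts)
    for attempt, child in enumerate(children):
        topo = generate_rgg(n, delta, child)
        if is_connected(topo):
            return topo, attempt
    raise RuntimeError(
        f"no connected RGG found in {max_attempts} attempts (n={n}, delta={delta})"
    )


def generate_erdos_renyi(n: int, p: float, seed: int) -> Topology:
    """Erdős–Rényi G(n, p); convenience alternative topology."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    ii, jj = np.nonzero(np.triu(mask, k=1))
    return Topology.from_pairs(n, zip(ii.tolist(), jj.tolist()))


def generate_ring_lattice(n: int, k: int) -> Topology:
    """k-regular ring: each node linked to its k nearest ring neighbours (k even)."""
    if k % 2 != 0 or k < 0 or k > n - 1:
        raise ValueError(f"k must be even and in [0, n-1], got k={k}, n={n}")
    pairs = []
    for i in range(n):
        for off in range(1, k // 2 + 1):
            pairs.append((i, (i + off) % n))
    return Topology.from_pairs(n, pairs)


def radius_for_target_degree(
    n: int,
    kappa: float,
    seed: int,
    n_samples: int = 200,
    tol: float = 0.5,
) -> float:
    """Connection radius delta giving RGGs a target mean degree ``kappa``.

    The finite square's boundary biases the naive ``n * pi * delta^2``
    estimate, so the radius is found by bisection on the *empirical* mean
    degree averaged over ``n_samples`` RGG draws.

    Returns a delta whose resampled mean degree lies within ``tol`` of
    ``kappa``.
    """
    if not 0 < kappa <= n - 1:
        raise ValueError(f"kappa must be in (0, n-1], got kappa={kappa}, n={n}")
    if kappa == n - 1:
        return float(np.sqrt(2.0))

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_samples)]

    def empirical_mean_degree(delta: float) -> float:
        return float(np.mean([generate_rgg(n, delta, s).mean_degree for s in seeds]))

    lo, hi = 1e-6, float(np.sqrt(2.0))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = empirical_mean_degree(mid)
        if abs(m - kappa) <= tol * 0.5:
            return mid
        if m < kappa:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def is_connected(topology: Topology) -> bool:
    """True iff a single component spans all nodes (BFS from node 0)."""
    if topology.n == 1:
        return True
    adj = topology.neighbour_lists()
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == topology.n


def metropolis_hastings_weights(topology: Topology) -> np.ndarray:
    """Doubly stochastic averaging matrix F from the Metropolis–Hastings rule.

    Off-diagonal ``w_ij = 1 / (1 + max(d_i, d_j))`` for edges, zero for
    non-edges; the diagonal absorbs the remainder so rows sum to one.
    Symmetry of the rule makes columns sum to one as well, which is what
    guarantees averaging consensus preserves the mean.

    Raises
    ------
    ValueError
        If the topology is disconnected (consensus is not guaranteed).
    """
    if not is_connected(topology):
        raise ValueError("Metropolis–Hastings weights require a connected graph")
    d = topology.degrees()
    f = np.zeros((topology.n, topology.n))
    for i, j in topology.edges:
        w = 1.0 / (1.0 + max(d[i], d[j]))
        f[i, j] = f[j, i] = w
    np.fill_diagonal(f, 1.0 - f.sum(axis=1))
    return f


def safe_epsilon(topology: Topology) -> float:
    """Uniform step size making ``I - eps * L`` doubly stochastic.

    ``eps = 1 / (1 + max_i d_i)`` keeps every diagonal entry of
    ``I - eps * L`` strictly positive, a safe decentralized choice each
    agent can compute from its neighbourhood alone.
    """
    return 1.0 / (1.0 + int(topology.degrees().max(initial=0)))


def spectral_radius(matrix: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest-|.| eigenvalue and its eigenvector of a square real matrix.

    Returns ``(rho, v)`` where ``v`` is the (unit-norm) eigenvector of the
    dominant eigenvalue; for real symmetric inputs both are real.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if np.allclose(matrix, matrix.T):
        vals, vecs = np.linalg.eigh(matrix)
        idx = int(np.argmax(np.abs(vals)))
        return float(abs(vals[idx])), vecs[:, idx]
    vals, vecs = np.linalg.eig(matrix)
    idx = int(np.argmax(np.abs(vals)))
    return float(abs(vals[idx])), np.real_if_close(vecs[:, idx])


def write_edge_list(topology: Topology, path) -> None:
    """Serialize as plain text: header ``n=<N>``, then one ``i j`` per line."""
    with open(path, "w") as fh:
        fh.write(f"n={topology.n}\n")
        for i, j in sorted(topology.edges):
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> Topology:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("n="):
            raise ValueError(f"bad edge-list header: {header!r}")
        n = int(header[2:])
        pairs = []
        for line in fh:
            line = line.strip()
            if line:
                i, j = line.split()
                pairs.append((int(i), int(j)))
    return Topology.from_pairs(n, pairs)
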