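"""NeighborNet split networks: agglomerative circular ordering plus
non-negative least-squares split weights, and column-bootstrap supports.

The agglomeration follows the neighbor-joining-style two-stage selection on
clusters of one or two linked nodes: first pick the cluster pair with the
minimal NJ Q-criterion on cluster-averaged distances, then pick the node
pair (treating the chosen clusters' nodes as temporary singletons) with the
minimal Q-criterion, and contract the resulting three-node path with the
(2/3, 1/3) distance reduction. Expanding the contractions in reverse yields
a circular ordering of the taxa; split weights are then fitted by NNLS over
all splits of that circular ordering, which for a tree-additive input
reproduces exactly the tree's splits and branch lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .distances import DistanceMatrix, distance_matrix
from .types import AlignedSet, SequenceRecord


@dataclass(frozen=True)
class Split:
    """One side of a bipartition of the taxon set, with weight and optional
    bootstrap support. ``side`` is canonical: the side NOT containing the
    first taxon in the reference ordering."""

    side: frozenset[str]
    weight: float
    support: float | None = None


@dataclass
class SplitSet:
    taxa: tuple[str, ...]
    splits: list[Split] = field(default_factory=list)
    circular_order: tuple[str, ...] | None = None

    def canonical(self, side) -> frozenset[str]:
        side = frozenset(side)
        return frozenset(self.taxa) - side if self.taxa[0] in side else side

    def weight_of(self, side) -> float:
        target = self.canonical(side)
        for s in self.splits:
            if s.side == target:
                return s.weight
        return 0.0

    def nontrivial(self) -> list[Split]:
        n = len(self.taxa)
        return [s for s in self.splits if 1 < len(s.side) < n - 1]


# ---------------------------------------------------------------------------
# circular ordering


def _cluster_avg(d, members_a, members_b) -> float:
    return float(np.mean([[d[x][y] for y in members_b] for x in members_a]))


def neighbor_net_ordering(dm: DistanceMatrix) -> tuple[str, ...]:
    """Circular taxon ordering by NeighborNet agglomeration."""
    n = len(dm.taxa)
    if n < 3:
        return tuple(dm.taxa)
    # node-level working distances, node ids are ints; 0..n-1 are taxa
    d: dict[int, dict[int, float]] = {
        i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    clusters: list[list[int]] = [[i] for i in range(n)]
    next_id = itertools.count(n)
    expansions: list[tuple[int, int, int, int, int]] = []  # (u, v, x, y, z)

    def reduce3(x: int, y: int, z: int) -> tuple[int, int]:
        """Contract path x-y-z into u-v with the (2/3, 1/3) reduction."""
        u, v = next(next_id), next(next_id)
        others = [w for w in d if w not in (x, y, z)]
        d[u], d[v] = {}, {}
        for w in others:
            du = (2.0 / 3.0) * d[x][w] + (1.0 / 3.0) * d[y][w]
            dv = (2.0 / 3.0) * d[z][w] + (1.0 / 3.0) * d[y][w]
            d[u][w] = du
            d[w][u] = du
            d[v][w] = dv
            d[w][v] = dv
        duv = (d[x][y] + d[y][z] + d[x][z]) / 3.0
        d[u][v] = duv
        d[v][u] = duv
        for dead in (x, y, z):
            for w in list(d[dead]):
                d[w].pop(dead, None)
            del d[dead]
        expansions.append((u, v, x, y, z))
        return u, v

    while len(clusters) > 1:
        m = len(clusters)
        # cluster-average distance matrix
        D = [[0.0] * m for _ in range(m)]
        for i, j in itertools.combinations(range(m), 2):
            D[i][j] = D[j][i] = _cluster_avg(d, clusters[i], clusters[j])
        if m == 2:
            ai, bi = 0, 1
        else:
            R = [sum(row) for row in D]
            best = None
            for i, j in itertools.combinations(range(m), 2):
                q = (m - 2) * D[i][j] - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
            _, ai, bi = best
        A, B = clusters[ai], clusters[bi]
        # node-level selection: nodes of A and B as temporary singletons
        others = [clusters[k] for k in range(m) if k not in (ai, bi)]
        mhat = len(others) + len(A) + len(B)
        pool = A + B

        def rhat(x: int) -> float:
            s = sum(_cluster_avg(d, [x], c) for c in others)
            s += sum(d[x][z] for z in pool if z != x)
            return s

        best = None
        for x in A:
            for y in B:
                q = (mhat - 2) * d[x][y] - rhat(x) - rhat(y)
                if best is None or q < best[0] - 1e-12:
                    best = (q, x, y)
        _, x, y = best
        # join the two cluster paths through (x, y) and contract to <= 2 nodes
        path = (A if A[-1] == x else A[::-1]) + (B if B[0] == y else B[::-1])
        if len(path) == 2:
            new_nodes = path
        elif len(path) == 3:
            new_nodes = list(reduce3(*path))
        else:  # 4 nodes: two successive contractions
            p, q_ = reduce3(path[0], path[1], path[2])
            new_nodes = list(reduce3(p, q_, path[3]))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(new_nodes)

    cycle = list(clusters[0])
    for u, v, x, y, z in reversed(expansions):
        iu = cycle.index(u)
        iv = cycle.index(v)
        nlen = len(cycle)
        # rotate so the pair sits at the front (rotation of a cycle is free)
        if (iu + 1) % nlen == iv:
            cycle = cycle[iu:] + cycle[:iu]
            cycle = [x, y, z] + cycle[2:]
        elif (iv + 1) % nlen == iu:
            cycle = cycle[iv:] + cycle[:iv]
            cycle = [z, y, x] + cycle[2:]
        else:
            raise AssertionError("expansion nodes not adjacent in cycle")
    return tuple(dm.taxa[i] for i in cycle)


# ---------------------------------------------------------------------------
# split weights


def circular_splits(order) -> list[frozenset]:
    """All n(n-1)/2 splits induced by contiguous arcs of a circular order
    (arcs not containing the first element, so each split appears once)."""
    order = list(order)
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i + 1, n + 1):
            out.append(frozenset(order[i:j]))
    return out


def fit_split_weights(dm: DistanceMatrix, order, threshold: float = 1e-6) -> SplitSet:
    """Non-negative least-squares split weights for the circular split
    system of ``order`` against the observed distances; splits with weight
    below ``threshold`` are dropped (SplitsTree behaviour)."""
    n = len(dm.taxa)
    idx = {t: k for k, t in enumerate(dm.taxa)}
    pairs = list(itertools.combinations(range(n), 2))
    splits = circular_splits(order)
    A = np.zeros((len(pairs), len(splits)))
    for col, side in enumerate(splits):
        mask = np.zeros(n, dtype=bool)
        for t in side:
            mask[idx[t]] = True
        for row, (i, j) in enumerate(pairs):
            if mask[i] != mask[j]:
                A[row, col] = 1.0
    dvec = np.array([dm.d[i, j] for i, j in pairs])
    w, _ = nnls(A, dvec)
    out = SplitSet(tuple(dm.taxa), circular_order=tuple(order))
    for side, weight in zip(splits, w):
        if weight >= threshold:
            out.splits.append(Split(out.canonical(side), float(weight)))
    return out


def neighbor_net(dm: DistanceMatrix, threshold: float = 1e-6) -> SplitSet:
    """Full NeighborNet: circular ordering + NNLS split weights."""
    if len(dm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    order = neighbor_net_ordering(dm)
    return fit_split_weights(dm, order, threshold)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: AlignedSet,
    n_reps: int = 1000,
    seed: int = 0,
    metric: str = "p",
    threshold: float = 1e-6,
) -> SplitSet:
    """Column bootstrap for NeighborNet splits.

    Resamples alignment columns with replacement ``n_reps`` times; the
    support of each split of the full-data network is the fraction of
    replicates whose network contains the same bipartition. Deterministic
    under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = neighbor_net(distance_matrix(aln, metric), threshold)
    counts = {s.side: 0 for s in base.splits}
    rng = np.random.default_rng(seed)
    L = aln.L
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        recs = [
            SequenceRecord("".join(["b_", r.id]), "".join(r.seq[c] for c in cols), r.group, r.role)
            for r in aln.records
        ]
        # keep original ids for split comparison
        recs = [
            SequenceRecord(orig.id, rec.seq, orig.group, orig.role)
            for orig, rec in zip(aln.records, recs)
        ]
        try:
            rep = neighbor_net(distance_matrix(AlignedSet.from_records(recs), metric), threshold)
        except ValueError:
            continue
        rep_sides = {s.side for s in rep.splits}
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    out = SplitSet(base.taxa, circular_order=base.circular_order)
    for s in base.splits:
        out.splits.append(Split(s.side, s.weight, counts[s.side] / n_reps))
    return out
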