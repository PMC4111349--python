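"""Pairwise distances, group identity summaries, ribotype delimitation and
statistical-parsimony (TCS-style) haplotype networks.

Ambiguity codes are handled "as average": a column contributes the expected
mismatch (or expected transition/transversion fractions for K2P) over the
joint expansion of both characters. All distances use pairwise gap deletion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np

from . import alphabet
from .types import AlignedSet, SequenceRecord

# ---------------------------------------------------------------------------
# pairwise distances


def _column_sets(a: str, b: str):
    sa = alphabet.expand(a, permissive_n=False)
    sb = alphabet.expand(b, permissive_n=False)
    if not sa or not sb:
        return None
    return sa, sb


def p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Uncorrected p-distance with ambiguity averaging and pairwise gap
    deletion: mean over comparable columns of 1 - |matching resolutions| /
    (|S_a| * |S_b|)."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    total = 0.0
    n = 0
    for ca, cb in zip(a.seq, b.seq):
        sets = _column_sets(ca, cb)
        if sets is None:
            continue
        sa, sb = sets
        total += 1.0 - len(sa & sb) / (len(sa) * len(sb))
        n += 1
    if n == 0:
        raise ValueError(f"no comparable columns between {a.id!r} and {b.id!r}")
    return total / n


def _expected_PQ(a: SequenceRecord, b: SequenceRecord) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) fractions, averaging over
    joint IUPAC expansions with pairwise gap deletion."""
    P = Q = 0.0
    n = 0
    for ca, cb in zip(a.seq, b.seq):
        sets = _column_sets(ca, cb)
        if sets is None:
            continue
        sa, sb = sets
        npairs = len(sa) * len(sb)
        ts = sum(1 for x in sa for y in sb if alphabet.is_transition(x, y))
        tv = sum(1 for x in sa for y in sb if x != y and not alphabet.is_transition(x, y))
        P += ts / npairs
        Q += tv / npairs
        n += 1
    if n == 0:
        raise ValueError(f"no comparable columns between {a.id!r} and {b.id!r}")
    return P / n, Q / n


def k2p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Kimura 2-parameter distance: -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    P, Q = _expected_PQ(a, b)
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise ValueError(
            f"K2P distance saturated between {a.id!r} and {b.id!r} (P={P:.4g}, Q={Q:.4g})"
        )
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


def distance_matrix(aln: AlignedSet, metric: str = "p") -> DistanceMatrix:
    """All-pairs distance matrix (metric 'p' or 'k2p')."""
    fn = {"p": p_distance, "k2p": k2p_distance}[metric]
    n = len(aln)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(aln.records[i], aln.records[j])
    return DistanceMatrix(tuple(r.id for r in aln.records), d)


def round3(x: float) -> float:
    """Round half-up to 3 decimals (the convention used for identity values)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def group_identity(
    aln: AlignedSet, group_a: str, group_b: str | None = None, *, rounded: bool = True
) -> float:
    """Mean genetic identity (1 - mean p-distance) within a group, or between
    two groups; the unweighted mean over all qualifying pairs."""
    by_group = aln.groups()
    if group_b is None or group_b == group_a:
        members = by_group.get(group_a, [])
        if len(members) < 2:
            raise ValueError(f"group {group_a!r} has <2 members; within-identity undefined")
        pairs = list(itertools.combinations(members, 2))
    else:
        ma, mb = by_group.get(group_a, []), by_group.get(group_b, [])
        if not ma or not mb:
            raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
        pairs = [(x, y) for x in ma for y in mb]
    mean_p = sum(p_distance(x, y) for x, y in pairs) / len(pairs)
    identity = 1.0 - mean_p
    return round3(identity) if rounded else identity


# ---------------------------------------------------------------------------
# ribotype delimitation


@dataclass(frozen=True)
class Ribotype:
    representative: SequenceRecord
    member_ids: tuple[str, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.member_ids)


def delimit_ribotypes(seqs, *, permissive_n: bool = False) -> list[Ribotype]:
    """Group aligned sequences into exact-identity classes.

    Default: N matches nothing, so a sequence is identical to another only by
    literal string equality. ``permissive_n=True`` instead merges a sequence
    into the first ribotype whose representative is compatible at every
    column (N/ambiguity overlap counts as compatible).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    ribotypes: list[list[SequenceRecord]] = []
    for rec in seqs:
        placed = False
        for members in ribotypes:
            rep = members[0]
            if permissive_n:
                ok = all(
                    not alphabet.expand(x) or not alphabet.expand(y)
                    or alphabet.expand(x) & alphabet.expand(y)
                    for x, y in zip(rec.seq, rep.seq)
                )
            else:
                ok = rec.seq == rep.seq
            if ok:
                members.append(rec)
                placed = True
                break
        if not placed:
            ribotypes.append([rec])
    return [Ribotype(m[0], tuple(r.id for r in m)) for m in ribotypes]


# ---------------------------------------------------------------------------
# statistical parsimony (TCS-style)


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j observed differences over L sites are all single
    hits (no site struck twice), under uniform placement of changes:
    prod_{i=1}^{j-1} (1 - i/L). Multiple hits at one site are what create
    homoplasy (parallelism or reversal), so this is the probability that the
    j differences are non-homoplastic."""
    if j < 1:
        return 1.0
    if j > L:
        return 0.0
    p = 1.0
    for i in range(1, j):
        p *= 1.0 - i / L
    return p


def parsimony_limit(L: int, prob: float = 0.95) -> int:
    """Largest step count j whose non-homoplasy probability is still >= prob
    (the TCS connection limit; 95% by convention)."""
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    j = 1
    while j + 1 <= L and parsimony_probability(j + 1, L) >= prob:
        j += 1
    return j


def hamming_steps(a: SequenceRecord, b: SequenceRecord) -> int:
    """Absolute number of differing shared non-gap columns (literal states;
    a ribotype is a literal sequence class)."""
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    return sum(
        1
        for x, y in zip(a.seq, b.seq)
        if x != alphabet.GAP and y != alphabet.GAP and x != y
    )


def build_parsimony_network(ribotypes, limit: int) -> nx.Graph:
    """Statistical-parsimony network over ribotypes.

    Pairs are joined in ascending step order; an edge is added only when its
    endpoints are not yet connected by strictly shorter steps (ties at one
    step level are joined simultaneously), and never beyond ``limit`` steps.
    Multi-step edges are materialized with unlabeled intermediate nodes, as
    a TCS graph draws them. Disconnected components are allowed.

    Node attributes: ``kind`` ('ribotype' or 'intermediate'), and for
    ribotypes ``multiplicity`` and ``members``.
    """
    ribotypes = list(ribotypes)
    g = nx.Graph(connection_limit=limit)
    for rt in ribotypes:
        g.add_node(
            rt.representative.id,
            kind="ribotype",
            multiplicity=rt.multiplicity,
            members=rt.member_ids,
        )
    dists: dict[tuple[int, int], int] = {}
    for i, j in itertools.combinations(range(len(ribotypes)), 2):
        dists[(i, j)] = hamming_steps(
            ribotypes[i].representative, ribotypes[j].representative
        )
    components = nx.utils.UnionFind(range(len(ribotypes)))
    accepted: list[tuple[int, int, int]] = []
    for step in range(1, limit + 1):
        level = [
            (i, j)
            for (i, j), d in dists.items()
            if d == step and components[i] != components[j]
        ]
        for i, j in level:
            accepted.append((i, j, step))
        for i, j in level:
            components.union(i, j)
    mediator = itertools.count(1)
    for i, j, step in accepted:
        u = ribotypes[i].representative.id
        v = ribotypes[j].representative.id
        path = [u]
        for _ in range(step - 1):
            node = f"__mv{next(mediator)}"
            g.add_node(node, kind="intermediate")
            path.append(node)
        path.append(v)
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b, step=1)
        g.nodes[u].setdefault("links", []).append((v, step))
    return g


def minimum_spanning_network(ribotypes, limit: int) -> set[tuple[str, str, int]]:
    """Direct-from-definition minimum spanning network: an edge (u, v) with
    d(u, v) = k <= limit belongs to the network iff u and v are not connected
    using only edges of distance < k. Returns {(id_u, id_v, steps)} with
    id_u < id_v. (Used as an independent cross-check for small inputs.)"""
    ribotypes = list(ribotypes)
    n = len(ribotypes)
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = hamming_steps(ribotypes[i].representative, ribotypes[j].representative)
    out: set[tuple[str, str, int]] = set()
    for (i, j), k in d.items():
        if k > limit:
            continue
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(
            (a, b) for (a, b), dd in d.items() if dd < k and dd <= limit
        )
        if not nx.has_path(g, i, j):
            u = ribotypes[i].representative.id
            v = ribotypes[j].representative.id
            out.add((min(u, v), max(u, v), k))
    return out


def network_edge_set(g: nx.Graph) -> set[tuple[str, str, int]]:
    """Collapse a parsimony network's intermediate chains back into
    (ribotype, ribotype, steps) edges for comparison purposes."""
    out: set[tuple[str, str, int]] = set()
    for u, data in g.nodes(data=True):
        for v, step in data.get("links", []):
            out.add((min(u, v), max(u, v), step))
    return out
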