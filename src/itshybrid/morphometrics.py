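"""Landmark geometric morphometrics: generalized Procrustes analysis (GPA),
bilateral symmetrization, relative warps (PCA of aligned coordinates),
group mean shapes, Procrustes distances, two-group permutation tests and a
tangent-space adequacy check.

Shapes are 2D landmark configurations. Reflection is never allowed in the
Procrustes rotation (leaves are oriented objects). Relative warps are
computed with no bending-energy weighting (alpha = 0), i.e. an ordinary PCA
of the Procrustes-aligned coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .types import LandmarkConfiguration


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def centroid_size(x: np.ndarray) -> float:
    c = _center(np.asarray(x, dtype=float))
    return float(np.sqrt((c**2).sum()))


def _unit(x: np.ndarray) -> np.ndarray:
    c = _center(np.asarray(x, dtype=float))
    s = np.sqrt((c**2).sum())
    if s == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return c / s


def optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||x R - target||_F.

    Both inputs are assumed centered.
    """
    u, s, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    return u @ corr @ vt


@dataclass
class AlignedShapes:
    """Procrustes-aligned configurations: each centered, unit centroid size,
    rotated to the consensus; the consensus is the re-standardized mean."""

    configs: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    ids: tuple[str, ...]
    groups: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.configs.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.configs.reshape(self.n, -1)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group])


def gpa(configs, tol: float = 1e-8, max_iter: int = 200) -> AlignedShapes:
    """Generalized Procrustes analysis of :class:`LandmarkConfiguration`s.

    Iterates rotate-to-consensus / update-consensus after centering and
    scaling every configuration to unit centroid size, until the consensus
    moves less than ``tol``.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = configs[0].n_landmarks
    if any(c.n_landmarks != k for c in configs):
        raise ValueError("landmark counts differ between configurations")
    sizes = np.array([centroid_size(c.coords) for c in configs])
    x = np.stack([_unit(c.coords) for c in configs])
    consensus = x[0].copy()
    for _ in range(max_iter):
        for i in range(len(configs)):
            x[i] = x[i] @ optimal_rotation(x[i], consensus)
        new = _unit(x.mean(axis=0))
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    for i in range(len(configs)):
        x[i] = x[i] @ optimal_rotation(x[i], consensus)
    return AlignedShapes(
        configs=x,
        centroid_sizes=sizes,
        consensus=consensus,
        ids=tuple(c.id for c in configs),
        groups=tuple(c.group for c in configs),
    )


def gpa_residual(aligned: AlignedShapes) -> float:
    """Sum of squared distances of aligned configurations to the consensus."""
    return float(((aligned.configs - aligned.consensus) ** 2).sum())


# ---------------------------------------------------------------------------
# bilateral symmetrization (object symmetry)


def _reflect_relabel(x: np.ndarray, pairing, midline) -> np.ndarray:
    """Reflect across the y-axis and swap paired left/right labels."""
    y = x.copy()
    y[:, 0] = -y[:, 0]
    out = y.copy()
    for left, right in pairing:
        out[left] = y[right]
        out[right] = y[left]
    return out


def symmetrize(config, pairing, midline) -> np.ndarray:
    """Symmetric average of a configuration and its reflected, relabeled
    copy (object-symmetry correction).

    ``pairing`` lists (left, right) 0-based landmark index pairs, ``midline``
    the unpaired indices; together they must cover every landmark exactly
    once. The mirror copy is optimally rotated onto the original before
    averaging; a final average with the map image makes the output exactly
    invariant under the reflection map, and the operation idempotent.
    """
    x = np.asarray(
        config.coords if isinstance(config, LandmarkConfiguration) else config, dtype=float
    )
    k = x.shape[0]
    used = sorted(itertools.chain(midline, *pairing))
    if used != list(range(k)):
        raise ValueError("pairing + midline must cover all landmarks exactly once")
    x = _center(x)
    t = _reflect_relabel(x, pairing, midline)
    s0 = (x + t @ optimal_rotation(t, x)) / 2.0
    return (s0 + _reflect_relabel(s0, pairing, midline)) / 2.0


# ---------------------------------------------------------------------------
# relative warps (PCA of aligned coordinates, alpha = 0)


@dataclass
class RelativeWarps:
    scores: np.ndarray  # (n, k)
    variance_fractions: np.ndarray  # (k,)
    loadings: np.ndarray  # (k, 2p) principal axes
    mean: np.ndarray  # (2p,) mean flattened shape


def relative_warps(aligned: AlignedShapes) -> RelativeWarps:
    if aligned.n <= 2:
        raise ValueError("relative warps need more than 2 specimens")
    flat = aligned.flat
    mean = flat.mean(axis=0)
    centered = flat - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2
    total = eig.sum()
    nz = int((s > 1e-12 * max(s[0], 1.0)).sum())
    scores = u[:, :nz] * s[:nz]
    fractions = eig[:nz] / total if total > 0 else np.zeros(nz)
    return RelativeWarps(scores, fractions, vt[:nz], mean)


# ---------------------------------------------------------------------------
# mean shapes and Procrustes distances


def group_mean_shape(aligned: AlignedShapes, group: str) -> np.ndarray:
    idx = aligned.group_indices(group)
    if idx.size == 0:
        raise ValueError(f"empty group {group!r}")
    return _unit(aligned.configs[idx].mean(axis=0))


def procrustes_distance(a, b, kind: str = "full") -> float:
    """Procrustes distance between two configurations after optimal
    translation, scaling and rotation (no reflection).

    ``full``: sqrt(1 - beta^2); ``partial``: sqrt(2 - 2 beta); where beta is
    the maximized shape correlation (sum of signed singular values of the
    cross-product of the unit-size centered shapes).
    """
    xa = _unit(np.asarray(a, dtype=float))
    xb = _unit(np.asarray(b, dtype=float))
    if xa.shape != xb.shape:
        raise ValueError(f"landmark counts differ: {xa.shape} vs {xb.shape}")
    u, s, vt = np.linalg.svd(xa.T @ xb)
    d = np.sign(np.linalg.det(u @ vt))
    beta = s[0] + d * s[1]
    beta = min(beta, 1.0)
    if kind == "full":
        return float(np.sqrt(max(0.0, 1.0 - beta**2)))
    if kind == "partial":
        return float(np.sqrt(max(0.0, 2.0 - 2.0 * beta)))
    raise ValueError(f"unknown distance kind {kind!r}")


# ---------------------------------------------------------------------------
# permutation test on relative-warp scores


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    n_permutations: int
    n_warps_used: int


def permutation_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    n_warps: int = 12,
) -> tuple[float, float]:
    """Two-group permutation test on specimen scores.

    Statistic: Euclidean distance between group mean score vectors, using
    the first ``n_warps`` columns. p = (# permuted >= observed + 1) /
    (n_perm + 1); deterministic under the seed. Returns (statistic, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))[:, :n_warps]
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))[:, :n_warps]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 specimens")
    # canonicalize group order: the statistic is label-symmetric, so this
    # makes the seeded p-value exactly invariant under a group swap
    if b.tobytes() < a.tobytes():
        a, b = b, a
    obs = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    pooled = np.vstack([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        stat = float(np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)))
        if stat >= obs:
            exceed += 1
    return obs, (exceed + 1) / (n_perm + 1)


def compare_groups(
    aligned: AlignedShapes,
    warps: RelativeWarps,
    group_a: str,
    group_b: str,
    n_perm: int = 9999,
    seed: int = 0,
    n_warps: int = 12,
    distance_kind: str = "full",
) -> GroupComparison:
    """Procrustes distance between group mean shapes plus the two-group
    permutation test on relative-warp scores."""
    ia, ib = aligned.group_indices(group_a), aligned.group_indices(group_b)
    dist = procrustes_distance(
        group_mean_shape(aligned, group_a), group_mean_shape(aligned, group_b), distance_kind
    )
    k = min(n_warps, warps.scores.shape[1])
    _, p = permutation_test(warps.scores[ia], warps.scores[ib], n_perm, seed, k)
    return GroupComparison(group_a, group_b, dist, p, n_perm, k)


# ---------------------------------------------------------------------------
# tangent-space adequacy


def tangent_check(aligned: AlignedShapes) -> tuple[float, float]:
    """Correlation and regression slope of tangent-space (Euclidean)
    distances against Procrustes distances across all specimen pairs.

    Near 1.0 for small shape variation; (nan, nan) when all shapes are
    identical.
    """
    if aligned.n < 3:
        raise ValueError("tangent check needs at least 3 specimens")
    proc, tang = [], []
    for i, j in itertools.combinations(range(aligned.n), 2):
        proc.append(procrustes_distance(aligned.configs[i], aligned.configs[j]))
        tang.append(float(np.linalg.norm(aligned.flat[i] - aligned.flat[j])))
    proc = np.array(proc)
    tang = np.array(tang)
    if proc.std() == 0 or tang.std() == 0:
        return float("nan"), float("nan")
    corr = float(np.corrcoef(proc, tang)[0, 1])
    slope = float((proc @ tang) / (proc @ proc))  # through-origin regression
    return corr, slope
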