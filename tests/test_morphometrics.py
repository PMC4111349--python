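"""GPA, symmetrization, relative warps, Procrustes distances, permutation
tests and tangent-space adequacy."""

import itertools

import numpy as np
import pytest
from scipy import stats

from itshybrid import morphometrics as morpho
from itshybrid.synthetic import (
    LANDMARK_MIDLINE,
    LANDMARK_PAIRING,
    SimConfig,
    default_mean_shapes,
    gen_landmarks,
)
from itshybrid.types import LandmarkConfiguration


def cfgs(arrays, group="g"):
    return [LandmarkConfiguration(f"c{i}", group, a) for i, a in enumerate(arrays)]


TRI = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])


class TestGpa:
    def test_identical_shapes_align_exactly(self):
        aligned = morpho.gpa(cfgs([TRI, TRI.copy()]))
        assert morpho.gpa_residual(aligned) == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(aligned.configs[0], aligned.configs[1])

    def test_similarity_transform_invisible(self):
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        other = TRI @ rot.T * 2.0 + np.array([5.0, -3.0])
        aligned = morpho.gpa(cfgs([TRI, other]))
        assert morpho.gpa_residual(aligned) == pytest.approx(0.0, abs=1e-12)

    def test_two_config_residual_matches_svd_oracle(self, rng):
        # for two shapes the GPA residual is 1 - beta where beta is the sum
        # of signed singular values of the unit pre-shapes' cross-product
        x = rng.normal(size=(4, 2))
        y = rng.normal(size=(4, 2))

        def unit(a):
            a = a - a.mean(0)
            return a / np.sqrt((a**2).sum())

        u, s, vt = np.linalg.svd(unit(x).T @ unit(y))
        beta = s[0] + np.sign(np.linalg.det(u @ vt)) * s[1]
        # residual about the unit-size consensus: 4 - 4 sqrt((1 + beta)/2)
        aligned = morpho.gpa(cfgs([x, y]), tol=1e-12)
        expected = 4.0 - 4.0 * np.sqrt((1.0 + beta) / 2.0)
        assert morpho.gpa_residual(aligned) == pytest.approx(expected, abs=1e-8)

    def test_residual_invariant_to_input_rotation(self, rng):
        arrays = [rng.normal(size=(14, 2)) for _ in range(5)]
        r1 = morpho.gpa_residual(morpho.gpa(cfgs(arrays)))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        arrays[2] = arrays[2] @ rot.T * 3.0
        r2 = morpho.gpa_residual(morpho.gpa(cfgs(arrays)))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_config_is_error(self):
        degenerate = np.zeros((3, 2))
        with pytest.raises(ValueError, match="degenerate"):
            morpho.gpa(cfgs([TRI, degenerate]))

    def test_consensus_is_unit_size(self, study):
        aligned = morpho.gpa(study.landmarks[:30])
        assert np.sqrt((aligned.consensus**2).sum()) == pytest.approx(1.0)
        assert np.allclose(aligned.consensus.mean(0), 0.0, atol=1e-12)


class TestSymmetrize:
    PAIRING = [(1, 3)]
    MIDLINE = [0, 2]

    def test_symmetric_config_unchanged(self):
        sym = np.array([[0.0, 1.0], [-0.5, 0.0], [0.0, -1.0], [0.5, 0.0]])
        out = morpho.symmetrize(sym, self.PAIRING, self.MIDLINE)
        assert np.allclose(out, sym - sym.mean(0), atol=1e-12)

    def test_idempotent(self, rng):
        for _ in range(10):
            x = rng.normal(size=(4, 2))
            s1 = morpho.symmetrize(x, self.PAIRING, self.MIDLINE)
            s2 = morpho.symmetrize(s1, self.PAIRING, self.MIDLINE)
            assert np.allclose(s1, s2, atol=1e-10)

    def test_output_invariant_under_reflection_map(self, rng):
        x = rng.normal(size=(14, 2))
        out = morpho.symmetrize(x, LANDMARK_PAIRING, LANDMARK_MIDLINE)
        reflected = out.copy()
        reflected[:, 0] = -reflected[:, 0]
        relabeled = reflected.copy()
        for left, right in LANDMARK_PAIRING:
            relabeled[left] = reflected[right]
            relabeled[right] = reflected[left]
        assert np.allclose(relabeled, out, atol=1e-12)

    def test_matches_manual_reflection_average(self):
        # a configuration already aligned with its mirror (optimal rotation
        # is the identity): the result is the plain average with the
        # reflected, relabeled copy
        x = np.array([[0.0, 1.1], [-0.6, 0.1], [0.0, -0.9], [0.4, 0.1]])
        x = x - x.mean(0)
        t = x.copy()
        t[:, 0] = -t[:, 0]
        t[[1, 3]] = t[[3, 1]]
        m = x.T @ t  # symmetric cross-product => optimal rotation is identity
        assert abs(m[0, 1] - m[1, 0]) < 1e-12
        expected = (x + t) / 2
        got = morpho.symmetrize(x, self.PAIRING, self.MIDLINE)
        assert np.allclose(got, expected, atol=1e-12)

    def test_incomplete_pairing_is_error(self):
        with pytest.raises(ValueError, match="cover"):
            morpho.symmetrize(np.zeros((4, 2)) + TRI[:1], [(1, 3)], [0])


class TestRelativeWarps:
    def test_single_direction_of_variation(self):
        base = np.array([[0.0, 1.0], [1.0, 0.0], [-1.0, 0.0], [0.0, -1.0]])
        arrays = []
        for t in np.linspace(-0.05, 0.05, 8):
            a = base.copy()
            a[0, 1] += t
            arrays.append(a)
        aligned = morpho.gpa(cfgs(arrays))
        warps = morpho.relative_warps(aligned)
        assert warps.variance_fractions[0] == pytest.approx(1.0, abs=1e-4)

    def test_fractions_sum_to_one(self, study):
        aligned = morpho.gpa(study.landmarks)
        warps = morpho.relative_warps(aligned)
        assert warps.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(warps.variance_fractions) <= 1e-12)
        assert np.allclose(warps.scores.mean(0), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, study):
        aligned = morpho.gpa(study.landmarks[:40])
        warps = morpho.relative_warps(aligned)
        flat = aligned.flat - aligned.flat.mean(0)
        eigvals = np.linalg.eigvalsh(flat.T @ flat)[::-1]
        k = len(warps.variance_fractions)
        assert np.allclose(
            warps.variance_fractions, eigvals[:k] / eigvals.sum(), atol=1e-10
        )

    def test_clusters_separate_along_warps(self):
        shapes = default_mean_shapes()
        cfg = SimConfig(
            seed=3,
            landmark_groups={"notabilis": 15, "variabilis": 15},
            landmark_sigma=0.01,
        )
        configs, _ = gen_landmarks(cfg)
        aligned = morpho.gpa(configs)
        warps = morpho.relative_warps(aligned)
        ia = aligned.group_indices("notabilis")
        ib = aligned.group_indices("variabilis")
        between = np.linalg.norm(
            warps.scores[ia, :2].mean(0) - warps.scores[ib, :2].mean(0)
        )
        within = warps.scores[ia, :2].std() + warps.scores[ib, :2].std()
        assert between > within


class TestMeanShapesAndDistance:
    def test_single_member_group_mean_is_member(self, study):
        aligned = morpho.gpa(study.landmarks[:3])
        only = aligned.groups[0]
        sub = morpho.gpa(study.landmarks[:2] + study.landmarks[28:29])
        mean = morpho.group_mean_shape(sub, sub.groups[-1])
        assert np.allclose(mean, sub.configs[-1], atol=1e-12)

    def test_empty_group_is_error(self, study):
        aligned = morpho.gpa(study.landmarks[:4])
        with pytest.raises(ValueError, match="empty group"):
            morpho.group_mean_shape(aligned, "missing")

    @pytest.mark.parametrize("kind", ["full", "partial"])
    def test_distance_zero_for_similarity_transforms(self, kind):
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        other = TRI @ rot.T * 3.0 + 7.0
        assert morpho.procrustes_distance(TRI, other, kind) == pytest.approx(0.0, abs=1e-6)

    def test_fixed_quadrilaterals_match_svd_closed_form(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        b = np.array([[0.0, 0.0], [1.2, 0.1], [0.9, 1.1], [-0.2, 0.8]])

        def unit(x):
            x = x - x.mean(0)
            return x / np.sqrt((x**2).sum())

        u, s, vt = np.linalg.svd(unit(a).T @ unit(b))
        beta = s[0] + np.sign(np.linalg.det(u @ vt)) * s[1]
        assert morpho.procrustes_distance(a, b) == pytest.approx(np.sqrt(1 - beta**2))
        assert morpho.procrustes_distance(a, b, "partial") == pytest.approx(
            np.sqrt(2 - 2 * beta)
        )

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 6, 2))
        assert morpho.procrustes_distance(a, b) == pytest.approx(
            morpho.procrustes_distance(b, a), abs=1e-10
        )

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 5, 2))
            dab = morpho.procrustes_distance(a, b)
            dbc = morpho.procrustes_distance(b, c)
            dac = morpho.procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-9

    def test_group_mean_recovery_from_simulation(self):
        # mean of a simulated group converges to the generator mean shape
        cfg = SimConfig(
            seed=21, landmark_groups={"notabilis": 200}, landmark_sigma=0.02
        )
        configs, truth = gen_landmarks(cfg)
        aligned = morpho.gpa(configs)
        mean = morpho.group_mean_shape(aligned, "notabilis")
        d = morpho.procrustes_distance(mean, truth.mean_shapes["notabilis"])
        assert d < 0.01


class TestPermutationTest:
    def test_minimum_attainable_p(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) + 50.0
        _, p = morpho.permutation_test(a, b, n_perm=9999, seed=1)
        assert p == pytest.approx(1 / 10_000)

    def test_label_swap_symmetry(self, rng):
        a = rng.normal(size=(8, 4))
        b = rng.normal(size=(8, 4))
        _, p1 = morpho.permutation_test(a, b, n_perm=499, seed=7)
        _, p2 = morpho.permutation_test(b, a, n_perm=499, seed=7)
        assert p1 == p2

    def test_null_p_values_uniform(self):
        # identically distributed groups: p-values must be uniform on (0,1]
        pvals = []
        for k in range(500):
            r = np.random.default_rng(5000 + k)
            a = r.normal(size=(6, 3))
            b = r.normal(size=(6, 3))
            _, p = morpho.permutation_test(a, b, n_perm=99, seed=k)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_permutations_is_error(self, rng):
        with pytest.raises(ValueError):
            morpho.permutation_test(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), 0, 1)


class TestTangentCheck:
    def test_small_variation_high_correlation(self, rng):
        base = default_mean_shapes()["notabilis"]
        arrays = [base + rng.normal(0, 0.005, base.shape) for _ in range(12)]
        aligned = morpho.gpa(cfgs(arrays))
        corr, slope = morpho.tangent_check(aligned)
        assert corr > 0.999
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_identical_shapes_degenerate(self):
        aligned = morpho.gpa(cfgs([TRI, TRI.copy(), TRI.copy()]))
        corr, slope = morpho.tangent_check(aligned)
        assert np.isnan(corr) and np.isnan(slope)

    def test_wide_scatter_in_unit_interval(self, rng):
        arrays = [rng.normal(size=(6, 2)) for _ in range(8)]
        aligned = morpho.gpa(cfgs(arrays))
        corr, _ = morpho.tangent_check(aligned)
        assert 0.0 < corr <= 1.0
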