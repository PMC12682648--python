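"""Step-rule tests: scaling clamp, index partition, BB ratios against
independently coded expressions, partitioned variants, and the SS* switch."""

import numpy as np
import pytest

from mpsgp import (
    ScalingDiag,
    StepHistory,
    bb1_step,
    bb2_star_step,
    bb2_step,
    bb_partitioned,
    clamp_alpha,
    partition_indices,
    scaling_matrix,
    select_step_size,
    ss_star_select,
)


def hist(s, z, alpha=1.0):
    return StepHistory(s_prev=np.asarray(s, float), z_prev=np.asarray(z, float), alpha_prev=alpha)


def diag(d, bound=10.0):
    return ScalingDiag(diag=np.asarray(d, float), bound=bound)


class TestScalingMatrix:
    def test_band_interior_passthrough(self):
        assert scaling_matrix(np.array([0.5]), 10.0).diag[0] == 0.5

    def test_lower_and_upper_clamp(self):
        d = scaling_matrix(np.array([0.0, 1e6]), 10.0).diag
        assert d[0] == pytest.approx(0.1)
        assert d[1] == pytest.approx(10.0)

    def test_rejects_bound_at_most_one(self):
        with pytest.raises(ValueError):
            scaling_matrix(np.ones(3), 1.0)


class TestPartition:
    def test_strictly_positive_iterate_gives_empty_J(self, rng):
        x = rng.uniform(1, 5, size=10)
        g = rng.normal(size=10)
        part = partition_indices(x, g, 0.5)
        assert part.n_zero == 0
        assert np.all(part.I)

    def test_all_zero_with_zero_gradient_gives_full_J(self):
        part = partition_indices(np.zeros(5), np.zeros(5), 0.0)
        assert part.n_zero == 5

    def test_band_condition_enumeration(self):
        # x=(0,0,1), grad=(0.5,2,-1), lam=1: index 0 passes (|x|=0 and
        # -0.5 in [-1,1]); index 1 fails the band (-2 not in [-1,1]);
        # index 2 fails the zero test
        part = partition_indices(
            np.array([0.0, 0.0, 1.0]), np.array([0.5, 2.0, -1.0]), 1.0
        )
        np.testing.assert_array_equal(part.J, [True, False, False])
        np.testing.assert_array_equal(part.I, [False, True, True])

    def test_masks_partition_index_set(self, rng):
        x = np.where(rng.uniform(size=20) < 0.4, 0.0, rng.uniform(1, 3, size=20))
        g = rng.normal(size=20)
        part = partition_indices(x, g, 0.3)
        assert np.all(part.J ^ part.I)


class TestClassicalBB:
    def test_scalar_quadratic_inverse_curvature(self):
        # f = c/2 x^2: z = c*s, both rules give 1/c
        c, s = 4.0, 0.7
        h = hist([s], [c * s])
        D = diag([1.0], bound=2.0)
        assert bb1_step(h, D) == pytest.approx(1 / c)
        assert bb2_step(h, D) == pytest.approx(1 / c)

    def test_identity_scaling_reduces_to_classical(self, rng):
        s = rng.normal(size=10)
        z = s + 0.1 * rng.normal(size=10)
        h = hist(s, z)
        D = diag(np.ones(10), bound=2.0)
        assert bb1_step(h, D) == pytest.approx((s @ s) / (s @ z), rel=1e-12)
        assert bb2_step(h, D) == pytest.approx((s @ z) / (z @ z), rel=1e-12)

    def test_matches_independent_expression(self, rng):
        for _ in range(20):
            s = rng.normal(size=10)
            z = rng.normal(size=10)
            d = rng.uniform(0.1, 10, size=10)
            h, D = hist(s, z), diag(d)
            # independent loop-based evaluation
            num1 = sum(s[i] ** 2 / d[i] ** 2 for i in range(10))
            den1 = sum(s[i] * z[i] / d[i] for i in range(10))
            num2 = sum(s[i] * z[i] * d[i] for i in range(10))
            den2 = sum(z[i] ** 2 * d[i] ** 2 for i in range(10))
            a1, a2 = bb1_step(h, D), bb2_step(h, D)
            if den1 > 0:
                assert a1 == pytest.approx(num1 / den1, rel=1e-12)
            else:
                assert a1 is None
            if num2 > 0:
                assert a2 == pytest.approx(num2 / den2, rel=1e-12)
            else:
                assert a2 is None

    def test_bb1_dominates_bb2_on_convex_quadratics(self, rng):
        # with D = I and z = Q s (Q spd), Cauchy-Schwarz gives BB1 >= BB2 > 0
        count = 0
        for _ in range(500):
            B = rng.normal(size=(6, 6))
            Q = B @ B.T + 0.1 * np.eye(6)
            s = rng.normal(size=6)
            z = Q @ s
            h = hist(s, z)
            D = diag(np.ones(6), bound=2.0)
            a1, a2 = bb1_step(h, D), bb2_step(h, D)
            assert a1 is not None and a2 is not None
            assert a1 >= a2 > 0
            count += 1
        assert count == 500

    def test_previous_scaling_reading(self, rng):
        s, z = rng.normal(size=5), rng.normal(size=5)
        d_prev = rng.uniform(0.5, 2.0, size=5)
        h = hist(s, z)
        D_prev = diag(d_prev)
        a = bb1_step(h, diag(np.ones(5)), scaling="previous", D_prev=D_prev)
        num = np.sum(s * s * d_prev * d_prev)
        den = np.sum(s * z * d_prev)
        if den > 0:
            assert a == pytest.approx(num / den, rel=1e-12)
        else:
            assert a is None


class TestPartitionedBB:
    def _random_instance(self, rng, n=12, n_zero=4):
        s = rng.normal(size=n)
        z = rng.normal(size=n)
        d = rng.uniform(0.1, 10, size=n)
        J = np.zeros(n, bool)
        J[rng.choice(n, size=n_zero, replace=False)] = True
        from mpsgp import IndexPartition

        return hist(s, z), diag(d), IndexPartition(J=J, I=~J)

    def test_empty_J_reduces_to_classical(self, rng):
        from mpsgp import IndexPartition

        s, z = rng.normal(size=8), rng.normal(size=8)
        d = rng.uniform(0.5, 5, size=8)
        h, D = hist(s, z), diag(d)
        part = IndexPartition(J=np.zeros(8, bool), I=np.ones(8, bool))
        assert bb_partitioned(h, D, part, "bb1") == bb1_step(h, D)
        assert bb_partitioned(h, D, part, "bb2") == bb2_step(h, D)
        assert bb2_star_step(h, D, part) == bb2_step(h, D)

    def test_matches_masked_evaluation(self, rng):
        for _ in range(20):
            h, D, part = self._random_instance(rng)
            s, z, d = h.s_prev, h.z_prev, D.diag
            I, J = part.I, part.J
            num1 = np.sum((s**2 / d**2)[I])
            den1 = np.sum((s * z / d)[I])
            num2 = np.sum((s * z * d)[I])
            den2I = np.sum((z**2 * d**2)[I])
            den2J = np.sum((z**2 * d**2)[J])
            a1 = bb_partitioned(h, D, part, "bb1")
            a2 = bb_partitioned(h, D, part, "bb2")
            a2s = bb2_star_step(h, D, part)
            assert a1 == (pytest.approx(num1 / den1, rel=1e-12) if den1 > 0 else None)
            assert a2 == (
                pytest.approx(num2 / (den2I + den2J), rel=1e-12) if num2 > 0 else None
            )
            assert a2s == (pytest.approx(num2 / den2I, rel=1e-12) if num2 > 0 else None)

    def test_bb2_star_takes_larger_steps(self, rng):
        # dropping the z_J curvature strictly enlarges the step when z_J != 0
        found_strict = False
        for _ in range(50):
            h, D, part = self._random_instance(rng)
            a2 = bb_partitioned(h, D, part, "bb2")
            a2s = bb2_star_step(h, D, part)
            if a2 is not None and a2s is not None:
                assert a2s >= a2
                zJ = h.z_prev[part.J]
                if np.any(zJ != 0):
                    assert a2s > a2
                    found_strict = True
        assert found_strict

    def test_empty_I_undefined(self):
        from mpsgp import IndexPartition

        h = hist(np.ones(3), np.ones(3))
        part = IndexPartition(J=np.ones(3, bool), I=np.zeros(3, bool))
        assert bb_partitioned(h, diag(np.ones(3)), part, "bb1") is None
        assert bb2_star_step(h, diag(np.ones(3)), part) is None


class TestSSStarSelect:
    def test_small_ratio_picks_bb1(self):
        assert ss_star_select(0.1, 1.0, 0.15) == (0.1, "BB1")

    def test_large_ratio_picks_bb2_star(self):
        assert ss_star_select(0.5, 1.0, 0.15) == (1.0, "BB2*")

    def test_boundary_ratio_is_inclusive_bb2_star(self):
        # ratio exactly tau goes to the BB2* branch
        alpha, rule = ss_star_select(0.15, 1.0, 0.15)
        assert rule == "BB2*" and alpha == 1.0

    def test_scale_equivariance(self, rng):
        for _ in range(20):
            b1 = float(rng.uniform(0.01, 5))
            b2 = float(rng.uniform(0.01, 5))
            c = float(rng.uniform(0.1, 100))
            a, r = ss_star_select(b1, b2, 0.15)
            ac, rc = ss_star_select(c * b1, c * b2, 0.15)
            assert rc == r
            assert ac == pytest.approx(c * a, rel=1e-12)

    def test_nonpositive_candidates_rejected(self):
        with pytest.raises(ValueError):
            ss_star_select(-1.0, 1.0, 0.15)
        with pytest.raises(ValueError):
            ss_star_select(1.0, 0.0, 0.15)


class TestClampAlpha:
    def test_upper_clamp(self):
        assert clamp_alpha(1e7, 1e-10, 1e5, 1.0) == 1e5

    def test_undefined_maps_to_fallback(self):
        assert clamp_alpha(None, 1e-10, 1e5, 1e5) == 1e5

    def test_in_band_passthrough(self):
        assert clamp_alpha(1.3, 1e-10, 1e5, 1.0) == 1.3

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            clamp_alpha(1.0, 1.0, 0.5, 1.0)


class TestSelectStepSize:
    def test_all_rules_stay_in_bounds(self, rng):
        from mpsgp import IndexPartition

        for rule in ("bb1", "bb2", "ss-approx", "bb2star", "ssstar"):
            for _ in range(30):
                s, z = rng.normal(size=8), rng.normal(size=8)
                d = rng.uniform(0.1, 10, size=8)
                J = rng.uniform(size=8) < 0.3
                part = IndexPartition(J=J, I=~J)
                alpha, used = select_step_size(
                    rule, hist(s, z), diag(d), part,
                    tau=0.15, alpha_min=1e-10, alpha_max=1e5,
                )
                assert 1e-10 <= alpha <= 1e5

    def test_degenerate_history_falls_back_to_alpha_max(self):
        from mpsgp import IndexPartition

        # z orthogonal-ish: craft s, z with non-positive curvature everywhere
        s = np.array([1.0, 1.0])
        z = np.array([-1.0, -1.0])
        part = IndexPartition(J=np.zeros(2, bool), I=np.ones(2, bool))
        alpha, used = select_step_size(
            "ssstar", hist(s, z), diag(np.ones(2)), part,
            tau=0.15, alpha_min=1e-10, alpha_max=1e5,
        )
        assert alpha == 1e5 and used == "FB"

    def test_unknown_rule_rejected(self, rng):
        from mpsgp import IndexPartition

        part = IndexPartition(J=np.zeros(2, bool), I=np.ones(2, bool))
        with pytest.raises(ValueError):
            select_step_size(
                "nope", hist(np.ones(2), np.ones(2)), diag(np.ones(2)), part,
                tau=0.15, alpha_min=1e-10, alpha_max=1e5,
            )
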