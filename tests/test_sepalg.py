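import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepint.errors import BasisMismatchError, SurrogateTargetError
from sepint.geometry import FamilyKind, PoseFamily, apply_pose, make_pose
from sepint.particles import ParticleSet
from sepint.sepalg import (
    CharacteristicModel,
    PosePolynomial,
    accumulate_characteristics,
    compute_d2_range,
    d2_polynomial,
    pair_expansion,
    poly_multiply,
    poly_power,
    posed_coordinate_polynomial,
    primitive_set_for,
    primitive_values,
)
from sepint.evaluator import brute_force_net, net_value
from sepint.surrogate import (
    PolynomialSurrogate,
    TARGET_SHAPE_F,
    fit_surrogate,
)

TR = PoseFamily(FamilyKind.TRANSLATION_X1)
ROT = PoseFamily(FamilyKind.ROTATION_X3)
SE3 = PoseFamily(FamilyKind.GENERAL_SE3)


def _random_se3_values(rng, n):
    return [np.concatenate([rng.normal(0, 1, 3), rng.normal(0, 2, 3)])
            for _ in range(n)]


def _random_poly(basis, rng, n_terms=4, max_exp=3):
    terms = {}
    for _ in range(n_terms):
        exps = tuple(int(rng.integers(0, max_exp + 1))
                     for _ in range(basis.n))
        terms[exps] = float(rng.normal())
    return PosePolynomial(basis, terms)


class TestD2Polynomial:
    def test_translation_single_pair(self):
        poly = d2_polynomial((0, 0, 0), (1, 0, 0), TR)
        assert poly.terms == {(0,): 1.0, (1,): 2.0, (2,): 1.0}

    def test_rotation_chord_length(self):
        poly = d2_polynomial((1, 0, 0), (1, 0, 0), ROT)
        assert poly.terms == {(0, 0): 2.0, (0, 1): -2.0}

    @pytest.mark.parametrize("family,values_of", [
        (TR, lambda rng: [[v] for v in rng.uniform(-3, 3, 50)]),
        (ROT, lambda rng: [[v] for v in rng.uniform(-math.pi, math.pi, 50)]),
        (SE3, lambda rng: _random_se3_values(rng, 50)),
    ], ids=["translation", "rotation", "se3"])
    def test_matches_direct_distance(self, family, values_of, rng):
        """Evaluating the d^2 pose polynomial equals |R q0 + x - p0|^2
        computed directly, at 50 random poses."""
        p0, q0 = rng.normal(0, 2, 3), rng.normal(0, 2, 3)
        poly = d2_polynomial(p0, q0, family)
        for v in values_of(rng):
            direct = np.sum((apply_pose(make_pose(family, v), q0) - p0) ** 2)
            assert poly.evaluate(primitive_values(family, v)) == pytest.approx(
                direct, rel=1e-10)

    def test_rotation_reduced_structure(self, rng):
        """After the cos^2 reduction the pair d^2 has at most the five-term
        {1, sin, cos, sin*cos?} structure: degree <= 1 monomials only."""
        poly = d2_polynomial(rng.normal(0, 2, 3), rng.normal(0, 2, 3), ROT)
        assert all(sum(e) <= 1 for e in poly.terms)


class TestPolyAlgebra:
    def test_square_of_linear(self):
        basis = primitive_set_for(FamilyKind.TRANSLATION_X1)
        p = PosePolynomial(basis, {(0,): 1.0, (1,): 1.0})
        assert poly_multiply(p, p).terms == {(0,): 1.0, (1,): 2.0, (2,): 1.0}

    def test_cos_squared_reduction(self):
        basis = primitive_set_for(FamilyKind.ROTATION_X3)
        s = PosePolynomial(basis, {(1, 0): 1.0})
        c = PosePolynomial(basis, {(0, 1): 1.0})
        prod = poly_multiply(s, poly_multiply(c, c))
        assert prod.terms == {(1, 0): 1.0, (3, 0): -1.0}

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_commutative_and_associative(self, seed):
        rng = np.random.default_rng(seed)
        basis = primitive_set_for(FamilyKind.ROTATION_X3)
        a, b, c = (_random_poly(basis, rng) for _ in range(3))
        ab = poly_multiply(a, b)
        ba = poly_multiply(b, a)
        assert set(ab.terms) == set(ba.terms)
        for k in ab.terms:
            assert ab.terms[k] == pytest.approx(ba.terms[k], rel=1e-12)
        left = poly_multiply(poly_multiply(a, b), c)
        right = poly_multiply(a, poly_multiply(b, c))
        for k in set(left.terms) | set(right.terms):
            assert left.terms.get(k, 0.0) == pytest.approx(
                right.terms.get(k, 0.0), rel=1e-9, abs=1e-12)

    def test_power_zero_is_one(self, rng):
        basis = primitive_set_for(FamilyKind.TRANSLATION_X1)
        p = _random_poly(basis, rng)
        assert poly_power(p, 0).terms == {(0,): 1.0}

    def test_monomial_power(self):
        basis = primitive_set_for(FamilyKind.TRANSLATION_X1)
        x = PosePolynomial(basis, {(1,): 1.0})
        assert poly_power(x, 5).terms == {(5,): 1.0}

    def test_power_matches_multinomial_theorem(self, rng):
        """x^4 of a trinomial equals the explicit multinomial expansion
        sum C(n; a1..ar) prod g_k^{a_k} h_k^{a_k} (independent oracle)."""
        basis = primitive_set_for(FamilyKind.GENERAL_SE3)  # no reduction
        exps = [tuple(int(rng.integers(0, 3)) for _ in range(basis.n))
                for _ in range(3)]
        coeffs = rng.normal(size=3)
        poly = PosePolynomial(basis, dict(zip(exps, coeffs)))
        n = 4
        expected: dict = {}
        for alphas in itertools.product(range(n + 1), repeat=3):
            if sum(alphas) != n:
                continue
            c = math.factorial(n)
            key = [0] * basis.n
            val = 1.0
            for a, e, g in zip(alphas, exps, coeffs):
                c //= math.factorial(a)
                val *= g ** a
                for i, ei in enumerate(e):
                    key[i] += a * ei
            k = tuple(key)
            expected[k] = expected.get(k, 0.0) + c * val
        result = poly_power(poly, n).terms
        for k in set(expected) | set(result):
            assert result.get(k, 0.0) == pytest.approx(
                expected.get(k, 0.0), rel=1e-10, abs=1e-12)

    def test_basis_mismatch_rejected(self, rng):
        a = _random_poly(primitive_set_for(FamilyKind.TRANSLATION_X1), rng)
        b = PosePolynomial(primitive_set_for(FamilyKind.ROTATION_X3),
                           {(0, 1): 1.0})
        with pytest.raises(BasisMismatchError):
            poly_multiply(a, b)

    def test_negative_power_rejected(self, rng):
        a = _random_poly(primitive_set_for(FamilyKind.TRANSLATION_X1), rng)
        with pytest.raises(ValueError):
            poly_power(a, -1)


class TestPosedCoordinate:
    def test_translation_first_coordinate(self):
        poly = posed_coordinate_polynomial((1, 2, 3), 1, TR)
        assert poly.terms == {(0,): 1.0, (1,): 1.0}

    def test_rotation_second_coordinate_of_unit_x(self):
        poly = posed_coordinate_polynomial((1, 0, 0), 2, ROT)
        assert poly.terms == {(1, 0): 1.0}

    def test_se3_matches_apply_pose(self, rng):
        q0 = rng.normal(0, 2, 3)
        polys = [posed_coordinate_polynomial(q0, c, SE3) for c in (1, 2, 3)]
        for v in _random_se3_values(rng, 10):
            direct = apply_pose(make_pose(SE3, v), q0)
            vals = primitive_values(SE3, v)
            for c in range(3):
                assert polys[c].evaluate(vals) == pytest.approx(
                    direct[c], rel=1e-10, abs=1e-12)
        assert all(p.degree() <= 1 for p in polys)


class TestPairExpansion:
    def test_identity_surrogate_single_pair(self, poly_energy):
        """With surrogate f = d^2, the single-pair energy expansion is just
        the d^2 polynomial times the prefactor."""
        law, _ = poly_energy
        surr = PolynomialSurrogate([0.0, 1.0], (1e-6, 100.0), TARGET_SHAPE_F)
        [poly] = pair_expansion((0, 0, 0), (1, 0, 0), 2.0, 3.0, surr, law,
                                TR, "energy")
        assert poly.terms == {(0,): 6.0, (1,): 12.0, (2,): 6.0}

    def test_translation_degree9_monomial_count(self, poly_energy, rng):
        """A degree-9 energy expansion along x1 contains only x1^0..x1^18."""
        law, _ = poly_energy
        surr = PolynomialSurrogate(rng.normal(size=10), (1e-6, 100.0),
                                   TARGET_SHAPE_F)
        [poly] = pair_expansion(rng.normal(0, 1, 3), rng.normal(3, 1, 3),
                                1.0, 1.0, surr, law, TR, "energy")
        assert poly.n_terms <= 19
        assert max(e[0] for e in poly.terms) <= 18

    def test_rotation_degree9_basis_shape(self, poly_energy, rng):
        """A degree-9 rotation expansion reduces to the
        {sin^k, sin^k cos} family with k <= 9."""
        law, _ = poly_energy
        surr = PolynomialSurrogate(rng.normal(size=10), (1e-6, 100.0),
                                   TARGET_SHAPE_F)
        [poly] = pair_expansion(rng.normal(0, 1, 3), rng.normal(3, 1, 3),
                                1.0, 1.0, surr, law, ROT, "energy")
        for (k, e) in poly.terms:
            assert e <= 1 and k <= 9

    def test_target_mismatch_rejected(self, poly_energy):
        law, surr = poly_energy  # surrogate targets shape_f
        with pytest.raises(SurrogateTargetError):
            pair_expansion((0, 0, 0), (1, 0, 0), 1.0, 1.0, surr, law, TR,
                           "force")


class TestAccumulate:
    def test_linearity_duplicated_pair(self, poly_energy):
        law, surr = poly_energy
        single = ParticleSet([[0.0, 0.0, 0.0]], [1.0])
        double = ParticleSet([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]], [1.0, 1.0])
        q = ParticleSet([[2.0, 0.0, 0.0]], [1.0])
        m1 = accumulate_characteristics(single, q, surr, law, TR, "energy")
        m2 = accumulate_characteristics(double, q, surr, law, TR, "energy")
        assert m1.monomials == m2.monomials
        np.testing.assert_allclose(m2.coefficients, 2.0 * m1.coefficients,
                                   rtol=1e-14)

    def test_single_pair_reduces_to_pair_expansion(self, poly_energy):
        law, surr = poly_energy
        p0, q0 = np.array([0.3, -0.2, 0.5]), np.array([2.5, 0.4, -0.1])
        P = ParticleSet([p0], [1.3])
        Q = ParticleSet([q0], [0.7])
        model = accumulate_characteristics(P, Q, surr, law, TR, "energy")
        [poly] = pair_expansion(p0, q0, 1.3, 0.7, surr, law, TR, "energy")
        for mono, coef in zip(model.monomials, model.coefficients[0]):
            assert coef == pytest.approx(poly.terms.get(mono, 0.0), rel=1e-12)

    def test_additivity_over_body_partition(self, poly_energy, rng):
        """Characteristics of P1 u P2 equal the sum of those of (P1,Q) and
        (P2,Q)."""
        law, surr = poly_energy
        coords = rng.normal(0, 1, (6, 3))
        props = rng.uniform(0.5, 1.5, 6)
        Q = ParticleSet(rng.normal(4, 1, (4, 3)), rng.uniform(0.5, 1.5, 4))
        whole = accumulate_characteristics(
            ParticleSet(coords, props), Q, surr, law, TR, "energy")
        part1 = accumulate_characteristics(
            ParticleSet(coords[:2], props[:2]), Q, surr, law, TR, "energy")
        part2 = accumulate_characteristics(
            ParticleSet(coords[2:], props[2:]), Q, surr, law, TR, "energy")

        def as_dict(m):
            return dict(zip(m.monomials, m.coefficients[0]))

        d1, d2, dw = as_dict(part1), as_dict(part2), as_dict(whole)
        for k in set(d1) | set(d2) | set(dw):
            assert dw.get(k, 0.0) == pytest.approx(
                d1.get(k, 0.0) + d2.get(k, 0.0), rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("family", [TR, ROT], ids=["translation",
                                                       "rotation"])
    @pytest.mark.parametrize("output", ["energy", "force", "moment"])
    def test_fast_engine_matches_generic(self, family, output, small_pair,
                                         poly_energy, poly_force, rng):
        """The vectorized dense engine and the sparse per-pair engine produce
        the same net values."""
        P, Q = small_pair
        law, surr = poly_energy if output == "energy" else poly_force
        fast = accumulate_characteristics(P, Q, surr, law, family, output,
                                          engine="fast")
        generic = accumulate_characteristics(P, Q, surr, law, family, output,
                                             engine="generic")
        for v in rng.uniform(-2, 2, 8):
            np.testing.assert_allclose(
                np.atleast_1d(net_value(fast, [v])),
                np.atleast_1d(net_value(generic, [v])), rtol=1e-9, atol=1e-9)

    def test_exact_polynomial_matches_brute_force(self, poly_energy, rng):
        """Lemma-1 pipeline with zero regression error: the model equals the
        brute-force pairwise sum at 20 poses, M = N = 10."""
        law, surr = poly_energy
        P = ParticleSet(rng.normal(0, 1, (10, 3)), rng.uniform(0.5, 1.5, 10))
        Q = ParticleSet(rng.normal(4, 1, (10, 3)), rng.uniform(0.5, 1.5, 10))
        model = accumulate_characteristics(P, Q, surr, law, TR, "energy")
        for v in rng.uniform(0, 5, 20):
            brute = brute_force_net(P, Q, law, make_pose(TR, [v]), "energy")
            assert net_value(model, [v]) == pytest.approx(brute, rel=1e-9)

    def test_model_bytes_independent_of_sweep(self, poly_energy, small_pair):
        law, surr = poly_energy
        P, Q = small_pair
        m1 = accumulate_characteristics(P, Q, surr, law, TR, "energy")
        blob1 = json.dumps(m1.to_json(), sort_keys=True)
        for v in (0.0, 1.0, 4.0):  # evaluate a sweep in between
            net_value(m1, [v])
        m2 = accumulate_characteristics(P, Q, surr, law, TR, "energy")
        assert json.dumps(m2.to_json(), sort_keys=True) == blob1

    def test_model_json_round_trip(self, poly_energy, small_pair, tmp_path):
        law, surr = poly_energy
        P, Q = small_pair
        model = accumulate_characteristics(P, Q, surr, law, ROT, "energy")
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CharacteristicModel.load(path)
        assert loaded.monomials == model.monomials
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        assert net_value(loaded, [0.7]) == pytest.approx(
            net_value(model, [0.7]))


class TestD2Range:
    def test_static_single_points(self):
        P = ParticleSet([[0.0, 0.0, 0.0]], [1.0])
        Q = ParticleSet([[1.0, 0.0, 0.0]], [1.0])
        assert compute_d2_range(P, Q, TR, (0.0, 0.0)) == (1.0, 1.0)

    def test_translated_single_points(self):
        P = ParticleSet([[0.0, 0.0, 0.0]], [1.0])
        Q = ParticleSet([[1.0, 0.0, 0.0]], [1.0])
        lo, hi = compute_d2_range(P, Q, TR, (0.0, 5.0), grid=11)
        assert (lo, hi) == (1.0, 36.0)

    def test_brackets_direct_recomputation(self, small_pair, rng):
        P, Q = small_pair
        lo, hi = compute_d2_range(P, Q, ROT, (-math.pi / 2, 0.0), grid=21)
        for v in np.linspace(-math.pi / 2, 0.0, 21):
            qp = apply_pose(make_pose(ROT, [v]), Q.coords)
            d2 = ((qp[None, :, :] - P.coords[:, None, :]) ** 2).sum(-1)
            assert d2.min() >= lo - 1e-12
            assert d2.max() <= hi + 1e-12
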