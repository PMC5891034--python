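import numpy as np
import pytest

from sepint.interactions import make_law
from sepint.particles import ParticleSet
from sepint.surrogate import (
    PolynomialSurrogate,
    TARGET_SHAPE_F,
    TARGET_SHAPE_F_OVER_D,
)

#: coefficients of the exact polynomial-in-d^2 debug law used throughout
POLY_COEFFS = (2.0, 3.0, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair(rng):
    """Two small, well-separated random particle sets."""
    P = ParticleSet(rng.normal(0.0, 1.0, (5, 3)),
                    rng.uniform(0.5, 1.5, 5), label="P")
    Q = ParticleSet(rng.normal(4.0, 1.0, (6, 3)),
                    rng.uniform(0.5, 1.5, 6), label="Q")
    return P, Q


@pytest.fixture
def poly_energy():
    """Exact-polynomial energy law plus the surrogate that reproduces it
    with zero regression error."""
    law = make_law("poly_d2", coeffs=POLY_COEFFS)
    surr = PolynomialSurrogate(np.asarray(POLY_COEFFS), (1e-6, 1e4),
                               TARGET_SHAPE_F)
    return law, surr


@pytest.fixture
def poly_force():
    """Exact-polynomial central-force law (|f|/d is the polynomial)."""
    law = make_law("poly_d2", coeffs=POLY_COEFFS,
                   output_kind="central_force_vector")
    surr = PolynomialSurrogate(np.asarray(POLY_COEFFS), (1e-6, 1e4),
                               TARGET_SHAPE_F_OVER_D)
    return law, surr
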