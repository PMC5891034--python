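"""Pairwise distance-dependent interaction laws.

Every law factors as ``magnitude(d, lp, lq) = prefactor(lp, lq) * shape(d)``
where ``lp``/``lq`` are the pose-independent scalar properties of the two
particles (e.g. charges) and ``shape`` carries the whole distance
dependence.  This separability of the scalar prefactor is what lets the
geometry coefficients of a pair expansion be pre-summed; laws that do not
factor this way are rejected at registration.

Both ``shape`` and ``prefactor`` must accept NumPy arrays (broadcasting),
which the brute-force oracle and the vectorized accumulation rely on.

Units: the default dielectric constant satisfies ``4*pi*eps = 1``, so the
Coulomb energy is simply ``lp*lq/d``; all reported energies are then
dimensionless products of the charge and length units chosen by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import SeparabilityError, SingularityError

__all__ = [
    "InteractionLaw",
    "coulomb_energy",
    "make_law",
    "registered_laws",
    "check_separable",
    "central_force_components",
    "pairwise_moment",
    "EPS_DEFAULT",
]

#: Dielectric constant normalized so that 4*pi*eps = 1.
EPS_DEFAULT = 1.0 / (4.0 * math.pi)

SCALAR_ENERGY = "scalar_energy"
CENTRAL_FORCE = "central_force_vector"

_D_TINY = 1e-300


@dataclass(frozen=True)
class InteractionLaw:
    """A pairwise law ``prefactor(lp, lq) * shape(d)``.

    ``output_kind`` is ``"scalar_energy"`` for scalar laws and
    ``"central_force_vector"`` for laws whose value is the magnitude of a
    central force directed along the pair separation.  For vector laws the
    quantity expanded in the pose algebra is ``|f|/d`` (so components come
    out as polynomials times coordinate differences); ``shape_over_d``
    provides it, with an optional exact override for laws where the division
    can be done symbolically.
    """

    name: str
    shape: Callable[[np.ndarray], np.ndarray]
    prefactor: Callable[[np.ndarray, np.ndarray], np.ndarray]
    output_kind: str = SCALAR_ENERGY
    params: Mapping[str, object] = field(default_factory=dict)
    shape_over_d_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def magnitude(self, d, lp, lq):
        return self.prefactor(lp, lq) * self.shape(d)

    def shape_over_d(self, d):
        if self.shape_over_d_fn is not None:
            return self.shape_over_d_fn(d)
        return self.shape(d) / d


def coulomb_energy(lam_i: float, lam_j: float, d: float,
                   eps: float = EPS_DEFAULT):
    """Electrostatic energy of two point charges: ``lam_i*lam_j/(4*pi*eps*d)``."""
    if eps <= 0:
        raise ValueError("dielectric constant must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise SingularityError("coulomb energy requires d > 0")
    out = lam_i * lam_j / (4.0 * math.pi * eps * d)
    return float(out) if out.ndim == 0 else out


def check_separable(law: InteractionLaw, rng: np.random.Generator | None = None,
                    n: int = 64, tol: float = 1e-10) -> None:
    """Verify on a random grid that the law's property dependence factors
    through ``prefactor`` alone; raise :class:`SeparabilityError` otherwise."""
    rng = rng or np.random.default_rng(0)
    d = rng.uniform(0.5, 5.0, n)
    lp = rng.uniform(0.5, 2.0, n)
    lq = rng.uniform(0.5, 2.0, n)
    s11 = law.prefactor(1.0, 1.0)
    lhs = law.magnitude(d, lp, lq)
    rhs = law.prefactor(lp, lq) * law.magnitude(d, 1.0, 1.0) / s11
    scale = np.max(np.abs(lhs)) + 1e-30
    if np.max(np.abs(lhs - rhs)) > tol * scale:
        raise SeparabilityError(
            f"law {law.name!r} does not factor as prefactor(lp,lq)*shape(d)"
        )


def _product_prefactor(lp, lq):
    return np.asarray(lp, dtype=float) * np.asarray(lq, dtype=float)


def _unit_prefactor(lp, lq):
    shape = np.broadcast(np.asarray(lp), np.asarray(lq)).shape
    return np.ones(shape) if shape else 1.0


def _coulomb_energy_law(eps: float = EPS_DEFAULT) -> InteractionLaw:
    c = 1.0 / (4.0 * math.pi * eps)
    return InteractionLaw(
        name="coulomb_energy",
        shape=lambda d: c / d,
        prefactor=_product_prefactor,
        output_kind=SCALAR_ENERGY,
        params={"eps": eps},
    )


def _coulomb_force_law(eps: float = EPS_DEFAULT) -> InteractionLaw:
    # |f| = lp*lq/(4 pi eps d^2); the expanded quantity |f|/d = c/d^3
    c = 1.0 / (4.0 * math.pi * eps)
    return InteractionLaw(
        name="coulomb_force",
        shape=lambda d: c / d**2,
        prefactor=_product_prefactor,
        output_kind=CENTRAL_FORCE,
        params={"eps": eps},
        shape_over_d_fn=lambda d: c / d**3,
    )


def _spring_law(k: float = 1.0) -> InteractionLaw:
    return InteractionLaw(
        name="spring",
        shape=lambda d: k * np.asarray(d, dtype=float),
        prefactor=_unit_prefactor,
        output_kind=CENTRAL_FORCE,
        params={"k": k},
        shape_over_d_fn=lambda d: k * np.ones_like(np.asarray(d, dtype=float)),
    )


def _power_law(amplitude: float = 1.0, exponent: int = 6,
               output_kind: str = SCALAR_ENERGY) -> InteractionLaw:
    return InteractionLaw(
        name="power_law",
        shape=lambda d: amplitude / np.asarray(d, dtype=float) ** exponent,
        prefactor=_product_prefactor,
        output_kind=output_kind,
        params={"amplitude": amplitude, "exponent": exponent},
    )


def _lj_energy_law(a: float = 1.0, b: float = 1.0) -> InteractionLaw:
    # Lennard-Jones-like A/d^12 - B/d^6; property-free, so s == 1.
    return InteractionLaw(
        name="lj_energy",
        shape=lambda d: a / np.asarray(d, dtype=float) ** 12
        - b / np.asarray(d, dtype=float) ** 6,
        prefactor=_unit_prefactor,
        output_kind=SCALAR_ENERGY,
        params={"a": a, "b": b},
    )


def _poly_d2_law(coeffs: Sequence[float] = (0.0, 1.0),
                 output_kind: str = SCALAR_ENERGY) -> InteractionLaw:
    """Debug law whose shape is an exact polynomial in d^2.

    For ``scalar_energy`` the energy shape is ``sum c_k (d^2)^k``; for
    ``central_force_vector`` the *ratio* |f|/d is that polynomial (so the
    magnitude is d times it), making the whole pipeline regression-free.
    """
    c = np.asarray(coeffs, dtype=float)

    def poly(d):
        return np.polynomial.polynomial.polyval(
            np.asarray(d, dtype=float) ** 2, c)

    if output_kind == SCALAR_ENERGY:
        return InteractionLaw("poly_d2", poly, _product_prefactor,
                              SCALAR_ENERGY, {"coeffs": tuple(c)})
    return InteractionLaw(
        "poly_d2", lambda d: np.asarray(d, dtype=float) * poly(d),
        _product_prefactor, CENTRAL_FORCE, {"coeffs": tuple(c)},
        shape_over_d_fn=poly,
    )


_FACTORIES: dict[str, Callable[..., InteractionLaw]] = {
    "coulomb_energy": _coulomb_energy_law,
    "coulomb_force": _coulomb_force_law,
    "spring": _spring_law,
    "power_law": _power_law,
    "lj_energy": _lj_energy_law,
    "poly_d2": _poly_d2_law,
}


def registered_laws() -> tuple[str, ...]:
    return tuple(_FACTORIES)


def make_law(name: str, **params) -> InteractionLaw:
    """Build a registered law by name and verify prefactor separability."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown interaction law {name!r}; known: {sorted(_FACTORIES)}"
        ) from None
    law = factory(**params)
    check_separable(law)
    return law


def central_force_components(law: InteractionLaw, p, q_posed, lam_i, lam_j):
    """Cartesian components of a central pairwise force:
    ``(|f|/d) * (q_l - p_l)`` for l = 1..3 (directed from p toward q)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q_posed, dtype=float)
    diff = q - p
    d = float(np.linalg.norm(diff))
    if d < 1e-12:
        raise SingularityError("coincident points in central force evaluation")
    fod = float(law.prefactor(lam_i, lam_j)) * float(law.shape_over_d(d))
    return fod * diff


def pairwise_moment(q_posed, force):
    """Moment of a pairwise force about the origin of P's frame:
    ``q_posed x force``."""
    return np.cross(np.asarray(q_posed, dtype=float),
                    np.asarray(force, dtype=float))
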