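"""Pose-basis algebra and characteristic-constant accumulation.

A pairwise quantity such as the squared distance between a fixed point of P
and a posed point of Q is a *pose polynomial*: a sum of monomials in a small
set of scalar pose primitives (``x1`` for 1-D translation; ``sin theta``,
``cos theta`` for 1-D rotation; the nine rotation-matrix entries plus the
translation for general rigid motion) whose numeric coefficients depend only
on the reference geometry of the pair.  Raising such a polynomial to integer
powers — which composing with the squared-distance surrogate requires —
stays inside the same algebra, so the per-pair expansion of the surrogated
law is a pose polynomial too.  Summing those expansions termwise over all
M*N pairs yields the *characteristic constants* C_k: after this one-time
quadratic pass, the net interaction at any pose costs one evaluation of each
pose basis monomial, independent of the particle counts.

Two interchangeable accumulation engines are provided: a generic sparse one
valid for every family, and a vectorized dense one for the two one-parameter
families where the basis is a small enumerable list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    BasisMismatchError,
    SurrogateTargetError,
    UnsupportedFamilyError,
)
from .geometry import FamilyKind, PoseFamily, Pose, apply_pose, make_pose
from .interactions import (
    CENTRAL_FORCE,
    SCALAR_ENERGY,
    InteractionLaw,
)
from .particles import ParticleSet
from .surrogate import (
    PolynomialSurrogate,
    TARGET_SHAPE_F,
    TARGET_SHAPE_F_OVER_D,
)

__all__ = [
    "PosePrimitiveSet",
    "PosePolynomial",
    "CharacteristicModel",
    "primitive_set_for",
    "primitive_values",
    "d2_polynomial",
    "posed_coordinate_polynomial",
    "poly_multiply",
    "poly_power",
    "pair_expansion",
    "accumulate_characteristics",
    "compute_d2_range",
    "OUTPUT_ENERGY",
    "OUTPUT_FORCE",
    "OUTPUT_MOMENT",
]

OUTPUT_ENERGY = "energy"
OUTPUT_FORCE = "force"
OUTPUT_MOMENT = "moment"

_COMPONENT_LABELS = {
    OUTPUT_ENERGY: ("energy",),
    OUTPUT_FORCE: ("fx", "fy", "fz"),
    OUTPUT_MOMENT: ("mx", "my", "mz"),
}

#: relative tolerance below which monomial coefficients are pruned
PRUNE_RTOL = 1e-14

_SE3_PRIMS = tuple(f"R{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)) + (
    "x1", "x2", "x3")

_PRIMITIVES = {
    FamilyKind.TRANSLATION_X1: ("x1",),
    FamilyKind.ROTATION_X3: ("sin_theta", "cos_theta"),
    FamilyKind.GENERAL_SE3: _SE3_PRIMS,
}


@dataclass(frozen=True)
class PosePrimitiveSet:
    """Named scalar pose functions plus the rewrite rule applied to their
    monomials (for the rotation family: cos^2 -> 1 - sin^2, so reduced
    monomials carry a cosine exponent of at most one)."""

    name: str
    primitives: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.primitives)

    def reduce_term(self, exps: tuple[int, ...], coeff: float
                    ) -> dict[tuple[int, ...], float]:
        if self.name != FamilyKind.ROTATION_X3.value or exps[1] < 2:
            return {exps: coeff}
        a, e = exps
        m, rem = divmod(e, 2)
        out: dict[tuple[int, ...], float] = {}
        # cos^e = (1 - sin^2)^m * cos^rem, expanded binomially
        for j in range(m + 1):
            key = (a + 2 * j, rem)
            out[key] = out.get(key, 0.0) + coeff * math.comb(m, j) * (-1.0) ** j
        return out


@lru_cache(maxsize=None)
def primitive_set_for(kind: FamilyKind) -> PosePrimitiveSet:
    kind = FamilyKind(kind)
    return PosePrimitiveSet(kind.value, _PRIMITIVES[kind])


def primitive_values(family: PoseFamily, values: Sequence[float]) -> np.ndarray:
    """Numeric values of the family's pose primitives at a free-parameter
    vector: ``[x1]``; ``[sin theta, cos theta]``; or the nine rotation-matrix
    entries (row-major) followed by the translation."""
    kind = family.kind
    vals = np.asarray(values, dtype=float).ravel()
    if kind is FamilyKind.TRANSLATION_X1:
        return np.array([vals[0]])
    if kind is FamilyKind.ROTATION_X3:
        return np.array([math.sin(vals[0]), math.cos(vals[0])])
    if kind is FamilyKind.GENERAL_SE3:
        pose = make_pose(family, vals)
        return np.concatenate(
            [pose.rotation_matrix().ravel(), pose.translation])
    raise UnsupportedFamilyError(str(kind))


class PosePolynomial:
    """Sparse multivariate polynomial over a pose-primitive set.

    Terms map exponent tuples (one non-negative integer per primitive) to
    numeric coefficients; construction applies the basis reduction rules and
    drops coefficients below ``PRUNE_RTOL`` relative to the largest one.
    """

    __slots__ = ("basis", "terms")

    def __init__(self, basis: PosePrimitiveSet,
                 terms: Mapping[tuple[int, ...], float] | None = None):
        self.basis = basis
        reduced: dict[tuple[int, ...], float] = {}
        for exps, coeff in (terms or {}).items():
            if coeff == 0.0:
                continue
            for k, v in basis.reduce_term(tuple(exps), float(coeff)).items():
                reduced[k] = reduced.get(k, 0.0) + v
        self.terms = _pruned(reduced)

    # -- constructors -------------------------------------------------
    @classmethod
    def constant(cls, basis: PosePrimitiveSet, c: float) -> "PosePolynomial":
        return cls(basis, {(0,) * basis.n: float(c)})

    @classmethod
    def from_primitive(cls, basis: PosePrimitiveSet, name: str,
                       coeff: float = 1.0) -> "PosePolynomial":
        idx = basis.primitives.index(name)
        exps = tuple(1 if i == idx else 0 for i in range(basis.n))
        return cls(basis, {exps: float(coeff)})

    # -- algebra ------------------------------------------------------
    def _check(self, other: "PosePolynomial") -> None:
        if self.basis.name != other.basis.name:
            raise BasisMismatchError(
                f"cannot combine polynomials over bases "
                f"{self.basis.name!r} and {other.basis.name!r}"
            )

    def __add__(self, other):
        if isinstance(other, (int, float)):
            other = PosePolynomial.constant(self.basis, other)
        self._check(other)
        out = dict(self.terms)
        for k, v in other.terms.items():
            out[k] = out.get(k, 0.0) + v
        return PosePolynomial(self.basis, out)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + other.scale(-1.0)

    def scale(self, c: float) -> "PosePolynomial":
        return PosePolynomial(
            self.basis, {k: v * c for k, v in self.terms.items()})

    def multiply(self, other: "PosePolynomial") -> "PosePolynomial":
        self._check(other)
        out: dict[tuple[int, ...], float] = {}
        for ea, ca in self.terms.items():
            for eb, cb in other.terms.items():
                key = tuple(x + y for x, y in zip(ea, eb))
                out[key] = out.get(key, 0.0) + ca * cb
        return PosePolynomial(self.basis, out)

    def power(self, k: int) -> "PosePolynomial":
        if k < 0 or k != int(k):
            raise ValueError("power exponent must be a non-negative integer")
        result = PosePolynomial.constant(self.basis, 1.0)
        for _ in range(int(k)):
            result = result.multiply(self)
        return result

    # -- queries ------------------------------------------------------
    def evaluate(self, prim_values: Sequence[float]) -> float:
        v = np.asarray(prim_values, dtype=float)
        total = 0.0
        for exps, coeff in self.terms.items():
            total += coeff * float(np.prod(v ** np.asarray(exps)))
        return total

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def degree(self) -> int:
        return max((sum(e) for e in self.terms), default=0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PosePolynomial({self.basis.name}, {self.terms})"


def _pruned(terms: dict[tuple[int, ...], float]) -> dict[tuple[int, ...], float]:
    if not terms:
        return {}
    cmax = max(abs(c) for c in terms.values())
    if cmax == 0.0:
        return {}
    cut = PRUNE_RTOL * cmax
    return {k: v for k, v in terms.items() if abs(v) > cut}


def poly_multiply(a: PosePolynomial, b: PosePolynomial) -> PosePolynomial:
    """Distributive product of two pose polynomials over the same basis."""
    return a.multiply(b)


def poly_power(a: PosePolynomial, k: int) -> PosePolynomial:
    """k-fold product of ``a`` with itself; ``k = 0`` gives the constant 1."""
    return a.power(k)


def posed_coordinate_polynomial(q0: Sequence[float], component: int,
                                family: PoseFamily) -> PosePolynomial:
    """The ``component``-th (1-based) coordinate of a posed point of Q as a
    degree-<=1 pose polynomial."""
    if component not in (1, 2, 3):
        raise ValueError("component must be 1, 2 or 3")
    q0 = np.asarray(q0, dtype=float)
    basis = primitive_set_for(family.kind)
    kind = family.kind
    l = component - 1
    fix = family.fixed_translation()
    if kind is FamilyKind.TRANSLATION_X1:
        terms = {(0,): q0[l] + fix[l]}
        if l == 0:
            terms[(1,)] = terms.get((1,), 0.0) + 1.0
        return PosePolynomial(basis, terms)
    if kind is FamilyKind.ROTATION_X3:
        # q(theta) = (q1 c - q2 s, q1 s + q2 c, q3) + fixed offset
        if l == 0:
            return PosePolynomial(
                basis, {(0, 0): fix[0], (0, 1): q0[0], (1, 0): -q0[1]})
        if l == 1:
            return PosePolynomial(
                basis, {(0, 0): fix[1], (1, 0): q0[0], (0, 1): q0[1]})
        return PosePolynomial(basis, {(0, 0): q0[2] + fix[2]})
    if kind is FamilyKind.GENERAL_SE3:
        terms: dict[tuple[int, ...], float] = {}
        n = basis.n
        for m in range(3):
            idx = 3 * l + m  # R_{l+1, m+1}
            exps = tuple(1 if i == idx else 0 for i in range(n))
            terms[exps] = q0[m]
        exps = tuple(1 if i == 9 + l else 0 for i in range(n))
        terms[exps] = terms.get(exps, 0.0) + 1.0
        return PosePolynomial(basis, terms)
    raise UnsupportedFamilyError(str(kind))


def d2_polynomial(p0: Sequence[float], q0: Sequence[float],
                  family: PoseFamily) -> PosePolynomial:
    """Squared distance between fixed ``p0`` and posed ``q0`` as a pose
    polynomial: ``sum_l (q_l(pose) - p0_l)^2`` expanded in the family's
    primitives (with the cos^2 reduction applied for the rotation family)."""
    p0 = np.asarray(p0, dtype=float)
    basis = primitive_set_for(family.kind)
    total = PosePolynomial.constant(basis, 0.0)
    for comp in (1, 2, 3):
        cl = posed_coordinate_polynomial(q0, comp, family) - float(p0[comp - 1])
        total = total + cl.multiply(cl)
    return total


def _surrogate_poly(d2p: PosePolynomial,
                    coeffs: np.ndarray) -> PosePolynomial:
    """``sum_k a_k (d2p)^k`` built by iterated multiplication."""
    basis = d2p.basis
    acc = PosePolynomial.constant(basis, float(coeffs[0]))
    cur = PosePolynomial.constant(basis, 1.0)
    for a_k in coeffs[1:]:
        cur = cur.multiply(d2p)
        acc = acc + cur.scale(float(a_k))
    return acc


def _check_target(surrogate: PolynomialSurrogate, output_kind: str) -> None:
    want = TARGET_SHAPE_F if output_kind == OUTPUT_ENERGY else TARGET_SHAPE_F_OVER_D
    if surrogate.target != want:
        raise SurrogateTargetError(
            f"surrogate target {surrogate.target!r} cannot produce "
            f"{output_kind!r} output (expected {want!r})"
        )


def pair_expansion(p0, q0, lam_i: float, lam_j: float,
                   surrogate: PolynomialSurrogate, law: InteractionLaw,
                   family: PoseFamily, output_kind: str
                   ) -> list[PosePolynomial]:
    """Expansion of one pair's contribution as pose polynomials, one per
    output component.

    Energy: ``s(lam_i, lam_j) * sum_k a_k (d^2)^k``.  Force component l:
    the |f|/d expansion times ``(q_l(pose) - p0_l)``.  Moment: the cross
    product of the posed coordinates with the force components, expanded in
    the same algebra.
    """
    _check_target(surrogate, output_kind)
    p0 = np.asarray(p0, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    s = float(law.prefactor(lam_i, lam_j))
    phi = _surrogate_poly(d2_polynomial(p0, q0, family), surrogate.coeffs)
    if output_kind == OUTPUT_ENERGY:
        return [phi.scale(s)]
    coords = [posed_coordinate_polynomial(q0, c, family) for c in (1, 2, 3)]
    force = [
        phi.multiply(coords[l] - float(p0[l])).scale(s) for l in range(3)
    ]
    if output_kind == OUTPUT_FORCE:
        return force
    if output_kind == OUTPUT_MOMENT:
        c1, c2, c3 = coords
        f1, f2, f3 = force
        return [
            c2.multiply(f3) - c3.multiply(f2),
            c3.multiply(f1) - c1.multiply(f3),
            c1.multiply(f2) - c2.multiply(f1),
        ]
    raise ValueError(f"unknown output kind {output_kind!r}")


@dataclass
class CharacteristicModel:
    """Pre-summed geometry of a body pair: a shared pose-monomial list plus
    one characteristic-constant vector per output component.

    Evaluating the net interaction at a pose reduces to the dot products of
    these vectors with the monomial values — no pairwise work remains.
    """

    family_kind: FamilyKind
    fixed_values: dict[str, float]
    monomials: list[tuple[int, ...]]
    component_labels: tuple[str, ...]
    coefficients: np.ndarray  # (n_components, n_monomials)
    output_kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.family_kind = FamilyKind(self.family_kind)
        self.coefficients = np.atleast_2d(
            np.asarray(self.coefficients, dtype=float))
        if self.coefficients.shape != (len(self.component_labels),
                                       len(self.monomials)):
            raise ValueError("coefficient matrix shape mismatch")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("characteristic constants must be finite")

    @property
    def basis(self) -> PosePrimitiveSet:
        return primitive_set_for(self.family_kind)

    @property
    def family(self) -> PoseFamily:
        return PoseFamily(self.family_kind, self.fixed_values)

    @property
    def n_terms(self) -> int:
        return len(self.monomials)

    @property
    def exponent_matrix(self) -> np.ndarray:
        return np.asarray(self.monomials, dtype=int).reshape(
            len(self.monomials), self.basis.n)

    # -- serialization ------------------------------------------------
    def to_json(self) -> dict:
        return {
            "family": self.family_kind.value,
            "fixed_values": self.fixed_values,
            "primitives": list(self.basis.primitives),
            "monomials": [list(m) for m in self.monomials],
            "components": list(self.component_labels),
            "coefficients": self.coefficients.tolist(),
            "output_kind": self.output_kind,
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CharacteristicModel":
        return cls(
            FamilyKind(obj["family"]),
            dict(obj.get("fixed_values", {})),
            [tuple(m) for m in obj["monomials"]],
            tuple(obj["components"]),
            np.asarray(obj["coefficients"], dtype=float),
            obj["output_kind"],
            dict(obj.get("provenance", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CharacteristicModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def compute_d2_range(P: ParticleSet, Q: ParticleSet, family: PoseFamily,
                     sweep: Sequence[float], grid: int = 101
                     ) -> tuple[float, float]:
    """Min/max pairwise squared distance over ``grid`` evenly spaced values
    of the family's (single) sweep parameter; exact at the evaluated poses.

    For ``general_se3``, ``sweep`` must instead be an iterable of full
    parameter vectors and ``grid`` is ignored.
    """
    if P.n == 0 or Q.n == 0:
        raise ValueError("particle sets must be non-empty")
    if family.kind is FamilyKind.GENERAL_SE3:
        values: Iterable[Sequence[float]] = [np.asarray(v, float) for v in sweep]
    else:
        if grid < 2:
            raise ValueError("grid must be at least 2")
        lo, hi = float(sweep[0]), float(sweep[1])
        values = [[v] for v in np.linspace(lo, hi, grid)]
    d2_min, d2_max = np.inf, -np.inf
    for v in values:
        pose = make_pose(family, v)
        qp = apply_pose(pose, Q.coords)
        diff = qp[None, :, :] - P.coords[:, None, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        d2_min = min(d2_min, float(d2.min()))
        d2_max = max(d2_max, float(d2.max()))
    return d2_min, d2_max


# ----------------------------------------------------------------------
# accumulation engines
# ----------------------------------------------------------------------

def accumulate_characteristics(P: ParticleSet, Q: ParticleSet,
                               surrogate: PolynomialSurrogate,
                               law: InteractionLaw, family: PoseFamily,
                               output_kind: str, *,
                               engine: str = "auto",
                               chunk: int = 131072) -> CharacteristicModel:
    """Sum the pair expansions of all M*N pairs into characteristic
    constants (one O(M*N) preprocessing pass; the resulting model size is
    independent of M and N).

    ``engine="fast"`` selects the vectorized dense path (translation and
    rotation families only); ``engine="generic"`` the sparse per-pair path;
    ``"auto"`` picks the fast path whenever it applies.  Both engines
    produce the same constants to rounding.
    """
    _check_target(surrogate, output_kind)
    if output_kind not in _COMPONENT_LABELS:
        raise ValueError(f"unknown output kind {output_kind!r}")
    fast_ok = family.kind in (FamilyKind.TRANSLATION_X1, FamilyKind.ROTATION_X3)
    if engine == "auto":
        engine = "fast" if fast_ok else "generic"
    if engine == "fast" and not fast_ok:
        raise UnsupportedFamilyError(
            f"fast engine does not support family {family.kind.value}")
    if engine not in ("fast", "generic"):
        raise ValueError(f"unknown engine {engine!r}")

    labels = _COMPONENT_LABELS[output_kind]
    provenance = {
        "p_label": P.label, "q_label": Q.label, "M": int(P.n), "N": int(Q.n),
        "law": law.name, "law_params": {k: v for k, v in law.params.items()},
        "surrogate": surrogate.to_json(),
        "family": family.kind.value,
        "engine": engine,
    }

    if engine == "generic":
        monomials, coeffs = _accumulate_generic(
            P, Q, surrogate, law, family, output_kind)
    elif family.kind is FamilyKind.TRANSLATION_X1:
        monomials, coeffs = _accumulate_fast_translation(
            P, Q, surrogate, law, family, output_kind, chunk)
    else:
        monomials, coeffs = _accumulate_fast_rotation(
            P, Q, surrogate, law, family, output_kind, chunk)

    return CharacteristicModel(
        family.kind, dict(family.fixed_values), monomials, labels,
        coeffs, output_kind, provenance)


def _accumulate_generic(P, Q, surrogate, law, family, output_kind):
    labels = _COMPONENT_LABELS[output_kind]
    sums: list[dict[tuple[int, ...], float]] = [dict() for _ in labels]
    comps: list[dict[tuple[int, ...], float]] = [dict() for _ in labels]
    for i in range(P.n):
        for j in range(Q.n):
            polys = pair_expansion(
                P.coords[i], Q.coords[j], P.props[i], Q.props[j],
                surrogate, law, family, output_kind)
            for c, poly in enumerate(polys):
                s, comp = sums[c], comps[c]
                for key, val in poly.terms.items():
                    # Kahan compensation per coefficient
                    y = val - comp.get(key, 0.0)
                    t = s.get(key, 0.0) + y
                    comp[key] = (t - s.get(key, 0.0)) - y
                    s[key] = t
    keys = sorted(set().union(*[set(s) for s in sums]))
    coeffs = np.array([[s.get(k, 0.0) for k in keys] for s in sums])
    keys, coeffs = _prune_model(keys, coeffs)
    return keys, coeffs


def _prune_model(monomials, coeffs):
    if coeffs.size == 0:
        return monomials, coeffs
    cmax = np.max(np.abs(coeffs))
    if cmax == 0.0:
        return [monomials[0]] if monomials else [], coeffs[:, :1]
    keep = np.max(np.abs(coeffs), axis=0) > PRUNE_RTOL * cmax
    if not keep.any():
        keep[0] = True
    return [m for m, k in zip(monomials, keep) if k], coeffs[:, keep]


class _Kahan:
    """Compensated accumulation of equally shaped arrays across chunks."""

    def __init__(self, shape):
        self.sum = np.zeros(shape)
        self.comp = np.zeros(shape)

    def add(self, inc):
        y = inc - self.comp
        t = self.sum + y
        self.comp = (t - self.sum) - y
        self.sum = t


def _pair_chunks(P, Q, chunk):
    total = P.n * Q.n
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        yield idx // Q.n, idx % Q.n


def _tr_mul(arr, used, c0, c1, quadratic):
    """Multiply row polynomials (coefficients in x1) by ``c0 + c1*x1``
    (+ ``x1^2`` when ``quadratic``)."""
    out = np.zeros_like(arr)
    seg = arr[:, :used]
    out[:, :used] = seg * c0[:, None]
    out[:, 1:used + 1] += seg * c1[:, None]
    if quadratic:
        out[:, 2:used + 2] += seg
        return out, used + 2
    return out, used + 1


def _accumulate_fast_translation(P, Q, surrogate, law, family, output_kind,
                                 chunk):
    a = surrogate.coeffs
    deg = surrogate.degree
    L = 2 * deg + 3
    fix = family.fixed_translation()
    n_comp = len(_COMPONENT_LABELS[output_kind])
    acc_C = _Kahan((n_comp, L))
    for i_idx, j_idx in _pair_chunks(P, Q, chunk):
        m = i_idx.size
        dp = P.coords[i_idx]
        qf = Q.coords[j_idx] + fix
        delta = qf - dp
        D0 = np.einsum("ij,ij->i", delta, delta)
        b1 = 2.0 * delta[:, 0]
        s = np.asarray(law.prefactor(P.props[i_idx], Q.props[j_idx]),
                       dtype=float)
        acc = np.zeros((m, L))
        acc[:, 0] = a[0]
        cur = np.zeros((m, L))
        cur[:, 0] = 1.0
        used = 1
        for k in range(1, deg + 1):
            cur, used = _tr_mul(cur, used, D0, b1, quadratic=True)
            acc[:, :used] += a[k] * cur[:, :used]
        if output_kind == OUTPUT_ENERGY:
            acc_C.add((s @ acc)[None, :])
            continue
        F = []
        for l in range(3):
            Fl = acc * delta[:, l][:, None]
            if l == 0:
                Fl[:, 1:] += acc[:, :-1]
            F.append(Fl)
        if output_kind == OUTPUT_FORCE:
            acc_C.add(np.stack([s @ Fl for Fl in F]))
            continue
        # moment: posed coordinates q_l(x1) = qf_l (+ x1 for l = 1)
        q1, q2, q3 = qf[:, 0][:, None], qf[:, 1][:, None], qf[:, 2][:, None]

        def _x_shift(A):
            out = np.zeros_like(A)
            out[:, 1:] = A[:, :-1]
            return out

        m1 = q2 * F[2] - q3 * F[1]
        m2 = q3 * F[0] - (q1 * F[2] + _x_shift(F[2]))
        m3 = (q1 * F[1] + _x_shift(F[1])) - q2 * F[0]
        acc_C.add(np.stack([s @ m1, s @ m2, s @ m3]))
    C = acc_C.sum
    monomials = [(k,) for k in range(L)]
    return _prune_model(monomials, C)


def _rot_mul(arr, K, A, B):
    """Multiply row polynomials over (sin, cos) — stored as (m, L, 2) with
    cosine exponent 0 or 1 — by ``K + A*cos + B*sin``, applying the
    cos^2 -> 1 - sin^2 reduction."""
    out = K[:, None, None] * arr
    out[:, 1:, :] += B[:, None, None] * arr[:, :-1, :]
    out[:, :, 1] += A[:, None] * arr[:, :, 0]
    out[:, :, 0] += A[:, None] * arr[:, :, 1]
    out[:, 2:, 0] -= A[:, None] * arr[:, :-2, 1]
    return out


def _accumulate_fast_rotation(P, Q, surrogate, law, family, output_kind,
                              chunk):
    a = surrogate.coeffs
    deg = surrogate.degree
    L = deg + 3
    fix = family.fixed_translation()
    n_comp = len(_COMPONENT_LABELS[output_kind])
    acc_C = _Kahan((n_comp, L, 2))
    zero = None
    for i_idx, j_idx in _pair_chunks(P, Q, chunk):
        m = i_idx.size
        dp = P.coords[i_idx]
        q = Q.coords[j_idx]
        w = fix - dp  # constant part of q(theta) - p
        K = (np.einsum("ij,ij->i", q, q) + np.einsum("ij,ij->i", w, w)
             + 2.0 * w[:, 2] * q[:, 2])
        A = 2.0 * (w[:, 0] * q[:, 0] + w[:, 1] * q[:, 1])
        B = 2.0 * (w[:, 1] * q[:, 0] - w[:, 0] * q[:, 1])
        s = np.asarray(law.prefactor(P.props[i_idx], Q.props[j_idx]),
                       dtype=float)
        acc = np.zeros((m, L, 2))
        acc[:, 0, 0] = a[0]
        cur = np.zeros((m, L, 2))
        cur[:, 0, 0] = 1.0
        for k in range(1, deg + 1):
            cur = _rot_mul(cur, K, A, B)
            acc += a[k] * cur
        if output_kind == OUTPUT_ENERGY:
            acc_C.add(np.einsum("i,iab->ab", s, acc)[None])
            continue
        if zero is None or zero.size != m:
            zero = np.zeros(m)
        # triples (constant, cos coeff, sin coeff) of q_l(theta) - p_l
        delta_tr = [
            (w[:, 0], q[:, 0], -q[:, 1]),
            (w[:, 1], q[:, 1], q[:, 0]),
            (w[:, 2] + q[:, 2], zero, zero),
        ]
        F = [_rot_mul(acc, *t) for t in delta_tr]
        if output_kind == OUTPUT_FORCE:
            acc_C.add(np.stack([np.einsum("i,iab->ab", s, Fl) for Fl in F]))
            continue
        # posed coordinates themselves (no -p) for the moment arm
        coord_tr = [
            (np.full(m, fix[0]), q[:, 0], -q[:, 1]),
            (np.full(m, fix[1]), q[:, 1], q[:, 0]),
            (fix[2] + q[:, 2], zero, zero),
        ]
        m1 = _rot_mul(F[2], *coord_tr[1]) - _rot_mul(F[1], *coord_tr[2])
        m2 = _rot_mul(F[0], *coord_tr[2]) - _rot_mul(F[2], *coord_tr[0])
        m3 = _rot_mul(F[1], *coord_tr[0]) - _rot_mul(F[0], *coord_tr[1])
        acc_C.add(np.stack([np.einsum("i,iab->ab", s, mm)
                            for mm in (m1, m2, m3)]))
    C = acc_C.sum  # (n_comp, L, 2)
    monomials = [(k, e) for e in (0, 1) for k in range(L)]
    coeffs = np.concatenate([C[:, :, 0], C[:, :, 1]], axis=1)
    return _prune_model(monomials, coeffs)
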