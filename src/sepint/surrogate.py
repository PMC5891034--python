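"""Polynomial-in-squared-distance surrogates of pairwise laws.

The distance shape of a law is replaced by ``sum_k a_k (d^2)^k`` over a
stated validity range of squared distance.  Working in ``d^2`` rather than
``d`` is what makes the later pose expansion close after finitely many
terms.  The fit is unweighted least squares on a uniform-in-``d`` grid,
performed in a Chebyshev basis on the rescaled variable for numerical
stability and converted exactly to monomial coefficients in ``d^2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PolynomialSurrogate",
    "fit_surrogate",
    "eval_surrogate",
    "TARGET_SHAPE_F",
    "TARGET_SHAPE_F_OVER_D",
]

#: the surrogate approximates the law's magnitude shape f(d)
TARGET_SHAPE_F = "shape_f"
#: the surrogate approximates |f(d)|/d (used for force/moment components)
TARGET_SHAPE_F_OVER_D = "shape_f_over_d"


@dataclass
class PolynomialSurrogate:
    """Monomial coefficients ``a_0..a_n`` in the variable ``d^2``, their
    validity domain ``[d2_min, d2_max]``, and fit diagnostics.

    ``sigma_r`` is the root-mean-square residual over the fit sample and
    ``max_rel_error`` the worst relative residual; both feed the error
    analysis of the net interaction.
    """

    coeffs: np.ndarray
    domain: tuple[float, float]
    target: str = TARGET_SHAPE_F
    sigma_r: float = 0.0
    max_rel_error: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        self.domain = (float(self.domain[0]), float(self.domain[1]))
        if self.domain[1] <= self.domain[0]:
            raise ValueError("surrogate domain must be a non-degenerate interval")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be non-negative")
        if self.target not in (TARGET_SHAPE_F, TARGET_SHAPE_F_OVER_D):
            raise ValueError(f"unknown surrogate target {self.target!r}")

    @property
    def degree(self) -> int:
        return self.coeffs.size - 1

    def __call__(self, d2):
        return eval_surrogate(self, d2)

    def to_json(self) -> dict:
        return {
            "degree": self.degree,
            "coeffs": self.coeffs.tolist(),
            "domain": list(self.domain),
            "target": self.target,
            "sigma_r": self.sigma_r,
            "max_rel_error": self.max_rel_error,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PolynomialSurrogate":
        return cls(np.asarray(obj["coeffs"], dtype=float),
                   tuple(obj["domain"]), obj["target"],
                   float(obj["sigma_r"]), float(obj["max_rel_error"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PolynomialSurrogate":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_surrogate(shape: Callable[[np.ndarray], np.ndarray],
                  domain: Sequence[float],
                  degree: int = 9,
                  n_samples: int = 2000,
                  target: str = TARGET_SHAPE_F) -> PolynomialSurrogate:
    """Least-squares fit of ``shape(d)`` by a degree-``degree`` polynomial in
    ``d^2`` over ``domain = [d2_min, d2_max]``.

    Samples lie on a uniform grid in ``d`` (endpoints included), which
    weights the short range — where singular laws vary fastest — more
    heavily than a uniform grid in ``d^2`` would.
    """
    d2_lo, d2_hi = float(domain[0]), float(domain[1])
    if not d2_hi > d2_lo:
        raise ValueError("fit domain must be a non-degenerate interval")
    if d2_lo < 0:
        raise ValueError("squared-distance domain cannot be negative")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if n_samples <= degree:
        raise ValueError("n_samples must exceed the polynomial degree")

    d = np.linspace(np.sqrt(d2_lo), np.sqrt(d2_hi), n_samples)
    t = d * d
    y = np.asarray(shape(d), dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(
            "shape produced non-finite values on the fit domain "
            "(singular law sampled too close to d = 0?)"
        )

    cheb = np.polynomial.Chebyshev.fit(t, y, degree)
    mono = cheb.convert(kind=np.polynomial.Polynomial)
    coeffs = np.zeros(degree + 1)
    coeffs[: mono.coef.size] = mono.coef

    fit_vals = np.polynomial.polynomial.polyval(t, coeffs)
    # conversion sanity: the monomial form must reproduce the stable fit
    drift = np.max(np.abs(fit_vals - cheb(t)))
    scale = np.max(np.abs(y)) + 1e-300
    if drift > 1e-8 * scale:
        warnings.warn(
            "ill-conditioned conversion to monomial coefficients "
            f"(degree {degree}); estimated evaluation error "
            f"{drift:.3g} (relative {drift / scale:.3g})",
            RuntimeWarning,
        )

    resid = fit_vals - y
    sigma_r = float(np.sqrt(np.mean(resid**2)))
    nz = np.abs(y) > 1e-300
    max_rel = float(np.max(np.abs(resid[nz]) / np.abs(y[nz]))) if nz.any() else 0.0
    return PolynomialSurrogate(coeffs, (d2_lo, d2_hi), target, sigma_r, max_rel)


def eval_surrogate(s: PolynomialSurrogate, d2):
    """Evaluate ``sum_k a_k (d2)^k`` (Horner).  Values outside the validity
    domain are extrapolated with a warning rather than rejected, so that
    slightly out-of-range poses (e.g. almost-rigid perturbations) still
    evaluate."""
    d2 = np.asarray(d2, dtype=float)
    lo, hi = s.domain
    slack = 1e-9 * (hi - lo)
    if np.any(d2 < lo - slack) or np.any(d2 > hi + slack):
        warnings.warn(
            f"evaluating surrogate outside its domain [{lo:.6g}, {hi:.6g}]; "
            "extrapolated values may be inaccurate",
            RuntimeWarning,
        )
    out = np.polynomial.polynomial.polyval(d2, s.coeffs)
    return float(out) if out.ndim == 0 else out
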