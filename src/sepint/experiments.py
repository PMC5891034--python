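"""Synthetic study harness: randomly charged boxes, almost-rigid
perturbations, the regression-error propagation study, and end-to-end
experiment presets.

Each preset runs the full pipeline — generate particles, compute the
squared-distance range of the sweep, fit the surrogate, accumulate
characteristic constants, sweep with the brute-force reference, and report
the average percent error — for one of the canonical study conditions: a
1-D translation or rotation of one randomly charged box past another, with
energy, force or moment output.

Geometry of the default box pair
--------------------------------
P's cross-section is ``a1 x a2`` and Q's is ``a3 x a4``; both boxes are one
length unit thick along x1 and separated by a unit gap.  With the
translation preset's ``a1 = a2 = 3`` and ``a3 = a4 = 1`` this puts P at
``[0,1] x [0,3] x [0,3]`` and Q at ``[2,3] x [0,1] x [0,1]``, so a sweep of
``0 <= x1 <= 5`` spans squared distances from exactly 1 (facing corners at
closest approach) to exactly 82 at the box extremes.  Charges default to
i.i.d. uniform on [0.5, 1.5]: single-sign, so the net energy stays bounded
away from zero and percent errors are well conditioned; mixed-sign draws
are available through the charge-law config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .evaluator import (
    SweepResult,
    average_percent_error,
    brute_force_net,
    net_value,
    pairwise_counter,
    sweep,
)
from .geometry import FamilyKind, PoseFamily, make_pose
from .interactions import InteractionLaw, make_law
from .particles import ParticleSet
from .sepalg import (
    OUTPUT_ENERGY,
    accumulate_characteristics,
    compute_d2_range,
)
from .surrogate import (
    TARGET_SHAPE_F,
    TARGET_SHAPE_F_OVER_D,
    fit_surrogate,
)

__all__ = [
    "ParticleSet",
    "ChargeLawConfig",
    "BoxSpec",
    "SweepSpec",
    "LawConfig",
    "ExperimentConfig",
    "ErrorPropagationReport",
    "generate_box_particles",
    "perturb_particles",
    "error_propagation_sim",
    "preset_config",
    "preset_names",
    "run_experiment",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# configuration schema
# ----------------------------------------------------------------------

class ChargeLawConfig(BaseModel):
    """Distribution of the per-particle scalar property."""

    name: Literal["uniform", "normal"] = "uniform"
    params: dict[str, float] = Field(
        default_factory=lambda: {"low": 0.5, "high": 1.5})


class BoxSpec(BaseModel):
    """A box of uniformly placed particles with random scalar properties."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_particles: int = Field(500, ge=1)
    charge_law: ChargeLawConfig = Field(default_factory=ChargeLawConfig)
    seed: Optional[int] = None  # None: derived from the experiment seed

    @field_validator("dims")
    @classmethod
    def _positive_dims(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("box dimensions must be positive")
        return v


class SweepSpec(BaseModel):
    start: float = 0.0
    stop: float = 5.0
    n_snapshots: int = Field(500, ge=1)

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_snapshots)


class LawConfig(BaseModel):
    name: str = "coulomb_energy"
    params: dict = Field(default_factory=dict)

    def build(self) -> InteractionLaw:
        return make_law(self.name, **self.params)


class ExperimentConfig(BaseModel):
    """Full specification of one end-to-end experiment."""

    label: str = "custom"
    family: Literal["translation_x1", "rotation_x3"] = "translation_x1"
    output: Literal["energy", "force", "moment"] = "energy"
    law: LawConfig = Field(default_factory=LawConfig)
    box_p: BoxSpec = Field(default_factory=BoxSpec)
    box_q: BoxSpec = Field(default_factory=BoxSpec)
    sweep: SweepSpec = Field(default_factory=SweepSpec)
    degree: int = Field(9, ge=0)
    fit_samples: int = Field(2000, ge=2)
    d2_grid: int = Field(101, ge=2)
    domain_pad: float = Field(0.01, ge=0.0)
    perturb_edge: float = Field(0.0, ge=0.0)
    error_metric: Literal["mean_abs", "rms", "signed"] = "mean_abs"
    seed: int = 0


# ----------------------------------------------------------------------
# synthetic data
# ----------------------------------------------------------------------

def _draw_props(law: ChargeLawConfig, n: int, rng: np.random.Generator
                ) -> np.ndarray:
    if law.name == "uniform":
        return rng.uniform(law.params.get("low", 0.5),
                           law.params.get("high", 1.5), n)
    if law.name == "normal":
        return rng.normal(law.params.get("mean", 1.0),
                          law.params.get("std", 0.25), n)
    raise ValueError(f"unknown charge law {law.name!r}")


def generate_box_particles(spec: BoxSpec, label: str = "box") -> ParticleSet:
    """Particles i.i.d. uniform inside the box, properties drawn from the
    charge law; fully reproducible from the spec's seed."""
    if spec.seed is None:
        raise ValueError("BoxSpec.seed must be set before generation")
    rng = np.random.default_rng(spec.seed)
    coords = np.asarray(spec.origin) + rng.uniform(
        0.0, 1.0, (spec.n_particles, 3)) * np.asarray(spec.dims)
    props = _draw_props(spec.charge_law, spec.n_particles, rng)
    return ParticleSet(coords, props, label=label)


def perturb_particles(ps: ParticleSet, edge: float, seed: int,
                      snapshot_index: int) -> ParticleSet:
    """Displace every coordinate by an independent uniform draw in
    ``[-edge/2, +edge/2]`` per axis — an almost-rigid body whose particles
    fluctuate inside a cube of the given edge around their reference
    positions.  Draws are fresh per snapshot (keyed by ``snapshot_index``);
    properties are unchanged."""
    if edge < 0:
        raise ValueError("perturbation edge must be non-negative")
    if edge == 0:
        return ParticleSet(ps.coords.copy(), ps.props.copy(), ps.label)
    rng = np.random.default_rng(
        np.random.SeedSequence((int(seed), int(snapshot_index))))
    disp = rng.uniform(-edge / 2.0, edge / 2.0, ps.coords.shape)
    return ParticleSet(ps.coords + disp, ps.props.copy(), ps.label)


# ----------------------------------------------------------------------
# error propagation (net effect of i.i.d. regression residuals)
# ----------------------------------------------------------------------

@dataclass
class ErrorPropagationReport:
    """Monte-Carlo study of how per-pair regression residuals accumulate.

    With i.i.d. normal residuals of standard deviation ``sigma_r``, the sum
    over M*N pairs has standard deviation ``sqrt(M*N)*sigma_r``
    (``iid_prediction``); ``paper_linear_prediction`` records the larger
    ``M*N*sigma_r`` figure, which the simulation treats only as an upper
    bound."""

    M: int
    N: int
    sigma_r: float
    reps: int
    empirical_net_std: float
    iid_prediction: float
    paper_linear_prediction: float


def error_propagation_sim(M: int, N: int, sigma_r: float, reps: int,
                          seed: int) -> ErrorPropagationReport:
    """Draw ``reps`` realizations of the net residual ``sum_ij eps_ij`` with
    ``eps_ij ~ N(0, sigma_r^2)`` i.i.d. and report the empirical standard
    deviation next to both closed-form predictions."""
    if reps < 100:
        raise ValueError("reps must be at least 100")
    rng = np.random.default_rng(seed)
    nets = np.zeros(reps)
    # chunk over reps to bound memory at large M*N
    mn = M * N
    step = max(1, int(2e7) // max(mn, 1))
    for start in range(0, reps, step):
        stop = min(start + step, reps)
        nets[start:stop] = rng.normal(
            0.0, sigma_r, (stop - start, mn)).sum(axis=1) if sigma_r > 0 else 0.0
    return ErrorPropagationReport(
        M=M, N=N, sigma_r=float(sigma_r), reps=int(reps),
        empirical_net_std=float(np.std(nets)),
        iid_prediction=float(np.sqrt(mn) * sigma_r),
        paper_linear_prediction=float(mn * sigma_r),
    )


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

def _translation_boxes() -> dict:
    return {
        "box_p": {"origin": (0.0, 0.0, 0.0), "dims": (1.0, 3.0, 3.0)},
        "box_q": {"origin": (2.0, 0.0, 0.0), "dims": (1.0, 1.0, 1.0)},
    }


def _unit_boxes() -> dict:
    return {
        "box_p": {"origin": (0.0, 0.0, 0.0), "dims": (1.0, 1.0, 1.0)},
        "box_q": {"origin": (2.0, 0.0, 0.0), "dims": (1.0, 1.0, 1.0)},
    }


def _presets() -> dict[str, dict]:
    return {
        "translation_energy": {
            "label": "translation_energy",
            "family": "translation_x1",
            "output": "energy",
            "law": {"name": "coulomb_energy"},
            "sweep": {"start": 0.0, "stop": 5.0, "n_snapshots": 500},
            **_translation_boxes(),
        },
        "rotation_energy": {
            "label": "rotation_energy",
            "family": "rotation_x3",
            "output": "energy",
            "law": {"name": "coulomb_energy"},
            "sweep": {"start": -np.pi / 2.0, "stop": 0.0, "n_snapshots": 500},
            **_translation_boxes(),
        },
        "almost_rigid": {
            "label": "almost_rigid",
            "family": "translation_x1",
            "output": "energy",
            "law": {"name": "coulomb_energy"},
            "sweep": {"start": 0.0, "stop": 5.0, "n_snapshots": 500},
            "perturb_edge": 0.5,
            **_translation_boxes(),
        },
        "force": {
            "label": "force",
            "family": "translation_x1",
            "output": "force",
            "law": {"name": "coulomb_force"},
            "sweep": {"start": 0.0, "stop": 2.0, "n_snapshots": 500},
            **_unit_boxes(),
        },
        "moment": {
            "label": "moment",
            "family": "translation_x1",
            "output": "moment",
            "law": {"name": "coulomb_force"},
            "sweep": {"start": 0.0, "stop": 2.0, "n_snapshots": 500},
            **_unit_boxes(),
        },
    }


def preset_names() -> tuple[str, ...]:
    return tuple(_presets())


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def preset_config(name: str, **overrides) -> ExperimentConfig:
    """A preset's :class:`ExperimentConfig`, optionally with (nested)
    overrides, e.g. ``preset_config("force", sweep={"n_snapshots": 50})``."""
    presets = _presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(presets)}")
    merged = _deep_merge(presets[name], overrides)
    return ExperimentConfig.model_validate(merged)


# ----------------------------------------------------------------------
# end-to-end harness
# ----------------------------------------------------------------------

def _shape_for(law: InteractionLaw, output: str):
    if output == OUTPUT_ENERGY:
        return law.shape, TARGET_SHAPE_F
    return law.shape_over_d, TARGET_SHAPE_F_OVER_D


def run_experiment(config: ExperimentConfig | dict,
                   out_dir: str | Path | None = None) -> dict:
    """Run one experiment end to end and return its report.

    Pipeline: generate both boxes, compute the sweep's squared-distance
    range, fit the surrogate over the (1%-padded) range, accumulate the
    characteristic model, sweep with the brute-force reference (using
    per-snapshot perturbed coordinates when ``perturb_edge > 0``), and
    average the per-snapshot relative error.  If ``out_dir`` is given, the
    particle sets, surrogate, model, per-pose series and a JSON summary are
    written there.
    """
    if isinstance(config, dict):
        config = ExperimentConfig.model_validate(config)
    ss = np.random.SeedSequence(config.seed)
    seed_p, seed_q, seed_pp, seed_pq = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(4))

    box_p = config.box_p if config.box_p.seed is not None else \
        config.box_p.model_copy(update={"seed": seed_p})
    box_q = config.box_q if config.box_q.seed is not None else \
        config.box_q.model_copy(update={"seed": seed_q})
    P = generate_box_particles(box_p, label="P")
    Q = generate_box_particles(box_q, label="Q")

    family = PoseFamily(FamilyKind(config.family))
    law = config.law.build()
    values = config.sweep.values()

    d2_lo, d2_hi = compute_d2_range(
        P, Q, family, (config.sweep.start, config.sweep.stop),
        grid=config.d2_grid)
    width = d2_hi - d2_lo
    lo = max(d2_lo - config.domain_pad * width, 1e-12)
    hi = d2_hi + config.domain_pad * width

    shape, target = _shape_for(law, config.output)
    surr = fit_surrogate(shape, (lo, hi), degree=config.degree,
                         n_samples=config.fit_samples, target=target)
    model = accumulate_characteristics(
        P, Q, surr, law, family, config.output)

    logger.info(
        "experiment %s: seed=%d d2=[%.6g, %.6g] sigma_r=%.3g "
        "max_rel_error=%.3g r=%d", config.label, config.seed, d2_lo, d2_hi,
        surr.sigma_r, surr.max_rel_error, model.n_terms)

    if config.perturb_edge > 0:
        result = _perturbed_sweep(model, P, Q, law, family, values,
                                  config.perturb_edge, seed_pp, seed_pq)
    else:
        result = sweep(model, P, Q, law, family, values, with_brute=True)

    err = average_percent_error(result, config.error_metric)
    report = {
        "label": config.label,
        "average_percent_error": err,
        "excluded_count": result.excluded_count,
        "d2_range": [d2_lo, d2_hi],
        "fit_domain": list(surr.domain),
        "surrogate": {"degree": surr.degree, "sigma_r": surr.sigma_r,
                      "max_rel_error": surr.max_rel_error},
        "n_terms": model.n_terms,
        "pairwise_eval_count_approx": result.pairwise_eval_count,
        "M": P.n, "N": Q.n,
        "n_snapshots": len(values),
        "config": json.loads(config.model_dump_json()),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        P.to_csv(out / "particles_p.csv")
        Q.to_csv(out / "particles_q.csv")
        surr.save(out / "surrogate.json")
        model.save(out / "model.json")
        result.to_csv(out / "series.csv")
        (out / "summary.json").write_text(json.dumps(report, indent=1))

    report["sweep_result"] = result
    report["model"] = model
    return report


def _perturbed_sweep(model, P, Q, law, family, values, edge, seed_p, seed_q
                     ) -> SweepResult:
    """Sweep in which the brute-force reference uses per-snapshot perturbed
    coordinates (both bodies) while the model assumes rigidity."""
    n = len(values)
    n_comp = len(model.component_labels)
    approx = np.zeros((n, n_comp))
    brute = np.zeros((n, n_comp))
    before = pairwise_counter.count
    for k, v in enumerate(values):
        approx[k] = net_value(model, [v])
    approx_evals = pairwise_counter.count - before
    for k, v in enumerate(values):
        Pk = perturb_particles(P, edge, seed_p, k)
        Qk = perturb_particles(Q, edge, seed_q, k)
        pose = make_pose(family, [v])
        brute[k] = brute_force_net(Pk, Qk, law, pose, model.output_kind)
    return SweepResult(np.asarray(values, float), model.output_kind,
                       model.component_labels, approx, brute,
                       pairwise_eval_count=approx_evals)
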