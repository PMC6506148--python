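"""Synthetic inputs with the statistical structure the pipeline assumes.

The real screen (millions of compounds docked against 10 receptor models
for each of 4 kinase targets, and triplicate fly vials) is emulated at
desk scale:

* docking scores follow a one-factor Gaussian model — each compound draws
  a latent affinity per target and each ensemble model observes
  ``sqrt(rho)*latent + sqrt(1-rho)*noise``, so ``rho`` is the inter-model
  score correlation the consensus filter exploits; a planted active set
  (shared across targets, emulating pathway polypharmacology) has its
  latent shifted down by ``effect_shift`` score units;
* assay counts are binomial — each replicate vial fixes P pupal cases and
  draws adults A ~ Binomial(P, true_viability/100);
* pocket fixtures are analytic sphere/shell/blocked-sphere geometries
  whose true free volume has a closed form.

Everything is a pure function of the config (seed included): identical
configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assays import AssayRecord
from .consensus import DockingScoreTable
from .pocket import InclusionRegion, StructureModel

__all__ = ["SimConfig", "AssayArm", "simulate_scores", "simulate_assay", "make_toy_pocket"]


@dataclass(frozen=True)
class AssayArm:
    condition: str
    genotype: str
    true_viability: float  # percent
    n_replicates: int = 3


# Default arms mirror a rescue experiment layout: lethal model genotype under
# vehicle and single/combination drug arms, plus wild-type toxicity controls.
_DEFAULT_ARMS = (
    AssayArm("vehicle", "model", 0.0),
    AssayArm("drug_A", "model", 3.0),
    AssayArm("drug_B", "model", 1.0),
    AssayArm("drug_A+drug_B", "model", 6.0),
    AssayArm("vehicle", "control", 97.0),
    AssayArm("drug_A", "control", 96.0),
    AssayArm("drug_B", "control", 97.0),
    AssayArm("drug_A+drug_B", "control", 95.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen/assay/pocket generators."""

    n_compounds: int = 2000
    n_targets: int = 4
    n_models_per_target: int = 10
    n_actives_per_target: int = 50
    effect_shift: float = 2.0  # score units; actives score this much better
    inter_model_correlation: float = 0.5
    assay_arms: tuple[AssayArm, ...] = _DEFAULT_ARMS
    pupal_count: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_targets, self.n_models_per_target,
               self.n_actives_per_target, self.pupal_count) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_actives_per_target > self.n_compounds:
            raise ValueError("n_actives_per_target exceeds n_compounds")
        if not (0.0 <= self.inter_model_correlation < 1.0):
            raise ValueError("inter_model_correlation must lie in [0, 1)")
        for arm in self.assay_arms:
            if not (0.0 <= arm.true_viability <= 100.0):
                raise ValueError(
                    f"true viability of {arm.condition!r} outside [0, 100]"
                )


def simulate_scores(
    config: SimConfig,
) -> tuple[dict[str, DockingScoreTable], dict[str, frozenset[str]]]:
    """Per-target score tables plus the planted active-label sets.

    Scores are standard-normal based (lower = better); the active set is
    drawn once and shared across targets, and each active's per-target
    latent is shifted down by ``effect_shift``.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_compounds))
    compound_ids = tuple(f"C{i:0{width}d}" for i in range(1, config.n_compounds + 1))
    model_ids = tuple(f"m{j:02d}" for j in range(1, config.n_models_per_target + 1))

    active_idx = rng.choice(config.n_compounds, size=config.n_actives_per_target, replace=False)
    active_set = frozenset(compound_ids[i] for i in active_idx)

    rho = config.inter_model_correlation
    tables: dict[str, DockingScoreTable] = {}
    actives: dict[str, frozenset[str]] = {}
    for t in range(1, config.n_targets + 1):
        target_id = f"T{t}"
        latent = rng.standard_normal(config.n_compounds)
        latent[active_idx] -= config.effect_shift
        noise = rng.standard_normal((config.n_compounds, config.n_models_per_target))
        scores = math.sqrt(rho) * latent[:, None] + math.sqrt(1.0 - rho) * noise
        tables[target_id] = DockingScoreTable(
            target_id=target_id,
            compound_ids=compound_ids,
            model_ids=model_ids,
            scores=scores,
        )
        actives[target_id] = active_set
    return tables, actives


def simulate_assay(config: SimConfig) -> list[AssayRecord]:
    """Replicate assay counts: P fixed per vial, A ~ Binomial(P, v/100)."""
    rng = np.random.default_rng(config.seed + 1)  # decouple from score stream
    records = []
    for arm in config.assay_arms:
        adults = rng.binomial(config.pupal_count, arm.true_viability / 100.0,
                              size=arm.n_replicates)
        for rep, a in enumerate(adults, start=1):
            records.append(
                AssayRecord(
                    condition=arm.condition,
                    genotype=arm.genotype,
                    replicate=rep,
                    P=config.pupal_count,
                    A=int(a),
                )
            )
    return records


def _lens_volume(R: float, r: float, d: float) -> float:
    """Volume of the intersection of spheres with radii R, r at distance d."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rm = min(R, r)
        return 4.0 / 3.0 * math.pi * rm**3
    return (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
        / (12 * d)
    )


def make_toy_pocket(
    shape: str, **params: float
) -> tuple[StructureModel, InclusionRegion, float]:
    """Analytic validation fixtures for the pocket-volume computation.

    Shapes (all centred at the origin unless noted):

    - ``sphere(radius)``: empty structure, one inclusion sphere;
      true volume (4/3)*pi*r^3.
    - ``shell(outer_radius, inner_radius)``: one central blocking atom of
      radius ``inner_radius``; true volume (4/3)*pi*(R^3 - r^3).
    - ``blocked_sphere(radius, blocker_radius, blocker_distance)``: one
      atom offset along +x; true volume subtracts the sphere-sphere lens.
    """
    if shape == "sphere":
        r = float(params["radius"])
        if r <= 0:
            raise ValueError("radius must be positive")
        structure = StructureModel("toy_sphere", (), np.empty((0, 3)), np.empty(0))
        region = InclusionRegion(np.zeros((1, 3)), np.array([r]))
        return structure, region, 4.0 / 3.0 * math.pi * r**3
    if shape == "shell":
        ro = float(params["outer_radius"])
        ri = float(params["inner_radius"])
        if not (0 < ri < ro):
            raise ValueError("need 0 < inner_radius < outer_radius")
        structure = StructureModel(
            "toy_shell", ("C",), np.zeros((1, 3)), np.array([ri])
        )
        region = InclusionRegion(np.zeros((1, 3)), np.array([ro]))
        return structure, region, 4.0 / 3.0 * math.pi * (ro**3 - ri**3)
    if shape == "blocked_sphere":
        r = float(params["radius"])
        rb = float(params["blocker_radius"])
        d = float(params["blocker_distance"])
        if r <= 0 or rb <= 0 or d < 0:
            raise ValueError("radii must be positive and distance non-negative")
        structure = StructureModel(
            "toy_blocked", ("C",), np.array([[d, 0.0, 0.0]]), np.array([rb])
        )
        region = InclusionRegion(np.zeros((1, 3)), np.array([r]))
        true = 4.0 / 3.0 * math.pi * r**3 - _lens_volume(r, rb, d)
        return structure, region, max(true, 0.0)
    raise ValueError(f"unsupported shape {shape!r}")
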