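"""Seeded generators for synthetic models and pairwise matrices.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without external data:

* random gene–organ membership models with closed-form base weights,
  mutant losses and contributions (the oracle arithmetic is written out
  here independently of :mod:`floralquant.model`);
* perfectly consistent ratio matrices from a known weight vector (priority
  recovery oracle);
* random Saaty-scale reciprocal matrices (the random-index ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ahp import PairwiseMatrix, _random_saaty_values
from .model import FloralModel, GeneClassSpec, OrganSpec
from .rounding import NO_ROUNDING

__all__ = [
    "SyntheticModelSpec",
    "SyntheticGroundTruth",
    "generate_model",
    "generate_consistent_matrix",
    "generate_saaty_matrix",
]


@dataclass(frozen=True)
class SyntheticModelSpec:
    n_organs: int = 4
    n_base_classes: int = 3
    membership_density: float = 0.5
    include_global_class: bool = True
    include_competence_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organs < 1 or self.n_base_classes < 1:
            raise ValueError("need at least one organ and one base class")
        if not 0 < self.membership_density <= 1:
            raise ValueError("membership density must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Closed-form expectations computed at generation time.

    Values are unrounded; they are the oracle the pipeline derivations are
    checked against.
    """

    base_organ_weights: Mapping[str, float]
    mutant_loss: Mapping[str, float]
    contributions: Mapping[str, float]


def generate_model(spec: SyntheticModelSpec) -> tuple[FloralModel, SyntheticGroundTruth]:
    """Random membership model plus its analytically derived scores.

    Memberships are i.i.d. Bernoulli(density) per (gene, organ), re-drawn
    until every organ has at least one base builder and at least one gene
    has a nonzero loss (an infeasibility error after 1000 attempts).  An
    E-like global class and an AGL6-like competence class are appended
    when requested.
    """
    rng = np.random.default_rng(spec.seed)
    organs = [f"organ{k+1}" for k in range(spec.n_organs)]
    genes = [f"g{k+1}" for k in range(spec.n_base_classes)]
    membership = None
    for _ in range(1000):
        m = rng.random((spec.n_base_classes, spec.n_organs)) < spec.membership_density
        if m.any(axis=0).all() and m.any():
            membership = m
            break
    if membership is None:
        raise ValueError(
            "infeasible spec: density too low to cover every organ with a base class"
        )

    builds = {g: {organs[j] for j in range(spec.n_organs) if membership[i, j]}
              for i, g in enumerate(genes)}
    gene_specs = [GeneClassSpec(name=g, builds_organs=frozenset(builds[g]))
                  for g in genes]
    if spec.include_global_class:
        builds["E*"] = set(organs)
        gene_specs.append(GeneClassSpec(name="E*", builds_organs=frozenset(organs)))
    if spec.include_competence_class:
        builds["C*"] = set(organs)
        gene_specs.append(
            GeneClassSpec(name="C*", builds_organs=frozenset(organs), in_base_model=False)
        )

    base_names = [g.name for g in gene_specs if g.in_base_model]
    organ_specs = tuple(
        OrganSpec(
            name=o,
            whorl_index=j + 1,
            importance=float(j + 1),
            required_classes=frozenset(g for g in builds if o in builds[g]),
        )
        for j, o in enumerate(organs)
    )
    model = FloralModel(organs=organ_specs, gene_classes=tuple(gene_specs))

    # --- independent closed-form ground truth (duplicate arithmetic) ----
    counts = {o: sum(1 for g in base_names if o in builds[g]) for o in organs}
    total_units = sum(counts.values())
    weights = {o: counts[o] / total_units for o in organs}
    # loss of g = total weight of organs requiring g
    losses = {g: sum(weights[o] for o in organs if o in builds[g]) for g in base_names}
    loss_total = sum(losses.values())
    contribs = {g: losses[g] / loss_total for g in base_names}
    truth = SyntheticGroundTruth(
        base_organ_weights=weights, mutant_loss=losses, contributions=contribs
    )
    return model, truth


def model_to_dict(model: FloralModel) -> dict:
    """Plain-dict (YAML-ready) form of a model config."""
    return {
        "organs": [
            {"name": o.name, "whorl_index": o.whorl_index,
             "importance": float(o.importance),
             "required_classes": sorted(o.required_classes)}
            for o in model.organs
        ],
        "gene_classes": [
            {"name": g.name, "builds_organs": sorted(g.builds_organs),
             "in_base_model": g.in_base_model}
            for g in model.gene_classes
        ],
        "reproductive_organs": sorted(model.reproductive_organs),
        "early_reproductive_classes": list(model.early_reproductive_classes),
    }


def write_fixtures(directory, seed: int = 0) -> list:
    """Regenerate the versioned fixture set (byte-stable for a seed).

    Writes a synthetic model with its closed-form ground truth, a
    consistent ratio matrix, and a random Saaty matrix.
    """
    import yaml
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    model, truth = generate_model(SyntheticModelSpec(seed=seed))
    doc = model_to_dict(model)
    doc["ground_truth"] = {
        "base_organ_weights": {k: round(v, 12) for k, v in truth.base_organ_weights.items()},
        "mutant_loss": {k: round(v, 12) for k, v in truth.mutant_loss.items()},
        "contributions": {k: round(v, 12) for k, v in truth.contributions.items()},
    }
    p = directory / f"synthetic_model_seed{seed}.yaml"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# synthetic fixture, seed={seed}; regenerate with "
                 "`floralquant synth --fixtures <dir>`\n")
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)
    written.append(p)

    for name, matrix in (
        ("consistent_matrix_n4.csv",
         generate_consistent_matrix({"c1": 1.0, "c2": 2.0, "c3": 3.0, "c4": 4.0})),
        (f"saaty_matrix_n4_seed{seed}.csv", generate_saaty_matrix(4, seed=seed)),
    ):
        p = directory / name
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            matrix.to_frame().to_csv(fh, index_label="", float_format="%.10g",
                                     lineterminator="\n")
        written.append(p)
    return written


def generate_consistent_matrix(
    weights: Sequence[float] | Mapping[str, float],
    labels: Sequence[str] | None = None,
) -> PairwiseMatrix:
    """Perfectly consistent ratio matrix a_ij = w_i / w_j."""
    if isinstance(weights, Mapping):
        labels = tuple(weights)
        w = np.asarray([weights[k] for k in labels], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(
            f"c{k+1}" for k in range(len(w))
        )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    values = w[:, None] / w[None, :]
    return PairwiseMatrix(labels=labels, values=values, construction="ratio",
                          rounding=NO_ROUNDING)


def generate_saaty_matrix(n: int, seed: int = 0) -> PairwiseMatrix:
    """Random reciprocal matrix with upper-triangle entries i.i.d. uniform
    on the 17-point Saaty scale."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    values = _random_saaty_values(n, rng)
    labels = tuple(f"c{k+1}" for k in range(n))
    return PairwiseMatrix(labels=labels, values=values, construction="explicit",
                          rounding=NO_ROUNDING)
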