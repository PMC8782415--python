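"""Combinatorial gene–organ model of floral organ identity.

The ABCDE model specifies each of the four floral organs by the joint
presence of a small set of MADS-box gene classes (sepals A+E, petals A+B+E,
stamens B+C/D+E, carpels C/D+E).  This module turns that combinatorial
structure into quantitative scores:

* **base organ weights** — each organ's share of "gene units", normalized
  to sum 1 over organs;
* **mutant-loss values** — for each gene class, the weight of the organs a
  loss-of-function mutant fails to build (1 minus the weight it still
  forms);
* **contribution values** — mutant losses normalized to sum 1 over the
  base classes;
* a **residual contribution** for non-base "competence" classes such as
  AGL6, derived from the reproductive-organ weight share;
* **gradient values** — organ importance × summed contributions of the
  organ's builder classes; and
* a **combination table** of contribution sums over gene subsets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .rounding import NO_ROUNDING, RoundingPolicy

__all__ = [
    "OrganSpec",
    "GeneClassSpec",
    "FloralModel",
    "ContributionResult",
    "CombinationTable",
    "GradientResult",
    "ModelError",
    "load_model",
    "default_model",
    "derive_base_organ_weights",
    "mutant_phenotype",
    "mutant_loss_value",
    "derive_contributions",
    "derive_nonbase_contribution",
    "combination_table",
    "gradient_values",
]


class ModelError(ValueError):
    """Invalid model definition or degenerate derivation."""


@dataclass(frozen=True)
class OrganSpec:
    """One floral organ (whorl position, importance, specifying classes)."""

    name: str
    whorl_index: int
    importance: float
    required_classes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_classes", frozenset(self.required_classes))
        if self.importance <= 0:
            raise ModelError(f"organ {self.name!r}: importance must be positive")
        if not self.required_classes:
            raise ModelError(f"organ {self.name!r}: required_classes must be non-empty")


@dataclass(frozen=True)
class GeneClassSpec:
    """One gene class and the organs whose identity it helps specify.

    ``in_base_model`` marks the classes that enter base-weight counting and
    contribution normalization (A/B/CD/E); competence classes such as AGL6
    set it False and receive a residual value instead.
    """

    name: str
    builds_organs: frozenset[str]
    in_base_model: bool = True
    unit_contribution: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "builds_organs", frozenset(self.builds_organs))
        if self.unit_contribution <= 0:
            raise ModelError(f"gene class {self.name!r}: unit_contribution must be positive")


@dataclass(frozen=True)
class FloralModel:
    organs: tuple[OrganSpec, ...]
    gene_classes: tuple[GeneClassSpec, ...]
    reproductive_organs: frozenset[str] = frozenset()
    early_reproductive_classes: tuple[str, ...] = ()
    mutant_phenotype_overrides: Mapping[str, frozenset[str]] = field(default_factory=dict)
    reference_gradients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "organs", tuple(self.organs))
        object.__setattr__(self, "gene_classes", tuple(self.gene_classes))
        object.__setattr__(self, "reproductive_organs", frozenset(self.reproductive_organs))
        object.__setattr__(
            self, "early_reproductive_classes", tuple(self.early_reproductive_classes)
        )
        self._validate()

    def _validate(self) -> None:
        organ_names = [o.name for o in self.organs]
        gene_names = [g.name for g in self.gene_classes]
        if len(set(organ_names)) != len(organ_names):
            raise ModelError("duplicate organ names")
        if len(set(gene_names)) != len(gene_names):
            raise ModelError("duplicate gene class names")
        if not any(g.in_base_model for g in self.gene_classes):
            raise ModelError("model needs at least one base-model gene class")
        organ_set = set(organ_names)
        for g in self.gene_classes:
            extra = g.builds_organs - organ_set
            if extra:
                raise ModelError(f"gene class {g.name!r} builds unknown organs {sorted(extra)}")
        for o in self.organs:
            extra = o.required_classes - set(gene_names)
            if extra:
                raise ModelError(f"organ {o.name!r} requires unknown classes {sorted(extra)}")
        # membership must be stated consistently from both sides
        for o in self.organs:
            for g in self.gene_classes:
                if (g.name in o.required_classes) != (o.name in g.builds_organs):
                    raise ModelError(
                        f"inconsistent membership: organ {o.name!r} / class {g.name!r}"
                    )
        if self.reproductive_organs - organ_set:
            raise ModelError("reproductive_organs contains unknown organ names")
        for c in self.early_reproductive_classes:
            if c not in gene_names:
                raise ModelError(f"early reproductive class {c!r} not in model")

    # -- lookups -----------------------------------------------------------
    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.organs)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.gene_classes)

    @property
    def base_classes(self) -> tuple[GeneClassSpec, ...]:
        return tuple(g for g in self.gene_classes if g.in_base_model)

    @property
    def nonbase_classes(self) -> tuple[GeneClassSpec, ...]:
        return tuple(g for g in self.gene_classes if not g.in_base_model)

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise ModelError(f"unknown organ {name!r}")

    def gene(self, name: str) -> GeneClassSpec:
        for g in self.gene_classes:
            if g.name == name:
                return g
        raise ModelError(f"unknown gene class {name!r}")

    @property
    def globally_required_classes(self) -> frozenset[str]:
        """Base classes required by every organ (E-like)."""
        all_organs = set(self.organ_names)
        return frozenset(
            g.name for g in self.base_classes if g.builds_organs == all_organs
        )

    @property
    def competence_classes(self) -> frozenset[str]:
        """Non-base classes required by every organ (AGL6-like)."""
        all_organs = set(self.organ_names)
        return frozenset(
            g.name for g in self.nonbase_classes if g.builds_organs == all_organs
        )


@dataclass(frozen=True)
class ContributionResult:
    base_organ_weights: Mapping[str, float]
    mutant_loss: Mapping[str, float]
    contributions: Mapping[str, float]
    nonbase_contributions: Mapping[str, float]
    rounding: RoundingPolicy
    warnings: tuple[str, ...] = ()

    @property
    def agl6_value(self) -> float | None:
        for name in ("AGL6", "agl6"):
            if name in self.nonbase_contributions:
                return self.nonbase_contributions[name]
        if len(self.nonbase_contributions) == 1:
            return next(iter(self.nonbase_contributions.values()))
        return None

    @property
    def all_contributions(self) -> dict[str, float]:
        out = dict(self.contributions)
        out.update(self.nonbase_contributions)
        return out


@dataclass(frozen=True)
class CombinationTable:
    organs: tuple[str, ...]
    rows: Mapping[str, Mapping[str, float]]
    rounding: RoundingPolicy

    def cell(self, label: str, organ: str) -> float:
        return self.rows[label][organ]


@dataclass(frozen=True)
class GradientResult:
    values: Mapping[str, float]
    provenance: str  # "computed" | "reference"


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------

def derive_base_organ_weights(model: FloralModel) -> dict[str, float]:
    """Organ weight = its base-class unit count / total unit count.

    Only ``in_base_model`` classes count; each contributes its
    ``unit_contribution`` (default 1 unit) to every organ it specifies.
    """
    base = {g.name: g.unit_contribution for g in model.base_classes}
    counts = {
        o.name: sum(base[c] for c in o.required_classes if c in base)
        for o in model.organs
    }
    total = sum(counts.values())
    if total == 0:
        raise ModelError("no base class specifies any organ")
    return {name: count / total for name, count in counts.items()}


def mutant_phenotype(model: FloralModel, gene: str) -> frozenset[str]:
    """Organs a loss-of-function mutant of ``gene`` still forms.

    Default rule: the complement of the gene's organ memberships (an organ
    forms iff it does not require the gene).  An explicit override table on
    the model replaces the derived set, since observed mutant phenotypes
    are data, not a theorem.
    """
    if gene in model.mutant_phenotype_overrides:
        return frozenset(model.mutant_phenotype_overrides[gene])
    g = model.gene(gene)
    return frozenset(o.name for o in model.organs if g.name not in o.required_classes)


def mutant_loss_value(
    model: FloralModel, gene: str, base_weights: Mapping[str, float]
) -> float:
    """1 minus the summed base weights of the organs the mutant still forms."""
    formed = mutant_phenotype(model, gene)
    return 1.0 - sum(base_weights[o] for o in formed)


def derive_contributions(
    model: FloralModel, rounding: RoundingPolicy = RoundingPolicy(3, "half-up")
) -> ContributionResult:
    """Normalize base-class mutant losses into contribution values.

    Non-base (competence) classes are excluded from the normalization and
    receive residual values via :func:`derive_nonbase_contribution`.
    """
    weights = derive_base_organ_weights(model)
    losses = {g.name: mutant_loss_value(model, g.name, weights) for g in model.base_classes}
    total = sum(losses.values())
    if total == 0:
        raise ModelError("degenerate model: all mutant losses are zero")
    raw = {name: loss / total for name, loss in losses.items()}
    contributions = rounding.apply_map(raw)
    warnings: list[str] = []
    nonbase: dict[str, float] = {}
    for g in model.nonbase_classes:
        value = derive_nonbase_contribution(model, contributions, g.name, weights=weights)
        if value < 0:
            warnings.append(
                f"residual contribution of {g.name!r} is negative ({value:.6g})"
            )
        nonbase[g.name] = rounding.apply(value)
    return ContributionResult(
        base_organ_weights=weights,
        mutant_loss=losses,
        contributions=contributions,
        nonbase_contributions=nonbase,
        rounding=rounding,
        warnings=tuple(warnings),
    )


def derive_nonbase_contribution(
    model: FloralModel,
    contributions: Mapping[str, float],
    gene: str,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Residual contribution of a non-base class.

    The reproductive organs (stamens + carpels by default) carry a fixed
    share of the base organ weight; the early reproductive classes (B, CD
    by default) plus the competence class are taken to account for exactly
    that share, so the competence value is the share minus the early
    classes' contributions (0.5 − 0.231 − 0.192 = 0.077 for AGL6).
    """
    g = model.gene(gene)
    if g.in_base_model:
        raise ModelError(f"{gene!r} is a base-model class; no residual is defined")
    if weights is None:
        weights = derive_base_organ_weights(model)
    share = sum(weights[o] for o in model.reproductive_organs)
    early = sum(contributions[c] for c in model.early_reproductive_classes)
    return share - early


def combination_table(
    model: FloralModel,
    contributions: Mapping[str, float],
    subsets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    rounding: RoundingPolicy = RoundingPolicy(3, "half-up"),
) -> CombinationTable:
    """Contribution sums of gene subsets per organ.

    ``cell(S, o)`` sums the contributions of the subset members that build
    organ ``o``.  ``subsets`` maps row labels to member names; an unlabeled
    sequence gets "+"-joined labels.
    """
    if not isinstance(subsets, Mapping):
        subsets = {"+".join(s): s for s in subsets}
    rows: dict[str, dict[str, float]] = {}
    for label, members in subsets.items():
        members = list(members)
        for m in members:
            if m not in contributions:
                raise ModelError(f"subset {label!r}: unknown member {m!r}")
        row = {}
        for o in model.organs:
            cell = sum(
                contributions[m]
                for m in members
                if o.name in model.gene(m).builds_organs
            )
            row[o.name] = rounding.apply(cell)
        rows[label] = row
    return CombinationTable(organs=model.organ_names, rows=rows, rounding=rounding)


def gradient_values(
    model: FloralModel,
    contributions: Mapping[str, float],
    mode: str = "computed",
    reference_values: Mapping[str, float] | None = None,
) -> GradientResult:
    """Organ gradient = importance × summed base contributions of builders.

    ``mode="reference"`` returns the published vector carried on the model
    config instead of recomputing; provenance records which was used (the
    published vector is not reproducible from the stated product formula —
    see the diff report in :mod:`floralquant.replication`).
    """
    if mode == "reference":
        ref = reference_values or model.reference_gradients
        if not ref:
            raise ModelError("no reference gradient values available for this model")
        if set(ref) != set(model.organ_names):
            raise ModelError("reference gradient labels do not match model organs")
        return GradientResult(values=dict(ref), provenance="reference")
    if mode != "computed":
        raise ModelError(f"unknown gradient mode {mode!r}")
    base_names = {g.name for g in model.base_classes}
    values = {}
    for o in model.organs:
        total = sum(
            contributions[c] for c in o.required_classes if c in base_names
        )
        values[o.name] = o.importance * total
    return GradientResult(values=values, provenance="computed")


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def load_model(source: str | Path | io.TextIOBase | Mapping) -> FloralModel:
    """Build a :class:`FloralModel` from a YAML/JSON config (path, stream or dict)."""
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, io.TextIOBase):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    try:
        organs = tuple(
            OrganSpec(
                name=o["name"],
                whorl_index=int(o["whorl_index"]),
                importance=float(o["importance"]),
                required_classes=frozenset(o["required_classes"]),
            )
            for o in doc["organs"]
        )
        genes = tuple(
            GeneClassSpec(
                name=g["name"],
                builds_organs=frozenset(g["builds_organs"]),
                in_base_model=bool(g.get("in_base_model", True)),
                unit_contribution=float(g.get("unit_contribution", 1.0)),
            )
            for g in doc["gene_classes"]
        )
    except KeyError as exc:
        raise ModelError(f"model config missing key: {exc}") from exc
    overrides = {
        k: frozenset(v) for k, v in (doc.get("mutant_phenotype_overrides") or {}).items()
    }
    return FloralModel(
        organs=organs,
        gene_classes=genes,
        reproductive_organs=frozenset(doc.get("reproductive_organs", ())),
        early_reproductive_classes=tuple(doc.get("early_reproductive_classes", ())),
        mutant_phenotype_overrides=overrides,
        reference_gradients=dict(doc.get("reference_gradients") or {}),
    )


def default_model() -> FloralModel:
    """The packaged ABCDE+AGL6 model (four whorls, five gene classes)."""
    from importlib import resources

    with resources.files("floralquant.data").joinpath("abcde_agl6.yaml").open() as fh:
        return load_model(fh)
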