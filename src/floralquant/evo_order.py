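"""Enumeration and rule-filtering of gene-class emergence orders.

Candidate evolutionary scenarios are weak orders (ordered set partitions,
ties = simultaneous emergence) over the "free" gene classes, appended to a
fixed prefix (B then CD by default, the reading of the phylogeny).  Each
scenario is screened by flower-formability rules: a stage with all
identity requirements of an organ present (including the E-like globally
required class and the AGL6-like competence class) can form that organ.
The default rule set rejects any scenario where the A class precedes the
E class (no flower forms without E) and any where the E class strictly
precedes the competence class (defective development without AGL6),
leaving exactly the two admissible orders
B -> CD -> AGL6 -> E -> A and B -> CD -> AGL6/E -> A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .model import FloralModel

__all__ = [
    "EmergenceScenario",
    "StageState",
    "Rule",
    "RuleAudit",
    "formable_organs",
    "enumerate_weak_orders",
    "default_rules",
    "admissible_orders",
    "scenario_timeline",
]

_MAX_FREE = 6  # 6 classes -> 4683 weak orders; factorial guard


@dataclass(frozen=True)
class EmergenceScenario:
    """Ranks (1 = earliest, equal rank = simultaneous) over gene classes."""

    ranks: Mapping[str, int]
    fixed_prefix: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))
        object.__setattr__(self, "fixed_prefix", tuple(self.fixed_prefix))
        values = sorted(set(self.ranks.values()))
        if values != list(range(1, len(values) + 1)):
            raise ValueError("ranks must be contiguous from 1")
        free_min = min(
            (r for c, r in self.ranks.items() if c not in self.fixed_prefix),
            default=None,
        )
        for k, c in enumerate(self.fixed_prefix):
            if self.ranks.get(c) != k + 1:
                raise ValueError("prefix classes must occupy the leading ranks in order")
            if free_min is not None and self.ranks[c] >= free_min:
                raise ValueError("prefix classes must strictly precede free classes")

    @property
    def stages(self) -> list[frozenset[str]]:
        """Classes grouped by rank, earliest first."""
        out: dict[int, set[str]] = {}
        for c, r in self.ranks.items():
            out.setdefault(r, set()).add(c)
        return [frozenset(out[r]) for r in sorted(out)]

    def describe(self) -> str:
        return " -> ".join("/".join(sorted(s)) for s in self.stages)


@dataclass(frozen=True)
class StageState:
    stage: int
    present: frozenset[str]
    formable: frozenset[str]


@dataclass(frozen=True)
class Rule:
    """Named pure predicate over (scenario, model); returns (ok, reason)."""

    name: str
    description: str
    predicate: Callable[[EmergenceScenario, FloralModel], tuple[bool, str]]

    def check(self, scenario: EmergenceScenario, model: FloralModel) -> tuple[bool, str]:
        return self.predicate(scenario, model)


@dataclass(frozen=True)
class RuleAudit:
    scenario: EmergenceScenario
    admissible: bool
    eliminated_by: str | None
    reason: str | None


def formable_organs(model: FloralModel, present: Iterable[str]) -> frozenset[str]:
    """Organs whose full identity requirement is met by ``present`` classes.

    The globally required (E-like) and competence (AGL6-like) classes must
    all be present for anything to form.
    """
    present = frozenset(present)
    unknown = present - set(model.gene_names)
    if unknown:
        raise ValueError(f"unknown gene classes: {sorted(unknown)}")
    if not (model.globally_required_classes <= present):
        return frozenset()
    if not (model.competence_classes <= present):
        return frozenset()
    return frozenset(
        o.name for o in model.organs if o.required_classes <= present
    )


def _ordered_set_partitions(items: tuple[str, ...]):
    """All ordered set partitions (weak orders) of ``items``.

    Recursive first-block construction: every non-empty subset can be the
    earliest block; recurse on the remainder.
    """
    if not items:
        yield []
        return
    n = len(items)
    for mask in range(1, 1 << n):
        block = frozenset(items[k] for k in range(n) if mask >> k & 1)
        remainder = tuple(x for x in items if x not in block)
        for tail in _ordered_set_partitions(remainder):
            yield [block] + tail


def enumerate_weak_orders(
    free_classes: Iterable[str], fixed_prefix: Sequence[str] = ("B", "CD")
) -> list[EmergenceScenario]:
    """All weak orders of the free classes after the fixed prefix.

    The count is the ordered Bell (Fubini) number of the free-class count:
    1, 3, 13, 75, 541, ... for 1-5 classes.
    """
    free = tuple(sorted(set(free_classes)))
    prefix = tuple(fixed_prefix)
    if set(free) & set(prefix):
        raise ValueError("free classes overlap the fixed prefix")
    if len(free) > _MAX_FREE:
        raise ValueError(f"refusing to enumerate more than {_MAX_FREE} free classes")
    scenarios = []
    for blocks in _ordered_set_partitions(free):
        ranks = {c: k + 1 for k, c in enumerate(prefix)}
        for offset, block in enumerate(blocks):
            for c in block:
                ranks[c] = len(prefix) + 1 + offset
        scenarios.append(EmergenceScenario(ranks=ranks, fixed_prefix=prefix))
    return scenarios


def _precedes_rule(name, description, earlier, later, strict):
    def predicate(s: EmergenceScenario, _m: FloralModel) -> tuple[bool, str]:
        if earlier not in s.ranks or later not in s.ranks:
            return True, "classes not in scenario; rule vacuous"
        a, b = s.ranks[earlier], s.ranks[later]
        ok = a < b if strict else a <= b
        rel = "strictly before" if strict else "no later than"
        if ok:
            return True, f"{earlier} emerges {rel} {later}"
        return False, f"{earlier} (rank {a}) does not emerge {rel} {later} (rank {b})"
    return Rule(name=name, description=description, predicate=predicate)


def default_rules(
    e_class: str = "E", a_class: str = "A", competence_class: str = "AGL6"
) -> list[Rule]:
    """The two formability rules distilled from the case analysis.

    R1: the E-like class strictly precedes the A-like class (with A but
    without E no flower forms, so every A-before-E path is rejected).
    R2: the competence class precedes or ties the E-like class (E without
    the competence class gives defective development).
    """
    return [
        _precedes_rule(
            "E-before-A",
            "flowers cannot form while A is present but E absent",
            e_class, a_class, strict=True,
        ),
        _precedes_rule(
            "competence-before-E",
            "development is defective while E is present but the competence class absent",
            competence_class, e_class, strict=False,
        ),
    ]


def admissible_orders(
    model: FloralModel,
    scenarios: Iterable[EmergenceScenario],
    rules: Sequence[Rule],
) -> tuple[list[EmergenceScenario], list[RuleAudit]]:
    """Filter scenarios through the rules, keeping an elimination audit."""
    admissible, audit = [], []
    for s in scenarios:
        eliminated_by = reason = None
        for rule in rules:
            ok, why = rule.check(s, model)
            if not ok:
                eliminated_by, reason = rule.name, why
                break
        if eliminated_by is None:
            admissible.append(s)
            audit.append(RuleAudit(s, True, None, None))
        else:
            audit.append(RuleAudit(s, False, eliminated_by, reason))
    return admissible, audit


def scenario_timeline(model: FloralModel, scenario: EmergenceScenario) -> list[StageState]:
    """Per-stage present classes and model-derived formable organs.

    Presence accumulates stage by stage, so formable sets are nested
    (monotone non-decreasing) along any scenario.
    """
    present: set[str] = set()
    states = []
    for k, block in enumerate(scenario.stages, start=1):
        present |= block
        states.append(
            StageState(
                stage=k,
                present=frozenset(present),
                formable=formable_organs(model, present),
            )
        )
    return states
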