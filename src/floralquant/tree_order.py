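"""Gene-class emergence order read off a rooted, class-labeled tree.

Given a Newick topology whose tips are assigned to gene classes, each
class is ranked by the depth (in node counts from the root) at which its
lineage diverges from lineages of other classes: for every tip, the
deepest ancestor whose subtree still contains another class, minimized
over the class's tips ("earliest divergence of any member").  Classes
diverging at the same node tie.  Ladder topologies therefore yield the
ladder order, and a basal polytomy yields an all-tied rank.

Branch lengths are ignored by default (order is read off topology); a
branch-length depth mode is available.  Monophyly of each class is tested
and reported — non-monophyly is a warning, not an error.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import Phylo

__all__ = [
    "LabeledTree",
    "ClassOrder",
    "TreeOrderError",
    "parse_labeled_tree",
    "emergence_order",
    "read_class_map",
    "packaged_example_tree",
]


class TreeOrderError(ValueError):
    """Invalid tree, labeling, or class map."""


@dataclass(frozen=True)
class LabeledTree:
    tree: "Phylo.BaseTree.Tree"
    tip_to_class: Mapping[str, str]

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.tip_to_class.values())


@dataclass(frozen=True)
class ClassOrder:
    ranks: Mapping[str, int]
    split_depths: Mapping[str, int | float]
    monophyletic: Mapping[str, bool]
    warnings: tuple[str, ...] = ()

    @property
    def tied_groups(self) -> list[frozenset[str]]:
        """Classes grouped by rank, earliest first; groups of >1 are
        unresolved simultaneous emergences."""
        by_rank: dict[int, set[str]] = {}
        for c, r in self.ranks.items():
            by_rank.setdefault(r, set()).add(c)
        return [frozenset(by_rank[r]) for r in sorted(by_rank)]

    def describe(self) -> str:
        return " -> ".join("/".join(sorted(g)) for g in self.tied_groups)


def read_class_map(source: str | Path | io.TextIOBase) -> dict[str, str]:
    """Two-column CSV ``tip_pattern,class`` (prefix or regex patterns)."""
    if isinstance(source, io.TextIOBase):
        rows = list(csv.reader(source))
    else:
        rows = list(csv.reader(Path(source).read_text().splitlines()))
    mapping = {}
    for row in rows:
        if not row or row[0].startswith("#"):
            continue
        if row[0].strip().lower() in ("tip_pattern", "pattern"):
            continue
        if len(row) < 2:
            raise TreeOrderError(f"malformed class-map row: {row!r}")
        mapping[row[0].strip()] = row[1].strip()
    return mapping


def _classify_tip(name: str, label_map: Mapping[str, str]) -> str | None:
    if name in label_map:
        return label_map[name]
    # longest pattern first, so e.g. an "AGL6" prefix beats a bare "A"
    for pattern in sorted(label_map, key=len, reverse=True):
        cls = label_map[pattern]
        if name.startswith(pattern):
            return cls
        try:
            if re.fullmatch(pattern, name):
                return cls
        except re.error:
            pass
    return None


def parse_labeled_tree(
    newick: str | Path, label_map: Mapping[str, str]
) -> LabeledTree:
    """Parse a rooted Newick tree and map every tip to a gene class.

    ``newick`` may be a path or the Newick text itself.  The topology is
    interpreted as rooted exactly as written (basal polytomies allowed).
    Unmapped tips are an error naming the tip; at least two distinct
    classes are required.
    """
    text = None
    if isinstance(newick, Path):
        text = newick.read_text()
    elif isinstance(newick, str):
        text = Path(newick).read_text() if "(" not in newick and Path(newick).exists() else newick
        if "(" not in text:
            raise TreeOrderError("input does not look like Newick")
    tree = Phylo.read(io.StringIO(text), "newick")
    tree.rooted = True
    tips = tree.get_terminals()
    if not tips:
        raise TreeOrderError("tree has no tips")
    tip_to_class = {}
    for tip in tips:
        if tip.name is None:
            raise TreeOrderError("tree contains an unnamed tip")
        cls = _classify_tip(tip.name, label_map)
        if cls is None:
            raise TreeOrderError(f"tip {tip.name!r} matches no class-map entry")
        tip_to_class[tip.name] = cls
    if len(set(tip_to_class.values())) < 2:
        raise TreeOrderError("need at least two gene classes on the tree")
    return LabeledTree(tree=tree, tip_to_class=tip_to_class)


def emergence_order(labeled: LabeledTree, use_branch_lengths: bool = False) -> ClassOrder:
    """Rank classes by divergence depth from the root (see module docs)."""
    tree = labeled.tree
    root = tree.root

    # subtree class sets and node depths in one traversal
    class_sets: dict[int, frozenset[str]] = {}

    def fill(clade) -> frozenset[str]:
        if clade.is_terminal():
            s = frozenset([labeled.tip_to_class[clade.name]])
        else:
            s = frozenset().union(*(fill(ch) for ch in clade.clades))
        class_sets[id(clade)] = s
        return s

    fill(root)

    depths: dict[str, float] = {}
    for tip in tree.get_terminals():
        cls = labeled.tip_to_class[tip.name]
        path = [root] + tree.get_path(tip)  # root ... tip
        depth = 0.0
        split_depth = 0.0
        for node in path:
            if node is not root:
                depth += (node.branch_length or 0.0) if use_branch_lengths else 1.0
            others = class_sets[id(node)] - {cls}
            if others:
                split_depth = depth
        depths[cls] = min(depths.get(cls, float("inf")), split_depth)

    order = sorted(set(depths.values()))
    rank_of = {d: k + 1 for k, d in enumerate(order)}
    ranks = {c: rank_of[d] for c, d in depths.items()}

    mono, warnings = {}, []
    for cls in labeled.classes:
        tips = [t for t in tree.get_terminals() if labeled.tip_to_class[t.name] == cls]
        if len(tips) == 1:
            mono[cls] = True
            continue
        mrca = tree.common_ancestor(tips)
        mono[cls] = class_sets[id(mrca)] == frozenset([cls])
        if not mono[cls]:
            warnings.append(f"class {cls!r} is not monophyletic; ranked by its "
                            "earliest-diverging member")
    if not use_branch_lengths:
        depths = {c: int(d) for c, d in depths.items()}
    return ClassOrder(ranks=ranks, split_depths=depths, monophyletic=mono,
                      warnings=tuple(warnings))


def packaged_example_tree() -> LabeledTree:
    """The packaged synthetic transcription of the published topology.

    A ladder with a terminal trifurcation — (B, (CD, (AGL6, E, A))) with
    two tips per class — encoding the stated emergence order
    B -> CD -> AGL6/E/A; it is a stand-in topology, not a posterior tree.
    """
    from importlib import resources

    data = resources.files("floralquant.data")
    newick = data.joinpath("example_topology.nwk").read_text()
    with data.joinpath("example_topology_classes.csv").open() as fh:
        label_map = read_class_map(fh)
    return parse_labeled_tree(newick, label_map)
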