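"""The staged modification forest.

Every placed mark hangs from exactly one of the four virtual stage-0 roots
(A, C, G, U) through its curated parent chain; the *stage* of a mark is its
edge distance from the root, i.e. the cumulative number of chemical steps
separating it from the unmodified ribonucleoside.  Cross-talk edges record
enzymatic conversions between trees (cytidine derivatives deaminated to
uridine derivatives); they are annotations on the forest and never take part
in stage computation, descendant sets, or counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .census import (Census, CensusValidationError, ModificationRecord,
                     validate_census)

__all__ = [
    "ROOTS",
    "DEFAULT_CROSS_TALK",
    "CrossTalkEdge",
    "ModificationForest",
    "StageMatrix",
    "ForestError",
    "build_forest",
    "compute_stage",
    "stage_matrix",
    "branch_total",
    "tree_height",
    "first_stage_range",
    "descendants",
    "path_to_root",
]

ROOTS = ("A", "C", "G", "U")
MAX_STAGE = 9


class ForestError(ValueError):
    """Raised for structural problems while building or querying the forest."""


@dataclass(frozen=True)
class CrossTalkEdge:
    """A between-tree conversion, e.g. deamination of a C mark to a U mark."""

    source: str
    target: str
    kind: str


#: Conversions the survey text states: cytidine can be enzymatically
#: deaminated to uridine, and m3C directly to m3U.
DEFAULT_CROSS_TALK = (
    CrossTalkEdge("C", "U", "deamination C→U"),
    CrossTalkEdge("m3C", "m3U", "deamination C→U"),
)


@dataclass(frozen=True)
class ModificationForest:
    """Rooted forest over the placed records of a census."""

    roots: tuple[str, ...]
    nodes: dict[str, ModificationRecord]          # placed records only
    children: dict[str, tuple[str, ...]]          # node -> sorted child names
    parent: dict[str, str]                        # node -> parent (root or node)
    cross_talk: tuple[CrossTalkEdge, ...]

    def tree_edges(self) -> Iterable[tuple[str, str]]:
        """(parent, child) pairs, children in deterministic order."""
        for p in self.roots + tuple(sorted(self.nodes)):
            for c in self.children.get(p, ()):
                yield (p, c)


@dataclass(frozen=True)
class StageMatrix:
    """Per-base × per-stage counts of placed marks (stages 1..9)."""

    counts: dict[tuple[str, int], int]
    branch_totals: dict[str, int]
    grand_total: int


def build_forest(census: Census,
                 cross_talk: tuple[CrossTalkEdge, ...] = DEFAULT_CROSS_TALK
                 ) -> ModificationForest:
    """Assemble the forest from a valid census.

    Placed records without an explicit parent attach to their root base at
    stage 1; unplaced and nascent records are excluded.
    """
    report = validate_census(census)
    if not report.ok:
        raise CensusValidationError(report)

    nodes = {r.short_name: r for r in census.by_status("placed")}
    parent: dict[str, str] = {}
    for r in nodes.values():
        if r.parent:
            p = nodes.get(r.parent)
            if p is None:
                raise ForestError(f"{r.short_name}: parent {r.parent!r} not placed")
            if p.root_base != r.root_base:
                raise ForestError(
                    f"{r.short_name} ({r.root_base}-derived) has parent "
                    f"{r.parent} ({p.root_base}-derived)")
            parent[r.short_name] = r.parent
        else:
            parent[r.short_name] = r.root_base

    # cycle check by walking each chain to a root
    for start in nodes:
        seen = [start]
        cur = start
        while cur not in ROOTS:
            cur = parent[cur]
            if cur in seen:
                cycle = seen[seen.index(cur):] + [cur]
                raise ForestError("cycle in parent links: " + " -> ".join(cycle))
            seen.append(cur)

    children: dict[str, list[str]] = {}
    for name, p in parent.items():
        children.setdefault(p, []).append(name)
    sorted_children = {p: tuple(sorted(cs)) for p, cs in children.items()}

    known = set(nodes) | set(ROOTS)
    if cross_talk is DEFAULT_CROSS_TALK:
        # shipped defaults are annotations: keep only those whose endpoints
        # this census actually contains
        edges = tuple(e for e in cross_talk
                      if e.source in known and e.target in known)
    else:
        edges = tuple(cross_talk)
    for e in edges:
        if e.source not in known or e.target not in known:
            raise ForestError(f"cross-talk edge {e.source}->{e.target}: unknown node")
        src_root = e.source if e.source in ROOTS else nodes[e.source].root_base
        tgt_root = e.target if e.target in ROOTS else nodes[e.target].root_base
        if src_root == tgt_root:
            raise ForestError(
                f"cross-talk edge {e.source}->{e.target} stays inside the "
                f"{src_root} tree")

    return ModificationForest(roots=ROOTS, nodes=nodes,
                              children=sorted_children, parent=dict(parent),
                              cross_talk=edges)


def compute_stage(forest: ModificationForest, name: str) -> int:
    """Edge distance from the node's root; roots are stage 0."""
    if name in forest.roots:
        return 0
    if name not in forest.nodes:
        raise ForestError(f"{name!r} is not placed in the forest")
    stage = 0
    cur = name
    while cur not in forest.roots:
        cur = forest.parent[cur]
        stage += 1
    return stage


def stage_matrix(forest: ModificationForest) -> StageMatrix:
    """The per-base × per-stage count grid over placed nodes."""
    counts = {(b, s): 0 for b in ROOTS for s in range(1, MAX_STAGE + 1)}
    for name, rec in forest.nodes.items():
        counts[(rec.root_base, compute_stage(forest, name))] += 1
    branch_totals = {
        b: sum(counts[(b, s)] for s in range(1, MAX_STAGE + 1)) for b in ROOTS}
    return StageMatrix(counts=counts, branch_totals=branch_totals,
                       grand_total=sum(branch_totals.values()))


def branch_total(forest: ModificationForest, base: str) -> int:
    """Number of placed marks derived from ``base``."""
    _check_base(base)
    return sum(1 for r in forest.nodes.values() if r.root_base == base)


def tree_height(forest: ModificationForest, base: str) -> int:
    """Maximum stage reached in the tree rooted at ``base`` (0 if empty)."""
    _check_base(base)
    stages = [compute_stage(forest, n) for n, r in forest.nodes.items()
              if r.root_base == base]
    return max(stages, default=0)


def first_stage_range(forest: ModificationForest) -> tuple[int, int]:
    """(min, max) of stage-1 counts across the four trees."""
    firsts = [len(forest.children.get(b, ())) for b in ROOTS]
    return (min(firsts), max(firsts))


def descendants(forest: ModificationForest, name: str) -> set[str]:
    """All marks in the subtree below ``name`` (excluding ``name`` itself)."""
    if name not in forest.nodes and name not in forest.roots:
        raise ForestError(f"unknown node {name!r}")
    out: set[str] = set()
    stack = list(forest.children.get(name, ()))
    while stack:
        n = stack.pop()
        out.add(n)
        stack.extend(forest.children.get(n, ()))
    return out


def path_to_root(forest: ModificationForest, name: str) -> list[str]:
    """[name, parent, ..., root] along the curated lineage."""
    if name in forest.roots:
        return [name]
    if name not in forest.nodes:
        raise ForestError(f"unknown node {name!r}")
    path = [name]
    cur = name
    while cur not in forest.roots:
        cur = forest.parent[cur]
        path.append(cur)
    return path


def _check_base(base: str) -> None:
    if base not in ROOTS:
        raise ForestError(f"unknown root base {base!r}")
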