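"""Graph exports: DOT, Newick and node-link JSON.

All exporters are deterministic — identical forest and configuration yield
identical bytes — so diffs of exported trees are meaningful.  Stage colors
use a fixed nine-entry palette keyed by stage index (the tree figures use
node border color the same way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .forest import MAX_STAGE, ModificationForest, ForestError, compute_stage

__all__ = ["ExportConfig", "STAGE_PALETTE", "to_dot", "to_newick", "to_json_graph"]

#: One color per stage 1..9 (index 0 = roots).
STAGE_PALETTE = (
    "#000000",  # stage 0: the four roots
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666", "#e41a1c",
)


@dataclass(frozen=True)
class ExportConfig:
    color_by_stage: bool = True
    include_cross_talk: bool = False
    base_filter: Optional[frozenset] = None   # subset of {A,C,G,U}
    label: str = "short_name"                 # short_name | full_name | both


def _bases(forest: ModificationForest, config: ExportConfig) -> tuple[str, ...]:
    if config.base_filter is None:
        return forest.roots
    bad = set(config.base_filter) - set(forest.roots)
    if bad:
        raise ForestError(f"unknown base(s) in filter: {sorted(bad)}")
    return tuple(b for b in forest.roots if b in config.base_filter)


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _node_label(forest: ModificationForest, name: str, label_mode: str) -> str:
    """Escaped DOT label; "both" puts the full name on a second line."""
    if name in forest.roots:
        return _dot_escape(name)
    rec = forest.nodes[name]
    if label_mode == "full_name":
        return _dot_escape(rec.full_name)
    if label_mode == "both":
        return _dot_escape(rec.short_name) + "\\n" + _dot_escape(rec.full_name)
    return _dot_escape(rec.short_name)


def to_dot(forest: ModificationForest, config: ExportConfig = ExportConfig()) -> str:
    """One DOT digraph; tree edges solid, cross-talk edges dashed."""
    bases = _bases(forest, config)
    names = [b for b in bases] + sorted(
        n for n, r in forest.nodes.items() if r.root_base in bases)
    lines = ["digraph modification_forest {", "  rankdir=LR;",
             "  node [shape=box];"]
    for n in names:
        stage = compute_stage(forest, n)
        attrs = [f'label="{_node_label(forest, n, config.label)}"',
                 f"stage={stage}"]
        if config.color_by_stage:
            attrs.append(f'color="{STAGE_PALETTE[stage]}"')
        lines.append(f'  "{_dot_escape(n)}" [{" ".join(attrs)}];')
    present = set(names)
    for p, c in forest.tree_edges():
        if p in present and c in present:
            lines.append(f'  "{_dot_escape(p)}" -> "{_dot_escape(c)}";')
    if config.include_cross_talk:
        for e in forest.cross_talk:
            if e.source in present and e.target in present:
                lines.append(
                    f'  "{_dot_escape(e.source)}" -> "{_dot_escape(e.target)}" '
                    f'[style=dashed label="{_dot_escape(e.kind)}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


_NEEDS_QUOTE = set(",():;'[] \t")


def _newick_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(forest: ModificationForest, name: str) -> str:
    kids = forest.children.get(name, ())
    label = _newick_label(name)
    if not kids:
        return label
    inner = ",".join(_newick_node(forest, k) for k in kids)
    return f"({inner}){label}"


def to_newick(forest: ModificationForest, base: str) -> str:
    """One rooted Newick string for the tree of ``base``; no branch lengths.

    Labels containing Newick-reserved characters (e.g. the comma in
    ``m2,2G``) are single-quoted with internal quotes doubled.
    """
    if base not in forest.roots:
        raise ForestError(f"unknown root base {base!r}")
    return _newick_node(forest, base) + ";"


def to_json_graph(forest: ModificationForest) -> str:
    """Node-link JSON with stage attributes; deterministic ordering."""
    nodes = []
    for b in forest.roots:
        nodes.append({"id": b, "stage": 0, "root_base": b, "is_root": True})
    for n in sorted(forest.nodes):
        r = forest.nodes[n]
        nodes.append({
            "id": n,
            "stage": compute_stage(forest, n),
            "root_base": r.root_base,
            "is_root": False,
            "full_name": r.full_name,
        })
    links = [{"source": p, "target": c, "kind": "parent"}
             for p, c in forest.tree_edges()]
    links += [{"source": e.source, "target": e.target, "kind": e.kind}
              for e in forest.cross_talk]
    return json.dumps({"nodes": nodes, "links": links},
                      ensure_ascii=False, indent=1) + "\n"
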