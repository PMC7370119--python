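"""Parsing of RNA-modification short names.

A short name such as ``m2,2,7G`` or ``mcm5s2U`` encodes a root ribonucleoside
(A, C, G or U) plus a multiset of chemical operations.  The tokenizer is
table-driven (``data/tokens.json``): prefixes are matched greedily
left-to-right (longest token first, each optionally followed by a
comma-separated locant list), the core is a plain base letter or a registered
special symbol, and the suffixes ``m`` / ``r(p)`` denote ribose
2'-O-methylation / 2'-O-ribosylation.

Special cores fall in two groups: simple editing/isomer symbols (I, Ψ, D,
C+, k2C) that contribute an implied operation, and atomic family symbols
(queuosine and wyosine families) whose internal multi-step chemistry is not
decomposed — for those ``atomic_core`` is true and the operation count is
undefined.  Exact matches against the core registry take precedence over
prefix tokenization, which keeps e.g. ``mimG`` (methylwyosine) from also
reading as methyl + isopentenyl + methyl + guanosine.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .census import Census, ValidationReport

__all__ = [
    "ModOperation",
    "Decomposition",
    "NameParseError",
    "normalize_name",
    "parse_short_name",
    "check_consistency",
]

OPERATION_KINDS = frozenset({
    "methylation", "2'-O-methylation", "2'-O-ribosylation", "thiolation",
    "selenation", "geranylthiolation", "acetylation", "formylation",
    "hydroxylation", "hydroxymethylation", "methoxylation",
    "aminomethyl-side-chain", "carboxymethyl-side-chain",
    "carbamoylmethyl-side-chain", "taurinomethyl-side-chain",
    "threonylcarbamoylation", "glycinylcarbamoylation", "isopentenylation",
    "aminocarboxypropylation", "lysidination", "agmatination", "deamination",
    "isomerization", "reduction", "glycosylation", "glutamylation", "complex",
})


class NameParseError(ValueError):
    """Raised when a short name cannot be parsed unambiguously."""


@dataclass(frozen=True, order=True)
class ModOperation:
    """One chemical operation applied ``count`` times at ``site``."""

    kind: str
    site: str
    count: int = 1


@dataclass(frozen=True)
class Decomposition:
    """Parser output: root base plus the multiset of operations."""

    root_base: str
    operations: tuple[ModOperation, ...]
    canonical_name: str
    atomic_core: bool = False

    @property
    def op_count(self) -> int:
        return sum(op.count for op in self.operations)


def _load_tables():
    doc = json.loads(
        resources.files("rnamodcensus.data").joinpath("tokens.json")
        .read_text(encoding="utf-8"))
    prefixes = doc["prefixes"]
    cores = doc["cores"]
    suffixes = doc["suffixes"]
    aliases = doc["aliases"]
    return prefixes, cores, suffixes, aliases


_PREFIXES, _CORES, _SUFFIXES, _ALIASES = _load_tables()
_PREFIX_BY_LEN = sorted(_PREFIXES, key=len, reverse=True)
_CORE_BY_LEN = sorted(_CORES, key=len, reverse=True)
_LOCANT_RE = re.compile(r"(\d+(?:,\d+)*)")


def normalize_name(raw: str) -> str:
    """NFC-normalize, strip whitespace, and map registered ASCII aliases."""
    if raw is None or not str(raw).strip():
        raise NameParseError("empty modification name")
    name = unicodedata.normalize("NFC", str(raw).strip())
    if name in _ALIASES:
        return _ALIASES[name]
    if "psi" in name:
        name = name.replace("psi", "Ψ")
    return name


def _merge_ops(raw_ops: list[tuple[str, str]]) -> tuple[ModOperation, ...]:
    counts: dict[tuple[str, str], int] = {}
    for kind, site in raw_ops:
        counts[(kind, site)] = counts.get((kind, site), 0) + 1
    return tuple(sorted(
        ModOperation(kind=k, site=s, count=c) for (k, s), c in counts.items()))


def _tokenize_prefix(prefix: str) -> Optional[list[tuple[str, str]]]:
    """Greedy longest-match tokenization; None when the prefix is rejected."""
    ops: list[tuple[str, str]] = []
    pos = 0
    while pos < len(prefix):
        for tok in _PREFIX_BY_LEN:
            if prefix.startswith(tok, pos):
                pos += len(tok)
                m = _LOCANT_RE.match(prefix, pos)
                spec = _PREFIXES[tok]
                if m:
                    pos = m.end()
                    for locant in m.group(1).split(","):
                        ops.append((spec["kind"], spec["site"].format(n=locant)))
                else:
                    ops.append((spec["kind"], ""))
                break
        else:
            return None
    return ops


def _unconsumed(prefix: str) -> str:
    """Longest tokenizable head of ``prefix``, for the error message."""
    pos = 0
    while pos < len(prefix):
        advanced = False
        for tok in _PREFIX_BY_LEN:
            if prefix.startswith(tok, pos):
                pos += len(tok)
                m = _LOCANT_RE.match(prefix, pos)
                if m:
                    pos = m.end()
                advanced = True
                break
        if not advanced:
            break
    return prefix[pos:]


def parse_short_name(name: str) -> Decomposition:
    """Parse a canonical short name into a :class:`Decomposition`.

    Call :func:`normalize_name` first for raw user input.
    """
    if not name:
        raise NameParseError("empty modification name")

    # 1. exact match against the core registry (atomic family symbols and
    #    plain/special cores used verbatim)
    if name in _CORES:
        spec = _CORES[name]
        ops = _merge_ops([(o["kind"], o["site"]) for o in spec.get("ops", [])])
        return Decomposition(root_base=spec["root"], operations=ops,
                             canonical_name=name,
                             atomic_core=bool(spec.get("atomic", False)))

    # 2. split as prefixes + core + optional suffix; the core is matched at
    #    the tail, longest core first
    candidates: list[Decomposition] = []
    for suffix in ("", "m", "r(p)"):
        for core in _CORE_BY_LEN:
            tail = core + suffix
            if not name.endswith(tail):
                continue
            prefix = name[: len(name) - len(tail)]
            if not prefix and not suffix:
                continue  # a bare core was handled in step 1
            prefix_ops = _tokenize_prefix(prefix)
            if prefix_ops is None:
                continue
            spec = _CORES[core]
            raw = list(prefix_ops)
            raw += [(o["kind"], o["site"]) for o in spec.get("ops", [])]
            if suffix:
                s = _SUFFIXES[suffix]
                raw.append((s["kind"], s["site"]))
            candidates.append(Decomposition(
                root_base=spec["root"], operations=_merge_ops(raw),
                canonical_name=name,
                atomic_core=bool(spec.get("atomic", False))))

    distinct = {(d.root_base, d.operations, d.atomic_core) for d in candidates}
    if len(distinct) > 1:
        raise NameParseError(f"ambiguous parse for {name!r}: "
                             f"{len(distinct)} distinct decompositions")
    if candidates:
        return candidates[0]

    # no parse: produce a useful message
    has_core = any(c in name for c in _CORE_BY_LEN)
    if not has_core:
        raise NameParseError(f"no core found in {name!r}")
    raise NameParseError(
        f"cannot parse {name!r}: unknown token near {_unconsumed(name)!r}")


# -- cross-checking parser vs curated lineage --------------------------------

def _curated_stage(census: Census, short_name: str) -> Optional[int]:
    by_name = {r.short_name: r for r in census.records}
    stage = 0
    cur = by_name.get(short_name)
    while cur is not None:
        stage += 1
        if not cur.parent:
            return stage
        cur = by_name.get(cur.parent)
        if stage > len(by_name):
            return None  # cycle; validate_census reports it
    return None


def check_consistency(census: Census) -> ValidationReport:
    """Check every placed record's name against its curated lineage.

    The parsed root base must agree with the curated one, and for
    non-atomic cores the operation count is a lower bound on the curated
    stage (compound side-chain tokens count as one operation while the
    staged scheme counts every chemical step), so 1 <= op_count <= stage.
    """
    violations: list[tuple[str, str, str]] = []
    for r in census.by_status("placed"):
        try:
            dec = parse_short_name(normalize_name(r.short_name))
        except NameParseError as exc:
            violations.append(("parse-error", r.short_name, str(exc)))
            continue
        if dec.root_base != r.root_base:
            violations.append((
                "root-mismatch", r.short_name,
                f"name parses to root {dec.root_base}, curated root {r.root_base}"))
            continue
        if dec.atomic_core:
            continue
        stage = _curated_stage(census, r.short_name)
        if stage is None:
            continue
        if dec.op_count < 1:
            violations.append(("op-count-zero", r.short_name,
                               "placed record decomposes to zero operations"))
        elif dec.op_count > stage:
            violations.append((
                "op-count-exceeds-stage", r.short_name,
                f"{dec.op_count} operations but curated stage {stage}"))
    return ValidationReport(violations=tuple(violations))
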