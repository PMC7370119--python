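"""Indexed queries over census annotations.

These reproduce the two content views the survey draws from the census: the
tRNA map (which marks sit at which position of the canonical 76-residue
tRNA) and the mRNA map (which marks occur in which transcript region, at
which motif).

Position labels are text throughout — tRNA numbering includes inserted
residues such as 20A, 20B and 47b — and may carry a kingdom qualifier
("22[bacteria]" for the bacteria-only m1A22); a qualified entry matches both
the bare label and a kingdom-qualified query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from typing import Optional

from .census import (Census, CensusError, KINGDOMS, MRNA_REGIONS,
                     ModificationRecord, PLACEMENT_STATUSES, RNA_CLASSES,
                     ROOT_BASES)

__all__ = ["QueryFilter", "query", "positions_report", "mrna_map"]

_QUALIFIER_RE = re.compile(r"^(?P<label>[^\[\]]+)(?:\[(?P<kingdom>[^\[\]]+)\])?$")


@dataclass(frozen=True)
class QueryFilter:
    """Conjunction of optional criteria; an empty filter matches everything."""

    kingdom: Optional[str] = None
    rna_class: Optional[str] = None
    trna_position: Optional[str] = None
    mrna_region: Optional[str] = None
    motif: Optional[str] = None
    enzyme: Optional[str] = None      # matched across writers/readers/erasers
    status: Optional[str] = None
    root_base: Optional[str] = None

    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))


def _split_position(entry: str) -> tuple[str, Optional[str]]:
    m = _QUALIFIER_RE.match(entry)
    if not m:
        return entry, None
    return m.group("label"), m.group("kingdom")


def _position_matches(record_entry: str, wanted: str) -> bool:
    rec_label, rec_kingdom = _split_position(record_entry)
    want_label, want_kingdom = _split_position(wanted)
    if rec_label != want_label:
        return False
    return want_kingdom is None or want_kingdom == rec_kingdom


def _check_filter(f: QueryFilter) -> None:
    checks = (
        ("kingdom", f.kingdom, KINGDOMS),
        ("rna_class", f.rna_class, RNA_CLASSES),
        ("mrna_region", f.mrna_region, MRNA_REGIONS),
        ("status", f.status, PLACEMENT_STATUSES),
        ("root_base", f.root_base, ROOT_BASES),
    )
    for name, value, allowed in checks:
        if value is not None and value not in allowed:
            raise CensusError(f"unknown {name} value {value!r}")


def matches(record: ModificationRecord, f: QueryFilter) -> bool:
    """True when the record satisfies every populated filter field."""
    if f.kingdom is not None and f.kingdom not in record.kingdoms:
        return False
    if f.rna_class is not None and f.rna_class not in record.rna_classes:
        return False
    if f.trna_position is not None and not any(
            _position_matches(p, f.trna_position) for p in record.trna_positions):
        return False
    if f.mrna_region is not None and f.mrna_region not in record.mrna_regions:
        return False
    if f.motif is not None and f.motif not in record.motifs:
        return False
    if f.enzyme is not None:
        wanted = f.enzyme.casefold()
        pool = record.writers + record.readers + record.erasers
        if not any(g.casefold() == wanted for g in pool):
            return False
    if f.status is not None and record.status != f.status:
        return False
    if f.root_base is not None and record.root_base != f.root_base:
        return False
    return True


def query(census: Census, f: QueryFilter) -> list[ModificationRecord]:
    """AND-semantics filter over the census, ordered by short name."""
    _check_filter(f)
    hits = [r for r in census.records if matches(r, f)]
    return sorted(hits, key=lambda r: r.short_name)


def position_sort_key(label: str) -> tuple[int, str]:
    """Numeric order with letter suffixes after their number (20, 20A, 20B, 21)."""
    m = re.match(r"^(\d+)(.*)$", label)
    if m:
        return (int(m.group(1)), m.group(2))
    return (10**9, label)


def positions_report(census: Census) -> dict[str, list[str]]:
    """tRNA position -> sorted marks observed there (the tRNA-map view)."""
    by_pos: dict[str, set[str]] = {}
    for r in census.records:
        for entry in r.trna_positions:
            label, _ = _split_position(entry)
            by_pos.setdefault(label, set()).add(r.short_name)
    return {
        label: sorted(by_pos[label])
        for label in sorted(by_pos, key=position_sort_key)
    }


def mrna_map(census: Census) -> dict[str, list[tuple[str, tuple[str, ...]]]]:
    """mRNA region -> [(mark, motifs)] (the mRNA-map view).

    A mark appears under every region it is annotated with.
    """
    by_region: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for r in census.records:
        for region in r.mrna_regions:
            by_region.setdefault(region, []).append((r.short_name, r.motifs))
    return {
        region: sorted(by_region[region])
        for region in sorted(by_region)
    }
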