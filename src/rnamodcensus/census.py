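"""Domain types and I/O for the curated census of epitranscriptomic marks.

A census row is one modified ribonucleoside (a "mark") with its identity,
its lineage inside the staged modification forest, and annotations gathered
from the survey literature: the kingdoms it occurs in, the RNA classes that
carry it, tRNA positions, mRNA regions and motifs, and the cognate
writer/reader/eraser proteins.

Two on-disk dialects are supported:

* TSV — UTF-8, header row, one column per record field, multi-valued cells
  joined with ";" (short names themselves contain commas, e.g. ``m2,2G``),
  empty cell = absent.
* JSON — ``{version, source_note, records: [...]}`` with record keys matching
  the TSV columns; keys whose value is empty (or ``reversible: "unknown"``)
  may be omitted.  A schema file ships with the package and is enforced on
  load.
"""

from __future__ import annotations

import io
import json
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "PLACEMENT_STATUSES",
    "ROOT_BASES",
    "KINGDOMS",
    "RNA_CLASSES",
    "MRNA_REGIONS",
    "REVERSIBLE_VALUES",
    "TSV_COLUMNS",
    "ModificationRecord",
    "Census",
    "ValidationReport",
    "CensusError",
    "CensusValidationError",
    "load_census",
    "load_packaged_census",
    "write_census",
    "validate_census",
    "records_to_tsv",
]

# -- controlled vocabularies -------------------------------------------------

PLACEMENT_STATUSES = frozenset({"placed", "unplaced", "nascent"})
ROOT_BASES = frozenset({"A", "C", "G", "U"})
KINGDOMS = frozenset({"eukarya", "bacteria", "archaea"})
RNA_CLASSES = frozenset({
    "tRNA", "rRNA", "mRNA", "lncRNA", "snRNA", "snoRNA",
    "miRNA", "piRNA", "tsRNA", "viral",
})
MRNA_REGIONS = frozenset({
    "5'UTR", "CDS", "near-start", "near-stop", "3'UTR",
    "cap-adjacent", "internal-exon",
})
REVERSIBLE_VALUES = frozenset({"yes", "no", "unknown"})

TSV_COLUMNS = (
    "short_name", "ascii_alias", "full_name", "status", "root_base",
    "parent", "alt_parents", "kingdoms", "rna_classes", "trna_positions",
    "mrna_regions", "motifs", "writers", "readers", "erasers",
    "reversible", "stoichiometry_note", "notes", "refs",
)
_LIST_COLUMNS = frozenset({
    "alt_parents", "kingdoms", "rna_classes", "trna_positions",
    "mrna_regions", "motifs", "writers", "readers", "erasers", "refs",
})
_LIST_SEP = ";"


class CensusError(ValueError):
    """Raised for malformed census inputs (I/O level errors)."""


class CensusValidationError(CensusError):
    """Raised when an operation refuses an invalid census; carries the report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(
            f"{v[0]}({v[1] or '-'}): {v[2]}" for v in report.violations[:5])
        more = "" if len(report.violations) <= 5 else " ..."
        super().__init__(f"census is invalid: {lines}{more}")


@dataclass(frozen=True)
class ModificationRecord:
    """One epitranscriptomic mark and its curated annotations."""

    short_name: str
    ascii_alias: str
    full_name: str
    status: str
    root_base: str = ""            # "" = absent (nascent marks only)
    parent: str = ""               # "" = stage-1 child of the root, or not placed
    alt_parents: tuple[str, ...] = ()
    kingdoms: tuple[str, ...] = ()
    rna_classes: tuple[str, ...] = ()
    trna_positions: tuple[str, ...] = ()   # text labels: "34", "47b", "22[bacteria]"
    mrna_regions: tuple[str, ...] = ()
    motifs: tuple[str, ...] = ()
    writers: tuple[str, ...] = ()
    readers: tuple[str, ...] = ()
    erasers: tuple[str, ...] = ()
    reversible: str = "unknown"
    stoichiometry_note: str = ""
    notes: str = ""
    refs: tuple[str, ...] = ()


@dataclass(frozen=True)
class Census:
    """An ordered, validated collection of modification records."""

    records: tuple[ModificationRecord, ...]
    version: str = ""
    source_note: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, short_name: str) -> ModificationRecord:
        rec = self.find(short_name)
        if rec is None:
            raise KeyError(short_name)
        return rec

    def find(self, name: str) -> Optional[ModificationRecord]:
        """Look a record up by canonical short name or ASCII alias."""
        name = unicodedata.normalize("NFC", name)
        for r in self.records:
            if r.short_name == name or r.ascii_alias == name:
                return r
        return None

    def by_status(self, status: str) -> tuple[ModificationRecord, ...]:
        return tuple(r for r in self.records if r.status == status)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validate_census: violations are data, not exceptions."""

    violations: tuple[tuple[str, str, str], ...]  # (rule_id, short_name or "", message)

    @property
    def ok(self) -> bool:
        return not self.violations


# -- loading -----------------------------------------------------------------

def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def _record_from_strings(row: dict[str, str], where: str) -> ModificationRecord:
    kwargs: dict = {}
    for col in TSV_COLUMNS:
        raw = _nfc(row.get(col, "") or "")
        if col in _LIST_COLUMNS:
            kwargs[col] = tuple(
                p.strip() for p in raw.split(_LIST_SEP) if p.strip()) if raw else ()
        else:
            kwargs[col] = raw.strip() if col != "notes" else raw
    if not kwargs["short_name"]:
        raise CensusError(f"{where}: empty short_name")
    if not kwargs["reversible"]:
        kwargs["reversible"] = "unknown"
    _check_enums(kwargs, where)
    return ModificationRecord(**kwargs)


def _check_enums(kw: dict, where: str) -> None:
    def bad(col, value):
        raise CensusError(f"{where}, column {col!r}: malformed value {value!r}")
    if kw["status"] not in PLACEMENT_STATUSES:
        bad("status", kw["status"])
    if kw["root_base"] and kw["root_base"] not in ROOT_BASES:
        bad("root_base", kw["root_base"])
    if kw["reversible"] not in REVERSIBLE_VALUES:
        bad("reversible", kw["reversible"])
    for k in kw["kingdoms"]:
        if k not in KINGDOMS:
            bad("kingdoms", k)
    for c in kw["rna_classes"]:
        if c not in RNA_CLASSES:
            bad("rna_classes", c)
    for m in kw["mrna_regions"]:
        if m not in MRNA_REGIONS:
            bad("mrna_regions", m)


def _resolve_references(records: tuple[ModificationRecord, ...]) -> None:
    seen: dict[str, int] = {}
    for i, r in enumerate(records):
        if r.short_name in seen:
            raise CensusError(
                f"duplicate short_name {r.short_name!r} in rows "
                f"{seen[r.short_name] + 1} and {i + 1}")
        seen[r.short_name] = i
    for r in records:
        for ref, label in [(r.parent, "parent")] + [
                (a, "alt_parent") for a in r.alt_parents]:
            if ref and ref not in seen:
                raise CensusError(
                    f"record {r.short_name!r}: unresolvable {label} {ref!r}")


def _load_tsv(text: str) -> Census:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                     keep_default_na=False, na_filter=False)
    got = tuple(df.columns)
    unknown = [c for c in got if c not in TSV_COLUMNS]
    missing = [c for c in TSV_COLUMNS if c not in got]
    if unknown:
        raise CensusError(f"unknown TSV column(s): {unknown}")
    if missing:
        raise CensusError(f"missing TSV column(s): {missing}")
    records = tuple(
        _record_from_strings(dict(row), f"row {i + 2}")  # +2: header is line 1
        for i, row in df.iterrows())
    _resolve_references(records)
    return Census(records=records)


def _load_json(text: str) -> Census:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CensusError(f"not valid JSON: {exc}") from exc
    _enforce_schema(doc)
    records = []
    for i, obj in enumerate(doc["records"]):
        row = {}
        for col in TSV_COLUMNS:
            v = obj.get(col, "")
            row[col] = _LIST_SEP.join(v) if isinstance(v, list) else v
        records.append(_record_from_strings(row, f"records[{i}]"))
    records = tuple(records)
    _resolve_references(records)
    return Census(records=records, version=_nfc(doc.get("version", "")),
                  source_note=_nfc(doc.get("source_note", "")))


def _enforce_schema(doc) -> None:
    """Enforce the shipped JSON-dialect schema (self-contained checker)."""
    schema = json.loads(
        resources.files("rnamodcensus.data").joinpath("census.schema.json")
        .read_text(encoding="utf-8"))
    errors: list[str] = []
    _check_node(doc, schema, "$", errors)
    if errors:
        raise CensusError("JSON dialect schema violation: " + "; ".join(errors[:5]))


def _check_node(value, schema, path, errors) -> None:
    t = schema.get("type")
    if t == "object":
        if not isinstance(value, dict):
            errors.append(f"{path}: expected object")
            return
        for req in schema.get("required", ()):
            if req not in value:
                errors.append(f"{path}: missing required key {req!r}")
        props = schema.get("properties", {})
        for k, v in value.items():
            if k in props:
                _check_node(v, props[k], f"{path}.{k}", errors)
            elif not schema.get("additionalProperties", True):
                errors.append(f"{path}: unknown key {k!r}")
    elif t == "array":
        if not isinstance(value, list):
            errors.append(f"{path}: expected array")
            return
        items = schema.get("items")
        if items:
            for i, v in enumerate(value):
                _check_node(v, items, f"{path}[{i}]", errors)
    elif t == "string":
        if not isinstance(value, str):
            errors.append(f"{path}: expected string")
            return
        if "enum" in schema and value not in schema["enum"]:
            errors.append(f"{path}: {value!r} not one of the allowed values")


def load_census(source: Union[str, Path, bytes], format: str = "auto") -> Census:
    """Load a census from a path or raw bytes in the TSV or JSON dialect."""
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    else:
        path = Path(source)
        if not path.exists():
            raise CensusError(f"no such census file: {path}")
        text = path.read_bytes().decode("utf-8")
        if format == "auto":
            suffix = path.suffix.lower()
            if suffix in (".tsv", ".tab", ".txt"):
                format = "tsv"
            elif suffix == ".json":
                format = "json"
    if format == "auto":
        format = "json" if text.lstrip()[:1] == "{" else "tsv"
    if format == "tsv":
        return _load_tsv(text)
    if format == "json":
        return _load_json(text)
    raise CensusError(f"unknown census format {format!r}")


def load_packaged_census() -> Census:
    """Load the census curated into the package."""
    data = (resources.files("rnamodcensus.data") / "census.json").read_bytes()
    return load_census(data, format="json")


# -- writing -----------------------------------------------------------------

def _record_row(r: ModificationRecord) -> list[str]:
    out = []
    for col in TSV_COLUMNS:
        v = getattr(r, col)
        out.append(_LIST_SEP.join(v) if isinstance(v, tuple) else v)
    return out


def records_to_tsv(records: Iterable[ModificationRecord]) -> bytes:
    """Serialize records as the TSV dialect (used for query exports too)."""
    lines = ["\t".join(TSV_COLUMNS)]
    for r in records:
        lines.append("\t".join(_record_row(r)))
    return ("\n".join(lines) + "\n").encode("utf-8")


def write_census(census: Census, format: str) -> bytes:
    """Serialize a census; refuses to write an invalid one."""
    report = validate_census(census)
    if not report.ok:
        raise CensusValidationError(report)
    if format == "tsv":
        return records_to_tsv(census.records)
    if format == "json":
        recs = []
        for r in census.records:
            obj = {}
            for col in TSV_COLUMNS:
                v = getattr(r, col)
                if isinstance(v, tuple):
                    if v:
                        obj[col] = list(v)
                elif v and not (col == "reversible" and v == "unknown"):
                    obj[col] = v
            recs.append(obj)
        doc = {"version": census.version, "source_note": census.source_note,
               "records": recs}
        return (json.dumps(doc, ensure_ascii=False, indent=1) + "\n").encode("utf-8")
    raise CensusError(f"unknown census format {format!r}")


# -- validation --------------------------------------------------------------

def validate_census(census: Census) -> ValidationReport:
    """Check every record-level and census-level invariant.

    The lineage rules mirror the staged-forest model: a placed mark derives
    from a placed substrate of the same root base, and parent chains must
    terminate at the root.
    """
    v: list[tuple[str, str, str]] = []
    names: dict[str, int] = {}
    for i, r in enumerate(census.records):
        if not r.short_name:
            v.append(("empty-short-name", "", f"record #{i + 1} has no short_name"))
            continue
        if r.short_name in names:
            v.append(("duplicate-short-name", r.short_name,
                      f"records #{names[r.short_name] + 1} and #{i + 1} share a name"))
        else:
            names[r.short_name] = i
    by_name = {r.short_name: r for r in census.records}

    for r in census.records:
        n = r.short_name
        if r.status not in PLACEMENT_STATUSES:
            v.append(("bad-status", n, f"status {r.status!r}"))
            continue
        if r.status == "placed":
            if r.root_base not in ROOT_BASES:
                v.append(("placed-missing-root", n,
                          f"placed record needs root_base in A/C/G/U, got {r.root_base!r}"))
            if r.parent:
                p = by_name.get(r.parent)
                if p is None:
                    v.append(("unresolved-parent", n, f"parent {r.parent!r} not in census"))
                elif p.status != "placed":
                    v.append(("parent-not-placed", n,
                              f"parent {r.parent!r} has status {p.status}"))
                elif p.root_base != r.root_base:
                    v.append(("parent-root-mismatch", n,
                              f"parent {r.parent!r} is {p.root_base}-derived, "
                              f"record is {r.root_base}-derived"))
        elif r.status == "nascent":
            if r.parent:
                v.append(("nascent-has-parent", n, f"parent {r.parent!r}"))
            if r.root_base:
                v.append(("nascent-has-root", n, f"root_base {r.root_base!r}"))
        else:  # unplaced
            if r.parent:
                v.append(("unplaced-has-parent", n, f"parent {r.parent!r}"))
        for a in r.alt_parents:
            if a not in by_name:
                v.append(("unresolved-alt-parent", n, f"alt_parent {a!r} not in census"))
        if r.reversible not in REVERSIBLE_VALUES:
            v.append(("bad-reversible", n, f"reversible {r.reversible!r}"))
        for k in r.kingdoms:
            if k not in KINGDOMS:
                v.append(("bad-kingdom", n, f"kingdom {k!r}"))
        for c in r.rna_classes:
            if c not in RNA_CLASSES:
                v.append(("bad-rna-class", n, f"rna_class {c!r}"))
        for m in r.mrna_regions:
            if m not in MRNA_REGIONS:
                v.append(("bad-mrna-region", n, f"mrna_region {m!r}"))
        if r.trna_positions and "tRNA" not in r.rna_classes:
            v.append(("trna-position-without-class", n,
                      "has tRNA positions but tRNA not in rna_classes"))
        if r.mrna_regions and "mRNA" not in r.rna_classes:
            v.append(("mrna-annotation-without-class", n,
                      "has mRNA regions but mRNA not in rna_classes"))

    # parent chains terminate (no cycles among resolvable placed parents);
    # each distinct cycle is reported once no matter how many chains reach it
    reported_cycles: set[frozenset] = set()
    for r in census.records:
        if r.status != "placed" or not r.parent:
            continue
        seen = [r.short_name]
        cur = r
        while cur.parent:
            if cur.parent in seen:
                cycle = seen[seen.index(cur.parent):] + [cur.parent]
                key = frozenset(cycle)
                if key not in reported_cycles:
                    reported_cycles.add(key)
                    v.append(("parent-cycle", cycle[0],
                              "cycle: " + " -> ".join(cycle)))
                break
            seen.append(cur.parent)
            nxt = by_name.get(cur.parent)
            if nxt is None or nxt.status != "placed":
                break
            cur = nxt

    # report each violation once
    unique = tuple(dict.fromkeys(v))
    return ValidationReport(violations=unique)
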