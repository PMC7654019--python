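"""Attribute schemas, record containers, normalization and delimited-file I/O.

Linkage operates on person-level records described by a small set of typed
attributes (names, dates of birth, sex, municipality codes).  All values are
normalized to a restricted uppercase-ASCII alphabet on load so that every
downstream comparison works on a canonical representation; missingness is
uniformly encoded as the empty string.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "KINDS",
    "Attribute",
    "AttributeSchema",
    "Record",
    "Dataset",
    "normalize_value",
    "load_dataset",
    "write_linked_output",
]

#: supported attribute kinds
KINDS = ("string", "categorical", "date", "ibge")

#: characters allowed in a normalized value (after accent folding)
_ALPHABET_RE = re.compile(r"[^A-Z0-9 \-]")
_WS_RE = re.compile(r"\s+")

#: strptime patterns for the supported input date dialects
_DATE_DIALECTS = {
    "DD-MM-YYYY": ("%d-%m-%Y", "%d/%m/%Y"),
    "MM-DD-YYYY": ("%m-%d-%Y", "%m/%d/%Y"),
    "YYYY-MM-DD": ("%Y-%m-%d", "%Y/%m/%d"),
}


@dataclass(frozen=True)
class Attribute:
    """One linkage attribute: its name, type kind and comparison weight."""

    name: str
    kind: str
    weight: float

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValueError("attribute name must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(
                f"unknown attribute kind {self.kind!r}; expected one of {KINDS}"
            )
        if self.weight < 0:
            raise ValueError(f"attribute {self.name!r}: weight must be >= 0")


class AttributeSchema:
    """Ordered collection of linkage attributes with kinds and weights.

    Parameters
    ----------
    attributes
        Iterable of ``(name, kind, weight)`` triples or :class:`Attribute`
        instances.  Names must be unique; weights non-negative with at least
        one strictly positive.
    """

    def __init__(self, attributes: Iterable[Attribute | tuple]) -> None:
        attrs = [
            a if isinstance(a, Attribute) else Attribute(*a) for a in attributes
        ]
        if not attrs:
            raise ValueError("schema needs at least one attribute")
        names = [a.name for a in attrs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate attribute names: {dupes}")
        if not any(a.weight > 0 for a in attrs):
            raise ValueError("at least one attribute weight must be > 0")
        self._attrs: tuple[Attribute, ...] = tuple(attrs)
        self._by_name = {a.name: a for a in attrs}

    @property
    def attributes(self) -> tuple[Attribute, ...]:
        return self._attrs

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self._attrs)

    def kind(self, name: str) -> str:
        return self._by_name[name].kind

    def weight(self, name: str) -> float:
        return self._by_name[name].weight

    def __len__(self) -> int:
        return len(self._attrs)

    def __iter__(self):
        return iter(self._attrs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other) -> bool:
        return isinstance(other, AttributeSchema) and self._attrs == other._attrs

    def __repr__(self) -> str:
        inner = ", ".join(f"{a.name}:{a.kind}(w={a.weight:g})" for a in self._attrs)
        return f"AttributeSchema({inner})"


@dataclass
class Record:
    """A single person-level record: an id plus normalized attribute values.

    ``values`` keys are exactly the schema attribute names; the empty string
    denotes a missing value.  ``extras`` carries non-linkage columns (for
    instance a shared unique key used to build ground truth) and never
    participates in indexing or comparison.
    """

    record_id: str
    values: dict[str, str]
    extras: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> str:
        if name in self.values:
            return self.values[name]
        return self.extras.get(name, "")

    def non_missing(self, schema: AttributeSchema) -> list[str]:
        """Names of schema attributes with a non-missing value."""
        return [a.name for a in schema if self.values.get(a.name, "")]


class Dataset:
    """An ordered collection of records conforming to one schema."""

    def __init__(self, schema: AttributeSchema, records: Sequence[Record],
                 label: str = "") -> None:
        seen: set[str] = set()
        want = set(schema.names)
        for r in records:
            if r.record_id in seen:
                raise ValueError(f"duplicate record id {r.record_id!r}")
            seen.add(r.record_id)
            if set(r.values) != want:
                raise ValueError(
                    f"record {r.record_id!r} keys {sorted(r.values)} do not "
                    f"match schema attributes {sorted(want)}"
                )
        self.schema = schema
        self.records: list[Record] = list(records)
        self.label = label
        self._by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> Record:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame (id column first, then schema attributes)."""
        rows = [
            {"record_id": r.record_id, **r.values, **r.extras}
            for r in self.records
        ]
        return pd.DataFrame(rows)


def _fold_ascii(text: str) -> str:
    """Strip accents to their ASCII base characters (NFKD decomposition)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return decomposed.encode("ascii", "ignore").decode("ascii")


def normalize_value(raw: object, kind: str, date_dialect: str = "DD-MM-YYYY") -> str:
    """Normalize one raw value for a given attribute kind.

    Text is uppercased, accent-folded to ASCII, restricted to the alphabet
    ``A-Z 0-9 space hyphen`` and whitespace-collapsed.  Dates are parsed in
    the declared input dialect (ISO always accepted, making the operation
    idempotent) and canonicalized to ``YYYY-MM-DD``; unparseable dates become
    missing (empty string).  Never raises on bad data.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ""
    text = str(raw).strip()
    if not text:
        return ""
    text = _fold_ascii(text).upper()
    text = _ALPHABET_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    if kind == "date":
        return _canonical_date(text, date_dialect)
    return text


def _canonical_date(text: str, dialect: str) -> str:
    if dialect not in _DATE_DIALECTS:
        raise ValueError(
            f"unknown date dialect {dialect!r}; expected one of "
            f"{sorted(_DATE_DIALECTS)}"
        )
    candidate = text.replace(" ", "-")
    patterns = _DATE_DIALECTS[dialect]
    if dialect != "YYYY-MM-DD":
        # ISO input is always accepted so normalization is idempotent
        patterns = patterns + _DATE_DIALECTS["YYYY-MM-DD"]
    for pat in patterns:
        try:
            return datetime.strptime(candidate, pat).strftime("%Y-%m-%d")
        except ValueError:
            continue
    return ""


def load_dataset(path: str | Path, schema: AttributeSchema, id_column: str,
                 label: str = "", date_dialect: str = "DD-MM-YYYY") -> Dataset:
    """Read a CSV file into a :class:`Dataset`, normalizing every value.

    The header must contain ``id_column`` and every schema attribute; any
    additional columns are kept verbatim in each record's ``extras``.  Row
    order is preserved.  Duplicate ids fail with the offending id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in [id_column, *schema.names] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c != id_column and c not in schema]
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        rid = str(row_d[id_column]).strip()
        if rid in seen:
            raise ValueError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        values = {
            a.name: normalize_value(row_d[a.name], a.kind, date_dialect)
            for a in schema
        }
        extras = {c: str(row_d[c]) for c in extra_cols}
        records.append(Record(rid, values, extras))
    return Dataset(schema, records, label=label or path.stem)


def write_linked_output(result, A: Dataset, B: Dataset, path: str | Path) -> None:
    """Write one CSV row per linked B record with the pair laid side by side.

    Columns: ``b_id, a_id, score, stage`` then each linkage attribute from B
    and from A (suffixed ``_b`` / ``_a``).  Unaccepted records keep their best
    score but leave the A-side cells empty.
    """
    names = B.schema.names
    rows = []
    for p in result.pairs:
        b = B[p.b_id]
        a = A[p.a_id] if (p.accepted and p.a_id is not None) else None
        row: dict[str, object] = {
            "b_id": p.b_id,
            "a_id": p.a_id if a is not None else "",
            "score": "" if p.score is None else f"{p.score:.6f}",
            "stage": p.stage or "",
        }
        for n in names:
            row[f"{n}_b"] = b.values[n]
        for n in names:
            row[f"{n}_a"] = a.values[n] if a is not None else ""
        rows.append(row)
    cols = ["b_id", "a_id", "score", "stage"]
    cols += [f"{n}_b" for n in names] + [f"{n}_a" for n in names]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
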