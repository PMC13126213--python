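"""Readers and writers for labeled abstract collections (CSV and RIS), plus
study-eligibility checks.

Default CSV layout: UTF-8, comma separated, header row with columns
``record_id, title, abstract, label_included, key_study``.  RIS carries the
text in the standard TI/AB tags and the relevance label in a custom tag
(default ``U1``; RIS has no standard relevance tag, so the tag is
configurable).  The key-study flag travels in ``U2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import Collection, Record

#: Accepted spellings of the relevance label, case-insensitive.
_LABEL_VALUES = {
    "1": 1, "0": 0,
    "yes": 1, "no": 0,
    "included": 1, "excluded": 0,
    "relevant": 1, "irrelevant": 0,
    "true": 1, "false": 0,
}

_TRUTHY = {"1", "yes", "true"}


@dataclass
class ColumnMapping:
    """Column / RIS-tag names designating each Record field."""

    id: str = "record_id"
    title: str = "title"
    abstract: str = "abstract"
    label: str = "label_included"
    key_study: str = "key_study"
    ris_label_tag: str = "U1"
    ris_key_tag: str = "U2"


DEFAULT_MAPPING = ColumnMapping()


def coerce_label(value: object) -> int:
    """Coerce a raw label cell to 0/1; raises on anything unrecognised."""
    text = str(value).strip().lower()
    if text not in _LABEL_VALUES:
        raise ValueError(f"unrecognised relevance label {value!r}")
    return _LABEL_VALUES[text]


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, mapping: ColumnMapping) -> Collection:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if mapping.label not in frame.columns:
        raise ValueError(f"{path}: missing label column {mapping.label!r}")
    records = []
    n_textless = 0
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        data = dict(zip(frame.columns, row))
        rid = data.get(mapping.id, "") or f"rec{row_idx:06d}"
        title = data.get(mapping.title, "")
        abstract = data.get(mapping.abstract, "")
        if not abstract and not title:
            n_textless += 1
        try:
            label = coerce_label(data[mapping.label])
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_idx}: {exc}") from exc
        key = str(data.get(mapping.key_study, "0")).strip().lower() in _TRUTHY
        try:
            records.append(
                Record(id=rid, title=title, abstract=abstract, label=label,
                       is_key_study=key)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_idx}: {exc}") from exc
    if n_textless:
        warnings.warn(
            f"{path}: {n_textless} record(s) lack both title and abstract",
            stacklevel=3,
        )
    return Collection(records, name=path.stem)


def _write_csv(collection: Collection, path: Path, mapping: ColumnMapping) -> None:
    frame = pd.DataFrame(
        {
            mapping.id: [r.id for r in collection],
            mapping.title: [r.title for r in collection],
            mapping.abstract: [r.abstract for r in collection],
            mapping.label: [r.label for r in collection],
            mapping.key_study: [int(r.is_key_study) for r in collection],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RIS (minimal tagged format: "XX  - value" lines, records end with ER)
# ---------------------------------------------------------------------------

def _read_ris(path: Path, mapping: ColumnMapping) -> Collection:
    records: list[Record] = []
    current: dict[str, str] = {}
    saw_label = False

    def flush(rec_idx: int) -> None:
        nonlocal current
        if not current:
            return
        if mapping.ris_label_tag not in current:
            raise ValueError(
                f"{path}: record {rec_idx}: missing label tag "
                f"{mapping.ris_label_tag!r}"
            )
        rid = current.get("ID", "") or f"rec{rec_idx:06d}"
        records.append(
            Record(
                id=rid,
                title=current.get("TI", ""),
                abstract=current.get("AB", ""),
                label=coerce_label(current[mapping.ris_label_tag]),
                is_key_study=current.get(mapping.ris_key_tag, "0").strip().lower()
                in _TRUTHY,
            )
        )
        current = {}

    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    for line in text.splitlines():
        if not line.strip():
            continue
        if len(line) < 6 or line[2:6] != "  - ":
            # continuation of the previous tag value
            if current:
                last = list(current)[-1]
                current[last] += " " + line.strip()
            continue
        tag, value = line[:2], line[6:].strip()
        if tag == "ER":
            flush(len(records))
        else:
            current[tag] = value
        if tag == mapping.ris_label_tag:
            saw_label = True
    flush(len(records))
    if not saw_label:
        raise ValueError(
            f"{path}: no {mapping.ris_label_tag!r} label tag found in any record"
        )
    return Collection(records, name=path.stem)


def _write_ris(collection: Collection, path: Path, mapping: ColumnMapping) -> None:
    lines: list[str] = []
    for r in collection:
        lines.append("TY  - JOUR")
        lines.append(f"ID  - {r.id}")
        if r.title:
            lines.append(f"TI  - {r.title}")
        if r.abstract:
            lines.append(f"AB  - {r.abstract}")
        lines.append(f"{mapping.ris_label_tag}  - {r.label}")
        lines.append(f"{mapping.ris_key_tag}  - {int(r.is_key_study)}")
        lines.append("ER  - ")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_collection(
    path: str | Path,
    format: str | None = None,
    mapping: ColumnMapping = DEFAULT_MAPPING,
) -> Collection:
    """Read a labeled collection from CSV or RIS.

    ``format`` defaults to the file extension (".ris" -> ris, else csv).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("ris" if path.suffix.lower() == ".ris" else "csv")
    if fmt == "csv":
        return _read_csv(path, mapping)
    if fmt == "ris":
        return _read_ris(path, mapping)
    raise ValueError(f"unknown format {fmt!r}")


def write_collection(
    collection: Collection,
    path: str | Path,
    format: str | None = None,
    mapping: ColumnMapping = DEFAULT_MAPPING,
) -> None:
    """Write a collection to CSV or RIS, re-readable by :func:`read_collection`."""
    path = Path(path)
    fmt = format or ("ris" if path.suffix.lower() == ".ris" else "csv")
    if fmt == "csv":
        _write_csv(collection, path, mapping)
    elif fmt == "ris":
        _write_ris(collection, path, mapping)
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class EligibilityResult:
    eligible: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.eligible


#: Inclusion thresholds per study design. Study 1 requires at least 1,000
#: screened abstracts with at least 50 relevant; Study 2 additionally needs a
#: deep irrelevant pool (collections with fewer than 4,000 irrelevant or 50
#: relevant abstracts are excluded, i.e. eligibility is >= 4,000 irrelevant).
STUDY1_MIN_N = 1000
STUDY1_MIN_R = 50
STUDY2_MIN_IRRELEVANT = 4000
STUDY2_MIN_R = 50


def check_eligibility(collection: Collection, study: str) -> EligibilityResult:
    """Check whether a collection qualifies for a study design.

    Boundaries are inclusive ("at least"): study1 needs N >= 1000 and
    R >= 50; study2 needs N - R >= 4000 and R >= 50.
    """
    reasons: list[str] = []
    n, r = collection.N, collection.R
    if study == "study1":
        if n < STUDY1_MIN_N:
            reasons.append(f"N below {STUDY1_MIN_N} (got {n})")
        if r < STUDY1_MIN_R:
            reasons.append(f"R below {STUDY1_MIN_R} (got {r})")
    elif study == "study2":
        if n - r < STUDY2_MIN_IRRELEVANT:
            reasons.append(
                f"irrelevant count below {STUDY2_MIN_IRRELEVANT} (got {n - r})"
            )
        if r < STUDY2_MIN_R:
            reasons.append(f"R below {STUDY2_MIN_R} (got {r})")
    else:
        raise ValueError(f"unknown study {study!r}")
    return EligibilityResult(eligible=not reasons, reasons=reasons)
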