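"""Data model for labeled abstract collections.

A :class:`Record` is one screened reference (title + abstract) carrying the
oracle relevance label that simulation mode replays in place of a human
reviewer.  A :class:`Collection` is an ordered set of records; its two summary
counts are ``N`` (total records) and ``R`` (relevant records), the quantities
every downstream prevalence, cost, and sensitivity computation is expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

RELEVANT = 1
IRRELEVANT = 0


@dataclass(frozen=True)
class Record:
    """One labeled abstract.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    title, abstract : str
        Free text; either may be empty but not both.
    label : int
        Oracle relevance decision, 1 = relevant, 0 = irrelevant.
    is_key_study : bool
        Marked relevant before screening started; used by the key-study
        stopping rule.
    """

    id: str
    title: str = ""
    abstract: str = ""
    label: int = IRRELEVANT
    is_key_study: bool = False

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.title and not self.abstract:
            raise ValueError(f"record {self.id!r}: title and abstract both empty")

    @property
    def text(self) -> str:
        """Title and abstract joined — the text fed to feature extractors."""
        return f"{self.title} {self.abstract}".strip()

    def with_label(self, label: int) -> "Record":
        return replace(self, label=label)


@dataclass
class Collection:
    """An ordered list of records with unique ids.

    Attributes
    ----------
    records : list of Record
    name : str
        Optional provenance tag (file stem, generator spec, condition id).
    """

    records: list[Record] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record id {dup!r} in collection")

    # -- counts ---------------------------------------------------------
    @property
    def N(self) -> int:
        """Total number of records."""
        return len(self.records)

    @property
    def R(self) -> int:
        """Number of relevant records."""
        return sum(r.label == RELEVANT for r in self.records)

    @property
    def prevalence(self) -> float:
        """Fraction of relevant records, R / N."""
        if self.N == 0:
            raise ValueError("prevalence undefined for an empty collection")
        return self.R / self.N

    # -- access ---------------------------------------------------------
    def __len__(self) -> int:
        return self.N

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Record:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def by_id(self, record_id: str) -> Record:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def relevant(self) -> list[Record]:
        return [r for r in self.records if r.label == RELEVANT]

    def irrelevant(self) -> list[Record]:
        return [r for r in self.records if r.label == IRRELEVANT]

    def subset(self, ids: Iterable[str], name: str = "") -> "Collection":
        """New collection keeping only ``ids``, in this collection's order."""
        wanted = set(ids)
        return Collection(
            [r for r in self.records if r.id in wanted],
            name=name or self.name,
        )

    def without(self, ids: Iterable[str], name: str = "") -> "Collection":
        dropped = set(ids)
        return Collection(
            [r for r in self.records if r.id not in dropped],
            name=name or self.name,
        )
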