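"""Practical recommendations: prevalence estimation from a random
prescreening phase, prevalence-band cutoff lookup, and workload projection.

The recommended workflow: randomly screen at least max(1% of the retrieved
records, 100) until one relevant record is found; estimate prevalence as
relevant-found / randomly-screened; look up the stopping cutoffs for the
prevalence band; project the workload saving as
``1 - (random share + time-based cutoff + data-driven cutoff)``.

The default band table carries only the two entry sets that are fully
specified by the recommendation text (the [2.5%, 7.5%) band: time-based 35%,
data-driven 5%; the (0, 2.5%) band: time-based 40%, breakout 15%).  Bands
without configured cutoffs fail closed — the lookup raises rather than
guesses — and the table is user-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandEntry:
    """Cutoffs recommended for one prevalence band [low, high)."""

    low: float
    high: float
    time_based_cutoff: float | None = None
    data_driven_cutoff: float | None = None
    breakout_cutoff: float | None = None

    def contains(self, prevalence: float) -> bool:
        return self.low <= prevalence < self.high

    @property
    def configured(self) -> bool:
        return any(
            c is not None
            for c in (self.time_based_cutoff, self.data_driven_cutoff,
                      self.breakout_cutoff)
        )


@dataclass(frozen=True)
class RecommendationTable:
    """Prevalence bands partitioning (0, 1), each with optional cutoffs."""

    bands: tuple[BandEntry, ...] = ()

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.low)
        object.__setattr__(self, "bands", tuple(ordered))
        edge = 0.0
        for band in self.bands:
            if band.low != edge:
                raise ValueError("bands must partition (0, 1) without gaps/overlap")
            if not 0 <= band.low < band.high <= 1:
                raise ValueError(f"invalid band [{band.low}, {band.high})")
            edge = band.high
        if self.bands and edge != 1.0:
            raise ValueError("bands must cover up to prevalence 1")

    def band_for(self, prevalence: float) -> BandEntry:
        for band in self.bands:
            if band.contains(prevalence):
                return band
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")


#: Band edges 2.5% and 7.5%; only text-anchored cutoffs are shipped.
DEFAULT_TABLE = RecommendationTable(
    bands=(
        BandEntry(0.0, 0.025, time_based_cutoff=0.40, breakout_cutoff=0.15),
        BandEntry(0.025, 0.075, time_based_cutoff=0.35, data_driven_cutoff=0.05),
        BandEntry(0.075, 1.0),  # unconfigured: lookup fails closed
    )
)


@dataclass(frozen=True)
class Recommendation:
    """Projected stopping configuration and workload saving."""

    estimated_prevalence: float | None
    band: BandEntry | None
    saving_fraction: float
    abstracts_saved: int
    hours_saved: float
    seconds_per_abstract: float = 30.0
    expected_relevant_count: float | None = None

    @property
    def hours_saved_rounded(self) -> int:
        return round(self.hours_saved)


def estimate_prevalence(n_relevant_found: int, n_random_screened: int) -> float:
    """Relevant records found divided by records randomly screened.

    Multiplying the quotient by the total number of retrieved records gives an
    expected relevant *count*, not a prevalence; see
    :func:`expected_relevant_count`.
    """
    if n_random_screened < 1:
        raise ValueError("no records screened: prevalence undefined")
    if n_relevant_found < 0 or n_relevant_found > n_random_screened:
        raise ValueError("relevant-found count out of range")
    if n_relevant_found == 0:
        warnings.warn(
            "no relevant record found yet: the random prescreening phase is "
            "not complete and the prevalence estimate is 0",
            stacklevel=2,
        )
    return n_relevant_found / n_random_screened


def expected_relevant_count(prevalence: float, n_total: int) -> float:
    """Projected number of relevant records in the full retrieval."""
    return prevalence * n_total


def lookup_cutoffs(
    prevalence: float, table: RecommendationTable = DEFAULT_TABLE
) -> BandEntry:
    """Cutoffs of the band containing ``prevalence``; fail-closed.

    Raises when the band carries no configured cutoffs: values for such bands
    must be supplied by the user rather than invented.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    band = table.band_for(prevalence)
    if not band.configured:
        raise ValueError(
            f"no cutoffs configured for the prevalence band "
            f"[{band.low:.3f}, {band.high:.3f}); supply values via a custom "
            "RecommendationTable"
        )
    return band


def compute_workload_saving(
    n_total: int,
    random_fraction: float,
    time_based_cutoff: float,
    data_driven_cutoff: float = 0.0,
    seconds_per_abstract: float = 30.0,
    estimated_prevalence: float | None = None,
    band: BandEntry | None = None,
) -> Recommendation:
    """Project the workload saved by stopping per the recommended rules.

    The screened share is the random-phase fraction plus the time-based
    cutoff plus the data-driven allowance; saving is its complement.  Hours
    assume ``seconds_per_abstract`` (default 30 s) per screened record.
    """
    screened = random_fraction + time_based_cutoff + data_driven_cutoff
    if screened > 1.0 + 1e-12:
        raise ValueError(f"screened fractions sum to {screened:.3f} > 1")
    if min(random_fraction, time_based_cutoff, data_driven_cutoff) < 0:
        raise ValueError("fractions must be nonnegative")
    saving = 1.0 - screened
    abstracts_saved = round(saving * n_total)
    hours_saved = abstracts_saved * seconds_per_abstract / 3600.0
    return Recommendation(
        estimated_prevalence=estimated_prevalence,
        band=band,
        saving_fraction=saving,
        abstracts_saved=abstracts_saved,
        hours_saved=hours_saved,
        seconds_per_abstract=seconds_per_abstract,
        expected_relevant_count=(
            expected_relevant_count(estimated_prevalence, n_total)
            if estimated_prevalence is not None
            else None
        ),
    )


def recommend(
    n_total: int,
    n_random_screened: int,
    n_relevant_found: int,
    table: RecommendationTable = DEFAULT_TABLE,
    random_fraction: float = 0.01,
    seconds_per_abstract: float = 30.0,
) -> Recommendation:
    """End-to-end recommendation from the random prescreening outcome."""
    prevalence = estimate_prevalence(n_relevant_found, n_random_screened)
    band = lookup_cutoffs(prevalence, table)
    return compute_workload_saving(
        n_total=n_total,
        random_fraction=random_fraction,
        time_based_cutoff=band.time_based_cutoff or 0.0,
        data_driven_cutoff=band.data_driven_cutoff or 0.0,
        seconds_per_abstract=seconds_per_abstract,
        estimated_prevalence=prevalence,
        band=band,
    )
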