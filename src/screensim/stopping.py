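"""Stopping criteria evaluated post hoc on screening traces.

Because every simulation runs to exhaustion, a stopping rule is a pure
function of the trace: it returns the first (1-based) position at which its
condition *has been met*, or ``None`` if it never triggers.  "Met" is
permanent — once a qualifying consecutive-irrelevant run has completed, the
data-driven criterion stays satisfied at every later position, which is the
checklist semantics combined rules (such as the SAFE active-learning phase)
require.

Rules:

* ``DataDrivenRule`` — a run of ``cutoff`` consecutive irrelevant labels
  (commonly 50 in a row); fractional cutoffs are converted per trace as
  ceil(fraction * N_s).
* ``TimeBasedRule`` — a fixed fraction of the screening set, ceil(f * N_s).
* ``KeyStudyRule`` — all pre-identified key studies surfaced.
* ``CombinedRule`` — every member satisfied (position = max over members).
* ``BreakoutRule`` — a high-cutoff consecutive-irrelevant run that may end
  screening before a fallback (usually time-based) rule would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .metrics import confusion_at, screening_cost_at_sensitivity, sensitivity
from .simulate import ScreeningTrace


@dataclass(frozen=True)
class StopOutcome:
    """Where a rule stopped a trace and what that stop cost/achieved."""

    stop_position: int | None
    sensitivity_at_stop: float | None
    sc_at_stop: float | None
    triggered_by: tuple[str, ...] = ()
    diagnostics: str = ""

    @property
    def stopped(self) -> bool:
        return self.stop_position is not None


def _fraction_to_count(cutoff: float | int, n_s: int) -> int:
    """Fractional cutoffs become counts via ceil(fraction * N_s)."""
    if isinstance(cutoff, int) or (isinstance(cutoff, float) and cutoff >= 1):
        count = int(cutoff)
    else:
        count = math.ceil(Fraction(cutoff).limit_denominator(10**6) * n_s)
    if count < 1:
        raise ValueError(f"cutoff {cutoff!r} resolves to a count below 1")
    return count


def _first_run_end(labels: np.ndarray, run_length: int) -> int | None:
    """1-based position ending the first run of ``run_length`` irrelevant labels."""
    run = 0
    for i, lab in enumerate(labels):
        run = run + 1 if lab == 0 else 0
        if run >= run_length:
            return i + 1
    return None


class StoppingRule:
    rule_id: str = "base"

    def first_met(self, trace: ScreeningTrace) -> int | None:
        raise NotImplementedError

    def outcome(self, trace: ScreeningTrace) -> StopOutcome:
        pos = self.first_met(trace)
        if pos is None:
            return StopOutcome(
                None, None, None, (),
                diagnostics=f"{self.rule_id}: condition never satisfied on trace",
            )
        counts = confusion_at(trace, pos)
        return StopOutcome(
            stop_position=pos,
            sensitivity_at_stop=sensitivity(counts),
            sc_at_stop=pos / trace.n_screened_total,
            triggered_by=(self.rule_id,),
        )


@dataclass(frozen=True)
class DataDrivenRule(StoppingRule):
    """Stop after ``cutoff`` consecutive irrelevant labels."""

    cutoff: float | int = 50
    rule_id: str = "data_driven"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def first_met(self, trace: ScreeningTrace) -> int | None:
        count = _fraction_to_count(self.cutoff, trace.n_screened_total)
        return _first_run_end(trace.labels, count)


@dataclass(frozen=True)
class TimeBasedRule(StoppingRule):
    """Stop once a fixed fraction of the screening set has been screened."""

    fraction: float = 0.10
    rule_id: str = "time_based"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")

    def first_met(self, trace: ScreeningTrace) -> int:
        return math.ceil(
            Fraction(self.fraction).limit_denominator(10**6)
            * trace.n_screened_total
        )


@dataclass(frozen=True)
class KeyStudyRule(StoppingRule):
    """Stop only after every key study has surfaced in the trace."""

    key_ids: frozenset[str] = frozenset()
    rule_id: str = "key_study"

    def __post_init__(self) -> None:
        object.__setattr__(self, "key_ids", frozenset(self.key_ids))
        if not self.key_ids:
            raise ValueError("key_ids must be nonempty")

    def first_met(self, trace: ScreeningTrace) -> int:
        positions = {rid: i + 1 for i, rid in enumerate(trace.ordered_ids)}
        missing = self.key_ids - positions.keys()
        if missing:
            raise ValueError(f"key ids absent from trace: {sorted(missing)}")
        return max(positions[k] for k in self.key_ids)


@dataclass(frozen=True)
class MinimumFindsRule(StoppingRule):
    """Stop only once TP reaches a floor — e.g. twice the relevant records
    found during the random prescreening phase (the SAFE doubling criterion)."""

    min_tp: int = 1
    rule_id: str = "minimum_finds"

    def __post_init__(self) -> None:
        if self.min_tp < 1:
            raise ValueError("min_tp must be >= 1")

    def first_met(self, trace: ScreeningTrace) -> int | None:
        cum = np.cumsum(trace.labels)
        hits = np.nonzero(cum >= self.min_tp)[0]
        return int(hits[0]) + 1 if hits.size else None


@dataclass(frozen=True)
class CombinedRule(StoppingRule):
    """All member criteria must have been met (the SAFE phase-A semantics)."""

    members: tuple[StoppingRule, ...] = ()
    rule_id: str = "combined"

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ValueError("combined rule needs >= 2 members")

    def first_met(self, trace: ScreeningTrace) -> int | None:
        positions = [m.first_met(trace) for m in self.members]
        if any(p is None for p in positions):
            return None
        return max(positions)  # type: ignore[type-var]

    def outcome(self, trace: ScreeningTrace) -> StopOutcome:
        positions = {m.rule_id: m.first_met(trace) for m in self.members}
        unmet = [rid for rid, p in positions.items() if p is None]
        if unmet:
            return StopOutcome(
                None, None, None, (),
                diagnostics=f"members never satisfied: {', '.join(unmet)}",
            )
        pos = max(positions.values())  # type: ignore[arg-type]
        counts = confusion_at(trace, pos)
        return StopOutcome(
            stop_position=pos,
            sensitivity_at_stop=sensitivity(counts),
            sc_at_stop=pos / trace.n_screened_total,
            triggered_by=tuple(sorted(positions)),
        )


@dataclass(frozen=True)
class BreakoutRule(StoppingRule):
    """High-cutoff consecutive-irrelevant rule racing a fallback rule.

    Stops at whichever comes first: a consecutive-irrelevant run of
    ceil(breakout_fraction * N_s), or the fallback rule's stop position.  When
    the ranking performs well, the breakout ends screening long before a
    conservative time-based fallback would.
    """

    breakout_fraction: float = 0.15
    fallback: StoppingRule = field(default_factory=lambda: TimeBasedRule(0.40))
    rule_id: str = "breakout"

    def __post_init__(self) -> None:
        if not 0.0 < self.breakout_fraction < 1.0:
            raise ValueError("breakout_fraction must be in (0, 1)")

    def first_met(self, trace: ScreeningTrace) -> int | None:
        run_len = math.ceil(
            Fraction(self.breakout_fraction).limit_denominator(10**6)
            * trace.n_screened_total
        )
        run_pos = _first_run_end(trace.labels, run_len)
        fallback_pos = self.fallback.first_met(trace)
        candidates = [p for p in (run_pos, fallback_pos) if p is not None]
        return min(candidates) if candidates else None


def safe_phase1_check(
    n_total: int,
    n_random_screened: int,
    n_relevant_found: int,
    minimum_screened: int = 100,
) -> bool:
    """Has the random prescreening phase screened enough?

    True once at least max(1% of the collection, ``minimum_screened``) records
    have been screened at random and at least one relevant record was found.
    """
    if n_random_screened > n_total:
        raise ValueError("cannot screen more records than the collection holds")
    threshold = max(math.ceil(0.01 * n_total), minimum_screened)
    return n_random_screened >= threshold and n_relevant_found >= 1


def evaluate_rules(
    trace: ScreeningTrace, rules: Iterable[StoppingRule]
) -> "list[tuple[str, StopOutcome]]":
    """Evaluate several rules on one trace; rows joinable to metric tables."""
    return [(rule.rule_id, rule.outcome(trace)) for rule in rules]


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def rules_from_config(config: Sequence[dict]) -> list[StoppingRule]:
    """Build rules from a list of dicts (e.g. parsed from YAML).

    Each entry needs a ``rule`` key: data_driven, time_based, key_study,
    minimum_finds, combined (with ``members``), or breakout (with optional
    ``fallback``).
    """
    out: list[StoppingRule] = []
    for entry in config:
        kind = entry.get("rule")
        if kind == "data_driven":
            out.append(DataDrivenRule(cutoff=entry["cutoff"]))
        elif kind == "time_based":
            out.append(TimeBasedRule(fraction=entry["fraction"]))
        elif kind == "key_study":
            out.append(KeyStudyRule(key_ids=frozenset(entry["key_ids"])))
        elif kind == "minimum_finds":
            out.append(MinimumFindsRule(min_tp=entry["min_tp"]))
        elif kind == "combined":
            out.append(CombinedRule(members=tuple(rules_from_config(entry["members"]))))
        elif kind == "breakout":
            fallback = (
                rules_from_config([entry["fallback"]])[0]
                if "fallback" in entry
                else TimeBasedRule(0.40)
            )
            out.append(
                BreakoutRule(
                    breakout_fraction=entry["breakout_fraction"], fallback=fallback
                )
            )
        else:
            raise ValueError(f"unknown stopping rule {kind!r}")
    return out
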