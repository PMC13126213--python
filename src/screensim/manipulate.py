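"""Dataset manipulation: prevalence-ratio subsetting, fixed-relevant-count
sampling, and training-set selection.

Two manipulation designs are implemented.  *Ratio sampling* (Study-1 style)
subsets an existing collection to an exact target prevalence by discarding
records from whichever class is over-represented.  *Fixed-relevant sampling*
(Study-2 style) draws exactly ``n_rel`` relevant records and the number of
irrelevant records that makes the prevalence come out exactly, so the number
of relevant records is constant across prevalence conditions.

Prevalence arithmetic is exact: target fractions are converted to reduced
rationals and subset sizes solved in integers, never compared in floating
point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._seeds import derive_seed
from .records import Collection, Record


def _as_fraction(p: float | str | Fraction) -> Fraction:
    """Exact rational form of a prevalence given as float, str, or Fraction."""
    if isinstance(p, Fraction):
        frac = p
    elif isinstance(p, str):
        frac = Fraction(p)
    else:
        # floats like 0.025 are decimal in intent; snap to the nearest simple
        # rational rather than the exact binary expansion
        frac = Fraction(p).limit_denominator(10**6)
    if not 0 < frac < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {p!r}")
    return frac


@dataclass(frozen=True)
class TrainingSetSpec:
    """Composition of the initial training set for a simulation run."""

    n_rel_train: int = 1
    n_irrel_train: int = 1
    disjoint_from_screening: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rel_train < 1 or self.n_irrel_train < 1:
            raise ValueError("training set needs >= 1 record of each class")


def manipulate_prevalence_ratio(
    collection: Collection, p: float | str | Fraction, seed: int
) -> Collection:
    """Largest random subset of ``collection`` with prevalence exactly ``p``.

    With ``p = a/b`` reduced, any exact-prevalence subset has ``k*a`` relevant
    and ``k*(b-a)`` irrelevant records; the largest feasible
    ``k = min(R // a, I // (b - a))`` is used.  When the original prevalence is
    below ``p`` this keeps all relevant records and discards irrelevant ones;
    above ``p`` it keeps (nearly) all irrelevant records and discards relevant
    ones — the two directions of the ratio manipulation.  Sampling is uniform
    without replacement and seeded.
    """
    frac = _as_fraction(p)
    a, b = frac.numerator, frac.denominator
    rel = collection.relevant()
    irr = collection.irrelevant()
    if not rel or not irr:
        raise ValueError("collection must contain both classes")
    k = min(len(rel) // a, len(irr) // (b - a))
    if k < 1:
        raise ValueError(
            f"no subset of {collection.name or 'collection'} "
            f"(R={len(rel)}, I={len(irr)}) achieves prevalence {frac} exactly"
        )
    n_rel, n_irr = k * a, k * (b - a)
    rng = np.random.default_rng(derive_seed(seed, "ratio", str(frac)))
    keep_rel = rng.choice(len(rel), size=n_rel, replace=False)
    keep_irr = rng.choice(len(irr), size=n_irr, replace=False)
    kept_ids = {rel[i].id for i in keep_rel} | {irr[i].id for i in keep_irr}
    return collection.subset(
        kept_ids, name=f"{collection.name}-p{float(frac):g}"
    )


def sample_fixed_relevant(
    collection: Collection, n_rel: int, p: float | str | Fraction, seed: int
) -> Collection:
    """Sample exactly ``n_rel`` relevant plus ``n_rel*(1-p)/p`` irrelevant records.

    Total size is ``n_rel / p`` (e.g. 20 relevant at 1% -> 2,000 records).
    Raises if either class is too shallow or if ``n_rel / p`` is not integral.
    """
    frac = _as_fraction(p)
    n_irr_frac = n_rel * (1 - frac) / frac
    if n_irr_frac.denominator != 1:
        raise ValueError(
            f"n_rel={n_rel} at prevalence {frac} gives a non-integer "
            f"irrelevant count {n_irr_frac}"
        )
    n_irr = int(n_irr_frac)
    rel = collection.relevant()
    irr = collection.irrelevant()
    if len(rel) < n_rel:
        raise ValueError(f"need {n_rel} relevant records, pool has {len(rel)}")
    if len(irr) < n_irr:
        raise ValueError(f"need {n_irr} irrelevant records, pool has {len(irr)}")
    rng = np.random.default_rng(derive_seed(seed, "fixed", n_rel, str(frac)))
    keep_rel = rng.choice(len(rel), size=n_rel, replace=False)
    keep_irr = rng.choice(len(irr), size=n_irr, replace=False)
    kept_ids = {rel[i].id for i in keep_rel} | {irr[i].id for i in keep_irr}
    return collection.subset(
        kept_ids, name=f"{collection.name}-nrel{n_rel}-p{float(frac):g}"
    )


def sample_training_set(
    pool: Collection,
    spec: TrainingSetSpec,
    screening: Collection | None = None,
) -> tuple[list[Record], Collection]:
    """Draw an initial training set and return it with the screening set.

    Two accounting modes:

    * ``disjoint_from_screening=False`` (Study-1 style): training records are
      members of the collection itself; the screening set is the full pool and
      the trace will carry the training records at its first positions.
    * ``disjoint_from_screening=True`` (Study-2 style): training is drawn from
      the pool *outside* the screening set, so screening-set composition is
      identical across training-set conditions.  Pass the pre-sampled
      ``screening`` collection; training is drawn from ``pool`` minus its ids.

    Sampling is uniform without replacement, seeded from ``spec.seed``.
    """
    if spec.disjoint_from_screening:
        if screening is None:
            raise ValueError(
                "disjoint training requires the screening set to be supplied"
            )
        reserve = pool.without(screening.ids())
    else:
        if screening is not None and screening is not pool:
            raise ValueError(
                "non-disjoint training draws from the screening pool itself"
            )
        screening = pool
        reserve = pool

    rel = reserve.relevant()
    irr = reserve.irrelevant()
    if len(rel) < spec.n_rel_train:
        raise ValueError(
            f"pool has {len(rel)} relevant records, "
            f"training needs {spec.n_rel_train}"
        )
    if len(irr) < spec.n_irrel_train:
        raise ValueError(
            f"pool has {len(irr)} irrelevant records, "
            f"training needs {spec.n_irrel_train}"
        )
    rng = np.random.default_rng(
        derive_seed(spec.seed, "train", spec.n_rel_train, spec.n_irrel_train)
    )
    pick_rel = rng.choice(len(rel), size=spec.n_rel_train, replace=False)
    pick_irr = rng.choice(len(irr), size=spec.n_irrel_train, replace=False)
    training = [rel[i] for i in pick_rel] + [irr[i] for i in pick_irr]
    return training, screening
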