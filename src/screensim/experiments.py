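"""Factorial experiment orchestration and aggregation.

A design crosses collections x conditions x replications x algorithms.  Two
study layouts are supported:

* ``study1`` — prevalence-ratio manipulation of whole collections, one
  relevant + one irrelevant training record drawn from inside the collection,
  each artificial collection screened by every algorithm.
* ``study2`` — fixed-relevant-count sampling (constant number of relevant
  records across prevalence conditions), training sets of 1/2/5 relevant + 10
  irrelevant records drawn disjointly from the screening set.

``enumerate_runs`` produces the full manifest with deterministic per-run
sub-seeds; ``execute`` runs (a thinned share of) the manifest end to end and
returns a tidy table, one metric per row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .engine import ALConfig
from .manipulate import (
    TrainingSetSpec,
    manipulate_prevalence_ratio,
    sample_fixed_relevant,
    sample_training_set,
)
from .metrics import (
    fpr_at_sensitivity,
    rrf_at,
    screening_cost_at_sensitivity,
    wss_at_sensitivity,
)
from .records import Collection
from .simulate import run_random_order, run_simulation


@dataclass
class ExperimentDesign:
    """Grid definition for one study."""

    study_id: str
    n_collections: int
    prevalence_grid: list[float]
    algorithms: list[ALConfig]
    n_replications: int = 1000
    n_rel_grid: list[int] = field(default_factory=list)          # study2 only
    training_grid: list[TrainingSetSpec] = field(default_factory=list)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.study_id not in ("study1", "study2"):
            raise ValueError(f"unknown study {self.study_id!r}")
        if not self.prevalence_grid or not self.algorithms:
            raise ValueError("prevalence grid and algorithms must be nonempty")
        if self.n_collections < 1 or self.n_replications < 1:
            raise ValueError("counts must be >= 1")
        if self.study_id == "study2" and not self.n_rel_grid:
            raise ValueError("study2 requires an n_rel grid")
        if not self.training_grid:
            default = (
                TrainingSetSpec(1, 1, disjoint_from_screening=False)
                if self.study_id == "study1"
                else TrainingSetSpec(1, 10, disjoint_from_screening=True)
            )
            self.training_grid = [default]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        algorithms = [ALConfig(**a) for a in raw.pop("algorithms")]
        training = [TrainingSetSpec(**t) for t in raw.pop("training_grid", [])]
        return cls(algorithms=algorithms, training_grid=training, **raw)

    # -- design arithmetic ---------------------------------------------
    @property
    def n_artificial_collections(self) -> int:
        """Artificial collections: collections x conditions x replications."""
        n = self.n_collections * len(self.prevalence_grid) * self.n_replications
        if self.study_id == "study2":
            n *= len(self.n_rel_grid)
        return n

    @property
    def n_runs(self) -> int:
        """Simulation runs: artificial collections x algorithms (x training)."""
        n = self.n_artificial_collections * len(self.algorithms)
        n *= len(self.training_grid)
        return n


def enumerate_runs(design: ExperimentDesign) -> pd.DataFrame:
    """Full cross-product run manifest with per-run sub-seeds.

    Row count equals ``design.n_runs`` exactly.  The sub-seed of a run depends
    only on (master seed, collection, condition, replication, training,
    algorithm), never on enumeration order.
    """
    n_rel_levels = design.n_rel_grid if design.study_id == "study2" else [None]
    rows = []
    for ci in range(design.n_collections):
        for p in design.prevalence_grid:
            for n_rel in n_rel_levels:
                for rep in range(design.n_replications):
                    for t_idx, tspec in enumerate(design.training_grid):
                        for a_idx, algo in enumerate(design.algorithms):
                            rows.append(
                                (
                                    ci, p, n_rel, rep, t_idx, a_idx,
                                    derive_seed(
                                        design.master_seed,
                                        ci, p, n_rel, rep,
                                        tspec.n_rel_train, algo.name,
                                    ),
                                )
                            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "collection", "prevalence", "n_rel", "replication",
            "training_idx", "algorithm_idx", "seed",
        ],
    )
    manifest.insert(0, "run_id", np.arange(len(manifest)))
    return manifest


def _thin(manifest: pd.DataFrame, design: ExperimentDesign,
          scale_factor: float) -> pd.DataFrame:
    """Keep the first ceil(scale * n_replications) replications per cell."""
    if not 0.0 < scale_factor <= 1.0:
        raise ValueError("scale_factor must be in (0, 1]")
    keep = math.ceil(scale_factor * design.n_replications)
    return manifest[manifest["replication"] < keep]


def _run_one(
    design: ExperimentDesign,
    collections: list[Collection],
    row,
    include_random_baseline: bool,
) -> list[dict]:
    source = collections[int(row.collection)]
    seed = int(row.seed)
    tspec_base = design.training_grid[int(row.training_idx)]
    algo = design.algorithms[int(row.algorithm_idx)]
    algo = ALConfig(
        classifier_id=algo.classifier_id,
        extractor_id=algo.extractor_id,
        query_strategy=algo.query_strategy,
        balance_strategy=algo.balance_strategy,
        retrain_interval=algo.retrain_interval,
        seed=seed,
    )
    tspec = TrainingSetSpec(
        n_rel_train=tspec_base.n_rel_train,
        n_irrel_train=tspec_base.n_irrel_train,
        disjoint_from_screening=tspec_base.disjoint_from_screening,
        seed=seed,
    )
    if design.study_id == "study1":
        artificial = manipulate_prevalence_ratio(source, row.prevalence, seed)
        training, screening = sample_training_set(artificial, tspec)
    else:
        screening = sample_fixed_relevant(
            source, int(row.n_rel), row.prevalence, seed
        )
        training, screening = sample_training_set(source, tspec, screening=screening)

    out = []

    def metric_rows(trace, algorithm_name):
        for m in (
            screening_cost_at_sensitivity(trace),
            fpr_at_sensitivity(trace),
            wss_at_sensitivity(trace),
            rrf_at(trace, 0.10),
        ):
            out.append(
                {
                    "run_id": int(row.run_id),
                    "collection": int(row.collection),
                    "prevalence": row.prevalence,
                    "n_rel": row.n_rel,
                    "replication": int(row.replication),
                    "n_rel_train": tspec.n_rel_train,
                    "algorithm": algorithm_name,
                    "metric_id": m.metric_id,
                    "level": m.level,
                    "value": m.value,
                    "error": "",
                }
            )

    trace = run_simulation(screening, training, algo)
    metric_rows(trace, algo.name)
    if include_random_baseline:
        metric_rows(run_random_order(screening, seed), "random")
    return out


def execute(
    design: ExperimentDesign,
    collections: list[Collection],
    scale_factor: float = 1.0,
    include_random_baseline: bool = False,
) -> pd.DataFrame:
    """Run (a thinned share of) the design; tidy results, one metric per row.

    Individual run failures are recorded as rows with a nonempty ``error``
    column rather than aborting the sweep.
    """
    if len(collections) < design.n_collections:
        raise ValueError(
            f"design expects {design.n_collections} collections, "
            f"got {len(collections)}"
        )
    manifest = _thin(enumerate_runs(design), design, scale_factor)
    rows: list[dict] = []
    for row in manifest.itertuples(index=False):
        try:
            rows.extend(_run_one(design, collections, row, include_random_baseline))
        except Exception as exc:  # noqa: BLE001 - per-run isolation
            rows.append(
                {
                    "run_id": int(row.run_id),
                    "collection": int(row.collection),
                    "prevalence": row.prevalence,
                    "n_rel": row.n_rel,
                    "replication": int(row.replication),
                    "n_rel_train": design.training_grid[int(row.training_idx)].n_rel_train,
                    "algorithm": design.algorithms[int(row.algorithm_idx)].name,
                    "metric_id": "",
                    "level": np.nan,
                    "value": np.nan,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PerformanceSummary:
    """Replication-level aggregation of one metric."""

    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    q90: float
    n_runs: int


def summarize(values) -> PerformanceSummary:
    """Summary statistics with linear-interpolation quantiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of values")
    q25, med, q75, q90 = np.quantile(arr, [0.25, 0.5, 0.75, 0.90], method="linear")
    return PerformanceSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        q90=float(q90),
        n_runs=int(arr.size),
    )


def plot_summary(summaries: dict[str, PerformanceSummary], ax=None):
    """Bar + IQR whiskers + 90th-percentile point, one bar per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(summaries)
    medians = [summaries[n].median for n in names]
    lo = [summaries[n].median - summaries[n].q25 for n in names]
    hi = [summaries[n].q75 - summaries[n].median for n in names]
    x = np.arange(len(names))
    ax.bar(x, medians, yerr=[lo, hi], capsize=4)
    ax.plot(x, [summaries[n].q90 for n in names], "o", color="black")
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("metric value")
    return ax
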