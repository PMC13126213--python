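"""The active-learning screening simulation.

Simulation mode replays a recorded screening: a model is fitted on the labeled
records, the unlabeled records are ranked by predicted relevance, the
top-ranked record's stored label is revealed, and the cycle repeats.  The run
always continues until the screening set is exhausted, producing a complete
:class:`ScreeningTrace`; stopping rules are evaluated afterwards on the trace,
so every rule is compared on identical orderings.

Two accounting modes mirror the two manipulation designs: when the initial
training records are members of the screening collection they occupy the first
trace positions and count as screened (Study-1 style); when the training set
is drawn outside the screening set the trace covers the screening records only
(Study-2 style).

Between refits (``retrain_interval`` > 1) the simulator walks down the current
ranking without re-ranking mid-batch; labeled records leave the candidate pool
immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .engine import ALConfig, FeatureMatrix, balance_training, extract_features, fit_model, rank_candidates
from .records import Collection, Record


@dataclass
class ScreeningTrace:
    """The ordered outcome of one simulated screening run.

    ``ordered_ids``/``labels`` give, position by position (1-based in all
    reporting), which record was screened and its oracle label.
    ``includes_training_in_positions`` records the accounting mode.
    """

    ordered_ids: list[str]
    labels: np.ndarray  # int array aligned to ordered_ids
    training_ids: list[str] = field(default_factory=list)
    config: ALConfig | None = None
    seed: int = 0
    includes_training_in_positions: bool = False
    key_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ordered_ids) != len(self.labels):
            raise ValueError("ids and labels length mismatch")
        if len(set(self.ordered_ids)) != len(self.ordered_ids):
            raise ValueError("trace contains duplicate record ids")

    @property
    def n_screened_total(self) -> int:
        """N_s — size of the screening set under this trace's accounting."""
        return len(self.ordered_ids)

    @property
    def n_relevant(self) -> int:
        """R — relevant records in the screening set."""
        return int(self.labels.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.labels) + 1),
                "record_id": self.ordered_ids,
                "label": self.labels,
                "cumulative_tp": np.cumsum(self.labels),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _oracle_scores(records: list[Record]) -> np.ndarray:
    # analytic perfect-ranking stub: score = oracle label
    return np.array([float(r.label) for r in records])


def run_simulation(
    screening: Collection,
    training: list[Record],
    config: ALConfig,
) -> ScreeningTrace:
    """Simulate active-learning screening of ``screening`` to exhaustion.

    ``training`` must contain both classes.  If every training record belongs
    to the screening collection, the run uses Study-1 accounting (training
    records pre-screened at positions 1..t); if none does, Study-2 accounting
    (training external, trace covers screening records only).  Deterministic
    given ``config.seed``.

    ``classifier_id='oracle'`` scores candidates by their stored label — the
    analytic perfect-ranking stub used for closed-form checks.
    """
    if not any(r.label == 1 for r in training) or not any(
        r.label == 0 for r in training
    ):
        raise ValueError("training set must contain both classes")
    screening_ids = set(screening.ids())
    overlap = {r.id for r in training} & screening_ids
    if overlap and len(overlap) != len(training):
        raise ValueError(
            "training set straddles the screening collection: "
            "must be fully inside (Study-1) or fully outside (Study-2)"
        )
    internal_training = bool(overlap)

    candidates: list[Record] = (
        [r for r in screening if r.id not in overlap]
        if internal_training
        else list(screening.records)
    )

    use_oracle = config.classifier_id == "oracle"
    features: FeatureMatrix | None = None
    if not use_oracle:
        extra = () if internal_training else tuple(training)
        features = extract_features(screening, config.extractor_id, extra_records=extra)

    labeled: list[tuple[Record, int]] = [(r, r.label) for r in training]
    revealed_ids: list[str] = []
    revealed_labels: list[int] = []
    n_fits = 0

    while candidates:
        if use_oracle:
            scores = _oracle_scores(candidates)
            order = np.argsort(-scores, kind="stable")
            ranked = [candidates[i].id for i in order]
        else:
            balanced = balance_training(
                labeled,
                strategy=config.balance_strategy,
                seed=derive_seed(config.seed, "balance", n_fits),
            )
            model = fit_model(
                features,
                balanced,
                config.classifier_id,
                seed=derive_seed(config.seed, "fit", n_fits),
            )
            ranked = rank_candidates(model, features, [r.id for r in candidates])
        n_fits += 1

        by_id = {r.id: r for r in candidates}
        batch = ranked[: config.retrain_interval]
        for rid in batch:
            rec = by_id[rid]
            revealed_ids.append(rid)
            revealed_labels.append(rec.label)
        batch_set = set(batch)
        candidates = [r for r in candidates if r.id not in batch_set]

    if internal_training:
        ordered_ids = [r.id for r in training] + revealed_ids
        labels = [r.label for r in training] + revealed_labels
    else:
        ordered_ids = revealed_ids
        labels = revealed_labels

    return ScreeningTrace(
        ordered_ids=ordered_ids,
        labels=np.array(labels, dtype=int),
        training_ids=[r.id for r in training],
        config=config,
        seed=config.seed,
        includes_training_in_positions=internal_training,
        key_ids=frozenset(r.id for r in screening if r.is_key_study),
    )


def run_random_order(screening: Collection, seed: int) -> ScreeningTrace:
    """Uniformly random screening order — the no-model baseline."""
    if screening.N == 0:
        raise ValueError("screening set is empty")
    rng = np.random.default_rng(derive_seed(seed, "random-order"))
    order = rng.permutation(screening.N)
    records = [screening[i] for i in order]
    return ScreeningTrace(
        ordered_ids=[r.id for r in records],
        labels=np.array([r.label for r in records], dtype=int),
        training_ids=[],
        config=None,
        seed=seed,
        includes_training_in_positions=False,
        key_ids=frozenset(r.id for r in screening if r.is_key_study),
    )


def expected_fit_count(n_candidates: int, retrain_interval: int) -> int:
    """Number of model fits a full run performs: ceil(candidates / interval)."""
    return math.ceil(n_candidates / retrain_interval)
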