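"""Synthetic labeled abstract collections with controllable difficulty.

The generator emulates the two facts about screening corpora that drive every
downstream result: the class imbalance (prevalence of relevant records is
typically 0.5-10%) and the lexical separability between the relevant and
irrelevant class.  Documents are bags of synthetic tokens drawn from two
multinomials over a shared vocabulary:

* irrelevant documents draw every token from a *background* distribution;
* relevant documents draw each token from a mixture
  ``signal_strength * signal-block distribution
  + (1 - signal_strength) * background``,
  where the signal block is a vocabulary slice the background never uses.

``signal_strength = 0`` makes the class-conditional distributions identical
(no classifier can beat chance); ``signal_strength = 1`` with
``noise_rate = 0`` makes the classes lexically disjoint and the task
near-separable for TF-IDF + linear models.  A ``noise_rate`` fraction of
relevant documents is generated from the background instead, emulating
relevant records unlike anything in the training set — the ones real screeners
find late.

Document lengths are Poisson around ``doc_length_mean`` (floored at 4 tokens
so every record has a title and a non-empty abstract).  All randomness flows
from one integer seed through counter-style sub-seed derivation, so suites
reproduce exactly regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._seeds import derive_seed
from .records import Collection, Record

_SIGNAL_FRACTION = 0.1  # share of the vocabulary reserved for the signal block


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of one synthetic collection.

    Defaults describe a mid-sized screening corpus: 1,000 records at 5%
    prevalence, a moderately separable task (signal_strength 0.7), and 10% of
    relevant records that look like background noise.
    """

    n_total: int = 1000
    prevalence: float = 0.05
    vocab_size: int = 500
    signal_strength: float = 0.7
    doc_length_mean: float = 40.0
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if int(round(self.n_total * self.prevalence)) < 1:
            raise ValueError("n_total * prevalence rounds below one relevant record")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.vocab_size < 20:
            raise ValueError("vocab_size must be >= 20")

    @property
    def n_relevant(self) -> int:
        return int(round(self.n_total * self.prevalence))


def _token_distributions(
    spec: SyntheticCorpusSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Background and relevant-class token distributions over the vocabulary."""
    n_signal = max(10, int(spec.vocab_size * _SIGNAL_FRACTION))
    n_background = spec.vocab_size - n_signal
    # Zipf-ish weights make the background look like natural token frequencies.
    background = np.zeros(spec.vocab_size)
    background[:n_background] = 1.0 / np.arange(1, n_background + 1)
    background /= background.sum()
    signal = np.zeros(spec.vocab_size)
    signal[n_background:] = rng.dirichlet(np.ones(n_signal))
    relevant = spec.signal_strength * signal + (1 - spec.signal_strength) * background
    return background, relevant


def _make_doc(
    rid: str,
    label: int,
    dist: np.ndarray,
    spec: SyntheticCorpusSpec,
    rng: np.random.Generator,
) -> Record:
    length = max(4, int(rng.poisson(spec.doc_length_mean)))
    token_ids = rng.choice(len(dist), size=length, p=dist)
    words = [f"w{t:05d}" for t in token_ids]
    return Record(
        id=rid,
        title=" ".join(words[:4]),
        abstract=" ".join(words[4:]),
        label=label,
    )


def generate_corpus(spec: SyntheticCorpusSpec) -> Collection:
    """Generate one labeled collection from ``spec``.

    The emitted collection has exactly ``round(n_total * prevalence)`` relevant
    records; record order is a seeded shuffle so labels carry no positional
    information.  Byte-identical for identical specs.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "corpus"))
    background, relevant_dist = _token_distributions(spec, rng)
    n_rel = spec.n_relevant
    n_noisy = int(round(n_rel * spec.noise_rate))

    records: list[Record] = []
    for i in range(n_rel):
        dist = background if i < n_noisy else relevant_dist
        records.append(_make_doc(f"rel{i:05d}", 1, dist, spec, rng))
    for i in range(spec.n_total - n_rel):
        records.append(_make_doc(f"irr{i:05d}", 0, background, spec, rng))

    order = rng.permutation(len(records))
    return Collection(
        [records[i] for i in order],
        name=f"synthetic-n{spec.n_total}-p{spec.prevalence:g}-s{spec.seed}",
    )


def generate_suite(
    n_collections: int,
    base_spec: SyntheticCorpusSpec,
    heterogeneity: float = 0.0,
    seed: int = 0,
) -> list[Collection]:
    """Generate a suite of collections with per-collection jitter.

    ``heterogeneity`` is a relative jitter applied to ``signal_strength`` and
    ``doc_length_mean`` (uniform in ±heterogeneity), emulating the
    between-collection variability of real screening corpora.  Each collection
    receives a distinct deterministic sub-seed.
    """
    if n_collections < 1:
        raise ValueError("n_collections must be >= 1")
    collections = []
    for i in range(n_collections):
        jitter_rng = np.random.default_rng(derive_seed(seed, "suite-jitter", i))
        if heterogeneity > 0:
            sig = base_spec.signal_strength * (
                1 + jitter_rng.uniform(-heterogeneity, heterogeneity)
            )
            sig = float(np.clip(sig, 0.0, 1.0))
            dlen = base_spec.doc_length_mean * (
                1 + jitter_rng.uniform(-heterogeneity, heterogeneity)
            )
        else:
            sig = base_spec.signal_strength
            dlen = base_spec.doc_length_mean
        spec_i = replace(
            base_spec,
            signal_strength=sig,
            doc_length_mean=dlen,
            seed=derive_seed(seed, "suite-member", i),
        )
        member = generate_corpus(spec_i)
        member.name = f"{member.name}-suite{i:02d}"
        collections.append(member)
    return collections
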