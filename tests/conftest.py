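"""Shared fixtures: tiny handmade collections and trace builders."""

from __future__ import annotations

import numpy as np
import pytest

from screensim import Collection, Record, ScreeningTrace


def make_record(i: int, label: int, text: str = "", key: bool = False) -> Record:
    return Record(
        id=f"r{i:04d}",
        title=text or f"title {i}",
        abstract=text or f"abstract text number {i}",
        label=label,
        is_key_study=key,
    )


def make_collection(labels, texts=None, name="toy") -> Collection:
    records = [
        make_record(i, lab, texts[i] if texts else "")
        for i, lab in enumerate(labels)
    ]
    return Collection(records, name=name)


def make_trace(labels, key_positions=()) -> ScreeningTrace:
    """A trace with the given label sequence; ids follow trace order."""
    labels = list(labels)
    key_ids = {f"t{p:05d}" for p in key_positions}
    return ScreeningTrace(
        ordered_ids=[f"t{i:05d}" for i in range(len(labels))],
        labels=np.asarray(labels, dtype=int),
        key_ids=frozenset(key_ids),
    )


@pytest.fixture
def tiny_collection() -> Collection:
    """10 records, 3 relevant, lexically separable classes."""
    rel_text = "signal biomarker cohort outcome intervention trial"
    irr_text = "archive museum pottery catalog excavation field"
    labels = [1, 0, 0, 1, 0, 0, 0, 1, 0, 0]
    texts = [rel_text if l == 1 else irr_text for l in labels]
    return make_collection(labels, texts)


@pytest.fixture
def medium_corpus():
    """Synthetic 300-record collection at 10% prevalence, moderate signal."""
    from screensim import SyntheticCorpusSpec, generate_corpus

    return generate_corpus(
        SyntheticCorpusSpec(
            n_total=300, prevalence=0.10, vocab_size=300,
            doc_length_mean=25, signal_strength=0.8, noise_rate=0.0, seed=11,
        )
    )
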