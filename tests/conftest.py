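"""Shared fixtures.

The heavier fixtures (synthetic benchmarks and their cross-validation
results) are session-scoped so that several tests can interrogate one run.
Problem sizes are chosen to keep the whole suite comfortably fast on a
single CPU while leaving enough samples for the statistical assertions
(binomial standard errors, permutation nulls) to have narrow bands.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from carbonsite import (
    GeneratorSpec,
    RFConfig,
    SampleSet,
    WindowConfig,
    build_benchmark,
    effect_preset,
    generate_corpus,
    target_cross_validate,
)
from carbonsite.seq_io import NEGATIVE_LABEL, POSITIVE_LABEL


def make_benchmark(n_proteins: int, site_rate: float, strength: str,
                   seed: int) -> SampleSet:
    spec = GeneratorSpec(
        n_proteins=n_proteins,
        length_range=(80, 200),
        site_rate=site_rate,
        effect=effect_preset(strength),
        seed=seed,
    )
    proteins, annotations, _ = generate_corpus(spec)
    return build_benchmark(proteins, annotations,
                           WindowConfig(filter_enabled=False))


def permute_labels(sample_set: SampleSet, seed: int) -> SampleSet:
    """Reassign the positive/negative labels at random, preserving the
    class sizes — the permutation null for the whole pipeline."""
    windows = list(sample_set.positives) + list(sample_set.negatives)
    labels = ([POSITIVE_LABEL] * sample_set.n_positive
              + [NEGATIVE_LABEL] * sample_set.n_negative)
    rng = np.random.default_rng(seed)
    shuffled = [labels[i] for i in rng.permutation(len(labels))]
    relabeled = [replace(w, label=lab) for w, lab in zip(windows, shuffled)]
    return SampleSet(
        center_type=sample_set.center_type,
        xi=sample_set.xi,
        positives=[w for w in relabeled if w.label == POSITIVE_LABEL],
        negatives=[w for w in relabeled if w.label == NEGATIVE_LABEL],
    )


@pytest.fixture(scope="session")
def small_benchmark() -> SampleSet:
    """A quick strongly-separated benchmark for unit-level tests."""
    return make_benchmark(n_proteins=30, site_rate=0.4, strength="strong",
                          seed=7)


@pytest.fixture(scope="session")
def strong_benchmark() -> SampleSet:
    """~2000 experiment-confirmed samples with strong planted signal."""
    return make_benchmark(n_proteins=300, site_rate=0.4, strength="strong",
                          seed=11)


@pytest.fixture(scope="session")
def strong_cv(strong_benchmark):
    """Target 10-fold CV on the strong benchmark."""
    return target_cross_validate(strong_benchmark, k=10, seed=11,
                                 rf_config=RFConfig(n_trees=200))


@pytest.fixture(scope="session")
def permuted_cv(strong_benchmark):
    """The same CV after destroying the label-sequence association."""
    null_set = permute_labels(strong_benchmark, seed=99)
    return target_cross_validate(null_set, k=10, seed=11,
                                 rf_config=RFConfig(n_trees=200))
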