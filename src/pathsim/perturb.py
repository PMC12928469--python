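"""Data-degradation procedures: missing alleles, surplus alleles, mislabels.

These emulate the imperfections of real case/control panels: the analyst's
SNP list may omit loci that actually drive the disease (``drop_features``),
include loci that do not (``add_features``), and the phenotype labels may
call genetically susceptible individuals healthy (``mislabel_cases``).
Disease status is always fixed by the *full* genotype before any
perturbation; drop/add change only the feature view, and mislabeling applies
to training labels alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .population import LabeledPopulation

__all__ = [
    "PerturbationSpec",
    "drop_features",
    "add_features",
    "mislabel_cases",
    "mislabel_population",
]

KINDS = ("drop_features", "add_features", "mislabel_cases")


@dataclass(frozen=True)
class PerturbationSpec:
    """One declarative perturbation: what, and how much."""

    kind: str
    fraction: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not 0 <= self.fraction <= 1:
            raise ConfigError("fraction must lie in [0, 1]")

    @property
    def applies_to_training_labels(self) -> bool:
        return self.kind == "mislabel_cases"

    def describe(self) -> str:
        return f"{self.kind}:{self.fraction:g}"


def drop_features(pop: LabeledPopulation, fraction: float, seed=None):
    """Remove a uniformly random ``floor(fraction * F)`` column subset.

    Labels are untouched: status was decided by the full genotype, the
    classifier simply no longer sees some of the loci that decided it.
    """
    if not 0 <= fraction < 1:
        raise DataError("drop fraction must lie in [0, 1)")
    k = int(fraction * pop.n_features)
    if k >= pop.n_features:
        raise DataError("cannot drop every feature column")
    if k == 0:
        return pop.copy()
    rng = np.random.default_rng(seed)
    drop = rng.choice(pop.n_features, size=k, replace=False)
    keep = np.setdiff1d(np.arange(pop.n_features), drop)
    meta = dict(pop.meta)
    meta["perturbations"] = list(meta.get("perturbations", [])) + [
        f"drop_features:{fraction:g}"
    ]
    return LabeledPopulation(
        pop.X[:, keep],
        pop.y.copy(),
        [pop.feature_names[i] for i in keep],
        meta,
    )


def add_features(pop: LabeledPopulation, fraction: float, seed=None):
    """Append ``floor(fraction * F)`` irrelevant columns.

    Each added entry is drawn i.i.d. from the pooled empirical {0, 1, 2}
    distribution of the existing matrix, independent of the labels.
    """
    if fraction < 0:
        raise DataError("add fraction must be >= 0")
    k = int(fraction * pop.n_features)
    if k == 0:
        return pop.copy()
    rng = np.random.default_rng(seed)
    counts = np.bincount(np.asarray(pop.X).ravel(), minlength=3)[:3]
    probs = counts / counts.sum()
    noise = rng.choice(3, size=(pop.n, k), p=probs).astype(pop.X.dtype)
    meta = dict(pop.meta)
    meta["perturbations"] = list(meta.get("perturbations", [])) + [
        f"add_features:{fraction:g}"
    ]
    return LabeledPopulation(
        np.hstack([pop.X, noise]),
        pop.y.copy(),
        list(pop.feature_names) + [f"noise_{i}" for i in range(k)],
        meta,
    )


def mislabel_cases(labels, fraction: float, seed=None, reverse: bool = False) -> np.ndarray:
    """Flip exactly ``round(fraction * n_cases)`` Case labels to Control.

    Round-half-up; Controls are never touched.  This is the direction the
    replicated experiments examine (genetically susceptible individuals who
    have not yet manifested disease).  ``reverse=True`` flips Control labels
    to Case instead — available for sensitivity checks but not part of the
    replicated study.
    """
    if not 0 <= fraction <= 1:
        raise DataError("mislabel fraction must lie in [0, 1]")
    y = np.asarray(labels).astype(np.int8, copy=True)
    source, target = (0, 1) if reverse else (1, 0)
    pool = np.flatnonzero(y == source)
    n_flip = int(np.floor(fraction * pool.size + 0.5))
    if n_flip == 0:
        return y
    rng = np.random.default_rng(seed)
    flip = rng.choice(pool, size=n_flip, replace=False)
    y[flip] = target
    return y


def mislabel_population(pop: LabeledPopulation, fraction: float, seed=None):
    """Population-level mislabeling; refuses to run on a test partition."""
    if pop.meta.get("partition") == "test":
        raise DataError("mislabeling must only be applied to a training partition")
    out = pop.copy()
    out.y = mislabel_cases(pop.y, fraction, seed)
    out.meta["perturbations"] = list(out.meta.get("perturbations", [])) + [
        f"mislabel_cases:{fraction:g}"
    ]
    return out
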