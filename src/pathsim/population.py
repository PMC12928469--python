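"""Labeled genotype populations: the substrate handed to the classifiers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io as _io
from .errors import DataError

__all__ = ["LabeledPopulation"]


@dataclass
class LabeledPopulation:
    """A genotype feature matrix with Case/Control labels and provenance.

    ``y`` is 1 for Case, 0 for Control.  ``meta`` carries provenance such as
    the generating model, seeds, the size descriptor (e.g. ``"200%"``) and —
    after splitting — the partition tag (``"train"``/``"test"``).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y).astype(np.int8)
        if self.X.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        if self.y.shape[0] != self.X.shape[0]:
            raise DataError("one label per row required")
        if not np.isin(self.y, [0, 1]).all():
            raise DataError("labels must be 0 (Control) or 1 (Case)")
        if self.feature_names is None:
            self.feature_names = _io.default_locus_names(self.X.shape[1])
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.X.shape[1]:
            raise DataError("one feature name per column required")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.y.sum())

    def copy(self) -> "LabeledPopulation":
        return LabeledPopulation(
            self.X.copy(), self.y.copy(), list(self.feature_names), dict(self.meta)
        )

    def subset(self, rows) -> "LabeledPopulation":
        rows = np.asarray(rows)
        return LabeledPopulation(
            self.X[rows], self.y[rows], list(self.feature_names), dict(self.meta)
        )

    @classmethod
    def from_matrices(cls, case_X, control_X, feature_names=None, meta=None):
        """Stack a Case matrix over a Control matrix with matching labels."""
        case_X, control_X = np.asarray(case_X), np.asarray(control_X)
        if case_X.shape[1] != control_X.shape[1]:
            raise DataError("case and control matrices must share loci")
        X = np.vstack([case_X, control_X])
        y = np.concatenate(
            [np.ones(case_X.shape[0], np.int8), np.zeros(control_X.shape[0], np.int8)]
        )
        return cls(X, y, feature_names, dict(meta or {}))

    def write_csv(self, path) -> None:
        _io.write_genotype_csv(path, self.X, self.y, self.feature_names)

    @classmethod
    def read_csv(cls, path) -> "LabeledPopulation":
        X, labels, names = _io.read_genotype_csv(path)
        if labels is None:
            raise DataError(f"{path} has no status column")
        return cls(X, labels, names)
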