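"""Reverse-engineering disease structure from a trained neural network.

A trained one-hidden-layer network encodes, in its input-to-hidden weight
matrix, how each locus participates in the decision.  Loci that sit in the
same pathway play interchangeable roles in the threshold arithmetic, so
their weight rows tend to be similar; embedding the rows in the plane with
t-SNE makes that structure visible, and the *pathway purity* statistic
(fraction of a locus's k nearest neighbours sharing a pathway label)
quantifies it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline

from .errors import ConfigError, DataError
from .models import DiseaseModel

__all__ = [
    "WeightTable",
    "Embedding2D",
    "extract_weights",
    "embed",
    "pathway_purity",
    "cluster_agreement",
    "plot_embedding",
]

#: Label given to features (e.g. surplus noise columns) outside every pathway.
NO_PATHWAY = "none"


def _pathway_labels(model: DiseaseModel, feature_names) -> tuple:
    """Per-feature frozensets of pathway ids; loci in no pathway get 'none'."""
    by_locus = {}
    for pid, loci in model.pathway_map().items():
        for j in loci:
            by_locus.setdefault(j, set()).add(pid)
    labels = []
    for f, _name in enumerate(feature_names):
        labels.append(frozenset(by_locus.get(f, {NO_PATHWAY})))
    return tuple(labels)


@dataclass
class WeightTable:
    """L x H input-to-hidden weight matrix with per-locus pathway labels."""

    weights: np.ndarray
    feature_names: list
    labels: tuple  # per feature: frozenset of pathway ids

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise DataError("weight table must be 2-D (loci x hidden units)")
        if len(self.feature_names) != self.weights.shape[0]:
            raise DataError("one feature name per weight row required")
        if len(self.labels) != self.weights.shape[0]:
            raise DataError("one pathway label set per weight row required")

    @property
    def n_loci(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


def _find_mlp(handle):
    if isinstance(handle, MLPClassifier):
        return handle
    if isinstance(handle, Pipeline):
        for _, step in handle.steps:
            if isinstance(step, MLPClassifier):
                return step
    est = getattr(handle, "estimator", None)
    if isinstance(est, (MLPClassifier, Pipeline)):
        return _find_mlp(est)
    raise TypeError(
        "weight extraction needs a trained neural network (MLPClassifier), "
        f"got {type(handle).__name__}"
    )


def extract_weights(handle, model: DiseaseModel, feature_names=None) -> WeightTable:
    """Tabulate the input-to-hidden weights of a trained network.

    ``handle`` may be an ``MLPClassifier``, a pipeline containing one, or a
    :class:`~pathsim.mleval.FitResult`.  Row order equals input feature
    order; rows are annotated with pathway membership from the generating
    model (overlap loci carry two labels, features outside the model carry
    ``'none'``).
    """
    mlp = _find_mlp(handle)
    if not hasattr(mlp, "coefs_"):
        raise TypeError("the network has not been fitted")
    w = np.asarray(mlp.coefs_[0], dtype=float)
    if feature_names is None:
        feature_names = [f"locus_{j}" for j in range(w.shape[0])]
    return WeightTable(w, list(feature_names), _pathway_labels(model, feature_names))


@dataclass
class Embedding2D:
    """Planar t-SNE embedding of the weight-table rows."""

    points: np.ndarray
    feature_names: list
    labels: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.feature_names,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "pathways": ["|".join(sorted(s)) for s in self.labels],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def embed(table: WeightTable, perplexity: float = 8.0, seed=None) -> Embedding2D:
    """t-SNE the weight rows into the plane (deterministic under a seed)."""
    n = table.n_loci
    if n <= 3 * perplexity:
        raise ConfigError(
            f"need more than 3*perplexity loci ({n} rows, perplexity {perplexity})"
        )
    if np.allclose(table.weights, table.weights[0]):
        warnings.warn("all weight rows identical; embedding is degenerate")
    seed = None if seed is None else int(seed)
    ts = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed
    )
    pts = ts.fit_transform(table.weights)
    return Embedding2D(np.asarray(pts, float), list(table.feature_names), table.labels)


def _labels_and_matrix(table_or_embedding, labels):
    if isinstance(table_or_embedding, WeightTable):
        return table_or_embedding.weights, table_or_embedding.labels
    if isinstance(table_or_embedding, Embedding2D):
        return table_or_embedding.points, table_or_embedding.labels
    X = np.asarray(table_or_embedding, dtype=float)
    if labels is None:
        raise DataError("labels are required with a bare matrix")
    norm = tuple(
        lab if isinstance(lab, frozenset) else frozenset([lab]) for lab in labels
    )
    return X, norm


def pathway_purity(table_or_embedding, labels=None, k: int = 5) -> float:
    """Mean fraction of each locus's k nearest neighbours sharing a pathway.

    Works on the raw weight table (default for quantitative claims, since it
    avoids t-SNE stochasticity) or on a 2-D embedding.  A neighbour matches
    when its label set intersects the locus's (overlap loci match on either
    pathway).  Chance level for P equally filled disjoint pathways is ~1/P.
    """
    X, labs = _labels_and_matrix(table_or_embedding, labels)
    n = X.shape[0]
    if k <= 0:
        raise DataError("k must be positive")
    if k >= n:
        raise DataError(f"k={k} must be smaller than the number of loci ({n})")
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    hits = np.empty(n)
    for r in range(n):
        hits[r] = sum(bool(labs[r] & labs[q]) for q in order[r]) / k
    return float(hits.mean())


def cluster_agreement(points, binary_labels, seed=None) -> float:
    """Best-permutation accuracy of a 2-means split against binary labels.

    Used to ask whether an embedding separates the two sub-diseases of a
    subtype model better than chance (0.5 for balanced labels).
    """
    pts = np.asarray(points, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise DataError("binary labels required")
    km = KMeans(n_clusters=2, n_init=10, random_state=None if seed is None else int(seed))
    assign = km.fit_predict(pts)
    acc = (assign == y).mean()
    return float(max(acc, 1 - acc))


def plot_embedding(embedding: Embedding2D, path=None, ax=None):
    """Scatter the embedding, one colour per (sorted) pathway label set."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    keys = ["|".join(sorted(s)) for s in embedding.labels]
    for key in sorted(set(keys)):
        mask = np.array([k == key for k in keys])
        ax.scatter(
            embedding.points[mask, 0], embedding.points[mask, 1], label=key, s=30
        )
    ax.legend(fontsize=7, loc="best")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
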