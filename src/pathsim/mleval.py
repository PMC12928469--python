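"""Classifier panel, stratified splitting, AUC scoring and model comparison.

The panel mirrors a standard case/control benchmark: Gaussian naive Bayes,
logistic regression, a decision tree, a random forest, and a feed-forward
neural network with a single hidden layer of 25 sigmoid units (fully
connected, SGD with learning rate 0.3 and momentum 0.2, up to 500 epochs,
standardized inputs).  AUC is the rank statistic: the probability that a
random Case outscores a random Control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, SplitError
from .population import LabeledPopulation

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "split",
    "FitResult",
    "train_and_score",
    "auc_score",
    "compare_models",
]

CLASSIFIER_KINDS = ("NB", "LR", "DT", "RF", "NN")

#: Neural-network defaults: one hidden layer of 25 sigmoid units trained by
#: constant-rate SGD with momentum, emulating a classic MLP configuration.
NN_DEFAULTS = dict(
    hidden_layer_sizes=(25,),
    activation="logistic",
    solver="sgd",
    learning_rate="constant",
    learning_rate_init=0.3,
    momentum=0.2,
    nesterovs_momentum=False,
    batch_size="auto",
    max_iter=500,
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A panel member: which algorithm, with optional hyperparameter overrides."""

    kind: str
    params: tuple = ()

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )
        object.__setattr__(self, "params", tuple(dict(self.params).items()))

    def build(self, seed=None):
        """Instantiate the scikit-learn estimator behind this spec."""
        seed = None if seed is None else int(seed)
        overrides = dict(self.params)
        if self.kind == "NB":
            return GaussianNB(**overrides)
        if self.kind == "LR":
            return LogisticRegression(max_iter=1000, **overrides)
        if self.kind == "DT":
            return DecisionTreeClassifier(random_state=seed, **overrides)
        if self.kind == "RF":
            return RandomForestClassifier(
                n_estimators=100, random_state=seed, **overrides
            )
        nn = MLPClassifier(**{**NN_DEFAULTS, **overrides}, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("nn", nn)])


def split(pop: LabeledPopulation, train_fraction: float = 2 / 3, seed=None):
    """Stratified random train/test partition.

    Returns ``(train, test)`` populations tagged with ``meta['partition']``.
    Both classes must be present on both sides.
    """
    if not 0 < train_fraction < 1:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    if pop.n_cases == 0 or pop.n_controls == 0:
        raise SplitError("both classes must be present before splitting")
    seed = None if seed is None else int(seed)
    idx_train, idx_test = train_test_split(
        np.arange(pop.n),
        train_size=train_fraction,
        stratify=pop.y,
        random_state=seed,
    )
    parts = []
    for name, idx in (("train", idx_train), ("test", idx_test)):
        part = pop.subset(np.sort(idx))
        part.meta["partition"] = name
        if part.n_cases == 0 or part.n_controls == 0:
            raise SplitError(f"{name} partition lost a class; use a larger set")
        parts.append(part)
    return tuple(parts)


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


@dataclass
class FitResult:
    """A fitted panel member and its held-out AUC."""

    spec: ClassifierSpec
    estimator: object
    auc: float
    converged: bool = True

    @property
    def kind(self) -> str:
        return self.spec.kind


def train_and_score(
    train: LabeledPopulation,
    test: LabeledPopulation,
    spec: ClassifierSpec,
    seed=None,
) -> FitResult:
    """Fit on the training partition only; score the test partition by AUC.

    Non-convergence (the NN hitting its epoch cap) is flagged on the result
    but the AUC is still reported.
    """
    if train.n_cases == 0 or train.n_controls == 0:
        raise SplitError("training partition must contain both classes")
    est = spec.build(seed)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(train.X, train.y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    case_col = list(est.classes_).index(1)
    scores = est.predict_proba(test.X)[:, case_col]
    return FitResult(spec, est, auc_score(test.y, scores), converged)


def compare_models(aucs_a, aucs_b) -> float:
    """One-tailed Welch t-test p-value for mean(a) > mean(b).

    With zero variance on both sides the t statistic is undefined; equal
    means then report p = 0.5, otherwise the direction decides 0 or 1.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("need at least two replicates per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.5
        return 0.0 if a.mean() > b.mean() else 1.0
    t = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t.pvalue)
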