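"""Pathway-threshold disease models and the Case/Control classification oracle.

An individual's disease-relevant genotype is a vector of risk-allele doses,
one integer in {0, 1, 2} per locus (homozygous wild type, heterozygous,
homozygous risk).  A disease model groups loci into pathways.  A pathway
*malfunctions* when its (optionally weighted) risk-allele burden strictly
exceeds a per-pathway threshold ``mg``; an individual is a **Case** when the
(optionally weighted) number of malfunctioning pathways strictly exceeds a
second threshold ``mp``, and a **Control** otherwise.  The double threshold
makes the genotype-phenotype map inherently non-additive: once a pathway has
failed, further risk alleles in it contribute nothing, and pathway interplay
adds a second non-additive layer.

Four model variants are provided:

``SimpleModel``
    Disjoint pathways, unit weights everywhere.
``WeightedModel``
    Disjoint pathways; loci split into high-/low-risk weight classes and
    pathways into central/peripheral weight classes.
``OverlapModel``
    Unit weights, but pathways come in pairs that share two loci; a shared
    dose is counted in both pathway burdens.
``SubtypeModel``
    Two disjoint ``SimpleModel`` sub-diseases labelled as one phenotype:
    Case if either sub-model fires.

All thresholds are strict (``>``), all weights are positive, so increasing
any single dose can never flip a Case to a Control (monotonicity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError

__all__ = [
    "DiseaseStatus",
    "PathwayAssignment",
    "DiseaseModel",
    "SimpleModel",
    "WeightedModel",
    "OverlapModel",
    "SubtypeModel",
    "pathway_burden",
    "prevalence",
    "load_model",
    "model_from_dict",
    "named_model",
    "NAMED_MODELS",
]


class DiseaseStatus(enum.Enum):
    """Binary phenotype assigned by a disease model."""

    CONTROL = 0
    CASE = 1

    def __str__(self) -> str:  # "Case" / "Control", the on-disk spelling
        return self.name.capitalize()

    @classmethod
    def parse(cls, value) -> "DiseaseStatus":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            name = value.strip().upper()
            if name in cls.__members__:
                return cls[name]
        if value in (0, 1):
            return cls(int(value))
        raise ConfigError(f"cannot interpret {value!r} as a disease status")


def _as_genotype(g) -> np.ndarray:
    arr = np.asarray(g)
    if arr.ndim != 1:
        raise DataError(f"genotype must be 1-D, got shape {arr.shape}")
    return arr


def pathway_burden(g, loci: Sequence[int], locus_weights=None) -> float:
    """Weighted risk-allele burden of one pathway for one genotype.

    Returns ``sum_j w_j * dose_j`` over the listed loci; ``w_j = 1`` when no
    weights are supplied.  ``locus_weights`` may be a per-locus array indexed
    by locus, or a mapping ``{locus: weight}``.
    """
    arr = _as_genotype(g)
    idx = np.asarray(loci, dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= arr.size):
        raise DataError(
            f"pathway locus index out of range for genotype of length {arr.size}"
        )
    doses = arr[idx].astype(float)
    if locus_weights is None:
        return float(doses.sum())
    if isinstance(locus_weights, Mapping):
        w = np.array([float(locus_weights.get(int(j), 1.0)) for j in idx])
    else:
        w = np.asarray(locus_weights, dtype=float)[idx]
    return float((w * doses).sum())


@dataclass(frozen=True)
class PathwayAssignment:
    """Ordered assignment of loci (0-based genotype columns) to pathways."""

    pathways: tuple

    def __post_init__(self):
        norm = tuple(tuple(int(j) for j in p) for p in self.pathways)
        object.__setattr__(self, "pathways", norm)
        if not norm:
            raise ConfigError("a model needs at least one pathway")
        sizes = {len(p) for p in norm}
        if len(sizes) != 1:
            raise ConfigError(f"pathways must all have the same size, got {sizes}")
        for p in norm:
            if len(set(p)) != len(p):
                raise ConfigError(f"pathway {p} repeats a locus")
            if min(p) < 0:
                raise ConfigError("locus indices must be non-negative")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def genes_per_pathway(self) -> int:
        return len(self.pathways[0])

    @property
    def loci(self) -> tuple:
        """Sorted tuple of all distinct loci the assignment touches."""
        return tuple(sorted({j for p in self.pathways for j in p}))

    @property
    def n_loci_required(self) -> int:
        """Minimum genotype length this assignment can be evaluated on."""
        return max(self.loci) + 1

    def is_disjoint(self) -> bool:
        return len(self.loci) == sum(len(p) for p in self.pathways)

    @classmethod
    def blocks(cls, n_pathways: int, genes_per_pathway: int, start: int = 0):
        """Consecutive disjoint blocks: pathway i gets loci
        ``start + i*R .. start + (i+1)*R - 1``."""
        r = genes_per_pathway
        return cls(
            tuple(
                tuple(range(start + i * r, start + (i + 1) * r))
                for i in range(n_pathways)
            )
        )

    @classmethod
    def paired_overlap(
        cls, n_pathways: int, genes_per_pathway: int, shared: int = 2, start: int = 0
    ):
        """Pathways in consecutive pairs (0,1), (2,3), ... where each pair
        shares its ``shared`` lowest-index loci; pairs are mutually disjoint."""
        if n_pathways % 2:
            raise ConfigError("paired overlap needs an even number of pathways")
        r = genes_per_pathway
        if shared >= r:
            raise ConfigError("shared loci must be fewer than genes per pathway")
        own = r - shared
        paths, c = [], start
        for _ in range(n_pathways // 2):
            common = tuple(range(c, c + shared))
            a = common + tuple(range(c + shared, c + shared + own))
            b = common + tuple(range(c + shared + own, c + shared + 2 * own))
            paths += [a, b]
            c += shared + 2 * own
        return cls(tuple(paths))


class DiseaseModel:
    """Common behaviour of all pathway-threshold models."""

    assignment: PathwayAssignment

    # -- classification -------------------------------------------------

    def _burden_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, P) array of per-pathway burdens for a genotype matrix."""
        raise NotImplementedError

    def _case_mask(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def classify_matrix(self, X) -> np.ndarray:
        """Boolean Case mask for each row of a genotype matrix."""
        X = np.asarray(X)
        if X.ndim != 2:
            raise DataError(f"expected a 2-D genotype matrix, got shape {X.shape}")
        if X.shape[1] < self.n_loci_required:
            raise DataError(
                f"model needs {self.n_loci_required} loci, matrix has {X.shape[1]}"
            )
        return self._case_mask(X)

    def classify(self, g) -> DiseaseStatus:
        """Deterministic Case/Control call for a single genotype."""
        g = _as_genotype(g)
        case = bool(self.classify_matrix(g[None, :])[0])
        return DiseaseStatus.CASE if case else DiseaseStatus.CONTROL

    # -- metadata -------------------------------------------------------

    @property
    def loci(self) -> tuple:
        return self.assignment.loci

    @property
    def n_loci_required(self) -> int:
        return self.assignment.n_loci_required

    def pathway_map(self) -> dict:
        """Mapping pathway-id -> tuple of loci, ids stable across runs."""
        return {
            f"p{i}": p for i, p in enumerate(self.assignment.pathways)
        }

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        raise NotImplementedError

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class SimpleModel(DiseaseModel):
    """Disjoint unit-weight pathways; the baseline disease architecture.

    A pathway malfunctions when its dose sum strictly exceeds ``mg``; the
    individual is Case when strictly more than ``mp`` pathways malfunction.
    Degenerate settings (``mp >= P`` means nobody can be Case, ``mg >= 2R``
    means no pathway can fail) are permitted on purpose — they are useful as
    all-Control oracles.
    """

    assignment: PathwayAssignment
    mg: float
    mp: float

    variant = "simple"

    def __post_init__(self):
        if self.mg < 0 or self.mp < 0:
            raise ConfigError("thresholds must be non-negative")
        if not self.assignment.is_disjoint():
            raise ConfigError(f"{self.variant} model pathways must be disjoint")

    def _burden_matrix(self, X):
        return np.stack(
            [X[:, list(p)].sum(axis=1) for p in self.assignment.pathways], axis=1
        ).astype(float)

    def _case_mask(self, X):
        malf = self._burden_matrix(X) > self.mg
        return malf.sum(axis=1) > self.mp

    def to_dict(self):
        return {
            "variant": self.variant,
            "pathways": [list(p) for p in self.assignment.pathways],
            "mg": float(self.mg),
            "mp": float(self.mp),
        }

    @classmethod
    def from_parameters(cls, n_pathways, genes_per_pathway, mg, mp, start=0):
        return cls(
            PathwayAssignment.blocks(n_pathways, genes_per_pathway, start), mg, mp
        )


@dataclass(frozen=True)
class WeightedModel(DiseaseModel):
    """Disjoint pathways with locus- and pathway-level weights.

    Pathway burden is ``sum_j rw_j * dose_j``; the Case criterion compares the
    *weighted* sum of malfunctioning-pathway indicators against ``mp``.
    """

    assignment: PathwayAssignment
    locus_weights: dict
    pathway_weights: tuple
    mg: float
    mp: float

    variant = "weighted"

    def __post_init__(self):
        if not self.assignment.is_disjoint():
            raise ConfigError("weighted model pathways must be disjoint")
        lw = {int(k): float(v) for k, v in dict(self.locus_weights).items()}
        pw = tuple(float(w) for w in self.pathway_weights)
        object.__setattr__(self, "locus_weights", lw)
        object.__setattr__(self, "pathway_weights", pw)
        if len(pw) != self.assignment.n_pathways:
            raise ConfigError("need one pathway weight per pathway")
        if any(w <= 0 for w in pw) or any(w <= 0 for w in lw.values()):
            raise ConfigError("all weights must be positive")
        if self.mg < 0 or self.mp < 0:
            raise ConfigError("thresholds must be non-negative")
        warr = np.ones(self.assignment.n_loci_required)
        for k, v in lw.items():
            warr[k] = v
        object.__setattr__(self, "_weight_array", warr)

    def _burden_matrix(self, X):
        w = self._weight_array
        return np.stack(
            [
                (X[:, list(p)] * w[list(p)]).sum(axis=1)
                for p in self.assignment.pathways
            ],
            axis=1,
        ).astype(float)

    def _case_mask(self, X):
        malf = self._burden_matrix(X) > self.mg
        pe = malf @ np.asarray(self.pathway_weights)
        return pe > self.mp

    def to_dict(self):
        return {
            "variant": self.variant,
            "pathways": [list(p) for p in self.assignment.pathways],
            "locus_weights": {int(k): float(v) for k, v in self.locus_weights.items()},
            "pathway_weights": list(self.pathway_weights),
            "mg": float(self.mg),
            "mp": float(self.mp),
        }


@dataclass(frozen=True)
class OverlapModel(SimpleModel):
    """Unit-weight model whose pathway pairs share two loci.

    A shared dose is counted in both members of its pair, so the effective
    contribution of an overlap locus is doubled relative to a private one.
    The burden/threshold arithmetic is otherwise identical to ``SimpleModel``.
    """

    variant = "overlap"

    def __post_init__(self):
        if self.mg < 0 or self.mp < 0:
            raise ConfigError("thresholds must be non-negative")
        paths = self.assignment.pathways
        if len(paths) % 2:
            raise ConfigError("overlap model needs an even number of pathways")
        for k in range(0, len(paths), 2):
            a, b = set(paths[k]), set(paths[k + 1])
            if len(a & b) != 2:
                raise ConfigError(
                    f"pathways {k} and {k + 1} must share exactly 2 loci, "
                    f"share {len(a & b)}"
                )
            others = {
                j
                for i, p in enumerate(paths)
                if i not in (k, k + 1)
                for j in p
            }
            if (a | b) & others:
                raise ConfigError("overlap is only allowed within a pathway pair")


@dataclass(frozen=True)
class SubtypeModel(DiseaseModel):
    """Two disjoint Simple sub-diseases reported as a single phenotype."""

    sub1: SimpleModel
    sub2: SimpleModel

    variant = "subtype"

    def __post_init__(self):
        if set(self.sub1.loci) & set(self.sub2.loci):
            raise ConfigError("subtype sub-models must use disjoint loci")

    @property
    def assignment(self) -> PathwayAssignment:
        return PathwayAssignment(
            self.sub1.assignment.pathways + self.sub2.assignment.pathways
        )

    def _case_mask(self, X):
        return self.sub1.classify_matrix(X) | self.sub2.classify_matrix(X)

    def pathway_map(self):
        out = {}
        for tag, sub in (("s1", self.sub1), ("s2", self.sub2)):
            for i, p in enumerate(sub.assignment.pathways):
                out[f"{tag}.p{i}"] = p
        return out

    def to_dict(self):
        return {
            "variant": self.variant,
            "sub1": self.sub1.to_dict(),
            "sub2": self.sub2.to_dict(),
        }


def prevalence(model: DiseaseModel, matrix) -> float:
    """Fraction of rows of ``matrix`` the model classifies as Case.

    Applied to the core Case matrix this is the study's in-model disease
    prevalence: a proxy for how hard it is to *be* a Case under the model.
    """
    X = np.asarray(matrix)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DataError("prevalence needs a non-empty 2-D genotype matrix")
    return float(model.classify_matrix(X).mean())


# -- serialization entry points -----------------------------------------


def model_from_dict(d: Mapping) -> DiseaseModel:
    try:
        variant = d["variant"]
    except KeyError:
        raise ConfigError("model config is missing the 'variant' field")
    if variant == "subtype":
        sub1 = model_from_dict(d["sub1"])
        sub2 = model_from_dict(d["sub2"])
        if not (isinstance(sub1, SimpleModel) and isinstance(sub2, SimpleModel)):
            raise ConfigError("subtype sub-models must be simple models")
        return SubtypeModel(sub1, sub2)
    try:
        assignment = PathwayAssignment(tuple(tuple(p) for p in d["pathways"]))
        if variant == "simple":
            return SimpleModel(assignment, d["mg"], d["mp"])
        if variant == "overlap":
            return OverlapModel(assignment, d["mg"], d["mp"])
        if variant == "weighted":
            return WeightedModel(
                assignment,
                d["locus_weights"],
                tuple(d["pathway_weights"]),
                d["mg"],
                d["mp"],
            )
    except KeyError as exc:
        raise ConfigError(f"model config is missing field {exc}")
    raise ConfigError(f"unknown model variant {variant!r}")


def load_model(path) -> DiseaseModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ConfigError(f"{path} does not contain a model mapping")
    return model_from_dict(d)


# -- the study's named parameterizations --------------------------------


def default_weighted() -> WeightedModel:
    """Weighted model: P=8, R=6, mg=20, mp=11; per pathway 2 high-risk loci
    (weight 5) and 4 low-risk loci (weight 2.5); 3 central pathways
    (weight 5) and 5 peripheral ones (weight 2.2)."""
    assignment = PathwayAssignment.blocks(8, 6)
    lw = {}
    for p in assignment.pathways:
        for j in p[:2]:
            lw[j] = 5.0
        for j in p[2:]:
            lw[j] = 2.5
    pw = (5.0,) * 3 + (2.2,) * 5
    return WeightedModel(assignment, lw, pw, mg=20, mp=11)


def default_simple() -> SimpleModel:
    """Common-disease Simple model: P=8, R=6, mg=5, mp=4.

    Because pathway burdens are integers, thresholds act on an integer grid;
    this is the common-disease setting on that grid (measured prevalence on
    the calibrated core is ~50%, the next grid point down is the
    low-prevalence model at ~24%)."""
    return SimpleModel.from_parameters(8, 6, mg=5, mp=4)


def low_prevalence_simple() -> SimpleModel:
    """Simple model tuned rare: P=8, R=6, mg=5, mp=5."""
    return SimpleModel.from_parameters(8, 6, mg=5, mp=5)


def default_overlap() -> OverlapModel:
    """Overlap model: P=8, R=7, mg=5, mp=6; pairs share 2 loci, 48 loci total."""
    return OverlapModel(PathwayAssignment.paired_overlap(8, 7, shared=2), mg=5, mp=6)


def low_prevalence_overlap() -> OverlapModel:
    """Overlap model tuned rare: P=8, R=7, mg=6, mp=5."""
    return OverlapModel(PathwayAssignment.paired_overlap(8, 7, shared=2), mg=6, mp=5)


def single_subtype() -> SimpleModel:
    """One 24-locus sub-disease alone: P=4, R=6, mg=5, mp=2 on loci 0-23.

    The printed sub-model parameter pair is infeasible in the other ordering
    (a pathway-count threshold of 5 can never be strictly exceeded by 4
    pathways), so the feasible ordering is the default here.
    """
    return SimpleModel.from_parameters(4, 6, mg=5, mp=2, start=0)


def default_subtype() -> SubtypeModel:
    """Two disjoint 24-locus sub-diseases labelled as one phenotype."""
    return SubtypeModel(
        single_subtype(),
        SimpleModel.from_parameters(4, 6, mg=5, mp=2, start=24),
    )


NAMED_MODELS = {
    "simple-default": default_simple,
    "simple-low-prevalence": low_prevalence_simple,
    "weighted-default": default_weighted,
    "overlap-default": default_overlap,
    "overlap-low-prevalence": low_prevalence_overlap,
    "subtype-default": default_subtype,
    "single-subtype": single_subtype,
}


def named_model(name: str) -> DiseaseModel:
    """Build one of the study's stock parameterizations by name."""
    try:
        return NAMED_MODELS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown model name {name!r}; choose from {sorted(NAMED_MODELS)}"
        )
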