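"""End-to-end experiment runner: generate, perturb, split, train, compare.

A replicate of an experiment is one full pass through the pipeline:
calibrate per-locus frequencies, sample the synthetic core, expand Case and
Control populations to the requested size with the rectangle shuffle under
the disease model, apply any feature/label perturbations, split 2:1
(stratified), train each panel classifier on the training side, and score
the held-out AUC.  Replicates differ only by their spawned seeds; a master
seed deterministically derives every per-stage stream, so results are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mleval import ClassifierSpec, split, train_and_score
from .models import DiseaseModel, model_from_dict, named_model
from .perturb import (
    PerturbationSpec,
    add_features,
    drop_features,
    mislabel_population,
)
from .population import LabeledPopulation
from .shuffle import expand_population
from .synth import CoreProfile, calibrate_frequencies, sample_core

__all__ = [
    "generate_population",
    "ExperimentConfig",
    "ExperimentResult",
    "Experiment",
    "run_experiment",
]


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_population(
    model: DiseaseModel,
    profile: CoreProfile = None,
    size: float = 1.0,
    seed=None,
    expand_kwargs=None,
) -> LabeledPopulation:
    """Build one labelled population of ``size`` x the core set size.

    ``size=1.0`` is the study's "100%": ``profile.n_case`` Cases plus
    ``profile.n_control`` Controls, each manufactured from its own calibrated
    synthetic core by model-consistent rectangle-shuffle expansion.
    """
    profile = profile or CoreProfile()
    if size <= 0:
        raise ConfigError("population size multiplier must be positive")
    ss = _seed_seq(seed)
    locus_ss, case_s, ctrl_s, case_e, ctrl_e = ss.spawn(5)
    p_case = calibrate_frequencies(profile, "case", locus_ss)
    p_ctrl = calibrate_frequencies(profile, "control", locus_ss)
    core_case = sample_core(p_case, profile.n_case, case_s)
    core_ctrl = sample_core(p_ctrl, profile.n_control, ctrl_s)
    n_case = int(round(size * profile.n_case))
    n_ctrl = int(round(size * profile.n_control))
    kw = dict(expand_kwargs or {})
    case_X, case_rep = expand_population(
        core_case, model, "Case", n_case, seed=case_e, **kw
    )
    ctrl_X, ctrl_rep = expand_population(
        core_ctrl, model, "Control", n_ctrl, seed=ctrl_e, **kw
    )
    meta = {
        "size": f"{round(100 * size):d}%",
        "seed_entropy": ss.entropy,
        "model": model.to_dict(),
        "case_expansion": case_rep,
        "control_expansion": ctrl_rep,
    }
    return LabeledPopulation.from_matrices(case_X, ctrl_X, meta=meta)


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment."""

    model: DiseaseModel
    profile: CoreProfile = field(default_factory=CoreProfile)
    sizes: tuple = (1.0,)
    classifiers: tuple = (ClassifierSpec("NN"),)
    perturbations: tuple = ()
    n_replicates: int = 20
    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")
        object.__setattr__(self, "sizes", tuple(float(s) for s in self.sizes))
        object.__setattr__(self, "classifiers", tuple(self.classifiers))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        """Build a config from a YAML/JSON-style mapping.

        ``model`` may be an inline model mapping or the name of a stock
        parameterization (e.g. ``simple-default``).
        """
        d = dict(d)
        model = d.pop("model")
        if isinstance(model, str):
            model = named_model(model)
        elif isinstance(model, dict):
            model = model_from_dict(model)
        profile = CoreProfile(**d.pop("profile", {}))
        classifiers = tuple(
            ClassifierSpec(c) if isinstance(c, str) else ClassifierSpec(**c)
            for c in d.pop("classifiers", ["NN"])
        )
        perturbations = tuple(
            PerturbationSpec(**p) for p in d.pop("perturbations", [])
        )
        known = {"sizes", "n_replicates", "train_fraction", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown experiment config fields: {sorted(unknown)}")
        return cls(
            model=model,
            profile=profile,
            classifiers=classifiers,
            perturbations=perturbations,
            **{k: d[k] for k in known & set(d)},
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "profile": {
                "n_loci": self.profile.n_loci,
                "n_case": self.profile.n_case,
                "n_control": self.profile.n_control,
                "case_load": self.profile.case_load,
                "control_load": self.profile.control_load,
                "frequency_dispersion": self.profile.frequency_dispersion,
            },
            "sizes": list(self.sizes),
            "classifiers": [
                {"kind": c.kind, **dict(c.params)} for c in self.classifiers
            ],
            "perturbations": [
                {"kind": p.kind, "fraction": p.fraction} for p in self.perturbations
            ],
            "n_replicates": self.n_replicates,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


@dataclass
class ExperimentResult:
    """Per-replicate AUC table plus aggregation helpers."""

    records: pd.DataFrame
    config: ExperimentConfig
    fits: list = field(default_factory=list)

    def aucs(self, classifier=None, size=None) -> np.ndarray:
        df = self.records
        if classifier is not None:
            df = df[df["classifier"] == classifier]
        if size is not None:
            df = df[np.isclose(df["size"], size)]
        return df["auc"].to_numpy()

    def mean_auc(self, classifier=None, size=None) -> float:
        return float(self.aucs(classifier, size).mean())

    def summary(self) -> pd.DataFrame:
        """Mean AUC, standard error and replicate count per condition."""
        return (
            self.records.groupby(["size", "classifier"])["auc"]
            .agg(mean_auc="mean", se="sem", n_replicates="count")
            .reset_index()
        )

    def write_csv(self, records_path, summary_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if summary_path:
            self.summary().to_csv(summary_path, index=False)


class Experiment:
    """Runner for one :class:`ExperimentConfig`; ``run()`` -> result object."""

    def __init__(self, config: ExperimentConfig):
        self.config = config

    def run(self, keep_fits: bool = False, progress: bool = False) -> ExperimentResult:
        cfg = self.config
        rows, fits = [], []
        for r in range(cfg.n_replicates):
            rep_ss = np.random.SeedSequence([int(cfg.seed), r])
            gen_ss, pert_ss, split_ss, clf_ss = rep_ss.spawn(4)
            for s_i, size in enumerate(cfg.sizes):
                pop = generate_population(
                    cfg.model, cfg.profile, size, seed=gen_ss.spawn(1)[0]
                )
                for pert in cfg.perturbations:
                    child = _int_seed(pert_ss.spawn(1)[0])
                    if pert.kind == "drop_features":
                        pop = drop_features(pop, pert.fraction, child)
                    elif pert.kind == "add_features":
                        pop = add_features(pop, pert.fraction, child)
                train, test = split(
                    pop, cfg.train_fraction, _int_seed(split_ss.spawn(1)[0])
                )
                for pert in cfg.perturbations:
                    if pert.applies_to_training_labels:
                        child = _int_seed(pert_ss.spawn(1)[0])
                        train = mislabel_population(train, pert.fraction, child)
                for spec in cfg.classifiers:
                    fit = train_and_score(
                        train, test, spec, _int_seed(clf_ss.spawn(1)[0])
                    )
                    rows.append(
                        {
                            "replicate": r,
                            "size": size,
                            "classifier": spec.kind,
                            "perturbations": ";".join(
                                p.describe() for p in cfg.perturbations
                            ),
                            "auc": fit.auc,
                            "converged": fit.converged,
                        }
                    )
                    if keep_fits:
                        fits.append((r, size, fit, pop))
                if progress:
                    print(
                        f"replicate {r} size {size:g}: "
                        + ", ".join(
                            f"{row['classifier']}={row['auc']:.3f}"
                            for row in rows[-len(cfg.classifiers):]
                        )
                    )
        return ExperimentResult(pd.DataFrame(rows), cfg, fits)


def run_experiment(config: ExperimentConfig, **kwargs) -> ExperimentResult:
    """Convenience wrapper: ``Experiment(config).run(**kwargs)``."""
    return Experiment(config).run(**kwargs)
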