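"""Disease-model oracle tests: burden arithmetic, thresholds, enumeration."""

import itertools

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from pathsim import (
    ConfigError,
    DataError,
    DiseaseStatus,
    OverlapModel,
    PathwayAssignment,
    SimpleModel,
    SubtypeModel,
    WeightedModel,
    model_from_dict,
    named_model,
    pathway_burden,
    prevalence,
)
from pathsim.models import default_weighted


# --- literal reference evaluator (independent of the vectorized path) ----


def oracle_classify(g, model):
    """Evaluate the threshold formulas literally with Python scalars."""
    if isinstance(model, SubtypeModel):
        return oracle_classify(g, model.sub1) or oracle_classify(g, model.sub2)
    malf = []
    for p in model.assignment.pathways:
        if isinstance(model, WeightedModel):
            re_i = sum(model.locus_weights.get(j, 1.0) * g[j] for j in p)
        else:
            re_i = sum(g[j] for j in p)
        malf.append(1 if re_i > model.mg else 0)
    if isinstance(model, WeightedModel):
        pe = sum(w * th for w, th in zip(model.pathway_weights, malf))
    else:
        pe = sum(malf)
    return pe > model.mp


def tiny_models():
    simple = SimpleModel(PathwayAssignment.blocks(2, 3), mg=2, mp=1)
    weighted = WeightedModel(
        PathwayAssignment.blocks(2, 3),
        {0: 2.0, 3: 2.0},
        (1.0, 3.0),
        mg=3,
        mp=1,
    )
    overlap = OverlapModel(
        PathwayAssignment.paired_overlap(2, 3, shared=2), mg=2, mp=0
    )
    subtype = SubtypeModel(
        SimpleModel(PathwayAssignment.blocks(1, 3), mg=3, mp=0),
        SimpleModel(PathwayAssignment.blocks(1, 3, start=3), mg=4, mp=0),
    )
    return {
        "simple": simple,
        "weighted": weighted,
        "overlap": overlap,
        "subtype": subtype,
    }


# --- pathway burden -------------------------------------------------------


def test_pathway_burden_examples():
    assert pathway_burden([0] * 6, [0, 2, 4]) == 0.0
    assert pathway_burden([2, 1, 0], [0, 1, 2]) == 3.0
    # one weighted pathway: high-risk doses (2, 2), low-risk doses (0, 0, 0, 1)
    weights = {0: 5.0, 1: 5.0, 2: 2.5, 3: 2.5, 4: 2.5, 5: 2.5}
    assert pathway_burden([2, 2, 0, 0, 0, 1], range(6), weights) == 22.5


def test_pathway_burden_index_error():
    with pytest.raises(DataError):
        pathway_burden([0, 1], [0, 5])


# --- classification hand examples ----------------------------------------


def test_all_zero_genotype_is_control():
    for model in tiny_models().values():
        assert model.classify([0] * 8) is DiseaseStatus.CONTROL


def test_simple_hand_example(tiny_simple):
    # both pathways burden 3 > 2, so 2 malfunctioning > 1
    assert tiny_simple.classify([2, 1, 0, 2, 1, 0]) is DiseaseStatus.CASE


def _weighted_genotype(paths, fire):
    """Doses making exactly the given weighted-model pathways malfunction."""
    g = np.zeros(48, dtype=int)
    for i in fire:
        p = paths[i]
        g[p[0]] = 2  # 2*5
        g[p[1]] = 2  # + 2*5
        g[p[2]] = 1  # + 2.5 => 22.5 > 20
    return g


def test_weighted_pathway_weight_thresholds():
    model = default_weighted()
    paths = model.assignment.pathways
    # two central pathways: Pe = 10, not > 11
    g = _weighted_genotype(paths, [0, 1])
    assert model.classify(g) is DiseaseStatus.CONTROL
    # add one peripheral: Pe = 12.2 > 11
    g = _weighted_genotype(paths, [0, 1, 3])
    assert model.classify(g) is DiseaseStatus.CASE


# --- exhaustive enumeration ----------------------------------------------


@pytest.mark.parametrize("name", ["simple", "weighted", "overlap", "subtype"])
def test_exhaustive_oracle_equivalence(name):
    """Vectorized classifier agrees with the literal evaluator on every
    genotype of a small model."""
    model = tiny_models()[name]
    L = model.n_loci_required
    grid = np.array(list(itertools.product((0, 1, 2), repeat=L)), dtype=np.int8)
    fast = model.classify_matrix(grid)
    slow = np.array([oracle_classify(g, model) for g in grid])
    assert np.array_equal(fast, slow)


def test_simple_exhaustive_case_count(tiny_simple):
    """Frozen regression: 289 of the 3^6 genotypes are Case."""
    grid = np.array(
        list(itertools.product((0, 1, 2), repeat=6)), dtype=np.int8
    )
    assert int(tiny_simple.classify_matrix(grid).sum()) == 289


# --- invariants -----------------------------------------------------------


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    name=st.sampled_from(["simple", "weighted", "overlap", "subtype"]),
    data=st.data(),
)
def test_dose_increase_never_flips_case_to_control(name, data):
    model = tiny_models()[name]
    L = model.n_loci_required
    g = np.array(
        data.draw(st.lists(st.integers(0, 2), min_size=L, max_size=L))
    )
    j = data.draw(st.integers(0, L - 1))
    if g[j] == 2:
        return
    before = model.classify(g)
    g2 = g.copy()
    g2[j] += 1
    after = model.classify(g2)
    assert not (
        before is DiseaseStatus.CASE and after is DiseaseStatus.CONTROL
    )


def test_classify_is_deterministic(rng):
    model = named_model("overlap-default")
    X = rng.integers(0, 3, size=(50, 48))
    a = model.classify_matrix(X)
    assert np.array_equal(a, model.classify_matrix(X))


def test_subtype_is_disjunction_of_submodels(rng):
    model = named_model("subtype-default")
    X = rng.integers(0, 3, size=(200, 48))
    combined = model.classify_matrix(X)
    either = model.sub1.classify_matrix(X) | model.sub2.classify_matrix(X)
    assert np.array_equal(combined, either)


def test_overlap_counts_shared_loci_in_both_pathways(rng):
    """Duplicating shared-locus doses into both burdens equals the model's
    burden matrix."""
    model = tiny_models()["overlap"]
    X = rng.integers(0, 3, size=(40, model.n_loci_required))
    burdens = model._burden_matrix(X)
    for k, p in enumerate(model.assignment.pathways):
        manual = X[:, list(p)].sum(axis=1)
        assert np.array_equal(burdens[:, k], manual)


# --- prevalence -----------------------------------------------------------


def test_prevalence_degenerate_cases(rng):
    X = rng.integers(0, 3, size=(30, 6))
    unreachable = SimpleModel(PathwayAssignment.blocks(2, 3), mg=2, mp=2)
    assert prevalence(unreachable, X) == 0.0
    certain = SimpleModel(PathwayAssignment.blocks(2, 3), mg=2, mp=1)
    assert prevalence(certain, np.full((10, 6), 2)) == 1.0


def test_prevalence_rejects_empty():
    model = SimpleModel(PathwayAssignment.blocks(2, 3), mg=2, mp=1)
    with pytest.raises(DataError):
        prevalence(model, np.empty((0, 6)))


# --- construction validation ---------------------------------------------


def test_assignment_validation_errors():
    with pytest.raises(ConfigError):
        PathwayAssignment(((0, 1), (2, 3, 4)))  # unequal sizes
    with pytest.raises(ConfigError):
        PathwayAssignment(((0, 0, 1),))  # repeated locus
    with pytest.raises(ConfigError):
        SimpleModel(PathwayAssignment(((0, 1, 2), (2, 3, 4))), 1, 0)  # overlap
    with pytest.raises(ConfigError):
        WeightedModel(
            PathwayAssignment.blocks(2, 2), {0: -1.0}, (1.0, 1.0), 1, 0
        )  # negative weight
    with pytest.raises(ConfigError):
        SubtypeModel(
            SimpleModel(PathwayAssignment.blocks(1, 3), 1, 0),
            SimpleModel(PathwayAssignment.blocks(1, 3, start=2), 1, 0),
        )  # shared locus 2


def test_paired_overlap_uses_48_distinct_loci():
    model = named_model("overlap-default")
    assert model.assignment.n_pathways == 8
    assert model.assignment.genes_per_pathway == 7
    assert len(model.loci) == 48
    for k in range(0, 8, 2):
        shared = set(model.assignment.pathways[k]) & set(
            model.assignment.pathways[k + 1]
        )
        assert len(shared) == 2


def test_stock_models_cover_48_loci():
    for name in (
        "simple-default",
        "simple-low-prevalence",
        "weighted-default",
        "overlap-default",
        "subtype-default",
    ):
        assert named_model(name).n_loci_required == 48


# --- serialization --------------------------------------------------------


@pytest.mark.parametrize(
    "name",
    [
        "simple-default",
        "weighted-default",
        "overlap-default",
        "subtype-default",
    ],
)
def test_model_yaml_round_trip(tmp_path, name, rng):
    model = named_model(name)
    path = tmp_path / "model.yaml"
    model.save(path)
    again = model_from_dict(yaml.safe_load(path.read_text()))
    assert again.to_dict() == model.to_dict()
    X = rng.integers(0, 3, size=(30, 48))
    assert np.array_equal(again.classify_matrix(X), model.classify_matrix(X))


def test_model_from_dict_errors():
    with pytest.raises(ConfigError):
        model_from_dict({"pathways": [[0, 1]]})  # missing variant
    with pytest.raises(ConfigError):
        model_from_dict({"variant": "nope"})
    with pytest.raises(ConfigError):
        named_model("not-a-model")
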