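"""Calibrated synthetic core genotype data.

The study's seed data were 48 Crohn's-disease risk loci from a case/control
GWAS (3004 cases, 1949 controls) with mean risk-allele loads of 46.5 and 43.5
respectively.  That data set is not redistributable, so this module generates
a synthetic stand-in with the same printed statistics: per-locus risk-allele
frequencies are drawn from a Beta distribution around the load-implied mean
and then shifted additively so the expected load matches the group target
*exactly*; genotypes are sampled as Hardy-Weinberg doses, Binomial(2, p_j).

Calling :func:`calibrate_frequencies` for both groups with the *same* seed
yields parallel frequency vectors (one shared heterogeneity draw, shifted to
each target), so the case/control difference at every locus is the small
uniform load shift — mirroring real data, where no single locus separates
the classes.

Also implements the nearest-neighbour missing-value fill used on the original
data: each missing cell is copied from the closest same-class row by Hamming
distance over mutually observed loci, cascading to the next-closest donor
when needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "MISSING",
    "CoreProfile",
    "calibrate_frequencies",
    "sample_core",
    "generate_core",
    "impute_missing",
]

#: Sentinel for a missing dose in integer matrices (files use empty cells/NA).
MISSING = -1


@dataclass(frozen=True)
class CoreProfile:
    """Statistical profile the synthetic core data are calibrated to.

    ``frequency_dispersion`` is the standard deviation of the per-locus
    risk-allele frequencies around their common mean; 0 makes every locus
    identical.  The default 0.12 gives frequencies spanning roughly 0.2-0.75,
    a realistic spread for common GWAS risk alleles.
    """

    n_loci: int = 48
    n_case: int = 3004
    n_control: int = 1949
    case_load: float = 46.5
    control_load: float = 43.5
    frequency_dispersion: float = 0.12

    def __post_init__(self):
        if self.n_loci <= 0:
            raise ConfigError("n_loci must be positive")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigError("group sizes must be positive")
        for load in (self.case_load, self.control_load):
            if not 0 < load < 2 * self.n_loci:
                raise ConfigError(
                    f"target load {load} infeasible for {self.n_loci} loci"
                )
        if self.frequency_dispersion < 0:
            raise ConfigError("frequency_dispersion must be >= 0")

    def target_load(self, group) -> float:
        g = str(group).lower()
        if g == "case":
            return self.case_load
        if g == "control":
            return self.control_load
        raise ConfigError(f"group must be 'case' or 'control', got {group!r}")

    def group_size(self, group) -> int:
        return self.n_case if str(group).lower() == "case" else self.n_control


def calibrate_frequencies(profile: CoreProfile, group, seed=None) -> np.ndarray:
    """Per-locus risk-allele frequencies whose expected load hits the target.

    Draws a heterogeneous base vector from a Beta distribution centred on the
    case/control midpoint frequency with sd ``profile.frequency_dispersion``,
    then shifts it additively so that ``sum(2 p_j)`` equals the group's load
    target exactly.  The base draw depends only on ``seed``, not on ``group``,
    so the two groups share one heterogeneity pattern when seeded alike.
    """
    rng = np.random.default_rng(seed)
    L = profile.n_loci
    target = profile.target_load(group)
    mid = (profile.case_load + profile.control_load) / (4.0 * L)
    sd = profile.frequency_dispersion
    if sd == 0:
        base = np.full(L, mid)
    else:
        var = sd * sd
        if var >= mid * (1 - mid):
            raise ConfigError(
                f"dispersion {sd} too large for mean frequency {mid:.3f}"
            )
        k = mid * (1 - mid) / var - 1.0
        base = rng.beta(mid * k, (1 - mid) * k, size=L)
    p = base + (target / (2.0 * L) - base.mean())
    if (p <= 1e-9).any() or (p >= 1 - 1e-9).any():
        raise ConfigError(
            "rescaling to the load target pushed a frequency outside (0, 1); "
            "lower frequency_dispersion or move the target load"
        )
    return p


def sample_core(freqs, n: int, seed=None) -> np.ndarray:
    """Sample an ``n`` x ``L`` dose matrix, entry j ~ Binomial(2, p_j)."""
    if n <= 0:
        raise DataError("number of individuals must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ConfigError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def generate_core(profile: CoreProfile, seed=None):
    """Generate the calibrated core (case_matrix, control_matrix) pair.

    One seed stream controls the shared per-locus heterogeneity, two further
    independent streams control the genotype draws of each group.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    locus_ss, case_ss, ctrl_ss = ss.spawn(3)
    p_case = calibrate_frequencies(profile, "case", locus_ss)
    p_ctrl = calibrate_frequencies(profile, "control", locus_ss)
    case = sample_core(p_case, profile.n_case, case_ss)
    ctrl = sample_core(p_ctrl, profile.n_control, ctrl_ss)
    return case, ctrl


def _to_working(m) -> np.ndarray:
    """Int copy with MISSING where the input had NaN or the sentinel."""
    arr = np.asarray(m)
    if np.issubdtype(arr.dtype, np.floating):
        work = np.where(np.isnan(arr), MISSING, arr).astype(np.int64)
    else:
        work = arr.astype(np.int64, copy=True)
    bad = (work != MISSING) & ((work < 0) | (work > 2))
    if bad.any():
        raise DataError("doses must be 0, 1, 2 or missing")
    return work


def impute_missing(m, labels) -> np.ndarray:
    """Fill missing doses from the nearest same-class row.

    For each row with missing cells, candidate donors of the same class are
    ranked by Hamming distance computed over loci observed in *both* rows
    (ties broken by lower row index).  Each missing cell takes the value of
    the closest donor that has one there; donors are consulted in rank order.
    Non-missing entries are never altered.
    """
    work = _to_working(m)
    labels = np.asarray(labels)
    if labels.shape[0] != work.shape[0]:
        raise DataError("need one class label per row")
    miss = work == MISSING
    if not miss.any():
        return work
    if (~miss).sum(axis=1).min() == 0:
        raise DataError("a row with every locus missing cannot be imputed")
    out = work.copy()
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        sub = work[rows]
        sub_obs = sub != MISSING
        for local_r in np.flatnonzero(miss[rows].any(axis=1)):
            if len(rows) < 2:
                raise DataError(
                    f"class {cls!r} has no donor rows for imputation"
                )
            row, row_obs = sub[local_r], sub_obs[local_r]
            both = row_obs[None, :] & sub_obs
            dist = ((sub != row[None, :]) & both).sum(axis=1)
            order = np.argsort(dist, kind="stable")  # stable = lowest index wins ties
            order = order[order != local_r]
            for col in np.flatnonzero(row == MISSING):
                for donor in order:
                    if sub_obs[donor, col]:
                        out[rows[local_r], col] = sub[donor, col]
                        break
                else:
                    raise DataError(
                        f"no same-class donor has a value at locus {col}"
                    )
    return out
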