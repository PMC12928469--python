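"""Rectangle shuffle and model-consistent population expansion.

A *rectangle swap* picks two rows and two columns whose four corner entries
hold two values in crossed positions (``m[a,i] == m[b,j]``, ``m[a,j] ==
m[b,i]``, ``m[a,i] != m[a,j]``) and exchanges them within each row.  Every
row sum and every column sum of the integer matrix is preserved exactly, so
a long chain of such swaps randomizes the internal arrangement of a genotype
matrix while keeping both the per-individual risk-allele loads and the
per-locus allele counts fixed.

One *epoch* performs ``ceil(N*M*ln(N*M))`` accepted swaps (rejected
proposals are resampled and not counted), enough to decorrelate the matrix
from its origin.  Population expansion alternates epochs with a phenotype
check: rows that classify as the target status under the generating disease
model are *moved* from the working matrix into the output pool, and the
remaining rows are shuffled again.  Moving (rather than copying) rows means
nearly every core individual is placed exactly once per pass, so the output
load distribution tracks the core's — and it is why production gets harder
as the pool fills: the stragglers are the rows whose allele loads rarely
realize the target phenotype.  When rectangle epochs dry up (typically past
~80% of the requested size), the method falls back to independent
within-row value permutation (which preserves each row's load but lets
column counts drift) under the same accept/reject rule.  Targets larger
than the core are met by repeated passes, each starting from a fresh copy
of the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import (
    DataError,
    DegenerateMatrixError,
    ExpansionStallError,
    InvalidSwapError,
)
from .models import DiseaseModel, DiseaseStatus

__all__ = [
    "SwapProposal",
    "apply_swap",
    "swap_budget",
    "shuffle_epoch",
    "ExpansionReport",
    "expand_population",
]


@dataclass(frozen=True)
class SwapProposal:
    """Candidate rectangle swap on rows (a, b) and columns (i, j)."""

    row_a: int
    row_b: int
    col_i: int
    col_j: int

    def is_valid(self, m) -> bool:
        m = np.asarray(m)
        a, b, i, j = self.row_a, self.row_b, self.col_i, self.col_j
        if a == b or i == j:
            return False
        if not (0 <= a < m.shape[0] and 0 <= b < m.shape[0]):
            return False
        if not (0 <= i < m.shape[1] and 0 <= j < m.shape[1]):
            return False
        return bool(m[a, i] == m[b, j] and m[a, j] == m[b, i] and m[a, i] != m[a, j])


def apply_swap(m, proposal: SwapProposal) -> np.ndarray:
    """Apply a valid rectangle swap, returning a new matrix.

    Raises :class:`InvalidSwapError` (the proposal is rejected, the input is
    untouched) when the crossed-value condition does not hold.
    """
    if not proposal.is_valid(m):
        raise InvalidSwapError(f"{proposal} is not a valid rectangle swap")
    out = np.array(m, copy=True)
    a, b, i, j = proposal.row_a, proposal.row_b, proposal.col_i, proposal.col_j
    out[a, i], out[a, j] = out[a, j], out[a, i]
    out[b, i], out[b, j] = out[b, j], out[b, i]
    return out


def swap_budget(n_rows: int, n_cols: int) -> int:
    """Accepted-swap count for one epoch: ``ceil(N*M*ln(N*M))``."""
    nm = n_rows * n_cols
    if nm < 2:
        return 0
    return int(math.ceil(nm * math.log(nm)))


@njit(cache=True)
def _swap_chain(m, n_swaps, seed, max_failures):  # pragma: no cover - jitted
    np.random.seed(seed)
    n, c = m.shape
    span = n * n * c * c  # one uniform draw encodes (a, b, i, j) exactly
    done = 0
    failures = 0
    while done < n_swaps:
        r = np.random.randint(0, span)
        a = r % n
        r //= n
        b = r % n
        r //= n
        i = r % c
        j = r // c
        if (
            a != b
            and i != j
            and m[a, i] == m[b, j]
            and m[a, j] == m[b, i]
            and m[a, i] != m[a, j]
        ):
            t = m[a, i]
            m[a, i] = m[a, j]
            m[a, j] = t
            t = m[b, i]
            m[b, i] = m[b, j]
            m[b, j] = t
            done += 1
            failures = 0
        else:
            failures += 1
            if failures > max_failures:
                return done
    return done


def shuffle_epoch(m, seed=None, n_swaps=None, max_failures=None) -> np.ndarray:
    """Run one epoch of accepted rectangle swaps on a copy of ``m``.

    Proposals are drawn uniformly over (row pair, column pair); invalid ones
    are resampled and do not count toward the budget.  Raises
    :class:`DegenerateMatrixError` if ``max_failures`` consecutive proposals
    are rejected (e.g. a constant matrix admits no valid swap).
    """
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise DataError("can only shuffle a 2-D matrix")
    if n_swaps is None:
        n_swaps = swap_budget(*arr.shape)
    if n_swaps == 0:
        return arr.copy()
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateMatrixError("need at least 2 rows and 2 columns to swap")
    if max_failures is None:
        max_failures = max(100_000, 50 * arr.size)
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    # int8 keeps the working matrix cache-resident; fall back for wide ranges
    dtype = np.int8 if (arr.min() >= -128 and arr.max() <= 127) else np.int64
    work = np.ascontiguousarray(arr, dtype=dtype)
    if work is arr:
        work = work.copy()
    done = _swap_chain(work, int(n_swaps), kernel_seed, int(max_failures))
    if done < n_swaps:
        raise DegenerateMatrixError(
            f"only {done}/{n_swaps} swaps accepted before stalling; "
            "matrix admits too few valid rectangle swaps"
        )
    return work.astype(arr.dtype)


@dataclass
class ExpansionReport:
    """Bookkeeping for one expansion run."""

    target_n: int
    epochs: int = 0
    accepted_per_epoch: list = field(default_factory=list)
    fallback_fraction: float = 0.8
    fallback_triggered: bool = False
    n_fallback_rows: int = 0
    passes: int = 0
    n_unplaced_rows: int = 0

    @property
    def n_rectangle_rows(self) -> int:
        return int(sum(self.accepted_per_epoch))


def expand_population(
    core,
    model: DiseaseModel,
    target_status,
    target_n: int,
    seed=None,
    fallback_fraction: float = 0.8,
    n_epochs=None,
    rect_patience: int = 10,
    fallback_patience: int = 200,
    min_accept_rate: float = 0.005,
    dedup: bool = False,
):
    """Manufacture ``target_n`` rows of ``target_status`` from a core matrix.

    Each *pass* starts from a fresh copy of the core and tries to convert up
    to one core's worth of rows.  Rectangle epochs shuffle the working
    matrix; rows the model assigns the target status are moved into the
    output pool and the remainder is shuffled again, so every core row is
    placed at most once per pass and the pooled load distribution tracks the
    core's.  Late epochs run on small remainder matrices and are cheap, so
    rectangle production is given generous patience.  When it does dry up —
    ``rect_patience`` consecutive empty epochs, or the per-epoch acceptance
    rate dropping below ``min_accept_rate`` once ``fallback_fraction`` of
    the pass target is pooled — the pass falls back to independent within-row value
    permutation of the stragglers under the same accept/reject rule; rows
    still unplaced after ``fallback_patience`` consecutive empty fallback
    rounds are abandoned (counted in the report).  Passes repeat until
    ``target_n`` rows are pooled.

    ``n_epochs`` caps the total number of rectangle epochs; ``n_epochs=0``
    is the identity configuration, returning the first ``target_n`` core
    rows that already hold the target status.  Returns
    ``(matrix, ExpansionReport)``.
    """
    core = np.asarray(core)
    if core.ndim != 2:
        raise DataError("core must be a 2-D genotype matrix")
    status = DiseaseStatus.parse(target_status)
    want_case = status is DiseaseStatus.CASE
    if target_n <= 0:
        raise DataError("target_n must be positive")
    if not 0 < fallback_fraction <= 1:
        raise DataError("fallback_fraction must be in (0, 1]")

    report = ExpansionReport(target_n=target_n, fallback_fraction=fallback_fraction)
    if n_epochs == 0:
        keep = model.classify_matrix(core) == want_case
        filtered = core[keep]
        if target_n > filtered.shape[0]:
            raise DataError(
                "identity configuration (0 epochs) needs target_n core rows "
                "already holding the target status"
            )
        return filtered[:target_n].copy(), report

    rng = np.random.default_rng(seed)
    pool = []
    seen = set() if dedup else None
    total = 0
    pass_target = core.shape[0]

    def _collect(candidates, mask):
        """Move accepted rows into the pool; return (taken, surviving rows)."""
        nonlocal total
        idx = np.flatnonzero(mask)
        taken_idx = []
        for i in idx:
            if seen is not None:
                key = candidates[i].tobytes()
                if key in seen:
                    continue
                seen.add(key)
            pool.append(candidates[i].copy())
            taken_idx.append(i)
        total += len(taken_idx)
        remaining = np.delete(candidates, taken_idx, axis=0) if taken_idx else None
        return len(taken_idx), remaining

    # Every pass converts as much of a fresh core copy as it can; stopping a
    # pass early would harvest only the easiest (load-biased) rows, skewing
    # the output, so passes run to exhaustion and any surplus is subsampled
    # uniformly at the end.
    while total < target_n:
        report.passes += 1
        working = core.copy()
        pass_start = total
        zero_streak = 0

        # rectangle phase: exact row *and* column marginal preservation
        while (
            total - pass_start < pass_target
            and working.shape[0] >= 2
            and working.shape[1] >= 2
            and (n_epochs is None or report.epochs < n_epochs)
        ):
            n_before = working.shape[0]
            try:
                shuffled = shuffle_epoch(working, seed=rng)
            except DegenerateMatrixError:
                break
            report.epochs += 1
            mask = model.classify_matrix(shuffled) == want_case
            taken, remaining = _collect(shuffled, mask)
            working = shuffled if remaining is None else remaining
            report.accepted_per_epoch.append(taken)
            zero_streak = zero_streak + 1 if taken == 0 else 0
            if zero_streak >= rect_patience:
                break
            if (
                total - pass_start >= fallback_fraction * pass_target
                and taken / n_before < min_accept_rate
            ):
                break

        # fallback phase: per-row load preserved, column counts may drift
        if total - pass_start < pass_target and working.shape[0] > 0:
            report.fallback_triggered = True
            zero_streak = 0
            while total - pass_start < pass_target and working.shape[0] > 0:
                permuted = rng.permuted(working, axis=1)
                mask = model.classify_matrix(permuted) == want_case
                taken, remaining = _collect(permuted, mask)
                working = permuted if remaining is None else remaining
                report.n_fallback_rows += taken
                zero_streak = zero_streak + 1 if taken == 0 else 0
                if zero_streak >= fallback_patience:
                    report.n_unplaced_rows += working.shape[0]
                    break

        if total == pass_start:
            raise ExpansionStallError(
                f"a full expansion pass produced no {status} rows "
                f"({total}/{target_n} pooled); the model may be near-degenerate "
                "for this core"
            )

    out = np.vstack(pool).astype(core.dtype)
    if out.shape[0] > target_n:
        keep = np.sort(rng.choice(out.shape[0], size=target_n, replace=False))
        out = out[keep]
    return out, report
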