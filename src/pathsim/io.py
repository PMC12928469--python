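"""CSV/TSV genotype matrix I/O.

On-disk dialect: one header row of locus identifiers (``locus_0`` ...,
0-based indexing), one row per individual, doses 0/1/2, missing cells empty
(or ``NA``), plus an optional trailing ``status`` column holding ``Case`` /
``Control``.  A headerless dose matrix with a separate one-label-per-line
file is also accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .synth import MISSING

__all__ = [
    "default_locus_names",
    "write_genotype_csv",
    "read_genotype_csv",
    "read_labels",
    "write_labels",
]

STATUS_COLUMN = "status"


def default_locus_names(n: int):
    return [f"locus_{j}" for j in range(n)]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_genotype_csv(path, X, labels=None, locus_names=None) -> None:
    """Write a dose matrix (and optional 0/1 or Case/Control labels)."""
    X = np.asarray(X)
    names = locus_names or default_locus_names(X.shape[1])
    df = pd.DataFrame(X, columns=names).astype("Int64")
    df = df.mask(df == MISSING)  # missing -> empty cell
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != X.shape[0]:
            raise DataError("need one label per row")
        if labels.dtype.kind in "iub":
            labels = np.where(labels.astype(int) == 1, "Case", "Control")
        df[STATUS_COLUMN] = labels
    df.to_csv(path, index=False, sep=_sep_for(path))


def read_genotype_csv(path, header: bool = True):
    """Read a dose matrix.

    Returns ``(X, labels, locus_names)``; ``labels`` is a 0/1 array (1=Case)
    or None, ``X`` uses the MISSING sentinel for empty/NA cells.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=0 if header else None,
                     na_values=["NA"])
    labels = None
    if header and STATUS_COLUMN in df.columns:
        raw = df.pop(STATUS_COLUMN).astype(str).str.strip().str.capitalize()
        if not raw.isin(["Case", "Control"]).all():
            raise DataError(f"unrecognized entries in '{STATUS_COLUMN}' column")
        labels = (raw == "Case").to_numpy().astype(np.int8)
    values = df.to_numpy(dtype=float)
    X = np.where(np.isnan(values), MISSING, values)
    if not np.array_equal(X, np.round(X)):
        raise DataError("doses must be integers")
    X = X.astype(np.int8)
    if ((X != MISSING) & ((X < 0) | (X > 2))).any():
        raise DataError("doses must be 0, 1 or 2")
    names = [str(c) for c in df.columns] if header else default_locus_names(X.shape[1])
    return X, labels, names


def read_labels(path) -> np.ndarray:
    """Read a one-label-per-line Case/Control file into a 0/1 array."""
    with open(path) as fh:
        raw = [line.strip() for line in fh if line.strip()]
    norm = [s.capitalize() for s in raw]
    if any(s not in ("Case", "Control") for s in norm):
        raise DataError("labels file must contain only Case/Control lines")
    return np.array([1 if s == "Case" else 0 for s in norm], dtype=np.int8)


def write_labels(path, labels) -> None:
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        for y in labels:
            fh.write(("Case" if int(y) == 1 else "Control") + "\n")
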