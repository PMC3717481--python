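"""Reading, writing and preprocessing of plain-text data vectors.

Input files are untagged whitespace-delimited floats in one of two dialects:

* ``triplet`` (compatibility default): exactly three values per line, read
  row-major; the final line may carry one or two values when n mod 3 != 0.
* ``flat``: one value per line.

Preprocessing mirrors what is done before visualization: min-max
normalization onto a strictly positive radius interval, component-wise
averaging and differencing of vector collections, and PCA-based
dimensionality reduction of a sample collection.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DimensionalityError, ParseError, PlurigonError

#: Default normalization target: keeps every radius strictly positive and
#: centers the nominal sphere at radius 1.
DEFAULT_TARGET = (0.5, 1.5)

#: A closed triangulated surface needs at least 4 vertices.
MIN_DIMENSIONS = 4

DIALECTS = ("flat", "triplet")


@dataclass(frozen=True)
class DataVector:
    """An ordered n-dimensional real vector whose components become radii.

    Parameters
    ----------
    values : array-like of float
        The vector components, in file order. Component k keeps identity k
        through the whole pipeline (vertex k of the mesh).
    source_label : str
        Free-text provenance tag (file name, group name, ...).
    normalized : bool
        True once :func:`normalize_values` has been applied.
    norm_params : dict or None
        ``{"min": ..., "max": ..., "target": (a, b)}`` recorded at
        normalization time so values can be mapped back.
    """

    values: np.ndarray
    source_label: str = ""
    normalized: bool = False
    norm_params: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise DimensionalityError("DataVector values must be one-dimensional")
        if arr.size == 0:
            raise DimensionalityError("DataVector cannot be empty")
        if not np.all(np.isfinite(arr)):
            raise PlurigonError("DataVector values must all be finite")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n(self) -> int:
        return len(self)

    def require_dimensionality(self, minimum: int = MIN_DIMENSIONS) -> "DataVector":
        if len(self) < minimum:
            raise DimensionalityError(
                f"vector has {len(self)} values; at least {minimum} are required "
                "for a closed triangulated surface"
            )
        return self


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_vector(path: str | os.PathLike, dialect: str = "triplet") -> DataVector:
    """Read a data vector from a plain-text file.

    Raises
    ------
    ParseError
        On a non-numeric token or a dialect violation, naming the line.
    DimensionalityError
        If fewer than 4 values are read.
    """
    _check_dialect(dialect)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    # Trailing blank lines are tolerated; interior blank lines are not.
    while lines and lines[-1].strip() == "":
        lines.pop()
    if not lines:
        raise ParseError(f"empty vector file: {path}")
    n_lines = len(lines)
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            raise ParseError("blank line inside vector file", line=lineno)
        if dialect == "flat" and len(tokens) != 1:
            raise ParseError(
                f"flat dialect expects one value per line, got {len(tokens)}",
                line=lineno,
            )
        if dialect == "triplet":
            if lineno < n_lines and len(tokens) != 3:
                raise ParseError(
                    f"triplet dialect expects three values per line, got {len(tokens)}",
                    line=lineno,
                )
            if lineno == n_lines and not 1 <= len(tokens) <= 3:
                raise ParseError(
                    f"final triplet line must carry 1-3 values, got {len(tokens)}",
                    line=lineno,
                )
        for tok in tokens:
            try:
                values.append(float(tok))
            except ValueError:
                raise ParseError(f"non-numeric token {tok!r}", line=lineno) from None
    if len(values) < MIN_DIMENSIONS:
        raise DimensionalityError(
            f"{path}: read {len(values)} values; at least {MIN_DIMENSIONS} required"
        )
    return DataVector(np.array(values), source_label=str(path))


def write_vector(
    v: DataVector, path: str | os.PathLike, dialect: str = "triplet"
) -> None:
    """Write a vector so that :func:`read_vector` reproduces it exactly.

    Values are serialized with :func:`repr`, which round-trips IEEE doubles.
    """
    _check_dialect(dialect)
    vals = v.values
    lines: list[str] = []
    if dialect == "flat":
        lines = [repr(float(x)) for x in vals]
    else:
        for i in range(0, len(vals), 3):
            lines.append(" ".join(repr(float(x)) for x in vals[i : i + 3]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def normalize_values(
    v: DataVector, target: tuple[float, float] = DEFAULT_TARGET
) -> DataVector:
    """Min-max map the values affinely onto the positive interval ``target``.

    A constant vector maps to the interval midpoint. The original min/max and
    the target are recorded in ``norm_params`` for back-mapping.
    """
    a, b = float(target[0]), float(target[1])
    if not (0 < a < b):
        raise ValueError(f"target must satisfy 0 < a < b, got ({a}, {b})")
    lo = float(v.values.min())
    hi = float(v.values.max())
    if hi > lo:
        scaled = a + (v.values - lo) * (b - a) / (hi - lo)
    else:
        scaled = np.full_like(v.values, (a + b) / 2.0)
    return DataVector(
        scaled,
        source_label=v.source_label,
        normalized=True,
        norm_params={"min": lo, "max": hi, "target": (a, b)},
    )


def _stack(vs: Sequence[DataVector]) -> np.ndarray:
    if len(vs) == 0:
        raise DimensionalityError("need at least one vector")
    lengths = {len(v) for v in vs}
    if len(lengths) != 1:
        offending = [f"{v.source_label or i}: n={len(v)}" for i, v in enumerate(vs)]
        raise DimensionalityError(
            "all vectors must share one length; got " + ", ".join(offending)
        )
    return np.stack([v.values for v in vs])


def mean_vector(vs: Sequence[DataVector]) -> DataVector:
    """Component-wise arithmetic mean of a collection of equal-length vectors."""
    X = _stack(vs)
    return DataVector(X.mean(axis=0), source_label="mean")


def difference_vector(a: DataVector, b: DataVector) -> DataVector:
    """Component-wise a - b."""
    if len(a) != len(b):
        raise DimensionalityError(
            f"length mismatch: {len(a)} vs {len(b)}"
        )
    return DataVector(a.values - b.values, source_label="difference")


def reduce_dimensions(vs: Sequence[DataVector], d: int) -> list[DataVector]:
    """Project each vector onto the top-d principal axes of the collection.

    The collection is centered but not scaled (components share units);
    output components are ordered by descending explained variance. Pairwise
    distances between samples are preserved whenever d spans all nonzero
    variance directions.
    """
    from sklearn.decomposition import PCA

    X = _stack(vs)
    if len(vs) < 2:
        raise DimensionalityError("dimensionality reduction needs at least 2 vectors")
    max_d = min(X.shape)
    if not 0 < d <= max_d:
        raise DimensionalityError(
            f"target dimensionality {d} outside valid range 1..{max_d}"
        )
    if float(X.var(axis=0).max()) == 0.0:
        # Constant collection: zero variance in every direction; documented
        # convention is all-zero scores.
        scores = np.zeros((X.shape[0], d))
    else:
        scores = PCA(n_components=d, svd_solver="full").fit_transform(X)
    return [
        DataVector(row, source_label=v.source_label)
        for row, v in zip(scores, vs)
    ]
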