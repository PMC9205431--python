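"""Containers and elementary transforms for region-level activity and
connectivity matrices.

The pipeline works with four kinds of objects:

* :class:`ActivityTimeSeries` — an ``N x t_max`` matrix of continuous
  (BOLD-like) activity, one row per region of interest (ROI);
* :class:`BinarizedActivity` — the same grid reduced to active/inactive
  spin states in ``{-1, +1}`` by thresholding the z-scored series;
* :class:`StructuralConnectome` — a symmetric nonnegative matrix ``W`` of
  anatomical connection strengths (e.g., from tractography), used to
  constrain coupling magnitudes during inference;
* :class:`FunctionalConnectivity` — a matrix of Pearson correlations
  between regional series (observed or simulated).

All matrices travel as plain delimited text (CSV/TSV) with an optional
label header so that every artifact of the pipeline is inspectable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConstantRegionError,
    NegativeEntryError,
    ParseError,
    ShapeError,
    SymmetryError,
)

__all__ = [
    "ActivityTimeSeries",
    "BinarizedActivity",
    "StructuralConnectome",
    "FunctionalConnectivity",
    "zscore",
    "binarize",
    "pearson_fc",
    "read_matrix",
    "write_matrix",
    "read_activity",
    "write_activity",
]

_SYM_TOL = 1e-9


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


def _check_2d(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ShapeError(f"{what} must be 2-D, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ParseError(f"{what} contains non-finite or missing entries")
    return arr


def _check_square_symmetric(m: np.ndarray, what: str) -> np.ndarray:
    m = _check_2d(m, what)
    if m.shape[0] != m.shape[1]:
        raise ShapeError(f"{what} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0.0):
        raise SymmetryError(f"{what} is not symmetric within {_SYM_TOL}")
    return m


@dataclass
class ActivityTimeSeries:
    """Continuous regional activity, regions in rows, time in columns."""

    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _check_2d(self.values, "activity matrix")
        n, t = self.values.shape
        if n < 2 or t < 2:
            raise ShapeError(f"need N >= 2 regions and t_max >= 2, got {n} x {t}")
        if not self.region_labels:
            self.region_labels = _default_labels(n)
        if len(self.region_labels) != n:
            raise ShapeError("label count does not match row count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def t_max(self) -> int:
        return self.values.shape[1]


@dataclass
class BinarizedActivity:
    """Spin states in {-1, +1}: +1 active, -1 inactive."""

    states: np.ndarray
    threshold_used: float = 0.0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.states)
        if arr.ndim != 2:
            raise ShapeError(f"state matrix must be 2-D, got shape {arr.shape}")
        if not np.isin(arr, (-1, 1)).all():
            raise ShapeError("state entries must be exactly -1 or +1")
        self.states = arr.astype(np.int8)
        if not self.region_labels:
            self.region_labels = _default_labels(arr.shape[0])
        if len(self.region_labels) != arr.shape[0]:
            raise ShapeError("label count does not match row count")

    @property
    def n_regions(self) -> int:
        return self.states.shape[0]

    @property
    def t_max(self) -> int:
        return self.states.shape[1]


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative connection-strength matrix with zero diagonal."""

    W: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    normalization_mode: str = "none"  # none | max_one | unit_mean

    def __post_init__(self) -> None:
        self.W = _check_square_symmetric(self.W, "structural connectome")
        if (self.W < 0).any():
            raise NegativeEntryError("structural connectome has negative entries")
        if np.abs(np.diag(self.W)).max(initial=0.0) > _SYM_TOL:
            raise SymmetryError("structural connectome diagonal must be zero")
        np.fill_diagonal(self.W, 0.0)
        self.W = 0.5 * (self.W + self.W.T)  # exact symmetry
        if not self.region_labels:
            self.region_labels = _default_labels(self.W.shape[0])
        if len(self.region_labels) != self.W.shape[0]:
            raise ShapeError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def normalized(self, mode: str = "max_one") -> "StructuralConnectome":
        """Return a rescaled copy: ``max_one`` divides by the largest entry,
        ``unit_mean`` by the mean of the nonzero entries."""
        W = self.W.copy()
        if mode == "max_one":
            peak = W.max()
            if peak > 0:
                W = W / peak
        elif mode == "unit_mean":
            nz = W[W > 0]
            if nz.size:
                W = W / nz.mean()
        elif mode != "none":
            raise ValueError(f"unknown normalization mode {mode!r}")
        return StructuralConnectome(W, list(self.region_labels), mode)


@dataclass
class FunctionalConnectivity:
    """Pearson correlation matrix between regional series."""

    fc: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    source: str = "observed_continuous"  # observed_continuous | observed_binary | simulated

    def __post_init__(self) -> None:
        self.fc = _check_square_symmetric(self.fc, "functional connectivity")
        if np.abs(np.diag(self.fc) - 1.0).max(initial=0.0) > 1e-6:
            raise ShapeError("functional connectivity diagonal must be 1")
        if self.fc.min() < -1.0 - 1e-9 or self.fc.max() > 1.0 + 1e-9:
            raise ShapeError("correlations must lie in [-1, 1]")
        self.fc = np.clip(0.5 * (self.fc + self.fc.T), -1.0, 1.0)
        np.fill_diagonal(self.fc, 1.0)
        if not self.region_labels:
            self.region_labels = _default_labels(self.fc.shape[0])
        if len(self.region_labels) != self.fc.shape[0]:
            raise ShapeError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.fc.shape[0]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def zscore(ts: ActivityTimeSeries) -> ActivityTimeSeries:
    """Standardize each region's series to zero mean and unit variance.

    Uses the sample standard deviation (``ddof=1``). Pairwise Pearson
    correlations are unchanged because the map is affine per row.

    Raises
    ------
    ConstantRegionError
        If any region's raw series is constant.
    """
    x = ts.values
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.region_labels[i] for i in bad[:5]]
        raise ConstantRegionError(f"constant series for region(s) {names}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return ActivityTimeSeries(z, list(ts.region_labels))


def _is_zscored(x: np.ndarray, tol: float = 1e-6) -> bool:
    return (
        np.abs(x.mean(axis=1)).max() <= tol
        and np.abs(x.std(axis=1, ddof=1) - 1.0).max() <= tol
    )


def binarize(ts: ActivityTimeSeries, threshold: float = 0.0, assume_zscored: bool = False) -> BinarizedActivity:
    """Threshold the z-scored series into spin states.

    An entry becomes ``+1`` where ``z > threshold`` and ``-1`` otherwise
    (values exactly at the threshold count as inactive). ``ts`` is z-scored
    internally first unless it already is or ``assume_zscored`` is set.
    ``threshold`` is in SD units; 0 and +/-1 are the values typically
    compared.
    """
    if not assume_zscored and not _is_zscored(ts.values):
        ts = zscore(ts)
    states = np.where(ts.values > threshold, 1, -1).astype(np.int8)
    return BinarizedActivity(states, float(threshold), list(ts.region_labels))


def pearson_fc(m: ActivityTimeSeries | BinarizedActivity) -> FunctionalConnectivity:
    """Pearson correlation matrix across time for continuous or binary input."""
    if isinstance(m, BinarizedActivity):
        x = m.states.astype(float)
        source = "observed_binary"
    else:
        x = m.values
        source = "observed_continuous"
    if x.shape[1] < 3:
        raise ShapeError("need t_max >= 3 for a correlation matrix")
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [m.region_labels[i] for i in bad[:5]]
        raise ConstantRegionError(f"zero-variance series for region(s) {names}")
    fc = np.corrcoef(x)
    return FunctionalConnectivity(np.clip(fc, -1.0, 1.0), list(m.region_labels), source)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") and "\t" in first_line else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _parse_block(text: str, path: str) -> tuple[np.ndarray, list[str] | None]:
    """Parse a delimited block with an optional label header row/column."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = [[tok.strip() for tok in ln.split(delim)] for ln in lines]
    width = {len(r) for r in rows}
    if len(width) > 1:
        raise ParseError(f"{path}: ragged rows (widths {sorted(width)})")

    has_header = any(not _is_number(tok) for tok in rows[0][1:])
    body = rows[1:] if has_header else rows
    if not body:
        raise ParseError(f"{path}: no data rows")
    has_labels = any(not _is_number(r[0]) for r in body)
    labels: list[str] | None = None
    if has_labels:
        labels = [r[0] for r in body]
        rows = [r[1:] for r in body]
    elif has_header:
        labels = rows[0]
        rows = body
    else:
        rows = body
    try:
        data = np.array([[float(tok) for tok in r] for r in rows], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry ({exc})") from None
    return data, labels


def read_matrix(path: str | Path, expect: str):
    """Read a square matrix from delimited text.

    ``expect`` selects validation and return type: ``"structural"`` ->
    :class:`StructuralConnectome`, ``"functional"`` ->
    :class:`FunctionalConnectivity`, ``"coupling"`` ->
    :class:`~fse.pmem_inference.CouplingMatrix`.
    """
    path = Path(path)
    data, labels = _parse_block(path.read_text(), str(path))
    if data.shape[0] != data.shape[1]:
        raise ShapeError(f"{path}: expected a square matrix, got {data.shape}")
    labels = labels or _default_labels(data.shape[0])
    if expect == "structural":
        return StructuralConnectome(data, labels)
    if expect == "functional":
        return FunctionalConnectivity(data, labels)
    if expect == "coupling":
        from .pmem_inference import CouplingMatrix

        return CouplingMatrix(data, labels)
    raise ValueError(f"unknown expect kind {expect!r}")


def _matrix_of(obj) -> tuple[np.ndarray, list[str]]:
    for attr in ("W", "fc", "J"):
        if hasattr(obj, attr):
            return getattr(obj, attr), obj.region_labels
    raise TypeError(f"cannot extract a matrix from {type(obj).__name__}")


def write_matrix(obj, path: str | Path) -> None:
    """Write a matrix object as labeled delimited text (round-trip exact)."""
    path = Path(path)
    m, labels = _matrix_of(obj)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    buf = io.StringIO()
    buf.write("label" + delim + delim.join(labels) + "\n")
    for lab, row in zip(labels, m):
        buf.write(lab + delim + delim.join(_FMT % v for v in row) + "\n")
    path.write_text(buf.getvalue())


def read_activity(path: str | Path) -> ActivityTimeSeries:
    """Read an activity matrix (regions in rows, label column optional)."""
    path = Path(path)
    data, labels = _parse_block(path.read_text(), str(path))
    return ActivityTimeSeries(data, labels or _default_labels(data.shape[0]))


def write_activity(ts: ActivityTimeSeries | BinarizedActivity, path: str | Path) -> None:
    path = Path(path)
    m = ts.states if isinstance(ts, BinarizedActivity) else ts.values
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    buf = io.StringIO()
    for lab, row in zip(ts.region_labels, np.asarray(m, dtype=float)):
        buf.write(lab + delim + delim.join(_FMT % v for v in row) + "\n")
    path.write_text(buf.getvalue())
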