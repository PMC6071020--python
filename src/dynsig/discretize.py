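"""Tri-state discretization of continuous expression data.

Pathway signaling is modeled over discrete gene regulatory states:
downregulated (D), non-regulated (N), and upregulated (U). This module
holds the two core containers — :class:`ExpressionMatrix` for continuous
gene-by-sample data with a two-class label vector, and
:class:`StateMatrix` for the discretized states — and the discretizers
that map one to the other.

Three discretization rules are provided, all reducible to a per-gene pair
of cut points ``(lo, hi)`` with the mapping ``value < lo -> D``,
``value > hi -> U``, else ``N``:

``zscore``
    per-gene standardization; cuts at ``mean ± k·sd`` (default ``k=1``,
    sample sd with ``ddof=1``). A zero-variance gene maps every sample
    to N (with a warning).
``fixed``
    global thresholds shared by all genes (default ``(2, 4)``, the
    midpoints of the simulator's state emission means 1/3/5).
``quantile``
    per-gene quantile cuts (default lower/upper 25%).

States are stored internally as ``int8`` codes ``0/1/2`` for ``D/N/U``;
on disk the conventional ``-1/0/1`` encoding is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STATES",
    "STATE_CODES",
    "ExpressionMatrix",
    "StateMatrix",
    "as_state_codes",
    "codes_to_states",
    "gene_thresholds",
    "apply_thresholds",
    "discretize_matrix",
]

#: Ordered state alphabet; index order (D=0, N=1, U=2) is part of the
#: file and API contract.
STATES: tuple[str, str, str] = ("D", "N", "U")
STATE_CODES: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: On-disk integer encoding: D=-1, N=0, U=1.
FILE_CODES: tuple[int, int, int] = (-1, 0, 1)
_FILE_TO_CODE = {-1: 0, 0: 1, 1: 2}


def as_state_codes(x) -> np.ndarray:
    """Coerce a sequence of states ('D'/'N'/'U' strings or 0/1/2 ints)
    to an ``int8`` code array."""
    if isinstance(x, str):
        x = list(x)  # "DNU" -> ['D', 'N', 'U']
    arr = np.asarray(x)
    if arr.dtype.kind in "iu":
        if arr.size and (arr.min() < 0 or arr.max() > 2):
            raise ValueError("integer state codes must be in {0, 1, 2}")
        return arr.astype(np.int8)
    out = np.empty(arr.shape, dtype=np.int8)
    flat, oflat = arr.ravel(), out.ravel()
    for i, v in enumerate(flat):
        try:
            oflat[i] = STATE_CODES[v]
        except KeyError:
            raise ValueError(f"unknown regulatory state {v!r}; expected one of {STATES}")
    return out


def codes_to_states(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`as_state_codes`: codes to 'D'/'N'/'U' strings."""
    return np.asarray(STATES, dtype=object)[np.asarray(codes)]


def _check_ids_labels(n_genes, n_samples, gene_ids, sample_ids, labels):
    if len(gene_ids) != n_genes:
        raise ValueError(f"{len(gene_ids)} gene ids for {n_genes} rows")
    if len(sample_ids) != n_samples:
        raise ValueError(f"{len(sample_ids)} sample ids for {n_samples} columns")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids must be unique")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample ids must be unique")
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if labels.shape != (n_samples,):
            raise ValueError("labels must have one entry per sample")
        classes = _class_order(labels)
        if len(classes) != 2:
            raise ValueError(f"exactly two sample classes required, got {list(classes)}")
    return labels


def _class_order(labels) -> tuple:
    """Distinct labels in order of first appearance (class1 first)."""
    seen: dict = {}
    for v in labels:
        seen.setdefault(v, None)
    return tuple(seen)


@dataclass
class ExpressionMatrix:
    """Continuous gene-by-sample expression with two-class sample labels.

    Parameters
    ----------
    values : (M, N) float array
        Expression of M genes in N samples; no missing values allowed.
    gene_ids, sample_ids : sequences of unique identifiers.
    labels : length-N sequence
        Per-sample class label; exactly two distinct classes, both
        non-empty.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values; "
                             "impute or drop them before loading")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = _check_ids_labels(*self.values.shape, self.gene_ids,
                                        self.sample_ids, self.labels)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple:
        """The two class labels, in order of first appearance."""
        return _class_order(self.labels)

    def class_mask(self, label) -> np.ndarray:
        return np.asarray([v == label for v in self.labels], dtype=bool)


@dataclass
class StateMatrix:
    """Gene-by-sample matrix of discrete regulatory states.

    ``states`` holds ``int8`` codes 0/1/2 for D/N/U; identifiers and
    labels mirror the source :class:`ExpressionMatrix`.
    """

    states: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.states = as_state_codes(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D genes x samples matrix")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = _check_ids_labels(*self.states.shape, self.gene_ids,
                                        self.sample_ids, self.labels)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.states.shape[0]

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    @property
    def classes(self) -> tuple:
        return _class_order(self.labels)

    def class_mask(self, label) -> np.ndarray:
        return np.asarray([v == label for v in self.labels], dtype=bool)

    def gene_row(self, gene) -> int:
        """Row index of ``gene``; KeyError if absent."""
        return self._gene_index[gene]

    def __contains__(self, gene) -> bool:
        return gene in self._gene_index

    def to_file_encoding(self) -> np.ndarray:
        """States as the on-disk -1/0/1 integer encoding."""
        return np.asarray(FILE_CODES, dtype=np.int8)[self.states]


def gene_thresholds(values: np.ndarray, method: str = "zscore", *,
                    k: float = 1.0,
                    thresholds: tuple[float, float] = (2.0, 4.0),
                    quantiles: tuple[float, float] = (0.25, 0.75),
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene cut points ``(lo, hi)`` for the chosen discretizer.

    Every supported method reduces to thresholding, which makes the state
    mapping monotone in expression by construction and lets the same cuts
    be re-applied (idempotence).
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if method == "fixed":
        lo, hi = thresholds
        if not lo < hi:
            raise ValueError(f"fixed thresholds must satisfy lo < hi, got {thresholds}")
        return np.full(m, float(lo)), np.full(m, float(hi))
    if method == "zscore":
        if k <= 0:
            raise ValueError(f"zscore cut k must be positive, got {k}")
        mean = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(m)
        flat = sd == 0
        if flat.any():
            warnings.warn(f"{int(flat.sum())} zero-variance gene(s) mapped to all-N "
                          "under the zscore discretizer")
        lo = np.where(flat, -np.inf, mean - k * sd)
        hi = np.where(flat, np.inf, mean + k * sd)
        return lo, hi
    if method == "quantile":
        qlo, qhi = quantiles
        if not 0 < qlo < qhi < 1:
            raise ValueError(f"quantiles must satisfy 0 < lo < hi < 1, got {quantiles}")
        lo = np.quantile(values, qlo, axis=1)
        hi = np.quantile(values, qhi, axis=1)
        return lo, hi
    raise ValueError(f"unknown discretization method {method!r}; "
                     "expected 'zscore', 'fixed' or 'quantile'")


def apply_thresholds(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Map values to state codes: ``< lo -> D``, ``> hi -> U``, else N."""
    values = np.asarray(values, dtype=float)
    lo = np.asarray(lo, dtype=float)[:, None]
    hi = np.asarray(hi, dtype=float)[:, None]
    codes = np.ones(values.shape, dtype=np.int8)  # N
    codes[values < lo] = 0                        # D
    codes[values > hi] = 2                        # U
    return codes


def discretize_matrix(expr: ExpressionMatrix, method: str = "zscore", **kwargs
                      ) -> StateMatrix:
    """Discretize an :class:`ExpressionMatrix` into a :class:`StateMatrix`.

    Parameters
    ----------
    expr : ExpressionMatrix
    method : {'zscore', 'fixed', 'quantile'}
    **kwargs
        Method parameters forwarded to :func:`gene_thresholds`
        (``k``, ``thresholds``, ``quantiles``).
    """
    if expr.n_samples < 2:
        raise ValueError("discretization requires at least 2 samples per gene")
    lo, hi = gene_thresholds(expr.values, method, **kwargs)
    codes = apply_thresholds(expr.values, lo, hi)
    return StateMatrix(codes, expr.gene_ids, expr.sample_ids, expr.labels)
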