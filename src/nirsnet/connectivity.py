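"""Functional-connectivity estimation between fNIRS channels.

Connectivity is the pairwise Pearson correlation of channel time series
over a chosen segment (resting state or the full task session).  Matrices
are Fisher r-to-z transformed before any averaging or group statistics
(correlations are not additive), and binarized either at a fixed
correlation threshold (0.8 in the reference analysis) or at a proportional
sparsity level that keeps the strongest fraction of edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import HemoglobinSeries

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel matrix with kind and threshold provenance.

    ``kind`` is 'r' (correlations, unit diagonal), 'z' (Fisher-transformed,
    zero diagonal) or 'binary' (adjacency, zero diagonal).
    """

    values: np.ndarray
    kind: str = "r"
    segment: str | None = None
    threshold: float | None = None
    sparsity: float | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("r", "z", "binary"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind == "r" and np.nanmax(np.abs(v)) > 1 + 1e-10:
            raise ValueError("r-kind matrix has entries outside [-1, 1]")
        if not self.labels:
            self.labels = [f"CH{i + 1:02d}" for i in range(v.shape[0])]
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle entries (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def fc_matrix(
    series: HemoglobinSeries | np.ndarray,
    segment: tuple[float, float] | slice | None = None,
    chromophore: str = "hbo",
    segment_name: str | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation matrix over a segment of the recording.

    ``segment`` may be a (start, stop) window in seconds (requires a
    HemoglobinSeries) or a sample slice.  Channels with zero variance get
    zero rows/columns (with a warning) and a unit diagonal.
    """
    if isinstance(series, HemoglobinSeries):
        data = series.select(chromophore)
        labels = list(series.channels)
        if isinstance(segment, tuple):
            i0 = int(round(segment[0] * series.fs))
            i1 = int(round(segment[1] * series.fs))
            segment = slice(i0, i1)
    else:
        data = np.asarray(series, dtype=float)
        labels = []
    if isinstance(segment, slice):
        data = data[segment]
    if data.shape[0] < 30:
        raise ValueError(f"segment too short for correlation ({data.shape[0]} samples)")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    dead = np.flatnonzero(np.ptp(data, axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    if dead.size:
        warnings.warn(
            f"zero-variance channel(s) {dead.tolist()}: correlations set to 0",
            stacklevel=2,
        )
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(values=r, kind="r", segment=segment_name, labels=labels)


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = atanh(r), with the diagonal set to 0.

    r is clipped to +/-(1 - 1e-7) so duplicated channels stay finite.
    """
    if matrix.kind != "r":
        raise ValueError("fisher_z expects an r-kind matrix")
    z = np.arctanh(np.clip(matrix.values, -_CLIP, _CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z, kind="z", segment=matrix.segment, labels=list(matrix.labels)
    )


def binarize_fixed(matrix: ConnectivityMatrix, threshold: float = 0.8) -> ConnectivityMatrix:
    """Edge (i, j) = 1 iff r(i, j) > threshold (signed r, i != j)."""
    if matrix.kind != "r":
        raise ValueError("binarize_fixed expects an r-kind matrix")
    if not (-1.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (-1, 1)")
    a = (matrix.values > threshold).astype(float)
    np.fill_diagonal(a, 0.0)
    a = np.maximum(a, a.T)
    return ConnectivityMatrix(
        values=a,
        kind="binary",
        segment=matrix.segment,
        threshold=threshold,
        labels=list(matrix.labels),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def binarize_sparsity(matrix: ConnectivityMatrix, sparsity: float) -> ConnectivityMatrix:
    """Keep the round(s * N(N-1)/2) strongest off-diagonal edges by signed r.

    Ties are broken by (row, column) channel order.
    """
    if matrix.kind != "r":
        raise ValueError("binarize_sparsity expects an r-kind matrix")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    n = matrix.n
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.values[iu, ju]
    k = _round_half_up(sparsity * n * (n - 1) / 2.0)
    # stable sort on descending value with (i, j) tie-break
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    a = np.zeros((n, n))
    a[iu[keep], ju[keep]] = 1.0
    a = a + a.T
    return ConnectivityMatrix(
        values=a,
        kind="binary",
        segment=matrix.segment,
        sparsity=sparsity,
        labels=list(matrix.labels),
    )


def group_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average r-kind matrices in Fisher z-space and transform back to r."""
    if not matrices:
        raise ValueError("cannot average an empty collection")
    n = matrices[0].n
    zs = []
    for m in matrices:
        if m.n != n:
            raise ValueError("matrices must share dimensions")
        zs.append(fisher_z(m).values)
    r = np.tanh(np.mean(zs, axis=0))
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        kind="r",
        segment=matrices[0].segment,
        labels=list(matrices[0].labels),
    )


def mean_offdiag_z(matrix: ConnectivityMatrix) -> float:
    """Subject-level scalar connectivity: mean Fisher z over the upper triangle."""
    return float(fisher_z(matrix).off_diagonal().mean())
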