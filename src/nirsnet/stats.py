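"""Group-level statistics: t-tests on summaries and raw values, scalar
connectivity comparisons, metric-score correlation, and the power-based
sample-size computation.

All significance calls default to alpha = 0.01 (two-tailed), the threshold
used throughout the reference analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .connectivity import ConnectivityMatrix, mean_offdiag_z

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one scalar endpoint in one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, label: str, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(
            label=label,
            n=values.size,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)),
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str  # 'paired' | 'two-sample pooled' | 'two-sample welch'
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < self.alpha


def two_sample_t_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Two-sample t-test from printed means/SDs/ns.

    ``variant='pooled'`` is the classical Student test (equal variances);
    ``variant='welch'`` uses the Welch-Satterthwaite correction.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        return TestResult(0.0, a.n + b.n - 2, np.nan, f"two-sample {variant}",
                          alpha, degenerate=True)
    va, vb = a.sd**2, b.sd**2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        sea2, seb2 = va / a.n, vb / b.n
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (
            sea2**2 / (a.n - 1) + seb2**2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), f"two-sample {variant}", alpha)


def two_sample_t(
    x: np.ndarray,
    y: np.ndarray,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Two-sample t-test from raw per-subject values (via group summaries;
    the summary-form pooled test is exact for raw data)."""
    a = GroupSummary.from_values("a", x)
    b = GroupSummary.from_values("b", y)
    return two_sample_t_summary(a, b, variant=variant, alpha=alpha)


def paired_t(x: np.ndarray, y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Paired t-test on per-subject differences x - y (two-tailed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return TestResult(np.nan, n - 1, np.nan, "paired", alpha, degenerate=True)
    t = d.mean() * math.sqrt(n) / sd
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p), "paired", alpha)


def fc_compare(
    matrices_a: list[ConnectivityMatrix],
    matrices_b: list[ConnectivityMatrix],
    paired: bool = False,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Compare two sets of subject-level connectivity matrices.

    Each subject is reduced to the mean Fisher z over the upper triangle;
    the scalar series are then compared by a paired or two-sample t-test.
    """
    if not matrices_a or not matrices_b:
        raise ValueError("both collections must be non-empty")
    n = matrices_a[0].n
    for m in matrices_a + matrices_b:
        if m.n != n:
            raise ValueError("matrix dimensions differ across subjects")
    za = np.array([mean_offdiag_z(m) for m in matrices_a])
    zb = np.array([mean_offdiag_z(m) for m in matrices_b])
    if paired:
        return paired_t(za, zb, alpha=alpha)
    return two_sample_t(za, zb, variant=variant, alpha=alpha)


def metric_score_correlation(metrics: np.ndarray, scores: np.ndarray) -> float:
    """Pearson correlation between a network metric and cognitive scores
    across visits/subjects."""
    metrics = np.asarray(metrics, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if metrics.shape != scores.shape or metrics.size < 3:
        raise ValueError("need aligned sequences of length >= 3")
    if metrics.std() == 0 or scores.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(metrics, scores)[0, 1])


@dataclass(frozen=True)
class SampleSize:
    n_base: int
    n_final: int
    effect_size: float


def sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    dropout: float = 0.15,
) -> SampleSize:
    """Per-group sample size for a two-sample comparison of means.

    n_base = ceil(2 (z_{1-alpha/2} + z_{1-beta})^2 / d^2) with d = delta/sd,
    then inflated for the anticipated dropout rate:
    n_final = ceil(n_base / (1 - dropout)).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if not (0 <= dropout < 1):
        raise ValueError("dropout must lie in [0, 1)")
    d = delta / sd
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    n_base = math.ceil(2 * (z_a + z_b) ** 2 / d**2)
    n_final = math.ceil(n_base / (1 - dropout))
    return SampleSize(n_base=n_base, n_final=n_final, effect_size=d)


def inflate_for_dropout(n_base: int, dropout: float = 0.15) -> int:
    """ceil(n_base / (1 - dropout)); identity when dropout is 0."""
    if not (0 <= dropout < 1):
        raise ValueError("dropout must lie in [0, 1)")
    return math.ceil(n_base / (1 - dropout))
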