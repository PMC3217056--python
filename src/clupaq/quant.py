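"""Differential analysis of aligned spectra via the BW-ratio.

For every frequency instance j the ratio of the between-group to the
within-group sum of squares is computed across the cohort,

    BW(j) = sum_i sum_k I(y_i = k) (xbar_kj - xbar_.j)^2
          / sum_i sum_k I(y_i = k) (x_ij - xbar_kj)^2,

a distribution-free analogue of the one-way ANOVA F statistic: with K groups
and N spectra, BW = F * (K-1)/(N-K) exactly. Inference uses a bootstrap null:
each column is centred by its group means, then resampled with replacement
(group sizes preserved) and BW recomputed; the critical value is the
empirical quantile at a Bonferroni-style level alpha/n_peaks, where n_peaks
is the (average) number of detected peaks — columns of one NMR peak are
redundant, so adjusting per column would be needlessly harsh. Contiguous
runs of super-critical columns are reported as significant regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SpectrumSet

__all__ = [
    "GroupDesign",
    "BWProfile",
    "bw_ratio",
    "bw_profile",
    "bootstrap_null",
    "critical_threshold",
    "significant_regions",
    "bw_analysis",
]

FLAG_OK = 0
FLAG_ZERO_ZERO = 1  # 0/0: no variance at all -> BW defined as 0
FLAG_INF = 2  # between-group signal with zero within-group variance


@dataclass
class GroupDesign:
    """Group labels y_i of the cohort rows.

    Needs >= 2 groups with >= 2 members each so within-group variance is
    estimable.
    """

    labels: list[str]

    def __post_init__(self) -> None:
        labels = [str(v) for v in self.labels]
        self.labels = labels
        self.groups = sorted(set(labels))
        self.counts = np.array([labels.count(g) for g in self.groups])
        if len(self.groups) < 2:
            raise ValueError("need >= 2 distinct groups")
        if np.any(self.counts < 2):
            small = [g for g, c in zip(self.groups, self.counts) if c < 2]
            raise ValueError(f"groups {small} have fewer than 2 members")
        self.codes = np.array([self.groups.index(v) for v in labels])

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass
class BWProfile:
    """Per-frequency BW values, bootstrap critical values and regions."""

    bw: np.ndarray
    flags: np.ndarray
    critical: np.ndarray
    regions: list[tuple[int, int]]
    alpha: float
    n_peaks: int
    n_bootstrap: int
    seed: int
    pooled_null: bool = False
    params: dict = field(default_factory=dict)


def _bw_columns(X: np.ndarray, design: GroupDesign) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised BW over the columns of X (n_spectra x n_columns)."""
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for k in range(design.k):
        rows = X[design.codes == k]
        mk = rows.mean(axis=0)
        num += rows.shape[0] * (mk - grand) ** 2
        den += ((rows - mk) ** 2).sum(axis=0)
    flags = np.full(X.shape[1], FLAG_OK)
    zero_den = den == 0
    flags[zero_den & (num > 0)] = FLAG_INF
    flags[zero_den & (num == 0)] = FLAG_ZERO_ZERO
    with np.errstate(divide="ignore", invalid="ignore"):
        bw = num / den
    bw[flags == FLAG_INF] = np.inf
    bw[flags == FLAG_ZERO_ZERO] = 0.0
    return bw, flags


def bw_ratio(column: np.ndarray, design: GroupDesign) -> float:
    """BW-ratio of a single frequency instance.

    Zero within-group variance with a nonzero between-group term returns
    ``inf``; a fully constant column returns 0. Use :func:`bw_profile` to
    recover the sentinel flags.
    """
    col = np.asarray(column, dtype=float)
    if col.size != design.n:
        raise ValueError("column length must equal the number of spectra")
    bw, _ = _bw_columns(col.reshape(-1, 1), design)
    return float(bw[0])


def bw_profile(
    spectra: SpectrumSet | np.ndarray, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray]:
    """BW-ratio for every column of the aligned matrix; returns (bw, flags)."""
    X = spectra.intensities if isinstance(spectra, SpectrumSet) else np.asarray(spectra, float)
    if X.shape[0] != design.n:
        raise ValueError("matrix rows must match the design labels")
    return _bw_columns(X, design)


def bootstrap_null(
    spectra: SpectrumSet | np.ndarray,
    design: GroupDesign,
    n_iterations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sample the null distribution of BW under no group effect.

    Each column is centred by its group means (all group means become 0),
    then per iteration every column independently redraws n values with
    replacement from its centred pool, keeping the original group sizes.
    Returns an array of shape ``(n_iterations, n_columns)``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X = spectra.intensities if isinstance(spectra, SpectrumSet) else np.asarray(spectra, float)
    n, p = X.shape
    centred = X.copy()
    for k in range(design.k):
        rows = design.codes == k
        centred[rows] -= X[rows].mean(axis=0)
    rng = np.random.default_rng(seed)
    cols = np.arange(p)
    out = np.empty((n_iterations, p))
    for t in range(n_iterations):
        idx = rng.integers(0, n, size=(n, p))
        out[t], _ = _bw_columns(centred[idx, cols], design)
    return out


def critical_threshold(
    null_samples: np.ndarray,
    alpha: float = 0.05,
    n_peaks: int = 1,
    pooled: bool = False,
) -> np.ndarray | float:
    """Empirical critical BW value at the Bonferroni-adjusted level.

    Per-frequency by default: the ``1 - alpha/n_peaks`` quantile of each
    column's null samples. With ``pooled=True`` one scalar threshold is
    taken from all samples pooled. When the adjusted tail is finer than the
    bootstrap resolution the maximum sample is returned with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("no null samples")
    level = alpha / n_peaks
    count = null_samples.size if pooled else null_samples.shape[0]
    if level < 1.0 / count:
        warnings.warn(
            f"adjusted level {level:.3g} is beyond the bootstrap resolution "
            f"(1/{count}); returning the maximum null sample",
            stacklevel=2,
        )
        return float(null_samples.max()) if pooled else null_samples.max(axis=0)
    finite = np.where(np.isfinite(null_samples), null_samples, np.nan)
    if pooled:
        return float(np.nanquantile(finite, 1 - level, method="higher"))
    return np.nanquantile(finite, 1 - level, axis=0, method="higher")


def significant_regions(
    bw: np.ndarray, critical: np.ndarray | float
) -> list[tuple[int, int]]:
    """Maximal half-open runs of consecutive columns with bw > critical."""
    above = np.asarray(bw) > critical
    edges = np.flatnonzero(np.diff(np.concatenate([[False], above, [False]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def bw_analysis(
    spectra: SpectrumSet | np.ndarray,
    design: GroupDesign,
    alpha: float = 0.05,
    n_peaks: int = 1,
    n_bootstrap: int = 1000,
    seed: int = 0,
    pooled_null: bool = False,
) -> BWProfile:
    """Full BW differential analysis: profile, bootstrap null, regions.

    Infinite-BW columns (zero within-group variance) count as significant
    only when their between-group numerator exceeds the finite-sample
    critical value; they stay flagged in the profile.
    """
    bw, flags = bw_profile(spectra, design)
    null = bootstrap_null(spectra, design, n_bootstrap, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        critical = critical_threshold(null, alpha, n_peaks, pooled=pooled_null)
    regions = significant_regions(bw, critical)
    return BWProfile(
        bw=bw,
        flags=flags,
        critical=np.broadcast_to(np.asarray(critical, float), bw.shape).copy(),
        regions=regions,
        alpha=alpha,
        n_peaks=n_peaks,
        n_bootstrap=n_bootstrap,
        seed=seed,
        pooled_null=pooled_null,
    )
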