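"""Hierarchical Cluster-based Peak Alignment (CluPA).

A target spectrum is aligned to the reference top-down. At each level the
current region (bounded left and right by the lowest target-intensity points
flanking the merged peak list) receives one rigid integer shift estimated by
FFT cross-correlation; the merged reference+target peak list is then — after
the shift — clustered hierarchically on peak position, the dendrogram is cut
below the root into two clusters, and each half that still holds peaks of
both spectra recurses. Shifting first and grouping afterwards reduces peak
overlap before clustering, which is what makes the two-way cut reliable.

Sign convention: a lag is the displacement *added* to target indices, so a
target delayed by ``k`` points (peaks at higher indices than the reference)
yields lag ``-k``, and the segment moves left. Shifts are rigid and integer;
no warping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.fft import irfft, rfft

from .io import Spectrum, SpectrumSet
from .peaks import PeakList

__all__ = [
    "AlignmentParams",
    "MergedPeakList",
    "SegmentShift",
    "AlignmentTrace",
    "find_shift_region",
    "find_shift_step",
    "apply_shift",
    "build_cluster_tree",
    "cut_tree_two",
    "satisfied_condition",
    "clupa_align",
    "align_set",
    "pairwise_correlation_map",
]

REF, TARGET = 0, 1


@dataclass
class AlignmentParams:
    """Controls for one CluPA run.

    max_shift
        Largest allowed |lag| per segment, in points. About 0.05 ppm —
        roughly 100 points at typical digital resolution — is a sensible
        ceiling for 1H NMR.
    linkage
        Inter-cluster distance for the dendrogram: single, complete or
        average (default).
    min_peaks_to_recurse
        A segment recurses only with at least this many merged peaks (and
        peaks of both spectra); 3 reproduces the stop at two remaining peaks.
    exclude_mask
        Half-open index intervals that must never be shifted; a segment
        overlapping one keeps lag 0.
    max_depth
        Recursion cap (None = unbounded); depth 0 applies only the single
        global shift.
    """

    max_shift: int = 100
    linkage: str = "average"
    min_peaks_to_recurse: int = 3
    exclude_mask: tuple[tuple[int, int], ...] = ()
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if self.linkage not in ("single", "complete", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.min_peaks_to_recurse < 2:
            raise ValueError("min_peaks_to_recurse must be >= 2")


@dataclass
class MergedPeakList:
    """Reference + target peaks pooled and sorted by position.

    ``owners[i]`` is 0 for a reference-owned, 1 for a target-owned entry.
    """

    positions: np.ndarray
    owners: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.owners = np.asarray(self.owners, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.owners = self.owners[order]
        self.intensities = self.intensities[order]

    @classmethod
    def from_peaklists(cls, ref: PeakList, target: PeakList) -> "MergedPeakList":
        return cls(
            positions=np.concatenate([ref.positions, target.positions]),
            owners=np.concatenate(
                [np.full(len(ref), REF), np.full(len(target), TARGET)]
            ),
            intensities=np.concatenate([ref.intensities, target.intensities]),
        )

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class SegmentShift:
    start: int
    end: int
    lag: int
    depth: int
    clamped_peaks: int = 0


@dataclass
class AlignmentTrace:
    """Diagnostic log of every segment shift applied to one target."""

    shifts: list[SegmentShift] = field(default_factory=list)

    @property
    def points_moved(self) -> int:
        return sum((s.end - s.start) for s in self.shifts if s.lag != 0)

    @property
    def max_abs_lag(self) -> int:
        return max((abs(s.lag) for s in self.shifts), default=0)


def find_shift_region(
    target: np.ndarray, peak_positions: np.ndarray, outer: tuple[int, int]
) -> tuple[int, int]:
    """Bound the shift region by the quietest flanking points of the target.

    The region starts at the lowest-intensity point between ``outer.start``
    and the leftmost peak, and ends just past the lowest-intensity point
    between the rightmost peak and ``outer.end``; ties take the earliest
    index. The returned half-open interval contains every peak position.
    """
    if peak_positions.size == 0:
        raise ValueError("peak list is empty")
    lo, hi = outer
    left_peak = int(peak_positions.min())
    right_peak = int(peak_positions.max())
    if not (lo <= left_peak and right_peak < hi):
        raise ValueError("outer interval must contain all merged peaks")
    start = lo + int(np.argmin(target[lo : left_peak + 1]))
    end = right_peak + int(np.argmin(target[right_peak:hi])) + 1
    return start, end


def find_shift_step(ref_segment: np.ndarray, target_segment: np.ndarray, max_shift: int) -> int:
    """Best integer lag by circular FFT cross-correlation, |lag| <= max_shift.

    Both segments are raised to a common floor (their own minimum is
    subtracted) before correlating; the shorter one is zero-padded. The lag
    is the displacement to add to target indices. Ties resolve to the
    smallest |lag|, then to the negative lag. All-zero information gives 0.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    a = np.asarray(ref_segment, dtype=float)
    b = np.asarray(target_segment, dtype=float)
    n = max(a.size, b.size)
    if n == 0:
        return 0
    a = np.pad(a, (0, n - a.size))
    b = np.pad(b, (0, n - b.size))
    a = a - a.min()
    b = b - b.min()
    if not (np.any(a) and np.any(b)):
        return 0
    # c[s] = sum_i a[i] * b[(i - s) mod n]: correlation after shifting b by +s
    c = irfft(rfft(a) * np.conj(rfft(b)), n)
    m = min(max_shift, n - 1)
    lags = np.concatenate([np.arange(0, m + 1), np.arange(-m, 0)])
    scores = c[lags % n]
    # ordering by (|lag|, lag) makes the first strict max the tie-winner
    order = np.lexsort((lags, np.abs(lags)))
    best = order[int(np.argmax(scores[order]))]
    return int(lags[best])


def _shift_segment(x: np.ndarray, lag: int, start: int, end: int) -> None:
    """Rigidly translate ``x[start:end]`` by ``lag`` in place.

    Vacated points take the value of the nearest surviving edge point inside
    the region (boundary-value extension); everything outside is untouched.
    """
    if lag == 0 or end <= start:
        return
    seg = x[start:end].copy()
    d = end - start
    k = min(abs(lag), d - 1)
    if lag > 0:
        x[start + k : end] = seg[: d - k]
        x[start : start + k] = seg[0]
    else:
        x[start : end - k] = seg[k:]
        x[end - k : end] = seg[-1]


def apply_shift(
    target: Spectrum | np.ndarray,
    merged: MergedPeakList,
    lag: int,
    region: tuple[int, int],
) -> tuple[np.ndarray, MergedPeakList, int]:
    """Shift the target's intensities and its peaks inside ``region`` by ``lag``.

    Reference-owned entries and all data outside the region are untouched.
    Target peaks that would leave the region are clamped to its edge; the
    returned int counts them. Returns new arrays (the inputs are not
    modified).
    """
    x = np.array(target.intensities if isinstance(target, Spectrum) else target, dtype=float)
    start, end = region
    if not (0 <= start < end <= x.size):
        raise ValueError("region outside spectrum")
    _shift_segment(x, lag, start, end)

    pos = merged.positions.copy()
    movable = (merged.owners == TARGET) & (pos >= start) & (pos < end)
    moved = pos[movable] + lag
    clamped = int(np.sum((moved < start) | (moved > end - 1)))
    pos[movable] = np.clip(moved, start, end - 1)
    return x, replace(merged, positions=pos), clamped


def build_cluster_tree(merged: MergedPeakList | np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative dendrogram on 1-D peak positions (scipy linkage matrix)."""
    pos = merged.positions if isinstance(merged, MergedPeakList) else np.asarray(merged)
    if pos.size < 2:
        raise ValueError("need at least 2 peaks to build a cluster tree")
    return linkage(np.asarray(pos, dtype=float).reshape(-1, 1), method=method)


def cut_tree_two(tree: np.ndarray, n_leaves: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Split the dendrogram into the two clusters below the root merge.

    Returns boolean masks (left, right) over the leaves; "left" is the
    cluster holding the smaller minimum position index. The masks are
    disjoint, non-empty and exhaustive.
    """
    n = tree.shape[0] + 1 if n_leaves is None else n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (i, j, _, _) in enumerate(tree[:-1]):  # all merges but the root
        members[n + k] = members.pop(int(i)) + members.pop(int(j))
    (a, b) = (np.array(v, dtype=int) for v in members.values())
    if a.min() > b.min():
        a, b = b, a
    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    left[a] = True
    right[b] = True
    return left, right


def satisfied_condition(merged: MergedPeakList, params: AlignmentParams) -> bool:
    """Whether a segment's peak list warrants further recursive alignment.

    Requires peaks of both the reference and the target, and at least
    ``min_peaks_to_recurse`` entries in total.
    """
    if len(merged) < params.min_peaks_to_recurse:
        return False
    return bool(np.any(merged.owners == REF) and np.any(merged.owners == TARGET))


def _overlaps_mask(region: tuple[int, int], mask: tuple[tuple[int, int], ...]) -> bool:
    s, e = region
    return any(s < me and ms < e for ms, me in mask)


def clupa_align(
    ref: Spectrum | np.ndarray,
    target: Spectrum | np.ndarray,
    merged: MergedPeakList,
    params: AlignmentParams | None = None,
) -> tuple[np.ndarray, AlignmentTrace]:
    """Align one target spectrum to the reference with recursive CluPA.

    Implemented iteratively with an explicit work stack; each child segment
    holds strictly fewer peaks than its parent, so termination is
    guaranteed. The dendrogram is built on the merged peak list *after* the
    segment shift has been applied.
    """
    params = params or AlignmentParams()
    r = np.asarray(ref.intensities if isinstance(ref, Spectrum) else ref, dtype=float)
    x = np.array(target.intensities if isinstance(target, Spectrum) else target, dtype=float)
    if r.size != x.size:
        raise ValueError("reference and target must have equal length")
    trace = AlignmentTrace()
    if len(merged) == 0:
        return x, trace

    stack: list[tuple[MergedPeakList, tuple[int, int], int]] = [(merged, (0, x.size), 0)]
    while stack:
        peaks, outer, depth = stack.pop()
        start, end = find_shift_region(x, peaks.positions, outer)
        if _overlaps_mask((start, end), params.exclude_mask):
            lag = 0
        else:
            m = min(params.max_shift, end - start - 1)
            lag = find_shift_step(r[start:end], x[start:end], m) if m >= 1 else 0
        clamped = 0
        if lag != 0:
            _shift_segment(x, lag, start, end)
            pos = peaks.positions.copy()
            movable = (peaks.owners == TARGET) & (pos >= start) & (pos < end)
            moved = pos[movable] + lag
            clamped = int(np.sum((moved < start) | (moved > end - 1)))
            pos[movable] = np.clip(moved, start, end - 1)
            peaks = replace(peaks, positions=pos)
        trace.shifts.append(SegmentShift(start, end, lag, depth, clamped))

        if params.max_depth is not None and depth >= params.max_depth:
            continue
        if len(peaks) < 2:
            continue
        tree = build_cluster_tree(peaks, params.linkage)
        left, right = cut_tree_two(tree, len(peaks))
        lmax = int(peaks.positions[left].max())
        rmin = int(peaks.positions[right].min())
        boundary = min(max((lmax + rmin) // 2 + 1, start + 1), end - 1)
        for mask, child_outer in (
            (left, (start, boundary)),
            (right, (boundary, end)),
        ):
            child = MergedPeakList(
                peaks.positions[mask], peaks.owners[mask], peaks.intensities[mask]
            )
            if not satisfied_condition(child, params):
                continue
            lo, hi = child_outer
            # a boundary clipped into the cluster span: fall back to the span
            lo = min(lo, int(child.positions.min()))
            hi = max(hi, int(child.positions.max()) + 1)
            stack.append((child, (lo, hi), depth + 1))
    return x, trace


def align_set(
    spectra: SpectrumSet,
    peaklists: list[PeakList],
    ref_index: int,
    params: AlignmentParams | None = None,
) -> tuple[SpectrumSet, list[AlignmentTrace | None]]:
    """Align every spectrum of a cohort to the chosen reference.

    The reference row is returned unchanged; a spectrum with no detected
    peaks is passed through unaligned (its trace is None). Row order and ids
    are preserved.
    """
    params = params or AlignmentParams()
    if not (0 <= ref_index < spectra.n_spectra):
        raise ValueError("ref_index out of range")
    if len(peaklists) != spectra.n_spectra:
        raise ValueError("need one peak list per spectrum")
    out = spectra.intensities.copy()
    traces: list[AlignmentTrace | None] = []
    ref_pl = peaklists[ref_index]
    for i in range(spectra.n_spectra):
        if i == ref_index:
            traces.append(AlignmentTrace())
            continue
        if len(peaklists[i]) == 0 or len(ref_pl) == 0:
            traces.append(None)
            continue
        merged = MergedPeakList.from_peaklists(ref_pl, peaklists[i])
        aligned, trace = clupa_align(out[ref_index], spectra.intensities[i], merged, params)
        out[i] = aligned
        traces.append(trace)
    return (
        SpectrumSet(out, ids=list(spectra.ids), ppm=spectra.ppm, groups=spectra.groups),
        traces,
    )


def pairwise_correlation_map(spectra: SpectrumSet) -> tuple[np.ndarray, float]:
    """Pearson correlation between every spectrum pair, plus the off-diagonal mean.

    Zero-variance spectra get 0 against every partner (their own diagonal
    stays 1).
    """
    if spectra.n_spectra < 2:
        raise ValueError("need at least 2 spectra")
    X = spectra.intensities
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    n = corr.shape[0]
    mean = float((corr.sum() - n) / (n * (n - 1)))
    return corr, mean
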