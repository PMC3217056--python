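"""Per-spectrum peak detection: segmented CWT with ridge-line filtering.

A continuous wavelet transform (Mexican-hat mother wavelet) is computed over
a geometric ladder of scales; chains of local coefficient maxima that persist
across scales ("ridge lines") mark real peaks, while noise decorrelates
quickly as the scale grows. Running the detector on the full spectrum at once
is slow and insensitive to weak peaks next to dominant ones, so the spectrum
is cut into equal segments (a power of two wide) and the detector is applied
to a four-segment window sliding one segment at a time; overlap protects
peaks sitting in segment margins. Per-window detections are merged,
deduplicated and filtered by a raw-intensity floor (``baseline_thresh``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import find_peaks

from .io import Spectrum, SpectrumSet

__all__ = [
    "PeakList",
    "CWTOptions",
    "PeakDetectionParams",
    "sliding_windows",
    "detect_peaks_cwt",
    "detect_peaks",
    "detect_peaks_set",
]

DEFAULT_SCALES = (1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64)


@dataclass
class PeakList:
    """Detected peaks of one spectrum: sorted 0-based indices + raw intensities."""

    spectrum_id: str
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size != self.intensities.size:
            raise ValueError("positions and intensities must align")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class CWTOptions:
    """Knobs of the ridge-line CWT detector.

    scales
        Wavelet scales (in points); must be increasing. The ladder should
        reach roughly the half-width of the broadest expected peak.
    min_snr
        Minimum ratio of the strongest ridge coefficient to the local noise
        floor (95th percentile of absolute smallest-scale coefficients).
    min_ridge_length
        Minimum number of scales a ridge must persist over; defaults to a
        quarter of the ladder.
    gap_thresh
        Scales a ridge may skip before being closed.
    noise_window
        Half-width (points) of the neighbourhood used for the noise floor.
    """

    scales: tuple[int, ...] = DEFAULT_SCALES
    min_snr: float = 3.0
    min_ridge_length: int | None = None
    gap_thresh: int = 2
    noise_window: int = 200

    @property
    def ridge_length(self) -> int:
        if self.min_ridge_length is not None:
            return self.min_ridge_length
        return max(2, len(self.scales) // 4)


@dataclass
class PeakDetectionParams:
    segment_size: int = 1024
    baseline_thresh: float = 0.0
    cwt: CWTOptions = field(default_factory=CWTOptions)

    def __post_init__(self) -> None:
        s = self.segment_size
        if s < 4 or (s & (s - 1)) != 0:
            raise ValueError("segment_size must be a power of two and >= 4")
        if self.baseline_thresh < 0:
            raise ValueError("baseline_thresh must be non-negative")


def sliding_windows(spectrum_length: int, segment_size: int) -> list[tuple[int, int]]:
    """Half-open windows of four segments, sliding one segment at a time.

    Consecutive windows start one segment apart; the last window is clipped
    at the spectrum end. Their union covers ``[0, spectrum_length)``.
    """
    if spectrum_length < 1 or segment_size < 1:
        raise ValueError("lengths must be positive")
    if spectrum_length <= 4 * segment_size:
        return [(0, spectrum_length)]
    n_seg = -(-spectrum_length // segment_size)  # ceil
    return [
        (i * segment_size, min(i * segment_size + 4 * segment_size, spectrum_length))
        for i in range(n_seg - 3)
    ]


def _ridge_lines(coef: np.ndarray, scales: np.ndarray, gap_thresh: int):
    """Link per-scale coefficient maxima into ridges, largest scale first.

    Returns a list of ridges, each a list of ``(scale_index, position)``
    ordered from large to small scale.
    """
    n_scales, n = coef.shape
    maxima = []
    for si in range(n_scales):
        dist = max(1, int(scales[si]))
        idx, _ = find_peaks(coef[si], distance=dist)
        maxima.append(idx)

    active: list[dict] = []
    closed: list[list[tuple[int, int]]] = []
    for si in range(n_scales - 1, -1, -1):
        cols = maxima[si]
        taken = np.zeros(cols.size, dtype=bool)
        max_dist = max(3.0, float(scales[si]))
        # deterministic: visit ridges in order of their last position
        for ridge in sorted(active, key=lambda r: r["points"][-1][1]):
            last = ridge["points"][-1][1]
            if cols.size:
                d = np.abs(cols - last)
                d[taken] = np.iinfo(np.int64).max
                j = int(np.argmin(d))
                if d[j] <= max_dist:
                    taken[j] = True
                    ridge["points"].append((si, int(cols[j])))
                    ridge["gap"] = 0
                    continue
            ridge["gap"] += 1
        still = []
        for ridge in active:
            if ridge["gap"] > gap_thresh:
                closed.append(ridge["points"])
            else:
                still.append(ridge)
        active = still
        for j, c in enumerate(cols):
            if not taken[j]:
                active.append({"points": [(si, int(c))], "gap": 0})
    closed.extend(r["points"] for r in active)
    return closed


def detect_peaks_cwt(
    window_intensities: np.ndarray, options: CWTOptions | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect peaks in one window; returns (positions, snr) sorted by position.

    Positions are local maxima supported by ridge lines across the scale
    range that pass the SNR threshold. A window shorter than the smallest
    wavelet support yields an empty result. Deterministic for fixed input.
    """
    opts = options or CWTOptions()
    x = np.asarray(window_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    scales = np.asarray([s for s in opts.scales if s * 4 < x.size], dtype=float)
    if scales.size < 2 or not np.any(x != x[0]):
        return np.empty(0, dtype=int), np.empty(0)

    coef, _ = pywt.cwt(x, scales, "mexh")
    ridges = _ridge_lines(coef, scales, opts.gap_thresh)

    abs_small = np.abs(coef[0])
    pos_list, snr_list = [], []
    for ridge in ridges:
        if len(ridge) < opts.ridge_length:
            continue
        best = max(coef[si, p] for si, p in ridge)
        if best <= 0:
            continue
        si_min, pos = min(ridge)  # point at the smallest scale reached
        lo = max(0, pos - opts.noise_window)
        hi = min(x.size, pos + opts.noise_window + 1)
        noise = np.percentile(abs_small[lo:hi], 95)
        snr = np.inf if noise <= 0 else best / noise
        if snr >= opts.min_snr:
            pos_list.append(pos)
            snr_list.append(snr)

    if not pos_list:
        return np.empty(0, dtype=int), np.empty(0)
    order = np.argsort(pos_list, kind="stable")
    return np.asarray(pos_list, dtype=int)[order], np.asarray(snr_list)[order]


def _dedupe(positions: np.ndarray, intensities: np.ndarray, tol: int = 2):
    """Collapse detections within ``tol`` indices to the most intense one."""
    if positions.size == 0:
        return positions, intensities
    order = np.argsort(positions, kind="stable")
    pos, inten = positions[order], intensities[order]
    keep_pos, keep_int = [], []
    c_start = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] - pos[i - 1] > tol:
            j = c_start + int(np.argmax(inten[c_start:i]))
            keep_pos.append(pos[j])
            keep_int.append(inten[j])
            c_start = i
    return np.asarray(keep_pos, dtype=int), np.asarray(keep_int)


def detect_peaks(spectrum: Spectrum, params: PeakDetectionParams | None = None) -> PeakList:
    """Detect all peaks of one spectrum.

    Applies the CWT detector in sliding windows, maps detections to global
    indices, deduplicates window overlaps (closer than 2 indices: the higher
    raw intensity wins) and drops peaks at or below ``baseline_thresh``.
    Peak intensity is the raw spectrum value at the detected index.
    """
    params = params or PeakDetectionParams()
    x = spectrum.intensities
    all_pos: list[int] = []
    for a, b in sliding_windows(x.size, params.segment_size):
        pos, _ = detect_peaks_cwt(x[a:b], params.cwt)
        all_pos.extend(int(p) + a for p in pos)
    pos = np.asarray(sorted(set(all_pos)), dtype=int)
    inten = x[pos] if pos.size else np.empty(0)
    pos, inten = _dedupe(pos, inten)
    if pos.size:
        keep = inten > params.baseline_thresh
        pos, inten = pos[keep], inten[keep]
    return PeakList(spectrum_id=spectrum.id, positions=pos, intensities=inten)


def detect_peaks_set(
    spectra: SpectrumSet, params: PeakDetectionParams | None = None
) -> list[PeakList]:
    """One PeakList per spectrum, in cohort order."""
    return [detect_peaks(spectra[i], params) for i in range(spectra.n_spectra)]
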