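"""Reference-spectrum selection by the nearest-peak goodness criterion.

The reference is the spectrum whose peak list is, in aggregate, closest to
every other spectrum's peaks. For a candidate S and another spectrum T the
directed distance is the sum over T's peaks of the distance to the nearest
peak of S (asymmetric by construction); the goodness of S is the negative of
this sum over all T != S, and the reference is the argmax. A candidate with
many spurious peaks can win — every extra peak can only shrink nearest-peak
distances — which is a documented property of the criterion, not a bug.
Distances are in index units; ppm is metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import PeakList

__all__ = ["GoodnessTable", "directed_distance", "goodness", "select_reference"]


@dataclass
class GoodnessTable:
    """Per-spectrum goodness (non-positive, index units) and the argmax."""

    spectrum_ids: list[str]
    goodness: np.ndarray
    selected_index: int

    @property
    def selected_id(self) -> str:
        return self.spectrum_ids[self.selected_index]

    def ranking(self) -> np.ndarray:
        """Candidate indices from best (the reference) to worst."""
        # stable sort on -goodness keeps the lowest-index-wins tie rule
        return np.argsort(-self.goodness, kind="stable")


def directed_distance(candidate_peaks: np.ndarray, other_peaks: np.ndarray) -> float:
    """Sum over peaks of ``other`` of the distance to the nearest candidate peak.

    Not symmetric: every peak of ``other`` is charged, but candidate peaks
    with no counterpart cost nothing.
    """
    cand = np.asarray(candidate_peaks, dtype=float)
    other = np.asarray(other_peaks, dtype=float)
    if cand.size == 0:
        raise ValueError("candidate peak list is empty: no nearest peak exists")
    if other.size == 0:
        return 0.0
    cand = np.sort(cand)
    j = np.searchsorted(cand, other)
    right = cand[np.minimum(j, cand.size - 1)]
    left = cand[np.maximum(j - 1, 0)]
    return float(np.sum(np.minimum(np.abs(right - other), np.abs(left - other))))


def goodness(candidate: PeakList, all_spectra: list[PeakList]) -> float:
    """Negative total directed distance from every other spectrum to the candidate."""
    if len(candidate) == 0:
        raise ValueError(f"candidate {candidate.spectrum_id!r} has no peaks")
    total = 0.0
    for other in all_spectra:
        if other is candidate or other.spectrum_id == candidate.spectrum_id:
            continue
        total += directed_distance(candidate.positions, other.positions)
    return -total


def select_reference(all_spectra: list[PeakList]) -> GoodnessTable:
    """Rank all candidates by goodness and pick the best as reference.

    Spectra with empty peak lists are excluded from candidacy (goodness
    ``-inf``) but still contribute distances as targets. Ties at the argmax
    resolve to the lowest spectrum index.
    """
    if len(all_spectra) < 2:
        raise ValueError("need at least 2 spectra to select a reference")
    if all(len(pl) == 0 for pl in all_spectra):
        raise ValueError("all peak lists are empty")
    values = np.full(len(all_spectra), -np.inf)
    for i, cand in enumerate(all_spectra):
        if len(cand) == 0:
            continue
        values[i] = goodness(cand, all_spectra)
    selected = int(np.argmax(values))  # np.argmax takes the first maximum
    return GoodnessTable(
        spectrum_ids=[pl.spectrum_id for pl in all_spectra],
        goodness=values,
        selected_index=selected,
    )
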