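"""Delimited-text I/O for spectrum matrices, peak tables and reports.

Coordinate conventions for the whole package live here:

* spectra are rows of a rectangular matrix, frequency instances are columns;
* internal coordinates are 0-based integer column indices;
* a ppm axis, when present, is presentation-only metadata attached to the
  column axis (strictly monotone, descending allowed);
* all index intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_matrix",
    "write_spectrum_matrix",
    "write_peak_table",
    "read_peak_table",
]


class FormatError(ValueError):
    """A delimited input file violates the rectangular-matrix contract."""


def _validate_ppm(ppm: np.ndarray, n: int) -> np.ndarray:
    ppm = np.asarray(ppm, dtype=float)
    if ppm.shape != (n,):
        raise ValueError(f"ppm axis has length {ppm.size}, expected {n}")
    d = np.diff(ppm)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm axis must be strictly monotone")
    return ppm


@dataclass
class Spectrum:
    """A single 1D spectrum: intensities on an implicit 0-based index axis."""

    intensities: np.ndarray
    id: str = "S0"
    ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("a spectrum needs at least 2 intensity values")
        if self.ppm is not None:
            self.ppm = _validate_ppm(self.ppm, self.intensities.size)

    def __len__(self) -> int:
        return self.intensities.size


@dataclass
class SpectrumSet:
    """An ordered cohort of equal-length spectra (rows of one matrix)."""

    intensities: np.ndarray
    ids: list[str] = field(default_factory=list)
    ppm: np.ndarray | None = None
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        n, p = self.intensities.shape
        if n < 1:
            raise ValueError("a SpectrumSet needs at least one spectrum")
        if p < 2:
            raise ValueError("spectra need at least 2 points")
        if not self.ids:
            self.ids = [f"S{i}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} spectra")
        if self.ppm is not None:
            self.ppm = _validate_ppm(self.ppm, p)
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("group_labels must have one entry per spectrum")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def __len__(self) -> int:
        return self.n_spectra

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.intensities[i], id=self.ids[i], ppm=self.ppm)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], groups: list[str] | None = None) -> "SpectrumSet":
        lengths = {len(s) for s in spectra}
        if len(lengths) != 1:
            raise ValueError(f"spectra have unequal lengths: {sorted(lengths)}")
        return cls(
            np.vstack([s.intensities for s in spectra]),
            ids=[s.id for s in spectra],
            ppm=spectra[0].ppm,
            groups=groups,
        )


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_spectrum_matrix(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool = False,
    id_column: bool = False,
    ppm_row: bool = False,
) -> SpectrumSet:
    """Read a rectangular spectra-by-frequencies matrix from delimited text.

    Parameters
    ----------
    delimiter
        Field separator; auto-detected from the first line (tab vs comma)
        when ``None``.
    has_header
        First line is a column header and is skipped.
    id_column
        First column holds spectrum ids (otherwise ids are positional).
    ppm_row
        The first data row is the ppm axis, not a spectrum.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        if delimiter is None:
            delimiter = _sniff_delimiter(first)
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=delimiter))

    if has_header:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")

    ids: list[str] = []
    values: list[list[float]] = []
    width: int | None = None
    for r, row in enumerate(rows, start=1 + int(has_header)):
        if id_column:
            ids.append(row[0])
            cells = row[1:]
        else:
            cells = row
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}: row {r} has {len(cells)} fields, expected {width}"
            )
        parsed = []
        for c, cell in enumerate(cells, start=1 + int(id_column)):
            try:
                parsed.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {r}, column {c}"
                ) from exc
        values.append(parsed)

    ppm = None
    if ppm_row:
        ppm = np.asarray(values[0])
        values = values[1:]
        if id_column:
            ids = ids[1:]
        if not values:
            raise FormatError(f"{path}: ppm row present but no spectra")

    return SpectrumSet(np.asarray(values), ids=ids if id_column else [], ppm=ppm)


def write_spectrum_matrix(
    spectra: SpectrumSet,
    path: str | Path,
    delimiter: str = ",",
    id_column: bool = False,
    ppm_row: bool = False,
) -> None:
    """Write a SpectrumSet as delimited text with 17 significant digits.

    ``read_spectrum_matrix`` inverts this bit-faithfully (float round-trip).
    """
    if spectra.n_spectra == 0:
        raise ValueError("refusing to write an empty SpectrumSet")
    if ppm_row and spectra.ppm is None:
        raise ValueError("ppm_row requested but the set carries no ppm axis")
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        if ppm_row:
            prefix = ["ppm"] if id_column else []
            w.writerow(prefix + [f"{v:.17g}" for v in spectra.ppm])
        for i in range(spectra.n_spectra):
            prefix = [spectra.ids[i]] if id_column else []
            w.writerow(prefix + [f"{v:.17g}" for v in spectra.intensities[i]])


def write_peak_table(peaks: Iterable, path: str | Path) -> None:
    """Write peak lists as TSV with columns spectrum_id, peak_index, intensity.

    Rows are sorted by (spectrum_id, peak_index); an empty collection yields
    a header-only file.
    """
    records = []
    for pl in peaks:
        for pos, inten in zip(pl.positions, pl.intensities):
            records.append((pl.spectrum_id, int(pos), float(inten)))
    df = pd.DataFrame(records, columns=["spectrum_id", "peak_index", "intensity"])
    df = df.sort_values(["spectrum_id", "peak_index"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> list:
    """Read a peak table back into one PeakList per spectrum_id.

    Returns peak lists ordered by spectrum_id (the table's sort order).
    """
    from .peaks import PeakList  # local import: io must not depend on pywt

    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("spectrum_id", sort=True):
        grp = grp.sort_values("peak_index")
        out.append(
            PeakList(
                spectrum_id=str(sid),
                positions=grp["peak_index"].to_numpy(dtype=int),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return out
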