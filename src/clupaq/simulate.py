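"""Synthetic 1D NMR cohorts with known ground truth.

Spectra are sums of Lorentzian lines — the natural line shape of NMR
resonances — h * w^2 / ((x - a)^2 + w^2) with apex a, height h and
half-width-at-half-maximum w, plus additive Gaussian noise. Cohorts carry
controlled misalignment (integer shifts, global or per region, so the truth
is exact for CluPA's rigid integer shifts), optional group-specific
intensity effects, and a full :class:`SyntheticTruth` record that, together
with the seed, determines the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Spectrum, SpectrumSet
from .quant import GroupDesign

__all__ = [
    "Peak",
    "SyntheticTruth",
    "lorentzian",
    "make_spectrum",
    "make_misaligned_cohort",
    "make_group_effect_cohort",
]


@dataclass(frozen=True)
class Peak:
    """One template line: apex index, height, half-width (points)."""

    apex: int
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("peak width must be >= 1 point")


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct a cohort and score a method on it."""

    length: int
    template_peaks: list[Peak]
    shifts: np.ndarray  # (n_spectra,) global or (n_spectra, n_regions)
    regions: list[tuple[int, int]] | None
    noise_sd: float
    seed: int
    apexes: np.ndarray = field(default=None)  # (n_spectra, n_peaks) true apex per spectrum
    effect_columns: np.ndarray | None = None
    effect_size: float = 0.0
    effect_group: str | None = None


def lorentzian(length: int, apex: float, height: float, width: float) -> np.ndarray:
    x = np.arange(length, dtype=float)
    return height * width**2 / ((x - apex) ** 2 + width**2)


def make_spectrum(
    length: int,
    peaks: list[Peak] | list[tuple],
    noise_sd: float = 0.0,
    seed: int = 0,
    id: str = "S0",
) -> Spectrum:
    """Sum of Lorentzian lines plus Gaussian noise; deterministic given seed.

    Overlapping apexes are allowed (overlap-region fixtures rely on them).
    """
    peaks = [p if isinstance(p, Peak) else Peak(*p) for p in peaks]
    for p in peaks:
        if not 0 <= p.apex < length:
            raise ValueError(f"apex {p.apex} outside [0, {length})")
    x = np.zeros(length)
    for p in peaks:
        x += lorentzian(length, p.apex, p.height, p.width)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, size=length)
    return Spectrum(x, id=id)


def _shifted_peaks(
    peaks: list[Peak], shift: np.ndarray, regions: list[tuple[int, int]] | None, length: int
) -> list[Peak]:
    out = []
    for p in peaks:
        if regions is None:
            s = int(shift)
        else:
            s = 0
            for r, (a, b) in enumerate(regions):
                if a <= p.apex < b:
                    s = int(shift[r])
                    break
        apex = int(np.clip(p.apex + s, 0, length - 1))
        out.append(Peak(apex, p.height, p.width))
    return out


def make_misaligned_cohort(
    template_peaks: list[Peak] | list[tuple],
    n_spectra: int,
    length: int = 8192,
    shift_model: str = "global",
    shift_range: tuple[int, int] = (-50, 50),
    regions: list[tuple[int, int]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumSet, SyntheticTruth]:
    """Cohort sharing one peak template, each spectrum randomly shifted.

    ``shift_model="global"`` draws one integer shift per spectrum from the
    closed ``shift_range``; ``"per-region"`` draws one shift per (disjoint)
    region independently, emulating local chemical-shift variation.
    """
    template = [p if isinstance(p, Peak) else Peak(*p) for p in template_peaks]
    if shift_model not in ("global", "per-region"):
        raise ValueError("shift_model must be 'global' or 'per-region'")
    if shift_model == "per-region":
        if not regions:
            raise ValueError("per-region shifts need regions")
        srt = sorted(regions)
        for (a0, b0), (a1, b1) in zip(srt, srt[1:]):
            if b0 > a1:
                raise ValueError(f"regions {(a0, b0)} and {(a1, b1)} overlap")
    else:
        regions = None

    rng = np.random.default_rng(seed)
    lo, hi = shift_range
    shape = (n_spectra,) if regions is None else (n_spectra, len(regions))
    shifts = rng.integers(lo, hi + 1, size=shape)

    spectra, apexes = [], []
    for i in range(n_spectra):
        pk = _shifted_peaks(template, shifts[i], regions, length)
        apexes.append([p.apex for p in pk])
        spectra.append(
            make_spectrum(length, pk, noise_sd, seed=int(rng.integers(0, 2**31)), id=f"S{i}")
        )
    truth = SyntheticTruth(
        length=length,
        template_peaks=template,
        shifts=shifts,
        regions=regions,
        noise_sd=noise_sd,
        seed=seed,
        apexes=np.asarray(apexes, dtype=int),
    )
    return SpectrumSet.from_spectra(spectra), truth


def make_group_effect_cohort(
    template_peaks: list[Peak] | list[tuple],
    n_per_group: int,
    length: int = 2048,
    effect_columns: np.ndarray | list[int] | None = None,
    effect_size: float = 0.0,
    noise_sd: float = 1.0,
    groups: tuple[str, str] = ("A", "B"),
    shift_range: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> tuple[SpectrumSet, GroupDesign, SyntheticTruth]:
    """Two-group cohort with an intensity effect on designated columns.

    The second group's spectra get a mean offset of ``effect_size *
    noise_sd`` added at ``effect_columns``; with ``effect_size=0`` the
    groups are exchangeable. Misalignment is off by default (quantitation
    assumes aligned input) but available through ``shift_range``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive (effects are in SD units)")
    sset, truth = make_misaligned_cohort(
        template_peaks,
        n_spectra=2 * n_per_group,
        length=length,
        shift_model="global",
        shift_range=shift_range,
        noise_sd=noise_sd,
        seed=seed,
    )
    labels = [groups[0]] * n_per_group + [groups[1]] * n_per_group
    cols = np.asarray(effect_columns if effect_columns is not None else [], dtype=int)
    X = sset.intensities
    if cols.size and effect_size != 0.0:
        X[n_per_group:, cols[None, :]] += effect_size * noise_sd
    truth.effect_columns = cols
    truth.effect_size = effect_size
    truth.effect_group = groups[1]
    out = SpectrumSet(X, ids=list(sset.ids), groups=labels)
    return out, GroupDesign(labels), truth
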