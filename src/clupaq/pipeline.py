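"""End-to-end workflow: detect -> reference -> align -> quantify.

A run is fully reproducible from its :class:`RunConfig` plus the input
matrix; every intermediate is written as delimited text and a JSON manifest
records versions, parameters and the seed.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clupa import AlignmentParams, align_set
from .io import SpectrumSet, read_spectrum_matrix, write_peak_table, write_spectrum_matrix
from .peaks import CWTOptions, PeakDetectionParams, detect_peaks_set
from .quant import GroupDesign, bw_analysis
from .reference import select_reference

log = logging.getLogger("clupaq")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run (INI-serialisable)."""

    input_path: str
    output_dir: str
    groups: list[str] | None = None
    seed: int = 0
    # detect
    segment_size: int = 1024
    baseline_thresh: float = 0.0
    min_snr: float = 3.0
    scales: tuple[int, ...] | None = None
    # align
    reference: str = "auto"  # or an integer row index
    max_shift: int = 100
    linkage: str = "average"
    exclude: tuple[tuple[int, int], ...] = ()
    # quantify
    skip_quantify: bool = False
    alpha: float = 0.05
    n_bootstrap: int = 1000
    n_peaks: int | None = None  # None: average detected peak count
    pooled_null: bool = False

    @classmethod
    def from_ini(cls, path: str | Path, **overrides) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(path)

        def get(section, key, cast, default):
            if cp.has_option(section, key):
                return cast(cp.get(section, key))
            return default

        cfg = cls(
            input_path=cp.get("io", "input"),
            output_dir=cp.get("io", "output_dir"),
            seed=get("io", "seed", int, 0),
            segment_size=get("detect", "segment_size", int, 1024),
            baseline_thresh=get("detect", "baseline_thresh", float, 0.0),
            min_snr=get("detect", "min_snr", float, 3.0),
            reference=get("align", "reference", str, "auto"),
            max_shift=get("align", "max_shift", int, 100),
            linkage=get("align", "linkage", str, "average"),
            alpha=get("quantify", "alpha", float, 0.05),
            n_bootstrap=get("quantify", "n_bootstrap", int, 1000),
        )
        if cp.has_option("quantify", "groups"):
            cfg.groups = cp.get("quantify", "groups").split(",")
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def _write_trace(traces, ids, path: Path) -> None:
    rows = []
    for sid, tr in zip(ids, traces):
        if tr is None:
            rows.append((sid, -1, -1, 0, -1, "no-peaks"))
            continue
        for s in tr.shifts:
            rows.append((sid, s.start, s.end, s.lag, s.depth, ""))
    pd.DataFrame(
        rows, columns=["spectrum_id", "start", "end", "lag", "depth", "note"]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, spectra: SpectrumSet | None = None) -> dict:
    """Execute the four workflow stages and write all artifacts.

    Returns the manifest dict. ``spectra`` may be passed directly to skip
    the input-reading stage (used by the simulate subcommand and tests).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spectra is None:
        spectra = read_spectrum_matrix(config.input_path)
    if config.groups is not None:
        spectra.groups = list(config.groups)

    # 1. peak detection
    cwt = CWTOptions(min_snr=config.min_snr, **(
        {"scales": tuple(config.scales)} if config.scales else {}
    ))
    det = PeakDetectionParams(
        segment_size=config.segment_size, baseline_thresh=config.baseline_thresh, cwt=cwt
    )
    try:
        peaklists = detect_peaks_set(spectra, det)
    except Exception as exc:
        raise RuntimeError(f"stage detect failed: {exc}") from exc
    write_peak_table(peaklists, out / "peaks.tsv")
    log.info("detected %s peaks", sum(len(p) for p in peaklists))

    # 2. reference selection
    if config.reference == "auto":
        table = select_reference(peaklists)
        ref_index = table.selected_index
        pd.DataFrame(
            {"spectrum_id": table.spectrum_ids, "goodness": table.goodness,
             "selected": [i == ref_index for i in range(len(table.goodness))]}
        ).to_csv(out / "goodness.tsv", sep="\t", index=False)
    else:
        ref_index = int(config.reference)
        (out / "goodness.tsv").write_text(
            "spectrum_id\tgoodness\tselected\n"
            f"{spectra.ids[ref_index]}\tNA\tTrue\n"
        )
    log.info("reference: row %d (%s)", ref_index, spectra.ids[ref_index])

    # 3. alignment
    params = AlignmentParams(
        max_shift=config.max_shift, linkage=config.linkage, exclude_mask=config.exclude
    )
    try:
        aligned, traces = align_set(spectra, peaklists, ref_index, params)
    except Exception as exc:
        raise RuntimeError(f"stage align failed: {exc}") from exc
    write_spectrum_matrix(aligned, out / "aligned.csv")
    _write_trace(traces, spectra.ids, out / "trace.tsv")

    # 4. quantitation
    n_regions = None
    if not config.skip_quantify and spectra.groups is not None:
        n_peaks = config.n_peaks
        if n_peaks is None:
            n_peaks = max(1, round(np.mean([len(p) for p in peaklists])))
        design = GroupDesign(spectra.groups)
        profile = bw_analysis(
            aligned, design, alpha=config.alpha, n_peaks=n_peaks,
            n_bootstrap=config.n_bootstrap, seed=config.seed,
            pooled_null=config.pooled_null,
        )
        pd.DataFrame(
            {"column": np.arange(profile.bw.size), "bw": profile.bw,
             "critical": profile.critical,
             "significant": profile.bw > profile.critical,
             "flag": profile.flags}
        ).to_csv(out / "bw_report.tsv", sep="\t", index=False, float_format="%.12g")
        pd.DataFrame(profile.regions, columns=["start", "end"]).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
        n_regions = len(profile.regions)

    manifest = {
        "clupaq_version": __version__,
        "seed": config.seed,
        "reference_index": ref_index,
        "n_spectra": spectra.n_spectra,
        "n_points": spectra.n_points,
        "n_significant_regions": n_regions,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
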