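"""Pick the alignment reference by the goodness criterion.

Simulates a cohort of shifted copies of one template, detects peaks, and
ranks each spectrum by goodness = minus the summed nearest-peak distances
from every other spectrum. The winner (goodness closest to 0) is the most
central spectrum — the best template to align everything else against.
"""

from clupaq import Peak, PeakDetectionParams, detect_peaks_set, make_misaligned_cohort, select_reference

cohort, truth = make_misaligned_cohort(
    [Peak(500, 100.0, 6.0), Peak(1500, 80.0, 8.0), Peak(2600, 120.0, 6.0)],
    n_spectra=7,
    length=4096,
    shift_range=(-40, 40),
    noise_sd=4.0,
    seed=3,
)
peaklists = detect_peaks_set(cohort, PeakDetectionParams(1024, baseline_thresh=20.0))
table = select_reference(peaklists)

print("true global shift vs goodness (index units, 0 = perfectly central):")
for sid, shift, g in zip(table.spectrum_ids, truth.shifts, table.goodness):
    marker = "  <- reference" if sid == table.selected_id else ""
    print(f"  {sid}: shift {shift:+3d}, goodness {g:8.1f}{marker}")
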