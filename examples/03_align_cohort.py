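"""Align a misaligned cohort with CluPA and quantify the improvement.

Each simulated spectrum carries a random global shift of up to 50 points.
After recursive cluster-based alignment the mean pairwise Pearson
correlation between spectra rises sharply — the standard diagnostic that
corresponding peaks now share columns.
"""

from clupaq import (
    AlignmentParams,
    Peak,
    PeakDetectionParams,
    align_set,
    detect_peaks_set,
    make_misaligned_cohort,
    pairwise_correlation_map,
    select_reference,
)

cohort, _ = make_misaligned_cohort(
    [Peak(a, h, w) for a, h, w in
     [(600, 100, 6), (1400, 70, 8), (2500, 130, 5), (3300, 90, 7), (3900, 60, 9)]],
    n_spectra=10,
    length=4608,
    shift_range=(-50, 50),
    noise_sd=4.0,
    seed=5,
)
peaklists = detect_peaks_set(cohort, PeakDetectionParams(512, baseline_thresh=20.0))
ref_index = select_reference(peaklists).selected_index
aligned, traces = align_set(cohort, peaklists, ref_index, AlignmentParams(max_shift=100))

_, before = pairwise_correlation_map(cohort)
_, after = pairwise_correlation_map(aligned)
applied = [s.lag for t in traces if t is not None for s in t.shifts if s.lag != 0]

print(f"reference spectrum:          row {ref_index}")
print(f"segment shifts applied:      {len(applied)} (largest |lag| = {max(map(abs, applied))})")
print(f"mean pairwise correlation:   {before:.3f} before -> {after:.3f} after")
print("a rise toward 1 means peak columns are now comparable across spectra")
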