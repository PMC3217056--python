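"""Detect peaks in a simulated 1D NMR spectrum.

Builds a three-line spectrum with additive noise, runs the segmented CWT
detector and prints where the peaks were found. The detected indices should
sit within a point or two of the true apexes (400, 1200, 3000); the
intensities are raw spectrum values at those indices, which is what the
baseline threshold filters on.
"""

from clupaq import Peak, PeakDetectionParams, detect_peaks
from clupaq.simulate import make_spectrum

spectrum = make_spectrum(
    4096,
    [Peak(400, 120.0, 6.0), Peak(1200, 60.0, 9.0), Peak(3000, 200.0, 5.0)],
    noise_sd=3.0,
    seed=1,
)
params = PeakDetectionParams(segment_size=1024, baseline_thresh=20.0)
peaks = detect_peaks(spectrum, params)

print(f"true apexes:      400, 1200, 3000")
print(f"detected indices: {', '.join(map(str, peaks.positions))}")
print(f"raw intensities:  {', '.join(f'{v:.1f}' for v in peaks.intensities)}")
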