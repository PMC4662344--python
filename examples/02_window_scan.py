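"""Sliding-window scan: find the climate period that best predicts phenology.

Builds a synthetic daily temperature series whose year-to-year signal lives
in Julian days 97-129, ties annual mean laying dates to that window's mean
temperature (correlation ~0.75), and scans all 3,828 candidate windows
(spans 5-91 days inside days 60-151) for the strongest Pearson correlation.
"""

import numpy as np

from phenoplast.simulate import simulate_window_scan_dataset
from phenoplast.windows import scan_windows

rng = np.random.default_rng(1)
series, phenology = simulate_window_scan_dataset(rng)

scan = scan_windows(series, phenology)
print(f"scanned {len(scan)} candidate windows over {len(phenology)} years\n")
print("top five windows by |r|:")
print(scan.head(5).to_string(index=False))

top = scan.iloc[0]
print(
    f"\nbest window: Julian days {int(top.start_day)}-{int(top.end_day)} "
    f"(r = {top.r:.3f}, p = {top.p:.4f}); the signal was planted in days 97-129."
)
print(
    "A negative r means warmer springs -> earlier laying. With only 10 years "
    "the top-ranked window is noisy; windows overlapping the planted period "
    "should dominate the top ranks."
)
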