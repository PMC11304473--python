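"""Compute the 17 flood/drainage/transition descriptors for one field.

A ten-day toy record is enough to exercise every descriptor family:
flooded-day percentages (A), drained-day percentages and dry-spell
durations (B), and rapid-transition counts (C).
"""

import pandas as pd

from paddyghg import WaterLevelSeries, compute_descriptors

levels = [3, 6, 11, 0, -4, -8, -12, 6, -6, -2]
series = WaterLevelSeries(
    "toy", pd.date_range("2022-07-01", periods=len(levels), freq="D"), levels
)
desc = compute_descriptors(series)
print(desc.as_series().round(2).to_string())
print()
print("A1=40: 4 of 10 days ponded.  A2-A4: one flooded day in 0-5 cm, two")
print("in 5-10 cm, one above 10 cm.  Two flood events (C1=2): a 3-day spell")
print("and a 1-day spell (A5=A6=50).  C2=1: the level fell from +6 to -6 cm")
print("in a single day; C3=2 counts all drops larger than 10 cm/day.")
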