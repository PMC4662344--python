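"""Calendar conventions and the photoperiod contrast across the study area.

Laying dates are recorded as Julian days (January 1 = day 1). The nest-box
network spans ~80 km of latitude around 45.57 N; because day length grows
with latitude in late May, birds at the network's northern edge experience a
few more minutes of daylight on the season's mean laying date than birds at
the southern edge — a spatial photoperiod cue comparable in size to the
day-to-day change.
"""

import numpy as np

from phenoplast import day_length_minutes, julian_day

print("Julian day of May 20 (mean laying date):", julian_day("2005-05-20"))
print("Scan frame: March 1 =", julian_day("2005-03-01"), " May 31 =", julian_day("2005-05-31"))

half_deg = 40.0 / (2 * np.pi * 6371.0 / 360.0)  # 40 km in degrees of latitude
south = day_length_minutes(45.57 - half_deg, "2005-05-20")
north = day_length_minutes(45.57 + half_deg, "2005-05-20")
print(f"\nDay length May 20, southern edge: {south:.1f} min, northern edge: {north:.1f} min")
print(f"Spatial contrast over 80 km of latitude: {north - south:.1f} min (~5 min)")

d1 = day_length_minutes(45.57, "2005-05-20")
d2 = day_length_minutes(45.57, "2005-05-21")
print(f"Temporal contrast May 20 -> May 21 at the centroid: {d2 - d1:.1f} min (~2 min)")
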