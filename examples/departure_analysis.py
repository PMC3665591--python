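"""Summarize the nocturnal departures of the packaged radio-tracking table.

The 30 tracked birds yield 16 timed departures and 15 departure directions.
The circular mean and mean resultant length R describe where and how tightly
the directions cluster; the Rayleigh p-value tests uniformity; the linear
summaries show how soon after sunset (and at what sun elevation) birds left.
"""

import json

from wheatear_stopover.pipeline import run_departure_analysis
from wheatear_stopover.synthdata import table1_fixture

report = run_departure_analysis(table1_fixture(), declination=11.19, seed=0)
print(json.dumps(report, indent=1))
print()
d = report["direction"]
t = report["minutes_after_sunset"]
print(
    f"{d['n']} directions cluster around {d['mean_direction']:.0f} deg "
    f"(R = {d['R']:.2f}, Rayleigh p = {d['rayleigh_p']:.1e}): a tight "
    "south-westerly heading, far from the 337 deg great-circle prediction."
)
print(
    f"{t['n']} departures averaged {t['mean']:.0f} +/- {t['sd']:.0f} min after "
    "sunset - birds leave in twilight, maximizing the night available for flight."
)
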