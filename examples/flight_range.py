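"""Fuel loads, flight durations and nocturnal flight range.

A fuel load f (fuel mass as a fraction of lean mass) buys 100 ln(1+f) hours
of flight.  The realized nocturnal range is further limited by the time left
between departure and sunrise, and stretched or shrunk by the tailwind.
"""

from wheatear_stopover import energetics as en

for f in (0.21, 0.25, 0.42):
    print(f"fuel load {f:.2f}  ->  potential flight {en.flight_duration(f):5.1f} h")

need = en.fuel_for_duration(9.0)
print(f"\nfuel needed for a 9-h flight (longest study night): {need:.3f}")
print(f"mean departure load 0.42 is {0.42 / need:.1f}x that requirement")

r = en.nocturnal_flight_range(
    fuel_load=0.42, minutes_after_sunset=85, night_length_min=540,
    tailwind_kmh=10.0,
)
print(
    f"\ndeparting 85 min into a 540-min night with fuel 0.42 and a 10 km/h "
    f"tailwind:\n  flight {r.nocturnal_flight_duration:.2f} h (time-limited, "
    f"fuel allowed {r.fuel_limited_duration:.1f} h), range {r.total_range:.0f} km"
)

f_star = en.time_minimizer_departure_load(0.04, 3.0)
print(
    f"\ntime-minimizer optimum at deposition rate 0.04/day, 3-day settling: "
    f"departure load {f_star:.2f}"
)
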