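"""Reconstruct hourly temperatures for one winter day from Tmin/Tmax.

A mid-January day at 29.7 °N (northern-Florida latitude): daytime
follows a sine from Tmin at sunrise through Tmax in mid-afternoon,
night follows a logarithmic decay toward the next morning's Tmin.
"""

import datetime as dt

import thermoscape as ts
from thermoscape.hourly import DayWeather

lat = 29.68
days = [
    DayWeather(dt.date(2002, 1, 14), tmin=4.0, tmax=14.0),
    DayWeather(dt.date(2002, 1, 15), tmin=5.0, tmax=16.0),
    DayWeather(dt.date(2002, 1, 16), tmin=2.0, tmax=12.0),
]
solar = ts.solar_times(lat, days[1].date)
print(f"Jan 15 at {lat} °N: sunrise {solar.sunrise:.2f} h, "
      f"sunset {solar.sunset:.2f} h, daylength {solar.daylength:.2f} h")

hourly = ts.hourly_temperatures(days[0], days[1], days[2], solar)
print("\nhour  temp °C")
for h, t in enumerate(hourly.temps):
    tag = "  (daylight)" if solar.sunrise <= h <= solar.sunset else ""
    print(f"  {h:02d}   {t:6.2f}{tag}")
print("\nThe daytime maximum equals the day's Tmax; overnight the series "
      "decays toward the next day's Tmin, so cold runs can span midnight.")
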