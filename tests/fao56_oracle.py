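"""Independent scalar FAO-56 Penman-Monteith reference ETo.

Written line by line from the FAO Irrigation and Drainage Paper 56 worked
equation sheet as an oracle for the vectorised implementation in
``maizegap.climate``.  Deliberately plain scalar ``math`` code with the
intermediate quantities named as in the equation sheet; shares only the
package's documented conventions (mean-RH actual vapour pressure, 10 m -> 2 m
log-profile wind conversion, G = 0, result floored at zero).
"""

import math


def eto_day(
    tmin: float,
    tmax: float,
    rh_mean: float,
    wind10: float,
    srad: float,
    latitude_deg: float,
    doy: int,
    elevation: float = 0.0,
) -> float:
    tmean = (tmin + tmax) / 2.0

    # saturation vapour pressure (Eq. 11-12) and actual vapour pressure (Eq. 19)
    def e0(t):
        return 0.6108 * math.exp(17.27 * t / (t + 237.3))

    es = (e0(tmax) + e0(tmin)) / 2.0
    ea = rh_mean / 100.0 * es

    # slope of the saturation vapour pressure curve (Eq. 13)
    slope = 4098.0 * e0(tmean) / (tmean + 237.3) ** 2

    # atmospheric pressure (Eq. 7) and psychrometric constant (Eq. 8)
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    # wind speed at 2 m (Eq. 47)
    u2 = wind10 * 4.87 / math.log(67.8 * 10.0 - 5.42)

    # extraterrestrial radiation (Eq. 21-25)
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi / 365.0 * doy)
    delta = 0.409 * math.sin(2.0 * math.pi / 365.0 * doy - 1.39)
    arg = -math.tan(phi) * math.tan(delta)
    arg = max(-1.0, min(1.0, arg))
    omega_s = math.acos(arg)
    ra = (
        24.0 * 60.0 / math.pi
        * 0.0820
        * dr
        * (
            omega_s * math.sin(phi) * math.sin(delta)
            + math.cos(phi) * math.cos(delta) * math.sin(omega_s)
        )
    )
    ra = max(ra, 0.0)

    # clear-sky and net radiation (Eq. 37-40)
    rso = (0.75 + 2e-5 * elevation) * ra
    rel = srad / rso if rso > 0.0 else 0.5
    rel = max(0.05, min(1.0, rel))
    rns = (1.0 - 0.23) * srad
    sigma = 4.903e-9
    rnl = (
        sigma
        * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
        / 2.0
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rnl = max(rnl, 0.0)  # longwave loss floored at zero under heavy overcast
    rn = rns - rnl

    # combination equation (Eq. 6), G = 0 at daily scale
    num = 0.408 * slope * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = slope + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)
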