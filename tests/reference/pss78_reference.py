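"""Independent scalar transcription of PSS-78 for cross-checking.

Transcribed directly from the published algorithm (Lewis & Perkin 1980;
UNESCO Technical Papers in Marine Science 44) with the Hill et al. (1986)
extension below salinity 2.  Deliberately written scalar-by-scalar, with
explicit power terms, and kept free of any import from the package under
test so the two routes to a salinity value stay independent.

Check values carried by the standard itself:
  * R = 1, t = 15 degC, p = 0        -> S = 35.0000
  * R = 1.888091, t = 40, p = 10000  -> S = 40.0000  (SAL78 test case)
"""

import math

C35_15_0 = 42.914  # mS/cm


def salinity_from_conductivity(cond_ms_cm: float, t: float, p: float = 0.0) -> float:
    """Practical salinity from in-situ conductivity (mS/cm), temperature, pressure."""
    R = cond_ms_cm / C35_15_0
    return salinity_from_ratio(R, t, p)


def salinity_from_ratio(R: float, t: float, p: float = 0.0) -> float:
    # rt: conductivity ratio of standard seawater at t relative to 15 degC
    rt = (0.6766097
          + 2.00564e-2 * t
          + 1.104259e-4 * t ** 2
          - 6.9698e-7 * t ** 3
          + 1.0031e-9 * t ** 4)
    # Rp: pressure correction
    Rp = 1.0 + (p * (2.070e-5 - 6.370e-10 * p + 3.989e-15 * p ** 2)
                / (1.0 + 3.426e-2 * t + 4.464e-4 * t ** 2
                   + (4.215e-1 - 3.107e-3 * t) * R))
    Rt = R / (Rp * rt)
    s = _sal(Rt, t)
    if s < 2.0:
        s -= _hill_correction(Rt, t)
    return s


def _sal(Rt: float, t: float) -> float:
    sr = math.sqrt(Rt) if Rt > 0 else 0.0
    s = (0.0080
         - 0.1692 * sr
         + 25.3851 * sr ** 2
         + 14.0941 * sr ** 3
         - 7.0261 * sr ** 4
         + 2.7081 * sr ** 5)
    ds = (0.0005
          - 0.0056 * sr
          - 0.0066 * sr ** 2
          - 0.0375 * sr ** 3
          + 0.0636 * sr ** 4
          - 0.0144 * sr ** 5)
    return s + ds * (t - 15.0) / (1.0 + 0.0162 * (t - 15.0))


def _hill_correction(Rt: float, t: float) -> float:
    x = 400.0 * Rt
    y = 100.0 * Rt
    ft = (t - 15.0) / (1.0 + 0.0162 * (t - 15.0))
    return (0.0080 / (1.0 + 1.5 * x + x ** 2)
            + 0.0005 * ft / (1.0 + math.sqrt(y) + y ** 1.5))


def conductivity_from_salinity(s: float, t: float, p: float = 0.0,
                               tol: float = 1e-12) -> float:
    """Invert the scale by bisection (for building test grids)."""
    lo, hi = 0.0, 2.0 * C35_15_0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if salinity_from_conductivity(mid, t, p) < s:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
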