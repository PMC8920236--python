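"""Physical and derived quantities.

Covers the arithmetic layer of the integration: electrical conductivity to
practical salinity (PSS-78 with the low-salinity extension), net volume
from flowmeter counts, catch per unit effort, carbon-mass biomass, and the
matched-gear undersampling comparison between the mesozooplankton net and
the microzooplankton pump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DomainError

__all__ = [
    "ec_to_salinity",
    "specific_conductance_to_in_situ",
    "flowmeter_volume",
    "compute_cpue",
    "BiomassEntry",
    "biomass",
    "read_biomass_csv",
    "write_biomass_csv",
    "flag_undersampled",
    "apply_undersampled_flags",
    "write_undersampled_csv",
    "read_undersampled_csv",
]

# --- PSS-78 --------------------------------------------------------------
#
# Practical Salinity Scale 1978 (Lewis & Perkin): salinity as a polynomial
# in the square root of the conductivity ratio Rt, valid for 2 <= S <= 42,
# with the low-salinity extension (Hill et al. 1986) below S = 2 which
# drives S to exactly 0 at zero conductivity.  Temperatures are taken on
# the 1968 scale the polynomials were fitted to; the difference from ITS-90
# (< 0.01 degC over the field range) is far below probe accuracy.

_C35_15_0 = 42.914  # conductivity of KCl-standard seawater, mS/cm

_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_K = 0.0162
_C = (0.6766097, 2.00564e-2, 1.104259e-4, -6.9698e-7, 1.0031e-9)
_D = (3.426e-2, 4.464e-4, 4.215e-1, -3.107e-3)
_E = (2.070e-5, -6.370e-10, 3.989e-15)


def _rt_of_t(t):
    """Temperature dependence of standard-seawater conductivity, rt(t)."""
    return _C[0] + t * (_C[1] + t * (_C[2] + t * (_C[3] + t * _C[4])))


def _poly_sqrt_rt(coeffs, srt):
    out = np.zeros_like(srt)
    for c in reversed(coeffs):
        out = out * srt + c
    return out


def specific_conductance_to_in_situ(ec25, temperature):
    """Convert specific conductance (normalized to 25 degC) to in-situ.

    Field probes (YSI) typically report specific conductance; PSS-78 wants
    the conductivity at the measured temperature.  The rescaling uses the
    standard-seawater temperature function rt(t)/rt(25), which is exact at
    S = 35 and within instrument accuracy elsewhere.
    """
    ec25 = np.asarray(ec25, dtype=float)
    t = np.asarray(temperature, dtype=float)
    return ec25 * _rt_of_t(t) / _rt_of_t(25.0)


def ec_to_salinity(
    conductivity,
    temperature,
    pressure=0.0,
    *,
    input_type: str = "specific_conductance_25c",
):
    """Electrical conductivity (mS/cm) to practical salinity.

    Parameters
    ----------
    conductivity
        Conductivity in mS/cm.  By default interpreted as specific
        conductance standardized to 25 degC (the common field-probe
        convention); pass ``input_type="in_situ"`` for conductivity at the
        measured temperature.
    temperature
        Water temperature in degC (valid -2..40).
    pressure
        Gauge pressure in decibars (0 for surface grabs).

    Returns practical salinity (dimensionless).  Values above 42 are
    outside the scale's validity and trigger a warning but are returned.
    """
    cond = np.asarray(conductivity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if np.any(cond < 0):
        raise DomainError("negative conductivity")
    if np.any((t < -2) | (t > 40)):
        raise DomainError("temperature outside -2..40 degC")
    if input_type == "specific_conductance_25c":
        cond = specific_conductance_to_in_situ(cond, t)
    elif input_type != "in_situ":
        raise ConfigError(f"unknown input_type: {input_type!r}")

    R = cond / _C35_15_0
    rt = _rt_of_t(t)
    p = np.asarray(pressure, dtype=float)
    Rp = 1.0 + p * (_E[0] + p * (_E[1] + p * _E[2])) / (
        1.0 + _D[0] * t + _D[1] * t * t + (_D[2] + _D[3] * t) * R
    )
    Rt = R / (Rp * rt)
    srt = np.sqrt(np.clip(Rt, 0.0, None))
    ft = (t - 15.0) / (1.0 + _K * (t - 15.0))
    S = _poly_sqrt_rt(_A, srt) + ft * _poly_sqrt_rt(_B, srt)

    # low-salinity extension: subtract the zero offset smoothly below S=2
    x = 400.0 * Rt
    y = 100.0 * Rt
    corr = _A[0] / (1.0 + 1.5 * x + x * x) + _B[0] * ft / (1.0 + np.sqrt(y) + y * np.sqrt(y))
    S = np.where(S < 2.0, S - corr, S)

    if np.any(S > 42.0):
        warnings.warn("salinity above 42: outside PSS-78 validity", stacklevel=2)
    return S if S.ndim else float(S)


# --- volume / CPUE / biomass --------------------------------------------


def flowmeter_volume(rotation_count, flowmeter_constant, mouth_area):
    """Volume sampled by a net tow, m^3.

    The flowmeter in the net mouth converts rotations to distance towed;
    distance times mouth area is the water column filtered:
    ``volume = count * constant * area``.
    """
    area = np.asarray(mouth_area, dtype=float)
    if np.any(area == 0):
        raise ConfigError("net mouth area must be positive")
    count = np.asarray(rotation_count, dtype=float)
    const = np.asarray(flowmeter_constant, dtype=float)
    if np.any(count < 0) or np.any(const < 0) or np.any(area < 0):
        raise DomainError("flowmeter inputs must be non-negative")
    out = count * const * area
    return out if out.ndim else float(out)


def compute_cpue(organisms_counted, subsample_fraction, volume):
    """Catch per unit effort, individuals per m^3.

    ``count / subsample_fraction`` scales the enumerated aliquots back to
    the whole sample; dividing by the volume filtered gives a density.
    """
    count = np.asarray(organisms_counted, dtype=float)
    frac = np.asarray(subsample_fraction, dtype=float)
    vol = np.asarray(volume, dtype=float)
    if np.any((frac <= 0) | (frac > 1)):
        raise DomainError("subsample_fraction must be in (0, 1]")
    if np.any(vol <= 0):
        raise DomainError("volume must be positive")
    if np.any(count < 0):
        raise DomainError("negative count")
    out = count / frac / vol
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BiomassEntry:
    """Literature carbon mass for one taxon/life stage."""

    taxlifestage: str
    carbon_mass_micrograms: float
    reference: str = ""

    def __post_init__(self):
        if not self.carbon_mass_micrograms > 0:
            raise DomainError(f"{self.taxlifestage}: carbon mass must be positive")


def biomass(catch: pd.DataFrame, table: Iterable[BiomassEntry]) -> pd.DataFrame:
    """Attach carbon concentration (ug C per m^3) to a catch table.

    Biomass = CPUE x per-individual carbon mass.  Taxa without a
    literature value get missing biomass, never zero — absence of a
    conversion is not absence of carbon.
    """
    lookup = {e.taxlifestage: e.carbon_mass_micrograms for e in table}
    out = catch.copy()
    mass = out["Taxlifestage"].map(lookup)
    out["Carbon_mass_micrograms"] = mass
    out["BPUE"] = out["CPUE"] * mass
    return out


_BIOMASS_COLUMNS = ["Taxlifestage", "Carbon_mass_micrograms", "Reference"]


def write_biomass_csv(entries: Iterable[BiomassEntry], path) -> None:
    pd.DataFrame(
        [
            {"Taxlifestage": e.taxlifestage,
             "Carbon_mass_micrograms": e.carbon_mass_micrograms,
             "Reference": e.reference}
            for e in entries
        ],
        columns=_BIOMASS_COLUMNS,
    ).to_csv(path, index=False, na_rep="NA")


def read_biomass_csv(path) -> list[BiomassEntry]:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    return [
        BiomassEntry(
            taxlifestage=str(r["Taxlifestage"]),
            carbon_mass_micrograms=float(r["Carbon_mass_micrograms"]),
            reference="" if pd.isna(r.get("Reference")) else str(r["Reference"]),
        )
        for _, r in df.iterrows()
    ]


# --- matched-gear undersampling comparison ------------------------------


def flag_undersampled(
    catch_a: pd.DataFrame,
    catch_b: pd.DataFrame,
    env_a: pd.DataFrame,
    env_b: pd.DataFrame,
    *,
    gear_a: str = "Meso",
    gear_b: str = "Micro",
    retain_ratio_threshold: float = 0.75,
    shared_taxa: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Compare total catch of two gears on matched station-dates.

    Restricts both catch tables to the (Station, Date) pairs sampled by
    both gears, totals CPUE per taxon/life stage over those samples, and
    computes ``ratio = total_a / total_b``.  A taxon whose ratio falls
    below ``retain_ratio_threshold`` is flagged as undersampled by gear A;
    above ``1/threshold``, by gear B.  Only taxa counted by both gears are
    compared (pass ``shared_taxa`` to restrict explicitly; by default taxa
    present in both catch tables are used).

    Returns a frame with columns Taxlifestage, CPUE_<gear_a>, CPUE_<gear_b>,
    Ratio, FlaggedGear ("none" when within band).
    """
    if not 0 < retain_ratio_threshold <= 1:
        raise ConfigError("retain_ratio_threshold must be in (0, 1]")
    pairs_a = env_a[["Station", "Date"]].drop_duplicates()
    pairs_b = env_b[["Station", "Date"]].drop_duplicates()
    matched = pairs_a.merge(pairs_b, on=["Station", "Date"])
    if matched.empty:
        raise AlignmentError("no matched (station, date) pairs between gears")

    def _totals(catch, env):
        ids = env.merge(matched, on=["Station", "Date"])["SampleID"]
        sub = catch[catch["SampleID"].isin(set(ids))]
        return sub.groupby("Taxlifestage")["CPUE"].sum(min_count=1)

    tot_a = _totals(catch_a, env_a)
    tot_b = _totals(catch_b, env_b)
    if shared_taxa is None:
        shared = sorted(set(tot_a.index) & set(tot_b.index))
    else:
        shared = sorted(shared_taxa)
    rows = []
    for taxls in shared:
        a = float(tot_a.get(taxls, np.nan))
        b = float(tot_b.get(taxls, np.nan))
        if np.isnan(a) or np.isnan(b):
            continue
        ratio = a / b if b > 0 else (np.inf if a > 0 else np.nan)
        if np.isnan(ratio):
            flagged = "none"
        elif ratio < retain_ratio_threshold:
            flagged = gear_a
        elif ratio > 1.0 / retain_ratio_threshold:
            flagged = gear_b
        else:
            flagged = "none"
        rows.append(
            {
                "Taxlifestage": taxls,
                f"CPUE_{gear_a}": a,
                f"CPUE_{gear_b}": b,
                "Ratio": ratio,
                "FlaggedGear": flagged,
            }
        )
    return pd.DataFrame(rows)


def apply_undersampled_flags(catch: pd.DataFrame, comparison: pd.DataFrame, size_class_of_gear: dict[str, str]) -> pd.DataFrame:
    """Set the Undersampled column from a gear-comparison table.

    ``size_class_of_gear`` maps a FlaggedGear label to the SizeClass whose
    records it taints (e.g. ``{"Meso": "Meso", "Micro": "Micro"}``).
    Records are only flagged, never deleted.
    """
    out = catch.copy()
    if "Undersampled" not in out.columns:
        out["Undersampled"] = False
    for _, row in comparison.iterrows():
        if row["FlaggedGear"] == "none":
            continue
        sc = size_class_of_gear.get(row["FlaggedGear"])
        mask = (out["Taxlifestage"] == row["Taxlifestage"])
        if sc is not None and "SizeClass" in out.columns:
            mask &= out["SizeClass"] == sc
        out.loc[mask, "Undersampled"] = True
    return out


def write_undersampled_csv(comparison: pd.DataFrame, path) -> None:
    flagged = comparison[comparison["FlaggedGear"] != "none"]
    flagged.to_csv(path, index=False, na_rep="NA")


def read_undersampled_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=False)
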