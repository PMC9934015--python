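"""Flux unit registry and exact dimensional conversions.

The pipelines report carbon fluxes in three unit systems: instantaneous
micromole CO2 fluxes from the tower, daily carbon mass fluxes used for the
eddy-covariance daily estimates, and annual per-hectare mass fluxes used for
the plot budgets.  Conversions use the molar mass of carbon (12.011 g/mol)
and a 365-day year; they are exact and round-trip to floating point.
"""

from __future__ import annotations

MOLAR_MASS_C = 12.011  # g C per mol CO2 carbon
SECONDS_PER_DAY = 86_400.0
SECONDS_PER_YEAR = 365.0 * SECONDS_PER_DAY  # 31,536,000 s, 365-day year
SECONDS_PER_HALFHOUR = 1_800.0

#: multiply a flux in umol CO2 m-2 s-1 held constant for one day to get g C m-2 d-1
UMOL_S_TO_GC_DAY = SECONDS_PER_DAY * MOLAR_MASS_C * 1e-6  # 1.0377504

#: multiply g C m-2 d-1 by this to get Mg C ha-1 yr-1 (0.01 Mg/ha per g/m2, 365 d/yr)
GC_DAY_TO_MGC_HA_YR = 0.01 * 365.0  # 3.65

UMOL_CO2_M2_S = "umol CO2 m-2 s-1"
GC_M2_D = "g C m-2 d-1"
MGC_HA_YR = "Mg C ha-1 yr-1"

# conversion factors to the common base unit g C m-2 d-1
_TO_GC_DAY = {
    UMOL_CO2_M2_S: UMOL_S_TO_GC_DAY,
    GC_M2_D: 1.0,
    MGC_HA_YR: 1.0 / GC_DAY_TO_MGC_HA_YR,
}

# accepted spellings for each registered unit
_ALIASES = {
    UMOL_CO2_M2_S: {
        UMOL_CO2_M2_S, "umol m-2 s-1", "umol/m2/s", "umolCO2 m-2 s-1",
        "µmol CO2 m-2 s-1", "µmol m⁻² s⁻¹",
    },
    GC_M2_D: {GC_M2_D, "g C m-2 d-1", "gC m-2 d-1", "g/m2/d", "g C m⁻² d⁻¹"},
    MGC_HA_YR: {MGC_HA_YR, "MgC ha-1 yr-1", "Mg/ha/yr", "Mg C ha⁻¹ yr⁻¹"},
}


def _canonical(unit: str) -> str:
    for canon, names in _ALIASES.items():
        if unit in names or unit.strip() in names:
            return canon
    raise ValueError(
        f"unknown flux unit {unit!r}; registered units: {sorted(_TO_GC_DAY)}"
    )


def convert_flux_units(value, from_unit: str, to_unit: str):
    """Convert a carbon flux between registered units.

    Parameters
    ----------
    value : float or array-like
        Flux magnitude in ``from_unit``.
    from_unit, to_unit : str
        Unit names from the registry (micromole CO2 per m2 per s,
        g C per m2 per day, or Mg C per ha per year).

    Returns
    -------
    float or ndarray
        The same flux expressed in ``to_unit`` (exact, 365-day year).
    """
    src = _canonical(from_unit)
    dst = _canonical(to_unit)
    return value * (_TO_GC_DAY[src] / _TO_GC_DAY[dst])
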