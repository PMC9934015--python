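"""Plot-level carbon-budget assembly, scaling, and group comparison.

Implements the bookkeeping side of a complete forest carbon budget built
from intensive 1-ha monitoring plots: soil-respiration partitioning from
exclusion collars, chamber fluxes scaled to the plot via stem/deadwood
surface areas and leaf area index, assembly of the eleven components into
NPP, autotrophic (R_a) and heterotrophic (R_h) respiration, and the
bookkeeping identities

    R_eco = R_a + R_h
    GPP   = NPP + R_a
    NEE   = R_eco - GPP = R_h - NPP   (positive NEE: source to atmosphere)

with standard errors propagated in quadrature throughout.  All plot-level
component fluxes are expressed in Mg C ha-1 yr-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import TestResult, propagate_se, rank_sum_test, t_test
from .synthetic import COMPONENTS, NPP_COMPONENTS, RA_COMPONENTS, RH_COMPONENTS
from .units import MGC_HA_YR, UMOL_CO2_M2_S, convert_flux_units

__all__ = [
    "SoilPartitionDesign",
    "SoilCollarSet",
    "StemScalingInput",
    "DeadwoodScalingInput",
    "LeafScalingInput",
    "PlotBudget",
    "GroupComparison",
    "BudgetAssembler",
    "partition_soil_respiration",
    "scale_stem_respiration",
    "scale_deadwood_respiration",
    "scale_leaf_respiration",
    "cylinder_lateral_area",
    "assemble_budget",
    "compare_groups",
    "collar_set_from_replicates",
]

_UMOL_TO_MG = convert_flux_units(1.0, UMOL_CO2_M2_S, MGC_HA_YR)
_PLOT_GROUND_M2 = 10_000.0


# ---------------------------------------------------------------------------
# soil partitioning

@dataclass
class SoilPartitionDesign:
    """Which treatment differences identify each soil component.

    ``differences`` maps a component name to ``(minuend, subtrahend)``
    treatment labels; a ``None`` subtrahend means the treatment itself
    measures the component.  The default follows a cumulative exclusion
    design: collars excluding roots, then roots + mycorrhiza, then
    everything but soil organic matter.
    """

    differences: dict = field(default_factory=lambda: {
        "fine_root_r": ("total", "no_roots"),
        "mycorrhiza_rh": ("no_roots", "no_roots_no_myco"),
        "litter_rh": ("no_roots_no_myco", "som_only"),
        "som_rh": ("som_only", None),
    })


@dataclass
class SoilCollarSet:
    """Per-treatment mean soil CO2 efflux and SE for one plot."""

    plot: str
    means: dict            # treatment -> mean flux
    ses: dict              # treatment -> SE of the mean
    n_replicates: dict = field(default_factory=dict)
    flux_unit: str = UMOL_CO2_M2_S

    def __post_init__(self):
        if any(n < 1 for n in self.n_replicates.values()):
            raise ValueError("replicate counts must be >= 1")


def collar_set_from_replicates(collars: pd.DataFrame, plot: str) -> SoilCollarSet:
    """Build a SoilCollarSet from a replicate-level collar table.

    Expects columns ``plot``, ``treatment``, ``flux`` (umol CO2 m-2 s-1).
    """
    sub = collars[collars["plot"] == plot]
    g = sub.groupby("treatment")["flux"]
    n = g.size()
    return SoilCollarSet(
        plot=plot,
        means=g.mean().to_dict(),
        ses=(g.std(ddof=1).fillna(0.0) / np.sqrt(n)).to_dict(),
        n_replicates=n.to_dict(),
    )


def partition_soil_respiration(collars: SoilCollarSet,
                               design: SoilPartitionDesign | None = None,
                               out_unit: str = MGC_HA_YR) -> pd.DataFrame:
    """Difference the collar treatments into soil flux components.

    Each component is the declared difference of treatment means with SE
    combined in quadrature; components re-sum to the total soil efflux by
    construction of a cumulative design.  Components whose treatments are
    missing are returned with NaN value and provenance "unavailable".
    """
    design = design or SoilPartitionDesign()
    factor = convert_flux_units(1.0, collars.flux_unit, out_unit)
    rows = []
    for comp, (minu, subt) in design.differences.items():
        if minu not in collars.means or (subt is not None and subt not in collars.means):
            rows.append({"plot": collars.plot, "component": comp, "value": np.nan,
                         "se": np.nan, "provenance": "unavailable"})
            continue
        if subt is None:
            val = collars.means[minu]
            se = collars.ses.get(minu, 0.0)
        else:
            val = collars.means[minu] - collars.means[subt]
            _, se = propagate_se([(0.0, collars.ses.get(minu, 0.0)),
                                  (0.0, collars.ses.get(subt, 0.0))])
        rows.append({"plot": collars.plot, "component": comp,
                     "value": val * factor, "se": se * factor,
                     "provenance": "partitioned"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chamber-flux scaling

@dataclass
class StemScalingInput:
    """Per-tree stem CO2 efflux plus the census needed to scale it."""

    plot: str
    tree_fluxes: np.ndarray        # umol CO2 m-2 stem s-1, measured trees
    census_diameters_cm: np.ndarray
    allometry_a: float             # stem area (m2) = a * D(cm)^b
    allometry_b: float

    def __post_init__(self):
        self.tree_fluxes = np.asarray(self.tree_fluxes, dtype=float)
        self.census_diameters_cm = np.asarray(self.census_diameters_cm, dtype=float)
        if self.tree_fluxes.size < 1:
            raise ValueError("at least one measured tree is required")
        if self.census_diameters_cm.size < 1:
            raise ValueError("empty census")
        if (self.census_diameters_cm <= 0).any():
            raise ValueError("census diameters must be > 0")


def _scale_area_flux(plot, component, fluxes, area_m2, ground_m2=_PLOT_GROUND_M2):
    """Scale a per-surface-area chamber flux to the plot, Mg C ha-1 yr-1."""
    mean = float(np.mean(fluxes))
    se = float(np.std(fluxes, ddof=1) / np.sqrt(len(fluxes))) if len(fluxes) > 1 else 0.0
    factor = area_m2 / ground_m2 * _UMOL_TO_MG
    return pd.DataFrame([{"plot": plot, "component": component,
                          "value": mean * factor, "se": se * factor,
                          "provenance": "scaled"}])


def scale_stem_respiration(inp: StemScalingInput) -> pd.DataFrame:
    """Scale per-stem-area respiration to the plot via allometric stem area.

    Total stem surface area is the allometric area a * D^b summed over the
    census; the plot flux is the between-tree mean per-area flux times the
    total area, with SE propagated from the between-tree SE.
    """
    area = float(np.sum(inp.allometry_a * inp.census_diameters_cm ** inp.allometry_b))
    return _scale_area_flux(inp.plot, "stem_r", inp.tree_fluxes, area)


@dataclass
class DeadwoodScalingInput:
    """Per-piece deadwood efflux plus the >= 10 cm inventory for scaling."""

    plot: str
    piece_fluxes: np.ndarray            # umol CO2 m-2 wood s-1
    inventory_diameters_cm: np.ndarray  # all pieces >= 10 cm
    inventory_lengths_m: np.ndarray

    def __post_init__(self):
        self.piece_fluxes = np.asarray(self.piece_fluxes, dtype=float)
        self.inventory_diameters_cm = np.asarray(self.inventory_diameters_cm, dtype=float)
        self.inventory_lengths_m = np.asarray(self.inventory_lengths_m, dtype=float)
        if self.piece_fluxes.size < 1:
            raise ValueError("at least one measured deadwood piece is required")
        if (self.inventory_diameters_cm < 10.0).any():
            raise ValueError("deadwood inventory is defined for pieces >= 10 cm diameter")


def cylinder_lateral_area(diameter_cm, length_m):
    """Lateral surface area (m2) of a cylindrical deadwood piece."""
    return np.pi * np.asarray(diameter_cm, dtype=float) / 100.0 * np.asarray(
        length_m, dtype=float)


def scale_deadwood_respiration(inp: DeadwoodScalingInput) -> pd.DataFrame:
    """Scale per-wood-area respiration to the plot via inventory surface area."""
    area = float(np.sum(cylinder_lateral_area(inp.inventory_diameters_cm,
                                              inp.inventory_lengths_m)))
    return _scale_area_flux(inp.plot, "deadwood_rh", inp.piece_fluxes, area)


@dataclass
class LeafScalingInput:
    """Sun/shade leaf dark respiration with canopy structure for scaling."""

    plot: str
    r_sun: float                  # umol CO2 m-2 leaf s-1
    r_shade: float
    f_sun: float
    f_shade: float
    lai: float
    inhibition_factor: float = 0.67
    daylight_hours: float = 12.0
    r_sun_se: float = 0.0
    r_shade_se: float = 0.0

    def __post_init__(self):
        if not np.isclose(self.f_sun + self.f_shade, 1.0):
            raise ValueError("sun and shade fractions must sum to 1")
        if not (0.0 <= self.f_sun <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.lai <= 0:
            raise ValueError("LAI must be > 0")
        if not (0.0 < self.inhibition_factor <= 1.0):
            raise ValueError("inhibition factor must be in (0, 1]")


def scale_leaf_respiration(inp: LeafScalingInput) -> pd.DataFrame:
    """Scale leaf dark respiration to the canopy, with daytime inhibition.

    Canopy flux = (R_sun f_sun + R_shade f_shade) x LAI, with the light
    inhibition factor (default 0.67) applied to the daylight fraction of
    the diurnal cycle only — the 24-h effective multiplier is
    (h_day * factor + (24 - h_day)) / 24.
    """
    mean_leaf = inp.r_sun * inp.f_sun + inp.r_shade * inp.f_shade
    se_leaf = float(np.hypot(inp.f_sun * inp.r_sun_se, inp.f_shade * inp.r_shade_se))
    h = inp.daylight_hours
    diurnal = (h * inp.inhibition_factor + (24.0 - h)) / 24.0
    factor = inp.lai * diurnal * _UMOL_TO_MG
    return pd.DataFrame([{"plot": inp.plot, "component": "leaf_r",
                          "value": mean_leaf * factor, "se": se_leaf * factor,
                          "provenance": "scaled"}])


# ---------------------------------------------------------------------------
# budget assembly

_AGGREGATES = {
    "NPP": NPP_COMPONENTS,
    "R_a": RA_COMPONENTS,
    "R_h": RH_COMPONENTS,
}


@dataclass
class PlotBudget:
    """Assembled carbon budget for one plot (Mg C ha-1 yr-1)."""

    plot: str
    group: str
    values: dict          # NPP, R_a, R_h, R_eco, GPP, NEE
    ses: dict
    complete: bool = True


class BudgetAssembler(BaseEstimator, TransformerMixin):
    """Assemble component tables into plot budgets (transform-shaped).

    ``transform`` takes a long component table (plot, component, value, se)
    and returns one budget row per plot with NPP, R_a, R_h, R_eco, GPP and
    NEE plus quadrature-propagated SEs.  A plot missing any of the eleven
    components is flagged incomplete and its aggregates withheld unless an
    imputation mapping supplies the missing values.

    Parameters
    ----------
    groups : dict or None
        Optional plot -> logging-class mapping carried into the output.
    impute : dict or None
        component -> (value, se) fallbacks for missing components; used
        with a warning flag in the output (provenance column "imputed").
    """

    def __init__(self, groups=None, impute=None):
        self.groups = groups
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None):
        self.components_ = tuple(COMPONENTS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for plot, sub in X.groupby("plot", sort=False):
            comp = {r["component"]: (r["value"], r.get("se", 0.0))
                    for _, r in sub.iterrows()
                    if np.isfinite(r["value"])}
            imputed = []
            if self.impute:
                for c, vs in self.impute.items():
                    if c not in comp:
                        comp[c] = vs
                        imputed.append(c)
            missing = [c for c in COMPONENTS if c not in comp]
            row = {"plot": plot,
                   "group": (self.groups or {}).get(plot, sub["group"].iat[0]
                                                    if "group" in sub else ""),
                   "complete": not missing,
                   "imputed": ",".join(imputed),
                   "missing": ",".join(missing)}
            if missing:
                for q in ("NPP", "R_a", "R_h", "R_eco", "GPP", "NEE"):
                    row[q] = np.nan
                    row[f"{q}_se"] = np.nan
                rows.append(row)
                continue
            vals, ses = {}, {}
            for agg, parts in _AGGREGATES.items():
                vals[agg], ses[agg] = propagate_se([comp[c] for c in parts])
            vals["R_eco"], ses["R_eco"] = propagate_se(
                [comp[c] for c in RA_COMPONENTS + RH_COMPONENTS])
            vals["GPP"], ses["GPP"] = propagate_se(
                [comp[c] for c in NPP_COMPONENTS + RA_COMPONENTS])
            # NEE = R_h - NPP; the R_a terms cancel algebraically, so the SE
            # follows from the heterotrophic and productivity terms only
            vals["NEE"], ses["NEE"] = propagate_se(
                [comp[c] for c in RH_COMPONENTS]
                + [(-comp[c][0], comp[c][1]) for c in NPP_COMPONENTS])
            for q in ("NPP", "R_a", "R_h", "R_eco", "GPP", "NEE"):
                row[q] = vals[q]
                row[f"{q}_se"] = ses[q]
            rows.append(row)
        return pd.DataFrame(rows)


def assemble_budget(components: pd.DataFrame, groups: dict | None = None,
                    impute: dict | None = None) -> pd.DataFrame:
    """Assemble plot budgets from a long component table (wrapper)."""
    return BudgetAssembler(groups=groups, impute=impute).fit(components).transform(components)


def components_from_raw_tables(tables: dict, allometry: tuple[float, float],
                               design: SoilPartitionDesign | None = None) -> pd.DataFrame:
    """Run every scaling/partitioning stage over raw measurement tables.

    ``tables`` uses the layout the synthetic generator emits (and that field
    data can be coerced into): replicate collar fluxes, per-tree stem fluxes
    with a census, per-piece deadwood fluxes with an inventory, leaf
    respiration inputs, and directly consumed component values.  Returns the
    long component table ready for :func:`assemble_budget`.
    """
    a, b = allometry
    parts = []
    plots = sorted(tables["collars"]["plot"].unique())
    for plot in plots:
        parts.append(partition_soil_respiration(
            collar_set_from_replicates(tables["collars"], plot), design))
        stems = tables["stems"].query("plot == @plot")["flux"].to_numpy()
        census = tables["census"].query("plot == @plot")["diameter_cm"].to_numpy()
        parts.append(scale_stem_respiration(
            StemScalingInput(plot, stems, census, a, b)))
        dw = tables["deadwood"].query("plot == @plot")["flux"].to_numpy()
        inv = tables["deadwood_inventory"].query("plot == @plot")
        parts.append(scale_deadwood_respiration(DeadwoodScalingInput(
            plot, dw, inv["diameter_cm"].to_numpy(), inv["length_m"].to_numpy())))
        leaf = tables["leaf"].query("plot == @plot").iloc[0]
        parts.append(scale_leaf_respiration(LeafScalingInput(
            plot, leaf["r_sun"], leaf["r_shade"], leaf["f_sun"], leaf["f_shade"],
            leaf["lai"], leaf["inhibition_factor"],
            r_sun_se=leaf.get("r_sun_se", 0.0), r_shade_se=leaf.get("r_shade_se", 0.0))))
    direct = tables["components"].copy()
    direct["provenance"] = "measured"
    parts.append(direct)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparison:
    """Two-group test outcome for one budget quantity or component."""

    quantity: str
    group_a: str
    group_b: str
    t: TestResult
    rank_sum: TestResult
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int


def compare_groups(budgets: pd.DataFrame, quantity: str,
                   group_a: str = "unlogged", group_b: str = "logged",
                   pooled: bool = False) -> GroupComparison:
    """Compare a budget quantity between two plot groups.

    ``group_b = "logged"`` pools every non-unlogged class.  Reports a
    two-sample t test (Welch by default, pooled optional) and the rank-sum
    test, plus group means with between-plot SEs (SD across plots / sqrt n).
    """
    if quantity not in budgets:
        raise KeyError(f"quantity {quantity!r} not in budget table")
    grp = budgets["group"].astype(str)
    a = budgets.loc[grp == group_a, quantity].dropna()
    if group_b == "logged":
        b = budgets.loc[grp != group_a, quantity].dropna()
    else:
        b = budgets.loc[grp == group_b, quantity].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return GroupComparison(
        quantity=quantity, group_a=group_a, group_b=group_b,
        t=t_test(a, b, pooled=pooled),
        rank_sum=rank_sum_test(a, b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0,
        se_b=float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else 0.0,
        n_a=len(a), n_b=len(b),
    )
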