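"""Synthetic flux-tower series and plot-level component datasets.

Both generators are the inverse of the analysis stages: the tower series is
driven by a known light-response + respiration model so that u*-threshold
detection, gap filling and daytime partitioning can be tested by parameter
recovery; the plot generator draws component measurements around known group
means so budget assembly and group comparison can be tested the same way.

Default parameter values describe the study conditions the package targets:
a moist, aseasonal tropical site observed over three measuring periods of
65, 100 and 290 days (455 days total), roughly half the record missing, a
nocturnal friction-velocity artefact below 0.29 m s-1, and eleven carbon
budget components per 1-ha plot across a logging-intensity gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import UMOL_CO2_M2_S, MGC_HA_YR, convert_flux_units

__all__ = [
    "PeriodSpec",
    "TowerSimConfig",
    "GroupTruth",
    "PlotSimConfig",
    "TruthBundle",
    "lloyd_taylor",
    "light_response_nee",
    "simulate_tower_series",
    "simulate_plot_dataset",
    "COMPONENTS",
    "NPP_COMPONENTS",
    "RA_COMPONENTS",
    "RH_COMPONENTS",
    "SOIL_TREATMENTS",
]

# ---------------------------------------------------------------------------
# shared model pieces

T_REF_C = 15.0     # Lloyd-Taylor reference temperature, deg C
T0_C = -46.02      # Lloyd-Taylor zero-kelvin offset, deg C


def lloyd_taylor(tair_c, rb, e0):
    """Exponential (Lloyd-Taylor) respiration, umol CO2 m-2 s-1.

    R(T) = rb * exp(E0 * (1/(Tref - T0) - 1/(T - T0))) with temperatures in
    deg C, Tref = 15 and T0 = -46.02, so rb is the respiration at 15 deg C.
    """
    tair_c = np.asarray(tair_c, dtype=float)
    return rb * np.exp(e0 * (1.0 / (T_REF_C - T0_C) - 1.0 / (tair_c - T0_C)))


def _beta_vpd(vpd, beta0, k, vpd0):
    """Maximum uptake capacity, down-regulated exponentially above VPD0."""
    vpd = np.asarray(vpd, dtype=float)
    return np.where(vpd > vpd0, beta0 * np.exp(-k * (vpd - vpd0)), beta0)


def light_response_nee(rg, tair, vpd, alpha, beta0, k, rb, e0, vpd0=10.0):
    """Noise-free NEE from the rectangular-hyperbola daytime model.

    NEE = -(alpha*beta*Rg)/(alpha*Rg + beta) + R(T), with beta reduced above
    the VPD0 threshold; at Rg = 0 the uptake term vanishes and NEE equals
    respiration.  Sign convention: positive NEE is a source to the
    atmosphere.
    """
    rg = np.asarray(rg, dtype=float)
    beta = _beta_vpd(vpd, beta0, k, vpd0)
    denom = alpha * rg + beta
    uptake = np.where(denom > 0, alpha * beta * rg / np.where(denom > 0, denom, 1.0), 0.0)
    return -uptake + lloyd_taylor(tair, rb, e0)


# ---------------------------------------------------------------------------
# tower simulation

@dataclass
class PeriodSpec:
    """One measuring period: a label, a start date and a length in days."""

    label: str
    start: str  # ISO date
    n_days: int


@dataclass
class TowerSimConfig:
    """Configuration and ground truth for the half-hourly tower simulator.

    Radiation follows a clear-sky half-sine over a fixed photoperiod
    (aseasonal site, no seasonal cycle); air temperature a sinusoidal
    diurnal cycle; VPD is linearly coupled to temperature.  The flux model
    parameters are the "true" values the partitioning stage should recover.
    """

    periods: tuple[PeriodSpec, ...] = (
        PeriodSpec("10-y recovery", "2012-09-01", 65),
        PeriodSpec("active salvage logging", "2015-03-01", 100),
        PeriodSpec("2-3 y recovery", "2017-06-01", 290),
    )
    # drivers
    rg_max: float = 800.0          # W m-2 at solar noon
    photoperiod_h: float = 12.0    # daylight hours (sunrise 06:00)
    tair_mean: float = 26.7        # deg C, site daily mean
    tair_amplitude: float = 6.0    # deg C, diurnal peak-to-trough
    vpd_day_mean: float = 9.0      # hPa at the daily mean temperature
    vpd_slope: float = 1.5         # hPa per deg C of temperature anomaly
    # true flux parameters
    alpha_true: float = 0.06       # umol CO2 per J (initial light-response slope)
    beta0_true: float = 45.0       # umol m-2 s-1, max uptake at VPD <= VPD0
    k_true: float = 0.05           # hPa-1, VPD sensitivity
    rb_true: float = 8.0           # umol m-2 s-1, respiration at 15 deg C
    e0_true: float = 180.0         # K, temperature sensitivity
    vpd0: float = 10.0             # hPa
    # per-period multipliers on (beta0, rb): the three periods differ in flux
    # magnitude (highest ~10 y after logging, lowest 2-3 y after salvage)
    period_scales: dict = field(default_factory=lambda: {
        "10-y recovery": 1.15,
        "active salvage logging": 1.0,
        "2-3 y recovery": 0.85,
    })
    # noise / artefacts
    noise_sd: float = 2.0          # umol m-2 s-1
    noise_model: str = "additive"  # or "proportional" (sd scales with |NEE|)
    gap_fraction: float = 0.495
    block_gap_share: float = 0.5   # share of the gap mass placed in day blocks
    block_days: int = 3
    # friction velocity
    ustar_night_median: float = 0.30   # m s-1, lognormal median at night
    ustar_night_sigma: float = 0.6     # lognormal sigma
    ustar_day_median: float = 0.50
    ustar_day_sigma: float = 0.4
    ustar_threshold_true: float = 0.29  # m s-1
    attenuation: float = 0.5            # multiplier on nocturnal NEE below threshold
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must be in [0, 1]")
        for name in ("alpha_true", "beta0_true", "rb_true", "e0_true",
                     "rg_max", "ustar_threshold_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        for p in self.periods:
            if p.n_days < 1:
                raise ValueError("each period needs n_days >= 1")


@dataclass
class TruthBundle:
    """Exact parameter values and truth series behind one simulated dataset."""

    config: object
    seed: int
    params: dict
    truth_table: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return dict(self.params)


def _diurnal_drivers(cfg: TowerSimConfig, hours: np.ndarray):
    """Rg, Tair, VPD at fractional hour-of-day (half-hour midpoints)."""
    sunrise = 12.0 - cfg.photoperiod_h / 2.0
    frac = (hours - sunrise) / cfg.photoperiod_h
    rg = np.where((frac > 0) & (frac < 1), cfg.rg_max * np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    # temperature maximum at 14:00, minimum at 02:00
    tair = cfg.tair_mean + (cfg.tair_amplitude / 2.0) * np.sin(2 * np.pi * (hours - 8.0) / 24.0)
    vpd = np.maximum(0.0, cfg.vpd_day_mean + cfg.vpd_slope * (tair - cfg.tair_mean))
    return rg, tair, vpd


def _insert_gaps(n: int, cfg: TowerSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean gap mask hitting the configured fraction almost exactly.

    A configurable share of the gap mass is laid down as multi-day blocks
    (instrument outages); the remainder as isolated half-hours, topping the
    realized count up to round(fraction * n).
    """
    n_gap = int(round(cfg.gap_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if n_gap == 0:
        return mask
    block_len = cfg.block_days * 48
    n_blocks = int(cfg.block_gap_share * n_gap / block_len) if block_len < n else 0
    day_starts = np.arange(0, max(n - block_len, 1), 48)
    if n_blocks > 0 and day_starts.size > 0:
        starts = rng.choice(day_starts, size=min(n_blocks, day_starts.size), replace=False)
        for s in starts:
            mask[s:s + block_len] = True
    short = n_gap - int(mask.sum())
    if short > 0:
        avail = np.flatnonzero(~mask)
        mask[rng.choice(avail, size=min(short, avail.size), replace=False)] = True
    elif short < 0:
        on = np.flatnonzero(mask)
        mask[rng.choice(on, size=-short, replace=False)] = False
    return mask


def simulate_tower_series(config: TowerSimConfig | None = None):
    """Generate a half-hourly FLUXNET-style table with known ground truth.

    Returns
    -------
    (records, truth) : (pandas.DataFrame, TruthBundle)
        ``records`` has one row per half hour (48 per day,
        half-hour-ending timestamps as the index) with columns
        TIMESTAMP_START, TIMESTAMP_END, NEE, SW_IN, TA, VPD, USTAR, PERIOD,
        QC.  ``truth`` carries the true parameters and the noise-free
        NEE/GPP/RECO series plus the gap and attenuation masks.
    """
    cfg = config or TowerSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    frames = []
    for period in cfg.periods:
        start = pd.Timestamp(period.start)
        ends = start + pd.timedelta_range("30min", periods=48 * period.n_days, freq="30min")
        frames.append(pd.DataFrame({"PERIOD": period.label}, index=ends))
    df = pd.concat(frames)
    df.index.name = "time"

    mid = df.index - pd.Timedelta(minutes=15)
    hours = mid.hour + mid.minute / 60.0
    rg, tair, vpd = _diurnal_drivers(cfg, np.asarray(hours, dtype=float))

    scale = df["PERIOD"].map(lambda p: cfg.period_scales.get(p, 1.0)).to_numpy()
    beta0 = cfg.beta0_true * scale
    rb = cfg.rb_true * scale

    beta = _beta_vpd(vpd, beta0, cfg.k_true, cfg.vpd0)
    denom = cfg.alpha_true * rg + beta
    gpp_true = np.where(rg > 0, cfg.alpha_true * beta * rg / np.where(denom > 0, denom, 1.0), 0.0)
    reco_true = lloyd_taylor(tair, rb, cfg.e0_true)
    nee_true = reco_true - gpp_true

    night = rg <= 0
    n = len(df)
    ustar = np.where(
        night,
        rng.lognormal(math.log(cfg.ustar_night_median), cfg.ustar_night_sigma, n),
        rng.lognormal(math.log(cfg.ustar_day_median), cfg.ustar_day_sigma, n),
    )
    attenuated = night & (ustar < cfg.ustar_threshold_true)
    nee_meas = np.where(attenuated, cfg.attenuation * nee_true, nee_true)

    if cfg.noise_sd > 0:
        if cfg.noise_model == "proportional":
            noise = rng.normal(0.0, 1.0, n) * cfg.noise_sd * np.maximum(np.abs(nee_meas), 1.0) / 5.0
        else:
            noise = rng.normal(0.0, cfg.noise_sd, n)
        nee_meas = nee_meas + noise

    gap = _insert_gaps(n, cfg, rng)
    nee_col = np.where(gap, np.nan, nee_meas)

    records = pd.DataFrame(
        {
            "TIMESTAMP_START": (df.index - pd.Timedelta(minutes=30)).strftime("%Y%m%d%H%M"),
            "TIMESTAMP_END": df.index.strftime("%Y%m%d%H%M"),
            "NEE": nee_col,
            "SW_IN": rg,
            "TA": tair,
            "VPD": vpd,
            "USTAR": ustar,
            "PERIOD": df["PERIOD"].to_numpy(),
            "QC": np.where(gap, "gap", "original"),
        },
        index=df.index,
    )

    truth_table = pd.DataFrame(
        {
            "NEE_true": nee_true,
            "GPP_true": gpp_true,
            "RECO_true": reco_true,
            "attenuated": attenuated,
            "gap": gap,
        },
        index=df.index,
    )
    params = {
        "alpha": cfg.alpha_true,
        "beta0": cfg.beta0_true,
        "k": cfg.k_true,
        "rb": cfg.rb_true,
        "e0": cfg.e0_true,
        "vpd0": cfg.vpd0,
        "ustar_threshold": cfg.ustar_threshold_true,
        "attenuation": cfg.attenuation,
        "gap_fraction": cfg.gap_fraction,
        "period_scales": dict(cfg.period_scales),
        "seed": cfg.seed,
    }
    return records, TruthBundle(cfg, cfg.seed, params, truth_table)


# ---------------------------------------------------------------------------
# plot simulation

NPP_COMPONENTS = ("woody_npp", "canopy_npp", "fine_root_npp")
RA_COMPONENTS = ("stem_r", "coarse_root_r", "fine_root_r", "leaf_r")
RH_COMPONENTS = ("litter_rh", "mycorrhiza_rh", "som_rh", "deadwood_rh")
COMPONENTS = NPP_COMPONENTS + RA_COMPONENTS + RH_COMPONENTS

#: cumulative-exclusion collar treatments; each excludes one more component
SOIL_TREATMENTS = ("total", "no_roots", "no_roots_no_myco", "som_only")

_UMOL_TO_MG = convert_flux_units(1.0, UMOL_CO2_M2_S, MGC_HA_YR)  # ~3.788
_PLOT_GROUND_M2 = 10_000.0  # 1-ha plot


@dataclass
class GroupTruth:
    """True component means (Mg C ha-1 yr-1) for one logging class."""

    means: dict
    between_plot_sd: float = 0.5


def _default_groups() -> dict:
    # component means chosen to be realistic for Bornean lowland forest:
    # similar NPP across classes, an allocation shift from canopy to wood in
    # logged plots, and elevated heterotrophic (soil organic matter and
    # deadwood) respiration after logging.
    unlogged = {
        "woody_npp": 2.5, "canopy_npp": 4.5, "fine_root_npp": 3.0,
        "stem_r": 3.0, "coarse_root_r": 1.0, "fine_root_r": 3.5, "leaf_r": 5.0,
        "litter_rh": 2.0, "mycorrhiza_rh": 1.0, "som_rh": 4.0, "deadwood_rh": 2.3,
    }
    moderate = {
        "woody_npp": 3.5, "canopy_npp": 3.5, "fine_root_npp": 3.0,
        "stem_r": 3.3, "coarse_root_r": 1.2, "fine_root_r": 3.3, "leaf_r": 5.0,
        "litter_rh": 2.3, "mycorrhiza_rh": 0.9, "som_rh": 4.8, "deadwood_rh": 3.8,
    }
    heavy = {
        "woody_npp": 4.0, "canopy_npp": 3.0, "fine_root_npp": 3.0,
        "stem_r": 3.5, "coarse_root_r": 1.3, "fine_root_r": 3.2, "leaf_r": 5.0,
        "litter_rh": 2.5, "mycorrhiza_rh": 0.8, "som_rh": 5.8, "deadwood_rh": 6.4,
    }
    return {
        "unlogged": GroupTruth(unlogged),
        "moderately logged": GroupTruth(moderate),
        "heavily logged": GroupTruth(heavy),
    }


@dataclass
class PlotSimConfig:
    """Configuration for the plot-level component dataset simulator."""

    groups: dict = field(default_factory=_default_groups)
    plots_per_group: dict = field(default_factory=lambda: {
        "unlogged": 6, "moderately logged": 2, "heavily logged": 3,
    })
    collars_per_treatment: int = 8
    stem_trees: int = 35
    census_stems: int = 450
    deadwood_pieces_measured: int = 25
    deadwood_pieces_inventory: int = 60
    # measurement noise (relative SD on replicate-level measurements)
    replicate_noise_rel: float = 0.15
    npp_se_rel: float = 0.10
    lai_unlogged: float = 5.5
    lai_logged: float = 4.0
    f_sun: float = 0.30
    inhibition_factor: float = 0.67
    allometry_a: float = 0.05   # stem surface area (m2) = a * D(cm)^b
    allometry_b: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("collars_per_treatment", "stem_trees",
                     "deadwood_pieces_measured", "plots_per_group"):
            val = getattr(self, name)
            if isinstance(val, dict):
                if any(v < 1 for v in val.values()):
                    raise ValueError(f"{name} entries must be >= 1")
            elif val < 1:
                raise ValueError(f"{name} must be >= 1")
        for g, truth in self.groups.items():
            if truth.between_plot_sd < 0:
                raise ValueError("between_plot_sd must be >= 0")
            missing = set(COMPONENTS) - set(truth.means)
            if missing:
                raise ValueError(f"group {g!r} missing components {sorted(missing)}")


def _rel_noise(rng, values, rel):
    values = np.asarray(values, dtype=float)
    if rel <= 0:
        return values
    return values + rng.normal(0.0, rel * np.maximum(np.abs(values), 1e-12))


def simulate_plot_dataset(config: PlotSimConfig | None = None):
    """Generate raw plot measurement tables with known component truths.

    Returns
    -------
    (tables, truth_components, truth) :
        ``tables`` is a dict of DataFrames — ``collars`` (replicate soil
        fluxes per exclusion treatment, umol CO2 m-2 s-1), ``stems``
        (per-tree flux per stem area), ``census`` (live-stem diameters),
        ``deadwood`` (measured pieces) and ``deadwood_inventory``, ``leaf``
        (sun/shade dark respiration, fractions, LAI), and ``components``
        (directly consumed NPP + coarse-root respiration values with SEs).
        ``truth_components`` holds the plot-level component values
        (Mg C ha-1 yr-1) the biometric pipeline should recover.
    """
    cfg = config or PlotSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    collar_rows, stem_rows, census_rows = [], [], []
    dw_rows, dw_inv_rows, leaf_rows, comp_rows, truth_rows = [], [], [], [], []

    for group, truth in cfg.groups.items():
        n_plots = cfg.plots_per_group.get(group, 0)
        if n_plots < 1:
            raise ValueError(f"plots_per_group[{group!r}] must be >= 1")
        for p in range(n_plots):
            plot_id = f"{group.split()[0].upper()[:3]}-{p + 1:02d}"
            # plot-level truth = group mean + between-plot deviation
            plot_truth = {
                c: truth.means[c] + (rng.normal(0.0, truth.between_plot_sd)
                                     if truth.between_plot_sd > 0 else 0.0)
                for c in COMPONENTS
            }
            plot_truth = {c: max(v, 0.05) for c, v in plot_truth.items()}
            for c, v in plot_truth.items():
                truth_rows.append({"plot": plot_id, "group": group,
                                   "component": c, "value": v})

            # --- soil collars: cumulative exclusion design -----------------
            som = plot_truth["som_rh"]
            litter = plot_truth["litter_rh"]
            myco = plot_truth["mycorrhiza_rh"]
            root = plot_truth["fine_root_r"]
            treatment_truth_mg = {
                "som_only": som,
                "no_roots_no_myco": som + litter,
                "no_roots": som + litter + myco,
                "total": som + litter + myco + root,
            }
            for treatment, mg in treatment_truth_mg.items():
                flux = mg / _UMOL_TO_MG  # umol CO2 m-2 s-1 at ground level
                reps = _rel_noise(rng, np.full(cfg.collars_per_treatment, flux),
                                  cfg.replicate_noise_rel)
                for i, f in enumerate(reps):
                    collar_rows.append({"plot": plot_id, "treatment": treatment,
                                        "collar": i + 1, "flux": f})

            # --- stem respiration + census --------------------------------
            diam = rng.lognormal(math.log(20.0), 0.5, cfg.census_stems)
            diam = np.clip(diam, 10.0, 120.0)
            area_total = float(np.sum(cfg.allometry_a * diam ** cfg.allometry_b))
            stem_flux_mean = plot_truth["stem_r"] * _PLOT_GROUND_M2 / (
                _UMOL_TO_MG * area_total)
            tree_flux = _rel_noise(rng, np.full(cfg.stem_trees, stem_flux_mean),
                                   cfg.replicate_noise_rel)
            for i, f in enumerate(tree_flux):
                stem_rows.append({"plot": plot_id, "tree": i + 1, "flux": f})
            for i, d in enumerate(diam):
                census_rows.append({"plot": plot_id, "stem": i + 1, "diameter_cm": d})

            # --- deadwood ---------------------------------------------------
            dw_d = np.clip(rng.lognormal(math.log(22.0), 0.4,
                                         cfg.deadwood_pieces_inventory), 10.0, 100.0)
            dw_len = np.clip(rng.lognormal(math.log(3.0), 0.5,
                                           cfg.deadwood_pieces_inventory), 0.5, 20.0)
            dw_area_total = float(np.sum(np.pi * dw_d / 100.0 * dw_len))
            dw_flux_mean = plot_truth["deadwood_rh"] * _PLOT_GROUND_M2 / (
                _UMOL_TO_MG * dw_area_total)
            dw_flux = _rel_noise(rng, np.full(cfg.deadwood_pieces_measured, dw_flux_mean),
                                 cfg.replicate_noise_rel)
            for i, f in enumerate(dw_flux):
                dw_rows.append({"plot": plot_id, "piece": i + 1, "flux": f})
            for i, (d, ln) in enumerate(zip(dw_d, dw_len)):
                dw_inv_rows.append({"plot": plot_id, "piece": i + 1,
                                    "diameter_cm": d, "length_m": ln})

            # --- leaf dark respiration -------------------------------------
            lai = cfg.lai_unlogged if group == "unlogged" else cfg.lai_logged
            f_sun = cfg.f_sun
            daylight_factor = (12.0 * cfg.inhibition_factor + 12.0) / 24.0
            # R_shade = 0.6 * R_sun; solve R_sun from the plot truth
            mean_needed = plot_truth["leaf_r"] / (lai * daylight_factor * _UMOL_TO_MG)
            r_sun = mean_needed / (f_sun + 0.6 * (1.0 - f_sun))
            r_shade = 0.6 * r_sun
            r_sun_m, r_shade_m = _rel_noise(rng, [r_sun, r_shade],
                                            cfg.replicate_noise_rel / math.sqrt(10))
            leaf_rows.append({
                "plot": plot_id, "r_sun": r_sun_m, "r_shade": r_shade_m,
                "r_sun_se": cfg.replicate_noise_rel * r_sun / math.sqrt(10),
                "r_shade_se": cfg.replicate_noise_rel * r_shade / math.sqrt(10),
                "f_sun": f_sun, "f_shade": 1.0 - f_sun, "lai": lai,
                "inhibition_factor": cfg.inhibition_factor,
            })

            # --- directly consumed components (NPP, coarse-root R) ----------
            for c in NPP_COMPONENTS + ("coarse_root_r",):
                se = cfg.npp_se_rel * plot_truth[c]
                val = _rel_noise(rng, [plot_truth[c]], cfg.npp_se_rel)[0]
                comp_rows.append({"plot": plot_id, "component": c,
                                  "value": val, "se": se})

    tables = {
        "collars": pd.DataFrame(collar_rows),
        "stems": pd.DataFrame(stem_rows),
        "census": pd.DataFrame(census_rows),
        "deadwood": pd.DataFrame(dw_rows),
        "deadwood_inventory": pd.DataFrame(dw_inv_rows),
        "leaf": pd.DataFrame(leaf_rows),
        "components": pd.DataFrame(comp_rows),
    }
    truth_components = pd.DataFrame(truth_rows)
    params = {
        "groups": {g: dict(t.means) for g, t in cfg.groups.items()},
        "allometry": (cfg.allometry_a, cfg.allometry_b),
        "inhibition_factor": cfg.inhibition_factor,
        "seed": cfg.seed,
    }
    return tables, truth_components, TruthBundle(cfg, cfg.seed, params, truth_components)
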