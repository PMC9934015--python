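"""Eddy-covariance NEE processing: u* filtering, gap filling, partitioning.

The pipeline turns a half-hourly table of net ecosystem exchange (NEE) and
meteorology into u*-filtered, gap-filled, partitioned daily NEE/GPP/Reco
series with an uncertainty budget and per-period statistics.  Stages are
sklearn-style estimators (fit/transform, fitted attributes with trailing
underscores) so they compose with pipelines and grid search; the
module-level functions are thin wrappers.

Sign convention throughout: positive NEE is a net source of CO2 to the
atmosphere, and NEE = Reco - GPP with GPP >= 0.

Expected columns (FLUXNET-style): NEE, SW_IN (global radiation, W m-2),
TA (air temperature, deg C), VPD (hPa), USTAR (m s-1), with a uniform
30-minute DatetimeIndex of half-hour-ending timestamps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import TestResult, rank_sum_test, signed_rank_test
from .synthetic import lloyd_taylor
from .units import MOLAR_MASS_C, SECONDS_PER_HALFHOUR

__all__ = [
    "ThresholdNotEstimableError",
    "UStarThreshold",
    "UStarThresholdEstimator",
    "MDSGapFiller",
    "DaytimePartitioner",
    "UncertaintyBudget",
    "PeriodSummary",
    "estimate_ustar_threshold",
    "filter_low_turbulence",
    "gapfill_mds",
    "fit_daytime_partition",
    "partition_series",
    "aggregate_daily",
    "uncertainty_budget",
    "relative_uncertainty",
    "summarize_periods",
    "validate_halfhourly",
]

#: multiply a half-hourly mean flux in umol CO2 m-2 s-1 by this to get its
#: contribution to the daily total in g C m-2
HALFHOUR_TO_GC = SECONDS_PER_HALFHOUR * MOLAR_MASS_C * 1e-6


def validate_halfhourly(df: pd.DataFrame) -> pd.DataFrame:
    """Check the half-hourly record invariants; returns the frame unchanged."""
    if not isinstance(df.index, pd.DatetimeIndex):
        raise ValueError("records need a DatetimeIndex of half-hour-ending timestamps")
    if len(df) > 1:
        deltas = np.diff(df.index.view("i8"))
        if not (deltas > 0).all():
            raise ValueError("timestamps must be strictly increasing")
    for col, lo in (("SW_IN", 0.0), ("VPD", 0.0), ("USTAR", 0.0)):
        if col in df and (df[col].dropna() < lo).any():
            raise ValueError(f"{col} must be >= {lo}")
    return df


# ---------------------------------------------------------------------------
# u* threshold (moving point method)

class ThresholdNotEstimableError(RuntimeError):
    """Raised when nocturnal data cannot support threshold detection."""


@dataclass
class UStarThreshold:
    """A friction-velocity threshold with its detection metadata."""

    threshold: float                    # m s-1
    class_thresholds: pd.DataFrame      # per (season, temperature class)
    bin_width: float                    # representative u* bin spacing, m s-1
    degenerate: bool = False            # no detectable suppression
    n_nocturnal: int = 0
    method: str = "moving point"


class UStarThresholdEstimator(BaseEstimator):
    """Detect the nocturnal friction-velocity threshold (moving point method).

    Nocturnal records are stratified by season and air-temperature class;
    within each class the records are sorted into equal-count u* bins, and
    the class threshold is the mean u* of the lowest bin whose mean NEE
    reaches ``criterion`` (default 95%) of the mean NEE of the higher bins.
    Class thresholds are aggregated to a single mean threshold.

    Parameters
    ----------
    n_temp_classes : int
        Temperature strata per season (quantile-based).
    n_ustar_bins : int
        Equal-count u* bins per temperature class.
    criterion : float
        Fraction of the higher-bin mean NEE a bin must reach.
    n_compare_bins : int or None
        How many higher bins enter the reference mean; None (default)
        compares against all higher bins, which stays robust when the
        suppression is a plateau rather than a monotone ramp.
    night_rg : float
        Records with SW_IN at or below this (W m-2) are nocturnal.
    season : {"quarter", "none"}
        Seasonal stratification; "none" treats the record as one season.
    corr_limit : float or None
        Classes where \\|Spearman rho(TA, USTAR)\\| exceeds this are skipped
        (temperature/turbulence confounding guard); None disables the check.
    """

    def __init__(self, n_temp_classes=6, n_ustar_bins=20, criterion=0.95,
                 n_compare_bins=None, night_rg=10.0, season="quarter",
                 corr_limit=0.5, min_records_per_season=240):
        self.n_temp_classes = n_temp_classes
        self.n_ustar_bins = n_ustar_bins
        self.criterion = criterion
        self.n_compare_bins = n_compare_bins
        self.night_rg = night_rg
        self.season = season
        self.corr_limit = corr_limit
        self.min_records_per_season = min_records_per_season

    def fit(self, X: pd.DataFrame, y=None):
        validate_halfhourly(X)
        night = X[(X["SW_IN"] <= self.night_rg)
                  & X["NEE"].notna() & X["USTAR"].notna()]
        if len(night) < 2 * self.n_ustar_bins:
            raise ThresholdNotEstimableError(
                f"only {len(night)} nocturnal records with NEE and u*; "
                "threshold not estimable")

        if self.season == "quarter":
            season_keys = list(zip(night.index.year, night.index.quarter))
        else:
            season_keys = [0] * len(night)
        night = night.assign(_season=season_keys)
        counts = night.groupby("_season").size()
        good = counts[counts >= self.min_records_per_season].index
        if len(good) == 0:
            night["_season"] = 0  # fall back to a single season
        else:
            night = night[night["_season"].isin(good)]

        rows = []
        for season, sub in night.groupby("_season"):
            n_classes = min(self.n_temp_classes, max(1, len(sub) // (2 * self.n_ustar_bins)))
            try:
                tclass = pd.qcut(sub["TA"], n_classes, labels=False, duplicates="drop")
            except ValueError:
                tclass = pd.Series(0, index=sub.index)
            for tc, cls in sub.groupby(tclass):
                if len(cls) < 2 * min(self.n_ustar_bins, 10):
                    continue
                if self.corr_limit is not None and cls["TA"].nunique() > 2:
                    rho = spearmanr(cls["TA"], cls["USTAR"]).statistic
                    if np.isfinite(rho) and abs(rho) > self.corr_limit:
                        continue
                thr, width, at_floor = self._class_threshold(cls)
                rows.append({"season": season, "temp_class": tc,
                             "threshold": thr, "bin_width": width,
                             "at_lowest_bin": at_floor, "n": len(cls)})
        table = pd.DataFrame(rows)
        valid = table.dropna(subset=["threshold"]) if len(table) else table
        if len(valid) == 0:
            raise ThresholdNotEstimableError(
                "no temperature class produced a threshold; not estimable")
        self.threshold_ = float(valid["threshold"].mean())
        self.bin_width_ = float(np.nanmedian(valid["bin_width"]))
        # no-suppression series fire at the lowest bin in (nearly) every
        # class; a majority rule keeps the flag robust to sampling noise
        self.degenerate_ = bool(valid["at_lowest_bin"].mean() >= 0.5)
        self.class_thresholds_ = table
        self.n_nocturnal_ = int(len(night))
        return self

    def _class_threshold(self, cls: pd.DataFrame):
        """Threshold of one temperature class from equal-count u* bins."""
        order = cls.sort_values("USTAR")
        bins = np.array_split(np.arange(len(order)), self.n_ustar_bins)
        u = np.array([order["USTAR"].to_numpy()[b].mean() for b in bins if len(b)])
        nee = np.array([order["NEE"].to_numpy()[b].mean() for b in bins if len(b)])
        widths = np.diff(u)
        width = float(np.median(widths)) if len(widths) else np.nan
        stop = len(u) if self.n_compare_bins is None else None
        for i in range(len(u) - 1):
            hi = nee[i + 1:stop or i + 1 + self.n_compare_bins]
            ref = hi.mean()
            if ref > 0 and nee[i] >= self.criterion * ref:
                # midpoint between the last failing and first passing bin
                # centers; less biased than the passing bin's own center
                thr = u[i] if i == 0 else 0.5 * (u[i - 1] + u[i])
                return float(thr), width, i == 0
        return np.nan, width, False

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted threshold (see :func:`filter_low_turbulence`)."""
        return filter_low_turbulence(X, self.result_, night_rg=self.night_rg)

    @property
    def result_(self) -> UStarThreshold:
        return UStarThreshold(
            threshold=self.threshold_,
            class_thresholds=self.class_thresholds_,
            bin_width=self.bin_width_,
            degenerate=self.degenerate_,
            n_nocturnal=self.n_nocturnal_,
        )


def estimate_ustar_threshold(records: pd.DataFrame, **kwargs) -> UStarThreshold:
    """Estimate the nocturnal u* threshold via the moving point method."""
    return UStarThresholdEstimator(**kwargs).fit(records).result_


def filter_low_turbulence(records: pd.DataFrame,
                          threshold: UStarThreshold | float,
                          night_rg: float = 10.0) -> pd.DataFrame:
    """Discard nocturnal NEE measured under low turbulence.

    Nocturnal records (SW_IN <= ``night_rg``) with u* below the threshold
    get NEE set to missing and quality flag "filtered"; daytime records are
    untouched.  The number of removed records is stored in the returned
    frame's ``attrs["n_filtered"]``.
    """
    thr = threshold.threshold if isinstance(threshold, UStarThreshold) else float(threshold)
    out = records.copy()
    night = out["SW_IN"] <= night_rg
    low = night & out["USTAR"].notna() & (out["USTAR"] < thr)
    removed = int((low & out["NEE"].notna()).sum())
    out.loc[low, "NEE"] = np.nan
    if "QC" not in out:
        out["QC"] = "original"
    out.loc[low, "QC"] = "filtered"
    out.attrs["n_filtered"] = removed
    return out


# ---------------------------------------------------------------------------
# gap filling (marginal distribution sampling)

def _default_ladder(max_window: int):
    """Tiered donor-search ladder: similar-conditions lookups in expanding
    windows, then radiation-only, then time-of-day climatology."""
    ladder = [("full", 7), ("full", 14), ("rg", 7), ("tod", 1), ("tod", 2)]
    ladder += [("full", w) for w in range(21, max_window + 1, 7)]
    ladder += [("rg", w) for w in range(14, max_window + 1, 7)]
    ladder += [("tod", w) for w in range(7, max_window + 1, 7)]
    return ladder


class MDSGapFiller(BaseEstimator, TransformerMixin):
    """Fill missing NEE by marginal distribution sampling.

    A missing half hour is replaced by the mean of observed NEE under
    similar meteorological conditions — global radiation within
    ``rg_tol`` W m-2, air temperature within ``ta_tol`` deg C and VPD
    within ``vpd_tol`` hPa — searched in a time window that expands tier by
    tier; when no similar-conditions donors exist the search degrades to
    radiation-only similarity and finally to a time-of-day climatology
    (same half hour +/- 1 h).  Each filled value carries the standard
    deviation of its donor set and a tier label.  Only days containing at
    least one observation are filled.
    """

    def __init__(self, rg_tol=50.0, ta_tol=2.5, vpd_tol=5.0,
                 min_donors=2, max_window=70, night_rg=10.0):
        self.rg_tol = rg_tol
        self.ta_tol = ta_tol
        self.vpd_tol = vpd_tol
        self.min_donors = min_donors
        self.max_window = max_window
        self.night_rg = night_rg

    def fit(self, X: pd.DataFrame, y=None):
        validate_halfhourly(X)
        self.n_records_ = len(X)
        self.ladder_ = _default_ladder(self.max_window)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return ``X`` with columns NEE_f, NEE_fsd, NEE_fqc and fill_tier.

        NEE_fqc is 0 for originally observed values (fill SD 0) and the
        1-based ladder tier otherwise; unfillable records keep NEE_f = NaN
        with tier label "unfilled".
        """
        df = X.copy()
        nee = df["NEE"].to_numpy(dtype=float)
        rg = df["SW_IN"].to_numpy(dtype=float)
        ta = df["TA"].to_numpy(dtype=float) if "TA" in df else np.full(len(df), np.nan)
        vpd = df["VPD"].to_numpy(dtype=float) if "VPD" in df else np.full(len(df), np.nan)
        observed = np.isfinite(nee)

        filled = nee.copy()
        fsd = np.where(observed, 0.0, np.nan)
        fqc = np.where(observed, 0, -1)
        tier_label = np.where(observed, "original", "unfilled").astype(object)

        # only days with at least one observation are filled
        day = (df.index - pd.Timedelta("1ns")).normalize()
        day_codes, _ = pd.factorize(day)
        day_has_obs = np.zeros(day_codes.max() + 1, dtype=bool)
        np.add.at(day_has_obs, day_codes[observed], True)

        per_tier = {}
        n = len(df)
        for i in np.flatnonzero(~observed):
            if not day_has_obs[day_codes[i]]:
                continue
            for t_idx, (mode, win) in enumerate(self.ladder_, start=1):
                donors = self._donors(i, mode, win, n, observed, rg, ta, vpd)
                if donors is None or donors.size < max(self.min_donors, 2):
                    continue
                vals = nee[donors]
                filled[i] = vals.mean()
                fsd[i] = vals.std(ddof=1)
                fqc[i] = t_idx
                label = f"{mode}±{win}d"
                tier_label[i] = label
                per_tier[label] = per_tier.get(label, 0) + 1
                break

        df["NEE_f"] = filled
        df["NEE_fsd"] = fsd
        df["NEE_fqc"] = fqc
        df["fill_tier"] = tier_label
        df.attrs["fills_per_tier"] = per_tier
        df.attrs["n_unfilled"] = int((fqc == -1).sum())
        self.fills_per_tier_ = per_tier
        return df

    def _donors(self, i, mode, win, n, observed, rg, ta, vpd):
        half = win * 48
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if mode == "tod":
            # same half hour +/- 1 h (2 half-hour steps), +/- win days
            offs = np.arange(-win, win + 1)[:, None] * 48 + np.arange(-2, 3)[None, :]
            cand = (i + offs).ravel()
            cand = cand[(cand >= 0) & (cand < n) & (cand != i)]
            cand = cand[observed[cand]]
            return cand if cand.size else None
        sl = slice(lo, hi)
        mask = observed[sl].copy()
        if mode == "full":
            if not (np.isfinite(rg[i]) and np.isfinite(ta[i]) and np.isfinite(vpd[i])):
                return None
            mask &= (np.abs(rg[sl] - rg[i]) <= self.rg_tol)
            mask &= (np.abs(ta[sl] - ta[i]) <= self.ta_tol)
            mask &= (np.abs(vpd[sl] - vpd[i]) <= self.vpd_tol)
        elif mode == "rg":
            if not np.isfinite(rg[i]):
                return None
            mask &= (np.abs(rg[sl] - rg[i]) <= self.rg_tol)
        idx = np.flatnonzero(mask) + lo
        idx = idx[idx != i]
        return idx if idx.size else None


def gapfill_mds(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Gap-fill NEE by marginal distribution sampling (see MDSGapFiller)."""
    return MDSGapFiller(**kwargs).fit(records).transform(records)


# ---------------------------------------------------------------------------
# daytime partitioning (light response with VPD limitation)

def _nee_daytime_model(rg, ta, vpd, alpha, beta0, k, rb, e0, vpd0):
    beta = np.where(vpd > vpd0, beta0 * np.exp(-k * (vpd - vpd0)), beta0)
    uptake = alpha * beta * rg / (alpha * rg + beta)
    return -uptake + lloyd_taylor(ta, rb, e0)


class DaytimePartitioner(BaseEstimator):
    """Split NEE into GPP and ecosystem respiration via the daytime method.

    Fits, in moving windows, the rectangular-hyperbola light response

        NEE = -(alpha * beta * Rg) / (alpha * Rg + beta) + rb * f(Ta; E0)

    with the maximum uptake capacity beta down-regulated above a VPD
    threshold: beta = beta0 for VPD <= VPD0 and
    beta = beta0 * exp(-k (VPD - VPD0)) otherwise.  The temperature
    sensitivity E0 of the exponential respiration term is estimated once
    from nocturnal data over the whole series (short windows leave it
    unidentifiable) and held fixed within windows.

    After fitting, ``transform`` assigns each half hour the respiration of
    its nearest valid window, derives GPP = Reco - NEE, forces nocturnal
    GPP to zero and clamps negative GPP (fit noise) to zero with the
    residual pushed into Reco, preserving NEE = Reco - GPP per record.

    Parameters
    ----------
    window_days : int
        Moving-window length in days (default 7).
    step_days : int
        Window advance per fit.
    vpd0 : float
        VPD threshold, hPa (default 10).
    night_rg : float
        Daytime records have SW_IN above this cutoff (W m-2).
    min_points : int
        Minimum daytime points for a window fit.
    min_vpd_points : int
        Minimum points above VPD0 for the VPD sensitivity k to be
        identifiable; otherwise k is fixed at 0 and flagged.
    use_filled : bool
        Fit on gap-filled values too (default: observed only).
    """

    def __init__(self, window_days=7, step_days=2, vpd0=10.0, night_rg=10.0,
                 min_points=20, min_vpd_points=5, use_filled=False,
                 e0_bounds=(30.0, 450.0)):
        self.window_days = window_days
        self.step_days = step_days
        self.vpd0 = vpd0
        self.night_rg = night_rg
        self.min_points = min_points
        self.min_vpd_points = min_vpd_points
        self.use_filled = use_filled
        self.e0_bounds = e0_bounds

    # -- nocturnal E0 -------------------------------------------------------
    def _fit_e0(self, night: pd.DataFrame):
        ta = night["TA"].to_numpy(float)
        nee = night["NEE"].to_numpy(float)
        ok = np.isfinite(ta) & np.isfinite(nee)
        if ok.sum() < 10:
            raise RuntimeError("too few nocturnal records to estimate E0")
        lo, hi = self.e0_bounds
        popt, _ = curve_fit(
            lambda t, rb, e0: lloyd_taylor(t, rb, e0),
            ta[ok], nee[ok], p0=(3.0, 150.0),
            bounds=([1e-6, lo], [100.0, hi]), maxfev=10000)
        return float(popt[0]), float(popt[1])

    def fit(self, X: pd.DataFrame, y=None):
        validate_halfhourly(X)
        nee_col = "NEE_f" if (self.use_filled and "NEE_f" in X) else "NEE"
        obs = X[X[nee_col].notna()]
        if not self.use_filled and "QC" in obs:
            obs = obs[obs["QC"] == "original"]

        night = obs[obs["SW_IN"] <= self.night_rg]
        self.rb_night_, self.e0_ = self._fit_e0(night.rename(columns={nee_col: "NEE"}))

        day = obs[obs["SW_IN"] > self.night_rg]
        if len(day) == 0:
            raise RuntimeError("no daytime records; partitioning aborted")

        start = X.index[0].normalize()
        end = X.index[-1]
        half = pd.Timedelta(days=self.window_days / 2)
        centers = pd.date_range(start + half, end, freq=f"{self.step_days}D")
        rows = []
        for c in centers:
            w = day[(day.index >= c - half) & (day.index < c + half)]
            rows.append(self._fit_window(c, w, nee_col))
        fits = pd.DataFrame(rows)
        if len(fits) == 0 or not fits["valid"].any():
            raise RuntimeError("no valid light-response window in the series; "
                               "partitioning aborted")
        self.fits_ = fits
        self.n_windows_invalid_ = int((~fits["valid"]).sum())
        return self

    def _fit_window(self, center, w: pd.DataFrame, nee_col: str) -> dict:
        base = {"center": center, "n_points": len(w), "alpha": np.nan,
                "beta0": np.nan, "k": np.nan, "rb": np.nan, "e0": self.e0_,
                "vpd0": self.vpd0, "rmse": np.nan, "r2": np.nan,
                "valid": False, "k_identifiable": False}
        if len(w) < self.min_points:
            return base
        rg = w["SW_IN"].to_numpy(float)
        ta = w["TA"].to_numpy(float)
        vpd = w["VPD"].to_numpy(float)
        nee = w[nee_col].to_numpy(float)
        ok = np.isfinite(rg) & np.isfinite(ta) & np.isfinite(vpd) & np.isfinite(nee)
        if ok.sum() < self.min_points:
            return base
        rg, ta, vpd, nee = rg[ok], ta[ok], vpd[ok], nee[ok]

        k_ident = int((vpd > self.vpd0).sum()) >= self.min_vpd_points
        base["k_identifiable"] = k_ident
        rb0 = max(float(lloyd_taylor(ta.mean(), 1.0, self.e0_)) * 3.0, 0.5)
        beta_guess = float(np.clip(rb0 - np.min(nee), 1.0, 250.0))

        e0 = self.e0_
        vpd0 = self.vpd0
        try:
            if k_ident:
                popt, _ = curve_fit(
                    lambda X_, a, b, k, r: _nee_daytime_model(
                        X_[0], X_[1], X_[2], a, b, k, r, e0, vpd0),
                    np.vstack([rg, ta, vpd]), nee,
                    p0=(0.02, beta_guess, 0.05, rb0),
                    bounds=([1e-7, 0.1, 0.0, 0.0], [0.5, 300.0, 3.0, 100.0]),
                    maxfev=20000)
                alpha, beta0, k, rb = popt
            else:
                popt, _ = curve_fit(
                    lambda X_, a, b, r: _nee_daytime_model(
                        X_[0], X_[1], X_[2], a, b, 0.0, r, e0, vpd0),
                    np.vstack([rg, ta, vpd]), nee,
                    p0=(0.02, beta_guess, rb0),
                    bounds=([1e-7, 0.1, 0.0], [0.5, 300.0, 100.0]),
                    maxfev=20000)
                alpha, beta0, rb = popt
                k = 0.0
        except RuntimeError:
            return base

        pred = _nee_daytime_model(rg, ta, vpd, alpha, beta0, k, rb, e0, vpd0)
        resid = nee - pred
        ss_tot = float(np.sum((nee - nee.mean()) ** 2))
        base.update(alpha=float(alpha), beta0=float(beta0), k=float(k),
                    rb=float(rb), rmse=float(np.sqrt(np.mean(resid**2))),
                    r2=1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan,
                    valid=bool(beta0 < 295.0 and alpha < 0.49))
        return base

    # -- apply --------------------------------------------------------------
    def transform(self, filled: pd.DataFrame) -> pd.DataFrame:
        """Attach per-record RECO and GPP columns to a gap-filled frame."""
        df = filled.copy()
        nee_col = "NEE_f" if "NEE_f" in df else "NEE"
        valid = self.fits_[self.fits_["valid"]].sort_values("center")
        centers = valid["center"].to_numpy()
        # nearest valid window per record (invalid windows bridged)
        pos = np.searchsorted(centers, df.index.to_numpy())
        pos = np.clip(pos, 0, len(centers) - 1)
        left = np.clip(pos - 1, 0, len(centers) - 1)
        use_left = np.abs(df.index.to_numpy() - centers[left]) <= np.abs(
            df.index.to_numpy() - centers[pos])
        nearest = np.where(use_left, left, pos)
        rb = valid["rb"].to_numpy()[nearest]

        ta = df["TA"].to_numpy(float)
        rg = df["SW_IN"].to_numpy(float)
        nee = df[nee_col].to_numpy(float)
        reco = rb * np.asarray(lloyd_taylor(ta, 1.0, self.e0_))
        gpp = reco - nee

        night = rg <= self.night_rg
        reco = np.where(night, nee, reco)
        gpp = np.where(night, 0.0, gpp)
        neg = (~night) & (gpp < 0)
        self.n_clamped_ = int(np.nansum(neg & np.isfinite(gpp)))
        reco = np.where(neg, nee, reco)
        gpp = np.where(neg, 0.0, gpp)

        excluded = ~np.isfinite(nee) | ~np.isfinite(reco)
        reco[excluded] = np.nan
        gpp[excluded] = np.nan
        df["RECO"] = reco
        df["GPP"] = gpp
        df["part_excluded"] = excluded
        return df


def fit_daytime_partition(records: pd.DataFrame, window_days: int = 7,
                          **kwargs) -> pd.DataFrame:
    """Fit the daytime light-response model in moving windows.

    Returns the per-window parameter table (one row per window with alpha,
    beta0, k, rb, E0, validity flags and goodness of fit).
    """
    return DaytimePartitioner(window_days=window_days, **kwargs).fit(records).fits_


def partition_series(filled: pd.DataFrame,
                     partitioner: DaytimePartitioner) -> pd.DataFrame:
    """Per-record GPP and Reco from a fitted partitioner (wrapper)."""
    return partitioner.transform(filled)


# ---------------------------------------------------------------------------
# daily aggregation

def aggregate_daily(part: pd.DataFrame, period_col: str = "PERIOD") -> pd.DataFrame:
    """Aggregate partitioned half-hourly fluxes to daily g C m-2 d-1.

    A day (half-open interval of 48 half-hour-ending records) enters the
    table only if it is complete — 48 records, none excluded from
    partitioning — and contains at least one originally observed value.
    Excluded days are listed in ``attrs["days_excluded"]``.
    """
    df = part.copy()
    day = (df.index - pd.Timedelta("1ns")).normalize()
    nee_col = "NEE_f" if "NEE_f" in df else "NEE"
    fqc = df["NEE_fqc"] if "NEE_fqc" in df else pd.Series(0, index=df.index)

    rows, excluded = [], []
    for d, sub in df.groupby(day):
        sub_fqc = fqc.loc[sub.index]
        n_obs = int((sub_fqc == 0).sum())
        complete = (len(sub) == 48
                    and sub[nee_col].notna().all()
                    and sub["RECO"].notna().all())
        if not complete or n_obs == 0:
            excluded.append(str(d.date()))
            continue
        rows.append({
            "date": d,
            "NEE": float(sub[nee_col].sum() * HALFHOUR_TO_GC),
            "GPP": float(sub["GPP"].sum() * HALFHOUR_TO_GC),
            "RECO": float(sub["RECO"].sum() * HALFHOUR_TO_GC),
            "frac_filled": float((sub_fqc > 0).mean()),
            "period": sub[period_col].mode().iat[0] if period_col in sub else "all",
            "n_observed": n_obs,
        })
    daily = pd.DataFrame(rows).set_index("date") if rows else pd.DataFrame(
        columns=["NEE", "GPP", "RECO", "frac_filled", "period", "n_observed"])
    daily.attrs["days_excluded"] = excluded
    return daily


# ---------------------------------------------------------------------------
# uncertainty budget

#: default per-source random-error SDs (g C m-2 d-1) entering the random
#: term in quadrature; the sources follow the usual tower error inventory
#: (u*, wind speed, air density, momentum flux) with magnitudes that are a
#: documented, configurable default rather than site measurements.
DEFAULT_RANDOM_ERROR_SOURCES = {
    "ustar": 0.25,
    "wind_speed": 0.25,
    "air_density": 0.25,
    "momentum_flux": 0.25,
}


@dataclass
class UncertaintyBudget:
    """Root-sum-of-squares uncertainty budget for daily NEE."""

    terms: dict                      # g C m-2 d-1 per named term
    total: float                     # sqrt of the sum of squared terms
    fractions: dict                  # squared-term share of total^2
    relative_uncertainty: dict = field(default_factory=dict)  # % per flux
    warnings: list = field(default_factory=list)


def relative_uncertainty(mean: float, sd: float) -> int:
    """SD/mean x 100, rounded to the nearest integer percent."""
    return int(round(abs(sd / mean) * 100.0))


def uncertainty_budget(daily: pd.DataFrame, filled: pd.DataFrame | None = None,
                       random_error_sources: dict | None = None) -> UncertaintyBudget:
    """Combine random, gap-filling and observed-SD error terms by RSS.

    The random term combines the configured per-source SDs in quadrature;
    the gap-filling term propagates the per-record fill SDs to a
    representative daily value (root mean square across days); the
    observed-SD term is the standard deviation of the daily NEE estimates.
    """
    warns = []
    sources = DEFAULT_RANDOM_ERROR_SOURCES if random_error_sources is None \
        else random_error_sources
    random_term = float(np.sqrt(np.sum(np.square(list(sources.values())))))

    if filled is not None and "NEE_fsd" in filled:
        day = (filled.index - pd.Timedelta("1ns")).normalize()
        fsd2 = (filled["NEE_fsd"].fillna(0.0) ** 2).groupby(day).sum()
        daily_fill_se = np.sqrt(fsd2.to_numpy()) * HALFHOUR_TO_GC
        gap_term = float(np.sqrt(np.mean(daily_fill_se**2))) if daily_fill_se.size else 0.0
    else:
        gap_term = 0.0
        warns.append("fill SDs unavailable; gap-filling term omitted")

    obs_term = float(daily["NEE"].std(ddof=1)) if len(daily) > 1 else 0.0

    terms = {"random": random_term, "gap_filling": gap_term, "observed_sd": obs_term}
    total = float(np.sqrt(np.sum(np.square(list(terms.values())))))
    fractions = {k: (v**2 / total**2 if total > 0 else 0.0) for k, v in terms.items()}

    rel = {}
    for flux in ("NEE", "GPP", "RECO"):
        if flux in daily and len(daily) > 1 and daily[flux].mean() != 0:
            rel[flux] = relative_uncertainty(daily[flux].mean(), daily[flux].std(ddof=1))
    if warns:
        warnings.warn("; ".join(warns), stacklevel=2)
    return UncertaintyBudget(terms, total, fractions, rel, warns)


# ---------------------------------------------------------------------------
# period summaries

@dataclass
class PeriodSummary:
    """Per-period daily-flux statistics."""

    period: str
    n_days: int
    means: dict
    sds: dict
    relative_uncertainty: dict


def summarize_periods(daily: pd.DataFrame, test: str = "rank-sum"):
    """Per-period mean/SD of daily NEE, GPP, Reco and pairwise tests.

    Pairwise two-sample rank tests between periods use days as replicates
    (exact enumeration for small n, normal approximation otherwise); a
    paired signed-rank variant is available via ``test="signed-rank"``.
    Returns ``(summaries, tests)``; with a single period the test table is
    empty.
    """
    fluxes = ("NEE", "GPP", "RECO")
    summaries = []
    for period, sub in daily.groupby("period", sort=False):
        means = {f: float(sub[f].mean()) for f in fluxes}
        sds = {f: float(sub[f].std(ddof=1)) if len(sub) > 1 else 0.0 for f in fluxes}
        rel = {f: relative_uncertainty(means[f], sds[f])
               for f in fluxes if means[f] != 0 and len(sub) > 1}
        summaries.append(PeriodSummary(str(period), len(sub), means, sds, rel))

    rows = []
    labels = [s.period for s in summaries]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = daily[daily["period"] == labels[i]]
            b = daily[daily["period"] == labels[j]]
            if len(a) < 2 or len(b) < 2:
                continue
            for f in fluxes:
                if test == "signed-rank":
                    m = min(len(a), len(b))
                    res: TestResult = signed_rank_test(a[f].to_numpy()[:m],
                                                       b[f].to_numpy()[:m])
                else:
                    res = rank_sum_test(a[f], b[f])
                rows.append({"period_a": labels[i], "period_b": labels[j],
                             "flux": f, "test": res.test,
                             "statistic": res.statistic, "p_value": res.p_value})
    tests = pd.DataFrame(rows)
    return summaries, tests
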