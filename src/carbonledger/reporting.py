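"""Cross-method comparison and delimited-text report bundles.

The eddy-covariance and plot-based pipelines estimate the same three
quantities (NEE, GPP, ecosystem respiration) in different units on
different footprints; this module aligns them in a common unit, builds 95%
confidence intervals on each side and reports whether they overlap, and
writes every pipeline output as a reproducible delimited-text bundle with
a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
from scipy import stats as sps

from .units import GC_M2_D, MGC_HA_YR, convert_flux_units

__all__ = ["MethodComparison", "compare_methods", "build_report"]


@dataclass
class MethodComparison:
    """An eddy estimate and a biometric estimate of one flux, aligned."""

    quantity: str              # NEE | GPP | R_eco
    unit: str
    eddy_mean: float
    eddy_ci: tuple[float, float]
    biometric_mean: float
    biometric_ci: tuple[float, float]
    overlap: bool
    difference: float          # eddy - biometric, common unit


def _interval(mean, half):
    return (mean - half, mean + half)


def _overlaps(a, b):
    return a[0] <= b[1] and b[0] <= a[1]


def compare_methods(quantity: str,
                    eddy_mean: float, eddy_uncertainty: float,
                    biometric_mean: float, biometric_se: float,
                    eddy_unit: str = GC_M2_D,
                    biometric_unit: str = MGC_HA_YR,
                    unit: str = MGC_HA_YR,
                    biometric_n: int | None = None,
                    z: float = 1.96) -> MethodComparison:
    """Align the two methods' estimates of one flux and compare their CIs.

    The eddy CI is mean +/- 1.96 x its total (RSS) uncertainty — the daily
    estimates are numerous, so a normal multiplier is used.  The biometric
    CI uses a t multiplier with n - 1 df when the estimate is a group mean
    over ``biometric_n`` plots, and the normal multiplier for a single plot
    whose SE comes from component error propagation.
    """
    e_mean = convert_flux_units(eddy_mean, eddy_unit, unit)
    e_half = z * convert_flux_units(eddy_uncertainty, eddy_unit, unit)
    b_mean = convert_flux_units(biometric_mean, biometric_unit, unit)
    mult = z if biometric_n is None or biometric_n < 2 else float(
        sps.t.ppf(0.975, biometric_n - 1))
    b_half = mult * convert_flux_units(biometric_se, biometric_unit, unit)
    eddy_ci = _interval(e_mean, abs(e_half))
    bio_ci = _interval(b_mean, abs(b_half))
    return MethodComparison(
        quantity=quantity, unit=unit,
        eddy_mean=e_mean, eddy_ci=eddy_ci,
        biometric_mean=b_mean, biometric_ci=bio_ci,
        overlap=_overlaps(eddy_ci, bio_ci),
        difference=e_mean - b_mean,
    )


def _config_hash(config) -> str:
    payload = json.dumps(repr(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_report(out_dir, daily: pd.DataFrame | None = None,
                 period_summaries=None, period_tests: pd.DataFrame | None = None,
                 budgets: pd.DataFrame | None = None,
                 group_comparisons=None,
                 method_comparisons=None,
                 config=None, seed=None, inputs=None) -> dict:
    """Write all pipeline outputs as delimited text plus a run manifest.

    Missing sections are recorded as explicit "no results" markers in the
    manifest rather than silently absent.  Returns the manifest dict.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def _write(name, df):
        path = out / f"{name}.csv"
        df.to_csv(path, float_format="%.10g")
        written[name] = {"path": path.name, "rows": int(len(df))}

    if daily is not None and len(daily):
        _write("daily_fluxes", daily)
    if period_summaries:
        rows = []
        for s in period_summaries:
            row = {"period": s.period, "n_days": s.n_days}
            for f, v in s.means.items():
                row[f"{f}_mean"] = v
            for f, v in s.sds.items():
                row[f"{f}_sd"] = v
            rows.append(row)
        _write("period_summaries", pd.DataFrame(rows).set_index("period"))
    if period_tests is not None and len(period_tests):
        _write("period_tests", period_tests.set_index("period_a"))
    if budgets is not None and len(budgets):
        _write("plot_budgets", budgets.set_index("plot"))
    if group_comparisons:
        rows = []
        for c in group_comparisons:
            rows.append({
                "quantity": c.quantity, "group_a": c.group_a, "group_b": c.group_b,
                "mean_a": c.mean_a, "se_a": c.se_a, "n_a": c.n_a,
                "mean_b": c.mean_b, "se_b": c.se_b, "n_b": c.n_b,
                "t": c.t.statistic, "t_df": c.t.df, "t_p": c.t.p_value,
                "ranksum_stat": c.rank_sum.statistic, "ranksum_p": c.rank_sum.p_value,
            })
        _write("group_comparisons", pd.DataFrame(rows).set_index("quantity"))
    if method_comparisons:
        _write("method_comparison",
               pd.DataFrame([asdict(m) for m in method_comparisons]).set_index("quantity"))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config) if config is not None else None,
        "inputs": inputs or {},
        "tables": written if written else "no results",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
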