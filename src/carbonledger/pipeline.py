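"""End-to-end convenience drivers for the two pipelines."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import budget as bg
from . import eddy

__all__ = ["EddyResults", "process_tower", "process_plots"]


@dataclass
class EddyResults:
    """Everything the tower pipeline produces, in processing order."""

    threshold: eddy.UStarThreshold | None
    filtered: pd.DataFrame
    filled: pd.DataFrame
    fits: pd.DataFrame
    partitioned: pd.DataFrame
    daily: pd.DataFrame
    uncertainty: eddy.UncertaintyBudget
    summaries: list
    tests: pd.DataFrame
    log: dict


def process_tower(records: pd.DataFrame, ustar="auto", vpd0: float = 10.0,
                  window_days: int = 7, step_days: int = 2,
                  random_error_sources: dict | None = None,
                  partitioner_kwargs: dict | None = None,
                  gapfiller_kwargs: dict | None = None,
                  threshold_kwargs: dict | None = None) -> EddyResults:
    """Run u* filtering, gap filling, partitioning and daily aggregation.

    ``ustar`` is "auto" (moving-point detection), a numeric threshold, or
    None to skip filtering.
    """
    eddy.validate_halfhourly(records)
    threshold = None
    if ustar == "auto":
        threshold = eddy.estimate_ustar_threshold(records, **(threshold_kwargs or {}))
        filtered = eddy.filter_low_turbulence(records, threshold)
    elif ustar is None:
        filtered = records.copy()
        filtered.attrs["n_filtered"] = 0
    else:
        filtered = eddy.filter_low_turbulence(records, float(ustar))

    filler = eddy.MDSGapFiller(**(gapfiller_kwargs or {})).fit(filtered)
    filled = filler.transform(filtered)

    part_kwargs = dict(window_days=window_days, step_days=step_days, vpd0=vpd0)
    part_kwargs.update(partitioner_kwargs or {})
    partitioner = eddy.DaytimePartitioner(**part_kwargs).fit(filled)
    partitioned = partitioner.transform(filled)

    daily = eddy.aggregate_daily(partitioned)
    uncertainty = eddy.uncertainty_budget(daily, filled,
                                          random_error_sources=random_error_sources)
    summaries, tests = eddy.summarize_periods(daily)
    log = {
        "n_records": len(records),
        "n_filtered": filtered.attrs.get("n_filtered", 0),
        "fills_per_tier": filled.attrs.get("fills_per_tier", {}),
        "n_unfilled": filled.attrs.get("n_unfilled", 0),
        "n_windows_invalid": partitioner.n_windows_invalid_,
        "n_gpp_clamped": partitioner.n_clamped_,
        "days_excluded": daily.attrs.get("days_excluded", []),
    }
    return EddyResults(threshold, filtered, filled, partitioner.fits_,
                       partitioned, daily, uncertainty, summaries, tests, log)


def process_plots(tables: dict, allometry: tuple[float, float],
                  design: bg.SoilPartitionDesign | None = None,
                  groups: dict | None = None) -> pd.DataFrame:
    """Raw measurement tables -> assembled plot budgets."""
    components = bg.components_from_raw_tables(tables, allometry, design)
    return bg.assemble_budget(components, groups=groups)
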