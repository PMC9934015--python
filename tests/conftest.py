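"""Shared fixtures: small synthetic runs reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from carbonledger.synthetic import (
    PeriodSpec,
    PlotSimConfig,
    TowerSimConfig,
    simulate_plot_dataset,
    simulate_tower_series,
)

TRUE_PARAMS = {"alpha": 0.06, "beta0": 45.0, "k": 0.05, "rb": 8.0, "e0": 180.0}


def single_period_config(n_days, **overrides):
    """A one-period tower config with unit period scaling."""
    defaults = dict(
        periods=(PeriodSpec("only", "2015-01-01", n_days),),
        period_scales={"only": 1.0},
    )
    defaults.update(overrides)
    return TowerSimConfig(**defaults)


@pytest.fixture(scope="session")
def tower_noiseless():
    """21 noise-free, gap-free days; partitioning is exactly invertible."""
    cfg = single_period_config(21, noise_sd=0.0, gap_fraction=0.0, seed=3)
    records, truth = simulate_tower_series(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def tower_noisy():
    """A realistic 455-day single-period run with noise and gaps."""
    cfg = single_period_config(455, noise_sd=2.0, gap_fraction=0.495, seed=11)
    records, truth = simulate_tower_series(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def plot_sim_noiseless():
    """Plot dataset with all noise off: pipeline must recover truth exactly."""
    cfg = PlotSimConfig(seed=5, replicate_noise_rel=0.0, npp_se_rel=0.0)
    for g in cfg.groups.values():
        g.between_plot_sd = 0.0
    tables, truth_components, truth = simulate_plot_dataset(cfg)
    return cfg, tables, truth_components, truth


@pytest.fixture(scope="session")
def plot_sim_noisy():
    cfg = PlotSimConfig(seed=9)
    tables, truth_components, truth = simulate_plot_dataset(cfg)
    return cfg, tables, truth_components, truth


def make_halfhourly(n, start="2015-06-01 00:30", seed=0, nee=None, rg=None,
                    ta=None, vpd=None, ustar=None, period="all"):
    """Hand-buildable half-hourly frame with sane defaults."""
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=n, freq="30min")
    hours = (idx - pd.Timedelta(minutes=15)).hour + (idx - pd.Timedelta(minutes=15)).minute / 60
    if rg is None:
        frac = (np.asarray(hours, float) - 6.0) / 12.0
        rg = np.where((frac > 0) & (frac < 1), 700 * np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    if ta is None:
        ta = 26.0 + 3.0 * np.sin(2 * np.pi * (np.asarray(hours, float) - 8) / 24)
    if vpd is None:
        vpd = np.maximum(0.0, 8.0 + 1.5 * (np.asarray(ta, float) - 26.0))
    if ustar is None:
        ustar = rng.lognormal(np.log(0.3), 0.5, n)
    if nee is None:
        nee = rng.normal(2.0, 1.0, n)
    return pd.DataFrame(
        {"NEE": nee, "SW_IN": rg, "TA": ta, "VPD": vpd, "USTAR": ustar,
         "PERIOD": period, "QC": "original"},
        index=idx,
    )
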