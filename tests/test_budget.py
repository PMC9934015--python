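"""Biometric budget: partitioning, scaling, assembly, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carbonledger.budget import (
    BudgetAssembler,
    DeadwoodScalingInput,
    LeafScalingInput,
    SoilCollarSet,
    SoilPartitionDesign,
    StemScalingInput,
    assemble_budget,
    compare_groups,
    components_from_raw_tables,
    cylinder_lateral_area,
    partition_soil_respiration,
    scale_deadwood_respiration,
    scale_leaf_respiration,
    scale_stem_respiration,
)
from carbonledger.synthetic import (
    COMPONENTS,
    NPP_COMPONENTS,
    RH_COMPONENTS,
    PlotSimConfig,
    simulate_plot_dataset,
)
from carbonledger.units import MGC_HA_YR, convert_flux_units

UMOL_TO_MG = convert_flux_units(1.0, "umol CO2 m-2 s-1", MGC_HA_YR)


def _collars(means, ses=None):
    return SoilCollarSet("P1", means, ses or {t: 0.0 for t in means},
                        {t: 4 for t in means}, flux_unit=MGC_HA_YR)


class TestSoilPartition:
    def test_cumulative_design_difference_oracle(self):
        """total 10 / no-roots 7 / no-roots-no-myco 6 / SOM-only 4
        -> root 3, mycorrhiza 1, litter 2, SOM 4; components re-sum to 10."""
        comp = partition_soil_respiration(
            _collars({"total": 10.0, "no_roots": 7.0,
                      "no_roots_no_myco": 6.0, "som_only": 4.0}))
        vals = comp.set_index("component")["value"]
        assert vals["fine_root_r"] == pytest.approx(3.0)
        assert vals["mycorrhiza_rh"] == pytest.approx(1.0)
        assert vals["litter_rh"] == pytest.approx(2.0)
        assert vals["som_rh"] == pytest.approx(4.0)
        assert vals.sum() == pytest.approx(10.0)

    def test_equal_treatments_put_everything_in_som(self):
        comp = partition_soil_respiration(
            _collars({t: 6.0 for t in ("total", "no_roots",
                                       "no_roots_no_myco", "som_only")}))
        vals = comp.set_index("component")["value"]
        assert vals["som_rh"] == pytest.approx(6.0)
        assert vals[["fine_root_r", "mycorrhiza_rh", "litter_rh"]].abs().max() < 1e-12

    def test_se_quadrature_three_four_five(self):
        comp = partition_soil_respiration(_collars(
            {"total": 10.0, "no_roots": 7.0, "no_roots_no_myco": 6.0, "som_only": 4.0},
            {"total": 0.3, "no_roots": 0.4, "no_roots_no_myco": 0.0, "som_only": 0.0}))
        se = comp.set_index("component")["se"]
        assert se["fine_root_r"] == pytest.approx(0.5)

    def test_missing_treatment_flagged_unavailable(self):
        comp = partition_soil_respiration(_collars({"total": 10.0, "som_only": 4.0}))
        row = comp[comp["component"] == "fine_root_r"].iloc[0]
        assert np.isnan(row["value"])
        assert row["provenance"] == "unavailable"


class TestScaling:
    def test_stem_dimensional_analysis_oracle(self):
        """1 umol m-2 s-1 over 10,000 m2 stem area on 1 ha -> ~3.79 Mg C/ha/yr."""
        # a D for which a * D^b = 100 m2 per tree, 100 trees -> 10,000 m2
        inp = StemScalingInput("P1", np.array([1.0, 1.0]),
                               np.full(100, (100 / 0.05) ** (1 / 1.5)),
                               allometry_a=0.05, allometry_b=1.5)
        out = scale_stem_respiration(inp)
        expected = 12.011e-6 * 31_536_000 * 10_000 / 1e6  # g C -> Mg C on 1 ha
        assert out["value"].iloc[0] == pytest.approx(3.7880, abs=2e-3)
        assert out["value"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_zero_flux_scales_to_zero(self):
        inp = StemScalingInput("P1", np.zeros(5), np.full(50, 30.0), 0.05, 1.5)
        assert scale_stem_respiration(inp)["value"].iloc[0] == 0.0

    def test_linear_allometry_doubles_with_diameter(self):
        d = np.full(50, 30.0)
        base = scale_stem_respiration(StemScalingInput("P1", np.ones(5), d, 0.05, 1.0))
        doubled = scale_stem_respiration(StemScalingInput("P1", np.ones(5), 2 * d, 0.05, 1.0))
        assert doubled["value"].iloc[0] == pytest.approx(2 * base["value"].iloc[0])

    def test_deadwood_cylinder_geometry(self):
        """A 20 cm x 2 m piece has lateral area pi * 0.2 * 2 = 1.257 m2."""
        assert cylinder_lateral_area(20.0, 2.0) == pytest.approx(1.2566, abs=1e-4)
        inp = DeadwoodScalingInput("P1", np.array([1.0, 1.0]),
                                   np.array([20.0]), np.array([2.0]))
        out = scale_deadwood_respiration(inp)
        assert out["value"].iloc[0] == pytest.approx(
            1.2566 / 10_000 * UMOL_TO_MG, rel=1e-3)

    def test_halving_inventory_halves_flux(self):
        full = DeadwoodScalingInput("P1", np.ones(3), np.full(10, 20.0), np.full(10, 2.0))
        half = DeadwoodScalingInput("P1", np.ones(3), np.full(5, 20.0), np.full(5, 2.0))
        assert scale_deadwood_respiration(half)["value"].iloc[0] == pytest.approx(
            scale_deadwood_respiration(full)["value"].iloc[0] / 2)

    def test_deadwood_inventory_rejects_small_pieces(self):
        with pytest.raises(ValueError, match=">= 10 cm"):
            DeadwoodScalingInput("P1", np.ones(2), np.array([8.0]), np.array([1.0]))

    def test_leaf_fraction_independence_when_sun_equals_shade(self):
        """R_sun = R_shade = r gives canopy flux r x LAI before correction."""
        out = scale_leaf_respiration(LeafScalingInput(
            "P1", 0.5, 0.5, 0.3, 0.7, lai=4.0, inhibition_factor=1.0))
        assert out["value"].iloc[0] == pytest.approx(0.5 * 4.0 * UMOL_TO_MG)

    def test_leaf_inhibition_factor_one_is_uncorrected(self):
        kw = dict(r_sun=0.8, r_shade=0.4, f_sun=0.25, f_shade=0.75, lai=4.0)
        raw = scale_leaf_respiration(LeafScalingInput("P1", **kw, inhibition_factor=1.0))
        assert raw["value"].iloc[0] == pytest.approx(
            (0.8 * 0.25 + 0.4 * 0.75) * 4.0 * UMOL_TO_MG)

    def test_leaf_hand_computed_chain(self):
        """Step-by-step arithmetic: 0.5 umol x LAI 4, 0.67 on 12 daylight hours."""
        out = scale_leaf_respiration(LeafScalingInput(
            "P1", 0.8, 0.4, 0.25, 0.75, lai=4.0, inhibition_factor=0.67))
        mean_leaf = 0.8 * 0.25 + 0.4 * 0.75        # 0.5 umol m-2 leaf s-1
        canopy = mean_leaf * 4.0                    # per ground area
        diurnal = (12 * 0.67 + 12) / 24             # 0.835
        assert out["value"].iloc[0] == pytest.approx(canopy * diurnal * UMOL_TO_MG)

    def test_leaf_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LeafScalingInput("P1", 0.8, 0.4, 0.5, 0.6, lai=4.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.1, max_value=5.0))
    def test_scaling_is_homogeneous_in_flux(self, flux, scale):
        d = np.full(20, 25.0)
        one = scale_stem_respiration(
            StemScalingInput("P", np.full(4, flux), d, 0.05, 1.5))["value"].iloc[0]
        scaled = scale_stem_respiration(
            StemScalingInput("P", np.full(4, flux * scale), d, 0.05, 1.5))["value"].iloc[0]
        assert scaled == pytest.approx(scale * one, rel=1e-9)


def _component_table(values, plot="P1", ses=None):
    rows = []
    for i, c in enumerate(COMPONENTS):
        rows.append({"plot": plot, "component": c, "value": values[i],
                     "se": (ses[i] if ses else 0.0), "provenance": "measured"})
    return pd.DataFrame(rows)


class TestAssembly:
    def test_all_zero_components_give_zero_budget(self):
        b = assemble_budget(_component_table([0.0] * 11)).iloc[0]
        for q in ("NPP", "R_a", "R_h", "R_eco", "GPP", "NEE"):
            assert b[q] == 0.0

    def test_printed_means_identity(self):
        """Any split with R_eco = 12.20 and GPP = 8.84 yields NEE = 3.36."""
        vals = {"woody_npp": 2.0, "canopy_npp": 1.84, "fine_root_npp": 1.0,
                "stem_r": 1.0, "coarse_root_r": 1.0, "fine_root_r": 1.0,
                "leaf_r": 1.0,
                "litter_rh": 2.0, "mycorrhiza_rh": 1.0, "som_rh": 3.0,
                "deadwood_rh": 2.2}
        b = assemble_budget(_component_table([vals[c] for c in COMPONENTS])).iloc[0]
        assert b["R_eco"] == pytest.approx(12.20)
        assert b["GPP"] == pytest.approx(8.84)
        assert b["NEE"] == pytest.approx(3.36, abs=1e-9)

    def test_both_nee_formulations_agree_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.uniform(0, 10, 11)
            b = assemble_budget(_component_table(vals)).iloc[0]
            assert b["NEE"] == pytest.approx(b["R_eco"] - b["GPP"], abs=1e-10)
            assert b["R_eco"] == pytest.approx(b["R_a"] + b["R_h"], abs=1e-10)
            assert b["GPP"] == pytest.approx(b["NPP"] + b["R_a"], abs=1e-10)

    def test_se_propagation_through_aggregates(self):
        ses = [1.0] * 11
        b = assemble_budget(_component_table([1.0] * 11, ses=ses)).iloc[0]
        assert b["NPP_se"] == pytest.approx(np.sqrt(3))
        assert b["R_eco_se"] == pytest.approx(np.sqrt(8))
        assert b["NEE_se"] == pytest.approx(np.sqrt(7))  # R_h (4) + NPP (3) terms

    def test_missing_component_withholds_aggregates(self):
        df = _component_table([1.0] * 11)
        df = df[df["component"] != "leaf_r"]
        b = assemble_budget(df).iloc[0]
        assert not b["complete"]
        assert np.isnan(b["NEE"])
        assert b["missing"] == "leaf_r"

    def test_imputation_hook_completes_budget(self):
        df = _component_table([1.0] * 11)
        df = df[df["component"] != "leaf_r"]
        b = assemble_budget(df, impute={"leaf_r": (1.0, 0.5)}).iloc[0]
        assert b["complete"]
        assert b["imputed"] == "leaf_r"
        assert b["NEE"] == pytest.approx(4.0 - 3.0)


class TestRecovery:
    def test_noiseless_pipeline_recovers_truth_exactly(self, plot_sim_noiseless):
        cfg, tables, truth_components, _ = plot_sim_noiseless
        comps = components_from_raw_tables(tables, (cfg.allometry_a, cfg.allometry_b))
        merged = comps.merge(truth_components, on=["plot", "component"],
                             suffixes=("", "_true"))
        assert len(merged) == len(truth_components)
        np.testing.assert_allclose(merged["value"], merged["value_true"], rtol=1e-9)

    def test_group_mean_recovery_within_two_se_over_seeds(self):
        """Monte-Carlo: recovered group means track configured truths."""
        hits = total = 0
        for seed in range(100):
            cfg = PlotSimConfig(seed=seed)
            tables, tc, _ = simulate_plot_dataset(cfg)
            comps = components_from_raw_tables(tables, (cfg.allometry_a, cfg.allometry_b))
            groups = tc.drop_duplicates("plot").set_index("plot")["group"].to_dict()
            budgets = assemble_budget(comps, groups=groups)
            for gname, gt in cfg.groups.items():
                truth_nee = (sum(gt.means[c] for c in RH_COMPONENTS)
                             - sum(gt.means[c] for c in NPP_COMPONENTS))
                sub = budgets[budgets["group"] == gname]["NEE"]
                # true between-plot SE: 7 independent component deviations
                se = gt.between_plot_sd * np.sqrt(7) / np.sqrt(len(sub))
                total += 1
                if abs(sub.mean() - truth_nee) <= 2 * se:
                    hits += 1
        assert hits / total >= 0.9


class TestGroupComparison:
    def test_identical_groups_t_zero_p_one(self, plot_sim_noiseless):
        budgets = pd.DataFrame({
            "plot": list("abcdef"),
            "group": ["unlogged"] * 3 + ["heavily logged"] * 3,
            "NEE": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        })
        res = compare_groups(budgets, "NEE")
        assert res.t.statistic == 0.0
        assert res.t.p_value == pytest.approx(1.0)
        assert res.rank_sum.p_value == pytest.approx(1.0)

    def test_pooled_t_closed_form_through_comparison(self):
        budgets = pd.DataFrame({
            "plot": list("abcdef"),
            "group": ["unlogged"] * 3 + ["heavily logged"] * 3,
            "NEE": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
        })
        res = compare_groups(budgets, "NEE", pooled=True)
        assert res.t.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.t.df == 4

    def test_empty_group_raises(self):
        budgets = pd.DataFrame({"plot": ["a"], "group": ["unlogged"], "NEE": [1.0]})
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(budgets, "NEE")

    def test_logged_pools_both_logged_classes(self, plot_sim_noiseless):
        cfg, tables, tc, _ = plot_sim_noiseless
        groups = tc.drop_duplicates("plot").set_index("plot")["group"].to_dict()
        comps = components_from_raw_tables(tables, (cfg.allometry_a, cfg.allometry_b))
        budgets = assemble_budget(comps, groups=groups)
        res = compare_groups(budgets, "NEE", "unlogged", "logged")
        assert res.n_a == 6 and res.n_b == 5
        # noiseless: group means equal the configured truths
        assert res.mean_a == pytest.approx(-0.7, abs=1e-9)
        assert res.mean_b == pytest.approx((2 * 1.8 + 3 * 5.5) / 5, abs=1e-9)
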