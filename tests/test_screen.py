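"""Plate normalization, control statistics, scoring, and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netscreen import (
    PHASE_COLS,
    ScreenError,
    aggregate_genes,
    average_replicates,
    compute_normalization_factors,
    control_statistics,
    hit_rate_by_class,
    normalize_wells,
    run_screen,
    score_and_call,
    validate_wells,
)
from netscreen.network import RoleAssignment


def make_wells(rows):
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "replicate_id", "target",
                                       "is_control"] + PHASE_COLS)


def well(plate, wid, target, control, g1, rep=1):
    # one free parameter; the others scale along to keep rows easy to read
    return (plate, wid, rep, target, control, g1, g1 / 2, g1 / 4, g1 / 8)


class TestNormalizationFactors:
    def test_single_plate_factor_is_one(self):
        wells = make_wells([well("P1", "W0", "GFP", True, 50),
                            well("P1", "W1", "a", False, 40),
                            well("P1", "W2", "b", False, 60)])
        factors = compute_normalization_factors(wells)
        assert np.allclose(factors.factor.to_numpy(), 1.0)

    def test_two_plate_means_40_60(self, simple_wells):
        factors = compute_normalization_factors(simple_wells)
        assert factors.global_mean["pct_g1"] == pytest.approx(50.0)
        assert factors.factor.loc[("P1", 1), "pct_g1"] == pytest.approx(1.25)
        assert factors.factor.loc[("P2", 1), "pct_g1"] == pytest.approx(50 / 60)

    def test_controls_excluded_from_factors(self, simple_wells):
        crazy = simple_wells.copy()
        crazy.loc[crazy["is_control"], PHASE_COLS] = 9999.0
        factors = compute_normalization_factors(crazy)
        reference = compute_normalization_factors(simple_wells)
        pd.testing.assert_frame_equal(factors.factor, reference.factor)

    def test_plate_without_samples_rejected(self):
        wells = make_wells([well("P1", "W0", "GFP", True, 50),
                            well("P1", "W1", "a", False, 40),
                            well("P2", "W0", "GFP", True, 50)])
        with pytest.raises(ScreenError, match="non-control|control"):
            compute_normalization_factors(wells)


class TestNormalization:
    def test_identity_factor_preserves_values(self):
        wells = make_wells([well("P1", "W0", "GFP", True, 50),
                            well("P1", "W1", "a", False, 40),
                            well("P1", "W2", "b", False, 60)])
        normalized = normalize_wells(wells, compute_normalization_factors(wells))
        pd.testing.assert_frame_equal(normalized, wells, check_dtype=False)

    def test_hand_computed_scaling(self, simple_wells):
        normalized = normalize_wells(simple_wells, compute_normalization_factors(simple_wells))
        # P1 sample raw 30 in pct_g1, factor 1.25 -> 37.5
        row = normalized[(normalized["target"] == "geneP10")].iloc[0]
        assert row["pct_g1"] == pytest.approx(30 * 1.25)

    def test_plate_means_equal_global_mean_after(self, simple_wells):
        factors = compute_normalization_factors(simple_wells)
        normalized = normalize_wells(simple_wells, factors)
        samples = normalized[~normalized["is_control"]]
        for _, plate in samples.groupby(["plate_id", "replicate_id"]):
            assert np.allclose(plate[PHASE_COLS].mean(), factors.global_mean, atol=1e-12)

    def test_missing_factor_rejected(self, simple_wells):
        factors = compute_normalization_factors(simple_wells[simple_wells.plate_id == "P1"])
        with pytest.raises(ScreenError, match="P2"):
            normalize_wells(simple_wells, factors)


class TestReplicatesAndControls:
    def test_duplicate_average(self):
        wells = make_wells([well("P1", "W1", "a", False, 40, rep=1),
                            well("P1", "W1", "a", False, 50, rep=2),
                            well("P1", "W0", "GFP", True, 45, rep=1),
                            well("P1", "W0", "GFP", True, 45, rep=2)])
        out = average_replicates(wells)
        assert out.loc["a", "pct_g1"] == pytest.approx(45.0)
        assert out.loc["a", "n_replicates"] == 2

    def test_single_replicate_flagged(self):
        wells = make_wells([well("P1", "W1", "a", False, 40)])
        out = average_replicates(wells)
        assert out.loc["a", "pct_g1"] == 40 and out.loc["a", "n_replicates"] == 1

    def test_control_stats_hand_example(self):
        wells = make_wells([well("P1", f"W{i}", "GFP", True, v) for i, v in
                            enumerate((48.0, 50.0, 52.0))])
        stats = control_statistics(wells)
        assert stats.mean["pct_g1"] == pytest.approx(50.0)
        assert stats.sd["pct_g1"] == pytest.approx(2.0)  # sample SD, n-1

    def test_identical_controls_have_zero_sd(self):
        wells = make_wells([well("P1", f"W{i}", "GFP", True, 50.0) for i in range(3)])
        assert (control_statistics(wells).sd == 0).all()

    def test_too_few_controls_rejected(self):
        wells = make_wells([well("P1", "W0", "GFP", True, 50.0)])
        with pytest.raises(ScreenError, match=">=2"):
            control_statistics(wells)

    def test_sigma_source_all_uses_samples(self, simple_wells):
        stats = control_statistics(simple_wells, sigma_source="all")
        assert stats.n_controls == 4  # the four sample wells


class TestScoring:
    def make_stats(self):
        wells = make_wells([well("P1", f"W{i}", "GFP", True, v) for i, v in
                            enumerate((48.0, 50.0, 52.0))])
        return control_statistics(wells)  # mean 50, sd 2 in pct_g1

    def test_exactly_three_sigma_is_not_a_hit(self):
        stats = self.make_stats()
        vec = pd.DataFrame({c: [stats.mean[c]] for c in PHASE_COLS}, index=["x"])
        vec["pct_g1"] = stats.mean["pct_g1"] + 3 * stats.sd["pct_g1"]
        out = score_and_call(vec, stats)
        assert out.loc["x", "z_g1"] == pytest.approx(3.0)
        assert not out.loc["x", "hit"]

    def test_above_threshold_flags_phenotype(self):
        stats = self.make_stats()
        vec = pd.DataFrame({c: [stats.mean[c]] for c in PHASE_COLS}, index=["x"])
        vec["pct_subg1"] = stats.mean["pct_subg1"] + 3.5 * stats.sd["pct_subg1"]
        out = score_and_call(vec, stats)
        assert out.loc["x", "hit"] and out.loc["x", "phenotypes"] == "subG1"

    def test_decreases_never_flagged(self):
        stats = self.make_stats()
        vec = pd.DataFrame({c: [stats.mean[c]] for c in PHASE_COLS}, index=["x"])
        vec["pct_g1"] = stats.mean["pct_g1"] - 5 * stats.sd["pct_g1"]
        assert not score_and_call(vec, stats).loc["x", "hit"]

    def test_zero_sd_rejected(self):
        wells = make_wells([well("P1", f"W{i}", "GFP", True, 50.0) for i in range(3)])
        stats = control_statistics(wells)
        vec = pd.DataFrame({c: [50.0] for c in PHASE_COLS}, index=["x"])
        with pytest.raises(ScreenError, match="control SD"):
            score_and_call(vec, stats)

    def test_monotone_in_value(self):
        stats = self.make_stats()
        base = {c: [float(stats.mean[c])] * 2 for c in PHASE_COLS}
        vec = pd.DataFrame(base, index=["lo", "hi"])
        vec.loc["lo", "pct_g1"] = stats.mean["pct_g1"] + 3.1 * stats.sd["pct_g1"]
        vec.loc["hi", "pct_g1"] = stats.mean["pct_g1"] + 9 * stats.sd["pct_g1"]
        out = score_and_call(vec, stats)
        assert out.loc["lo", "hit"] and out.loc["hi", "hit"]


class TestGeneAggregation:
    def amplicon_calls(self):
        return pd.DataFrame(
            {
                "z_g1": [4.0, 1.0, 0.5],
                "z_g2m": [0.0, 0.2, 0.1],
                "z_gt_g2m": [0.0, 0.0, 0.0],
                "z_subg1": [0.0, 3.6, 0.0],
                "hit": [True, True, False],
                "phenotypes": ["G1", "subG1", ""],
            },
            index=pd.Index(["amp1", "amp2", "amp3"], name="target"),
        )

    def test_any_amplicon_hit_and_phenotype_union(self):
        calls = self.amplicon_calls()
        out = aggregate_genes(calls, {"amp1": "geneA", "amp2": "geneA", "amp3": "geneB"})
        assert bool(out.loc["geneA", "hit"]) and not bool(out.loc["geneB", "hit"])
        assert out.loc["geneA", "phenotypes"] == "G1,subG1"
        assert out.loc["geneA", "z_g1"] == 4.0  # strongest z retained

    def test_unmapped_amplicons_excluded(self):
        out = aggregate_genes(self.amplicon_calls(), {"amp1": "geneA"})
        assert list(out.index) == ["geneA"]

    def test_identity_mapping_by_default(self):
        out = aggregate_genes(self.amplicon_calls())
        assert list(out.index) == ["amp1", "amp2", "amp3"]


class TestHitRates:
    def test_toy_rates(self):
        calls = pd.DataFrame(
            {"hit": [True] * 3 + [False] * 9},
            index=[f"g{i}" for i in range(12)],
        )
        roles = RoleAssignment({f"g{i}": "interactor" for i in range(12)})
        table = hit_rate_by_class(calls, roles)
        assert table.loc["interactor", "hit_rate_pct"] == pytest.approx(25.0)
        assert table.loc["interactor", "tested"] == 12

    def test_fraction_matching_published_convention(self):
        # 160 hits of 1303 tested reports as 12.3% after presentation rounding
        assert round(100 * 160 / 1303, 1) == 12.3

    def test_zero_hits_zero_rate(self):
        calls = pd.DataFrame({"hit": [False, False]}, index=["a", "b"])
        roles = RoleAssignment({"a": "bait", "b": "bait"})
        assert hit_rate_by_class(calls, roles).loc["bait", "hit_rate_pct"] == 0.0


class TestWellValidation:
    def test_missing_columns_rejected(self):
        with pytest.raises(ScreenError, match="missing columns"):
            validate_wells(pd.DataFrame({"plate_id": []}))

    def test_duplicate_well_rejected(self):
        wells = make_wells([well("P1", "W0", "GFP", True, 50),
                            well("P1", "W0", "a", False, 40)])
        with pytest.raises(ScreenError, match="duplicate"):
            validate_wells(wells)

    def test_plate_without_control_rejected(self):
        wells = make_wells([well("P1", "W0", "a", False, 40),
                            well("P1", "W1", "b", False, 60)])
        with pytest.raises(ScreenError, match="control"):
            validate_wells(wells)


class TestScaleEquivariance:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.05, max_value=20.0, allow_nan=False))
    def test_plate_scaling_leaves_calls_unchanged(self, scale):
        rng = np.random.default_rng(17)
        rows = []
        for plate in ("P1", "P2", "P3"):
            rows.append(well(plate, "W0", "GFP", True, 50 + rng.normal(0, 1)))
            rows.append(well(plate, "Wc", "GFP", True, 50 + rng.normal(0, 1)))
            for i in range(10):
                rows.append(well(plate, f"W{i+1}", f"{plate}g{i}", False,
                                 50 + rng.normal(0, 2) + (30 if (plate, i) == ("P2", 3) else 0)))
        wells = make_wells(rows)
        scaled = wells.copy()
        mask = scaled["plate_id"] == "P2"
        scaled.loc[mask, PHASE_COLS] *= scale
        base = run_screen(wells)
        after = run_screen(scaled)
        pd.testing.assert_series_equal(base["hit"], after["hit"])
        assert np.allclose(
            base[[c for c in base if c.startswith("z_")]],
            after[[c for c in after if c.startswith("z_")]],
        )
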