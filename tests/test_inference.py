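"""Standardized impacts, insecticide efficacy, harvest adaptation."""

import math

import numpy as np
import pandas as pd
import pytest

import weevilinf as wv
from weevilinf.errors import InsufficientDataError, ValidationError
from weevilinf.inference import (
    baseline_profile,
    expected_infestation,
    harvest_adaptation,
    insecticide_model,
    standardized_impacts,
)
from weevilinf.multimodel import AveragedParameter, confidence_set, enumerate_and_fit, average_parameters
from weevilinf.registry import TruthRecord

from conftest import make_table


def avgp(name, weight, natural):
    return AveragedParameter(name=name, weight=weight, natural_avg=natural,
                             shrinkage_avg=natural * weight, se=0.0,
                             ci_low=natural, ci_high=natural)


class TestBaseline:
    def test_rules_mean_mode_zero(self, table138, registry):
        table, _ = table138
        prof = baseline_profile(table, registry)
        assert prof.notes["soil_clay"] == "mean"
        assert prof.values["soil_clay"] == pytest.approx(
            table["soil_clay"].mean())
        # treatment counts are zeroed even though their sample mean is not
        assert prof.values["insecticide_dec"] == 0
        assert prof.notes["insecticide_dec"] == "zero"
        assert table["insecticide_dec"].mean() > 0
        assert prof.notes["n_hillings"] == "mode"
        assert prof.values["n_hillings"] == 2
        assert prof.notes["carbofuran"] == "mode"

    def test_constant_column_baseline_is_that_value(self, registry):
        table, _ = wv.generate_dataset(registry, seed=2)
        table["soil_clay"] = 17.5
        prof = baseline_profile(table, registry)
        assert prof.values["soil_clay"] == 17.5

    def test_bimodal_tie_takes_lower_level(self, registry):
        table, _ = wv.generate_dataset(registry, n_fields=10, seed=3)
        table["n_hillings"] = [1, 2] * 5
        prof = baseline_profile(table, registry)
        assert prof.values["n_hillings"] == 1

    def test_empty_table_rejected(self, registry):
        with pytest.raises(ValidationError):
            baseline_profile(pd.DataFrame(), registry)


class TestImpacts:
    def test_zero_shrinkage_gives_zero_impact(self, table138, registry):
        table, _ = table138
        avg = [avgp("intercept", 1.0, 0.4), avgp("soil_clay", 0.5, 0.0)]
        prof = baseline_profile(table, registry)
        (imp,) = standardized_impacts(avg, prof, table, registry)
        assert imp.delta_infestation == pytest.approx(0.0, abs=1e-12)

    def test_continuous_plus_one_sd_squared_difference(self, table138,
                                                       registry):
        """Impact equals (b + beta*SD)^2 - b^2, never a linear approximation."""
        table, _ = table138
        beta, b0 = 0.519, 0.4
        avg = [avgp("intercept", 1.0, b0), avgp("perimeter_area", 1.0, beta)]
        prof = baseline_profile(table, registry)
        (imp,) = standardized_impacts(avg, prof, table, registry)
        sd = table["perimeter_area"].std(ddof=1)
        mean = table["perimeter_area"].mean()
        base = b0 + beta * mean
        expect = ((base + beta * sd) ** 2 - base ** 2) * 100
        assert imp.perturbation == "+1 SD"
        assert imp.delta_infestation == pytest.approx(expect, rel=1e-9)

    def test_attenuation_by_parameter_weight(self, table138, registry):
        """A w_p < 1 parameter's impact is attenuated via its shrinkage
        estimate relative to the same natural estimate at w_p = 1."""
        table, _ = table138
        prof = baseline_profile(table, registry)
        full = [avgp("intercept", 1.0, 0.4), avgp("organic_matter", 1.0, -0.012)]
        part = [avgp("intercept", 1.0, 0.4), avgp("organic_matter", 0.21, -0.012)]
        (i_full,) = standardized_impacts(full, prof, table, registry)
        (i_part,) = standardized_impacts(part, prof, table, registry)
        # shrinkage scales the slope by 0.21; on the squared scale the
        # attenuation factor shifts slightly because the baseline moves too
        ratio = i_part.delta_infestation / i_full.delta_infestation
        assert 0.15 < ratio < 0.32
        assert np.sign(i_part.delta_infestation) == np.sign(i_full.delta_infestation)

    def test_hillings_perturbed_downward(self, table138, registry):
        table, _ = table138
        avg = [avgp("intercept", 1.0, 0.4), avgp("n_hillings", 1.0, 0.127)]
        prof = baseline_profile(table, registry)
        (imp,) = standardized_impacts(avg, prof, table, registry)
        assert imp.perturbation == "-1 unit"
        # a positive effect perturbed downward predicts fewer infestations
        assert imp.delta_infestation < 0

    def test_counts_perturbed_plus_one_unit(self, table138, registry):
        table, _ = table138
        avg = [avgp("intercept", 1.0, 0.4),
               avgp("insecticide_jan", 1.0, -0.053)]
        prof = baseline_profile(table, registry)
        (imp,) = standardized_impacts(avg, prof, table, registry)
        assert imp.perturbation == "+1 unit"
        expect = ((0.4 - 0.053) ** 2 - 0.4**2) * 100
        assert imp.delta_infestation == pytest.approx(expect, rel=1e-9)

    def test_negative_sqrt_prediction_clamped(self, table138, registry):
        table, _ = table138
        avg = [avgp("intercept", 1.0, 0.02),
               avgp("insecticide_jan", 1.0, -0.5)]
        prof = baseline_profile(table, registry)
        with pytest.warns(UserWarning, match="clamped"):
            (imp,) = standardized_impacts(avg, prof, table, registry)
        assert imp.delta_infestation == pytest.approx(-0.02**2 * 100)


class TestInsecticide:
    def test_recovers_temporal_decay(self, registry):
        """Dec/Jan effects negative, Feb/Mar near zero, as in the truth."""
        est = {m: [] for m in ("insecticide_dec", "insecticide_jan",
                               "insecticide_feb", "insecticide_mar")}
        for rep in range(30):
            table, _ = make_table(registry, seed=3000 + rep)
            out = insecticide_model(table, registry).set_index("month")
            for m in est:
                est[m].append(out.loc[m, "estimate"])
        means = {m: np.nanmean(v) for m, v in est.items()}
        assert means["insecticide_dec"] < -0.02
        assert means["insecticide_jan"] < -0.02
        assert abs(means["insecticide_feb"]) < 0.02
        # March counts are nearly all zero, so its estimate is noisy
        assert abs(means["insecticide_mar"]) < 0.08

    def test_all_zero_counts_dropped(self, table138, registry):
        table, _ = table138
        table = table.copy()
        for m in ("insecticide_dec", "insecticide_jan", "insecticide_feb",
                  "insecticide_mar"):
            table[m] = 0
        with pytest.warns(UserWarning, match="constant"):
            out = insecticide_model(table, registry)
        assert out["estimate"].isna().all()

    def test_insufficient_data(self, registry):
        table, _ = wv.generate_dataset(registry, n_fields=4, n_observers=1,
                                       seed=1)
        table = wv.attach_response(table)
        # force all four columns non-constant so none are dropped
        table["insecticide_dec"] = [0, 1, 0, 1]
        table["insecticide_jan"] = [1, 0, 0, 1]
        table["insecticide_feb"] = [0, 0, 1, 1]
        table["insecticide_mar"] = [1, 1, 0, 0]
        with pytest.raises(InsufficientDataError):
            insecticide_model(table, registry)


class TestHarvest:
    def test_noiseless_line_recovered_exactly(self, table138, registry):
        table, _ = table138
        expected = np.linspace(0.02, 0.5, len(table))
        table = table.copy()
        table["harvest_day"] = 207.4 - 15.97 * expected
        fit = harvest_adaptation(table, expected)
        assert fit.slope == pytest.approx(-15.97, abs=1e-9)
        assert fit.intercept == pytest.approx(207.4, abs=1e-9)
        assert fit.df == len(table) - 2
        assert fit.p_value < 1e-12

    def test_noisy_line_recovered_within_two_se(self, registry):
        rng = np.random.default_rng(8)
        table, _ = make_table(registry, seed=55)
        expected = rng.uniform(0.0, 0.6, len(table))
        table = table.copy()
        table["harvest_day"] = 207.4 - 15.97 * expected + rng.normal(0, 9, 138)
        fit = harvest_adaptation(table, expected)
        assert fit.df == 136
        # slope SE ~ 9 / (sd(x) sqrt(n)) ~ 4.4
        assert abs(fit.slope + 15.97) < 2 * 4.6

    def test_null_slope_near_zero(self, table138, registry):
        table, truth = table138
        rng = np.random.default_rng(1)
        expected = rng.uniform(0.0, 0.5, len(table))   # unrelated to harvest
        fit = harvest_adaptation(table, expected)
        assert fit.p_value > 0.001

    def test_zero_variance_expected_rejected(self, table138, registry):
        table, _ = table138
        with pytest.raises(ValidationError):
            harvest_adaptation(table, np.full(len(table), 0.3))

    def test_expected_infestation_matches_manual_prediction(self, small_table,
                                                            small_registry):
        table, _ = small_table
        cset = confidence_set(enumerate_and_fit(
            table, [s.name for s in small_registry], small_registry))
        avg = average_parameters(cset, table, small_registry)
        pred = expected_infestation(table, avg, small_registry)
        assert pred.shape == (len(table),)
        assert np.all(pred >= 0)
        # spot-check one field by hand
        coefs = {a.name: a.shrinkage_avg for a in avg}
        row = table.iloc[3]
        s = coefs["intercept"] + sum(
            coefs[n] * row[n] for n in coefs
            if n not in ("intercept",) and not n.startswith("observer"))
        assert pred[3] == pytest.approx(max(s, 0.0) ** 2, rel=1e-9)
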