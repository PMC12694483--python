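"""Synthetic trial generator: determinism, truth consistency, designed
structure and pipeline recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nbudget import (SyntheticDesign, ValidationError, emission_table,
                     flux_table, generate, recover_effects, summary_table,
                     truth_season_emission)


@pytest.fixture(scope="module")
def noise_free():
    design = SyntheticDesign(seed=42, cv=0.0)
    return design, generate(design)


@pytest.fixture(scope="module")
def noisy():
    design = SyntheticDesign(seed=42, cv=0.08)
    return design, generate(design)


def test_same_seed_reproduces_identical_tables(noisy):
    design, data = noisy
    again = generate(SyntheticDesign(seed=42, cv=0.08))
    for name in ("soil", "plant", "chamber", "truth"):
        pd.testing.assert_frame_equal(getattr(data, name), getattr(again, name))


def test_different_seed_changes_observations():
    a = generate(SyntheticDesign(seed=1)).soil.no3_mg_kg
    b = generate(SyntheticDesign(seed=2)).soil.no3_mg_kg
    assert not np.allclose(a, b)


def test_design_validation():
    with pytest.raises(ValidationError):
        SyntheticDesign(cv=-0.1)
    with pytest.raises(ValidationError):
        SyntheticDesign(plant_peak_rate=100.0)
    with pytest.raises(ValidationError):
        SyntheticDesign(pattern_effects={"FP": 1.0, "JM": 0.0, "PM": 1.1})


def test_factorial_shape(noisy):
    _, data = noisy
    # 2 years x 3 patterns x 4 rates x 3 reps
    plots = data.plant.groupby(["year", "pattern", "n_rate", "replicate"])
    assert len(plots) == 72
    assert set(data.plant.cut) == {1, 2, 3}
    # soil: two sampling dates x three layers per plot
    soil_counts = data.soil.groupby(["year", "pattern", "n_rate", "replicate"]).size()
    assert (soil_counts == 6).all()
    # FP plots carry one flat chamber; JM/PM a ridge+furrow pair
    pos = data.chamber.groupby("pattern")["position"].unique()
    assert set(pos["FP"]) == {"flat"}
    assert set(pos["PM"]) == {"ridge", "furrow"}


def test_noise_free_soil_matches_truth(noise_free):
    _, data = noise_free
    truth = data.truth.query("variable == 'soil_no3'")
    soil = data.soil.assign(
        date=data.soil.date.astype(str),
        detail=data.soil.depth_top_cm.map("{:g}".format) + "-"
        + data.soil.depth_bottom_cm.map("{:g}".format))
    merged = soil.merge(
        truth, on=["year", "pattern", "n_rate", "replicate", "date", "detail"])
    assert len(merged) == len(soil)
    assert np.allclose(merged.no3_mg_kg, merged.truth)


def test_noise_free_plant_ordering_and_peak(noise_free):
    design, data = noise_free
    summary = summary_table(data.plant)
    means = (summary.groupby(["pattern", "n_rate"])["plant_n_kg_ha"]
             .mean().unstack("pattern"))
    assert ((means["PM"] > means["JM"]) & (means["JM"] > means["FP"])).all()
    by_rate = summary.groupby("n_rate")["plant_n_kg_ha"].mean()
    assert by_rate.idxmax() == design.plant_peak_rate


def test_noise_free_recovery_is_exact(noise_free):
    design, data = noise_free
    report = recover_effects(data, design)
    assert report.ok
    assert report.emission_max_rel_error < 0.01


def test_noisy_replicate_means_preserve_ordering(noisy):
    design, data = noisy
    report = recover_effects(data, design)
    assert report.pattern_order_ok and report.peak_rate_ok


def test_recovery_invariant_to_row_order(noisy):
    design, data = noisy
    shuffled = dataclasses.replace(
        data,
        plant=data.plant.sample(frac=1, random_state=0).reset_index(drop=True),
        chamber=data.chamber.sample(frac=1, random_state=0).reset_index(drop=True))
    a, b = recover_effects(data, design), recover_effects(shuffled, design)
    assert a == b


def test_seasonal_totals_in_observed_band(noisy):
    _, data = noisy
    em = emission_table(flux_table(data.chamber, w_ridge=0.5))
    mean = em.groupby(["year", "pattern", "n_rate"])["n2o_emission_kg_ha"].mean()
    assert mean.between(1.2, 3.0).all()


def test_second_year_exceeds_first(noise_free):
    _, data = noise_free
    em = emission_table(flux_table(data.chamber)).groupby("year")[
        "n2o_emission_kg_ha"].mean()
    assert em[2024] > em[2023]
    soil = data.soil.groupby("year")["no3_mg_kg"].mean()
    assert soil[2024] > soil[2023]


def test_truth_emission_oracle_scales_with_rate():
    design = SyntheticDesign()
    lo = truth_season_emission(design, 2023, "FP", 0.0)
    hi = truth_season_emission(design, 2023, "FP", 240.0)
    assert hi == pytest.approx(lo * design.n2o_response(240.0), rel=1e-9)
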