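"""Coverage, limiting-AA identification, predicted gain, tissue panel, power."""
import math

import numpy as np
import pytest

import exomatch as em

from conftest import random_profile


def test_identical_profiles_give_full_coverage(ratios):
    rep = em.coverage(ratios["FLYAA"], ratios["FLYAA"].relabel("demand"))
    assert all(c == pytest.approx(100.0) for c in rep.coverage.values())
    assert rep.limiting_coverage == pytest.approx(100.0)
    assert rep.predicted_gain == pytest.approx(0.0, abs=1e-9)


def test_male_demand_limited_by_tryptophan(ratios):
    rep = em.coverage(ratios["FLYAA"], ratios["MALEAA"])
    assert rep.limiting_aa == "W"
    # printed ratios: 100 * 0.010/0.012 (renormalization cancels: both sums 1.001)
    assert rep.limiting_coverage == pytest.approx(100 * 0.010 / 0.012, abs=1e-9)
    assert rep.predicted_gain == pytest.approx(20.0, abs=1e-9)


def test_female_demand_limited_by_lysine(ratios):
    rep = em.coverage(ratios["FLYAA"], ratios["FEMALEAA"])
    assert rep.limiting_aa == "K"
    assert rep.predicted_gain == pytest.approx(20.0, abs=1.0)


def test_nonessential_never_selected_as_limiting():
    # serine (non-essential) has the worst coverage by construction
    diet = em.AAProfile.from_mapping({"K": 0.4, "W": 0.4, "S": 0.2}, "diet")
    demand = em.AAProfile.from_mapping({"K": 0.25, "W": 0.25, "S": 0.5}, "demand")
    rep = em.coverage(diet, demand)
    assert rep.coverage["S"] < min(rep.coverage["K"], rep.coverage["W"])
    assert rep.limiting_aa in {"K", "W"}


def test_zero_demand_sentinels():
    diet = em.AAProfile.from_mapping({"K": 0.5, "W": 0.25, "M": 0.25}, "diet")
    demand = em.AAProfile.from_mapping({"K": 0.5, "M": 0.5}, "demand")
    rep = em.coverage(diet, demand)
    assert rep.coverage["W"] == math.inf
    assert "W" in rep.unbounded
    assert rep.limiting_aa != "W"
    assert "A" in rep.excluded  # absent from both


def test_coverage_ties_reported_alphabetically():
    diet = em.AAProfile.from_mapping({"K": 0.2, "W": 0.2, "M": 0.6}, "diet")
    demand = em.AAProfile.from_mapping({"K": 0.4, "W": 0.4, "M": 0.2}, "demand")
    rep = em.coverage(diet, demand)
    assert rep.tied_limiting == ("K", "W")
    assert rep.limiting_aa == "K"


def test_essentials_override():
    diet = em.AAProfile.from_mapping({"S": 0.2, "K": 0.8}, "diet")
    demand = em.AAProfile.from_mapping({"S": 0.5, "K": 0.5}, "demand")
    rep = em.coverage(diet, demand, essentials=frozenset({"S"}))
    assert rep.limiting_aa == "S"


@pytest.mark.parametrize("cov,gain", [(100.0, 0.0), (50.0, 100.0), (83.3333333333, 20.0)])
def test_predicted_gain_closed_form(cov, gain, ratios):
    rep = em.coverage(ratios["FLYAA"], ratios["FLYAA"])
    rep = em.CoverageReport(
        diet_label="d", demand_label="q", coverage=rep.coverage,
        limiting_aa="W", limiting_coverage=cov, tied_limiting=("W",),
    )
    assert em.predicted_gain(rep) == pytest.approx(gain, abs=1e-6)


def test_predicted_gain_unbounded_when_limiting_absent():
    rep = em.CoverageReport(
        diet_label="d", demand_label="q", coverage={}, limiting_aa="W",
        limiting_coverage=0.0, tied_limiting=("W",),
    )
    assert em.predicted_gain(rep) == math.inf


def test_min_coverage_over_all_aas_cannot_exceed_100():
    # pigeonhole: two normalized profiles cannot strictly dominate each other
    rng = np.random.default_rng(12)
    for _ in range(100):
        diet, demand = random_profile(rng), random_profile(rng)
        rep = em.coverage(diet, demand)
        assert min(rep.coverage.values()) <= 100.0 + 1e-9


def test_coverage_scale_consistency(ratios):
    # coverage is built from molar fractions; total diet concentration is
    # irrelevant by construction, asserted via the formulation round trip
    recipe_lo = em.formulate(ratios["FLYAA"], 2.1)
    recipe_hi = em.formulate(ratios["FLYAA"], 10.7)
    assert np.allclose(recipe_lo.molar_fractions(), recipe_hi.molar_fractions(), atol=1e-12)


def test_tissue_panel_identical_diets_zero_gain_difference(ratios):
    diets = {"a": ratios["FLYAA"], "b": ratios["FLYAA"]}
    demands = {"t1": ratios["MALEAA"], "t2": ratios["FEMALEAA"]}
    panel = em.tissue_panel(diets, demands)
    assert np.allclose(panel.gain_difference("a", "b").to_numpy(), 0.0)
    assert set(panel.summary["tissue"]) == {"t1", "t2"}
    assert len(panel.coverage_long) == 2 * 2 * 20


def test_tissue_panel_constructed_limiting_aas(ratios):
    base = ratios["FLYAA"]
    # deplete one essential AA per constructed tissue demand -> that AA's
    # coverage is inflated, so demand built by *enriching* makes it limiting
    diets = {"FLYAA": base}
    demands = {}
    for aa in ("W", "K", "H"):
        v = base.values.copy()
        v[em.AMINO_ACIDS.index(aa)] *= 2.0
        demands[f"needs-{aa}"] = em.AAProfile(v / v.sum(), f"needs-{aa}")
    panel = em.tissue_panel(diets, demands)
    got = panel.summary.set_index("tissue")["limiting_aa"]
    assert got["needs-W"] == "W" and got["needs-K"] == "K" and got["needs-H"] == "H"


def test_tissue_panel_dominating_diet_better_everywhere(ratios):
    demands = {"t1": ratios["MALEAA"], "t2": ratios["FEMALEAA"]}
    good = ratios["FEMALEAA"].relabel("good")
    # diet strictly worse on every essential AA: shift essential mass to glycine
    v = good.values.copy()
    ess = np.array([aa in em.ESSENTIAL_AAS for aa in em.AMINO_ACIDS])
    v[ess] *= 0.5
    v[em.AMINO_ACIDS.index("G")] += (good.values[ess] * 0.5).sum()
    bad = em.AAProfile(v / v.sum(), "bad")
    panel = em.tissue_panel({"good": good, "bad": bad}, demands)
    s = panel.summary.set_index(["tissue", "diet"])["limiting_coverage_pct"]
    for t in demands:
        assert s[(t, "good")] > s[(t, "bad")]


def test_power_formula_and_inverses():
    assert em.power_sample_size(z=2, sigma=1, e=1, solve_for="n") == pytest.approx(4.0)
    rng = np.random.default_rng(13)
    for _ in range(50):
        z, sigma, e = rng.uniform(0.5, 4, size=3)
        n = em.power_sample_size(z=z, sigma=sigma, e=e, solve_for="n")
        assert n == pytest.approx((z * sigma / e) ** 2)
        assert em.power_sample_size(z=z, sigma=sigma, n=n, solve_for="e") == pytest.approx(e)
        assert em.power_sample_size(sigma=sigma, e=e, n=n, solve_for="z") == pytest.approx(z)
        assert em.power_sample_size(z=z, e=e, n=n, solve_for="sigma") == pytest.approx(sigma)
    with pytest.raises(ValueError, match="missing"):
        em.power_sample_size(z=2, sigma=1, solve_for="n")
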