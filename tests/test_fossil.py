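"""Fossil-application chain: egg mass, CS/AEN/CY estimators, ranges,
prediction-band classification."""

import math

import numpy as np
import pytest

from paleoallom.allometry import fit_from_power_law
from paleoallom.fossil import (
    classify_against_models,
    classify_taxon,
    egg_mass_from_dimensions,
    estimate_annual_egg_number,
    estimate_clutch_size,
    estimate_clutches_per_year,
    fossil_egg_mass,
    propagate_ranges,
)
from paleoallom.model_selection import ModelSet, build_model_sets
from paleoallom.records import FossilEggSpec, FossilTaxonRecord
from paleoallom.reporting import round_half_up
from paleoallom.simulate import generate_extant_dataset

from conftest import make_group


class TestEggMass:
    def test_asymmetrical_hand_evaluation(self):
        spec = FossilEggSpec(L=14, D=6, shape="asymmetrical")
        # V = 0.51 * 14 * 36 = 257.04 cm^3; EM = 1.13 g/cm^3 * V
        assert egg_mass_from_dimensions(spec) == pytest.approx(0.2904552, rel=1e-9)

    def test_ellipsoid_hand_evaluation(self):
        spec = FossilEggSpec(L=18, D=14, shape="ellipsoid")
        assert egg_mass_from_dimensions(spec) == pytest.approx(2.0892, rel=1e-3)

    def test_shape_coefficient_ratio(self):
        a = egg_mass_from_dimensions(FossilEggSpec(L=10, D=8, shape="asymmetrical"))
        e = egg_mass_from_dimensions(FossilEggSpec(L=10, D=8, shape="ellipsoid"))
        assert e / a == pytest.approx(0.524 / 0.51, rel=1e-12)

    def test_doubling_diameter_quadruples_mass(self):
        m1 = egg_mass_from_dimensions(FossilEggSpec(L=20, D=5, shape="ellipsoid"))
        m2 = egg_mass_from_dimensions(FossilEggSpec(L=20, D=10, shape="ellipsoid"))
        assert m2 == pytest.approx(4 * m1, rel=1e-12)

    def test_density_override_scales_linearly(self):
        m1 = egg_mass_from_dimensions(FossilEggSpec(L=14, D=6, shape="asymmetrical"))
        m2 = egg_mass_from_dimensions(
            FossilEggSpec(L=14, D=6, shape="asymmetrical", density=2.26)
        )
        assert m2 == pytest.approx(2 * m1, rel=1e-12)


class TestRatioEstimators:
    def test_clutch_size_identity_when_cm_equals_em(self):
        cm = fit_from_power_law(0.5, 0.0, "CM", "m")  # constant CM = 0.5 kg
        assert estimate_clutch_size(cm, BM=10.0, EM=0.5) == pytest.approx(1.0)

    def test_trait_mismatch_rejected(self):
        em_model = fit_from_power_law(0.1, 0.7, "EM", "m")
        with pytest.raises(ValueError, match="EM"):
            estimate_clutch_size(em_model, 10.0, 0.1)
        with pytest.raises(ValueError):
            estimate_annual_egg_number(em_model, 10.0, 0.1)

    def test_aen_times_em_is_model_acm(self, recovered_models):
        """AEN * EM equals the predicted annual clutch mass at the same
        body mass for any taxon sharing that mass."""
        acm = recovered_models["ACM"].by_label("reptile")
        for em in (0.128, 1.741, 5.211):
            aen = estimate_annual_egg_number(acm, 22399.0, em)
            assert aen * em == pytest.approx(acm.predict(22399.0), rel=1e-12)

    def test_cy_division_and_identity(self):
        assert estimate_clutches_per_year(20.4, 23) == pytest.approx(20.4 / 23)
        assert estimate_clutches_per_year(28.0, 28.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            estimate_clutches_per_year(10.0, 0.0)

    def test_monotone_in_body_mass(self, recovered_models):
        cm = recovered_models["CM"].by_label("bird")
        acm = recovered_models["ACM"].by_label("bird")
        bms = np.logspace(1, 5, 30)
        cs = [estimate_clutch_size(cm, bm, 0.5) for bm in bms]
        aen = [estimate_annual_egg_number(acm, bm, 0.5) for bm in bms]
        assert np.all(np.diff(cs) > 0) and np.all(np.diff(aen) > 0)


class TestPrintedRowChecks:
    """Spot-checks of the chain against independently reported estimates
    for the dinosaur taxa (1-decimal report precision)."""

    def test_prosauropod_bird_model_clutch_size(self, recovered_models):
        cm_bird = recovered_models["CM"].by_label("bird")
        cs = estimate_clutch_size(cm_bird, 175.0, 0.128)
        assert round_half_up(cs, 1) == 132.4

    def test_theropod_tortoise_model_clutch_size(self, recovered_models):
        cm_tort = recovered_models["CM"].by_label("tortoise")
        cs = estimate_clutch_size(cm_tort, 44.0, 0.329)
        assert round_half_up(cs, 1) == 2.9

    def test_sauropod_reptile_aen_interpolated_at_mean_mass(self, recovered_models):
        acm = recovered_models["ACM"].by_label("reptile")
        aen = estimate_annual_egg_number(acm, 22399.0, 1.741)
        assert round_half_up(aen, 1) == 141.7

    def test_same_mass_oospecies_rescaling(self, recovered_models):
        """At equal body mass AEN scales inversely with egg mass."""
        acm = recovered_models["ACM"].by_label("reptile")
        aen_small_egg = estimate_annual_egg_number(acm, 5000.0, 1.741)
        aen_large_egg = estimate_annual_egg_number(acm, 5000.0, 5.211)
        assert aen_large_egg == pytest.approx(aen_small_egg * 1.741 / 5.211, rel=1e-12)
        assert round_half_up(aen_large_egg, 1) == 16.0


class TestPropagateRanges:
    def test_cy_bracket_from_clutch_size_extremes(self, recovered_models):
        taxon = FossilTaxonRecord(
            taxon="Megaloolithus mammilare",
            clade="sauropodomorph",
            BM_min=5000, BM_mean=22399, BM_max=75000,
            EM=5.211, CS_min=9, CS_mean=19, CS_max=28,
        )
        results = propagate_ranges(taxon, recovered_models)
        at_5000 = [
            r for r in results if r.BM_used == 5000 and r.acm_label == "reptile"
        ][0]
        lo, hi = at_5000.CY_bracket
        assert round_half_up(at_5000.CY, 1) == 0.8
        assert (round_half_up(lo, 1), round_half_up(hi, 1)) == (0.6, 1.8)

    def test_degenerate_clutch_range_collapses_bracket(self, recovered_models):
        taxon = FossilTaxonRecord(
            taxon="x", clade="hadrosaur",
            BM_min=1000, BM_mean=1000, BM_max=1000,
            EM=1.0, CS_min=16, CS_mean=16, CS_max=16,
        )
        (res,) = [
            r for r in propagate_ranges(taxon, recovered_models)
            if r.model_label == "bird"
        ]
        assert res.CY_bracket[0] == pytest.approx(res.CY)
        assert res.CY_bracket[1] == pytest.approx(res.CY)

    def test_one_row_per_mass_and_model(self, recovered_models, dinosaur_taxa):
        troodon = next(t for t in dinosaur_taxa if "Troodon" in t.taxon)
        results = propagate_ranges(troodon, recovered_models)
        assert len(results) == 3 * 3  # 3 body masses x 3 extant groups

    def test_bracket_straddles_point_estimate(self, recovered_models, dinosaur_taxa):
        for taxon in dinosaur_taxa:
            for r in propagate_ranges(taxon, recovered_models):
                lo, hi = r.CY_bracket
                assert lo <= r.CY <= hi

    def test_small_model_clutch_reported_not_clamped(self, recovered_models):
        # an egg heavier than the predicted clutch yields CS_model < 1
        taxon = FossilTaxonRecord(
            taxon="big-egg", clade="theropod",
            BM_min=30, BM_mean=30, BM_max=30, EM=3.0,
            CS_min=5, CS_mean=5, CS_max=5,
        )
        results = propagate_ranges(taxon, recovered_models)
        tort = [r for r in results if r.model_label == "tortoise"][0]
        assert 0 < tort.CS_model < 1


@pytest.fixture(scope="module")
def em_models():
    specs = [
        make_group("bird", c=0.054, b=0.74, sigma=0.15, n=150, bm_range=(0.2, 100)),
        make_group("crocodile", c=0.009, b=0.45, sigma=0.15, n=40, bm_range=(20, 1000)),
    ]
    ds = generate_extant_dataset(specs, seed=77)
    return build_model_sets(ds, traits=("EM",))["EM"]


class TestClassification:
    def test_point_inside_band_is_within(self, em_models):
        model = em_models.model_for_group("bird")
        y = model.predict(10.0)
        cls = classify_against_models(em_models, 10.0, y)
        assert cls.positions[model.group_label] == "within"
        assert cls.nearest_model == model.group_label

    def test_point_above_every_band(self, em_models):
        from paleoallom.allometry import prediction_interval

        hi = max(
            prediction_interval(m, 10.0).hi for m in em_models.models
        )
        cls = classify_against_models(em_models, 10.0, hi * 10)
        assert all(p == "above" for p in cls.positions.values())
        assert cls.nearest_model in [m.group_label for m in em_models.models]

    def test_nearest_model_uses_vertical_log_distance(self, em_models):
        bird = em_models.model_for_group("bird")
        croc = em_models.model_for_group("crocodile")
        bm = 50.0
        # midpoint in log space, nudged toward the bird line
        mid = math.sqrt(bird.predict(bm) * croc.predict(bm))
        nudged = mid * (bird.predict(bm) / mid) ** 0.2
        cls = classify_against_models(em_models, bm, nudged)
        assert cls.nearest_model == "bird"

    def test_classify_taxon_covers_available_traits(self, em_models):
        taxon = FossilTaxonRecord(
            taxon="t", clade="theropod",
            BM_min=30, BM_mean=40, BM_max=50, EM=0.3,
            CS_min=20, CS_mean=23, CS_max=24,
        )
        out = classify_taxon(taxon, {"EM": em_models})
        assert set(out) == {"EM"}
        assert len(out["EM"]) == 3  # one classification per body mass

    def test_max_cs_substitution_raises_cm(self, em_models):
        # with use_max_cs the implied clutch mass grows by CS_max/CS_mean
        taxon = FossilTaxonRecord(
            taxon="t", clade="sauropodomorph",
            BM_min=30, BM_mean=40, BM_max=50, EM=0.3,
            CS_min=15, CS_mean=28, CS_max=40,
        )
        specs = [
            make_group("bird", trait="CM", c=0.25, b=0.82, sigma=0.15, n=100),
            make_group("crocodile", trait="CM", c=0.055, b=0.82, sigma=0.15, n=40),
        ]
        ds = generate_extant_dataset(specs, seed=78)
        cm_set = build_model_sets(ds, traits=("CM",))["CM"]
        base = classify_taxon(taxon, {"CM": cm_set})["CM"][0]
        bumped = classify_taxon(taxon, {"CM": cm_set}, use_max_cs=True)["CM"][0]
        assert bumped.value == pytest.approx(base.value * 40 / 28)


def test_fossil_egg_mass_prefers_direct_value():
    spec = FossilEggSpec(L=14, D=6, shape="asymmetrical")
    t = FossilTaxonRecord(
        taxon="t", clade="theropod", BM_min=40, BM_mean=44, BM_max=51,
        EM=0.329, egg=spec,
    )
    assert fossil_egg_mass(t) == 0.329
    t2 = FossilTaxonRecord(
        taxon="t2", clade="theropod", BM_min=40, BM_mean=44, BM_max=51, egg=spec,
    )
    assert fossil_egg_mass(t2) == pytest.approx(egg_mass_from_dimensions(spec))
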