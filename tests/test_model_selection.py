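"""ANCOVA homogeneity testing and the model-merging decision tree."""

import numpy as np
import pytest
import scipy.stats as st

from paleoallom.allometry import fit_loglog_ols
from paleoallom.model_selection import (
    ancova_homogeneity,
    build_model_sets,
    fit_all_groups,
    load_model_sets,
    merge_models,
    save_model_sets,
)
from paleoallom.records import InsufficientDataError
from paleoallom.simulate import generate_extant_dataset

from conftest import make_group


def two_group_dataset(c2=0.01, b2=0.7, sigma=0.1, n=100, seed=5):
    specs = [
        make_group("bird", c=0.01, b=0.7, sigma=sigma, n=n),
        make_group("crocodile", c=c2, b=b2, sigma=sigma, n=n),
    ]
    return generate_extant_dataset(specs, seed=seed)


class TestAncova:
    def test_identical_laws_are_homogeneous(self):
        ds = two_group_dataset()
        hom = ancova_homogeneity(ds, "EM")
        assert hom.p_interaction_overall > 0.05
        assert hom.p_group_overall > 0.05

    def test_offset_intercepts_detected(self):
        ds = two_group_dataset(c2=0.01 * 10 ** 0.5)
        hom = ancova_homogeneity(ds, "EM")
        assert hom.p_interaction_overall > 0.05
        assert hom.p_group_overall < 1e-6

    def test_different_slopes_detected(self):
        ds = two_group_dataset(b2=0.9)
        hom = ancova_homogeneity(ds, "EM")
        assert hom.p_interaction_overall < 1e-6

    def test_two_group_interaction_f_equals_slope_difference_t_squared(self):
        """For two groups the interaction F-test is the t-test of the
        slope difference: F = t^2, so the p-values agree."""
        ds = two_group_dataset(b2=0.75, seed=9)
        hom = ancova_homogeneity(ds, "EM")
        f1 = fit_loglog_ols(ds, "bird", "EM")
        f2 = fit_loglog_ols(ds, "crocodile", "EM")
        # pooled residual variance of the two separate fits
        rss = f1.s2 * f1.df_resid + f2.s2 * f2.df_resid
        df = f1.df_resid + f2.df_resid
        se = np.sqrt(rss / df * (1 / f1.Sxx + 1 / f2.Sxx))
        t = (f1.slope - f2.slope) / se
        p_t = 2 * st.t.sf(abs(t), df)
        assert hom.p_interaction_overall == pytest.approx(p_t, rel=1e-8)

    def test_small_group_raises(self, tiny_dataset):
        with pytest.raises(InsufficientDataError, match="crocodile"):
            ancova_homogeneity(tiny_dataset, "EM")

    def test_pairwise_modes(self):
        specs = [
            make_group("bird", c=0.01, b=0.7, sigma=0.1, n=60),
            make_group("crocodile", c=0.01, b=0.7, sigma=0.1, n=60),
            make_group("tortoise", c=0.01, b=0.7, sigma=0.1, n=60),
        ]
        ds = generate_extant_dataset(specs, seed=21)
        auto = ancova_homogeneity(ds, "EM", pairwise="auto")
        always = ancova_homogeneity(ds, "EM", pairwise="always")
        assert auto.pairwise == {}  # nothing significant: no pairwise runs
        assert len(always.pairwise) == 3


class TestMergeDecisionTree:
    def em_like_dataset(self, seed=31):
        """Bird slope distinct; crocodile/tortoise share a slope but not
        an intercept (egg-mass-like structure)."""
        specs = [
            make_group("bird", c=0.054, b=0.74, sigma=0.12, n=200, bm_range=(0.2, 100)),
            make_group("crocodile", c=0.009, b=0.45, sigma=0.12, n=40, bm_range=(20, 1000)),
            make_group("tortoise", c=0.005, b=0.45, sigma=0.12, n=40, bm_range=(1, 300)),
        ]
        return generate_extant_dataset(specs, seed=seed)

    def acm_like_dataset(self, seed=37):
        """Crocodile/tortoise indistinguishable in slope and intercept;
        bird shares the slope but not the intercept."""
        specs = [
            make_group("bird", trait="ACM", c=0.433, b=0.725, sigma=0.15, n=200,
                       bm_range=(0.2, 100)),
            make_group("crocodile", trait="ACM", c=0.17, b=0.725, sigma=0.15, n=40,
                       bm_range=(20, 1000)),
            make_group("tortoise", trait="ACM", c=0.17, b=0.725, sigma=0.15, n=40,
                       bm_range=(1, 300)),
        ]
        return generate_extant_dataset(specs, seed=seed)

    def test_em_like_pattern_gives_three_models_with_shared_reptile_slope(self):
        ds = self.em_like_dataset()
        fits = fit_all_groups(ds, "EM")
        hom = ancova_homogeneity(ds, "EM")
        ms = merge_models(fits, hom, ds)
        assert len(ms.models) == 3
        croc = ms.model_for_group("crocodile")
        tort = ms.model_for_group("tortoise")
        bird = ms.model_for_group("bird")
        assert croc.slope == tort.slope  # common slope, shared exactly
        assert croc.intercept_log10 != tort.intercept_log10
        assert not bird.slope_fixed  # kept its own free-slope OLS fit

    def test_acm_like_pattern_merges_crocodile_and_tortoise(self):
        ds = self.acm_like_dataset()
        fits = fit_all_groups(ds, "ACM")
        hom = ancova_homogeneity(ds, "ACM")
        ms = merge_models(
            fits, hom, ds, merged_labels={frozenset({"crocodile", "tortoise"}): "reptile"}
        )
        assert len(ms.models) == 2
        assert set(ms.labels) == {"bird", "reptile"}
        reptile = ms.model_for_group("crocodile")
        assert reptile is ms.model_for_group("tortoise")
        assert reptile.n == 80  # pooled records back the merged model
        # bird and reptile share the common slope
        assert ms.model_for_group("bird").slope == pytest.approx(reptile.slope)

    def test_all_distinct_slopes_keep_input_fits(self):
        specs = [
            make_group("bird", c=0.01, b=0.9, sigma=0.05, n=120),
            make_group("crocodile", c=0.01, b=0.7, sigma=0.05, n=120),
            make_group("tortoise", c=0.01, b=0.5, sigma=0.05, n=120),
        ]
        ds = generate_extant_dataset(specs, seed=41)
        fits = fit_all_groups(ds, "EM")
        hom = ancova_homogeneity(ds, "EM")
        ms = merge_models(fits, hom, ds)
        assert len(ms.models) == 3
        for f in fits:
            kept = ms.model_for_group(f.group_label)
            assert kept.slope == f.slope and not kept.slope_fixed

    def test_groups_partition_in_every_branch(self):
        for ds, trait in [
            (self.em_like_dataset(), "EM"),
            (self.acm_like_dataset(), "ACM"),
        ]:
            fits = fit_all_groups(ds, trait)
            hom = ancova_homogeneity(ds, trait)
            ms = merge_models(fits, hom, ds)
            assert set(ms.coverage) == set(ds.groups)  # no group lost
            assert set(ms.coverage.values()) == set(ms.labels)  # none dangling

    def test_merge_is_idempotent_on_already_merged_set(self):
        from paleoallom.model_selection import HomogeneityResult

        ds = two_group_dataset(seed=43)
        fits = fit_all_groups(ds, "EM")
        hom = ancova_homogeneity(ds, "EM")
        ms = merge_models(fits, hom, ds)
        assert len(ms.models) == 1  # same law: full merge
        merged = ms.models[0]
        # feeding the merged model back with a no-difference result is a no-op
        trivial = HomogeneityResult(
            trait="EM",
            groups=(merged.group_label,),
            p_interaction_overall=1.0,
            p_group_overall=1.0,
            pairwise={},
        )
        again = merge_models([merged], trivial, ds)
        assert again.models == (merged,)

    def test_label_mismatch_rejected(self):
        ds = two_group_dataset()
        fits = fit_all_groups(ds, "EM")
        hom = ancova_homogeneity(ds, "EM")
        with pytest.raises(ValueError):
            merge_models(fits[:1], hom, ds)


class TestSerialization:
    def test_model_sets_round_trip(self, tmp_path):
        specs = [
            make_group("bird", trait="CM", c=0.25, b=0.82, sigma=0.15, n=100),
            make_group("crocodile", trait="CM", c=0.055, b=0.82, sigma=0.15, n=40),
        ]
        ds = generate_extant_dataset(specs, seed=50)
        model_sets = build_model_sets(ds, traits=("CM",))
        path = tmp_path / "models.yaml"
        save_model_sets(model_sets, path)
        back = load_model_sets(path)
        orig = model_sets["CM"]
        loaded = back["CM"]
        assert loaded.labels == orig.labels
        assert dict(loaded.coverage) == dict(orig.coverage)
        for a, b in zip(orig.models, loaded.models):
            assert b.slope == pytest.approx(a.slope, rel=1e-12)
            assert b.intercept_log10 == pytest.approx(a.intercept_log10, rel=1e-12)
            assert b.s2 == pytest.approx(a.s2, rel=1e-12)
            assert b.n == a.n
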