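"""Homogeneity testing and merging of per-group allometric models.

Groups whose log10-log10 regression lines are statistically
indistinguishable are collapsed into shared models by a three-branch
decision tree:

(i)   slopes homogeneous, intercepts different -> one model per group
      with a common slope (the unweighted mean of the groupwise OLS
      slopes) and a per-group normalization constant;
(ii)  slopes and intercepts both homogeneous -> a single merged model
      with the averaged slope and averaged normalization constant;
(iii) a group whose slope differs from every other group keeps its own
      free-slope OLS fit.

Homogeneity is judged by nested-model F-tests (extra sum of squares):
the slope-by-group interaction term tests slope equality given
``log10 Y ~ log10 BM + group``, and the group term tests intercept
equality given a common slope.  For two groups these coincide with the
coefficient t-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st
import statsmodels.api as sm
import yaml

from .allometry import AllometricFit, fit_along_line, fit_loglog_ols, refit_fixed_slope
from .records import InsufficientDataError, TraitDataset

__all__ = [
    "HomogeneityResult",
    "ModelSet",
    "ancova_homogeneity",
    "merge_models",
    "fit_all_groups",
    "build_model_sets",
    "save_model_sets",
    "load_model_sets",
]


@dataclass(frozen=True)
class HomogeneityResult:
    """ANCOVA p-values for slope and intercept equality across groups."""

    trait: str
    groups: tuple[str, ...]
    p_interaction_overall: float
    p_group_overall: float
    pairwise: Mapping[tuple[str, str], tuple[float, float]]  # (p_interaction, p_group)
    alpha: float = 0.05

    def pair(self, a: str, b: str) -> tuple[float, float]:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return self.pairwise[key]


@dataclass(frozen=True)
class ModelSet:
    """The final per-trait models after homogeneity-driven merging.

    ``coverage`` maps every input group to the label of the model that
    now represents it; ``provenance`` records which branch of the
    decision tree produced each model.
    """

    trait: str
    models: tuple[AllometricFit, ...]
    coverage: Mapping[str, str]
    provenance: Mapping[str, str]
    alpha: float = 0.05

    def model_for_group(self, group: str) -> AllometricFit:
        label = self.coverage.get(group, group)
        return self.by_label(label)

    def by_label(self, label: str) -> AllometricFit:
        for m in self.models:
            if m.group_label == label:
                return m
        raise KeyError(f"no model labelled {label!r} in {self.trait} model set")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.group_label for m in self.models)


# ---------------------------------------------------------------------------
# core ANCOVA on arrays


def _nested_f(rss_r: float, df_r: int, rss_f: float, df_f: int) -> float:
    """p-value of the extra-sum-of-squares F-test (reduced vs full)."""
    if df_f <= 0 or rss_f <= 0:
        return float("nan")
    f = ((rss_r - rss_f) / (df_r - df_f)) / (rss_f / df_f)
    return float(st.f.sf(f, df_r - df_f, df_f))

def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    res = sm.OLS(y, X).fit()
    return float(res.ssr), int(res.df_resid)


def _ancova_arrays(x: np.ndarray, y: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """(p_interaction, p_group) for pooled log-log data with group codes.

    Compares ``y ~ x + group + x:group`` against ``y ~ x + group``
    (slope homogeneity) and ``y ~ x + group`` against ``y ~ x``
    (intercept homogeneity given a common slope).
    """
    levels = np.unique(codes)
    dummies = np.column_stack([(codes == g).astype(float) for g in levels[1:]])
    ones = np.ones_like(x)
    X0 = np.column_stack([ones, x])
    X1 = np.column_stack([ones, x, dummies])
    X2 = np.column_stack([ones, x, dummies, dummies * x[:, None]])
    rss0, df0 = _rss(y, X0)
    rss1, df1 = _rss(y, X1)
    rss2, df2 = _rss(y, X2)
    return _nested_f(rss1, df1, rss2, df2), _nested_f(rss0, df0, rss1, df1)


def _pooled_arrays(dataset: TraitDataset, trait: str, clusters: Sequence[Sequence[str]]):
    """Stack per-cluster (x, y) with integer codes, one code per cluster."""
    xs, ys, cs = [], [], []
    for code, members in enumerate(clusters):
        for g in members:
            x, y = dataset.xy(g, trait)
            xs.append(x)
            ys.append(y)
            cs.append(np.full(len(x), code))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(cs)


def ancova_homogeneity(
    dataset: TraitDataset,
    trait: str,
    groups: Sequence[str] | None = None,
    alpha: float = 0.05,
    pairwise: str = "auto",
) -> HomogeneityResult:
    """Test homogeneity of the per-group regression lines for one trait.

    Parameters
    ----------
    pairwise
        ``"auto"`` fills the pairwise table only when an overall test is
        significant at ``alpha``; ``"always"`` fills it unconditionally.
    """
    if groups is None:
        groups = dataset.groups
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("homogeneity testing needs at least two groups")
    for g in groups:
        if len(dataset.group_records(g)) < 3:
            raise InsufficientDataError(f"group {g!r} has fewer than 3 records")
    if pairwise not in ("auto", "always"):
        raise ValueError("pairwise must be 'auto' or 'always'")

    x, y, codes = _pooled_arrays(dataset, trait, [[g] for g in groups])
    p_int, p_grp = _ancova_arrays(x, y, codes)

    table: dict[tuple[str, str], tuple[float, float]] = {}
    if pairwise == "always" or (
        len(groups) > 2 and (p_int < alpha or p_grp < alpha)
    ):
        for a, b in itertools.combinations(groups, 2):
            xa, ya, ca = _pooled_arrays(dataset, trait, [[a], [b]])
            table[(a, b)] = _ancova_arrays(xa, ya, ca)
    return HomogeneityResult(
        trait=trait,
        groups=groups,
        p_interaction_overall=p_int,
        p_group_overall=p_grp,
        pairwise=table,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# merging


def _cluster_p(
    dataset: TraitDataset, trait: str, A: Sequence[str], B: Sequence[str]
) -> tuple[float, float]:
    """Two-sample ANCOVA p-values treating each cluster as one pooled group."""
    x, y, codes = _pooled_arrays(dataset, trait, [A, B])
    return _ancova_arrays(x, y, codes)


def _greedy_clusters(
    dataset: TraitDataset,
    trait: str,
    members: Sequence[str],
    alpha: float,
    which: int,
) -> list[list[str]]:
    """Agglomerate groups whose lines are homogeneous.

    ``which`` selects the criterion: 0 = slope (interaction p), 1 =
    intercept given common slope (group p).  The pair of clusters with
    the largest criterion p-value is merged first and the remaining
    clusters are re-tested against the pooled merge, so ambiguous
    patterns like {A~B, B~C, A!~C} resolve deterministically.
    """
    clusters = [[g] for g in members]
    while len(clusters) > 1:
        best, best_p = None, -1.0
        for i, j in itertools.combinations(range(len(clusters)), 2):
            p = _cluster_p(dataset, trait, clusters[i], clusters[j])[which]
            if p > best_p:
                best, best_p = (i, j), p
        if best_p < alpha:
            break
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


def fit_all_groups(dataset: TraitDataset, trait: str) -> list[AllometricFit]:
    """Free-slope OLS fits for every group in the dataset."""
    return [fit_loglog_ols(dataset, g, trait) for g in dataset.groups]


def merge_models(
    fits: Sequence[AllometricFit],
    homogeneity: HomogeneityResult,
    dataset: TraitDataset,
    merged_labels: Mapping[frozenset, str] | None = None,
) -> ModelSet:
    """Apply the merging decision tree to per-group OLS fits.

    ``merged_labels`` optionally renames merged clusters (e.g. the
    crocodile+tortoise annual-clutch-mass model to ``"reptile"``).
    """
    trait = homogeneity.trait
    by_group = {f.group_label: f for f in fits}
    groups = list(homogeneity.groups)
    if set(by_group) != set(groups):
        raise ValueError(
            f"fits cover {sorted(by_group)} but homogeneity covers {sorted(groups)}"
        )
    alpha = homogeneity.alpha
    merged_labels = merged_labels or {}

    def label_for(members: Sequence[str]) -> str:
        if len(members) == 1:
            return members[0]
        return merged_labels.get(frozenset(members), "+".join(members))

    if len(groups) == 1:
        only = by_group[groups[0]]
        return ModelSet(
            trait=trait,
            models=(only,),
            coverage={groups[0]: only.group_label},
            provenance={only.group_label: "single group (no comparison possible)"},
            alpha=alpha,
        )

    models: list[AllometricFit] = []
    coverage: dict[str, str] = {}
    provenance: dict[str, str] = {}

    # Stage 1: slope-homogeneous clusters.  With a non-significant
    # overall interaction all slopes are homogeneous; otherwise groups
    # are agglomerated by pairwise slope tests.
    if homogeneity.p_interaction_overall >= alpha:
        slope_clusters = [list(groups)]
    else:
        slope_clusters = _greedy_clusters(dataset, trait, groups, alpha, which=0)

    for cluster in slope_clusters:
        if len(cluster) == 1:
            # branch (iii): slope differs from all other groups
            g = cluster[0]
            models.append(by_group[g])
            coverage[g] = g
            provenance[g] = "distinct slope: kept free-slope OLS fit"
            continue

        b_common = float(np.mean([by_group[g].slope for g in cluster]))
        refits = {g: refit_fixed_slope(dataset, g, trait, b_common) for g in cluster}

        # Intercept homogeneity inside the slope cluster
        if len(slope_clusters) == 1 and homogeneity.p_group_overall >= alpha:
            icl = [list(cluster)]
        else:
            icl = _greedy_clusters(dataset, trait, cluster, alpha, which=1)

        for members in icl:
            if len(members) == 1:
                g = members[0]
                models.append(refits[g])
                coverage[g] = g
                provenance[g] = (
                    f"common slope {b_common:.6g} across {'+'.join(cluster)}; "
                    "own normalization constant"
                )
            else:
                label = label_for(members)
                a_common = float(
                    np.mean([refits[g].intercept_log10 for g in members])
                )
                merged = fit_along_line(
                    dataset, members, trait, b_common, a_common, label
                )
                models.append(merged)
                for g in members:
                    coverage[g] = label
                provenance[label] = (
                    f"slopes and intercepts homogeneous across {'+'.join(members)}; "
                    "averaged slope and normalization constant, records pooled"
                )

    return ModelSet(
        trait=trait,
        models=tuple(models),
        coverage=coverage,
        provenance=provenance,
        alpha=alpha,
    )


def build_model_sets(
    dataset: TraitDataset,
    traits: Sequence[str] = ("EM", "CM", "ACM"),
    alpha: float = 0.05,
    merged_labels: Mapping[frozenset, str] | None = None,
) -> dict[str, ModelSet]:
    """Fit, test and merge every trait in one call (fit -> compare -> merge)."""
    out: dict[str, ModelSet] = {}
    for trait in traits:
        fits = fit_all_groups(dataset, trait)
        if len(dataset.groups) < 2:
            only = fits[0]
            out[trait] = ModelSet(
                trait=trait,
                models=(only,),
                coverage={only.group_label: only.group_label},
                provenance={only.group_label: "single group (no comparison possible)"},
                alpha=alpha,
            )
            continue
        hom = ancova_homogeneity(dataset, trait, alpha=alpha)
        out[trait] = merge_models(fits, hom, dataset, merged_labels=merged_labels)
    return out


# ---------------------------------------------------------------------------
# serialization (small key-value text file so the fossil stage can run
# without refitting)


def save_model_sets(model_sets: Mapping[str, ModelSet], path: str | Path) -> None:
    doc = {}
    for trait, ms in model_sets.items():
        doc[trait] = {
            "alpha": ms.alpha,
            "coverage": dict(ms.coverage),
            "provenance": dict(ms.provenance),
            "models": [m.to_dict() for m in ms.models],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model_sets(path: str | Path) -> dict[str, ModelSet]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for trait, entry in doc.items():
        out[trait] = ModelSet(
            trait=trait,
            models=tuple(AllometricFit.from_dict(d) for d in entry["models"]),
            coverage=dict(entry["coverage"]),
            provenance=dict(entry.get("provenance", {})),
            alpha=float(entry.get("alpha", 0.05)),
        )
    return out
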