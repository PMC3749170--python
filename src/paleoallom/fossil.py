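"""Application of extant allometric models to fossil taxa.

Given fitted clutch-mass (CM) and annual-clutch-mass (ACM) models and a
fossil taxon's body mass BM and egg mass EM, the estimators are the
ratio identities

    CS  = CM(BM) / EM      model-based clutch size, eggs
    AEN = ACM(BM) / EM     annual egg number, eggs/yr
    CY  = AEN / CS_fossil  clutches per year, 1/yr

where CS_fossil is the clutch size documented in the fossil record.
Fossil uncertainty is propagated by evaluating every reported body mass
(min, mean, max) as its own row and by bracketing CY with the clutch
size extremes at a fixed AEN.  Estimates are continuous values; no
integer rounding is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .allometry import AllometricFit, prediction_interval, predict_trait
from .model_selection import ModelSet
from .records import FossilEggSpec, FossilTaxonRecord

__all__ = [
    "EGG_VOLUME_COEFFICIENTS",
    "Classification",
    "InferenceResult",
    "egg_mass_from_dimensions",
    "estimate_clutch_size",
    "estimate_annual_egg_number",
    "estimate_clutches_per_year",
    "propagate_ranges",
    "classify_against_models",
    "classify_taxon",
    "fossil_egg_mass",
]

#: Egg volume V = k * L * D^2 (cm^3): asymmetrical (bird-like) eggs take
#: k = 0.51, ellipsoid/globular (crocodile-like) eggs k = 0.524.
EGG_VOLUME_COEFFICIENTS = {"asymmetrical": 0.51, "ellipsoid": 0.524}


def egg_mass_from_dimensions(spec: FossilEggSpec) -> float:
    """Egg mass (kg) from fossil egg length, diameter and shape.

    The egg volume follows ``k * L * D**2`` with the shape-specific
    coefficient and the mass assumes a whole-egg density of 1.13 g/cm^3
    (the default on :class:`FossilEggSpec`).
    """
    try:
        k = EGG_VOLUME_COEFFICIENTS[spec.shape]
    except KeyError:  # pragma: no cover - FossilEggSpec already validates
        raise ValueError(f"unknown egg shape {spec.shape!r}")
    volume_cm3 = k * spec.L * spec.D**2
    return spec.density * volume_cm3 / 1000.0


def fossil_egg_mass(taxon: FossilTaxonRecord) -> float:
    """Direct egg mass if recorded, otherwise derived from dimensions."""
    if taxon.EM is not None:
        return taxon.EM
    return egg_mass_from_dimensions(taxon.egg)


def _require_trait(model: AllometricFit, trait: str) -> None:
    if model.trait != trait:
        raise ValueError(
            f"model {model.group_label!r} predicts {model.trait}, not {trait}"
        )


def estimate_clutch_size(cm_model: AllometricFit, BM: float, EM: float) -> float:
    """Model-based clutch size: predicted clutch mass divided by egg mass.

    May legitimately fall below one egg (a taxon whose egg outweighs the
    clutch mass predicted for its body size); the value is reported
    as-is rather than clamped.
    """
    _require_trait(cm_model, "CM")
    if EM <= 0:
        raise ValueError("egg mass must be > 0")
    return predict_trait(cm_model, BM) / EM


def estimate_annual_egg_number(acm_model: AllometricFit, BM: float, EM: float) -> float:
    """Annual egg number: predicted annual clutch mass divided by egg mass."""
    _require_trait(acm_model, "ACM")
    if EM <= 0:
        raise ValueError("egg mass must be > 0")
    return predict_trait(acm_model, BM) / EM


def estimate_clutches_per_year(AEN: float, CS_fossil: float) -> float:
    """Clutches per year: annual egg number divided by fossil clutch size."""
    if CS_fossil <= 0:
        raise ValueError("fossil clutch size must be > 0")
    if AEN <= 0:
        raise ValueError("annual egg number must be > 0")
    return AEN / CS_fossil


@dataclass(frozen=True)
class Classification:
    """Position of one fossil trait value relative to every model band."""

    trait: str
    BM: float
    value: float
    positions: Mapping[str, str]  # model label -> below / within / above
    nearest_model: str


@dataclass(frozen=True)
class InferenceResult:
    """Estimates for one fossil taxon under one extant model at one BM.

    ``model_label`` is the extant group whose clutch-mass model supplied
    CS_model; ``acm_label`` names the (possibly merged) annual-clutch-
    mass model behind AEN and CY.  ``CY_bracket`` pairs the single AEN
    at this body mass with the fossil clutch-size extremes, i.e.
    ``[AEN / CS_max, AEN / CS_min]``.
    """

    taxon: str
    model_label: str
    acm_label: str
    BM_used: float
    EM_used: float
    CS_model: float
    AEN: float
    CY: float | None
    CY_bracket: tuple[float, float] | None
    CS_fossil: float | None = None


def propagate_ranges(
    taxon: FossilTaxonRecord, model_sets: Mapping[str, ModelSet]
) -> list[InferenceResult]:
    """Estimates for every (body mass, extant model) combination.

    Requires fitted CM and ACM model sets.  Each distinct reported body
    mass produces its own set of rows; the CY bracket at each body mass
    comes from dividing that row's AEN by the fossil clutch-size
    extremes.
    """
    for trait in ("CM", "ACM"):
        if trait not in model_sets:
            raise ValueError(f"model_sets must include a {trait} model set")
    cm_set = model_sets["CM"]
    acm_set = model_sets["ACM"]
    em = fossil_egg_mass(taxon)

    results: list[InferenceResult] = []
    for bm in taxon.bm_values:
        for group in cm_set.coverage:
            cm_model = cm_set.model_for_group(group)
            acm_model = acm_set.model_for_group(group)
            cs_model = estimate_clutch_size(cm_model, bm, em)
            aen = estimate_annual_egg_number(acm_model, bm, em)
            cy = bracket = None
            if taxon.CS_mean is not None:
                cy = estimate_clutches_per_year(aen, taxon.CS_mean)
                bracket = (aen / taxon.CS_max, aen / taxon.CS_min)
            results.append(
                InferenceResult(
                    taxon=taxon.taxon,
                    model_label=group,
                    acm_label=acm_model.group_label,
                    BM_used=bm,
                    EM_used=em,
                    CS_model=cs_model,
                    AEN=aen,
                    CY=cy,
                    CY_bracket=bracket,
                    CS_fossil=taxon.CS_mean,
                )
            )
    return results


def classify_against_models(
    model_set: ModelSet,
    BM: float,
    trait_value: float,
    level: float = 0.95,
    taxon: str | None = None,
) -> Classification:
    """Place a fossil trait value against every model's prediction band.

    A point is ``within`` a model when log10(value) lies inside that
    model's prediction interval at log10(BM), ``below``/``above``
    otherwise.  The nearest model minimises the vertical (trait-axis)
    log10 distance to its regression line; perpendicular distance is not
    used.
    """
    if trait_value <= 0 or BM <= 0:
        raise ValueError("body mass and trait value must be > 0")
    positions: dict[str, str] = {}
    distances: dict[str, float] = {}
    for model in model_set.models:
        band = prediction_interval(model, BM, level=level)
        if trait_value < band.lo:
            positions[model.group_label] = "below"
        elif trait_value > band.hi:
            positions[model.group_label] = "above"
        else:
            positions[model.group_label] = "within"
        distances[model.group_label] = abs(
            math.log10(trait_value) - math.log10(band.y_hat)
        )
    nearest = min(distances, key=distances.get)
    return Classification(
        trait=model_set.trait,
        BM=BM,
        value=trait_value,
        positions=positions,
        nearest_model=nearest,
    )


def classify_taxon(
    taxon: FossilTaxonRecord,
    model_sets: Mapping[str, ModelSet],
    level: float = 0.95,
    use_max_cs: bool = False,
) -> dict[str, list[Classification]]:
    """Classify a taxon's EM, CM and ACM against the fitted bands.

    Egg mass is classified at each reported body mass using the single
    (mean) fossil egg mass.  Clutch mass is ``EM * CS_fossil`` and
    annual clutch mass additionally multiplies by the assumed breeding
    frequency (baseline one clutch per year).  ``use_max_cs`` substitutes
    the maximum reported clutch size for the mean when forming CM and
    ACM, a scenario relevant for taxa whose fossil clutches may be
    incomplete.
    """
    em = fossil_egg_mass(taxon)
    cs = None
    if taxon.CS_mean is not None:
        cs = taxon.CS_max if use_max_cs else taxon.CS_mean
    values = {"EM": em}
    if cs is not None:
        values["CM"] = em * cs
        values["ACM"] = em * cs * taxon.assumed_CY

    out: dict[str, list[Classification]] = {}
    for trait, value in values.items():
        if trait not in model_sets:
            continue
        out[trait] = [
            classify_against_models(
                model_sets[trait], bm, value, level=level, taxon=taxon.taxon
            )
            for bm in taxon.bm_values
        ]
    return out
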