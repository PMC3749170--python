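"""Synthetic calibration datasets and fossil taxa with known ground truth.

The generator emulates the statistical structure the fitting chain
assumes: within each taxonomic group a reproductive trait follows a
power law of body mass with multiplicative lognormal scatter,

    log10 Y = log10 c + b * log10 BM + Normal(0, sigma_log10),

with body masses sampled log-uniformly over the group's range.  A single
integer seed drives every stream: it is expanded with
``numpy.random.SeedSequence(seed).spawn``, one child per group in spec
order (and one extra child per taxon for fossil generation), so adding a
group never perturbs the draws of the previous ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fossil import EGG_VOLUME_COEFFICIENTS
from .records import (
    ExtantSpeciesRecord,
    FossilEggSpec,
    FossilTaxonRecord,
    TraitDataset,
    TRAITS,
)

__all__ = [
    "GroupLawSpec",
    "generate_extant_dataset",
    "generate_fossil_taxa",
    "default_group_specs",
    "generate_reference_like_dataset",
    "REFERENCE_LAWS",
]


@dataclass(frozen=True)
class GroupLawSpec:
    """Ground-truth power law for one group and one trait.

    ``c_true`` is the normalization constant (kg at BM = 1 kg),
    ``b_true`` the exponent, ``sigma_log10`` the residual standard
    deviation in log10 space and ``BM_range`` the (min, max) body-mass
    interval (kg) sampled log-uniformly.
    """

    group_label: str
    trait: str
    c_true: float
    b_true: float
    sigma_log10: float
    n: int
    BM_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.c_true <= 0 or self.sigma_log10 < 0:
            raise ValueError("c_true must be > 0 and sigma_log10 >= 0")
        if not math.isfinite(self.b_true):
            raise ValueError("b_true must be finite")
        if self.n < 3:
            raise ValueError("n must be >= 3 (fitting needs df >= 1)")
        lo, hi = self.BM_range
        if not (0 < lo <= hi):
            raise ValueError("BM_range must be positive and ordered")


def _decompose(trait: str, Y: np.ndarray, BM: np.ndarray, rng: np.random.Generator):
    """Split trait values into (EM, CS, CY) so the trait is reproduced exactly.

    The companion quantities are drawn from plausible ranges (clutch
    sizes a few eggs, one to three clutches per year); only the
    generated trait itself is guaranteed to follow the specified law.
    Clutch size is inflated where needed so the egg never outweighs the
    body (EM < BM).
    """
    n = len(Y)
    cs = np.exp(rng.normal(math.log(6.0), 0.35, n))
    cs = np.maximum(cs, 1.0)
    cy = rng.integers(1, 4, n).astype(float)
    if trait == "EM":
        # truncate rare extreme draws: an egg cannot outweigh its layer
        em = np.minimum(Y, 0.9 * BM)
    elif trait == "CM":
        em = Y / cs
    else:  # ACM
        em = Y / (cs * cy)
    # enforce EM < BM by enlarging the clutch where the draw was too small
    bad = em >= BM
    if np.any(bad) and trait != "EM":
        factor = np.ones(n)
        factor[bad] = 2.0 * em[bad] / BM[bad]
        cs = cs * factor
        if trait == "CM":
            em = Y / cs
        else:
            em = Y / (cs * cy)
    return em, cs, cy


def generate_extant_dataset(
    specs: Sequence[GroupLawSpec], seed: int
) -> TraitDataset:
    """Generate a calibration dataset from per-group trait laws.

    All specs must describe the same trait.  For a fixed seed the output
    is fully deterministic.  With ``sigma_log10 = 0`` every species lies
    exactly on its group's law and a subsequent fit recovers the true
    coefficients to numerical precision.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    traits = {s.trait for s in specs}
    if len(traits) > 1:
        raise ValueError(f"specs mix traits {sorted(traits)}; one trait per dataset")
    trait = specs[0].trait

    children = np.random.SeedSequence(seed).spawn(len(specs))
    records: list[ExtantSpeciesRecord] = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        lo, hi = np.log10(spec.BM_range[0]), np.log10(spec.BM_range[1])
        x = rng.uniform(lo, hi, spec.n)
        logY = (
            math.log10(spec.c_true)
            + spec.b_true * x
            + rng.normal(0.0, spec.sigma_log10, spec.n)
        )
        BM = 10.0**x
        Y = 10.0**logY
        em, cs, cy = _decompose(trait, Y, BM, rng)
        for i in range(spec.n):
            records.append(
                ExtantSpeciesRecord(
                    species_id=f"{spec.group_label}_{i:04d}",
                    group=spec.group_label,
                    BM=float(BM[i]),
                    EM=float(em[i]),
                    CS=float(cs[i]),
                    CY=float(cy[i]),
                )
            )
    return TraitDataset(records)


def generate_fossil_taxa(
    n: int,
    law: GroupLawSpec,
    seed: int,
    clade: str = "sauropodomorph",
    cy_choices: Sequence[float] = (1.0, 2.0, 3.0),
) -> tuple[list[FossilTaxonRecord], list[dict]]:
    """Generate fossil taxa whose ground truth is known.

    ``law`` must be a clutch-mass (CM) law; each taxon receives a body
    mass triple, a true clutch size and breeding frequency, an egg mass
    consistent with the CM law, and egg dimensions consistent with that
    egg mass (shape chosen by clade: asymmetrical for theropods,
    ellipsoid otherwise).  Returns the records and a ground-truth table
    (one dict per taxon with the true CS, CY and egg mass) so recovery
    can be scored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if law.trait != "CM":
        raise ValueError("fossil generation expects a clutch-mass (CM) law")
    shape = "asymmetrical" if clade == "theropod" else "ellipsoid"
    k = EGG_VOLUME_COEFFICIENTS[shape]
    density = 1.13

    children = np.random.SeedSequence(seed).spawn(n)
    records, truth = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        lo, hi = np.log10(law.BM_range[0]), np.log10(law.BM_range[1])
        bm_mean = 10.0 ** rng.uniform(lo, hi)
        bm_min = bm_mean * rng.uniform(0.7, 0.95)
        bm_max = bm_mean * rng.uniform(1.05, 1.4)
        cm = law.c_true * bm_mean**law.b_true * 10.0 ** rng.normal(
            0.0, law.sigma_log10
        )
        cs_true = max(2.0, math.exp(rng.normal(math.log(12.0), 0.3)))
        em = cm / cs_true
        cy_true = float(rng.choice(np.asarray(cy_choices, dtype=float)))
        # egg dimensions back-solved from mass: EM[g] = density*k*ar*D^3
        ar = rng.uniform(1.2, 1.9)
        D = (1000.0 * em / (density * k * ar)) ** (1.0 / 3.0)
        L = ar * D
        cs_min = math.floor(0.8 * cs_true)
        cs_max = math.ceil(1.2 * cs_true)
        rec = FossilTaxonRecord(
            taxon=f"synth_taxon_{i:03d}",
            clade=clade,
            BM_min=bm_min,
            BM_mean=bm_mean,
            BM_max=bm_max,
            EM=em,
            egg=FossilEggSpec(L=L, D=D, shape=shape),
            CS_min=float(max(1, cs_min)),
            CS_mean=float(cs_true),
            CS_max=float(cs_max),
        )
        records.append(rec)
        truth.append(
            {
                "taxon": rec.taxon,
                "CS_true": cs_true,
                "CY_true": cy_true,
                "EM_true": em,
                "CM_true": cm,
                "ACM_true": cm * cy_true,
            }
        )
    return records, truth


# ---------------------------------------------------------------------------
# defaults emulating the extant calibration structure


#: Per-group (c, b) laws and residual scatter used by the default
#: generators.  Values are chosen to mimic the broad structure of real
#: reproductive allometries: birds have steeper, heavier egg-mass
#: scaling than crocodiles and tortoises; clutch mass and annual clutch
#: mass share slopes across groups with group-specific normalization
#: constants; crocodiles and tortoises are nearly indistinguishable in
#: annual clutch mass.  These are generator defaults, not estimates of
#: any real dataset.
REFERENCE_LAWS: dict[str, dict[str, tuple[float, float]]] = {
    "bird": {"EM": (0.054, 0.74), "CM": (0.25, 0.82), "ACM": (0.433, 0.725)},
    "crocodile": {"EM": (0.009, 0.45), "CM": (0.055, 0.82), "ACM": (0.170, 0.725)},
    "tortoise": {"EM": (0.005, 0.43), "CM": (0.020, 0.82), "ACM": (0.178, 0.725)},
}

_GROUP_DEFAULTS = {
    # group: (n, BM_range); sample sizes follow the calibration table
    # sizes typical for these clades, body masses in kg
    "bird": (217, (0.2, 100.0)),
    "crocodile": (22, (20.0, 1000.0)),
    "tortoise": (20, (1.0, 300.0)),
}


def default_group_specs(trait: str, sigma_log10: float = 0.2) -> list[GroupLawSpec]:
    """Bird/crocodile/tortoise law specs for one trait."""
    specs = []
    for group, (n, bm_range) in _GROUP_DEFAULTS.items():
        c, b = REFERENCE_LAWS[group][trait]
        specs.append(
            GroupLawSpec(
                group_label=group,
                trait=trait,
                c_true=c,
                b_true=b,
                sigma_log10=sigma_log10,
                n=n,
                BM_range=bm_range,
            )
        )
    return specs


def generate_reference_like_dataset(seed: int) -> TraitDataset:
    """One joint calibration table whose EM, CM and ACM all scale.

    Egg mass follows each group's EM law; clutch size and clutches per
    year are drawn so the products EM*CS and EM*CS*CY follow the CM and
    ACM laws of :data:`REFERENCE_LAWS` (the residual scatter of the
    product traits accumulates the component scatters).  Suitable for
    exercising the full fit -> compare -> merge -> apply pipeline: with
    the default laws the merge stage yields three egg-mass models
    (crocodile and tortoise sharing a slope), three clutch-mass models
    with one common slope, and two annual-clutch-mass models (bird and
    a merged crocodile+tortoise model).
    """
    children = np.random.SeedSequence(seed).spawn(len(_GROUP_DEFAULTS))
    records = []
    for (group, (n, bm_range)), child in zip(_GROUP_DEFAULTS.items(), children):
        rng = np.random.default_rng(child)
        cE, bE = REFERENCE_LAWS[group]["EM"]
        cC, bC = REFERENCE_LAWS[group]["CM"]
        cA, bA = REFERENCE_LAWS[group]["ACM"]
        lo, hi = np.log10(bm_range[0]), np.log10(bm_range[1])
        x = rng.uniform(lo, hi, n)
        BM = 10.0**x
        em = 10.0 ** (math.log10(cE) + bE * x + rng.normal(0, 0.18, n))
        cs = 10.0 ** (
            math.log10(cC / cE) + (bC - bE) * x + rng.normal(0, 0.15, n)
        )
        cy = 10.0 ** (
            math.log10(cA / cC) + (bA - bC) * x + rng.normal(0, 0.10, n)
        )
        cs = np.maximum(cs, 1.0)
        # keep the egg strictly lighter than the body
        em = np.minimum(em, 0.5 * BM)
        for i in range(n):
            records.append(
                ExtantSpeciesRecord(
                    species_id=f"{group}_{i:04d}",
                    group=group,
                    BM=float(BM[i]),
                    EM=float(em[i]),
                    CS=float(cs[i]),
                    CY=float(cy[i]),
                )
            )
    return TraitDataset(records)
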