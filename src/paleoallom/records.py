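"""Core record types for extant calibration species and fossil taxa.

All masses are stored in kilograms, egg dimensions in centimetres and
breeding frequency in clutches per year.  Derived quantities follow the
standard identities of reproductive allometry:

    clutch mass        CM  = EM * CS
    annual clutch mass ACM = CM * CY

where EM is egg mass, CS clutch size and CY the number of clutches laid
per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GROUPS",
    "TRAITS",
    "CLADES",
    "EGG_SHAPES",
    "ValidationError",
    "SchemaError",
    "InsufficientDataError",
    "ExtantSpeciesRecord",
    "FossilEggSpec",
    "FossilTaxonRecord",
    "TraitDataset",
]

#: Taxonomic groups recognised in the extant calibration set.
GROUPS = ("bird", "crocodile", "tortoise")

#: Reproductive traits modelled as power laws of body mass.
TRAITS = ("EM", "CM", "ACM")

#: Clade classes recognised for fossil taxa.
CLADES = ("theropod", "hadrosaur", "sauropodomorph")

#: Egg geometries with their volume coefficients (V = k * L * D^2, cm^3).
EGG_SHAPES = ("asymmetrical", "ellipsoid")


class ValidationError(ValueError):
    """A record violates a unit, sign or ordering invariant."""


class SchemaError(ValueError):
    """A table is missing required columns or declares unknown units."""


class InsufficientDataError(ValueError):
    """Too few records to fit or test a model for a group."""


@dataclass(frozen=True)
class ExtantSpeciesRecord:
    """One extant calibration species with measured and derived traits.

    CM and ACM are always recomputed from EM, CS and CY on construction
    so the product identities hold exactly.
    """

    species_id: str
    group: str
    BM: float  # body mass, kg
    EM: float  # egg mass, kg
    CS: float  # clutch size, eggs
    CY: float  # clutches per year, 1/yr
    order_tag: str | None = None
    CM: float = field(init=False)  # clutch mass, kg
    ACM: float = field(init=False)  # annual clutch mass, kg/yr

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.species_id!r}: group {self.group!r} not one of {GROUPS}"
            )
        for name in ("BM", "EM", "CY"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{self.species_id!r}: {name} must be > 0, got {v!r}")
        if not (math.isfinite(self.CS) and self.CS >= 1):
            raise ValidationError(f"{self.species_id!r}: CS must be >= 1, got {self.CS!r}")
        if self.EM >= self.BM:
            raise ValidationError(
                f"{self.species_id!r}: egg mass {self.EM} kg not below body mass {self.BM} kg"
            )
        object.__setattr__(self, "CM", self.EM * self.CS)
        object.__setattr__(self, "ACM", self.CM * self.CY)

    def trait_value(self, trait: str) -> float:
        """Value of one of the modelled traits (EM, CM or ACM)."""
        if trait not in TRAITS:
            raise ValueError(f"unknown trait {trait!r}")
        return getattr(self, trait)


@dataclass(frozen=True)
class FossilEggSpec:
    """Fossil egg dimensions used to reconstruct egg mass from volume.

    Volume is ``k * L * D**2`` with k = 0.51 for asymmetrical (bird-like)
    eggs and k = 0.524 for ellipsoid/globular (crocodile-like) eggs; mass
    follows from a whole-egg density of 1.13 g/cm^3.
    """

    L: float  # egg length, cm
    D: float  # egg diameter, cm
    shape: str  # "asymmetrical" or "ellipsoid"
    density: float = 1.13  # g/cm^3

    def __post_init__(self) -> None:
        if self.shape not in EGG_SHAPES:
            raise ValidationError(f"egg shape {self.shape!r} not one of {EGG_SHAPES}")
        if not (self.D > 0 and self.L >= self.D):
            raise ValidationError(f"egg dimensions must satisfy L >= D > 0, got L={self.L}, D={self.D}")
        if not self.density > 0:
            raise ValidationError(f"egg density must be > 0, got {self.density}")


@dataclass(frozen=True)
class FossilTaxonRecord:
    """A fossil taxon with body-mass and clutch-size ranges.

    Either a direct egg mass ``EM`` (kg) or a :class:`FossilEggSpec` must
    be provided; when only dimensions are known the egg mass is derived at
    read time.  Ranges are (min, mean, max) with min <= mean <= max; a
    degenerate range collapses to the single known value.  ``assumed_CY``
    is the baseline breeding frequency (one clutch per year unless
    overridden).
    """

    taxon: str
    clade: str
    BM_min: float
    BM_mean: float
    BM_max: float
    EM: float | None = None
    egg: FossilEggSpec | None = None
    CS_min: float | None = None
    CS_mean: float | None = None
    CS_max: float | None = None
    assumed_CY: float = 1.0

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValidationError(f"{self.taxon!r}: clade {self.clade!r} not one of {CLADES}")
        if not (0 < self.BM_min <= self.BM_mean <= self.BM_max):
            raise ValidationError(
                f"{self.taxon!r}: body-mass range must satisfy 0 < min <= mean <= max, "
                f"got ({self.BM_min}, {self.BM_mean}, {self.BM_max})"
            )
        if self.EM is None and self.egg is None:
            raise ValidationError(f"{self.taxon!r}: needs either EM or egg dimensions")
        if self.EM is not None and self.EM <= 0:
            raise ValidationError(f"{self.taxon!r}: EM must be > 0, got {self.EM}")
        cs = (self.CS_min, self.CS_mean, self.CS_max)
        if any(v is not None for v in cs):
            if any(v is None for v in cs):
                raise ValidationError(f"{self.taxon!r}: clutch-size range must be complete")
            if not (0 < self.CS_min <= self.CS_mean <= self.CS_max):
                raise ValidationError(
                    f"{self.taxon!r}: clutch-size range must satisfy 0 < min <= mean <= max"
                )
        if not self.assumed_CY > 0:
            raise ValidationError(f"{self.taxon!r}: assumed_CY must be > 0")

    @property
    def bm_values(self) -> tuple[float, ...]:
        """Distinct body masses in increasing order (1 to 3 values)."""
        seen: list[float] = []
        for v in (self.BM_min, self.BM_mean, self.BM_max):
            if v not in seen:
                seen.append(v)
        return tuple(seen)


class TraitDataset:
    """An extant calibration table partitioned by taxonomic group.

    Holds the full species records; each fitting routine extracts the
    (body mass, trait) pairs it needs.  Groups are kept in first-seen
    order.  Duplicated species identifiers within a group are rejected;
    averaging of literature duplicates happens at read time.
    """

    def __init__(self, records: Iterable[ExtantSpeciesRecord]):
        self.records: list[ExtantSpeciesRecord] = list(records)
        seen: dict[tuple[str, str], bool] = {}
        for r in self.records:
            key = (r.group, r.species_id)
            if key in seen:
                raise ValidationError(
                    f"duplicated species_id {r.species_id!r} within group {r.group!r}"
                )
            seen[key] = True
        self.groups: tuple[str, ...] = tuple(
            dict.fromkeys(r.group for r in self.records)
        )

    def __len__(self) -> int:
        return len(self.records)

    def group_records(self, group: str) -> list[ExtantSpeciesRecord]:
        return [r for r in self.records if r.group == group]

    def group_counts(self) -> Mapping[str, int]:
        return {g: len(self.group_records(g)) for g in self.groups}

    def subset(self, groups: Sequence[str]) -> "TraitDataset":
        wanted = set(groups)
        return TraitDataset(r for r in self.records if r.group in wanted)

    def xy(self, group: str, trait: str):
        """(log10 BM, log10 trait) arrays for one group."""
        import numpy as np

        recs = self.group_records(group)
        x = np.log10([r.BM for r in recs])
        y = np.log10([r.trait_value(trait) for r in recs])
        return x, y
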