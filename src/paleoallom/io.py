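"""Reading and writing the delimited-text calibration and fossil tables.

The canonical column layouts are::

    extant.csv:  species_id, group, order_tag, BM_kg, EM_kg, CS, CY
    fossil.csv:  taxon, clade, BM_min_kg, BM_mean_kg, BM_max_kg, EM_kg,
                 egg_L_cm, egg_D_cm, egg_shape, CS_min, CS_mean, CS_max

Mass columns declare their unit in the header suffix (``_kg`` or ``_g``);
gram values are converted to kilograms on ingest, because literature body
and egg masses mix units.  Duplicated species rows (repeat literature
measurements) are averaged arithmetically per trait on ingest.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    ExtantSpeciesRecord,
    FossilEggSpec,
    FossilTaxonRecord,
    SchemaError,
    TraitDataset,
    ValidationError,
)

__all__ = [
    "read_extant_table",
    "write_extant_table",
    "read_fossil_table",
    "write_fossil_table",
]

_MASS_UNITS = {"kg": 1.0, "g": 1e-3}


def _find_mass_column(df: pd.DataFrame, stem: str) -> tuple[str, float] | None:
    """Locate ``<stem>_kg`` or ``<stem>_g`` and return (name, factor to kg)."""
    for unit, factor in _MASS_UNITS.items():
        name = f"{stem}_{unit}"
        if name in df.columns:
            return name, factor
    return None


def _require_mass_column(df: pd.DataFrame, stem: str) -> tuple[str, float]:
    found = _find_mass_column(df, stem)
    if found is None:
        raise SchemaError(f"missing required column {stem}_kg (or {stem}_g)")
    return found


def read_extant_table(path: str | Path, sep: str = ",") -> TraitDataset:
    """Read an extant calibration table into a :class:`TraitDataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    sep
        Field delimiter; comma by default, pass ``"\\t"`` for tab.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ValidationError
        If a row violates a record invariant (the message carries the
        species identifier).
    """
    df = pd.read_csv(path, sep=sep)
    for col in ("species_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col}")
    bm_col, bm_f = _require_mass_column(df, "BM")
    em_col, em_f = _require_mass_column(df, "EM")
    for col in ("CS", "CY"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col}")

    work = pd.DataFrame(
        {
            "species_id": df["species_id"].astype(str),
            "group": df["group"].astype(str),
            "order_tag": df["order_tag"] if "order_tag" in df.columns else None,
            "BM": df[bm_col].astype(float) * bm_f,
            "EM": df[em_col].astype(float) * em_f,
            "CS": df["CS"].astype(float),
            "CY": df["CY"].astype(float),
        }
    )
    # repeat literature measurements for one species: arithmetic mean per trait
    agg = work.groupby(["group", "species_id"], sort=False).agg(
        {"BM": "mean", "EM": "mean", "CS": "mean", "CY": "mean", "order_tag": "first"}
    )
    records = []
    for (group, species_id), row in agg.iterrows():
        tag = row["order_tag"]
        if tag is None or (isinstance(tag, float) and math.isnan(tag)):
            tag = None
        records.append(
            ExtantSpeciesRecord(
                species_id=species_id,
                group=group,
                BM=row["BM"],
                EM=row["EM"],
                CS=row["CS"],
                CY=row["CY"],
                order_tag=tag,
            )
        )
    return TraitDataset(records)


def write_extant_table(dataset: TraitDataset, path: str | Path, sep: str = ",") -> None:
    """Write a calibration dataset back to delimited text (kg units)."""
    rows = [
        {
            "species_id": r.species_id,
            "group": r.group,
            "order_tag": r.order_tag if r.order_tag is not None else "",
            "BM_kg": r.BM,
            "EM_kg": r.EM,
            "CS": r.CS,
            "CY": r.CY,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def _opt(row, col) -> float | None:
    if col not in row or row[col] is None:
        return None
    v = row[col]
    if isinstance(v, str) and not v.strip():
        return None
    v = float(v)
    return None if math.isnan(v) else v


def read_fossil_table(path: str | Path, sep: str = ",") -> list[FossilTaxonRecord]:
    """Read a fossil taxon table.

    Each row must provide either a direct egg mass or egg dimensions
    (length, diameter, shape); in the latter case the egg mass is derived
    from the egg volume.  Missing min/max columns collapse onto the mean
    (degenerate range).
    """
    from .fossil import egg_mass_from_dimensions

    df = pd.read_csv(path, sep=sep)
    for col in ("taxon", "clade"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col}")
    if _find_mass_column(df, "BM_mean") is None:
        raise SchemaError("missing required column BM_mean_kg (or BM_mean_g)")

    records = []
    for _, row in df.iterrows():
        bm_mean = None
        triple = {}
        for stem in ("BM_min", "BM_mean", "BM_max"):
            found = _find_mass_column(df, stem)
            if found is not None:
                name, f = found
                v = _opt(row, name)
                triple[stem] = v * f if v is not None else None
            else:
                triple[stem] = None
        bm_mean = triple["BM_mean"]
        if bm_mean is None:
            raise ValidationError(f"{row['taxon']!r}: BM_mean is required")
        bm_min = triple["BM_min"] if triple["BM_min"] is not None else bm_mean
        bm_max = triple["BM_max"] if triple["BM_max"] is not None else bm_mean

        em = None
        found = _find_mass_column(df, "EM")
        if found is not None:
            name, f = found
            v = _opt(row, name)
            em = v * f if v is not None else None
        egg = None
        L = _opt(row, "egg_L_cm")
        D = _opt(row, "egg_D_cm")
        shape = row.get("egg_shape")
        if isinstance(shape, float) and math.isnan(shape):
            shape = None
        if L is not None and D is not None and shape:
            egg = FossilEggSpec(L=L, D=D, shape=str(shape))
        if em is None and egg is None:
            raise ValidationError(
                f"{row['taxon']!r}: needs either EM or complete egg dimensions"
            )
        if em is None:
            em = egg_mass_from_dimensions(egg)

        cs_mean = _opt(row, "CS_mean")
        cs_min = _opt(row, "CS_min")
        cs_max = _opt(row, "CS_max")
        if cs_mean is not None:
            cs_min = cs_min if cs_min is not None else cs_mean
            cs_max = cs_max if cs_max is not None else cs_mean

        cy = _opt(row, "assumed_CY")
        records.append(
            FossilTaxonRecord(
                taxon=str(row["taxon"]),
                clade=str(row["clade"]),
                BM_min=bm_min,
                BM_mean=bm_mean,
                BM_max=bm_max,
                EM=em,
                egg=egg,
                CS_min=cs_min,
                CS_mean=cs_mean,
                CS_max=cs_max,
                assumed_CY=cy if cy is not None else 1.0,
            )
        )
    return records


def write_fossil_table(
    records: Iterable[FossilTaxonRecord], path: str | Path, sep: str = ","
) -> None:
    """Write fossil taxon records to delimited text (kg / cm units)."""
    rows = []
    for r in records:
        rows.append(
            {
                "taxon": r.taxon,
                "clade": r.clade,
                "BM_min_kg": r.BM_min,
                "BM_mean_kg": r.BM_mean,
                "BM_max_kg": r.BM_max,
                "EM_kg": r.EM if r.EM is not None else "",
                "egg_L_cm": r.egg.L if r.egg else "",
                "egg_D_cm": r.egg.D if r.egg else "",
                "egg_shape": r.egg.shape if r.egg else "",
                "CS_min": r.CS_min if r.CS_min is not None else "",
                "CS_mean": r.CS_mean if r.CS_mean is not None else "",
                "CS_max": r.CS_max if r.CS_max is not None else "",
                "assumed_CY": r.assumed_CY,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")
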