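"""Report tables: rounding, bracket formatting and wide summary tables.

Report cells are rounded half-up (0.25 -> 0.3) at a configurable number
of decimals; stored values always keep full precision and rounding is
applied only at formatting time.  Ranges print as ``"x [min, max]"``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fossil import Classification, InferenceResult
from .model_selection import HomogeneityResult

__all__ = [
    "round_half_up",
    "format_value",
    "format_bracket",
    "render_tables",
    "raw_estimates_frame",
    "render_homogeneity",
    "render_classification",
]


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at one decimal), as a float."""
    if digits < 0:
        raise ValueError("digits must be >= 0")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_value(x: float | None, digits: int = 1) -> str:
    if x is None:
        return ""
    return f"{round_half_up(x, digits):.{digits}f}"


def format_bracket(
    value: float, lo: float | None, hi: float | None, digits: int = 1
) -> str:
    """``"x [min, max]"``; plain ``"x"`` when the range is degenerate."""
    v = format_value(value, digits)
    if lo is None or hi is None:
        return v
    return f"{v} [{format_value(lo, digits)}, {format_value(hi, digits)}]"


def raw_estimates_frame(results: Iterable[InferenceResult]) -> pd.DataFrame:
    """Long-format estimates, one row per (taxon, body mass, model)."""
    rows = []
    for r in results:
        rows.append(
            {
                "taxon": r.taxon,
                "model": r.model_label,
                "acm_model": r.acm_label,
                "BM_kg": r.BM_used,
                "EM_kg": r.EM_used,
                "CS_fossil": r.CS_fossil,
                "CS_model": r.CS_model,
                "AEN": r.AEN,
                "CY": r.CY,
                "CY_min": r.CY_bracket[0] if r.CY_bracket else None,
                "CY_max": r.CY_bracket[1] if r.CY_bracket else None,
            }
        )
    return pd.DataFrame(rows)


def render_tables(
    results: Sequence[InferenceResult], digits: int = 1
) -> pd.DataFrame:
    """Wide report, one row per (taxon, body mass).

    Per clutch-mass model a ``CS_<label>`` column; per annual-clutch-mass
    model ``AEN_<label>`` and ``CY_<label>`` columns, the latter with the
    clutch-size bracket appended.  Cells are formatted strings rounded
    half-up at ``digits`` decimals.
    """
    rows: dict[tuple[str, float], dict] = {}
    for r in results:
        key = (r.taxon, r.BM_used)
        row = rows.setdefault(
            key,
            {
                "taxon": r.taxon,
                "BM_kg": f"{r.BM_used:g}",
                "EM_kg": f"{r.EM_used:.3f}",
                "CS_fossil": format_value(r.CS_fossil, 0) if r.CS_fossil else "",
            },
        )
        row[f"CS_{r.model_label}"] = format_value(r.CS_model, digits)
        aen_col = f"AEN_{r.acm_label}"
        if aen_col not in row:
            row[aen_col] = format_value(r.AEN, digits)
            if r.CY is not None:
                lo, hi = r.CY_bracket if r.CY_bracket else (None, None)
                row[f"CY_{r.acm_label}"] = format_bracket(r.CY, lo, hi, digits)
    return pd.DataFrame(list(rows.values()))


def render_homogeneity(results: Mapping[str, HomogeneityResult]) -> pd.DataFrame:
    """Per-trait overall and pairwise ANCOVA p-values as a long table."""
    rows = []
    for trait, hom in results.items():
        rows.append(
            {
                "trait": trait,
                "comparison": "overall",
                "p_slopes": hom.p_interaction_overall,
                "p_intercepts": hom.p_group_overall,
                "alpha": hom.alpha,
            }
        )
        for (a, b), (p_int, p_grp) in hom.pairwise.items():
            rows.append(
                {
                    "trait": trait,
                    "comparison": f"{a} vs {b}",
                    "p_slopes": p_int,
                    "p_intercepts": p_grp,
                    "alpha": hom.alpha,
                }
            )
    return pd.DataFrame(rows)


def render_classification(
    classifications: Mapping[str, Mapping[str, list[Classification]]],
) -> pd.DataFrame:
    """Long table: taxon, trait, body mass, model, position, nearest model."""
    rows = []
    for taxon, per_trait in classifications.items():
        for trait, cls_list in per_trait.items():
            for cls in cls_list:
                for label, position in cls.positions.items():
                    rows.append(
                        {
                            "taxon": taxon,
                            "trait": trait,
                            "BM_kg": cls.BM,
                            "value": cls.value,
                            "model": label,
                            "position": position,
                            "nearest_model": cls.nearest_model,
                        }
                    )
    return pd.DataFrame(rows)
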