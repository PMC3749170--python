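"""Bundled fossil reference data for the nine studied dinosaur taxa.

The table compiles, from the paleontological literature, the body-mass
ranges (kg), reconstructed egg masses (kg) and fossil clutch-size ranges
for four theropods, two hadrosaurs and three sauropodomorph taxa (two of
them oospecies, i.e. parataxa defined on eggs).  Alongside it sit
published model-based estimates — clutch sizes and annual egg numbers
reported for these taxa under extant bird, crocodile and tortoise
models — from which the underlying extant power laws can be recovered
exactly: two reported predictions at two different body masses determine
a power law uniquely on log-log axes.

These recovered laws support point prediction only (no residual
statistics), which is all the downstream clutch-size / annual-egg-number
/ clutches-per-year estimators need.
"""

from __future__ import annotations

from .allometry import (
    AllometricFit,
    fit_from_power_law,
    fit_loglog_xy,
    power_law_through_points,
)
from .model_selection import ModelSet
from .records import FossilTaxonRecord

__all__ = [
    "load_dinosaur_taxa",
    "reference_model_sets",
    "dinosaur_egg_mass_allometry",
]

# taxon, clade, BM (min, mean, max) kg, EM kg, CS (min, mean, max)
_DINOSAUR_ROWS = [
    ("Troodon formosus", "theropod", (34, 44, 51), 0.329, (22, 23, 24)),
    ("Oviraptor philoceratops", "theropod", (33, 37, 40), 0.262, (20, 24, 30)),
    ("Citipati osmolskae", "theropod", (79, 79, 79), 0.473, (15, 22, 30)),
    ("Lourinhanosaurus antunesi", "theropod", (176, 176, 176), 0.602, (25, 63, 100)),
    ("lambeosaurine", "hadrosaur", (2390, 3344, 5057), 4.737, (22, 22, 22)),
    ("Maiasaura peeblesorum", "hadrosaur", (1500, 2556, 4079), 1.023, (16, 16, 16)),
    ("Massospondylus carinatus", "sauropodomorph", (107, 175, 280), 0.128, (34, 34, 34)),
    ("Megaloolithus mammilare", "sauropodomorph", (5000, 22399, 75000), 5.211, (9, 19, 28)),
    ("Megaloolithus patagonicus", "sauropodomorph", (5000, 22399, 75000), 1.741, (15, 28, 40)),
]


def load_dinosaur_taxa() -> list[FossilTaxonRecord]:
    """The nine-taxon dinosaur table as validated records."""
    records = []
    for taxon, clade, bm, em, cs in _DINOSAUR_ROWS:
        records.append(
            FossilTaxonRecord(
                taxon=taxon,
                clade=clade,
                BM_min=bm[0],
                BM_mean=bm[1],
                BM_max=bm[2],
                EM=em,
                CS_min=cs[0],
                CS_mean=cs[1],
                CS_max=cs[2],
            )
        )
    return records


# Published model-based estimates used as anchors for law recovery.
# Clutch-mass laws: reported model clutch sizes for Massospondylus
# carinatus (EM 0.128 kg) at its minimum and maximum body masses; each
# clutch size times the egg mass gives the predicted clutch mass at that
# body mass.
_CM_ANCHORS = {
    # model label: (BM1, CS1, BM2, CS2), EM
    "tortoise": ((107.0, 14.0, 280.0, 27.8), 0.128),
    "crocodile": ((107.0, 39.7, 280.0, 79.1), 0.128),
    "bird": ((107.0, 93.1, 280.0, 185.3), 0.128),
}

# Annual-clutch-mass laws: reported annual egg numbers for the
# Megaloolithus patagonicus producer (EM 1.741 kg) at the minimum and
# maximum sauropod body masses; AEN times egg mass gives the predicted
# annual clutch mass.
_ACM_ANCHORS = {
    "reptile": ((5000.0, 47.8, 75000.0, 340.1), 1.741),
    "bird": ((5000.0, 119.1, 75000.0, 847.3), 1.741),
}


def _law_from_anchor(anchor, em: float, trait: str, label: str) -> AllometricFit:
    bm1, ratio1, bm2, ratio2 = anchor
    c, b = power_law_through_points(bm1, ratio1 * em, bm2, ratio2 * em)
    return fit_from_power_law(c, b, trait, label)


def reference_model_sets() -> dict[str, ModelSet]:
    """CM and ACM model sets recovered from published estimates.

    The clutch-mass set has one model per extant group (bird, crocodile,
    tortoise); the annual-clutch-mass set has a bird model and a merged
    crocodile+tortoise ("reptile") model, mirroring the merged structure
    of the original analysis.  The fits carry exact coefficients but no
    residual statistics, so they support prediction and the ratio
    estimators but not prediction intervals.
    """
    cm_models = tuple(
        _law_from_anchor(anchor, em, "CM", label)
        for label, (anchor, em) in _CM_ANCHORS.items()
    )
    cm_set = ModelSet(
        trait="CM",
        models=cm_models,
        coverage={"tortoise": "tortoise", "crocodile": "crocodile", "bird": "bird"},
        provenance={m.group_label: "recovered from published estimates" for m in cm_models},
    )
    acm_models = tuple(
        _law_from_anchor(anchor, em, "ACM", label)
        for label, (anchor, em) in _ACM_ANCHORS.items()
    )
    acm_set = ModelSet(
        trait="ACM",
        models=acm_models,
        coverage={"tortoise": "reptile", "crocodile": "reptile", "bird": "bird"},
        provenance={m.group_label: "recovered from published estimates" for m in acm_models},
    )
    return {"CM": cm_set, "ACM": acm_set}


def dinosaur_egg_mass_allometry(
    taxa: list[FossilTaxonRecord] | None = None, which_bm: str = "mean"
) -> AllometricFit:
    """Egg-mass-on-body-mass regression across the dinosaur taxa themselves.

    Fits log10 EM against log10 BM over the (by default nine) fossil
    taxa, one point per taxon.  ``which_bm`` selects which body-mass
    column anchors each taxon ("min", "mean" or "max"): which masses
    best represent the egg producers is genuinely uncertain (oospecies
    are assigned to mass ranges, not individuals), so the inputs are a
    choice the caller makes rather than a fixed convention, and the
    coefficients shift accordingly.
    """
    import numpy as np

    from .fossil import fossil_egg_mass

    if which_bm not in ("min", "mean", "max"):
        raise ValueError("which_bm must be 'min', 'mean' or 'max'")
    if taxa is None:
        taxa = load_dinosaur_taxa()
    bm = np.array([getattr(t, f"BM_{which_bm}") for t in taxa], dtype=float)
    em = np.array([fossil_egg_mass(t) for t in taxa], dtype=float)
    return fit_loglog_xy(np.log10(bm), np.log10(em), "EM", "dinosaur")
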