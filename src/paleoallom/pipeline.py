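"""End-to-end pipeline: fit -> compare -> merge -> apply -> report."""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .fossil import classify_taxon, propagate_ranges
from .io import read_extant_table, read_fossil_table
from .model_selection import (
    ancova_homogeneity,
    fit_all_groups,
    load_model_sets,
    merge_models,
    save_model_sets,
)
from .records import FossilEggSpec, FossilTaxonRecord
from .reporting import (
    raw_estimates_frame,
    render_classification,
    render_homogeneity,
    render_tables,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

#: Merged-model display names: the pooled crocodile+tortoise model is
#: conventionally called the reptile model.
REPTILE_LABELS = {frozenset({"crocodile", "tortoise"}): "reptile"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    extant_path: str | None = None
    fossil_path: str | None = None
    out_dir: str = "paleoallom_out"
    model_file: str | None = None  # skip fitting stages when given
    alpha: float = 0.05
    pi_level: float = 0.95
    digits: int = 1
    sep: str = ","
    use_max_cs: bool = False  # substitute max fossil CS when classifying CM/ACM
    egg_density: float = 1.13  # g/cm^3, override re-derives EM from dimensions
    cy_baseline: float = 1.0  # assumed clutches per year for fossil taxa
    seed: int | None = None  # recorded in the run log only

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.pi_level < 1:
            raise ValueError("pi_level must be in (0, 1)")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def _apply_overrides(taxa: list[FossilTaxonRecord], config: PipelineConfig):
    out = []
    for t in taxa:
        changes = {}
        if config.cy_baseline != t.assumed_CY:
            changes["assumed_CY"] = config.cy_baseline
        if config.egg_density != 1.13 and t.egg is not None:
            egg = FossilEggSpec(
                L=t.egg.L, D=t.egg.D, shape=t.egg.shape, density=config.egg_density
            )
            changes["egg"] = egg
            changes["EM"] = None  # force re-derivation from dimensions
        out.append(dataclasses.replace(t, **changes) if changes else t)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory artifacts (model sets, homogeneity
    results, estimate and classification frames).  When ``model_file``
    is set the fitting/comparison stages are skipped and the serialized
    models are used directly.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"paleoallom {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"alpha={config.alpha} pi_level={config.pi_level} digits={config.digits}",
        f"seed={config.seed}",
    ]
    artifacts: dict = {}

    if config.model_file:
        model_sets = _stage("load-models")(load_model_sets)(config.model_file)
        log.append(f"models loaded from {config.model_file}; fitting skipped")
        homogeneity = {}
    else:
        if not config.extant_path:
            raise PipelineError("stage 'fit' failed: no extant table or model file given")
        dataset = _stage("read-extant")(read_extant_table)(
            config.extant_path, sep=config.sep
        )
        log.append(
            f"extant table {config.extant_path}: "
            + ", ".join(f"{g}={n}" for g, n in dataset.group_counts().items())
        )
        homogeneity = {}
        model_sets = {}
        for trait in ("EM", "CM", "ACM"):
            fits = _stage("fit")(fit_all_groups)(dataset, trait)
            hom = _stage("compare")(ancova_homogeneity)(
                dataset, trait, alpha=config.alpha
            )
            ms = _stage("merge")(merge_models)(
                fits, hom, dataset, merged_labels=REPTILE_LABELS
            )
            homogeneity[trait] = hom
            model_sets[trait] = ms
            log.append(
                f"{trait}: p_slopes={hom.p_interaction_overall:.3g} "
                f"p_intercepts={hom.p_group_overall:.3g} -> "
                f"{len(ms.models)} model(s): {', '.join(ms.labels)}"
            )
            for label, why in ms.provenance.items():
                log.append(f"  {trait}/{label}: {why}")
        render_homogeneity(homogeneity).to_csv(
            out_dir / "homogeneity.csv", index=False
        )
        save_model_sets(model_sets, out_dir / "models.yaml")

    artifacts["model_sets"] = model_sets
    artifacts["homogeneity"] = homogeneity

    if config.fossil_path:
        taxa = _stage("read-fossil")(read_fossil_table)(
            config.fossil_path, sep=config.sep
        )
        taxa = _apply_overrides(taxa, config)
        log.append(f"fossil table {config.fossil_path}: {len(taxa)} taxa")

        results = []
        for taxon in taxa:
            results.extend(_stage("apply")(propagate_ranges)(taxon, model_sets))
        raw = raw_estimates_frame(results)
        raw.to_csv(out_dir / "estimates_raw.csv", index=False)
        render_tables(results, digits=config.digits).to_csv(
            out_dir / "estimates.csv", index=False
        )
        artifacts["estimates"] = raw
        artifacts["results"] = results

        classifiable = {
            t: ms for t, ms in model_sets.items()
            if all(m.has_interval_stats for m in ms.models)
        }
        if classifiable:
            classifications = {
                t.taxon: _stage("classify")(classify_taxon)(
                    t, classifiable, level=config.pi_level, use_max_cs=config.use_max_cs
                )
                for t in taxa
            }
            cls_frame = render_classification(classifications)
            cls_frame.to_csv(out_dir / "classification.csv", index=False)
            artifacts["classification"] = cls_frame
        else:
            log.append("models carry no residual statistics; classification skipped")

    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    artifacts["log"] = log
    return artifacts
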