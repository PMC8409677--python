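"""End-to-end experiment orchestration.

Two experiment modes, reflecting what can actually be synthesized:

* feature mode — 30-descriptor vectors are sampled directly from the
  per-taxon statistics book and fed to Tukey grouping, factor analysis
  and discriminant classification (the surrogate of the published
  classification experiment);
* image mode — grains are rasterized, rendered into focal stacks,
  segmented, EDF-composed and measured, producing a feature table from
  pixels (small fields; exercises the whole imaging chain).

All randomness derives from one seed through named substreams, so a run
is fully reproducible and each stage can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import edf as edf_mod
from . import phantoms, segmentation, stats
from .book import DESCRIPTORS, MODALITIES, TAXA
from .stackio import FeatureTable, write_feature_table

REPORT_SCHEMA_VERSION = 1


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    child = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return np.random.default_rng(child)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full reproduction run."""

    modalities: Sequence[str] = MODALITIES
    taxa: Sequence[str] = TAXA
    n_per_taxon: int = 300          # feature-mode sample size per taxon
    alpha: float = 0.05
    cross_validate: bool = False
    rng_seed: int = 0
    # image-mode extras
    image_grains_per_taxon: int = 1
    image_size: int = 768
    image_taxa: Sequence[str] = ("Brassica", "Salix")

    def __post_init__(self) -> None:
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {unknown}")


def measure_mask_population(appearance: "phantoms.TaxonAppearance",
                            n: int, pixel_size: float,
                            rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Rasterize ``n`` grains and measure Length/Elongation on each mask.

    Returns arrays of the measured MaxFeret (µm), MaxFeret/MinFeret, and
    the generating true axes — the parameter-recovery experiment used to
    validate the geometry chain against the published size tables.
    """
    from .descriptors import feret_diameters

    length = np.empty(n)
    elong = np.empty(n)
    true_major = np.empty(n)
    true_ratio = np.empty(n)
    for i in range(n):
        mask, truth = phantoms.make_grain_mask(appearance, pixel_size, rng)
        max_f, min_f, _ = feret_diameters(mask, pixel_size)
        length[i] = max_f
        elong[i] = max_f / min_f
        true_major[i] = truth.true_major_um
        true_ratio[i] = truth.true_major_um / truth.true_minor_um
    return {"length": length, "elongation": elong,
            "true_major": true_major, "true_ratio": true_ratio}


def run_feature_experiment(config: RunConfig, modality: str) -> Dict:
    """Feature-mode chain for one modality: sample → Tukey → FA → LDA → CCR."""
    rng = stage_rng(config.rng_seed, f"sample:{modality}")
    table = phantoms.sample_feature_table(
        n_per_taxon=config.n_per_taxon, modality=modality,
        rng_seed=rng, taxa=config.taxa)

    letters = {}
    for desc in DESCRIPTORS:
        grouping = stats.tukey_letters(table, desc, alpha=config.alpha)
        letters[desc] = {t: grouping.letters[t] for t in grouping.groups}

    report = stats.classify_pipeline(table, cross_validate=config.cross_validate,
                                     rng_seed=config.rng_seed)
    fm = report.factor_model
    total = fm.eigenvalues.sum()
    return {
        "modality": modality,
        "n_per_taxon": config.n_per_taxon,
        "tukey_letters": letters,
        "scree": {
            "eigenvalues": [float(v) for v in fm.eigenvalues],
            "retained": [int(j) for j in report.retained],
            "retained_information_pct":
                float(100.0 * fm.eigenvalues[report.retained].sum() / total),
            "first_two_information_pct":
                float(100.0 * fm.eigenvalues[:2].sum() / total),
        },
        "confusion": {
            "classes": report.confusion.classes,
            "counts": report.confusion.counts.tolist(),
            "per_class_ccr": report.confusion.per_class_ccr,
            "overall_ccr": report.confusion.overall_ccr,
        },
        "table": table,
    }


def run_image_experiment(config: RunConfig, modality: str) -> Dict:
    """Image-mode chain for one modality on a small rendered field."""
    rng = stage_rng(config.rng_seed, f"scene:{modality}")
    appearances = [phantoms.appearance_from_book(t, modality)
                   for t in config.image_taxa]
    scene_cfg = phantoms.SceneConfig(
        taxa=appearances, grains_per_taxon=config.image_grains_per_taxon,
        image_size=config.image_size, rng_seed=config.rng_seed)
    grains = phantoms.make_scene(scene_cfg, modality, rng)
    stack = phantoms.render_focal_stack(grains, scene_cfg, modality, rng)
    edf_result = edf_mod.compose_edf(stack)
    # area floor ~ a 10 µm disc: rejects blur-ring artifacts, keeps grains
    min_area = int(np.pi * (5.0 / scene_cfg.pixel_size) ** 2 / 4)
    segmented = segmentation.segment_field(edf_result.composite, modality,
                                           min_area=min_area,
                                           field_id=stack.field_id)
    taxa_labels = [_match_truth(g, grains) for g in segmented]
    from .descriptors import extract_features
    table = extract_features(stack, segmented, edf_result, taxa=taxa_labels)
    return {
        "modality": modality,
        "n_true_grains": len(grains),
        "n_segmented": len(segmented),
        "table": table,
    }


def _match_truth(grain: segmentation.GrainMask,
                 truths: Sequence[phantoms.GrainTruth]) -> str:
    """Label a segmented grain by the ground-truth grain it overlaps most."""
    best, best_ov = "unknown", 0
    for truth in truths:
        ov = int((grain.mask & truth.mask).sum())
        if ov > best_ov:
            best, best_ov = truth.taxon, ov
    return best


def run_all(config: RunConfig, out_dir: Optional[str] = None) -> Dict:
    """Full reproduction run over the configured modalities.

    Produces per-modality feature tables, Tukey letter tables for all 30
    descriptors, scree data, confusion matrices and CCRs; returns a
    JSON-serializable summary (tables are written to ``out_dir`` when
    given and dropped from the summary).
    """
    summary: Dict = {"schema_version": REPORT_SCHEMA_VERSION,
                     "rng_seed": config.rng_seed,
                     "modalities": {}}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for modality in config.modalities:
        result = run_feature_experiment(config, modality)
        table: FeatureTable = result.pop("table")
        if out:
            write_feature_table(table, out / f"features_{modality}.csv")
        summary["modalities"][modality] = result
    if out:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
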