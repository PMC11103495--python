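"""End-to-end pipeline driver.

Executes, per tissue: calibration → tissue masking → DTA mapping →
round-to-round registration → nuclear segmentation → feature extraction,
then pools the per-cell tables across tissues for QC/normalization and the
cohort-level statistics. Every artifact is stamped with the configuration
hash, seed and SF used, and rerunning with an identical configuration
reproduces an identical cell table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    ScalingFactor,
    calibrate_from_series,
    read_titration_csv,
)
from .dta import ChannelImage, DTAMap, compute_dta_map, make_tissue_mask
from .io import RunConfig, TissueEntry, load_stack, write_dta_map, write_labels, write_mask
from .qc import run_qc_chain
from .registration import RigidTransform, apply_transform, register_rounds
from .segmentation import extract_features, segment_nuclei
from .stats import StatResult, anova_lsd, summarize_cohort

__all__ = ["PipelineResult", "run_pipeline", "load_scaling_factor", "process_tissue"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Artifacts of a full run (also written under the output directory)."""

    cells: pd.DataFrame
    cells_qc: pd.DataFrame
    sf: ScalingFactor
    transforms: dict[str, dict[int, RigidTransform]]
    qc_report: dict
    cohort_summaries: dict[str, dict]
    stat_results: dict[str, StatResult]
    out_dir: Path


def load_scaling_factor(source: str | Path) -> ScalingFactor:
    """SF from a JSON file or fitted from a titration CSV."""
    source = Path(source)
    if source.suffix.lower() == ".json":
        return ScalingFactor.from_json(source)
    series = read_titration_csv(source)
    try:
        return calibrate_from_series(series["targeted"], series["untargeted"])
    except KeyError as err:
        raise ValueError(
            f"titration CSV must contain 'targeted' and 'untargeted' probes, "
            f"found {sorted(series)}"
        ) from err


def process_tissue(
    tissue: TissueEntry,
    config: RunConfig,
    sf: ScalingFactor,
    base_dir: str | Path = ".",
    out_dir: Path | None = None,
    provenance: dict | None = None,
) -> tuple[pd.DataFrame, dict[int, RigidTransform], DTAMap]:
    """Run the image stages for one tissue and return its cell table."""
    rounds = load_stack(tissue, base_dir=base_dir)
    if 0 not in rounds or "DAPI" not in rounds[0]:
        raise ValueError(f"tissue {tissue.tissue_id!r}: round 0 must contain a DAPI channel")
    ref_dapi = rounds[0]["DAPI"]

    # register every later round to round 0 via DAPI, resample its channels
    transforms: dict[int, RigidTransform] = {}
    registered: dict[str, ChannelImage] = {}
    for round_idx in sorted(rounds):
        round_images = rounds[round_idx]
        if round_idx == 0:
            tf = RigidTransform(0.0, 0.0)
        else:
            if "DAPI" not in round_images:
                raise ValueError(
                    f"tissue {tissue.tissue_id!r}: round {round_idx} lacks DAPI "
                    "for registration"
                )
            tf = register_rounds(ref_dapi, round_images["DAPI"])
        transforms[round_idx] = tf
        correction = tf.inverse()
        for name, img in round_images.items():
            if name == "DAPI":
                continue
            pixels = (
                img.pixels.copy()
                if correction.is_identity()
                else apply_transform(img.pixels, correction)
            )
            registered[name] = ChannelImage(
                pixels=np.clip(pixels, 0.0, None),
                wavelength=img.wavelength,
                label=img.label,
                exposure_ms=img.exposure_ms,
            )
        logger.info(
            "tissue %s round %d: shift (%.2f, %.2f), score %.3f",
            tissue.tissue_id, round_idx, tf.dy, tf.dx, tf.score,
        )

    if config.tissue_reference_channel not in registered:
        raise ValueError(
            f"tissue {tissue.tissue_id!r}: reference channel "
            f"{config.tissue_reference_channel!r} not found for masking"
        )
    mask = make_tissue_mask(registered[config.tissue_reference_channel])

    for probe in (config.targeted_channel, config.untargeted_channel):
        if probe not in registered:
            raise ValueError(f"tissue {tissue.tissue_id!r}: probe channel {probe!r} missing")
    dta_map = compute_dta_map(
        registered[config.targeted_channel],
        registered[config.untargeted_channel],
        sf,
        mask=mask,
        floor_eps=config.floor_eps,
    )

    labels = segment_nuclei(ref_dapi, min_area_px=config.min_nucleus_area_px)
    logger.info("tissue %s: %d nuclei, %d valid DTA px", tissue.tissue_id,
                labels.n_cells, int(dta_map.valid.sum()))

    feature_stack = {
        name: img
        for name, img in registered.items()
        if name not in (config.targeted_channel, config.untargeted_channel)
    }
    cells = extract_features(
        labels,
        feature_stack,
        dta=dta_map,
        cell_expansion_px=config.cell_expansion_px,
        af_channels=config.af_channels,
    )
    cells.insert(0, "tissue_id", tissue.tissue_id)
    cells.insert(1, "cohort", tissue.cohort)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dta_map(out_dir / f"{tissue.tissue_id}_dta.tif", dta_map, provenance=provenance)
        write_mask(out_dir / f"{tissue.tissue_id}_mask.tif", mask)
        write_labels(out_dir / f"{tissue.tissue_id}_labels.tif", labels.labels)
        for round_idx, tf in transforms.items():
            tf.to_json(out_dir / f"{tissue.tissue_id}_r{round_idx}_transform.json")
    return cells, transforms, dta_map


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> PipelineResult:
    """Execute the full analysis described by a run configuration.

    Stage order: calibrate → (per tissue) mask/DTA/register/segment/quantify
    → pooled QC chain → cohort statistics. Any stage error aborts with the
    stage and tissue named in the exception.
    """
    config.validate(base_dir=base_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "software_version": __version__,
        "seed": config.seed,
    }

    sf_path = Path(config.sf_source)
    if not sf_path.is_absolute():
        sf_path = Path(base_dir) / sf_path
    sf = load_scaling_factor(sf_path)
    sf.to_json(out_dir / "scaling_factor.json")
    provenance["sf_used"] = sf.sf

    tables = []
    transforms: dict[str, dict[int, RigidTransform]] = {}
    for tissue in config.tissues:
        try:
            cells, tfs, _ = process_tissue(
                tissue, config, sf, base_dir=base_dir, out_dir=out_dir, provenance=provenance
            )
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at tissue {tissue.tissue_id!r}: {err}"
            ) from err
        tables.append(cells)
        transforms[tissue.tissue_id] = tfs
    cells_all = pd.concat(tables, ignore_index=True)
    cells_all.to_csv(out_dir / "cells_raw.csv", index=False)

    exposures = {
        ch.name: ch.exposure_ms for tissue in config.tissues for ch in tissue.channels
    }
    # autofluorescence columns are keyed by wavelength after extraction
    for af_name, wl in config.af_channels.items():
        if af_name in exposures:
            exposures[wl] = exposures[af_name]
    cohorts = {t.cohort for t in config.tissues}
    do_zscore = config.zscore
    if do_zscore and config.spec.control_label not in cohorts:
        raise RuntimeError(
            f"pipeline failed at z-score stage: control cohort "
            f"{config.spec.control_label!r} is required for control-anchored "
            f"z-scoring but no tissue carries that cohort label "
            f"(set zscore: false to skip)"
        )
    try:
        cells_qc, qc_report = run_qc_chain(
            cells_all,
            config.spec,
            exposures=exposures,
            channel_wavelength_map=config.channel_wavelength_map,
            zscore=do_zscore,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at QC stage: {err}") from err
    cells_qc.to_csv(out_dir / "cells_qc.csv", index=False)
    (out_dir / "qc_report.json").write_text(json.dumps(qc_report, indent=2) + "\n")

    # cohort-level statistics on z-scored biomarkers and DTA
    stat_results: dict[str, StatResult] = {}
    cohort_summaries: dict[str, dict] = {}
    value_columns = [c for c in cells_qc.columns if c.startswith("mean_")]
    if "dta_mean" in cells_qc.columns:
        value_columns.append("dta_mean")
    if len(cohorts) >= 2:
        for col in value_columns:
            groups = {}
            for cohort, sub in cells_qc.groupby("cohort"):
                vals = sub[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size >= 2:
                    groups[str(cohort)] = vals
            if len(groups) >= 2:
                stat_results[col] = anova_lsd(groups)
    for col in value_columns:
        cohort_summaries[col] = {}
        for cohort, sub in cells_qc.groupby("cohort"):
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                cohort_summaries[col][str(cohort)] = vars(summarize_cohort(str(cohort), vals))

    results_payload = {
        "provenance": provenance,
        "cohort_summaries": cohort_summaries,
        "anova_lsd": {
            col: {
                "F": r.statistic,
                "p_value": r.p_value,
                "pairwise": [vars(p) for p in r.pairwise],
            }
            for col, r in stat_results.items()
        },
    }
    (out_dir / "stat_results.json").write_text(json.dumps(results_payload, indent=2) + "\n")

    return PipelineResult(
        cells=cells_all,
        cells_qc=cells_qc,
        sf=sf,
        transforms=transforms,
        qc_report=qc_report,
        cohort_summaries=cohort_summaries,
        stat_results=stat_results,
        out_dir=out_dir,
    )
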