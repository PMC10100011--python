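"""End-to-end orchestration: phantom -> segment -> postprocess -> quantify
-> compare.

Stage order is fixed: inference, per-class largest almost-connected
component, SUV leakage removal, quantification.  Each stage logs its
input/output voxel counts; both postprocessing stages can only shrink a
mask, so the logged counts are non-increasing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import agreement_report, dice
from .imagevol import CT_HU, PET_SUV, BinaryMask, LabelMap, ScalarVolume, write_volume
from .phantom import PhantomCase, PhantomSpec, generate_cohort, perturb_mask
from .postproc import PostprocParams, almost_connected_filter, bone_mask_from_ct, remove_suv_leakage
from .quant import UptakeStats, suv_stats
from .unet import NetSpec, TrainConfig, UNet3D, infer_labelmap, inference_spec_for, reference_segmenter

log = logging.getLogger("carotiq")

SIDES = ("carotid_left", "carotid_right")


@dataclass
class PipelineConfig:
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    net_spec: NetSpec = field(default_factory=NetSpec)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    postproc: PostprocParams = field(default_factory=PostprocParams)
    use_reference_segmenter: bool = True
    model: UNet3D | None = None
    cohort_n: int = 10
    observer_dilation_mm: float = 1.37
    observer_erosion_mm: float = 1.37
    observer_flip_rate: float = 0.05
    seed: int = 0
    debug_dir: Path | None = None


@dataclass
class CaseResult:
    labelmap: LabelMap
    masks: dict[str, BinaryMask]
    stats: dict[str, UptakeStats]
    stage_counts: dict[str, dict[str, int]]


def run_case(ct: ScalarVolume, pet: ScalarVolume, segmenter,
             params: PostprocParams = PostprocParams(),
             debug_dir: Path | None = None) -> CaseResult:
    """Run the full per-case pipeline.

    ``segmenter`` is either a trained :class:`UNet3D` or the string
    ``"reference"`` for the rule-based segmenter.  An empty initial
    segmentation is not an error: it yields zeroed, flagged statistics.
    """
    t0 = time.perf_counter()
    if segmenter == "reference":
        labelmap = reference_segmenter(ct, pet)
    elif isinstance(segmenter, UNet3D):
        spec = inference_spec_for(ct.grid.shape, segmenter.spec)
        labelmap = infer_labelmap(ct, segmenter, spec)
    else:
        raise TypeError("segmenter must be a UNet3D or the string 'reference'")
    log.info("stage=inference voxels_left=%d voxels_right=%d elapsed=%.2fs",
             int((labelmap.classes == 1).sum()), int((labelmap.classes == 2).sum()),
             time.perf_counter() - t0)
    bone = bone_mask_from_ct(ct, params)
    masks, stats, counts = {}, {}, {}
    for side in SIDES:
        initial = labelmap.side_mask(side)
        filtered = almost_connected_filter(initial, params)
        cleaned = remove_suv_leakage(filtered, pet, bone, params)
        counts[side] = {"initial": initial.count, "component_filter": filtered.count,
                        "leakage_removal": cleaned.count}
        if cleaned.count == 0:
            log.warning("stage=quantify side=%s empty segmentation", side)
        log.info("stage=postproc side=%s initial=%d filtered=%d cleaned=%d",
                 side, initial.count, filtered.count, cleaned.count)
        masks[side] = cleaned
        stats[side] = suv_stats(pet, cleaned)
    if debug_dir is not None:
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        write_volume(labelmap, debug_dir / "initial_labelmap.nii.gz")
        write_volume(bone, debug_dir / "bone.nii.gz")
        for side, m in masks.items():
            write_volume(m, debug_dir / f"{side}_final.nii.gz")
    return CaseResult(labelmap=labelmap, masks=masks, stats=stats, stage_counts=counts)


def stats_frame(rows: list[tuple[str, str, UptakeStats]]) -> pd.DataFrame:
    """Long per-case, per-side statistics table."""
    return pd.DataFrame([
        {"case_id": cid, "side": side, **st.as_dict()} for cid, side, st in rows
    ])


def run_agreement_study(config: PipelineConfig, out_dir) -> dict:
    """Simulated method-comparison study on a phantom cohort.

    Method A: the automated pipeline (reference segmenter by default).
    Method B: a simulated second observer — the ground-truth masks perturbed
    by dilation/erosion and random boundary flips.  Produces per-method
    statistics tables, the per-quantity agreement report (bias, LoA, exact
    LoA confidence limits, paired t), and a per-case Dice table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort_n, config.phantom_spec, config.seed)
    rows_a, rows_b, dice_rows = [], [], []
    rng = np.random.default_rng(config.seed + 1)
    if config.use_reference_segmenter:
        segmenter = "reference"
    elif config.model is not None:
        segmenter = config.model
    else:
        raise ValueError("use_reference_segmenter is False but no model was provided")
    for case in cohort:
        result = run_case(case.ct, case.pet, segmenter, config.postproc)
        truth = {"carotid_left": case.truth_left, "carotid_right": case.truth_right}
        for side in SIDES:
            observer = perturb_mask(truth[side], config.observer_dilation_mm,
                                    config.observer_erosion_mm,
                                    seed=int(rng.integers(2**31 - 1)),
                                    flip_rate=config.observer_flip_rate)
            rows_a.append((case.case_id, side, result.stats[side]))
            rows_b.append((case.case_id, side, suv_stats(case.pet, observer)))
            dice_rows.append({"case_id": case.case_id, "side": side,
                              "dice": dice(result.masks[side], observer).value})
    stats_a = stats_frame(rows_a)
    stats_b = stats_frame(rows_b)
    report = agreement_report(stats_a, stats_b)
    dice_df = pd.DataFrame(dice_rows)
    stats_a.to_csv(out_dir / "stats_pipeline.csv", index=False)
    stats_b.to_csv(out_dir / "stats_observer.csv", index=False)
    report.to_csv(out_dir / "agreement_report.csv", index=False)
    dice_df.to_csv(out_dir / "dice.csv", index=False)
    (out_dir / "agreement_report.json").write_text(
        json.dumps(report.to_dict(orient="records"), indent=2))
    echo_config(config, out_dir / "config_echo.yaml")
    return {"stats_a": stats_a, "stats_b": stats_b, "report": report, "dice": dice_df}


def echo_config(config: PipelineConfig, path) -> None:
    """Write a YAML echo of the full configuration for provenance."""
    def plain(obj):
        if isinstance(obj, UNet3D):
            return f"UNet3D(levels={obj.spec.levels}, base_channels={obj.spec.base_channels})"
        if hasattr(obj, "__dataclass_fields__"):
            return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (tuple, list)):
            return [plain(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj
    Path(path).write_text(yaml.safe_dump(plain(config), sort_keys=False))
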