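"""End-to-end orchestration: simulate -> expression -> chip -> copy number
-> downstream comparisons, with a reproducibility manifest.

Every threshold any stage consumes is recorded in the manifest, together
with the config snapshot, the seed, input digests and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, RegionSet, read_annotation, read_regions, write_bed12, write_regions
from .chip import classify_binding, enrichment_pipeline, gene_binding_values
from .compare import (
    compare_bins,
    flag_fraction,
    has_distance_summary,
    has_distances,
    knockdown_effect,
    length_effect_correlation,
    length_split_comparison,
    overlap_fraction,
)
from .config import ConfigError, EnrichmentParams, SimulationConfig, load_config, validate_config
from .copynum import compare_copy_x_vs_autosomes, gene_copy_ratio
from .expression import (
    ExpressionTable,
    all_arm_statistics,
    arm_statistics,
    classify_compensation,
    filter_expressed,
    mf_ratio,
    read_expression,
    write_expression,
)
from .simulate import SimulatedStudy, simulate_study
from .tracks import read_track, write_track

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    outdir: str
    summary: dict[str, Any]
    manifest: dict[str, Any]


def _load_inputs(cfg: dict) -> SimulatedStudy | dict:
    required = ["annotation", "expression", "ip_track", "input_male_track"]
    missing = [k for k in required if not cfg.get(k)]
    if missing:
        raise ConfigError(
            f"simulation disabled and required inputs missing: {', '.join(missing)}"
        )
    enr: EnrichmentParams = cfg["enrichment"]
    data: dict[str, Any] = {"digests": {}}
    ann = read_annotation(cfg["annotation"])
    data["annotation"] = ann
    data["expression"] = read_expression(cfg["expression"])
    data["ip"] = read_track(cfg["ip_track"], enr.grid_step, ann.arms)
    data["input_male"] = read_track(cfg["input_male_track"], enr.grid_step, ann.arms)
    for key in ("annotation", "expression", "ip_track", "input_male_track"):
        data["digests"][key] = _digest(cfg[key])
    for key, loader in (
        ("input_female_track", lambda p: read_track(p, enr.grid_step, ann.arms)),
        ("has", lambda p: read_regions(p, "HAS")),
        ("under_replicated", lambda p: read_regions(p, "under_replicated")),
    ):
        if cfg.get(key):
            data[key.removesuffix("_track")] = loader(cfg[key])
            data["digests"][key] = _digest(cfg[key])
    if cfg.get("housekeeping"):
        hk = pd.read_csv(cfg["housekeeping"], sep="\t", index_col=0)
        data["housekeeping"] = dict(hk.iloc[:, 0].astype(bool))
        data["digests"]["housekeeping"] = _digest(cfg["housekeeping"])
    return data


def run_pipeline(config: str | dict, outdir: str | None = None) -> RunResult:
    """Run the full analysis described by a config file or dict."""
    if isinstance(config, (str, os.PathLike)):
        cfg, warns = load_config(os.fspath(config))
    else:
        cfg, warns = validate_config(config)
    for w in warns:
        log.warning(w)
    outdir = outdir or cfg.get("outdir") or "results/run"
    os.makedirs(outdir, exist_ok=True)

    sim_cfg: SimulationConfig = cfg["simulation"]
    enr: EnrichmentParams = cfg["enrichment"]
    threshold = float(cfg["expression_threshold"])
    ref_arm = cfg["reference_arm"]
    length_threshold = int(cfg["length_threshold"])
    summary: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": int(cfg["seed"]),
        "config": _config_snapshot(cfg),
        "input_digests": {},
        "thresholds": {
            "expression_threshold": threshold,
            "reference_arm": ref_arm,
            "length_threshold": length_threshold,
            "smooth1_window": enr.smooth1_window,
            "grid_step": enr.grid_step,
            "input_floor_min": enr.input_floor_min,
            "smooth2_window": enr.smooth2_window,
            "min_points_per_window": enr.min_points_per_window,
            "exclude_first_exonic_bp": enr.exclude_first_exonic_bp,
            "top_fraction": enr.top_fraction,
            "min_points_per_gene": enr.min_points_per_gene,
            "copy_smooth_window": enr.copy_smooth_window,
            "binding_bins": ["Unbound", "(3,4]", "(4,5]", "(5,inf)"],
        },
    }
    t0 = time.time()

    # ---- stage: inputs -------------------------------------------------
    stage = "simulate" if cfg.get("simulate", True) else "load"
    try:
        if cfg.get("simulate", True):
            study = simulate_study(sim_cfg)
            ann, expr = study.annotation, study.expression
            has, ur, hk = study.has, study.under_replicated, study.housekeeping
            _write_simulated(study, outdir)
        else:
            data = _load_inputs(cfg)
            ann = data["annotation"]
            expr = data["expression"]
            has = data.get("has")
            ur = data.get("under_replicated")
            hk = data.get("housekeeping")
            manifest["input_digests"] = data["digests"]
            study = None
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    log.info("stage %s done in %.1fs", stage, time.time() - t0)

    # ---- stage: expression --------------------------------------------
    t = time.time()
    try:
        expressed = filter_expressed(expr, ["male", "female"], threshold)
        ratios = mf_ratio(expr, "male", "female", sorted(expressed))
        arm_stats = all_arm_statistics(ratios, ann)
        ref_stats = arm_statistics(ratios, ann, ref_arm)
        comp = classify_compensation(ratios, ref_stats)
        comp["arm"] = [ann[g].arm for g in comp.index]
        comp.to_csv(os.path.join(outdir, "compensation.tsv"), sep="\t")
        arm_stats.to_csv(os.path.join(outdir, "arm_stats.tsv"), sep="\t", index=False)
        x_comp = comp[comp["arm"] == "X"]
        summary["n_expressed_x"] = int(len(x_comp))
        summary["compensated_fraction_x"] = (
            float(x_comp["compensated"].mean()) if len(x_comp) else float("nan")
        )
        manifest["thresholds"]["compensation_bounds"] = [
            float(ref_stats.lower),
            float(ref_stats.upper),
        ]
    except Exception as exc:
        raise PipelineError("expression", exc) from exc
    log.info("stage expression done in %.1fs", time.time() - t)

    # ---- stage: chip ---------------------------------------------------
    t = time.time()
    try:
        if study is not None:
            ip, input_male = study.ip, study.input_male
            input_female = study.input_female
        else:
            ip, input_male = data["ip"], data["input_male"]
            input_female = data.get("input_female")
        ratio_track = enrichment_pipeline(ip, input_male, enr)
        write_track(ratio_track, os.path.join(outdir, "enrichment.bedgraph"))
        values = gene_binding_values(ann, ratio_track, enr)
        calls, binding_ref = classify_binding(values, ann, ref_arm, expressed)
        calls.to_csv(os.path.join(outdir, "binding_calls.tsv"), sep="\t")
        manifest["thresholds"]["binding_cutoff"] = float(binding_ref.cutoff)
        x_calls = calls[calls["arm"] == "X"]
        x_expr_calls = x_calls[x_calls.index.isin(expressed)]
        summary["binding_reference_mean"] = binding_ref.mean
        summary["binding_reference_sd"] = binding_ref.sd
        summary["bin_sizes"] = dict(
            x_expr_calls["bin"].value_counts().sort_index()
        )
        comp_unbound = x_expr_calls.index[
            (~x_expr_calls["bound"])
            & x_expr_calls.index.map(lambda g: bool(comp.loc[g, "compensated"])
                                     if g in comp.index else False)
        ]
        summary["n_compensated_unbound"] = int(len(comp_unbound))
    except Exception as exc:
        raise PipelineError("chip", exc) from exc
    log.info("stage chip done in %.1fs", time.time() - t)

    # ---- stage: copynumber --------------------------------------------
    t = time.time()
    try:
        if input_female is not None:
            compensated_set = set(comp.index[comp["compensated"]])
            cr = gene_copy_ratio(
                input_male,
                input_female,
                ann,
                genes=sorted(compensated_set),
                params=enr,
                normalize_depth=bool(cfg.get("normalize_input_depth", True)),
            )
            cr.to_csv(os.path.join(outdir, "copy_ratios.tsv"), sep="\t")
            cmp_copy = compare_copy_x_vs_autosomes(cr, ann)
            summary["copy_number_comparison"] = cmp_copy.summary()
        else:
            summary["copy_number_comparison"] = None
    except Exception as exc:
        raise PipelineError("copynumber", exc) from exc
    log.info("stage copynumber done in %.1fs", time.time() - t)

    # ---- stage: analyze ------------------------------------------------
    t = time.time()
    try:
        comparisons: list[dict] = []
        if "knockdown" in expr.data.columns and "control" in expr.data.columns:
            effects = knockdown_effect(expr, "knockdown", "control", threshold)
            auto_ids = [g for g in effects.index if ann[g].arm != "X" and g in expressed]
            auto_eff = effects.loc[auto_ids]
            bins_df, bin_cmps = compare_bins(effects, x_expr_calls, auto_eff)
            bins_df.to_csv(os.path.join(outdir, "effect_bins.tsv"), sep="\t", index=False)
            comparisons += [c.summary() for c in bin_cmps]
            ls = length_split_comparison(effects, x_expr_calls, ann, length_threshold)
            comparisons.append(ls.summary())
            summary["length_split_p"] = ls.p_value
            corr = length_effect_correlation(effects, x_expr_calls, ann)
            summary["length_effect_correlation"] = corr
        if has is not None and len(has) > 0:
            dists = has_distances(ann, has, genes=list(x_expr_calls.index))
            hd = has_distance_summary(dists, x_expr_calls, ann, length_threshold)
            hd.to_csv(os.path.join(outdir, "has_distances.tsv"), sep="\t", index=False)
            summary["has_distance_means"] = {
                r["group"]: r["mean_distance"] for _, r in hd.iterrows()
            }
        if ur is not None and len(ur) > 0:
            comp_x = set(comp.index[(comp["compensated"]) & (comp["arm"] == "X")])
            unbound_comp = [g for g in comp_x if g in x_expr_calls.index
                            and not x_expr_calls.loc[g, "bound"]]
            strong_comp = [g for g in comp_x if g in x_expr_calls.index
                           and x_expr_calls.loc[g, "value"] > 5]
            summary["under_replicated_overlap"] = {
                "unbound_compensated": overlap_fraction(ann, unbound_comp, ur)
                if unbound_comp else float("nan"),
                "strongly_bound_compensated": overlap_fraction(ann, strong_comp, ur)
                if strong_comp else float("nan"),
            }
        if hk:
            bound_ids = list(x_expr_calls.index[x_expr_calls["bound"]])
            unbound_ids = list(x_expr_calls.index[~x_expr_calls["bound"]])
            summary["housekeeping_fraction"] = {
                "bound": flag_fraction(hk, bound_ids) if bound_ids else float("nan"),
                "unbound": flag_fraction(hk, unbound_ids) if unbound_ids else float("nan"),
            }
        if comparisons:
            pd.DataFrame(comparisons).to_csv(
                os.path.join(outdir, "comparisons.tsv"), sep="\t", index=False
            )
            summary["n_tests"] = len(comparisons)
    except Exception as exc:
        raise PipelineError("analyze", exc) from exc
    log.info("stage analyze done in %.1fs", time.time() - t)

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True, default_flow_style=False)
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, outdir)
    return RunResult(outdir=outdir, summary=summary, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_snapshot(cfg: dict) -> dict:
    snap = {}
    for k, v in cfg.items():
        if k == "simulation":
            snap[k] = v.to_dict()
        elif k == "enrichment":
            snap[k] = {f: getattr(v, f) for f in v.__dataclass_fields__}
        else:
            snap[k] = v
    return snap


def _write_simulated(study: SimulatedStudy, outdir: str) -> None:
    write_bed12(study.annotation, os.path.join(outdir, "annotation.bed"))
    write_expression(study.expression, os.path.join(outdir, "expression.tsv"))
    study.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
    study.true_folds.to_frame().to_csv(os.path.join(outdir, "true_folds.tsv"), sep="\t")
    write_regions(study.has, os.path.join(outdir, "has.bed"))
    write_regions(study.under_replicated, os.path.join(outdir, "under_replicated.bed"))
    pd.Series(study.housekeeping, name="housekeeping").rename_axis("gene_id").to_frame(
    ).to_csv(os.path.join(outdir, "housekeeping.tsv"), sep="\t")
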