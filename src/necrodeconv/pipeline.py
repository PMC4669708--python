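"""End-to-end orchestration: simulate -> screen -> fit -> infer -> score.

A run is described by a YAML/dict configuration with a global ``seed``,
an output directory, an ordered ``stages`` list and one optional section
per stage.  Stage outputs are pure functions of inputs plus config, so a
repeated run with the same configuration reproduces every file; the
machine-readable run report records package and library versions, the
seed, a hash of the canonical configuration, and per-stage summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, io
from .dose_response import estimate_ec50, estimate_ic50, fit_hill, fit_kd
from .inference import infer_proteins
from .scoring import plot_targets, score_targets
from .screen import call_hits, normalize_plate, recover_planted_hits
from .simulate import (
    CurveSimConfig,
    PulldownSimConfig,
    ScreenSimConfig,
    simulate_curve,
    simulate_pulldown,
    simulate_screen,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate_screen", "screen", "simulate_curve", "fit",
                "simulate_pulldown", "infer", "score")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build(cfg_cls, section: dict, seed: int):
    kwargs = dict(section or {})
    kwargs.setdefault("seed", seed)
    field_names = {f.name for f in dataclasses.fields(cfg_cls)}
    unknown = set(kwargs) - field_names
    if unknown:
        raise ValueError(f"unknown {cfg_cls.__name__} option(s): {sorted(unknown)}")
    return cfg_cls(**kwargs)


def validate_config(config: dict) -> list:
    stages = config.get("stages") or list(KNOWN_STAGES)
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    inputs = config.get("inputs", {})
    needs = {
        "screen": ("simulate_screen", "plates"),
        "fit": ("simulate_curve", "curve"),
        "infer": ("simulate_pulldown", "psms"),
        "score": ("infer", "profiles"),
    }
    for stage, (producer, input_key) in needs.items():
        if stage in stages and producer not in stages and input_key not in inputs:
            raise ValueError(
                f"stage {stage!r} needs the {producer!r} stage or an "
                f"'inputs.{input_key}' path"
            )
    return list(stages)


def run(config: dict) -> dict:
    """Execute the selected stages in dependency order.

    Returns the run report (also written to ``<outdir>/report.json``).
    """
    stages = validate_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "necrodeconv_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    report: dict = {
        "package": "necrodeconv",
        "version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "seed": seed,
        "config_hash": config_hash(config),
        "stages": {},
    }
    state: dict = {}
    for stage in [s for s in KNOWN_STAGES if s in stages]:
        try:
            summary = _run_stage(stage, config, state, inputs, outdir, seed)
        except Exception as exc:  # halt with the failing stage named
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = summary
        logger.info("stage %s: %s", stage, summary)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_stage(stage: str, config: dict, state: dict, inputs: dict, outdir: Path,
               seed: int) -> dict:
    if stage == "simulate_screen":
        cfg = _build(ScreenSimConfig, config.get("simulate_screen"), seed)
        wells = simulate_screen(cfg)
        io.write_wells(wells, outdir / "plates.csv")
        state["wells"] = wells
        state["planted"] = set(cfg.planted_hits)
        return {"n_wells": len(wells), "n_plates": wells["plate_id"].nunique(),
                "seed": cfg.seed}

    if stage == "screen":
        wells = state.get("wells")
        if wells is None:
            wells = io.read_wells(inputs["plates"])
        norm = normalize_plate(wells)
        calls = call_hits(norm, **(config.get("screen") or {}))
        io.write_wells(norm, outdir / "normalized.csv")
        io.write_table(calls, outdir / "hits.tsv")
        summary = {"n_compounds": int(calls["compound"].nunique()) if len(calls) else 0,
                   "n_hits": int(calls["hit"].sum()),
                   "n_robust_hits": int(calls.loc[calls["robust_hit"], "compound"].nunique())}
        if state.get("planted") is not None:
            recovery = recover_planted_hits(calls, state["planted"])
            io.write_table(recovery, outdir / "hit_recovery.tsv")
            summary["recovery"] = recovery.to_dict("records")
        return summary

    if stage == "simulate_curve":
        section = dict(config.get("simulate_curve") or {})
        if "true_params" in section:
            section["true_params"] = tuple(section["true_params"])
        if "dose_design" in section:
            section["dose_design"] = tuple(section["dose_design"])
        cfg = _build(CurveSimConfig, section, seed)
        series = simulate_curve(cfg)
        io.write_curve(series, outdir / "curve.csv")
        state["curve"] = series
        return {"n_points": len(series.points), "model": cfg.model, "seed": cfg.seed}

    if stage == "fit":
        series = state.get("curve")
        if series is None:
            series = io.read_curve(inputs["curve"])
        section = dict(config.get("fit") or {})
        kind = section.pop("kind", "ec50")
        fitter = {"ec50": estimate_ec50, "ic50": estimate_ic50, "kd": fit_kd,
                  "hill": fit_hill}[kind]
        fit = fitter(series, **section)
        result = {"kind": kind, "background": fit.background, "signal": fit.signal,
                  "midpoint_M": fit.midpoint, "slope": fit.slope, "rss": fit.rss,
                  "converged": fit.converged, "censored": fit.censored,
                  "reported_midpoint_M": fit.reported_midpoint, "flags": list(fit.flags)}
        with open(outdir / "fit.json", "w") as fh:
            json.dump(result, fh, indent=2)
        return result

    if stage == "simulate_pulldown":
        cfg = _build(PulldownSimConfig, config.get("simulate_pulldown"), seed)
        psms, truth = simulate_pulldown(cfg)
        io.write_psms(psms, outdir / "psms.tsv")
        io.write_table(truth, outdir / "pulldown_truth.tsv")
        state["psms"] = psms
        state["pulldown_truth"] = truth
        return {"n_psms": len(psms), "n_proteins": len(truth),
                "n_true_targets": int((truth["kind"] == "target").sum()), "seed": cfg.seed}

    if stage == "infer":
        psms = state.get("psms")
        if psms is None:
            psms = io.read_psms(inputs["psms"])
        result = infer_proteins(psms, **(config.get("infer") or {}))
        io.write_table(result.target.groups, outdir / "groups.tsv")
        io.write_table(result.target.profiles, outdir / "group_profiles.tsv")
        state["profiles"] = result.target.profiles
        return {
            "n_target_groups": result.target.n_groups,
            "n_decoy_groups": result.decoy.n_groups,
            "protein_fdr": result.fdr.protein_fdr,
            "peptide_fdr": result.fdr.peptide_fdr,
            "fdr_pass": bool(result.fdr.protein_pass and result.fdr.peptide_pass),
        }

    if stage == "score":
        profiles = state.get("profiles")
        if profiles is None:
            profiles = io.read_table(inputs["profiles"])
        section = dict(config.get("score") or {})
        section.setdefault("seed", seed)
        make_plot = section.pop("plot", True)
        scores = score_targets(profiles, **section)
        io.write_table(scores, outdir / "targets.tsv")
        if make_plot:
            plot_targets(scores, str(outdir / "targets.svg"),
                         alpha=section.get("alpha", 0.05))
        summary = {"n_groups": len(scores), "n_specific": int(scores["specific"].sum())}
        truth = state.get("pulldown_truth")
        if truth is not None:
            planted = set(truth.loc[truth["kind"] == "target", "accession"])
            called = set(scores.loc[scores["specific"], "group_id"])
            summary["planted_targets_called"] = sorted(planted & called)
            summary["planted_targets_missed"] = sorted(planted - called)
        return summary

    raise ValueError(f"unhandled stage {stage!r}")
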