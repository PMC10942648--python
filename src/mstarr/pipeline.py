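"""End-to-end pipeline driver.

Stages: input (files or synthetic) -> per-treatment detection and
repeatability filters -> precision-weighted model fit -> permutation
empirical FDR -> classification -> optional condition-specificity. All
randomness flows from one master seed, split deterministically per stage;
the run log records seeds, versions, and window counts surviving each
filter.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import CountMatrix
from .fdr import TreatmentResult, analyze_treatment, condition_specific
from .io import read_count_table, write_results, write_track
from .qc import detection_filter, repeatability_filter, sample_qc_report

log = logging.getLogger("mstarr")


@dataclass
class PipelineResult:
    """Everything a run produces, before/besides the files on disk."""

    treatments: dict[str, dict[str, Any]] = field(default_factory=dict)
    condition_profile: pd.DataFrame | None = None
    upset: pd.DataFrame | None = None
    run_log: dict[str, Any] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _child_seeds(master: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def _validate(config: dict) -> dict:
    cfg = dict(config)
    cfg.setdefault("seed", 1)
    cfg.setdefault("fdr", 0.01)
    cfg.setdefault("permutations", 100)
    cfg.setdefault("moderate", True)
    cfg.setdefault("quality_weights", True)
    cfg.setdefault("filters", {})
    if cfg["permutations"] <= 0:
        raise ValueError("config requires a positive permutation count")
    if not (0 < cfg["fdr"] < 1):
        raise ValueError("fdr threshold must lie in (0, 1)")
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ValueError("config must name exactly one of `synthetic` or `inputs`")
    return cfg


@_stage("input")
def _load_counts(cfg: dict) -> tuple[CountMatrix, pd.DataFrame | None]:
    if "synthetic" in cfg:
        from .simulate import simulate_mstarr_experiment

        params = dict(cfg["synthetic"])
        params.setdefault("seed", _child_seeds(cfg["seed"], 1)[0])
        cm, truth = simulate_mstarr_experiment(**params)
        return cm, truth
    cm = read_count_table(cfg["inputs"]["counts"], cfg["inputs"]["meta"])
    return cm, None


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis described by a config mapping.

    Returns the in-memory result bundle; when ``output_dir`` is given (or
    named in the config) also writes per-treatment result tables, BED
    tracks of regulatory and methylation-dependent windows, the QC report,
    and a JSON run log.
    """
    cfg = _validate(config)
    outdir = Path(output_dir or cfg.get("output_dir", "")) if (output_dir or cfg.get("output_dir")) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    cm, truth = _load_counts(cfg)
    treatments = sorted({s.treatment for s in cm.samples})
    seeds = _child_seeds(cfg["seed"], len(treatments) + 1)

    result = PipelineResult()
    result.run_log = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "permutations": cfg["permutations"],
        "fdr_threshold": cfg["fdr"],
        "n_windows_input": len(cm.windows),
        "treatments": {},
    }

    fl = cfg["filters"]
    exclude_partial = fl.get("exclude_partial", True)
    q_frames = {}
    for t_i, trt in enumerate(treatments):
        sub = cm.subset_samples(
            np.array([s.treatment == trt for s in cm.samples])
        )
        det = _stage("detection_filter")(detection_filter)(
            sub,
            min_dna_per_methcond=fl.get("min_dna", 3),
            min_rna_either_methcond=fl.get("min_rna", 3),
        )
        partial = np.array([w.partial for w in sub.windows])
        if exclude_partial:
            det = det & ~partial
        detected = sub.subset_windows(det)
        rep = _stage("repeatability_filter")(repeatability_filter)(
            detected,
            pair_frac=fl.get("pair_frac", 0.25),
            central_quantile=fl.get("central_quantile", 0.90),
            scale=fl.get("repeatability_scale", "log2cpm"),
        )
        analyzed = detected.subset_windows(rep)
        qc = sample_qc_report(analyzed)

        res: TreatmentResult = _stage("model_fdr")(analyze_treatment)(
            analyzed,
            n_perm=cfg["permutations"],
            seed=seeds[t_i],
            fdr_threshold=cfg["fdr"],
            moderate=cfg["moderate"],
            quality_weights=cfg["quality_weights"],
        )

        table = res.classification.copy()
        table.insert(0, "window_id", analyzed.window_ids)
        for j, name in enumerate(("mu", "beta_meth", "beta_rna_unmeth", "beta_rna_meth")):
            table[name] = res.fits.beta[:, j]
        table["p_unmeth"] = res.fits.p_unmeth
        table["p_meth"] = res.fits.p_meth
        table["p_act"] = res.p_act
        table["p_int"] = res.fits.p_int

        result.treatments[trt] = {
            "detection_mask": det,
            "repeatability_mask": rep,
            "qc": qc,
            "result": res,
            "table": table,
            "summary": res.summary,
        }
        result.run_log["treatments"][trt] = {
            "seed": seeds[t_i],
            "n_detected": int(det.sum()),
            "n_after_repeatability": int(rep.sum()),
            "n_positive_beta": res.N,
            **res.summary,
        }
        q_frames[trt] = pd.Series(res.q_act, index=analyzed.window_ids)

        if outdir:
            write_results(table, outdir / f"{trt}_windowfits.tsv")
            qc.to_csv(outdir / f"{trt}_sample_qc.tsv", sep="\t", index=False)
            flags = np.where(
                table["methylation_dependent"], "MD",
                np.where(table["regulatory"], "regulatory", ""),
            )
            write_track(analyzed.windows, flags, outdir / f"{trt}_track.bed",
                        name=f"mstarr_{trt}")

    if len(treatments) >= 2:
        q_df = pd.DataFrame(q_frames)
        profile, upset = condition_specific(q_df, fdr_threshold=cfg["fdr"],
                                            mode=cfg.get("specificity_mode", "default"),
                                            stringent_fdr=cfg.get("stringent_fdr", 0.10))
        result.condition_profile = profile
        result.upset = upset
        if outdir:
            profile.rename_axis("window_id").to_csv(outdir / "condition_profile.tsv", sep="\t")
            upset.to_csv(outdir / "upset_counts.tsv", sep="\t", index=False)

    if truth is not None:
        result.run_log["synthetic"] = True
        result.treatments[treatments[0]]["truth"] = truth
    if outdir:
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(result.run_log, fh, indent=2)
    return result
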