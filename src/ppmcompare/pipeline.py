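"""End-to-end runs from a config file: comparison reports and evaluations.

A run config (YAML) has the shape::

    input:
      synthetic: {grid_shape: [40, 48, 34], n_subjects: 16, seed: 7, ...}
      # or: nifti_dir: path/to/images, mask: path/to/mask.nii.gz
    methods:
      - {kind: clusterwise, alpha: 0.05, cdt_p: 0.001}
      - {kind: voxelwise_fwe, alpha: 0.05}
      - {kind: bayes, d: 0.5, tau: 5}
    evaluation:          # optional
      noise: {R: 10, fraction: 0.25, seed: 1}
      # or: sweep: {P: 10, target_mm: [-4, 48, 12], seed: 1}
    output_dir: out/

Outputs: report.csv (survived-voxel counts, one column per method), a
binary NIfTI mask and cluster-table CSV per method, t / log-odds maps,
tidy evaluation CSVs, and run_log.jsonl recording every parameter and
seed consumed.
"""

from __future__ import annotations

import glob
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bayesian, classical, evaluation, synthetic
from .evaluation import DatasetAnalysis, MethodSpec, survived_count
from .synthetic import SubjectImageSet
from .volume_io import StatVolume, read_nifti, write_nifti

__all__ = [
    "RunConfig",
    "load_config",
    "load_images",
    "default_method_grid",
    "methods_from_config",
    "run_comparison",
    "run_evaluation",
]

#: the full published comparison layout: 2 classical + 4 d x 3 tau Bayesian
GUIDELINE_DS = (0.2, 0.5, 0.8, 1.0)
GUIDELINE_TAUS = (3.0, 5.0, 10.0)


@dataclass
class RunConfig:
    input: dict
    methods: list
    evaluation: dict | None = None
    output_dir: str = "out"
    label: str = "dataset"

    def __post_init__(self):
        if not isinstance(self.input, dict) or not (
            "synthetic" in self.input or "nifti_dir" in self.input
        ):
            raise ValueError("input: must contain 'synthetic' or 'nifti_dir'")
        if not self.methods:
            raise ValueError("methods: at least one method is required")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        methods = methods_from_config(raw.get("methods", []))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"methods: {exc}") from exc
    return RunConfig(
        input=raw.get("input", {}),
        methods=methods,
        evaluation=raw.get("evaluation"),
        output_dir=raw.get("output_dir", "out"),
        label=raw.get("label", "dataset"),
    )


def default_method_grid() -> list:
    """The published 14-column layout: clusterwise, voxelwise FWE, and the
    Bayesian d x tau grid."""
    methods = [MethodSpec.clusterwise(), MethodSpec.voxelwise()]
    for d in GUIDELINE_DS:
        for tau in GUIDELINE_TAUS:
            methods.append(MethodSpec.bayes(d=d, tau=tau))
    return methods


def methods_from_config(entries) -> list:
    if entries in (None, [], "full_grid"):
        return default_method_grid()
    out = []
    for i, e in enumerate(entries):
        kind = e.get("kind")
        kwargs = {k: v for k, v in e.items() if k not in ("kind", "name")}
        name = e.get("name")
        if kind == "clusterwise":
            out.append(MethodSpec.clusterwise(name=name, **kwargs))
        elif kind == "voxelwise_fwe":
            out.append(MethodSpec.voxelwise(name=name, **kwargs))
        elif kind == "bayes":
            out.append(MethodSpec.bayes(name=name, **kwargs))
        else:
            raise ValueError(f"methods[{i}].kind: unknown kind {kind!r}")
    return out


def load_images(cfg: RunConfig) -> SubjectImageSet:
    """Materialize the input dataset (synthetic or a directory of NIfTIs)."""
    if "synthetic" in cfg.input:
        spec = synthetic.spec_from_dict(cfg.input["synthetic"] or {})
        images, _ = synthetic.generate_subject_images(spec)
        return images
    nifti_dir = cfg.input["nifti_dir"]
    mask_path = cfg.input.get("mask")
    paths = sorted(
        glob.glob(os.path.join(nifti_dir, "*.nii"))
        + glob.glob(os.path.join(nifti_dir, "*.nii.gz"))
    )
    if mask_path:
        paths = [p for p in paths
                 if os.path.abspath(p) != os.path.abspath(mask_path)]
    if len(paths) < 2:
        raise ValueError(f"input.nifti_dir: fewer than 2 NIfTI files in {nifti_dir}")
    vols = [read_nifti(p, kind="contrast") for p in paths]
    if mask_path:
        mvol = read_nifti(mask_path)
        inside = np.isfinite(mvol.values) & (mvol.values > 0)
    else:
        inside = np.ones(vols[0].grid.shape, dtype=bool)
        for v in vols:
            inside &= np.isfinite(v.values) & (v.values != 0)
    from .volume_io import BrainMask

    return SubjectImageSet(vols, BrainMask(vols[0].grid, inside))


class _RunLog:
    """JSON-lines log: one record per pipeline stage."""

    def __init__(self, path):
        self.path = path
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        self._fh = open(path, "a")

    def record(self, stage: str, **payload):
        rec = {"stage": stage, "wall_time": time.time(), **payload}
        self._fh.write(json.dumps(rec, default=_jsonable) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def run_comparison(cfg: RunConfig) -> pd.DataFrame:
    """Fit both branches, threshold with every configured method, and write
    the survived-voxel report plus all maps and cluster tables."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    log = _RunLog(os.path.join(cfg.output_dir, "run_log.jsonl"))
    log.record("config", input=cfg.input, methods=[m.name for m in cfg.methods],
               output_dir=cfg.output_dir)

    images = load_images(cfg)
    ana = DatasetAnalysis(images)
    log.record("fit", n=images.n, V=images.mask.V, df=ana.glm.df)

    counts = {}
    for m in cfg.methods:
        try:
            act = ana.run(m)
        except Exception as exc:  # per-method failure: record, continue
            log.record("method_failed", method=m.name, error=str(exc))
            counts[m.name] = np.nan
            continue
        counts[m.name] = survived_count(act)
        mask_vol = StatVolume(images.grid, act.active.astype(float), "contrast")
        write_nifti(mask_vol, os.path.join(cfg.output_dir, f"{m.name}_mask.nii.gz"))
        if act.details is not None:
            act.details.clusters.to_csv(
                os.path.join(cfg.output_dir, f"{m.name}_clusters.csv"), index=False
            )
        extra = {}
        if m.kind in ("clusterwise", "voxelwise_fwe"):
            extra = act.details.thresholds_used
        elif act.details is not None:
            extra = {"cB": ana.prior.cB, "gamma": act.details.spec.gamma,
                     "tau": act.details.spec.tau, "d": act.details.spec.d}
        log.record("method", method=m.name, survived=counts[m.name], **extra)

    # shared maps
    write_nifti(ana.glm.tmap, os.path.join(cfg.output_dir, "tmap.nii.gz"))
    try:
        if ana.prior.cB > 0:
            write_nifti(ana.posterior.post_mean,
                        os.path.join(cfg.output_dir, "post_mean.nii.gz"))
            write_nifti(ana.posterior.post_var,
                        os.path.join(cfg.output_dir, "post_var.nii.gz"))
    except ValueError:
        pass
    try:
        sm = ana.smoothness
        log.record("smoothness", fwhm_voxels=list(sm.fwhm_voxels),
                   resels=list(sm.resels))
    except ValueError as exc:
        log.record("smoothness_failed", error=str(exc))

    report = pd.DataFrame([counts], index=pd.Index([cfg.label], name="contrast"))
    report.to_csv(os.path.join(cfg.output_dir, "report.csv"))
    log.record("report", path="report.csv")
    log.close()
    return report


def run_evaluation(cfg: RunConfig):
    """Dispatch to the noise-robustness or sample-size-sweep protocol."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    log = _RunLog(os.path.join(cfg.output_dir, "run_log.jsonl"))
    if not cfg.evaluation:
        log.record("evaluation", status="none requested; nothing to do")
        log.close()
        return None
    images = load_images(cfg)
    if "noise" in cfg.evaluation:
        p = cfg.evaluation["noise"] or {}
        res = evaluation.noise_robustness_experiment(
            images, cfg.methods, R=int(p.get("R", 10)),
            fraction=float(p.get("fraction", 0.25)), seed=int(p.get("seed", 0)),
        )
        res.table.to_csv(os.path.join(cfg.output_dir, "noise_eval.csv"), index=False)
        log.record("evaluation", protocol="noise", R=res.R, fraction=res.fraction,
                   seeds=res.seeds)
        log.close()
        return res
    if "sweep" in cfg.evaluation:
        p = cfg.evaluation["sweep"] or {}
        res = evaluation.sample_size_sweep(
            images, cfg.methods, P=int(p.get("P", 10)),
            target_mm=tuple(p.get("target_mm", (-4.0, 48.0, 12.0))),
            seed=int(p.get("seed", 0)),
        )
        res.table.to_csv(os.path.join(cfg.output_dir, "sweep.csv"), index=False)
        res.orders_frame().to_csv(os.path.join(cfg.output_dir, "orders.csv"))
        log.record("evaluation", protocol="sweep", P=res.P,
                   target_mm=list(res.target_mm),
                   seed=int(p.get("seed", 0)))
        log.close()
        return res
    log.close()
    raise ValueError("evaluation: expected a 'noise' or 'sweep' section")
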