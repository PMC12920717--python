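"""End-to-end analysis workflows with machine-readable provenance.

Each function wires the library modules into one of the standard analyses —
per-sample metric tables, model fitting, prediction, depth resampling,
cohort simulation, leave-one-out evaluation — and returns (or writes) a
provenance record carrying the inputs, seed, parameters, and package
version, so every run is reproducible from its record alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agemodel import (
    AgeModel,
    BelowModelSupportError,
    EvaluationReport,
    fit_age_model,
    loo_evaluate,
    predict_phyloage,
)
from .depth import DepthProfile, simulate_depth
from .metrics import lambda_metric, metric_report
from .simulate import SimulatedIndividual, SimulationParams, simulate_cohort
from .trees import PhylogenyTree
from .vfs import VFS, filter_tip_variants, read_vfs, write_genotype_matrix, write_vfs

__all__ = [
    "provenance_record",
    "compute_metrics",
    "fit_model",
    "predict",
    "depth_resample",
    "run_simulation",
    "run_loo",
]


def provenance_record(step: str, seed: int | None = None,
                      parameters: dict | None = None,
                      inputs: Sequence[str] = ()) -> dict:
    return {
        "tool": "vfsage",
        "version": __version__,
        "step": step,
        "seed": seed,
        "parameters": parameters or {},
        "inputs": list(inputs),
    }


def _load_vfs_inputs(inputs: Iterable) -> tuple[list[VFS], list[str]]:
    loaded, names = [], []
    for item in inputs:
        if isinstance(item, VFS):
            loaded.append(item)
            names.append(f"<in-memory:{item.sample_id}>")
        else:
            path = Path(item)
            fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
            loaded.append(read_vfs(path, format=fmt))
            names.append(str(path))
    return loaded, names


def compute_metrics(
    inputs: Iterable,
    threshold: float = 0.01,
    matrices: Sequence[pd.DataFrame | None] | None = None,
    trees: Sequence[PhylogenyTree | None] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample metric table for a collection of VFS inputs (paths or
    in-memory spectra); one row per sample."""
    spectra, names = _load_vfs_inputs(inputs)
    rows = []
    for i, vfs in enumerate(spectra):
        matrix = matrices[i] if matrices is not None else None
        tree = trees[i] if trees is not None else None
        report = metric_report(vfs, matrix=matrix, tree=tree,
                               threshold=threshold, seed=seed)
        rows.append(dataclasses.asdict(report))
    table = pd.DataFrame(rows)
    prov = provenance_record("compute_metrics", seed=seed,
                             parameters={"threshold": threshold}, inputs=names)
    return table, prov


def fit_model(
    cohort: pd.DataFrame | str | Path,
    init_a: float = 0.001,
    init_b: float = 0.3,
    threshold: float = 0.01,
    depth: float | None = None,
    panel_tag: str = "full",
    model_out: str | Path | None = None,
) -> AgeModel:
    """Fit a decay–age model from a cohort table (columns: age, lambda).

    ``depth`` records the mean read depth the training spectra were
    resampled to; it becomes part of the model's provenance so prediction
    can warn on mismatched sequencing designs.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort, sep="\t")
    model = fit_age_model(
        cohort, init_a=init_a, init_b=init_b, threshold=threshold,
        depth_profile="full" if depth is None else depth,
        panel_tag=panel_tag, drop_nonpositive=True,
    )
    if model_out is not None:
        model.to_json(model_out)
    return model


def predict(
    model: AgeModel | str | Path,
    inputs: Iterable,
    depth: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Predict physiological blood age for each input spectrum.

    Rows carry the decay metric, the prediction, the residual against
    chronological age when known, and a status column: ``ok``,
    ``negative_prediction`` (reported as-is, not clipped) or
    ``below_support`` (no retained variants).  A depth that differs from the
    model's training depth profile triggers a warning.
    """
    if not isinstance(model, AgeModel):
        model = AgeModel.from_json(Path(model))
    run_depth = "full" if depth is None else depth
    if run_depth != model.depth_profile:
        warnings.warn(
            f"depth profile mismatch: model trained at {model.depth_profile!r}"
            f" but prediction requested at {run_depth!r}",
            stacklevel=2,
        )
    spectra, names = _load_vfs_inputs(inputs)
    rows = []
    for vfs in spectra:
        lam = lambda_metric(vfs, model.threshold)
        try:
            pred = predict_phyloage(model, lam)
            status = "negative_prediction" if pred < 0 else "ok"
        except BelowModelSupportError:
            pred = np.nan
            status = "below_support"
        rows.append({
            "sample_id": vfs.sample_id,
            "lambda": lam,
            "phyloage_star": pred,
            "age": vfs.age,
            "residual": pred - vfs.age if vfs.age is not None else np.nan,
            "status": status,
        })
    table = pd.DataFrame(rows)
    prov = provenance_record(
        "predict", parameters={"a": model.a, "b": model.b,
                               "threshold": model.threshold,
                               "depth_profile": model.depth_profile},
        inputs=names)
    return table, prov


def depth_resample(
    inputs: Iterable,
    mean_depth: float,
    seed: int = 0,
    threshold: float = 0.01,
) -> tuple[list[VFS], dict]:
    """Tip-filter each spectrum, resample it at finite depth, and re-apply
    the threshold to the observed VAFs."""
    spectra, names = _load_vfs_inputs(inputs)
    profile = DepthProfile(mean_depth=mean_depth, seed=seed,
                           reapply_threshold=threshold)
    out = [simulate_depth(filter_tip_variants(v, threshold), profile)
           for v in spectra]
    prov = provenance_record(
        "depth_resample", seed=seed,
        parameters={"mean_depth": mean_depth, "threshold": threshold,
                    "min_alt_reads": profile.min_alt_reads},
        inputs=names)
    return out, prov


def run_simulation(
    ages: Sequence[float],
    params: SimulationParams | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    tip_mutations: bool = True,
) -> tuple[list[SimulatedIndividual], dict]:
    """Simulate a cohort and (optionally) write one directory per cohort:
    newick trees, genotype-matrix and VFS TSVs, per-individual ground truth,
    and a manifest.  The manifest is byte-identical across runs with the
    same seed and parameters."""
    params = params or SimulationParams()
    cohort = simulate_cohort(ages, params, seed=seed,
                             tip_mutations=tip_mutations)
    manifest = {
        "provenance": provenance_record(
            "simulate", seed=params.seed if seed is None else seed,
            parameters={
                f.name: getattr(params, f.name)
                for f in dataclasses.fields(params)
                if f.name != "clade_size_distribution"
            },
        ),
        "individuals": [],
    }
    for ind in cohort:
        entry = {
            "sample_id": ind.sample_id,
            "age": ind.age,
            "n_variants": len(ind.vfs),
            "true_decay": ind.true_decay,
            "ch_events": [[t, s] for t, s in ind.ch_events],
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            ind.tree.to_newick(out_dir / f"{ind.sample_id}.nwk")
            write_vfs(ind.vfs, out_dir / f"{ind.sample_id}.vfs.tsv")
            if ind.matrix is not None:
                write_genotype_matrix(ind.matrix,
                                      out_dir / f"{ind.sample_id}.matrix.tsv")
            (out_dir / f"{ind.sample_id}.truth.json").write_text(
                json.dumps(entry, sort_keys=True, indent=2) + "\n")
        manifest["individuals"].append(entry)
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return cohort, manifest


def run_loo(
    cohort: pd.DataFrame | str | Path,
    seed: int = 0,
    report_out: str | Path | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation from a cohort table (columns: age, lambda)."""
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort, sep="\t")
    report = loo_evaluate(cohort, seed=seed)
    if report_out is not None:
        report.to_tsv(report_out)
    return report
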