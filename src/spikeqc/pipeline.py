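"""End-to-end orchestration: design -> simulate -> QC -> DE -> PCA.

``run_pipeline`` performs the complete benchmark on the canonical designs:
the 8x8 Latin-square dilution pools drive the platform characterisation
(LOD, linearity, precision) on both simulated platforms, and the
normal/disease condition panels drive fold-change accuracy, volcano
classification against truth, cross-platform concordance and PCA
discrimination.  Everything is deterministic given the top-level seed
(per-stage substreams are derived from it), and a JSON manifest records the
inputs, seed and a parameter hash alongside all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sqio
from .diffexp import PanelComparison, platform_concordance
from .microarray import MicroarrayQC, normalize_75th
from .multivariate import group_separation, pca
from .panels import condition_panel_pair, dilution_pool_design, validate_design
from .qpcr import QpcrQC, panel_fold_changes
from .simulate import (
    ArraySimParams,
    QpcrSimParams,
    derive_seed,
    simulate_microarray,
    simulate_panel_pair_microarray,
    simulate_panel_pair_qpcr,
    simulate_qpcr,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("spikeqc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Top-level pipeline configuration (all options have defaults).

    ``array_params`` / ``qpcr_params`` override individual simulator fields;
    analysis options mirror the model-class defaults.  Unknown keys are
    rejected by :meth:`from_dict`.
    """

    out_dir: str = "spikeqc-out"
    seed: int = 1
    n_runs: int = 3
    arrays_per_panel_per_run: int = 2
    array_params: dict = field(default_factory=dict)
    qpcr_params: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    linear_range: str | tuple[float, float] = "auto"
    detection_threshold: float = 0.5
    reference_level: float = 1e6
    fc_cutoffs: tuple[float, ...] = (3.0, 2.0, 1.5, 1.1)
    p_cutoff: float = 0.05
    fc_tolerance: float = 0.10
    n_components: int = 4
    verbosity: int = 1

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for sub in ("array_params", "qpcr_params"):
            if sub in data:
                params_cls = ArraySimParams if sub == "array_params" else QpcrSimParams
                valid = {f.name for f in dataclasses.fields(params_cls)}
                bad = set(data[sub]) - valid
                if bad:
                    raise PipelineError(f"unknown {sub} keys: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError(f"config {path} must be a mapping")
        return cls.from_dict(data)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full benchmark; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    pools = dilution_pool_design()
    pair = condition_panel_pair()
    sqio.write_design(pools, out / "pools_design.tsv")
    sqio.write_design_wide(pools, out / "pools_design_wide.tsv")
    sqio.write_truth(pair, out / "panel_truth.tsv")
    vr = validate_design(pools)

    ap = ArraySimParams(**{"seed": derive_seed(seed, "pools-array"), **config.array_params})
    qp = QpcrSimParams(**{"seed": derive_seed(seed, "pools-qpcr"), **config.qpcr_params})

    array_res, qpcr_res = _characterise(config, pools, ap, qp, out)
    de_summary = _panels(config, pair, seed, out)

    lod_called = _joint_lod(array_res, qpcr_res)
    qc_summary = {
        "design_valid": vr.ok,
        "pool_totals": vr.sample_totals,
        "array": {
            "lod_raw": array_res.lod,
            "lod_level": array_res.lod_level(),
            "detection": array_res.detection.to_dict("records"),
            "linear_fits": {
                s: dataclasses.asdict(f) for s, f in array_res.linear_fits.items()
            },
        },
        "qpcr": {
            "lod_level": qpcr_res.lod_level(),
            "positive_fractions": qpcr_res.positives.to_dict("records"),
            "linear_fits": {
                s: dataclasses.asdict(f) for s, f in qpcr_res.linear_fits.items()
            },
        },
        "joint_lod_level": lod_called,
    }
    _dump(qc_summary, out / "qc_summary.json")
    _dump(de_summary, out / "de_summary.json")

    param_blob = json.dumps(
        {"array": dataclasses.asdict(ap), "qpcr": dataclasses.asdict(qp)},
        sort_keys=True,
        default=_json_default,
    )
    from . import __version__

    manifest = {
        "package": "spikeqc",
        "version": __version__,
        "seed": seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("array_params", "qpcr_params")
        },
        "parameter_hash": hashlib.sha256(param_blob.encode()).hexdigest(),
        "outputs": sorted(p.name for p in out.iterdir()),
        "joint_lod_level": lod_called,
    }
    _dump(manifest, out / "manifest.json")
    return manifest


@_stage("characterise-platforms")
def _characterise(config, pools, ap, qp, out: Path):
    array_ds = simulate_microarray(pools, ap, n_runs=config.n_runs)
    qpcr_ds = simulate_qpcr(pools, qp, n_runs=config.n_runs)
    sqio.write_intensity_table(array_ds.intensities, out / "pools_intensities.tsv")
    sqio.write_ct_table(qpcr_ds.cts, out / "pools_cts.tsv")

    array_res = MicroarrayQC(
        array_ds.intensities,
        pools,
        pseudocount=config.pseudocount,
        linear_range=config.linear_range,
        detection_threshold=config.detection_threshold,
    ).fit()
    eff = qp.efficiencies_for(pools.standard_ids)
    qpcr_res = QpcrQC(
        qpcr_ds.cts,
        pools,
        efficiency=eff,
        reference_level=config.reference_level,
        detection_threshold=config.detection_threshold,
    ).fit()
    array_res.precision.to_csv(out / "array_precision.tsv", sep="\t", index=False)
    qpcr_res.precision.to_csv(out / "qpcr_precision.tsv", sep="\t", index=False)
    (out / "array_qc.txt").write_text(array_res.summary() + "\n")
    (out / "qpcr_qc.txt").write_text(qpcr_res.summary() + "\n")
    return array_res, qpcr_res


@_stage("condition-panels")
def _panels(config, pair, seed: int, out: Path) -> dict:
    ap = ArraySimParams(**{"seed": derive_seed(seed, "panels-array"), **config.array_params})
    qp = QpcrSimParams(**{"seed": derive_seed(seed, "panels-qpcr"), **config.qpcr_params})
    arr = simulate_panel_pair_microarray(
        pair, ap, n_runs=config.n_runs, arrays_per_panel_per_run=config.arrays_per_panel_per_run
    )
    qpc = simulate_panel_pair_qpcr(pair, qp, n_runs=config.n_runs)
    sqio.write_intensity_table(arr.intensities, out / "panels_intensities.tsv")
    sqio.write_ct_table(qpc.cts, out / "panels_cts.tsv")

    normalized = normalize_75th(arr.intensities, config.pseudocount)
    spike_ids = [s.id for s in pair.design_A.standards]
    probes = normalized[normalized["standard_id"].isin(spike_ids)]
    norm_A = probes[probes["sample"] == "A"]
    norm_B = probes[probes["sample"] == "B"]
    comp = PanelComparison(
        norm_A,
        norm_B,
        pair.expected_fc,
        fc_cutoffs=config.fc_cutoffs,
        p_cutoff=config.p_cutoff,
        tolerance=config.fc_tolerance,
    ).fit()
    comp.fold_changes.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    (out / "diffexp.txt").write_text(comp.summary() + "\n")

    eff = qp.efficiencies_for([s.id for s in pair.design_A.standards])
    qfc = panel_fold_changes(qpc.cts, eff)
    qfc_mean = (2.0 ** qfc.groupby("assay_id")["log2_fc"].mean()).to_dict()
    slope, pearson_r = platform_concordance(comp.per_standard_fc(), qfc_mean)

    mat = probes.pivot(index="array_id", columns="feature_id", values="log2_norm")
    cond = pca(mat, mode="conditions", n_components=config.n_components)
    ent = pca(mat, mode="entities", n_components=config.n_components)
    labels = [a.split("-")[0] for a in mat.index]
    sil = group_separation(cond.scores, labels)
    cond.scores.to_csv(out / "pca_conditions_scores.tsv", sep="\t")
    ent.scores.to_csv(out / "pca_entities_scores.tsv", sep="\t")

    return {
        "accuracy": comp.accuracy.to_dict("records"),
        "observed_fc": comp.per_standard_fc().to_dict(),
        "qpcr_fc": qfc_mean,
        "concordance": {"slope": slope, "pearson_r": pearson_r},
        "confusion": {
            f"{c:g}": dataclasses.asdict(m) for c, m in comp.confusions.items()
        },
        "pca": {
            "conditions_variance_fraction": cond.variance_fraction[: config.n_components],
            "entities_variance_fraction": ent.variance_fraction[: config.n_components],
            "panel_silhouette_pc12": sil,
        },
    }


def _joint_lod(array_res, qpcr_res) -> float:
    """Lowest nonzero level detected (threshold rule) on both platforms."""
    det = array_res.detection.set_index("level")["fraction_above_lod"]
    pos = qpcr_res.positives.set_index("level")["positive_fraction"]
    thr_a = array_res.model.detection_threshold
    thr_q = qpcr_res.model.detection_threshold
    levels = sorted(set(det.index) & set(pos.index))
    for lv in levels:
        if lv > 0 and det[lv] >= thr_a and pos[lv] >= thr_q:
            return float(lv)
    return float("inf")
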