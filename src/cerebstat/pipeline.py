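"""End-to-end orchestration: simulate or load, then run every stage.

A run is described by a :class:`RunConfig` (parsed from YAML or JSON); all
randomness is routed through the single run seed, every output TSV carries
a provenance header, and the log records how many cells and genes survive
each filter, so a rerun with the same config and seed reproduces the result
files byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import composition as comp
from . import continuity as cont
from . import io as cio
from . import spatial as spat
from .core import CellAnnotation, ValidationError, normalize_counts
from .power import PowerParams, detection_probability
from .simulate import AtlasSimConfig, ClusterSpec, simulate_atlas

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, stage parameters and the run seed."""

    outdir: str
    seed: int = 0
    # either explicit inputs ...
    matrix: str | None = None
    genes: str | None = None
    cells: str | None = None
    annotations: str | None = None
    # ... or a built-in demo simulation
    simulate: dict | None = None
    # stage parameters
    alpha: float = 0.01
    q_max: float = 0.001
    min_le: float = 2.0
    min_r: float = 0.85
    n_top: int = 200
    max_cells: int = 5000
    downsample: dict | None = None  # {"outer_type": ..., "n_target": ...}
    continuity_pair: tuple | None = None  # (cluster_a, cluster_b)
    power: dict = field(default_factory=lambda: {"n": 611034, "p": 0.0015,
                                                 "k": 70, "m_types": 10})
    normalize_scale: float = 1e4

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
        cfg = cls(**raw)
        for key in ("matrix", "genes", "cells", "annotations"):
            val = getattr(cfg, key)
            if val is not None and not os.path.exists(val):
                raise ValidationError(f"config path for {key!r} does not exist: {val}")
        return cfg


def _demo_sim_config(params: dict, seed: int) -> AtlasSimConfig:
    clusters = [ClusterSpec(**c) for c in params.get("clusters", [])]
    if not clusters:
        n_regions = params.get("n_regions", 16)
        uniform = tuple(np.full(n_regions, 1.0 / n_regions))
        enriched = np.full(n_regions, 0.7 / (n_regions - 1))
        enriched[0] = 0.3
        clusters = [
            ClusterSpec("granule_1", "granule", 4000, tuple(enriched)),
            ClusterSpec("granule_2", "granule", 8000, uniform),
            ClusterSpec("mli_1", "MLI", 3000, uniform),
        ]
        params = {**params, "n_regions": n_regions}
    kwargs = {k: v for k, v in params.items() if k != "clusters"}
    return AtlasSimConfig(clusters=clusters, seed=seed, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> composition -> spatial genes -> power [-> continuity].

    Returns a dict of output paths; aborts with the failing stage named.
    """
    os.makedirs(config.outdir, exist_ok=True)
    outputs = {}
    meta = {"seed": config.seed}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    # --- stage: inputs -------------------------------------------------
    try:
        if config.simulate is not None or config.matrix is None:
            sim_cfg = _demo_sim_config(config.simulate or {}, config.seed)
            expr, ann = simulate_atlas(sim_cfg)
            cio.write_expression(expr, out("matrix.mtx"), out("genes.tsv"), out("cells.tsv"))
            cio.write_annotation(ann, out("annotations.tsv"))
            outputs["matrix"] = out("matrix.mtx")
        else:
            expr = cio.read_expression(config.matrix, config.genes, config.cells)
            ann = cio.read_annotation(config.annotations)
            ann.validate_against(expr)
    except Exception as exc:
        raise ValidationError(f"stage 'inputs' failed: {exc}; check paths/config") from exc
    log.info("inputs: %d genes x %d cells, %d annotated", expr.n_genes, expr.n_cells, len(ann))

    # --- stage: composition --------------------------------------------
    try:
        downsample = None
        if config.downsample:
            downsample = (config.downsample["outer_type"], config.downsample["n_target"])
        res, le = comp.analyze_composition(
            ann, downsample=downsample, seed=config.seed,
            q_max=config.q_max, min_max_le=config.min_le, min_r=config.min_r,
        )
        cio.write_result_table(res.reset_index(), out("composition.tsv"), seed=config.seed,
                               params={"q_max": config.q_max, "min_le": config.min_le,
                                       "min_r": config.min_r})
        cio.write_result_table(le.reset_index(names="cluster"), out("lobule_enrichment.tsv"),
                               seed=config.seed)
        outputs["composition"] = out("composition.tsv")
        outputs["lobule_enrichment"] = out("lobule_enrichment.tsv")
    except Exception as exc:
        raise ValidationError(f"stage 'composition' failed: {exc}") from exc

    # --- stage: spatial genes ------------------------------------------
    try:
        norm = normalize_counts(expr, scale=config.normalize_scale)
        logvmr = spat.compute_logvmr(norm, ann.table["lobule"].to_numpy())
        n_defined = int(np.isfinite(logvmr.to_numpy()).sum())
        log.info("spatial: %d/%d genes with defined logVMR", n_defined, len(logvmr))
        spatial_res = spat.select_spatial_genes(logvmr, alpha=config.alpha)
        cio.write_result_table(spatial_res, out("spatial_genes.tsv"), seed=config.seed,
                               params={"alpha": config.alpha})
        outputs["spatial_genes"] = out("spatial_genes.tsv")
    except Exception as exc:
        raise ValidationError(f"stage 'spatial-genes' failed: {exc}") from exc

    # --- stage: power ---------------------------------------------------
    prob = detection_probability(PowerParams(**config.power))
    with open(out("power.json"), "w") as fh:
        json.dump({**config.power, "probability": prob, **meta}, fh, indent=2)
    outputs["power"] = out("power.json")

    # --- stage: continuity (optional pair) ------------------------------
    if config.continuity_pair is not None:
        try:
            a_name, b_name = config.continuity_pair
            mask_a = (ann.table["cluster"] == a_name).to_numpy()
            mask_b = (ann.table["cluster"] == b_name).to_numpy()
            sub_a = normalize_counts(expr.subset_cells(mask_a), config.normalize_scale)
            sub_b = normalize_counts(expr.subset_cells(mask_b), config.normalize_scale)
            results, curve = cont.compare_pair(
                sub_a, sub_b, n_top=config.n_top, max_cells=config.max_cells,
                seed=config.seed,
            )
            cio.write_result_table(results, out("continuity.tsv"), seed=config.seed,
                                   params={"pair": f"{a_name} vs {b_name}"})
            cio.write_result_table(curve, out("continuity_ecdf.tsv"), seed=config.seed)
            outputs["continuity"] = out("continuity.tsv")
        except Exception as exc:
            raise ValidationError(f"stage 'continuity' failed: {exc}") from exc

    return outputs
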