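"""Configuration-driven end-to-end pipeline and exporters.

One config object describes a full run: ingest (or simulate) a session,
normalize it, build the Mapper shape graph, annotate nodes with tasks,
score mesoscale structure (modularity, coreness), project to the temporal
connectivity matrix and detect transitions. Every artifact embeds the seed
and a hash of the resolved configuration, so equal configs give
byte-identical metrics files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import data_model, mapper, mesoscale, nulls, temporal
from .data_model import TaskDesign, VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "export_graph",
    "import_graph",
    "split_half_analysis",
    "perturbation_analysis",
]


class InputConfig(BaseModel):
    image: str
    mask: str
    labels: str
    tr: float | None = None


class SimulateConfig(BaseModel):
    frame_count: int = 1017
    tr: float = 1.5
    cnr: float = 1.0


class PreprocessConfig(BaseModel):
    bandpass: bool = False
    low_hz: float = 0.009
    high_hz: float = 0.08
    normalize: bool = True


class MapperConfig(BaseModel):
    resolution: int = 30
    gain: float = 3.0
    metric: str = "manhattan"
    filter_name: str = "tsne"


class MesoscaleConfig(BaseModel):
    grid_step: float = 0.1
    sa_proposals: int = 10_000
    sa_restarts: int = 3
    weighted: bool = False


class TransitionConfig(BaseModel):
    n_expected: int | None = None     # None: one per task-block boundary
    boundary_kind: str = "evoked"
    penalty: float | None = None


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "shapegraph_out"
    input: InputConfig | None = None
    simulate: SimulateConfig | None = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    mapper: MapperConfig = Field(default_factory=MapperConfig)
    mesoscale: MesoscaleConfig = Field(default_factory=MesoscaleConfig)
    transitions: TransitionConfig = Field(default_factory=TransitionConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (out_dir excluded)."""
        doc = self.model_dump()
        doc.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    vs: VolumeSeries
    design: TaskDesign
    graph: mapper.ShapeGraph
    annotation: mesoscale.TaskAnnotation
    q: mesoscale.ModularityResult | None
    coreness: mesoscale.CorenessResult
    tcm: temporal.TCMatrix
    trace: temporal.DegreeTrace
    transitions: temporal.TransitionSet
    lags: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def _acquire(cfg: PipelineConfig) -> tuple[VolumeSeries, TaskDesign]:
    if cfg.input is not None:
        for attr in ("image", "mask", "labels"):
            p = Path(getattr(cfg.input, attr))
            if not p.exists():
                raise FileNotFoundError(f"config input.{attr}: {p} does not exist")
        vs = data_model.load_volume_series(cfg.input.image, cfg.input.mask,
                                           tr=cfg.input.tr)
        design = TaskDesign.from_csv(cfg.input.labels)
        if design.frame_count != vs.frame_count:
            raise ValueError("label file and image disagree on frame count")
        return vs, design
    sim = cfg.simulate or SimulateConfig()
    spec = nulls.EvokedSpec(cnr=sim.cnr)
    return nulls.simulate_cmp_session(tr=sim.tr, seed=cfg.seed,
                                      frame_count=sim.frame_count, spec=spec)


def _metrics_for(vs, design, sg, ann, q, cs, trace, transitions, lags) -> dict:
    by_task = mesoscale.coreness_by_task(cs, ann)
    dtcm: dict[str, float] = {}
    for task in design.task_set + [data_model.INSTRUCTION_LABEL]:
        sel = design.labels[:vs.frame_count] == task
        if sel.any():
            dtcm[task] = float(trace.values[sel].mean())
    return {
        "n_frames": vs.frame_count,
        "n_voxels": vs.voxel_count,
        "n_nodes": sg.node_count,
        "n_edges": len(sg.edges),
        "q_mod": None if q is None else q.q_mod,
        "q_unnormalized": None if q is None else q.unnormalized,
        "coreness_by_task": by_task.to_dict(orient="records"),
        "d_tcm_by_task": dtcm,
        "change_points": [int(c) for c in transitions.change_points],
        "mean_abs_lag_s": lags.attrs.get("mean_abs_lag_s"),
        "max_abs_lag_s": lags.attrs.get("max_abs_lag_s"),
        "n_missed_boundaries": lags.attrs.get("n_missed"),
    }


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 write: bool = True) -> PipelineResult:
    """Execute the full pipeline described by ``cfg``.

    Stages: acquire -> (band-pass) -> normalize -> Mapper -> annotate ->
    Q_mod + coreness -> TCM -> degree trace -> change points -> lags.
    Artifacts (graph JSON/GraphML, node table, metrics JSON, TCM, traces)
    are written under ``out_dir`` unless ``write=False``.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    vs, design = _acquire(cfg)
    logger.info("stage acquire: %d frames x %d voxels", vs.frame_count,
                vs.voxel_count)
    if cfg.preprocess.bandpass:
        vs = data_model.temporal_bandpass(vs, cfg.preprocess.low_hz,
                                          cfg.preprocess.high_hz)
        logger.info("stage bandpass: %g-%g Hz", cfg.preprocess.low_hz,
                    cfg.preprocess.high_hz)
    if cfg.preprocess.normalize:
        vs = data_model.normalize_frames(vs)
        logger.info("stage normalize: %d frames x %d voxels", vs.frame_count,
                    vs.voxel_count)

    params = mapper.MapperParams(resolution=cfg.mapper.resolution,
                                 gain=cfg.mapper.gain,
                                 metric=cfg.mapper.metric,
                                 filter_name=cfg.mapper.filter_name,
                                 seed=cfg.seed)
    sg = mapper.build_mapper_graph(vs, params)
    logger.info("stage mapper: %d nodes, %d edges", sg.node_count, len(sg.edges))

    ann = mesoscale.annotate_nodes(sg, design)
    q = None
    if len(sg.edges) > 0:
        q = mesoscale.modularity(sg, ann, weighted=cfg.mesoscale.weighted)
    sa = mesoscale.SASettings(proposals=cfg.mesoscale.sa_proposals,
                              restarts=cfg.mesoscale.sa_restarts)
    cs = mesoscale.coreness_scores(sg, grid_step=cfg.mesoscale.grid_step,
                                   sa=sa, seed=cfg.seed,
                                   weighted=cfg.mesoscale.weighted)
    logger.info("stage mesoscale: q_mod=%s", None if q is None else q.q_mod)

    tcm = temporal.build_tcm(sg, frame_count=vs.frame_count, tr=vs.tr)
    trace = temporal.degree_trace(tcm)
    n_expected = cfg.transitions.n_expected
    if n_expected is None:
        n_expected = int(design.boundaries(cfg.transitions.boundary_kind).size)
    ts = temporal.detect_transitions(trace, n_expected=n_expected or None,
                                    penalty=cfg.transitions.penalty)
    lags = temporal.transition_lags(ts, design, vs.tr,
                                    kind=cfg.transitions.boundary_kind)
    logger.info("stage temporal: %d change points", ts.change_points.size)

    metrics = {
        "schema_version": 1,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        **_metrics_for(vs, design, sg, ann, q, cs, trace, ts, lags),
    }
    result = PipelineResult(config=cfg, vs=vs, design=design, graph=sg,
                            annotation=ann, q=q, coreness=cs, tcm=tcm,
                            trace=trace, transitions=ts, lags=lags,
                            metrics=metrics)
    if write:
        _write_bundle(result, out)
    return result


def _write_bundle(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    export_graph(res.graph, res.annotation, res.coreness, out / "shape_graph")
    node_table(res.graph, res.annotation, res.coreness).to_csv(
        out / "node_table.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(res.metrics, fh, indent=1, sort_keys=True)
        fh.write("\n")
    np.savez_compressed(out / "tcm.npz",
                        tcm=res.tcm.matrix.astype(np.uint8), tr=res.tcm.tr)
    pd.DataFrame({"frame": np.arange(res.trace.values.size),
                  "d_tcm": res.trace.values}).to_csv(
        out / "degree_trace.csv", index=False)
    lag_df = res.lags.copy()
    lag_df.insert(1, "time_s", lag_df["boundary_frame"] * res.tcm.tr)
    lag_df.to_csv(out / "transitions.csv", index=False)
    res.design.to_csv(out / "task_design.csv")
    logger.info("wrote bundle to %s", out)


def node_table(sg, ann, cs) -> pd.DataFrame:
    rows = []
    for k in range(sg.node_count):
        rows.append({
            "node_id": k,
            "size": int(len(sg.nodes[k])),
            "majority_label": ann.majority[k],
            "tie": bool(ann.ties[k]),
            "proportions": json.dumps(ann.proportions[k], sort_keys=True),
            "cs": float(cs.cs[k]),
        })
    return pd.DataFrame(rows)


def export_graph(sg, ann, cs, base_path) -> tuple[Path, Path]:
    """Write annotated shape graph as GraphML and JSON (.graphml / .json).

    Nodes carry size, frame list, majority label, label proportions and
    coreness; ordering is deterministic. The JSON round-trips through
    :func:`import_graph`.
    """
    base = Path(base_path)
    if ann is not None and ann.node_count != sg.node_count:
        raise ValueError("annotation and graph node sets disagree")
    if cs is not None and len(cs.cs) != sg.node_count:
        raise ValueError("coreness and graph node sets disagree")
    g = sg.to_networkx()
    doc = json.loads(sg.to_json())
    doc["annotations"] = None
    doc["coreness"] = None
    if ann is None:
        import warnings
        warnings.warn("exporting graph without annotations")
    else:
        doc["annotations"] = {
            "majority": list(ann.majority),
            "proportions": ann.proportions,
            "ties": [bool(t) for t in ann.ties],
            "label_order": ann.label_order,
        }
        for k in range(sg.node_count):
            g.nodes[k]["majority_label"] = ann.majority[k]
            g.nodes[k]["proportions"] = json.dumps(ann.proportions[k],
                                                   sort_keys=True)
    if cs is not None:
        doc["coreness"] = [float(x) for x in cs.cs]
        for k in range(sg.node_count):
            g.nodes[k]["cs"] = float(cs.cs[k])
    json_path = base.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    graphml_path = base.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return graphml_path, json_path


def import_graph(json_path):
    """Re-load an exported shape-graph JSON document."""
    with open(json_path) as fh:
        text = fh.read()
    return mapper.ShapeGraph.from_json(text)


def split_half_analysis(vs: VolumeSeries, design: TaskDesign,
                        cfg: PipelineConfig) -> dict:
    """Run Mapper + mesoscale metrics independently on each half session.

    The first half receives the extra frame when the count is odd. Returns
    per-half metrics plus whether the rest-lowest coreness ordering agrees
    between halves (the reliability criterion).
    """
    import warnings
    cut = (vs.frame_count + 1) // 2
    halves = [(VolumeSeries(data=vs.data[:cut], tr=vs.tr, mask=vs.mask,
                            affine=vs.affine), design.split_half()[0]),
              (VolumeSeries(data=vs.data[cut:], tr=vs.tr, mask=vs.mask,
                            affine=vs.affine), design.split_half()[1])]
    reports = []
    for idx, (half_vs, half_design) in enumerate(halves):
        present = {l for l in half_design.labels if l in half_design.task_set}
        if len(present) < 2:
            warnings.warn(f"half {idx}: fewer than 2 task types present")
        if cfg.preprocess.normalize:
            half_vs = data_model.normalize_frames(half_vs)
        params = mapper.MapperParams(resolution=cfg.mapper.resolution,
                                     gain=cfg.mapper.gain,
                                     metric=cfg.mapper.metric,
                                     filter_name=cfg.mapper.filter_name,
                                     seed=cfg.seed)
        sg = mapper.build_mapper_graph(half_vs, params)
        ann = mesoscale.annotate_nodes(sg, half_design)
        q = mesoscale.modularity(sg, ann) if sg.edges else None
        sa = mesoscale.SASettings(proposals=cfg.mesoscale.sa_proposals,
                                  restarts=cfg.mesoscale.sa_restarts)
        cs = mesoscale.coreness_scores(sg, grid_step=cfg.mesoscale.grid_step,
                                       sa=sa, seed=cfg.seed)
        table = mesoscale.coreness_by_task(cs, ann)
        reports.append({"half": idx, "n_nodes": sg.node_count,
                        "n_edges": len(sg.edges),
                        "q_mod": None if q is None else q.q_mod,
                        "coreness_by_task": table})
    rest = design.task_set[0] if design.task_set else None

    def rest_lowest(table: pd.DataFrame) -> bool | None:
        tasks = table[table["task"] != data_model.INSTRUCTION_LABEL]
        if rest not in set(tasks["task"]):
            return None
        rest_cs = float(tasks.loc[tasks["task"] == rest, "mean_cs"].iloc[0])
        others = tasks.loc[tasks["task"] != rest, "mean_cs"]
        return bool((rest_cs < others).all()) if len(others) else None

    flags = [rest_lowest(r["coreness_by_task"]) for r in reports]
    return {"halves": reports, "rest_lowest": flags,
            "ordering_agrees": flags[0] is not None and flags[0] == flags[1]}


def perturbation_analysis(vs: VolumeSeries, design: TaskDesign,
                          resolutions=range(10, 71, 10),
                          gains=np.arange(2.0, 5.01, 0.5),
                          metric: str = "manhattan",
                          filter_name: str = "tsne",
                          seed: int = 0) -> pd.DataFrame:
    """Score the R x G binning grid (default 7 x 7 = 49 configurations)."""
    grid = [mapper.MapperParams(resolution=int(r), gain=float(g),
                                metric=metric, filter_name=filter_name,
                                seed=seed)
            for r in resolutions for g in gains]
    _, rows = mapper.parameter_search(vs, design, grid, return_table=True)
    return pd.DataFrame(rows)
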