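"""End-to-end orchestration: simulate → process → infer → score → compare.

A :class:`RunConfig` bundles the per-stage parameter blocks; a single
global seed deterministically derives one seed per stage (by hashing the
stage name), so any stage can be rerun in isolation and identical configs
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from neuromotif._errors import NeuromotifError, ValidationError
from neuromotif import calcium, funcnet, graphstats, simulate, structure

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger("neuromotif.pipeline")


class PipelineError(NeuromotifError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed by hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    motif_id: str | None = "B5"
    layout_file: str | None = None
    simulation: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)   # baseline, margin_k
    inference: dict = field(default_factory=dict)    # max_lag, n_surrogates, percentile
    metrics: dict = field(default_factory=dict)      # n_null, null_method
    output_dir: str = "neuromotif_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config requires a seed")
        self.seed = int(self.seed)
        if self.motif_id is None and self.layout_file is None:
            raise ValidationError("config needs motif_id or layout_file")
        # validate blocks eagerly against their module types / ranges
        simulate.SimulationConfig(**{**self.simulation, "seed": 0})
        margin_k = self.processing.get("margin_k", 2.0)
        if margin_k < 0:
            raise ValidationError("margin_k must be >= 0")
        baseline = self.processing.get("baseline", "mean")
        if baseline not in ("mean", "percentile"):
            raise ValidationError(f"unknown baseline mode {baseline!r}")
        if self.inference.get("n_surrogates", 20) < 19:
            raise ValidationError("n_surrogates must be >= 19")
        if self.metrics.get("n_null", 20) < 10:
            raise ValidationError("n_null must be >= 10")
        if self.metrics.get("null_method", "degree_preserving_rewire") not in (
                "degree_preserving_rewire", "erdos_renyi"):
            raise ValidationError("unknown null_method")

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        if "seed" not in obj:
            raise ValidationError("config requires a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        if not isinstance(obj, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(obj)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write all standard outputs.

    Writes the neuron table, traces, ΔF/F0 raster, correlation matrix,
    functional network, distance profile, population matrix, graph metrics,
    structure-function agreement and a JSON report echoing the config.
    Returns the report dict.  On a stage failure the partial outputs are
    retained next to a ``FAILED.json`` marker and :class:`PipelineError`
    is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # output_dir is a storage location, not part of the scientific run:
    # identical configs must produce byte-identical files wherever written
    echoed = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    report: dict = {"config": echoed, "stages": {}, "files": {}}
    stage = "init"
    try:
        # --- structure -----------------------------------------------------
        stage = "structure"
        t0 = time.perf_counter()
        if config.layout_file:
            layout = structure.layout_from_json(
                Path(config.layout_file).read_text())
        else:
            layout = structure.get_motif(config.motif_id)
        (out / "layout.json").write_text(structure.layout_to_json(layout))
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "n_populations": layout.n_populations,
            "n_directed_edges": len(layout.directed_edges())}
        logger.info("stage=%s populations=%d", stage, layout.n_populations)

        # --- simulate ------------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        sim_cfg = simulate.SimulationConfig(
            **{**config.simulation, "seed": stage_seed(config.seed, stage)})
        neurons = simulate.layout_neurons(layout, sim_cfg)
        truth = simulate.simulate_spikes(layout, neurons, sim_cfg)
        rec = simulate.render_traces(truth, sim_cfg)
        neurons.to_csv(out / "neurons.csv", index=False)
        calcium.recording_to_csv(rec, out / "traces.csv")
        pd.DataFrame(truth.raster).to_csv(out / "true_raster.csv", index=False)
        _write_json(out / "ground_truth_events.json", truth.events_to_json())
        _write_json(out / "simulation_config.json", sim_cfg.to_dict())
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "n_neurons": len(neurons), "n_frames": truth.n_frames,
            "n_true_spikes": int(truth.raster.sum())}
        logger.info("stage=%s neurons=%d spikes=%d", stage, len(neurons),
                    int(truth.raster.sum()))

        # --- process -------------------------------------------------------
        stage = "process"
        t0 = time.perf_counter()
        dff = calcium.compute_dff(
            rec, baseline=config.processing.get("baseline", "mean"),
            percentile=config.processing.get("baseline_percentile", 10.0))
        raster = calcium.detect_spikes(
            dff, margin_k=config.processing.get("margin_k", 2.0))
        if truth.raster.sum() == 0 or raster.n_spikes == 0:
            raise ValidationError("no activity: nothing to detect")
        pd.DataFrame(raster.raster).to_csv(out / "raster.csv", index=False)
        _write_json(out / "qc.json", {
            "f0": dict(zip(map(str, dff.neuron_ids), dff.f0.tolist())),
            "spike_counts": dict(zip(map(str, raster.neuron_ids),
                                     raster.raster.sum(axis=1).tolist()))})
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "n_detected_spikes": raster.n_spikes}
        logger.info("stage=%s detected=%d", stage, raster.n_spikes)

        # --- infer ---------------------------------------------------------
        stage = "infer"
        t0 = time.perf_counter()
        inf = config.inference
        net = funcnet.build_functional_network(
            dff, max_lag=inf.get("max_lag", 5),
            n_surrogates=inf.get("n_surrogates", 20),
            percentile=inf.get("percentile", 99.0),
            seed=stage_seed(config.seed, stage))
        prof = funcnet.distance_profile(net.correlation, neurons,
                                        n_bins=inf.get("n_bins", 10))
        cutoff = inf.get("population_cutoff", net.threshold)
        popmat = funcnet.population_functional_matrix(net, neurons, cutoff)
        pd.DataFrame(net.correlation).to_csv(out / "correlation.csv",
                                             index=False)
        pd.DataFrame(net.adjacency).to_csv(out / "functional_adjacency.csv",
                                           index=False)
        pd.DataFrame({
            "bin_left_um": prof.bin_edges[:-1],
            "bin_right_um": prof.bin_edges[1:],
            "mean_corr": prof.mean, "sd_corr": prof.sd,
            "n_pairs": prof.count}).to_csv(out / "distance_profile.csv",
                                           index=False)
        pd.DataFrame(popmat.matrix, index=popmat.populations,
                     columns=popmat.populations).to_csv(
            out / "population_matrix.csv")
        _write_json(out / "population_adjacency.json", {
            "populations": popmat.populations,
            "adjacency": popmat.adjacency.tolist(),
            "cutoff": popmat.cutoff})
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "threshold": net.threshold,
            "n_functional_edges": int(net.adjacency.sum() // 2)}
        logger.info("stage=%s threshold=%.3f", stage, net.threshold)

        # --- metrics -------------------------------------------------------
        stage = "metrics"
        t0 = time.perf_counter()
        met = graphstats.small_world_metrics(
            net.adjacency,
            n_null=config.metrics.get("n_null", 20),
            null_method=config.metrics.get("null_method",
                                           "degree_preserving_rewire"),
            seed=stage_seed(config.seed, stage))
        _write_json(out / "graph_metrics.json", met.to_dict())
        pd.DataFrame(sorted(met.degree_histogram.items()),
                     columns=["degree", "n_nodes"]).to_csv(
            out / "degree_histogram.csv", index=False)
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "small_world": met.small_world}
        logger.info("stage=%s small_world=%s", stage, met.small_world)

        # --- compare -------------------------------------------------------
        stage = "compare"
        t0 = time.perf_counter()
        agree = structure.compare_structure_function(
            layout.adjacency, popmat.adjacency)
        _write_json(out / "structure_function.json", {
            "jaccard": agree.jaccard,
            "shared": sorted(sorted(e) for e in agree.shared),
            "functional_only": sorted(sorted(e) for e in agree.functional_only),
            "structural_only": sorted(sorted(e) for e in agree.structural_only),
        })
        report["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "jaccard": agree.jaccard}
        logger.info("stage=%s jaccard=%.3f", stage, agree.jaccard)

        report["small_world"] = met.small_world
        report["jaccard"] = agree.jaccard
    except Exception as exc:  # noqa: BLE001 - translated into PipelineError
        _write_json(out / "FAILED.json", {"stage": stage, "cause": str(exc)})
        raise PipelineError(stage, str(exc)) from exc

    # file checksums make reruns auditable; elapsed times stay out of them
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name in ("report.json",):
            continue
        report["files"][f.name] = _sha256(f)
    checksum_report = {k: v for k, v in report.items()}
    for st in checksum_report["stages"].values():
        st.pop("elapsed_s", None)
    _write_json(out / "report.json", checksum_report)
    return report
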