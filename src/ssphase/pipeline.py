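"""End-to-end orchestration: graph -> counts -> SSF/QC -> clusters ->
orientation -> phase geometry -> haplotype marker export."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import counting, graph as graph_mod
from .clustering import (
    UNCLUSTERED,
    ClusterConfig,
    Clustering,
    batch_by_coverage,
    initial_clustering,
    refine_clusters,
)
from .counting import StrandCountMatrix
from .graph import AssemblyGraph, UnitigFilter, filter_by_length, remove_rdna_tangle
from .orientation import OrientationAssignment, correct_all_clusters, write_orientation_tsv
from .phasing import PhaseConfig, PhasingResult, phase_clusters
from .ssf import QCConfig, SSFMatrix, compute_ssf, discretize_states, qc_filter


@dataclass
class RunConfig:
    """Every tunable of the engine, serializable to one flat YAML mapping."""

    min_unitig_length: int = graph_mod.DEFAULT_MIN_LENGTH
    seed: int = 0
    orientation_low_margin: float = 0.05
    qc: QCConfig = field(default_factory=QCConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)

    def to_flat_dict(self) -> dict:
        out = {
            "min_unitig_length": self.min_unitig_length,
            "seed": self.seed,
            "orientation_low_margin": self.orientation_low_margin,
        }
        for prefix, sub in (("qc", self.qc), ("cluster", self.cluster), ("phase", self.phase)):
            for k, v in asdict(sub).items():
                out[f"{prefix}.{k}"] = v
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "RunConfig":
        cfg = cls()
        groups = {"qc": cfg.qc, "cluster": cfg.cluster, "phase": cfg.phase}
        for key, value in flat.items():
            if "." in key:
                prefix, name = key.split(".", 1)
                sub = groups.get(prefix)
                if sub is None or not hasattr(sub, name):
                    raise KeyError(f"unknown config key {key!r}")
                setattr(sub, name, value)
            else:
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown config key {key!r}")
                setattr(cfg, key, value)
        return cfg

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def read_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    graph: AssemblyGraph
    unitig_filter: UnitigFilter
    qc_report: object
    ssf_all: SSFMatrix
    ssf_phase: SSFMatrix
    clustering: Clustering
    orientation: OrientationAssignment
    phasing: PhasingResult
    summary: dict
    zero_signal_unitigs: list[str]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    graph: AssemblyGraph,
    counts_all: StrandCountMatrix,
    counts_phase: StrandCountMatrix,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    log=print,
) -> PipelineResult:
    """Run the full phasing engine on a graph plus two count channels.

    Stage outputs are written under ``outdir`` (if given) as TSVs plus a
    machine-readable ``summary.json``; partial outputs are preserved when a
    later stage fails.
    """
    config = config or RunConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_flat_dict()}
    t0 = time.time()

    def banner(stage: str) -> None:
        log(f"[ssphase] {stage} (t+{time.time() - t0:.1f}s)")

    # -- graph ---------------------------------------------------------------
    banner("graph: components, rDNA tangle, length filter")
    try:
        graph = remove_rdna_tangle(graph, short_len=config.min_unitig_length)
        ufilter = filter_by_length(graph, config.min_unitig_length)
        if outdir is not None:
            graph_mod.write_unitig_filter_tsv(graph, ufilter, outdir / "unitig_filter.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("graph", exc) from exc
    summary["n_unitigs_input"] = len(graph.lengths)
    summary["n_unitigs_length_filtered"] = len(ufilter.removed)
    summary["removed_bp_fraction"] = ufilter.removed_bp_fraction
    log(
        f"  retained {len(ufilter.retained)} unitigs; removed "
        f"{len(ufilter.removed)} ({100 * ufilter.removed_bp_fraction:.2f}% of bp)"
    )

    # -- counting / QC -------------------------------------------------------
    banner("strand state: SSF + QC")
    try:
        keep = sorted(set(ufilter.retained) & set(counts_all.unitig_ids))
        counts_all = counts_all.subset(unitigs=keep)
        ssf_all0 = compute_ssf(counts_all)
        states = discretize_states(ssf_all0, config.qc)
        qc = qc_filter(states, counts_all, config.qc)
        libs, units = qc.retained_libraries, qc.retained_unitigs
        counts_all = counts_all.subset(unitigs=units, libraries=libs)
        counts_phase = counts_phase.subset(
            unitigs=[u for u in units if u in set(counts_phase.unitig_ids)],
            libraries=libs,
        )
        ssf_all = compute_ssf(counts_all)
        ssf_phase = compute_ssf(counts_phase)
        if outdir is not None:
            qc.library_stats.to_csv(outdir / "library_qc.tsv", sep="\t")
            qc.unitig_stats.to_csv(outdir / "unitig_qc.tsv", sep="\t")
            ssf_all.write_tsv(outdir / "ssf_all_reads.tsv")
            ssf_phase.write_tsv(outdir / "ssf_phase_informative.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("strand_state", exc) from exc
    summary["n_libraries_input"] = len(qc.library_stats)
    summary["n_libraries_retained"] = len(libs)
    summary["n_unitigs_qc_dropped"] = int((qc.unitig_stats["retained"] == 0).sum())
    log(f"  libraries retained: {len(libs)}; unitigs retained: {len(units)}")

    # -- clustering ----------------------------------------------------------
    banner("chromosome clustering")
    try:
        zero_signal = sorted(set(ssf_all.unitig_ids) - set(ssf_all.nonzero_unitigs()))
        clusterable = [u for u in ssf_all.unitig_ids if u not in set(zero_signal)]
        lengths = {u: graph.lengths[u] for u in counts_all.unitig_ids}
        tot = counts_all.total.sum(axis=1)
        coverage = {u: float(t) / lengths[u] for u, t in zip(counts_all.unitig_ids, tot)}
        batches = batch_by_coverage(clusterable, coverage, config.cluster)
        clustering = initial_clustering(ssf_all, batches, graph, config.cluster)
        clustering = refine_clusters(
            clustering, ssf_all, graph, config.cluster, coverage
        )
        for u in zero_signal:
            clustering.label[u] = UNCLUSTERED
        if outdir is not None:
            _write_clusters_tsv(clustering, graph, outdir / "clusters.tsv")
            with open(outdir / "cluster_history.log", "w") as fh:
                for ev in clustering.history:
                    fh.write("\t".join(str(x) for x in ev) + "\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("chromosome_clustering", exc) from exc
    summary["n_clusters"] = clustering.n_clusters()
    summary["n_unclustered"] = sum(
        1 for c in clustering.label.values() if c == UNCLUSTERED
    )
    summary["n_zero_signal_unitigs"] = len(zero_signal)
    log(f"  clusters: {summary['n_clusters']}; unclustered: {summary['n_unclustered']}")

    # -- orientation ---------------------------------------------------------
    banner("orientation correction")
    try:
        orientation = correct_all_clusters(
            ssf_all, clustering.clusters(), low_margin=config.orientation_low_margin
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("orientation_correction", exc) from exc
    summary["n_flipped"] = len(orientation.flipped_ids())

    # -- phasing -------------------------------------------------------------
    banner("haplotype phasing")
    try:
        phasing = phase_clusters(
            clustering,
            orientation,
            ssf_all,
            ssf_phase,
            counts_phase,
            lengths,
            config.phase,
        )
        if outdir is not None:
            write_orientation_tsv(
                phasing.orientation, phasing.clustering.label, outdir / "orientation.tsv"
            )
            phasing.write_markers_tsv(outdir / "marker_counts.tsv")
            phasing.write_geometry_tsv(outdir / "geometry.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("haplotype_phasing", exc) from exc
    summary["n_flipped"] = len(phasing.orientation.flipped_ids())
    summary["n_haploid_clusters"] = len(phasing.haploid_clusters)
    summary["merged_haploid_cluster"] = phasing.merged_haploid_cluster
    summary["calls"] = (
        phasing.markers["call"].value_counts().to_dict() if len(phasing.markers) else {}
    )
    summary["n_unphased_clusters"] = len(phasing.unphased_clusters)
    log(f"  calls: {summary['calls']}")

    summary["wall_time_s"] = round(time.time() - t0, 3)
    if outdir is not None:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)

    return PipelineResult(
        graph=graph,
        unitig_filter=ufilter,
        qc_report=qc,
        ssf_all=ssf_all,
        ssf_phase=ssf_phase,
        clustering=clustering,
        orientation=phasing.orientation,
        phasing=phasing,
        summary=summary,
        zero_signal_unitigs=zero_signal,
    )


def _write_clusters_tsv(clustering: Clustering, graph: AssemblyGraph, path: Path) -> None:
    rows = [
        {
            "unitig": u,
            "cluster": clustering.label[u],
            "component": graph.component_id.get(u, -1),
        }
        for u in sorted(clustering.label)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_counts(
    counts_all_tsv: str | Path, counts_phase_tsv: str | Path
) -> tuple[StrandCountMatrix, StrandCountMatrix]:
    """Read the two pre-computed count tables (the --from-counts input path)."""
    return (
        StrandCountMatrix.read_tsv(counts_all_tsv, channel=counting.ALL_READS),
        StrandCountMatrix.read_tsv(counts_phase_tsv, channel=counting.PHASE_INFORMATIVE),
    )
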