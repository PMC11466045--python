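"""Synthetic Strand-seq count generator with planted ground truth.

Emulates the Strand-seq generative model the engine assumes: each chromosome
homolog independently passes one template strand (Watson or Crick, P = 1/2)
to every library, so a diploid chromosome inherits a matched (WW/CC) or
unmatched (WC/CW) strand state per library at 50/50.  Reads from a homolog
land on that homolog's template strand.  The all-read channel draws reads
from both homologs of a unitig's chromosome (near-identical homologs attract
both); the phase-informative channel draws only from the unitig's own
homolog(s) — an idealization of the single-SMEM uniqueness filter, relaxable
through ``leakage_rate``.  Planted misorientations swap Watson and Crick in
both channels; degenerate background adds symmetric W/C noise; low-quality
libraries get an elevated background rate.

Counts per cell are Poisson around the configured depths, so at desk scale
the generator reproduces the geometric structure (shared v_clust directions,
the chromosome plane, haploid 1-D rays) that the clustering and phasing
stages estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import ALL_READS, PHASE_INFORMATIVE, StrandCountMatrix
from .graph import AssemblyGraph


@dataclass
class SimConfig:
    n_autosomes: int = 22
    include_xy: bool = True
    unitigs_per_haplotype: int = 5
    homozygous_fraction: float = 0.2  # of a diploid chromosome's unitigs
    n_libraries: int = 96
    depth: float = 20.0  # expected phase-channel reads per het unitig-library cell
    allreads_multiplier: float = 2.0
    background_rate: float = 0.05
    misorientation_rate: float = 0.10
    low_quality_fraction: float = 0.0
    low_quality_background: float = 1.0  # background rate used for low-class libraries
    leakage_rate: float = 0.0  # imperfect uniqueness filtering in the phase channel
    min_unitig_length: int = 60_000
    max_unitig_length: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.homozygous_fraction,
            self.background_rate,
            self.misorientation_rate,
            self.low_quality_fraction,
            self.leakage_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_libraries < 1:
            raise ValueError("need at least one library")


@dataclass
class GroundTruth:
    unitigs: pd.DataFrame  # index unitig: chromosome, haplotype, flipped, length
    states: pd.DataFrame  # index (chromosome, library): hA, hB ('W'/'C'; hB NaN for haploid)
    library_classes: dict[str, str]  # library -> 'high' | 'low'

    def chromosome_of(self) -> dict[str, str]:
        return self.unitigs["chromosome"].to_dict()

    def haplotype_of(self) -> dict[str, str]:
        return self.unitigs["haplotype"].to_dict()


@dataclass
class SimResult:
    counts_all: StrandCountMatrix
    counts_phase: StrandCountMatrix
    truth: GroundTruth
    graph: AssemblyGraph
    config: SimConfig


def _chromosomes(cfg: SimConfig) -> list[tuple[str, bool]]:
    """(name, is_haploid) pairs."""
    chroms = [(f"chr{i:02d}", False) for i in range(1, cfg.n_autosomes + 1)]
    if cfg.include_xy:
        chroms += [("chrX", True), ("chrY", True)]
    return chroms


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Draw one synthetic dataset: two count channels, truth, and a GFA graph."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    libraries = [f"lib{j:03d}" for j in range(cfg.n_libraries)]
    n_low = int(round(cfg.low_quality_fraction * cfg.n_libraries))
    # low-class libraries drawn once, deterministically under the seed
    low_set = set(rng.choice(cfg.n_libraries, size=n_low, replace=False).tolist())
    lib_class = {
        lib: ("low" if j in low_set else "high") for j, lib in enumerate(libraries)
    }
    bg_rate = np.array(
        [
            cfg.low_quality_background if lib_class[lib] == "low" else cfg.background_rate
            for lib in libraries
        ]
    )

    chroms = _chromosomes(cfg)
    unitig_rows: list[dict] = []
    chains: dict[str, list[str]] = {}
    n_haploid_seen = 0
    for chrom, haploid in chroms:
        if haploid:
            # haploid chromosomes carry one homolog each; alternating labels
            # reflect that X and Y end up on different haplotypes
            hap_label = "A" if n_haploid_seen % 2 == 0 else "B"
            n_haploid_seen += 1
            plan = [(hap_label, i) for i in range(cfg.unitigs_per_haplotype)]
        else:
            n_hom = int(round(cfg.homozygous_fraction * 2 * cfg.unitigs_per_haplotype))
            plan = (
                [("A", i) for i in range(cfg.unitigs_per_haplotype)]
                + [("H", i) for i in range(n_hom)]
                + [("B", i) for i in range(cfg.unitigs_per_haplotype)]
            )
        chain = []
        for hap, i in plan:
            uid = f"{chrom}_{hap}{i:02d}"
            length = int(rng.integers(cfg.min_unitig_length, cfg.max_unitig_length + 1))
            flipped = bool(rng.random() < cfg.misorientation_rate)
            unitig_rows.append(
                {
                    "unitig": uid,
                    "chromosome": chrom,
                    "haplotype": {"A": "A", "B": "B", "H": "HOM"}[hap],
                    "flipped": flipped,
                    "length": length,
                    "haploid": haploid,
                }
            )
            chain.append(uid)
        chains[chrom] = chain

    unitigs_df = pd.DataFrame(unitig_rows).set_index("unitig").sort_index()
    unitig_ids = list(unitigs_df.index)

    # per (chromosome, library) homolog template strands
    state_rows = []
    hA: dict[str, np.ndarray] = {}
    hB: dict[str, np.ndarray] = {}
    for chrom, haploid in chroms:
        a = rng.integers(0, 2, size=cfg.n_libraries)  # 1 = Watson template
        b = np.full(cfg.n_libraries, -1) if haploid else rng.integers(0, 2, size=cfg.n_libraries)
        hA[chrom], hB[chrom] = a, b
        for j, lib in enumerate(libraries):
            state_rows.append(
                {
                    "chromosome": chrom,
                    "library": lib,
                    "hA": "W" if a[j] else "C",
                    "hB": (None if haploid else ("W" if b[j] else "C")),
                }
            )
    states_df = pd.DataFrame(state_rows).set_index(["chromosome", "library"])

    n_u, n_l = len(unitig_ids), cfg.n_libraries
    w_all = np.zeros((n_u, n_l), dtype=np.int64)
    c_all = np.zeros_like(w_all)
    w_ph = np.zeros_like(w_all)
    c_ph = np.zeros_like(w_all)

    def add_strand_counts(w, c, strand_is_watson: np.ndarray, n: np.ndarray, row: int):
        w[row] += np.where(strand_is_watson == 1, n, 0)
        c[row] += np.where(strand_is_watson == 1, 0, n)

    for row, uid in enumerate(unitig_ids):
        info = unitigs_df.loc[uid]
        chrom, hap, haploid = info["chromosome"], info["haplotype"], info["haploid"]
        a, b = hA[chrom], hB[chrom]

        # all-read channel: both homologs of the chromosome attract reads
        mean_half = cfg.allreads_multiplier * cfg.depth / 2.0
        add_strand_counts(w_all, c_all, a, rng.poisson(mean_half, n_l), row)
        if not haploid:
            add_strand_counts(w_all, c_all, b, rng.poisson(mean_half, n_l), row)

        # phase channel: only the unitig's own homolog(s)
        if haploid:
            add_strand_counts(w_ph, c_ph, a, rng.poisson(cfg.depth, n_l), row)
        else:
            if hap in ("A", "HOM"):
                add_strand_counts(w_ph, c_ph, a, rng.poisson(cfg.depth, n_l), row)
            if hap in ("B", "HOM"):
                add_strand_counts(w_ph, c_ph, b, rng.poisson(cfg.depth, n_l), row)
        if cfg.leakage_rate > 0 and hap in ("A", "B") and not haploid:
            other = b if hap == "A" else a
            add_strand_counts(
                w_ph, c_ph, other, rng.poisson(cfg.leakage_rate * cfg.depth, n_l), row
            )

        # symmetric degenerate background, per channel
        w_all[row] += rng.poisson(bg_rate * cfg.allreads_multiplier * cfg.depth / 2.0)
        c_all[row] += rng.poisson(bg_rate * cfg.allreads_multiplier * cfg.depth / 2.0)
        w_ph[row] += rng.poisson(bg_rate * cfg.depth / 2.0)
        c_ph[row] += rng.poisson(bg_rate * cfg.depth / 2.0)

        if info["flipped"]:
            w_all[row], c_all[row] = c_all[row].copy(), w_all[row].copy()
            w_ph[row], c_ph[row] = c_ph[row].copy(), w_ph[row].copy()

    counts_all = StrandCountMatrix(
        channel=ALL_READS, watson=w_all, crick=c_all,
        unitig_ids=unitig_ids, library_ids=libraries,
    )
    counts_phase = StrandCountMatrix(
        channel=PHASE_INFORMATIVE, watson=w_ph, crick=c_ph,
        unitig_ids=unitig_ids, library_ids=libraries,
    )

    lengths = unitigs_df["length"].to_dict()
    links = set()
    for chrom, chain in chains.items():
        for u, v in zip(chain, chain[1:]):
            links.add(frozenset((u, v)))
    graph = AssemblyGraph(lengths=lengths, links=links)

    truth = GroundTruth(
        unitigs=unitigs_df.drop(columns=["haploid"]),
        states=states_df,
        library_classes=lib_class,
    )
    return SimResult(
        counts_all=counts_all, counts_phase=counts_phase, truth=truth,
        graph=graph, config=cfg,
    )


def titrate_quality(
    sim: SimResult,
    high_fraction: float,
    n_sets: int,
    set_size: int = 96,
    seed: int = 0,
) -> list[list[str]]:
    """Library subsets mixing quality classes, for titration experiments.

    Each of ``n_sets`` sets has ``round(high_fraction * set_size)`` libraries
    sampled without replacement from the high class and the remainder from
    the low class.  At 0% or 100% there is only one possible set, which is
    returned once regardless of ``n_sets``.
    """
    if not 0 <= high_fraction <= 1:
        raise ValueError("high_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    high = sorted(l for l, c in sim.truth.library_classes.items() if c == "high")
    low = sorted(l for l, c in sim.truth.library_classes.items() if c == "low")
    n_high = int(round(high_fraction * set_size))
    n_low = set_size - n_high
    if n_high > len(high) or n_low > len(low):
        raise ValueError(
            f"cannot sample {n_high} high + {n_low} low libraries from "
            f"{len(high)} high / {len(low)} low"
        )
    if n_high in (0, len(high)) and n_low in (0, len(low)):
        # the sample is forced: there is only one possible set
        return [sorted(high[: n_high] + low[: n_low])]
    sets = []
    for _ in range(n_sets):
        hs = rng.choice(high, size=n_high, replace=False).tolist()
        ls = rng.choice(low, size=n_low, replace=False).tolist()
        sets.append(sorted(hs + ls))
    return sets


# ---------------------------------------------------------------------------
# fixture writers


def write_fixture(sim: SimResult, outdir: str | Path) -> None:
    """Write counts, truth tables, and the GFA for a simulated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.counts_all.write_tsv(outdir / "counts_all.tsv")
    sim.counts_phase.write_tsv(outdir / "counts_phase.tsv")
    sim.truth.unitigs.to_csv(outdir / "truth_unitigs.tsv", sep="\t")
    sim.truth.states.to_csv(outdir / "truth_states.tsv", sep="\t")
    write_gfa(sim.graph, outdir / "sim.gfa")


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in graph.unitigs:
            fh.write(f"S\t{u}\t*\tLN:i:{graph.lengths[u]}\n")
        for link in sorted(graph.links, key=sorted):
            ends = sorted(link)
            a, b = (ends[0], ends[0]) if len(ends) == 1 else (ends[0], ends[1])
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\n")


def write_sam_fixtures(sim: SimResult, outdir: str | Path) -> list[Path]:
    """Emit one minimal SAM file per library reproducing the all-read counts.

    Each count becomes one first-mate, properly paired 50 bp record (reverse
    strand for Watson).  Intended for small configurations only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for u in sim.counts_all.unitig_ids:
        header.append(f"@SQ\tSN:{u}\tLN:{sim.graph.lengths[u]}")
    paths = []
    seq = "A" * 50
    for j, lib in enumerate(sim.counts_all.library_ids):
        path = outdir / f"{lib}.sam"
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            k = 0
            for i, u in enumerate(sim.counts_all.unitig_ids):
                for flag, n in ((83, sim.counts_all.watson[i, j]), (99, sim.counts_all.crick[i, j])):
                    for _ in range(int(n)):
                        fh.write(
                            f"r{j}_{k}\t{flag}\t{u}\t1\t60\t50M\t=\t100\t150\t{seq}\t*\n"
                        )
                        k += 1
        paths.append(path)
    return paths


def write_fastmap_fixtures(sim: SimResult, outdir: str | Path) -> list[Path]:
    """Emit one ``bwa fastmap``-style text file per library reproducing the
    phase-informative counts (one single-SMEM read per count)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, lib in enumerate(sim.counts_phase.library_ids):
        path = outdir / f"{lib}.fastmap"
        with open(path, "w") as fh:
            k = 0
            for i, u in enumerate(sim.counts_phase.unitig_ids):
                for sign, n in (("-", sim.counts_phase.watson[i, j]), ("+", sim.counts_phase.crick[i, j])):
                    for _ in range(int(n)):
                        fh.write(f"SQ\tp{j}_{k}\t50\n")
                        fh.write(f"EM\t0\t50\t1\t{u}:{sign}1\n")
                        fh.write("//\n")
                        k += 1
        paths.append(path)
    return paths
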