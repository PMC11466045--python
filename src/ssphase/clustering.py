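"""Chromosome clustering of unitig SSF vectors by absolute cosine similarity.

Unitigs from the same pair of homologous chromosomes share their strand-state
pattern across Strand-seq libraries, so their SSF vectors point along a common
ideal direction (v_clust).  Cosine similarity on unit-normalized vectors
captures this, and taking its absolute value makes the metric blind to
misoriented unitigs, whose vectors are negated.  Clustering proceeds in
coverage-ranked batches through three operations — growing, creation, and
merging — followed by a two-round refinement that unclusters spurious labels,
absorbs stragglers on single-cluster components, and re-clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import AssemblyGraph
from .ssf import SSFMatrix

UNCLUSTERED = -1


@dataclass
class ClusterConfig:
    # The similarity thresholds are this package's defaults: on ideal
    # geometry same-chromosome similarity -> 1 while cross-chromosome
    # similarity concentrates near sqrt(matched-library overlap) ~ 0.5
    # for independent inheritance, so 0.6 separates them with margin
    # at >= 48 libraries.
    sim_threshold_grow: float = 0.6
    sim_threshold_create: float = 0.6
    sim_threshold_merge: float = 0.6
    batch_size: int = 1000
    min_batches: int = 5
    min_cluster_size: int = 3
    component_frac: float = 0.02  # clusters under 2% of a component's bp are noise

    def __post_init__(self) -> None:
        for t in (
            self.sim_threshold_grow,
            self.sim_threshold_create,
            self.sim_threshold_merge,
        ):
            if not 0 < t < 1:
                raise ValueError("similarity thresholds must be in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class Clustering:
    """Cluster labels per unitig plus an ordered event log."""

    label: dict[str, int]
    history: list[tuple] = field(default_factory=list)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for u in sorted(self.label):
            cid = self.label[u]
            if cid != UNCLUSTERED:
                out.setdefault(cid, []).append(u)
        return out

    def n_clusters(self) -> int:
        return len(self.clusters())


def abs_cos_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """|cos| of the angle between two SSF vectors, in [0, 1].

    Absolute value clusters by parallelism regardless of direction, which is
    what tolerates misoriented unitigs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(min(1.0, abs(np.dot(a, b)) / (na * nb)))


def batch_by_coverage(
    unitigs: list[str], coverage: dict[str, float], cfg: ClusterConfig | None = None
) -> list[list[str]]:
    """Coverage-quantile batches, highest mean coverage first.

    Groups of ``batch_size`` unitigs; if that yields fewer than
    ``min_batches`` groups the unitigs are split into ``min_batches`` equal
    quantiles instead (empty quantiles are skipped).
    """
    cfg = cfg or ClusterConfig()
    ranked = sorted(unitigs, key=lambda u: (-coverage[u], u))
    n = len(ranked)
    n_full = math.ceil(n / cfg.batch_size)
    if n_full >= cfg.min_batches:
        chunks = [ranked[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)]
    else:
        chunks = [list(part) for part in np.array_split(np.asarray(ranked, object), cfg.min_batches)]
    return [c for c in chunks if c]


class _Engine:
    """Shared machinery for initial clustering and re-clustering.

    Works on the unit-normalized SSF rows of the participating unitigs; all
    pairwise absolute cosine similarities are precomputed, and per-cluster
    column sums of that matrix make unitig-cluster and cluster-cluster mean
    similarities O(1) to query.
    """

    def __init__(
        self,
        ids: list[str],
        unit_vectors: np.ndarray,
        components: dict[str, int],
        cfg: ClusterConfig,
    ) -> None:
        self.ids = ids
        self.index = {u: i for i, u in enumerate(ids)}
        self.cfg = cfg
        self.comp = np.asarray([components[u] for u in ids])
        sim = np.abs(unit_vectors @ unit_vectors.T)
        np.clip(sim, 0.0, 1.0, out=sim)
        self.S = sim
        n = len(ids)
        self.label = np.full(n, UNCLUSTERED, dtype=int)
        self.active = np.zeros(n, dtype=bool)  # admitted to the process
        self.members: dict[int, list[int]] = {}
        self.colsum: dict[int, np.ndarray] = {}  # S[:, members].sum(axis=1)
        self.next_id = 0
        self.history: list[tuple] = []

    # -- bookkeeping --------------------------------------------------------

    def seed_cluster(self, cid: int, rows: list[int]) -> None:
        self.members[cid] = list(rows)
        self.colsum[cid] = self.S[:, rows].sum(axis=1)
        self.label[rows] = cid
        self.next_id = max(self.next_id, cid + 1)

    def _assign(self, row: int, cid: int) -> None:
        self.label[row] = cid
        self.members[cid].append(row)
        self.colsum[cid] += self.S[:, row]

    def _new_cluster(self, rows: list[int]) -> int:
        cid = self.next_id
        self.next_id += 1
        self.seed_cluster(cid, rows)
        return cid

    def _merge(self, a: int, b: int) -> int:
        rows = self.members.pop(a) + self.members.pop(b)
        ca, cb = self.colsum.pop(a), self.colsum.pop(b)
        cid = self.next_id
        self.next_id += 1
        self.members[cid] = rows
        self.colsum[cid] = ca + cb
        self.label[rows] = cid
        return cid

    def _unclustered_rows(self) -> np.ndarray:
        return np.flatnonzero(self.active & (self.label == UNCLUSTERED))

    def unitig_cluster_sim(self, row: int, cid: int) -> float:
        return float(self.colsum[cid][row] / len(self.members[cid]))

    def cluster_cluster_sim(self, a: int, b: int) -> float:
        rows_a = self.members[a]
        return float(self.colsum[b][rows_a].sum() / (len(rows_a) * len(self.members[b])))

    # -- the three operations ------------------------------------------------

    def grow_step(self) -> bool:
        rows = self._unclustered_rows()
        cids = sorted(self.members)
        if rows.size == 0 or not cids:
            return False
        # sims[i, j] = mean similarity of unclustered row i to cluster cids[j]
        sims = np.column_stack(
            [self.colsum[c][rows] / len(self.members[c]) for c in cids]
        )
        smax = float(sims.max())
        if smax <= self.cfg.sim_threshold_grow:
            return False
        ii, jj = np.nonzero(sims >= smax - 1e-15)
        uid, cid = min((self.ids[rows[i]], cids[j]) for i, j in zip(ii, jj))
        self._assign(self.index[uid], cid)
        self.history.append(("grow", uid, cid, smax))
        return True

    def create_step(self) -> bool:
        rows = self._unclustered_rows()
        if rows.size < 2:
            return False
        sub = self.S[np.ix_(rows, rows)].copy()
        np.fill_diagonal(sub, -1.0)
        smax = sub.max()
        if smax <= self.cfg.sim_threshold_create:
            return False
        ii, jj = np.nonzero(sub >= smax - 1e-15)
        pairs = sorted(
            tuple(sorted((self.ids[rows[i]], self.ids[rows[j]]))) for i, j in zip(ii, jj)
        )
        u, v = pairs[0]
        cid = self._new_cluster([self.index[u], self.index[v]])
        self.history.append(("create", (u, v), cid, float(smax)))
        return True

    def merge_pass(self, restrict_component: int | None = None) -> bool:
        """Repeatedly merge the best cluster pair above threshold."""
        fired = False
        while True:
            cids = sorted(self.members)
            if restrict_component is not None:
                cids = [
                    c
                    for c in cids
                    if (self.comp[self.members[c]] == restrict_component).any()
                ]
            best = (-1.0, -1, -1)
            for i, a in enumerate(cids):
                for b in cids[i + 1 :]:
                    s = self.cluster_cluster_sim(a, b)
                    if s > best[0] + 1e-15 or (
                        abs(s - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
                    ):
                        best = (s, a, b)
            if best[0] > self.cfg.sim_threshold_merge:
                cid = self._merge(best[1], best[2])
                self.history.append(("merge", (best[1], best[2]), cid, best[0]))
                fired = True
            else:
                return fired

    def merge_phase(self) -> bool:
        fired = False
        for comp in sorted(set(self.comp.tolist())):
            fired |= self.merge_pass(restrict_component=comp)
        fired |= self.merge_pass(restrict_component=None)
        return fired

    # -- the loop ------------------------------------------------------------

    def round(self) -> bool:
        """GROW to exhaustion, CREATE (looping back to GROW), then MERGE."""
        fired = False
        while True:
            while self.grow_step():
                fired = True
            if not self.create_step():
                break
            fired = True
        fired |= self.merge_phase()
        return fired

    def run(self, batches: list[list[str]]) -> None:
        for batch in batches:
            self.active[[self.index[u] for u in batch]] = True
            self.round()
        # all batches admitted: iterate to a fixed point
        while self.round():
            pass


def initial_clustering(
    ssf: SSFMatrix,
    batches: list[list[str]],
    graph: AssemblyGraph,
    cfg: ClusterConfig | None = None,
    existing: Clustering | None = None,
) -> Clustering:
    """Batched agglomerative clustering of the unitigs listed in ``batches``.

    With ``existing`` given, its clusters are kept alive as grow/merge
    targets while the batched unitigs are (re-)admitted — this is the
    re-clustering round used during refinement.
    """
    cfg = cfg or ClusterConfig()
    participating = sorted({u for b in batches for u in b})
    if existing is not None:
        participating = sorted(set(participating) | {
            u for u, c in existing.label.items() if c != UNCLUSTERED
        })
    unit = ssf.subset(unitigs=participating).unit_rows()
    norms = np.linalg.norm(unit, axis=1)
    if (norms == 0).any():
        bad = [u for u, n in zip(participating, norms) if n == 0]
        raise ValueError(f"zero-signal unitigs must be excluded before clustering: {bad[:5]}")
    eng = _Engine(participating, unit, graph.component_id, cfg)
    history: list[tuple] = []
    if existing is not None:
        history = list(existing.history)
        for cid, members in existing.clusters().items():
            rows = [eng.index[u] for u in members]
            eng.seed_cluster(cid, rows)
            eng.active[rows] = True  # existing members stay in play
    eng.run(batches)
    label = {u: int(c) for u, c in zip(eng.ids, eng.label)}
    return Clustering(label=label, history=history + eng.history)


def refine_clusters(
    clustering: Clustering,
    ssf: SSFMatrix,
    graph: AssemblyGraph,
    cfg: ClusterConfig | None = None,
    coverage: dict[str, float] | None = None,
) -> Clustering:
    """Two-round refinement: uncluster noise, absorb, re-cluster, repeat.

    Per round: (1) clusters below the minimum size are dissolved; (2) on each
    connected component, labels of clusters covering less than
    ``component_frac`` of the component's bp are dropped; (3) components
    carrying exactly one cluster absorb their unclustered unitigs.  Between
    the two rounds the unclustered unitigs are re-clustered with the batched
    machinery, with the surviving clusters as targets.
    """
    cfg = cfg or ClusterConfig()
    label = dict(clustering.label)
    history = list(clustering.history)
    _refine_round(label, graph, cfg, history)
    unclustered = sorted(u for u, c in label.items() if c == UNCLUSTERED)
    if unclustered:
        cov = coverage or {u: 1.0 for u in unclustered}
        batches = batch_by_coverage(unclustered, {u: cov.get(u, 0.0) for u in unclustered}, cfg)
        reclustered = initial_clustering(
            ssf, batches, graph, cfg, existing=Clustering(label=label, history=history)
        )
        label = dict(reclustered.label)
        history = list(reclustered.history)
    _refine_round(label, graph, cfg, history)
    return Clustering(label=label, history=history)


def _refine_round(
    label: dict[str, int], graph: AssemblyGraph, cfg: ClusterConfig, history: list[tuple]
) -> None:
    # (1) dissolve clusters smaller than the minimum size
    sizes: dict[int, int] = {}
    for c in label.values():
        if c != UNCLUSTERED:
            sizes[c] = sizes.get(c, 0) + 1
    for u in sorted(label):
        c = label[u]
        if c != UNCLUSTERED and sizes[c] < cfg.min_cluster_size:
            label[u] = UNCLUSTERED
            history.append(("uncluster_small", u, c, sizes[c]))

    # (2) per component, drop labels of clusters under the bp fraction floor
    comp_bp: dict[int, int] = {}
    comp_cluster_bp: dict[tuple[int, int], int] = {}
    for u in label:
        comp = graph.component_id[u]
        comp_bp[comp] = comp_bp.get(comp, 0) + graph.lengths[u]
        c = label[u]
        if c != UNCLUSTERED:
            key = (comp, c)
            comp_cluster_bp[key] = comp_cluster_bp.get(key, 0) + graph.lengths[u]
    for u in sorted(label):
        c = label[u]
        if c == UNCLUSTERED:
            continue
        comp = graph.component_id[u]
        frac = comp_cluster_bp[(comp, c)] / comp_bp[comp]
        if frac < cfg.component_frac:
            label[u] = UNCLUSTERED
            history.append(("uncluster_component_frac", u, c, frac))

    # (3) single-cluster components absorb their unclustered unitigs
    comp_clusters: dict[int, set[int]] = {}
    for u, c in label.items():
        if c != UNCLUSTERED:
            comp_clusters.setdefault(graph.component_id[u], set()).add(c)
    for u in sorted(label):
        if label[u] == UNCLUSTERED:
            clusters_here = comp_clusters.get(graph.component_id[u], set())
            if len(clusters_here) == 1:
                (c,) = clusters_here
                label[u] = c
                history.append(("absorb_single_cluster_component", u, c, None))
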