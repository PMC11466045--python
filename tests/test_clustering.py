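import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ssphase as sp
from conftest import make_ssf
from ssphase.clustering import (
    UNCLUSTERED,
    ClusterConfig,
    Clustering,
    abs_cos_similarity,
    batch_by_coverage,
    initial_clustering,
    refine_clusters,
)
from ssphase.graph import AssemblyGraph


class TestAbsCosSimilarity:
    def test_identity_orthogonality_negation(self):
        a = np.array([1.0, -1.0, 0.0, 1.0])
        b = np.array([0.0, 0.0, 1.0, 0.0])
        assert abs_cos_similarity(a, a) == pytest.approx(1.0)
        assert abs_cos_similarity(a, b) == pytest.approx(0.0)
        assert abs_cos_similarity(a, -a) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            abs_cos_similarity(np.zeros(3), np.ones(3))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(np.float64, 6, elements=st.floats(-1, 1)),
        arrays(np.float64, 6, elements=st.floats(-1, 1)),
        st.floats(-4, 4).filter(lambda x: abs(x) > 1e-3),
    )
    def test_symmetric_scale_invariant_bounded(self, a, b, alpha):
        if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
            return
        s = abs_cos_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(abs_cos_similarity(b, a))
        assert s == pytest.approx(abs_cos_similarity(alpha * a, b), abs=1e-9)


class TestBatching:
    def test_large_input_batches_by_size(self):
        ids = [f"u{i:05d}" for i in range(12000)]
        cov = {u: float(i) for i, u in enumerate(ids)}
        batches = batch_by_coverage(ids, cov, ClusterConfig())
        assert len(batches) == 12 and all(len(b) == 1000 for b in batches)
        # descending mean coverage
        means = [np.mean([cov[u] for u in b]) for b in batches]
        assert means == sorted(means, reverse=True)

    def test_small_input_splits_into_five_quantiles(self):
        ids = [f"u{i}" for i in range(3000)]
        cov = {u: float(i) for i, u in enumerate(ids)}
        batches = batch_by_coverage(ids, cov, ClusterConfig())
        assert len(batches) == 5 and all(len(b) == 600 for b in batches)

    def test_degenerate_tiny_input_skips_empty_quantiles(self):
        ids = ["a", "b", "c", "d"]
        cov = dict.fromkeys(ids, 1.0)
        batches = batch_by_coverage(ids, cov, ClusterConfig())
        assert sum(len(b) for b in batches) == 4
        assert all(b for b in batches)


def planted_toy():
    """Noiseless 3-chromosome toy: 9 unitigs, 8 libraries, orthogonal patterns."""
    patterns = {
        "chrA": np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float),
        "chrB": np.array([0, 0, 0, 0, 1, 1, -1, -1], dtype=float),
        "chrC": np.array([1, -1, 1, -1, 0, 0, 0, 0], dtype=float),
    }
    rows, truth = [], []
    for chrom, pat in patterns.items():
        for k in range(3):
            rows.append(pat * (1 if k % 2 == 0 else -1))  # mix orientations
            truth.append(chrom)
    return np.array(rows), truth


def test_initial_clustering_recovers_planted_toy():
    """Brute-force check first: within-chromosome |cos| is 1 and
    cross-chromosome |cos| is below threshold, so the planted partition is
    the unique outcome."""
    values, truth = planted_toy()
    unit = values / np.linalg.norm(values, axis=1, keepdims=True)
    for i, j in itertools.combinations(range(len(values)), 2):
        s = abs(unit[i] @ unit[j])
        if truth[i] == truth[j]:
            assert s == pytest.approx(1.0)
        else:
            assert s < 0.6

    ssf = make_ssf(values)
    graph = AssemblyGraph(lengths={u: 100_000 for u in ssf.unitig_ids})
    batches = batch_by_coverage(ssf.unitig_ids, dict.fromkeys(ssf.unitig_ids, 1.0))
    clustering = initial_clustering(ssf, batches, graph)
    labels = [clustering.label[u] for u in ssf.unitig_ids]
    assert len(set(labels)) == 3
    for i, j in itertools.combinations(range(len(truth)), 2):
        assert (labels[i] == labels[j]) == (truth[i] == truth[j])


def test_single_unitig_stays_unclustered():
    ssf = make_ssf([[1.0, 0.0, -1.0]])
    graph = AssemblyGraph(lengths={"u00": 100_000})
    clustering = initial_clustering(ssf, [["u00"]], graph)
    assert clustering.label["u00"] == UNCLUSTERED


def test_identical_pair_forms_cluster_by_creation():
    ssf = make_ssf([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0]])
    graph = AssemblyGraph(lengths={"u00": 1, "u01": 1})
    clustering = initial_clustering(ssf, [["u00", "u01"]], graph)
    assert clustering.label["u00"] == clustering.label["u01"] != UNCLUSTERED
    assert any(ev[0] == "create" for ev in clustering.history)


def test_zero_signal_unitigs_rejected():
    ssf = make_ssf([[0.0, 0.0], [1.0, 0.0]])
    graph = AssemblyGraph(lengths={"u00": 1, "u01": 1})
    with pytest.raises(ValueError, match="zero-signal"):
        initial_clustering(ssf, [["u00", "u01"]], graph)


class TestRefinement:
    def _setup(self, labels, lengths, links=()):
        graph = AssemblyGraph(
            lengths=lengths, links={frozenset(e) for e in links}
        )
        return Clustering(label=dict(labels)), graph

    def test_small_cluster_dissolved(self):
        values = np.vstack([np.tile([1.0, 0.0], (3, 1)), [[0.0, 1.0]]])
        ssf = make_ssf(values)
        lengths = {u: 100_000 for u in ssf.unitig_ids}
        clustering, graph = self._setup(
            {"u00": 0, "u01": 0, "u02": 0, "u03": 1}, lengths
        )
        out = refine_clusters(clustering, ssf, graph, ClusterConfig(min_cluster_size=3))
        assert out.label["u03"] == UNCLUSTERED
        assert out.label["u00"] == 0

    def test_component_bp_fraction_rule(self):
        # one component; cluster 1 covers 1% of its bp -> dissolved
        ids = [f"u{i:02d}" for i in range(11)]
        values = np.tile([1.0, 0.0], (11, 1))
        values[-3:] = [0.0, 1.0]
        ssf = make_ssf(values)
        lengths = {u: 10_000_000 for u in ids[:8]}
        lengths.update({u: 270_000 for u in ids[8:]})  # ~1% of the component
        links = [(a, b) for a, b in zip(ids, ids[1:])]
        clustering, graph = self._setup(
            {**{u: 0 for u in ids[:8]}, **{u: 1 for u in ids[8:]}}, lengths, links
        )
        cfg = ClusterConfig(component_frac=0.02, min_cluster_size=3)
        out = refine_clusters(clustering, ssf, graph, cfg)
        assert all(out.label[u] != 1 for u in ids[8:])

    def test_single_cluster_component_absorbs_unclustered(self):
        ids = ["u00", "u01", "u02", "u03", "u04", "u05"]
        values = np.tile([1.0, 0.0], (6, 1))
        ssf = make_ssf(values)
        lengths = {u: 1_000_000 for u in ids}
        links = [(a, b) for a, b in zip(ids, ids[1:])]
        clustering, graph = self._setup(
            {"u00": 0, "u01": 0, "u02": 0, "u03": UNCLUSTERED, "u04": UNCLUSTERED,
             "u05": UNCLUSTERED},
            lengths,
            links,
        )
        out = refine_clusters(clustering, ssf, graph, ClusterConfig())
        assert all(out.label[u] == 0 for u in ids)


class TestRecoveryProperties:
    def _cluster(self, sim, counts_all):
        ssf = sp.compute_ssf(counts_all)
        clusterable = ssf.nonzero_unitigs()
        cov = {
            u: float(t) / sim.graph.lengths[u]
            for u, t in zip(counts_all.unitig_ids, counts_all.total.sum(axis=1))
        }
        batches = batch_by_coverage(clusterable, cov)
        clustering = initial_clustering(ssf.subset(unitigs=sorted(clusterable)), batches, sim.graph)
        return refine_clusters(clustering, ssf, sim.graph, coverage=cov)

    def test_planted_partition_recovery_and_flip_invariance(self, small_sim):
        sim = small_sim
        clustering = self._cluster(sim, sim.counts_all)
        truth = sim.truth.chromosome_of()
        by_label = {}
        for u, c in clustering.label.items():
            by_label.setdefault(c, set()).add(truth[u])
        assert UNCLUSTERED not in by_label
        assert all(len(chroms) == 1 for chroms in by_label.values())
        assert len(by_label) == 5  # 3 autosomes + X + Y

        # negating any subset of unitig vectors leaves the partition unchanged
        rng = np.random.default_rng(0)
        ids = sim.counts_all.unitig_ids
        flip = [u for u in ids if rng.random() < 0.5]
        flipped = self._cluster(sim, sim.counts_all.flip_unitigs(flip))
        for u, v in itertools.combinations(ids, 2):
            assert (clustering.label[u] == clustering.label[v]) == (
                flipped.label[u] == flipped.label[v]
            )

    def test_determinism(self, small_sim):
        c1 = self._cluster(small_sim, small_sim.counts_all)
        c2 = self._cluster(small_sim, small_sim.counts_all)
        assert c1.label == c2.label
        assert c1.history == c2.history
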