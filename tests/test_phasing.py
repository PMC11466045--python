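import numpy as np
import pytest

import ssphase as sp
from ssphase.counting import StrandCountMatrix
from ssphase.phasing import (
    HAP_A,
    HAP_B,
    HOMOZYGOUS,
    UNASSIGNED,
    ClusterPhaseGeometry,
    DegenerateClusterError,
    PhaseConfig,
    call_haplotypes,
    compute_v_clust,
    detect_haploid_clusters,
    discretize_vphase,
    haploid_bisection_correction,
    infer_plane_and_vphase,
    pool_markers,
    rotate_in_plane,
)
from conftest import make_ssf


class TestVClust:
    def test_identical_vectors_any_weights(self):
        v = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        out = compute_v_clust(np.vstack([v, v]), np.array([1.0, 9.0]))
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_length_weighted_mix(self):
        vecs = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = compute_v_clust(vecs, np.array([3.0, 1.0]))
        np.testing.assert_allclose(out, np.array([3.0, 1.0]) / np.sqrt(10), atol=1e-12)

    def test_single_unitig(self):
        v = np.array([0.0, 1.0])
        np.testing.assert_allclose(compute_v_clust(v[None, :], np.array([5.0])), v)

    def test_cancellation_is_an_error(self):
        v = np.array([1.0, 0.0])
        with pytest.raises(DegenerateClusterError):
            compute_v_clust(np.vstack([v, -v]), np.array([2.0, 2.0]))


class TestPlaneAndVphase:
    def test_worked_four_library_example(self, toy_phase_vectors):
        m, p, h, v_clust = toy_phase_vectors
        geom = infer_plane_and_vphase(np.vstack([m, p, h]), v_clust)
        expected = np.array([0.0, 1.0, 0.0, -1.0]) / np.sqrt(2)
        sign = np.sign(geom.v_phase_raw @ expected)
        np.testing.assert_allclose(sign * geom.v_phase_raw, expected, atol=1e-9)
        np.testing.assert_allclose(
            sign * geom.v_phase, np.array([0.0, 1.0, 0.0, -1.0]), atol=1e-9
        )
        # v_phase is parallel to the maternal-paternal difference
        diff = (m - p) / np.linalg.norm(m - p)
        assert abs(geom.v_phase_raw @ diff) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonality_by_construction(self, toy_phase_vectors):
        m, p, h, v_clust = toy_phase_vectors
        geom = infer_plane_and_vphase(np.vstack([m, p, h]), v_clust)
        assert abs(geom.v_clust @ geom.v_phase_raw) < 1e-8

    def test_double_rotation_negates(self):
        basis = np.eye(2)
        v = np.array([1.0, 0.0])
        out = rotate_in_plane(rotate_in_plane(v, basis, np.pi / 2), basis, np.pi / 2)
        np.testing.assert_allclose(out, -v, atol=1e-12)

    def test_one_dimensional_cluster_directed_to_haploid_path(self):
        ray = np.array([1.0, 1.0, 0.0, 0.0]) / np.sqrt(2)
        X = np.vstack([ray, ray, -ray])
        with pytest.raises(DegenerateClusterError, match="haploid"):
            infer_plane_and_vphase(X, ray)


class TestHaploidDetection:
    def test_xy_ray_cluster_flagged_and_merged(self):
        ray_x = np.array([1.0, 1.0, -1.0, 1.0]) / 2
        ray_y = np.array([1.0, -1.0, -1.0, -1.0]) / 2
        values = np.vstack([ray_x, ray_x, -ray_x, ray_y, -ray_y, ray_y])
        ssf = make_ssf(values, channel="phase_informative")
        clusters = {0: ["u00", "u01", "u02"], 1: ["u03", "u04", "u05"]}
        haploid, var = detect_haploid_clusters(ssf, clusters)
        assert haploid == {0, 1}
        assert var[0][0] == pytest.approx(1.0)
        assert var[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_diploid_three_direction_cluster_not_flagged(self, toy_phase_vectors):
        m, p, h, _ = toy_phase_vectors
        ssf = make_ssf(np.vstack([m, p, h]), channel="phase_informative")
        haploid, var = detect_haploid_clusters(ssf, {0: ["u00", "u01", "u02"]})
        assert haploid == set()
        assert var[0][1] > 0.20

    def test_conjunction_of_thresholds(self):
        # two unit vectors at 60 degrees: explained variance (1 +/- cos60)/2,
        # i.e. PC1 = 75% passes the first condition but PC2 = 25% fails the second
        X = np.array([[1.0, 0.0], [0.5, np.sqrt(3.0) / 2]])
        ssf = make_ssf(X, channel="phase_informative")
        haploid, var = detect_haploid_clusters(ssf, {0: ["u00", "u01"]})
        assert var[0] == (pytest.approx(0.75), pytest.approx(0.25))
        assert haploid == set()


class TestBisectionCorrection:
    def _geometry(self):
        return ClusterPhaseGeometry(
            cluster=0,
            v_clust=np.array([1.0, 0.0]),
            plane_basis=np.eye(2),
            v_phase_raw=np.array([0.0, 1.0]),
            v_phase=np.array([0.0, 1.0]),
            pc_variance=(0.9, 0.1),
            is_haploid=True,
        )

    @staticmethod
    def _ray(deg):
        t = np.deg2rad(deg)
        return np.array([np.cos(t), np.sin(t)])

    def test_asymmetric_rays_bisected(self):
        geom = haploid_bisection_correction(
            self._geometry(), np.vstack([self._ray(20), self._ray(-40)])
        )
        angle = np.arctan2(geom.v_clust[1], geom.v_clust[0])
        assert angle == pytest.approx(np.deg2rad(-10), abs=1e-6)
        assert abs(geom.v_clust @ geom.v_phase_raw) < 1e-8

    def test_symmetric_rays_are_fixed_point(self):
        geom = haploid_bisection_correction(
            self._geometry(), np.vstack([self._ray(30), self._ray(-30)])
        )
        np.testing.assert_allclose(geom.v_clust, [1.0, 0.0], atol=1e-12)

    def test_single_ray_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            geom = haploid_bisection_correction(
                self._geometry(), np.vstack([self._ray(25), self._ray(20)])
            )
        np.testing.assert_allclose(geom.v_clust, [1.0, 0.0])


def toy_counts(d=10):
    """Counts for the worked toy: maternal, paternal, homozygous unitig over
    4 libraries (2 and 4 unmatched)."""
    w = np.array(
        [
            [d, d, 0, 0],  # maternal: watson in lib1(matched) and lib2
            [d, 0, 0, d],  # paternal: watson in lib1, lib4
            [d, d // 2, 0, d // 2],  # homozygous: split in unmatched libs
        ]
    )
    c = np.array(
        [
            [0, 0, d, d],
            [0, d, d, 0],
            [0, d // 2, d, d // 2],
        ]
    )
    return StrandCountMatrix(
        channel="phase_informative",
        watson=w,
        crick=c,
        unitig_ids=["mat", "pat", "hom"],
        library_ids=["l1", "l2", "l3", "l4"],
    )


def toy_geometry(v_phase):
    v_phase = np.asarray(v_phase, dtype=float)
    raw = v_phase / np.linalg.norm(v_phase)
    return ClusterPhaseGeometry(
        cluster=0,
        v_clust=np.array([1.0, 0.0, -1.0, 0.0]) / np.sqrt(2),
        plane_basis=np.eye(4)[:2],
        v_phase_raw=raw,
        v_phase=v_phase,
        pc_variance=(0.6, 0.4),
    )


class TestPooling:
    def test_worked_example_counts(self):
        d = 10
        pooled = pool_markers(toy_counts(d), toy_geometry([0, 1, 0, -1]))
        assert pooled.loc["mat", "hapA_markers"] == 2 * d
        assert pooled.loc["mat", "hapB_markers"] == 0
        assert pooled.loc["pat", "hapA_markers"] == 0
        assert pooled.loc["pat", "hapB_markers"] == 2 * d
        assert pooled.loc["hom", "hapA_markers"] == d
        assert pooled.loc["hom", "hapB_markers"] == d

    def test_negating_vphase_swaps_haplotype_labels(self):
        a = pool_markers(toy_counts(), toy_geometry([0, 1, 0, -1]))
        b = pool_markers(toy_counts(), toy_geometry([0, -1, 0, 1]))
        np.testing.assert_array_equal(
            a["hapA_markers"].values, b["hapB_markers"].values
        )
        np.testing.assert_array_equal(
            a["hapB_markers"].values, b["hapA_markers"].values
        )

    def test_marker_conservation(self):
        counts = toy_counts(8)
        geom = toy_geometry([0, 1, 0, -1])
        pooled = pool_markers(counts, geom)
        informative = np.abs(geom.v_phase) > 0
        assert (
            pooled["hapA_markers"].sum() + pooled["hapB_markers"].sum()
            == counts.total[:, informative].sum()
        )


class TestCalling:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (100, 2, HAP_A),
            (2, 100, HAP_B),
            (50, 50, HOMOZYGOUS),
            (2, 1, UNASSIGNED),  # total below the evidence floor
        ],
    )
    def test_thresholds(self, a, b, expected):
        import pandas as pd

        df = pd.DataFrame(
            {"hapA_markers": [a], "hapB_markers": [b]},
            index=pd.Index(["u"], name="node"),
        )
        out = call_haplotypes(df, PhaseConfig(min_markers=10, purity=0.9))
        assert out.loc["u", "call"] == expected


def test_discretize_vphase_relative_threshold():
    raw = np.array([0.9, -0.5, 0.1, 0.44])
    np.testing.assert_array_equal(
        discretize_vphase(raw, frac=0.5), [1.0, -1.0, 0.0, 0.0]
    )


def test_pipeline_marker_conservation_noiseless():
    """On a noiseless run the pooled markers account for every
    phase-informative read in the v_phase != 0 libraries, exactly."""
    sim = sp.simulate(
        sp.SimConfig(
            n_autosomes=3,
            include_xy=False,
            n_libraries=48,
            background_rate=0.0,
            misorientation_rate=0.0,
            seed=9,
        )
    )
    res = sp.run_pipeline(sim.graph, sim.counts_all, sim.counts_phase, log=lambda *a: None)
    counts = res.phasing.markers
    for cid, geom in res.phasing.geometries.items():
        members = sorted(res.phasing.clustering.clusters()[cid])
        sub = sim.counts_phase.subset(
            unitigs=members, libraries=list(res.ssf_phase.library_ids)
        )
        informative = np.abs(geom.v_phase) > 0
        pooled = counts.loc[members]
        assert (
            pooled["hapA_markers"].sum() + pooled["hapB_markers"].sum()
            == sub.total[:, informative].sum()
        )
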