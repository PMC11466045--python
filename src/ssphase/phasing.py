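"""Per-cluster phase geometry, haplotype-informative library pooling, calls.

In the phase-informative channel, a diploid cluster's unitig SSF vectors fall
on three ideal directions — maternal, paternal, and homozygous — all lying in
a 2-D "chromosome plane".  The plane is spanned by ``v_clust`` (the cluster's
shared direction, estimated as the size-weighted average of the
orientation-corrected all-read vectors) and ``v_phase`` (proportional to the
difference of the two haplotype vectors).  Because they are orthogonal,
``v_phase`` is recovered by projecting ``v_clust`` into the plane inferred
from the first two principal directions and rotating it 90 degrees in-plane.

The non-zero components of the discretized ``v_phase`` mark the unmatched
(phase-informative) libraries, and their signs say which strand belongs to
which haplotype: after swapping Watson/Crick counts in the ``-1`` libraries,
Watson totals over informative libraries count one haplotype's markers and
Crick totals the other's.  The haplotype labels themselves are arbitrary
(parent-of-origin is unknown): negating ``v_phase`` swaps them exactly.

Haploid chromosomes (e.g., X and Y in a male sample) have no second haplotype:
their phase-channel vectors stay on a single line, detected by an uncentered
PCA variance rule (PC1 > 70% and PC2 < 20%), merged into one cluster, and given
a bisection correction that undoes the size-weighted average's bias toward the
larger haploid chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import UNCLUSTERED, Clustering
from .counting import StrandCountMatrix
from .orientation import OrientationAssignment, correct_orientation
from .ssf import SSFMatrix

HAP_A, HAP_B, HOMOZYGOUS, UNASSIGNED = "HAP_A", "HAP_B", "HOMOZYGOUS", "UNASSIGNED"


@dataclass
class PhaseConfig:
    pc1_haploid_min: float = 0.70  # PC1 explained-variance floor for haploid flag
    pc2_haploid_max: float = 0.20  # PC2 explained-variance ceiling for haploid flag
    vphase_discretize_frac: float = 0.5  # |comp| >= frac * max|comp| keeps its sign
    min_markers: int = 10  # fallback caller: evidence floor
    purity: float = 0.8  # fallback caller: majority fraction for a haplotype call
    continuous_weights: bool = False  # pool with |v_phase_raw| instead of 0/1
    center_pca: bool = False  # mean-center before PCA (diagnostic only)


@dataclass
class ClusterPhaseGeometry:
    cluster: int
    v_clust: np.ndarray  # unit, over libraries
    plane_basis: np.ndarray  # (2, n_libraries), orthonormal principal directions
    v_phase_raw: np.ndarray  # unit, in-plane, orthogonal to v_clust
    v_phase: np.ndarray  # components in {-1, 0, +1}
    pc_variance: tuple[float, float]
    is_haploid: bool = False
    library_ids: list[str] = field(default_factory=list)


class DegenerateClusterError(RuntimeError):
    """Raised when a cluster's phase geometry cannot be inferred."""


def principal_directions(X: np.ndarray, center: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal directions and explained-variance fractions of the rows of X.

    Uncentered by default: the phase geometry reasons about directions from
    the origin, and haploid clusters are recognised precisely because their
    vectors lie on a single ray through 0 — mean-centering would erase that
    signature.
    """
    X = np.asarray(X, dtype=float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    fracs = (s**2) / total if total > 0 else np.zeros_like(s)
    return vt, fracs


def detect_haploid_clusters(
    ssf_phase: SSFMatrix,
    clusters: dict[int, list[str]],
    cfg: PhaseConfig | None = None,
) -> tuple[set[int], dict[int, tuple[float, float]]]:
    """Flag clusters whose phase-channel vectors are one-dimensional.

    Returns the haploid cluster ids and each cluster's (PC1, PC2) variance
    fractions.  Clusters with fewer than two non-zero phase vectors cannot be
    assessed and are left unflagged.
    """
    cfg = cfg or PhaseConfig()
    haploid: set[int] = set()
    variances: dict[int, tuple[float, float]] = {}
    for cid in sorted(clusters):
        sub = ssf_phase.subset(unitigs=sorted(clusters[cid]))
        unit = sub.unit_rows()
        unit = unit[np.linalg.norm(unit, axis=1) > 0]
        if unit.shape[0] < 2:
            variances[cid] = (float("nan"), float("nan"))
            continue
        _, fracs = principal_directions(unit, center=cfg.center_pca)
        pc1 = float(fracs[0])
        pc2 = float(fracs[1]) if fracs.size > 1 else 0.0
        variances[cid] = (pc1, pc2)
        if pc1 > cfg.pc1_haploid_min and pc2 < cfg.pc2_haploid_max:
            haploid.add(cid)
    return haploid, variances


def merge_clusters(clustering: Clustering, to_merge: set[int]) -> tuple[Clustering, int]:
    """Relabel all clusters in ``to_merge`` to a fresh cluster id."""
    new_id = max((c for c in clustering.label.values() if c != UNCLUSTERED), default=-1) + 1
    label = {
        u: (new_id if c in to_merge else c) for u, c in clustering.label.items()
    }
    history = clustering.history + [("merge_haploid", tuple(sorted(to_merge)), new_id, None)]
    return Clustering(label=label, history=history), new_id


def compute_v_clust(unit_vectors: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Size-weighted average of orientation-corrected unit vectors, normalized.

    Length weighting keeps a more fragmented haplotype from dominating the
    estimate through sheer unitig count.
    """
    v = (np.asarray(lengths, dtype=float)[:, None] * unit_vectors).sum(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DegenerateClusterError("size-weighted vector sum cancelled to zero")
    return v / norm


def rotate_in_plane(vec: np.ndarray, basis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``vec`` (assumed in span(basis)) by ``angle`` (counterclockwise
    in basis coordinates)."""
    coords = basis @ vec
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    return basis.T @ (rot @ coords)


def discretize_vphase(v_phase_raw: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Components at least ``frac`` of the largest magnitude keep their sign;
    the rest are zeroed (matched-state libraries carry no phase signal)."""
    mags = np.abs(v_phase_raw)
    cut = frac * mags.max()
    out = np.where(mags >= cut, np.sign(v_phase_raw), 0.0)
    return out


def infer_plane_and_vphase(
    phase_unit_vectors: np.ndarray,
    v_clust: np.ndarray,
    cfg: PhaseConfig | None = None,
    cluster: int = -1,
    library_ids: list[str] | None = None,
) -> ClusterPhaseGeometry:
    """Infer the chromosome plane and the v_clust/v_phase orthogonal basis.

    The plane is spanned by the first two principal directions of the
    phase-channel unit vectors; v_phase is the 90-degree in-plane rotation of
    v_clust's projection.  The rotation direction (and hence which haplotype
    is labeled A) is arbitrary.
    """
    cfg = cfg or PhaseConfig()
    X = np.asarray(phase_unit_vectors, dtype=float)
    X = X[np.linalg.norm(X, axis=1) > 0]
    if X.shape[0] < 2:
        raise DegenerateClusterError(
            f"cluster {cluster}: need >= 2 non-zero phase vectors for a plane"
        )
    vt, fracs = principal_directions(X, center=cfg.center_pca)
    if fracs.size < 2 or fracs[1] <= 1e-12:
        raise DegenerateClusterError(
            f"cluster {cluster}: phase vectors are one-dimensional; "
            "this cluster should go through the haploid path"
        )
    basis = vt[:2]
    proj = basis @ v_clust
    norm = np.linalg.norm(proj)
    if norm == 0:
        raise DegenerateClusterError(
            f"cluster {cluster}: v_clust is orthogonal to the chromosome plane"
        )
    proj = proj / norm
    rotated = np.array([-proj[1], proj[0]])  # 90 deg CCW in basis coordinates
    v_phase_raw = basis.T @ rotated
    v_phase_raw = v_phase_raw / np.linalg.norm(v_phase_raw)
    return ClusterPhaseGeometry(
        cluster=cluster,
        v_clust=np.asarray(v_clust, dtype=float),
        plane_basis=basis,
        v_phase_raw=v_phase_raw,
        v_phase=discretize_vphase(v_phase_raw, cfg.vphase_discretize_frac),
        pc_variance=(float(fracs[0]), float(fracs[1])),
        library_ids=list(library_ids or []),
    )


def haploid_bisection_correction(
    geometry: ClusterPhaseGeometry,
    phase_unit_vectors: np.ndarray,
    cfg: PhaseConfig | None = None,
) -> ClusterPhaseGeometry:
    """Rotate (v_clust, v_phase) so v_clust bisects the two haploid rays.

    The size-weighted v_clust is biased toward the larger haploid chromosome;
    in (v_clust, v_phase) coordinates the two chromosomes' unitigs have
    coordinate products of opposite sign, so the extremal-product unitigs are
    representatives of either ray and the basis is rotated to put v_clust on
    their bisector.
    """
    cfg = cfg or PhaseConfig()
    if not geometry.is_haploid:
        raise ValueError("bisection correction applies only to haploid clusters")
    X = np.asarray(phase_unit_vectors, dtype=float)
    X = X[np.linalg.norm(X, axis=1) > 0]
    a = X @ geometry.v_clust
    b = X @ geometry.v_phase_raw
    products = a * b
    if products.size == 0 or np.all(products == 0):
        warnings.warn("bisection correction skipped: all coordinate products are zero")
        return geometry
    hi, lo = int(np.argmax(products)), int(np.argmin(products))
    if products[hi] <= 0 or products[lo] >= 0:
        warnings.warn(
            "bisection correction skipped: no representatives on both sides "
            "(single haploid ray?)"
        )
        return geometry
    theta_hi = float(np.arctan2(b[hi], a[hi]))
    theta_lo = float(np.arctan2(b[lo], a[lo]))
    delta = (theta_hi + theta_lo) / 2.0
    v_clust = rotate_in_plane(geometry.v_clust, geometry.plane_basis, delta)
    v_phase_raw = rotate_in_plane(geometry.v_phase_raw, geometry.plane_basis, delta)
    return ClusterPhaseGeometry(
        cluster=geometry.cluster,
        v_clust=v_clust / np.linalg.norm(v_clust),
        plane_basis=geometry.plane_basis,
        v_phase_raw=v_phase_raw / np.linalg.norm(v_phase_raw),
        v_phase=discretize_vphase(v_phase_raw, cfg.vphase_discretize_frac),
        pc_variance=geometry.pc_variance,
        is_haploid=True,
        library_ids=geometry.library_ids,
    )


def pool_markers(
    counts: StrandCountMatrix,
    geometry: ClusterPhaseGeometry,
    cfg: PhaseConfig | None = None,
) -> pd.DataFrame:
    """Pool phase-informative counts into per-unitig haplotype marker counts.

    Libraries where v_phase = -1 have their Watson/Crick counts swapped so
    that Watson consistently marks one haplotype; marker counts are then the
    dot products of the count columns with |v_phase| (or with the continuous
    in-plane magnitudes when configured).
    """
    cfg = cfg or PhaseConfig()
    v_phase = geometry.v_phase
    w = counts.watson.astype(float).copy()
    c = counts.crick.astype(float).copy()
    neg = v_phase < 0
    w[:, neg], c[:, neg] = counts.crick.astype(float)[:, neg], counts.watson.astype(float)[:, neg]
    weight = np.abs(geometry.v_phase_raw) if cfg.continuous_weights else np.abs(v_phase)
    hap_a = w @ weight
    hap_b = c @ weight
    return pd.DataFrame(
        {"hapA_markers": hap_a, "hapB_markers": hap_b},
        index=pd.Index(counts.unitig_ids, name="node"),
    )


def call_haplotypes(markers: pd.DataFrame, cfg: PhaseConfig | None = None) -> pd.DataFrame:
    """Internal fallback caller over pooled marker counts.

    The production route hands the counts to a graph-threading tool; this
    caller gives a usable label when threading is not run.
    """
    cfg = cfg or PhaseConfig()
    total = markers["hapA_markers"] + markers["hapB_markers"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(total > 0, markers["hapA_markers"] / np.where(total > 0, total, 1), 0.5)
    call = np.full(len(markers), HOMOZYGOUS, dtype=object)
    call[frac_a >= cfg.purity] = HAP_A
    call[(1 - frac_a) >= cfg.purity] = HAP_B
    call[total < cfg.min_markers] = UNASSIGNED
    out = markers.copy()
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# orchestration over all clusters


@dataclass
class PhasingResult:
    markers: pd.DataFrame  # node, hapA_markers, hapB_markers, call, cluster, flip
    geometries: dict[int, ClusterPhaseGeometry]
    haploid_clusters: set[int]
    merged_haploid_cluster: int | None
    pc_variances: dict[int, tuple[float, float]]
    clustering: Clustering  # after any haploid merge
    orientation: OrientationAssignment
    unphased_clusters: dict[int, str] = field(default_factory=dict)

    def write_markers_tsv(self, path) -> None:
        df = self.markers.copy()
        df["hapA_markers"] = df["hapA_markers"].round().astype(int)
        df["hapB_markers"] = df["hapB_markers"].round().astype(int)
        df.to_csv(path, sep="\t")

    def write_geometry_tsv(self, path) -> None:
        rows = []
        for cid in sorted(self.geometries):
            g = self.geometries[cid]
            rows.append(
                {
                    "cluster": cid,
                    "is_haploid": int(g.is_haploid),
                    "pc1_variance": g.pc_variance[0],
                    "pc2_variance": g.pc_variance[1],
                    "v_clust": ",".join(f"{x:.6f}" for x in g.v_clust),
                    "v_phase": ",".join(f"{x:+.0f}" for x in g.v_phase),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def phase_clusters(
    clustering: Clustering,
    orientation: OrientationAssignment,
    ssf_all: SSFMatrix,
    ssf_phase: SSFMatrix,
    counts_phase: StrandCountMatrix,
    lengths: dict[str, int],
    cfg: PhaseConfig | None = None,
) -> PhasingResult:
    """Haploid detection/merge, per-cluster geometry, pooling, and calling.

    Merged haploid clusters get their orientation correction re-run (merging
    changes the membership the correction saw) and the bisection correction
    applied before pooling.
    """
    cfg = cfg or PhaseConfig()
    clusters = clustering.clusters()
    haploid, pc_var = detect_haploid_clusters(ssf_phase, clusters, cfg)

    merged_id: int | None = None
    orientation = OrientationAssignment(
        flip=dict(orientation.flip),
        flagged=dict(orientation.flagged),
        margin=dict(orientation.margin),
    )
    if haploid:
        clustering, merged_id = merge_clusters(clustering, haploid)
        clusters = clustering.clusters()
        redo = correct_orientation(ssf_all, clusters[merged_id])
        orientation.update(redo)

    geometries: dict[int, ClusterPhaseGeometry] = {}
    unphased: dict[int, str] = {}
    marker_frames: list[pd.DataFrame] = []
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        flip_rows = np.array([orientation.flip.get(u, False) for u in members])
        sign = np.where(flip_rows, -1.0, 1.0)[:, None]

        unit_all = ssf_all.subset(unitigs=members).unit_rows() * sign
        unit_phase = ssf_phase.subset(unitigs=members).unit_rows() * sign
        sub_counts = counts_phase.subset(unitigs=members).flip_unitigs(
            [u for u, f in zip(members, flip_rows) if f]
        )
        lens = np.array([lengths[u] for u in members], dtype=float)

        try:
            nz = np.linalg.norm(unit_all, axis=1) > 0
            if not nz.any():
                raise DegenerateClusterError(f"cluster {cid}: no all-read signal")
            v_clust = compute_v_clust(unit_all[nz], lens[nz])
            geom = infer_plane_and_vphase(
                unit_phase, v_clust, cfg, cluster=cid,
                library_ids=list(ssf_phase.library_ids),
            )
            geom.is_haploid = cid == merged_id
            if geom.is_haploid:
                geom = haploid_bisection_correction(geom, unit_phase, cfg)
            geometries[cid] = geom
        except DegenerateClusterError as exc:
            unphased[cid] = str(exc)
            df = pd.DataFrame(
                {
                    "hapA_markers": 0.0,
                    "hapB_markers": 0.0,
                    "call": UNASSIGNED,
                    "cluster": cid,
                    "flip": [int(orientation.flip.get(u, False)) for u in members],
                },
                index=pd.Index(members, name="node"),
            )
            marker_frames.append(df)
            continue

        pooled = pool_markers(sub_counts, geom, cfg)
        called = call_haplotypes(pooled, cfg)
        called["cluster"] = cid
        called["flip"] = [int(orientation.flip.get(u, False)) for u in members]
        marker_frames.append(called)

    markers = (
        pd.concat(marker_frames).sort_index()
        if marker_frames
        else pd.DataFrame(
            columns=["hapA_markers", "hapB_markers", "call", "cluster", "flip"]
        )
    )
    return PhasingResult(
        markers=markers,
        geometries=geometries,
        haploid_clusters=haploid,
        merged_haploid_cluster=merged_id,
        pc_variances=pc_var,
        clustering=clustering,
        orientation=orientation,
        unphased_clusters=unphased,
    )
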