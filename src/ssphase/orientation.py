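"""Misorientation detection within chromosome clusters.

A unitig assembled in reverse complement relative to its cluster has its
Watson/Crick counts — and hence its SSF vector — negated.  Within one cluster
the vectors therefore form two antipodal bundles.  Signed (non-absolute)
cosine similarity separates them: hierarchical clustering of the cluster's
vectors *plus a flipped copy of each* is cut at two clusters, the flipped
copies guaranteeing that both orientations are represented even when every
original unitig already agrees.  Only original copies are read off the cut;
one side is fixed as the reference orientation and the other side is flipped.
The global sign is arbitrary — only relative orientation matters downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .ssf import SSFMatrix


@dataclass
class OrientationAssignment:
    """flip[u] is True when u's W/C counts should be swapped; flagged[u]
    marks unitigs whose assignment carries no or inconsistent evidence."""

    flip: dict[str, bool]
    flagged: dict[str, bool] = field(default_factory=dict)
    margin: dict[str, float] = field(default_factory=dict)

    def flipped_ids(self) -> list[str]:
        return sorted(u for u, f in self.flip.items() if f)

    def update(self, other: "OrientationAssignment") -> None:
        self.flip.update(other.flip)
        self.flagged.update(other.flagged)
        self.margin.update(other.margin)


def correct_orientation(
    ssf: SSFMatrix, members: list[str], low_margin: float = 0.05
) -> OrientationAssignment:
    """Two-cluster hierarchical clustering of one cluster's vectors and their
    negations; average linkage on distance 1 - cos.

    The side containing the un-flipped copy of the lexicographically smallest
    non-zero unitig is the reference orientation.  A unitig whose original
    and flipped copy land on the *same* side has inconsistent evidence: it is
    left unflipped and flagged (with a warning).  Zero-signal unitigs are
    likewise left unflipped and flagged.
    """
    members = sorted(members)
    sub = ssf.subset(unitigs=members)
    norms = np.linalg.norm(sub.values, axis=1)
    nonzero = [u for u, n in zip(members, norms) if n > 0]
    zero = [u for u, n in zip(members, norms) if n == 0]

    flip = {u: False for u in members}
    flagged = {u: u in zero for u in members}
    margin = {u: 0.0 for u in members}
    if not nonzero:
        return OrientationAssignment(flip=flip, flagged=flagged, margin=margin)

    unit = ssf.subset(unitigs=nonzero).unit_rows()
    n = len(nonzero)
    aug = np.vstack([unit, -unit])  # originals first, flipped copies second
    if n == 1:
        return OrientationAssignment(flip=flip, flagged=flagged, margin={**margin, nonzero[0]: 2.0})

    dist = pdist(aug, metric="cosine")  # 1 - cos on unit vectors
    sides = fcluster(linkage(dist, method="average"), t=2, criterion="maxclust")

    ref_side = sides[0]  # un-flipped copy of the smallest id
    cos = aug @ aug.T
    for i, u in enumerate(nonzero):
        if sides[i] == sides[i + n]:
            warnings.warn(
                f"orientation evidence inconsistent for unitig {u}: original and "
                "flipped copy clustered together",
                stacklevel=2,
            )
            flagged[u] = True
            continue
        flip[u] = sides[i] != ref_side
        own = sides == sides[i]
        own[i] = False
        other = sides != sides[i]
        m = float(cos[i, own].mean() - cos[i, other].mean()) if own.any() else 2.0
        margin[u] = m
        if m < low_margin:
            flagged[u] = True
    return OrientationAssignment(flip=flip, flagged=flagged, margin=margin)


def correct_all_clusters(
    ssf: SSFMatrix, clusters: dict[int, list[str]], low_margin: float = 0.05
) -> OrientationAssignment:
    """Run orientation correction independently on every cluster."""
    out = OrientationAssignment(flip={})
    for cid in sorted(clusters):
        out.update(correct_orientation(ssf, clusters[cid], low_margin=low_margin))
    return out


def write_orientation_tsv(
    assignment: OrientationAssignment, cluster_of: dict[str, int], path
) -> None:
    with open(path, "w") as fh:
        fh.write("unitig\tcluster\tflip\tflagged\n")
        for u in sorted(assignment.flip):
            fh.write(
                f"{u}\t{cluster_of.get(u, -1)}\t{int(assignment.flip[u])}"
                f"\t{int(assignment.flagged.get(u, False))}\n"
            )
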