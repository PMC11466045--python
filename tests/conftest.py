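import numpy as np
import pytest

import ssphase as sp
from ssphase.ssf import SSFMatrix


@pytest.fixture(scope="session")
def toy_phase_vectors():
    """4-library worked example: libraries 1 and 3 matched, 2 and 4 unmatched.

    Maternal, paternal and homozygous unit vectors in the phase channel,
    plus the cluster direction they share.
    """
    maternal = np.array([1.0, 1.0, -1.0, -1.0]) / 2
    paternal = np.array([1.0, -1.0, -1.0, 1.0]) / 2
    homozygous = np.array([1.0, 0.0, -1.0, 0.0]) / np.sqrt(2)
    v_clust = np.array([1.0, 0.0, -1.0, 0.0]) / np.sqrt(2)
    return maternal, paternal, homozygous, v_clust


@pytest.fixture(scope="session")
def small_sim():
    """3 autosomes + XY, 48 libraries — fast but fully structured."""
    return sp.simulate(sp.SimConfig(n_autosomes=3, n_libraries=48, seed=42))


@pytest.fixture(scope="session")
def default_sim():
    """The full study configuration (22 autosomes + XY, 96 libraries)."""
    return sp.simulate(sp.SimConfig(seed=1))


def make_ssf(values, channel="all_reads", weights=None):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.where(values != 0, 10, 0)
    n_u, n_l = values.shape
    return SSFMatrix(
        channel=channel,
        values=values,
        weights=np.asarray(weights),
        unitig_ids=[f"u{i:02d}" for i in range(n_u)],
        library_ids=[f"lib{j:02d}" for j in range(n_l)],
    )


def bp_weighted_call_accuracy(sim, result):
    """Haplotype-call accuracy vs planted truth, best label swap per cluster."""
    markers = result.phasing.markers
    hap = sim.truth.haplotype_of()
    lengths = sim.truth.unitigs["length"].to_dict()
    to_call = {"A": "HAP_A", "B": "HAP_B", "HOM": "HOMOZYGOUS"}
    swap = {"HAP_A": "HAP_B", "HAP_B": "HAP_A"}
    correct = total = 0
    for _, grp in markers.groupby("cluster"):
        direct = flipped = bp = 0
        for u, row in grp.iterrows():
            w = lengths[u]
            bp += w
            truth_call = to_call[hap[u]]
            direct += w * (row["call"] == truth_call)
            flipped += w * (swap.get(row["call"], row["call"]) == truth_call)
        correct += max(direct, flipped)
        total += bp
    return correct / total if total else 0.0


def orientation_accuracy(sim, flip):
    """Fraction of unitigs with correct orientation, best global sign per
    planted chromosome (only relative orientation is identifiable)."""
    truth_flip = sim.truth.unitigs["flipped"].to_dict()
    chrom = sim.truth.chromosome_of()
    by_chrom = {}
    for u in flip:
        by_chrom.setdefault(chrom[u], []).append(u)
    ok = tot = 0
    for members in by_chrom.values():
        det = np.array([flip[u] for u in members])
        tru = np.array([truth_flip[u] for u in members])
        ok += max((det == tru).sum(), (det != tru).sum())
        tot += len(members)
    return ok / tot
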