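"""Strand-state-frequency (SSF) vectors and library/unitig quality control.

For a unitig with ``w`` Watson and ``c`` Crick reads in a library, the strand
state frequency is ``(w - c) / (w + c)``: +1/-1 for a matched strand state
(all reads one strand), near 0 for an unmatched WC/CW state.  The vector of
SSF values over libraries is the clustering and phasing feature.

QC mirrors contiBAIT-style preprocessing: every unitig is expected to inherit
matched and unmatched states in a roughly 50/50 ratio across libraries, so a
library that is unmatched almost everywhere indicates failed Strand-seq
chemistry and is discarded, as are libraries and unitigs with too few
alignments to call states confidently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import StrandCountMatrix

MATCHED, UNMATCHED, NO_CALL = "matched", "unmatched", "no_call"


@dataclass
class QCConfig:
    """Thresholds for state discretization and library/unitig QC.

    These defaults are this package's choices (the upstream preprocessing
    values are not published); all are surfaced in the run config.
    """

    tau: float = 0.5  # |SSF| >= tau calls a matched state
    min_cell_count: int = 5  # reads needed to call a state at all
    max_unmatched_frac: float = 0.8  # library discarded above this
    min_unitigs_per_lib: int = 20  # library needs calls on this many unitigs
    min_unitig_count: int = 10  # unitig needs this many reads in retained libs

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


@dataclass
class SSFMatrix:
    """SSF values (unitig x library) plus the w+c weights behind them."""

    channel: str
    values: np.ndarray  # float in [-1, 1]
    weights: np.ndarray  # int, w + c
    unitig_ids: list[str]
    library_ids: list[str]
    _uindex: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if np.abs(self.values).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("|SSF| must be <= 1")
        if ((self.weights == 0) & (self.values != 0)).any():
            raise ValueError("zero-weight cells must have SSF 0")
        self._uindex = {u: i for i, u in enumerate(self.unitig_ids)}

    def row(self, unitig: str) -> np.ndarray:
        return self.values[self._uindex[unitig]]

    def unit_rows(self) -> np.ndarray:
        """Row-normalized values; all-zero rows stay zero."""
        norms = np.linalg.norm(self.values, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norms > 0, self.values / norms, 0.0)
        return unit

    def nonzero_unitigs(self) -> list[str]:
        keep = np.linalg.norm(self.values, axis=1) > 0
        return [u for u, k in zip(self.unitig_ids, keep) if k]

    def subset(self, unitigs=None, libraries=None) -> "SSFMatrix":
        unitigs = list(self.unitig_ids) if unitigs is None else list(unitigs)
        libraries = list(self.library_ids) if libraries is None else list(libraries)
        li = {l: j for j, l in enumerate(self.library_ids)}
        rows = [self._uindex[u] for u in unitigs]
        cols = [li[l] for l in libraries]
        return SSFMatrix(
            channel=self.channel,
            values=self.values[np.ix_(rows, cols)].copy(),
            weights=self.weights[np.ix_(rows, cols)].copy(),
            unitig_ids=unitigs,
            library_ids=libraries,
        )

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            np.round(self.values, 6), index=self.unitig_ids, columns=self.library_ids
        )
        df.to_csv(path, sep="\t", index_label="unitig", float_format="%.6f")


@dataclass
class LibraryQCReport:
    """Per-library and per-unitig QC outcome, reproducible from counts+config."""

    library_stats: pd.DataFrame  # index library: n_unitigs_covered, fraction_unmatched, retained
    unitig_stats: pd.DataFrame  # index unitig: total_count, retained
    retained_libraries: list[str]
    retained_unitigs: list[str]


def compute_ssf(counts: StrandCountMatrix) -> SSFMatrix:
    """SSF = (w - c)/(w + c); cells with no reads get 0 (no signal).

    The zero convention makes uncovered libraries contribute nothing to
    cosine similarity, which is the geometry the clustering expects.
    """
    w = counts.watson.astype(float)
    c = counts.crick.astype(float)
    tot = w + c
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(tot > 0, (w - c) / np.where(tot > 0, tot, 1.0), 0.0)
    return SSFMatrix(
        channel=counts.channel,
        values=values,
        weights=counts.total,
        unitig_ids=list(counts.unitig_ids),
        library_ids=list(counts.library_ids),
    )


def discretize_states(ssf: SSFMatrix, cfg: QCConfig | None = None) -> np.ndarray:
    """Threshold SSF into matched / unmatched / no_call per cell."""
    cfg = cfg or QCConfig()
    states = np.full(ssf.values.shape, NO_CALL, dtype=object)
    callable_ = ssf.weights >= cfg.min_cell_count
    states[callable_ & (np.abs(ssf.values) >= cfg.tau)] = MATCHED
    states[callable_ & (np.abs(ssf.values) < cfg.tau)] = UNMATCHED
    return states


def qc_filter(
    states: np.ndarray, counts: StrandCountMatrix, cfg: QCConfig | None = None
) -> LibraryQCReport:
    """Drop failing libraries, then unitigs with too little retained evidence."""
    cfg = cfg or QCConfig()
    called = states != NO_CALL
    n_covered = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac_unmatched = np.where(
            n_covered > 0, (states == UNMATCHED).sum(axis=0) / np.maximum(n_covered, 1), 0.0
        )
    lib_ok = (frac_unmatched <= cfg.max_unmatched_frac) & (
        n_covered >= cfg.min_unitigs_per_lib
    )
    if not lib_ok.any():
        raise RuntimeError(
            "all libraries failed QC; review tau/max_unmatched_frac/"
            "min_unitigs_per_lib thresholds against the input depth"
        )
    retained_libs = [l for l, ok in zip(counts.library_ids, lib_ok) if ok]

    unitig_total = counts.total[:, lib_ok].sum(axis=1)
    unitig_ok = unitig_total >= cfg.min_unitig_count
    retained_unitigs = [u for u, ok in zip(counts.unitig_ids, unitig_ok) if ok]

    lib_df = pd.DataFrame(
        {
            "n_unitigs_covered": n_covered,
            "fraction_unmatched": frac_unmatched,
            "retained": lib_ok.astype(int),
        },
        index=pd.Index(counts.library_ids, name="library"),
    )
    unitig_df = pd.DataFrame(
        {"total_count": unitig_total, "retained": unitig_ok.astype(int)},
        index=pd.Index(counts.unitig_ids, name="unitig"),
    )
    return LibraryQCReport(
        library_stats=lib_df,
        unitig_stats=unitig_df,
        retained_libraries=retained_libs,
        retained_unitigs=retained_unitigs,
    )
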