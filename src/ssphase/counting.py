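"""Per-unitig, per-library Watson/Crick alignment counting.

Two evidence channels feed the engine:

* ``all_reads`` — conventional paired-end alignments (SAM/BAM), used for
  chromosome clustering and orientation correction;
* ``phase_informative`` — reads with exactly one super-maximal exact match
  (SMEM, ``bwa fastmap`` text output), which align to sequence unique in the
  graph and therefore carry haplotype signal.

Orientation convention: reads on a unitig's **reverse** strand are counted as
Watson, forward-strand reads as Crick.  The mapping is arbitrary — a global
W/C relabel only negates every strand-state-frequency vector, which the
sign-free clustering and phasing math downstream tolerate — but it is fixed
and applied consistently to both channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

ALL_READS = "all_reads"
PHASE_INFORMATIVE = "phase_informative"

#: strand -> counted channel column (reverse = Watson, forward = Crick)
WATSON_STRAND = "reverse"


@dataclass
class AlignmentRecord:
    """One SAM-style alignment, reduced to the fields the filters inspect."""

    read_id: str
    library_id: str
    unitig_id: str
    strand: str  # "forward" | "reverse"
    mate: str  # "first" | "second"
    duplicate: bool = False
    secondary: bool = False
    supplementary: bool = False
    proper_pair: bool = True


@dataclass
class SmemRecord:
    """One read's SMEMs from ``bwa fastmap``: hit list plus the SMEM count."""

    read_id: str
    library_id: str
    matches: list[tuple[str, str]]  # (unitig_id, strand) of the first SMEM
    n_smem: int


@dataclass
class StrandCountMatrix:
    """Watson/Crick count matrices, unitig x library, for one channel."""

    channel: str
    watson: np.ndarray  # int, shape (n_unitigs, n_libraries)
    crick: np.ndarray
    unitig_ids: list[str]
    library_ids: list[str]
    _uindex: dict[str, int] = field(repr=False, default_factory=dict)
    _lindex: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.watson = np.asarray(self.watson)
        self.crick = np.asarray(self.crick)
        if self.watson.shape != self.crick.shape:
            raise ValueError("watson and crick matrices must share shape")
        if self.watson.shape != (len(self.unitig_ids), len(self.library_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.watson < 0).any() or (self.crick < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.unitig_ids)) != len(self.unitig_ids):
            raise ValueError("duplicate unitig ids")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ValueError("duplicate library ids")
        self._uindex = {u: i for i, u in enumerate(self.unitig_ids)}
        self._lindex = {l: j for j, l in enumerate(self.library_ids)}

    @property
    def total(self) -> np.ndarray:
        return self.watson + self.crick

    def swapped(self) -> "StrandCountMatrix":
        """W <-> C everywhere (a global relabel of strand orientation)."""
        return StrandCountMatrix(
            channel=self.channel,
            watson=self.crick.copy(),
            crick=self.watson.copy(),
            unitig_ids=list(self.unitig_ids),
            library_ids=list(self.library_ids),
        )

    def subset(
        self,
        unitigs: Sequence[str] | None = None,
        libraries: Sequence[str] | None = None,
    ) -> "StrandCountMatrix":
        unitigs = list(self.unitig_ids) if unitigs is None else list(unitigs)
        libraries = list(self.library_ids) if libraries is None else list(libraries)
        ui = [self._uindex[u] for u in unitigs]
        lj = [self._lindex[l] for l in libraries]
        return StrandCountMatrix(
            channel=self.channel,
            watson=self.watson[np.ix_(ui, lj)].copy(),
            crick=self.crick[np.ix_(ui, lj)].copy(),
            unitig_ids=unitigs,
            library_ids=libraries,
        )

    def flip_unitigs(self, to_flip: Iterable[str]) -> "StrandCountMatrix":
        """Swap W/C counts on the given unitigs only (orientation correction)."""
        w = self.watson.copy()
        c = self.crick.copy()
        rows = [self._uindex[u] for u in to_flip]
        w[rows], c[rows] = self.crick[rows], self.watson[rows]
        return StrandCountMatrix(
            channel=self.channel,
            watson=w,
            crick=c,
            unitig_ids=list(self.unitig_ids),
            library_ids=list(self.library_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts table (unitig, library, watson, crick)."""
        ui, lj = np.meshgrid(
            np.arange(len(self.unitig_ids)),
            np.arange(len(self.library_ids)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "unitig": np.asarray(self.unitig_ids)[ui.ravel()],
                "library": np.asarray(self.library_ids)[lj.ravel()],
                "watson": self.watson.ravel(),
                "crick": self.crick.ravel(),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, channel: str) -> "StrandCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"unitig": str, "library": str})
        unitigs = list(dict.fromkeys(df["unitig"]))
        libraries = list(dict.fromkeys(df["library"]))
        return cls.from_records(
            zip(df["library"], df["unitig"], df["watson"], df["crick"]),
            libraries=libraries,
            unitigs=unitigs,
            channel=channel,
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int, int]],
        libraries: Sequence[str],
        unitigs: Sequence[str],
        channel: str,
    ) -> "StrandCountMatrix":
        """Build from (library, unitig, watson, crick) tuples, summing repeats."""
        unitigs = list(unitigs)
        libraries = list(libraries)
        uindex = {u: i for i, u in enumerate(unitigs)}
        lindex = {l: j for j, l in enumerate(libraries)}
        w = np.zeros((len(unitigs), len(libraries)), dtype=np.int64)
        c = np.zeros_like(w)
        for lib, unitig, nw, nc in records:
            if unitig not in uindex:
                raise KeyError(f"unknown unitig id {unitig!r}")
            if lib not in lindex:
                raise KeyError(f"unknown library id {lib!r}")
            w[uindex[unitig], lindex[lib]] += nw
            c[uindex[unitig], lindex[lib]] += nc
        return cls(
            channel=channel, watson=w, crick=c, unitig_ids=unitigs, library_ids=libraries
        )


def filter_mem_alignments(
    records: Iterable[AlignmentRecord],
) -> Iterator[AlignmentRecord]:
    """Keep first-mate, non-duplicate, non-secondary, non-supplementary,
    properly paired alignments."""
    for rec in records:
        if (
            rec.mate == "first"
            and not rec.duplicate
            and not rec.secondary
            and not rec.supplementary
            and rec.proper_pair
        ):
            yield rec


def filter_single_smem(
    records: Iterable[SmemRecord],
) -> Iterator[tuple[str, str, str, str]]:
    """Keep reads with exactly one SMEM that places uniquely.

    Reads with more than one SMEM align across non-unique sequence and are
    dropped; so is a single SMEM with multiple placements (or a suppressed
    hit list), since no single unitig can be reported for it.
    """
    for rec in records:
        if rec.n_smem != 1 or len(rec.matches) != 1:
            continue
        unitig, strand = rec.matches[0]
        yield rec.read_id, rec.library_id, unitig, strand


def count_alignments(
    filtered: Iterable[tuple[str, str, str, str]],
    libraries: Sequence[str],
    unitigs: Sequence[str],
    channel: str,
) -> StrandCountMatrix:
    """Tally filtered (read, library, unitig, strand) records into W/C counts.

    Reverse-strand records increment Watson, forward-strand Crick.
    """

    def to_counts() -> Iterator[tuple[str, str, int, int]]:
        for _read, lib, unitig, strand in filtered:
            if strand not in ("forward", "reverse"):
                raise ValueError(f"bad strand {strand!r}")
            is_watson = (strand == WATSON_STRAND)
            yield lib, unitig, int(is_watson), int(not is_watson)

    return StrandCountMatrix.from_records(
        to_counts(), libraries=libraries, unitigs=unitigs, channel=channel
    )


# ---------------------------------------------------------------------------
# readers for the on-disk formats


def iter_sam_records(path: str | Path, library_id: str | None = None) -> Iterator[AlignmentRecord]:
    """Yield AlignmentRecords from one per-library SAM/BAM file.

    The library id defaults to the file stem; read-group-based naming is the
    caller's concern (pass ``library_id`` explicitly).
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            yield AlignmentRecord(
                read_id=aln.query_name or "",
                library_id=lib,
                unitig_id=aln.reference_name,
                strand="reverse" if aln.is_reverse else "forward",
                mate="second" if (aln.is_paired and aln.is_read2) else "first",
                duplicate=aln.is_duplicate,
                secondary=aln.is_secondary,
                supplementary=aln.is_supplementary,
                proper_pair=aln.is_proper_pair,
            )


def iter_fastmap_records(
    path: str | Path, library_id: str | None = None
) -> Iterator[SmemRecord]:
    """Parse ``bwa fastmap`` text output into SmemRecords.

    The format is blocks of::

        SQ <read name> <read length>
        EM <start> <end> <n_hits> <unitig>:<sign><pos> ...
        ...
        //

    An EM line whose hit list is suppressed (ends in ``*``, hit cap exceeded)
    marks the read as repetitive; it is reported with an empty match list so
    the single-SMEM filter drops it.
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    read_id: str | None = None
    em_lines: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "SQ":
                read_id = fields[1]
                em_lines = []
            elif fields[0] == "EM":
                em_lines.append(fields)
            elif fields[0] == "//":
                if read_id is not None:
                    yield _smem_from_block(read_id, lib, em_lines)
                read_id = None
                em_lines = []
    if read_id is not None:
        yield _smem_from_block(read_id, lib, em_lines)


def _smem_from_block(read_id: str, lib: str, em_lines: list[list[str]]) -> SmemRecord:
    n_smem = len(em_lines)
    matches: list[tuple[str, str]] = []
    if n_smem == 1:
        fields = em_lines[0]
        hits = fields[4:]
        if not (hits and hits[-1] == "*"):  # suppressed hit list => repetitive
            for hit in hits:
                ref, _, pos = hit.rpartition(":")
                strand = "forward" if pos.startswith("+") else "reverse"
                matches.append((ref, strand))
        else:
            n_smem = 2  # treat capped reads as multi-SMEM: repetitive by construction
    return SmemRecord(read_id=read_id, library_id=lib, matches=matches, n_smem=n_smem)


def count_sam_files(
    paths: Sequence[str | Path], unitigs: Sequence[str]
) -> StrandCountMatrix:
    """All-read channel counts from one SAM/BAM file per library."""
    libraries = [Path(p).stem for p in paths]

    def stream() -> Iterator[tuple[str, str, str, str]]:
        known = set(unitigs)
        for p in paths:
            for rec in filter_mem_alignments(iter_sam_records(p)):
                if rec.unitig_id in known:
                    yield rec.read_id, rec.library_id, rec.unitig_id, rec.strand

    return count_alignments(stream(), libraries, unitigs, channel=ALL_READS)


def count_fastmap_files(
    paths: Sequence[str | Path], unitigs: Sequence[str]
) -> StrandCountMatrix:
    """Phase-informative channel counts from one fastmap file per library."""
    libraries = [Path(p).stem for p in paths]

    def stream() -> Iterator[tuple[str, str, str, str]]:
        known = set(unitigs)
        for p in paths:
            for rec in filter_single_smem(iter_fastmap_records(p)):
                if rec[2] in known:
                    yield rec

    return count_alignments(stream(), libraries, unitigs, channel=PHASE_INFORMATIVE)
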