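"""Assembly-graph input, connected components, and unitig length filtering.

The phasing engine treats the assembly graph as an undirected adjacency
structure over unitigs: link-end orientations are parsed and stored, but the
phasing math operates on per-unitig alignment counts, not on graph walks.
Connected components are used as a clustering heuristic (unitigs on the same
component are more likely to come from the same chromosome), after an attempt
to break the dense short-node tangle that joins the acrocentric chromosomes
through the rDNA array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

DEFAULT_MIN_LENGTH = 50_000  # bp; unitigs shorter than this are noise-prone


class GFAParseError(ValueError):
    """Raised for a malformed GFA line, naming the line number."""


@dataclass
class AssemblyGraph:
    """Unitig graph: ids, lengths, undirected links, component labels.

    ``links`` stores one entry per L line as a frozenset of the two endpoint
    ids (self-links collapse to a singleton frozenset).  ``link_orients``
    retains the parsed end orientations for round-tripping; nothing downstream
    interprets them.
    """

    lengths: dict[str, int]
    links: set[frozenset[str]] = field(default_factory=set)
    link_orients: dict[frozenset[str], list[tuple[str, str, str, str]]] = field(
        default_factory=dict
    )
    component_id: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"unitig {u!r} has non-positive length {length}")
        for link in self.links:
            for end in link:
                if end not in self.lengths:
                    raise ValueError(f"link endpoint {end!r} is not a known unitig")
        if not self.component_id:
            self.component_id = self._compute_components()

    @property
    def unitigs(self) -> list[str]:
        return sorted(self.lengths)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.lengths)
        for link in self.links:
            ends = sorted(link)
            if len(ends) == 1:  # self-link
                g.add_edge(ends[0], ends[0])
            else:
                g.add_edge(ends[0], ends[1])
        return g

    def _compute_components(self) -> dict[str, int]:
        # Deterministic labels: components ordered by their smallest member id.
        comps = sorted(
            (sorted(c) for c in nx.connected_components(self.to_networkx())),
            key=lambda members: members[0],
        )
        return {u: i for i, members in enumerate(comps) for u in members}

    def component_bp(self) -> dict[int, int]:
        """Summed unitig length per component."""
        totals: dict[int, int] = {}
        for u, length in self.lengths.items():
            cid = self.component_id[u]
            totals[cid] = totals.get(cid, 0) + length
        return totals

    def drop_unitigs(self, to_drop: set[str]) -> "AssemblyGraph":
        """New graph without ``to_drop`` and all edges touching them."""
        lengths = {u: l for u, l in self.lengths.items() if u not in to_drop}
        links = {lk for lk in self.links if not (lk & to_drop)}
        orients = {lk: v for lk, v in self.link_orients.items() if lk in links}
        return AssemblyGraph(lengths=lengths, links=links, link_orients=orients)


@dataclass
class UnitigFilter:
    """Length-filter outcome: retained/removed id sets and the bp fraction lost."""

    min_length: int
    retained: set[str]
    removed: set[str]
    removed_bp_fraction: float


def read_gfa(path: str | Path) -> AssemblyGraph:
    """Read a GFA1 file (S and L lines; other record types are ignored).

    Segment length comes from the sequence if given, else from the ``LN:i``
    tag; an S line with neither is an error.
    """
    lengths: dict[str, int] = {}
    links: set[frozenset[str]] = set()
    orients: dict[frozenset[str], list[tuple[str, str, str, str]]] = {}
    raw_links: list[tuple[int, str, str, str, str]] = []

    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"{path}:{lineno}: S line has < 3 fields")
                name, seq = fields[1], fields[2]
                if name in lengths:
                    raise GFAParseError(f"{path}:{lineno}: duplicate segment {name!r}")
                if seq != "*":
                    lengths[name] = len(seq)
                else:
                    ln = _ln_tag(fields[3:])
                    if ln is None:
                        raise GFAParseError(
                            f"{path}:{lineno}: segment {name!r} has neither "
                            "sequence nor LN:i tag"
                        )
                    lengths[name] = ln
            elif tag == "L":
                if len(fields) < 5:
                    raise GFAParseError(f"{path}:{lineno}: L line has < 5 fields")
                fr, fo, to, to_o = fields[1], fields[2], fields[3], fields[4]
                if fo not in "+-" or to_o not in "+-":
                    raise GFAParseError(f"{path}:{lineno}: bad link orientation")
                raw_links.append((lineno, fr, fo, to, to_o))
            # H, P, W, C, J and anything else: out of scope, skipped.

    for lineno, fr, fo, to, to_o in raw_links:
        for end in (fr, to):
            if end not in lengths:
                raise GFAParseError(
                    f"{path}:{lineno}: link endpoint {end!r} is not a segment"
                )
        key = frozenset((fr, to))
        links.add(key)
        orients.setdefault(key, []).append((fr, fo, to, to_o))

    return AssemblyGraph(lengths=lengths, links=links, link_orients=orients)


def remove_rdna_tangle(
    graph: AssemblyGraph, short_len: int = DEFAULT_MIN_LENGTH
) -> AssemblyGraph:
    """Remove the largest short-node tangle from the bp-largest component.

    The component with the most summed base pairs is taken as the putative
    acrocentric component.  Within it, connected subgraphs induced by nodes
    shorter than ``short_len`` are enumerated; the largest one (by summed bp,
    ties by node count then smallest member id) is removed together with all
    edges touching it, and components are recomputed.  A graph whose largest
    component has no short node is returned unchanged.
    """
    if short_len <= 0:
        raise ValueError("short_len must be positive")
    bp = graph.component_bp()
    if not bp:
        return graph
    target = max(bp, key=lambda cid: (bp[cid], -cid))
    short = {
        u
        for u in graph.lengths
        if graph.component_id[u] == target and graph.lengths[u] < short_len
    }
    if not short:
        return graph
    sub = graph.to_networkx().subgraph(short)
    tangles = [sorted(c) for c in nx.connected_components(sub)]

    def tangle_key(members: list[str]) -> tuple[int, int, str]:
        total = sum(graph.lengths[u] for u in members)
        # bp, then node count; lexicographic smallest id breaks remaining ties
        return (total, len(members), members[0])

    tangles.sort(key=lambda m: (-tangle_key(m)[0], -tangle_key(m)[1], tangle_key(m)[2]))
    return graph.drop_unitigs(set(tangles[0]))


def filter_by_length(
    graph: AssemblyGraph, min_length: int = DEFAULT_MIN_LENGTH
) -> UnitigFilter:
    """Split unitigs into retained (length >= ``min_length``) and removed."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    retained = {u for u, l in graph.lengths.items() if l >= min_length}
    removed = set(graph.lengths) - retained
    total = sum(graph.lengths.values())
    removed_bp = sum(graph.lengths[u] for u in removed)
    frac = removed_bp / total if total else 0.0
    return UnitigFilter(
        min_length=min_length,
        retained=retained,
        removed=removed,
        removed_bp_fraction=frac,
    )


def write_unitig_filter_tsv(
    graph: AssemblyGraph, unitig_filter: UnitigFilter, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("unitig\tlength\tcomponent\tretained\n")
        for u in graph.unitigs:
            kept = int(u in unitig_filter.retained)
            fh.write(f"{u}\t{graph.lengths[u]}\t{graph.component_id[u]}\t{kept}\n")


def _ln_tag(tags: list[str]) -> int | None:
    for t in tags:
        if t.startswith("LN:i:"):
            return int(t.split(":", 2)[2])
    return None
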