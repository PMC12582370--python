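"""Homology graph over aligned sequence sections and its segmentation into modules.

Vertices are sections of elements that took part in at least one pairwise
local alignment. Two sections are connected when (1) they form an alignment
pair with e-value below threshold, or (2) they lie on the same element and
mutually overlap above threshold. Connected components, found with a
disjoint-set (union-find) structure, become modules; homology is treated as
strand-agnostic.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

from .io_formats import AlignmentHit

__all__ = [
    "Section",
    "ModuleDef",
    "HomologyGraph",
    "DisjointSet",
    "build_graph",
    "connected_components",
    "call_modules",
    "mutual_overlap",
    "write_module_bed",
]


@dataclass(frozen=True, order=True)
class Section:
    """A 0-based half-open span on one element."""

    element_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad section interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ModuleDef:
    """One module: a connected component of homologous sections."""

    module_id: str
    members: list[Section]
    rep_length: float  # median member length, nt

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class HomologyGraph:
    vertices: list[Section]
    edges: list[tuple[Section, Section]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def mutual_overlap(a: Section | tuple[int, int], b: Section | tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) — both intervals must clear the
    threshold, so the minimum of the two per-interval ratios is used."""
    astart, aend = (a.start, a.end) if isinstance(a, Section) else a
    bstart, bend = (b.start, b.end) if isinstance(b, Section) else b
    ov = min(aend, bend) - max(astart, bstart)
    if ov <= 0:
        return 0.0
    return min(ov / (aend - astart), ov / (bend - bstart))


class DisjointSet:
    """Union-find with path compression and union by rank."""

    def __init__(self) -> None:
        self._parent: dict[Hashable, Hashable] = {}
        self._rank: dict[Hashable, int] = {}

    def add(self, x: Hashable) -> None:
        if x not in self._parent:
            self._parent[x] = x
            self._rank[x] = 0

    def find(self, x: Hashable) -> Hashable:
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, x: Hashable, y: Hashable) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return
        if self._rank[rx] < self._rank[ry]:
            rx, ry = ry, rx
        self._parent[ry] = rx
        if self._rank[rx] == self._rank[ry]:
            self._rank[rx] += 1

    def groups(self) -> list[list[Hashable]]:
        by_root: dict[Hashable, list[Hashable]] = {}
        for x in self._parent:
            by_root.setdefault(self.find(x), []).append(x)
        return list(by_root.values())


def _overlap_pairs(
    sections: list[Section], threshold: float, containment: bool
) -> list[tuple[Section, Section]]:
    """Index pairs of same-element sections whose overlap ratio clears the
    threshold, vectorized. The symmetric mutual overlap min(ov/|a|, ov/|b|)
    equals ov / max(|a|, |b|); the containment ratio is ov / min(|a|, |b|)."""
    import numpy as np

    m = len(sections)
    if m < 2:
        return []
    starts = np.array([s.start for s in sections])
    ends = np.array([s.end for s in sections])
    lens = ends - starts
    ov = np.minimum.outer(ends, ends) - np.maximum.outer(starts, starts)
    denom = (np.minimum if containment else np.maximum).outer(lens, lens)
    mask = (ov > 0) & (ov >= threshold * denom)
    mask &= np.triu(np.ones((m, m), dtype=bool), k=1)
    ii, jj = np.nonzero(mask)
    return [(sections[i], sections[j]) for i, j in zip(ii.tolist(), jj.tolist())]


def build_graph(
    hits: Iterable[AlignmentHit],
    evalue_max: float = 1e-5,
    min_mutual_overlap: float = 0.8,
    min_section_len: int = 30,
) -> HomologyGraph:
    """Build the undirected homology graph from normalized alignment hits.

    Sections shorter than ``min_section_len`` are discarded outright; they are
    too short to represent a reliable homologous region.
    """
    if not (0.0 < min_mutual_overlap <= 1.0):
        raise ValueError(f"min_mutual_overlap {min_mutual_overlap} outside (0, 1]")

    vertices: set[Section] = set()
    edges: set[tuple[Section, Section]] = set()

    def _edge(a: Section, b: Section) -> tuple[Section, Section]:
        return (a, b) if a <= b else (b, a)

    for h in hits:
        if min(h.qend - h.qstart, h.send - h.sstart) < min_section_len:
            continue
        q = Section(h.qid, h.qstart, h.qend)
        s = Section(h.sid, h.sstart, h.send)
        if q == s:
            continue
        vertices.add(q)
        vertices.add(s)
        if h.evalue < evalue_max:  # condition (1): aligned homologous pair
            edges.add(_edge(q, s))

    # condition (2): same element, mutual positional overlap above threshold
    by_element: dict[str, list[Section]] = {}
    for v in vertices:
        by_element.setdefault(v.element_id, []).append(v)
    key = lambda s: (s.element_id, s.start, s.end)
    for sections in by_element.values():
        sections.sort(key=key)
        for a, b in _overlap_pairs(sections, min_mutual_overlap, containment=False):
            edges.add(_edge(a, b))

    return HomologyGraph(
        vertices=sorted(vertices, key=key),
        edges=sorted(edges, key=lambda e: (key(e[0]), key(e[1]))),
    )


def connected_components(graph: HomologyGraph) -> list[list[Section]]:
    """Partition the graph's sections into maximal connected components using
    the disjoint-set structure (sections interned to integer ids so the
    union-find runs on plain ints). Deterministic: components sorted by
    their smallest member, members sorted within each component."""
    key = lambda s: (s.element_id, s.start, s.end)
    idx = {v: i for i, v in enumerate(graph.vertices)}
    ds = DisjointSet()
    for i in range(len(graph.vertices)):
        ds.add(i)
    for a, b in graph.edges:
        ds.union(idx[a], idx[b])
    comps = [
        sorted((graph.vertices[i] for i in g), key=key) for g in ds.groups()
    ]
    comps.sort(key=lambda g: key(g[0]))
    return comps


def _containment_overlap(a: Section, b: Section) -> float:
    """overlap / length of the shorter interval; 1.0 for nested sections."""
    ov = min(a.end, b.end) - max(a.start, b.start)
    return max(ov, 0) / min(len(a), len(b))


def _fuse_same_element(sections: list[Section], min_mutual_overlap: float) -> list[Section]:
    """Fuse overlapping same-element sections of one component into the union
    of their intervals; transitive via union-find.

    Fusion uses the containment ratio (overlap over the shorter interval) so
    that nested sections of the same module collapse to one member instead of
    emitting stacked repeats; graph edges keep the stricter symmetric
    mutual-overlap criterion.
    """
    by_el: dict[str, list[Section]] = {}
    for s in sections:
        by_el.setdefault(s.element_id, []).append(s)
    key = lambda s: (s.element_id, s.start, s.end)
    fused: list[Section] = []
    for el_sections in by_el.values():
        el_sections.sort(key=key)
        idx = {s: i for i, s in enumerate(el_sections)}
        ds = DisjointSet()
        for i in range(len(el_sections)):
            ds.add(i)
        for a, b in _overlap_pairs(el_sections, min_mutual_overlap, containment=True):
            ds.union(idx[a], idx[b])
        for group in ds.groups():
            members = [el_sections[i] for i in group]
            fused.append(
                Section(
                    members[0].element_id,
                    min(s.start for s in members),
                    max(s.end for s in members),
                )
            )
    return sorted(fused, key=key)


def call_modules(
    components: Sequence[Sequence[Section]],
    min_members: int = 2,
    min_mutual_overlap: float = 0.8,
) -> list[ModuleDef]:
    """Turn connected components into modules.

    Components with fewer than ``min_members`` sections are dropped. Within a
    component, overlapping sections of the same element are fused into one
    member section. Module ids are assigned deterministically: "b" + rank by
    descending member count, ties broken by the smallest member section.
    """
    candidates: list[list[Section]] = []
    for comp in components:
        if len(comp) < min_members:
            continue
        candidates.append(_fuse_same_element(list(comp), min_mutual_overlap))

    candidates.sort(key=lambda members: (-len(members), members[0]))
    modules = []
    for rank, members in enumerate(candidates, start=1):
        modules.append(
            ModuleDef(
                module_id=f"b{rank}",
                members=members,
                rep_length=statistics.median(len(s) for s in members),
            )
        )
    return modules


def write_module_bed(modules: Iterable[ModuleDef], path) -> None:
    """BED-like TSV dump of module member sections (element_id, start, end, module_id)."""
    with open(path, "w") as fh:
        for mod in modules:
            for s in mod.members:
                fh.write(f"{s.element_id}\t{s.start}\t{s.end}\t{mod.module_id}\n")
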