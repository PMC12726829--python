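"""Neuronal morphologies as three linked tree graphs.

A morphology is represented at three abstraction levels:

* :class:`PointTree` — the raw reconstruction: 3D points with radii and
  parent links (one per SWC data line).
* :class:`SectionTree` — unbranched stretches between bifurcation points
  (and domain changes), the topological unit.
* :class:`SegmentTree` — each section subdivided into ``nseg`` equal
  arclength segments, the spatial unit of numerical integration; every
  segment is one RC compartment.

All distances are in micrometres.  Internal node indices are 0-based;
1-based SWC ids appear only in I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PointNode",
    "PointTree",
    "Section",
    "SectionTree",
    "Segment",
    "SegmentTree",
    "MorphometricSummary",
    "read_swc",
    "write_swc",
    "split_to_sections",
    "build_segments",
    "segment_centers",
    "nseg_from_dlambda",
    "lambda_f",
    "frustum_area",
    "morphometrics",
]

# SWC structure-type codes <-> domain names
SWC_DOMAINS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
DOMAIN_CODES = {v: k for k, v in SWC_DOMAINS.items()}


class SWCError(ValueError):
    """Malformed SWC content (cycles, multiple roots, missing parents)."""


@dataclass
class PointNode:
    """One reconstruction point (an SWC data line)."""

    idx: int
    domain: str
    x: float
    y: float
    z: float
    radius: float
    parent: int | None  # index into PointTree.nodes, None for root

    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _domain_name(code: int) -> str:
    return SWC_DOMAINS.get(code, f"custom_{code}")


def _domain_code(name: str) -> int:
    if name in DOMAIN_CODES:
        return DOMAIN_CODES[name]
    if name.startswith("custom_"):
        return int(name.split("_", 1)[1])
    return 5


class PointTree:
    """Rooted tree of reconstruction points.

    Nodes are kept topologically sorted (parents before children);
    :meth:`children` gives the forward adjacency.
    """

    def __init__(self, nodes: list[PointNode]):
        self.nodes = nodes
        self._sort()
        self._validate()

    # -- construction / invariants -------------------------------------

    def _sort(self) -> None:
        """Topologically sort nodes and remap parent indices."""
        n = len(self.nodes)
        children: dict[int | None, list[int]] = {}
        for i, nd in enumerate(self.nodes):
            children.setdefault(nd.parent, []).append(i)
        order: list[int] = []
        stack = list(reversed(children.get(None, [])))
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(children.get(i, [])))
        if len(order) != n:
            raise SWCError("cyclic or disconnected parent references")
        remap = {old: new for new, old in enumerate(order)}
        new_nodes = []
        for new, old in enumerate(order):
            nd = self.nodes[old]
            parent = None if nd.parent is None else remap[nd.parent]
            new_nodes.append(
                PointNode(new, nd.domain, nd.x, nd.y, nd.z, nd.radius, parent)
            )
        self.nodes = new_nodes

    def _validate(self) -> None:
        roots = [nd for nd in self.nodes if nd.parent is None]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        for nd in self.nodes:
            if nd.radius <= 0:
                raise SWCError(f"non-positive radius at node {nd.idx}")
            if nd.parent is not None and nd.parent >= nd.idx:
                raise SWCError("nodes not topologically sorted")

    # -- queries --------------------------------------------------------

    @property
    def root(self) -> PointNode:
        return self.nodes[0]

    def children(self, idx: int) -> list[int]:
        return [nd.idx for nd in self.nodes if nd.parent == idx]

    def children_map(self) -> dict[int, list[int]]:
        cm: dict[int, list[int]] = {nd.idx: [] for nd in self.nodes}
        for nd in self.nodes:
            if nd.parent is not None:
                cm[nd.parent].append(nd.idx)
        return cm

    def subtree(self, idx: int) -> list[int]:
        """Indices of idx and all its descendants, in tree order."""
        cm = self.children_map()
        out, stack = [], [idx]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(reversed(cm[i]))
        return out

    def edge_length(self, idx: int) -> float:
        """Euclidean distance from a node to its parent (root -> 0)."""
        nd = self.nodes[idx]
        if nd.parent is None:
            return 0.0
        return float(np.linalg.norm(nd.coords() - self.nodes[nd.parent].coords()))

    def path_distance(self, idx: int) -> float:
        """Path distance (µm) from the root to a node, along the tree."""
        d = 0.0
        nd = self.nodes[idx]
        while nd.parent is not None:
            d += self.edge_length(nd.idx)
            nd = self.nodes[nd.parent]
        return d

    def total_length(self) -> float:
        return sum(self.edge_length(i) for i in range(len(self.nodes)))

    # -- editing --------------------------------------------------------

    def insert_node(
        self, parent: int, domain: str, x: float, y: float, z: float, radius: float
    ) -> int:
        if parent < 0 or parent >= len(self.nodes):
            raise ValueError(f"parent node {parent} does not exist")
        idx = len(self.nodes)
        self.nodes.append(PointNode(idx, domain, x, y, z, radius, parent))
        return idx

    def remove_node(self, idx: int) -> None:
        """Remove a single node, reattaching its children to its parent."""
        if self.nodes[idx].parent is None:
            raise ValueError("cannot remove the root node")
        parent = self.nodes[idx].parent
        keep = [nd for nd in self.nodes if nd.idx != idx]
        for nd in keep:
            if nd.parent == idx:
                nd.parent = parent
        self._renumber(keep)

    def remove_subtree(self, idx: int) -> None:
        if self.nodes[idx].parent is None:
            raise ValueError("cannot remove the root subtree")
        doomed = set(self.subtree(idx))
        keep = [nd for nd in self.nodes if nd.idx not in doomed]
        self._renumber(keep)

    def translate_subtree(self, idx: int, dx: float, dy: float, dz: float) -> None:
        for i in self.subtree(idx):
            nd = self.nodes[i]
            nd.x += dx
            nd.y += dy
            nd.z += dz

    def _renumber(self, keep: list[PointNode]) -> None:
        remap = {nd.idx: new for new, nd in enumerate(keep)}
        for new, nd in enumerate(keep):
            nd.parent = None if nd.parent is None else remap[nd.parent]
            nd.idx = new
        self.nodes = keep
        self._validate()

    def copy(self) -> "PointTree":
        return PointTree(
            [
                PointNode(nd.idx, nd.domain, nd.x, nd.y, nd.z, nd.radius, nd.parent)
                for nd in self.nodes
            ]
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(text: str) -> PointTree:
    """Parse 7-column SWC content into a :class:`PointTree`.

    Comment lines start with ``#``.  Child lines may precede their parent
    lines; the tree is re-sorted topologically.
    """
    raw: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"line {lineno}: expected 7 fields, got {len(fields)}")
        try:
            sid = int(fields[0])
            code = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            pid = int(fields[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
        if sid in raw:
            raise SWCError(f"line {lineno}: duplicate id {sid}")
        raw[sid] = (code, x, y, z, r, pid)
    if not raw:
        raise SWCError("no data lines")
    ids = sorted(raw)
    id_to_idx = {sid: i for i, sid in enumerate(ids)}
    nodes = []
    for sid in ids:
        code, x, y, z, r, pid = raw[sid]
        if pid == -1:
            parent = None
        elif pid in id_to_idx:
            parent = id_to_idx[pid]
        else:
            raise SWCError(f"node {sid}: missing parent id {pid}")
        nodes.append(PointNode(id_to_idx[sid], _domain_name(code), x, y, z, r, parent))
    return PointTree(nodes)


def write_swc(tree: PointTree, comment: str | None = None) -> str:
    """Serialize a tree to SWC with contiguous 1-based ids in tree order."""
    lines = []
    if comment:
        lines.extend(f"# {c}" for c in comment.splitlines())
    for nd in tree.nodes:
        pid = -1 if nd.parent is None else nd.parent + 1
        lines.append(
            f"{nd.idx + 1} {_domain_code(nd.domain)} {nd.x:g} {nd.y:g} {nd.z:g} "
            f"{nd.radius:g} {pid}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sections
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """Unbranched stretch between bifurcation points (or root / leaf).

    ``point_ids`` partition the point tree: every point belongs to
    exactly one section.  For geometry each non-root section is anchored
    at its first point's parent, so connection gaps count toward length.
    A single-point soma is treated as a sphere (L = diam).
    """

    idx: int
    domain: str
    point_ids: list[int]
    parent: int | None = None  # section index
    children: list[int] = field(default_factory=list)
    nseg: int = 1

    # filled by SectionTree
    _arc: np.ndarray | None = None    # cumulative arclength at profile knots
    _radii: np.ndarray | None = None  # radius at profile knots

    @property
    def is_spherical(self) -> bool:
        return self.domain == "soma" and len(self.point_ids) == 1

    @property
    def length(self) -> float:
        return float(self._arc[-1])

    def radius_at(self, x: float) -> float:
        """Radius (µm) at relative arclength position x in [0, 1]."""
        return float(np.interp(x * self._arc[-1], self._arc, self._radii))

    def lateral_area(self) -> float:
        if self.is_spherical:
            return 4.0 * math.pi * self._radii[0] ** 2
        total = 0.0
        for i in range(len(self._arc) - 1):
            total += frustum_area(
                self._radii[i], self._radii[i + 1], self._arc[i + 1] - self._arc[i]
            )
        return total


def frustum_area(r1: float, r2: float, h: float) -> float:
    """Lateral surface of a conical frustum with axial length h (µm²)."""
    slant = math.sqrt(h * h + (r2 - r1) ** 2)
    return math.pi * (r1 + r2) * slant


class SectionTree:
    """Sections of one morphology, cross-linked to its point tree."""

    def __init__(self, ptree: PointTree, sections: list[Section]):
        self.ptree = ptree
        self.sections = sections
        self.point_section = {}
        for sec in sections:
            for pid in sec.point_ids:
                self.point_section[pid] = sec.idx
        for sec in sections:
            self._build_profile(sec)

    def _build_profile(self, sec: Section) -> None:
        nodes = self.ptree.nodes
        pts = [nodes[i] for i in sec.point_ids]
        if sec.is_spherical:
            sec._arc = np.array([0.0, 2.0 * pts[0].radius])
            sec._radii = np.array([pts[0].radius, pts[0].radius])
            return
        anchor_idx = nodes[sec.point_ids[0]].parent
        knots: list[tuple[float, float]] = []
        if anchor_idx is not None:
            anchor = nodes[anchor_idx]
            # dendrites attached to the soma keep their own calibre
            r = pts[0].radius if anchor.domain != sec.domain else anchor.radius
            knots.append((0.0, r))
            prev = anchor.coords()
            arc = 0.0
        else:
            knots.append((0.0, pts[0].radius))
            prev = pts[0].coords()
            arc = 0.0
            pts = pts[1:]
        for p in pts:
            arc += float(np.linalg.norm(p.coords() - prev))
            knots.append((arc, p.radius))
            prev = p.coords()
        # collapse duplicate arclengths (zero-length edges); the later
        # point wins, so a repeated junction point sets the calibre
        dedup: list[tuple[float, float]] = []
        for arc_k, r_k in knots:
            if dedup and arc_k == dedup[-1][0]:
                dedup[-1] = (arc_k, r_k)
            else:
                dedup.append((arc_k, r_k))
        if len(dedup) == 1:
            dedup.append((dedup[0][0], dedup[0][1]))
        sec._arc = np.array([k[0] for k in dedup])
        sec._radii = np.array([k[1] for k in dedup])

    @property
    def root(self) -> Section:
        return self.sections[0]

    def section_of_point(self, pid: int) -> Section:
        return self.sections[self.point_section[pid]]

    def path_distance_to_start(self, sec: Section) -> float:
        """Path distance (µm) from the tree root to a section's 0-end."""
        first = self.ptree.nodes[sec.point_ids[0]]
        if first.parent is None:
            return 0.0
        # anchored sections start at the parent (branch) point
        return self.ptree.path_distance(first.parent)

    def total_length(self) -> float:
        return sum(s.length for s in self.sections)


def split_to_sections(ptree: PointTree) -> SectionTree:
    """Partition a point tree into unbranched sections.

    Boundaries fall at the root, at bifurcation points (the branch point
    is the *last* point of its section), and at domain changes.
    """
    cm = ptree.children_map()
    sections: list[Section] = []
    root = ptree.root.idx
    # iterative traversal (deep trees would overflow recursion)
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        start, parent_sec = stack.pop()
        domain = ptree.nodes[start].domain
        pids = [start]
        cur = start
        while True:
            kids = cm[cur]
            if len(kids) != 1:
                break
            nxt = kids[0]
            if ptree.nodes[nxt].domain != domain:
                break
            pids.append(nxt)
            cur = nxt
        sec = Section(len(sections), domain, pids, parent=parent_sec)
        sections.append(sec)
        if parent_sec is not None:
            sections[parent_sec].children.append(sec.idx)
        for k in reversed(cm[cur]):
            if k not in pids:
                stack.append((k, sec.idx))
    return SectionTree(ptree, sections)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

def segment_centers(nseg: int) -> list[float]:
    """Relative centers (2i-1)/(2*nseg), i = 1..nseg, of a section's segments."""
    if nseg < 1 or nseg % 2 == 0:
        raise ValueError(f"nseg must be a positive odd integer, got {nseg}")
    return [(2 * i - 1) / (2 * nseg) for i in range(1, nseg + 1)]


def lambda_f(
    diam: float, f: float = 100.0, Ra: float = 150.0, cm: float = 1.0
) -> float:
    """AC length constant (µm) at frequency f (Hz).

    diam in µm, Ra in Ω·cm, cm in µF/cm²; the 1e5 factor reconciles the
    mixed units to micrometres.
    """
    if diam <= 0 or Ra <= 0 or cm <= 0 or f <= 0:
        raise ValueError("diam, f, Ra, cm must be positive")
    return 1e5 * math.sqrt(diam / (4.0 * math.pi * f * Ra * cm))


def nseg_from_dlambda(
    length: float,
    diam: float,
    d_lambda: float = 0.1,
    f: float = 100.0,
    Ra: float = 150.0,
    cm: float = 1.0,
) -> int:
    """Odd segment count so each segment is at most ~d_lambda·λ_f long."""
    if length <= 0:
        raise ValueError("section length must be positive")
    if not (0 < d_lambda <= 1):
        raise ValueError("d_lambda must lie in (0, 1]")
    lam = lambda_f(diam, f, Ra, cm)
    return int((length / (d_lambda * lam) + 0.9) / 2) * 2 + 1


@dataclass
class Segment:
    """One equal-arclength subdivision of a section: one RC compartment."""

    idx: int
    section: Section
    x: float          # relative center position in (0, 1)
    length: float     # µm
    diam: float       # µm, interpolated at center
    area: float       # µm², lateral (sphere area for spherical soma)
    parent: int | None  # segment index

    @property
    def domain(self) -> str:
        return self.section.domain


class SegmentTree:
    """All segments of a discretized morphology, in elimination order."""

    def __init__(self, sectree: SectionTree):
        self.sectree = sectree
        self.segments: list[Segment] = []
        self.section_segments: dict[int, list[int]] = {}
        self._build()

    def _build(self) -> None:
        sec_last: dict[int, int] = {}   # section idx -> its last segment idx
        for sec in self.sectree.sections:
            segs = []
            if sec.is_spherical:
                r = sec._radii[0]
                parent = None if sec.parent is None else sec_last[sec.parent]
                seg = Segment(
                    len(self.segments), sec, 0.5, 2 * r, 2 * r,
                    4 * math.pi * r * r, parent,
                )
                self.segments.append(seg)
                segs.append(seg.idx)
            else:
                L = sec.length
                n = sec.nseg
                prev = None if sec.parent is None else sec_last[sec.parent]
                for i, xc in enumerate(segment_centers(n)):
                    lo, hi = i / n, (i + 1) / n
                    seg = Segment(
                        len(self.segments), sec, xc, L / n,
                        2.0 * sec.radius_at(xc),
                        self._arc_area(sec, lo, hi),
                        prev,
                    )
                    self.segments.append(seg)
                    segs.append(seg.idx)
                    prev = seg.idx
            self.section_segments[sec.idx] = segs
            sec_last[sec.idx] = segs[-1]

    @staticmethod
    def _arc_area(sec: Section, lo: float, hi: float) -> float:
        """Lateral area of a section's [lo, hi] relative-arclength slice."""
        L = sec.length
        a, b = lo * L, hi * L
        knots = [a] + [t for t in sec._arc if a < t < b] + [b]
        total = 0.0
        for t0, t1 in zip(knots[:-1], knots[1:]):
            r0 = float(np.interp(t0, sec._arc, sec._radii))
            r1 = float(np.interp(t1, sec._arc, sec._radii))
            total += frustum_area(r0, r1, t1 - t0)
        return total

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def path_distance(self, seg: Segment, origin: str = "root") -> float:
        """Path distance (µm) from the origin to a segment's center.

        origin='root' measures from the tree root; 'domain' measures from
        the first entry into the segment's domain along its path.
        """
        sec = seg.section
        d = self.sectree.path_distance_to_start(sec) + seg.x * (
            0.0 if sec.is_spherical else sec.length
        )
        if origin == "root":
            return d
        if origin == "domain":
            return d - self._domain_start_distance(sec)
        raise ValueError(f"unknown origin {origin!r}")

    def _domain_start_distance(self, sec: Section) -> float:
        """Distance from root to where this section's domain begins."""
        cur = sec
        while (
            cur.parent is not None
            and self.sectree.sections[cur.parent].domain == sec.domain
        ):
            cur = self.sectree.sections[cur.parent]
        return self.sectree.path_distance_to_start(cur)

    def domain_max_distance(self, seg: Segment) -> float:
        """Max path length within the segment's domain sub-tree (for
        relative-distance normalization, per root stem of the domain)."""
        sec = seg.section
        top = sec
        while (
            top.parent is not None
            and self.sectree.sections[top.parent].domain == sec.domain
        ):
            top = self.sectree.sections[top.parent]
        start = self.sectree.path_distance_to_start(top)
        best = 0.0
        stack = [top.idx]
        while stack:
            i = stack.pop()
            s = self.sectree.sections[i]
            if s.domain != sec.domain:
                continue
            end = self.sectree.path_distance_to_start(s) + (
                0.0 if s.is_spherical else s.length
            )
            best = max(best, end - start)
            stack.extend(s.children)
        return best

    def relative_distance(self, seg: Segment) -> float:
        """Relative distance in [0, 1] within the segment's domain."""
        denom = self.domain_max_distance(seg)
        if denom == 0:
            return 0.0
        return self.path_distance(seg, origin="domain") / denom


def build_segments(
    sectree: SectionTree,
    nseg: int | None = None,
    d_lambda: float | None = None,
    f: float = 100.0,
    Ra: float = 150.0,
    cm: float = 1.0,
) -> SegmentTree:
    """Assign per-section nseg (fixed or by the d_lambda rule) and segment."""
    for sec in sectree.sections:
        if sec.is_spherical:
            sec.nseg = 1
        elif d_lambda is not None:
            diam = 2.0 * sec.radius_at(0.5)
            sec.nseg = nseg_from_dlambda(sec.length, diam, d_lambda, f, Ra, cm)
        elif nseg is not None:
            if nseg < 1 or nseg % 2 == 0:
                raise ValueError("nseg must be a positive odd integer")
            sec.nseg = nseg
        else:
            sec.nseg = 1
    return SegmentTree(sectree)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

@dataclass
class MorphometricSummary:
    n_sections: int
    n_segments: int
    n_bifurcations: int
    n_roots: int
    n_leaves: int
    mean_diam: float
    mean_length: float
    mean_area: float
    total_area: float
    total_length: float


def morphometrics(
    stree: SegmentTree, selection: Iterable[Segment] | None = None
) -> MorphometricSummary:
    """Summary statistics over a segment selection.

    Counts of roots, leaves, and bifurcations refer to the whole tree;
    the remaining statistics are scoped to the selection.
    """
    segs = list(selection) if selection is not None else list(stree.segments)
    sections = {s.section.idx for s in segs}
    n_bif = sum(1 for sec in stree.sectree.sections if len(sec.children) >= 2)
    n_leaves = sum(1 for sec in stree.sectree.sections if not sec.children)
    if segs:
        diams = np.array([s.diam for s in segs])
        lengths = np.array([s.length for s in segs])
        areas = np.array([s.area for s in segs])
        means = (float(diams.mean()), float(lengths.mean()), float(areas.mean()))
        totals = (float(areas.sum()), float(lengths.sum()))
    else:
        means = (0.0, 0.0, 0.0)
        totals = (0.0, 0.0)
    return MorphometricSummary(
        n_sections=len(sections),
        n_segments=len(segs),
        n_bifurcations=n_bif,
        n_roots=1,
        n_leaves=n_leaves,
        mean_diam=means[0],
        mean_length=means[1],
        mean_area=means[2],
        total_area=totals[0],
        total_length=totals[1],
    )
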