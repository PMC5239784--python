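"""Clonal clustering and lineage-tree assembly.

Sequences are first coarsely grouped by CDR3 length and V/J gene family
number, then linked within each group by a nearest-distance rule under an
asymmetric SHM distance.  The distance resembles a Hamming distance with
two adjustments: a run of M consecutive mismatches adds M^2 (penalizing
junction differences between unrelated clones), and each individual
mismatch is adjusted by how common the implied mutation is under somatic
hypermutation — favored AID/strand-bias mutations (C>T, G>A, A>G, A>T)
subtract 0.5, mildly common ones (T>C, A>C) add nothing, and all rarer
mutations add 0.5.  The asymmetry orients parent-child edges.

The nearest-neighbor linkage graph has one cycle per connected component
(the root is not yet known); the cycle member with the smallest total SHM
distance to the rest of the component becomes the root.  Roots of small
trees are then iteratively attached to sequences of other trees whenever
the attachment distance stays within a cutoff (3% of the sequence length
by default), annotations are unified to the root's, and the tree is
rerooted if another member sits closer to the predicted germline.
"""

from __future__ import annotations

import copy

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import encode
from .annotate import Annotation, germline_read, recount_mismatches
from .germline import GermlineDatabase, family_number

FAVORED_MUTATIONS = {("C", "T"), ("G", "A"), ("A", "G"), ("A", "T")}
NEUTRAL_MUTATIONS = {("T", "C"), ("A", "C")}


@dataclass(frozen=True)
class ShmDistanceParams:
    favored_weight: float = -0.5
    neutral_weight: float = 0.0
    other_weight: float = 0.5
    favored: frozenset = frozenset(FAVORED_MUTATIONS)
    neutral: frozenset = frozenset(NEUTRAL_MUTATIONS)


DEFAULT_SHM_PARAMS = ShmDistanceParams()


def shm_distance(parent_seq: str, child_seq: str,
                 params: ShmDistanceParams = DEFAULT_SHM_PARAMS) -> float:
    """Asymmetric SHM distance from a parent sequence to a child sequence."""
    if len(parent_seq) != len(child_seq):
        raise ValueError("sequences must have equal length")
    p = encode(parent_seq)
    c = encode(child_seq)
    mm = p != c
    if not mm.any():
        return 0.0
    dist = 0.0
    idx = np.flatnonzero(mm)
    run_start = idx[0]
    prev = idx[0]
    for i in list(idx[1:]) + [None]:
        if i is None or i != prev + 1:
            run = prev - run_start + 1
            dist += run * run
            if i is not None:
                run_start = i
        prev = i if i is not None else prev
    for i in idx:
        pair = (parent_seq[i], child_seq[i])
        if pair in params.favored:
            dist += params.favored_weight
        elif pair in params.neutral:
            dist += params.neutral_weight
        else:
            dist += params.other_weight
    return dist


@dataclass
class Member:
    """One unique sequence entering the clustering stage.

    ``annotation`` is the working copy mutated by unification;
    ``original`` preserves the member's own Step-1 annotation so a later
    root change can adopt the new root's own gene calls.
    """

    id: str
    annotation: Annotation
    template_count: int = 1
    original: Annotation = None

    def __post_init__(self):
        if self.original is None:
            self.original = copy.deepcopy(self.annotation)

    @property
    def sequence(self) -> str:
        return self.annotation.sequence


def coarse_group(members: list[Member]):
    """Partition by (CDR3 length, V family number, J family number).

    Members with no CDR3 call land in the ``None`` reject group.
    """
    groups: dict = {}
    for m in members:
        ann = m.annotation
        if not ann.ok or ann.cdr3_span is None:
            groups.setdefault(None, []).append(m)
            continue
        key = (ann.cdr3_span.length, family_number(ann.v_name),
               family_number(ann.j_name))
        groups.setdefault(key, []).append(m)
    return groups


@dataclass
class LineageTree:
    """Rooted multifurcating tree over unique sequences.

    ``parent`` maps child id -> (parent id, SHM distance of the edge).
    """

    members: dict  # id -> Member
    root: str
    parent: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return sorted(self.members)

    def children(self, node: str) -> list[str]:
        return sorted(i for i, (p, _) in self.parent.items() if p == node)

    def n_descendants(self, node: str) -> int:
        total = 0
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                total += 1
                stack.append(c)
        return total

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((p, c, d) for c, (p, d) in self.parent.items())


def _anchored_distance(parent_seq: str, child_seq: str, params) -> float:
    """SHM distance over the common 3'-anchored span.

    Reads end on the conserved 118Trp codon, so unequal-length sequences
    (e.g. after an indel correction) are compared over their common
    suffix.
    """
    n = min(len(parent_seq), len(child_seq))
    return shm_distance(parent_seq[-n:], child_seq[-n:], params)


def _pairwise(members: list[Member], params) -> np.ndarray:
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = _anchored_distance(members[i].sequence,
                                             members[j].sequence, params)
    return d


def _orient(members, adjacency, root_idx, dist) -> LineageTree:
    """Breadth-first orientation of an undirected linkage away from the root."""
    ids = [m.id for m in members]
    tree = LineageTree(members={m.id: m for m in members}, root=ids[root_idx])
    seen = {root_idx}
    frontier = [root_idx]
    while frontier:
        nxt = []
        for u in sorted(frontier):
            for v in sorted(adjacency[u]):
                if v not in seen:
                    seen.add(v)
                    tree.parent[ids[v]] = (ids[u], float(dist[u, v]))
                    nxt.append(v)
        frontier = nxt
    return tree


def build_forest(members: list[Member],
                 params: ShmDistanceParams = DEFAULT_SHM_PARAMS) -> list[LineageTree]:
    """Nearest-distance linkage within one coarse group.

    Each sequence links to its nearest neighbor (proximity = smaller of
    the two directed distances; ties broken by higher template count then
    id).  The directed nearest-neighbor map has exactly one cycle per
    component; the cycle member with the smallest total SHM distance to
    the rest of the component becomes the root, ties broken by the
    highest VDJ alignment score.
    """
    if len(members) == 1:
        return [LineageTree(members={members[0].id: members[0]}, root=members[0].id)]
    members = sorted(members, key=lambda m: m.id)
    n = len(members)
    d = _pairwise(members, params)
    prox = np.minimum(d, d.T)

    nn = np.empty(n, dtype=int)
    for i in range(n):
        cands = [(prox[i, j], -members[j].template_count, members[j].id, j)
                 for j in range(n) if j != i]
        nn[i] = min(cands)[3]

    adjacency = {i: set() for i in range(n)}
    for i in range(n):
        adjacency[i].add(nn[i])
        adjacency[nn[i]].add(i)

    comp = np.full(n, -1)
    ncomp = 0
    for i in range(n):
        if comp[i] < 0:
            stack = [i]
            while stack:
                u = stack.pop()
                if comp[u] < 0:
                    comp[u] = ncomp
                    stack.extend(adjacency[u])
            ncomp += 1

    trees = []
    for c in range(ncomp):
        nodes = [i for i in range(n) if comp[i] == c]
        # the functional graph i -> nn[i] restricted to this component has
        # exactly one cycle; walk from any node until a repeat
        seen_order = []
        seen = set()
        u = nodes[0]
        while u not in seen:
            seen.add(u)
            seen_order.append(u)
            u = nn[u]
        cycle = seen_order[seen_order.index(u):]
        best = min(cycle, key=lambda i: (d[i, nodes].sum(),
                                         -members[i].annotation.total_score,
                                         members[i].id))
        sub_adj = {i: adjacency[i] & set(nodes) for i in nodes}
        trees.append(_orient(members, sub_adj, best, d))
    return trees


def merge_clusters(trees: list[LineageTree], cutoff_fraction: float = 0.03,
                   params: ShmDistanceParams = DEFAULT_SHM_PARAMS) -> list[LineageTree]:
    """Iteratively attach roots of small trees to sequences of other trees.

    A root joins another tree (becoming a child of its nearest sequence
    there) whenever the parent-to-root SHM distance is at most
    ``cutoff_fraction`` times the sequence length.  Merges are processed
    in ascending best-merge distance, ties by root id, until none apply.
    """
    trees = list(trees)
    while len(trees) > 1:
        candidates = []
        for ti, t in enumerate(trees):
            root_seq = t.members[t.root].sequence
            cutoff = cutoff_fraction * len(root_seq)
            best = None
            for tj, other in enumerate(trees):
                if tj == ti:
                    continue
                for mid in other.ids:
                    seq = other.members[mid].sequence
                    dist = _anchored_distance(seq, root_seq, params)
                    if dist <= cutoff and (best is None or (dist, mid) < best[:2]):
                        best = (dist, mid, tj)
            if best is not None:
                candidates.append((best[0], t.root, ti, best[1], best[2]))
        if not candidates:
            break
        dist, root_id, ti, parent_id, tj = min(candidates)
        src, dst = trees[ti], trees[tj]
        dst.members.update(src.members)
        dst.parent.update(src.parent)
        dst.parent[root_id] = (parent_id, dist)
        trees.pop(ti)
    return trees


@dataclass
class CloneCluster:
    """A lineage tree plus the unified annotation of its root.

    After unification every member carries the root's V/D/J names and
    segment demarcations; ``germline_guess`` is the predicted unmutated
    sequence (germline V/D/J bases with the root's N-region bases) and
    ``member_mismatches`` maps member id -> per-segment mismatch positions
    against that germline.
    """

    tree: LineageTree
    annotation: Optional[Annotation] = None
    germline_guess: Optional[str] = None
    member_mismatches: dict = field(default_factory=dict)

    @property
    def root(self) -> str:
        return self.tree.root

    @property
    def ids(self) -> list[str]:
        return self.tree.ids

    def member(self, mid: str) -> Member:
        return self.tree.members[mid]

    def germline_mismatch_count(self, mid: str) -> int:
        return sum(len(v) for v in self.member_mismatches[mid].values())


def unify_annotations(cluster: CloneCluster, db: GermlineDatabase,
                      reset: bool = False) -> CloneCluster:
    """Apply the root's annotation cluster-wide and recount mismatches.

    On first call (or ``reset=True`` after rerooting) the cluster adopts a
    copy of the root member's own Step-1 annotation; later calls
    propagate the current (possibly refined) cluster annotation.
    """
    if cluster.annotation is None or reset:
        root_member = cluster.tree.members[cluster.root]
        src = root_member.original if root_member.original is not None \
            else root_member.annotation
        cluster.annotation = copy.deepcopy(src)
    root_ann = cluster.annotation
    cluster.germline_guess = germline_read(root_ann, db)
    cluster.member_mismatches = {}
    for mid in cluster.ids:
        member = cluster.tree.members[mid]
        ann = member.annotation
        ann.v_name, ann.d_name, ann.j_name = (root_ann.v_name, root_ann.d_name,
                                              root_ann.j_name)
        ann.v_span, ann.nvd_span, ann.d_span = (root_ann.v_span, root_ann.nvd_span,
                                                root_ann.d_span)
        ann.ndj_span, ann.j_span = root_ann.ndj_span, root_ann.j_span
        ann.v_gene_span, ann.d_gene_span, ann.j_gene_span = (
            root_ann.v_gene_span, root_ann.d_gene_span, root_ann.j_gene_span)
        ann.cdr3_span = root_ann.cdr3_span
        if ann.cdr3_span is not None:
            ann.cdr3_seq = ann.cdr3_span.extract(ann.sequence)
        from .annotate import NRegion
        if root_ann.nvd_span is not None:
            ann.n_vd = NRegion(root_ann.nvd_span.extract(ann.sequence), "VD")
        if root_ann.ndj_span is not None:
            ann.n_dj = NRegion(root_ann.ndj_span.extract(ann.sequence), "DJ")
        mism = recount_mismatches(ann, cluster.germline_guess)
        ann.mismatches = mism
        cluster.member_mismatches[mid] = mism
    return cluster


def reroot_cluster(cluster: CloneCluster, db: GermlineDatabase) -> CloneCluster:
    """Reroot on the member closest to the predicted germline.

    A non-root member becomes the root only if it has strictly fewer raw
    germline mismatches (ties keep the current root); edges are then
    re-oriented away from the new root with recomputed directed distances.
    """
    counts = {mid: cluster.germline_mismatch_count(mid) for mid in cluster.ids}
    best = min(cluster.ids, key=lambda m: (counts[m], m != cluster.root, m))
    if best == cluster.root or counts[best] >= counts[cluster.root]:
        return cluster
    tree = cluster.tree
    adjacency = {mid: set() for mid in tree.ids}
    for child, (par, _) in tree.parent.items():
        adjacency[child].add(par)
        adjacency[par].add(child)
    new = LineageTree(members=tree.members, root=best)
    seen = {best}
    frontier = [best]
    while frontier:
        nxt = []
        for u in sorted(frontier):
            for v in sorted(adjacency[u]):
                if v not in seen:
                    seen.add(v)
                    d = _anchored_distance(tree.members[u].sequence,
                                           tree.members[v].sequence, DEFAULT_SHM_PARAMS)
                    new.parent[v] = (u, d)
                    nxt.append(v)
        frontier = nxt
    cluster.tree = new
    return unify_annotations(cluster, db, reset=True)
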