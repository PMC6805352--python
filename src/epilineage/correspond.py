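"""Cross-embryo corresponding-cell identification and consensus trees.

The matcher follows the recursive procedure used for the tracked embryos:
starting from manually assigned root pairs, each matched division is
compared through per-daughter features (relative daughter position, the
daughters' subsequent cell-cycle lengths, and their descendant counts
within a horizon), combined by weighting coefficients into a similarity
score; the best-scoring daughter assignment re-roots the recursion.

Because recordings end (~34 hpf) while divisions keep occurring, embryos
are compared at ``t_compare`` (default 30 hpf) and the remaining frames up
to ``t_compare + guard`` serve as "known divisions to come": a division
present in one embryo and absent from the other within the guard window is
a real difference; one that cannot be ruled out because the recording ends
first is censored, never a difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lineage_core import LineageError, LineageTree, LineageName

__all__ = [
    "FeatureWeights", "DivisionFeatures", "RigidTransform", "register_frames",
    "division_features", "pairing_similarity", "CorrespondenceMap",
    "match_lineages", "DifferenceEntry", "DifferenceReport",
    "count_differences", "difference_report", "ConsensusNode", "ConsensusTree",
    "build_consensus", "max_timing_asynchrony",
]


# ---------------------------------------------------------------------------
# Features and similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureWeights:
    """Weights of the three feature families and the cycle-length scale."""
    w_pos: float = 1.0
    w_cycle: float = 1.0
    w_desc: float = 1.0
    tau_cycle: float = 2.0  # hours

    def __post_init__(self):
        if self.w_pos < 0 or self.w_cycle < 0 or self.w_desc < 0:
            raise LineageError("feature weights must be non-negative")
        if self.w_pos + self.w_cycle + self.w_desc <= 0:
            raise LineageError("at least one feature weight must be positive")


@dataclass
class DivisionFeatures:
    """Per-daughter features of one division (daughter order = uid order)."""
    daughter_offsets: tuple[np.ndarray, np.ndarray]   # unit vectors
    cycle_lengths: tuple[float, float]                # hours (or lower bound)
    cycle_censored: tuple[bool, bool]
    descendant_counts: tuple[int, int]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the apical (z) axis aligning one embryo onto another."""
    angle_deg: float

    @property
    def matrix(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T


def register_frames(tree_a: LineageTree, tree_b: LineageTree,
                    method: str = "auto") -> RigidTransform:
    """Rotation about z mapping tree_b coordinates into tree_a's frame.

    With frame metadata on both trees, the dorsal azimuths are aligned
    directly; otherwise at least 3 named landmark cells present in both
    trees are used in a least-squares planar orthogonal fit.
    """
    have_meta = ("dorsal_azimuth_deg" in tree_a.frame
                 and "dorsal_azimuth_deg" in tree_b.frame)
    if method == "metadata" or (method == "auto" and have_meta):
        if not have_meta:
            raise LineageError("frame metadata missing for registration")
        return RigidTransform(float(tree_a.frame["dorsal_azimuth_deg"])
                              - float(tree_b.frame["dorsal_azimuth_deg"]))
    names_a = {n.name.render(): uid for uid, n in tree_a.nodes.items() if n.name}
    names_b = {n.name.render(): uid for uid, n in tree_b.nodes.items() if n.name}
    common = sorted(set(names_a) & set(names_b))
    if len(common) < 3:
        raise LineageError(
            f"need >=3 shared landmark cells, found {len(common)}")
    acc = 0j
    for nm in common:
        pa = np.array(tree_a.nodes[names_a[nm]].positions[0][1:4])
        pb = np.array(tree_b.nodes[names_b[nm]].positions[0][1:4])
        acc += complex(pa[0], pa[1]) * complex(pb[0], pb[1]).conjugate()
    return RigidTransform(math.degrees(np.angle(acc)))


def division_features(tree: LineageTree, uid: str, horizon: float,
                      offset_window: float = 1.0) -> DivisionFeatures:
    """Features of a division: daughter offsets, cycles, descendant counts.

    Daughter offsets are computed from positions averaged over
    ``offset_window`` hours around the division (robust to per-timepoint
    noise); cycles of daughters that never divide within the recording are
    censored with the observed lower bound; descendant counts include only
    cells born before ``horizon``.
    """
    node = tree.nodes[uid]
    if node.end_fate != "divided":
        raise LineageError(f"cell {uid} did not divide")
    if horizon < node.end_time:
        raise LineageError("horizon precedes the division")
    kids = tree.children(uid)
    m_pts = np.array([p[1:4] for p in node.positions
                      if p[0] >= node.end_time - offset_window])
    if m_pts.size == 0:
        m_pts = np.array([node.positions[-1][1:4]])
    mother_pos = m_pts.mean(axis=0)
    offsets, cycles, censored, counts = [], [], [], []
    for k in kids:
        d = tree.nodes[k]
        pts = np.array([p[1:4] for p in d.positions
                        if p[0] <= d.birth_time + offset_window])
        if pts.size == 0:
            pts = np.array([d.positions[0][1:4]])
        off = pts.mean(axis=0) - mother_pos
        n = np.linalg.norm(off)
        offsets.append(off / n if n > 1e-12 else np.array([0.0, 0.0, 1.0]))
        if d.end_fate == "divided":
            cycles.append(d.end_time - d.birth_time)
            censored.append(False)
        else:
            cycles.append(d.end_time - d.birth_time)
            censored.append(True)
        counts.append(sum(1 for x in tree.descendants(k)
                          if tree.nodes[x].birth_time <= horizon))
    return DivisionFeatures(daughter_offsets=tuple(offsets),
                            cycle_lengths=tuple(cycles),
                            cycle_censored=tuple(censored),
                            descendant_counts=tuple(counts))


def _cycle_kernel(c1, cens1, c2, cens2, tau):
    if not cens1 and not cens2:
        return math.exp(-abs(c1 - c2) / tau)
    if cens1 and cens2:
        return 1.0
    bound, obs = (c1, c2) if cens1 else (c2, c1)
    return math.exp(-max(0.0, bound - obs) / tau)


def pairing_similarity(fa: DivisionFeatures, fb: DivisionFeatures,
                       w: FeatureWeights | None = None,
                       transform_b: RigidTransform | None = None
                       ) -> tuple[float, str]:
    """Similarity of two divisions under the best daughter assignment.

    Score in [0, 1]; 1.0 for identical features.  Returns the score and the
    chosen pairing ("straight": daughter 1<->1, or "swapped").  Exact ties
    are broken toward the assignment with smaller summed angular distance
    between paired offsets, then toward the straight pairing.
    """
    w = w or FeatureWeights()
    offs_b = fb.daughter_offsets
    if transform_b is not None:
        offs_b = tuple(transform_b.apply(o) for o in offs_b)

    def one(assign):
        s_pos = s_cyc = s_desc = 0.0
        ang = 0.0
        for i, j in assign:
            cos = float(np.clip(np.dot(fa.daughter_offsets[i], offs_b[j]), -1, 1))
            s_pos += (1.0 + cos) / 2.0
            ang += math.acos(cos)
            s_cyc += _cycle_kernel(fa.cycle_lengths[i], fa.cycle_censored[i],
                                   fb.cycle_lengths[j], fb.cycle_censored[j],
                                   w.tau_cycle)
            n1, n2 = fa.descendant_counts[i], fb.descendant_counts[j]
            s_desc += 1.0 - abs(n1 - n2) / max(n1, n2, 1)
        score = (w.w_pos * s_pos + w.w_cycle * s_cyc + w.w_desc * s_desc) \
            / (2.0 * (w.w_pos + w.w_cycle + w.w_desc))
        return score, ang

    s_str, ang_str = one(((0, 0), (1, 1)))
    s_swp, ang_swp = one(((0, 1), (1, 0)))
    if abs(s_str - s_swp) < 1e-12:
        if ang_swp < ang_str - 1e-12:
            return s_swp, "swapped"
        return s_str, "straight"
    return (s_str, "straight") if s_str > s_swp else (s_swp, "swapped")


# ---------------------------------------------------------------------------
# Recursive matching
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceMap:
    embryo_a: str
    embryo_b: str
    t_compare: float
    guard: float
    pairs: dict[str, tuple[str, float, str]] = field(default_factory=dict)
    unmatched_a: dict[str, str] = field(default_factory=dict)  # uid -> reason
    unmatched_b: dict[str, str] = field(default_factory=dict)

    @property
    def pairs_ba(self) -> dict[str, str]:
        return {v[0]: u for u, v in self.pairs.items()}

    def real_differences(self, side: str) -> set[str]:
        d = self.unmatched_a if side == "a" else self.unmatched_b
        return {u for u, r in d.items() if r == "real_difference"}

    def to_dict(self) -> dict:
        return {
            "schema": "epilineage.map/1",
            "embryo_a": self.embryo_a, "embryo_b": self.embryo_b,
            "t_compare": self.t_compare, "guard": self.guard,
            "pairs": {u: {"b": v[0], "score": v[1], "pairing": v[2]}
                      for u, v in self.pairs.items()},
            "unmatched_a": self.unmatched_a, "unmatched_b": self.unmatched_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrespondenceMap":
        m = cls(d["embryo_a"], d["embryo_b"], d["t_compare"], d["guard"])
        m.pairs = {u: (v["b"], v["score"], v["pairing"])
                   for u, v in d["pairs"].items()}
        m.unmatched_a = dict(d["unmatched_a"])
        m.unmatched_b = dict(d["unmatched_b"])
        return m


def match_lineages(tree_a: LineageTree, tree_b: LineageTree,
                   root_pairs: list[tuple[str, str]],
                   t_compare: float = 30.0, guard: float = 3.0,
                   weights: FeatureWeights | None = None,
                   transform_b: RigidTransform | None = None
                   ) -> CorrespondenceMap:
    """Recursive greedy corresponding-cell assignment between two embryos."""
    for ua, ub in root_pairs:
        if ua not in tree_a.nodes:
            raise LineageError(f"root {ua} absent from {tree_a.embryo_id}")
        if ub not in tree_b.nodes:
            raise LineageError(f"root {ub} absent from {tree_b.embryo_id}")
    w = weights or FeatureWeights()
    horizon = t_compare + guard
    end_a, end_b = tree_a.recording_window[1], tree_b.recording_window[1]
    cmap = CorrespondenceMap(tree_a.embryo_id, tree_b.embryo_id,
                             t_compare, guard)

    def flag_subtree(tree, store, uids, reason):
        for u in uids:
            for x in [u] + tree.descendants(u):
                store.setdefault(x, reason)

    stack: list[tuple[str, str, float]] = [(ua, ub, 1.0) for ua, ub in root_pairs]
    while stack:
        ua, ub, score = stack.pop()
        cmap.pairs[ua] = (ub, score, "straight")
        na, nb = tree_a.nodes[ua], tree_b.nodes[ub]
        da, db = na.end_fate == "divided", nb.end_fate == "divided"
        if da and db:
            ta, tb = na.end_time, nb.end_time
            if min(ta, tb) < t_compare and max(ta, tb) > horizon:
                early_a = ta < tb
                if early_a:
                    flag_subtree(tree_a, cmap.unmatched_a, tree_a.children(ua),
                                 "real_difference")
                    flag_subtree(tree_b, cmap.unmatched_b, tree_b.children(ub),
                                 "censored")
                else:
                    flag_subtree(tree_b, cmap.unmatched_b, tree_b.children(ub),
                                 "real_difference")
                    flag_subtree(tree_a, cmap.unmatched_a, tree_a.children(ua),
                                 "censored")
                continue
            fa = division_features(tree_a, ua, max(horizon, ta))
            fb = division_features(tree_b, ub, max(horizon, tb))
            s, pairing = pairing_similarity(fa, fb, w, transform_b)
            kids_a, kids_b = tree_a.children(ua), tree_b.children(ub)
            if pairing == "swapped":
                kids_b = [kids_b[1], kids_b[0]]
            cmap.pairs[ua] = (ub, score, pairing)
            stack.append((kids_a[0], kids_b[0], s))
            stack.append((kids_a[1], kids_b[1], s))
        elif da or db:
            tree_u, tree_v = (tree_a, tree_b) if da else (tree_b, tree_a)
            store_u = cmap.unmatched_a if da else cmap.unmatched_b
            store_v = cmap.unmatched_b if da else cmap.unmatched_a
            node_u = na if da else nb
            node_v = nb if da else na
            uid_u = ua if da else ub
            end_v = end_b if da else end_a
            tu = node_u.end_time
            if tu >= t_compare:
                reason = "censored"
            elif node_v.end_fate in ("terminal", "apoptotic", "migrated_out") \
                    or end_v >= horizon:
                # the guard window was fully observed (or the cell visibly
                # differentiated / left) with no division: a real difference
                reason = "real_difference"
            else:
                reason = "censored"
            flag_subtree(tree_u, store_u, tree_u.children(uid_u), reason)
        # both leaves: matched terminal pair, nothing to do
    return cmap


# ---------------------------------------------------------------------------
# Difference quantification
# ---------------------------------------------------------------------------

@dataclass
class DifferenceEntry:
    time: float
    counts: dict[str, int]          # embryo id -> differing cells
    totals: dict[str, int]          # embryo id -> alive cells
    percentage: float               # 100 * sum(counts) / sum(totals)
    differing: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class DifferenceReport:
    entries: list[DifferenceEntry]

    def percentages(self) -> list[tuple[float, float]]:
        return [(e.time, e.percentage) for e in self.entries]


def _maps_by_pair(maps) -> dict[tuple[str, str], CorrespondenceMap]:
    out = {}
    for m in maps:
        out[(m.embryo_a, m.embryo_b)] = m
    return out


def _real_diff_set(maps_idx, eid: str, other: str) -> set[str]:
    if (eid, other) in maps_idx:
        return maps_idx[(eid, other)].real_differences("a")
    if (other, eid) in maps_idx:
        return maps_idx[(other, eid)].real_differences("b")
    raise LineageError(f"no correspondence map between {eid} and {other}")


def count_differences(trees: list[LineageTree], maps, t: float) -> DifferenceEntry:
    """Cells at time t that are absent from BOTH other embryos.

    A cell counts as differing for its embryo when it (or its originating
    division) is flagged as a real difference against each of the other two
    embryos; censored cells never count.
    """
    if not any(tr.recording_window[0] <= t <= tr.recording_window[1]
               for tr in trees):
        raise LineageError(f"time {t} outside every recording window")
    if len(trees) < 3:
        raise LineageError("difference counting needs a cohort of >=3 embryos")
    maps_idx = _maps_by_pair(maps)
    counts, totals, differing = {}, {}, {}
    for tr in trees:
        eid = tr.embryo_id
        others = [o.embryo_id for o in trees if o.embryo_id != eid]
        diff_sets = [_real_diff_set(maps_idx, eid, o) for o in others]
        alive = tr.alive_at(t)
        totals[eid] = len(alive)
        hits = sorted(u for u in alive if all(u in s for s in diff_sets))
        counts[eid] = len(hits)
        differing[eid] = hits
    pct = 100.0 * sum(counts.values()) / max(1, sum(totals.values()))
    return DifferenceEntry(time=t, counts=counts, totals=totals,
                           percentage=pct, differing=differing)


def difference_report(trees, maps, times) -> DifferenceReport:
    return DifferenceReport([count_differences(trees, maps, t) for t in times])


# ---------------------------------------------------------------------------
# Consensus tree
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNode:
    rid: str
    support: int                    # embryos containing the cell
    division_support: int           # embryos in which the cell divides
    t_min: float | None             # division-time range across embryos
    t_max: float | None
    name: LineageName | None
    parent: str | None
    children: tuple[str, ...] = ()
    low_support: bool = False       # originating division seen in 2 of 3 only
    members: dict[str, str] = field(default_factory=dict)  # embryo id -> uid


@dataclass
class ConsensusTree:
    cohort: tuple[str, ...]
    nodes: dict[str, ConsensusNode]
    roots: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "schema": "epilineage.consensus/1",
            "cohort": list(self.cohort),
            "roots": list(self.roots),
            "nodes": {rid: {
                "support": n.support, "division_support": n.division_support,
                "t_min": n.t_min, "t_max": n.t_max,
                "name": n.name.render() if n.name else None,
                "parent": n.parent, "children": list(n.children),
                "low_support": n.low_support, "members": n.members,
            } for rid, n in self.nodes.items()},
        }

    def to_newick(self) -> str:
        def render(rid):
            n = self.nodes[rid]
            body = (f"({','.join(render(c) for c in n.children)})"
                    if n.children else "")
            label = n.name.render() if n.name else n.rid
            length = 0.0 if n.t_min is None else n.t_min
            return f"{body}{label}_{n.rid}:{length:.4f}"
        return "\n".join(f"{render(r)};" for r in self.roots)


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _correspondence_classes(trees, maps, strict: bool = True):
    """Union-find classes of (embryo_id, uid) linked by the pairwise maps.

    A class containing two cells of the same embryo indicates mutually
    inconsistent pairings across the maps; with ``strict`` this raises,
    otherwise such classes are dropped from the result.
    """
    uf = _UnionFind()
    for tr in trees:
        for uid in tr.nodes:
            uf.find((tr.embryo_id, uid))
    for m in maps:
        for ua, (ub, _s, _p) in m.pairs.items():
            uf.union((m.embryo_a, ua), (m.embryo_b, ub))
    classes: dict = {}
    for tr in trees:
        for uid in tr.nodes:
            classes.setdefault(uf.find((tr.embryo_id, uid)), []).append(
                (tr.embryo_id, uid))
    bad = []
    for key, members in classes.items():
        eids = [e for e, _ in members]
        if len(eids) != len(set(eids)):
            if strict:
                dup = sorted(u for _e, u in members)
                raise LineageError(
                    f"inconsistent correspondences: one class contains {dup}")
            bad.append(key)
    for key in bad:
        del classes[key]
    return classes


def build_consensus(trees: list[LineageTree], maps,
                    strict: bool = True) -> ConsensusTree:
    """Merge a cohort into one tree, keeping divisions with majority support.

    ``strict`` controls how mutually inconsistent pairings across the maps
    are handled: raise (default) or silently drop the conflicting classes.
    """
    if len(trees) < 2:
        raise LineageError("consensus needs >=2 embryos")
    cohort = tuple(tr.embryo_id for tr in trees)
    need = len(trees) // 2 + 1
    by_id = {tr.embryo_id: tr for tr in trees}
    classes = _correspondence_classes(trees, maps, strict=strict)
    cls_of = {(e, u): key for key, members in classes.items()
              for e, u in members}

    def division_info(members):
        times = []
        for e, u in members:
            node = by_id[e].nodes[u]
            if node.end_fate == "divided":
                times.append(node.end_time)
        return times

    # roots: classes containing a root of the first tree
    root_keys = []
    seen = set()
    for r in sorted(by_id[cohort[0]].roots):
        k = cls_of.get((cohort[0], r))
        if k is not None and k not in seen:
            seen.add(k)
            root_keys.append(k)

    nodes: dict[str, ConsensusNode] = {}
    order: list[tuple[str, ...]] = []
    queue: list[tuple[tuple, str | None, bool]] = [(k, None, False)
                                                  for k in root_keys]
    entries = []
    while queue:
        key, parent_rid, low = queue.pop(0)
        members = classes[key]
        min_birth = min(by_id[e].nodes[u].birth_time for e, u in members)
        entries.append((key, parent_rid, low, min_birth, members))
        div_times = division_info(members)
        if len(div_times) >= need:
            child_keys: dict[tuple, list] = {}
            for e, u in members:
                node = by_id[e].nodes[u]
                if node.end_fate == "divided":
                    for c in by_id[e].children(u):
                        k2 = cls_of.get((e, c))
                        if k2 is not None:
                            child_keys.setdefault(k2, []).append((e, c))
            kids = sorted(child_keys, key=lambda k2: min(
                by_id[e].nodes[u].birth_time for e, u in classes[k2]))
            if len(kids) > 2:
                # keep the two best-supported daughter classes
                kids = sorted(kids, key=lambda k2: -len(classes[k2]))[:2]
                kids = sorted(kids, key=lambda k2: min(
                    by_id[e].nodes[u].birth_time for e, u in classes[k2]))
            for k2 in kids:
                queue.append((k2, key, len(div_times) == 2 and len(trees) == 3))

    # deterministic breadth-first birth-time rid assignment
    rid_of: dict[tuple, str] = {}
    for i, (key, _p, _l, _b, _m) in enumerate(
            sorted(entries, key=lambda x: (x[3], str(x[0]))), start=1):
        rid_of[key] = f"r{i}"
    for key, parent_key, low, _b, members in entries:
        rid = rid_of[key]
        names = {by_id[e].nodes[u].name.render()
                 for e, u in members if by_id[e].nodes[u].name}
        name = None
        if len(names) == 1:
            from .lineage_core import parse_lineage_name
            name = parse_lineage_name(next(iter(names)))
        div_times = division_info(members)
        nodes[rid] = ConsensusNode(
            rid=rid, support=len(members), division_support=len(div_times),
            t_min=min(div_times) if div_times else None,
            t_max=max(div_times) if div_times else None,
            name=name,
            parent=rid_of.get(parent_key) if parent_key is not None else None,
            low_support=low, members={e: u for e, u in members})
    def _class_birth(rid2: str) -> float:
        return min(by_id[e].nodes[u].birth_time
                   for e, u in nodes[rid2].members.items())

    for rid, n in nodes.items():
        kids = [r for r, m2 in nodes.items() if m2.parent == rid]
        n.children = tuple(sorted(kids, key=_class_birth))
    roots = tuple(rid_of[k] for k in root_keys)
    return ConsensusTree(cohort=cohort, nodes=nodes, roots=roots)


def max_timing_asynchrony(trees: list[LineageTree], maps,
                          window: tuple[float, float]) -> float | None:
    """Mean (latest - earliest) time of corresponding divisions in a window.

    Only divisions observed in every cohort member contribute; a division is
    assigned to the window by its mean time across embryos.  Returns None if
    the window contains no corresponding divisions.
    """
    by_id = {tr.embryo_id: tr for tr in trees}
    classes = _correspondence_classes(trees, maps, strict=False)
    lo, hi = window
    ranges = []
    for members in classes.values():
        if len(members) != len(trees):
            continue
        times = [by_id[e].nodes[u].end_time for e, u in members
                 if by_id[e].nodes[u].end_fate == "divided"]
        if len(times) != len(trees):
            continue
        mean_t = sum(times) / len(times)
        if lo <= mean_t <= hi:
            ranges.append(max(times) - min(times))
    return float(np.mean(ranges)) if ranges else None
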