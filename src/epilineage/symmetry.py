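"""Bilateral-founder detection, symmetry classes, and symmetry scoring.

A bilateral founder pair is two cells that (i) occupy mirror positions
across the sagittal plane, (ii) produce clones with similar lineage-tree
topology, and (iii) are born at roughly the same developmental time.
Detection keeps only the earliest qualifying generation of each clone
(otherwise every descendant pair of a founder pair would also qualify) and
assigns each cell to at most one pair.

Symmetry classes relate a pair's two lineage names: identical division
index under the A<->B/C<->D quadrant swap (the predominant left-right
homology), identical under the A<->C swap, same-quadrant origin, or
non-corresponding lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .lineage_core import LineageError, LineageTree, bilateral_partner_name

__all__ = [
    "MirrorPlane", "FounderPair", "FounderParams", "estimate_mirror_plane",
    "clone_topology_similarity", "detect_bilateral_founders",
    "classify_founder_pair", "rotational_symmetry_score",
]


@dataclass(frozen=True)
class MirrorPlane:
    """A candidate sagittal plane: contains the apical (z) axis.

    ``azimuth_deg`` is the azimuth of the plane's *normal* in the x-y plane
    (0 for the canonical plane x = 0), reduced to [0, 180).
    """
    azimuth_deg: float
    fitted: bool = False

    def normal(self) -> np.ndarray:
        a = math.radians(self.azimuth_deg)
        return np.array([math.cos(a), math.sin(a), 0.0])

    def reflect(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = self.normal()
        out = p - 2.0 * np.outer(p @ n, n)
        return out[0] if np.asarray(points).ndim == 1 else out

    def side(self, point) -> float:
        """Signed side of a point: negative = left (A/D quadrants)."""
        return float(np.dot(np.asarray(point, dtype=float), self.normal()))


@dataclass
class FounderPair:
    left_uid: str
    right_uid: str
    birth_times: tuple[float, float]
    mirror_distance: float
    topology_score: float
    symmetry_class: str
    pair_id: int | None = None


@dataclass(frozen=True)
class FounderParams:
    """Detection tolerances (the qualitative criteria made quantitative)."""
    dt_tol: float = 1.0          # hours between the pair's birth times
    mirror_eps: float = 0.10     # mirror-position tolerance, fraction of R
    topo_min: float = 0.8        # minimum clone-topology similarity
    birth_window: float = 0.5    # hours over which birth positions are averaged
    horizon: float | None = None  # clone comparison horizon (recording end)


# ---------------------------------------------------------------------------
# Mirror-plane estimation
# ---------------------------------------------------------------------------

def _symmetry_cost(points: np.ndarray, azimuth_deg: float) -> float:
    plane = MirrorPlane(azimuth_deg)
    mirrored = plane.reflect(points)
    tree_p = cKDTree(points)
    tree_m = cKDTree(mirrored)
    d1, _ = tree_m.query(points)
    d2, _ = tree_p.query(mirrored)
    return float((d1.mean() + d2.mean()) / 2.0)


def estimate_mirror_plane(tree: LineageTree, t: float,
                          coarse_step_deg: float = 1.0) -> MirrorPlane:
    """Plane through the apical axis minimizing symmetric NN distance.

    Scans candidate azimuths coarsely, then refines around the minimum with
    a bounded scalar optimization.
    """
    alive = tree.alive_at(t)
    if len(alive) < 10:
        raise LineageError(f"need >=10 cells alive at {t}, found {len(alive)}")
    pts = np.array([tree.nodes[u].position_at(t) for u in alive])
    spread = pts[:, :2].std(axis=0)
    if np.all(spread < 1e-9):
        raise LineageError("degenerate cell cloud: all cells on the apical axis")
    grid = np.arange(0.0, 180.0, coarse_step_deg)
    costs = [_symmetry_cost(pts, a) for a in grid]
    best = int(np.argmin(costs))
    lo = grid[best] - coarse_step_deg
    hi = grid[best] + coarse_step_deg
    res = minimize_scalar(lambda a: _symmetry_cost(pts, a),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return MirrorPlane(float(res.x) % 180.0, fitted=True)


# ---------------------------------------------------------------------------
# Clone topology similarity
# ---------------------------------------------------------------------------

def clone_topology_similarity(tree: LineageTree, uid_u: str, uid_v: str,
                              dt_tol: float = 1.0,
                              horizon: float | None = None) -> float:
    """Normalized count of matchable divisions between two clones.

    Divisions are matched recursively from the clone roots (a division can
    only match within a matched parent) when their clone-relative birth
    times differ by at most ``dt_tol``; the score is
    ``2 * matched / (divisions_u + divisions_v)``, and 1.0 when neither
    clone divides (two terminal cells).
    """
    if horizon is None:
        horizon = tree.recording_window[1]

    def n_div(root):
        return sum(1 for x in [root] + tree.descendants(root)
                   if tree.nodes[x].end_fate == "divided"
                   and tree.nodes[x].end_time <= horizon)

    t0u = tree.nodes[uid_u].birth_time
    t0v = tree.nodes[uid_v].birth_time

    @lru_cache(maxsize=None)
    def matched(a: str, b: str) -> int:
        na, nb = tree.nodes[a], tree.nodes[b]
        if na.end_fate != "divided" or nb.end_fate != "divided":
            return 0
        if na.end_time > horizon or nb.end_time > horizon:
            return 0
        if abs((na.end_time - t0u) - (nb.end_time - t0v)) > dt_tol:
            return 0
        ka, kb = tree.children(a), tree.children(b)
        straight = matched(ka[0], kb[0]) + matched(ka[1], kb[1])
        swapped = matched(ka[0], kb[1]) + matched(ka[1], kb[0])
        return 1 + max(straight, swapped)

    total = n_div(uid_u) + n_div(uid_v)
    if total == 0:
        return 1.0
    score = 2.0 * matched(uid_u, uid_v) / total
    matched.cache_clear()
    return score


# ---------------------------------------------------------------------------
# Founder detection
# ---------------------------------------------------------------------------

def _birth_position(tree: LineageTree, uid: str, window: float) -> np.ndarray:
    n = tree.nodes[uid]
    pts = np.array([p[1:4] for p in n.positions
                    if p[0] <= n.birth_time + window])
    if pts.size == 0:
        pts = np.array([n.positions[0][1:4]])
    return pts.mean(axis=0)


def detect_bilateral_founders(tree: LineageTree,
                              plane: MirrorPlane | None = None,
                              params: FounderParams | None = None
                              ) -> list[FounderPair]:
    """All bilateral founder pairs of an embryo, sorted by birth time."""
    plane = plane if plane is not None else MirrorPlane(0.0)
    prm = params or FounderParams()
    horizon = prm.horizon if prm.horizon is not None else tree.recording_window[1]

    uids = [u for u in tree.nodes]
    pos = {u: _birth_position(tree, u, prm.birth_window) for u in uids}
    radius = float(np.percentile([np.linalg.norm(p) for p in pos.values()], 95))
    eps = prm.mirror_eps * radius
    side = {u: plane.side(pos[u]) for u in uids}
    lefts = sorted((u for u in uids if side[u] < 0),
                   key=lambda u: tree.nodes[u].birth_time)
    rights = sorted((u for u in uids if side[u] > 0),
                    key=lambda u: tree.nodes[u].birth_time)
    if not lefts or not rights:
        return []
    r_birth = np.array([tree.nodes[u].birth_time for u in rights])

    candidates: list[tuple[str, str, float, float]] = []
    for u in lefts:
        bu = tree.nodes[u].birth_time
        i0 = np.searchsorted(r_birth, bu - prm.dt_tol, side="left")
        i1 = np.searchsorted(r_birth, bu + prm.dt_tol, side="right")
        mu = plane.reflect(pos[u])
        for v in rights[i0:i1]:
            d = float(np.linalg.norm(mu - pos[v]))
            if d > eps:
                continue
            topo = clone_topology_similarity(tree, u, v, prm.dt_tol, horizon)
            if topo >= prm.topo_min:
                candidates.append((u, v, d, topo))

    cand_set = {(u, v) for u, v, _d, _t in candidates}

    def has_candidate_ancestor(u, v):
        anc_u = [u] + tree.ancestors(u)
        anc_v = set([v] + tree.ancestors(v))
        for au in anc_u:
            for av in anc_v:
                if (au, av) != (u, v) and (au, av) in cand_set:
                    return True
        return False

    founders = [c for c in candidates if not has_candidate_ancestor(c[0], c[1])]
    founders.sort(key=lambda c: (-c[3], c[2], c[0], c[1]))
    used: set[str] = set()
    out: list[FounderPair] = []
    for u, v, d, topo in founders:
        if u in used or v in used:
            continue
        used.update((u, v))
        out.append(FounderPair(
            left_uid=u, right_uid=v,
            birth_times=(tree.nodes[u].birth_time, tree.nodes[v].birth_time),
            mirror_distance=d, topology_score=topo,
            symmetry_class=classify_founder_pair(tree, u, v)))
    out.sort(key=lambda p: (min(p.birth_times), p.left_uid))
    return out


def classify_founder_pair(tree: LineageTree, left_uid: str,
                          right_uid: str) -> str:
    """Symmetry class of a pair from its lineage names (UNNAMED if absent)."""
    nl = tree.nodes[left_uid].name
    nr = tree.nodes[right_uid].name
    if nl is None or nr is None:
        return "UNNAMED"
    if nl.is_shorthand or nr.is_shorthand:
        raise LineageError("founder classification needs concrete quadrants")
    if bilateral_partner_name(nl, "AB_CD") == nr:
        return "QUADRANT_HOMOLOG_ABCD"
    if bilateral_partner_name(nl, "AC") == nr:
        return "AC_HOMOLOG"
    if nl.quadrant == nr.quadrant:
        return "SINGLE_QUADRANT"
    return "NON_CORRESPONDING"


# ---------------------------------------------------------------------------
# Rotational symmetry
# ---------------------------------------------------------------------------

def rotational_symmetry_score(tree: LineageTree, uids, n: int,
                              t: float) -> float:
    """How well a cell set maps onto itself under a 2 pi / n rotation.

    1 - (mean NN distance between the set and its rotation about the apical
    axis) / (mean NN spacing within the set), clamped to [0, 1].
    """
    if n < 2:
        raise LineageError("rotational order n must be >= 2")
    uids = list(uids)
    if len(uids) < n:
        raise LineageError(f"need at least n={n} cells, got {len(uids)}")
    pts = np.array([tree.nodes[u].position_at(t) for u in uids])
    a = 2.0 * math.pi / n
    rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    rotated = pts @ rot.T
    kd = cKDTree(pts)
    d_rot, _ = kd.query(rotated)
    d_self, _ = kd.query(pts, k=2)
    spacing = float(d_self[:, 1].mean())
    if spacing <= 0:
        raise LineageError("coincident cells in rotational scoring")
    return float(np.clip(1.0 - d_rot.mean() / spacing, 0.0, 1.0))
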