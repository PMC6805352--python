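"""Spiralian nomenclature, lineage-tree data model, track I/O and time calibration.

The cell names follow the standard spiralian convention: a micromere-quartet
tier, a lowercase quadrant letter, and a division index over the alphabet
``{1, 2, a, b}``, e.g. ``1a-1122``.  The shorthand quadrant ``m`` (as in
``1m-111``) refers collectively to the four quadrant homologs a-d.

Trees are stored as flat uid -> node mappings with parent links; positions
are per-cell time series of (t, x, y, z).  The spatial convention is
right-handed with +z apical (animal pole), +y dorsal (D-quadrant side),
+x toward the C quadrant, and the sagittal mirror plane at x = 0.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LineageName",
    "parse_lineage_name",
    "expand_shorthand",
    "bilateral_partner_name",
    "CellNode",
    "LineageTree",
    "LineageError",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "to_newick",
    "CalibrationCurve",
    "calibrate_time",
    "DEFAULT_FRAME",
]

_QUADRANTS = frozenset("ABCDM")
_INDEX_ALPHABET = frozenset("12ab")

#: Spatial convention attached to every tree: apical axis, dorsal azimuth
#: (degrees, measured from +x counter-clockwise) and the sagittal plane.
DEFAULT_FRAME = {"apical_axis": "+z", "dorsal_azimuth_deg": 90.0, "mirror_plane": "x=0"}


class LineageError(ValueError):
    """Raised for invalid lineage names or inconsistent trees."""


class TrackFormatError(ValueError):
    """Raised when a track table violates the format contract."""


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class LineageName:
    """A spiralian blastomere name: tier, quadrant and division index.

    ``quadrant`` is one of A, B, C, D or M, where M is the collective
    shorthand for all four quadrant homologs.  ``index`` is a (possibly
    empty) string over the alphabet {1, 2, a, b}; digits mark the early
    spiral-era naming, letters the later bilateral era.
    """

    quadrant: str
    tier: int
    index: str = ""

    def __post_init__(self) -> None:
        if self.quadrant not in _QUADRANTS:
            raise LineageError(f"unknown quadrant {self.quadrant!r}")
        if self.tier < 1:
            raise LineageError(f"tier must be a positive integer, got {self.tier}")
        for ch in self.index:
            if ch not in _INDEX_ALPHABET:
                raise LineageError(f"illegal index character {ch!r} in {self.index!r}")

    def render(self) -> str:
        base = f"{self.tier}{self.quadrant.lower()}"
        return f"{base}-{self.index}" if self.index else base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def is_shorthand(self) -> bool:
        return self.quadrant == "M"

    def child(self, ch: str) -> "LineageName":
        """Name of the daughter whose index extends this one by ``ch``."""
        return replace(self, index=self.index + ch)

    def parent(self) -> "LineageName":
        if not self.index:
            raise LineageError(f"{self.render()} has no parent within its tier")
        return replace(self, index=self.index[:-1])


def parse_lineage_name(text: str) -> LineageName:
    """Parse a rendered spiralian name such as ``1a-1122`` or ``1m-111``.

    Commas and whitespace inside the index are stripped (printed tables use
    thousands-style commas, e.g. ``1d-11,221``).  Raises :class:`LineageError`
    naming the offending character on bad input.
    """
    if not text or not text.strip():
        raise LineageError("empty lineage name")
    s = text.strip()
    i = 0
    while i < len(s) and s[i].isdigit():
        i += 1
    if i == 0:
        raise LineageError(f"missing tier number in {text!r}")
    tier = int(s[:i])
    if i >= len(s):
        raise LineageError(f"missing quadrant letter in {text!r}")
    q = s[i].upper()
    if q not in _QUADRANTS:
        raise LineageError(f"unknown quadrant letter {s[i]!r} in {text!r}")
    rest = s[i + 1:]
    if rest.startswith("-"):
        rest = rest[1:]
    index = "".join(ch for ch in rest if ch not in ", \t")
    for ch in index:
        if ch not in _INDEX_ALPHABET:
            raise LineageError(f"illegal index character {ch!r} in {text!r}")
    return LineageName(quadrant=q, tier=tier, index=index)


def expand_shorthand(name: LineageName) -> tuple[LineageName, ...]:
    """Expand a 1m-xyz shorthand to the four concrete quadrant homologs."""
    if not name.is_shorthand:
        raise LineageError(f"{name.render()} is not a quadrant shorthand")
    return tuple(replace(name, quadrant=q) for q in "ABCD")


_PARTNER_SCHEMES = {
    "AB_CD": {"A": "B", "B": "A", "C": "D", "D": "C"},
    "AC": {"A": "C", "C": "A", "B": "B", "D": "D"},
}


def bilateral_partner_name(name: LineageName, scheme: str = "AB_CD") -> LineageName:
    """Quadrant-swapped mirror name under the given homology scheme.

    ``AB_CD`` swaps A<->B and C<->D (the predominant left/right homology in
    the episphere); ``AC`` swaps A<->C (the rarer symmetry scheme, with B and
    D mapping to themselves).  Both maps are involutions.
    """
    if name.is_shorthand:
        raise LineageError("cannot mirror the quadrant shorthand 1m")
    try:
        mapping = _PARTNER_SCHEMES[scheme]
    except KeyError:
        raise LineageError(f"unknown partner scheme {scheme!r}") from None
    return replace(name, quadrant=mapping[name.quadrant])


# ---------------------------------------------------------------------------
# Tree model
# ---------------------------------------------------------------------------

END_FATES = ("divided", "terminal", "apoptotic", "migrated_out", "censored")


@dataclass
class CellNode:
    """One tracked cell: lifetime, fate, optional name/rid and 4D positions."""

    uid: str
    birth_time: float
    end_time: float
    end_fate: str = "terminal"
    parent_uid: str | None = None
    name: LineageName | None = None
    rid: str | None = None
    positions: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_fate not in END_FATES:
            raise LineageError(f"unknown end fate {self.end_fate!r}")
        if self.end_time < self.birth_time:
            raise LineageError(
                f"cell {self.uid}: end time {self.end_time} before birth {self.birth_time}")

    @property
    def lifetime(self) -> float:
        return self.end_time - self.birth_time

    def alive_at(self, t: float) -> bool:
        return self.birth_time <= t < self.end_time or (
            self.end_fate != "divided" and t == self.end_time)

    def position_at(self, t: float) -> np.ndarray:
        """Linearly interpolated (x, y, z) at time t within the lifetime."""
        if not self.positions:
            raise LineageError(f"cell {self.uid} carries no positions")
        pts = np.asarray(self.positions, dtype=float)
        x = np.interp(t, pts[:, 0], pts[:, 1])
        y = np.interp(t, pts[:, 0], pts[:, 2])
        z = np.interp(t, pts[:, 0], pts[:, 3])
        return np.array([x, y, z])


class LineageTree:
    """A tracked embryo: uid -> :class:`CellNode` with parent links."""

    def __init__(self, embryo_id: str, nodes: dict[str, CellNode],
                 recording_window: tuple[float, float] | None = None,
                 frame: dict | None = None, validate: bool = True) -> None:
        self.embryo_id = embryo_id
        self.nodes = dict(nodes)
        self.frame = dict(DEFAULT_FRAME if frame is None else frame)
        self._children: dict[str, list[str]] = {uid: [] for uid in self.nodes}
        self.roots: set[str] = set()
        for uid, node in self.nodes.items():
            if node.parent_uid is None:
                self.roots.add(uid)
            else:
                if node.parent_uid not in self.nodes:
                    raise LineageError(
                        f"cell {uid} references missing parent {node.parent_uid}")
                self._children[node.parent_uid].append(uid)
        for kids in self._children.values():
            kids.sort()
        if recording_window is None:
            ts = [n.birth_time for n in self.nodes.values()]
            te = [n.end_time for n in self.nodes.values()]
            recording_window = (min(ts), max(te)) if ts else (0.0, 0.0)
        self.recording_window = (float(recording_window[0]), float(recording_window[1]))
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def children(self, uid: str) -> list[str]:
        return self._children[uid]

    def parent(self, uid: str) -> str | None:
        return self.nodes[uid].parent_uid

    def ancestors(self, uid: str) -> list[str]:
        out = []
        cur = self.nodes[uid].parent_uid
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_uid
        return out

    def descendants(self, uid: str) -> list[str]:
        out, stack = [], list(self._children[uid])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children[v])
        return out

    def subtree(self, uid: str) -> list[str]:
        return [uid] + self.descendants(uid)

    def alive_at(self, t: float) -> list[str]:
        return [uid for uid, n in self.nodes.items() if n.alive_at(t)]

    def divisions(self) -> list[str]:
        return [uid for uid, n in self.nodes.items() if n.end_fate == "divided"]

    def by_name(self, name: LineageName | str) -> str:
        if isinstance(name, str):
            name = parse_lineage_name(name)
        hits = [uid for uid, n in self.nodes.items() if n.name == name]
        if not hits:
            raise LineageError(f"no cell named {name.render()} in {self.embryo_id}")
        if len(hits) > 1:
            raise LineageError(f"name {name.render()} is not unique in {self.embryo_id}")
        return hits[0]

    # -- validation --------------------------------------------------------

    def validate(self, time_tol: float = 0.01) -> None:
        seen: set[str] = set()
        for root in self.roots:
            stack = [root]
            while stack:
                v = stack.pop()
                if v in seen:
                    raise LineageError(f"cycle detected at cell {v}")
                seen.add(v)
                stack.extend(self._children[v])
        if len(seen) != len(self.nodes):
            raise LineageError("parent links do not form a forest")
        for uid, node in self.nodes.items():
            kids = self._children[uid]
            if node.end_fate == "divided":
                if len(kids) != 2:
                    raise LineageError(
                        f"divided cell {uid} has {len(kids)} children, expected 2")
            elif kids:
                raise LineageError(
                    f"non-divided cell {uid} ({node.end_fate}) has children")
            for k in kids:
                if abs(self.nodes[k].birth_time - node.end_time) > time_tol:
                    raise LineageError(
                        f"cell {k} born at {self.nodes[k].birth_time} but mother "
                        f"{uid} ends at {node.end_time}")
            if node.positions:
                ts = [p[0] for p in node.positions]
                if any(b <= a for a, b in zip(ts, ts[1:])):
                    raise LineageError(f"cell {uid}: position times not increasing")
                if ts[0] < node.birth_time - time_tol or ts[-1] > node.end_time + time_tol:
                    raise LineageError(
                        f"cell {uid}: positions outside lifetime "
                        f"[{node.birth_time}, {node.end_time}]")
            if node.name is not None and node.parent_uid is not None:
                pname = self.nodes[node.parent_uid].name
                if pname is not None:
                    ok = (node.name.quadrant == pname.quadrant
                          and node.name.tier == pname.tier
                          and len(node.name.index) == len(pname.index) + 1
                          and node.name.index[:-1] == pname.index)
                    if not ok:
                        raise LineageError(
                            f"name {node.name.render()} of {uid} does not extend "
                            f"parent name {pname.render()}")


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["t", "x", "y", "z", "cell_id", "parent_id", "name", "rid"]


def read_tracks(stream, embryo_id: str = "embryo",
                recording_window: tuple[float, float] | None = None) -> LineageTree:
    """Read a TSV track table (one row per cell per timepoint) into a tree.

    Birth/end times are the first/last timestamps of each cell; a cell with
    two children is recorded as divided, otherwise as terminal.  Orphan
    parent references and birth-vs-mother-end gaps beyond 0.01 h are
    rejected with the offending row/uid named.
    """
    df = pd.read_csv(stream, sep="\t", dtype={"cell_id": str, "parent_id": str,
                                              "name": str, "rid": str},
                     keep_default_na=False)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.sort_values(["cell_id", "t"], kind="mergesort")
    nodes: dict[str, CellNode] = {}
    child_count: dict[str, int] = {}
    for cell_id, grp in df.groupby("cell_id", sort=False):
        ts = grp["t"].to_numpy(dtype=float)
        parent_vals = set(grp["parent_id"])
        name_vals = set(grp["name"])
        rid_vals = set(grp["rid"])
        if len(parent_vals) > 1 or len(name_vals) > 1 or len(rid_vals) > 1:
            raise TrackFormatError(
                f"cell {cell_id}: parent/name/rid differ between rows")
        parent = parent_vals.pop() or None
        name_s = name_vals.pop() or None
        rid = rid_vals.pop() or None
        positions = list(zip(ts, grp["x"].astype(float), grp["y"].astype(float),
                             grp["z"].astype(float)))
        nodes[cell_id] = CellNode(
            uid=cell_id, birth_time=float(ts[0]), end_time=float(ts[-1]),
            parent_uid=parent,
            name=parse_lineage_name(name_s) if name_s else None,
            rid=rid, positions=positions)
        if parent:
            child_count[parent] = child_count.get(parent, 0) + 1
    for cell_id, node in nodes.items():
        if node.parent_uid is not None and node.parent_uid not in nodes:
            raise TrackFormatError(
                f"cell {cell_id} references parent {node.parent_uid} absent from file")
    for cell_id, n in child_count.items():
        if n == 2:
            nodes[cell_id].end_fate = "divided"
            for other in nodes.values():
                if other.parent_uid == cell_id:
                    gap = other.birth_time - nodes[cell_id].end_time
                    if abs(gap) > 0.01:
                        raise TrackFormatError(
                            f"cell {other.uid} born {gap:+.3f} h away from end of "
                            f"mother {cell_id}")
                    # snap to the mother's end so the tree invariant is exact
                    other.birth_time = nodes[cell_id].end_time
        elif n != 0:
            raise TrackFormatError(f"cell {cell_id} has {n} children, expected 0 or 2")
    return LineageTree(embryo_id, nodes, recording_window=recording_window)


def write_tracks(tree: LineageTree, stream=None) -> str | None:
    """Write a tree to TSV in canonical (cell_id, t) row order.

    Returns the text when ``stream`` is None, otherwise writes to the stream.
    Round-trips with :func:`read_tracks` byte-identically.
    """
    rows = []
    for uid in sorted(tree.nodes):
        node = tree.nodes[uid]
        pts = node.positions or [(node.birth_time, 0.0, 0.0, 0.0)]
        for (t, x, y, z) in pts:
            rows.append((t, x, y, z, uid, node.parent_uid or "",
                         node.name.render() if node.name else "", node.rid or ""))
    buf = io.StringIO()
    buf.write("\t".join(TRACK_COLUMNS) + "\n")
    for (t, x, y, z, uid, parent, name, rid) in rows:
        buf.write(f"{t:.3f}\t{x:.4f}\t{y:.4f}\t{z:.4f}\t{uid}\t{parent}\t{name}\t{rid}\n")
    text = buf.getvalue()
    if stream is None:
        return text
    stream.write(text)
    return None


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _newick_label(node: CellNode, label: str) -> str:
    if label == "uid":
        return node.uid
    if label == "rid":
        return node.rid or node.uid
    if label == "name":
        return node.name.render() if node.name else node.uid
    raise LineageError(f"unknown label scheme {label!r}")


def to_newick(tree: LineageTree, label: str = "name",
              suffix_duplicates: bool = False) -> str:
    """Newick string with branch lengths equal to cell lifetimes in hours.

    Duplicate labels under the chosen scheme raise unless
    ``suffix_duplicates`` asks for uid-suffixed disambiguation.  A forest
    (several roots) is emitted as one tree per line.
    """
    labels: dict[str, str] = {}
    seen: dict[str, int] = {}
    for uid, node in tree.nodes.items():
        lab = _newick_label(node, label)
        if lab in seen:
            if not suffix_duplicates:
                raise LineageError(f"duplicate Newick label {lab!r}")
            lab = f"{lab}__{uid}"
        seen[lab] = 1
        labels[uid] = lab.replace(" ", "_")

    def render(uid: str) -> str:
        node = tree.nodes[uid]
        kids = tree.children(uid)
        body = f"({','.join(render(k) for k in kids)})" if kids else ""
        return f"{body}{labels[uid]}:{node.lifetime:.6f}"

    return "\n".join(f"{render(r)};" for r in sorted(tree.roots))


# ---------------------------------------------------------------------------
# Temporal calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Nuclei-count -> developmental-time anchors, strictly increasing in both.

    Built from counts of episphere nuclei in embryos fixed at known stages;
    movie frames are mapped to hours post fertilization by piecewise-linear
    interpolation between anchors.
    """

    anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise LineageError("calibration needs at least 2 anchors")
        counts = [a[0] for a in self.anchors]
        times = [a[1] for a in self.anchors]
        if any(c2 <= c1 for c1, c2 in zip(counts, counts[1:])) or \
           any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise LineageError("calibration anchors must strictly increase "
                               "in both count and time")


def calibrate_time(curve: CalibrationCurve, observed_count: int) -> float:
    """Developmental time (hpf) for an observed episphere nuclei count.

    Exact at anchors, monotone in between; counts outside the anchored range
    are clamped to the terminal anchor times with a warning.
    """
    if observed_count < 1:
        raise LineageError("nuclei count must be positive")
    counts = np.array([a[0] for a in curve.anchors], dtype=float)
    times = np.array([a[1] for a in curve.anchors], dtype=float)
    if observed_count < counts[0] or observed_count > counts[-1]:
        warnings.warn(
            f"nuclei count {observed_count} outside calibrated range "
            f"[{int(counts[0])}, {int(counts[-1])}]; clamping", stacklevel=2)
    return float(np.interp(observed_count, counts, times))


def mirror_x(point: np.ndarray) -> np.ndarray:
    """Reflect a point through the sagittal plane x = 0."""
    p = np.asarray(point, dtype=float).copy()
    p[0] = -p[0]
    return p


def azimuth_deg(point) -> float:
    """Azimuth of a point in the x-y plane, degrees in [0, 360)."""
    a = math.degrees(math.atan2(point[1], point[0]))
    return a % 360.0
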