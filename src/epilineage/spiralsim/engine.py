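"""Episphere embryo synthesis: scripted program + parametric growth + noise.

``simulate_embryo`` realizes the canonical program deterministically (the
canonical phase uses hash-derived, seed-independent draws, so a
zero-variability embryo is identical across seeds), then applies the
variability model with counter-based, per-cell random streams.

Clone growth of the bilateral founder pairs is generated once for the left
member and mirrored to the right member (times and topology equal,
positions reflected through x = 0), which makes canonical founder clones
exactly bilaterally symmetric, as in the stereotypic phase of the real
embryo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..lineage_core import CellNode, LineageName, LineageTree, LineageError
from .placement import anchor_position, growth_offset_direction, hash01
from .program import (APOPTOSIS_DELAY, MIGRATION_DELAY, CanonicalProgram,
                      canonical_program)
from .variability import VariabilityModel, rng_for

_GROWTH_STEP = 0.03   # tangent offset between growth siblings (hemisphere R=1)
_CLONE_RADIUS = 0.05   # max spread of a growth clone around its root anchor
_SAMPLE_DT = 0.5       # position sampling interval, hours


@dataclass
class _CanonCell:
    uid: str
    name: LineageName | None
    parent: str | None
    birth: float
    division: float | None = None   # canonical division time, None if leaf
    mode: str | None = None         # division mode if it divides
    children: tuple[str, ...] = ()
    leaf_fate: str = "terminal"     # end fate if it does not divide
    end_offset: float | None = None  # early death (apoptosis / migration)
    b111_variable: bool = False
    anchor: np.ndarray | None = field(repr=False, default=None)
    #: identity used for the division-timing jitter stream: the right member
    #: of a founder clone shares the key of its left mirror counterpart, so
    #: left/right homologs stay near-synchronous WITHIN an embryo while
    #: different embryos draw independently
    jitter_key: str | None = None


@dataclass
class SimulatedEmbryo:
    tree: LineageTree
    truth: dict[str, str]                      # uid -> canonical identity
    founder_truth: dict[int, tuple[str, str]]  # pair id -> (left, right) uids
    division_modes: dict[str, tuple[str, float]]  # uid -> (mode, time)
    seed: int


# ---------------------------------------------------------------------------
# Canonical cell set
# ---------------------------------------------------------------------------

def _mirror(p: np.ndarray) -> np.ndarray:
    q = p.copy()
    q[0] = -q[0]
    return q


def _clamp_to_clone(pos: np.ndarray, root: np.ndarray) -> np.ndarray:
    d = pos - root
    n = np.linalg.norm(d)
    if n > _CLONE_RADIUS:
        pos = root + d * (_CLONE_RADIUS / n)
    return pos / np.linalg.norm(pos)


def _build_canonical(program: CanonicalProgram, t_end: float) -> dict[str, _CanonCell]:
    cells: dict[str, _CanonCell] = {}
    growth_roots: list[tuple[str, str]] = []   # (uid, growth key)

    def add_scripted(name: LineageName, parent: str | None, birth: float,
                     tags: frozenset) -> None:
        uid = name.render()
        anchor = anchor_position(name)
        if anchor is None:
            raise LineageError(f"no anchor for scripted cell {uid}")
        cell = _CanonCell(uid, name, parent, birth, anchor=anchor)
        cells[uid] = cell
        grow_key = next((t.split(":", 1)[1] for t in tags
                         if t.startswith("grow:")), None)
        if grow_key is not None:
            growth_roots.append((uid, grow_key))
            return
        if "b111_variable" in tags:
            cell.b111_variable = True
            return
        event = program.by_mother.get(uid)
        if event is None:
            if "apoptotic" in tags:
                cell.leaf_fate, cell.end_offset = "apoptotic", APOPTOSIS_DELAY
            elif "migrates_out" in tags:
                cell.leaf_fate, cell.end_offset = "migrated_out", MIGRATION_DELAY
            return
        if event.time >= t_end:
            cell.leaf_fate = "censored"
            return
        cell.division = event.time
        cell.mode = event.mode
        cell.children = tuple(d.render() for d in event.daughters)
        for d, fates in zip(event.daughters, event.fates):
            add_scripted(d, uid, event.time, fates)

    for q in "abcd":
        add_scripted(LineageName(q.upper(), 1), None, 2.0, frozenset({"none"}))

    # pair growth roots across founder clones: the right-side counterpart of
    # a left-side root sits at the same clone-relative suffix
    right_of: dict[str, str] = {}   # right root uid -> left root uid
    for fe in program.founder_registry:
        for uid, _key in growth_roots:
            nm = cells[uid].name
            if (nm.quadrant == fe.left.quadrant and nm.tier == fe.left.tier
                    and nm.index.startswith(fe.left.index)):
                rel = nm.index[len(fe.left.index):]
                partner = LineageName(fe.right.quadrant, fe.right.tier,
                                      fe.right.index + rel).render()
                if partner in cells and partner != uid:
                    right_of[partner] = uid

    def grow(root_uid: str, key: str, mirror_into: str | None) -> None:
        params = program.growth[key]
        root = cells[root_uid]
        pattern = root_uid  # shared between the two mirror instantiations
        plan: list[tuple[str, float, float | None, bool, np.ndarray]] = []

        def rec(path: str, birth: float, pos: np.ndarray) -> None:
            cyc = params.cycle_mean * (
                1.0 + params.cycle_spread * (2.0 * hash01(pattern, "cyc", path) - 1.0))
            div: float | None = birth + cyc
            differentiated = bool(
                path and hash01(pattern, "term", path) < params.terminal_fraction)
            if differentiated:
                div = None
            censored = div is not None and div >= t_end
            if censored:
                div = None
            plan.append((path, birth, div, censored, pos))
            if div is not None:
                step = _GROWTH_STEP * max(0.5, 1.0 - 0.1 * len(path))
                d = growth_offset_direction(pattern + "/" + path, pos) * step
                rec(path + "1", div, _clamp_to_clone(pos + d, root.anchor))
                rec(path + "2", div, _clamp_to_clone(pos - d, root.anchor))

        rec("", root.birth, root.anchor / np.linalg.norm(root.anchor))
        for side_root, flip in ((root_uid, False), (mirror_into, True)):
            if side_root is None:
                continue
            for path, birth, div, censored, pos in plan:
                uid = side_root if path == "" else f"{side_root}/{path}"
                kids = (() if div is None else
                        (f"{side_root}/{path}1", f"{side_root}/{path}2"))
                p = _mirror(pos) if flip else pos
                if path == "":
                    cell = cells[side_root]
                else:
                    parent = (side_root if len(path) == 1
                              else f"{side_root}/{path[:-1]}")
                    cell = _CanonCell(uid, None, parent, birth, anchor=p)
                    cells[uid] = cell
                cell.division = div
                cell.mode = "bilateral" if div is not None else None
                cell.children = kids
                if div is None:
                    cell.leaf_fate = "censored" if censored else "terminal"

    handled_rights = set(right_of)
    left_to_right = {l: r for r, l in right_of.items()}
    for uid, key in growth_roots:
        if uid in handled_rights:
            continue
        grow(uid, key, mirror_into=left_to_right.get(uid))

    # share the timing-jitter identity between mirror counterparts: map the
    # scripted subtree of every right founder onto the left one
    for fe in program.founder_registry:
        for uid, cell in cells.items():
            nm = cell.name
            if nm is None:
                continue
            if (nm.quadrant == fe.right.quadrant and nm.tier == fe.right.tier
                    and nm.index.startswith(fe.right.index)):
                rel = nm.index[len(fe.right.index):]
                left_uid = LineageName(fe.left.quadrant, fe.left.tier,
                                       fe.left.index + rel).render()
                if left_uid in cells and left_uid != uid:
                    cell.jitter_key = left_uid
    # growth cells of a mirrored right clone reuse the left pattern path
    for right_root, left_root in right_of.items():
        cells[right_root].jitter_key = left_root
        for uid, cell in cells.items():
            if uid.startswith(right_root + "/"):
                cell.jitter_key = left_root + uid[len(right_root):]
    return cells


# ---------------------------------------------------------------------------
# Realization (variability + tree assembly)
# ---------------------------------------------------------------------------

def simulate_embryo(program: CanonicalProgram | None = None,
                    variability: VariabilityModel | None = None,
                    seed: int = 0, t_end: float = 32.0,
                    embryo_id: str | None = None) -> SimulatedEmbryo:
    """One synthetic tracked episphere embryo up to ``t_end`` (2-34 hpf)."""
    if t_end < 2.0:
        raise LineageError("t_end must be >= 2 hpf")
    if t_end > 34.0:
        raise LineageError("t_end must be <= 34 hpf")
    if program is None:
        program = _default_program()
    var = variability if variability is not None else VariabilityModel()
    canon = _canonical_cached(program, t_end)
    zero = var.is_zero

    # --- realized division times ------------------------------------------
    birth_r: dict[str, float] = {}
    div_r: dict[str, float | None] = {}
    skipped: set[str] = set()
    censored_late: set[str] = set()
    extras: dict[str, float] = {}

    b111_div: dict[str, float] = {}
    if not zero and var.b111_probs[0] < 1.0:
        g = rng_for(seed, seed, "b111")
        cat = int(g.choice(3, p=list(var.b111_probs)))
        if cat > 0:
            t1 = min(float(g.uniform(*var.b111_first_division)), t_end - 0.4)
            b111_div["1b-111"] = t1
            if cat == 2:
                b111_div["1b-1111"] = min(t1 + 4.0, t_end - 0.2)

    for uid, cell in canon.items():
        if cell.parent is not None:
            if cell.parent not in birth_r or div_r.get(cell.parent) is None:
                continue  # parent absent or did not divide in this embryo
            b = div_r[cell.parent]
        else:
            b = 2.0
        birth_r[uid] = b
        d = cell.division
        if zero:
            div_r[uid] = d
            continue
        if d is not None:
            if cell.birth > var.deviation_onset and var.deviation_rate > 0 and \
                    rng_for(seed, seed, "dev", uid).uniform() < var.deviation_rate:
                skipped.add(uid)
                div_r[uid] = None
                continue
            jkey = cell.jitter_key or uid
            d2 = d + var.sigma(d) * float(rng_for(seed, seed, "jit", jkey).normal())
            d2 = max(d2, b + 0.15)
            if d2 >= t_end:
                censored_late.add(uid)
                div_r[uid] = None
            else:
                div_r[uid] = d2
        else:
            div_r[uid] = None
            eligible = (cell.leaf_fate == "terminal" and cell.end_offset is None
                        and not cell.b111_variable
                        and cell.birth > var.deviation_onset)
            if eligible and var.deviation_rate > 0 and \
                    rng_for(seed, seed, "dev", uid).uniform() < var.deviation_rate:
                tx = b + float(rng_for(seed, seed, "extra", uid).uniform(1.0, 4.5))
                if tx < t_end - 0.3:
                    extras[uid] = tx

    # --- assemble CellNodes -----------------------------------------------
    nodes: dict[str, CellNode] = {}
    modes: dict[str, tuple[str, float]] = {}
    truth: dict[str, str] = {}

    def sample_positions(uid, anchor, b, e):
        ts = list(np.arange(b, e, _SAMPLE_DT))
        # keep samples >2 ms-h apart so 3-decimal track output stays strictly
        # increasing; the final sample always sits exactly at the end time
        if ts and e - ts[-1] < 2e-3:
            ts[-1] = e
        elif not ts or e - ts[-1] > 1e-9:
            ts.append(e)
        pts = np.tile(anchor, (len(ts), 1))
        if not zero and var.position_noise > 0:
            g = rng_for(seed, seed, "pos", uid)
            pts = pts + g.normal(scale=var.position_noise, size=pts.shape)
        return [(float(t), float(p[0]), float(p[1]), float(p[2]))
                for t, p in zip(ts, pts)]

    def emit(uid, name, parent, b, e, fate, anchor):
        nodes[uid] = CellNode(uid=uid, name=name, parent_uid=parent,
                              birth_time=b, end_time=e, end_fate=fate,
                              positions=sample_positions(uid, anchor, b, e))

    for uid, cell in canon.items():
        if uid not in birth_r:
            continue
        b = birth_r[uid]
        d = b111_div.get(uid, div_r[uid])
        if d is not None:
            if uid in b111_div:
                div_r[uid] = d
                mode = "radial"
            else:
                mode = cell.mode
            emit(uid, cell.name, cell.parent, b, d, "divided", cell.anchor)
            modes[uid] = (mode, d)
        elif uid in extras:
            tx = extras[uid]
            emit(uid, cell.name, cell.parent, b, tx, "divided", cell.anchor)
            modes[uid] = ("bilateral", tx)
            dirv = growth_offset_direction("extra/" + uid, cell.anchor) * _GROWTH_STEP
            for i, sgn in ((1, 1.0), (2, -1.0)):
                a = cell.anchor + sgn * dirv
                emit(f"{uid}.x{i}", None, uid, tx, t_end, "terminal",
                     a / np.linalg.norm(a))
        else:
            if cell.end_offset is not None:
                e, fate = min(b + cell.end_offset, t_end), cell.leaf_fate
            elif uid in skipped:
                e, fate = t_end, "terminal"
            elif uid in censored_late:
                e, fate = t_end, "censored"
            else:
                e, fate = t_end, cell.leaf_fate
            emit(uid, cell.name, cell.parent, b, e, fate, cell.anchor)
        truth[uid] = uid

    # daughters of the variable ventral rosette cell 1b-111
    if "1b-111" in b111_div and "1b-111" in nodes:
        base = nodes["1b-111"]
        t1 = base.end_time
        for i in (1, 2):
            dname = base.name.child(str(i))
            duid = dname.render()
            t2 = b111_div.get(duid)
            a = np.array(base.positions[0][1:4])
            a += growth_offset_direction("b111/" + duid, a) * \
                _GROWTH_STEP * (1.0 if i == 1 else -1.0)
            a /= np.linalg.norm(a)
            fate = "divided" if t2 is not None else "terminal"
            emit(duid, dname, "1b-111", t1, t2 if t2 is not None else t_end, fate, a)
            if t2 is not None:
                modes[duid] = ("radial", t2)
                for j in (1, 2):
                    gname = dname.child(str(j))
                    ga = a + growth_offset_direction("b111g/" + gname.render(), a) \
                        * 0.01 * (1.0 if j == 1 else -1.0)
                    emit(gname.render(), gname, duid, t2, t_end, "terminal",
                         ga / np.linalg.norm(ga))

    eid = embryo_id if embryo_id is not None else f"sim-seed{seed}"
    tree = LineageTree(eid, nodes, recording_window=(2.0, t_end))
    founder_truth = {fe.pair_id: (fe.left.render(), fe.right.render())
                     for fe in program.founder_registry}
    return SimulatedEmbryo(tree=tree, truth=truth, founder_truth=founder_truth,
                           division_modes=modes, seed=seed)


def simulate_cohort(n: int, base_seed: int,
                    program: CanonicalProgram | None = None,
                    variability: VariabilityModel | None = None,
                    t_end: float = 32.0) -> list[SimulatedEmbryo]:
    """n independent embryos sharing one program (seeds base_seed + i)."""
    if n < 2:
        raise LineageError("a cohort needs at least 2 embryos")
    if program is None:
        program = _default_program()
    return [simulate_embryo(program, variability, seed=base_seed + i,
                            t_end=t_end, embryo_id=f"embryo{i + 1}")
            for i in range(n)]


def first_division_of_mode(embryo: SimulatedEmbryo, mode: str) -> float:
    """Earliest division time of the given mode (inf if none occurs)."""
    times = [t for m, t in embryo.division_modes.values()
             if m == mode or (mode == "spiral" and m.startswith("spiral"))]
    return min(times) if times else math.inf


def last_division_of_mode(embryo: SimulatedEmbryo, mode: str) -> float:
    """Latest division time of the given mode (-inf if none occurs)."""
    times = [t for m, t in embryo.division_modes.values()
             if m == mode or (mode == "spiral" and m.startswith("spiral"))]
    return max(times) if times else -math.inf


_PROGRAM_SINGLETON: CanonicalProgram | None = None
_CANON_CACHE: dict[tuple[int, float], dict[str, _CanonCell]] = {}


def _default_program() -> CanonicalProgram:
    global _PROGRAM_SINGLETON
    if _PROGRAM_SINGLETON is None:
        _PROGRAM_SINGLETON = canonical_program()
    return _PROGRAM_SINGLETON


def _canonical_cached(program: CanonicalProgram, t_end: float):
    key = (id(program), t_end)
    if key not in _CANON_CACHE:
        _CANON_CACHE[key] = _build_canonical(program, t_end)
    return _CANON_CACHE[key]
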