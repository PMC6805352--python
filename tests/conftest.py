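import numpy as np
import pytest

from epilineage.lineage_core import CellNode, LineageTree, parse_lineage_name
from epilineage.spiralsim import (VariabilityModel, canonical_program,
                                  simulate_cohort, simulate_embryo)


@pytest.fixture(scope="session")
def program():
    return canonical_program()


@pytest.fixture(scope="session")
def canonical_embryo(program):
    """Zero-variability embryo to 32 hpf (shared: it is deterministic)."""
    return simulate_embryo(program, VariabilityModel.zero(), seed=1, t_end=32.0)


@pytest.fixture(scope="session")
def zero_cohort(program):
    return simulate_cohort(3, base_seed=10, program=program,
                           variability=VariabilityModel.zero(), t_end=33.0)


@pytest.fixture(scope="session")
def default_cohort(program):
    return simulate_cohort(3, base_seed=42, program=program,
                           variability=VariabilityModel(), t_end=34.0)


# ---------------------------------------------------------------------------
# Small-tree construction helpers
# ---------------------------------------------------------------------------

def cell(uid, birth, end, parent=None, fate="terminal", name=None, xyz=(0, 0, 1)):
    """A CellNode with a static position track."""
    pos = [(birth, *xyz)]
    if end > birth:
        pos.append((end, *xyz))
    return CellNode(uid=uid, birth_time=birth, end_time=end, end_fate=fate,
                    parent_uid=parent,
                    name=parse_lineage_name(name) if name else None,
                    positions=pos)


def build_tree(cells, embryo_id="t", window=None):
    return LineageTree(embryo_id, {c.uid: c for c in cells},
                       recording_window=window)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class RandomTreeGen:
    """Random binary lineage trees with geometric daughter placement.

    ``grow()`` makes a fresh random topology; passing the returned plan
    back via ``base=`` yields a second realization of the same topology
    with jittered division times and noisy positions (a synthetic
    "second embryo" of the same individual lineage).
    """

    def __init__(self, rng):
        self.rng = rng
        self.plan = None

    def _make_plan(self, max_leaves, t_end):
        plan = {"c0": (None, 0.0, _unit([0.3, 0.2, 0.9]))}
        frontier, leaves = ["c0"], 1
        while frontier:
            uid = frontier.pop(0)
            if leaves >= max_leaves or self.rng.random() > 0.8:
                continue
            _parent, birth, p = plan[uid]
            div = birth + self.rng.uniform(2.0, 5.0)
            if div >= t_end - 1.0:
                continue
            d = self.rng.normal(size=3) * 0.15
            d -= np.dot(d, p) * p
            plan[uid + "1"] = (uid, div, _unit(p + d))
            plan[uid + "2"] = (uid, div, _unit(p - d))
            frontier += [uid + "1", uid + "2"]
            leaves += 1
        return plan

    def grow(self, max_leaves=8, t_end=20.0, jitter=0.0, noise=0.0,
             base=None):
        plan = base if base is not None else self._make_plan(max_leaves, t_end)
        self.plan = plan
        kids = {}
        for uid, (parent, _b, _p) in plan.items():
            if parent:
                kids.setdefault(parent, []).append(uid)
        real_birth, real_div = {}, {}
        for uid, (parent, _b, _p) in plan.items():  # insertion = topological
            b = 0.0 if parent is None else real_div[parent]
            real_birth[uid] = b
            if uid in kids:
                dv = plan[kids[uid][0]][1] + self.rng.normal() * jitter
                real_div[uid] = min(max(dv, b + 0.2), t_end - 0.1)
        nodes = []
        for uid, (parent, _b, p) in plan.items():
            divided = uid in kids
            xyz = tuple(p + self.rng.normal(size=3) * noise)
            nodes.append(cell(uid, real_birth[uid],
                              real_div[uid] if divided else t_end,
                              parent=parent,
                              fate="divided" if divided else "censored",
                              xyz=xyz))
        return build_tree(nodes, window=(0.0, t_end))
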