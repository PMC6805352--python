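"""Differentiated-cell annotations, lineage metrics, and clonality analysis.

The packaged annotation table lists the 62 differentiated cell types of the
30-hpf episphere with their consensus lineage names, reference IDs, marker
genes (cholinergic *chat*, neuropeptidergic *phc2*, serotonergic 5HT,
*syt*, *vacht*), approximate cell-cycle-exit times, and the number of
recordings supporting each lineage assignment.

Lineage metrics follow the standard definitions: lineage depth is the
number of divisions separating a cell from the zygote (trees rooted at the
first micromere quartet add a fixed offset of 3 for the zygote -> AB/CD ->
quadrant -> 1m divisions), cell age is the time since the last division,
and cycle length is the lifetime of a divided cell.

The clonality analysis asks whether a gene's expression is clonally
inherited: project labeled cells forward to a later stage by pure clonal
expansion and compare the projection with the observed expression (Jaccard
index; dynamically switching genes score well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .lineage_core import (LineageError, LineageName, LineageTree,
                           parse_lineage_name)

__all__ = [
    "AnnotationRecord", "ExpressionLabel", "MARKER_VOCABULARY",
    "load_annotations", "marker_cells", "lineage_depth", "cell_age",
    "cycle_length", "project_clone", "clonality_score",
]

MARKER_VOCABULARY = frozenset({"chat", "phc2", "syt", "5HT", "vacht", "none"})

#: divisions from the zygote to a first-quartet micromere (1m) root
DEFAULT_ROOT_DEPTH_OFFSET = 3


@dataclass(frozen=True)
class AnnotationRecord:
    index: int                      # numbering of the summary diagram, 1-62
    cell_type: str
    lineage: LineageName
    support: tuple[int, int]        # recordings with this lineage / analyzed
    literature_support: bool
    last_division: float            # hpf, approximate (cell-cycle exit)
    rid: str
    markers: frozenset
    multiplicity: int = 1
    variable_suffix: str = ""       # printed wildcard tail of a variable lineage
    caveat: str = ""


@dataclass(frozen=True)
class ExpressionLabel:
    """Cells observed expressing a gene at one stage (rIDs or uids)."""
    gene: str
    stage: float                    # hpf
    labeled: frozenset


def load_annotations(path=None) -> list[AnnotationRecord]:
    """Load and validate the annotation table (packaged fixture by default)."""
    if path is None:
        ref = resources.files("epilineage") / "fixtures" / "annotations_table1.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", keep_default_na=False, dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    df = df.fillna("")
    records = []
    seen_rids = set()
    for i, row in df.iterrows():
        try:
            lineage = parse_lineage_name(row["lineage"])
        except LineageError as exc:
            raise LineageError(f"annotation row {i + 2}: {exc}") from exc
        rid = row["rid"]
        if rid in seen_rids:
            raise LineageError(f"annotation row {i + 2}: duplicate rID {rid}")
        seen_rids.add(rid)
        markers = frozenset(m for m in row["markers"].split(",") if m)
        bad = markers - MARKER_VOCABULARY
        if bad:
            raise LineageError(
                f"annotation row {i + 2}: unknown marker(s) {sorted(bad)}")
        records.append(AnnotationRecord(
            index=int(row["index"]), cell_type=row["cell_type"],
            lineage=lineage,
            support=(int(row["support_k"]), int(row["support_n"])),
            literature_support=row["refs"].strip().lower() == "yes",
            last_division=float(row["last_division_hpf"]), rid=rid,
            markers=markers if markers else frozenset({"none"}),
            multiplicity=int(row["multiplicity"] or 1),
            variable_suffix=row.get("variable_suffix", ""),
            caveat=row.get("caveat", "")))
    return records


def marker_cells(records: list[AnnotationRecord], marker: str,
                 expand_multiplicity: bool = False):
    """Annotation records carrying a marker (or their multiplicity count)."""
    if marker not in MARKER_VOCABULARY:
        raise LineageError(
            f"unknown marker {marker!r}; valid: {sorted(MARKER_VOCABULARY)}")
    hits = [r for r in records if marker in r.markers]
    if expand_multiplicity:
        return sum(r.multiplicity for r in hits)
    return hits


# ---------------------------------------------------------------------------
# Lineage metrics
# ---------------------------------------------------------------------------

def _require_alive(tree: LineageTree, uid: str, t: float):
    node = tree.nodes[uid]
    if not node.alive_at(t):
        raise LineageError(f"cell {uid} is not alive at {t} hpf")
    return node


def lineage_depth(tree: LineageTree, uid: str, t: float,
                  root_offset: int = DEFAULT_ROOT_DEPTH_OFFSET) -> int:
    """Number of divisions from the zygote to the cell, at time t."""
    _require_alive(tree, uid, t)
    return len(tree.ancestors(uid)) + root_offset


def cell_age(tree: LineageTree, uid: str, t: float) -> float:
    """Hours since the cell's last division (its birth)."""
    node = _require_alive(tree, uid, t)
    return t - node.birth_time


def cycle_length(tree: LineageTree, uid: str) -> float:
    """Lifetime of a divided cell (birth to its own division), hours."""
    node = tree.nodes[uid]
    if node.end_fate != "divided":
        raise LineageError(f"cell {uid} did not divide; cycle undefined")
    return node.end_time - node.birth_time


# ---------------------------------------------------------------------------
# Clonal projection
# ---------------------------------------------------------------------------

def _resolve(tree: LineageTree, ref: str) -> str:
    if ref in tree.nodes:
        return ref
    for uid, n in tree.nodes.items():
        if n.rid == ref:
            return uid
    raise LineageError(f"labeled cell {ref!r} not found in {tree.embryo_id}")


def project_clone(tree: LineageTree, label: ExpressionLabel,
                  s: float, s_target: float) -> set[str]:
    """Clonal forward-projection of labeled cells from stage s to s_target.

    Returns the uids of all cells alive at ``s_target`` descending from (or
    identical to) the labeled cells alive at ``s``.
    """
    if s > s_target:
        raise LineageError("target stage precedes source stage")
    out: set[str] = set()
    for ref in label.labeled:
        uid = _resolve(tree, ref)
        if not tree.nodes[uid].alive_at(s):
            raise LineageError(f"labeled cell {ref} not alive at {s} hpf")
        for x in tree.subtree(uid):
            if tree.nodes[x].alive_at(s_target):
                out.add(x)
    return out


def clonality_score(observed: set, projected: set):
    """Jaccard agreement between observed and clonally projected cell sets.

    Returns ``(score, gained, lost)``: 1.0 means perfectly clonal
    inheritance; ``gained`` holds observed cells outside the projection
    (expression switched on), ``lost`` the projection outside the
    observation (switched off).  None when both sets are empty.
    """
    observed, projected = set(observed), set(projected)
    union = observed | projected
    if not union:
        return None
    inter = observed & projected
    return (len(inter) / len(union), observed - projected, projected - observed)
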