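"""The canonical episphere division program and its founder registry.

The scripted phase (2-16 hpf) is a transcription of the stereotypic
episphere lineage: spiral divisions producing the micromere tiers and the
prototroch rings, the first bilateral divisions (1m-112 at 6 hpf,
1m-1121 at 8 hpf), the apical-organ events, the D-quadrant exceptions
(1d-121 / 1d-1222 migrating out of the episphere, only two accessory
prototroch cells), and the stems leading to the 11 bilateral founder
pairs.  Late development (clone growth to 32-34 hpf) is parametric:
per-clone exponential proliferation with terminal-fate draws, fast in the
lateral (otx-territory) clones and slower medially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ..lineage_core import LineageName, LineageError, parse_lineage_name

DIVISION_MODES = ("spiral_cw", "spiral_ccw", "bilateral", "radial", "budding")

TERMINAL_FATES = {"primary_prototroch", "accessory_prototroch", "terminal",
                  "apoptotic", "migrates_out"}

#: hours an apoptotic cell persists after its birth before dissociating
APOPTOSIS_DELAY = 3.5
#: hours a migrating cell remains visible before leaving the episphere
MIGRATION_DELAY = 2.0


@dataclass(frozen=True)
class DivisionEvent:
    mother: LineageName
    time: float
    mode: str
    daughters: tuple[LineageName, LineageName]
    fates: tuple[frozenset, frozenset]

    def __post_init__(self):
        if self.mode not in DIVISION_MODES:
            raise LineageError(f"unknown division mode {self.mode!r}")
        for d in self.daughters:
            if not (d.quadrant == self.mother.quadrant
                    and d.tier == self.mother.tier
                    and len(d.index) == len(self.mother.index) + 1
                    and d.index[:-1] == self.mother.index):
                raise LineageError(
                    f"daughter {d.render()} does not extend mother "
                    f"{self.mother.render()}")


@dataclass(frozen=True)
class FounderEntry:
    pair_id: int
    left: LineageName
    right: LineageName
    origin_hpf: float
    symmetry_class: str
    verified: bool


@dataclass(frozen=True)
class GrowthParams:
    """Per-clone proliferation parameters for the parametric growth phase."""
    cycle_mean: float       # hours
    terminal_fraction: float  # per-division probability a daughter differentiates
    cycle_spread: float = 0.15  # deterministic relative spread of cycle lengths


#: default growth behavior per clone key used in the events fixture
DEFAULT_GROWTH = {
    "otx_fast": GrowthParams(3.1, 0.03),      # dorso-lateral otx territory
    "vent_fast": GrowthParams(3.5, 0.05),     # ventro-lateral territory
    "medial": GrowthParams(5.0, 0.10),        # medial six3-territory clones
    "gland_branch": GrowthParams(5.5, 0.20),
    "eye_branch": GrowthParams(4.5, 0.10),
    "rosette_slow": GrowthParams(6.5, 0.25),
}


@dataclass
class CanonicalProgram:
    events: list[DivisionEvent]
    founder_registry: list[FounderEntry]
    growth: dict[str, GrowthParams] = field(default_factory=lambda: dict(DEFAULT_GROWTH))

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.time, e.mother.render()))
        self.by_mother = {e.mother.render(): e for e in self.events}
        if len(self.by_mother) != len(self.events):
            raise LineageError("duplicate mother in division program")
        self._validate()

    # -- queries -----------------------------------------------------------

    def cells_with_fate(self, fate: str, quadrant: str | None = None) -> list[LineageName]:
        out = []
        for e in self.events:
            for d, fates in zip(e.daughters, e.fates):
                if fate in fates and (quadrant is None or d.quadrant == quadrant):
                    out.append(d)
        return sorted(out, key=lambda n: n.render())

    def primary_prototroch(self, quadrant: str) -> list[LineageName]:
        return self.cells_with_fate("primary_prototroch", quadrant)

    def accessory_prototroch(self, quadrant: str) -> list[LineageName]:
        return self.cells_with_fate("accessory_prototroch", quadrant)

    def growth_roots(self) -> list[tuple[LineageName, str]]:
        out = []
        for e in self.events:
            for d, fates in zip(e.daughters, e.fates):
                for f in fates:
                    if f.startswith("grow:"):
                        out.append((d, f.split(":", 1)[1]))
        return out

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        for q in "ABCD":
            npp = len(self.primary_prototroch(q))
            if npp != 3:
                raise LineageError(
                    f"quadrant {q}: {npp} primary prototroch cells, expected 3")
            nacc = len(self.accessory_prototroch(q))
            expected = 2 if q == "D" else 3
            if nacc != expected:
                raise LineageError(
                    f"quadrant {q}: {nacc} accessory prototroch cells, "
                    f"expected {expected}")
        if len(self.founder_registry) != 11:
            raise LineageError(
                f"founder registry has {len(self.founder_registry)} pairs, expected 11")
        for fe in self.founder_registry:
            if not (6.0 <= fe.origin_hpf <= 18.0):
                raise LineageError(
                    f"founder pair {fe.pair_id} origin {fe.origin_hpf} outside [6, 18]")
        # every non-terminal daughter must reappear as a mother
        for e in self.events:
            for d, fates in zip(e.daughters, e.fates):
                terminal = bool(fates & TERMINAL_FATES) or \
                    any(f.startswith("grow:") for f in fates) or "b111_variable" in fates
                if not terminal and d.render() not in self.by_mother:
                    raise LineageError(
                        f"daughter {d.render()} neither terminal nor a mother")
        for _, key in self.growth_roots():
            if key not in self.growth:
                raise LineageError(f"unknown growth key {key!r}")


def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("epilineage") / "fixtures" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def canonical_program() -> CanonicalProgram:
    """Load and validate the packaged canonical division program."""
    ev = _load_fixture("events.tsv")
    events = []
    for _, row in ev.iterrows():
        mother = parse_lineage_name(row["mother"])
        daughters = (mother.child(str(row["suffix1"])), mother.child(str(row["suffix2"])))
        fates = tuple(frozenset(str(row[c]).split("+")) for c in ("fate1", "fate2"))
        events.append(DivisionEvent(mother=mother, time=float(row["time_hpf"]),
                                    mode=row["mode"], daughters=daughters,
                                    fates=fates))
    fo = _load_fixture("founders.tsv")
    registry = [FounderEntry(pair_id=int(r["pair_id"]),
                             left=parse_lineage_name(r["left"]),
                             right=parse_lineage_name(r["right"]),
                             origin_hpf=float(r["origin_hpf"]),
                             symmetry_class=r["symmetry_class"],
                             verified=str(r["verified"]).lower() == "true")
                for _, r in fo.iterrows()]
    return CanonicalProgram(events=events, founder_registry=registry)
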