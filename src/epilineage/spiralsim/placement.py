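"""Cell placement on the unit hemisphere: division geometry and anchors.

Frame convention (shared with the whole package): +z apical, +y dorsal,
+x toward the C quadrant; the sagittal mirror plane is x = 0.  Quadrant
sectors sit at azimuths A=225, B=315, C=45, D=135 degrees, so that the
mirror maps A<->B and C<->D sectors onto each other, with the A and D
quadrants on the left (x < 0) body side.

Spiral-phase cells carry a global azimuthal twist (the residual rotation of
the oblique spiral divisions), so the rotationally symmetric structures
(prototroch ring, apical rosette) are *not* aligned with the sagittal
mirror: the midline passes between ring cells.  Cells that divide in the
bilateral mode are placed mirror-symmetrically by construction.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np

from ..lineage_core import LineageName, LineageError

QUADRANT_AZIMUTH = {"A": 225.0, "B": 315.0, "C": 45.0, "D": 135.0}

#: residual spiral twist (degrees) applied to all spiral-phase anchors
SPIRAL_TWIST = 20.0
#: phase offsets of the prototroch rings relative to the quadrant
#: boundaries; both keep the midline between ring cells, and they differ
#: from each other so the two rings prefer different rotational symmetry
#: planes, leaving the bilateral plane as the unique best mirror
RING_PHASE = 7.5
ACC_PHASE = 11.0


def sph(az_deg: float, pol_deg: float, r: float = 1.0) -> np.ndarray:
    """Cartesian point from azimuth/polar angles (degrees), +z apical."""
    az, pol = math.radians(az_deg), math.radians(pol_deg)
    return r * np.array([math.cos(az) * math.sin(pol),
                         math.sin(az) * math.sin(pol),
                         math.cos(pol)])


def hash01(*parts: str) -> float:
    """Deterministic uniform in [0, 1) from string parts (stable across runs)."""
    h = hashlib.md5("|".join(parts).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2.0 ** 64


# ---------------------------------------------------------------------------
# Division geometry
# ---------------------------------------------------------------------------

def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(e_az, e_pol) tangent unit vectors at unit point u (e_pol = posterior)."""
    ez = np.array([0.0, 0.0, 1.0])
    e_az = np.cross(ez, u)
    n = np.linalg.norm(e_az)
    if n < 1e-9:  # at the pole the azimuthal direction is degenerate
        e_az = np.array([0.0, 1.0, 0.0])
    else:
        e_az = e_az / n
    e_pol = np.cross(e_az, u)
    e_pol = e_pol / np.linalg.norm(e_pol)
    return e_az, e_pol


def place_daughters(mother_position, mode: str, chirality_state: int = 1,
                    separation: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the two daughters of a division at ``mother_position``.

    Spiral modes split along a direction rotated +/-45 degrees from the
    meridian (counter-clockwise for ``spiral_ccw`` viewed from the animal
    pole; ``chirality_state`` = -1 flips the alternation).  ``bilateral``
    splits along the local parallel with the sign chosen from the mother's
    body side, which makes daughter sets of mirror-placed mothers exactly
    mirror-symmetric.  ``radial`` splits along the meridian; ``budding``
    is a short radial split.  Daughters are re-projected onto the sphere of
    the mother's radius.  Daughter 1 is the more anterior (apical) one.
    """
    p = np.asarray(mother_position, dtype=float)
    r = float(np.linalg.norm(p))
    if r < 1e-12:
        raise LineageError("mother position has zero length")
    u = p / r
    e_az, e_pol = _tangent_basis(u)
    if mode in ("spiral_cw", "spiral_ccw"):
        sign = (1.0 if mode == "spiral_ccw" else -1.0) * float(chirality_state)
        beta = math.radians(45.0) * sign
        direction = math.cos(beta) * e_pol + math.sin(beta) * e_az
        half = 0.5 * separation
    elif mode == "bilateral":
        side = 1.0 if p[0] >= 0 else -1.0
        direction = e_az * side
        half = 0.5 * separation
    elif mode == "radial":
        direction = e_pol
        half = 0.5 * separation
    elif mode == "budding":
        direction = e_pol
        half = 0.25 * separation
    else:
        raise LineageError(f"unknown division mode {mode!r}")
    d1 = p - half * direction
    d2 = p + half * direction
    d1 = d1 / np.linalg.norm(d1) * r
    d2 = d2 / np.linalg.norm(d2) * r
    return d1, d2


# ---------------------------------------------------------------------------
# Anchors for scripted cells
# ---------------------------------------------------------------------------

# Early spiral-phase layout: per-name (azimuth offset from quadrant base
# + SPIRAL_TWIST, polar).  Keys are index strings.
_EARLY_OFFSETS = {
    "": (0.0, 40.0),
    "1": (0.0, 30.0),
    "2": (0.0, 55.0),
    "11": (-5.0, 25.0),
    "12": (8.0, 40.0),
    "112": (-8.0, 30.0),
    "21": (-10.0, 62.0),
    "22": (10.0, 68.0),
    "121": (12.0, 45.0),
}

# prototroch ring (polar 72): slot offsets from the quadrant azimuth
_PRIMARY_SLOTS = {"221": -30.0, "222": 0.0, "212": 30.0}
# accessory ring (polar 60-64)
_ACCESSORY_SLOTS = {"211": (-15.0, 64.0), "122": (15.0, 60.0), "1212": (45.0, 60.0)}
# apical rosette, twisted (no mirror alignment: the apical organ is
# neither rotationally nor bilaterally symmetric in its cell placement)
_ROSETTE = {"111": (25.0, 18.0)}

# Explicit anchors for the bilateral-era scripted cells (azimuth, polar).
# Mirror pairs are exact by construction; stem and leftover cells are kept
# >0.1 R away from the mirror image of any similarly-aged cell.
_NAMED_ANCHORS = {
    # --- lateral founder pair 4 (C|D homologs, 1m-1122) and clone
    "1d-1122": (150.0, 62.0), "1c-1122": (30.0, 62.0),
    "1d-11221": (155.0, 82.0), "1c-11221": (25.0, 82.0),   # head kidneys
    "1d-11222": (147.0, 60.0), "1c-11222": (33.0, 60.0),
    # --- lateral founder pair 9 (A|B homologs, 1m-1122) and gland branch
    "1a-1122": (210.0, 62.0), "1b-1122": (330.0, 62.0),
    "1a-11221": (214.0, 56.0), "1b-11221": (326.0, 56.0),
    "1a-11222": (206.0, 66.0), "1b-11222": (334.0, 66.0),
    "1a-112211": (217.0, 53.0), "1b-112211": (323.0, 53.0),
    "1a-112212": (211.0, 58.0), "1b-112212": (329.0, 58.0),
    "1a-1122111": (219.0, 50.0), "1b-1122111": (321.0, 50.0),
    "1a-1122112": (211.0, 47.0), "1b-1122112": (329.0, 47.0),  # apoptotic
    "1a-1122121": (208.0, 56.0), "1b-1122121": (332.0, 56.0),  # phc2 terminal
    "1a-1122122": (212.0, 60.0), "1b-1122122": (328.0, 60.0),
    "1a-11221111": (224.0, 50.0), "1b-11221111": (316.0, 50.0),
    "1a-11221112": (214.0, 44.0), "1b-11221112": (326.0, 44.0),
    "1a-112211121": (224.0, 44.0), "1b-112211121": (316.0, 44.0),  # glands
    "1a-112211122": (214.0, 40.0), "1b-112211122": (326.0, 40.0),
    "1a-11221221": (217.0, 64.0), "1b-11221221": (323.0, 64.0),
    "1a-11221222": (205.0, 61.0), "1b-11221222": (335.0, 61.0),   # glands
    # --- dorso-medial stems (C|D, descendants of 1m-1121)
    "1d-1121": (125.0, 30.0), "1c-1121": (55.0, 30.0),
    "1d-11211": (115.0, 35.0), "1c-11211": (65.0, 35.0),
    "1d-11212": (132.0, 28.0), "1c-11212": (48.0, 28.0),
    "1c-112111": (70.0, 42.0),
    "1c-112112": (50.0, 47.0),
    "1d-112122": (112.0, 25.0),
    "1d-1121222": (95.0, 14.0),                 # dorsal medial phc2 terminal
    "1c-112121": (48.0, 22.0), "1c-112122": (34.0, 14.0),
    # founder pairs 1, 2, 3, 5 (non-corresponding C|D lineages)
    "1d-112111": (118.0, 40.0), "1c-1121121": (62.0, 40.0),   # pair 1
    "1d-112112": (128.0, 55.0), "1c-1121122": (52.0, 55.0),   # pair 2
    "1d-112121": (103.0, 48.0), "1c-1121111": (77.0, 48.0),   # pair 3
    "1d-1121221": (140.0, 38.0), "1c-1121112": (40.0, 38.0),  # pair 5
    # --- ventro-medial stems (A|B, descendants of 1m-1121)
    "1a-1121": (232.0, 30.0), "1b-1121": (308.0, 30.0),
    "1a-11211": (222.0, 38.0), "1b-11211": (318.0, 38.0),
    "1a-11212": (245.0, 27.0), "1b-11212": (295.0, 27.0),
    "1a-112112": (235.0, 45.0),
    "1a-112121": (250.0, 33.0),
    "1a-1121212": (240.0, 18.0),
    "1a-112122": (205.0, 20.0),
    "1b-112111": (322.0, 30.0),
    "1b-112112": (292.0, 18.0),
    "1b-1121112": (316.0, 22.0),
    "1b-1121122": (296.0, 26.0),
    "1b-112121": (310.0, 47.0), "1b-112122": (325.0, 40.0),
    # founder pairs 7, 8 (non-corresponding A|B), 10 (single quadrant, A)
    "1a-112111": (242.0, 40.0), "1b-1121121": (298.0, 40.0),  # pair 7
    "1a-1121122": (235.0, 57.0), "1b-1121111": (305.0, 57.0),  # pair 8
    "1a-1121211": (255.0, 60.0), "1a-1121121": (285.0, 60.0),  # pair 10
    # --- A|C clone (founder pair 6) and eyes; same scripted times both sides
    "1a-1211": (186.0, 50.0), "1c-1211": (354.0, 50.0),
    "1a-12111": (192.0, 44.0), "1c-12111": (348.0, 44.0),     # apoptotic
    "1a-12112": (183.0, 54.0), "1c-12112": (357.0, 54.0),
    "1a-121121": (188.0, 58.0), "1c-121121": (352.0, 58.0),
    "1a-121122": (182.0, 48.0), "1c-121122": (358.0, 48.0),
    "1a-1211211": (194.0, 62.0), "1c-1211211": (346.0, 62.0),  # eye pigment
    "1a-1211212": (184.0, 66.0), "1c-1211212": (356.0, 66.0),  # photoreceptor
    # --- B-quadrant 1b-12 clone and founder pair 11 (single quadrant, B)
    "1b-1211": (290.0, 48.0),
    "1b-12111": (272.0, 42.0), "1b-12112": (284.0, 46.0),
    "1b-12111a": (252.0, 30.0), "1b-12111b": (240.0, 24.0),
    "1b-12111ab": (250.0, 44.0),
    "1b-121121": (281.0, 40.0), "1b-121122": (295.0, 58.0),   # 121122 = gland
    "1b-121121a": (299.0, 52.0),
    "1b-12111aa": (262.0, 35.0), "1b-121121b": (278.0, 35.0),  # pair 11
    # --- apical organ cells
    "1c-1111": (70.0, 10.0), "1c-1112": (86.0, 19.0),   # ampullary cells
    "1d-1111": (146.0, 14.0), "1d-1112": (176.0, 22.0),  # apical dorsal cells
    "1a-1111": (242.0, 16.0), "1a-1112": (262.0, 23.0),
    "1a-11111": (234.0, 12.0), "1a-11112": (252.0, 19.0),
    # D-quadrant migrating lineages head for the prototroch gap (azimuth ~93)
    "1d-121": (110.0, 68.0), "1d-1222": (100.0, 72.0),
}


def anchor_position(name: LineageName) -> np.ndarray | None:
    """Anchor (unit-sphere xyz) for a scripted canonical cell, or None."""
    key = name.render()
    if key in _NAMED_ANCHORS:
        az, pol = _NAMED_ANCHORS[key]
        return sph(az, pol)
    base = QUADRANT_AZIMUTH.get(name.quadrant)
    if base is None:
        return None
    idx = name.index
    if idx in _PRIMARY_SLOTS:
        az = base + _PRIMARY_SLOTS[idx] + RING_PHASE
        # the ring gap between 1c-212 and 1d-221: push the flanking cells apart
        if key == "1c-212":
            az -= 3.5
        elif key == "1d-221":
            az += 3.5
        return sph(az, 72.0)
    if idx in _ACCESSORY_SLOTS:
        off, pol = _ACCESSORY_SLOTS[idx]
        return sph(base + off + ACC_PHASE, pol)
    if key == "1d-1221":  # D's single late accessory cell
        return sph(QUADRANT_AZIMUTH["D"] + 15.0 + ACC_PHASE, 60.0)
    if idx in _ROSETTE:
        off, pol = _ROSETTE[idx]
        return sph(base + off, pol)
    if idx in _EARLY_OFFSETS:
        off, pol = _EARLY_OFFSETS[idx]
        return sph(base + off + SPIRAL_TWIST, pol)
    return None


def growth_offset_direction(tag: str, u: np.ndarray) -> np.ndarray:
    """Deterministic tangent direction at u for spreading growth daughters."""
    e_az, e_pol = _tangent_basis(u)
    psi = 2.0 * math.pi * hash01("growdir", tag)
    return math.cos(psi) * e_az + math.sin(psi) * e_pol
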