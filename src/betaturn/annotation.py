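"""Geometric annotation of beta-turns from backbone coordinates.

A beta-turn is a stretch of four consecutive residues i..i+3, none of
which lies in an alpha-helix, whose Calpha(i)-Calpha(i+3) distance is
below 7 Angstrom.  The turn type is determined by the backbone torsions
(phi, psi) of the two central residues i+1 and i+2, following the
Hutchinson-Thornton classification into nine named types plus the
catch-all type IV.

This module computes backbone dihedrals from N/CA/C coordinates, applies
the geometric turn rule, classifies turn types against the ideal-angle
table, and derives the per-residue six-channel binary labels (turn, I,
II, IV, VIII, NS) used by the predictor.  Types other than I, II, IV and
VIII are grouped into the miscellaneous "non-specific" (NS) class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Residue",
    "BackboneStructure",
    "TurnRecord",
    "ResidueLabels",
    "UndefinedAngleError",
    "CHANNELS",
    "TURN_TYPES",
    "IDEAL_TURN_ANGLES",
    "dihedral_angle",
    "phi_psi",
    "classify_turn_type",
    "assign_beta_turns",
    "labels_from_turns",
]

#: Maximum Calpha(i)-Calpha(i+3) distance (A, exclusive) for a beta-turn.
TURN_DISTANCE_CUTOFF = 7.0

#: Consecutive CA-CA distance (A) above which a chain break is declared.
CHAIN_BREAK_CUTOFF = 4.5

#: The six binary label channels emitted per residue, in output order.
CHANNELS = ("turn", "I", "II", "IV", "VIII", "NS")

#: Ideal (phi1, psi1, phi2, psi2) of the central residues, by turn type.
#: Type IV has no ideal-angle definition: it is the catch-all for turns
#: matching none of the specific types.
IDEAL_TURN_ANGLES: dict[str, tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIa1": (-60.0, 120.0, -90.0, 0.0),
    "VIa2": (-120.0, 120.0, -60.0, 0.0),
    "VIb": (-135.0, 135.0, -175.0, 160.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}

#: Precedence order when several specific types match (table row order).
_TYPE_PRECEDENCE = ("I", "I'", "II", "II'", "VIa1", "VIa2", "VIb", "VIII")

#: All recognised turn type labels, including the catch-all.
TURN_TYPES = _TYPE_PRECEDENCE + ("IV",)

#: Mapping of turn type to label channel; rare/mirror types collapse to NS.
TYPE_TO_CHANNEL = {
    "I": "I",
    "II": "II",
    "IV": "IV",
    "VIII": "VIII",
    "I'": "NS",
    "II'": "NS",
    "VIa1": "NS",
    "VIa2": "NS",
    "VIb": "NS",
}


class UndefinedAngleError(ValueError):
    """Raised when a torsion angle is geometrically undefined."""


@dataclass(frozen=True)
class Residue:
    """One residue's backbone: 1-based index, one-letter code, N/CA/C coords (A)."""

    index: int
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray


@dataclass
class BackboneStructure:
    """An unbroken stretch of backbone (N, CA, C per residue) of one chain.

    Indices are strictly increasing and consecutive CA-CA distances must
    stay below the chain-break cutoff; readers split chains at breaks
    before constructing instances.
    """

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("BackboneStructure requires at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for a, b in zip(self.residues, self.residues[1:]):
            d = float(np.linalg.norm(b.ca - a.ca))
            if d >= CHAIN_BREAK_CUTOFF:
                raise ValueError(
                    f"chain break between residues {a.index} and {b.index} "
                    f"(CA-CA {d:.2f} A >= {CHAIN_BREAK_CUTOFF} A); split the chain first"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass(frozen=True)
class TurnRecord:
    """An assigned beta-turn: 1-based position of residue i, and its type."""

    start: int
    type: str

    def __post_init__(self) -> None:
        if self.type not in TURN_TYPES:
            raise ValueError(f"unknown turn type {self.type!r}")


@dataclass
class ResidueLabels:
    """Six parallel 0/1 label sequences over a chain: turn, I, II, IV, VIII, NS."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, length: int) -> "ResidueLabels":
        return cls({ch: np.zeros(length, dtype=np.uint8) for ch in CHANNELS})

    def __len__(self) -> int:
        return len(self.data["turn"])

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel]

    def validate(self) -> None:
        length = len(self)
        for ch in CHANNELS:
            arr = self.data[ch]
            if len(arr) != length:
                raise ValueError("label channels have unequal lengths")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"channel {ch} contains non-binary values")
        for ch in CHANNELS[1:]:
            if np.any(self.data[ch] > self.data["turn"]):
                raise ValueError(f"type channel {ch} set outside a turn")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Sign follows the IUPAC convention: looking from p2 towards p3, a
    clockwise rotation of the far bond relative to the near bond is
    positive.  Raises :class:`UndefinedAngleError` when either bonded
    triple is collinear (the torsion has no defined value).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedAngleError("collinear points: torsion undefined")
    b2u = b2 / np.linalg.norm(b2)
    angle = math.degrees(math.atan2(float(np.dot(np.cross(n1, n2), b2u)),
                                    float(np.dot(n1, n2))))
    # canonicalise -180 -> +180 so the range is (-180, 180]
    if angle <= -180.0:
        angle += 360.0
    return angle


def phi_psi(structure: BackboneStructure) -> list[tuple[float | None, float | None]]:
    """Backbone (phi, psi) per residue; None at undefined chain termini.

    phi(k) is the torsion C(k-1)-N(k)-CA(k)-C(k); psi(k) is
    N(k)-CA(k)-C(k)-N(k+1).  The first residue has no phi and the last
    no psi.
    """
    res = structure.residues
    out: list[tuple[float | None, float | None]] = []
    for k, r in enumerate(res):
        phi = psi = None
        if k > 0:
            phi = dihedral_angle(res[k - 1].c, r.n, r.ca, r.c)
        if k < len(res) - 1:
            psi = dihedral_angle(r.n, r.ca, r.c, res[k + 1].n)
        out.append((phi, psi))
    return out


def _circular_deviation(a: float, b: float) -> float:
    """Absolute angular difference folded into [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_turn_type(phi1: float, psi1: float, phi2: float, psi2: float) -> str:
    """Classify a turn from the central residues' torsions.

    A specific type matches when each of the four angles is within 30
    degrees (circular) of its ideal value, allowing exactly one of the
    four to deviate by up to 45 degrees.  The first matching type in
    table precedence order wins; if none matches, the catch-all type IV
    is returned.
    """
    observed = (phi1, psi1, phi2, psi2)
    for ttype in _TYPE_PRECEDENCE:
        ideal = IDEAL_TURN_ANGLES[ttype]
        devs = [_circular_deviation(o, i) for o, i in zip(observed, ideal)]
        over_30 = [d for d in devs if d > 30.0]
        if not over_30 or (len(over_30) == 1 and over_30[0] <= 45.0):
            return ttype
    return "IV"


def assign_beta_turns(structure: BackboneStructure,
                      helix_mask) -> list[TurnRecord]:
    """Assign beta-turns: windows i..i+3 with CA(i)-CA(i+3) < 7 A, helix-free.

    ``helix_mask`` is a per-residue 0/1 sequence; a window is rejected if
    any of its four residues is helix-masked.  Windows whose central
    residues have undefined torsions are skipped.  Overlapping turns are
    all reported.  Chains shorter than four residues yield no turns.
    """
    length = len(structure)
    helix_mask = np.asarray(helix_mask, dtype=int)
    if len(helix_mask) != length:
        raise ValueError("helix_mask length must equal chain length")
    if length < 4:
        return []
    ca = structure.ca_coords()
    angles = phi_psi(structure)
    turns: list[TurnRecord] = []
    for i in range(length - 3):
        if helix_mask[i:i + 4].any():
            continue
        if float(np.linalg.norm(ca[i] - ca[i + 3])) >= TURN_DISTANCE_CUTOFF:
            continue
        phi1, psi1 = angles[i + 1]
        phi2, psi2 = angles[i + 2]
        if phi1 is None or psi1 is None or phi2 is None or psi2 is None:
            continue
        ttype = classify_turn_type(phi1, psi1, phi2, psi2)
        turns.append(TurnRecord(start=structure.residues[i].index, type=ttype))
    return turns


def labels_from_turns(turns: list[TurnRecord], length: int,
                      index_offset: int = 1) -> ResidueLabels:
    """Derive the six per-residue 0/1 channels from assigned turns.

    Every residue of every turn window is marked in the ``turn`` channel;
    the type channel follows the turn's type, with the mirror and VI
    types mapped to NS.  Overlapping turns of different types may set
    several type channels at one position.  ``index_offset`` is the
    1-based index of the chain's first residue.
    """
    labels = ResidueLabels.zeros(length)
    for t in turns:
        lo = t.start - index_offset
        hi = lo + 4
        if lo < 0 or hi > length:
            raise ValueError(f"turn at {t.start} does not fit in chain of length {length}")
        labels["turn"][lo:hi] = 1
        labels[TYPE_TO_CHANNEL[t.type]][lo:hi] = 1
    labels.validate()
    return labels
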