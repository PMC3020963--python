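"""Structural annotation: helical wheel faces and NOE restraint bookkeeping.

An ideal alpha-helix advances 100 degrees per residue around the helical
axis.  Projecting side chains onto the plane perpendicular to the axis
(a "helical wheel") makes amphipathicity visible: charged/polar residues
cluster on one face, hydrophobic residues on the other.  The face split
here is geometric: the mean direction of the charged + polar side chains
defines the hydrophilic face, and every residue within 90 degrees of that
direction is assigned to it.

NOE distance restraints are classified by sequence separation |i - j|:
short range (<= 1), medium range (1 < |i - j| < 5) and long range (>= 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidueWheelEntry",
    "HelixAnnotation",
    "ConstraintRecord",
    "ConstraintCounts",
    "wheel",
    "classify_constraints",
    "synthetic_constraints",
    "read_constraints",
]

#: Physicochemical classes used for wheel coloring and face assignment.
RESIDUE_CLASSES = {
    "R": "positive", "K": "positive", "H": "positive",
    "D": "negative", "E": "negative",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar",
    "C": "polar", "Y": "polar",
    "A": "nonpolar", "V": "nonpolar", "L": "nonpolar", "I": "nonpolar",
    "M": "nonpolar", "F": "nonpolar", "W": "nonpolar",
    "G": "special", "P": "special",
}

#: Classes contributing to the hydrophilic mean vector.
HYDROPHILIC_CLASSES = frozenset({"positive", "negative", "polar"})

#: Ideal alpha-helical periodicity, degrees per residue.
HELIX_PERIOD_DEG = 100.0


@dataclass(frozen=True)
class ResidueWheelEntry:
    residue: str
    index: int  # sequence position
    wheel_angle: float  # degrees in [0, 360)
    residue_class: str
    face: str  # "A" (hydrophilic) or "B"


@dataclass
class HelixAnnotation:
    sequence: str
    start_index: int
    residues: tuple[ResidueWheelEntry, ...]
    reference_angle: float  # degrees; direction of the hydrophilic face
    degenerate: bool = False  # no hydrophilic residues: fallback applied

    def face_members(self, face: str) -> set[str]:
        """Residue labels (e.g. 'T13') on one face."""
        return {
            f"{r.residue}{r.index}" for r in self.residues if r.face == face
        }


def _circular_distance(a: float, b: float) -> float:
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def wheel(
    sequence: str,
    start_index: int = 1,
    phase_deg: float = 0.0,
    period_deg: float = HELIX_PERIOD_DEG,
) -> HelixAnnotation:
    """Helical-wheel projection with physicochemical face assignment.

    Residue i (0-based offset from ``start_index``) sits at
    ``phase_deg + period_deg * i`` (mod 360).  Face A collects residues
    within 90 degrees of the mean direction of the charged and polar side
    chains; everything else is face B.  A sequence without any charged or
    polar residue is flagged degenerate and assigned entirely to face A.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 4:
        raise ValueError("need at least 4 residues for a wheel projection")
    bad = sorted(set(sequence) - set(RESIDUE_CLASSES))
    if bad:
        raise ValueError(f"non-standard residue letter(s): {bad}")

    angles = (phase_deg + period_deg * np.arange(len(sequence))) % 360.0
    classes = [RESIDUE_CLASSES[r] for r in sequence]

    hyd = [
        i for i, cls in enumerate(classes) if cls in HYDROPHILIC_CLASSES
    ]
    degenerate = len(hyd) == 0
    if degenerate:
        ref = 0.0
        faces = ["A"] * len(sequence)
    else:
        rad = np.deg2rad(angles[hyd])
        ref = math.degrees(
            math.atan2(float(np.sin(rad).sum()), float(np.cos(rad).sum()))
        ) % 360.0
        faces = [
            "A" if _circular_distance(a, ref) <= 90.0 else "B" for a in angles
        ]

    residues = tuple(
        ResidueWheelEntry(
            residue=r,
            index=start_index + i,
            wheel_angle=float(angles[i]),
            residue_class=classes[i],
            face=faces[i],
        )
        for i, r in enumerate(sequence)
    )
    return HelixAnnotation(
        sequence=sequence,
        start_index=start_index,
        residues=residues,
        reference_angle=ref,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ConstraintRecord:
    residue_i: int
    residue_j: int
    upper_bound: float | None  # Angstrom
    range_class: str  # short | medium | long


@dataclass
class ConstraintCounts:
    short: int
    medium: int
    long: int
    total: int
    rejected: list[tuple]  # records with i == j
    n_residues: int
    per_residue: float  # total / n_residues
    per_residue_floor: int
    density: dict[int, int]  # constraints touching each residue

    records: list[ConstraintRecord] = field(default_factory=list)


def _range_class(i: int, j: int) -> str:
    sep = abs(i - j)
    if sep <= 1:
        return "short"
    if sep < 5:
        return "medium"
    return "long"


def classify_constraints(
    records,
    n_residues: int | None = None,
) -> ConstraintCounts:
    """Classify (i, j[, bound]) restraint records by sequence separation.

    The classes partition all valid pairs, so the per-class counts sum to
    the total.  Records with ``i == j`` are rejected and reported.  The
    per-residue density is ``total / n_residues`` (default: the largest
    residue index seen), reported both exactly and floored to an integer.
    """
    classified: list[ConstraintRecord] = []
    rejected: list[tuple] = []
    density: dict[int, int] = {}
    for rec in records:
        i, j = int(rec[0]), int(rec[1])
        bound = float(rec[2]) if len(rec) > 2 and rec[2] is not None else None
        if i == j:
            rejected.append(tuple(rec))
            continue
        if i < 1 or j < 1:
            raise ValueError("residue indices must be 1-based positive integers")
        classified.append(ConstraintRecord(i, j, bound, _range_class(i, j)))
        density[i] = density.get(i, 0) + 1
        density[j] = density.get(j, 0) + 1

    n_short = sum(1 for r in classified if r.range_class == "short")
    n_medium = sum(1 for r in classified if r.range_class == "medium")
    n_long = sum(1 for r in classified if r.range_class == "long")
    total = len(classified)
    if n_residues is None:
        n_residues = max(density) if density else 0
    per = total / n_residues if n_residues else math.nan
    return ConstraintCounts(
        short=n_short,
        medium=n_medium,
        long=n_long,
        total=total,
        rejected=rejected,
        n_residues=n_residues,
        per_residue=per,
        per_residue_floor=int(math.floor(per)) if n_residues else 0,
        density=dict(sorted(density.items())),
        records=classified,
    )


def synthetic_constraints(
    n_short: int = 1259,
    n_medium: int = 498,
    n_long: int = 877,
    n_residues: int = 135,
    seed: int = 0,
) -> list[tuple[int, int, float]]:
    """Random restraint list with prescribed per-class counts (synthetic).

    Pairs are drawn uniformly within each sequence-separation class over a
    chain of ``n_residues`` residues, with nominal 5 A upper bounds.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int, float]] = []
    for n, (lo, hi) in (
        (n_short, (0, 1)),
        (n_medium, (2, 4)),
        (n_long, (5, n_residues - 1)),
    ):
        for _ in range(n):
            sep = int(rng.integers(lo, hi + 1))
            if sep == 0:
                sep = 1  # i == j would be rejected downstream
            i = int(rng.integers(1, n_residues - sep + 1))
            out.append((i, i + sep, 5.0))
    return out


def read_constraints(path) -> list[tuple[int, int, float | None]]:
    """Read whitespace-delimited restraints: ``i j [upper_bound_A]`` per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            i, j = int(parts[0]), int(parts[1])
            bound = float(parts[2]) if len(parts) > 2 else None
            out.append((i, j, bound))
    return out
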