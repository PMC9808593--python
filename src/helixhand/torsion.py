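"""Backbone and glycosidic torsion angles of nucleic acids.

The seven dihedral angles that describe a nucleotide's conformation are
computed directly from atomic coordinates:

* backbone: alpha (O3'(i-1)-P-O5'-C5'), beta (P-O5'-C5'-C4'),
  gamma (O5'-C5'-C4'-C3'), delta (C5'-C4'-C3'-O3'),
  epsilon (C4'-C3'-O3'-P(i+1)), zeta (C3'-O3'-P(i+1)-O5'(i+1));
* glycosidic: chi, O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for
  pyrimidines.

All angles follow the IUPAC sign convention (cis = 0, trans = 180,
positive = clockwise looking from the second to the third atom) and are
reported in degrees on [0, 360).  The unsigned-interval convention is
deliberate: the classification thresholds this package works with
(e.g. an alpha split near 252 degrees) live on that scale, and a split
threshold theta is itself constrained to [0, 360].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical feature order used everywhere (split tie-breaks, CSV columns).
ANGLE_NAMES: tuple[str, ...] = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
)

#: Collinearity guard on cross-product norms (squared-A^2 scale); real
#: structures sit many orders of magnitude above this.
COLLINEARITY_TOL = 1e-8

PURINE_CHI = ("O4'", "C1'", "N9", "C4")
PYRIMIDINE_CHI = ("O4'", "C1'", "N1", "C2")


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is requested for (near-)collinear atoms."""


def wrap_angle(x: float) -> float:
    """Map an angle in degrees onto [0, 360).

    ``wrap_angle(-60) == 300``; ``wrap_angle(360) == 0``.
    """
    if not math.isfinite(x):
        raise ValueError(f"angle must be finite, got {x!r}")
    wrapped = float(x) % 360.0
    # a tiny negative input rounds to exactly 360.0 under the modulo
    return wrapped if wrapped < 360.0 else 0.0


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle of four points, in degrees on [0, 360).

    Uses the atan2 formulation on the two bond-plane normals, which is
    numerically stable for torsions near 0/180.  Raises
    :class:`DegenerateGeometryError` if either atom triplet is collinear
    (cross-product norm below ``COLLINEARITY_TOL``).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEARITY_TOL or np.linalg.norm(n2) < COLLINEARITY_TOL:
        raise DegenerateGeometryError(
            "collinear atom triplet: torsion angle is undefined"
        )
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(math.degrees(math.atan2(y, x)))


@dataclass
class TorsionProfile:
    """The seven torsion angles of one nucleotide plus its identity.

    Angles are degrees on [0, 360) or ``None`` when the defining atoms are
    absent (5'-terminal residues lack alpha/beta, 3'-terminal residues lack
    epsilon/zeta).  A missing angle is always recorded explicitly, never
    silently replaced by zero.
    """

    source: str = ""
    chain: str = ""
    residue_seq: int = 0
    base: str = ""
    structural_class: str = ""
    label: Optional[int] = None
    tract_position: Optional[int] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    epsilon: Optional[float] = None
    zeta: Optional[float] = None
    chi: Optional[float] = None

    def angles(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in ANGLE_NAMES}

    @property
    def complete(self) -> bool:
        return all(getattr(self, name) is not None for name in ANGLE_NAMES)

    def missing(self) -> list[str]:
        return [name for name in ANGLE_NAMES if getattr(self, name) is None]


def _quadruple(unit, spec) -> Optional[list[np.ndarray]]:
    """Resolve an atom-name quadruple against a nucleotide and its links.

    ``spec`` entries are (owner, atom_name) with owner one of
    'prev'/'self'/'next'.  Returns None if any atom is unavailable.
    """
    points = []
    for owner, name in spec:
        if owner == "self":
            holder = unit
        elif owner == "prev":
            holder = unit.prev
        else:
            holder = unit.next
        if holder is None or name not in holder.atoms:
            return None
        points.append(holder.atoms[name])
    return points


def compute_profile(unit) -> TorsionProfile:
    """Compute all available torsion angles of one linked nucleotide.

    ``unit`` is a :class:`~helixhand.structure_io.NucleotideUnit` whose
    ``prev``/``next`` links were set from O3'-P connectivity.  Each angle is
    computed whenever its four atoms exist; otherwise it is left missing and
    a debug message records why.  Degenerate geometry in a real structure is
    treated as a missing angle with a warning rather than a failure.
    """
    base = unit.parent_base
    chi_spec = PURINE_CHI if base in ("A", "G") else PYRIMIDINE_CHI
    quadruples = {
        "alpha": (("prev", "O3'"), ("self", "P"), ("self", "O5'"), ("self", "C5'")),
        "beta": (("self", "P"), ("self", "O5'"), ("self", "C5'"), ("self", "C4'")),
        "gamma": (("self", "O5'"), ("self", "C5'"), ("self", "C4'"), ("self", "C3'")),
        "delta": (("self", "C5'"), ("self", "C4'"), ("self", "C3'"), ("self", "O3'")),
        "epsilon": (("self", "C4'"), ("self", "C3'"), ("self", "O3'"), ("next", "P")),
        "zeta": (("self", "C3'"), ("self", "O3'"), ("next", "P"), ("next", "O5'")),
        "chi": tuple(("self", name) for name in chi_spec),
    }
    profile = TorsionProfile(
        source=getattr(unit, "source", ""),
        chain=unit.chain_id,
        residue_seq=unit.residue_seq,
        base=base,
        structural_class=getattr(unit, "structural_class", "") or "",
        label=getattr(unit, "label", None),
        tract_position=getattr(unit, "tract_position", None),
    )
    for name, spec in quadruples.items():
        points = _quadruple(unit, spec)
        if points is None:
            logger.debug(
                "%s %s/%s: angle %s missing (atoms unavailable)",
                profile.source, unit.chain_id, unit.residue_seq, name,
            )
            continue
        try:
            setattr(profile, name, dihedral(*points))
        except DegenerateGeometryError:
            logger.warning(
                "%s %s/%s: angle %s degenerate, recorded as missing",
                profile.source, unit.chain_id, unit.residue_seq, name,
            )
    return profile
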