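"""Synthetic torsion-profile datasets and idealized PDB fixtures.

Two generators, both fully seed-reproducible:

* :func:`sample_dataset` draws labeled seven-angle feature vectors from
  per-class wrapped-normal mixtures.  The default parameterization
  (:func:`default_paper_spec`) emulates the class-conditional structure
  reported for the four structural families — left-handed quadruplex
  guanosine alpha concentrated on 150-200 degrees around 180, right-handed
  quadruplex alpha above 250 peaking at 300, a bimodal epsilon/zeta split
  between the first and second guanosine of each left-handed tract,
  Z-DNA's alternating syn-guanosine / anti-cytidine dinucleotide step, and
  a broad B-DNA spread with alpha on 240-360.  Angles are drawn
  independently within a subpopulation; real backbones covary, which the
  generator deliberately does not model.

* :func:`make_fixture_structure` builds small geometrically valid PDB
  chains from internal coordinates with every backbone and glycosidic
  torsion set to a known value, so the coordinate-to-angle stack can be
  tested against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .structure_io import AtomRecord, class_label, write_pdb
from .torsion import ANGLE_NAMES, wrap_angle


# ---------------------------------------------------------------------------
# distribution spec
# ---------------------------------------------------------------------------

@dataclass
class WrappedNormalComponent:
    """One wrapped-normal mixture component (degrees)."""

    mean: float
    sd: float
    weight: float = 1.0

    def validate(self):
        if not 0.0 <= self.mean < 360.0:
            raise ValueError(f"component mean {self.mean} outside [0, 360)")
        if self.sd <= 0:
            raise ValueError(f"component sd must be positive, got {self.sd}")
        if self.weight < 0:
            raise ValueError("component weight must be nonnegative")


@dataclass
class AngleMixture:
    components: list[WrappedNormalComponent]

    def validate(self):
        if not self.components:
            raise ValueError("angle mixture needs at least one component")
        for c in self.components:
            c.validate()
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights sum to {total}, expected 1")


@dataclass
class SubPopulation:
    """A recurring nucleotide kind within a class (cycled in order).

    Cycling subpopulations realizes within-class alternation: the two
    tract positions of left-handed quadruplex guanosines, or Z-DNA's
    syn-G / anti-C dinucleotide step.
    """

    name: str
    base: str
    angles: dict[str, AngleMixture]
    tract_position: Optional[int] = None

    def validate(self):
        missing = [a for a in ANGLE_NAMES if a not in self.angles]
        if missing:
            raise ValueError(f"subpopulation {self.name}: missing angles {missing}")
        for mixture in self.angles.values():
            mixture.validate()


@dataclass
class ClassSpec:
    structural_class: str
    n_samples: int
    subpopulations: list[SubPopulation]

    @property
    def label(self) -> int:
        return class_label(self.structural_class)

    def validate(self):
        if self.n_samples < 0:
            raise ValueError("per-class sample count must be nonnegative")
        if not self.subpopulations:
            raise ValueError(f"{self.structural_class}: no subpopulations")
        for sp in self.subpopulations:
            sp.validate()


@dataclass
class SyntheticSpec:
    """Per-class, per-angle generator parameters."""

    classes: dict[str, ClassSpec]

    def validate(self) -> "SyntheticSpec":
        for name, cls in self.classes.items():
            if name != cls.structural_class:
                raise ValueError(f"class key {name} != {cls.structural_class}")
            cls.validate()
        return self

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "SyntheticSpec":
        path = Path(str(source))
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text)
        classes = {}
        for cname, cdata in raw["classes"].items():
            subpops = []
            for sp in cdata["subpopulations"]:
                angles = {
                    angle: AngleMixture([
                        WrappedNormalComponent(float(m), float(s), float(w))
                        for m, s, w in comps
                    ])
                    for angle, comps in sp["angles"].items()
                }
                subpops.append(SubPopulation(
                    name=sp["name"],
                    base=sp["base"],
                    angles=angles,
                    tract_position=sp.get("tract_position"),
                ))
            classes[cname] = ClassSpec(
                structural_class=cname,
                n_samples=int(cdata["n_samples"]),
                subpopulations=subpops,
            )
        return cls(classes=classes).validate()

    def with_counts(self, **counts: int) -> "SyntheticSpec":
        """Copy of the spec with per-class sample counts replaced."""
        import copy
        spec = copy.deepcopy(self)
        for cname, n in counts.items():
            if cname not in spec.classes:
                raise KeyError(f"unknown class {cname}")
            spec.classes[cname].n_samples = int(n)
        return spec.validate()


def default_paper_spec() -> SyntheticSpec:
    """The shipped default generator parameterization.

    Loads ``data/default_torsion_spec.yaml`` (editable package data).  The
    per-class sample counts default to the curated-structure dataset sizes
    (125 LHG4 / 88 RHG4 / 76 Z-DNA / 175 B-DNA nucleotides).
    """
    text = resources.files("helixhand").joinpath(
        "data/default_torsion_spec.yaml"
    ).read_text()
    return SyntheticSpec.from_yaml(text)


def sample_dataset(
    spec: SyntheticSpec,
    seed: int = 0,
    classes: Optional[Sequence[str]] = None,
    name: str = "synthetic",
) -> Dataset:
    """Draw a labeled dataset from a generator spec.

    Each sample independently picks its mixture component per angle by
    weight and draws a wrapped normal, wrapped to [0, 360).  Samples cycle
    through the class's subpopulations in order.  Identical seeds yield
    identical datasets.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    selected = classes if classes is not None else list(spec.classes)
    rows = []
    for cname in selected:
        cls = spec.classes[cname]
        if cls.n_samples == 0:
            continue
        for i in range(cls.n_samples):
            sp = cls.subpopulations[i % len(cls.subpopulations)]
            row = {
                "pdb_id": f"SYN_{cname}",
                "chain": "A",
                "resseq": i + 1,
                "base": sp.base,
                "class": cname,
                "label": cls.label,
                "tract_position": sp.tract_position,
            }
            for angle in ANGLE_NAMES:
                mixture = sp.angles[angle]
                if len(mixture.components) == 1:
                    comp = mixture.components[0]
                else:
                    weights = [c.weight for c in mixture.components]
                    comp = mixture.components[
                        rng.choice(len(mixture.components), p=weights)
                    ]
                row[angle] = wrap_angle(rng.normal(comp.mean, comp.sd))
            rows.append(row)
    if not rows:
        raise ValueError("spec produced no samples (all class counts zero?)")
    frame = pd.DataFrame(rows)
    if frame["tract_position"].isna().all():
        frame = frame.drop(columns=["tract_position"])
    return Dataset(frame, name)


def g4_dataset(spec: Optional[SyntheticSpec] = None, seed: int = 0) -> Dataset:
    """Quadruplex-only draw (LHG4 + RHG4), named "G4"."""
    spec = spec or default_paper_spec()
    return sample_dataset(spec, seed, classes=["LHG4", "RHG4"], name="G4")


def duplex_dataset(spec: Optional[SyntheticSpec] = None, seed: int = 0) -> Dataset:
    """Duplex-only draw (ZDNA + BDNA), named "DH"."""
    spec = spec or default_paper_spec()
    return sample_dataset(spec, seed, classes=["ZDNA", "BDNA"], name="DH")


# ---------------------------------------------------------------------------
# idealized PDB fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("idealized-duplex", "idealized-quadruplex-column")

#: default generating torsions per fixture kind (degrees)
_KIND_TORSIONS = {
    "idealized-duplex": {
        "alpha": 300.0, "beta": 175.0, "gamma": 55.0, "delta": 130.0,
        "epsilon": 190.0, "zeta": 265.0, "chi": 250.0,
    },
    "idealized-quadruplex-column": {
        "alpha": 300.0, "beta": 180.0, "gamma": 55.0, "delta": 135.0,
        "epsilon": 215.0, "zeta": 255.0, "chi": 250.0,
    },
}

_KIND_BASES = {
    "idealized-duplex": ("DC", "DG"),
    "idealized-quadruplex-column": ("DG",),
}

# idealized bond lengths (A) and angles (degrees)
_B = {
    "O5'-C5'": 1.44, "C5'-C4'": 1.51, "C4'-C3'": 1.52, "C3'-O3'": 1.42,
    "O3'-P": 1.60, "P-O5'": 1.59, "C4'-O4'": 1.45, "O4'-C1'": 1.42,
    "C1'-N": 1.48, "N-C": 1.37,
}
_A = {
    "O5'-C5'-C4'": 110.0, "C5'-C4'-C3'": 116.0, "C4'-C3'-O3'": 111.0,
    "C3'-O3'-P": 119.0, "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.0,
    "O5'-C5'-C4'(next)": 110.0, "C5'-C4'-O4'": 110.0, "C4'-O4'-C1'": 109.0,
    "O4'-C1'-N": 108.0, "C1'-N-C": 127.0,
}


def _unit(v):
    return v / np.linalg.norm(v)


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d bonded to c with given internal coordinates.

    The natural-extension reference frame construction: |cd| = bond,
    angle(b, c, d) = angle_deg and dihedral(a, b, c, d) = torsion_deg in
    the IUPAC sign convention.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_fixture_structure(
    kind: str,
    n_residues: int,
    torsion_overrides: Optional[dict[int, dict[str, float]]] = None,
    chain_id: str = "A",
    return_records: bool = False,
):
    """Build an idealized nucleotide chain as PDB text with known torsions.

    The first residue is a 5'-OH terminus (no phosphate), so residue 1 has
    no alpha/beta and residue n no epsilon/zeta — exactly the angles a
    chain-terminal nucleotide cannot have.  ``torsion_overrides`` maps
    residue numbers (1-based) to per-angle replacement values.  Returns
    the PDB text and, per residue, the ground-truth generating torsions
    (only the angles that exist for that residue).  With
    ``return_records=True`` the full-precision in-memory atom records are
    returned as a third element (PDB text truncates coordinates to three
    decimals, which limits angle recovery from re-parsed files to roughly
    0.1 degree).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unsupported fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if n_residues < 2:
        raise ValueError("fixtures need at least 2 residues")
    overrides = torsion_overrides or {}
    base_cycle = _KIND_BASES[kind]
    defaults = _KIND_TORSIONS[kind]

    def torsion_of(resseq: int, angle: str) -> float:
        return float(overrides.get(resseq, {}).get(angle, defaults[angle]))

    atoms: dict[int, dict[str, np.ndarray]] = {i: {} for i in range(1, n_residues + 1)}
    # seed frame: 5'-OH terminus
    atoms[1]["O5'"] = np.array([0.0, 0.0, 0.0])
    atoms[1]["C5'"] = np.array([_B["O5'-C5'"], 0.0, 0.0])
    ang = math.radians(_A["O5'-C5'-C4'"])
    atoms[1]["C4'"] = atoms[1]["C5'"] + _B["C5'-C4'"] * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )

    truth: list[dict[str, float]] = []
    for i in range(1, n_residues + 1):
        res = atoms[i]
        res["C3'"] = _nerf(res["O5'"], res["C5'"], res["C4'"],
                           _B["C4'-C3'"], _A["C5'-C4'-C3'"], torsion_of(i, "gamma"))
        res["O4'"] = _nerf(res["O5'"], res["C5'"], res["C4'"],
                           _B["C4'-O4'"], _A["C5'-C4'-O4'"],
                           torsion_of(i, "gamma") + 122.0)
        res["C1'"] = _nerf(res["C5'"], res["C4'"], res["O4'"],
                           _B["O4'-C1'"], _A["C4'-O4'-C1'"], 242.0)
        purine = _KIND_BASES[kind][(i - 1) % len(base_cycle)] in ("DG", "DA")
        n_name, c_name = ("N9", "C4") if purine else ("N1", "C2")
        res[n_name] = _nerf(res["C4'"], res["O4'"], res["C1'"],
                            _B["C1'-N"], _A["O4'-C1'-N"], 240.0)
        res[c_name] = _nerf(res["O4'"], res["C1'"], res[n_name],
                            _B["N-C"], _A["C1'-N-C"], torsion_of(i, "chi"))
        res["O3'"] = _nerf(res["C5'"], res["C4'"], res["C3'"],
                           _B["C3'-O3'"], _A["C4'-C3'-O3'"], torsion_of(i, "delta"))

        record = {
            "gamma": torsion_of(i, "gamma"),
            "delta": torsion_of(i, "delta"),
            "chi": torsion_of(i, "chi"),
        }
        if i > 1:
            record["alpha"] = torsion_of(i, "alpha")
            record["beta"] = torsion_of(i, "beta")
        if i < n_residues:
            record["epsilon"] = torsion_of(i, "epsilon")
            record["zeta"] = torsion_of(i, "zeta")
            nxt = atoms[i + 1]
            nxt["P"] = _nerf(res["C4'"], res["C3'"], res["O3'"],
                             _B["O3'-P"], _A["C3'-O3'-P"], torsion_of(i, "epsilon"))
            nxt["O5'"] = _nerf(res["C3'"], res["O3'"], nxt["P"],
                               _B["P-O5'"], _A["O3'-P-O5'"], torsion_of(i, "zeta"))
            nxt["C5'"] = _nerf(res["O3'"], nxt["P"], nxt["O5'"],
                               _B["O5'-C5'"], _A["P-O5'-C5'"],
                               torsion_of(i + 1, "alpha"))
            nxt["C4'"] = _nerf(nxt["P"], nxt["O5'"], nxt["C5'"],
                               _B["C5'-C4'"], _A["O5'-C5'-C4'(next)"],
                               torsion_of(i + 1, "beta"))
        truth.append(record)

    records = []
    atom_order = ["P", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C1'",
                  "N9", "C4", "N1", "C2"]
    for i in range(1, n_residues + 1):
        resname = base_cycle[(i - 1) % len(base_cycle)]
        for name in atom_order:
            if name not in atoms[i]:
                continue
            records.append(AtomRecord(
                name=name,
                residue_name=resname,
                chain_id=chain_id,
                residue_seq=i,
                position=atoms[i][name],
                occupancy=1.0,
                element=name[0],
            ))
    if return_records:
        return write_pdb(records), truth, records
    return write_pdb(records), truth
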