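"""Labeled torsion-angle feature tables.

A :class:`Dataset` is a thin, validated wrapper around a pandas DataFrame
with one row per nucleotide: provenance columns (pdb_id, chain, resseq,
base, class, label, optionally tract_position) followed by the seven angle
features in canonical order.  Profiles with any missing angle are excluded
at assembly time — there is no imputation, so chain-terminal nucleotides
(which lack alpha/beta or epsilon/zeta) never enter a feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .torsion import ANGLE_NAMES, TorsionProfile

logger = logging.getLogger(__name__)

PROVENANCE_COLUMNS = ("pdb_id", "chain", "resseq", "base", "class", "label")
CSV_COLUMNS = PROVENANCE_COLUMNS + ANGLE_NAMES


class EmptyDatasetError(ValueError):
    """No samples survived assembly/selection."""


@dataclass
class LabeledSample:
    """One feature vector with its handedness label and provenance."""

    features: np.ndarray  # 7-vector, canonical angle order, degrees
    label: int
    pdb_id: str = ""
    structural_class: str = ""
    base: str = ""
    chain: str = ""
    resseq: int = 0
    tract_position: Optional[int] = None

    def __getattr__(self, name):
        if name in ANGLE_NAMES:
            return float(self.features[ANGLE_NAMES.index(name)])
        raise AttributeError(name)


class Dataset:
    """An ordered collection of labeled torsion-angle samples."""

    def __init__(self, frame: pd.DataFrame, name: str = ""):
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame lacks columns: {missing}")
        frame = frame.reset_index(drop=True)
        angles = frame[list(ANGLE_NAMES)].to_numpy(dtype=float)
        if np.isnan(angles).any():
            raise ValueError("dataset contains missing angle values")
        if ((angles < 0) | (angles >= 360)).any():
            raise ValueError("angles must lie in [0, 360)")
        if not frame["label"].isin([0, 1]).all():
            raise ValueError("labels must be 0 (LH) or 1 (RH)")
        self.frame = frame
        self.name = name

    # -- container basics ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterable[LabeledSample]:
        for _, row in self.frame.iterrows():
            yield LabeledSample(
                features=row[list(ANGLE_NAMES)].to_numpy(dtype=float),
                label=int(row["label"]),
                pdb_id=str(row["pdb_id"]),
                structural_class=str(row["class"]),
                base=str(row["base"]),
                chain=str(row["chain"]),
                resseq=int(row["resseq"]),
                tract_position=(
                    int(row["tract_position"])
                    if "tract_position" in row and pd.notna(row["tract_position"])
                    else None
                ),
            )

    def feature_matrix(self, features: Sequence[str] = ANGLE_NAMES) -> np.ndarray:
        return self.frame[list(features)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int(np.sum(y == 0)), int(np.sum(y == 1))

    def subset(self, indices, name: str = "") -> "Dataset":
        return Dataset(self.frame.iloc[np.asarray(indices)], name or self.name)

    def concat(self, other: "Dataset", name: str = "") -> "Dataset":
        cols = [c for c in self.frame.columns if c in other.frame.columns]
        merged = pd.concat(
            [self.frame[cols], other.frame[cols]], ignore_index=True
        )
        return Dataset(merged, name or f"{self.name}+{other.name}")

    # -- IO ------------------------------------------------------------------
    def to_csv(self, path: Union[str, Path, None] = None) -> Optional[str]:
        cols = list(CSV_COLUMNS)
        if "tract_position" in self.frame.columns:
            cols.insert(len(PROVENANCE_COLUMNS), "tract_position")
        out = self.frame[cols]
        if path is None:
            return out.to_csv(index=False)
        out.to_csv(path, index=False)
        return None

    @classmethod
    def from_csv(cls, path: Union[str, Path], name: str = "") -> "Dataset":
        frame = pd.read_csv(path)
        return cls(frame, name or Path(str(path)).stem)

    def __repr__(self):
        n_lh, n_rh = self.class_counts()
        return f"Dataset({self.name!r}, n={len(self)}, LH={n_lh}, RH={n_rh})"


def build_dataset(
    profiles: Sequence[TorsionProfile],
    name: str = "",
    require_complete: bool = True,
) -> Dataset:
    """Assemble torsion profiles into a labeled feature table.

    Profiles with any missing angle are excluded and logged with the
    missing angle names; an assembly that leaves no samples raises
    :class:`EmptyDatasetError`.
    """
    rows = []
    n_dropped = 0
    for p in profiles:
        if require_complete and not p.complete:
            n_dropped += 1
            logger.info(
                "excluding %s %s/%s: missing angle(s) %s",
                p.source, p.chain, p.residue_seq, ", ".join(p.missing()),
            )
            continue
        if p.label is None:
            raise ValueError(
                f"profile {p.source} {p.chain}/{p.residue_seq} carries no label"
            )
        row = {
            "pdb_id": p.source,
            "chain": p.chain,
            "resseq": p.residue_seq,
            "base": p.base,
            "class": p.structural_class,
            "label": int(p.label),
            "tract_position": p.tract_position,
        }
        row.update({a: getattr(p, a) for a in ANGLE_NAMES})
        rows.append(row)
    if not rows:
        raise EmptyDatasetError(
            f"no complete labeled profiles to assemble ({n_dropped} dropped)"
        )
    if n_dropped:
        logger.info("dataset %s: %d incomplete profile(s) excluded", name, n_dropped)
    frame = pd.DataFrame(rows)
    if frame["tract_position"].isna().all():
        frame = frame.drop(columns=["tract_position"])
    return Dataset(frame, name)


def class_proportion(ds: Dataset, label: int) -> float:
    """Percentage of samples carrying ``label`` (the majority baseline)."""
    if len(ds) == 0:
        raise EmptyDatasetError("cannot take proportions of an empty dataset")
    return 100.0 * float(np.sum(ds.labels == label)) / len(ds)


def angle_histograms(
    ds: Dataset, bin_width: float = 10.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-class, per-angle binned counts over [0, 360).

    Returns ``{(structural_class, angle): counts}`` with
    ``360 / bin_width`` bins; counts per class and angle sum to the class
    size.  ``bin_width`` must divide 360.
    """
    if bin_width <= 0 or not np.isclose(360.0 % bin_width, 0):
        raise ValueError("bin width must be a positive divisor of 360")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    out: dict[tuple[str, str], np.ndarray] = {}
    for cls, group in ds.frame.groupby("class", sort=True):
        for angle in ANGLE_NAMES:
            counts, _ = np.histogram(group[angle].to_numpy(float), bins=edges)
            out[(str(cls), angle)] = counts
    return out


def histogram_bin_edges(bin_width: float = 10.0) -> np.ndarray:
    n_bins = int(round(360.0 / bin_width))
    return np.linspace(0.0, 360.0, n_bins + 1)
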