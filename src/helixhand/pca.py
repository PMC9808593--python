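"""Two-component PCA of the seven-angle feature table.

The feature matrix is mean-centered (no variance scaling — all features
share the same unit, degrees) and decomposed by SVD; the first two right
singular vectors are the principal axes, with the sign convention that
each component's largest-magnitude loading is positive.  Explained
variance ratios come from the squared singular values.  Angles enter as
plain linear values on [0, 360), consistent with the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dataset import Dataset
from .torsion import ANGLE_NAMES


class DegenerateDataError(ValueError):
    """All samples identical: no principal directions exist."""


@dataclass
class PCAResult:
    """Fitted two-component PCA with projected training coordinates."""

    components: np.ndarray  # (2, 7), orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,), descending
    mean_vector: np.ndarray  # (7,), degrees
    projected: np.ndarray  # (n, 2)
    provenance: pd.DataFrame  # pdb_id / class / base / label per sample

    @property
    def component_1(self) -> np.ndarray:
        return self.components[0]

    @property
    def component_2(self) -> np.ndarray:
        return self.components[1]

    def coordinates_frame(self) -> pd.DataFrame:
        out = self.provenance.copy()
        out["pc1"] = self.projected[:, 0]
        out["pc2"] = self.projected[:, 1]
        return out

    def to_csv(self, path: Union[str, Path, None] = None) -> Optional[str]:
        frame = self.coordinates_frame()
        if path is None:
            return frame.to_csv(index=False)
        frame.to_csv(path, index=False)
        return None


def fit_pca(ds: Dataset) -> PCAResult:
    """Fit a two-component PCA to a dataset's angle features.

    Mean-centering only; components from the SVD of the centered matrix.
    Requires at least 3 samples and non-degenerate (not all identical)
    data.
    """
    if len(ds) < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = ds.feature_matrix()
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-12):
        raise DegenerateDataError("all samples identical; PCA is undefined")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(2):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    components = vt[:2]
    total = float(np.sum(s ** 2))
    ratios = (s[:2] ** 2) / total
    provenance_cols = [
        c for c in ("pdb_id", "chain", "resseq", "base", "class", "label",
                    "tract_position")
        if c in ds.frame.columns
    ]
    return PCAResult(
        components=components,
        explained_variance_ratio=ratios,
        mean_vector=mean,
        projected=Xc @ components.T,
        provenance=ds.frame[provenance_cols].copy(),
    )


def project(res: PCAResult, samples) -> np.ndarray:
    """Project complete samples onto the fitted components.

    ``samples`` may be a Dataset or an (n, 7) matrix in canonical angle
    order; the mean sample maps to (0, 0).
    """
    if hasattr(samples, "feature_matrix"):
        X = samples.feature_matrix()
    else:
        X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[1] != len(ANGLE_NAMES):
        raise ValueError(f"expected {len(ANGLE_NAMES)} features per sample")
    if np.isnan(X).any():
        raise ValueError("samples contain missing features")
    return (X - res.mean_vector) @ res.components.T


def plot_projection(res: PCAResult, path: Union[str, Path]) -> None:
    """Scatter the projected coordinates colored by structural class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = res.coordinates_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, group in frame.groupby("class"):
        ax.scatter(group["pc1"], group["pc2"], s=12, label=str(cls), alpha=0.7)
    var1, var2 = 100 * res.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({var1:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({var2:.1f}% variance)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
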