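"""Repeated random holdout validation and transfer experiments.

The evaluation protocol: a labeled dataset is split 70/30 into train and
test at random, an entropy decision tree is grown on the training split
and cost-complexity pruned, and accuracy (correct / total) is scored on
the held-out split; the whole procedure is repeated (1000 iterations by
default) with a fresh random partition each time, and the per-iteration
accuracies are summarized by their mean and standard deviation.

The transfer experiment measures how well handedness thresholds learned
on quadruplexes generalize to duplexes: per iteration, k duplex (B-/Z-DNA)
samples are mixed into the quadruplex training split and the tree is then
scored both on the held-out quadruplex split and on every duplex sample
that was not drawn into training.

All randomness flows from explicit integer seeds (iteration i uses
base_seed + i), so every report is reproducible bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import id3
from .dataset import Dataset
from .torsion import ANGLE_NAMES

DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_ITERATIONS = 1000


@dataclass
class ValidationReport:
    """Per-iteration accuracies and root-split records of one experiment."""

    accuracies: list[float]
    first_splits: list[Optional[tuple[str, float]]]
    n_iterations: int
    base_seed: int
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    complexity_parameter: float = id3.DEFAULT_CCP_ALPHA

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "base_seed": self.base_seed,
            "train_fraction": self.train_fraction,
            "complexity_parameter": self.complexity_parameter,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "min_accuracy": float(np.min(self.accuracies)),
            "max_accuracy": float(np.max(self.accuracies)),
        }

    def to_json(self, path: Union[str, Path, None] = None) -> Optional[str]:
        text = json.dumps(self.summary(), indent=2)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    def per_iteration_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "accuracy": self.accuracies,
            "first_split_feature": [
                (fs[0] if fs else "") for fs in self.first_splits
            ],
            "first_split_theta": [
                (fs[1] if fs else np.nan) for fs in self.first_splits
            ],
        })


def holdout_split(
    ds: Dataset,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Uniform random train/test partition.

    The test split takes ceil((1 - train_fraction) * N) samples (70/30 on
    213 nucleotides gives 149 train / 64 test), the training split the
    remainder; the two are disjoint and exhaustive by construction.
    """
    n = len(ds)
    counts = ds.class_counts()
    if min(counts) < 2:
        raise ValueError(
            f"holdout validation needs >= 2 samples per class, got {counts}"
        )
    # tiny epsilon guards float artifacts like (1 - 0.7) * 10 = 3.0000000004
    n_test = math.ceil((1.0 - train_fraction) * n - 1e-9)
    if n_test < 1 or n - n_test < 1:
        raise ValueError("dataset too small for the requested split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    assert len(np.intersect1d(train_idx, test_idx)) == 0
    assert len(train_idx) + len(test_idx) == n
    return ds.subset(train_idx, "train"), ds.subset(test_idx, "test")


def _train_and_score(
    train: Dataset,
    test: Dataset,
    candidate_features: Optional[Sequence[str]],
    ccp_alpha: float,
) -> tuple[float, Optional[tuple[str, float]], id3.TreeNode]:
    tree = id3.grow_tree(train, candidate_features=candidate_features)
    tree = id3.prune(tree, ccp_alpha)
    acc = id3.accuracy(tree, test)
    first = None if tree.is_leaf else (tree.feature, tree.threshold)
    return acc, first, tree


def repeated_holdout(
    ds: Dataset,
    n_iterations: int = DEFAULT_ITERATIONS,
    base_seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    complexity_parameter: float = id3.DEFAULT_CCP_ALPHA,
    candidate_features: Optional[Sequence[str]] = None,
) -> ValidationReport:
    """Repeated random 70/30 holdout evaluation of the pruned tree.

    Iteration i draws its partition from seed ``base_seed + i``; the
    report records each held-out accuracy and each tree's root split.
    """
    accuracies: list[float] = []
    first_splits: list[Optional[tuple[str, float]]] = []
    for i in range(n_iterations):
        train, test = holdout_split(ds, train_fraction, base_seed + i)
        acc, first, _ = _train_and_score(
            train, test, candidate_features, complexity_parameter
        )
        accuracies.append(acc)
        first_splits.append(first)
    return ValidationReport(
        accuracies=accuracies,
        first_splits=first_splits,
        n_iterations=n_iterations,
        base_seed=base_seed,
        train_fraction=train_fraction,
        complexity_parameter=complexity_parameter,
    )


DEFAULT_K_VALUES = (0, 10, 20, 30, 40, 50)


@dataclass
class TransferTable:
    """Mean accuracies (percent) by number of duplex samples added."""

    frame: pd.DataFrame  # columns: dh_samples_added, g4_accuracy, dh_accuracy
    n_iterations: int
    base_seed: int

    def to_csv(self, path: Union[str, Path, None] = None) -> Optional[str]:
        if path is None:
            return self.frame.to_csv(index=False)
        self.frame.to_csv(path, index=False)
        return None


def transfer_experiment(
    g4: Dataset,
    dh: Dataset,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    n_iterations: int = DEFAULT_ITERATIONS,
    base_seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    complexity_parameter: float = id3.DEFAULT_CCP_ALPHA,
) -> TransferTable:
    """Duplex-transfer experiment: augment quadruplex training with k
    duplex samples and score both families.

    Per iteration and per k: the quadruplex set is split 70/30 (the same
    seeds as :func:`repeated_holdout`, so k = 0 reproduces its
    accuracies exactly); k duplex samples are drawn uniformly without
    replacement and appended to the training split; the pruned tree is
    scored on the held-out quadruplex split and on all duplex samples not
    drawn into training.  Accuracies are averaged over iterations and
    reported in percent.
    """
    k_values = [int(k) for k in k_values]
    if any(k < 0 for k in k_values):
        raise ValueError("k values must be nonnegative")
    if max(k_values) >= len(dh):
        raise ValueError(
            f"k={max(k_values)} leaves no duplex samples to evaluate "
            f"(duplex pool has {len(dh)})"
        )
    rows = []
    for k in k_values:
        g4_accs = np.empty(n_iterations)
        dh_accs = np.empty(n_iterations)
        for i in range(n_iterations):
            train, test = holdout_split(g4, train_fraction, base_seed + i)
            if k > 0:
                draw_rng = np.random.default_rng([base_seed + i, 9001 + k])
                drawn = draw_rng.choice(len(dh), size=k, replace=False)
                train = train.concat(dh.subset(drawn, "dh-train"))
                held_dh = dh.subset(np.setdiff1d(np.arange(len(dh)), drawn))
            else:
                held_dh = dh
            acc, _, tree = _train_and_score(
                train, test, None, complexity_parameter
            )
            g4_accs[i] = acc
            dh_accs[i] = id3.accuracy(tree, held_dh)
        rows.append({
            "dh_samples_added": k,
            "g4_accuracy": 100.0 * float(np.mean(g4_accs)),
            "dh_accuracy": 100.0 * float(np.mean(dh_accs)),
            "g4_accuracy_sd": 100.0 * float(np.std(g4_accs)),
            "dh_accuracy_sd": 100.0 * float(np.std(dh_accs)),
        })
    return TransferTable(
        frame=pd.DataFrame(rows),
        n_iterations=n_iterations,
        base_seed=base_seed,
    )


def single_angle_assessment(
    ds: Dataset,
    n_iterations: int = DEFAULT_ITERATIONS,
    base_seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    complexity_parameter: float = id3.DEFAULT_CCP_ALPHA,
) -> dict[str, tuple[float, float]]:
    """Holdout accuracy of trees restricted to one angle at a time.

    Returns ``{angle: (mean_accuracy, sd_accuracy)}`` over the seven
    angles, using the same partition seeds for every angle so the
    comparison is paired.
    """
    out: dict[str, tuple[float, float]] = {}
    for angle in ANGLE_NAMES:
        report = repeated_holdout(
            ds,
            n_iterations=n_iterations,
            base_seed=base_seed,
            train_fraction=train_fraction,
            complexity_parameter=complexity_parameter,
            candidate_features=[angle],
        )
        out[angle] = (report.mean_accuracy, report.sd_accuracy)
    return out


def first_split_statistics(
    report: ValidationReport,
) -> tuple[str, float, float]:
    """Modal root-split feature, its frequency, and its mean threshold.

    The mode is taken over iterations whose tree actually split (trees
    pruned to a single leaf are excluded); ties go to the canonical angle
    order.  The mean threshold averages theta over the modal-feature
    iterations only.
    """
    records = [fs for fs in report.first_splits if fs is not None]
    if not records:
        raise ValueError("report contains no first-split records")
    counts = {name: 0 for name in ANGLE_NAMES}
    for feat, _ in records:
        counts[feat] += 1
    modal = max(ANGLE_NAMES, key=lambda name: counts[name])  # order breaks ties
    thetas = [theta for feat, theta in records if feat == modal]
    return modal, counts[modal] / len(records), float(np.mean(thetas))
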