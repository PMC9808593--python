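"""Entropy-impurity (ID3-style) decision trees over torsion-angle features.

The classifier at the heart of this package: a binary decision tree whose
internal nodes test a single torsion angle against a threshold theta in
[0, 360] and whose leaves carry class counts (n left-handed, n right-handed).
Splits maximize information gain

    gain = E(parent) - sum_children (n_child / n_parent) * E(child),

with the two-class Shannon entropy E(S) = -sum_i p_i log2 p_i (and
0*log2 0 = 0), so a pure node scores 0 bits and an even split 1 bit.
Candidate thresholds are midpoints between consecutive distinct sorted
feature values; ties are broken by the fixed feature order alpha, beta,
gamma, delta, epsilon, zeta, chi, then by the smallest threshold.  Angles
are treated as plain numbers on [0, 360) — no circular wrap-around in the
split search, matching how the thresholds are meant to be read.

Grown trees are simplified by minimal (weakest-link) cost-complexity
pruning with misclassification impurity, controlled by a complexity
parameter (default 0.04).  A closed-form two-angle rule distilled from
trained trees is also provided: alpha < 252 and beta > 150 classifies a
nucleotide as left-handed.
"""

from __future__ import annotations

import copy
import json
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .torsion import ANGLE_NAMES

#: distilled left-handedness rule thresholds (degrees)
RULE_ALPHA_MAX = 252.0
RULE_BETA_MIN = 150.0

DEFAULT_CCP_ALPHA = 0.04

#: information-gain floor guarding against float-noise splits
_GAIN_EPS = 1e-12


class NoGain:
    """Sentinel returned by :func:`best_split` when no split improves entropy."""

    def __repr__(self):
        return "NO_GAIN"

    def __bool__(self):
        return False


NO_GAIN = NoGain()


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy of a class-count vector, in bits.

    ``entropy((4, 0)) == 0.0`` and ``entropy((2, 2)) == 1.0``; the
    0*log2(0) = 0 convention applies.  All-zero counts are an error.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("entropy of an empty sample set is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum()) + 0.0


def _entropy2(c0, c1):
    """Vectorized two-class entropy for count arrays (0*log2 0 = 0)."""
    n = c0 + c1
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(n > 0, c0 / n, 0.0)
        p1 = np.where(n > 0, c1 / n, 0.0)
        h = -(np.where(p0 > 0, p0 * np.log2(p0), 0.0)
              + np.where(p1 > 0, p1 * np.log2(p1), 0.0))
    return h


@dataclass
class TreeNode:
    """A node of the decision tree.

    Internal nodes carry ``feature`` and ``threshold`` (samples with
    feature value <= threshold go left); leaves have both set to None.
    Every node records the class counts (n_LH, n_RH) of the samples that
    reached it during training.
    """

    class_counts: tuple[int, int]
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def predicted_label(self) -> int:
        """Majority class; ties predict 0 (left-handed)."""
        n_lh, n_rh = self.class_counts
        return 0 if n_lh >= n_rh else 1

    @property
    def n_samples(self) -> int:
        return int(self.class_counts[0] + self.class_counts[1])

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def _as_matrix(samples, features: Sequence[str]):
    """Coerce a Dataset, array or sequence of samples to (X, y)."""
    if hasattr(samples, "feature_matrix"):  # Dataset
        X = samples.feature_matrix(features)
        y = samples.labels
    else:
        X = np.asarray(samples, dtype=float)
        y = None
    return X, y


def best_split(
    X,
    y,
    candidate_features: Optional[Sequence[str]] = None,
) -> Union[tuple[str, float, float], NoGain]:
    """Exhaustive best (feature, threshold, gain) over midpoint candidates.

    ``X`` is an (n, 7) matrix in the canonical angle order; restricting
    ``candidate_features`` searches only those columns (in canonical
    order).  Returns :data:`NO_GAIN` when no threshold on any candidate
    feature improves entropy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 2 or len(np.unique(y)) < 2:
        return NO_GAIN
    if candidate_features is None:
        candidate_features = ANGLE_NAMES
    # canonical order drives the tie-break
    candidates = [f for f in ANGLE_NAMES if f in candidate_features]
    n = len(y)
    n0 = int(np.sum(y == 0))
    parent = entropy((n0, n - n0))

    best: Optional[tuple[float, str, float]] = None
    for feat in candidates:
        j = ANGLE_NAMES.index(feat)
        order = np.argsort(X[:, j], kind="mergesort")
        vs = X[order, j]
        ys = y[order]
        cum0 = np.cumsum(ys == 0)
        cut = np.nonzero(vs[:-1] < vs[1:])[0]  # boundaries between distinct values
        if cut.size == 0:
            continue
        nl = cut + 1
        l0 = cum0[cut]
        l1 = nl - l0
        r0 = n0 - l0
        r1 = (n - nl) - r0
        child = (nl * _entropy2(l0, l1) + (n - nl) * _entropy2(r0, r1)) / n
        gains = parent - child
        k = int(np.argmax(gains))  # first max -> smallest theta within feature
        if gains[k] <= _GAIN_EPS:
            continue
        if best is None or gains[k] > best[0]:  # ties keep the earlier feature
            theta = float((vs[cut[k]] + vs[cut[k] + 1]) / 2.0)
            best = (float(gains[k]), feat, theta)
    if best is None:
        return NO_GAIN
    gain, feat, theta = best
    return (feat, theta, gain)


def grow_tree(
    samples,
    labels=None,
    candidate_features: Optional[Sequence[str]] = None,
    min_gain: float = 0.0,
) -> TreeNode:
    """Grow a full tree by recursive entropy splitting.

    Recursion stops at pure nodes, when no split has positive gain, or —
    if ``min_gain`` is raised above zero — when the best achievable
    entropy drop falls below that floor (the alternative stopping rule to
    post-hoc pruning).  Deterministic given the data.
    """
    X, y = _as_matrix(samples, ANGLE_NAMES)
    if labels is not None:
        y = np.asarray(labels)
    if y is None:
        raise TypeError("labels are required when samples is a plain matrix")
    if len(y) == 0:
        raise ValueError("cannot grow a tree from an empty dataset")

    def build(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        counts = (int(np.sum(yi == 0)), int(np.sum(yi == 1)))
        if counts[0] == 0 or counts[1] == 0:
            return TreeNode(class_counts=counts)
        found = best_split(X[idx], yi, candidate_features)
        if found is NO_GAIN:
            return TreeNode(class_counts=counts)
        feat, theta, gain = found
        if gain < min_gain:
            return TreeNode(class_counts=counts)
        j = ANGLE_NAMES.index(feat)
        mask = X[idx, j] <= theta
        return TreeNode(
            class_counts=counts,
            feature=feat,
            threshold=theta,
            left=build(idx[mask]),
            right=build(idx[~mask]),
        )

    return build(np.arange(len(y)))


# ---------------------------------------------------------------------------
# minimal cost-complexity pruning
# ---------------------------------------------------------------------------

def _weakest_links(node: TreeNode, n_total: int, out: list):
    """Collect (effective_alpha, node) for every internal node."""
    if node.is_leaf:
        return min(node.class_counts) / n_total, 1
    r_subtree = 0.0
    leaves = 0
    for child in (node.left, node.right):
        r_c, l_c = _weakest_links(child, n_total, out)
        r_subtree += r_c
        leaves += l_c
    r_node = min(node.class_counts) / n_total
    g = (r_node - r_subtree) / (leaves - 1)
    out.append((g, node))
    return r_subtree, leaves


def prune(tree: TreeNode, complexity_parameter: float = DEFAULT_CCP_ALPHA) -> TreeNode:
    """Weakest-link cost-complexity pruning (Breiman et al.).

    Using misclassification rate R as the pruning impurity, each internal
    node t has an effective alpha g(t) = (R(t) - R(subtree_t)) /
    (|leaves of subtree_t| - 1).  Subtrees are collapsed weakest-first
    while the smallest g(t) is below ``complexity_parameter``; a value of
    0 leaves the tree unchanged, infinity collapses it to a single
    (majority) leaf.  The input tree is not modified; pruning is
    idempotent.
    """
    if complexity_parameter < 0:
        raise ValueError("complexity parameter must be nonnegative")
    tree = copy.deepcopy(tree)
    n_total = tree.n_samples
    while not tree.is_leaf:
        links: list = []
        _weakest_links(tree, n_total, links)
        g_min = min(g for g, _ in links)
        if not g_min < complexity_parameter:
            break
        for g, node in links:
            if g <= g_min + 1e-15 and not node.is_leaf:
                node.feature = None
                node.threshold = None
                node.left = None
                node.right = None
    return tree


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _feature_value(sample, name: str) -> float:
    if hasattr(sample, name):
        value = getattr(sample, name)
    elif isinstance(sample, dict):
        value = sample.get(name)
    else:
        arr = np.asarray(sample, dtype=float)
        if arr.shape != (len(ANGLE_NAMES),):
            raise ValueError(
                f"expected a sample with {len(ANGLE_NAMES)} angle features"
            )
        value = arr[ANGLE_NAMES.index(name)]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"sample is missing required feature {name!r}")
    return float(value)


def predict(tree: TreeNode, sample) -> int:
    """Route one sample down the tree; leaf majority decides (ties -> 0).

    A sample may be a 7-vector in canonical angle order, a mapping, or any
    object with angle attributes.  Routing goes left iff value <= theta.
    """
    node = tree
    while not node.is_leaf:
        value = _feature_value(sample, node.feature)
        node = node.left if value <= node.threshold else node.right
    return node.predicted_label


def predict_many(tree: TreeNode, X) -> np.ndarray:
    """Vector of predictions for an (n, 7) feature matrix or Dataset."""
    if hasattr(X, "feature_matrix"):
        X = X.feature_matrix()
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    out = np.empty(len(X), dtype=int)
    idx = np.arange(len(X))

    def route(node, rows):
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.predicted_label
            return
        j = ANGLE_NAMES.index(node.feature)
        mask = X[rows, j] <= node.threshold
        route(node.left, rows[mask])
        route(node.right, rows[~mask])

    route(tree, idx)
    return out


def accuracy(tree: TreeNode, samples, labels=None) -> float:
    """Fraction of samples classified correctly."""
    if hasattr(samples, "feature_matrix"):
        X = samples.feature_matrix()
        y = samples.labels
    else:
        X = np.asarray(samples, dtype=float)
        y = np.asarray(labels)
    return float(np.mean(predict_many(tree, X) == y))


def rule_classifier(sample) -> int:
    """Closed-form two-angle handedness rule.

    A nucleotide with alpha < 252 degrees and beta > 150 degrees is called
    left-handed (0); anything else right-handed (1).
    """
    alpha = _feature_value(sample, "alpha")
    beta = _feature_value(sample, "beta")
    return 0 if (alpha < RULE_ALPHA_MAX and beta > RULE_BETA_MIN) else 1


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def describe(tree: TreeNode) -> str:
    """Lossless indented text rendering of a tree.

    The rendering can be parsed back into an equivalent tree with
    :func:`parse_description`.
    """
    lines: list[str] = []

    def render(node: TreeNode, depth: int):
        pad = "  " * depth
        counts = f"counts={node.class_counts[0]},{node.class_counts[1]}"
        if node.is_leaf:
            lines.append(f"{pad}leaf {counts}")
        else:
            lines.append(
                f"{pad}node feature={node.feature} "
                f"theta={node.threshold!r} {counts}"
            )
            render(node.left, depth + 1)
            render(node.right, depth + 1)

    render(tree, 0)
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(
    r"^(?P<pad>(?:  )*)(?:node feature=(?P<feature>\w+) theta=(?P<theta>[-0-9.e+]+)"
    r" |leaf )counts=(?P<c0>\d+),(?P<c1>\d+)$"
)


def parse_description(text: str) -> TreeNode:
    """Parse :func:`describe` output back into a tree."""
    nodes: list[tuple[int, TreeNode]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _NODE_RE.match(line)
        if m is None:
            raise ValueError(f"unparseable tree line: {line!r}")
        depth = len(m.group("pad")) // 2
        node = TreeNode(
            class_counts=(int(m.group("c0")), int(m.group("c1"))),
            feature=m.group("feature"),
            threshold=float(m.group("theta")) if m.group("theta") else None,
        )
        nodes.append((depth, node))

    def attach(parent: TreeNode, depth: int, stream: Iterable):
        for slot in ("left", "right"):
            d, node = next(stream)
            if d != depth + 1:
                raise ValueError("malformed tree indentation")
            setattr(parent, slot, node)
            if not node.is_leaf:
                attach(node, d, stream)

    stream = iter(nodes)
    _, root = next(stream)
    if not root.is_leaf:
        attach(root, 0, stream)
    return root


def tree_to_json(tree: TreeNode) -> str:
    """JSON serialization (node objects with feature, threshold, counts)."""

    def encode(node: TreeNode):
        obj = {"class_counts": list(node.class_counts)}
        if not node.is_leaf:
            obj.update(
                feature=node.feature,
                threshold=node.threshold,
                left=encode(node.left),
                right=encode(node.right),
            )
        return obj

    return json.dumps(encode(tree), indent=2)


def tree_from_json(text: str) -> TreeNode:
    def decode(obj) -> TreeNode:
        node = TreeNode(class_counts=tuple(obj["class_counts"]))
        if "feature" in obj:
            node.feature = obj["feature"]
            node.threshold = float(obj["threshold"])
            node.left = decode(obj["left"])
            node.right = decode(obj["right"])
        return node

    return decode(json.loads(text))
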