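"""Iterative cluster analysis and weighted PCA ordination.

The assemblage is first clustered with size-heavy weights and the tree cut
into a few main branches (similar-sized seeds); each branch is then
re-clustered with shape-heavy weights, and a branch split is accepted only
if it improves the mean silhouette width of that branch's seeds in the
global partition by at least a configurable margin. The weighted PCA
scales feature i by sqrt(omega_i) before centring, so full-rank score
distances reproduce the weighted seed-to-seed distance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_samples

from .errors import ContractError, ParameterError
from .features import FeatureVector, WeightSchedule, distance_matrix, feature_matrix

LINKAGES = ("average", "complete", "ward")

#: minimum mean-silhouette improvement for accepting a within-branch split
SILHOUETTE_GAIN = 0.05


@dataclass
class _Node:
    """Binary dendrogram node; leaves carry a seed_id."""

    height: float
    seed_id: str | None = None
    children: tuple["_Node", "_Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.seed_id]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Binary merge tree over seed ids with merge heights (mm)."""

    root: _Node
    linkage_matrix: np.ndarray | None = None  # scipy Z when built directly
    seed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        leaves = self.root.leaves()
        if len(set(leaves)) != len(leaves):
            raise ContractError("dendrogram leaves are not unique")
        if not self.seed_ids:
            self.seed_ids = leaves
        if set(self.seed_ids) != set(leaves):
            raise ContractError("dendrogram leaves do not match seed_ids")
        self._check_monotone(self.root)

    def _check_monotone(self, node: _Node) -> None:
        if node.is_leaf:
            return
        for child in node.children:
            if child.height > node.height + 1e-9:
                raise ContractError("merge heights decrease root-ward")
            self._check_monotone(child)

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k clusters by repeatedly splitting the highest node."""
        if not 1 <= k <= len(self.seed_ids):
            raise ParameterError(f"cannot cut {len(self.seed_ids)} leaves into {k}")
        clusters: list[_Node] = [self.root]
        while len(clusters) < k:
            splittable = [c for c in clusters if not c.is_leaf]
            if not splittable:
                break
            top = max(splittable, key=lambda c: c.height)
            clusters.remove(top)
            clusters.extend(top.children)
        out: dict[str, int] = {}
        for i, c in enumerate(
            sorted(clusters, key=lambda c: min(c.leaves()))
        ):
            for leaf in c.leaves():
                out[leaf] = i
        return out

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{_newick_escape(node.seed_id)}:{length:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:.10g}"

        return fmt(self.root, self.root.height) + ";"


def _newick_escape(name: str) -> str:
    if any(ch in name for ch in "():;, '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _tree_from_scipy(Z: np.ndarray, seed_ids: Sequence[str]) -> _Node:
    nodes: dict[int, _Node] = {
        i: _Node(height=0.0, seed_id=s) for i, s in enumerate(seed_ids)
    }
    n = len(seed_ids)
    for i, (a, b, h, _) in enumerate(Z):
        left, right = nodes.pop(int(a)), nodes.pop(int(b))
        # clip: scipy may report marginally non-monotone heights for
        # average linkage on unusual inputs; the tree contract forbids it
        h = max(h, left.height, right.height)
        nodes[n + i] = _Node(height=float(h), children=(left, right))
    (root,) = nodes.values()
    return root


def cluster_tree(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative tree from a distance matrix (average linkage default)."""
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}")
    d = dist.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ContractError("distance matrix must be square and symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-10):
        raise ContractError("distance matrix diagonal must be zero")
    condensed = d[np.triu_indices_from(d, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    seed_ids = [str(i) for i in dist.index]
    return Dendrogram(
        root=_tree_from_scipy(Z, seed_ids),
        linkage_matrix=Z,
        seed_ids=seed_ids,
    )


@dataclass
class PCAResult:
    """Weighted principal-component scores of an assemblage."""

    scores: pd.DataFrame  # seeds x components
    explained_variance: np.ndarray  # per component
    components: np.ndarray  # (n_components, 42) in sqrt-weighted space
    mean: np.ndarray  # (42,) column means of the sqrt-weighted features
    omega: np.ndarray

    def transform(self, features: Sequence[FeatureVector]) -> np.ndarray:
        x = np.vstack([f.v for f in features]) * np.sqrt(self.omega)
        return (x - self.mean) @ self.components.T


def pca_embed(
    features: Sequence[FeatureVector],
    omega: np.ndarray,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the sqrt(omega)-scaled, column-centred feature matrix.

    At full rank the pairwise Euclidean distances between score rows equal
    the weighted seed distances exactly (the scaling plus rotation is an
    isometry of the centred data).
    """
    if len(features) < 2:
        raise ContractError("need at least 2 seeds")
    omega = np.asarray(omega, dtype=float)
    max_rank = min(len(features) - 1, 42)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ParameterError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    df = feature_matrix(features)
    x = df.to_numpy() * np.sqrt(omega)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :n_components] * s[:n_components]
    explained = s[:n_components] ** 2 / max(len(features) - 1, 1)
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=df.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ),
        explained_variance=explained,
        components=vt[:n_components],
        mean=mean,
        omega=omega,
    )


@dataclass
class ClassificationResult:
    """Outcome of the iterative CA/PCA procedure."""

    iteration_labels: list[dict[str, str]]  # per iteration, seed_id -> branch
    final_tree: Dendrogram
    pca: PCAResult

    @property
    def final_labels(self) -> dict[str, str]:
        return self.iteration_labels[-1]


def _mean_branch_silhouette(
    dist: np.ndarray, labels: np.ndarray, member_mask: np.ndarray
) -> float:
    """Mean silhouette width of the masked seeds under the global partition."""
    if len(set(labels.tolist())) < 2:
        return -1.0
    vals = silhouette_samples(dist, labels, metric="precomputed")
    return float(vals[member_mask].mean())


def iterative_classify(
    features: Sequence[FeatureVector],
    schedule: WeightSchedule,
    k1: int = 3,
    linkage: str = "average",
    silhouette_gain: float = SILHOUETTE_GAIN,
    max_split: int = 3,
) -> ClassificationResult:
    """Iterative reclassification over the weight schedule.

    Iteration 1 clusters all seeds with the first weight vector and cuts
    the tree into ``k1`` main branches. Each later iteration re-computes
    distances with its own weights and, within every branch of size >= 3,
    accepts the best 2- or 3-way split only if it raises the mean
    silhouette width of that branch's seeds (evaluated against the global
    partition with the current distances) by at least ``silhouette_gain``.
    The final dendrogram grafts the accepted sub-trees onto the
    iteration-1 skeleton; PCA scores use the final iteration's weights.
    """
    n = len(features)
    if k1 < 2:
        raise ParameterError("k1 must be >= 2")
    if n <= k1:
        raise ParameterError(f"need more seeds ({n}) than main branches ({k1})")
    ids = [f.seed_id or f"seed_{i}" for i, f in enumerate(features)]
    by_id = dict(zip(ids, features))

    dist1 = distance_matrix(features, schedule[0])
    tree1 = cluster_tree(dist1, linkage=linkage)
    cut1 = tree1.cut(k1)
    labels = {sid: f"B{cut1[sid] + 1}" for sid in ids}
    iteration_labels = [dict(labels)]

    # branch -> subtree nodes of the iteration-1 tree, for grafting
    subtrees: dict[str, _Node] = {}
    iter1_members: dict[str, frozenset[str]] = {}
    iter1_heights: dict[str, float] = {}
    for branch in sorted(set(labels.values())):
        members = [sid for sid in ids if labels[sid] == branch]
        node = _subtree_for(tree1.root, set(members))
        subtrees[branch] = node
        iter1_members[branch] = frozenset(members)
        iter1_heights[branch] = node.height

    for t in range(1, len(schedule)):
        omega = schedule[t]
        dist_t = distance_matrix(features, omega)
        d = dist_t.to_numpy()
        order = {sid: i for i, sid in enumerate(dist_t.index)}
        new_labels = dict(labels)
        for branch in sorted(set(labels.values())):
            members = [sid for sid in ids if labels[sid] == branch]
            if len(members) < 3:
                continue
            sub = dist_t.loc[members, members]
            sub_tree = cluster_tree(sub, linkage=linkage)
            # object dtype: branch ids grow ("B1" -> "B1.2") and fixed-width
            # numpy strings would silently truncate them
            lab_arr = np.array([labels[sid] for sid in dist_t.index], dtype=object)
            mask = np.array([labels[sid] == branch for sid in dist_t.index])
            base = _mean_branch_silhouette(d, lab_arr, mask)
            best_gain, best_cut, best_tree = 0.0, None, None
            for k in range(2, min(max_split, len(members) - 1) + 1):
                cut = sub_tree.cut(k)
                trial = lab_arr.copy()
                for sid, c in cut.items():
                    trial[order[sid]] = f"{branch}.{c + 1}"
                score = _mean_branch_silhouette(d, trial, mask)
                gain = score - base
                if gain > best_gain + 1e-12:
                    best_gain, best_cut, best_tree = gain, cut, sub_tree
            if best_cut is not None and best_gain >= silhouette_gain:
                for sid, c in best_cut.items():
                    new_labels[sid] = f"{branch}.{c + 1}"
                subtrees.pop(branch, None)
                for c in sorted(set(best_cut.values())):
                    mem = {sid for sid, cc in best_cut.items() if cc == c}
                    subtrees[f"{branch}.{c + 1}"] = _subtree_for(
                        best_tree.root, mem
                    )
        labels = new_labels
        iteration_labels.append(dict(labels))

    final_root = _graft(tree1.root, iter1_members, iter1_heights, subtrees)
    final_tree = Dendrogram(root=final_root, seed_ids=ids)
    pca = pca_embed(features, schedule[len(schedule) - 1])
    return ClassificationResult(
        iteration_labels=iteration_labels, final_tree=final_tree, pca=pca
    )


def _subtree_for(root: _Node, members: set[str]) -> _Node:
    """Smallest node whose leaf set equals ``members`` (falls back to a
    pruned copy when the members do not form a clade)."""
    found = _find_exact(root, members)
    if found is not None:
        return found
    return _prune(root, members)


def _find_exact(node: _Node, members: set[str]) -> _Node | None:
    leaves = set(node.leaves())
    if leaves == members:
        return node
    if node.is_leaf or not members.issubset(leaves):
        return None
    for child in node.children:
        hit = _find_exact(child, members)
        if hit is not None:
            return hit
    return None


def _prune(node: _Node, members: set[str]) -> _Node:
    if node.is_leaf:
        return node
    kept = [
        _prune(c, members)
        for c in node.children
        if set(c.leaves()) & members
    ]
    if len(kept) == 1:
        return kept[0]
    return _Node(height=node.height, children=(kept[0], kept[1]))


def _graft(
    skeleton: _Node,
    iter1_members: dict[str, frozenset[str]],
    iter1_heights: dict[str, float],
    subtrees: dict[str, _Node],
) -> _Node:
    """Replace each iteration-1 clade by its final (possibly re-split)
    sub-tree. Sub-trees live in a different weight space, so skeleton
    heights are raised where needed to keep merge heights monotone."""
    final_for: dict[frozenset[str], _Node] = {}
    for b1, members in iter1_members.items():
        parts = sorted(
            k for k in subtrees if k == b1 or k.startswith(b1 + ".")
        )
        if parts == [b1]:
            final_for[members] = _copy(subtrees[b1])
        else:
            nodes = [_copy(subtrees[k]) for k in parts]
            h = max([iter1_heights[b1]] + [nd.height for nd in nodes])
            joined = nodes[0]
            for nd in nodes[1:]:
                joined = _Node(height=h, children=(joined, nd))
            final_for[members] = joined

    def rebuild(node: _Node) -> _Node:
        leaves = frozenset(node.leaves())
        if leaves in final_for:
            return final_for[leaves]
        if node.is_leaf:
            return _Node(height=0.0, seed_id=node.seed_id)
        kids = tuple(rebuild(c) for c in node.children)
        h = max([node.height] + [k.height for k in kids])
        return _Node(height=h, children=kids)

    return rebuild(skeleton)


def _copy(node: _Node) -> _Node:
    if node.is_leaf:
        return _Node(height=node.height, seed_id=node.seed_id)
    return _Node(
        height=node.height, children=tuple(_copy(c) for c in node.children)
    )
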