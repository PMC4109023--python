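"""Hierarchical clustering of the thrombus parameter matrix with bootstrap
cluster support, and assignment of thrombus types I–III.

Surfaces (or parameters) are clustered agglomeratively under Euclidean
distance and complete linkage, with a fully specified tie-break so the merge
sequence is deterministic. Cluster support is estimated by multiscale
bootstrap: columns are resampled with replacement at several relative sample
sizes r = n'/n, the tree is rebuilt, and the per-cluster recovery frequency
BP(r) is extrapolated through the signed distance/curvature model
z(r) = v·√r + c/√r (probit scale, weighted least squares) to the
approximately unbiased p-value AU = 1 − Φ(v − c). AU above 0.90 is the
conventional threshold for a strongly supported cluster.

Cutting the surface tree at k = 3 and ranking clusters by mean normalized
activation gives the thrombus types: I (few single platelets), II (small,
poorly activated aggregates), III (large, fully activated aggregates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "ClusterTree",
    "TypeAssignment",
    "hcluster",
    "fit_au",
    "multiscale_bootstrap",
    "cut_types",
    "newick_export",
    "leave_one_out",
]

DEFAULT_SCALES = tuple(round(float(s), 10) for s in np.linspace(0.5, 1.4, 10))


@dataclass
class ClusterTree:
    """Agglomerative tree: leaves 0..n−1, internal node i created at merge i
    with id n+i. ``merges`` rows are (child_a, child_b, height), child ids
    sorted ascending. Bootstrap support, when computed, is attached as a
    per-internal-node table (bp, au, flags) plus the raw BP(r) table."""

    labels: list
    merges: list[tuple[int, int, float]]
    axis: str = "surfaces"
    support: pd.DataFrame | None = None
    bp_table: pd.DataFrame | None = None
    n_boot: int | None = None
    scales: tuple[float, ...] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafsets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set below each internal node."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for i, (a, b, _h) in enumerate(self.merges):
            sets[n + i] = sets[a] | sets[b]
        return {k: v for k, v in sets.items() if k >= n}

    def heights(self) -> np.ndarray:
        return np.asarray([h for _a, _b, h in self.merges])

    def leaf_order(self) -> list[int]:
        """Depth-first leaf order for dendrogram display."""
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _ = self.merges[node - n]
            return walk(a) + walk(b)

        return walk(n + len(self.merges) - 1)


@dataclass
class TypeAssignment:
    """Thrombus type (1 = I, 2 = II, 3 = III) per surface, with the
    cluster-ranking record that produced the mapping."""

    types: pd.Series
    mapping: list[dict]


def _merge_sequence(
    D: np.ndarray,
) -> tuple[list[tuple[int, int, float]], list[frozenset[int]]]:
    """Complete-linkage agglomeration on a full distance matrix.

    Ties are broken by the lexicographically smallest (id_a, id_b) pair,
    where ids number leaves in input order and internal nodes in creation
    order — so the merge sequence is a pure function of the distances.
    Returns the merge list and the per-merge leaf sets.
    """
    n = D.shape[0]
    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    ids = list(range(n))
    sets = [frozenset([i]) for i in range(n)]
    merges: list[tuple[int, int, float]] = []
    merged_sets: list[frozenset[int]] = []
    for step in range(n - 1):
        m = W.min()
        rr, cc = np.nonzero(W == m)
        best = None
        for r, c in zip(rr, cc):
            if r >= c:
                continue
            a, b = ids[r], ids[c]
            key = (min(a, b), max(a, b))
            if best is None or key < best[0]:
                best = (key, r, c)
        (a, b), i, j = best[0], best[1], best[2]
        merges.append((a, b, float(m)))
        merged_sets.append(sets[i] | sets[j])
        # complete linkage: distance to the union is the max of the parts
        new_row = np.maximum(W[i], W[j])
        W[i, :] = new_row
        W[:, i] = new_row
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        ids[i] = n + step
        sets[i] = merged_sets[-1]
    return merges, merged_sets


def _matrix_for_axis(m: pd.DataFrame, axis: str) -> pd.DataFrame:
    if axis == "surfaces":
        return m
    if axis == "parameters":
        return m.T
    raise ValueError("axis must be 'surfaces' or 'parameters'")


def hcluster(m: pd.DataFrame, axis: str = "surfaces") -> ClusterTree:
    """Euclidean complete-linkage tree over rows (surfaces) or columns.

    NaN cells are rejected; at least two items are required on the chosen
    axis. The merge sequence is deterministic, including under tied
    distances (lowest-index pair first).
    """
    X = _matrix_for_axis(m, axis)
    if X.isna().any().any():
        raise ValueError("matrix contains NaN cells; clean or aggregate first")
    if len(X) < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r}")
    D = squareform(pdist(X.to_numpy(), metric="euclidean"))
    merges, _ = _merge_sequence(D)
    return ClusterTree(labels=list(X.index), merges=merges, axis=axis)


def _leafsets_from_data(X: np.ndarray) -> set[frozenset[int]]:
    D = squareform(pdist(X, metric="euclidean"))
    _, merged = _merge_sequence(D)
    return set(merged)


def fit_au(bp: np.ndarray, r: np.ndarray, n_boot: int) -> dict:
    """Extrapolate per-scale bootstrap probabilities to an AU p-value.

    Fits z(r) = v·√r + c/√r to z = Φ⁻¹(1 − BP(r)) by weighted least squares
    (weights from the binomial variance of BP via the delta method), using
    only scales with 0 < BP < 1; AU = 1 − Φ(v − c). With fewer than 3 usable
    scales there is no finite probit to fit: AU is clamped to 1 (if clusters
    were mostly recovered) or 0, and flagged.
    """
    bp = np.asarray(bp, dtype=float)
    r = np.asarray(r, dtype=float)
    usable = (bp > 0) & (bp < 1)
    if usable.sum() < 3:
        return {
            "au": 1.0 if bp.mean() > 0.5 else 0.0,
            "v": np.nan,
            "c": np.nan,
            "flag": "clamped",
        }
    ru, bu = r[usable], bp[usable]
    z = norm.ppf(1.0 - bu)
    w = n_boot * norm.pdf(z) ** 2 / (bu * (1.0 - bu))
    M = np.column_stack([np.sqrt(ru), 1.0 / np.sqrt(ru)])
    WM = M * w[:, None]
    v, c = np.linalg.solve(M.T @ WM, WM.T @ z)
    return {"au": float(1.0 - norm.cdf(v - c)), "v": float(v), "c": float(c), "flag": ""}


def multiscale_bootstrap(
    m: pd.DataFrame,
    tree: ClusterTree,
    *,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int,
) -> ClusterTree:
    """Per-cluster BP(r) and AU support via multiscale column resampling.

    For each scale r, columns are resampled with replacement to size
    n' = round(r·n), the tree is rebuilt, and BP(r) is the fraction of
    replicates in which each original cluster (as a leaf set) reappears.
    Per cluster, probit-transformed BP values at the realized scales
    (0 < BP < 1 only; at least 3 usable scales) are fitted by weighted least
    squares to z(r) = v·√r + c/√r, and AU = 1 − Φ(v − c). Clusters recovered
    never or always at every scale have no finite probit; their AU is clamped
    to 0 or 1 and flagged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scales = tuple(float(s) for s in scales)
    if min(scales) >= 1 or max(scales) <= 1:
        raise ValueError("scales must straddle r = 1")
    X = _matrix_for_axis(m, tree.axis).to_numpy()
    if list(_matrix_for_axis(m, tree.axis).index) != list(tree.labels):
        raise ValueError("matrix labels do not match the tree's leaves")
    n_items, n_cols = X.shape
    rng = np.random.default_rng(seed)

    node_sets = tree.node_leafsets()
    nodes = sorted(node_sets)
    counts = np.zeros((len(scales), len(nodes)), dtype=int)
    realized = []
    # resampling schedule (part of the contract, so support is replayable
    # from the seed): scales in the given order, n_boot index draws each,
    # one rng.integers(0, n_cols, size=n') call per replicate
    for si, r in enumerate(scales):
        n_prime = max(2, int(round(r * n_cols)))
        realized.append(n_prime / n_cols)
        for _b in range(n_boot):
            idx = rng.integers(0, n_cols, size=n_prime)
            found = _leafsets_from_data(X[:, idx])
            for ni, node in enumerate(nodes):
                if node_sets[node] in found:
                    counts[si, ni] += 1
    bp = counts / n_boot
    r_real = np.asarray(realized)

    rows = []
    near1 = int(np.argmin(np.abs(r_real - 1)))
    for ni, node in enumerate(nodes):
        fit = fit_au(bp[:, ni], r_real, n_boot)
        rows.append({"node": node, "bp": float(bp[near1, ni]), **fit})
    support = pd.DataFrame(rows).set_index("node")
    bp_table = pd.DataFrame(bp.T, index=nodes, columns=[f"r={r:g}" for r in scales])
    return ClusterTree(
        labels=tree.labels,
        merges=tree.merges,
        axis=tree.axis,
        support=support,
        bp_table=bp_table,
        n_boot=n_boot,
        scales=scales,
    )


def cut_types(tree: ClusterTree, m: pd.DataFrame, k: int = 3) -> TypeAssignment:
    """Cut the surface tree at k clusters and rank them into types.

    Clusters are ranked by their mean normalized value over all parameters,
    ascending, so the least-activated cluster is type I and the most
    activated type III. Ties are broken by cluster size (descending), then by
    lowest surface index.
    """
    if tree.axis != "surfaces":
        raise ValueError("types are assigned from the surface tree")
    n = tree.n_leaves
    if k > n:
        raise ValueError("k cannot exceed the leaf count")
    heights = tree.heights()
    if k < n and np.all(heights == 0):
        raise ValueError("all rows identical: no k-cluster structure to cut")
    if k < n and k > 1 and heights[n - k - 1] == heights[n - k]:
        warnings.warn(
            "tied merge heights across the cut boundary; the k-cluster "
            "partition is not unique",
            stacklevel=2,
        )
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    alive = set(range(n))
    for i, (a, b, _h) in enumerate(tree.merges[: n - k]):
        sets[n + i] = sets[a] | sets[b]
        alive -= {a, b}
        alive.add(n + i)
    clusters = [sorted(sets[node]) for node in alive]

    X = _matrix_for_axis(m, "surfaces")
    if list(X.index) != list(tree.labels):
        raise ValueError("matrix labels do not match the tree's leaves")
    vals = X.to_numpy()
    record = []
    for leaves in clusters:
        record.append(
            {
                "surfaces": [tree.labels[i] for i in leaves],
                "mean_value": float(vals[leaves].mean()),
                "size": len(leaves),
                "min_index": min(leaves),
            }
        )
    record.sort(key=lambda r: (r["mean_value"], -r["size"], r["min_index"]))
    types = pd.Series(index=X.index, dtype=int, name="type")
    for rank, rec in enumerate(record, start=1):
        rec["type"] = rank
        types.loc[rec["surfaces"]] = rank
    return TypeAssignment(types=types, mapping=record)


def _newick_label(tree: ClusterTree, node: int, percent: bool) -> str:
    if tree.support is None or node not in tree.support.index:
        return ""
    row = tree.support.loc[node]
    if percent:
        return f"au{100 * row['au']:.1f}_bp{100 * row['bp']:.1f}"
    return f"au{row['au']:.3f}_bp{row['bp']:.3f}"


def newick_export(tree: ClusterTree, percent: bool = True) -> str:
    """Serialize the tree as Newick, AU/BP support as internal node labels.

    Branch lengths are the height differences between a node and its parent's
    merge height, so leaf-to-root path lengths reproduce the merge heights.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    for i, (_a, _b, h) in enumerate(tree.merges):
        height[n + i] = h

    def sanitize(label) -> str:
        return str(label).replace(" ", "_").replace(",", "_").replace(":", "_").replace("(", "_").replace(")", "_").replace(";", "_")

    def walk(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{sanitize(tree.labels[node])}:{bl:.10g}"
        a, b, h = tree.merges[node - n]
        inner = f"({walk(a, h)},{walk(b, h)}){_newick_label(tree, node, percent)}"
        return f"{inner}:{bl:.10g}"

    root = n + len(tree.merges) - 1
    a, b, h = tree.merges[root - n]
    return f"({walk(a, h)},{walk(b, h)}){_newick_label(tree, root, percent)};"


def leave_one_out(m: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Sensitivity of the type assignment to dropping one parameter or surface.

    Re-clusters after removing each column (parameter) and each row (surface)
    in turn and reports the Adjusted Rand Index of the resulting k-cluster
    partition against the full-data partition (restricted to shared
    surfaces).
    """
    from sklearn.metrics import adjusted_rand_score

    full = cut_types(hcluster(m), m, k=k).types
    rows = []
    for col in m.columns:
        sub = m.drop(columns=[col])
        t = cut_types(hcluster(sub), sub, k=k).types
        rows.append(
            {"left_out": col, "axis": "parameter",
             "ari": adjusted_rand_score(full.to_numpy(), t.to_numpy())}
        )
    for idx in m.index:
        sub = m.drop(index=[idx])
        t = cut_types(hcluster(sub), sub, k=k).types
        keep = full.drop(index=idx)
        rows.append(
            {"left_out": idx, "axis": "surface",
             "ari": adjusted_rand_score(keep.to_numpy(), t.to_numpy())}
        )
    return pd.DataFrame(rows)
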