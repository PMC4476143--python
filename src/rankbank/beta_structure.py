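"""Between-sample structure: distance matrices, average-linkage
clustering with bootstrap Jaccard stability, and permutational MANOVA.

The PERMANOVA is the Anderson pseudo-F on squared distances::

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F    = (SS_A / (a - 1)) / (SS_W / (N - a)),  SS_A = SS_T - SS_W

with significance from whole-sample label permutation and the +1
correction ``p = (1 + #{F* >= F_obs}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .otu_io import OtuTable, relative_abundance

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "DendrogramNode",
    "PermanovaResult",
    "distance_matrix",
    "upgma",
    "jaccard_stability",
    "permanova",
    "permanova_pairwise",
    "METRICS",
]

METRICS = ("bray_curtis", "euclidean", "manhattan", "canberra")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("nonzero diagonal")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValueError("matrix not symmetric")
        if self.metric == "bray_curtis" and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("Bray-Curtis distances must lie in [0, 1]")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([idx[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(rows, rows)], self.metric)


def _bray_curtis(x: np.ndarray) -> np.ndarray:
    """BC(u, v) = 1 - 2 sum(min(u_i, v_i)) / (sum u + sum v), condensed form."""
    n = x.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        totals = x[i].sum() + x[i + 1 :].sum(axis=1)
        out[k : k + n - 1 - i] = 1.0 - 2.0 * shared / totals
        k += n - 1 - i
    return out


def distance_matrix(
    table: OtuTable, metric: str = "bray_curtis", normalize: bool = True
) -> DistanceMatrix:
    """Pairwise dissimilarities between samples.

    By default distances are computed on relative abundances; pass
    ``normalize=False`` to use raw counts.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = relative_abundance(table).to_numpy() if normalize else table.counts.astype(float)
    if metric == "bray_curtis":
        cond = _bray_curtis(x)
    elif metric == "canberra":
        with np.errstate(invalid="ignore"):
            cond = pdist(x, metric="canberra")
    else:
        cond = pdist(x, metric={"manhattan": "cityblock"}.get(metric, metric))
    return DistanceMatrix(list(table.sample_ids), squareform(cond), metric)


# ---------------------------------------------------------------------------
# UPGMA with explicit node structure
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Binary merge node; leaves have ``height`` 0 and no children."""

    leaves: frozenset
    height: float
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None
    stability: float | None = None  # Jaccard stability mean, 0-100 scale

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def label(self) -> str:
        (only,) = self.leaves if self.is_leaf else (None,)
        return only if self.is_leaf else ""


@dataclass
class Dendrogram:
    """UPGMA merge tree over samples."""

    root: DendrogramNode
    sample_ids: list[str]

    def internal_nodes(self) -> list[DendrogramNode]:
        out = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def all_nodes(self) -> list[DendrogramNode]:
        out = []

        def walk(node: DendrogramNode) -> None:
            out.append(node)
            if not node.is_leaf:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels from cutting the tree into ``k`` groups.

        Splits the highest node repeatedly until ``k`` subtrees remain.
        """
        if not 1 <= k <= len(self.sample_ids):
            raise ValueError("k out of range")
        groups = [self.root]
        while len(groups) < k:
            top = max(
                (g for g in groups if not g.is_leaf),
                key=lambda g: g.height,
                default=None,
            )
            if top is None:
                break
            groups.remove(top)
            groups.extend([top.left, top.right])
        labels: dict[str, int] = {}
        for i, g in enumerate(groups):
            for leaf in g.leaves:
                labels[leaf] = i
        return labels

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise merge heights; UPGMA's induced ultrametric."""
        ids = sorted(self.sample_ids)
        idx = {s: i for i, s in enumerate(ids)}
        d = np.zeros((len(ids), len(ids)))

        def walk(node: DendrogramNode) -> None:
            if node.is_leaf:
                return
            for a in node.left.leaves:
                for b in node.right.leaves:
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = node.height
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return DistanceMatrix(ids, d, metric="cophenetic")

    def to_newick(self, with_stability: bool = False) -> str:
        def fmt(node: DendrogramNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                (name,) = node.leaves
                return f"{name}:{length:.6g}"
            inner = ",".join(
                fmt(c, node.height) for c in (node.left, node.right)
            )
            note = ""
            if with_stability and node.stability is not None:
                note = f"[&&NHX:stability={node.stability:.1f}]"
            return f"({inner}){note}:{length:.6g}"

        root = self.root
        inner = ",".join(fmt(c, root.height) for c in (root.left, root.right))
        note = ""
        if with_stability and root.stability is not None:
            note = f"[&&NHX:stability={root.stability:.1f}]"
        return f"({inner}){note};"


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage clustering.

    Ties in the minimum distance are broken deterministically by the
    lexicographically smallest member label of the candidate pair.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(leaves=frozenset([s]), height=0.0)
        for i, s in enumerate(dm.sample_ids)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: dm.sample_ids[i] for i in range(n)}  # lexicographic representative
    d = {frozenset((i, j)): dm.values[i, j]
         for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            (
                (d[frozenset((i, j))], tuple(sorted((reps[i], reps[j]))), i, j)
                for i, j in itertools.combinations(sorted(active), 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        height, _, i, j = best
        merged = DendrogramNode(
            leaves=nodes[i].leaves | nodes[j].leaves,
            height=float(height),
            left=nodes[i],
            right=nodes[j],
        )
        for k in active - {i, j}:
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        d.pop(frozenset((i, j)))
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    (root_id,) = active
    return Dendrogram(root=nodes[root_id], sample_ids=list(dm.sample_ids))


def _clusters_at(root: DendrogramNode, threshold: float) -> list[frozenset]:
    """Leaf sets of the maximal subtrees merged at or below ``threshold``."""
    out: list[frozenset] = []

    def walk(node: DendrogramNode) -> None:
        if node.height <= threshold or node.is_leaf:
            out.append(node.leaves)
        else:
            walk(node.left)
            walk(node.right)

    walk(root)
    return out


def jaccard_stability(
    table: OtuTable,
    metric: str = "bray_curtis",
    B: int = 100,
    seed: int | None = None,
    normalize: bool = True,
) -> Dendrogram:
    """Bootstrap Jaccard stability of every internal UPGMA node.

    For each of ``B`` bootstrap resamples of the samples (with
    replacement) the distance matrix and tree are recomputed.  A
    reference node is a cluster for cut heights between its own merge
    height and its parent's; it is matched (after restricting its leaf
    set to samples present in the resample) to the best-Jaccard cluster
    obtained by cutting the bootstrap tree at the midpoint of that
    interval.  The per-node mean over resamples is stored on the
    returned reference dendrogram on a 0-100 scale.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    ref_dm = distance_matrix(table, metric=metric, normalize=normalize)
    ref = upgma(ref_dm)
    ref_nodes = ref.internal_nodes()
    parent_height = {id(ref.root): ref.root.height}
    for node in ref_nodes:
        for child in (node.left, node.right):
            parent_height[id(child)] = node.height
    thresholds = [
        (node.height + parent_height[id(node)]) / 2.0 for node in ref_nodes
    ]
    sums = np.zeros(len(ref_nodes))
    counts = np.zeros(len(ref_nodes))
    n = table.n_samples
    for _ in range(B):
        pick = rng.integers(0, n, size=n)
        boot = OtuTable(
            sample_ids=[f"b{i}_{table.sample_ids[p]}" for i, p in enumerate(pick)],
            otu_ids=list(table.otu_ids),
            counts=table.counts[pick],
            label=table.label,
        )
        present = {table.sample_ids[p] for p in pick}
        boot_tree = upgma(distance_matrix(boot, metric=metric, normalize=normalize))
        for idx, node in enumerate(ref_nodes):
            restricted = node.leaves & present
            if not restricted:
                continue
            # map bootstrap leaf labels back to original sample ids
            boot_sets = [
                frozenset(lbl.split("_", 1)[1] for lbl in cluster)
                for cluster in _clusters_at(boot_tree.root, thresholds[idx])
            ]
            best = max(
                len(restricted & bs) / len(restricted | bs) for bs in boot_sets
            )
            sums[idx] += best
            counts[idx] += 1
    for idx, node in enumerate(ref_nodes):
        node.stability = float(100.0 * sums[idx] / counts[idx]) if counts[idx] else None
    return ref


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    f: float
    p: float
    df_among: int
    df_within: int
    n_permutations: int
    levels: tuple | None = None  # set for pairwise results


def _coerce_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, Mapping):
        return np.array([groups[s] for s in dm.sample_ids], dtype=object)
    if isinstance(groups, pd.Series):
        return groups.reindex(dm.sample_ids).to_numpy(dtype=object)
    g = np.asarray(groups, dtype=object)
    if g.size != dm.n:
        raise ValueError("groups length does not match distance matrix")
    return g


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        sub = d2[np.ix_(members, members)]
        ss_w += sub[np.triu_indices(members.size, 1)].sum() / members.size
    ss_a = ss_t - ss_w
    df_a = n_groups - 1
    df_w = n - n_groups
    if ss_w <= 0:
        return np.nan
    return (ss_a / df_a) / (ss_w / df_w)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-way permutational MANOVA on a distance matrix.

    ``groups`` may be an array aligned with ``dm.sample_ids``, a mapping
    from sample id to level, or a pandas Series indexed by sample id.
    """
    g = _coerce_groups(dm, groups)
    levels, codes = np.unique(g, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        bad = levels[np.argmin(sizes)]
        raise ValueError(f"singleton group {bad!r}")
    d2 = dm.values**2
    f_obs = _pseudo_f(d2, codes, levels.size)
    if not np.isfinite(f_obs):
        warnings.warn(
            "all within-group distances are zero; pseudo-F undefined", UserWarning
        )
        return PermanovaResult(factor, np.nan, np.nan, levels.size - 1,
                               dm.n - levels.size, n_permutations)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm = _pseudo_f(d2, rng.permutation(codes), levels.size)
        if np.isnan(f_perm) or f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        factor=factor,
        f=float(f_obs),
        p=float(p),
        df_among=levels.size - 1,
        df_within=dm.n - levels.size,
        n_permutations=n_permutations,
    )


def permanova_pairwise(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    factor: str = "group",
    adjust: str | None = None,
) -> list[PermanovaResult]:
    """PERMANOVA for every unordered pair of factor levels.

    Raw p-values by default; ``adjust="bh"`` additionally applies
    Benjamini-Hochberg and stores adjusted values in the returned
    dataframe from :func:`pairwise_to_dataframe`.  Pairs involving a
    singleton level are skipped with a warning.
    """
    g = _coerce_groups(dm, groups)
    levels = np.unique(g)
    rng = np.random.default_rng(seed)
    results = []
    for a, b in itertools.combinations(levels, 2):
        keep = np.flatnonzero((g == a) | (g == b))
        if min((g[keep] == a).sum(), (g[keep] == b).sum()) < 2:
            warnings.warn(f"skipping pair ({a!r}, {b!r}): singleton level",
                          UserWarning)
            continue
        sub_ids = [dm.sample_ids[i] for i in keep]
        sub = dm.submatrix(sub_ids)
        res = permanova(
            sub, g[keep], n_permutations=n_permutations,
            seed=int(rng.integers(2**31)), factor=factor,
        )
        results.append(
            PermanovaResult(
                factor=factor, f=res.f, p=res.p, df_among=res.df_among,
                df_within=res.df_within, n_permutations=res.n_permutations,
                levels=(a, b),
            )
        )
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def pairwise_to_dataframe(
    results: Sequence[PermanovaResult], adjust: str | None = None
) -> pd.DataFrame:
    rows = [
        {
            "level_a": r.levels[0],
            "level_b": r.levels[1],
            "f": r.f,
            "p": r.p,
            "df_among": r.df_among,
            "df_within": r.df_within,
            "n_permutations": r.n_permutations,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if adjust == "bh" and len(df):
        p = df["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        df["p_bh"] = adj
    return df
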