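"""Promoter-variant phylogeography: p-distances, neighbour joining, bootstrap.

Accessions are typed at binary promoter variants (SNPs and InDels treated
identically as two-state characters).  Pairwise distance is the mismatch
fraction over variants non-missing in both accessions (p-distance with
pairwise deletion).  Trees are built with the Saitou–Nei neighbour-joining
agglomeration using the Studier–Keppler Q-criterion; ties in Q are broken by
the smallest (row, column) index pair and negative branch lengths are clamped
to zero with the deficit shifted to the sister edge, so results are
reproducible bit-for-bit for a given input order.  Bootstrap support for each
internal bipartition of the reference tree comes from resampling variant
columns with replacement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Clade",
    "genotype_distance",
    "nj_tree",
    "to_newick",
    "bipartitions",
    "bootstrap_support",
    "cut_tree",
    "classify_fnl",
    "group_enrichment",
]


@dataclass
class Clade:
    """Tree node: leaves carry names; internal nodes may carry bootstrap
    support (percent)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def genotype_distance(calls: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mismatch-fraction matrix over shared non-missing variants."""
    if len(calls) < 2:
        raise ValueError("need at least 2 accessions")
    X = calls.to_numpy(dtype=float)
    M = ~np.isnan(X)
    if (~M).all(axis=1).any():
        bad = calls.index[(~M).all(axis=1)][0]
        raise ValueError(f"accession {bad!r} has no calls")
    Y = np.where(M, X, 0.0)
    Mf = M.astype(float)
    shared = Mf @ Mf.T
    off = ~np.eye(len(calls), dtype=bool)
    if (shared[off] < 1).any():
        i, j = np.argwhere((shared < 1) & off)[0]
        raise ValueError(
            f"accessions {calls.index[i]!r} and {calls.index[j]!r} share no calls"
        )
    diff = (Y * Mf) @ Mf.T + Mf @ (Y * Mf).T - 2.0 * Y @ Y.T
    with np.errstate(invalid="ignore"):
        D = diff / shared
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=calls.index, columns=calls.index)


def _check_distances(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")


def nj_tree(distances: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> Clade:
    """Neighbour-joining tree (Saitou–Nei, Studier–Keppler Q-criterion).

    Returns the root clade; for n ≥ 3 the root is the final trifurcation of
    the unrooted tree.  Deterministic: Q ties break at the smallest (row,
    column) pair, negative branch lengths are clamped with the deficit moved
    to the sister edge.
    """
    if isinstance(distances, pd.DataFrame):
        names = list(distances.index)
        D = distances.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distances, dtype=float).copy()
        if names is None:
            names = [f"t{i}" for i in range(D.shape[0])]
    _check_distances(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [Clade(name=str(nm)) for nm in names]
    if n == 2:
        for node in nodes:
            node.length = D[0, 1] / 2.0
        return Clade(children=nodes)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        u = sub.sum(axis=1)
        Q = (m - 2) * sub - u[:, None] - u[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first hit is the smallest (row, column) pair
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        b_i = 0.5 * d_ij + (u[i] - u[j]) / (2.0 * (m - 2))
        b_j = d_ij - b_i
        if b_i < 0:
            b_j += b_i
            b_i = 0.0
        if b_j < 0:
            b_i += b_j
            b_j = 0.0
        gi, gj = active[i], active[j]
        child_i, child_j = nodes[gi], nodes[gj]
        child_i.length = max(b_i, 0.0)
        child_j.length = max(b_j, 0.0)
        parent = Clade(children=[child_i, child_j])
        new_d = 0.5 * (D[gi, active] + D[gj, active] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_d
        D[active, k] = new_d
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [k]
    a, b, c = active
    b_a = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    b_b = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    b_c = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, bl in zip((a, b, c), (b_a, b_b, b_c)):
        nodes[idx].length = max(bl, 0.0)
    return Clade(children=[nodes[a], nodes[b], nodes[c]])


_NEEDS_QUOTE = re.compile(r"[\s(),:;'\"\[\]]")


def _quote(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(root: Clade, include_support: bool = True) -> str:
    """Serialise to Newick; bootstrap supports become internal node labels."""

    def fmt(node: Clade) -> str:
        if node.is_leaf:
            return f"{_quote(node.name)}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = ""
        if include_support and node.support is not None:
            label = f"{node.support:g}"
        return f"({inner}){label}:{node.length:.6g}"

    inner = ",".join(fmt(c) for c in root.children)
    return f"({inner});"


def bipartitions(root: Clade) -> dict[frozenset, Clade]:
    """Non-trivial bipartitions of the unrooted tree, keyed by the canonical
    side (the one not containing the lexicographically first leaf)."""
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    out: dict[frozenset, Clade] = {}

    def walk(node: Clade) -> None:
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    key = side if anchor not in side else all_leaves - side
                    out[key] = child
                walk(child)

    walk(root)
    return out


def bootstrap_support(
    calls: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> Clade:
    """Reference NJ tree with bootstrap supports on its internal edges.

    Variants (columns) are resampled with replacement ``n_boot`` times;
    support is the percentage of replicate trees containing each internal
    bipartition of the reference tree.  ``n_boot=0`` leaves supports unset.
    """
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    ref = nj_tree(genotype_distance(calls))
    if n_boot == 0:
        return ref
    parts = bipartitions(ref)
    counts = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    ncol = calls.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        rep = calls.iloc[:, cols]
        rep_parts = bipartitions(nj_tree(genotype_distance(rep)))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, node in parts.items():
        node.support = 100.0 * counts[key] / n_boot
    return ref


def cut_tree(root: Clade, k: int = 4) -> pd.Series:
    """Partition leaves into k groups by cutting the k−1 longest internal
    edges (a stand-in for reading groups off a published tree figure)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = []  # (length, canonical clade leafset)
    for key, node in bipartitions(root).items():
        edges.append((node.length, tuple(sorted(node.leaf_names()))))
    edges.sort(key=lambda e: (-e[0], e[1]))
    if len(edges) < k - 1:
        raise ValueError(f"tree has only {len(edges)} internal edges; cannot cut {k - 1}")
    cuts = [frozenset(names) for _, names in edges[: k - 1]]
    leaves = root.leaf_names()
    signature = {leaf: tuple(leaf in c for c in cuts) for leaf in leaves}
    group_of: dict[tuple, int] = {}
    labels = {}
    for leaf in leaves:
        sig = signature[leaf]
        if sig not in group_of:
            group_of[sig] = len(group_of) + 1
        labels[leaf] = f"group{group_of[sig]}"
    return pd.Series(labels, name="group")


def classify_fnl(phenotypes: pd.Series) -> tuple[pd.Series, float]:
    """Long/short classes at the panel-mean threshold (strictly greater =>
    long).  Missing phenotypes are excluded from the mean and left unclassed."""
    values = pd.Series(phenotypes, dtype=float)
    valid = values.dropna()
    if valid.empty:
        raise ValueError("need at least one phenotype")
    threshold = float(valid.mean())
    classes = pd.Series(
        np.where(values > threshold, "long", "short"), index=values.index,
        name="fnl_class",
    )
    classes[values.isna()] = pd.NA
    return classes, threshold


def group_enrichment(
    groups: pd.Series,
    classes: pd.Series,
    geography: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-tabulate tree group × phenotype class (× geography) with margins."""
    groups = pd.Series(groups)
    classes = pd.Series(classes)
    mismatch = groups.index.symmetric_difference(classes.index)
    if geography is not None:
        geography = pd.Series(geography)
        mismatch = mismatch.union(groups.index.symmetric_difference(geography.index))
    if len(mismatch):
        raise ValueError(f"label mismatch for accessions: {sorted(map(str, mismatch))}")
    if geography is None:
        return pd.crosstab(groups, classes, margins=True, margins_name="total")
    return pd.crosstab([groups, geography], classes, margins=True,
                       margins_name="total")
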