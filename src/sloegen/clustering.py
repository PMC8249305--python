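"""Genetic-distance analysis of presence/absence-coded polyploid genotypes.

Every observed (locus, allele) pair becomes a binary column scored 1 when
the accession carries the allele.  Pairwise similarity is the Dice
coefficient D = 2|A∩B|/(|A|+|B|), with pairwise deletion of loci missing in
either accession.  Clustering is UPGMA (unweighted group-average linkage) on
1−D; node support comes from bootstrap resampling of allele columns; fit is
measured by the cophenetic correlation with a leaf-label permutation test;
ordination is PCA of the column-centred binary matrix.

UPGMA is implemented here rather than delegated so that merge tie-breaking
is deterministic (lexicographically smallest accession-id pair) and so each
internal node keeps its leaf bipartition for bootstrap bookkeeping; tests
cross-check the heights against an independent average-linkage
implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PolyGenotype, SGenotype

__all__ = [
    "BinaryMatrix",
    "encode_binary",
    "dice_similarity",
    "dice_matrix",
    "Dendrogram",
    "DendrogramNode",
    "upgma",
    "bootstrap_supports",
    "cophenetic_correlation",
    "PCAResult",
    "pca",
]

S_LOCUS = "S"


@dataclass
class BinaryMatrix:
    """Accessions × (locus, allele) presence/absence matrix.

    ``data``: 0/1 DataFrame with a 2-level column index (locus, allele);
    ``scored``: accession × locus boolean DataFrame (False = locus missing,
    its cells in ``data`` are placeholders excluded by pairwise deletion).
    """

    data: pd.DataFrame
    scored: pd.DataFrame

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    def column_loci(self) -> np.ndarray:
        return self.data.columns.get_level_values(0).to_numpy()

    def resample_columns(self, rng: np.random.Generator, unit: str = "allele"):
        """Bootstrap replicate: resample columns (or whole loci) with
        replacement, keeping the column count (or locus count)."""
        if unit == "allele":
            idx = rng.integers(0, self.data.shape[1], self.data.shape[1])
        elif unit == "locus":
            loci = self.column_loci()
            unique = pd.unique(loci)
            chosen = rng.choice(unique, size=len(unique), replace=True)
            idx = np.concatenate([np.flatnonzero(loci == loc) for loc in chosen])
        else:
            raise ValueError("unit must be 'allele' or 'locus'")
        return BinaryMatrix(data=self.data.iloc[:, idx], scored=self.scored)


def encode_binary(
    genotypes: Sequence[PolyGenotype],
    sgenotypes: Sequence[SGenotype] | None = None,
) -> BinaryMatrix:
    """Score every observed (locus, allele) as present (1) or absent (0).

    S-genotypes, when given, are appended as extra columns under the
    pseudo-locus ``"S"`` (the merged SSR + S-locus dataset).
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 accessions")
    loci = sorted({loc for g in genotypes for loc in g.calls} |
                  {loc for g in genotypes for loc in g.missing})
    columns: list[tuple] = []
    for locus in loci:
        alleles = sorted({a for g in genotypes for a in (g.calls.get(locus) or ())},
                         key=lambda a: (isinstance(a, str), a))
        columns.extend((locus, a) for a in alleles)
    s_by_acc: dict[str, frozenset] = {}
    if sgenotypes:
        s_by_acc = {sg.accession_id: sg.allele_set for sg in sgenotypes}
        s_alleles = sorted(set().union(*s_by_acc.values())) if s_by_acc else []
        columns.extend((S_LOCUS, a) for a in s_alleles)
    accs = [g.accession_id for g in genotypes]
    data = np.zeros((len(accs), len(columns)), dtype=np.int8)
    all_loci = loci + ([S_LOCUS] if sgenotypes else [])
    scored = pd.DataFrame(True, index=accs, columns=all_loci)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, g in enumerate(genotypes):
        for locus in loci:
            alleles = g.alleles_at(locus)
            if alleles is None:
                scored.iloc[i, scored.columns.get_loc(locus)] = False
                continue
            for a in alleles:
                data[i, col_index[(locus, a)]] = 1
        if sgenotypes:
            s_set = s_by_acc.get(g.accession_id)
            if s_set is None:
                scored.iloc[i, scored.columns.get_loc(S_LOCUS)] = False
            else:
                for a in s_set:
                    data[i, col_index[(S_LOCUS, a)]] = 1
    df = pd.DataFrame(
        data, index=accs, columns=pd.MultiIndex.from_tuples(columns, names=["locus", "allele"])
    )
    return BinaryMatrix(data=df, scored=scored)


def dice_similarity(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) between two 0/1 rows."""
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice undefined: both profiles empty after masking")
    return 2.0 * np.logical_and(a, b).sum() / denom


def dice_matrix(matrix: BinaryMatrix, undefined: str = "raise") -> pd.DataFrame:
    """Pairwise Dice similarity with pairwise deletion of missing loci.

    ``undefined='zero'`` substitutes 0 for pairs empty after masking
    (used inside bootstrap replicates where raising would abort the run).
    """
    accs = matrix.accessions
    X = matrix.data.to_numpy(dtype=bool)
    col_loci = matrix.column_loci()
    scored = matrix.scored
    # per-accession boolean mask over columns: locus scored for that accession
    col_ok = np.stack([
        scored.loc[acc].reindex(col_loci).to_numpy(dtype=bool) for acc in accs
    ])
    n = len(accs)
    sim = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        ok = col_ok[i] & col_ok[j]
        a, b = X[i] & ok, X[j] & ok
        denom = a.sum() + b.sum()
        if denom == 0:
            if undefined == "zero":
                d = 0.0
            else:
                raise ValueError(
                    f"Dice undefined for ({accs[i]}, {accs[j]}): "
                    "no shared scored alleles"
                )
        else:
            d = 2.0 * (a & b).sum() / denom
        sim[i, j] = sim[j, i] = d
    return pd.DataFrame(sim, index=accs, columns=accs)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class DendrogramNode:
    leaves: frozenset
    height: float
    children: tuple = ()
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Rooted ultrametric merge tree from UPGMA."""

    root: DendrogramNode
    leaf_names: tuple[str, ...]

    def internal_nodes(self) -> list[DendrogramNode]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset]:
        """Leaf bipartitions of all internal nodes (including the root)."""
        return {n.leaves for n in self.internal_nodes()}

    def merge_heights(self) -> list[float]:
        return sorted(n.height for n in self.internal_nodes())

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Tree distance between leaves: 2 × height of their lowest common
        ancestor (ultrametric)."""
        names = list(self.leaf_names)
        idx = {n: i for i, n in enumerate(names)}
        mat = np.zeros((len(names), len(names)))

        def walk(node):
            if node.is_leaf:
                return
            for a, b in itertools.combinations(node.children, 2):
                for la in a.leaves:
                    for lb in b.leaves:
                        mat[idx[la], idx[lb]] = mat[idx[lb], idx[la]] = 2 * node.height
            for c in node.children:
                walk(c)

        walk(self.root)
        return pd.DataFrame(mat, index=names, columns=names)

    def newick(self, include_support: bool = True) -> str:
        """Newick string; bootstrap supports (if any) label internal nodes,
        branch lengths are parent height − child height."""

        def fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf:
                (name,) = node.leaves
                return f"{_newick_escape(name)}:{bl:.6g}"
            inner = ",".join(
                fmt(c, node.height) for c in sorted(node.children, key=lambda c: min(map(str, c.leaves)))
            )
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{bl:.6g}"

        root = self.root
        inner = ",".join(
            fmt(c, root.height) for c in sorted(root.children, key=lambda c: min(map(str, c.leaves)))
        )
        label = f"{root.support:g}" if include_support and root.support is not None else ""
        return f"({inner}){label};"


def _newick_escape(name: str) -> str:
    if any(ch in name for ch in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def upgma(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA (unweighted pair-group average) clustering of a distance matrix.

    At each step the minimum-distance pair of clusters merges at height
    d/2; ties are broken by the lexicographically smallest pair of minimal
    member ids, making the tree deterministic.  Merge heights are verified
    to be non-decreasing (ultrametricity) on every run.
    """
    names = list(distances.index)
    if list(distances.columns) != names:
        raise ValueError("distance matrix must have matching index and columns")
    D = distances.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    clusters: dict[int, DendrogramNode] = {
        i: DendrogramNode(leaves=frozenset([name]), height=0.0)
        for i, name in enumerate(names)
    }
    sizes = {i: 1 for i in clusters}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i, j in itertools.combinations(range(len(names)), 2)
    }
    key_of = {i: min(map(str, clusters[i].leaves)) for i in clusters}
    next_id = len(names)
    last_height = 0.0
    while len(clusters) > 1:
        # minimal distance, ties by lexicographic (min id, other id)
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((key_of[kv[0][0]], key_of[kv[0][1]])))),
        )
        (i, j), d = best
        height = d / 2.0
        if height < last_height - 1e-9:
            raise AssertionError("UPGMA merge heights decreased")  # pragma: no cover
        last_height = max(last_height, height)
        node = DendrogramNode(
            leaves=clusters[i].leaves | clusters[j].leaves,
            height=height,
            children=tuple(
                sorted((clusters[i], clusters[j]), key=lambda c: min(map(str, c.leaves)))
            ),
        )
        ni, nj = sizes[i], sizes[j]
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[k] = (ni * dik + nj * djk) / (ni + nj)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j], key_of[i], key_of[j]
        clusters[next_id] = node
        sizes[next_id] = ni + nj
        key_of[next_id] = min(map(str, node.leaves))
        for k, dk in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = dk
        next_id += 1
    (root,) = clusters.values()
    return Dendrogram(root=root, leaf_names=tuple(names))


def bootstrap_supports(
    matrix: BinaryMatrix,
    tree: Dendrogram,
    n_replicates: int = 2000,
    seed: int | np.random.Generator | None = None,
    unit: str = "allele",
) -> dict[frozenset, float]:
    """Bootstrap support (%) for every internal node of ``tree``.

    Allele columns (default) or whole loci are resampled with replacement;
    Dice + UPGMA are recomputed and a node's support is the percentage of
    replicate trees containing its exact leaf bipartition.  Supports are
    written back onto the tree's nodes and also returned keyed by clade.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = {node.leaves: 0 for node in tree.internal_nodes()}
    for _ in range(n_replicates):
        rep = matrix.resample_columns(rng, unit=unit)
        sim = dice_matrix(rep, undefined="zero")
        rep_tree = upgma(1.0 - sim)
        for clade in rep_tree.clades():
            if clade in target:
                target[clade] += 1
    supports = {clade: 100.0 * c / n_replicates for clade, c in target.items()}
    for node in tree.internal_nodes():
        node.support = supports[node.leaves]
    return supports


def cophenetic_correlation(
    tree: Dendrogram,
    distances: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """Cophenetic correlation of a dendrogram with a permutation p-value.

    r is the Pearson correlation between the input pairwise distances and
    the tree's cophenetic distances.  The null distribution is obtained by
    randomly permuting the assignment of leaf labels to tree positions
    (shuffling rows/columns of the cophenetic matrix); the p-value is
    one-sided (greater), with the +1 correction.  Returns (nan, None) when
    the input distances have zero variance.
    """
    names = list(tree.leaf_names)
    if len(names) < 3:
        raise ValueError("need at least 3 accessions")
    obs = distances.loc[names, names].to_numpy(dtype=float)
    coph = tree.cophenetic_matrix().loc[names, names].to_numpy()
    iu = np.triu_indices(len(names), k=1)
    x, y = obs[iu], coph[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), None
    r = float(stats.pearsonr(x, y).statistic)
    if n_permutations < 1:
        return r, None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    n = len(names)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_perm = coph[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(x, y_perm)[0, 1]
        if r_perm >= r - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return r, p


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame          # accessions × axes
    variance_fraction: np.ndarray  # over all axes, sums to 1
    loadings: pd.DataFrame         # columns × axes

    def axis_percent(self, k: int) -> float:
        return 100.0 * float(self.variance_fraction[k])


def pca(matrix: BinaryMatrix, correlation: bool = False) -> PCAResult:
    """PCA of the column-centred presence/absence matrix.

    Covariance-mode by default; ``correlation=True`` additionally scales
    columns to unit variance.  Sign convention: on each axis the loading
    with the largest magnitude is made positive.  Cells of missing loci are
    treated as absences.
    """
    if matrix.data.shape[0] < 3 or matrix.data.shape[1] < 2:
        raise ValueError("need >= 3 accessions and >= 2 columns")
    X = matrix.data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if correlation:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
        cols = matrix.data.columns[keep]
    else:
        cols = matrix.data.columns
    total_var = np.sum(X**2)
    if total_var == 0:
        raise ValueError("degenerate matrix: all columns constant")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| positive per axis
    for k in range(len(s)):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * s
    var_frac = s**2 / total_var
    axes = [f"PC{k+1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=axes),
        variance_fraction=var_frac,
        loadings=pd.DataFrame(Vt.T, index=cols, columns=axes),
    )
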