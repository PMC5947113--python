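"""Correlation, PCA and clustering over trait/hormone tables.

The association layer works on an accession x variable table (a pandas
DataFrame).  It provides:

* pairwise-complete Pearson correlation matrices with two-sided p-values
  from the t transform t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 df,
* significance flags at configurable levels (unadjusted by default, to
  match the convention of flagging raw P < 0.05 / P < 0.01;
  Benjamini-Hochberg optionally),
* PCA of the correlation matrix (i.e. PCA on standardized variables),
  with a deterministic loading-sign convention,
* hierarchical clustering of variables with 1 - r distance and average
  linkage by default, exported as a Newick string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "AssociationResult",
    "PCAResult",
    "ClusterResult",
    "AssocError",
    "pearson_matrix",
    "significance_flags",
    "pca_correlation",
    "hcluster",
]


class AssocError(ValueError):
    pass


@dataclass
class AssociationResult:
    """Correlation matrix bundle: r, two-sided p, pair counts n.

    All three are square DataFrames over the same variable index; the
    diagonal of ``r`` is 1 and the diagonal of ``p`` undefined (NaN).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pearson_matrix(table: pd.DataFrame, min_pairs: int = 3) -> AssociationResult:
    """Pairwise-complete Pearson correlations with p-values.

    Each pair of variables uses its complete observations only; pairs with
    fewer than ``min_pairs`` complete observations, and any pair involving
    a zero-variance column, get missing r/p (with a warning).
    """
    cols = list(table.columns)
    if len(cols) != len(set(cols)):
        raise AssocError("column names must be unique")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    values = table.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        n[i, i] = int(np.isfinite(values[:, i]).sum())
    for i in range(k):
        for j in range(i + 1, k):
            mask = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            nij = int(mask.sum())
            n[i, j] = n[j, i] = nij
            if nij < min_pairs:
                warnings.warn(
                    f"{cols[i]} vs {cols[j]}: only {nij} complete pairs "
                    f"(< {min_pairs}); correlation undefined"
                )
                continue
            x, y = values[mask, i], values[mask, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"{cols[i]} vs {cols[j]}: zero-variance column; "
                    "correlation undefined"
                )
                continue
            rij, pij = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(cols)
    return AssociationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def significance_flags(
    result: AssociationResult,
    levels: Sequence[float] = (0.05, 0.01),
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Per-cell significance flags at the smallest level exceeded.

    Returns a string matrix: "" (not significant), "*" for the looser
    level, "**" for the stricter one.  P-values are unadjusted by default;
    ``adjust="bh"`` applies Benjamini-Hochberg over the upper triangle.
    """
    levels = sorted(levels, reverse=True)  # loosest first
    p = result.p.copy()
    if adjust == "bh":
        iu = np.triu_indices(len(p), k=1)
        raw = p.to_numpy()[iu]
        finite = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if finite.any():
            adj[finite] = stats.false_discovery_control(raw[finite], method="bh")
        mat = p.to_numpy()
        mat[iu] = adj
        mat.T[iu] = adj
        p = pd.DataFrame(mat, index=p.index, columns=p.columns)
    elif adjust is not None:
        raise AssocError(f"unknown adjustment {adjust!r}")
    flags = pd.DataFrame("", index=p.index, columns=p.columns)
    for stars, level in enumerate(levels, start=1):
        flags = flags.mask(p < level, "*" * stars)
    np.fill_diagonal(flags.values, "")
    return flags


@dataclass
class PCAResult:
    """Eigendecomposition of a correlation matrix.

    ``loadings`` (variable x component) are the unit-norm eigenvectors,
    sign-fixed so each component's largest-magnitude loading is positive;
    ``variance_fraction`` is eigenvalue / sum(eigenvalues), non-increasing;
    ``scores`` are the standardized observations projected on the loadings.
    """

    loadings: pd.DataFrame
    variance_fraction: pd.Series
    scores: pd.DataFrame


def pca_correlation(table: pd.DataFrame) -> PCAResult:
    """PCA of the Pearson correlation matrix of ``table``.

    Rows with any missing value are dropped (complete-case); constant
    columns are an error because they cannot be standardized.
    """
    data = table.dropna(axis=0, how="any")
    if data.shape[1] < 2:
        raise AssocError("need >= 2 variables")
    if data.shape[0] < 3:
        raise AssocError("need >= 3 complete rows")
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    for name, s in zip(data.columns, sd):
        if s == 0:
            raise AssocError(f"constant column {name!r} cannot enter correlation PCA")
    z = (values - values.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[pivot, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    comps = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=comps)
    fractions = pd.Series(eigval / eigval.sum(), index=comps, name="variance_fraction")
    scores = pd.DataFrame(z @ eigvec, index=data.index, columns=comps)
    return PCAResult(loadings=loadings, variance_fraction=fractions, scores=scores)


@dataclass
class ClusterResult:
    """Hierarchical clustering of variables.

    ``linkage`` is the scipy linkage matrix over ``labels`` (merge heights
    non-decreasing for the supported linkages on these distances);
    ``newick`` is the ultrametric dendrogram as a Newick string.
    """

    labels: list[str]
    linkage: np.ndarray
    newick: str
    distance: str
    method: str


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        branch = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{branch:.10g}"

    if tree.is_leaf():
        return f"{labels[tree.id]}:0;"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def hcluster(
    table: pd.DataFrame,
    distance: str = "one-minus-r",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of the table's variables.

    ``distance``: "one-minus-r" (1 - Pearson r, the default, so perfectly
    correlated variables merge at height 0) or "euclidean" on standardized
    columns.  ``method``: any scipy linkage ("average" default).
    Variables whose correlations are undefined (zero variance, too few
    pairs) are dropped with a warning.
    """
    if table.shape[1] < 2:
        raise AssocError("need >= 2 variables")
    if distance == "one-minus-r":
        assoc = pearson_matrix(table)
        r = assoc.r
        bad = [c for c in r.columns if r[c].isna().any()]
        if bad:
            warnings.warn(f"dropping variables with undefined correlations: {bad}")
            keep = [c for c in r.columns if c not in bad]
            if len(keep) < 2:
                raise AssocError("fewer than 2 variables with defined correlations")
            r = r.loc[keep, keep]
        labels = list(r.columns)
        dmat = 1.0 - r.to_numpy()
        np.fill_diagonal(dmat, 0.0)
        dmat = np.clip(dmat, 0.0, None)
        condensed = dmat[np.triu_indices(len(labels), k=1)]
        link = hierarchy.linkage(condensed, method=method)
    elif distance == "euclidean":
        data = table.dropna(axis=0, how="any")
        sd = data.std(ddof=1)
        bad = [c for c in data.columns if sd[c] == 0]
        if bad:
            warnings.warn(f"dropping constant variables: {bad}")
            data = data.drop(columns=bad)
        if data.shape[1] < 2:
            raise AssocError("fewer than 2 usable variables")
        labels = list(data.columns)
        z = (data - data.mean()) / data.std(ddof=1)
        link = hierarchy.linkage(z.to_numpy().T, method=method, metric="euclidean")
    else:
        raise AssocError(f"unknown distance {distance!r}")
    return ClusterResult(
        labels=labels,
        linkage=link,
        newick=_linkage_to_newick(link, labels),
        distance=distance,
        method=method,
    )
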