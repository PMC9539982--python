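"""Distance matrices and (partial) Mantel permutation tests.

Phylogenetic distances are cophenetic (tip-to-tip path lengths); community
dissimilarity is the Jaccard distance on binary interaction profiles. The
Mantel statistic is the Pearson correlation of the strictly-lower-triangle
vectors of two conformable distance matrices; its p-value comes from jointly
permuting the row/column labels of the second matrix, one-tailed for
positive association by default, with the observed statistic included in
the reference set (p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), so p is
never 0). The partial Mantel statistic is the first-order partial
correlation r12.3 = (r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2)),
recomputed for each permutation of the second matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .exceptions import FormatError, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

_EPS = 1e-12


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix of a tree, as a labelled DataFrame."""
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("cophenetic distances need at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def root_to_tip_depths(tree: dendropy.Tree) -> pd.Series:
    """Root-to-tip path lengths (treating a missing root-edge length as 0)."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    return pd.Series(depths)


def tip_correlation_matrix(tree: dendropy.Tree, tips: list[str]) -> pd.DataFrame:
    """Phylogenetic tip correlations C_ij = shared root-to-MRCA path length
    normalised by sqrt(depth_i * depth_j).

    On an ultrametric tree this is the classic shared-branch-length
    correlation; on non-ultrametric trees it remains a valid correlation
    because the shared path is computed as (depth_i + depth_j - d_ij) / 2.
    """
    depths = root_to_tip_depths(tree)
    missing = [t for t in tips if t not in depths.index]
    if missing:
        raise ValidationError(f"community members not in tree: {missing}")
    d = cophenetic_distances(tree).loc[tips, tips].to_numpy()
    dep = depths.loc[tips].to_numpy()
    if (dep <= 0).any():
        raise UndefinedStatisticError("tip with zero root-to-tip depth; correlations undefined")
    shared = (dep[:, None] + dep[None, :] - d) / 2.0
    corr = shared / np.sqrt(np.outer(dep, dep))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=tips, columns=tips)


def jaccard_dissimilarity(incidence: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise Jaccard distance 1 - |intersection|/|union| of partner sets.

    axis="rows" compares row profiles (e.g. plants by their fungi);
    axis="columns" compares column profiles. Entities with empty partner
    sets are excluded with a warning (the distance is undefined for them).
    """
    if axis == "columns":
        incidence = incidence.T
    elif axis != "rows":
        raise ValidationError("axis must be 'rows' or 'columns'")
    b = (incidence.to_numpy() > 0).astype(np.int64)
    sizes = b.sum(axis=1)
    empty = incidence.index[sizes == 0].tolist()
    if empty:
        logger.warning("excluding entities with empty partner sets: %s", empty)
        keep = sizes > 0
        incidence = incidence.loc[keep]
        b = b[keep]
        sizes = sizes[keep]
    inter = b @ b.T
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=incidence.index, columns=incidence.index)


@dataclass(frozen=True)
class MantelResult:
    """Result of a (partial) Mantel permutation test."""

    r: float
    p: float
    n_perm: int
    n: int
    alternative: str = "greater"
    partial: bool = False
    controlled: str | None = None

    def summary(self) -> str:
        kind = "Partial Mantel" if self.partial else "Mantel"
        lines = [
            f"{kind} test (one-tailed '{self.alternative}', {self.n_perm} permutations)",
            f"  matrix size n = {self.n}",
            f"  r = {self.r:.4f}",
            f"  p = {self.p:.4g}",
        ]
        if self.partial and self.controlled:
            lines.insert(1, f"  controlling for: {self.controlled}")
        return "\n".join(lines)


def _check_distance_matrix(d: pd.DataFrame, name: str) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{name} is not square")
    if not np.allclose(arr, arr.T):
        raise ValidationError(f"{name} is not symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError(f"{name} has nonzero diagonal")
    if (arr < -_EPS).any():
        raise ValidationError(f"{name} has negative entries")
    return arr


def _aligned_arrays(*mats: pd.DataFrame) -> list[np.ndarray]:
    ids = list(mats[0].index)
    for m in mats[1:]:
        if list(m.index) != ids or list(m.columns) != list(mats[0].columns):
            raise ValidationError("distance matrices must share identical id order")
    return [_check_distance_matrix(m, f"matrix {k + 1}") for k, m in enumerate(mats)]


def _triangle(arr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(arr.shape[0], 1)
    return arr[iu]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < _EPS:
        raise UndefinedStatisticError("zero variance in distance triangle; r undefined")
    return (v - v.mean()) / sd


def _permuted_triangles(
    arr: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Triangle vectors of arr under n_perm random joint row/column label
    permutations, shape (n_perm, n*(n-1)/2)."""
    n = arr.shape[0]
    iu, ju = np.triu_indices(n, 1)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    return arr[perms[:, iu], perms[:, ju]]


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two conformable distance matrices."""
    a1, a2 = _aligned_arrays(d1, d2)
    n = a1.shape[0]
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 ids")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng() if rng is None else rng
    v1 = _standardize(_triangle(a1))
    v2 = _standardize(_triangle(a2))
    m = v1.size
    r_obs = float(v1 @ v2 / m)
    tri = _permuted_triangles(a2, n_perm, rng)
    mu = tri.mean(axis=1, keepdims=True)
    sd = tri.std(axis=1, keepdims=True)
    ok = (sd > _EPS).ravel()
    r_perm = np.full(n_perm, np.nan)
    r_perm[ok] = ((tri[ok] - mu[ok]) / sd[ok] @ v1) / m
    if alternative == "greater":
        extreme = np.nansum(r_perm >= r_obs - _EPS)
    else:
        extreme = np.nansum(r_perm <= r_obs + _EPS)
    p = (1.0 + float(extreme)) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n=n, alternative=alternative)


def _partial_r(r12: np.ndarray, r13: float, r23: np.ndarray) -> np.ndarray:
    denom = np.sqrt((1.0 - r13**2) * (1.0 - r23**2))
    return (r12 - r13 * r23) / denom


def partial_mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    d3: pd.DataFrame,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
    controlled: str | None = None,
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for d3.

    The labels of d2 are permuted and the full partial statistic (including
    the permuted r23) is recomputed each time.
    """
    a1, a2, a3 = _aligned_arrays(d1, d2, d3)
    n = a1.shape[0]
    if n < 4:
        raise ValidationError("partial Mantel test needs at least 4 ids")
    rng = np.random.default_rng() if rng is None else rng
    v1 = _standardize(_triangle(a1))
    v2 = _standardize(_triangle(a2))
    v3 = _standardize(_triangle(a3))
    m = v1.size
    r12 = float(v1 @ v2 / m)
    r13 = float(v1 @ v3 / m)
    r23 = float(v2 @ v3 / m)
    if min(1.0 - r13**2, 1.0 - r23**2) < _EPS:
        raise UndefinedStatisticError("|r13| or |r23| is 1; partial r undefined")
    r_obs = float(_partial_r(np.array(r12), r13, np.array(r23)))
    tri = _permuted_triangles(a2, n_perm, rng)
    mu = tri.mean(axis=1, keepdims=True)
    sd = tri.std(axis=1, keepdims=True)
    ok = (sd > _EPS).ravel()
    z = np.full((n_perm, m), np.nan)
    z[ok] = (tri[ok] - mu[ok]) / sd[ok]
    r12p = z @ v1 / m
    r23p = z @ v3 / m
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = _partial_r(r12p, r13, r23p)
    if alternative == "greater":
        extreme = np.nansum(r_perm >= r_obs - _EPS)
    else:
        extreme = np.nansum(r_perm <= r_obs + _EPS)
    p = (1.0 + float(extreme)) / (1.0 + n_perm)
    return MantelResult(
        r=r_obs,
        p=p,
        n_perm=n_perm,
        n=n,
        alternative=alternative,
        partial=True,
        controlled=controlled,
    )
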