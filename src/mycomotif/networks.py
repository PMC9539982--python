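"""Node- and pair-level descriptors of tripartite incidence networks.

The tripartite network is two binary incidence blocks over one aligned
fungal axis: mycoheterotrophs x fungi (the "antagonist" block) and
autotrophs x fungi (the "mutualist" block). Metrics here: normalised
degree, phylogenetic species variability (psv) of a plant's fungal
community, plant-plant fungal overlap, and fungal ecological similarity
(Jaccard and overlap measures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .exceptions import EmptyFilterError, ValidationError
from .io import GUILD_AUTOTROPH, GUILD_MYCOHETEROTROPH
from .phylo import tip_correlation_matrix

logger = logging.getLogger(__name__)


def _check_binary(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} block must be binary")


@dataclass
class TripartiteNetwork:
    """Two binary incidence blocks sharing one ordered fungal index."""

    mh: pd.DataFrame
    auto: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.mh.columns) != list(self.auto.columns):
            raise ValidationError("blocks must share identical, identically ordered fungal ids")
        if set(self.mh.index) & set(self.auto.index):
            raise ValidationError("plant ids must be disjoint between guild blocks")
        _check_binary(self.mh, "mycoheterotroph")
        _check_binary(self.auto, "autotroph")

    @classmethod
    def from_incidence(cls, incidence: pd.DataFrame, guild: pd.Series) -> "TripartiteNetwork":
        """Split one plant x fungus incidence matrix into guild blocks."""
        guild = guild.reindex(incidence.index)
        if guild.isna().any():
            raise ValidationError(
                f"plants without guild: {incidence.index[guild.isna()].tolist()}"
            )
        mh = incidence.loc[guild == GUILD_MYCOHETEROTROPH]
        auto = incidence.loc[guild == GUILD_AUTOTROPH]
        return cls(mh=mh, auto=auto)

    @property
    def fungi(self) -> list[str]:
        return list(self.mh.columns)

    @property
    def n_fungi(self) -> int:
        return self.mh.shape[1]

    def stacked(self) -> pd.DataFrame:
        """All plants (MH rows first) over the shared fungal axis."""
        return pd.concat([self.mh, self.auto], axis=0)

    def guild_of(self) -> pd.Series:
        return pd.Series(
            [GUILD_MYCOHETEROTROPH] * len(self.mh.index)
            + [GUILD_AUTOTROPH] * len(self.auto.index),
            index=list(self.mh.index) + list(self.auto.index),
        )


def normalized_degree(incidence: pd.DataFrame, axis: str = "rows") -> pd.Series:
    """Degree divided by the number of possible partners in the matrix.

    axis="rows": each row's fraction of realised columns (a plant's fraction
    of the network's fungi); axis="columns": each column's fraction of
    realised rows.
    """
    if incidence.size == 0:
        raise ValidationError("normalized degree of an empty matrix is undefined")
    if axis == "rows":
        return incidence.sum(axis=1) / incidence.shape[1]
    if axis == "columns":
        return incidence.sum(axis=0) / incidence.shape[0]
    raise ValidationError("axis must be 'rows' or 'columns'")


@dataclass(frozen=True)
class PSVResult:
    """Phylogenetic species variability of one community.

    psv is None when the community has fewer than two members (the index is
    undefined there); otherwise psv = 1 - mean off-diagonal phylogenetic
    correlation, in [0, 1]: 1 for phylogenetically unrelated members,
    approaching 0 as relatedness increases.
    """

    plant_id: str | None
    n: int
    psv: float | None

    @property
    def defined(self) -> bool:
        return self.psv is not None


def psv(
    community: list[str] | set[str],
    tree: dendropy.Tree,
    plant_id: str | None = None,
) -> PSVResult:
    """Phylogenetic species variability of a community on a tree."""
    members = sorted(set(community))
    n = len(members)
    if n < 2:
        return PSVResult(plant_id=plant_id, n=n, psv=None)
    corr = tip_correlation_matrix(tree, members).to_numpy()
    value = (n * np.trace(corr) - corr.sum()) / (n * (n - 1))
    return PSVResult(plant_id=plant_id, n=n, psv=float(value))


def community_psv(incidence: pd.DataFrame, tree: dendropy.Tree) -> list[PSVResult]:
    """psv of each row's partner community."""
    out = []
    for plant, row in incidence.iterrows():
        members = list(incidence.columns[row > 0])
        out.append(psv(members, tree, plant_id=str(plant)))
    return out


_PAIR_TYPE = {
    (GUILD_MYCOHETEROTROPH, GUILD_MYCOHETEROTROPH): "MH-MH",
    (GUILD_MYCOHETEROTROPH, GUILD_AUTOTROPH): "MH-A",
    (GUILD_AUTOTROPH, GUILD_MYCOHETEROTROPH): "MH-A",
    (GUILD_AUTOTROPH, GUILD_AUTOTROPH): "A-A",
}


def plant_plant_overlap(net: TripartiteNetwork) -> pd.DataFrame:
    """Weighted plant-plant edge list: weight = number of shared fungi.

    Every unordered plant pair with at least one shared fungus yields an
    edge, tagged MH-MH / MH-A / A-A.
    """
    stacked = net.stacked()
    guild = net.guild_of()
    b = stacked.to_numpy()
    shared = b @ b.T
    plants = list(stacked.index)
    rows = []
    for i in range(len(plants)):
        for j in range(i + 1, len(plants)):
            w = int(shared[i, j])
            if w > 0:
                rows.append(
                    {
                        "plant_1": plants[i],
                        "plant_2": plants[j],
                        "weight": w,
                        "pair_type": _PAIR_TYPE[(guild[plants[i]], guild[plants[j]])],
                    }
                )
    return pd.DataFrame(rows, columns=["plant_1", "plant_2", "weight", "pair_type"])


@dataclass
class FungalSimilarity:
    """Pairwise ecological similarity of fungi through shared plants.

    matrix: fungus x fungus similarity in [0, 1] (diagonal 1);
    measure: "jaccard" (shared / total partners) or "overlap"
    (shared / min partner count); degrees: plant-degree per fungus;
    shared: raw shared-plant counts C_ij.
    """

    matrix: pd.DataFrame
    measure: str
    degrees: pd.Series
    shared: pd.DataFrame

    def as_distance(self) -> pd.DataFrame:
        d = 1.0 - self.matrix
        np.fill_diagonal(d.to_numpy(), 0.0)
        return d


def fungal_similarity(incidence: pd.DataFrame, measure: str = "jaccard") -> FungalSimilarity:
    """Jaccard or overlap similarity between fungi (columns) of one block.

    Jaccard: C_ij / (d_i + d_j - C_ij); overlap: C_ij / min(d_i, d_j).
    Fungi with no plant partners in this block are excluded (both measures
    are 0/0 for them) with a logged warning.
    """
    if measure not in ("jaccard", "overlap"):
        raise ValidationError("measure must be 'jaccard' or 'overlap'")
    b = (incidence.to_numpy() > 0).astype(np.int64)
    deg = b.sum(axis=0)
    empty = incidence.columns[deg == 0].tolist()
    if empty:
        logger.warning("excluding %d zero-degree fungi from similarity: %s", len(empty), empty)
        keep = deg > 0
        incidence = incidence.loc[:, keep]
        b = b[:, keep]
        deg = deg[keep]
    if incidence.shape[1] == 0:
        raise EmptyFilterError("no fungus has a plant partner; similarity undefined")
    shared = b.T @ b
    if measure == "jaccard":
        denom = deg[:, None] + deg[None, :] - shared
    else:
        denom = np.minimum(deg[:, None], deg[None, :])
    sim = shared / denom
    np.fill_diagonal(sim, 1.0)
    fungi = list(incidence.columns)
    return FungalSimilarity(
        matrix=pd.DataFrame(sim, index=fungi, columns=fungi),
        measure=measure,
        degrees=pd.Series(deg, index=fungi),
        shared=pd.DataFrame(shared, index=fungi, columns=fungi),
    )


def restrict_to_shared_fungi(net: TripartiteNetwork) -> TripartiteNetwork:
    """Keep only fungi present in BOTH guild blocks.

    Plant rows left with no fungus are dropped with a log entry; an empty
    shared fungal set is an error.
    """
    shared = (net.mh.sum(axis=0) > 0) & (net.auto.sum(axis=0) > 0)
    if not shared.any():
        raise EmptyFilterError("no fungus is shared between the two guilds")
    mh = net.mh.loc[:, shared]
    auto = net.auto.loc[:, shared]
    for name, block in (("mycoheterotroph", mh), ("autotroph", auto)):
        empty_rows = block.index[block.sum(axis=1) == 0].tolist()
        if empty_rows:
            logger.info("shared-fungi restriction drops %s plants %s", name, empty_rows)
    mh = mh.loc[mh.sum(axis=1) > 0]
    auto = auto.loc[auto.sum(axis=1) > 0]
    return TripartiteNetwork(mh=mh, auto=auto)
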