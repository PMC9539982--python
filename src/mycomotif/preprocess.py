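"""Sample-level count tables -> species-level rarefied binary incidence.

The fixed pipeline order is: mask low-count cells -> drop shallow samples ->
aggregate samples into species communities -> drop shallow species -> rarefy
each species to a common read depth -> binarize. Masking guards against
tag-switching artefacts (cells below the read floor are zeroed, not whole
OTUs deleted, so an OTU genuinely present elsewhere survives); rarefaction
is without replacement (multivariate hypergeometric), so every rarefied
species row sums exactly to the depth and no cell exceeds its original
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyFilterError, RarefactionError, ValidationError
from .io import GUILDS, species_guilds

logger = logging.getLogger(__name__)


@dataclass
class SpeciesCommunities:
    """Species-level pooled fungal communities.

    counts: species x OTU integer DataFrame (sum over each species' retained
    samples); guild: species_id -> guild; n_samples: species_id -> number of
    samples pooled.
    """

    counts: pd.DataFrame
    guild: pd.Series
    n_samples: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.guild.index) or not self.counts.index.equals(
            self.n_samples.index
        ):
            raise ValidationError("counts, guild and n_samples must share the species index")
        if (self.n_samples < 1).any():
            raise ValidationError("every species must have at least one sample")

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def mask_low_count_cells(table: pd.DataFrame, min_otu_reads: int) -> pd.DataFrame:
    """Zero every cell with 0 < count < min_otu_reads; drop all-zero OTU columns."""
    if min_otu_reads < 1:
        raise ValidationError("min_otu_reads must be >= 1")
    masked = table.where(table >= min_otu_reads, 0)
    n_masked = int(((table > 0) & (table < min_otu_reads)).to_numpy().sum())
    keep = masked.sum(axis=0) > 0
    dropped = int((~keep).sum())
    if n_masked or dropped:
        logger.info(
            "cell mask (<%d reads): zeroed %d cells, dropped %d empty OTU columns",
            min_otu_reads,
            n_masked,
            dropped,
        )
    return masked.loc[:, keep]


def filter_samples(
    table: pd.DataFrame, metadata: pd.DataFrame, min_sample_reads: int
) -> pd.DataFrame:
    """Keep samples whose total read count is >= min_sample_reads."""
    if min_sample_reads < 1:
        raise ValidationError("min_sample_reads must be >= 1")
    known = set(metadata["sample_id"])
    missing = [s for s in table.index if s not in known]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    keep = table.sum(axis=1) >= min_sample_reads
    if not keep.any():
        raise EmptyFilterError(
            f"no sample has >= {min_sample_reads} reads; table empty after filtering"
        )
    removed = table.index[~keep].tolist()
    if removed:
        logger.info("sample filter (<%d reads): removed %s", min_sample_reads, removed)
    return table.loc[keep]


def aggregate_to_species(table: pd.DataFrame, metadata: pd.DataFrame) -> SpeciesCommunities:
    """Pool each species' samples into one community (elementwise sum)."""
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.index if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    species = meta.loc[table.index, "species_id"]
    counts = table.groupby(species).sum()
    counts.index.name = "species_id"
    n_samples = species.value_counts().reindex(counts.index)
    guild = species_guilds(metadata).reindex(counts.index)
    return SpeciesCommunities(counts=counts, guild=guild, n_samples=n_samples)


def filter_species(
    communities: SpeciesCommunities, min_species_reads: int
) -> SpeciesCommunities:
    """Drop species whose pooled read total is below min_species_reads.

    Both guilds must survive; a guild losing all its species aborts the
    pipeline because the tripartite analysis needs autotrophs and
    mycoheterotrophs.
    """
    if min_species_reads < 1:
        raise ValidationError("min_species_reads must be >= 1")
    totals = communities.totals()
    keep = totals >= min_species_reads
    removed = totals.index[~keep].tolist()
    for sp in removed:
        logger.info(
            "species filter (<%d reads): removed %s (%d reads)",
            min_species_reads,
            sp,
            int(totals[sp]),
        )
    kept_guilds = set(communities.guild[keep])
    for guild in GUILDS:
        if guild not in kept_guilds:
            raise EmptyFilterError(
                f"species filter at {min_species_reads} reads removed every {guild}"
            )
    return SpeciesCommunities(
        counts=communities.counts.loc[keep],
        guild=communities.guild[keep],
        n_samples=communities.n_samples[keep],
    )


def rarefy(
    communities: SpeciesCommunities | pd.DataFrame,
    depth: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Subsample each species' pooled reads to ``depth`` without replacement.

    Each row is an independent multivariate-hypergeometric draw, so row sums
    equal ``depth`` exactly and no cell can exceed its original count. A
    species with fewer than ``depth`` reads raises, naming the species.
    """
    counts = communities.counts if isinstance(communities, SpeciesCommunities) else communities
    totals = counts.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise RarefactionError(
            f"species below rarefaction depth {depth}: "
            + ", ".join(f"{sp} ({int(t)} reads)" for sp, t in short.items())
        )
    out = np.empty(counts.shape, dtype=np.int64)
    arr = counts.to_numpy()
    for i in range(arr.shape[0]):
        out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def binarize(table: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence: 1 iff count > 0; all-zero OTU columns dropped."""
    inc = (table > 0).astype(np.int8)
    keep = inc.sum(axis=0) > 0
    return inc.loc[:, keep]


def preprocess_pipeline(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    min_otu_reads: int,
    min_sample_reads: int,
    min_species_reads: int,
) -> SpeciesCommunities:
    """Deterministic head of the pipeline: mask -> sample filter -> aggregate
    -> species filter. Rarefaction/binarization are applied per replicate by
    the caller (they consume randomness)."""
    masked = mask_low_count_cells(table, min_otu_reads)
    filtered = filter_samples(masked, metadata, min_sample_reads)
    communities = aggregate_to_species(filtered, metadata)
    return filter_species(communities, min_species_reads)
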