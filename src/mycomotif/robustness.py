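"""Replication scaffolding: rarefaction ensembles, per-species sample
resampling, and multi-depth sweeps, each summarised as mean +- SD (and, for
motif tests, the fraction of replicates in which the diamond module was
overrepresented)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import EmptyFilterError, ValidationError
from .io import GUILDS
from .motifs import DiamondMotifResult
from .networks import TripartiteNetwork
from .preprocess import SpeciesCommunities, aggregate_to_species, binarize, rarefy

logger = logging.getLogger(__name__)

#: analysis functions map one rarefied binary tripartite network to either a
#: scalar metric or a DiamondMotifResult
AnalysisFn = Callable[[TripartiteNetwork], "float | DiamondMotifResult"]


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-metric summary over replicate rarefied / resampled matrices."""

    metric: str
    values: tuple[float, ...]
    fraction_overrepresented: float | None = None
    replicate_table: pd.DataFrame | None = None

    @property
    def n_reps(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=0))

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_reps": self.n_reps,
            "mean": self.mean,
            "sd": self.sd,
            "fraction_overrepresented": self.fraction_overrepresented,
        }

    def summary(self) -> str:
        line = f"{self.metric}: {self.mean:.2f} +- {self.sd:.2f} over {self.n_reps} replicates"
        if self.fraction_overrepresented is not None:
            line += f"; overrepresented in {100 * self.fraction_overrepresented:.1f}% of replicates"
        return line


def _summarise(
    metric: str, outputs: list, extra_cols: dict[str, list] | None = None
) -> EnsembleSummary:
    rows: list[dict] = []
    values: list[float] = []
    flags: list[bool] = []
    for k, out in enumerate(outputs):
        if isinstance(out, DiamondMotifResult):
            values.append(float(out.observed))
            flags.append(out.overrepresented)
            rows.append({"replicate": k, **out.to_dict()})
        else:
            values.append(float(out))
            rows.append({"replicate": k, "value": float(out)})
    table = pd.DataFrame(rows)
    for name, col in (extra_cols or {}).items():
        table[name] = col
    return EnsembleSummary(
        metric=metric,
        values=tuple(values),
        fraction_overrepresented=(sum(flags) / len(flags)) if flags else None,
        replicate_table=table,
    )


def _network_from_counts(counts: pd.DataFrame, guild: pd.Series) -> TripartiteNetwork:
    return TripartiteNetwork.from_incidence(binarize(counts), guild)


def rarefaction_ensemble(
    communities: SpeciesCommunities,
    depth: int,
    n_reps: int,
    analysis_fn: AnalysisFn,
    rng: np.random.Generator,
    metric: str = "metric",
) -> EnsembleSummary:
    """Apply ``analysis_fn`` to ``n_reps`` independent rarefy->binarize draws."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    outputs = []
    for _ in range(n_reps):
        rarefied = rarefy(communities, depth, rng)
        outputs.append(analysis_fn(_network_from_counts(rarefied, communities.guild)))
    return _summarise(metric, outputs)


def eligible_species(metadata: pd.DataFrame, k: int) -> pd.Series:
    """species_id -> sample count, restricted to species with >= k samples."""
    counts = metadata.groupby("species_id")["sample_id"].count()
    return counts[counts >= k]


def sample_resampling_ensemble(
    sample_table: pd.DataFrame,
    metadata: pd.DataFrame,
    k: int,
    n_reps: int,
    analysis_fn: AnalysisFn,
    rng: np.random.Generator,
    metric: str = "metric",
) -> EnsembleSummary:
    """Resample k samples per species (without replacement), n_reps times.

    Species with fewer than k samples are discarded. Each replicate is
    aggregated to species level, rarefied to that replicate's minimum
    species read total (logged per replicate), binarized and analysed.
    """
    if k < 1 or n_reps < 1:
        raise ValidationError("k and n_reps must be >= 1")
    meta = metadata[metadata["sample_id"].isin(sample_table.index)]
    keep_species = eligible_species(meta, k)
    meta = meta[meta["species_id"].isin(keep_species.index)]
    for guild in GUILDS:
        if guild not in set(meta["guild"]):
            raise EmptyFilterError(f"no {guild} species has >= {k} samples")
    by_species = {sp: grp["sample_id"].tolist() for sp, grp in meta.groupby("species_id")}
    outputs = []
    depths_used: list[int] = []
    for _ in range(n_reps):
        chosen: list[str] = []
        for samples in by_species.values():
            idx = rng.choice(len(samples), size=k, replace=False)
            chosen.extend(samples[i] for i in idx)
        sub = sample_table.loc[chosen]
        communities = aggregate_to_species(sub, meta)
        depth = int(communities.totals().min())
        depths_used.append(depth)
        rarefied = rarefy(communities, depth, rng)
        outputs.append(analysis_fn(_network_from_counts(rarefied, communities.guild)))
    logger.info(
        "resampling ensemble (k=%d): per-replicate rarefaction depths %d-%d",
        k,
        min(depths_used),
        max(depths_used),
    )
    return _summarise(metric, outputs, extra_cols={"rarefaction_depth": depths_used})


@dataclass(frozen=True)
class DepthSweepResult:
    """One EnsembleSummary per rarefaction depth."""

    summaries: dict[int, EnsembleSummary]
    skipped_depths: tuple[int, ...] = ()

    @property
    def depths(self) -> list[int]:
        return sorted(self.summaries)

    @property
    def conclusion_stable(self) -> bool | None:
        """True when every depth reaches the same overrepresentation verdict
        in a majority of its replicates; None for non-motif metrics."""
        fracs = [self.summaries[d].fraction_overrepresented for d in self.depths]
        if any(f is None for f in fracs):
            return None
        verdicts = [f > 0.5 for f in fracs]
        return all(v == verdicts[0] for v in verdicts)

    def means(self) -> pd.Series:
        return pd.Series({d: self.summaries[d].mean for d in self.depths})


def depth_sweep(
    communities: SpeciesCommunities,
    depths: list[int],
    n_reps_per_depth: int,
    analysis_fn: AnalysisFn,
    rng: np.random.Generator,
    metric: str = "metric",
) -> DepthSweepResult:
    """Rarefaction ensemble repeated at multiple depths.

    Depths exceeding some species' read total are skipped with a warning.
    """
    min_total = int(communities.totals().min())
    summaries: dict[int, EnsembleSummary] = {}
    skipped: list[int] = []
    for depth in depths:
        if depth > min_total:
            logger.warning("depth %d infeasible (min species total %d); skipped", depth, min_total)
            skipped.append(depth)
            continue
        summaries[depth] = rarefaction_ensemble(
            communities, depth, n_reps_per_depth, analysis_fn, rng,
            metric=f"{metric}@depth={depth}",
        )
    if not summaries:
        raise ValidationError("no feasible rarefaction depth")
    return DepthSweepResult(summaries=summaries, skipped_depths=tuple(skipped))
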