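"""End-to-end orchestration: preprocess -> metrics -> phylogenetic signal ->
motif tests (all / shared fungal scopes) -> robustness ensembles, with every
stage's dimensions logged and all randomness derived from the run seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .exceptions import MycomotifError, StageError
from .io import RunConfig, write_results
from .motifs import DiamondMotifResult, DiamondMotifTest
from .networks import (
    TripartiteNetwork,
    normalized_degree,
    fungal_similarity,
    restrict_to_shared_fungi,
)
from .phylo import (
    cophenetic_distances,
    jaccard_dissimilarity,
    mantel,
    partial_mantel,
    tip_correlation_matrix,
)
from .preprocess import (
    SpeciesCommunities,
    aggregate_to_species,
    binarize,
    filter_samples,
    filter_species,
    mask_low_count_cells,
    rarefy,
)
from .robustness import (
    DepthSweepResult,
    EnsembleSummary,
    depth_sweep,
    sample_resampling_ensemble,
)

logger = logging.getLogger(__name__)


def _mantel_summary(rows: list[tuple[float, float]]) -> dict[str, float]:
    arr = np.array(rows, dtype=float)
    r, p = arr[:, 0], arr[:, 1]
    return {
        "n_reps": int(np.sum(~np.isnan(r))),
        "r_mean": float(np.nanmean(r)),
        "r_sd": float(np.nanstd(r)),
        "p_mean": float(np.nanmean(p)),
        "p_sd": float(np.nanstd(p)),
        "fraction_significant": float(np.nanmean(p < 0.05)),
    }


@dataclass
class RunReport:
    """Self-contained record of one full analysis run."""

    config: RunConfig
    stages: list[dict] = field(default_factory=list)
    motif: dict[str, EnsembleSummary] = field(default_factory=dict)
    mantel_tests: dict[str, dict] = field(default_factory=dict)
    plant_metrics: pd.DataFrame | None = None
    resampling: dict[str, EnsembleSummary] = field(default_factory=dict)
    sweeps: dict[str, DepthSweepResult] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "versions": self.versions,
            "seed": self.config.seed,
            "stages": self.stages,
            "motif": {k: v.to_dict() for k, v in self.motif.items()},
            "mantel": self.mantel_tests,
            "plant_metrics": (
                None
                if self.plant_metrics is None
                else self.plant_metrics.round(10).to_dict(orient="index")
            ),
            "resampling": {k: v.to_dict() for k, v in self.resampling.items()},
            "depth_sweeps": {
                k: {
                    "means": {int(d): s.means()[d] for d in s.depths},
                    "fraction_overrepresented": {
                        int(d): s.summaries[d].fraction_overrepresented for d in s.depths
                    },
                    "conclusion_stable": s.conclusion_stable,
                    "skipped_depths": list(s.skipped_depths),
                }
                for k, s in self.sweeps.items()
            },
        }

    def summary(self) -> str:
        lines = [f"mycomotif {self.versions.get('mycomotif', '')} run (seed {self.config.seed})"]
        for st in self.stages:
            lines.append(f"  stage {st['stage']}: " + ", ".join(
                f"{k}={v}" for k, v in st.items() if k != "stage"))
        for scope, ens in self.motif.items():
            lines.append("  " + ens.summary())
        for name, ms in self.mantel_tests.items():
            lines.append(
                f"  Mantel {name}: r = {ms['r_mean']:.3f} +- {ms['r_sd']:.3f}, "
                f"p = {ms['p_mean']:.3g} +- {ms['p_sd']:.3g} "
                f"(significant in {100 * ms['fraction_significant']:.0f}% of replicates)"
            )
        for name, ens in self.resampling.items():
            lines.append("  resampling " + ens.summary())
        for name, sweep in self.sweeps.items():
            lines.append(
                f"  depth sweep {name}: means "
                + ", ".join(f"{d}:{sweep.means()[d]:.1f}" for d in sweep.depths)
                + f"; conclusion stable: {sweep.conclusion_stable}"
            )
        return "\n".join(lines)

    def write(self, directory: str | Path, overwrite: bool = False) -> list[Path]:
        tables = {}
        for scope, ens in self.motif.items():
            if ens.replicate_table is not None:
                tables[f"motif_{scope}_replicates"] = ens.replicate_table
        for name, ens in self.resampling.items():
            if ens.replicate_table is not None:
                tables[f"resampling_{name}_replicates"] = ens.replicate_table
        if self.plant_metrics is not None:
            tables["plant_metrics"] = self.plant_metrics.reset_index()
        return write_results(
            self.to_dict(), directory, config=self.config, tables=tables,
            overwrite=overwrite,
        )


def _safe_mantel(fn, *args, **kwargs) -> tuple[float, float]:
    try:
        res = fn(*args, **kwargs)
        return res.r, res.p
    except MycomotifError:
        return (np.nan, np.nan)


def run_full_analysis(
    config: RunConfig,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    fungal_tree: dendropy.Tree | None = None,
    plant_tree: dendropy.Tree | None = None,
    run_resampling: bool = True,
) -> RunReport:
    """Execute the whole analysis under one :class:`RunConfig`.

    Phylogeny-dependent analyses (psv, phylogenetic-signal Mantel tests,
    partial Mantel) run only when the corresponding tree is supplied. All
    randomness is derived from ``config.seed`` through named substreams, so
    a run is reproducible from config plus inputs alone.
    """
    report = RunReport(config=config)
    report.versions = {
        "mycomotif": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    root_seq = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(seq)
        for name, seq in zip(
            ("rarefaction", "null", "mantel", "resampling", "sweep"),
            root_seq.spawn(5),
        )
    }

    # ---- preprocessing (deterministic head) ----
    try:
        report.stages.append(
            {"stage": "input", "n_samples": counts.shape[0], "n_otus": counts.shape[1]}
        )
        masked = mask_low_count_cells(counts, config.min_otu_reads)
        report.stages.append(
            {"stage": "cell_mask", "n_samples": masked.shape[0], "n_otus": masked.shape[1]}
        )
        filtered = filter_samples(masked, metadata, config.min_sample_reads)
        report.stages.append(
            {"stage": "sample_filter", "n_samples": filtered.shape[0], "n_otus": filtered.shape[1]}
        )
        communities = aggregate_to_species(filtered, metadata)
        communities = filter_species(communities, config.min_species_reads)
        guild_counts = communities.guild.value_counts().to_dict()
        report.stages.append(
            {
                "stage": "species_filter",
                "n_species": communities.counts.shape[0],
                "n_otus": communities.counts.shape[1],
                **{f"n_{g}": int(n) for g, n in guild_counts.items()},
            }
        )
    except MycomotifError as exc:
        raise StageError("preprocess", str(exc)) from exc

    fungi_all = list(communities.counts.columns)
    coph_fungi = coph_plants = corr_fungi = None
    if fungal_tree is not None:
        coph_fungi = cophenetic_distances(fungal_tree)
        corr_fungi = tip_correlation_matrix(fungal_tree, fungi_all)
    if plant_tree is not None:
        coph_plants = cophenetic_distances(plant_tree)

    # ---- rarefaction replicate loop ----
    scopes = ("all", "shared") if config.fungal_scope == "both" else (config.fungal_scope,)
    motif_results: dict[str, list[DiamondMotifResult]] = {s: [] for s in scopes}
    mantel_rows: dict[str, list[tuple[float, float]]] = {}
    nd_rows: list[pd.Series] = []
    psv_rows: list[pd.Series] = []
    rng_rare, rng_null, rng_mantel = (
        streams["rarefaction"], streams["null"], streams["mantel"],
    )
    try:
        for _rep in range(config.n_rarefactions):
            rarefied = rarefy(communities, config.rarefy_depth, rng_rare)
            net = TripartiteNetwork.from_incidence(
                binarize(rarefied), communities.guild
            )
            for scope in scopes:
                motif_results[scope].append(
                    DiamondMotifTest(net, scope=scope).fit(
                        n_null=config.n_null, rng=rng_null
                    )
                )
            stacked = net.stacked()
            nd_rows.append(normalized_degree(stacked, axis="rows"))
            if corr_fungi is not None:
                psv_rep = {}
                for plant, row in stacked.iterrows():
                    members = list(stacked.columns[row > 0])
                    if len(members) < 2:
                        psv_rep[plant] = np.nan
                        continue
                    sub = corr_fungi.loc[members, members].to_numpy()
                    n = len(members)
                    psv_rep[plant] = (n * np.trace(sub) - sub.sum()) / (n * (n - 1))
                psv_rows.append(pd.Series(psv_rep))
            _mantel_replicate(
                net, coph_fungi, coph_plants, mantel_rows, config, rng_mantel
            )
    except MycomotifError as exc:
        raise StageError("rarefaction_loop", str(exc)) from exc

    from .robustness import _summarise  # per-replicate summary helper

    for scope in scopes:
        report.motif[f"diamond_modules_{scope}"] = _summarise(
            f"diamond_modules_{scope}", motif_results[scope]
        )
    report.mantel_tests = {
        name: _mantel_summary(rows) for name, rows in mantel_rows.items() if rows
    }
    nd = pd.concat(nd_rows, axis=1)
    metrics = pd.DataFrame(
        {
            "normalized_degree_mean": nd.mean(axis=1),
            "normalized_degree_sd": nd.std(axis=1, ddof=0),
        }
    )
    if psv_rows:
        ps = pd.concat(psv_rows, axis=1)
        metrics["psv_mean"] = ps.mean(axis=1)
        metrics["psv_sd"] = ps.std(axis=1, ddof=0)
    metrics.insert(0, "guild", communities.guild.reindex(metrics.index))
    metrics.index.name = "plant_id"
    report.plant_metrics = metrics

    # ---- per-species sample resampling ----
    if run_resampling:
        try:
            rng_res = streams["resampling"]
            for scope in scopes:
                report.resampling[f"diamond_modules_{scope}"] = sample_resampling_ensemble(
                    filtered,
                    metadata,
                    k=config.resample_k,
                    n_reps=config.n_resamples,
                    analysis_fn=lambda net, s=scope: DiamondMotifTest(net, scope=s).fit(
                        n_null=config.n_null, rng=rng_res
                    ),
                    rng=rng_res,
                    metric=f"diamond_modules_{scope}_resampled",
                )
        except MycomotifError as exc:
            raise StageError("resampling", str(exc)) from exc

    # ---- multi-depth sweep ----
    if config.depths:
        try:
            rng_sweep = streams["sweep"]
            for scope in scopes:
                report.sweeps[f"diamond_modules_{scope}"] = depth_sweep(
                    communities,
                    list(config.depths),
                    n_reps_per_depth=max(1, config.n_rarefactions // 10),
                    analysis_fn=lambda net, s=scope: DiamondMotifTest(net, scope=s).fit(
                        n_null=config.n_null, rng=rng_sweep
                    ),
                    rng=rng_sweep,
                    metric=f"diamond_modules_{scope}",
                )
        except MycomotifError as exc:
            raise StageError("depth_sweep", str(exc)) from exc

    return report


def _mantel_replicate(
    net: TripartiteNetwork,
    coph_fungi: pd.DataFrame | None,
    coph_plants: pd.DataFrame | None,
    rows: dict[str, list[tuple[float, float]]],
    config: RunConfig,
    rng: np.random.Generator,
) -> None:
    """All Mantel statistics of one rarefied replicate."""
    blocks = {"mutualistic": net.auto, "antagonistic": net.mh}
    n_perm = config.n_permutations
    for name, block in blocks.items():
        block = block.loc[:, block.sum(axis=0) > 0]
        if coph_fungi is not None and block.shape[1] >= 4:
            d_comm = jaccard_dissimilarity(block, axis="columns")
            ids = list(d_comm.index)
            d_phy = coph_fungi.loc[ids, ids]
            rows.setdefault(f"fungal_phylo_signal_{name}", []).append(
                _safe_mantel(mantel, d_phy, d_comm, n_perm, rng)
            )
        if coph_plants is not None and block.shape[0] >= 4:
            d_comm = jaccard_dissimilarity(block, axis="rows")
            ids = list(d_comm.index)
            if set(ids) <= set(coph_plants.index):
                d_phy = coph_plants.loc[ids, ids]
                rows.setdefault(f"plant_phylo_signal_{name}", []).append(
                    _safe_mantel(mantel, d_phy, d_comm, n_perm, rng)
                )
    # cross-guild similarity of the shared fungi
    try:
        shared_net = restrict_to_shared_fungi(net)
    except MycomotifError:
        return
    if shared_net.n_fungi < 4:
        return
    for measure in ("jaccard", "overlap"):
        s_mut = fungal_similarity(shared_net.auto, measure).as_distance()
        s_ant = fungal_similarity(shared_net.mh, measure).as_distance()
        common = [f for f in s_mut.index if f in set(s_ant.index)]
        if len(common) < 4:
            continue
        d1 = s_mut.loc[common, common]
        d2 = s_ant.loc[common, common]
        rows.setdefault(f"cross_guild_similarity_{measure}", []).append(
            _safe_mantel(mantel, d1, d2, n_perm, rng)
        )
        if coph_fungi is not None:
            d3 = coph_fungi.loc[common, common]
            rows.setdefault(f"cross_guild_similarity_{measure}_partial", []).append(
                _safe_mantel(
                    partial_mantel, d1, d2, d3, n_perm, rng,
                    controlled="fungal phylogeny",
                )
            )
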