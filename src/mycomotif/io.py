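"""Reading and writing of external artifacts, and run configuration.

Count tables and sample metadata travel as validated pandas DataFrames;
phylogenies as :class:`dendropy.Tree`. All tables are TSV (tab-separated,
UTF-8, header row). Guild labels are normalised to the canonical strings
``"autotroph"`` / ``"mycoheterotroph"``; matching on input is
case-insensitive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import dendropy
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

SCHEMA_VERSION = "1.0"

GUILD_AUTOTROPH = "autotroph"
GUILD_MYCOHETEROTROPH = "mycoheterotroph"
GUILDS = (GUILD_AUTOTROPH, GUILD_MYCOHETEROTROPH)

METADATA_COLUMNS = ("sample_id", "species_id", "guild", "subplot")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run.

    Defaults are the study-scale parameters: per-cell read floor 6,
    per-sample and per-species Glomeromycotina read floors 500, rarefaction
    depth 844 with 100 replicate rarefactions, 1000 null networks, 999
    Mantel permutations, and resampling of 3 samples per species in 1000
    replicates.
    """

    min_otu_reads: int = 6
    min_sample_reads: int = 500
    min_species_reads: int = 500
    rarefy_depth: int = 844
    n_rarefactions: int = 100
    n_null: int = 1000
    n_permutations: int = 999
    fungal_scope: str = "both"  # "all" | "shared" | "both"
    depths: tuple[int, ...] = ()
    resample_k: int = 3
    n_resamples: int = 1000
    seed: int = 0
    output_dir: str = "mycomotif_out"

    def __post_init__(self) -> None:
        for name in (
            "min_otu_reads",
            "min_sample_reads",
            "min_species_reads",
            "rarefy_depth",
            "n_rarefactions",
            "n_null",
            "n_permutations",
            "resample_k",
            "n_resamples",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        if self.fungal_scope not in ("all", "shared", "both"):
            raise ValidationError(f"fungal_scope must be all|shared|both, got {self.fungal_scope!r}")
        if any((not isinstance(d, (int, np.integer))) or d < 1 for d in self.depths):
            raise ValidationError("depths must be positive integers")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be set explicitly as an integer")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["depths"] = list(self.depths)
        return d


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a sample-x-OTU (or species-x-OTU) read-count table from TSV.

    The first column holds row ids, the header row holds OTU ids. Cells must
    be nonnegative integers.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate OTU ids {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: count table has no data rows or no OTU columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dups}")
    try:
        counts = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer cell in count table: {exc}") from exc
    if not (df == counts.astype(str)).to_numpy().all():
        # catches floats like "3.5" that int-cast would truncate
        bad = df.to_numpy()[(df != counts.astype(str)).to_numpy()][:3]
        raise FormatError(f"{path}: non-integer cells, e.g. {bad.tolist()}")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts are not allowed")
    counts.index = counts.index.astype(str)
    counts.index.name = "id"
    counts.columns = counts.columns.astype(str)
    return counts


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="id")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory count table (nonnegative integers, unique ids)."""
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValidationError("count table has duplicate row or column ids")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("count table has non-integer cells")
        table = table.astype(np.int64)
        arr = table.to_numpy()
    if (arr < 0).any():
        raise ValidationError("count table has negative cells")
    return table


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate per-sample metadata from TSV.

    Required columns: sample_id, species_id, guild, subplot. Guild values are
    normalised case-insensitively to "autotroph" / "mycoheterotroph"; a
    species listed under both guilds is a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns {missing}")
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    df = df.astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids {dups}")
    df["guild"] = df["guild"].str.strip().str.lower()
    unknown = sorted(set(df["guild"]) - set(GUILDS))
    if unknown:
        raise ValidationError(f"unknown guild value(s) {unknown}; expected one of {GUILDS}")
    guilds_per_species = df.groupby("species_id")["guild"].nunique()
    mixed = guilds_per_species[guilds_per_species > 1].index.tolist()
    if mixed:
        raise ValidationError(f"species with mixed guilds: {mixed}")
    return df.reset_index(drop=True)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def species_guilds(metadata: pd.DataFrame) -> pd.Series:
    """Map species_id -> guild (unique by the mixed-guild invariant)."""
    return metadata.drop_duplicates("species_id").set_index("species_id")["guild"]


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from exc
    return _validate_tree(tree, str(path))


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    return _validate_tree(tree, "<string>")


def _validate_tree(tree: dendropy.Tree, origin: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"{origin}: duplicate tip labels {dups}")
    if not labels:
        raise FormatError(f"{origin}: tree has no labelled tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"{origin}: negative branch length {edge.length}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


class _ResultEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_results(
    results: Mapping[str, Any],
    directory: str | Path,
    config: RunConfig | None = None,
    tables: Mapping[str, pd.DataFrame] | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """Write a structured result summary plus per-replicate tables.

    ``results`` is serialised to ``results.json`` with the schema version and
    the :class:`RunConfig` (and hence the seed) echoed; each entry of
    ``tables`` becomes ``<name>.tsv``. Re-writing into an existing results
    directory requires ``overwrite=True``.
    """
    directory = Path(directory)
    summary_path = directory / "results.json"
    if summary_path.exists() and not overwrite:
        raise FileExistsError(f"{summary_path} exists; pass overwrite=True to replace")
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict() if config is not None else None,
        "results": dict(results),
    }
    written = [summary_path]
    summary_path.write_text(json.dumps(payload, indent=2, cls=_ResultEncoder) + "\n")
    for name, frame in (tables or {}).items():
        table_path = directory / f"{name}.tsv"
        frame.to_csv(table_path, sep="\t", index=False)
        written.append(table_path)
    return written
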