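"""Tabular input containers, validation, abundance transforms and graph export.

The central container is :class:`FeatureTable`, a samples x taxa abundance
matrix that is either in ``counts`` mode (non-negative numbers, typically
integers from an amplicon workflow) or ``relative`` mode (rows summing to 1).
Taxonomy, sample metadata and soil-nutrient measurements get thin validated
wrappers around pandas DataFrames.

On-disk formats follow common amplicon tooling: tab-separated tables with
taxa as rows and samples as columns (``#`` comment lines ignored), BIOM 2.1
HDF5, and GraphML / SIF / edge-list exports for Gephi and Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "TaxonomyMap",
    "SampleMetadata",
    "NutrientTable",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "read_metadata",
    "read_nutrients",
    "to_relative_abundance",
    "collapse_to_genus",
    "filter_by_mean_relabund",
    "write_graph",
    "read_graphml",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

TILLAGE_LEVELS = ("NT", "MT")
STRAW_LEVELS = ("NS", "HS", "TS")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id. Non-negative.
    mode : {"counts", "relative"}
        In ``relative`` mode every row must sum to 1 (+- 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon identifiers")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite abundance value")
        if self.mode == "relative" and vals.size:
            # Rows sum to 1 after normalisation; a taxon-filtered table keeps
            # the original denominators, so sums may fall below 1 but never above.
            sums = vals.sum(axis=1)
            bad = (sums > 1.0 + 1e-9) | (sums <= 0)
            if bad.any():
                raise ValidationError(
                    f"invalid relative-mode row sum for sample "
                    f"{self.data.index[int(np.argmax(bad))]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def subset_samples(self, samples) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(samples)], self.mode)


@dataclass
class TaxonomyMap:
    """taxon_id -> ranked lineage (kingdom..genus).

    Unresolved ranks carry the literal marker ``"unassigned"``.
    """

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ValidationError(f"taxonomy missing ranks: {missing}")
        self.lineages = self.lineages[list(RANKS)].fillna(UNASSIGNED)
        self.lineages = self.lineages.replace("", UNASSIGNED)

    def genus_label(self, taxon_id: str) -> str:
        """Genus for *taxon_id*, or ``unclassified_<highest resolved rank>``.

        ASVs lacking a genus assignment are pooled per their most resolved
        parent rank so that named orders/families can still act as network
        nodes after genus collapse.
        """
        if taxon_id not in self.lineages.index:
            return f"unclassified_{UNASSIGNED}"
        row = self.lineages.loc[taxon_id]
        if row["genus"] != UNASSIGNED:
            return str(row["genus"])
        for rank in reversed(RANKS[:-1]):
            if row[rank] != UNASSIGNED:
                return f"unclassified_{row[rank]}"
        return f"unclassified_{UNASSIGNED}"


@dataclass
class SampleMetadata:
    """Per-sample design factors: tillage (NT/MT), straw (NS/HS/TS), replicate."""

    table: pd.DataFrame  # index sample_id; columns tillage, straw, replicate

    def __post_init__(self) -> None:
        for col in ("tillage", "straw"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad_t = set(self.table["tillage"]) - set(TILLAGE_LEVELS)
        bad_s = set(self.table["straw"]) - set(STRAW_LEVELS)
        if bad_t or bad_s:
            raise ValidationError(
                f"unknown factor levels: tillage={sorted(bad_t)}, straw={sorted(bad_s)}"
            )
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def treatment(self, sample_id: str) -> str:
        row = self.table.loc[sample_id]
        return f"{row['tillage']}-{row['straw']}"

    def samples_for(self, group: str) -> list:
        """Samples belonging to *group*.

        *group* is a single factor level (``"MT"``, ``"HS"``) or a combined
        treatment label ``"<tillage>-<straw>"`` (e.g. ``"NT-TS"``).
        """
        t = self.table
        if group in TILLAGE_LEVELS:
            mask = t["tillage"] == group
        elif group in STRAW_LEVELS:
            mask = t["straw"] == group
        elif "-" in group:
            til, st = group.split("-", 1)
            mask = (t["tillage"] == til) & (t["straw"] == st)
        else:
            raise KeyError(f"unknown group {group!r}")
        samples = list(t.index[mask])
        if not samples:
            raise KeyError(f"group {group!r} has zero samples")
        return samples

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")


@dataclass
class NutrientTable:
    """Samples x soil-chemistry variables, with a pool grouping.

    ``pools`` maps a pool label (e.g. ``"C"``, ``"labile-C"``,
    ``"inorganic-N"``) to the variable names that belong to it.
    """

    data: pd.DataFrame
    pools: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate nutrient variable names")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite nutrient value")
        unknown = {
            v for vs in self.pools.values() for v in vs if v not in self.data.columns
        }
        if unknown:
            raise ValidationError(f"pool variables absent from table: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def pool_table(self, pool: str) -> pd.DataFrame:
        return self.data[self.pools[pool]]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header row with sample columns required")
    return df


def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read an abundance table (taxa rows x sample columns) as counts.

    ``format="biom"`` reads BIOM 2.1 HDF5 via h5py.
    Orientation is normalised to samples x taxa.
    """
    if format == "tsv":
        df = _read_tsv_matrix(path)
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
        return FeatureTable(df.T, mode="counts")
    if format == "biom":
        return _read_biom_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _read_biom_hdf5(path) -> FeatureTable:
    """Minimal BIOM 2.1 reader: CSR matrix over observations (taxa)."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        )
    df = pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids)
    return FeatureTable(df.T, mode="counts")


def write_feature_table(t: FeatureTable, path) -> None:
    """Write taxa-rows x sample-columns TSV (the orientation we read)."""
    t.data.T.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxonomy(path) -> TaxonomyMap:
    """TSV with taxon_id first column and kingdom..genus columns."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyMap(df)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return SampleMetadata(df)


def read_nutrients(path, pools: dict | None = None) -> NutrientTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0).astype(float)
    return NutrientTable(df, pools or {})


# ---------------------------------------------------------------------------
# transforms


def to_relative_abundance(t: FeatureTable) -> FeatureTable:
    """Row-normalise counts to proportions (each sample sums to 1)."""
    if t.mode == "relative":
        return t
    sums = t.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero sample row: {list(zero.index)}")
    return FeatureTable(t.data.div(sums, axis=0), mode="relative")


def collapse_to_genus(t: FeatureTable, tax: TaxonomyMap) -> FeatureTable:
    """Sum taxa sharing a genus label; unassigned ASVs pool per parent rank."""
    labels = [tax.genus_label(tid) for tid in t.taxon_ids]
    collapsed = t.data.T.groupby(pd.Index(labels, name="genus"), sort=True).sum().T
    return FeatureTable(collapsed, mode=t.mode)


def filter_by_mean_relabund(t: FeatureTable, threshold: float = 0.005) -> FeatureTable:
    """Keep taxa with mean relative abundance strictly greater than *threshold*.

    The mean is taken over all samples; the default 0.5% cut is the usual
    node-inclusion rule for amplicon co-occurrence networks.
    """
    if t.mode != "relative":
        raise ValidationError("filter_by_mean_relabund requires relative mode")
    means = t.data.mean(axis=0)
    if threshold == 0:
        keep = means[means > 0].index
    else:
        keep = means[means > threshold].index
    if len(keep) == 0:
        raise ValidationError(
            f"no taxon exceeds mean relative abundance {threshold}; lower the threshold"
        )
    return FeatureTable(t.data[keep], mode="relative")


# ---------------------------------------------------------------------------
# graph export

_EDGE_ATTRS = ("r", "p_raw", "p_adj", "sign")


def write_graph(g: nx.Graph, path, format: str = "graphml") -> None:
    """Export a correlation network as GraphML, SIF or a tab edge list.

    GraphML and the edge list preserve per-edge r / p_raw / p_adj / sign;
    SIF keeps only connectivity (Cytoscape convention, interaction ``pp``).
    """
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\tpp\t{v}\n")
            for node in nx.isolates(g):
                fh.write(f"{node}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\t" + "\t".join(_EDGE_ATTRS) + "\n")
            for u, v, d in g.edges(data=True):
                vals = "\t".join(str(d.get(k, "")) for k in _EDGE_ATTRS)
                fh.write(f"{u}\t{v}\t{vals}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
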