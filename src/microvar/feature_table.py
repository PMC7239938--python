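"""Count-table container, I/O and normalizations.

The central object is :class:`FeatureTable`: an integer samples x taxa count
matrix with per-taxon ranked taxonomy strings. The transformations here are
the standard amplicon-table operations that precede community analysis:
rarefaction to even depth, relative abundance, taxonomic aggregation,
cumulative-sum-scaling (CSS) log normalization, and core-microbiota
detection by joint detection/prevalence thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("microvar")

#: ranked lineage levels used by :func:`aggregate`, outermost first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class FormatError(ValueError):
    """A file does not parse as the declared format."""


@dataclass
class FeatureTable:
    """Samples x taxa integer counts plus taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns taxon ids, nonnegative
        integer values.
    taxonomy
        Series mapping taxon id -> semicolon-delimited ranked lineage
        (kingdom;phylum;...;genus). Missing taxa get an unclassified
        lineage.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = None

    def __post_init__(self):
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate taxon id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise FormatError(
                f"non-integer count at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.taxonomy is None:
            self.taxonomy = pd.Series("unclassified", index=cols, name="lineage")
        else:
            self.taxonomy = self.taxonomy.reindex(cols).fillna("unclassified")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)


@dataclass
class NormalizedTable:
    """A transformed samples x taxa matrix with its normalization tag."""

    values: pd.DataFrame
    normalization: str  # one of {"relative", "css_log", "rarefied"}
    #: samples removed by the transformation (rarefaction only)
    dropped: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path, format: str = "tsv", taxonomy_path=None) -> FeatureTable:
    """Read a feature table from ``tsv`` (dense) or ``biom_triplet`` (sparse).

    Dense TSV: first column = sample id, header = taxon ids. Triplet TSV:
    columns ``sample``, ``taxon``, ``count``; absent entries are zeros.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom_triplet":
        trip = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if trip.shape[1] != 3:
            raise FormatError("triplet format needs exactly 3 columns")
        trip.columns = ["sample", "taxon", "count"]
        if trip.duplicated(["sample", "taxon"]).any():
            bad = trip[trip.duplicated(["sample", "taxon"])].iloc[0]
            raise FormatError(
                f"duplicate triplet entry: sample {bad['sample']!r}, "
                f"taxon {bad['taxon']!r}"
            )
        df = (
            trip.pivot(index="sample", columns="taxon", values="count")
            .fillna(0)
        )
        df.index.name = None
        df.columns.name = None
    else:
        raise ValidationError(f"unknown format: {format!r}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    return FeatureTable(df, taxonomy)


def write_table(table: FeatureTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.counts.to_csv(path, sep="\t", index_label="sample")
    elif format == "biom_triplet":
        stacked = table.counts.stack()
        stacked = stacked[stacked > 0]
        out = stacked.rename("count").reset_index()
        out.columns = ["sample", "taxon", "count"]
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown format: {format!r}")


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.iloc[:, 0].rename("lineage")


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    taxonomy.rename("lineage").to_csv(path, sep="\t", index_label="taxon")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def relative_abundance(table: FeatureTable) -> NormalizedTable:
    """Per-sample relative abundances (rows sum to 1; all-zero rows stay 0)."""
    totals = table.counts.sum(axis=1)
    values = table.counts.div(totals.replace(0, 1), axis=0)
    return NormalizedTable(values.astype(float), "relative")


def rarefy(table: FeatureTable, depth: int, seed=None) -> NormalizedTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped; their ids
    are logged and recorded on the result. Subsampling is multivariate
    hypergeometric, so every rarefied count is bounded by the original.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if len(keep) == 0:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds every sample total "
            f"(max {int(totals.max()) if len(totals) else 0})"
        )
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    rows = []
    for s in keep:
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    values = pd.DataFrame(np.array(rows), index=keep, columns=table.counts.columns)
    return NormalizedTable(values.astype(float), "rarefied", dropped=dropped)


def aggregate(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum counts over taxa sharing the lineage prefix at ``rank``.

    Taxa unclassified at that rank are pooled into one
    ``unclassified_<parent>`` bucket per deepest classified parent. Total
    reads are conserved.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    keys, lineages = {}, {}
    for taxon in table.taxon_ids:
        parts = [p.strip() for p in str(table.taxonomy[taxon]).split(";")]
        named = [p for p in parts if p and not p.lower().startswith("unclassified")]
        if len(named) > level:
            key = ";".join(named[: level + 1])
            lineage = key
        else:
            parent = named[-1] if named else "root"
            key = f"unclassified_{parent}"
            lineage = ";".join(named + [key]) if named else key
        keys[taxon] = key
        lineages[key] = lineage
    grouped = table.counts.T.groupby(pd.Series(keys)).sum().T
    taxonomy = pd.Series({k: lineages[k] for k in grouped.columns}, name="lineage")
    return FeatureTable(grouped, taxonomy)


def css_scaling_factors(table: FeatureTable, quantile: float = 0.5) -> pd.Series:
    """Per-sample CSS scaling factor: sum of counts at or below the sample's
    ``quantile`` of nonzero counts."""
    factors = {}
    for s in table.sample_ids:
        row = table.counts.loc[s].to_numpy()
        nonzero = row[row > 0]
        if nonzero.size == 0:
            raise ValidationError(f"all-zero sample: {s!r}")
        q = np.quantile(nonzero, quantile)
        factors[s] = float(row[row <= q].sum())
    return pd.Series(factors, name="css_factor").reindex(table.sample_ids)


def css_log(table: FeatureTable, quantile: float = 0.5) -> NormalizedTable:
    """Cumulative-sum-scaling normalization followed by a log2 transform.

    Each count is divided by its sample's cumulative count up to the
    ``quantile`` of that sample's nonzero counts, rescaled by the median
    scaling factor across samples, then mapped through ``log2(x + 1)``
    so zeros stay exactly 0.
    """
    s_j = css_scaling_factors(table, quantile)
    big_s = float(s_j.median())
    scaled = table.counts.div(s_j, axis=0) * big_s
    values = np.log2(scaled + 1.0)
    return NormalizedTable(values, "css_log")


def core_microbiota(
    table: FeatureTable,
    detection: float = 0.001,
    prevalence: float = 0.99,
    groups=None,
) -> list:
    """Taxa at relative abundance >= ``detection`` in >= ``prevalence`` of
    samples, evaluated within each group (time point) and intersected.

    ``groups`` is an optional per-sample label series; with ``None`` the
    whole table is one group. Defaults follow the reported core rule
    (0.1% detection, 99% prevalence); the stricter 99.9% prevalence is
    available via the argument.
    """
    if table.counts.size == 0:
        raise ValidationError("empty feature table")
    rel = relative_abundance(table).values
    if groups is None:
        group_iter = [(None, rel)]
    else:
        groups = pd.Series(groups).reindex(rel.index)
        group_iter = [
            (g, rel.loc[rel.index[groups == g]])
            for g in pd.unique(groups.dropna())
        ]
    core = None
    for _, sub in group_iter:
        prev = (sub >= detection).mean(axis=0)
        members = set(prev.index[prev >= prevalence])
        core = members if core is None else core & members
    return [t for t in table.taxon_ids if t in core]
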