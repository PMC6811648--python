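"""Query-to-partition assignment, MRCA labelling, and count-table utilities.

A query joins the partition holding at least a threshold fraction (default
50%) of its outlier set; ties at the top fraction, sub-threshold maxima and
empty outlier sets all leave the query unclassified — the method only
classifies when the data clearly support it. Partitions are labelled with
the MRCA of their members' lineages and the deduplicated species list.
Count-table helpers reproduce the abundance/prevalence filters and the
per-partition aggregation used for downstream differential-abundance
analysis (the model fitting itself is out of scope here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from atlastax.graph import PartitionSet
from atlastax.io_formats import CountTable, TaxonomyLineage
from atlastax.outliers import OutlierSet


@dataclass(frozen=True)
class Assignment:
    """One query's classification outcome."""

    query_id: str
    partition_id: int | None  # None == unclassified
    fraction: float | None

    @property
    def assigned(self) -> bool:
        return self.partition_id is not None


@dataclass(frozen=True)
class PartitionSummary:
    """Per-partition report row: members, MRCA label, species list."""

    partition_id: int
    members: frozenset[str]
    lineage: TaxonomyLineage
    species: tuple[str, ...]

    @property
    def mrca_rank(self) -> str:
        return self.lineage.deepest_rank


def assign_query(
    outlier_set: OutlierSet,
    partition_set: PartitionSet,
    threshold: float = 0.5,
) -> Assignment:
    """Assign a query to the partition holding most of its outlier set.

    The membership fraction of candidate partition P is
    |outliers intersect P| / |outliers|. The query is assigned to the
    unique argmax iff the maximum fraction meets ``threshold``; an empty
    outlier set, a sub-threshold maximum, or a tie leaves it unclassified.
    """
    if not outlier_set:
        return Assignment(outlier_set.query_id, None, None)
    membership = partition_set.membership
    tally: dict[int, int] = {}
    for ref in outlier_set.members:
        pid = membership.get(ref)
        if pid is None:
            raise ValueError(
                f"outlier member {ref} of query {outlier_set.query_id} "
                f"belongs to no partition"
            )
        tally[pid] = tally.get(pid, 0) + 1
    n = len(outlier_set)
    best = max(tally.values())
    winners = [pid for pid, cnt in tally.items() if cnt == best]
    fraction = best / n
    if fraction >= threshold and len(winners) == 1:
        return Assignment(outlier_set.query_id, winners[0], fraction)
    return Assignment(outlier_set.query_id, None, None)


def mrca(lineages: Sequence[TaxonomyLineage]) -> TaxonomyLineage:
    """Most recent common ancestor: the longest common rank prefix.

    Taxon names are compared rank by rank from the outermost level; a
    missing rank in any lineage ends the common prefix at the previous
    rank. Order-invariant and associative.
    """
    if not lineages:
        raise ValueError("mrca of no lineages")
    prefix: list[str] = []
    for i in range(min(len(l.names) for l in lineages)):
        names = {l.names[i] for l in lineages}
        if len(names) != 1 or not next(iter(names)):
            break
        prefix.append(next(iter(names)))
    return TaxonomyLineage(tuple(prefix))


def summarize_partitions(
    partition_set: PartitionSet,
    taxonomy: Mapping[str, TaxonomyLineage],
) -> list[PartitionSummary]:
    """Label every partition with its MRCA lineage and species list.

    Members without a lineage are excluded from the MRCA computation (with
    a warning) and surface as ``"unknown"`` in the species list; members
    whose lineage lacks a species-level name likewise contribute
    ``"unknown"``. The species list is deduplicated and sorted.
    """
    out: list[PartitionSummary] = []
    for pid, members in enumerate(partition_set):
        lineages = []
        species: set[str] = set()
        for ref in sorted(members):
            lin = taxonomy.get(ref)
            if lin is None or not lin:
                warnings.warn(f"no taxonomy for reference {ref}", stacklevel=2)
                species.add("unknown")
                continue
            lineages.append(lin)
            species.add(lin.species or "unknown")
        lineage = mrca(lineages) if lineages else TaxonomyLineage(())
        out.append(
            PartitionSummary(pid, frozenset(members), lineage, tuple(sorted(species)))
        )
    return out


def filter_count_table(
    table: CountTable,
    min_feature_reads: int = 20,
    min_sample_reads: int = 0,
    min_prevalence_per_group: float | None = None,
) -> CountTable:
    """Abundance / prevalence filtering of an OTU (or partition) table.

    Features with fewer than ``min_feature_reads`` total reads are dropped;
    with ``min_prevalence_per_group`` set, a feature must additionally be
    present (count > 0) in at least that fraction of the samples of at
    least one group (inclusive boundary). Samples whose totals, after the
    feature filter, fall below ``min_sample_reads`` are then dropped.
    """
    df = table.counts
    keep = df.sum(axis=1) >= min_feature_reads
    if min_prevalence_per_group is not None:
        if not table.groups:
            raise ValueError("prevalence filtering requires sample group labels")
        unknown = set(table.groups) - set(df.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")
        present = df > 0
        prevalent = pd.Series(False, index=df.index)
        for group in sorted(set(table.groups.values())):
            samples = [s for s in df.columns if table.groups.get(s) == group]
            if not samples:
                continue
            frac = present[samples].sum(axis=1) / len(samples)
            prevalent |= frac >= min_prevalence_per_group
        keep &= prevalent
    df = df.loc[keep]
    sample_keep = df.sum(axis=0) >= min_sample_reads
    df = df.loc[:, sample_keep]
    groups = {s: g for s, g in table.groups.items() if s in df.columns}
    return CountTable(df.copy(), groups)


def partition_feature_map(assignments: Iterable[Assignment]) -> dict[str, str]:
    """Map assigned query/OTU ids to partition feature labels."""
    return {
        a.query_id: f"partition_{a.partition_id}"
        for a in assignments
        if a.assigned
    }


def aggregate_by_partition(
    table: CountTable, feature_map: Mapping[str, str]
) -> CountTable:
    """Sum counts of features mapped to the same partition (or genus).

    Mapped features collapse into one row per label; unmapped features pass
    through unchanged as their own rows, mirroring the joint accounting of
    partitions and non-partitioned OTUs. Per-sample totals are conserved
    exactly. Aggregated rows come first (sorted by label), then unmapped
    features in their original order.
    """
    df = table.counts
    mapped = [f for f in df.index if f in feature_map]
    unmapped = [f for f in df.index if f not in feature_map]
    pieces = []
    if mapped:
        agg = df.loc[mapped].groupby(
            [feature_map[f] for f in mapped], sort=True
        ).sum()
        agg.index = agg.index.astype(str)
        pieces.append(agg)
    if unmapped:
        pieces.append(df.loc[unmapped])
    out = pd.concat(pieces) if pieces else df.iloc[0:0]
    out.index.name = "feature_id"
    return CountTable(out, dict(table.groups))
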