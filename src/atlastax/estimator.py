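"""Scikit-learn style estimator wrapping the two-phase pipeline.

``AtlasPartitioner`` is clusterer-shaped: ``fit`` consumes queries plus
their database hits, detects per-query outlier hit sets, builds and prunes
the confusion graph and extracts Louvain partitions over the reference
sequences (``partitions_``, ``labels_``); ``predict`` maps queries to
partitions through the fractional-membership rule. It follows the sklearn
estimator contract (``get_params`` / ``set_params``, fitted attributes with
a trailing underscore, ``check_is_fitted``-style validation) so it composes
with sklearn tooling; the module-level functions in :mod:`atlastax` remain
the underlying implementation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from atlastax.assignment import Assignment, assign_query, summarize_partitions
from atlastax.graph import (
    build_confusion_graph,
    edge_weight_threshold,
    filter_edges,
    louvain_partition,
)
from atlastax.io_formats import BlastHit, SequenceRecord, TaxonomyLineage
from atlastax.outliers import BildModel, detect_outliers


class AtlasPartitioner(BaseEstimator):
    """Sample-specific taxonomic partitioner over reference sequences.

    Parameters
    ----------
    alpha : float, default 0.5
        Symmetric Dirichlet pseudocount of the BILD column model
        (Jeffreys prior).
    background : tuple of 4 floats or None, default None
        Background nucleotide frequencies; None means uniform.
    min_gain : float, default 20.0
        Minimum split gain in bits for a non-empty outlier set.
    max_hits : int, default 100
        Hits per query considered in the split search.
    edge_sd_multiplier : float, default 2.0
        Edges below mean - multiplier * population-sd weight are pruned.
    resolution : float, default 1.0
        Louvain modularity resolution.
    assignment_threshold : float, default 0.5
        Minimum fraction of a query's outlier set inside one partition.
    random_state : int, default 42
        Seed for Louvain's node shuffling.

    Attributes
    ----------
    outlier_sets_ : dict query id -> OutlierSet
    graph_, filtered_graph_ : networkx.Graph
        Confusion graph before / after edge pruning.
    edge_threshold_ : float
    partitions_ : PartitionSet
    reference_ids_ : list of str
        Graph nodes, sorted; ``labels_[i]`` is the partition id of
        ``reference_ids_[i]``.
    labels_ : ndarray of int
    summaries_ : list of PartitionSummary, only when taxonomy was given.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        background: tuple[float, float, float, float] | None = None,
        min_gain: float = 20.0,
        max_hits: int = 100,
        edge_sd_multiplier: float = 2.0,
        resolution: float = 1.0,
        assignment_threshold: float = 0.5,
        random_state: int = 42,
    ) -> None:
        self.alpha = alpha
        self.background = background
        self.min_gain = min_gain
        self.max_hits = max_hits
        self.edge_sd_multiplier = edge_sd_multiplier
        self.resolution = resolution
        self.assignment_threshold = assignment_threshold
        self.random_state = random_state

    def _model(self) -> BildModel:
        bg = self.background or (0.25, 0.25, 0.25, 0.25)
        return BildModel(alpha=(float(self.alpha),) * 4, background=tuple(bg))

    def _validate(
        self,
        queries: Sequence[SequenceRecord],
        hits: Mapping[str, Sequence[BlastHit]],
    ) -> None:
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")
        if not 0.0 <= self.assignment_threshold <= 1.0:
            raise ValueError("assignment_threshold must be in [0, 1]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        ids = [q.id for q in queries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate query ids")
        stray = set(hits) - set(ids)
        if stray:
            raise ValueError(f"hits for unknown queries: {sorted(stray)[:5]}")

    def fit(
        self,
        queries: Sequence[SequenceRecord],
        hits: Mapping[str, Sequence[BlastHit]],
        taxonomy: Mapping[str, TaxonomyLineage] | None = None,
    ) -> "AtlasPartitioner":
        """Detect outlier sets and partition the confused references."""
        self._validate(queries, hits)
        model = self._model()
        self.outlier_sets_ = {
            q.id: detect_outliers(
                q, hits.get(q.id, ()), model=model,
                min_gain=self.min_gain, max_hits=self.max_hits,
            )
            for q in queries
        }
        self.graph_ = build_confusion_graph(self.outlier_sets_.values())
        self.edge_threshold_ = edge_weight_threshold(
            self.graph_, self.edge_sd_multiplier
        )
        self.filtered_graph_ = filter_edges(self.graph_, self.edge_sd_multiplier)
        self.partitions_ = louvain_partition(
            self.filtered_graph_,
            seed=self.random_state,
            resolution=self.resolution,
        )
        self.reference_ids_ = sorted(self.filtered_graph_.nodes())
        membership = self.partitions_.membership
        self.labels_ = np.array(
            [membership[r] for r in self.reference_ids_], dtype=int
        )
        if taxonomy is not None:
            self.summaries_ = summarize_partitions(self.partitions_, taxonomy)
        return self

    def predict(
        self,
        queries: Sequence[SequenceRecord] | None = None,
        hits: Mapping[str, Sequence[BlastHit]] | None = None,
    ) -> list[Assignment]:
        """Assign queries to the fitted partitions.

        With no arguments, assigns the training queries from their cached
        outlier sets. New queries must come with their hit tables; members
        of their outlier sets that were never partitioned leave the query
        unclassified (rather than erroring) since a fresh query may hit
        references unseen at fit time.
        """
        if not hasattr(self, "partitions_"):
            raise ValueError("AtlasPartitioner is not fitted yet")
        if queries is None:
            osets = [self.outlier_sets_[qid] for qid in self.outlier_sets_]
        else:
            if hits is None:
                raise ValueError("hits are required for new queries")
            model = self._model()
            osets = [
                detect_outliers(
                    q, hits.get(q.id, ()), model=model,
                    min_gain=self.min_gain, max_hits=self.max_hits,
                )
                for q in queries
            ]
        known = set(self.partitions_.membership)
        out = []
        for oset in osets:
            if oset and not set(oset.members) <= known:
                out.append(Assignment(oset.query_id, None, None))
                continue
            out.append(
                assign_query(oset, self.partitions_, self.assignment_threshold)
            )
        return out

    def fit_predict(
        self,
        queries: Sequence[SequenceRecord],
        hits: Mapping[str, Sequence[BlastHit]],
        taxonomy: Mapping[str, TaxonomyLineage] | None = None,
    ) -> list[Assignment]:
        return self.fit(queries, hits, taxonomy=taxonomy).predict()
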