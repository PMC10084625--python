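"""The marker-alignment decision procedure, from alignment table to taxon calls.

Seven stages: (1) drop short alignments; (2) Markov-cluster the marker graph
built from shared read alignments; (3) average alignment identity per marker
and per marker cluster; (4) reject taxa dominated by markers whose identity
average falls below their cluster average; (5) Markov-cluster surviving taxa
on counts of multiply aligned reads; (6) report unambiguous taxa (identity
>= 97%, >= 2 reads on >= 2 markers), dropping their ambiguous cluster-mates;
(7) report clusters without an unambiguous member as a single '?'-prefixed
joined call when they pool >= 4 markers and >= 8 reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from statistics import mean
from typing import Iterable, Sequence

from .io_model import AlignmentRecord
from .mcl_core import Clustering, WeightedGraph, mcl

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "MclParams",
    "MarkerStats",
    "TaxonCall",
    "filter_by_length",
    "build_marker_graph",
    "compute_marker_stats",
    "reject_inferior_taxa",
    "build_taxon_graph",
    "call_taxa",
    "detect_taxa",
]

UNAMBIGUOUS = "unambiguous"
STRONG_AMBIGUOUS = "strong_ambiguous"


@dataclass(frozen=True)
class Thresholds:
    """Default decision thresholds; every field is overridable."""

    min_aln_length: int = 60
    unambiguous_min_identity: float = 0.97
    unambiguous_min_reads: int = 2
    unambiguous_min_markers: int = 2
    strong_ambiguous_min_markers: int = 4
    strong_ambiguous_min_reads: int = 8
    inferior_marker_fraction: float = 0.5
    cluster_average_weighted: bool = False

    def __post_init__(self) -> None:
        for name in (
            "min_aln_length",
            "unambiguous_min_reads",
            "unambiguous_min_markers",
            "strong_ambiguous_min_markers",
            "strong_ambiguous_min_reads",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("unambiguous_min_identity", "inferior_marker_fraction"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value}")


@dataclass(frozen=True)
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    max_iterations: int = 100
    tolerance: float = 1e-6

    def run(self, graph: WeightedGraph) -> Clustering:
        return mcl(
            graph,
            inflation=self.inflation,
            expansion=self.expansion,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
        )


@dataclass(frozen=True)
class MarkerStats:
    marker_id: str
    taxon_id: str
    identity_average: float
    n_reads: int
    cluster_id: int


@dataclass(frozen=True)
class TaxonCall:
    """A reported taxon, or a '?'-prefixed joined cluster of ambiguous taxa."""

    label: str
    call_type: str
    member_taxa: frozenset[str]
    member_markers: frozenset[str]
    n_reads: int
    n_markers: int
    identity_average: float

    def __post_init__(self) -> None:
        if self.call_type == UNAMBIGUOUS and len(self.member_taxa) != 1:
            raise ValueError("unambiguous calls have exactly one member taxon")
        if self.call_type == STRONG_AMBIGUOUS and not self.label.startswith("?"):
            raise ValueError("strong-ambiguous labels start with '?'")


def filter_by_length(
    alignments: Iterable[AlignmentRecord], min_aln_length: int = 60
) -> list[AlignmentRecord]:
    """Keep alignments at least ``min_aln_length`` nucleotides long."""
    return [a for a in alignments if a.aln_length >= min_aln_length]


def build_marker_graph(alignments: Sequence[AlignmentRecord]) -> WeightedGraph:
    """Markers as nodes, counts of shared read alignments as edge weights."""
    reads_per_marker: dict[str, set[str]] = {}
    markers_per_read: dict[str, set[str]] = {}
    for a in alignments:
        reads_per_marker.setdefault(a.marker_id, set()).add(a.read_id)
        markers_per_read.setdefault(a.read_id, set()).add(a.marker_id)

    weights: dict[tuple[str, str], int] = {}
    for markers in markers_per_read.values():
        for m1, m2 in combinations(sorted(markers), 2):
            weights[(m1, m2)] = weights.get((m1, m2), 0) + 1

    return WeightedGraph.from_edges(weights, nodes=reads_per_marker)


def compute_marker_stats(
    alignments: Sequence[AlignmentRecord], marker_clustering: Clustering
) -> list[MarkerStats]:
    """Per-marker identity average and read count, tagged with the cluster."""
    by_marker: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_marker.setdefault(a.marker_id, []).append(a)
    stats = []
    for marker_id, recs in by_marker.items():
        stats.append(
            MarkerStats(
                marker_id=marker_id,
                taxon_id=recs[0].taxon_id,
                identity_average=mean(r.identity for r in recs),
                n_reads=len({r.read_id for r in recs}),
                cluster_id=marker_clustering.cluster_index(marker_id),
            )
        )
    return stats


def reject_inferior_taxa(
    marker_stats: Sequence[MarkerStats],
    inferior_marker_fraction: float = 0.5,
    weight_by_reads: bool = False,
) -> set[str]:
    """Taxa whose aligned markers are mostly below their cluster average are dropped.

    A marker is *inferior* when its identity average is strictly lower than
    the unweighted mean over its cluster's markers (optionally read-weighted).
    A taxon is rejected when inferior markers make up at least
    ``inferior_marker_fraction`` of its aligned markers — the boundary is
    inclusive, so exactly 50% rejects at the default.
    """
    by_cluster: dict[int, list[MarkerStats]] = {}
    for s in marker_stats:
        by_cluster.setdefault(s.cluster_id, []).append(s)

    cluster_average: dict[int, float] = {}
    for cid, members in by_cluster.items():
        if weight_by_reads:
            total = sum(m.n_reads for m in members)
            cluster_average[cid] = (
                sum(m.identity_average * m.n_reads for m in members) / total
            )
        else:
            cluster_average[cid] = mean(m.identity_average for m in members)

    n_markers: dict[str, int] = {}
    n_inferior: dict[str, int] = {}
    for s in marker_stats:
        n_markers[s.taxon_id] = n_markers.get(s.taxon_id, 0) + 1
        if s.identity_average < cluster_average[s.cluster_id]:
            n_inferior[s.taxon_id] = n_inferior.get(s.taxon_id, 0) + 1

    return {
        taxon
        for taxon, total in n_markers.items()
        if n_inferior.get(taxon, 0) / total < inferior_marker_fraction
    }


def build_taxon_graph(
    alignments: Sequence[AlignmentRecord], surviving_taxa: set[str]
) -> WeightedGraph:
    """Surviving taxa as nodes, counts of multiply aligned reads as weights."""
    taxa_per_read: dict[str, set[str]] = {}
    seen_taxa: set[str] = set()
    for a in alignments:
        if a.taxon_id not in surviving_taxa:
            continue
        seen_taxa.add(a.taxon_id)
        taxa_per_read.setdefault(a.read_id, set()).add(a.taxon_id)

    weights: dict[tuple[str, str], int] = {}
    for taxa in taxa_per_read.values():
        for t1, t2 in combinations(sorted(taxa), 2):
            weights[(t1, t2)] = weights.get((t1, t2), 0) + 1

    return WeightedGraph.from_edges(weights, nodes=sorted(seen_taxa))


@dataclass
class _Evidence:
    reads: set[str] = field(default_factory=set)
    markers: set[str] = field(default_factory=set)
    identities: list[float] = field(default_factory=list)

    def add(self, a: AlignmentRecord) -> None:
        self.reads.add(a.read_id)
        self.markers.add(a.marker_id)
        self.identities.append(a.identity)


def call_taxa(
    taxon_clustering: Clustering,
    alignments: Sequence[AlignmentRecord],
    thresholds: Thresholds | None = None,
) -> list[TaxonCall]:
    """Turn taxon clusters into reported calls.

    Per taxon, *unambiguous* requires average identity, distinct-read and
    distinct-marker floors all met.  In a cluster containing any unambiguous
    taxon only the unambiguous ones are reported; otherwise the cluster is
    reported as one strong-ambiguous call when its pooled evidence meets the
    marker and read floors, labelled with the sorted, comma-joined member
    names behind a '?'.
    """
    t = thresholds or Thresholds()
    evidence: dict[str, _Evidence] = {}
    for a in alignments:
        if a.taxon_id in taxon_clustering.nodes:
            evidence.setdefault(a.taxon_id, _Evidence()).add(a)

    calls: list[TaxonCall] = []
    for cluster in taxon_clustering.clusters:
        per_taxon = {tax: evidence.get(tax, _Evidence()) for tax in cluster}
        unambiguous = [
            tax
            for tax, ev in per_taxon.items()
            if ev.identities
            and mean(ev.identities) >= t.unambiguous_min_identity
            and len(ev.reads) >= t.unambiguous_min_reads
            and len(ev.markers) >= t.unambiguous_min_markers
        ]
        if unambiguous:
            for tax in sorted(unambiguous):
                ev = per_taxon[tax]
                calls.append(
                    TaxonCall(
                        label=tax,
                        call_type=UNAMBIGUOUS,
                        member_taxa=frozenset({tax}),
                        member_markers=frozenset(ev.markers),
                        n_reads=len(ev.reads),
                        n_markers=len(ev.markers),
                        identity_average=mean(ev.identities),
                    )
                )
            continue
        pooled = _Evidence()
        for ev in per_taxon.values():
            pooled.reads |= ev.reads
            pooled.markers |= ev.markers
            pooled.identities.extend(ev.identities)
        if (
            len(pooled.markers) >= t.strong_ambiguous_min_markers
            and len(pooled.reads) >= t.strong_ambiguous_min_reads
        ):
            members = sorted(cluster)
            calls.append(
                TaxonCall(
                    label="?" + ",".join(members),
                    call_type=STRONG_AMBIGUOUS,
                    member_taxa=frozenset(members),
                    member_markers=frozenset(pooled.markers),
                    n_reads=len(pooled.reads),
                    n_markers=len(pooled.markers),
                    identity_average=mean(pooled.identities),
                )
            )
    return calls


def detect_taxa(
    alignments: Sequence[AlignmentRecord],
    thresholds: Thresholds | None = None,
    mcl_params: MclParams | None = None,
) -> list[TaxonCall]:
    """Run the full seven-stage decision procedure."""
    t = thresholds or Thresholds()
    params = mcl_params or MclParams()

    kept = filter_by_length(alignments, t.min_aln_length)
    logger.info("length filter: %d of %d alignments kept", len(kept), len(alignments))
    if not kept:
        return []

    marker_graph = build_marker_graph(kept)
    marker_clusters = params.run(marker_graph)
    logger.info(
        "marker graph: %d markers in %d clusters",
        marker_graph.n_nodes,
        len(marker_clusters),
    )

    stats = compute_marker_stats(kept, marker_clusters)
    survivors = reject_inferior_taxa(
        stats, t.inferior_marker_fraction, weight_by_reads=t.cluster_average_weighted
    )
    logger.info(
        "inferior-marker filter: %d of %d taxa survive",
        len(survivors),
        len({s.taxon_id for s in stats}),
    )
    if not survivors:
        return []

    surviving_alignments = [a for a in kept if a.taxon_id in survivors]
    taxon_graph = build_taxon_graph(surviving_alignments, survivors)
    taxon_clusters = params.run(taxon_graph)
    logger.info("taxon graph: %d clusters", len(taxon_clusters))

    calls = call_taxa(taxon_clusters, surviving_alignments, t)
    logger.info("calls: %d", len(calls))
    return calls
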