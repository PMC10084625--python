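"""Pairwise taxon confusability: emit/accept rates, PCA, greedy subsampling.

For every pair (A, B) of taxa, eight rates summarize how reads flow between
the pair and the rest of the reference in a simulation: for each member X,
the rate at which X emits reads to its partner, emits reads outside the
pair, accepts reads from the partner, and accepts reads from outside.  PCA
of the 8-column feature table yields a 2-D confusability map; a greedy
distance-based subsample picks well-separated representative pairs from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PairConfusability",
    "PcaEmbedding",
    "FEATURE_COLUMNS",
    "pair_rates",
    "rates_table",
    "pca_embed",
    "greedy_subsample",
]

FEATURE_COLUMNS = [
    "emit_to_partner_a",
    "emit_outside_a",
    "accept_from_partner_a",
    "accept_from_outside_a",
    "emit_to_partner_b",
    "emit_outside_b",
    "accept_from_partner_b",
    "accept_from_outside_b",
]


@dataclass(frozen=True)
class PairConfusability:
    taxon_a: str
    taxon_b: str
    emit_to_partner_a: float
    emit_outside_a: float
    accept_from_partner_a: float
    accept_from_outside_a: float
    emit_to_partner_b: float
    emit_outside_b: float
    accept_from_partner_b: float
    accept_from_outside_b: float

    def __post_init__(self) -> None:
        for name in FEATURE_COLUMNS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def features(self) -> list[float]:
        return [getattr(self, name) for name in FEATURE_COLUMNS]

    def swapped(self) -> "PairConfusability":
        return PairConfusability(
            taxon_a=self.taxon_b,
            taxon_b=self.taxon_a,
            emit_to_partner_a=self.emit_to_partner_b,
            emit_outside_a=self.emit_outside_b,
            accept_from_partner_a=self.accept_from_partner_b,
            accept_from_outside_a=self.accept_from_outside_b,
            emit_to_partner_b=self.emit_to_partner_a,
            emit_outside_b=self.emit_outside_a,
            accept_from_partner_b=self.accept_from_partner_a,
            accept_from_outside_b=self.accept_from_outside_a,
        )


@dataclass(frozen=True)
class PcaEmbedding:
    coordinates: pd.DataFrame  # index matches the feature table; columns pc1, pc2, ...
    explained_variance_pct: np.ndarray  # per component, sums to 100


def _flow_lookup(read_flow_table: pd.DataFrame) -> tuple[dict, dict]:
    """(source, match) -> n_reads plus per-source totals."""
    flows: dict[tuple[str, str], float] = {}
    totals: dict[str, float] = {}
    for row in read_flow_table.itertuples(index=False):
        key = (row.source_taxon, row.match_taxon)
        flows[key] = flows.get(key, 0) + row.n_reads
        totals[row.source_taxon] = totals.get(row.source_taxon, 0) + row.n_reads
    return flows, totals


def pair_rates(
    read_flow_table: pd.DataFrame, pair: tuple[str, str]
) -> PairConfusability:
    """Compute the eight emit/accept rates for one taxon pair.

    ``read_flow_table`` needs columns source_taxon, match_taxon, n_reads
    (counts of reads sampled from a source whose best match is a taxon).
    Emit rates are normalized by the member's own sourced reads; accept
    rates by the sourced reads of the emitting side (the partner, or the
    pooled outside taxa).  An outside-accept rate with no outside reads
    is 0.  A pair member with zero sourced reads is an error.
    """
    a, b = pair
    flows, totals = _flow_lookup(read_flow_table)
    for member in pair:
        if totals.get(member, 0) <= 0:
            raise ValueError(f"pair member {member!r} sourced no reads")

    outside = {t for t in totals if t not in pair}
    outside_total = sum(totals[t] for t in outside)

    def emitted(source: str, to_partner: str) -> tuple[float, float]:
        to = flows.get((source, to_partner), 0) / totals[source]
        out = (
            sum(flows.get((source, t), 0) for t in _match_taxa(flows) - set(pair))
            / totals[source]
        )
        return to, out

    def accepted_from_outside(member: str) -> float:
        if outside_total == 0:
            return 0.0
        return sum(flows.get((t, member), 0) for t in outside) / outside_total

    def _match_taxa(flows: Mapping) -> set:
        return {m for (_, m) in flows}

    emit_ab, emit_out_a = emitted(a, b)
    emit_ba, emit_out_b = emitted(b, a)
    return PairConfusability(
        taxon_a=a,
        taxon_b=b,
        emit_to_partner_a=emit_ab,
        emit_outside_a=emit_out_a,
        accept_from_partner_a=emit_ba,
        accept_from_outside_a=accepted_from_outside(a),
        emit_to_partner_b=emit_ba,
        emit_outside_b=emit_out_b,
        accept_from_partner_b=emit_ab,
        accept_from_outside_b=accepted_from_outside(b),
    )


def rates_table(
    read_flow_table: pd.DataFrame, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Feature table over pairs (all source-taxon pairs by default)."""
    if pairs is None:
        sources = sorted(read_flow_table["source_taxon"].unique())
        pairs = list(combinations(sources, 2))
    rows = []
    for pair in pairs:
        pc = pair_rates(read_flow_table, pair)
        rows.append(
            {"taxon_a": pc.taxon_a, "taxon_b": pc.taxon_b}
            | dict(zip(FEATURE_COLUMNS, pc.features()))
        )
    df = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", *FEATURE_COLUMNS])
    return df.set_index(df["taxon_a"] + "|" + df["taxon_b"])


def pca_embed(feature_table: pd.DataFrame, scale: bool = False) -> PcaEmbedding:
    """PCA (SVD) of the per-pair rate features.

    Features are mean-centered; unit-variance scaling is off by default
    since all features are rates on [0, 1].  Component signs are fixed so
    each component's loadings sum positive.
    """
    x = feature_table[FEATURE_COLUMNS].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("feature table is constant; PCA undefined")
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd

    n_components = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)

    # Deterministic orientation: loadings of each component sum positive.
    for i, loading in enumerate(pca.components_):
        if loading.sum() < 0:
            pca.components_[i] = -loading
            coords[:, i] = -coords[:, i]

    explained = pca.explained_variance_ratio_ * 100.0
    columns = [f"pc{i + 1}" for i in range(coords.shape[1])]
    return PcaEmbedding(
        coordinates=pd.DataFrame(coords, index=feature_table.index, columns=columns),
        explained_variance_pct=explained,
    )


def greedy_subsample(
    points: pd.DataFrame | Mapping[Hashable, tuple[float, float]],
    min_distance: float,
    seed_point: Hashable,
) -> list[Hashable]:
    """Greedy distance-based subsample of labelled 2-D points.

    The seed is kept first; the remaining points are visited in ascending
    Euclidean distance from the seed (ties by label) and kept only when at
    least ``min_distance`` from every point already kept.
    """
    if isinstance(points, pd.DataFrame):
        coords = {
            label: (float(row.iloc[0]), float(row.iloc[1]))
            for label, row in points.iterrows()
        }
    else:
        coords = {k: (float(v[0]), float(v[1])) for k, v in points.items()}
    if seed_point not in coords:
        raise KeyError(f"seed point {seed_point!r} not among the points")

    sx, sy = coords[seed_point]
    order = sorted(
        (label for label in coords if label != seed_point),
        key=lambda lb: (math.dist(coords[lb], (sx, sy)), str(lb)),
    )
    kept = [seed_point]
    for label in order:
        if all(math.dist(coords[label], coords[k]) >= min_distance for k in kept):
            kept.append(label)
    return kept
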