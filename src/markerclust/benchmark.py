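"""Scoring of read mappings against truth, MAPQ filtering, and pair outcomes.

Precision is the fraction of correctly mapped reads among mapped reads;
recall the fraction of correctly mapped reads among all reads.  A read's
match is the taxon of its best-identity alignment; correctness compares
source and match lineages at a chosen rank (species by default, genus for
holdout evaluations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .detect import TaxonCall
from .io_model import AlignmentRecord

__all__ = [
    "EvalMetrics",
    "PairOutcome",
    "load_truth_table",
    "load_taxonomy",
    "score_mappings",
    "apply_mapq_filter",
    "classify_pair_outcome",
]


@dataclass(frozen=True)
class EvalMetrics:
    n_reads: int
    n_mapped: int
    n_correct: int
    per_taxon: pd.DataFrame  # source_taxon, n_reads, n_mapped, n_correct, precision, recall

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_reads if self.n_reads else 0.0

    @property
    def precision(self) -> float:
        """NaN when nothing mapped (undefined, flagged by precision_defined)."""
        return self.n_correct / self.n_mapped if self.n_mapped else float("nan")

    @property
    def precision_defined(self) -> bool:
        return self.n_mapped > 0


@dataclass(frozen=True)
class PairOutcome:
    category: str  # both_only | A_only | B_only | extra_taxa | none
    detected: frozenset[str]


def load_truth_table(path) -> dict[str, str]:
    """read_id -> source_taxon from a truth TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["read_id"], df["source_taxon"]))


def load_taxonomy(path) -> pd.DataFrame:
    """Flat lineage table indexed by taxon; columns are ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("taxon")


def _rank_of(taxonomy: pd.DataFrame, taxon: str, rank: str) -> str:
    if taxon not in taxonomy.index:
        raise KeyError(f"taxon {taxon!r} absent from the taxonomy table")
    return taxonomy.loc[taxon, rank]


def score_mappings(
    alignments: Sequence[AlignmentRecord],
    truth: dict[str, str],
    taxonomy: pd.DataFrame,
    rank: str = "species",
) -> EvalMetrics:
    """Score best-identity matches against the truth table at a lineage rank.

    Ties at the best identity are resolved favorably: the read counts as
    correct if any tied match is correct.  Truth reads missing from the
    taxonomy are a hard error.
    """
    best: dict[str, tuple[float, set[str]]] = {}
    for a in alignments:
        if a.read_id not in best or a.identity > best[a.read_id][0]:
            best[a.read_id] = (a.identity, {a.taxon_id})
        elif a.identity == best[a.read_id][0]:
            best[a.read_id][1].add(a.taxon_id)

    rows = []
    by_taxon: dict[str, dict[str, int]] = {}
    for read_id, source in truth.items():
        source_rank = _rank_of(taxonomy, source, rank)
        counts = by_taxon.setdefault(
            source, {"n_reads": 0, "n_mapped": 0, "n_correct": 0}
        )
        counts["n_reads"] += 1
        if read_id in best:
            counts["n_mapped"] += 1
            _, matches = best[read_id]
            if any(_rank_of(taxonomy, m, rank) == source_rank for m in matches):
                counts["n_correct"] += 1

    for taxon in sorted(by_taxon):
        c = by_taxon[taxon]
        rows.append(
            {
                "source_taxon": taxon,
                **c,
                "precision": c["n_correct"] / c["n_mapped"]
                if c["n_mapped"]
                else float("nan"),
                "recall": c["n_correct"] / c["n_reads"] if c["n_reads"] else 0.0,
            }
        )
    per_taxon = pd.DataFrame(
        rows,
        columns=["source_taxon", "n_reads", "n_mapped", "n_correct", "precision", "recall"],
    )
    return EvalMetrics(
        n_reads=int(per_taxon["n_reads"].sum()) if rows else 0,
        n_mapped=int(per_taxon["n_mapped"].sum()) if rows else 0,
        n_correct=int(per_taxon["n_correct"].sum()) if rows else 0,
        per_taxon=per_taxon,
    )


def apply_mapq_filter(
    alignments: Iterable[AlignmentRecord], min_mapq: int = 30
) -> list[AlignmentRecord]:
    """Keep alignments with MAPQ >= threshold; absent MAPQ is an error."""
    kept = []
    for a in alignments:
        if a.mapq is None:
            raise ValueError(f"alignment of {a.read_id!r} carries no MAPQ")
        if a.mapq >= min_mapq:
            kept.append(a)
    return kept


def classify_pair_outcome(
    calls: Sequence[TaxonCall], pair: tuple[str, str]
) -> PairOutcome:
    """Classify detection results for a two-taxon sample.

    ``detected`` is the union of member taxa over all calls (an ambiguous
    call naming both members counts as detecting both).
    """
    a, b = pair
    detected: set[str] = set()
    for call in calls:
        detected |= call.member_taxa
    if not detected:
        category = "none"
    elif detected - {a, b}:
        category = "extra_taxa"
    elif detected == {a, b}:
        category = "both_only"
    elif detected == {a}:
        category = "A_only"
    else:
        category = "B_only"
    return PairOutcome(category=category, detected=frozenset(detected))
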