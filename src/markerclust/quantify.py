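"""Copies-per-million quantification and report writing.

CPM follows the reads-per-kilobase-over-depth convention of integrated
metagenomic profilers: reads assigned to a call, normalized by the summed
length of its evidence markers and by sequencing depth.  An alternative
dialect sum-normalizes reads-per-kilobase across calls to one million.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .detect import TaxonCall

__all__ = ["QuantifiedCall", "compute_cpm", "quantify_calls", "write_report", "read_report"]

REPORT_COLUMNS = [
    "label",
    "call_type",
    "member_taxa",
    "n_reads",
    "n_markers",
    "identity_average",
    "cpm",
]


@dataclass(frozen=True)
class QuantifiedCall:
    call: TaxonCall
    cpm: float

    def __post_init__(self) -> None:
        if self.cpm < 0:
            raise ValueError(f"cpm must be non-negative, got {self.cpm}")
        if self.cpm == 0 and self.call.n_reads > 0:
            raise ValueError("cpm can only be 0 for calls without reads")


def _evidence_length(call: TaxonCall, marker_lengths: Mapping[str, int]) -> int:
    missing = [m for m in call.member_markers if m not in marker_lengths]
    if missing:
        raise ValueError(f"missing marker lengths for {sorted(missing)!r}")
    return sum(marker_lengths[m] for m in call.member_markers)


def compute_cpm(
    call: TaxonCall, marker_lengths: Mapping[str, int], total_reads: int
) -> float:
    """CPM = (reads / kilobases of evidence markers) / (depth / 1e6).

    ``total_reads`` is the sequencing depth of the sample, not just the
    aligned reads.  Invariant under joint scaling of reads and depth.
    """
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    if call.n_reads == 0:
        return 0.0
    length = _evidence_length(call, marker_lengths)
    if length <= 0:
        raise ValueError(f"evidence marker length must be positive for {call.label!r}")
    return (call.n_reads / (length / 1000.0)) / (total_reads / 1e6)


def quantify_calls(
    calls: Sequence[TaxonCall],
    marker_lengths: Mapping[str, int],
    total_reads: int,
    mode: str = "depth",
) -> list[QuantifiedCall]:
    """Attach CPM values to calls.

    ``mode="depth"`` divides reads-per-kilobase by depth in millions;
    ``mode="sum-normalized"`` rescales reads-per-kilobase so values sum to
    1e6 across calls (community-relative dialect).
    """
    if mode not in ("depth", "sum-normalized"):
        raise ValueError(f"unknown cpm mode {mode!r}")
    if mode == "depth":
        return [
            QuantifiedCall(c, compute_cpm(c, marker_lengths, total_reads))
            for c in calls
        ]
    rpk = [
        c.n_reads / (_evidence_length(c, marker_lengths) / 1000.0) for c in calls
    ]
    total = sum(rpk)
    if total == 0:
        return [QuantifiedCall(c, 0.0) for c in calls]
    return [QuantifiedCall(c, r / total * 1e6) for c, r in zip(calls, rpk)]


def _to_frame(calls: Sequence[QuantifiedCall]) -> pd.DataFrame:
    rows = [
        {
            "label": q.call.label,
            "call_type": q.call.call_type,
            "member_taxa": ",".join(sorted(q.call.member_taxa)),
            "n_reads": q.call.n_reads,
            "n_markers": q.call.n_markers,
            "identity_average": q.call.identity_average,
            "cpm": q.cpm,
        }
        for q in calls
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(
        ["cpm", "label"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def write_report(calls: Sequence[QuantifiedCall], destination) -> None:
    """Write the TSV report, ordered by descending CPM then label."""
    _to_frame(calls).to_csv(destination, sep="\t", index=False)


def read_report(source) -> pd.DataFrame:
    """Read a report back; floats round-trip exactly."""
    return pd.read_csv(
        source,
        sep="\t",
        dtype={
            "label": str,
            "call_type": str,
            "member_taxa": str,
            "n_reads": int,
            "n_markers": int,
            "identity_average": float,
            "cpm": float,
        },
    )
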