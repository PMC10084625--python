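"""Truth-labelled read simulation and synthetic fixture generation.

Two layers:

* a wgsim-style sampler that draws fixed-length reads (default 100 nt, base
  error 0) from a marker FASTA at a target fold-coverage, with an optional
  per-base substitution sweep for novel-strain experiments;
* a scenario-driven fixture generator that fabricates an internally
  consistent (FASTA, taxonomy TSV, truth TSV, SAM) bundle with controlled
  alignment identities, lengths and MAPQ values, standing in for an actual
  aligner run so the pipeline is testable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .io_model import MarkerNaming

__all__ = [
    "SimulatedRead",
    "reads_for_coverage",
    "sample_reads",
    "mutate_reads",
    "write_fastq",
    "write_truth_table",
    "MarkerDef",
    "AlignmentSpec",
    "ReadPlan",
    "Scenario",
    "FixturePaths",
    "generate_fixture",
    "detection_floor_scenario",
    "confusable_pair_scenario",
    "ambiguous_cluster_scenario",
    "ambiguous_trio_scenario",
    "inferior_marker_scenario",
    "unrepresented_species_scenario",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedRead:
    """A sampled read with full provenance for truth tracking."""

    source_taxon: str
    source_marker: str
    start: int  # 0-based, half-open [start, start + len)
    sequence: str
    index: int
    mutation_rate: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.source_taxon}:{self.source_marker}:{self.start}:{self.index}"


def reads_for_coverage(marker_length: int, coverage: float, read_length: int) -> int:
    """Number of reads to sample from one marker for a target fold-coverage.

    Lander-Waterman: N = c * L / l, rounded half away from zero.  Markers
    shorter than the read length cannot source a read and yield 0.
    """
    if marker_length <= 0 or coverage <= 0 or read_length <= 0:
        raise ValueError("marker_length, coverage and read_length must be positive")
    if marker_length < read_length:
        return 0
    return math.floor(coverage * marker_length / read_length + 0.5)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def sample_reads(
    reference_fasta: str | Path,
    coverage: float,
    read_length: int = 100,
    seed: int = 0,
    naming: MarkerNaming | None = None,
) -> list[SimulatedRead]:
    """Sample error-free reads uniformly from every marker in a FASTA.

    Start positions are uniform over the valid range; reads are exact
    substrings of their source marker.  Deterministic given ``seed``.
    Markers shorter than the read length are skipped.
    """
    naming = naming or MarkerNaming()
    rng = np.random.default_rng(seed)
    records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if not records:
        raise ValueError(f"empty reference FASTA: {reference_fasta}")
    reads: list[SimulatedRead] = []
    for rec in records:
        taxon, marker = naming.parse(rec.id)
        seq = str(rec.seq).upper()
        n = reads_for_coverage(len(seq), coverage, read_length)
        for i in range(n):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            reads.append(
                SimulatedRead(
                    source_taxon=taxon,
                    source_marker=marker,
                    start=start,
                    sequence=seq[start : start + read_length],
                    index=i,
                )
            )
    return reads


def mutate_reads(
    reads: Sequence[SimulatedRead], mutation_rate: float, seed: int = 0
) -> list[SimulatedRead]:
    """Substitute each base independently with the given probability.

    A substituted base is drawn uniformly from the three other bases;
    no indels are introduced.
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError(f"mutation_rate must be in [0, 1], got {mutation_rate}")
    if mutation_rate == 0.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    out: list[SimulatedRead] = []
    for read in reads:
        seq = np.array(list(read.sequence))
        hits = rng.random(len(seq)) < mutation_rate
        for pos in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = choices[int(rng.integers(0, len(choices)))]
        out.append(replace(read, sequence="".join(seq), mutation_rate=mutation_rate))
    return out


def write_fastq(reads: Iterable[SimulatedRead], destination: str | Path) -> None:
    with open(destination, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth_table(reads: Iterable[SimulatedRead], destination: str | Path) -> None:
    with open(destination, "w") as fh:
        fh.write("read_id\tsource_taxon\tsource_marker\n")
        for read in reads:
            fh.write(f"{read.name}\t{read.source_taxon}\t{read.source_marker}\n")


# --------------------------------------------------------------------------
# Scenario-driven fixture generation


@dataclass(frozen=True)
class MarkerDef:
    taxon_id: str
    length: int


@dataclass(frozen=True)
class AlignmentSpec:
    """One planned SAM record: where a read aligns and how well."""

    marker_id: str
    identity: float = 1.0
    aln_length: int = 100
    mapq: int = 42
    ref_start: int = 0


@dataclass(frozen=True)
class ReadPlan:
    """A read, its true source, and every alignment it should carry.

    An empty alignment list produces an unmapped SAM record (the read still
    counts toward sequencing depth and recall denominators).  The source
    taxon may be absent from the marker set — that is the unrepresented-
    species construction.
    """

    read_id: str
    source_taxon: str
    source_marker: str
    alignments: tuple[AlignmentSpec, ...] = ()


@dataclass
class Scenario:
    markers: dict[str, MarkerDef]
    reads: list[ReadPlan]
    genus: dict[str, str] = field(default_factory=dict)
    read_length: int = 100

    def taxa(self) -> set[str]:
        return {m.taxon_id for m in self.markers.values()}

    def genus_of(self, taxon: str) -> str:
        # Default: the underscore-separated prefix, mirroring Genus_species ids.
        return self.genus.get(taxon, taxon.split("_")[0])

    def validate(self) -> None:
        for plan in self.reads:
            for spec in plan.alignments:
                if spec.marker_id not in self.markers:
                    raise ValueError(
                        f"read {plan.read_id!r} aligns to unknown marker {spec.marker_id!r}"
                    )
                marker = self.markers[spec.marker_id]
                if spec.ref_start < 0 or spec.ref_start + spec.aln_length > marker.length:
                    raise ValueError(
                        f"alignment of {plan.read_id!r} to {spec.marker_id!r} "
                        f"([{spec.ref_start}, {spec.ref_start + spec.aln_length})) "
                        f"exceeds marker length {marker.length}"
                    )
                if not (0.0 <= spec.identity <= 1.0):
                    raise ValueError(
                        f"identity {spec.identity} out of [0, 1] for {plan.read_id!r}"
                    )
                if spec.mapq < 0:
                    raise ValueError(f"negative MAPQ for {plan.read_id!r}")


@dataclass(frozen=True)
class FixturePaths:
    fasta: Path
    taxonomy: Path
    truth: Path
    sam: Path


def _mutated_substring(
    rng: np.random.Generator, sequence: str, start: int, length: int, n_subs: int
) -> str:
    seq = np.array(list(sequence[start : start + length]))
    positions = rng.choice(length, size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def generate_fixture(
    scenario: Scenario,
    seed: int,
    out_dir: str | Path,
    naming: MarkerNaming | None = None,
    prefix: str = "fixture",
) -> FixturePaths:
    """Materialize a scenario as (marker FASTA, taxonomy TSV, truth TSV, SAM).

    The SAM validates against its own @SQ header, alignment identities are
    realized via NM tags and matching substituted query sequences, and the
    truth table covers every read.  Fully deterministic given ``seed``.
    """
    scenario.validate()
    naming = naming or MarkerNaming()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sequences = {
        marker_id: _random_sequence(rng, mdef.length)
        for marker_id, mdef in sorted(scenario.markers.items())
    }
    seq_name = {
        marker_id: f"{mdef.taxon_id}{naming.delimiter}{marker_id}"
        for marker_id, mdef in scenario.markers.items()
    }

    paths = FixturePaths(
        fasta=out / f"{prefix}.fasta",
        taxonomy=out / f"{prefix}.taxonomy.tsv",
        truth=out / f"{prefix}.truth.tsv",
        sam=out / f"{prefix}.sam",
    )

    with open(paths.fasta, "w") as fh:
        for marker_id in sorted(sequences):
            fh.write(f">{seq_name[marker_id]}\n{sequences[marker_id]}\n")

    truth_taxa = {p.source_taxon for p in scenario.reads}
    with open(paths.taxonomy, "w") as fh:
        fh.write("taxon\tspecies\tgenus\n")
        for taxon in sorted(scenario.taxa() | truth_taxa):
            fh.write(f"{taxon}\t{taxon}\t{scenario.genus_of(taxon)}\n")

    with open(paths.truth, "w") as fh:
        fh.write("read_id\tsource_taxon\tsource_marker\n")
        for plan in scenario.reads:
            fh.write(f"{plan.read_id}\t{plan.source_taxon}\t{plan.source_marker}\n")

    ordered_markers = sorted(scenario.markers)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": seq_name[m], "LN": scenario.markers[m].length}
            for m in ordered_markers
        ],
    }
    tid = {m: i for i, m in enumerate(ordered_markers)}
    with pysam.AlignmentFile(str(paths.sam), "wh", header=header) as sam:
        for plan in scenario.reads:
            if not plan.alignments:
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = plan.read_id
                rec.flag = 4  # unmapped
                rec.query_sequence = _random_sequence(rng, scenario.read_length)
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * scenario.read_length
                )
                sam.write(rec)
                continue
            for i, spec in enumerate(plan.alignments):
                n_subs = round((1.0 - spec.identity) * spec.aln_length)
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = plan.read_id
                rec.flag = 0 if i == 0 else 256  # secondaries after the first
                rec.reference_id = tid[spec.marker_id]
                rec.reference_start = spec.ref_start
                rec.mapping_quality = spec.mapq
                rec.cigarstring = f"{spec.aln_length}M"
                rec.query_sequence = _mutated_substring(
                    rng, sequences[spec.marker_id], spec.ref_start, spec.aln_length, n_subs
                )
                rec.query_qualities = pysam.qualitystring_to_array("I" * spec.aln_length)
                rec.set_tag("NM", n_subs)
                sam.write(rec)

    return paths


# --------------------------------------------------------------------------
# Canned scenarios


def detection_floor_scenario(
    taxon: str = "taxA",
    n_reads: int = 2,
    n_markers: int = 2,
    identity: float = 1.0,
    marker_length: int = 1000,
    aln_length: int = 100,
    mapq: int = 42,
) -> Scenario:
    """Minimal-evidence sample: ``n_reads`` reads, one per marker (cycling)."""
    markers = {
        f"{taxon}_m{i}": MarkerDef(taxon, marker_length) for i in range(n_markers)
    }
    marker_ids = sorted(markers)
    reads = [
        ReadPlan(
            read_id=f"r{j}",
            source_taxon=taxon,
            source_marker=marker_ids[j % n_markers],
            alignments=(
                AlignmentSpec(
                    marker_id=marker_ids[j % n_markers],
                    identity=identity,
                    aln_length=aln_length,
                    mapq=mapq,
                    ref_start=j * 10,
                ),
            ),
        )
        for j in range(n_reads)
    ]
    return Scenario(markers=markers, reads=reads)


def confusable_pair_scenario(
    taxon_a: str = "taxA",
    taxon_b: str = "taxB",
    cross_fraction: float = 0.3,
    n_reads_each: int = 10,
    n_markers_each: int = 4,
    identity_home: float = 1.0,
    identity_cross: float = 0.95,
    marker_length: int = 1000,
    aln_length: int = 100,
) -> Scenario:
    """Two taxa whose reads cross-map at a controlled rate.

    The first ``round(cross_fraction * n_reads_each)`` reads of each taxon
    carry an extra alignment to the partner taxon's homologous marker (with
    a low MAPQ, as a multi-mapper would).
    """
    markers: dict[str, MarkerDef] = {}
    for taxon in (taxon_a, taxon_b):
        for i in range(n_markers_each):
            markers[f"{taxon}_m{i}"] = MarkerDef(taxon, marker_length)

    n_cross = round(cross_fraction * n_reads_each)
    reads: list[ReadPlan] = []
    for taxon, partner in ((taxon_a, taxon_b), (taxon_b, taxon_a)):
        for j in range(n_reads_each):
            home = f"{taxon}_m{j % n_markers_each}"
            specs = [
                AlignmentSpec(
                    marker_id=home,
                    identity=identity_home,
                    aln_length=aln_length,
                    mapq=42 if j >= n_cross else 3,
                )
            ]
            if j < n_cross:
                specs.append(
                    AlignmentSpec(
                        marker_id=f"{partner}_m{j % n_markers_each}",
                        identity=identity_cross,
                        aln_length=aln_length,
                        mapq=3,
                    )
                )
            reads.append(
                ReadPlan(
                    read_id=f"{taxon}_r{j}",
                    source_taxon=taxon,
                    source_marker=home,
                    alignments=tuple(specs),
                )
            )
    return Scenario(markers=markers, reads=reads)


def ambiguous_cluster_scenario(
    taxon: str = "taxP",
    n_markers: int = 4,
    n_reads: int = 8,
    identity: float = 0.93,
    marker_length: int = 1000,
    aln_length: int = 100,
) -> Scenario:
    """A single low-identity taxon: candidate for a strong-ambiguous call.

    Each read aligns to one marker (cycling), all at the same sub-threshold
    identity, so the taxon forms its own cluster, no marker is inferior
    (singleton marker clusters equal their own average) and the pooled
    evidence spans ``n_markers`` markers and ``n_reads`` reads.
    """
    markers = {
        f"{taxon}_m{i}": MarkerDef(taxon, marker_length) for i in range(n_markers)
    }
    reads = [
        ReadPlan(
            read_id=f"r{j}",
            source_taxon=taxon,
            source_marker=f"{taxon}_m{j % n_markers}",
            alignments=(
                AlignmentSpec(
                    marker_id=f"{taxon}_m{j % n_markers}",
                    identity=identity,
                    aln_length=aln_length,
                    mapq=3,
                ),
            ),
        )
        for j in range(n_reads)
    ]
    return Scenario(markers=markers, reads=reads)


def ambiguous_trio_scenario(
    taxa: tuple[str, str, str] = ("taxA", "taxB", "taxC"),
    n_markers_each: int = 2,
    n_reads: int = 8,
    identity: float = 0.93,
    marker_length: int = 1000,
    aln_length: int = 100,
) -> Scenario:
    """Three taxa whose reads all cross-map: one joined '?' call end to end.

    Every read aligns to the homologous marker of all three taxa at the same
    sub-threshold identity.  The taxon graph is a triangle (which Markov
    clustering merges, unlike a two-node graph whose flow oscillates), no
    marker is inferior, and the pooled evidence spans all markers and reads.
    """
    markers: dict[str, MarkerDef] = {}
    for taxon in taxa:
        for i in range(n_markers_each):
            markers[f"{taxon}_m{i}"] = MarkerDef(taxon, marker_length)
    reads = [
        ReadPlan(
            read_id=f"r{j}",
            source_taxon=taxa[0],
            source_marker=f"{taxa[0]}_m{j % n_markers_each}",
            alignments=tuple(
                AlignmentSpec(
                    marker_id=f"{taxon}_m{j % n_markers_each}",
                    identity=identity,
                    aln_length=aln_length,
                    mapq=3,
                )
                for taxon in taxa
            ),
        )
        for j in range(n_reads)
    ]
    return Scenario(markers=markers, reads=reads)


def inferior_marker_scenario(
    target_taxon: str = "taxT",
    rival_taxon: str = "taxU",
    n_markers: int = 4,
    n_inferior: int = 2,
    inferior_identity: float = 0.9,
    marker_length: int = 1000,
    aln_length: int = 100,
) -> Scenario:
    """A taxon with a controlled number of inferior markers.

    ``n_inferior`` of the target's markers each share a read with a
    perfect-identity rival marker (so they fall below their two-marker
    cluster average); the rest get exclusive perfect reads and sit in
    singleton clusters, which are never inferior.
    """
    if not (0 <= n_inferior <= n_markers):
        raise ValueError("n_inferior must be between 0 and n_markers")
    markers: dict[str, MarkerDef] = {}
    for i in range(n_markers):
        markers[f"{target_taxon}_m{i}"] = MarkerDef(target_taxon, marker_length)
    for i in range(n_inferior):
        markers[f"{rival_taxon}_m{i}"] = MarkerDef(rival_taxon, marker_length)

    reads: list[ReadPlan] = []
    for i in range(n_markers):
        target_marker = f"{target_taxon}_m{i}"
        if i < n_inferior:
            reads.append(
                ReadPlan(
                    read_id=f"s{i}",
                    source_taxon=rival_taxon,
                    source_marker=f"{rival_taxon}_m{i}",
                    alignments=(
                        AlignmentSpec(
                            marker_id=target_marker,
                            identity=inferior_identity,
                            aln_length=aln_length,
                            mapq=3,
                        ),
                        AlignmentSpec(
                            marker_id=f"{rival_taxon}_m{i}",
                            identity=1.0,
                            aln_length=aln_length,
                            mapq=3,
                        ),
                    ),
                )
            )
        else:
            reads.append(
                ReadPlan(
                    read_id=f"u{i}",
                    source_taxon=target_taxon,
                    source_marker=target_marker,
                    alignments=(
                        AlignmentSpec(
                            marker_id=target_marker,
                            identity=1.0,
                            aln_length=aln_length,
                            mapq=42,
                        ),
                    ),
                )
            )
    return Scenario(markers=markers, reads=reads)


def unrepresented_species_scenario(
    truth_taxon: str = "Genus_novel",
    reference_taxon: str = "Genus_known",
    n_reads: int = 10,
    n_markers: int = 4,
    identity: float = 0.93,
    marker_length: int = 1000,
    aln_length: int = 100,
) -> Scenario:
    """Reads from a taxon absent from the reference, hitting a congener."""
    markers = {
        f"{reference_taxon}_m{i}": MarkerDef(reference_taxon, marker_length)
        for i in range(n_markers)
    }
    marker_ids = sorted(markers)
    genus = truth_taxon.split("_")[0]
    reads = [
        ReadPlan(
            read_id=f"r{j}",
            source_taxon=truth_taxon,
            source_marker=f"{truth_taxon}_m{j % n_markers}",
            alignments=(
                AlignmentSpec(
                    marker_id=marker_ids[j % n_markers],
                    identity=identity,
                    aln_length=aln_length,
                    mapq=11,
                ),
            ),
        )
        for j in range(n_reads)
    ]
    return Scenario(
        markers=markers,
        reads=reads,
        genus={truth_taxon: genus, reference_taxon: genus},
    )
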