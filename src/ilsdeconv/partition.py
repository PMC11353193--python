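"""Species-of-origin partitioning of alignments against a combined reference.

Reads sequenced from an introgression line are aligned against a combined
index of both parental genomes. Every fragment's candidate alignments form
a bundle, and each bundle is classified into exactly one of three subsets
by comparing the best alignment score (SAM ``AS`` tag) reached in each
genome:

* ``SLYC`` — best score strictly higher in the cultivated genome (A), or
  alignments exist only in A (including unique alignments);
* ``PENN`` — the symmetric rule for the wild genome (B);
* ``AMBI`` — alignments in both genomes with tied best scores.

For ambiguous fragments the genome-B entries are the ones retained for
downstream quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Tuple

import pysam


class PartitionError(ValueError):
    """Raised on malformed bundles or alignment records."""


class SubsetLabel(str, Enum):
    SLYC = "SLYC"
    PENN = "PENN"
    AMBI = "AMBI"


@dataclass(frozen=True)
class AlignmentRecord:
    """One candidate alignment of a fragment.

    position is a 0-based start (SAM's 1-based coordinate minus one).
    alignment_score is the integer AS tag; reported_hits the NH tag.
    """

    fragment_id: str
    genome: str  # "A" or "B"
    gene_id: str  # reference contig name
    position: int
    alignment_score: int
    reported_hits: int = 1
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.genome not in ("A", "B"):
            raise PartitionError(
                f"fragment {self.fragment_id}: genome must be 'A' or 'B', "
                f"got {self.genome!r}"
            )
        if self.reported_hits < 1:
            raise PartitionError(
                f"fragment {self.fragment_id}: NH must be >= 1"
            )


@dataclass(frozen=True)
class AlignmentBundle:
    """All candidate alignments of one fragment."""

    fragment_id: str
    records: Tuple[AlignmentRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise PartitionError(f"empty bundle for fragment {self.fragment_id}")
        for rec in self.records:
            if rec.fragment_id != self.fragment_id:
                raise PartitionError(
                    f"bundle {self.fragment_id} contains record of "
                    f"{rec.fragment_id}"
                )
        object.__setattr__(self, "records", tuple(self.records))


def classify_bundle(bundle: AlignmentBundle) -> SubsetLabel:
    """Assign a bundle to SLYC, PENN or AMBI by best-AS comparison.

    The label depends only on the per-genome maxima of the alignment
    scores; ties *within* one genome are irrelevant here and are resolved
    later by the EM quantifier.
    """
    best_a: Optional[int] = None
    best_b: Optional[int] = None
    for rec in bundle.records:
        if rec.genome == "A":
            if best_a is None or rec.alignment_score > best_a:
                best_a = rec.alignment_score
        else:
            if best_b is None or rec.alignment_score > best_b:
                best_b = rec.alignment_score
    if best_a is None:
        return SubsetLabel.PENN
    if best_b is None:
        return SubsetLabel.SLYC
    if best_a > best_b:
        return SubsetLabel.SLYC
    if best_b > best_a:
        return SubsetLabel.PENN
    return SubsetLabel.AMBI


def select_retained_records(
    bundle: AlignmentBundle, label: SubsetLabel
) -> List[AlignmentRecord]:
    """Records carried into quantification for a labelled bundle.

    SLYC keeps the genome-A records; PENN keeps genome-B; ambiguous
    fragments also keep only their genome-B entries.
    """
    keep_genome = "A" if label is SubsetLabel.SLYC else "B"
    return [rec for rec in bundle.records if rec.genome == keep_genome]


@dataclass
class PartitionSummary:
    n_fragments: int = 0
    counts: Dict[str, int] = field(
        default_factory=lambda: {"SLYC": 0, "PENN": 0, "AMBI": 0}
    )
    n_supplementary_dropped: int = 0

    @property
    def fractions(self) -> Dict[str, float]:
        total = max(self.n_fragments, 1)
        return {k: v / total for k, v in self.counts.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_fragments": self.n_fragments,
                "counts": self.counts,
                "fractions": self.fractions,
                "n_supplementary_dropped": self.n_supplementary_dropped,
            },
            indent=2,
        )


def default_genome_of(reference_name: str) -> str:
    """Infer the genome of a contig from its ``_A`` / ``_B`` suffix."""
    if reference_name.endswith("_A"):
        return "A"
    if reference_name.endswith("_B"):
        return "B"
    raise PartitionError(
        f"cannot infer genome for contig {reference_name!r}; provide an "
        "explicit contig->genome mapping"
    )


def _bundle_from_segments(
    fragment_id: str,
    segments: List[pysam.AlignedSegment],
    genome_of: Callable[[str], str],
) -> AlignmentBundle:
    records = []
    n_records = sum(1 for s in segments)
    for seg in segments:
        if not seg.has_tag("AS"):
            raise PartitionError(
                f"fragment {fragment_id}: alignment record lacks the AS tag "
                "needed for species-of-origin classification"
            )
        nh = seg.get_tag("NH") if seg.has_tag("NH") else n_records
        records.append(
            AlignmentRecord(
                fragment_id=fragment_id,
                genome=genome_of(seg.reference_name),
                gene_id=seg.reference_name,
                position=seg.reference_start,
                alignment_score=int(seg.get_tag("AS")),
                reported_hits=int(nh),
                is_secondary=seg.is_secondary,
            )
        )
    return AlignmentBundle(fragment_id=fragment_id, records=tuple(records))


def iter_bundles(
    sam_path: str | Path,
    genome_of: Callable[[str], str] = default_genome_of,
) -> Iterator[Tuple[AlignmentBundle, List[pysam.AlignedSegment]]]:
    """Yield (bundle, raw segments) per fragment from a name-grouped SAM/BAM.

    Unmapped and supplementary/chimeric segments are skipped (the latter
    tallied by partition_sam). Fragments must be grouped: a qname seen
    again after the group closed raises.
    """
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        current: Optional[str] = None
        seen: set[str] = set()
        segs: List[pysam.AlignedSegment] = []
        for seg in fh:
            if seg.is_unmapped:
                continue
            qname = seg.query_name
            if qname != current:
                if current is not None and segs:
                    yield _bundle_from_segments(
                        current, [s for s in segs if not s.is_supplementary],
                        genome_of,
                    ), segs
                if qname in seen:
                    raise PartitionError(
                        f"SAM not grouped by fragment: {qname} reappears"
                    )
                seen.add(qname)
                current = qname
                segs = []
            segs.append(seg)
        if current is not None and segs:
            yield _bundle_from_segments(
                current, [s for s in segs if not s.is_supplementary], genome_of
            ), segs


def partition_bundles(
    bundles: Iterable[AlignmentBundle],
    pure_species_mode: bool = False,
) -> Tuple[Dict[str, List[AlignmentBundle]], PartitionSummary]:
    """Classify in-memory bundles into the three subsets.

    In pure_species_mode (libraries aligned against a single genome, e.g.
    the pure cultivated-species genotype) every fragment goes to SLYC.
    """
    out: Dict[str, List[AlignmentBundle]] = {"SLYC": [], "PENN": [], "AMBI": []}
    summary = PartitionSummary()
    for bundle in bundles:
        label = (
            SubsetLabel.SLYC if pure_species_mode else classify_bundle(bundle)
        )
        out[label.value].append(bundle)
        summary.n_fragments += 1
        summary.counts[label.value] += 1
    return out, summary


def partition_sam(
    sam_path: str | Path,
    out_prefix: str | Path,
    pure_species_mode: bool = False,
    genome_of: Callable[[str], str] = default_genome_of,
) -> PartitionSummary:
    """Partition a name-grouped SAM/BAM into `.slyc/.penn/.ambi` SAM files.

    Retained records per the subset rule are written; a JSON summary with
    fragment counts and fractions is written to ``<prefix>.partition.json``.
    """
    out_prefix = Path(out_prefix)
    summary = PartitionSummary()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as template:
        header = template.header.to_dict()
    writers = {
        lab: pysam.AlignmentFile(
            str(out_prefix) + f".{lab.lower()}.sam", "wh", header=header
        )
        for lab in ("SLYC", "PENN", "AMBI")
    }
    try:
        for bundle, segs in iter_bundles(sam_path, genome_of):
            summary.n_supplementary_dropped += sum(
                1 for s in segs if s.is_supplementary
            )
            label = (
                SubsetLabel.SLYC if pure_species_mode
                else classify_bundle(bundle)
            )
            keep_genome = "A" if label is SubsetLabel.SLYC else "B"
            wrote = 0
            for seg in segs:
                if seg.is_supplementary:
                    continue
                if pure_species_mode or genome_of(seg.reference_name) == keep_genome:
                    writers[label.value].write(seg)
                    wrote += 1
            assert wrote > 0, f"no retained records for {bundle.fragment_id}"
            summary.n_fragments += 1
            summary.counts[label.value] += 1
    finally:
        for w in writers.values():
            w.close()
    with open(str(out_prefix) + ".partition.json", "w") as fh:
        fh.write(summary.to_json())
    return summary
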