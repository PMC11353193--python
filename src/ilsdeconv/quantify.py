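"""Gene-level expected counts per subset via a lightweight EM.

Fragments retained by the partitioner are assigned to the genes their
alignments overlap; within-genome multi-mapping fragments are resolved by
an expectation-maximisation over gene abundances. Expected counts are
left unrounded — the differential-expression stage consumes the
continuous estimates directly.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import read_gtf_genes
from .partition import AlignmentBundle, AlignmentRecord


class QuantificationError(ValueError):
    pass


@dataclass
class FragmentAssignment:
    """Candidate genes of one fragment with current fractional weights."""

    fragment_id: str
    gene_ids: Tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise QuantificationError(
                f"fragment {self.fragment_id}: weights must be >= 0 and sum to 1"
            )
        self.weights = w


@dataclass
class GeneIntervals:
    """Per-contig sorted gene intervals for overlap queries."""

    by_contig: Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]]

    @classmethod
    def from_models(cls, models: pd.DataFrame) -> "GeneIntervals":
        by_contig: Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]] = {}
        for contig, grp in models.groupby("contig"):
            grp = grp.sort_values("start0")
            starts = grp["start0"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise QuantificationError(
                    f"overlapping gene models on contig {contig}"
                )
            by_contig[contig] = (starts, ends, list(grp["gene_id"]))
        return cls(by_contig)

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneIntervals":
        return cls.from_models(read_gtf_genes(path))

    def overlapping(self, contig: str, start: int, end: int) -> List[str]:
        entry = self.by_contig.get(contig)
        if entry is None:
            return []
        starts, ends, ids = entry
        # non-overlapping sorted intervals: at most the two flanking ones
        # can intersect a short fragment
        i = bisect_right(starts, start) - 1
        hits = []
        for j in (i, i + 1):
            if 0 <= j < len(ids) and starts[j] < end and ends[j] > start:
                hits.append(ids[j])
        return hits


@dataclass
class AssignmentSet:
    """Fragment -> candidate-gene assignments for one subset/sample."""

    assignments: List[FragmentAssignment]
    n_unassigned: int = 0

    @property
    def n_fragments(self) -> int:
        return len(self.assignments)


def assign_fragments(
    bundles_or_records: Iterable[AlignmentBundle | Sequence[AlignmentRecord]],
    intervals: GeneIntervals,
    read_length: int,
) -> AssignmentSet:
    """Map each fragment's retained alignments onto gene intervals.

    A fragment's candidate set is the union of genes overlapped by any of
    its retained alignments; fragments hitting no gene are tallied as
    unassigned (not silently dropped).
    """
    assignments: List[FragmentAssignment] = []
    unassigned = 0
    for item in bundles_or_records:
        if isinstance(item, AlignmentBundle):
            frag, records = item.fragment_id, item.records
        else:
            records = list(item)
            frag = records[0].fragment_id
        genes: List[str] = []
        for rec in records:
            for g in intervals.overlapping(
                rec.gene_id, rec.position, rec.position + read_length
            ):
                if g not in genes:
                    genes.append(g)
        if not genes:
            unassigned += 1
            continue
        w = np.full(len(genes), 1.0 / len(genes))
        assignments.append(FragmentAssignment(frag, tuple(genes), w))
    return AssignmentSet(assignments=assignments, n_unassigned=unassigned)


def em_expected_counts(
    assignment_set: AssignmentSet,
    gene_ids: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> pd.Series:
    """EM over gene abundances; returns per-gene expected counts.

    theta starts uniform over genes with at least one candidate fragment;
    E-step w(f,g) proportional to theta_g over f's candidates; M-step
    theta_g proportional to the summed weights. Iterates until
    max|d theta| < tol or `max_iter`. The observed-data log-likelihood is
    asserted non-decreasing at every step. Expected count of gene g is
    the final summed weight. Genes named in `gene_ids` but receiving no
    fragments appear with count 0.
    """
    assignments = assignment_set.assignments
    if not assignments:
        index = pd.Index(list(gene_ids or []), name="gene_id")
        return pd.Series(0.0, index=index, name="expected_count")

    # compress to equivalence classes of identical candidate sets
    class_counts: Dict[Tuple[str, ...], int] = {}
    for a in assignments:
        key = tuple(sorted(a.gene_ids))
        class_counts[key] = class_counts.get(key, 0) + 1
    active: List[str] = sorted({g for key in class_counts for g in key})
    gidx = {g: i for i, g in enumerate(active)}
    classes = list(class_counts.items())
    n_frag = float(len(assignments))

    theta = np.full(len(active), 1.0 / len(active))
    member_idx = [np.array([gidx[g] for g in key]) for key, _ in classes]
    class_n = np.array([c for _, c in classes], dtype=float)

    def loglik(th: np.ndarray) -> float:
        per_class = np.array([th[idx].sum() for idx in member_idx])
        return float(np.dot(class_n, np.log(np.maximum(per_class, 1e-300))))

    prev_ll = loglik(theta)
    expected = np.zeros(len(active))
    for _ in range(max_iter):
        new_weight = np.zeros(len(active))
        for idx, n in zip(member_idx, class_n):
            th = theta[idx]
            tot = th.sum()
            if tot <= 0:
                new_weight[idx] += n / len(idx)
            else:
                new_weight[idx] += n * (th / tot)
        new_theta = new_weight / n_frag
        ll = loglik(new_theta)
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        expected = new_weight  # sum_f w(f,g): exact for unique fragments
        prev_ll = ll
        if delta < tol:
            break
    out = dict(zip(active, expected))
    universe = list(gene_ids) if gene_ids is not None else active
    index = pd.Index(universe, name="gene_id")
    return pd.Series(
        [out.get(g, 0.0) for g in universe], index=index, name="expected_count"
    )


def quantify_subset(
    bundles_or_records: Iterable[AlignmentBundle | Sequence[AlignmentRecord]],
    intervals: GeneIntervals,
    read_length: int,
    gene_ids: Sequence[str],
) -> Tuple[pd.Series, int]:
    """assign + EM for one subset of one sample; returns (counts, unassigned)."""
    aset = assign_fragments(bundles_or_records, intervals, read_length)
    counts = em_expected_counts(aset, gene_ids=gene_ids)
    total = counts.sum() + aset.n_unassigned
    if abs(total - (aset.n_fragments + aset.n_unassigned)) > 1e-6:
        raise QuantificationError(
            "fragment conservation violated: "
            f"{total} != {aset.n_fragments + aset.n_unassigned}"
        )
    return counts, aset.n_unassigned


def merge_subset_counts(
    counts_penn: pd.DataFrame,
    counts_ambi: pd.DataFrame,
    policy: str = "sum",
) -> pd.DataFrame | Tuple[pd.DataFrame, pd.DataFrame]:
    """Combine PENN and AMBI matrices over the wild-genome gene models.

    policy "sum" (default) adds the ambiguous fragments' expected counts
    into the PENN matrix gene-wise; "separate" returns both unchanged.
    """
    if policy not in ("sum", "separate"):
        raise QuantificationError(f"unknown ambi policy {policy!r}")
    if list(counts_penn.index) != list(counts_ambi.index) or list(
        counts_penn.columns
    ) != list(counts_ambi.columns):
        raise QuantificationError(
            "PENN and AMBI matrices must share gene universe and samples"
        )
    if policy == "separate":
        return counts_penn, counts_ambi
    return counts_penn + counts_ambi
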