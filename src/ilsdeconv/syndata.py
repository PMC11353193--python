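"""Synthetic dual-genome RNA-seq study generator.

Emulates the data structure of an introgression-line (IL) parasitism
experiment: two congeneric genomes diverged by point substitutions, ILs
carrying one interval of wild-relative (genome B) alleles in a cultivated
(genome A) background, negative-binomial counts with planted differential
expression between control and parasitized conditions, per-fragment
alignments against both genomes with NH/AS tags, pathway annotations, and
qPCR Ct tables referenced to an actin-like housekeeping gene.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .config import ConfigurationError, SimulationConfig
from .io import sam_header, write_fasta, write_gtf
from .partition import AlignmentBundle, AlignmentRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENOTYPES = ("Formula", "IL6-2", "IL6-3")
CONDITIONS = ("control", "parasitized")


@dataclass(frozen=True)
class SampleSpec:
    """One sequenced biological sample."""

    name: str
    genotype: str
    condition: str  # "control" | "parasitized"
    replicate: int


def study_design(config: SimulationConfig) -> List[SampleSpec]:
    """The default three-genotype, two-condition, replicated design."""
    samples = []
    short = {"Formula": "F", "IL6-2": "IL6-2", "IL6-3": "IL6-3"}
    for genotype in GENOTYPES:
        for condition in CONDITIONS:
            c = "c" if condition == "control" else "p"
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleSpec(
                        name=f"{short[genotype]}{c}{rep}",
                        genotype=genotype,
                        condition=condition,
                        replicate=rep,
                    )
                )
    return samples


def default_introgressions(config: SimulationConfig) -> Dict[str, frozenset]:
    """Per-genotype introgressed gene-index sets.

    Each IL carries one contiguous homozygous interval of genome-B
    alleles (~10% of genes), mirroring single-segment introgression
    lines; the cultivated genotype carries none.
    """
    n = config.n_genes_per_genome
    span = max(1, n // 10)
    il62 = frozenset(range(min(n, 3 * n // 5), min(n, 3 * n // 5 + span)))
    il63 = frozenset(range(min(n, 4 * n // 5), min(n, 4 * n // 5 + span)))
    return {"Formula": frozenset(), "IL6-2": il62, "IL6-3": il63}


# ---------------------------------------------------------------------------
# Genome pair


@dataclass
class GenomePair:
    """Two homologous genomes as per-gene contig sequences.

    Contigs are named ``<stem>_A`` / ``<stem>_B``; gene bodies occupy
    ``[flank, flank + gene_length)`` on each contig. genome B differs from
    genome A exactly at ``divergent_sites[stem]`` (positions on the contig).
    """

    gene_stems: List[str]
    genome_a: Dict[str, np.ndarray]  # stem -> uint8 base codes (0..3)
    genome_b: Dict[str, np.ndarray]
    divergent_sites: Dict[str, np.ndarray]
    gene_length: int
    flank: int

    @property
    def contig_length(self) -> int:
        return self.gene_length + 2 * self.flank

    def sequences(self, genome: str) -> Dict[str, str]:
        """Contig name -> nucleotide string for one genome."""
        src = self.genome_a if genome == "A" else self.genome_b
        return {
            f"{stem}_{genome}": _decode(src[stem]) for stem in self.gene_stems
        }

    def gene_models(self, genome: str) -> pd.DataFrame:
        """Single-exon gene models (contig, gene_id, start0, end)."""
        return pd.DataFrame(
            {
                "contig": [f"{s}_{genome}" for s in self.gene_stems],
                "gene_id": [f"{s}_{genome}" for s in self.gene_stems],
                "start0": self.flank,
                "end": self.flank + self.gene_length,
            }
        )


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_genome_pair(config: SimulationConfig) -> GenomePair:
    """Simulate genome A and a point-substitution-diverged genome B."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_genes_per_genome
    clen = config.gene_length + 2 * config.flank
    stems = [f"g{i:05d}" for i in range(n)]
    genome_a: Dict[str, np.ndarray] = {}
    genome_b: Dict[str, np.ndarray] = {}
    divergent: Dict[str, np.ndarray] = {}
    for stem in stems:
        a = rng.integers(0, 4, size=clen, dtype=np.uint8)
        mask = rng.random(clen) < config.divergence_rate
        sites = np.flatnonzero(mask)
        b = a.copy()
        # substitute to one of the three other bases
        b[sites] = (a[sites] + rng.integers(1, 4, size=sites.size)) % 4
        genome_a[stem] = a
        genome_b[stem] = b
        divergent[stem] = sites
    return GenomePair(
        gene_stems=stems,
        genome_a=genome_a,
        genome_b=genome_b,
        divergent_sites=divergent,
        gene_length=config.gene_length,
        flank=config.flank,
    )


# ---------------------------------------------------------------------------
# Counts


@dataclass
class TruthTable:
    """Ground truth of the simulation.

    genes: per gene stem — baseline relative abundance, planted log2FC of
    parasitized vs control, DE flag.
    fragments: per simulated fragment — origin genome/gene/position and
    the number of divergent sites the fragment covers (filled by
    simulate_alignment_bundles).
    """

    genes: pd.DataFrame
    fragments: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_counts(
    config: SimulationConfig,
    design: Sequence[SampleSpec],
) -> Tuple[pd.DataFrame, TruthTable]:
    """Draw a gene x sample true-count matrix under the NB model.

    Gene baselines are lognormal; DE genes get the planted effect split
    symmetrically across conditions (control x 2^{-s*L/2}, parasitized
    x 2^{+s*L/2}) so the condition mean ratio is exactly 2^{sL} while both
    conditions keep the same expected library size.
    """
    by_cond: Dict[str, int] = {}
    for s in design:
        by_cond[s.condition] = by_cond.get(s.condition, 0) + 1
    if any(v < 2 for v in by_cond.values()):
        raise ConfigurationError(
            "each condition needs >= 2 replicates (dispersion is "
            f"unestimable downstream); got {by_cond}"
        )
    rng = np.random.default_rng([config.seed, 202])
    n = config.n_genes_per_genome
    stems = [f"g{i:05d}" for i in range(n)]

    base = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    base /= base.sum()

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = np.zeros(n)
    half = n_de // 2
    shuffled = rng.permutation(de_idx)
    signs[shuffled[:half]] = 1.0
    signs[shuffled[half:]] = -1.0
    true_lfc = signs * config.de_log2fc

    counts = np.empty((n, len(design)), dtype=float)
    phi = config.nb_dispersion
    for j, sample in enumerate(design):
        shift = 0.5 if sample.condition == "parasitized" else -0.5
        mu = base * np.exp2(true_lfc * shift) * config.library_size_mean
        if phi <= 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)

    matrix = pd.DataFrame(
        counts, index=pd.Index(stems, name="gene_stem"),
        columns=[s.name for s in design],
    )
    genes = pd.DataFrame(
        {
            "gene_stem": stems,
            "baseline": base,
            "true_log2fc": true_lfc,
            "is_de": true_lfc != 0.0,
        }
    )
    return matrix, TruthTable(genes=genes)


# ---------------------------------------------------------------------------
# Fragment / alignment simulation


@dataclass
class SampleAlignments:
    """Vectorised per-sample fragment simulation output.

    Arrays are parallel over fragments; ``reads`` holds the (possibly
    error-bearing) base codes of each fragment.
    """

    sample: str
    fragment_ids: List[str]
    gene_index: np.ndarray  # index into pair.gene_stems
    origin_genome: np.ndarray  # '<U1' array of 'A'/'B'
    start: np.ndarray  # 0-based start on contig
    as_a: np.ndarray
    as_b: np.ndarray
    n_div_covered: np.ndarray
    reads: np.ndarray  # (n_fragments, read_length) uint8
    paralog: np.ndarray  # bool: fragment also maps to the ring-next gene
    dual: bool  # aligned against both genomes?

    def __len__(self) -> int:
        return len(self.fragment_ids)


def simulate_sample_alignments(
    config: SimulationConfig,
    pair: GenomePair,
    counts: pd.Series,
    sample: str,
    introgressed: frozenset,
    dual: bool,
    rng: np.random.Generator,
) -> SampleAlignments:
    """Simulate all fragments of one sample.

    Fragment origin allele: genome B for introgressed genes of an IL,
    genome A otherwise. Alignment scores against each genome are
    ``matches - mismatch_penalty * mismatches`` with mismatches counted
    against that genome's sequence at the fragment's locus.
    """
    L = config.read_length
    penalty = config.mismatch_penalty
    lo, hi = pair.flank, pair.flank + pair.gene_length - L + 1

    gi_chunks, og_chunks, st_chunks = [], [], []
    asa_chunks, asb_chunks, div_chunks, read_chunks, par_chunks = [], [], [], [], []
    n_genes = len(pair.gene_stems)
    offsets = np.arange(L)

    for gi, stem in enumerate(pair.gene_stems):
        c = int(round(counts.iloc[gi]))
        if c <= 0:
            continue
        origin_b = gi in introgressed
        seq_a = pair.genome_a[stem]
        seq_b = pair.genome_b[stem]
        origin_seq = seq_b if origin_b else seq_a
        starts = rng.integers(lo, hi, size=c)
        idx = starts[:, None] + offsets
        reads = origin_seq[idx].copy()
        if config.error_rate > 0:
            err = rng.random((c, L)) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                reads[err] = (reads[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
        mm_a = (reads != seq_a[idx]).sum(axis=1)
        mm_b = (reads != seq_b[idx]).sum(axis=1)
        as_a = L - (1 + penalty) * mm_a
        as_b = L - (1 + penalty) * mm_b
        sites = pair.divergent_sites[stem]
        ind = np.zeros(pair.contig_length + 1)
        ind[sites + 1] = 1.0
        cum = np.cumsum(ind)
        ndiv = (cum[starts + L] - cum[starts]).astype(int)
        par = (
            rng.random(c) < config.paralog_fraction
            if config.paralog_fraction > 0
            else np.zeros(c, dtype=bool)
        )
        gi_chunks.append(np.full(c, gi))
        og_chunks.append(np.full(c, "B" if origin_b else "A", dtype="<U1"))
        st_chunks.append(starts)
        asa_chunks.append(as_a)
        asb_chunks.append(as_b)
        div_chunks.append(ndiv)
        read_chunks.append(reads)
        par_chunks.append(par)

    if gi_chunks:
        gene_index = np.concatenate(gi_chunks)
        n_frag = gene_index.size
        out = SampleAlignments(
            sample=sample,
            fragment_ids=[f"{sample}:frag{i:07d}" for i in range(n_frag)],
            gene_index=gene_index,
            origin_genome=np.concatenate(og_chunks),
            start=np.concatenate(st_chunks),
            as_a=np.concatenate(asa_chunks),
            as_b=np.concatenate(asb_chunks),
            n_div_covered=np.concatenate(div_chunks),
            reads=np.concatenate(read_chunks, axis=0),
            paralog=np.concatenate(par_chunks),
            dual=dual,
        )
    else:
        out = SampleAlignments(
            sample=sample, fragment_ids=[],
            gene_index=np.empty(0, dtype=int),
            origin_genome=np.empty(0, dtype="<U1"),
            start=np.empty(0, dtype=int), as_a=np.empty(0, dtype=int),
            as_b=np.empty(0, dtype=int), n_div_covered=np.empty(0, dtype=int),
            reads=np.empty((0, L), dtype=np.uint8),
            paralog=np.empty(0, dtype=bool), dual=dual,
        )
    return out


def bundles_from_sample(
    pair: GenomePair, sim: SampleAlignments
) -> Iterator[AlignmentBundle]:
    """Materialise AlignmentBundle objects from a simulated sample."""
    n_genes = len(pair.gene_stems)
    for i, frag in enumerate(sim.fragment_ids):
        gi = int(sim.gene_index[i])
        stem = pair.gene_stems[gi]
        pos = int(sim.start[i])
        records = []

        def add(genome: str, gene_i: int, score: int) -> None:
            records.append(
                AlignmentRecord(
                    fragment_id=frag,
                    genome=genome,
                    gene_id=f"{pair.gene_stems[gene_i]}_{genome}",
                    position=pos,
                    alignment_score=int(score),
                    reported_hits=1,  # fixed below
                )
            )

        add("A", gi, sim.as_a[i])
        if sim.dual:
            add("B", gi, sim.as_b[i])
        if sim.paralog[i]:
            ring = (gi + 1) % n_genes
            add("A", ring, sim.as_a[i])
            if sim.dual:
                add("B", ring, sim.as_b[i])
        nh = len(records)
        records = [
            AlignmentRecord(
                fragment_id=r.fragment_id, genome=r.genome, gene_id=r.gene_id,
                position=r.position, alignment_score=r.alignment_score,
                reported_hits=nh, is_secondary=(k > 0),
            )
            for k, r in enumerate(records)
        ]
        yield AlignmentBundle(fragment_id=frag, records=tuple(records))


def simulate_alignment_bundles(
    config: SimulationConfig,
    pair: GenomePair,
    counts: pd.DataFrame,
    design: Sequence[SampleSpec],
    introgressions: Optional[Mapping[str, frozenset]] = None,
    dual_genotypes: Optional[Iterable[str]] = None,
) -> Tuple[Dict[str, SampleAlignments], pd.DataFrame]:
    """Simulate fragments + candidate alignments for every sample.

    Returns per-sample SampleAlignments and a fragment truth table
    (fragment_id, sample, origin genome/gene, start, divergent sites
    covered). The number of fragments per sample equals that sample's
    rounded column sum of `counts`.
    """
    if introgressions is None:
        introgressions = {
            s.genotype: config.introgression_genes for s in design
        }
    if dual_genotypes is None:
        dual_genotypes = {
            g for g, idx in introgressions.items() if len(idx) > 0
        }
    dual_set = set(dual_genotypes)
    sims: Dict[str, SampleAlignments] = {}
    truth_rows = []
    for sample in design:
        rng = np.random.default_rng(
            [config.seed, 303, _stable_hash(sample.name)]
        )
        sim = simulate_sample_alignments(
            config, pair, counts[sample.name], sample.name,
            introgressions.get(sample.genotype, frozenset()),
            dual=sample.genotype in dual_set, rng=rng,
        )
        sims[sample.name] = sim
        truth_rows.append(
            pd.DataFrame(
                {
                    "fragment_id": sim.fragment_ids,
                    "sample": sample.name,
                    "origin_genome": sim.origin_genome,
                    "origin_gene": [
                        pair.gene_stems[g] for g in sim.gene_index
                    ],
                    "start": sim.start,
                    "n_divergent_covered": sim.n_div_covered,
                }
            )
        )
    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows else pd.DataFrame()
    )
    return sims, truth


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash (Python's hash() is salted per process)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 2147483647
    return h


def write_sample_sam(
    pair: GenomePair, sim: SampleAlignments, path: str | Path
) -> None:
    """Write a sample's alignments as a name-grouped SAM with NH/AS tags.

    Dual-genome samples get a combined header listing both genomes'
    contigs; single-genome samples list genome A only.
    """
    clen = pair.contig_length
    contigs: Dict[str, int] = {}
    for stem in pair.gene_stems:
        contigs[f"{stem}_A"] = clen
    if sim.dual:
        for stem in pair.gene_stems:
            contigs[f"{stem}_B"] = clen
    header = pysam.AlignmentHeader.from_dict(sam_header(contigs))
    tid = {name: i for i, name in enumerate(contigs)}
    n_genes = len(pair.gene_stems)
    L = sim.reads.shape[1]
    cigar = [(0, L)]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, frag in enumerate(sim.fragment_ids):
            gi = int(sim.gene_index[i])
            stem = pair.gene_stems[gi]
            pos = int(sim.start[i])
            seq = _decode(sim.reads[i])
            targets = [(f"{stem}_A", int(sim.as_a[i]))]
            if sim.dual:
                targets.append((f"{stem}_B", int(sim.as_b[i])))
            if sim.paralog[i]:
                ring = pair.gene_stems[(gi + 1) % n_genes]
                targets.append((f"{ring}_A", int(sim.as_a[i])))
                if sim.dual:
                    targets.append((f"{ring}_B", int(sim.as_b[i])))
            nh = len(targets)
            for k, (contig, score) in enumerate(targets):
                a = pysam.AlignedSegment(header=header)
                a.query_name = frag
                a.flag = 256 if k > 0 else 0
                a.reference_id = tid[contig]
                a.reference_start = pos
                a.mapping_quality = 255
                a.cigar = cigar
                if k == 0:
                    a.query_sequence = seq
                a.set_tag("NH", nh)
                a.set_tag("AS", score)
                out.write(a)


# ---------------------------------------------------------------------------
# Pathway annotation


def simulate_pathway_annotation(
    config: SimulationConfig,
    truth: Optional[TruthTable] = None,
    n_pathways: int = 20,
    annotated_fraction: float = 0.35,
    n_de_enriched: int = 2,
    de_member_fraction: float = 0.7,
) -> pd.DataFrame:
    """Gene -> pathway annotation table for both species.

    Mirrors real pathway resources where only a minority (~35%) of genes
    carry pathway annotations and homologous genes of the two species are
    annotated to identically named pathways. When a truth table is
    supplied, the first ``n_de_enriched`` pathways draw
    ``de_member_fraction`` of their members from planted-DE genes, so the
    synthetic study carries genuinely over-represented pathways for the
    enrichment stage to find. Columns: gene_id, pathway_id,
    pathway_name, species.
    """
    rng = np.random.default_rng([config.seed, 404])
    n = config.n_genes_per_genome
    stems = [f"g{i:05d}" for i in range(n)]
    annotated = rng.random(n) < annotated_fraction
    rows = []

    def add(stem: str, pw: int) -> None:
        for species, suffix in (("A", "_A"), ("B", "_B")):
            rows.append(
                {
                    "gene_id": stem + suffix,
                    "pathway_id": f"pw{pw:03d}",
                    "pathway_name": f"pathway {pw:03d}",
                    "species": species,
                }
            )

    planted: Dict[int, set] = {}
    if truth is not None and n_de_enriched > 0:
        de_stems = list(truth.genes.loc[truth.genes["is_de"], "gene_stem"])
        other = list(truth.genes.loc[~truth.genes["is_de"], "gene_stem"])
        for pw in range(min(n_de_enriched, n_pathways)):
            size = min(30, max(5, len(de_stems) // 2))
            n_de = int(round(de_member_fraction * size))
            members = list(
                rng.choice(de_stems, size=min(n_de, len(de_stems)), replace=False)
            ) + list(
                rng.choice(other, size=min(size - n_de, len(other)), replace=False)
            )
            planted[pw] = set(members)
            for stem in members:
                add(stem, pw)

    planted_stems = set().union(*planted.values()) if planted else set()
    free_pathways = [
        pw for pw in range(n_pathways) if pw not in planted
    ] or list(range(n_pathways))
    for i, stem in enumerate(stems):
        if not annotated[i] or stem in planted_stems:
            continue
        k = int(rng.integers(1, 4))
        pws = rng.choice(
            free_pathways, size=min(k, len(free_pathways)), replace=False
        )
        for pw in pws:
            add(stem, int(pw))
    return pd.DataFrame(rows).drop_duplicates(
        subset=["gene_id", "pathway_id", "species"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct_table(
    config: SimulationConfig,
    expression: pd.DataFrame,
    reference_gene: str,
    design: Sequence[SampleSpec],
    genes: Optional[Sequence[str]] = None,
    n_technical: int = 3,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table.

    Ct model: Ct = c0 - log2(expression) + Normal(0, sigma) per technical
    replicate. The reference gene must have nonzero expression in every
    sample; zero-expression target wells are capped at ``ct_max`` and
    flagged in the ``capped`` column rather than dropped.
    """
    if reference_gene not in expression.index:
        raise ConfigurationError(f"reference gene {reference_gene!r} absent")
    ref = expression.loc[reference_gene]
    if (ref <= 0).any():
        raise ConfigurationError(
            f"reference gene {reference_gene!r} has zero expression in "
            f"samples {list(ref.index[ref <= 0])}"
        )
    if genes is None:
        genes = list(expression.index)
    rng = np.random.default_rng([config.seed, 505])
    rows = []
    for sample in design:
        for gene in genes:
            expr = float(expression.at[gene, sample.name])
            capped = expr <= 0
            base_ct = (
                config.ct_max if capped
                else config.ct_intercept - np.log2(expr)
            )
            noise = (
                rng.normal(0.0, config.ct_sigma, size=n_technical)
                if config.ct_sigma > 0 else np.zeros(n_technical)
            )
            for t in range(n_technical):
                ct = min(base_ct + noise[t], config.ct_max)
                rows.append(
                    {
                        "genotype": sample.genotype,
                        "condition": sample.condition,
                        "biological_replicate": sample.replicate,
                        "gene": gene,
                        "technical_replicate": t + 1,
                        "Ct": ct,
                        "capped": capped,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full-study writer


def write_study(
    config: SimulationConfig,
    outdir: str | Path,
    design: Optional[Sequence[SampleSpec]] = None,
    introgressions: Optional[Mapping[str, frozenset]] = None,
) -> Dict[str, object]:
    """Generate and write every input the pipeline consumes.

    FASTA per genome, GTF per genome, name-grouped SAM per sample,
    count/truth TSVs, pathway annotation TSV, and a qPCR Ct TSV.
    Returns the in-memory objects for direct pipeline use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = study_design(config)
    if introgressions is None:
        introgressions = default_introgressions(config)

    pair = make_genome_pair(config)
    write_fasta(pair.sequences("A"), outdir / "genome_A.fasta")
    write_fasta(pair.sequences("B"), outdir / "genome_B.fasta")
    write_gtf(pair.gene_models("A"), outdir / "genes_A.gtf")
    write_gtf(pair.gene_models("B"), outdir / "genes_B.gtf")

    counts, truth = simulate_counts(config, design)
    counts.to_csv(outdir / "true_counts.tsv", sep="\t")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    sims, frag_truth = simulate_alignment_bundles(
        config, pair, counts, design, introgressions
    )
    truth.fragments = frag_truth
    frag_truth.to_csv(outdir / "truth_fragments.tsv", sep="\t", index=False)
    for sample in design:
        write_sample_sam(pair, sims[sample.name], outdir / f"{sample.name}.sam")

    annotation = simulate_pathway_annotation(config, truth)
    annotation.to_csv(outdir / "pathways.tsv", sep="\t", index=False)

    ct = simulate_ct_table(
        config, counts, _pick_reference_gene(counts, truth), design,
        genes=_pick_panel_genes(counts, truth),
    )
    ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)

    return {
        "design": design,
        "introgressions": introgressions,
        "pair": pair,
        "counts": counts,
        "truth": truth,
        "sims": sims,
        "annotation": annotation,
        "ct": ct,
    }


def _pick_reference_gene(counts: pd.DataFrame, truth: TruthTable) -> str:
    """Actin stand-in: highly expressed non-DE gene with no zero sample."""
    stable = truth.genes.loc[~truth.genes["is_de"], "gene_stem"]
    sub = counts.loc[stable]
    sub = sub[(sub > 0).all(axis=1)]
    return str(sub.sum(axis=1).idxmax())


def _pick_panel_genes(
    counts: pd.DataFrame, truth: TruthTable, n: int = 14
) -> List[str]:
    """Validation panel: mostly planted-DE genes plus stable fillers."""
    expressed = counts.index[(counts > 0).all(axis=1)]
    de = [
        g for g in truth.genes.loc[truth.genes["is_de"], "gene_stem"]
        if g in set(expressed)
    ]
    non_de = [
        g for g in truth.genes.loc[~truth.genes["is_de"], "gene_stem"]
        if g in set(expressed)
    ]
    panel = de[: max(0, n - 5)] + non_de[: n - len(de[: max(0, n - 5)])]
    return panel[:n]
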