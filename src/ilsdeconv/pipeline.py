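"""End-to-end orchestration of the synthetic dual-genome study.

Chains the seven stages: synthetic data -> species-of-origin partition ->
EM quantification -> differential expression (five pair-wise contrasts) ->
pathway enrichment (separate and merged modes) -> qPCR ddCt validation ->
figure tables. All outputs are plain text under the run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, qpcr, report, syndata
from .config import SimulationConfig
from .partition import SubsetLabel, classify_bundle, partition_bundles, select_retained_records
from .quantify import (
    AssignmentSet,
    GeneIntervals,
    assign_fragments,
    em_expected_counts,
    merge_subset_counts,
)

logger = logging.getLogger("ilsdeconv")


@dataclass
class StudyResult:
    config: SimulationConfig
    design: List[syndata.SampleSpec]
    counts: Dict[str, pd.DataFrame]
    partition_summaries: Dict[str, Dict]
    de_tables: Dict[str, pd.DataFrame]
    de_summary: pd.DataFrame
    enrichment_results: Dict[str, pd.DataFrame]
    venn: pd.DataFrame
    qpcr_panel: pd.DataFrame
    truth: syndata.TruthTable
    annotation: pd.DataFrame


def quantify_sample_subsets(
    pair: syndata.GenomePair,
    sim: syndata.SampleAlignments,
    intervals_a: GeneIntervals,
    intervals_b: GeneIntervals,
    read_length: int,
    pure_species_mode: bool,
) -> Tuple[Dict[str, pd.Series], Dict[str, int], Dict[str, float]]:
    """Partition one sample's bundles and quantify each subset.

    Returns ({subset: expected counts}, {subset: unassigned}, fractions).
    """
    bundles = syndata.bundles_from_sample(pair, sim)
    parts, summary = partition_bundles(bundles, pure_species_mode)
    gene_ids_a = [f"{s}_A" for s in pair.gene_stems]
    gene_ids_b = [f"{s}_B" for s in pair.gene_stems]
    counts: Dict[str, pd.Series] = {}
    unassigned: Dict[str, int] = {}
    for label, gene_ids, intervals in (
        ("SLYC", gene_ids_a, intervals_a),
        ("PENN", gene_ids_b, intervals_b),
        ("AMBI", gene_ids_b, intervals_b),
    ):
        retained = [
            select_retained_records(b, SubsetLabel(label))
            for b in parts[label]
        ]
        retained = [r for r in retained if r]
        aset = assign_fragments(retained, intervals, read_length)
        counts[label] = em_expected_counts(aset, gene_ids=gene_ids)
        unassigned[label] = aset.n_unassigned
    return counts, unassigned, summary.fractions


def run_study(
    config: SimulationConfig,
    outdir: str | Path,
    ambi_policy: str = "sum",
    fdr: float = 0.05,
    render_figures: bool = True,
    write_inputs: bool = False,
) -> StudyResult:
    """Run the whole synthetic study and write results under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = syndata.study_design(config)
    introgressions = syndata.default_introgressions(config)

    logger.info("simulating genomes and counts")
    pair = syndata.make_genome_pair(config)
    counts_true, truth = syndata.simulate_counts(config, design)
    sims, frag_truth = syndata.simulate_alignment_bundles(
        config, pair, counts_true, design, introgressions
    )
    truth.fragments = frag_truth
    annotation = syndata.simulate_pathway_annotation(config, truth)
    if write_inputs:
        syndata.write_study(config, outdir / "inputs", design, introgressions)

    intervals_a = GeneIntervals.from_models(pair.gene_models("A"))
    intervals_b = GeneIntervals.from_models(pair.gene_models("B"))

    logger.info("partitioning and quantifying %d samples", len(design))
    matrices: Dict[str, Dict[str, pd.Series]] = {}
    part_summaries: Dict[str, Dict] = {}
    for sample in design:
        pure = len(introgressions.get(sample.genotype, ())) == 0
        subset_counts, unassigned, fractions = quantify_sample_subsets(
            pair, sims[sample.name], intervals_a, intervals_b,
            config.read_length, pure_species_mode=pure,
        )
        matrices[sample.name] = subset_counts
        part_summaries[sample.name] = {
            "fractions": fractions, "unassigned": unassigned,
        }

    def subset_matrix(genotype: str, label: str) -> pd.DataFrame:
        cols = [s.name for s in design if s.genotype == genotype]
        return pd.DataFrame({c: matrices[c][label] for c in cols})

    count_matrices: Dict[str, pd.DataFrame] = {}
    for genotype in syndata.GENOTYPES:
        slyc = subset_matrix(genotype, "SLYC")
        if len(introgressions.get(genotype, ())) == 0:
            count_matrices[f"{genotype}:A"] = slyc
        else:
            count_matrices[f"{genotype}:A"] = slyc
            merged = merge_subset_counts(
                subset_matrix(genotype, "PENN"),
                subset_matrix(genotype, "AMBI"),
                policy=ambi_policy,
            )
            if ambi_policy == "separate":
                merged = merged[0]
            count_matrices[f"{genotype}:B"] = merged

    contrasts = []
    for key, matrix in count_matrices.items():
        genotype = key.split(":")[0]
        groups = [
            s.condition for s in design
            if s.genotype == genotype
        ]
        contrasts.append(
            diffexpr.ContrastSpec(
                name=key, counts=matrix, groups=groups,
                contrast=("control", "parasitized"),
            )
        )

    logger.info("differential expression for %d contrasts", len(contrasts))
    de_tables, de_summary = diffexpr.run_contrasts(contrasts, fdr=fdr)

    logger.info("pathway enrichment")
    enrich_results: Dict[str, pd.DataFrame] = {}
    for genotype in ("IL6-2", "IL6-3"):
        separate = enrichment.enrich_separate(
            {
                "A": de_tables[f"{genotype}:A"],
                "B": de_tables[f"{genotype}:B"],
            },
            annotation, fdr=fdr,
        )
        enrich_results[f"{genotype}:A"] = separate["A"]
        enrich_results[f"{genotype}:B"] = separate["B"]
        enrich_results[f"{genotype}:merged"] = enrichment.enrich_merged(
            {
                "A": de_tables[f"{genotype}:A"],
                "B": de_tables[f"{genotype}:B"],
            },
            annotation, fdr=fdr,
        )
    venn, tops = enrichment.summarize_overlap(
        {
            k: v for k, v in enrich_results.items()
            if not k.endswith(":merged")
        }
    )

    logger.info("qPCR validation panel")
    reference = syndata._pick_reference_gene(counts_true, truth)
    panel_genes = syndata._pick_panel_genes(counts_true, truth)
    ct = syndata.simulate_ct_table(
        config, counts_true, reference, design,
        genes=panel_genes + [reference],
    )
    collapsed = qpcr.technical_collapse(ct)
    panel = qpcr.summarize_panel(
        collapsed, reference, panel_genes, list(syndata.GENOTYPES), alpha=fdr
    )

    logger.info("writing outputs")
    _write_outputs(
        outdir, count_matrices, part_summaries, de_tables, de_summary,
        enrich_results, venn, tops, panel, render_figures, fdr, contrasts,
    )

    return StudyResult(
        config=config, design=design, counts=count_matrices,
        partition_summaries=part_summaries, de_tables=de_tables,
        de_summary=de_summary, enrichment_results=enrich_results,
        venn=venn, qpcr_panel=panel, truth=truth, annotation=annotation,
    )


def _write_outputs(
    outdir: Path,
    count_matrices: Mapping[str, pd.DataFrame],
    part_summaries: Mapping[str, Dict],
    de_tables: Mapping[str, pd.DataFrame],
    de_summary: pd.DataFrame,
    enrich_results: Mapping[str, pd.DataFrame],
    venn: pd.DataFrame,
    tops: Mapping[str, pd.DataFrame],
    panel: pd.DataFrame,
    render_figures: bool,
    fdr: float,
    contrasts: Sequence[diffexpr.ContrastSpec],
) -> None:
    (outdir / "counts").mkdir(exist_ok=True)
    for key, matrix in count_matrices.items():
        matrix.to_csv(
            outdir / "counts" / f"counts_{key.replace(':', '_')}.tsv", sep="\t"
        )
    with open(outdir / "partition_summary.json", "w") as fh:
        json.dump(part_summaries, fh, indent=2)

    (outdir / "de").mkdir(exist_ok=True)
    for key, table in de_tables.items():
        table.to_csv(outdir / "de" / f"de_{key.replace(':', '_')}.tsv", sep="\t")
    de_summary.to_csv(outdir / "de" / "deg_summary.tsv", sep="\t", index=False)

    (outdir / "enrichment").mkdir(exist_ok=True)
    for key, table in enrich_results.items():
        table.to_csv(
            outdir / "enrichment" / f"enrich_{key.replace(':', '_')}.tsv",
            sep="\t", index=False,
        )
    venn.to_csv(outdir / "enrichment" / "venn_summary.tsv", sep="\t", index=False)
    with open(outdir / "enrichment" / "venn_summary.json", "w") as fh:
        json.dump(venn.to_dict(orient="records"), fh, indent=2)
    for key, table in tops.items():
        table.to_csv(
            outdir / "enrichment" / f"top20_{key.replace(':', '_')}.tsv",
            sep="\t", index=False,
        )

    panel.to_csv(outdir / "qpcr_panel.tsv", sep="\t", index=False)

    figures = outdir / "figures"
    figures.mkdir(exist_ok=True)
    bars = report.deg_count_bars(de_tables, fdr=fdr)
    bars.to_csv(figures / "deg_counts.tsv", sep="\t", index=False)
    spec = report.VolcanoSpec(fdr_threshold=fdr)
    by_name = {c.name: c for c in contrasts}
    for key, table in de_tables.items():
        stem = key.replace(":", "_")
        classes = report.volcano_classify(table, spec)
        volcano = table.assign(volcano_class=classes)
        volcano.to_csv(figures / f"volcano_{stem}.tsv", sep="\t")
        c = by_name[key]
        try:
            norm = diffexpr.tmm_factors(c.counts.loc[table.index])
            hm, meta = report.top50_heatmap_matrix(
                table, c.counts.loc[table.index], norm, c.groups, fdr=fdr
            )
            hm.to_csv(figures / f"heatmap_top50_{stem}.tsv", sep="\t")
        except ValueError:
            hm = None
        if render_figures:
            report.render_volcano(
                table, spec, figures / f"volcano_{stem}.png", key
            )
            if hm is not None:
                report.render_heatmap(
                    hm, figures / f"heatmap_top50_{stem}.png", key
                )
    if render_figures:
        report.render_deg_bars(bars, figures / "deg_counts.png")
        for row in venn.itertuples():
            report.render_venn2(
                row.unique_a, row.shared, row.unique_b,
                row.set_a, row.set_b,
                figures / f"venn_{row.set_a.replace(':', '_')}_vs_"
                f"{row.set_b.replace(':', '_')}.png",
                "significant pathways",
            )
        for key, table in tops.items():
            report.render_top_pathways(
                table,
                figures / f"top20_{key.replace(':', '_')}.png",
                key,
            )
        report.render_qpcr_panel(panel, figures / "qpcr_panel.png")
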