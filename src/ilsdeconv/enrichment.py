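"""Pathway over-representation analysis of DE gene sets.

Two approaches mirror the absence of a standard for hybrid material:
*separate* — each species' DE genes tested against that species' own
annotated universe; *merged* — per pathway, the two species' member lists
are concatenated (cross-species duplicates deliberately retained, since
homology links between the two annotation namespaces are unavailable in
real data) and a single test is run per introgression line.

The test is the one-sided hypergeometric upper tail on an annotated-genes
universe, BH-adjusted across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class EnrichmentError(ValueError):
    pass


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise EnrichmentError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class AnnotationIndex:
    """Pathway membership restricted to one universe of annotated genes."""

    members: Dict[str, List[str]]  # pathway_id -> member gene ids (list: duplicates allowed)
    names: Dict[str, str]
    universe: List[str]


def build_annotation_index(
    annotation: pd.DataFrame,
    species: Optional[str] = None,
    merged: bool = False,
) -> AnnotationIndex:
    """Index a (gene_id, pathway_id, pathway_name, species) table.

    species selects one species' annotations; merged concatenates both
    species' members per pathway without cross-species deduplication (the
    universe likewise concatenates both annotated gene lists, so a gene
    annotated in both species contributes two universe entries).
    """
    if species is not None and merged:
        raise EnrichmentError("choose either one species or merged, not both")
    df = annotation
    if species is not None:
        df = df[df["species"] == species]
    # membership is unique per (gene, species, pathway); merged mode keeps
    # cross-species duplicates of the same gene stem as separate entries
    df = df.drop_duplicates(subset=["gene_id", "species", "pathway_id"])
    members: Dict[str, List[str]] = {}
    names: Dict[str, str] = {}
    for row in df.itertuples():
        members.setdefault(row.pathway_id, []).append(row.gene_id)
        names[row.pathway_id] = row.pathway_name
    members = {pw: sorted(g) for pw, g in members.items()}
    uni_df = df.drop_duplicates(subset=["gene_id", "species"])
    universe = sorted(uni_df["gene_id"])
    return AnnotationIndex(members=members, names=names, universe=universe)


def hypergeom_enrich(
    de_genes: Iterable[str],
    index: AnnotationIndex,
    approach: str,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    The universe is the annotated gene list; DE genes outside it are
    excluded (they carry no pathway information). Pathways with no
    members are skipped. Returns one row per tested pathway with N, K,
    n, k, p and BH-adjusted p.
    """
    universe = index.universe
    uni_counts = pd.Series(universe).value_counts()
    de_set = set(de_genes)
    de_in_universe = [g for g in uni_counts.index if g in de_set]
    # multiplicity-aware: a gene duplicated in a merged universe
    # contributes its multiplicity to both N and (if DE) n and k
    N = len(universe)
    n = int(uni_counts.loc[de_in_universe].sum()) if de_in_universe else 0
    rows = []
    for pw, members in sorted(index.members.items()):
        K = len(members)
        if K == 0:
            continue
        k = sum(1 for g in members if g in de_set)
        rows.append(
            {
                "pathway_id": pw,
                "pathway_name": index.names.get(pw, pw),
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": hypergeom_pvalue(N, K, n, k),
                "approach": approach,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def de_gene_set(de_table: pd.DataFrame, fdr: float = 0.05) -> List[str]:
    """Genes significant at the FDR threshold, both directions pooled."""
    return list(de_table.index[de_table["FDR"] < fdr])


def enrich_separate(
    de_tables: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    fdr: float = 0.05,
) -> Dict[str, pd.DataFrame]:
    """Per-species enrichment: independent universes and BH corrections.

    de_tables maps species tag ("A"/"B") to that species' DE table.
    """
    out: Dict[str, pd.DataFrame] = {}
    for species, table in de_tables.items():
        index = build_annotation_index(annotation, species=species)
        genes = de_gene_set(table, fdr)
        unannotated = [g for g in genes if g not in set(index.universe)]
        result = hypergeom_enrich(
            genes, index, approach=f"separate:{species}"
        )
        if not result.empty:
            result.attrs["n_unannotated_de"] = len(unannotated)
        out[species] = result
    return out


def enrich_merged(
    de_tables: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    fdr: float = 0.05,
    dedup_by_stem: bool = False,
) -> pd.DataFrame:
    """Merged-gene-set enrichment: one test per pathway per line.

    Pathway members from both species are concatenated without
    cross-species deduplication; the universe concatenates both species'
    annotated gene lists. A pathway annotated in only one species is
    tested with that species' members alone.

    dedup_by_stem collapses homologous members sharing an ID stem
    (``<stem>_A`` / ``<stem>_B``) — usable on synthetic data where the
    homology link is known; off by default to reproduce the realistic
    duplicated-member behaviour.
    """
    if dedup_by_stem:
        annotation = annotation.assign(
            gene_id=annotation["gene_id"].str.replace(
                r"_(A|B)$", "", regex=True
            ),
            species="merged",
        )
    index = build_annotation_index(annotation, merged=True)
    genes: List[str] = []
    for table in de_tables.values():
        genes.extend(de_gene_set(table, fdr))
    if dedup_by_stem:
        genes = [g[:-2] if g.endswith(("_A", "_B")) else g for g in genes]
    return hypergeom_enrich(genes, index, approach="merged")


def significant_pathways(result: pd.DataFrame, alpha: float = 0.05) -> Set[str]:
    if result.empty:
        return set()
    return set(result.loc[result["adj_p"] < alpha, "pathway_id"])


def summarize_overlap(
    results: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    top_n: int = 20,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Venn counts of significant pathways across result sets + top-N tables.

    Returns (venn frame with unique/shared counts per pair of result
    sets, {set name: top-N table ordered by adjusted p, ties broken by
    raw p then pathway_id}).
    """
    sig = {name: significant_pathways(res, alpha) for name, res in results.items()}
    names = list(results)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "unique_a": len(sig[a] - sig[b]),
                    "shared": len(sig[a] & sig[b]),
                    "unique_b": len(sig[b] - sig[a]),
                }
            )
    venn = pd.DataFrame(rows)
    tops: Dict[str, pd.DataFrame] = {}
    for name, res in results.items():
        if res.empty:
            tops[name] = res
            continue
        ordered = res.sort_values(
            ["adj_p", "p_value", "pathway_id"], kind="mergesort"
        )
        tops[name] = ordered.head(top_n).reset_index(drop=True)
    return venn, tops
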