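"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA and GTF writers cover the synthetic genomes (one gene per contig,
single-exon gene models, 1-based inclusive GTF coordinates). SAM I/O goes
through pysam. Count matrices, truth tables, annotations and Ct tables are
TSVs handled with pandas.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, Mapping

import pandas as pd

_GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]
_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as uncompressed FASTA, wrapped to `width` columns."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    sequences: Dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_gtf(gene_models: pd.DataFrame, path: str | Path) -> None:
    """Write single-exon gene models as GTF.

    `gene_models` columns: contig, gene_id, start0 (0-based), end (exclusive).
    GTF is written 1-based inclusive.
    """
    with open(path, "w") as fh:
        for row in gene_models.itertuples():
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}.1";'
            for feature in ("gene", "exon"):
                fh.write(
                    f"{row.contig}\tilsdeconv\t{feature}\t{row.start0 + 1}\t"
                    f"{row.end}\t.\t+\t.\t{attrs}\n"
                )


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GTF into (contig, gene_id, start0, end).

    Only `gene` rows are used; coordinates are converted to 0-based
    half-open. Minimal by design: the pipeline's gene models are
    single-exon and the only attribute consumed is gene_id.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    genes = df[df["feature"] == "gene"].copy()
    ids = genes["attribute"].str.extract(_GENE_ID_RE.pattern, expand=False)
    if ids.isna().any():
        bad = genes.index[ids.isna()][0]
        raise ValueError(f"GTF gene row without gene_id attribute (row {bad})")
    out = pd.DataFrame({
        "contig": genes["seqname"].to_numpy(),
        "gene_id": ids.to_numpy(),
        "start0": genes["start"].to_numpy() - 1,
        "end": genes["end"].to_numpy(),
    })
    return out.reset_index(drop=True)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sam_header(contig_lengths: Mapping[str, int]) -> Dict:
    """pysam-style header dict listing every contig of the reference set."""
    return {
        "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }


def iter_fasta_lengths(sequences: Mapping[str, str]) -> Dict[str, int]:
    return {name: len(seq) for name, seq in sequences.items()}
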