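"""Simulation configuration for the synthetic dual-genome study.

The synthetic study emulates an introgression-line (IL) RNA-seq experiment:
a cultivated-species genome (genome A), a diverged wild-relative genome
(genome B), ILs carrying one homozygous interval of B alleles in an A
background, and control vs. parasitized root samples sequenced in
biological triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    seed:
        Master RNG seed. Identical config + seed gives bit-identical outputs.
    n_genes_per_genome:
        Number of homologous gene pairs. Each gene lives on its own contig
        with ``flank`` bp of intergenic sequence on either side.
    gene_length:
        Gene body length in bp (unspliced, single-isoform).
    divergence_rate:
        Per-bp substitution rate between genomes A and B. Must lie in
        [0, 0.25]; 0.02 reflects the ~2% coding divergence of congeneric
        tomato relatives.
    introgression_genes:
        Gene indices whose alleles are replaced by genome-B sequence in the
        IL genotype.
    n_replicates:
        Biological replicates per (genotype, condition); the study design
        uses 3 control + 3 parasitized plants per genotype.
    library_size_mean:
        Expected sequenced fragments per sample.
    nb_dispersion:
        Negative-binomial dispersion phi of true counts.
    de_fraction:
        Fraction of genes with a planted condition effect.
    de_log2fc:
        Planted |log2 fold change| of DE genes.
    read_length:
        Fragment read length in nt.
    error_rate:
        Per-base sequencing substitution error rate, in [0, 0.05).
    mismatch_penalty:
        Alignment-score penalty per mismatch; AS = matches - penalty * mismatches.
    paralog_fraction:
        Fraction of fragments that additionally multi-map to a paralog gene
        within the same genome (equal AS), exercising EM resolution.
    flank:
        Intergenic bp on each side of a gene body on its contig.
    ct_intercept:
        qPCR model intercept c0 in Ct = c0 - log2(expression) + N(0, sigma).
    ct_sigma:
        Technical Ct noise SD in cycles.
    ct_max:
        Ct cap reported for zero-expression wells.
    """

    seed: int = 0
    n_genes_per_genome: int = 500
    gene_length: int = 1000
    divergence_rate: float = 0.02
    introgression_genes: FrozenSet[int] = field(default_factory=frozenset)
    n_replicates: int = 3
    library_size_mean: float = 20_000.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    read_length: int = 150
    error_rate: float = 0.001
    mismatch_penalty: int = 2
    paralog_fraction: float = 0.0
    flank: int = 100
    ct_intercept: float = 30.0
    ct_sigma: float = 0.2
    ct_max: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence_rate <= 0.25):
            raise ConfigurationError(
                f"divergence_rate must be in [0, 0.25], got {self.divergence_rate}"
            )
        if not (0.0 <= self.error_rate < 0.05):
            raise ConfigurationError(
                f"error_rate must be in [0, 0.05), got {self.error_rate}"
            )
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigurationError(
                f"de_fraction must be in [0, 1], got {self.de_fraction}"
            )
        if self.n_genes_per_genome < 1:
            raise ConfigurationError("n_genes_per_genome must be >= 1")
        if self.gene_length <= self.read_length:
            raise ConfigurationError(
                f"gene_length ({self.gene_length}) must exceed read_length "
                f"({self.read_length})"
            )
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not (0.0 <= self.paralog_fraction <= 1.0):
            raise ConfigurationError("paralog_fraction must be in [0, 1]")
        bad = {
            g for g in self.introgression_genes
            if not (0 <= g < self.n_genes_per_genome)
        }
        if bad:
            raise ConfigurationError(
                f"introgression_genes outside [0, {self.n_genes_per_genome}): "
                f"{sorted(bad)}"
            )
        # frozen dataclass: normalise to frozenset through __setattr__ bypass
        object.__setattr__(
            self, "introgression_genes", frozenset(self.introgression_genes)
        )

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)
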