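"""Synthetic-data generator: genome pair, counts, fragments, Ct tables."""

import numpy as np
import pandas as pd
import pytest

from ilsdeconv import syndata
from ilsdeconv.config import ConfigurationError, SimulationConfig
from ilsdeconv.partition import classify_bundle, partition_bundles


class TestGenomePair:
    def test_zero_divergence_gives_identical_genomes(self):
        cfg = SimulationConfig(seed=1, n_genes_per_genome=10, divergence_rate=0.0)
        pair = syndata.make_genome_pair(cfg)
        for stem in pair.gene_stems:
            assert np.array_equal(pair.genome_a[stem], pair.genome_b[stem])
            assert pair.divergent_sites[stem].size == 0

    def test_genomes_differ_exactly_at_divergent_sites(self, genome_pair):
        for stem in genome_pair.gene_stems:
            diff = np.flatnonzero(
                genome_pair.genome_a[stem] != genome_pair.genome_b[stem]
            )
            assert np.array_equal(diff, genome_pair.divergent_sites[stem])

    def test_divergence_count_within_binomial_band(self):
        cfg = SimulationConfig(
            seed=3, n_genes_per_genome=50, gene_length=1000, flank=0,
            divergence_rate=0.02,
        )
        pair = syndata.make_genome_pair(cfg)
        mean_sites = np.mean(
            [pair.divergent_sites[s].size for s in pair.gene_stems]
        )
        expect = 0.02 * 1000
        sd = np.sqrt(1000 * 0.02 * 0.98 / 50)
        assert abs(mean_sites - expect) < 3 * sd

    def test_excessive_divergence_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(divergence_rate=0.3)

    def test_excessive_error_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(error_rate=0.05)

    def test_determinism_bit_identical(self, small_config):
        a = syndata.make_genome_pair(small_config)
        b = syndata.make_genome_pair(small_config)
        assert a.sequences("A") == b.sequences("A")
        assert a.sequences("B") == b.sequences("B")


class TestCounts:
    def test_no_planted_de_means_zero_true_lfc(self, two_group_design):
        cfg = SimulationConfig(seed=2, n_genes_per_genome=100, de_fraction=0.0)
        _, truth = syndata.simulate_counts(cfg, two_group_design)
        assert (truth.genes["true_log2fc"] == 0).all()
        assert not truth.genes["is_de"].any()

    def test_de_gene_count_matches_fraction(self, two_group_design):
        cfg = SimulationConfig(seed=2, n_genes_per_genome=500, de_fraction=0.1)
        _, truth = syndata.simulate_counts(cfg, two_group_design)
        assert truth.genes["is_de"].sum() == 50

    def test_library_sums_near_target(self, two_group_design):
        cfg = SimulationConfig(
            seed=4, n_genes_per_genome=500, library_size_mean=50_000.0,
        )
        counts, _ = syndata.simulate_counts(cfg, two_group_design)
        # NB column-sum SD bound, conservative via mu + phi*mu^2
        assert (abs(counts.sum(axis=0) - 50_000) < 0.15 * 50_000).all()

    def test_poisson_limit_variance_over_mean_near_one(self, two_group_design):
        cfg = SimulationConfig(
            seed=5, n_genes_per_genome=10_000, nb_dispersion=0.0,
            de_fraction=0.0, library_size_mean=10_000_000.0,
        )
        counts, _ = syndata.simulate_counts(cfg, two_group_design)
        y = counts.to_numpy()
        ratio = y.var(axis=1, ddof=1) / np.maximum(y.mean(axis=1), 1e-9)
        # per-gene ratios are chi2-noisy at 6 samples; their average is tight
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_single_replicate_condition_rejected(self):
        design = [
            syndata.SampleSpec("c1", "Formula", "control", 1),
            syndata.SampleSpec("c2", "Formula", "control", 2),
            syndata.SampleSpec("p1", "Formula", "parasitized", 1),
        ]
        with pytest.raises(ConfigurationError, match="2 replicates"):
            syndata.simulate_counts(SimulationConfig(seed=1), design)


@pytest.fixture(scope="module")
def sim_setup():
    cfg = SimulationConfig(
        seed=11, n_genes_per_genome=40, gene_length=400,
        library_size_mean=2000.0, error_rate=0.0,
        introgression_genes=frozenset(range(10)),
    )
    pair = syndata.make_genome_pair(cfg)
    design = [
        syndata.SampleSpec(f"s{i}", "IL", c, i % 3 + 1)
        for i, c in enumerate(["control"] * 3 + ["parasitized"] * 3)
    ]
    counts, _ = syndata.simulate_counts(cfg, design)
    sims, truth = syndata.simulate_alignment_bundles(
        cfg, pair, counts, design,
        introgressions={"IL": cfg.introgression_genes},
    )
    return cfg, pair, design, counts, sims, truth


class TestAlignmentSimulation:

    def test_fragment_conservation(self, sim_setup):
        cfg, pair, design, counts, sims, truth = sim_setup
        for sample in design:
            expected = int(counts[sample.name].round().sum())
            assert len(sims[sample.name]) == expected

    def test_every_fragment_appears_once_in_truth(self, sim_setup):
        *_, truth = sim_setup
        assert truth["fragment_id"].is_unique

    def test_no_divergent_site_no_error_ties_scores(self, sim_setup):
        cfg, pair, design, counts, sims, truth = sim_setup
        sim = sims[design[0].name]
        zero_cov = sim.n_div_covered == 0
        assert zero_cov.any()
        assert np.array_equal(sim.as_a[zero_cov], sim.as_b[zero_cov])

    def test_origin_b_with_divergent_coverage_scores_higher_on_b(self, sim_setup):
        cfg, pair, design, counts, sims, truth = sim_setup
        sim = sims[design[0].name]
        mask = (sim.origin_genome == "B") & (sim.n_div_covered >= 1)
        assert mask.any()
        assert (sim.as_b[mask] > sim.as_a[mask]).all()

    def test_divergent_overlap_fraction_monotone_in_divergence(self):
        fracs = []
        for rate in (0.005, 0.02, 0.05):
            cfg = SimulationConfig(
                seed=13, n_genes_per_genome=40, gene_length=400,
                library_size_mean=2000.0, divergence_rate=rate,
            )
            pair = syndata.make_genome_pair(cfg)
            design = [
                syndata.SampleSpec("s0", "X", "control", 1),
                syndata.SampleSpec("s1", "X", "control", 2),
                syndata.SampleSpec("s2", "X", "parasitized", 1),
                syndata.SampleSpec("s3", "X", "parasitized", 2),
            ]
            counts, _ = syndata.simulate_counts(cfg, design)
            sims, _ = syndata.simulate_alignment_bundles(
                cfg, pair, counts, design,
                introgressions={"X": frozenset()},
                dual_genotypes={"X"},
            )
            sim = sims["s0"]
            fracs.append((sim.n_div_covered > 0).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_determinism_identical_sam_bytes(self, tmp_path):
        cfg = SimulationConfig(
            seed=21, n_genes_per_genome=10, gene_length=300,
            library_size_mean=300.0,
        )
        pair = syndata.make_genome_pair(cfg)
        design = [
            syndata.SampleSpec("s0", "F", "control", 1),
            syndata.SampleSpec("s1", "F", "control", 2),
            syndata.SampleSpec("s2", "F", "parasitized", 1),
            syndata.SampleSpec("s3", "F", "parasitized", 2),
        ]
        counts, _ = syndata.simulate_counts(cfg, design)
        outs = []
        for tag in ("x", "y"):
            sims, _ = syndata.simulate_alignment_bundles(
                cfg, pair, counts, design,
                introgressions={"F": frozenset()}, dual_genotypes={"F"},
            )
            path = tmp_path / f"{tag}.sam"
            syndata.write_sample_sam(pair, sims["s0"], path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_paralog_fraction_adds_within_genome_multimapping(self):
        cfg = SimulationConfig(
            seed=31, n_genes_per_genome=10, gene_length=300,
            library_size_mean=500.0, paralog_fraction=1.0,
        )
        pair = syndata.make_genome_pair(cfg)
        design = [
            syndata.SampleSpec("s0", "F", "control", 1),
            syndata.SampleSpec("s1", "F", "control", 2),
            syndata.SampleSpec("s2", "F", "parasitized", 1),
            syndata.SampleSpec("s3", "F", "parasitized", 2),
        ]
        counts, _ = syndata.simulate_counts(cfg, design)
        sims, _ = syndata.simulate_alignment_bundles(
            cfg, pair, counts, design,
            introgressions={"F": frozenset()}, dual_genotypes={"F"},
        )
        bundle = next(syndata.bundles_from_sample(pair, sims["s0"]))
        genes_on_a = {r.gene_id for r in bundle.records if r.genome == "A"}
        assert len(genes_on_a) == 2  # homolog + ring paralog


@pytest.fixture(scope="module")
def design4():
    return [
        syndata.SampleSpec("c1", "F", "control", 1),
        syndata.SampleSpec("c2", "F", "control", 2),
        syndata.SampleSpec("p1", "F", "parasitized", 1),
        syndata.SampleSpec("p2", "F", "parasitized", 2),
    ]


class TestCtTable:

    def test_halved_expression_raises_ct_by_one(self, design4):
        cfg = SimulationConfig(seed=1, ct_sigma=0.0)
        expr = pd.DataFrame(
            {"c1": [100.0, 100.0], "c2": [100.0, 100.0],
             "p1": [50.0, 100.0], "p2": [50.0, 100.0]},
            index=["target", "ref"],
        )
        ct = syndata.simulate_ct_table(cfg, expr, "ref", design4)
        tgt = ct[ct["gene"] == "target"].groupby("condition")["Ct"].mean()
        assert tgt["parasitized"] - tgt["control"] == pytest.approx(1.0)

    def test_zero_sigma_identical_technical_replicates(self, design4):
        cfg = SimulationConfig(seed=1, ct_sigma=0.0)
        expr = pd.DataFrame(
            {s.name: [64.0, 32.0] for s in design4}, index=["a", "ref"]
        )
        ct = syndata.simulate_ct_table(cfg, expr, "ref", design4)
        spread = ct.groupby(["gene", "condition", "biological_replicate"])["Ct"].std()
        assert (spread.fillna(0.0) == 0).all()

    def test_zero_expression_capped_and_flagged(self, design4):
        cfg = SimulationConfig(seed=1, ct_sigma=0.0, ct_max=40.0)
        expr = pd.DataFrame(
            {s.name: [0.0, 32.0] for s in design4}, index=["dead", "ref"]
        )
        ct = syndata.simulate_ct_table(cfg, expr, "ref", design4)
        dead = ct[ct["gene"] == "dead"]
        assert (dead["Ct"] == 40.0).all() and dead["capped"].all()

    def test_zero_reference_expression_rejected(self, design4):
        cfg = SimulationConfig(seed=1)
        expr = pd.DataFrame(
            {s.name: [10.0, 0.0] for s in design4}, index=["a", "ref"]
        )
        with pytest.raises(ConfigurationError, match="ref"):
            syndata.simulate_ct_table(cfg, expr, "ref", design4)


class TestPathwayAnnotation:
    def test_both_species_share_pathway_space(self, small_config):
        ann = syndata.simulate_pathway_annotation(small_config)
        by_species = ann.groupby("species")["pathway_id"].apply(set)
        assert by_species["A"] == by_species["B"]

    def test_planted_enriched_pathway_targets_de_genes(
        self, small_config, two_group_design
    ):
        _, truth = syndata.simulate_counts(small_config, two_group_design)
        ann = syndata.simulate_pathway_annotation(small_config, truth)
        de = set(truth.genes.loc[truth.genes["is_de"], "gene_stem"])
        members = ann.loc[
            (ann["pathway_id"] == "pw000") & (ann["species"] == "A"), "gene_id"
        ].str.replace("_A", "", regex=False)
        frac_de = np.mean([g in de for g in members])
        assert frac_de >= 0.5
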