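"""Filtering, TMM, dispersion estimation, QL F-test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from conftest import nb_matrix
from ilsdeconv import diffexpr, syndata
from ilsdeconv.config import SimulationConfig
from ilsdeconv.diffexpr import (
    ContrastSpec,
    DEError,
    bh_adjust,
    estimate_dispersions,
    filter_low_abundance,
    ql_f_test,
    run_de,
    tmm_factors,
)

GROUPS = ["c", "c", "c", "p", "p", "p"]


class TestFilter:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            np.vstack([np.zeros(6), np.full(6, 1000.0)]),
            index=["dead", "alive"], columns=list("abcdef"),
        )
        filtered, kept = filter_low_abundance(counts, GROUPS)
        assert kept == ["alive"]

    def test_huge_gene_kept(self):
        counts = pd.DataFrame(
            np.vstack([np.full(6, 1e6), np.full(6, 100.0)]),
            index=["big", "mid"], columns=list("abcdef"),
        )
        _, kept = filter_low_abundance(counts, GROUPS)
        assert "big" in kept

    def test_rule_matches_direct_enumeration(self):
        # library sizes ~1e6 -> CPM cutoff = 10; smallest group m = 3
        rng = np.random.default_rng(0)
        n = 300
        y = rng.integers(0, 40, size=(n, 6)).astype(float)
        y[0] = 1e6  # dominate library size
        counts = pd.DataFrame(
            y, index=[f"g{i}" for i in range(n)], columns=list("abcdef")
        )
        filtered, kept = filter_low_abundance(counts, GROUPS)
        lib = y.sum(axis=0)
        cutoff = 10.0 / (np.median(lib) / 1e6)
        cpm = y / lib * 1e6
        expected = [
            f"g{i}" for i in range(n)
            if (cpm[i] >= cutoff).sum() >= 3 and y[i].sum() >= 15
        ]
        assert kept == expected

    def test_everything_filtered_is_an_error(self):
        counts = pd.DataFrame(
            np.full((3, 6), 0.5), index=list("xyz"), columns=list("abcdef")
        )
        with pytest.raises(DEError, match="filter"):
            filter_low_abundance(counts, GROUPS)


def tmm_oracle(counts: pd.DataFrame) -> np.ndarray:
    """Independent, loop-based coding of the TMM formula."""
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    p75 = []
    for j in range(y.shape[1]):
        p75.append(np.quantile(y[:, j] / lib[j], 0.75))
    ref = int(np.argmin([abs(v - np.mean(p75)) for v in p75]))
    factors = []
    for j in range(y.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ms, aas, ws = [], [], []
        for g in range(y.shape[0]):
            yj, yr = y[g, j], y[g, ref]
            if yj <= 0 or yr <= 0:
                continue
            ms.append(np.log2((yj / lib[j]) / (yr / lib[ref])))
            aas.append(0.5 * np.log2((yj / lib[j]) * (yr / lib[ref])))
            ws.append(
                1.0 / ((lib[j] - yj) / (lib[j] * yj)
                       + (lib[ref] - yr) / (lib[ref] * yr))
            )
        ms, aas, ws = map(np.array, (ms, aas, ws))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        mlo, mhi = np.quantile(ms, 0.3), np.quantile(ms, 0.7)
        alo, ahi = np.quantile(aas, 0.05), np.quantile(aas, 0.95)
        keep = (ms >= mlo) & (ms <= mhi) & (aas >= alo) & (aas <= ahi)
        factors.append(2 ** (np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101, dtype=float)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        norm = tmm_factors(counts)
        assert np.allclose(norm.factor, 1.0, atol=1e-12)

    def test_exact_scaling_absorbed_by_library_size(self):
        col = np.arange(1, 101, dtype=float)
        counts = pd.DataFrame({"a": col, "b": 3 * col})
        norm = tmm_factors(counts)
        assert np.allclose(norm.factor, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = nb_matrix(rng, 300, 5)
        norm = tmm_factors(counts)
        assert np.exp(np.mean(np.log(norm.factor))) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_independent_literal_implementation(self, rng):
        for _ in range(50):
            counts = nb_matrix(rng, 200, 4)
            norm = tmm_factors(counts)
            assert np.allclose(norm.factor, tmm_oracle(counts), atol=1e-10)

    def test_near_invariant_to_scaling_one_library(self, rng):
        # exact invariance is impossible with precision weights (the
        # scaled library's weight component rescales, the reference's
        # does not); the factors must still agree closely
        counts = nb_matrix(rng, 300, 4)
        norm1 = tmm_factors(counts)
        scaled = counts.copy()
        scaled["s1"] = scaled["s1"] * 7.0
        norm2 = tmm_factors(scaled)
        assert np.allclose(norm1.factor, norm2.factor, rtol=0.02)


class TestDispersions:
    def test_poisson_data_gives_tiny_common_dispersion(self, rng):
        base = rng.lognormal(np.log(200), 1.0, 2000)
        y = rng.poisson(base[:, None], size=(2000, 6)).astype(float)
        counts = pd.DataFrame(y, columns=list("abcdef"))
        disp = estimate_dispersions(counts, tmm_factors(counts), GROUPS)
        assert disp.common <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        counts = nb_matrix(rng, 2000, 6, mean=200.0, phi=0.1)
        disp = estimate_dispersions(counts, tmm_factors(counts), GROUPS)
        assert 0.08 <= disp.common <= 0.12

    def test_shrinkage_pulls_tagwise_toward_common(self, rng):
        counts = nb_matrix(rng, 500, 6, mean=200.0, phi=0.1)
        norm = tmm_factors(counts)
        shrunk = estimate_dispersions(counts, norm, GROUPS, prior_df=10.0)
        loose = estimate_dispersions(counts, norm, GROUPS, prior_df=0.01)
        d_shrunk = np.abs(np.log(shrunk.tagwise) - np.log(shrunk.common))
        d_loose = np.abs(np.log(loose.tagwise) - np.log(loose.common))
        assert d_shrunk.median() < d_loose.median()


class TestQLFTest:
    def test_identical_group_means_give_null_result(self):
        counts = pd.DataFrame(
            np.tile([100.0, 100.0, 100.0, 100.0, 100.0, 100.0], (20, 1)),
            columns=list("abcdef"),
        )
        norm = tmm_factors(counts)
        disp = estimate_dispersions(counts, norm, GROUPS)
        res = ql_f_test(counts, norm, GROUPS, disp, ("c", "p"))
        assert np.allclose(res["F"], 0.0, atol=1e-8)
        assert np.allclose(res["p_value"], 1.0, atol=1e-8)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)

    def test_swapping_group_labels_negates_log2fc(self, rng):
        counts = nb_matrix(rng, 300, 6, mean=150.0, phi=0.1)
        norm = tmm_factors(counts)
        disp = estimate_dispersions(counts, norm, GROUPS)
        fwd = ql_f_test(counts, norm, GROUPS, disp, ("c", "p"))
        rev = ql_f_test(counts, norm, GROUPS, disp, ("p", "c"))
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-9)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_planted_strong_gene_detected(self, rng):
        counts = nb_matrix(rng, 400, 6, mean=150.0, phi=0.05)
        counts.iloc[0, 3:] = counts.iloc[0, 3:] * 8.0  # planted log2FC ~ 3
        spec = ContrastSpec("t", counts, GROUPS, ("c", "p"))
        res = run_de(spec)
        assert res.loc["g0", "FDR"] < 0.05
        assert res.loc["g0", "log2FC"] > 2.0

    def test_mismatched_contrast_rejected(self, rng):
        counts = nb_matrix(rng, 50, 6)
        norm = tmm_factors(counts)
        disp = estimate_dispersions(counts, norm, GROUPS)
        with pytest.raises(DEError):
            ql_f_test(counts, norm, GROUPS, disp, ("c", "x"))


def bh_oracle(p):
    """Step-up rule computed literally from its definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / (np.sum(p <= p[j])))
            for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(candidates)
    return out


class TestBH:
    def test_hand_computed_stepup_case(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRunContrasts:
    def test_null_pipeline_rarely_significant(self):
        cfg = SimulationConfig(
            seed=9, n_genes_per_genome=1000, de_fraction=0.0,
            library_size_mean=200_000.0,
        )
        design = [
            syndata.SampleSpec(f"s{i}", "F", c, i % 3 + 1)
            for i, c in enumerate(["control"] * 3 + ["parasitized"] * 3)
        ]
        counts, _ = syndata.simulate_counts(cfg, design)
        spec = ContrastSpec(
            "null", counts, ["control"] * 3 + ["parasitized"] * 3,
            ("control", "parasitized"),
        )
        tables, summary = diffexpr.run_contrasts([spec])
        sig_frac = (summary["up"][0] + summary["down"][0]) / summary["n_tested"][0]
        assert sig_frac <= 0.01

    def test_missing_matrix_named_in_error(self):
        spec = ContrastSpec("absent", pd.DataFrame(), [], ("a", "b"))
        with pytest.raises(DEError, match="absent"):
            diffexpr.run_contrasts([spec])
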