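"""Normalization, fold changes, local Z, permutation p-values, hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulsa_screen.benchmarks import local_z_naive
from pulsa_screen.counting import CountMatrix
from pulsa_screen.screen_model import generate_library
from pulsa_screen.scoring import (
    ScoringConfig,
    aggregate_replicates,
    call_hits,
    gene_phenotype,
    gene_pvalue,
    guide_lfc,
    local_z,
    normalize,
    ntc_pseudogenes,
    score_screen,
)

CFG = ScoringConfig()


class TestNormalize:
    def test_printed_formula_hand_values(self):
        np.testing.assert_allclose(
            normalize([10, 20, 30]), [500_001.0, 1_000_001.0, 1_500_001.0]
        )

    def test_constant_sample(self):
        np.testing.assert_allclose(normalize([20, 20, 20]), [1_000_001.0] * 3)

    def test_zero_count_maps_to_pseudocount(self):
        out = normalize([0, 10, 20])
        assert out[0] == CFG.pseudocount

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="no positive counts"):
            normalize([0, 0, 0])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=50).filter(
            lambda c: sum(c) > 0
        ),
        st.integers(min_value=1, max_value=1000),
    )
    def test_scale_invariance(self, counts, factor):
        base = normalize(np.array(counts))
        scaled = normalize(np.array(counts) * factor)
        np.testing.assert_allclose(base, scaled, rtol=1e-12)


class TestGuideLfc:
    def test_identity_ratio_is_zero(self):
        assert guide_lfc([5.0, 7.0], [5.0, 7.0]).tolist() == [0.0, 0.0]

    def test_exact_ratio_two_gives_one(self):
        out = guide_lfc([2_000_002.0], [1_000_001.0])
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        a = guide_lfc([2_000_002.0], [1_000_001.0])
        b = guide_lfc([1_000_001.0], [2_000_002.0])
        assert a[0] == pytest.approx(-b[0], abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            guide_lfc([1.0, 2.0], [1.0])

    def test_configurable_base(self):
        out = guide_lfc([10.0], [1.0], ScoringConfig(log_base=10))
        assert out[0] == pytest.approx(1.0)


class TestLocalZ:
    def test_window4_hand_fixture(self):
        lfc = np.array([0.0, 0.0, 0.0, 4.0])
        abundance = np.array([1.0, 2.0, 3.0, 4.0])
        z = local_z(lfc, abundance, window=4)
        np.testing.assert_allclose(z, [-0.5, -0.5, -0.5, 1.5])

    def test_constant_lfc_gives_all_zero(self):
        z = local_z(np.full(50, 1.7), np.arange(50.0), window=10)
        assert (z == 0).all()

    def test_oracle_equivalence_on_random_data(self):
        rng = np.random.default_rng(4)
        n = 3000
        lfc = rng.normal(0, 1 + rng.random(n), n)
        ab = rng.lognormal(8, 1, n)
        for window in (3, 10, 400, 3000):
            np.testing.assert_allclose(
                local_z(lfc, ab, window), local_z_naive(lfc, ab, window), atol=1e-10
            )

    def test_exclude_focal_matches_naive(self):
        rng = np.random.default_rng(5)
        lfc = rng.normal(0, 1, 500)
        ab = rng.random(500)
        np.testing.assert_allclose(
            local_z(lfc, ab, 100, include_focal=False),
            local_z_naive(lfc, ab, 100, include_focal=False),
            atol=1e-10,
        )

    def test_full_window_members_standardized(self):
        # members of a shared full window, scored against it, have mean ~0 sd ~1
        rng = np.random.default_rng(6)
        n = 200
        z = local_z(rng.normal(0, 1, n), rng.random(n), window=n)
        assert abs(z.mean()) < 0.05
        assert abs(z.std(ddof=1) - 1) < 0.05

    def test_tie_break_by_guide_id_is_deterministic(self):
        lfc = np.array([1.0, 2.0, 3.0, 4.0])
        ab = np.array([5.0, 5.0, 5.0, 5.0])  # fully tied abundance
        ids = np.array(["d", "c", "b", "a"])
        z1 = local_z(lfc, ab, 2, tie_breaker=ids)
        z2 = local_z(lfc[::-1].copy(), ab, 2, tie_breaker=ids[::-1].copy())[::-1]
        np.testing.assert_allclose(z1, z2)

    def test_window_larger_than_n_clamps(self):
        lfc = np.array([0.0, 1.0, 2.0])
        z = local_z(lfc, np.arange(3.0), window=10)
        np.testing.assert_allclose(z, local_z_naive(lfc, np.arange(3.0), 3))

    def test_single_guide_raises(self):
        with pytest.raises(ValueError):
            local_z(np.array([1.0]), np.array([1.0]), window=2)


class TestGenePhenotype:
    def test_top_two_by_absolute_z(self):
        z = np.array([0.1, -3.0, 2.5, 0.2])
        out = gene_phenotype(z, ["G1"] * 4)
        assert out["phenotype"].iloc[0] == pytest.approx(-0.25)
        assert out["n_guides"].iloc[0] == 4

    def test_all_zero_z(self):
        out = gene_phenotype(np.zeros(4), ["G1"] * 4)
        assert out["phenotype"].iloc[0] == 0.0

    def test_single_guide_gene_flagged(self):
        out = gene_phenotype(np.array([1.7]), ["G1"])
        assert out["phenotype"].iloc[0] == 1.7
        assert out["n_guides"].iloc[0] == 1

    def test_multiple_genes_grouped(self):
        z = np.array([1.0, 2.0, -5.0, 0.5])
        out = gene_phenotype(z, ["A", "A", "B", "B"])
        assert out.loc[out["gene"] == "A", "phenotype"].iloc[0] == 1.5
        assert out.loc[out["gene"] == "B", "phenotype"].iloc[0] == -2.25

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gene_phenotype(np.array([]), [])


class TestGenePvalue:
    def test_exhaustive_three_choose_two(self):
        out = gene_pvalue(
            np.array([2.0, 3.0, 1.0]), ["G1", "G1", "other"], mode="exhaustive"
        )
        p = out.loc[out["gene"] == "G1", "p_value"].iloc[0]
        assert p == pytest.approx(1 / 3)

    def test_identical_z_gives_p_one(self):
        cfg = ScoringConfig(n_perm=500, seed=1)
        out = gene_pvalue(np.full(12, 2.0), np.repeat(["A", "B", "C"], 4), cfg, mode="sampled")
        assert (out["p_value"] == 1.0).all()

    def test_sampled_p_bounded_below_by_smoothing(self):
        cfg = ScoringConfig(n_perm=200, seed=2)
        rng = np.random.default_rng(2)
        z = np.concatenate([[50.0, 60.0], rng.normal(0, 1, 30)])
        genes = ["HIT"] * 2 + [f"N{i}" for i in range(30)]
        out = gene_pvalue(z, genes, cfg, mode="sampled", null_pool=rng.normal(0, 1, 200))
        assert out.loc[out["gene"] == "HIT", "p_value"].iloc[0] == pytest.approx(1 / 201)

    def test_two_sidedness(self):
        # symmetric pools give the same p for +m and -m observed means
        z = np.array([4.0, -4.0, 1.0, -1.0, 2.0, -2.0])
        genes = ["P", "M", "a", "b", "c", "d"]
        out = gene_pvalue(z, genes, mode="exhaustive")
        p_pos = out.loc[out["gene"] == "P", "p_value"].iloc[0]
        p_neg = out.loc[out["gene"] == "M", "p_value"].iloc[0]
        assert p_pos == p_neg

    def test_exhaustive_p_monotone_in_effect(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 9)
        last_p = 1.1
        for scale in (0.5, 1.5, 3.0, 6.0):
            z = np.concatenate([base, [scale, scale, scale]])
            genes = [f"N{i}" for i in range(9)] + ["HIT"] * 3
            out = gene_pvalue(z, genes, mode="exhaustive")
            p = out.loc[out["gene"] == "HIT", "p_value"].iloc[0]
            assert p <= last_p
            last_p = p

    def test_gene_larger_than_pool_raises(self):
        with pytest.raises(ValueError, match="pool"):
            gene_pvalue(np.array([1.0, 2.0]), ["G", "G"], null_pool=np.array([1.0]))


class TestAggregateReplicates:
    def _stats(self, z, lfc=None):
        n = len(z)
        return pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(n)],
                "gene": ["G1"] * n,
                "norm_pos": np.full(n, 10.0),
                "norm_neg": np.full(n, 5.0),
                "mean_abundance": np.full(n, 7.5),
                "lfc": lfc if lfc is not None else np.asarray(z, float),
                "local_z": np.asarray(z, float),
            }
        )

    def test_identical_replicates_idempotent(self):
        rep = self._stats([1.0, -2.0])
        out = aggregate_replicates([rep, rep.copy()])
        pd.testing.assert_frame_equal(out, rep)

    def test_single_replicate_identity(self):
        rep = self._stats([0.5])
        pd.testing.assert_frame_equal(aggregate_replicates([rep]), rep)

    def test_mean_rule(self):
        out = aggregate_replicates([self._stats([1.0]), self._stats([3.0])])
        assert out["local_z"].iloc[0] == 2.0

    def test_guide_set_mismatch_raises(self):
        a = self._stats([1.0, 2.0])
        b = self._stats([1.0, 2.0])
        b.loc[1, "guide_id"] = "other"
        with pytest.raises(ValueError, match="guide set"):
            aggregate_replicates([a, b])


class TestCallHits:
    @pytest.mark.parametrize(
        "p,phenotype,expected_hit,expected_dir",
        [
            (0.004, 1.2, True, 1),
            (0.004, -1.2, True, -1),
            (0.004, 0.5, False, 1),
            (0.5, 3.0, False, 1),
        ],
    )
    def test_threshold_logic(self, p, phenotype, expected_hit, expected_dir):
        df = pd.DataFrame({"gene": ["G"], "p_value": [p], "phenotype": [phenotype]})
        out = call_hits(df)
        assert bool(out["is_hit"].iloc[0]) is expected_hit
        assert out["direction"].iloc[0] == expected_dir


class TestNtcPseudogenes:
    def test_partition_arithmetic(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1, 1000)
        cfg = ScoringConfig(n_perm=200, seed=7)
        out = ntc_pseudogenes(z, 4, cfg, null_pool=rng.normal(0, 1, 2000))
        assert len(out) == 250

    def test_remainder_dropped(self):
        z = np.zeros(10)
        out = ntc_pseudogenes(z, 4, ScoringConfig(n_perm=100, seed=1), null_pool=np.ones(50))
        assert len(out) == 2

    def test_too_few_ntcs_raise(self):
        with pytest.raises(ValueError, match="NTC"):
            ntc_pseudogenes(np.zeros(3), 4)

    def test_null_pseudogene_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, 1000)
        pool = rng.normal(0, 1, 4000)
        cfg = ScoringConfig(n_perm=10_000, seed=8)
        out = ntc_pseudogenes(z, 4, cfg, null_pool=pool)
        ks = stats.kstest(out["p_value"], "uniform")
        assert ks.pvalue > 0.01


def _null_counts(library, seed, mean=200):
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("agg_r1", "dif_r1", "agg_r2", "dif_r2"):
        cols[name] = rng.poisson(mean, len(library))
    return CountMatrix(
        pd.DataFrame(cols, index=pd.Index(library.guide_ids, name="guide_id"))
    )


@pytest.fixture(scope="module")
def library():
    return generate_library(500, 4, 200, seed=21)


class TestScoreScreen:
    def test_null_screen_calibration(self, library):
        counts = _null_counts(library, seed=21)
        cfg = ScoringConfig(window=500, n_perm=2000, seed=21)
        results, guide_stats, ntc = score_screen(counts, library, cfg)
        frac = (results["p_value"] < 0.05).mean()
        assert 0.02 < frac < 0.08  # 3 binomial SDs around 0.05 for 500 genes
        assert len(results) == 500
        assert len(guide_stats) == len(library)
        assert ntc is not None and len(ntc) == 50

    def test_planted_gene_ranks_first(self, library):
        counts = _null_counts(library, seed=22)
        planted = library.targeting_genes[7]
        mask = library.genes == planted
        df = counts.counts.copy()
        df.loc[mask, ["agg_r1", "agg_r2"]] *= 8
        cfg = ScoringConfig(window=500, n_perm=2000, seed=22)
        results, _, _ = score_screen(CountMatrix(df), library, cfg)
        assert results["gene"].iloc[0] == planted
        assert results["p_value"].iloc[0] == results["p_value"].min()
        assert bool(results["is_hit"].iloc[0])

    def test_label_permutation_destroys_significance(self, library):
        counts = _null_counts(library, seed=23)
        planted = library.targeting_genes[3]
        mask = library.genes == planted
        df = counts.counts.copy()
        df.loc[mask, ["agg_r1", "agg_r2"]] *= 8
        cfg = ScoringConfig(window=500, n_perm=1000, seed=23)
        rng = np.random.default_rng(23)
        insignificant = 0
        n_shuffles = 10
        for _ in range(n_shuffles):
            shuffled = library.table.copy()
            shuffled["gene"] = rng.permutation(shuffled["gene"].to_numpy())
            shuf_lib = type(library)(shuffled)
            results, _, _ = score_screen(CountMatrix(df), shuf_lib, cfg)
            row = results.loc[results["gene"] == planted]
            if len(row) and row["p_value"].iloc[0] > 0.05:
                insignificant += 1
        assert insignificant >= 9

    def test_deterministic_for_fixed_seed(self, library):
        counts = _null_counts(library, seed=24)
        cfg = ScoringConfig(window=500, n_perm=500, seed=24)
        r1, g1, _ = score_screen(counts, library, cfg)
        r2, g2, _ = score_screen(counts, library, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_report_order_is_stable_sort(self, library):
        counts = _null_counts(library, seed=25)
        cfg = ScoringConfig(window=500, n_perm=500, seed=25)
        results, _, _ = score_screen(counts, library, cfg)
        key = list(zip(results["p_value"], -results["phenotype"].abs(), results["gene"]))
        assert key == sorted(key)
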