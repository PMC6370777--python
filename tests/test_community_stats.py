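import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from graftmicrobe import (
    CountMatrix,
    SampleMetadata,
    composition_summary,
    diversity_curves,
    permanova,
    raup_crick,
    taxon_anova,
)
from graftmicrobe.data_model import ValidationError


def make_metadata(varieties, locations=None, lines=None):
    n = len(varieties)
    locations = locations or ["l1"] * n
    lines = lines or ["x"] * n
    return SampleMetadata(
        pd.DataFrame(
            {"variety": varieties, "location": locations, "line": lines},
            index=[f"s{i}" for i in range(n)],
        )
    )


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------


def enumerate_raup_crick(s_pool: int, n1: int, n2: int, x_obs: int) -> float:
    """Exhaustive equiprobable null: every pair of assemblages of sizes
    (n1, n2) from a pool of s_pool species, dissimilarity =
    P(shared > x_obs) + 0.5 P(shared = x_obs)."""
    species = range(s_pool)
    gt = eq = total = 0
    for a in itertools.combinations(species, n1):
        sa = set(a)
        for b in itertools.combinations(species, n2):
            shared = len(sa & set(b))
            total += 1
            if shared > x_obs:
                gt += 1
            elif shared == x_obs:
                eq += 1
    return (gt + 0.5 * eq) / total


class TestRaupCrick:
    def test_all_species_everywhere_gives_half(self):
        m = CountMatrix(
            pd.DataFrame(
                np.ones((4, 6), dtype=int),
                index=[f"s{i}" for i in range(4)],
                columns=[f"f{j}" for j in range(6)],
            )
        )
        d = raup_crick(m, variant="null-model", n_sim=99, seed=0)
        off = d.data[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_analytic_matches_exhaustive_enumeration(self):
        # 3 samples over a 6-species pool with equal occurrence untestable
        # directly; the analytic form is per-pair so compare pair by pair
        counts = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [0, 1, 1, 1, 0, 0],
                [1, 0, 0, 0, 1, 0],
            ]
        )
        m = CountMatrix(
            pd.DataFrame(counts, index=["s0", "s1", "s2"], columns=[f"f{j}" for j in range(6)])
        )
        d = raup_crick(m, variant="analytic")
        presence = counts > 0
        for i, j in itertools.combinations(range(3), 2):
            x = int((presence[i] & presence[j]).sum())
            expected = enumerate_raup_crick(6, presence[i].sum(), presence[j].sum(), x)
            assert d.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_samples_more_dissimilar_than_chance(self):
        """Two samples sharing nothing sit at or above 0.5: the null can only
        share >= 0 species, so the upper-tail probability is at least the
        0.5-weighted mass of the x=0 tie (enumeration on a 5-species pool)."""
        counts = np.array([[1, 1, 0, 0, 0], [0, 0, 1, 1, 0]])
        expected = enumerate_raup_crick(5, 2, 2, 0)
        assert expected > 0.5
        m = CountMatrix(
            pd.DataFrame(counts, index=["s0", "s1"], columns=[f"f{j}" for j in range(5)])
        )
        d = raup_crick(m, variant="analytic")
        assert d.data[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_null_model_matches_analytic_on_equal_occurrence_pool(self):
        """When every species occurs equally often the occurrence-weighted
        null reduces to the equiprobable hypergeometric closed form."""
        # 4 samples, 12 species, each species in exactly 2 samples
        counts = np.zeros((4, 12), dtype=int)
        k = 0
        for i, j in itertools.combinations(range(4), 2):
            counts[i, k] = counts[j, k] = 1
            counts[i, k + 1] = counts[j, k + 1] = 1
            k += 2
        m = CountMatrix(
            pd.DataFrame(
                counts, index=[f"s{i}" for i in range(4)], columns=[f"f{j}" for j in range(12)]
            )
        )
        n_sim = 10_000
        sim = raup_crick(m, variant="null-model", n_sim=n_sim, seed=5)
        exact = raup_crick(m, variant="analytic")
        for i, j in itertools.combinations(range(4), 2):
            se = np.sqrt(max(exact.data[i, j] * (1 - exact.data[i, j]), 0.025) / n_sim)
            assert abs(sim.data[i, j] - exact.data[i, j]) < 3 * se + 0.5 / n_sim

    def test_zero_richness_sample_rejected(self):
        m = CountMatrix(pd.DataFrame([[1, 1], [0, 0]], index=["s0", "s1"], columns=["a", "b"]))
        with pytest.raises(ValidationError, match="s1"):
            raup_crick(m, n_sim=9)

    def test_bounds_and_symmetry(self, small_synthetic):
        matrix, _, _ = small_synthetic
        sub = matrix.select_samples(matrix.sample_ids[:12])
        d = raup_crick(sub, n_sim=199, seed=1)
        assert (d.data >= 0).all() and (d.data <= 1).all()
        np.testing.assert_allclose(d.data, d.data.T)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def sequential_anova_f(y, factors):
    """Classical sequential (type-I) ANOVA F statistics for univariate y —
    the independent oracle for PERMANOVA on Euclidean distances."""
    n = len(y)
    y = np.asarray(y, dtype=float)
    blocks = [np.ones((n, 1))]
    rank_prev, ss_prev = 1, 0.0
    yc = y - y.mean()
    ss_list, df_list = [], []
    for f in factors:
        blocks.append(pd.get_dummies(pd.Series(f), dtype=float).to_numpy())
        x = np.hstack(blocks)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        ss_model = np.sum((fitted - y.mean()) ** 2)
        rank = np.linalg.matrix_rank(x)
        ss_list.append(ss_model - ss_prev)
        df_list.append(rank - rank_prev)
        ss_prev, rank_prev = ss_model, rank
    ss_total = np.sum(yc**2)
    df_res = n - rank_prev
    ss_res = ss_total - ss_prev
    return [
        (ss / df) / (ss_res / df_res) for ss, df in zip(ss_list, df_list)
    ], ss_total, ss_res


def euclidean_dm(y):
    y = np.asarray(y, dtype=float)
    d = np.abs(y[:, None] - y[None, :])
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(len(y))])


class TestPermanova:
    def test_textbook_two_group_example(self):
        """Points {0,1} vs {2,3}: classical one-way ANOVA gives F=8, R2=0.8;
        PERMANOVA on Euclidean distances must agree exactly."""
        dm = euclidean_dm([0, 1, 2, 3])
        meta = make_metadata(["A", "A", "B", "B"])
        res = permanova(dm, meta, ["variety"], n_perm=99, seed=0)
        assert res.table.loc["variety", "pseudo_F"] == pytest.approx(8.0, abs=1e-10)
        assert res.r2("variety") == pytest.approx(0.8, abs=1e-12)

    def test_matches_sequential_anova_on_random_designs(self, rng):
        for _ in range(10):
            n = int(rng.integers(12, 25))
            y = rng.normal(size=n)
            v = rng.choice(["a", "b", "c"], size=n)
            l = rng.choice(["p", "q"], size=n)
            if len(set(v)) < 3 or len(set(l)) < 2:
                continue
            f_expected, ss_total, _ = sequential_anova_f(y, [v, l])
            meta = make_metadata(list(v), list(l))
            res = permanova(euclidean_dm(y), meta, ["variety", "location"], n_perm=9, seed=0)
            assert res.table.loc["variety", "pseudo_F"] == pytest.approx(f_expected[0], rel=1e-9)
            assert res.table.loc["location", "pseudo_F"] == pytest.approx(f_expected[1], rel=1e-9)

    def test_matches_skbio_one_way_pseudo_f(self, rng):
        """Independent library cross-check on a non-Euclidean random distance
        matrix with a single factor."""
        n = 15
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        expected = skbio_permanova(dm, grouping=groups, permutations=0)["test statistic"]
        res = permanova(dm, make_metadata(groups), ["variety"], n_perm=9, seed=0)
        assert res.table.loc["variety", "pseudo_F"] == pytest.approx(expected, rel=1e-9)

    def test_matches_vegan_adonis2(self, tmp_path, rng):
        """Cross-check sequential F and R2 against R vegan::adonis2."""
        n = 20
        y = rng.normal(size=(n, 3))
        v = list(np.repeat(["a", "b", "c", "d"], 5))
        l = list(np.tile(["p", "q", "r", "s", "t"], 4))
        np.savetxt(tmp_path / "y.tsv", y, delimiter="\t")
        pd.DataFrame({"v": v, "l": l}).to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        script = f"""
        suppressMessages(library(vegan))
        y <- as.matrix(read.table("{tmp_path}/y.tsv", sep="\\t"))
        meta <- read.table("{tmp_path}/meta.tsv", sep="\\t", header=TRUE)
        res <- adonis2(dist(y) ~ v + l, data=meta, permutations=9, by="terms")
        write.csv(as.data.frame(res), "{tmp_path}/out.csv")
        """
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)

        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(y)), ids=[f"s{i}" for i in range(n)])
        res = permanova(dm, make_metadata(v, l), ["variety", "location"], n_perm=9, seed=0)
        assert res.table.loc["variety", "pseudo_F"] == pytest.approx(ref.loc["v", "F"], rel=1e-6)
        assert res.table.loc["location", "pseudo_F"] == pytest.approx(ref.loc["l", "F"], rel=1e-6)
        assert res.r2("variety") == pytest.approx(ref.loc["v", "R2"], rel=1e-6)
        assert res.r2("location") == pytest.approx(ref.loc["l", "R2"], rel=1e-6)

    def test_r2_components_sum_to_one(self, rng):
        y = rng.normal(size=18)
        v = list(rng.choice(["a", "b", "c"], size=18))
        res = permanova(euclidean_dm(y), make_metadata(v), ["variety"], n_perm=9, seed=0)
        r2 = res.table.loc[["variety", "Residual"], "R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_term_order_matters_on_unbalanced_design(self, rng):
        y = rng.normal(size=16)
        v = ["a"] * 3 + ["b"] * 13
        l = ["p"] * 9 + ["q"] * 7
        r1 = permanova(euclidean_dm(y), make_metadata(v, l), ["variety", "location"], 9, 0)
        r2 = permanova(euclidean_dm(y), make_metadata(v, l), ["location", "variety"], 9, 0)
        assert r1.table.loc["variety", "SS"] != pytest.approx(
            r2.table.loc["variety", "SS"], rel=1e-6
        )

    def test_degenerate_distances_rejected(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=["s0", "s1", "s2", "s3"])
        with pytest.raises(ValidationError, match="degenerate"):
            permanova(dm, make_metadata(["a", "a", "b", "b"]), ["variety"], 9, 0)

    def test_permutation_p_reproducible(self, rng):
        y = rng.normal(size=20)
        v = list(rng.choice(["a", "b"], size=20))
        meta = make_metadata(v)
        p1 = permanova(euclidean_dm(y), meta, ["variety"], 199, seed=4).p("variety")
        p2 = permanova(euclidean_dm(y), meta, ["variety"], 199, seed=4).p("variety")
        assert p1 == p2


# ---------------------------------------------------------------------------
# per-taxon ANOVA
# ---------------------------------------------------------------------------


class TestTaxonAnova:
    def test_balanced_two_by_two_textbook(self):
        """2 varieties x 2 locations, 2 reps per cell, additive means:
        sequential SS reduce to the classical balanced two-way ANOVA."""
        # y = variety effect (0/6) + location effect (0/2) + dev {-1,+1}
        y = np.array([0 - 1, 0 + 1, 2 - 1, 2 + 1, 6 - 1, 6 + 1, 8 - 1, 8 + 1], dtype=float)
        v = ["a"] * 4 + ["b"] * 4
        l = ["p", "p", "q", "q"] * 2
        meta = make_metadata(v, l)
        props = pd.DataFrame({"t": y / 100.0}, index=meta.sample_ids)
        res = taxon_anova(props, meta)
        # SSA = 8*(3)^2 = 72, SSB = 8*(1)^2 = 8, SSE = 8, df = (1,1,5)
        assert res.loc["t", "variety_F"] == pytest.approx(72 / (8 / 5), rel=1e-9)
        assert res.loc["t", "location_F"] == pytest.approx(8 / (8 / 5), rel=1e-9)
        assert res.loc["t", "residual_df"] == 5

    def test_location_only_signal_gives_tiny_variety_f(self):
        # balanced design; within-cell deviations are identical for both
        # varieties, so the between-variety SS is zero up to rounding
        v = ["a", "b"] * 6
        l = ["p"] * 6 + ["q"] * 6
        base = np.where(np.array(l) == "p", 0.1, 0.3)
        d = 0.01
        dev = np.array([-d, -d, 0, 0, d, d] * 2)
        meta = make_metadata(list(v), list(l))
        props = pd.DataFrame({"t": base + dev}, index=meta.sample_ids)
        res = taxon_anova(props, meta)
        assert res.loc["t", "variety_F"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["t", "location_p"] < 1e-6

    def test_constant_taxon_flagged_not_raised(self):
        meta = make_metadata(["a", "a", "b", "b"], ["p", "q", "p", "q"])
        props = pd.DataFrame(
            {"flat": [0.5] * 4, "ok": [0.1, 0.2, 0.3, 0.4]}, index=meta.sample_ids
        )
        res = taxon_anova(props, meta)
        assert bool(res.loc["flat", "degenerate"])
        assert np.isnan(res.loc["flat", "variety_F"])
        assert not bool(res.loc["ok", "degenerate"])

    def test_occurrence_filter_applied(self):
        meta = make_metadata(["a", "a", "b", "b"], ["p", "q", "p", "q"])
        props = pd.DataFrame(
            {"rare": [0.1, 0, 0, 0], "common": [0.2, 0.3, 0.1, 0.4]},
            index=meta.sample_ids,
        )
        res = taxon_anova(props, meta, min_occurrence=3)
        assert list(res.index) == ["common"]

    def test_full_design_degrees_of_freedom(self, small_synthetic):
        from graftmicrobe import collapse_to_rank, rarefy, to_relative_abundance

        matrix, metadata, taxonomy = small_synthetic
        rarefied, _ = rarefy(matrix, 500, seed=0)
        meta = metadata.select_samples(rarefied.sample_ids)
        genus = collapse_to_rank(rarefied, taxonomy, "genus")
        props = to_relative_abundance(genus)
        res = taxon_anova(props, meta, min_occurrence=30)
        ok = res[~res["degenerate"]]
        assert (ok["variety_df"] == 8).all()
        assert (ok["location_df"] == 14).all()


# ---------------------------------------------------------------------------
# diversity curves
# ---------------------------------------------------------------------------


class TestDiversityCurves:
    def test_single_feature_curve_constant_one(self):
        m = CountMatrix(pd.DataFrame([[400]], index=["s1"], columns=["a"]))
        rare, _ = diversity_curves(m, step=100, n_perm=5, seed=0)
        np.testing.assert_allclose(rare["expected_richness"], 1.0)

    def test_endpoint_equals_observed_richness(self, random_matrix):
        rare, _ = diversity_curves(random_matrix, step=100, n_perm=5, seed=0)
        for sid, group in rare.groupby("sample_id"):
            observed = int((random_matrix.data.loc[sid] > 0).sum())
            assert group["expected_richness"].iloc[-1] == pytest.approx(observed, abs=1e-9)

    def test_accumulation_matches_exhaustive_average(self):
        """3 samples: the mean over random orderings estimates the exhaustive
        average over all 3! orderings (closed form: 1 - C(n-m_i,k)/C(n,k))."""
        counts = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]])
        m = CountMatrix(
            pd.DataFrame(counts, index=["s0", "s1", "s2"], columns=list("abcd"))
        )
        presence = counts > 0
        n = 3
        exact = []
        for k in range(1, n + 1):
            import math

            miss = [
                math.comb(n - presence[:, j].sum(), k) / math.comb(n, k)
                for j in range(4)
            ]
            exact.append(sum(1 - x for x in miss))
        _, acc = diversity_curves(m, step=1, n_perm=3000, seed=2)
        np.testing.assert_allclose(acc["mean_richness"], exact, atol=0.1)

    def test_step_larger_than_smallest_total_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            diversity_curves(random_matrix, step=10**9)


# ---------------------------------------------------------------------------
# composition summary
# ---------------------------------------------------------------------------


class TestCompositionSummary:
    def test_single_sample_equals_relative_abundance(self):
        m = CountMatrix(pd.DataFrame([[30, 70]], index=["s0"], columns=["a", "b"]))
        meta = make_metadata(["only"])
        out = composition_summary(m, meta)
        pooled = out.set_index("taxon")["pooled_proportion"]
        assert pooled["a"] == pytest.approx(0.3)
        assert pooled["b"] == pytest.approx(0.7)

    def test_pooled_proportions_sum_to_one_per_variety(self, small_synthetic):
        matrix, metadata, _ = small_synthetic
        out = composition_summary(matrix, metadata)
        sums = out.groupby("variety")["pooled_proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_pooled_weighs_samples_by_depth(self):
        # deep sample dominates pooled but not mean proportions
        m = CountMatrix(
            pd.DataFrame([[900, 100], [1, 9]], index=["s0", "s1"], columns=["a", "b"])
        )
        meta = make_metadata(["v", "v"])
        out = composition_summary(m, meta).set_index("taxon")
        assert out.loc["a", "pooled_proportion"] == pytest.approx(901 / 1010)
        assert out.loc["a", "mean_proportion"] == pytest.approx((0.9 + 0.1) / 2)
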