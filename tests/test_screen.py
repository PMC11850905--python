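"""Normalization, paired differential statistic, alpha-RRA and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacscreen import screen, simulate

# ---------------------------------------------------------------------------
# independent oracles


def brute_size_factors(counts: pd.DataFrame) -> list[float]:
    """Median-of-ratios by explicit loops."""
    ref = {}
    for g in counts.index:
        row = [counts.loc[g, s] for s in counts.columns]
        if all(v > 0 for v in row):
            ref[g] = math.exp(sum(math.log(v) for v in row) / len(row))
    factors = []
    for s in counts.columns:
        ratios = sorted(counts.loc[g, s] / ref[g] for g in ref)
        n = len(ratios)
        mid = (ratios[n // 2] if n % 2 else (ratios[n // 2 - 1] + ratios[n // 2]) / 2)
        factors.append(mid)
    return factors


def order_stat_cdf(x: float, j: int, k: int) -> float:
    """P(j-th order statistic of k uniforms <= x) by the binomial sum."""
    return sum(
        math.comb(k, i) * x**i * (1 - x) ** (k - i) for i in range(j, k + 1)
    )


def brute_rho(ranks: list[float], alpha: float) -> float:
    rr = sorted(ranks)
    vals = [
        order_stat_cdf(r, j, len(rr)) for j, r in enumerate(rr, start=1) if r < alpha
    ]
    return min(vals) if vals else 1.0


def brute_bh(pvals: list[float]) -> list[float]:
    """Step-up definition computed literally."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, pvals[i] * m / (pos + 1))
        adj[i] = min(running, 1.0)
    return adj


def brute_es(scores: pd.Series, gene_set: set, weight: float) -> float:
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    n, n_set = len(ordered), len(gene_set)
    total = sum(abs(ordered[g]) ** weight for g in gene_set)
    walk, best = 0.0, 0.0
    for g in ordered.index:
        if g in gene_set:
            walk += abs(ordered[g]) ** weight / total
        else:
            walk -= 1.0 / (n - n_set)
        if abs(walk) > abs(best):
            best = walk
    return best


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(screen.size_factors(counts), 1.0)

    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = screen.size_factors(counts)
        assert np.allclose(f, [1 / math.sqrt(2), math.sqrt(2)])

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            counts = pd.DataFrame(
                rng.integers(1, 500, size=(20, 4)), columns=list("abcd")
            )
            assert np.allclose(screen.size_factors(counts), brute_size_factors(counts))

    def test_scale_equivariance_relative_to_other_samples(self, rng):
        # scaling one sample by c also rescales every guide's geometric mean,
        # so equivariance holds for factor *ratios*, not the raw factor
        counts = pd.DataFrame(rng.integers(1, 200, size=(50, 3)), columns=list("abc"))
        scaled = counts.copy()
        scaled["b"] *= 7
        f0, f1 = screen.size_factors(counts), screen.size_factors(scaled)
        assert np.isclose(f1["b"] / f1["a"], 7 * f0["b"] / f0["a"])
        assert np.isclose(f1["c"] / f1["a"], f0["c"] / f0["a"])

    def test_all_rows_contain_zero_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            screen.size_factors(counts)


def test_filter_zero_guides_keeps_order():
    counts = pd.DataFrame(
        {"a": [0, 1, 0, 3], "b": [0, 0, 0, 1]}, index=["g1", "g2", "g3", "g4"]
    )
    out = screen.filter_zero_guides(counts)
    assert list(out.index) == ["g2", "g4"]


def test_filter_zero_guides_planted_rows(rng):
    mat = pd.DataFrame(rng.integers(1, 10, size=(100, 4)))
    zero_rows = rng.choice(100, size=7, replace=False)
    mat.iloc[zero_rows] = 0
    assert len(screen.filter_zero_guides(mat)) == 93


# ---------------------------------------------------------------------------
# paired differential


def _design(m: int) -> screen.ScreenDesign:
    return screen.ScreenDesign(simulate.screen_design_frame(m))


class TestPairedDifferential:
    def test_no_change_gives_null_stats(self):
        counts = pd.DataFrame(
            {
                "control_r1": [10.0, 20.0],
                "treated_r1": [10.0, 20.0],
                "control_r2": [10.0, 20.0],
                "treated_r2": [10.0, 20.0],
            },
            index=["g1", "g2"],
        )
        diff = screen.paired_differential(counts, _design(2))
        assert (diff["log2fc"] == 0).all()
        assert (diff["stat"] == 0).all()
        assert (diff["p"] == 1).all()

    def test_fourfold_guide_recovers_log2fc_2(self, rng):
        base = rng.integers(80, 120, size=50).astype(float)
        counts = pd.DataFrame(
            {
                "control_r1": base,
                "treated_r1": base,
                "control_r2": base,
                "treated_r2": base,
            },
            index=[f"g{i}" for i in range(50)],
        )
        counts.loc["g0", ["treated_r1", "treated_r2"]] *= 4
        # mild replicate jitter so variances are estimable
        counts.loc["g1":, "treated_r1"] *= 1.02
        norm = screen.normalize_counts(counts)
        diff = screen.paired_differential(norm, _design(2))
        assert diff.loc["g0", "log2fc"] == pytest.approx(2.0, abs=0.1)
        assert diff.loc["g0", "stat"] > 0

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"control_r1": [1.0], "treated_r1": [2.0]})
        with pytest.raises(ValueError, match="replicate"):
            screen.paired_differential(counts, _design(1))

    def test_stat_sign_agrees_with_log2fc(self, rng):
        counts = pd.DataFrame(
            rng.integers(10, 400, size=(80, 4)).astype(float),
            columns=["control_r1", "treated_r1", "control_r2", "treated_r2"],
        )
        diff = screen.paired_differential(counts, _design(2))
        nz = (diff["log2fc"] != 0) & (diff["stat"] != 0)
        assert (np.sign(diff.loc[nz, "stat"]) == np.sign(diff.loc[nz, "log2fc"])).all()

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps

        lib = simulate.make_library(25, 4, seed=31)
        cfg = simulate.ScreenSimConfig(
            n_replicates=2, depth_per_guide=500, nb_dispersion=0.1, seed=32
        )
        counts, _ = simulate.simulate_counts(lib, cfg)
        diff = screen.paired_differential(screen.normalize_counts(counts), _design(2))
        assert sps.kstest(diff["p"], "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# ranking and RRA


class TestRankGuides:
    def test_enriched_ranking(self):
        diff = pd.DataFrame({"stat": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        r = screen.rank_guides(diff, "enriched")
        assert r.loc[["a", "b", "c"], "r"].tolist() == [1 / 3, 1.0, 2 / 3]

    def test_depleted_ranking(self):
        diff = pd.DataFrame({"stat": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        r = screen.rank_guides(diff, "depleted")
        assert r.loc[["a", "b", "c"], "r"].tolist() == [1.0, 1 / 3, 2 / 3]

    def test_ties_break_lexicographically(self):
        diff = pd.DataFrame({"stat": [1.0, 1.0, 1.0]}, index=["c", "a", "b"])
        r = screen.rank_guides(diff, "enriched")
        assert r.loc[["a", "b", "c"], "rank"].tolist() == [1, 2, 3]


class TestAlphaRRA:
    def test_single_guide_rho_is_its_rank(self):
        ranks = pd.DataFrame({"r": [0.01]}, index=["g1"])
        out = screen.alpha_rra(ranks, {"g1": "G"}, alpha=0.1, n_perm=10, seed=0)
        assert out.loc["G", "rho"] == pytest.approx(0.01)

    def test_two_guide_closed_form(self):
        # min of P(U_(1 of 2) <= 0.05) = 1 - 0.95^2 and P(U_(2 of 2) <= 0.10) = 0.01
        ranks = pd.DataFrame({"r": [0.05, 0.10]}, index=["g1", "g2"])
        out = screen.alpha_rra(
            ranks, {"g1": "G", "g2": "G"}, alpha=0.25, n_perm=10, seed=0
        )
        assert out.loc["G", "rho"] == pytest.approx(0.01)
        assert out.loc["G", "k_sel"] == 2

    def test_rank_above_alpha_excluded(self):
        ranks = pd.DataFrame({"r": [0.05, 0.60]}, index=["g1", "g2"])
        out = screen.alpha_rra(
            ranks, {"g1": "G", "g2": "G"}, alpha=0.25, n_perm=10, seed=0
        )
        assert out.loc["G", "k_sel"] == 1
        assert out.loc["G", "rho"] == pytest.approx(1 - 0.95**2)

    def test_no_selected_guides_gives_rho_one(self):
        ranks = pd.DataFrame({"r": [0.5, 0.9]}, index=["g1", "g2"])
        out = screen.alpha_rra(
            ranks, {"g1": "G", "g2": "G"}, alpha=0.25, n_perm=10, seed=0
        )
        assert out.loc["G", "rho"] == 1.0

    def test_matches_brute_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 4))
            n_other = 30
            rvals = np.sort(rng.random(k + n_other))
            guides = [f"g{i}" for i in range(k + n_other)]
            picked = rng.choice(k + n_other, size=k, replace=False)
            g2g = {
                guides[i]: ("TARGET" if i in picked else f"O{i}")
                for i in range(k + n_other)
            }
            ranks = pd.DataFrame({"r": rvals}, index=guides)
            alpha = float(rng.uniform(0.2, 0.9))
            out = screen.alpha_rra(ranks, g2g, alpha=alpha, n_perm=5, seed=1)
            expected = brute_rho([rvals[i] for i in picked], alpha)
            assert out.loc["TARGET", "rho"] == pytest.approx(expected, rel=1e-9)

    def test_planted_gene_scores_best(self, rng):
        n = 2000
        r = (np.arange(n) + 1) / n
        rng.shuffle(r)
        guides = [f"g{i}" for i in range(n)]
        ranks = pd.DataFrame({"r": r}, index=guides)
        # plant one gene whose 4 guides sit in the top 2%
        top = np.argsort(r)[:4]
        g2g = {guides[i]: f"O{i // 4}" for i in range(n)}
        for i in top:
            g2g[guides[i]] = "PLANTED"
        out = screen.alpha_rra(ranks, g2g, alpha=0.25, n_perm=1000, seed=3)
        assert out["rho"].idxmin() == "PLANTED"
        assert out.loc["PLANTED", "p_perm"] == out["p_perm"].min()


class TestBHAdjust:
    def test_textbook_example(self):
        assert np.allclose(
            screen.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert screen.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(screen.bh_adjust(p), brute_bh(list(p)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_output_in_unit_interval_and_dominates_input_order(self, pvals):
        adj = screen.bh_adjust(pvals)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# intersection / GSEA / coverage


def _gene_table(genes, pvals):
    return pd.DataFrame(
        {"rho": pvals, "p_perm": pvals}, index=pd.Index(genes, name="gene")
    )


class TestTopFractionIntersection:
    def test_identical_tables_overlap_is_top_quarter(self):
        genes = [f"G{i}" for i in range(20)]
        t = _gene_table(genes, np.linspace(0.001, 1, 20))
        overlap, table = screen.top_fraction_intersection(t, t, 0.25)
        assert overlap == set(genes[:5])
        assert len(table) == 5

    def test_disjoint_top_sets_give_empty_overlap(self):
        genes = [f"G{i}" for i in range(8)]
        a = _gene_table(genes, [0.01, 0.02, 0.9, 0.9, 0.9, 0.9, 0.95, 1.0])
        b = _gene_table(genes, [0.9, 0.9, 0.9, 0.9, 0.95, 1.0, 0.01, 0.02])
        overlap, _ = screen.top_fraction_intersection(a, b, 0.25)
        assert overlap == set()

    def test_disjoint_universes_rejected(self):
        a = _gene_table(["A1"], [0.1])
        b = _gene_table(["B1"], [0.1])
        with pytest.raises(ValueError, match="overlap"):
            screen.top_fraction_intersection(a, b, 0.25)


class TestGseaEnrichment:
    def test_top_gene_singleton_hits_es_one_at_weight_zero(self):
        scores = pd.Series([5.0, 4.0, 3.0, 2.0], index=list("abcd"))
        res = screen.gsea_enrichment(scores, {"a"}, weight=0.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_interleaved_set_scores_near_zero(self):
        scores = pd.Series(np.arange(100, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(100)])
        interleaved = {f"g{i}" for i in range(0, 100, 2)}
        res = screen.gsea_enrichment(scores, interleaved, weight=0.0, n_perm=10, seed=0)
        assert abs(res.es) < 0.05

    def test_matches_brute_force_running_sum(self, rng):
        genes = [f"g{i}" for i in range(500)]
        scores = pd.Series(rng.normal(size=500), index=genes)
        for _ in range(20):
            members = set(rng.choice(genes, size=20, replace=False))
            res = screen.gsea_enrichment(scores, members, weight=1.0, n_perm=5, seed=2)
            assert res.es == pytest.approx(brute_es(scores, members, 1.0), rel=1e-9)

    def test_whole_universe_set_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            screen.gsea_enrichment(scores, {"a", "b"}, n_perm=5)


class TestRequiredCells:
    def test_screen_scale_transduction(self):
        assert screen.required_cells(500, 188509, 0.25) == 377_018_000

    def test_screen_scale_maintenance(self):
        assert screen.required_cells(500, 188509, 1.0) == 94_254_500

    def test_small_exact_case(self):
        assert screen.required_cells(1, 100, 1.0) == 100

    def test_bad_surviving_fraction(self):
        with pytest.raises(ValueError):
            screen.required_cells(500, 100, 0.0)
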