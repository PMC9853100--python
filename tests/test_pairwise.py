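"""All-pairs orchestration, FDR control, grid and taxon selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairratio import (
    CountTable,
    DomainError,
    amalgamate,
    bh_adjust,
    build_grid,
    count_taxa,
    enumerate_pairs,
    make_fixture_table,
    prevalence_filter,
    run_all_pairs,
    run_mww_mode,
    unwrap_taxa,
)
from pairratio.pairwise import SignificanceGrid


def table_from_counts(counts: np.ndarray, groups=None) -> CountTable:
    k, n = counts.shape
    taxa = [f"t{i+1}" for i in range(k)]
    samples = [f"s{j+1}" for j in range(n)]
    if groups is None:
        groups = np.where(np.arange(n) % 2, "treatment", "control")
    meta = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    return CountTable(counts=pd.DataFrame(counts, index=taxa, columns=samples), metadata=meta)


def grid_from_pairs(taxa, pairs, threshold=0.05) -> SignificanceGrid:
    mat = pd.DataFrame(False, index=taxa, columns=taxa)
    for a, b in pairs:
        mat.loc[a, b] = mat.loc[b, a] = True
    return SignificanceGrid(matrix=mat, threshold=threshold)


class TestEnumeratePairs:
    @pytest.mark.parametrize("k,expected", [(51, 1275), (2, 1), (4, 6)])
    def test_pair_counts(self, k, expected):
        table = table_from_counts(np.ones((k, 4), dtype=int))
        pairs = enumerate_pairs(table)
        assert len(pairs) == expected
        assert len(set(pairs)) == expected

    def test_deterministic_table_order(self):
        table = table_from_counts(np.ones((3, 4), dtype=int))
        assert enumerate_pairs(table) == [("t1", "t2"), ("t1", "t3"), ("t2", "t3")]

    def test_single_taxon_error(self):
        with pytest.raises(DomainError):
            enumerate_pairs(table_from_counts(np.ones((1, 4), dtype=int)))


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :2] = 5  # present in exactly 20% of samples
        counts[1, :1] = 5  # present in 10%
        out = prevalence_filter(table_from_counts(counts), 0.2)
        assert out.taxon_ids == ["t1"]

    def test_constructed_sixty_taxon_table(self, rng):
        counts = np.zeros((60, 20), dtype=int)
        for i in range(30):  # 30 taxa at 50% prevalence
            counts[i, rng.choice(20, 10, replace=False)] = 1
        for i in range(30, 60):  # 30 taxa at 10% prevalence
            counts[i, rng.choice(20, 2, replace=False)] = 1
        out = prevalence_filter(table_from_counts(counts), 0.2)
        assert out.n_taxa == 30
        assert out.n_samples == 20

    def test_empty_result_warns(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[:, 0] = 1
        with pytest.warns(UserWarning):
            out = prevalence_filter(table_from_counts(counts), 0.5)
        assert out.n_taxa == 0

    def test_invalid_threshold(self, small_table):
        with pytest.raises(DomainError):
            prevalence_filter(small_table, 0.0)


def _bh_oracle(p):
    """Independent textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(_bh_oracle(p), rel=1e-12)

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(_bh_oracle([0.01, 0.04]))

    def test_out_of_range_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_q_monotone_in_sorted_order_and_capped(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture(scope="module")
def planted_table():
    """4 comparably abundant taxa, one with a strong planted group effect."""
    return make_fixture_table(
        k_taxa=4, n_samples=60, sparsity_profile=[1.0] * 4,
        effect_spec={"taxon_01": 2.5}, seed=31, two_study=False,
        overdispersion_sd=0.7, base_weights=[0.4, 0.3, 0.2, 0.1],
    )


@pytest.fixture(scope="module")
def planted_results(planted_table):
    return run_all_pairs(planted_table, method="bbglm", seed=0)


class TestRunAllPairs:
    def test_planted_effect_found_only_in_its_ratios(self, planted_results):
        res = planted_results.set_index(["taxon_a", "taxon_b"])
        sig = res["q_value"] < 0.05
        involving = [p for p in sig.index if "taxon_01" in p]
        others = [p for p in sig.index if "taxon_01" not in p]
        assert all(sig[p] for p in involving)
        assert not any(sig[p] for p in others)

    def test_row_count_and_status(self, planted_results):
        assert len(planted_results) == 6
        assert set(planted_results["status"]) <= {"ok", "boundary"}

    def test_null_table_has_no_discoveries(self):
        table = make_fixture_table(k_taxa=6, n_samples=60, sparsity_profile=[1.0] * 6,
                                   seed=7, two_study=False)
        res = run_all_pairs(table, method="bbglm")
        assert (res["q_value"] < 0.05).sum() == 0

    def test_taxon_order_swap_flips_estimates(self, planted_table):
        res = run_all_pairs(planted_table, method="bbglm")
        rev = CountTable(counts=planted_table.counts.iloc[::-1].copy(),
                         metadata=planted_table.metadata.copy())
        res_rev = run_all_pairs(rev, method="bbglm")
        merged = res.merge(
            res_rev.rename(columns={"taxon_a": "taxon_b", "taxon_b": "taxon_a"}),
            on=["taxon_a", "taxon_b"], suffixes=("", "_rev"),
        )
        assert len(merged) == 6
        assert merged["estimate_rev"].to_numpy() == pytest.approx(
            -merged["estimate"].to_numpy(), abs=1e-5)
        assert merged["p_value_rev"].to_numpy() == pytest.approx(
            merged["p_value"].to_numpy(), abs=1e-5)

    def test_subcompositional_coherence_bit_identical(self, planted_table):
        res = run_all_pairs(planted_table, method="bbglm")
        sub = CountTable(counts=planted_table.counts.drop(index="taxon_04").copy(),
                         metadata=planted_table.metadata.copy())
        res_sub = run_all_pairs(sub, method="bbglm")
        row = res[(res.taxon_a == "taxon_02") & (res.taxon_b == "taxon_03")].iloc[0]
        row_sub = res_sub[(res_sub.taxon_a == "taxon_02") & (res_sub.taxon_b == "taxon_03")].iloc[0]
        assert row["estimate"] == row_sub["estimate"]  # bit-identical
        assert row["p_value"] == row_sub["p_value"]

    def test_min_information_rule_skips_and_shrinks_family(self, rng):
        # t3 and t4 are jointly absent except in 4 samples, so the (t3, t4)
        # pair has fewer than 5 informative samples per group
        n = 40
        counts = np.vstack([
            rng.integers(50, 200, n),
            rng.integers(50, 200, n),
            np.r_[[3, 5, 2, 4], np.zeros(n - 4, int)],
            np.r_[[1, 2, 3, 4], np.zeros(n - 4, int)],
        ])
        table = table_from_counts(counts)
        res = run_all_pairs(table, method="bbglm", min_informative=5)
        skipped = res[res["status"] == "skipped"]
        assert {("t3", "t4")} == set(zip(skipped["taxon_a"], skipped["taxon_b"]))
        assert skipped["p_value"].isna().all() and skipped["q_value"].isna().all()
        # remaining q-values form their own BH family
        ok = res[res["status"] != "skipped"]
        assert ok["q_value"].to_numpy() == pytest.approx(
            _bh_oracle(ok["p_value"].to_numpy()), rel=1e-9)

    def test_reference_methods_share_schema(self, planted_table):
        for method in ("lrlm", "lrlm_2", "lrw", "lrp"):
            res = run_all_pairs(planted_table, method=method, n_perm=299, seed=1)
            assert len(res) == 6
            assert res["method_tag"].eq(method).all()
            assert res["p_value"].between(0, 1).all()


class TestGrid:
    def test_no_significant_ratios_gives_empty_grid(self, rng):
        res = pd.DataFrame({"taxon_a": ["a", "a"], "taxon_b": ["b", "c"],
                            "q_value": [0.5, 0.9]})
        grid = build_grid(res)
        assert grid.matrix.shape == (0, 0)

    def test_three_pairs_give_six_true_cells(self):
        res = pd.DataFrame({
            "taxon_a": ["a", "a", "a", "b", "b", "c"],
            "taxon_b": ["b", "c", "d", "c", "d", "d"],
            "q_value": [0.01, 0.02, 0.03, 0.5, 0.6, 0.7],
        })
        grid = build_grid(res)
        assert grid.matrix.to_numpy().sum() == 6
        assert np.array_equal(grid.matrix.to_numpy(), grid.matrix.to_numpy().T)
        assert not np.diag(grid.matrix.to_numpy()).any()

    def test_grid_matches_per_cell_recomputation(self, planted_results):
        grid = build_grid(planted_results, q_threshold=0.05, restrict=False)
        for _, r in planted_results.iterrows():
            expect = bool(r["q_value"] < 0.05) if np.isfinite(r["q_value"]) else False
            assert bool(grid.matrix.loc[r["taxon_a"], r["taxon_b"]]) == expect


class TestRankings:
    def test_unwrap_star(self):
        grid = grid_from_pairs(["t1", "t2", "t3", "t4"], [("t1", "t2"), ("t1", "t3"), ("t1", "t4")])
        rank = unwrap_taxa(grid)
        assert rank.taxa == ["t1"]
        assert rank.counts == [3]

    def test_unwrap_empty(self):
        grid = grid_from_pairs(["t1", "t2"], [])
        assert unwrap_taxa(grid).taxa == []

    def test_unwrap_tie_break_by_table_order(self):
        grid = grid_from_pairs(["t1", "t2", "t3", "t4"], [("t1", "t2"), ("t3", "t4")])
        assert unwrap_taxa(grid).taxa == ["t1", "t3"]

    def test_unwrap_accounts_for_all_ratios(self, rng):
        taxa = [f"t{i}" for i in range(1, 9)]
        pairs = set()
        while len(pairs) < 10:
            i, j = sorted(rng.choice(8, 2, replace=False))
            pairs.add((taxa[i], taxa[j]))
        grid = grid_from_pairs(taxa, sorted(pairs))
        rank = unwrap_taxa(grid)
        assert len(rank.taxa) <= len(taxa)
        assert sum(rank.counts) == len(pairs)  # every significant ratio accounted once

    def test_count_ranking(self):
        grid = grid_from_pairs(["t1", "t2", "t3"], [("t1", "t2"), ("t1", "t3")])
        rank = count_taxa(grid)
        assert rank.taxa == ["t1", "t2", "t3"]
        assert rank.counts == [2, 1, 1]

    def test_count_star_graph(self):
        taxa = [f"t{i}" for i in range(1, 6)]
        grid = grid_from_pairs(taxa, [("t1", x) for x in taxa[1:]])
        rank = count_taxa(grid)
        assert rank.counts == [4, 1, 1, 1, 1]

    def test_count_empty_grid_all_zeros(self):
        grid = grid_from_pairs(["t1", "t2"], [])
        assert count_taxa(grid).counts == [0, 0]


class TestMWWMode:
    def test_two_taxon_table_equals_pairwise(self, rng):
        counts = np.vstack([rng.integers(50, 500, 40), rng.integers(50, 500, 40)])
        counts[0, 20:] = counts[0, 20:] * 3  # shift numerator in treatment group
        groups = np.repeat(["control", "treatment"], 20)
        table = table_from_counts(counts, groups=groups)
        pairwise = run_all_pairs(table, method="bbglm").iloc[0]
        mww = run_mww_mode(table).iloc[0]
        assert mww["estimate"] == pytest.approx(pairwise["estimate"], abs=1e-6)
        assert mww["p_value"] == pytest.approx(pairwise["p_value"], abs=1e-6)

    def test_dominant_shift_creates_closure_artifacts(self):
        """An absolute shift in the dominant taxon flags it (and possibly others)."""
        table = make_fixture_table(k_taxa=5, n_samples=80, sparsity_profile=[1.0] * 5,
                                   effect_spec={"taxon_01": 2.0}, seed=13,
                                   two_study=False, overdispersion_sd=0.6)
        res = run_mww_mode(table).set_index("taxon_a")
        assert res.loc["taxon_01", "q_value"] < 0.05


class TestAmalgamate:
    def test_counts_are_summed(self, small_table):
        out = amalgamate(small_table, ["taxonA", "taxonB"], new_id="AB")
        assert list(out.counts.loc["AB"]) == [15, 21, 37, 14]
        assert out.n_taxa == 2

    def test_unknown_taxon(self, small_table):
        with pytest.raises(DomainError):
            amalgamate(small_table, ["taxonA", "nope"])
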