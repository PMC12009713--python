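"""The enrichment engine: KS comparison, BH adjustment, and the model/results
pairing, checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsea import (
    RankedTaxa,
    TaxonSet,
    TaxonSetDatabase,
    TaxonSetEnrichment,
    bh_adjust,
    ks_two_sample,
    run_enrichment,
)

from .oracles import bh_oracle, brute_force_ks


class TestRankedTaxa:
    def test_rejects_duplicates_nonfinite_and_tiny_input(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedTaxa([("a", 1.0), ("a", 2.0)])
        with pytest.raises(ValueError, match="non-finite"):
            RankedTaxa({"a": np.nan, "b": 1.0})
        with pytest.raises(ValueError, match="at least 2"):
            RankedTaxa({"a": 1.0})

    def test_series_round_trip(self):
        ranked = RankedTaxa({"a": 1.5, "b": -0.5})
        assert RankedTaxa.from_series(ranked.to_series()) == ranked


class TestKsTwoSample:
    def test_identical_samples_give_zero_distance(self):
        out = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert out.statistic == 0.0
        assert out.p_value == 1.0
        assert out.tied

    def test_fully_separated_small_samples(self):
        # All C(5,2)=10 interleavings are equally likely under the null and
        # exactly 2 of them (members at either extreme) reach D = 1.
        out = ks_two_sample([4, 5], [1, 2, 3])
        assert out.statistic == 1.0
        assert out.p_value == pytest.approx(0.2, abs=1e-15)
        assert out.exact and not out.tied

    def test_matches_enumeration_oracle_on_random_splits(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(1, n))
            values = rng.normal(size=n)
            while len(np.unique(values)) < n:  # oracle needs distinct values
                values = rng.normal(size=n)
            out = ks_two_sample(values[:m], values[m:])
            d_ref, p_ref = brute_force_ks(values[:m], values[m:])
            assert out.statistic == pytest.approx(d_ref, abs=1e-12)
            assert out.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_empty_side_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_two_sample([], [1.0, 2.0])

    def test_cross_sample_ties_flagged_and_asymptotic(self):
        out = ks_two_sample([1.0, 2.0, 5.0], [2.0, 3.0, 4.0])
        assert out.tied and not out.exact

    def test_large_product_uses_asymptotic_path(self):
        rng = np.random.default_rng(0)
        out = ks_two_sample(rng.normal(size=60), rng.normal(size=250))
        assert not out.exact

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(2, 7), st.integers(0, 2 ** 16))
    def test_invariant_under_increasing_transforms(self, m, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=m), rng.normal(size=9 - m)
        base = ks_two_sample(x, y)
        for f in (np.exp, lambda v: 3 * v + 7, np.arctan):
            out = ks_two_sample(f(x), f(y))
            assert out.statistic == base.statistic
            assert out.p_value == base.p_value


class TestBhAdjust:
    def test_worked_example(self):
        # m*p_(j)/j = .04, .04, .04, .04; cumulative min leaves all at .04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_constant_vectors_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)


def _one_set_db(members, set_id="s1"):
    return TaxonSetDatabase([TaxonSet(set_id, set_id, "custom", tuple(members))])


class TestEnrichmentModel:
    def test_top_block_set_exact_p_and_median(self, small_ranked):
        # 5 members hold values {6..10} of 1..10: median 8, and p must equal
        # the exact two-sample KS p for that 5-vs-5 split (enumeration over
        # all C(10,5)=252 interleavings).
        db = _one_set_db([f"t{i}" for i in range(6, 11)])
        res = TaxonSetEnrichment(small_ranked, db, min_size=5).fit()
        row = res["s1"]
        assert row.median_rank == 8.0
        assert row.n_detected == 5
        d_ref, p_ref = brute_force_ks([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert row.ks_statistic == pytest.approx(d_ref, abs=1e-12)
        assert row.p_value == pytest.approx(p_ref, abs=1e-12)
        assert row.fdr == pytest.approx(p_ref, abs=1e-12)  # single test

    def test_even_count_median_is_mean_of_central_pair(self, small_ranked):
        db = _one_set_db(["t1", "t2", "t3", "t4", "t5", "t6"])
        row = run_enrichment(small_ranked, db, min_size=5)["s1"]
        assert row.median_rank == 3.5

    def test_no_surviving_set_gives_empty_result_with_warning(
            self, small_ranked, caplog):
        db = _one_set_db(["t1", "t2", "t3", "t4"])
        with caplog.at_level("WARNING"):
            res = run_enrichment(small_ranked, db, min_size=5)
        assert len(res) == 0
        assert any("no taxon set" in r.message for r in caplog.records)

    def test_set_covering_all_taxa_skipped_with_warning(self, small_ranked, caplog):
        db = _one_set_db([f"t{i}" for i in range(1, 11)])
        with caplog.at_level("WARNING"):
            res = run_enrichment(small_ranked, db, min_size=5)
        assert len(res) == 0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_bh_applied_across_tested_sets_only(self, null_background, fixture_db):
        res = run_enrichment(null_background, fixture_db, min_size=5)
        assert 0 < len(res) < len(fixture_db)  # some small sets filtered out
        raw = [r.p_value for r in res.rows]
        assert [r.fdr for r in res.rows] == pytest.approx(
            sorted(bh_oracle(raw)), abs=1e-12)

    def test_results_sorted_by_fdr_then_p_then_id(self, null_background, fixture_db):
        res = run_enrichment(null_background, fixture_db)
        keys = [(r.fdr, r.p_value, r.set_id) for r in res.rows]
        assert keys == sorted(keys)

    def test_permutation_symmetry(self, fixture_db, null_background):
        # Relabelling taxa while permuting values identically changes nothing.
        rng = np.random.default_rng(5)
        items = list(null_background.items())
        perm = rng.permutation(len(items))
        shuffled = RankedTaxa([items[i] for i in perm])
        a = run_enrichment(null_background, fixture_db).frame
        b = run_enrichment(shuffled, fixture_db).frame
        cols = ["set_id", "n_detected", "median_rank", "ks_statistic",
                "p_value", "fdr"]
        assert a[cols].equals(b[cols])

    def test_from_dataframe_constructor(self, fixture_db):
        import pandas as pd

        taxa = sorted(fixture_db.universe)[:60]
        frame = pd.DataFrame({
            "taxon": taxa,
            "log2FoldChange": np.linspace(-1, 1, 60),
        })
        res = TaxonSetEnrichment.from_dataframe(frame, fixture_db).fit()
        assert all(r.n_detected >= 5 for r in res.rows)

    def test_summary_mentions_counts_and_direction(self, null_background, fixture_db):
        res = run_enrichment(null_background, fixture_db)
        text = res.summary()
        assert "input taxa: 300" in text
        assert "FDR" in text and ("up" in text or "down" in text)

    def test_tsv_round_trip_preserves_values(self, tmp_path, null_background,
                                             fixture_db):
        import pandas as pd

        res = run_enrichment(null_background, fixture_db)
        out = tmp_path / "results.tsv"
        res.to_tsv(out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame.columns) == list(res.frame.columns)
        assert frame["p_value"].to_numpy() == pytest.approx(
            res.frame["p_value"].to_numpy(), rel=1e-9)
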