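"""Modified leave-one-out nearest-neighbour identification."""

import numpy as np
import pytest

from acaritax.distances import DistanceMatrix, distance_matrix
from acaritax.identification import (
    LOOConfig,
    loo_identify,
    results_to_frame,
    summarize_success,
    top_hit,
)
from acaritax.simulate import SyntheticConfig, generate_library
from conftest import make_dm, make_library, make_record


def _three_record_lib():
    # q's BIN-mate at 1%, a cross-BIN neighbour at 5%
    return make_library([
        make_record("q", "A" * 100, bin_id="B1", family="f1"),
        make_record("mate", "A" * 100, bin_id="B1", family="f1"),
        make_record("other", "A" * 100, bin_id="B2", family="f1"),
    ])


class TestTopHit:
    def test_exclusion_radius_skips_bin_mates(self):
        lib = _three_record_lib()
        D = make_dm(["q", "mate", "other"],
                    {("q", "mate"): 0.01, ("q", "other"): 0.05,
                     ("mate", "other"): 0.05}, overlap_bp=100)
        res = top_hit("q", lib, D, LOOConfig(exclusion_div=0.02))
        assert res.hit_id == "other"
        assert res.similarity == pytest.approx(95.0)

    def test_limited_overlap_gives_no_hit(self):
        lib = make_library([
            make_record("q", "A" * 100),
            make_record("r", "A" * 100),
        ])
        D = make_dm(["q", "r"], {("q", "r"): 0.05}, overlap_bp=40)  # 40% of 100
        res = top_hit("q", lib, D, LOOConfig(exclusion_div=0.02, min_overlap_frac=0.5))
        assert res.hit_id is None
        assert res.correct_family is None

    def test_equal_similarity_tie_goes_to_smallest_id(self):
        lib = make_library([
            make_record("q", "A" * 100),
            make_record("z", "A" * 100, bin_id="B2"),
            make_record("b", "A" * 100, bin_id="B3"),
        ])
        D = make_dm(["q", "z", "b"],
                    {("q", "z"): 0.05, ("q", "b"): 0.05, ("z", "b"): 0.2},
                    overlap_bp=100)
        res = top_hit("q", lib, D, LOOConfig(exclusion_div=0.02))
        assert res.hit_id == "b"

    def test_candidate_without_family_label_is_ineligible(self):
        lib = make_library([
            make_record("q", "A" * 100, family="f1"),
            make_record("r", "A" * 100, bin_id="B2", family=""),
            make_record("s", "A" * 100, bin_id="B3", family="f2"),
        ])
        D = make_dm(["q", "r", "s"],
                    {("q", "r"): 0.03, ("q", "s"): 0.10, ("r", "s"): 0.10},
                    overlap_bp=100)
        res = top_hit("q", lib, D, LOOConfig(exclusion_div=0.02))
        assert res.hit_id == "s"


class TestLOO:
    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            loo_identify(make_library([make_record("a", "ACGT")]))

    def test_two_records_different_orders_mispredict_each_other(self):
        lib = make_library([
            make_record("a", "A" * 50 + "C" * 50, order="o1", family="f1"),
            make_record("b", "A" * 50 + "G" * 50, order="o2", family="f2",
                        bin_id="B2"),
        ])
        results = loo_identify(lib, LOOConfig(exclusion_div=0.02))
        assert all(r.correct_order is False for r in results)
        assert results[0].hit_id == "b" and results[1].hit_id == "a"

    def test_zero_exclusion_equals_global_nearest_neighbour(self):
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=3, bins_per_family=2,
            seqs_per_bin=2, ambiguity_rate=0.0, seed=11,
        )
        lib, _ = generate_library(cfg)
        D = distance_matrix(lib)
        results = loo_identify(lib, LOOConfig(exclusion_div=0.0,
                                              min_overlap_frac=0.01), D)
        for k, res in enumerate(results):
            row = D.d[k].copy()
            row[k] = np.inf
            assert res.similarity == pytest.approx(100 * (1 - row.min()))

    def test_raising_exclusion_never_increases_similarity(self):
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=3, bins_per_family=2,
            seqs_per_bin=2, ambiguity_rate=0.0, seed=7,
        )
        lib, _ = generate_library(cfg)
        D = distance_matrix(lib)
        prev = None
        for excl in (0.0, 0.02, 0.05, 0.10):
            res = loo_identify(lib, LOOConfig(exclusion_div=excl), D)
            sims = np.array([r.similarity for r in res])
            if prev is not None:
                both = ~np.isnan(sims) & ~np.isnan(prev)
                assert (sims[both] <= prev[both] + 1e-12).all()
            prev = sims

    def test_multi_bin_families_identified_correctly(self):
        """With >=2 BINs per family, shallow within-family divergence and a
        10% interfamily floor, every query finds a same-family hit."""
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=4, bins_per_family=3,
            seqs_per_bin=2, intra_bin_max=0.02, interbin_range=(0.05, 0.08),
            bin_sibling_prob=0.0, interfamily_floor=0.10,
            ambiguity_rate=0.0, seed=42,
        )
        lib, _ = generate_library(cfg)
        results = loo_identify(lib, LOOConfig(exclusion_div=0.02))
        assert all(r.correct_family for r in results)
        assert all(r.correct_order for r in results)

    def test_single_bin_families_are_misassigned(self):
        """A family with one BIN cannot be identified once its own BIN is
        excluded: the nearest eligible hit lies in another family."""
        cfg = SyntheticConfig(
            n_orders=1, families_per_order=3, bins_per_family=1,
            seqs_per_bin=3, bin_sibling_prob=0.0, ambiguity_rate=0.0, seed=5,
        )
        lib, _ = generate_library(cfg)
        results = loo_identify(lib, LOOConfig(exclusion_div=0.02))
        assert all(r.correct_family is False for r in results)
        assert all(r.correct_order for r in results)  # same single order


class TestSummarize:
    def test_all_correct_fixture(self):
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=3, bins_per_family=3,
            seqs_per_bin=2, intra_bin_max=0.02, interbin_range=(0.05, 0.08),
            bin_sibling_prob=0.0, ambiguity_rate=0.0, seed=1,
        )
        lib, _ = generate_library(cfg)
        results = loo_identify(lib, LOOConfig(exclusion_div=0.02))
        summary = summarize_success(results, by="all")
        assert summary.loc[0, "pct_correct_order"] == 100.0
        assert summary.loc[0, "pct_correct_family"] == 100.0

    def test_grouped_counts_sum_to_global(self):
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=3, bins_per_family=(1, 4),
            seqs_per_bin=2, ambiguity_rate=0.0, seed=9,
        )
        lib, _ = generate_library(cfg)
        results = loo_identify(lib, LOOConfig(exclusion_div=0.02))
        g = summarize_success(results, by="order")
        a = summarize_success(results, by="all")
        assert g["n_queries"].sum() == a.loc[0, "n_queries"]
        assert g["n_with_hit"].sum() == a.loc[0, "n_with_hit"]
        assert g["n_unassignable"].sum() == a.loc[0, "n_unassignable"]

    def test_fraction_wrong_reflected_in_percentage(self):
        df = results_to_frame(
            loo_identify(
                generate_library(
                    SyntheticConfig(n_orders=1, families_per_order=2,
                                    bins_per_family=1, seqs_per_bin=5,
                                    bin_sibling_prob=0.0,
                                    ambiguity_rate=0.0, seed=2)
                )[0],
                LOOConfig(exclusion_div=0.02),
            )
        )
        summary = summarize_success(df, by="all")
        assert summary.loc[0, "pct_correct_family"] == 0.0
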