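"""Windowing, counting, masking, the CQ statistic and classification."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqscan import (
    CQConfig,
    apply_mask,
    calibrate,
    classify_cq,
    compute_cq,
    count_hits,
    count_hits_from_alignments,
    filter_and_classify,
    partition_windows,
)
from cqscan.cq import (
    FILTERED_LOW_MALE,
    FILTERED_MASKED,
    GREY,
    MALE_BIASED,
    STATUSES,
    UNBIASED,
)


class TestPartition:
    def test_exact_tiling(self):
        w = partition_windows({"A": 1500}, 500)
        assert list(zip(w["start"], w["end"])) == [(0, 500), (500, 1000), (1000, 1500)]

    def test_short_final_window_kept(self):
        w = partition_windows({"A": 1250}, 500)
        assert len(w) == 3
        assert (w.iloc[-1]["start"], w.iloc[-1]["end"]) == (1000, 1250)

    def test_nonpositive_length_names_chromosome(self):
        with pytest.raises(ValueError, match="'A'"):
            partition_windows({"A": 0}, 500)


class TestComputeCQ:
    @pytest.mark.parametrize(
        "f,m,expected",
        [
            (0, 100, 0.0),
            (1, 20, 1 / 20.01),
            (5, 0, 500.0),
            (100, 100, 100 / 100.01),
        ],
    )
    def test_printed_formula(self, f, m, expected):
        assert compute_cq(f, m) == pytest.approx(expected, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_cq(-1, 5)

    @given(f=st.integers(0, 10_000), m=st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, f, m):
        assert compute_cq(f + 1, m) > compute_cq(f, m)
        if f > 0:
            assert compute_cq(f, m + 1) < compute_cq(f, m)

    def test_agrees_with_rational_arithmetic(self):
        """Float evaluation matches exact Fraction arithmetic to 1e-12."""
        rng = np.random.default_rng(0)
        fs = rng.integers(0, 5000, size=20_000)
        ms = rng.integers(0, 5000, size=20_000)
        got = compute_cq(fs, ms)
        for f, m, g in zip(fs, ms, got):
            exact = Fraction(int(f) * 100, int(m) * 100 + 1)  # F / (M + 1/100)
            if exact == 0:
                assert g == 0
            else:
                assert abs(g - float(exact)) <= 1e-12 * float(exact)


class TestClassification:
    def test_retention_boundary_is_strict(self):
        """Exactly 20 male hits is excluded; 21 is retained."""
        w = partition_windows({"A": 1500}, 500)
        w["male_hits"] = [19, 20, 21]
        w["female_hits"] = 0
        out = filter_and_classify(w)
        assert out["status"].tolist() == [
            FILTERED_LOW_MALE, FILTERED_LOW_MALE, MALE_BIASED,
        ]
        assert out["cq"].isna().tolist() == [True, True, False]

    @pytest.mark.parametrize(
        "cq,expected",
        [
            (0.0, MALE_BIASED),
            (0.05, MALE_BIASED),  # inclusive upper bound of the plotted set
            (0.0500001, GREY),
            (0.30, GREY),
            (0.50, GREY),
            (0.51, UNBIASED),
            (0.90, UNBIASED),
        ],
    )
    def test_class_bounds(self, cq, expected):
        assert classify_cq(cq) == expected

    def test_exclusive_male_bias_option(self):
        config = CQConfig(male_bias_inclusive=False)
        assert classify_cq(0.05, config) == GREY
        assert classify_cq(0.0499, config) == MALE_BIASED

    def test_status_partition(self):
        """Every window carries exactly one status from the closed set."""
        rng = np.random.default_rng(5)
        w = partition_windows({"A": 50_000}, 500)
        w["female_hits"] = rng.integers(0, 200, len(w))
        w["male_hits"] = rng.integers(0, 200, len(w))
        w.loc[:4, "status"] = FILTERED_MASKED
        out = filter_and_classify(w)
        assert out["status"].isin(STATUSES).all()
        assert out["status"].notna().all()
        # cq defined exactly on retained windows
        retained = ~out["status"].isin([FILTERED_LOW_MALE, FILTERED_MASKED])
        assert out.loc[retained, "cq"].notna().all()
        assert out.loc[~retained, "cq"].isna().all()

    def test_normalization_rescales_by_depth_ratio(self):
        w = partition_windows({"A": 5000}, 500)
        w["female_hits"] = 200
        w["male_hits"] = 100
        raw = filter_and_classify(w, CQConfig())
        scaled = filter_and_classify(w, CQConfig(normalize=True))
        assert raw["cq"].mean() == pytest.approx(200 / 100.01)
        assert scaled["cq"].mean() == pytest.approx(100 / 100.01)


class TestMask:
    def test_merged_cover_fully_masks(self):
        w = partition_windows({"A": 500}, 500)
        masks = pd.DataFrame(
            [("A", 0, 250), ("A", 200, 500)], columns=["chrom", "start", "end"]
        )
        out = apply_mask(w, masks)
        assert out.loc[0, "masked_fraction"] == 1.0
        assert out.loc[0, "status"] == FILTERED_MASKED

    def test_partial_mask_retained(self):
        w = partition_windows({"A": 500}, 500)
        masks = pd.DataFrame([("A", 100, 200)], columns=["chrom", "start", "end"])
        out = apply_mask(w, masks)
        assert out.loc[0, "masked_fraction"] == pytest.approx(0.2)
        assert out.loc[0, "status"] != FILTERED_MASKED

    def test_no_masks(self):
        w = partition_windows({"A": 2000}, 500)
        out = apply_mask(w, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert (out["masked_fraction"] == 0).all()

    def test_masked_window_stays_filtered_through_classification(self):
        w = partition_windows({"A": 1000}, 500)
        w["male_hits"] = 100
        masks = pd.DataFrame([("A", 0, 500)], columns=["chrom", "start", "end"])
        out = filter_and_classify(apply_mask(w, masks))
        assert out.loc[0, "status"] == FILTERED_MASKED
        assert np.isnan(out.loc[0, "cq"])


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:A\tLN:1000\n"


def sam_record(name, pos, flag=0, mapq=60):
    return (
        f"{name}\t{flag}\tA\t{pos + 1}\t{mapq}\t50M\t*\t0\t0\t"
        f"{'A' * 50}\t{'I' * 50}\n"
    )


class TestCounting:
    def test_boundary_attribution_from_sam(self, tmp_path):
        """A read is counted in the window holding its leftmost base."""
        fem = tmp_path / "f.sam"
        fem.write_text(
            SAM_HEADER
            + sam_record("r1", 10)
            + sam_record("r2", 499)
            + sam_record("r3", 500)
        )
        male = tmp_path / "m.sam"
        male.write_text(SAM_HEADER)
        w = partition_windows({"A": 1000}, 500)
        out = count_hits_from_alignments(w, fem, male, window_size=500)
        assert out["female_hits"].tolist() == [2, 1]
        assert out["male_hits"].tolist() == [0, 0]

    def test_secondary_supplementary_unmapped_excluded(self, tmp_path):
        fem = tmp_path / "f.sam"
        fem.write_text(
            SAM_HEADER
            + sam_record("r1", 10)
            + sam_record("r2", 10, flag=256)   # secondary
            + sam_record("r3", 10, flag=2048)  # supplementary
            + "r4\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"  # unmapped
        )
        male = tmp_path / "m.sam"
        male.write_text(SAM_HEADER)
        w = partition_windows({"A": 1000}, 500)
        out = count_hits_from_alignments(w, fem, male, window_size=500)
        assert out["female_hits"].sum() == 1

    def test_count_table_round_trip(self, tmp_path, small_genome_config):
        """Counts written by the simulator are ingested unchanged."""
        from cqscan import simulate_genome_layout, simulate_window_counts
        from cqscan.io import read_count_table, write_count_table

        layout = simulate_genome_layout(small_genome_config)
        counts = simulate_window_counts(small_genome_config, layout)
        p = tmp_path / "counts.tsv"
        write_count_table(counts, p)
        w = partition_windows(layout.chrom_sizes, 500)
        out = count_hits(w, read_count_table(p))
        assert out["female_hits"].tolist() == counts["female_hits"].tolist()
        assert out["male_hits"].tolist() == counts["male_hits"].tolist()

    def test_unknown_chromosome_warns_and_skips(self):
        w = partition_windows({"A": 1000}, 500)
        counts = pd.DataFrame(
            [("A", 0, 500, 3, 4), ("Z", 0, 500, 9, 9)],
            columns=["chrom", "start", "end", "female_hits", "male_hits"],
        )
        with pytest.warns(UserWarning, match="Z"):
            out = count_hits(w, counts)
        assert out["female_hits"].sum() == 3


class TestCalibration:
    def test_single_window(self):
        w = partition_windows({"1": 500}, 500)
        w["female_hits"] = 100
        w["male_hits"] = 100
        out = filter_and_classify(w)
        report = calibrate(out, ["1"])
        assert report.per_chrom["1"]["mean_cq"] == pytest.approx(100 / 100.01)
        assert report.near_one

    def test_balanced_depths_near_one(self, small_genome_config):
        from cqscan import simulate_genome_layout, simulate_window_counts

        layout = simulate_genome_layout(small_genome_config)
        counts = simulate_window_counts(small_genome_config, layout)
        w = count_hits(partition_windows(layout.chrom_sizes, 500), counts)
        out = filter_and_classify(w)
        report = calibrate(out, ["1", "2"])
        assert report.near_one
        for stats in report.per_chrom.values():
            assert stats["mean_cq"] == pytest.approx(1.0, abs=0.1)
            assert stats["median_cq"] == pytest.approx(1.0, abs=0.1)

    def test_unbalanced_depth_flagged(self):
        """Female depth twice male: mean CQ ~ 2, not near one."""
        rng = np.random.default_rng(9)
        w = partition_windows({"1": 500_000}, 500)
        w["female_hits"] = rng.poisson(200, len(w))
        w["male_hits"] = rng.poisson(100, len(w))
        out = filter_and_classify(w)
        report = calibrate(out, ["1"])
        assert not report.near_one
        assert report.per_chrom["1"]["mean_cq"] == pytest.approx(2.0, abs=0.1)
        assert report.male_female_ratio == pytest.approx(0.5, abs=0.05)

    def test_empty_autosome_errors(self):
        w = partition_windows({"1": 500}, 500)  # all filtered_low_male
        out = filter_and_classify(w)
        with pytest.raises(ValueError, match="'1'"):
            calibrate(out, ["1"])


class TestNullAndPower:
    def test_no_locus_no_male_biased_calls(self):
        """Balanced 100x depths with no planted locus: the male-biased
        false-positive fraction stays below 1e-3 (Poisson tails)."""
        from cqscan import SimulationConfig, simulate_genome_layout, simulate_window_counts

        config = SimulationConfig(
            chrom_lengths={"1": 2_000_000, "2": 2_000_000}, seed=23
        )
        layout = simulate_genome_layout(config)
        counts = simulate_window_counts(config, layout)
        w = count_hits(partition_windows(layout.chrom_sizes, 500), counts)
        out = filter_and_classify(w)
        frac = (out["status"] == MALE_BIASED).mean()
        assert frac < 1e-3

    def test_hemizygous_windows_all_detected(self, small_genome_config):
        """Leak 0 at 100x: every retained in-locus window is male-biased."""
        from cqscan import simulate_genome_layout, simulate_window_counts

        layout = simulate_genome_layout(small_genome_config)
        counts = simulate_window_counts(small_genome_config, layout)
        w = count_hits(partition_windows(layout.chrom_sizes, 500), counts)
        out = filter_and_classify(w)
        chrom, start, end = small_genome_config.m_locus
        in_locus = (
            (out["chrom"] == chrom) & (out["start"] >= start) & (out["end"] <= end)
        )
        retained = out["cq"].notna()
        assert (out.loc[in_locus & retained, "status"] == MALE_BIASED).all()
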