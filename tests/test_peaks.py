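import numpy as np
import pandas as pd
import pytest

from chromatrace.peaks import (
    annotate_peaks,
    classify_promoter_configs,
    peak_trajectories,
    promoter_open_calls,
    reproducible_peaks,
    union_region_fold_change,
)
from chromatrace.simulate import PeakSimParams, build_annotation, simulate_peaksets
from oracles import (
    annotate_brute,
    chains_brute,
    intersect_brute,
    open_calls_brute,
)


def peaks_df(intervals, chrom="chr1", read_count=10):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["read_count"] = read_count
    return df


def random_peaks(rng, n, length=100_000, wmin=50, wmax=2_000, chrom="chr1"):
    starts = rng.integers(0, length - wmax, size=n)
    widths = rng.integers(wmin, wmax, size=n)
    return peaks_df(list(zip(starts, starts + widths)), chrom=chrom,
                    read_count=rng.integers(1, 100, size=n))


class TestReproduciblePeaks:
    def test_identical_sets_identity(self):
        pk = peaks_df([(100, 200), (500, 700)])
        out = reproducible_peaks([pk, pk.copy(), pk.copy()])
        assert list(zip(out["start"], out["end"])) == [(100, 200), (500, 700)]

    def test_three_donor_example(self):
        a = peaks_df([(100, 200)])
        b = peaks_df([(150, 250)])
        c = peaks_df([(150, 180)])
        out = reproducible_peaks([a, b, c])
        assert list(zip(out["start"], out["end"])) == [(150, 180)]

    def test_missing_chromosome_in_one_donor(self):
        a = peaks_df([(0, 100)], chrom="chr1")
        b = peaks_df([(0, 100)], chrom="chr2")
        out = reproducible_peaks([a, b])
        assert len(out) == 0

    def test_empty_donor_warns_and_empty(self):
        a = peaks_df([(0, 100)])
        b = peaks_df([])
        with pytest.warns(UserWarning, match="empty"):
            out = reproducible_peaks([a, b])
        assert len(out) == 0

    def test_read_counts_summed_over_contributors(self):
        a = peaks_df([(0, 100)], read_count=5)
        b = peaks_df([(50, 150)], read_count=7)
        out = reproducible_peaks([a, b])
        assert out.iloc[0]["read_count"] == 12

    def test_donor_order_symmetric(self, rng):
        sets = [random_peaks(rng, 30) for _ in range(3)]
        fwd = reproducible_peaks(sets)
        rev = reproducible_peaks(sets[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_idempotent_on_own_output(self, rng):
        sets = [random_peaks(rng, 30) for _ in range(3)]
        out = reproducible_peaks(sets)
        again = reproducible_peaks([out, out.copy()])
        pd.testing.assert_frame_equal(
            out[["chrom", "start", "end"]], again[["chrom", "start", "end"]]
        )

    def test_coverage_not_exceeding_min_donor(self, rng):
        sets = [random_peaks(rng, 40) for _ in range(3)]
        out = reproducible_peaks(sets)
        out_bp = (out["end"] - out["start"]).sum()
        for s in sets:
            cov = np.zeros(100_000 + 2_000, dtype=bool)
            for st, en in zip(s["start"], s["end"]):
                cov[st:en] = True
            assert out_bp <= cov.sum()

    def test_matches_bp_oracle(self, rng):
        for _ in range(5):
            sets = [random_peaks(rng, 50) for _ in range(3)]
            out = reproducible_peaks(sets)
            expected = intersect_brute(
                [list(zip(s["start"], s["end"])) for s in sets], 102_000
            )
            assert list(zip(out["start"], out["end"])) == expected

    def test_fewer_than_two_donors_errors(self):
        with pytest.raises(ValueError, match="2 donor"):
            reproducible_peaks([peaks_df([(0, 10)])])


class TestAnnotatePeaks:
    ANN = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [100, 180, 1_000],
            "end": [200, 400, 1_500],
            "category": ["promoter", "exon", "CpG"],
            "gene_id": ["G1", "G1", ""],
        }
    )

    def test_peak_spanning_promoter_and_exon_counts_twice(self):
        flags, totals = annotate_peaks(peaks_df([(150, 250)]), self.ANN)
        assert flags.loc[0, "promoter"] and flags.loc[0, "exon"]
        assert not flags.loc[0, "intergenic"]
        assert totals["promoter"] == 1 and totals["exon"] == 1

    def test_no_overlap_is_intergenic_only(self):
        flags, totals = annotate_peaks(peaks_df([(5_000, 5_100)]), self.ANN)
        assert flags.loc[0, "intergenic"]
        assert totals["intergenic"] == 1
        assert totals[["promoter", "exon", "CpG"]].sum() == 0

    def test_totals_can_exceed_peak_count(self):
        flags, totals = annotate_peaks(
            peaks_df([(150, 250), (1_100, 1_200)]), self.ANN
        )
        assert totals.sum() > 2

    def test_unknown_chromosome_listed(self):
        with pytest.raises(ValueError, match="chrX"):
            annotate_peaks(peaks_df([(0, 10)], chrom="chrX"), self.ANN)

    def test_matches_quadratic_oracle(self, rng):
        peaks = random_peaks(rng, 50)
        cats = ["promoter", "exon", "intron", "CpG", "CTCF"]
        feats = random_peaks(rng, 40)
        feats["category"] = rng.choice(cats, size=40)
        feats["gene_id"] = ""
        flags, totals = annotate_peaks(peaks, feats)
        feat_list = list(zip(feats["start"], feats["end"], feats["category"]))
        peak_list = list(zip(peaks["start"], peaks["end"]))
        sets, brute_totals = annotate_brute(peak_list, feat_list)
        for i, hit in enumerate(sets):
            got = {c for c in cats if c in flags.columns and flags.loc[i, c]}
            assert got == hit
        for cat, n in brute_totals.items():
            assert totals[cat] == n


class TestPromoterCalls:
    ANN = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [100, 500],
            "end": [200, 600],
            "category": ["promoter", "promoter"],
            "gene_id": ["G1", "G2"],
        }
    )

    def test_no_peaks_all_closed(self):
        calls = promoter_open_calls({"t1": peaks_df([])}, self.ANN)
        assert not calls["open_t1"].any()

    def test_exact_peak_opens_promoter(self):
        calls = promoter_open_calls({"t1": peaks_df([(100, 200)])}, self.ANN)
        assert calls.set_index("gene_id")["open_t1"].tolist() == [True, False]

    def test_matches_quadratic_oracle(self, rng):
        prom = random_peaks(rng, 30)
        prom["category"] = "promoter"
        prom["gene_id"] = [f"G{i}" for i in range(30)]
        pk = random_peaks(rng, 40)
        calls = promoter_open_calls({"t": pk}, prom)
        expected = open_calls_brute(
            list(zip(prom["start"], prom["end"])),
            list(zip(pk["start"], pk["end"])),
        )
        assert calls["open_t"].tolist() == expected


class TestConfigs:
    def test_four_way_classification(self):
        calls = pd.DataFrame(
            {
                "promoter_id": ["p1", "p2", "p3", "p4"],
                "gene_id": ["g1", "g2", "g3", "g4"],
                "chrom": "chr1",
                "start": [0, 10, 20, 30],
                "end": [5, 15, 25, 35],
                "open_t1": [True, True, False, False],
                "open_t2": [True, False, True, False],
            }
        )
        out = classify_promoter_configs(calls, "t1", "t2")
        assert out["config"].tolist() == [
            "open-open", "open-closed", "closed-open", "closed-closed"
        ]

    def test_partition_of_catalog(self, rng):
        n = 50
        calls = pd.DataFrame(
            {
                "promoter_id": [f"p{i}" for i in range(n)],
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 10,
                "end": np.arange(n) * 10 + 5,
                "open_a": rng.random(n) < 0.5,
                "open_b": rng.random(n) < 0.5,
            }
        )
        out = classify_promoter_configs(calls, "a", "b")
        assert len(out) == n  # exactly one config per promoter
        assert out["config"].isin(
            ["open-open", "open-closed", "closed-open", "closed-closed"]
        ).all()

    def test_missing_time_errors(self):
        calls = pd.DataFrame(
            {"promoter_id": [], "gene_id": [], "chrom": [], "start": [],
             "end": [], "open_t1": []}
        )
        with pytest.raises(ValueError, match="t2"):
            classify_promoter_configs(calls, "t1", "t2")

    def test_scripted_schedules_recovered(self):
        # open probabilities 1/0 per time, no dropout: exact recovery
        params = PeakSimParams(
            n_promoters=40, n_intergenic_sites=0,
            time_points=("t1", "t2"),
            open_probability_per_time=np.column_stack(
                [np.repeat([1, 1, 0, 0], 10), np.repeat([1, 0, 1, 0], 10)]
            ),
            readcount_mean_per_time=(20.0, 20.0),
            n_donors=2, donor_dropout=0.0, seed=5,
        )
        sim = simulate_peaksets(params)
        ann = build_annotation(sim.catalog)
        rep = {
            t: reproducible_peaks([sim.peaksets[(d, t)] for d in ("donor1", "donor2")])
            for t in ("t1", "t2")
        }
        calls = promoter_open_calls(rep, ann)
        out = classify_promoter_configs(calls, "t1", "t2").set_index("gene_id")
        expected = (["open-open"] * 10 + ["open-closed"] * 10
                    + ["closed-open"] * 10 + ["closed-closed"] * 10)
        got = [out.loc[f"G{i:05d}", "config"] for i in range(40)]
        assert got == expected


class TestTrajectories:
    def test_persistent_pattern(self):
        pk = peaks_df([(100, 200)])
        by_time = {t: pk.copy() for t in ("a", "b", "c", "d")}
        table, summary = peak_trajectories(by_time)
        assert table["pattern"].tolist() == ["1111"]
        assert summary["persistent_fraction"] == 1.0

    def test_single_time_presence(self):
        empty = peaks_df([])
        by_time = {"a": empty, "b": peaks_df([(100, 200)]),
                   "c": empty.copy(), "d": empty.copy()}
        table, summary = peak_trajectories(by_time)
        assert table["pattern"].tolist() == ["0100"]
        assert not table["persistent"].iloc[0]

    def test_counts_traced_with_zero_where_absent(self):
        by_time = {
            "a": peaks_df([(100, 200)], read_count=5),
            "b": peaks_df([]),
        }
        table, _ = peak_trajectories(by_time)
        assert table.loc[0, "count_a"] == 5 and table.loc[0, "count_b"] == 0

    def test_matches_union_find_oracle(self, rng):
        for _ in range(3):
            by_time = {t: random_peaks(rng, 25) for t in ("a", "b", "c")}
            table, _ = peak_trajectories(by_time)
            got = set(zip(table["start"], table["end"], table["pattern"]))
            expected = chains_brute(
                {t: list(zip(p["start"], p["end"])) for t, p in by_time.items()},
                102_000,
            )
            assert got == expected

    def test_scripted_schedule_recovered(self):
        params = PeakSimParams(
            n_promoters=30, n_intergenic_sites=30,
            open_probability_per_time=(1.0, 1.0, 1.0, 1.0),
            n_donors=2, donor_dropout=0.0, seed=6,
        )
        sim = simulate_peaksets(params)
        by_time = {
            t: reproducible_peaks(
                [sim.peaksets[(d, t)] for d in ("donor1", "donor2")]
            )
            for t in params.time_points
        }
        table, summary = peak_trajectories(by_time)
        assert summary["persistent_fraction"] == 1.0
        assert len(table) == 60


class TestFoldChange:
    def test_identical_counts_zero_fc(self):
        p1 = peaks_df([(0, 100), (500, 600)], read_count=10)
        p2 = p1.copy()
        out = union_region_fold_change(p1, p2)
        np.testing.assert_allclose(out["log2fc"], 0.0)

    def test_hand_computed_ratio(self):
        # single shared region holds all reads: c/N = 1 at both times, so a
        # 4x raw change cancels in normalization; use two regions instead
        p1 = peaks_df([(0, 100), (500, 600)], read_count=[10, 10])
        p2 = peaks_df([(0, 100), (500, 600)], read_count=[40, 10])
        out = union_region_fold_change(p1, p2, pseudocount=1e-12)
        # region 1: (40/50) / (10/20) = 1.6 -> log2 = 0.678...
        assert out.loc[0, "log2fc"] == pytest.approx(np.log2(1.6), abs=1e-6)
        # region 2: (10/50) / (10/20) = 0.4
        assert out.loc[1, "log2fc"] == pytest.approx(np.log2(0.4), abs=1e-6)

    def test_union_region_spans_both_peaks(self):
        p1 = peaks_df([(0, 100)], read_count=10)
        p2 = peaks_df([(50, 150)], read_count=10)
        out = union_region_fold_change(p1, p2)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 150)

    def test_private_region_positive_fc_bounded(self):
        p1 = peaks_df([(0, 100)], read_count=10)
        p2 = peaks_df([(0, 100), (500, 600)], read_count=[10, 30])
        out = union_region_fold_change(p1, p2, pseudocount=0.01)
        private = out[out["count_t1"] == 0].iloc[0]
        assert 0 < private["log2fc"] <= np.log2((1 + 0.01) / 0.01)

    def test_zero_library_errors(self):
        p1 = peaks_df([(0, 100)], read_count=0)
        p2 = peaks_df([(0, 100)], read_count=10)
        with pytest.raises(ValueError, match="library"):
            union_region_fold_change(p1, p2)
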