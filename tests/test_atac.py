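import numpy as np
import pandas as pd
import pytest

import escapeatlas as ea
from escapeatlas.atac import (
    DYN_DE_NOVO,
    DYN_STABLE,
    DYN_SWITCH,
    ESCAPE_PEAK,
    NOT_INFORMATIVE,
    XA_SPECIFIC,
    aged_enrichment,
    annotate_peaks,
    assign_called,
    assign_peak_ids,
    call_peak_escape,
    compartment_fraction_test,
    high_confidence_shifts,
    merge_peaks,
    peak_window_counts,
    summarize_peak_allelic,
    window_aged_enrichment,
)
from escapeatlas.config import AnalysisConfig
from escapeatlas.io import RegulatoryElement

from oracles import binom_p_greater, fisher_p_two_sided

CFG = AnalysisConfig()


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestMergePeaks:
    def test_one_bp_overlap_merges_book_ended_stay(self):
        union = merge_peaks(
            _peaks(
                [
                    ("chrX", 0, 100),
                    ("chrX", 99, 200),  # overlaps by 1 bp
                    ("chrX", 200, 300),  # book-ended, no shared base
                ]
            )
        )
        assert union[["start", "end"]].to_numpy().tolist() == [[0, 200], [200, 300]]

    def test_assign_called_by_overlap(self):
        union = merge_peaks(_peaks([("chrX", 0, 100), ("chrX", 500, 600)]))
        called = assign_called(union, {"s1": _peaks([("chrX", 50, 80)])})
        assert called.called.tolist() == [True, False]

    def test_assign_peak_ids_by_midpoint(self):
        union = merge_peaks(_peaks([("chrX", 0, 100), ("chrX", 500, 600)]))
        intervals = _peaks([("chrX", 40, 60), ("chrX", 900, 950)])
        out = assign_peak_ids(union, intervals)
        assert out.peak_id.iloc[0] == union.peak_id.iloc[0]
        assert pd.isna(out.peak_id.iloc[1])


class TestWindowCounts:
    def test_median_over_replicates(self):
        rows = []
        for rep, n in ((1, 4), (2, 6)):
            for i in range(n):
                rows.append(("chrX", i * 1000, i * 1000 + 500, "aged", rep))
        peaks = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "timepoint", "replicate"]
        )
        out = peak_window_counts(peaks, window=10_000_000, chrom_lengths={"chrX": 20_000_000})
        first = out[(out.start == 0) & (out.timepoint == "aged")]
        assert first.median_peaks.iloc[0] == 5.0

    def test_midpoint_boundary_goes_to_second_window(self):
        peaks = pd.DataFrame(
            [("chrX", 9_999_000, 10_001_000, "adult", 1)],
            columns=["chrom", "start", "end", "timepoint", "replicate"],
        )
        out = peak_window_counts(peaks, 10_000_000, {"chrX": 30_000_000})
        assert out.loc[out.start == 10_000_000, "median_peaks"].iloc[0] == 1.0
        assert out.loc[out.start == 0, "median_peaks"].iloc[0] == 0.0

    def test_each_peak_counted_exactly_once(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 99_000_000, 150)
        peaks = pd.DataFrame(
            {
                "chrom": "chrX",
                "start": starts,
                "end": starts + 1000,
                "timepoint": "adult",
                "replicate": 1,
            }
        )
        out = peak_window_counts(peaks, 10_000_000, {"chrX": 100_000_000})
        assert out.median_peaks.sum() == 150


class TestAgedEnrichment:
    def test_example(self):
        ratio, p = aged_enrichment(6, 2)
        assert ratio == pytest.approx(0.75)
        assert p == pytest.approx(37 / 256)
        assert p == pytest.approx(binom_p_greater(6, 8, 0.5), abs=1e-12)

    def test_empty_window(self):
        ratio, p = aged_enrichment(0, 0)
        assert np.isnan(ratio) and p == 1.0

    def test_null_center(self):
        ratio, p = aged_enrichment(10, 10)
        assert ratio == 0.5 and p > 0.5

    def test_complement_identity(self):
        for a, b in ((3, 7), (5, 5), (0, 9)):
            assert aged_enrichment(a, b)[0] == pytest.approx(1 - aged_enrichment(b, a)[0])

    def test_window_table(self):
        wc = pd.DataFrame(
            {
                "chrom": "chrX",
                "start": [0, 0],
                "end": [10, 10],
                "timepoint": ["adult", "aged"],
                "median_peaks": [2.0, 6.0],
            }
        )
        out = window_aged_enrichment(wc)
        assert out.enrichment_aged.iloc[0] == pytest.approx(0.75)


class TestCompartmentTest:
    def test_identical_tables_give_p_one(self):
        res = compartment_fraction_test(
            {"autosomes": {"adult": 100, "aged": 100}, "Xi": {"adult": 10, "aged": 10}}
        )
        assert res["Xi"].p_value == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        res = compartment_fraction_test(
            {"Xi": {"adult": 30, "aged": 60}, "rest": {"adult": 970, "aged": 940}}
        )
        assert res["Xi"].p_value == pytest.approx(
            fisher_p_two_sided(30, 60, 970, 940), abs=1e-9
        )

    def test_xi_doubling_lowers_p(self):
        equal = compartment_fraction_test(
            {"Xi": {"adult": 30, "aged": 30}, "rest": {"adult": 970, "aged": 970}}
        )
        doubled = compartment_fraction_test(
            {"Xi": {"adult": 30, "aged": 60}, "rest": {"adult": 970, "aged": 940}}
        )
        assert doubled["Xi"].p_value < equal["Xi"].p_value


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["peak_id", "timepoint", "replicate", "maternal", "paternal"]
    )


def _called(rows):
    return pd.DataFrame(rows, columns=["peak_id", "sample_id", "called"])


SAMPLE_TPS = {"adult_r1": "adult", "adult_r2": "adult", "aged_r1": "aged", "aged_r2": "aged"}


class TestPeakEscape:
    def test_dynamics_categories(self):
        counts = _counts(
            [
                # p1: de novo (not called in adult, escapes in aged)
                ("p1", "adult", 1, 30, 1), ("p1", "adult", 2, 28, 1),
                ("p1", "aged", 1, 18, 12), ("p1", "aged", 2, 20, 13),
                # p2: switch (Xa-specific adult AR 0.97, aged AR 0.8)
                ("p2", "adult", 1, 97, 3), ("p2", "adult", 2, 96, 4),
                ("p2", "aged", 1, 80, 20), ("p2", "aged", 2, 82, 18),
                # p3: stable Xa-specific
                ("p3", "adult", 1, 95, 5), ("p3", "adult", 2, 94, 6),
                ("p3", "aged", 1, 95, 5), ("p3", "aged", 2, 96, 4),
            ]
        )
        called = _called(
            [("p1", "adult_r1", False), ("p1", "adult_r2", False),
             ("p1", "aged_r1", True), ("p1", "aged_r2", True)]
            + [("p2", s, True) for s in SAMPLE_TPS]
            + [("p3", s, True) for s in SAMPLE_TPS]
        )
        summary = summarize_peak_allelic(counts, CFG.total_read_cutoff_bulk)
        out = call_peak_escape(summary, called, SAMPLE_TPS, CFG)
        dyn = out.drop_duplicates("peak_id").set_index("peak_id")["dynamics"]
        assert dyn["p1"] == DYN_DE_NOVO
        assert dyn["p2"] == DYN_SWITCH
        assert dyn["p3"] == DYN_STABLE
        status = out.set_index(["peak_id", "timepoint"])["escape_status"]
        assert status[("p2", "adult")] == XA_SPECIFIC
        assert status[("p2", "aged")] == ESCAPE_PEAK

    def test_low_coverage_not_informative(self):
        counts = _counts([("p1", "adult", 1, 5, 2), ("p1", "adult", 2, 4, 1)])
        summary = summarize_peak_allelic(counts, CFG.total_read_cutoff_bulk)
        out = call_peak_escape(summary, _called([]), {}, CFG)
        assert out.escape_status.iloc[0] == NOT_INFORMATIVE


class TestHighConfidenceShifts:
    def _summary(self, ar_adult, ar_aged):
        counts = _counts(
            [
                ("p", "adult", 1, int(ar_adult * 100), 100 - int(ar_adult * 100)),
                ("p", "adult", 2, int(ar_adult * 100), 100 - int(ar_adult * 100)),
                ("p", "aged", 1, int(ar_aged * 100), 100 - int(ar_aged * 100)),
                ("p", "aged", 2, int(ar_aged * 100), 100 - int(ar_aged * 100)),
            ]
        )
        return summarize_peak_allelic(counts, CFG.total_read_cutoff_bulk)

    def test_shared_replicates_and_delta_kept(self):
        called = _called([("p", s, True) for s in SAMPLE_TPS])
        out = high_confidence_shifts(self._summary(0.95, 0.80), called, SAMPLE_TPS, CFG)
        assert len(out) == 1
        assert out.delta_ar.iloc[0] == pytest.approx(0.15)

    def test_missing_aged_replicate_dropped(self):
        called = _called(
            [("p", "adult_r1", True), ("p", "adult_r2", True),
             ("p", "aged_r1", True), ("p", "aged_r2", False)]
        )
        out = high_confidence_shifts(self._summary(0.95, 0.65), called, SAMPLE_TPS, CFG)
        assert len(out) == 0

    def test_delta_below_cutoff_dropped(self):
        called = _called([("p", s, True) for s in SAMPLE_TPS])
        out = high_confidence_shifts(self._summary(0.95, 0.86), called, SAMPLE_TPS, CFG)
        assert len(out) == 0  # ΔAR 0.09 < 0.1, strict


class TestAnnotatePeaks:
    CRES = [
        RegulatoryElement("chrX", 1000, 2000, "promoter"),
        RegulatoryElement("chrX", 1500, 3000, "distal_enhancer"),
        RegulatoryElement("chrX", 5000, 6000, "ctcf"),
    ]

    def test_promoter_priority(self):
        peaks = _peaks([("chrX", 1400, 1600)])
        out = annotate_peaks(peaks, [1_000_000], self.CRES)
        assert out.cre_class.iloc[0] == "promoter"

    def test_enhancer_and_intergenic(self):
        peaks = _peaks([("chrX", 2500, 2600), ("chrX", 9000, 9100)])
        out = annotate_peaks(peaks, [1_000_000], self.CRES)
        assert out.cre_class.tolist() == ["enhancer", "intergenic"]

    def test_ctcf_only_maps_to_intergenic(self):
        out = annotate_peaks(_peaks([("chrX", 5100, 5200)]), [1_000_000], self.CRES)
        assert out.cre_class.iloc[0] == "intergenic"

    def test_within_proximity_flag(self):
        peaks = _peaks([("chrX", 150_000, 151_000)])
        out = annotate_peaks(peaks, [300_000], self.CRES, proximity=200_000)
        assert bool(out.within_proximity.iloc[0])
        far = annotate_peaks(peaks, [400_000], self.CRES, proximity=200_000)
        assert not bool(far.within_proximity.iloc[0])


class TestPlantedOpeningRecovery:
    def test_high_confidence_recovers_planted_peaks(self):
        sim = ea.simulate_atac(ea.SimConfig(seed=5))
        union = merge_peaks(pd.concat(sim.sample_peaks.values(), ignore_index=True))
        called = assign_called(union, sim.sample_peaks)
        counts = assign_peak_ids(union, sim.allele_counts).dropna(subset=["peak_id"])
        summary = summarize_peak_allelic(counts, CFG.total_read_cutoff_bulk)
        hc = high_confidence_shifts(summary, called, sim.sample_timepoints, CFG)
        truth_ids = assign_peak_ids(union, sim.truth)
        opening = set(truth_ids.loc[truth_ids.is_opening, "peak_id"].dropna())
        rec = ea.evaluate_recovery(hc.peak_id, opening)
        assert rec["recall"] >= 0.8
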