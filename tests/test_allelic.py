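import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escapeatlas.allelic import (
    aggregate_gene_counts,
    compute_ar,
    compute_tpm,
    correlate_ar_fc,
    sex_fold_change,
    summarize_allelic,
)


def _snps(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample_id", "maternal", "paternal"])


GENE = pd.DataFrame(
    {"gene_id": ["g1"], "chrom": ["chrX"], "start": [0], "end": [100]}
)


class TestComputeAr:
    @pytest.mark.parametrize(
        "m,p,expected", [(20, 0, 1.0), (50, 50, 0.5), (18, 2, 0.9), (0, 30, 0.0)]
    )
    def test_examples(self, m, p, expected):
        assert compute_ar(m, p) == pytest.approx(expected)

    def test_zero_total_is_undefined_not_zero(self):
        assert np.isnan(compute_ar(0, 0))

    @given(m=st.integers(0, 10_000), p=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_complement(self, m, p):
        if m + p == 0:
            return
        ar = compute_ar(m, p)
        assert 0.0 <= ar <= 1.0
        assert ar + compute_ar(p, m) == pytest.approx(1.0)


class TestAggregateGeneCounts:
    def test_minread_drops_low_coverage_snps(self):
        snps = _snps(
            [
                ("chrX", 10, "s1", 3, 1),
                ("chrX", 20, "s1", 5, 0),
                ("chrX", 30, "s1", 0, 0),
            ]
        )
        out = aggregate_gene_counts(snps, GENE, minread=1)
        assert (out.maternal.iloc[0], out.paternal.iloc[0]) == (8, 1)
        out2 = aggregate_gene_counts(snps, GENE, minread=2)
        assert (out2.maternal.iloc[0], out2.paternal.iloc[0]) == (8, 1)

    def test_half_open_excludes_end_position(self):
        snps = _snps([("chrX", 100, "s1", 9, 9)])
        out = aggregate_gene_counts(snps, GENE, minread=1)
        assert (out.maternal.iloc[0], out.paternal.iloc[0]) == (0, 0)

    def test_additive_over_snp_partition(self):
        rng = np.random.default_rng(5)
        rows = [
            ("chrX", int(rng.integers(0, 100)), f"s{rng.integers(1, 4)}",
             int(rng.integers(0, 10)), int(rng.integers(0, 10)))
            for _ in range(60)
        ]
        full = aggregate_gene_counts(_snps(rows), GENE, minread=1)
        part1 = aggregate_gene_counts(_snps(rows[:30]), GENE, minread=1)
        part2 = aggregate_gene_counts(_snps(rows[30:]), GENE, minread=1)
        merged = (
            pd.concat([part1, part2])
            .groupby(["gene_id", "sample_id"], as_index=False)[["maternal", "paternal"]]
            .sum()
        )
        combined = full.groupby(["gene_id", "sample_id"], as_index=False)[
            ["maternal", "paternal"]
        ].sum()
        pd.testing.assert_frame_equal(
            combined.sort_values("sample_id").reset_index(drop=True),
            merged.sort_values("sample_id").reset_index(drop=True),
        )


class TestSummarize:
    META = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "group": "heart",
            "sex": "female",
            "timepoint": "adult",
            "replicate": [1, 2, 3],
        }
    )

    def _summary(self, counts):
        df = pd.DataFrame(
            [("g1", s, m, p) for s, m, p in counts],
            columns=["gene_id", "sample_id", "maternal", "paternal"],
        )
        return summarize_allelic(df, self.META, total_cutoff=20, min_informative_samples=2)

    def test_median_of_three_informative(self):
        out = self._summary([("s1", 23, 2), ("s2", 22, 3), ("s3", 19, 1)])
        # ARs 0.92, 0.88, 0.95 -> median 0.92
        assert out.median_ar.iloc[0] == pytest.approx(0.92)
        assert out.n_informative.iloc[0] == 3

    def test_filter_then_median(self):
        out = self._summary([("s1", 25, 0), ("s2", 6, 6), ("s3", 15, 15)])
        # totals 25, 12, 30 -> informative ARs 1.0 and 0.5 -> median 0.75
        assert out.n_informative.iloc[0] == 2
        assert out.median_ar.iloc[0] == pytest.approx(0.75)

    def test_below_cutoff_everywhere_is_not_informative(self):
        out = self._summary([("s1", 5, 0), ("s2", 5, 0), ("s3", 5, 0)])
        assert not out.informative.iloc[0]
        assert np.isnan(out.median_ar.iloc[0])


class TestTpm:
    def _tpm(self, counts, lengths):
        df = pd.DataFrame(
            [(g, "s1", c) for g, c in counts], columns=["gene_id", "sample_id", "count"]
        )
        return compute_tpm(df, pd.Series(lengths))

    def test_proportional(self):
        out = self._tpm([("a", 10), ("b", 90)], {"a": 1000, "b": 1000})
        assert out.tpm.tolist() == pytest.approx([1e5, 9e5])

    def test_length_normalization(self):
        out = self._tpm([("a", 10), ("b", 10)], {"a": 1000, "b": 2000})
        assert out.tpm.tolist() == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_single_gene_is_one_million(self):
        out = self._tpm([("a", 7)], {"a": 123})
        assert out.tpm.iloc[0] == pytest.approx(1e6)

    def test_sums_to_one_million_per_sample(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        df = pd.DataFrame(
            [
                (g, s, int(rng.integers(0, 500)))
                for g in genes
                for s in ("s1", "s2")
            ],
            columns=["gene_id", "sample_id", "count"],
        )
        lengths = pd.Series({g: int(rng.integers(200, 5000)) for g in genes})
        out = compute_tpm(df, lengths)
        sums = out.groupby("sample_id")["tpm"].sum()
        assert np.allclose(sums, 1e6, rtol=1e-6)


class TestSexFoldChange:
    def test_ratio_of_medians(self):
        assert sex_fold_change([4, 6, 5], [2, 3, 2]) == pytest.approx(2.5)

    def test_identical_distributions(self):
        assert sex_fold_change([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_zero_male_median_is_undefined(self):
        assert np.isnan(sex_fold_change([1, 2], [0, 0, 0]))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            sex_fold_change([], [1])


class TestCorrelation:
    def test_monotone_directions(self):
        rho, _ = correlate_ar_fc([(0.5, 4), (0.7, 2), (0.9, 1)])
        assert rho == pytest.approx(-1.0)
        rho_up, _ = correlate_ar_fc([(0.1, 1), (0.2, 2), (0.3, 5)])
        assert rho_up == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        rho, p = correlate_ar_fc([(0.5, 1), (0.5, 2), (0.5, 3)])
        assert np.isnan(rho)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate_ar_fc([(0.5, 1), (0.6, 2)])
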