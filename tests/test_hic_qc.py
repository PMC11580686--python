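"""Hi-C metric unit and property tests: pair classification, duplicate
marking, link-separation binning, power-law fitting, ICI rates,
accessibility arithmetic and contact-matrix bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pair
from lrqc.hic_qc import (
    InsufficientDataError,
    LsdHistogram,
    PairClass,
    classify_pair,
    contact_matrix,
    fit_power_law,
    hic_metrics,
    ici_rates,
    lsd_histogram,
    mark_duplicates,
    total_accessibility,
)
from lrqc.io_formats import GenomeLayout


def _oracle_classify(unmapped, low_mapq, duplicate, inter):
    """Precedence table, spelled out independently of the implementation."""
    if unmapped or low_mapq:
        return PairClass.UNMAPPED
    if duplicate:
        return PairClass.DUPLICATE
    if inter:
        return PairClass.INTER
    return PairClass.INTRA


class TestClassifyPair:
    @pytest.mark.parametrize(
        "unmapped,low_mapq,duplicate,inter",
        list(itertools.product([False, True], repeat=4)),
    )
    def test_precedence_matches_enumerated_oracle(self, unmapped, low_mapq, duplicate, inter):
        pair = make_pair(
            chrom1=None if unmapped else "chr1",
            chrom2=None if unmapped else ("chr2" if inter else "chr1"),
            pos1=1000, pos2=51_000,
            duplicate=duplicate, unmapped=unmapped,
            mapq=0 if (unmapped or low_mapq) else 60,
        )
        assert classify_pair(pair, mapq_min=10) is _oracle_classify(
            unmapped, low_mapq, duplicate, inter
        )

    def test_intra_distance(self):
        pair = make_pair(pos1=1000, pos2=51_000)
        assert classify_pair(pair) is PairClass.INTRA
        assert pair.distance == 50_000


class TestMarkDuplicates:
    def test_identical_pair_flagged_second(self):
        pairs = [make_pair(pos1=10, pos2=500), make_pair(pos1=10, pos2=500)]
        out = mark_duplicates(pairs)
        assert [p.duplicate for p in out] == [False, True]

    def test_three_copies_among_ten_gives_d_point_two(self):
        pairs = [make_pair(pos1=10, pos2=500)] * 3 + [
            make_pair(pos1=i * 1000, pos2=i * 1000 + 70_000) for i in range(7)
        ]
        out = mark_duplicates(pairs)
        assert sum(p.duplicate for p in out) / len(out) == pytest.approx(0.2)

    def test_all_distinct_no_flags(self):
        pairs = [make_pair(pos1=i, pos2=i + 100) for i in range(10)]
        assert not any(p.duplicate for p in mark_duplicates(pairs))

    @given(st.lists(st.tuples(
        st.integers(0, 5), st.integers(0, 5), st.sampled_from("+-"), st.sampled_from("+-"),
    ), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_grouping_and_is_idempotent(self, keys):
        """Flag count per key = multiplicity - 1, regardless of order."""
        pairs = [make_pair(pos1=a, pos2=a + b, strand1=s1, strand2=s2)
                 for a, b, s1, s2 in keys]
        out = mark_duplicates(pairs)
        groups = {}
        for a, b, s1, s2 in keys:
            groups[(a, a + b, s1, s2)] = groups.get((a, a + b, s1, s2), 0) + 1
        assert sum(p.duplicate for p in out) == sum(n - 1 for n in groups.values())
        assert mark_duplicates(out) == out


class TestLsdHistogram:
    def test_hand_binning_and_percentages(self):
        pairs = [make_pair(pos1=0, pos2=d) for d in (150, 180, 50_000)]
        hist = lsd_histogram(pairs, bin_width=100)
        assert hist.counts == {1: 2, 500: 1}
        pct = hist.percentages()
        assert pct[1] == pytest.approx(200 / 3)
        assert pct[500] == pytest.approx(100 / 3)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_distance_zero_lands_in_bin_zero(self):
        hist = lsd_histogram([make_pair(pos1=7, pos2=7, strand2="-")])
        assert hist.counts == {0: 1}

    def test_inter_pairs_not_counted(self):
        pairs = [make_pair(pos1=0, pos2=100), make_pair(chrom2="chr2", pos1=0, pos2=100)]
        assert lsd_histogram(pairs).total == 1

    def test_no_intra_pairs_is_error(self):
        with pytest.raises(InsufficientDataError):
            lsd_histogram([make_pair(chrom2="chr2")])


class TestFitPowerLaw:
    @staticmethod
    def _full_hist(exponent, lo_bin=100, hi_bin=100_000, scale=1e12):
        hist = LsdHistogram(bin_width=100)
        idx = np.arange(lo_bin, hi_bin + 1)
        centers = (idx + 0.5) * 100.0
        hist.counts = {int(i): float(scale * c ** -exponent)
                       for i, c in zip(idx, centers)}
        return hist

    def test_exact_inverse_square_recovered(self):
        fit = fit_power_law(self._full_hist(2.0))
        assert fit.exponent == pytest.approx(2.000, abs=5e-4)
        assert fit.r_squared > 0.9999

    def test_constant_frequencies_give_zero_exponent(self):
        fit = fit_power_law(self._full_hist(0.0, scale=5.0))
        assert fit.exponent == pytest.approx(0.0, abs=5e-4)

    def test_insufficient_bins_is_error(self):
        hist = LsdHistogram(bin_width=100, counts={150: 4, 200: 2})
        with pytest.raises(InsufficientDataError):
            fit_power_law(hist)

    def test_exclusion_window_removes_artefact_peak(self):
        hist = self._full_hist(2.0)
        spike_bin = 50_000  # a spurious peak mid-tail
        hist.counts[spike_bin] += 1e6
        dirty = fit_power_law(hist)
        clean = fit_power_law(hist, exclusion_window=(4.9e6, 5.1e6))
        assert clean.r_squared > dirty.r_squared
        # log bins straddling the window edges keep only part of their raw
        # bins, so a small residual tilt remains
        assert clean.exponent == pytest.approx(2.0, abs=2e-2)


class TestIciRates:
    def test_four_inter_of_ten_fails_qc(self):
        pairs = [make_pair(chrom2="chr2", pos1=i, pos2=i) for i in range(4)]
        pairs += [make_pair(pos1=i, pos2=i + 1000) for i in range(6)]
        res = ici_rates(pairs)
        assert res.rate == pytest.approx(0.4)
        assert not res.qc_pass

    def test_zero_inter_passes(self):
        res = ici_rates([make_pair(pos1=i, pos2=i + 10) for i in range(5)])
        assert res.rate == 0.0 and res.qc_pass

    def test_exact_threshold_passes_strictly_above_fails(self):
        pairs = [make_pair(chrom2="chr2", pos1=i, pos2=i) for i in range(3)]
        pairs += [make_pair(pos1=i, pos2=i + 1000) for i in range(7)]
        res = ici_rates(pairs)
        assert res.rate == pytest.approx(0.30)
        assert res.qc_pass  # fails only when rate > threshold

    def test_per_chromosome_table(self):
        pairs = [make_pair(chrom1="chr1", chrom2="chr2", pos1=1, pos2=1),
                 make_pair(pos1=0, pos2=10)]
        table = ici_rates(pairs).per_chromosome.set_index("chromosome")
        assert table.loc["chr1", "n_pairs"] == 2
        assert table.loc["chr1", "ici_rate"] == pytest.approx(0.5)
        assert table.loc["chr2", "ici_rate"] == pytest.approx(1.0)

    def test_no_usable_pairs_is_error(self):
        with pytest.raises(InsufficientDataError):
            ici_rates([make_pair(unmapped=True, chrom1=None, chrom2=None, mapq=0)])


class TestTotalAccessibility:
    @pytest.mark.parametrize("d,c,u,expected", [
        (0.068, 0.127, 0.209, 0.596),
        (0.061, 0.162, 0.248, 0.529),
        (0.0, 0.0, 0.0, 1.0),
    ])
    def test_values(self, d, c, u, expected):
        assert total_accessibility(d, c, u) == pytest.approx(expected, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_accessibility(1.2, 0.0, 0.0)


class TestHicMetricsConservation:
    @given(st.lists(st.sampled_from(["un", "dup", "inter", "intra"]), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_classes_partition_and_rates_sum_to_one(self, classes):
        pairs = []
        for i, cls in enumerate(classes):
            if cls == "un":
                pairs.append(make_pair(chrom1=None, chrom2=None, unmapped=True, mapq=0))
            elif cls == "dup":
                pairs.append(make_pair(pos1=0, pos2=100, duplicate=True))
            elif cls == "inter":
                pairs.append(make_pair(chrom2="chr2", pos1=i, pos2=i))
            else:
                pairs.append(make_pair(pos1=7 * i, pos2=7 * i + 1000))
        m = hic_metrics(pairs, dedup=False)
        assert m.n_unmapped + m.n_duplicate + m.n_inter + m.n_intra == m.n_pairs
        total = (m.unmapped_rate + m.duplication_rate + m.ici_rate
                 + m.total_accessibility)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestContactMatrix:
    def test_single_intra_pair_single_entry(self):
        lay = GenomeLayout.from_dict({"chr1": 1000})
        mat, bins = contact_matrix([make_pair(pos1=50, pos2=250)], lay, bin_size=100)
        assert mat.sum() == 1
        assert (mat.row[0], mat.col[0]) == (0, 2)

    def test_bins_are_floor_division_with_offsets(self):
        lay = GenomeLayout.from_dict({"chr1": 1000, "chr2": 1000})
        mat, bins = contact_matrix(
            [make_pair(chrom1="chr1", pos1=950, chrom2="chr2", pos2=10)], lay, 100
        )
        assert (mat.row[0], mat.col[0]) == (9, 10)
        assert bins.loc[bins.bin_id == 10, "chromosome"].item() == "chr2"

    def test_duplicates_excluded(self):
        lay = GenomeLayout.from_dict({"chr1": 1000})
        pairs = [make_pair(pos1=50, pos2=250),
                 make_pair(pos1=50, pos2=250, duplicate=True)]
        mat, _ = contact_matrix(pairs, lay, 100)
        assert mat.sum() == 1

    def test_unknown_chromosome_rejected(self):
        lay = GenomeLayout.from_dict({"chr1": 1000})
        with pytest.raises(ValueError, match="absent"):
            contact_matrix([make_pair(chrom1="chrX", chrom2="chrX", pos1=1, pos2=2)], lay, 100)

    @given(st.lists(st.tuples(st.integers(0, 999), st.integers(0, 999),
                              st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_matrix_total_equals_usable_pairs(self, raw):
        lay = GenomeLayout.from_dict({"chr1": 1000, "chr2": 1000})
        pairs, usable = [], 0
        for p1, p2, inter, dup in raw:
            pair = make_pair(chrom2="chr2" if inter else "chr1",
                             pos1=p1, pos2=p2, duplicate=dup).canonical(lay)
            pairs.append(pair)
            usable += not dup
        mat, _ = contact_matrix(pairs, lay, 64)
        assert mat.sum() == usable
        assert (mat.row <= mat.col).all()
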