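"""Interval computations: nearest-TSS assignment, overlaps, profiles."""

import numpy as np
import pytest

from gutreg.formats import GeneRecord, GenomicRegion, SignalTrack
from gutreg.regions import (
    PeakSet,
    assign_peaks_to_genes,
    compare_peak_sets,
    count_overlapping_pairs,
    flanking_signal_matrix,
    mean_profile,
)


def _peak(chrom, start, end, name="p", summit=None):
    return GenomicRegion(chrom, start, end, name=name, summit_offset=summit)


class TestAssignment:
    def test_nearest_tss_within_cutoff(self, small_annotation):
        peaks = PeakSet("x", [_peak("chr1", 4900, 5100, summit=100)])  # summit 5000
        a = assign_peaks_to_genes(peaks, small_annotation)
        row = a.table.iloc[0]
        assert row["gene_id"] == "g1" and row["distance"] == 1000

    def test_beyond_cutoff_unassigned(self, small_annotation):
        peaks = PeakSet("x", [_peak("chr1", 49900, 50100, summit=100)])  # 50000
        a = assign_peaks_to_genes(peaks, small_annotation)
        assert a.table.iloc[0]["gene_id"] is None

    def test_tie_broken_by_lexicographic_gene_id(self):
        genes = [
            GeneRecord("gB", "chr1", "+", 6000),
            GeneRecord("gA", "chr1", "+", 4000),
        ]
        peaks = PeakSet("x", [_peak("chr1", 4900, 5100, summit=100)])
        a = assign_peaks_to_genes(peaks, genes)
        assert a.table.iloc[0]["gene_id"] == "gA"

    def test_missing_chromosome_unassigned(self, small_annotation):
        peaks = PeakSet("x", [_peak("chrZ", 100, 200)])
        a = assign_peaks_to_genes(peaks, small_annotation)
        assert a.table.iloc[0]["gene_id"] is None

    def test_midpoint_used_without_summit(self):
        genes = [GeneRecord("g", "chr1", "+", 150)]
        a = assign_peaks_to_genes(PeakSet("x", [_peak("chr1", 100, 201)]), genes)
        assert a.table.iloc[0]["distance"] == 0  # midpoint floor = 150

    def test_matches_all_pairs_brute_force(self, rng):
        # independent oracle: exhaustive scan over every gene
        for _ in range(200):
            n_genes = int(rng.integers(1, 12))
            genes = [
                GeneRecord(f"g{i:02d}", rng.choice(["c1", "c2"]), "+",
                           int(rng.integers(0, 60000)))
                for i in range(n_genes)
            ]
            peaks = []
            for j in range(int(rng.integers(1, 8))):
                start = int(rng.integers(0, 60000))
                peaks.append(
                    _peak(str(rng.choice(["c1", "c2"])), start, start + 200,
                          name=f"p{j}", summit=int(rng.integers(0, 200)))
                )
            result = assign_peaks_to_genes(PeakSet("x", peaks), genes, 10000)
            for (_, row), peak in zip(result.table.iterrows(), peaks):
                best = None
                for g in genes:
                    if g.chrom != peak.chrom:
                        continue
                    d = abs(peak.reference_point - g.tss)
                    if d > 10000:
                        continue
                    if best is None or d < best[1] or (d == best[1] and g.gene_id < best[0]):
                        best = (g.gene_id, d)
                if best is None:
                    assert row["gene_id"] is None
                else:
                    assert (row["gene_id"], row["distance"]) == best


class TestComparePeakSets:
    def test_overlapping_regions_shared(self):
        a = PeakSet("A", [_peak("chr1", 100, 200)])
        b = PeakSet("B", [_peak("chr1", 150, 250)])
        cmp = compare_peak_sets(a, b)
        assert cmp.counts() == {"shared_a": 1, "unique_a": 0,
                                "shared_b": 1, "unique_b": 0}

    def test_disjoint_regions_unique(self):
        a = PeakSet("A", [_peak("chr1", 100, 200)])
        b = PeakSet("B", [_peak("chr1", 300, 400)])
        cmp = compare_peak_sets(a, b)
        assert cmp.counts() == {"shared_a": 0, "unique_a": 1,
                                "shared_b": 0, "unique_b": 1}

    def test_self_comparison_fully_shared(self, rng):
        regions = [
            _peak("chr1", int(s), int(s) + 100, name=f"p{i}")
            for i, s in enumerate(rng.integers(0, 5000, size=10))
        ]
        a = PeakSet("A", regions)
        cmp = compare_peak_sets(a, a)
        assert cmp.counts()["unique_a"] == 0 and cmp.counts()["shared_a"] == 10

    def test_min_overlap_boundary_and_validation(self):
        a = PeakSet("A", [_peak("chr1", 100, 200)])
        b = PeakSet("B", [_peak("chr1", 199, 300)])
        assert compare_peak_sets(a, b, min_overlap=1).counts()["shared_a"] == 1
        assert compare_peak_sets(a, b, min_overlap=2).counts()["shared_a"] == 0
        with pytest.raises(ValueError):
            compare_peak_sets(a, b, min_overlap=0)

    def test_pair_counts_symmetric(self, rng):
        def random_set(label):
            return PeakSet(label, [
                _peak("c1", int(s), int(s + rng.integers(50, 300)), name=f"{label}{i}")
                for i, s in enumerate(rng.integers(0, 4000, size=15))
            ])

        a, b = random_set("A"), random_set("B")
        assert count_overlapping_pairs(a, b) == count_overlapping_pairs(b, a)


class TestProfiles:
    def _uniform_track(self, value=2.0, lib=1e6):
        return SignalTrack([("chr1", 0, 100_000, value)], library_size=lib)

    def _sites(self, positions):
        return PeakSet(
            "s",
            [_peak("chr1", p - 100, p + 100, name=f"s{p}", summit=100)
             for p in positions],
        )

    def test_uniform_coverage_gives_flat_matrix(self):
        m = flanking_signal_matrix(self._sites([5000, 20000]), self._uniform_track())
        assert m.values.shape == (2, 40)  # 2*1000/50 bins
        assert np.allclose(m.values, m.values[0, 0])

    def test_doubling_library_size_halves_values(self):
        sites = self._sites([5000])
        m1 = flanking_signal_matrix(sites, self._uniform_track(lib=1e6))
        m2 = flanking_signal_matrix(sites, self._uniform_track(lib=2e6))
        assert np.allclose(m1.values, 2 * m2.values)

    def test_zero_coverage_gives_zero_matrix(self):
        track = SignalTrack([("chr1", 0, 10, 0.0)], library_size=1e6)
        m = flanking_signal_matrix(self._sites([5000]), track)
        assert np.all(m.values == 0)

    def test_truncated_bins_flagged_and_zeroed(self):
        m = flanking_signal_matrix(self._sites([300]), self._uniform_track())
        # window [-700, 1300): 14 bins fall before position 0
        assert m.truncated[0, :14].all() and not m.truncated[0, 14:].any()
        assert np.all(m.values[0, :14] == 0)

    def test_shift_equivariance(self, rng):
        starts = np.arange(0, 3000, 100)
        values = rng.uniform(0, 5, size=starts.size)
        shift = 1234
        t1 = SignalTrack(
            [("chr1", int(s), int(s) + 100, float(v)) for s, v in zip(starts, values)],
            library_size=1e6,
        )
        t2 = SignalTrack(
            [("chr1", int(s) + shift, int(s) + shift + 100, float(v))
             for s, v in zip(starts, values)],
            library_size=1e6,
        )
        m1 = flanking_signal_matrix(self._sites([1500]), t1)
        m2 = flanking_signal_matrix(self._sites([1500 + shift]), t2)
        assert np.allclose(m1.values, m2.values)

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError):
            flanking_signal_matrix(self._sites([5000]), self._uniform_track(),
                                   flank=1000, bin_width=33)

    def test_mean_profile_single_site_identity(self):
        m = flanking_signal_matrix(self._sites([5000]), self._uniform_track())
        means, n = mean_profile(m)
        assert np.allclose(means, m.values[0])
        assert np.all(n == 1)

    def test_mean_profile_excludes_truncated_bins(self):
        m = flanking_signal_matrix(self._sites([300, 50_000]),
                                   self._uniform_track())
        means, n = mean_profile(m)
        assert np.all(n[:14] == 1) and np.all(n[14:] == 2)
        # truncated zeros must not drag the mean down
        assert np.allclose(means, means[-1])

    def test_mean_profile_empty_matrix_rejected(self):
        m = flanking_signal_matrix(PeakSet("s", []), self._uniform_track())
        with pytest.raises(ValueError):
            mean_profile(m)
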