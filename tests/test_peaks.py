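"""Deduplication, coverage binning, and the Poisson enrichment caller."""

import math

import numpy as np
import pytest

from conftest import make_reads
from rg4dyn.peaks import (CoverageTrack, annotate_peaks, call_peaks, coverage,
                          deduplicate)

SIZES = {"chr1": 10_000}


def track(plus: np.ndarray, total: int | None = None,
          bin_size: int = 10) -> CoverageTrack:
    bins = {("chr1", "+"): np.asarray(plus, dtype=np.int64),
            ("chr1", "-"): np.zeros(len(plus), dtype=np.int64)}
    tot = int(np.asarray(plus).sum()) if total is None else total
    # chromosome much larger than the covered stretch, as in a real genome,
    # so the genome-background floor stays below the local control rate
    return CoverageTrack(bins=bins, bin_size=bin_size, total=tot,
                         chrom_sizes={"chr1": max(len(plus) * bin_size, 10 ** 6)})


def poisson_sf_oracle(k: int, lam: float) -> float:
    """P(X >= k) by direct summation of the Poisson pmf."""
    return 1.0 - sum(math.exp(-lam) * lam ** j / math.factorial(j)
                     for j in range(k))


class TestDeduplicate:
    def test_identical_records_collapse(self):
        rs = make_reads([("chr1", "+", 100, 30), ("chr1", "+", 100, 30)])
        assert len(deduplicate(rs)) == 1

    def test_key_includes_length(self):
        rs = make_reads([("chr1", "+", 100, 30), ("chr1", "+", 100, 31)])
        assert len(deduplicate(rs)) == 2

    def test_empty_and_order_independence(self):
        assert len(deduplicate(make_reads([]))) == 0
        a = make_reads([("chr1", "+", 5, 20), ("chr1", "-", 5, 20),
                        ("chr1", "+", 5, 20)])
        b = make_reads(list(reversed(a.reads)))
        assert deduplicate(a).reads == deduplicate(b).reads


class TestCoverage:
    def test_read_lands_in_containing_bin(self):
        cov = coverage(make_reads([("chr1", "+", 25, 30)]), SIZES, bin_size=10)
        assert cov.bins[("chr1", "+")][2] == 1
        assert cov.bins[("chr1", "+")].sum() == 1

    def test_conservation_and_strand_separation(self):
        rng = np.random.default_rng(0)
        recs = [("chr1", "+-"[i % 2], int(p), 30)
                for i, p in enumerate(rng.integers(0, 10_000, size=1000))]
        cov = coverage(make_reads(recs), SIZES, bin_size=10)
        assert cov.counted() == 1000
        assert cov.bins[("chr1", "+")].sum() == 500

    def test_bin_one_equals_per_base_histogram(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 200, size=500)
        cov = coverage(make_reads([("chr1", "+", int(p), 20) for p in pos]),
                       {"chr1": 200}, bin_size=1)
        oracle = np.bincount(pos, minlength=200)
        np.testing.assert_array_equal(cov.bins[("chr1", "+")], oracle)

    def test_read_beyond_chromosome_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            coverage(make_reads([("chr1", "+", 10_500, 30)]), SIZES)


class TestCallPeaks:
    def test_significant_bin_matches_tail_oracle(self):
        """treat 8 over flat control rate 2: FE 4, P(X>=8; 2) ~ 1.1e-3."""
        t = np.full(100, 2); t[40] = 8
        c = np.full(100, 2)
        ps = call_peaks(track(t, total=1000), track(c, total=1000))
        assert len(ps) == 1
        pk = ps.peaks[0]
        assert pk.start == 400 and pk.end == 410 and pk.summit == 405
        assert pk.fold_enrichment == pytest.approx(4.0)
        assert pk.p_value == pytest.approx(poisson_sf_oracle(8, 2.0), rel=1e-9)

    def test_fold_enrichment_cutoff_binds_regardless_of_p(self):
        t = np.full(100, 2); t[40] = 3     # FE 1.5 < 2
        ps = call_peaks(track(t, total=1000), track(np.full(100, 2), total=1000))
        assert len(ps) == 0

    def test_identical_tracks_yield_nothing(self):
        arr = np.random.default_rng(2).poisson(5, size=500)
        ps = call_peaks(track(arr), track(arr.copy()))
        assert len(ps) == 0

    def test_mismatched_bin_sizes_error(self):
        with pytest.raises(ValueError, match="bin size"):
            call_peaks(track(np.ones(10), bin_size=10),
                       track(np.ones(10), bin_size=20))

    def test_merging_and_summit_tiebreak(self):
        t = np.full(200, 2)
        t[50] = 40; t[52] = 40             # gap 2 <= min_gap: one peak
        t[120] = 40                        # far away: second peak
        ps = call_peaks(track(t, total=1000), track(np.full(200, 2), total=1000))
        assert len(ps) == 2
        first = ps.peaks[0]
        assert (first.start, first.end) == (500, 530)
        assert first.summit == 505         # leftmost maximal bin

    def test_monotonicity_in_cutoffs(self):
        """Loosening p or FE never loses a peak: every strict-cutoff peak is
        contained in some loose-cutoff peak."""
        rng = np.random.default_rng(3)
        t = rng.poisson(5, size=800); t[rng.integers(0, 800, 25)] += 30
        c = rng.poisson(5, size=800)
        strict = call_peaks(track(t, total=4000), track(c, total=4000),
                            p_cutoff=0.001, fe_cutoff=3.0)
        loose = call_peaks(track(t, total=4000), track(c, total=4000),
                           p_cutoff=0.05, fe_cutoff=2.0)
        assert len(strict) > 0
        for pk in strict:
            assert any(l.start <= pk.start and pk.end <= l.end
                       and l.strand == pk.strand for l in loose)

    def test_equals_exhaustive_per_bin_oracle(self):
        """Full re-derivation: per-bin lambda rule, significance, merge,
        summit — all recomputed naively and compared."""
        from scipy.stats import poisson as pois

        rng = np.random.default_rng(4)
        t = rng.poisson(6, size=600); t[rng.integers(0, 600, 15)] += 40
        c = rng.poisson(6, size=600)
        tt, ct = track(t, total=5000), track(c, total=5000)
        ps = call_peaks(tt, ct, min_gap=3, local_bins=100)

        scale = tt.total / ct.total
        floor = tt.total * 10 / tt.genome_size
        n = len(t)
        # edge-replicated padding, window size 100 (left 50 / right 49),
        # local lambda = mean over covered (nonzero) bins in the window
        padded = np.pad(c.astype(float) * scale, (50, 49), mode="edge")
        lam = np.empty(n)
        for i in range(n):
            win = padded[i:i + 100]
            covered = win[win > 0]
            local = covered.mean() if covered.size else 0.0
            lam[i] = max(c[i] * scale, local, floor)
        sig = [i for i in range(n)
               if t[i] > 0 and t[i] / lam[i] >= 2.0
               and pois.sf(t[i] - 1, lam[i]) <= 0.05]
        # naive merge with gap <= 3 bins
        groups, cur = [], [sig[0]]
        for i in sig[1:]:
            if i - cur[-1] <= 3:
                cur.append(i)
            else:
                groups.append(cur); cur = [i]
        groups.append(cur)
        assert len(ps) == len(groups)
        for pk, grp in zip(ps, groups):
            assert pk.start == grp[0] * 10 and pk.end == (grp[-1] + 1) * 10
            member_counts = [t[i] for i in grp]
            summit_bin = grp[int(np.argmax(member_counts))]
            assert pk.summit == summit_bin * 10 + 5


class TestAnnotatePeaks:
    def _peakset(self, summit, strand="+"):
        from rg4dyn.peaks import Peak, PeakSet
        pk = Peak("chr1", strand, summit - 5, summit + 5, summit,
                  4.0, 1e-4, 1e-3, 20, 5.0)
        return PeakSet([pk])

    def test_utr5_beats_cds_precedence(self, single_exon_pair):
        # txP 5'UTR is genomic [100,300); also inside txP's exon body
        out = annotate_peaks(self._peakset(150), single_exon_pair)
        assert out[0]["feature"] == "5UTR"

    def test_upstream_requires_same_strand_within_2kb(self, single_exon_pair):
        # 500 nt upstream of txM's TSS (minus strand TSS at 3099)
        out = annotate_peaks(self._peakset(3599, "-"), single_exon_pair)
        assert out[0]["feature"] == "upstream"
        # same position, plus strand: nothing nearby on that strand
        out = annotate_peaks(self._peakset(3599, "+"), single_exon_pair)
        assert out[0]["feature"] == "intergenic"

    def test_repeat_colabel(self, single_exon_pair):
        out = annotate_peaks(self._peakset(150), single_exon_pair,
                             repeats={("chr1", "+"): [(140, 160, "LTR/ERVL")]})
        assert out[0]["repeat_class"] == "LTR/ERVL"
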