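"""Metaprofiles, region densities, PQS scanning and k-mer enrichment."""

import re

import numpy as np
import pytest

from conftest import make_reads
from rg4dyn.peaks import CoverageTrack, Peak, PeakSet
from rg4dyn.quant import (g_enrichment, metaprofile, peak_matrix,
                          peak_upstream_sequences, region_density, revcomp,
                          scan_pqs)

SIZES = {"chr1": 100_000}


def flat_track(value: int, nbins: int = 1000, total: int = 10_000_000
               ) -> CoverageTrack:
    bins = {("chr1", "+"): np.full(nbins, value, dtype=np.int64),
            ("chr1", "-"): np.full(nbins, value, dtype=np.int64)}
    return CoverageTrack(bins=bins, bin_size=10, total=total,
                         chrom_sizes={"chr1": nbins * 10})


class TestMetaprofile:
    def test_uniform_track_gives_flat_profile(self):
        prof = metaprofile(flat_track(3), [("chr1", 5000, "+")], w=500)
        np.testing.assert_allclose(prof.values, 3.0)  # 3 per bin per 10M reads

    def test_delta_signal_lands_in_center_bin(self):
        tr = flat_track(0)
        tr.bins[("chr1", "+")][500] = 10
        prof = metaprofile(tr, [("chr1", 5005, "+")], w=500)
        assert prof.values[50] == pytest.approx(10.0)
        assert prof.values.sum() == pytest.approx(10.0)

    def test_minus_strand_anchor_mirrors_plus(self):
        """Signal 3 bins genomically left of a minus-strand anchor is 3 bins
        downstream (3') and must land where genomically-right signal lands
        for a plus-strand anchor."""
        minus = flat_track(0)
        minus.bins[("chr1", "-")][497] = 7
        plus = flat_track(0)
        plus.bins[("chr1", "+")][503] = 7
        p_minus = metaprofile(minus, [("chr1", 5005, "-")], w=500)
        p_plus = metaprofile(plus, [("chr1", 5005, "+")], w=500)
        np.testing.assert_allclose(p_minus.values, p_plus.values)
        assert p_plus.values[53] == pytest.approx(7.0)

    def test_pooled_profile_is_mean_of_singletons(self):
        rng = np.random.default_rng(5)
        tr = flat_track(0)
        tr.bins[("chr1", "+")][:] = rng.poisson(4, 1000)
        anchors = [("chr1", int(p), "+") for p in rng.integers(2000, 8000, 7)]
        pooled = metaprofile(tr, anchors, w=500)
        singles = np.mean([metaprofile(tr, [a], w=500).values for a in anchors],
                          axis=0)
        np.testing.assert_allclose(pooled.values, singles, atol=1e-12)


class TestPeakMatrix:
    def _peaks(self, summits):
        return PeakSet([Peak("chr1", "+", s - 5, s + 5, s, 4.0, 1e-4, 1e-3,
                             20, 5.0) for s in summits])

    def test_rows_sorted_by_mean_descending(self):
        tr = flat_track(0)
        tr.bins[("chr1", "+")][100] = 5    # summit 1005
        tr.bins[("chr1", "+")][400] = 9    # summit 4005
        mat, names = peak_matrix(tr, self._peaks([1005, 4005]), w=500)
        assert mat[0].sum() > mat[1].sum()
        assert names[0].startswith("chr1:4000")

    def test_column_means_equal_metaprofile_at_summits(self):
        rng = np.random.default_rng(6)
        tr = flat_track(0)
        tr.bins[("chr1", "+")][:] = rng.poisson(3, 1000)
        summits = [1005, 2505, 7775]
        mat, _ = peak_matrix(tr, self._peaks(summits), w=500)
        prof = metaprofile(tr, [("chr1", s, "+") for s in summits], w=500)
        np.testing.assert_allclose(mat.mean(axis=0), prof.values, atol=1e-12)


class TestRegionDensity:
    def test_rpkm_formula(self, single_exon_pair):
        # 10 reads in txP's 200 nt 5'UTR (genomic [100,300)), 1e6 total mapped
        recs = [("chr1", "+", 150 + i, 30) for i in range(10)]
        rs = make_reads(recs)
        rs.total = 1_000_000
        dens = region_density(rs, single_exon_pair)
        assert dens.loc[("txP", "5UTR"), "rpkm"] == pytest.approx(
            10 * 1e9 / (200 * 1e6))  # = 50
        assert dens.loc[("txP", "CDS"), "rpkm"] == 0.0
        assert dens.loc[("txM", "full"), "rpkm"] == 0.0

    def test_matches_per_base_brute_force(self, small_cfg):
        """Randomized instance vs a per-base counting oracle, tol 1e-9."""
        from rg4dyn.simulate import simulate_lace_reads, simulate_transcriptome

        _, catalog, truth = simulate_transcriptome(small_cfg)
        reads = simulate_lace_reads(truth, catalog, small_cfg, "GV", "BG4")
        reads.reads = reads.reads[:20_000]
        reads.total = 20_000
        dens = region_density(reads, catalog)

        # oracle: label every exonic base of every transcript, then count
        for tid in list(catalog.transcripts)[:25]:
            t = catalog[tid]
            base_region = {}
            for tpos in range(t.mature_length):
                base_region[t.transcript_to_genomic(tpos)] = t.region_of(tpos)
            counts = {"5UTR": 0, "CDS": 0, "3UTR": 0, "full": 0}
            for r in reads.reads:
                if r.chrom == t.chrom and r.strand == t.strand \
                        and r.pos5 in base_region:
                    counts[base_region[r.pos5]] += 1
                    counts["full"] += 1
            for region in counts:
                length = (t.mature_length if region == "full"
                          else t.region_length(region))
                expected = counts[region] * 1e9 / (length * reads.total)
                assert dens.loc[(tid, region), "rpkm"] == pytest.approx(
                    expected, abs=1e-9)

    def test_signal_density_ordering_follows_5utr_enriched_planting(self):
        """With 5'UTR-densest planting, aggregate in-peak signal per kb obeys
        5UTR > CDS and 5UTR > 3UTR in the folded (GV) condition."""
        from rg4dyn.peaks import call_peaks, coverage, deduplicate
        from rg4dyn.quant import reads_in_peaks
        from rg4dyn.simulate import (SimulationConfig, simulate_lace_reads,
                                     simulate_transcriptome)

        cfg = SimulationConfig(seed=13, n_transcripts=80, read_depth=300_000)
        _, catalog, truth = simulate_transcriptome(cfg)
        bg4 = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "BG4"))
        igg = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "IgG"))
        peaks = call_peaks(coverage(bg4, catalog.chrom_sizes),
                           coverage(igg, catalog.chrom_sizes))
        dens = region_density(reads_in_peaks(bg4, peaks), catalog)
        agg = dens.groupby("region").sum()
        rate = agg["count"] / agg["length"]      # reads per nt of region
        assert rate["5UTR"] > rate["CDS"]
        assert rate["5UTR"] > rate["3UTR"]

    def test_region_counts_sum_to_full(self, small_cfg):
        from rg4dyn.simulate import simulate_lace_reads, simulate_transcriptome

        _, catalog, truth = simulate_transcriptome(small_cfg)
        reads = simulate_lace_reads(truth, catalog, small_cfg, "GV", "IgG")
        dens = region_density(reads, catalog)
        by_tx = dens["count"].unstack("region")
        np.testing.assert_array_equal(
            by_tx[["5UTR", "CDS", "3UTR"]].sum(axis=1), by_tx["full"])


class TestScanPqs:
    def test_minimal_pqs(self):
        m = scan_pqs("GGGAGGGAGGGAGGG")
        assert len(m) == 1 and (m[0].start, m[0].end) == (0, 15)
        assert m[0].loop_lengths == (1, 1, 1)

    def test_no_g_runs_no_match(self):
        assert scan_pqs("ACACACAC") == []

    def test_u_equivalent_to_t(self):
        assert len(scan_pqs("GGGUGGGUGGGUGGG")) == 1

    def test_five_tracts_single_greedy_match_vs_window_oracle(self):
        seq = "GGGAGGGAGGGAGGGAGGG"
        matches = scan_pqs(seq)
        assert len(matches) == 1
        # exhaustive window oracle: all substrings that are exactly a PQS
        full = re.compile(r"G{3,}([ACGT]{1,7}G{3,}){3}")
        windows = [(i, j) for i in range(len(seq))
                   for j in range(i + 1, len(seq) + 1)
                   if full.fullmatch(seq[i:j])]
        assert windows, "oracle found no PQS windows"
        leftmost = min(w[0] for w in windows)
        assert matches[0].start == leftmost

    def test_long_tracts_and_loops(self):
        m = scan_pqs("TTGGGGGTTATCGGGTTTTTTTGGGCAGGGGTT")
        assert len(m) == 1
        assert m[0].loop_lengths == (5, 7, 2)


class TestSequencesAndKmers:
    GENOME = {"chr1": "".join(
        np.random.default_rng(7).choice(list("ACGT"), 1000))}

    def _peak(self, start, end, strand):
        return PeakSet([Peak("chr1", strand, start, end, (start + end) // 2,
                             4.0, 1e-4, 1e-3, 20, 5.0)])

    def test_plus_peak_extends_upstream_left(self):
        seqs = peak_upstream_sequences(self._peak(100, 150, "+"), self.GENOME)
        assert seqs[0][1] == self.GENOME["chr1"][70:150]

    def test_minus_peak_extends_upstream_right_and_rcs(self):
        seqs = peak_upstream_sequences(self._peak(100, 150, "-"), self.GENOME)
        assert seqs[0][1] == revcomp(self.GENOME["chr1"][100:180])

    def test_clipping_at_contig_start(self):
        seqs = peak_upstream_sequences(self._peak(10, 40, "+"), self.GENOME)
        assert seqs[0][1] == self.GENOME["chr1"][0:40]

    def test_fasta_path_input_matches_in_memory_genome(self, tmp_path):
        from rg4dyn.simulate import write_fasta
        fa = tmp_path / "g.fa"
        write_fasta(self.GENOME, fa)
        ps = self._peak(100, 150, "-")
        assert peak_upstream_sequences(ps, str(fa)) == \
            peak_upstream_sequences(ps, self.GENOME)

    def test_g_rich_kmers_top_enrichment_on_planted_pqs(self):
        rng = np.random.default_rng(8)
        background = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(80)]
        fg = []
        for b in background[:40]:
            fg.append(b[:20] + "GGGAGGGAGGGAGGG" + b[35:])
        enr = g_enrichment(fg, background, k=6)
        assert enr.index[0].count("G") >= 4
        assert enr.iloc[0] > 1.0
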