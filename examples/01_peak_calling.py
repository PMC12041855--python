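"""Call rG4 RT-stop peaks on a simulated capture library and check recovery.

Simulates an immature-oocyte (GV) condition: a BG4 antibody-capture library
whose read 5' ends pile up at folded quadruplex sites, plus an IgG isotype
control, then calls treatment-over-control Poisson enrichment peaks.
"""

from rg4dyn.peaks import call_peaks, coverage, deduplicate
from rg4dyn.simulate import (SimulationConfig, simulate_lace_reads,
                             simulate_transcriptome)

cfg = SimulationConfig(seed=42, n_transcripts=60, read_depth=200_000)
genome, catalog, truth = simulate_transcriptome(cfg)
print(f"simulated {len(catalog)} transcripts carrying "
      f"{len(truth.sites)} planted quadruplex sites")

bg4 = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "BG4"))
igg = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "IgG"))
print(f"deduplicated libraries: BG4 {len(bg4)} reads, IgG {len(igg)} reads")

peaks = call_peaks(coverage(bg4, catalog.chrom_sizes),
                   coverage(igg, catalog.chrom_sizes))
hits = sum(1 for _, s in truth.sites.iterrows() if any(
    p.chrom == s.chrom and p.strand == s.strand
    and abs(p.summit - s.stop_gpos) <= 15 for p in peaks))
print(f"{len(peaks)} peaks called at p<=0.05, fold-enrichment>=2")
print(f"{hits}/{len(truth.sites)} planted sites have a peak summit within "
      "15 nt of the true reverse-transcription stop")
# Every planted site should be recovered and nearly every peak should be a
# planted site: the RT-stop pileup is ~50x the local background.
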