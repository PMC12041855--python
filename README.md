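# rg4dyn

Analysis of RNA G-quadruplex (rG4) dynamics from reverse-transcription-stop
profiling, with translatome integration — built for the mouse-oocyte setting
where maternal transcripts carry folded rG4s before meiotic resumption and
shed them during maturation.

## The problem

rG4s are four-stranded structures of stacked guanine tetrads. In low-input
antibody-capture RT-stop protocols (BG4 capture with an IgG isotype control),
reverse transcriptase terminates at the antibody-bound structure, so the
library's read **5′ ends** pile up at single-base RT stops marking rG4
positions. Mapping how these structures appear and disappear across oocyte
maturation stages (GV → MII), and what a quadruplex-stabilizing ligand (BYBX)
does to translation, requires several coordinated analyses:

* **Peak calling.** Per 10-nt bin and strand, treatment count *t* is tested
  against a control expectation λ = max(scaled control bin, scaled local mean
  over covered bins, genome background): a bin is significant when the
  Poisson upper tail P(X ≥ t; λ) ≤ 0.05 **and** t/λ ≥ 2; nearby significant
  bins merge into peaks.
* **Region densities.** rG4 RPKM per transcript region,
  RPKM = reads·10⁹ / (region length · total mapped reads), with 5′UTR / CDS /
  3′UTR derived from the annotation.
* **Stage and treatment dynamics.** Stage-specific vs shared rG4-bearing
  transcripts (hypergeometric overlap test), and per-transcript removal
  blockade under the ligand via the retention ratio
  ρ = (d_BYBX − d_DMSO) / (d_GV − d_DMSO), clamped to [0, 1].
* **Translatome.** Spike-in-normalized FPKM (FPKM = count·10⁹ / (L · E_s)
  with E_s the sample's total spike-in reads), translational efficiency
  TE = (RPF + ε)/(mRNA + ε), strict 2-fold change classes, and rG4 × TE
  quadrants; plus RNA-binding-protein binding-change classes from
  interactome-capture intensities.

Every stage is verifiable: a seeded synthetic-data generator plants canonical
quadruplex motifs (G≥3 tracts, 1–7 nt loops) with known per-condition
foldedness, known transcript abundances and known TE suppression, so peak
calling, density quantification and TE estimation can all be checked by
parameter recovery.

## Worked example

```python
from rg4dyn.peaks import call_peaks, coverage, deduplicate
from rg4dyn.simulate import (SimulationConfig, simulate_lace_reads,
                             simulate_transcriptome)

cfg = SimulationConfig(seed=42, n_transcripts=60, read_depth=200_000)
genome, catalog, truth = simulate_transcriptome(cfg)
bg4 = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "BG4"))
igg = deduplicate(simulate_lace_reads(truth, catalog, cfg, "GV", "IgG"))
peaks = call_peaks(coverage(bg4, catalog.chrom_sizes),
                   coverage(igg, catalog.chrom_sizes))
```

Running `python examples/01_peak_calling.py` (the same computation) prints:

```
simulated 60 transcripts carrying 30 planted quadruplex sites
deduplicated libraries: BG4 202091 reads, IgG 198211 reads
31 peaks called at p<=0.05, fold-enrichment>=2
30/30 planted sites have a peak summit within 15 nt of the true
reverse-transcription stop
```

i.e. at 50-fold RT-stop enrichment every planted site is recovered at
base-level precision, with one background peak. The other scripts in
`examples/` walk through region densities and removal categories
(`02_density_dynamics.py`), spike-normalized TE and rG4×TE quadrants
(`03_translatome.py`), RBP binding classes (`04_rbp_binding.py`) and
PQS scanning / k-mer enrichment (`05_pqs_and_motifs.py`).

A thin CLI mirrors the stages
(`rg4dyn simulate|callpeaks|quantify|dynamics|translatome|report`); all
artifacts are plain text (FASTA, BED, bedGraph, narrowPeak, TSV, JSON) and
byte-identical across runs given the same seed.

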