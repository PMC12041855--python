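# Methods

## Signal model

The assay being modelled is antibody-capture RT-stop profiling of RNA
G-quadruplexes: reverse transcription terminates at the antibody-bound
structure, and the terminated cDNA ends are amplified and sequenced. The
informative coordinate of every read is therefore its **5′ end**; for a
minus-strand alignment that is the rightmost genomic base of the alignment
interval. All coordinates are 0-based half-open internally; GTF input
(1-based closed) is converted on ingest.

A planted site's RT stop is placed at the transcript-coordinate base
immediately 3′ of the quadruplex (the first templated base the polymerase
fails to copy past, approaching from the 3′ side). The base-level offset of
real polymerase stalling is not precisely known, so it is exposed as
`rt_stop_offset` (default 0); recovery is always scored with a ±15 nt summit
tolerance, which is robust to small offsets.

## Peak calling

Libraries are deduplicated on the key (chrom, strand, 5′ position, length) —
one survivor per key, order-independently — then binned at 10 nt per strand.
Against the isotype control, each bin's expectation is

    lambda = max(scaled control bin,
                 scaled local control mean (covered bins, ~1 kb window),
                 treat_total * bin_size / genome_size)

and a bin is significant iff the Poisson upper tail P(X ≥ t; λ) ≤ 0.05 and
t/λ ≥ 2 (the raw-p and fold-enrichment cutoffs of the standard caller
configuration this replaces). Significant bins within 3 bins merge; the
summit is the leftmost maximal-treatment bin's center; a q-value column
(Benjamini–Hochberg over significant bins) is emitted for information only
and plays no role in acceptance.

Two deliberate differences from the common MACS-style workflow:

* **Stranded calling.** RT-stop libraries are stranded; treatment and
  control are compared within strand.
* **Local λ over covered bins.** A single-pass rule with one local window
  replaces sliding slocal/llocal machinery. The local mean is taken over
  *covered* (nonzero) control bins only: the signal is transcript-confined,
  and averaging in empty intergenic bins at transcript edges systematically
  underestimates λ there, which a direct check showed inflates the false
  discovery rate far beyond the intended calibration (marginal 2.0–2.2×
  fluctuations pass a λ that is 30% too low). Taking the max of the
  bin-level and local estimates plus the genome floor is strictly
  conservative and remains exactly reproducible by a brute-force per-bin
  oracle (see `tests/test_peaks.py`).

## Quantification

* **Region densities.** RPKM = reads·10⁹ / (region length · total mapped
  deduplicated reads). The denominator choice (per-library deduplicated
  totals) is stated in output metadata. A read counts toward every transcript
  whose exons contain its 5′ end (no multi-isoform rescue) — a documented
  simplification. `region_density` defaults to all read ends;
  `reads_in_peaks` restricts a library to the called peak space for *signal*
  densities. The pipeline uses the restricted densities for removal
  categories and condition density ratios, because the generator's uniform
  background is ~90 % of each library and would otherwise mask occupancy
  changes; both tables are always written.
* **Metaprofiles / peak matrices.** Signal normalized to counts per 10⁷
  mapped reads, windows on the coverage grid, minus-strand anchors flipped so
  the axis runs 5′→3′ with the anchor bin at the same index on both strands.
  Peak-matrix column means equal the metaprofile over the same summits by
  construction.
* **PQS scanning.** Canonical pattern G{3,}(N{1–7}G{3,}){3}, T≡U,
  non-overlapping left-to-right matches with lazily matched loops (a loop
  never swallows a G-tract that could open the next stem). Motif discovery is
  replaced by deterministic k-mer log2 enrichment with one pseudo-observation
  per sequence set.

## Dynamics and translatome

* A transcript is **rG4-containing** in a condition iff ≥ 1 peak summit maps
  into its exons (configurable to any-overlap). Cluster identities
  (A-specific + shared = A total) hold exactly by construction.
* **Overlap significance** is the hypergeometric upper tail — the standard
  exact test for set overlap; this replaces the ad hoc test sometimes quoted
  next to Venn diagrams, and the output metadata says so.
* **Removal categories.** Evaluable transcripts are rG4-containing at GV with
  ≥ 2-fold vehicle-arm removal (d_GV + ε ≥ 2 (d_DMSO + ε)); the retention
  ratio ρ = (d_BYBX − d_DMSO)/(d_GV − d_DMSO) (ε added throughout, clamped to
  [0,1]) is cut at 0.25 / 0.75 into not-affected / partially / completely
  blocked. The source analysis names the categories but no cutoffs; 0.25/0.75
  makes three non-degenerate classes and is scale-invariant (rescaling all
  densities and ε by c > 0 changes nothing). All thresholds are echoed in
  every report.
* **Spike normalization.** FPKM_t = count_t·10⁹ / (L_t · E_s) with E_s the
  sample's total spike-in-mapped reads; a median-of-ratios variant is
  available behind a flag. Because each sample receives the same spike pool,
  E_s absorbs the per-sample depth nuisance factor, which is exactly the
  property the simulation injects and the tests verify. RPF FPKM uses CDS
  length (footprints are CDS events); a full-length flag exists.
* **TE and classes.** TE = (RPF + ε)/(mRNA + ε), ε = 0.1 FPKM (the degenerate
  0/0 case is defined as 1 and flagged low-confidence, as is any transcript
  never reaching 1 mRNA FPKM). "More than 2-fold" is read strictly: a ratio
  of exactly 2 is unchanged. RBP classes: proteins without input signal are
  excluded; IP_mock > 0 with IP_bybx = 0 is completely blocked; otherwise the
  strict < 0.5 / > 2 fold-change cut.

## The synthetic-data generator

The generator defines the study conditions the package is tested under, on
one toy chromosome: 100 transcripts (5′UTR/CDS/3′UTR ≈ 200/900/400 nt,
±25 %, half with one intron), strand alternating, background sequence G-run
free by rejection so every canonical PQS present was planted. Per region, at
most one site is planted with probabilities 0.30 / 0.04 / 0.17
(5′UTR-densest per kilobase; ≈ 50 sites expected). Site foldedness f per
condition encodes the biology: high before meiotic resumption
(f_GV ~ U(0.7, 1)), removed at MII (f_DMSO ~ U(0, 0.1)), re-stabilized by the
ligand (f_BYBX ~ U(0.7, 1)).

Reads: background 5′ ends uniform over transcript positions with weight
abundance × length (abundance lognormal, σ = 0.25 log-units); in the capture
library each site adds Poisson reads at its RT stop with mean
(per-bin background) × λ_fold × f, λ_fold = 50; the control library has no
site term. Read lengths are U[20, 150] so single-base pileups survive
key-based deduplication; PCR duplicates (exact copies) are appended at rate
0.15. Expression: mRNA ~ Poisson(sf · depth · aL / Σ), RPF ~
Poisson(sf · depth · aτL_CDS / Σ) at depth 10⁶ per sample, with a hidden
per-sample factor sf ~ U(0.5, 2) that spike normalization must cancel, and
20 spike species on a 2^(k/2) concentration ladder (5 % of depth). True TE:
log₂ τ = τ₀ − α·Σf(5′UTR) − β·Σf(3′UTR), τ₀ ~ N(0, 0.5), α = 2.5, β = 0.6.
Negative-binomial over-dispersion is available (`dispersion`, default 0).
Every stream is seeded by name from the master seed (hash-stable), so all
outputs are byte-identical across runs and processes.

**How the scale and effect sizes were fixed.** The conditions form a joint
design and were chosen once, as a power calculation:

* At 5 × 10⁵ reads per library, 150 kb of transcribed sequence gives ~33
  background reads per 10-nt bin. Under the prescribed raw-p 0.05 / FE 2
  rule, the genome-wide expected number of 2-fold background fluctuations
  must be small relative to ~50 true sites for a ≤ 5 % empirical FDR; that
  requires a per-bin rate ≳ 20–30, which bounds the transcriptome size and
  the abundance spread (σ = 0.25). Real libraries are far more dispersed;
  see limitations.
* α must satisfy α · min(f gain) − 1 ≫ the log₂ counting noise (~0.2 at
  10⁶ counts over 500 transcripts) for ligand-folded 5′UTR transcripts to be
  classifiable as TE-down; α = 2.5 gives the weakest planted effect a
  ≥ 2.5 σ margin. β = 0.6 keeps a pure 3′UTR load below the 2-fold class
  boundary by design.
* λ_fold = 50 is a free choice (no quantitative enrichment magnitude is
  available for the real assay) and is echoed in every report.

## What the tests do and do not show

Passing recovery tests show the implementation is correct and calibrated
under the generator's assumptions. They do not show field performance on
real libraries, which differ in ways the generator deliberately omits:
sequencing errors, fragment-length structure, multi-isoform ambiguity,
heavy-tailed abundances, non-uniform background (RNase/RT sequence bias),
partial or heterogeneous folding, and real spike-in catalogs. Known
limitations within the model:

* Key-based deduplication saturates single-base pileups (≤ 131 distinct
  lengths per position), compressing the dynamic range of site signal; at
  pipeline scale this blurs "partial" vs "complete" removal blockade (the
  noiseless-category test isolates the classification rule itself).
* RPKM counts a read toward every overlapping isoform; quantitative
  densities on overlapping gene models are upper bounds.
* The Venn p-value printed by the pipeline is a hypergeometric tail over the
  catalog universe; it is sensitive to the universe definition, which is
  stated in the output.
* With an even number of profile bins the anchor bin sits at index w/bin;
  metaprofiles are exactly mirror-symmetric across strands by construction,
  at the cost of a half-bin asymmetry of the window around the anchor base.

## Problem sizes used in checks

Calibration and recovery run at the default conditions above (100
transcripts, 5 × 10⁵ reads per library; ≥ 10⁴ covered control bins for the
null check). TE recovery uses 500 transcripts at 10⁶ counts per sample. The
end-to-end determinism check runs the full pipeline twice at a reduced size
(40 transcripts, 5 × 10⁴ reads, 2 × 10⁵ counts) and compares artifact
hashes; structure and code paths are identical to the defaults.
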