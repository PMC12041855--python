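"""Synthetic oocyte-maturation data with known ground truth.

The generator builds a toy transcriptome with quadruplex-forming sequences
(PQS) planted preferentially in 5' UTRs, then emulates every downstream input
of the analysis:

* RT-stop read ends: a uniform background over transcribed positions plus,
  in the capture (BG4) library only, a pile-up at each planted site's 3' edge
  whose expected height is background_per_bin * lambda_fold * f, where f is
  the site's foldedness in that condition. The isotype (IgG) control has no
  site term. PCR duplicates are appended at a configured rate.
* mRNA / ribosome-footprint counts with spike-in rows: Poisson counts around
  true abundances, with a per-sample nuisance depth factor that spike
  normalization must cancel, and true translational efficiency suppressed by
  the per-transcript UTR foldedness load:
  log2 tau = tau0 - alpha * sum f(5'UTR sites) - beta * sum f(3'UTR sites).
* RNA-binding-protein intensities with planted binding-change classes.

Foldedness follows the biology being modelled: high before meiotic
resumption (GV), largely removed at metaphase II (MII + vehicle), and
re-stabilized when the quadruplex ligand is present (MII + BYBX). Everything
is deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import (REGION_3UTR, REGION_5UTR, REGION_CDS, ReadEnd,
                         ReadEndSet, TranscriptCatalog, TranscriptModel)

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "TruthTable",
    "simulate_transcriptome",
    "simulate_lace_reads",
    "simulate_expression",
    "simulate_rbp_intensities",
    "write_fasta",
    "write_bed12",
]

CONDITIONS = ("GV", "MII_DMSO", "MII_BYBX")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory.

    Defaults describe the study conditions the package is tested under:
    ~50 planted sites enriched in 5' UTRs, 50-fold RT-stop enrichment over
    background, 5e5 reads per RT-stop library, and strong 5'UTR TE
    suppression (alpha) with a milder 3'UTR term (beta).
    """

    seed: int
    n_transcripts: int = 100
    utr5_len: int = 200
    cds_len: int = 900
    utr3_len: int = 400
    length_jitter: float = 0.25          # uniform +/- fraction on region lengths
    intron_prob: float = 0.5
    intron_len: tuple[int, int] = (200, 500)
    # ~0.5 sites per transcript (=> ~50 sites at the default size), with the
    # highest per-kilobase planting density in the 5'UTR
    site_prob: dict = field(default_factory=lambda: {
        REGION_5UTR: 0.30, REGION_CDS: 0.04, REGION_3UTR: 0.17})
    f_ranges: dict = field(default_factory=lambda: {
        "GV": (0.7, 1.0), "MII_DMSO": (0.0, 0.1), "MII_BYBX": (0.7, 1.0)})
    read_depth: int = 500_000            # RT-stop reads per library
    lambda_fold: float = 50.0            # site enrichment over background
    site_bin_ref: int = 10               # bin width the enrichment is defined on
    rt_stop_offset: int = 0              # nt 3' of the site edge
    rt_stop_jitter_sd: float = 0.0
    pcr_dup_rate: float = 0.15
    read_len_range: tuple[int, int] = (20, 150)
    abundance_sigma: float = 0.25        # lognormal sd of true abundance
    expression_depth: int = 1_000_000    # expected mRNA counts per sample
    rpf_depth: int = 1_000_000
    alpha: float = 2.5                   # TE suppression per unit 5'UTR foldedness
    beta: float = 0.6                    # ... per unit 3'UTR foldedness
    tau0_sd: float = 0.5                 # log2 spread of baseline TE
    spike_frac: float = 0.05             # spike reads as fraction of depth
    n_ercc: int = 20
    ercc_length: int = 1000
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    dispersion: float = 0.0              # NB over-dispersion; 0 = Poisson
    n_rbp: int = 100
    rbp_class_counts: dict = field(default_factory=lambda: {
        "down": 20, "up": 10, "completely_blocked": 10,
        "unchanged": 55, "input_absent": 5})
    rbp_noise_sd: float = 0.1            # log2 multiplicative noise
    intergenic_gap: int = 500
    chrom_margin: int = 2000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.pcr_dup_rate <= 1:
            raise ValueError("pcr_dup_rate must be in [0,1]")
        for region, p in self.site_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"site probability for {region} not in [0,1]")
        for v in (self.lambda_fold, self.read_depth, self.expression_depth,
                  self.spike_frac, self.dispersion):
            if v < 0:
                raise ValueError("rates and depths must be >= 0")

    def rng(self, *stream: object) -> np.random.Generator:
        """A named deterministic random stream derived from the master seed."""
        # stable across processes (unlike hash())
        raw = hashlib.blake2s(repr(stream).encode()).digest()[:4]
        digest = int.from_bytes(raw, "big") % (2**31)
        return np.random.default_rng([int(self.seed), digest])


@dataclass
class TruthTable:
    """Ground truth of a simulation: planted sites, transcript parameters,
    and (once generated) RBP binding classes."""

    sites: pd.DataFrame        # site_id, transcript_id, region, tx/genomic pos, f_*
    transcripts: pd.DataFrame  # transcript_id, abundance, tau_<condition>, f loads
    rbps: pd.DataFrame | None = None

    def foldedness_load(self, condition: str, region: str) -> pd.Series:
        """Per-transcript sum of site foldedness in a region and condition."""
        if len(self.sites) == 0:
            return pd.Series(dtype=float)
        sub = self.sites[self.sites["region"] == region]
        return sub.groupby("transcript_id")[f"f_{condition}"].sum()


# ---------------------------------------------------------------------------
# transcriptome with planted PQS


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    """Random sequence free of G-runs >= 3 (background must carry no PQS)."""
    bases = "ACGT"
    out: list[str] = []
    run = 0
    draws = rng.integers(0, 4, size=n)
    redraws = rng.integers(0, 3, size=n)
    for i in range(n):
        b = bases[draws[i]]
        if b == "G" and run == 2:
            b = "ACT"[redraws[i]]
        run = run + 1 if b == "G" else 0
        out.append(b)
    return out


def _make_pqs(rng: np.random.Generator) -> str:
    """A canonical PQS: four G-tracts (3-4 G) with 1-7 nt G-free loops."""
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 8))
            parts.append("".join("ACT"[j] for j in rng.integers(0, 3, loop_len)))
    return "".join(parts)


def simulate_transcriptome(cfg: SimulationConfig
                           ) -> tuple[dict[str, str], TranscriptCatalog, TruthTable]:
    """Build the toy genome, its transcript catalog and the truth table.

    One chromosome; transcripts alternate strand and are separated by
    intergenic gaps. Half the transcripts carry one intron inside the CDS so
    coordinate mapping is exercised. Background sequence is G-run-free by
    construction; planted sites match the canonical PQS pattern and their
    coordinates (including the RT-stop base at the site's 3' edge) are
    recorded in the truth table.
    """
    rng = cfg.rng("transcriptome")
    chrom = "chr1"
    cursor = cfg.chrom_margin
    genome_parts: list[str] = [
        "".join(_random_bases(rng, cfg.chrom_margin))]
    models: dict[str, TranscriptModel] = {}
    site_rows: list[dict] = []
    tx_rows: list[dict] = []

    for i in range(cfg.n_transcripts):
        tid = f"tx{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        jit = lambda mean: max(60, int(round(mean * rng.uniform(
            1 - cfg.length_jitter, 1 + cfg.length_jitter))))
        u5, cds, u3 = jit(cfg.utr5_len), jit(cfg.cds_len), jit(cfg.utr3_len)
        mature = u5 + cds + u3

        # transcript sequence (5'->3'), then plant at most one PQS per region
        seq = _random_bases(rng, mature)
        region_spans = {REGION_5UTR: (0, u5), REGION_CDS: (u5, u5 + cds),
                        REGION_3UTR: (u5 + cds, mature)}
        planted: list[tuple[str, int, int]] = []
        for region, (lo, hi) in region_spans.items():
            if rng.uniform() >= cfg.site_prob[region]:
                continue
            pqs = _make_pqs(rng)
            # keep 2 nt inside the region on each side, plus room for the stop
            if hi - lo < len(pqs) + 6:
                continue  # region too short to host a PQS
            start = int(rng.integers(lo + 2, hi - len(pqs) - 2))
            seq[start:start + len(pqs)] = list(pqs)
            # A-flanks keep the planted tract boundaries exact
            seq[start - 1] = "A"
            seq[start + len(pqs)] = "A"
            planted.append((region, start, start + len(pqs)))

        # genomic layout: optional single intron inside the CDS
        exon_lens = [mature]
        if rng.uniform() < cfg.intron_prob and cds > 100:
            cut = u5 + int(rng.integers(20, cds - 20))
            exon_lens = [cut, mature - cut]
        intron = int(rng.integers(*cfg.intron_len)) if len(exon_lens) == 2 else 0

        g_start = cursor
        exons = []
        pos = g_start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron if j == 0 and len(exon_lens) == 2 else 0)
        g_end = pos

        # map CDS to genomic bounds (tx coords [u5, u5+cds))
        tmp = TranscriptModel(tid, f"gene{i:04d}", chrom, strand,
                              tuple(exons))
        g_a = tmp.transcript_to_genomic(u5)
        g_b = tmp.transcript_to_genomic(u5 + cds - 1)
        model = TranscriptModel(tid, f"gene{i:04d}", chrom, strand, tuple(exons),
                                min(g_a, g_b), max(g_a, g_b) + 1)
        models[tid] = model

        # genomic sequence for the transcript locus
        locus = _random_bases(rng, g_end - g_start)  # intron + placeholder
        for tpos in range(mature):
            g = model.transcript_to_genomic(tpos)
            base = seq[tpos]
            locus[g - g_start] = base if strand == "+" else _COMP[base]
        genome_parts.append("".join(locus))
        genome_parts.append("".join(_random_bases(rng, cfg.intergenic_gap)))
        cursor = g_end + cfg.intergenic_gap

        # truth rows
        fs = {c: None for c in CONDITIONS}
        for region, s, e in planted:
            stop_t = min(e + cfg.rt_stop_offset, mature - 1)
            row = {
                "site_id": f"{tid}:{region}",
                "transcript_id": tid, "region": region,
                "tx_start": s, "tx_end": e, "stop_tpos": stop_t,
                "chrom": chrom, "strand": strand,
                "stop_gpos": model.transcript_to_genomic(stop_t),
            }
            for cond in CONDITIONS:
                lo_f, hi_f = cfg.f_ranges[cond]
                row[f"f_{cond}"] = float(rng.uniform(lo_f, hi_f))
            site_rows.append(row)

        tx_rows.append({"transcript_id": tid, "mature_length": mature,
                        "cds_length": cds, "strand": strand})

    genome = {chrom: "".join(genome_parts) + "".join(
        _random_bases(rng, cfg.chrom_margin))}
    chrom_sizes = {chrom: len(genome[chrom])}
    catalog = TranscriptCatalog(models, chrom_sizes=chrom_sizes)

    sites = pd.DataFrame(site_rows, columns=[
        "site_id", "transcript_id", "region", "tx_start", "tx_end",
        "stop_tpos", "chrom", "strand", "stop_gpos",
        *(f"f_{c}" for c in CONDITIONS)])
    tx = pd.DataFrame(tx_rows).set_index("transcript_id")
    tx["abundance"] = np.exp(rng.normal(0.0, cfg.abundance_sigma,
                                        len(tx)))
    tau0 = rng.normal(0.0, cfg.tau0_sd, len(tx))
    truth = TruthTable(sites=sites, transcripts=tx)
    for cond in CONDITIONS:
        load5 = truth.foldedness_load(cond, REGION_5UTR).reindex(tx.index, fill_value=0.0)
        load3 = truth.foldedness_load(cond, REGION_3UTR).reindex(tx.index, fill_value=0.0)
        tx[f"load5_{cond}"] = load5
        tx[f"load3_{cond}"] = load3
        tx[f"tau_{cond}"] = 2.0 ** (tau0 - cfg.alpha * load5 - cfg.beta * load3)
    return genome, catalog, truth


# ---------------------------------------------------------------------------
# RT-stop read simulation


def _genomic_maps(catalog: TranscriptCatalog) -> dict[str, np.ndarray]:
    """Per-transcript array mapping transcript coordinate -> genomic position."""
    maps: dict[str, np.ndarray] = {}
    for t in catalog:
        plus = np.concatenate([np.arange(s, e) for s, e in t.exons])
        maps[t.transcript_id] = plus if t.strand == "+" else plus[::-1]
    return maps


def simulate_lace_reads(truth: TruthTable, catalog: TranscriptCatalog,
                        cfg: SimulationConfig, condition: str,
                        library: str = "BG4") -> ReadEndSet:
    """Simulate RT-stop read 5' ends for one library of one condition.

    Background 5' ends fall uniformly over transcribed positions, with
    per-transcript weight abundance * length. In the capture library each
    planted site adds Poisson reads at its RT-stop base with mean
    (background per ``site_bin_ref`` nt) * lambda_fold * foldedness. PCR
    duplicates (exact copies) are appended at the configured rate.
    """
    if library not in ("BG4", "IgG"):
        raise ValueError("library must be BG4 or IgG")
    if condition not in cfg.f_ranges:
        raise ValueError(f"no foldedness defined for condition {condition!r}")
    rng = cfg.rng("lace", condition, library)
    tx = truth.transcripts
    tids = list(tx.index)
    lengths = tx["mature_length"].to_numpy(dtype=float)
    weights = tx["abundance"].to_numpy() * lengths
    p = weights / weights.sum()
    gmaps = _genomic_maps(catalog)
    lmin, lmax = cfg.read_len_range

    records: list[ReadEnd] = []
    n_per_tx = rng.multinomial(cfg.read_depth, p)
    for tid, n in zip(tids, n_per_tx):
        if n == 0:
            continue
        t = catalog[tid]
        tpos = rng.integers(0, t.mature_length, size=n)
        gpos = gmaps[tid][tpos]
        rl = rng.integers(lmin, lmax + 1, size=n)
        records.extend(ReadEnd(t.chrom, t.strand, int(g), int(l))
                       for g, l in zip(gpos, rl))

    if library == "BG4" and len(truth.sites):
        per_base = cfg.read_depth * p / lengths  # background reads per nt
        rate_by_tid = dict(zip(tids, per_base * cfg.site_bin_ref))
        fcol = f"f_{condition}"
        for _, site in truth.sites.iterrows():
            mean = rate_by_tid[site["transcript_id"]] * cfg.lambda_fold * site[fcol]
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            t = catalog[site["transcript_id"]]
            stop = int(site["stop_tpos"])
            if cfg.rt_stop_jitter_sd > 0:
                tpos = np.clip(np.rint(rng.normal(stop, cfg.rt_stop_jitter_sd, n)),
                               0, t.mature_length - 1).astype(int)
            else:
                tpos = np.full(n, stop)
            gpos = gmaps[t.transcript_id][tpos]
            rl = rng.integers(lmin, lmax + 1, size=n)
            records.extend(ReadEnd(t.chrom, t.strand, int(g), int(l))
                           for g, l in zip(gpos, rl))

    if cfg.pcr_dup_rate > 0 and records:
        dup_mask = rng.uniform(size=len(records)) < cfg.pcr_dup_rate
        records.extend(r for r, d in zip(list(records), dup_mask) if d)

    return ReadEndSet(records, total=len(records), library=library,
                      condition=condition)


# ---------------------------------------------------------------------------
# expression / translatome simulation


def _noisy_poisson(rng: np.random.Generator, lam: np.ndarray,
                   dispersion: float) -> np.ndarray:
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * lam)
    return rng.poisson(lam)


def ercc_concentrations(cfg: SimulationConfig) -> pd.Series:
    """Known spike concentrations: a 2^(k/2) ladder over ``n_ercc`` species."""
    ids = [f"ERCC-{k:05d}" for k in range(cfg.n_ercc)]
    conc = 2.0 ** (np.arange(cfg.n_ercc) / 2.0)
    return pd.Series(conc / conc.sum(), index=ids, name="concentration")


def simulate_expression(truth: TruthTable, cfg: SimulationConfig,
                        condition: str) -> tuple[pd.Series, pd.Series]:
    """Poisson mRNA and ribosome-footprint counts for one condition,
    spike rows included.

    mRNA ~ Poisson(sf * depth * a_t * L_t / norm); RPF ~ Poisson(sf * depth *
    a_t * tau_t * L_CDS / norm). ``sf`` is a per-sample nuisance depth factor
    drawn once per (condition, assay); spike rows scale with the same factor,
    which is exactly what spike normalization must cancel.
    """
    tx = truth.transcripts
    conc = ercc_concentrations(cfg)
    out = []
    for assay, depth in (("mrna", cfg.expression_depth), ("rpf", cfg.rpf_depth)):
        rng = cfg.rng("expr", condition, assay)
        sf = rng.uniform(*cfg.size_factor_range)
        if assay == "mrna":
            w = tx["abundance"] * tx["mature_length"]
        else:
            w = tx["abundance"] * tx[f"tau_{condition}"] * tx["cds_length"]
        lam_tx = sf * depth * (w / w.sum()).to_numpy()
        lam_spike = sf * depth * cfg.spike_frac * conc.to_numpy()
        counts = _noisy_poisson(rng, np.concatenate([lam_tx, lam_spike]),
                                cfg.dispersion)
        out.append(pd.Series(counts,
                             index=list(tx.index) + list(conc.index),
                             name=f"{assay}_{condition}"))
    return out[0], out[1]


def expression_lengths(truth: TruthTable, cfg: SimulationConfig,
                       use_cds: bool = False) -> pd.Series:
    """Feature lengths for FPKM: transcript (or CDS) lengths plus spike lengths."""
    tx = truth.transcripts
    col = "cds_length" if use_cds else "mature_length"
    lens = tx[col].astype(float)
    spikes = pd.Series(float(cfg.ercc_length), index=ercc_concentrations(cfg).index)
    return pd.concat([lens, spikes])


# ---------------------------------------------------------------------------
# RBP intensities


def simulate_rbp_intensities(cfg: SimulationConfig) -> pd.DataFrame:
    """Protein intensity table (input, IP_mock, IP_bybx) with planted classes.

    Fold-change targets per class sit well away from the 0.5 / 2 decision
    boundaries; multiplicative log-normal noise (sd ``rbp_noise_sd`` log2
    units) is applied to every measured intensity.
    """
    rng = cfg.rng("rbp")
    fc_draw = {
        "down": lambda: 2.0 ** rng.uniform(-3.0, -1.5),
        "up": lambda: 2.0 ** rng.uniform(1.5, 3.0),
        "unchanged": lambda: 2.0 ** rng.uniform(-0.5, 0.5),
        "completely_blocked": lambda: 0.0,
        "input_absent": lambda: 1.0,
    }
    classes = [c for c, n in cfg.rbp_class_counts.items() for _ in range(n)]
    if len(classes) < cfg.n_rbp:
        classes += ["unchanged"] * (cfg.n_rbp - len(classes))
    classes = classes[:cfg.n_rbp]

    noise = lambda: 2.0 ** rng.normal(0.0, cfg.rbp_noise_sd)
    rows = []
    for i, cls in enumerate(classes):
        base = float(np.exp(rng.normal(3.0, 1.0)))
        ip_mock = base * noise()
        fc = fc_draw[cls]()
        ip_bybx = 0.0 if cls == "completely_blocked" else ip_mock * fc * noise()
        inp = 0.0 if cls == "input_absent" else base * noise()
        rows.append({"protein_id": f"RBP{i:03d}", "input": inp,
                     "IP_mock": ip_mock, "IP_bybx": ip_bybx,
                     "true_class": cls})
    return pd.DataFrame(rows).set_index("protein_id")


# ---------------------------------------------------------------------------
# text-format writers


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "wt") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_bed12(catalog: TranscriptCatalog, path) -> None:
    with open(path, "wt") as out:
        for tid in sorted(catalog.transcripts):
            t = catalog[tid]
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offs = ",".join(str(s - t.start) for s, _ in t.exons) + ","
            thick_s = t.cds_start if t.is_coding else t.start
            thick_e = t.cds_end if t.is_coding else t.start
            out.write("\t".join(map(str, [
                t.chrom, t.start, t.end, tid, 0, t.strand,
                thick_s, thick_e, 0, len(t.exons), sizes, offs])) + "\n")


def config_echo(cfg: SimulationConfig) -> dict:
    """JSON-ready copy of the configuration (for output metadata)."""
    d = asdict(cfg)
    d["intron_len"] = list(d["intron_len"])
    d["read_len_range"] = list(d["read_len_range"])
    d["size_factor_range"] = list(d["size_factor_range"])
    return d
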