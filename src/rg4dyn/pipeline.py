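"""End-to-end orchestration: simulate -> call peaks -> quantify -> classify.

This is the layer the command line and the reproducibility checks drive. All
artifacts are plain text (FASTA, BED, bedGraph, narrowPeak, TSV, JSON) and
every output embeds the parameter record, so two runs with the same seed and
configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import annotation, dynamics as dyn, peaks as pk, quant, simulate as sim
from . import translatome as tl

__all__ = ["PipelineParams", "call_condition_peaks", "density_by_condition",
           "run_pipeline", "write_simulated_inputs", "read_narrowpeak"]

log = logging.getLogger("rg4dyn")


@dataclass
class PipelineParams:
    """Analysis thresholds, echoed verbatim into every report."""

    bin_size: int = 10
    p_cutoff: float = 0.05
    fe_cutoff: float = 2.0
    min_gap: int = 3
    fc_up: float = 2.0
    fc_down: float = 0.5
    removal_fc: float = 2.0
    rho_lo: float = 0.25
    rho_hi: float = 0.75
    density_eps: float = 0.1
    te_eps: float = 0.1
    min_mrna_fpkm: float = 1.0
    upstream_ext: int = 30
    metaprofile_window: int = 1000
    peak_matrix_window: int = 500


def call_condition_peaks(bg4: annotation.ReadEndSet, igg: annotation.ReadEndSet,
                         chrom_sizes: dict[str, int],
                         params: PipelineParams) -> tuple[pk.PeakSet,
                                                          annotation.ReadEndSet]:
    """Dedup both libraries, build coverage, call treatment-over-control peaks.

    Returns the peak set and the deduplicated treatment reads (the density
    denominators downstream use the deduplicated totals).
    """
    bg4_dd = pk.deduplicate(bg4)
    igg_dd = pk.deduplicate(igg)
    log.info("dedup %s/%s: %d -> %d (BG4), %d -> %d (IgG)",
             bg4.condition, bg4.library, len(bg4), len(bg4_dd),
             len(igg), len(igg_dd))
    tcov = pk.coverage(bg4_dd, chrom_sizes, params.bin_size)
    ccov = pk.coverage(igg_dd, chrom_sizes, params.bin_size)
    peaks = pk.call_peaks(tcov, ccov, p_cutoff=params.p_cutoff,
                          fe_cutoff=params.fe_cutoff, min_gap=params.min_gap)
    log.info("%s: %d peaks", bg4.condition, len(peaks))
    return peaks, bg4_dd


def density_by_condition(dedup_reads: dict[str, annotation.ReadEndSet],
                         catalog: annotation.TranscriptCatalog) -> pd.DataFrame:
    """rG4 RPKM per (transcript, region), one column per condition."""
    cols = {}
    for cond, reads in dedup_reads.items():
        cols[cond] = quant.region_density(reads, catalog)["rpkm"]
    return pd.DataFrame(cols)


def run_pipeline(cfg: sim.SimulationConfig,
                 params: PipelineParams | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Full synthetic study: generate data, run every analysis stage, report.

    Returns a results dictionary (peaks, densities, classifications,
    translatome tables, the truth table, and the aggregated report). When
    ``outdir`` is given, all artifacts are written there as text files.
    """
    params = params or PipelineParams()
    genome, catalog, truth = sim.simulate_transcriptome(cfg)
    chrom_sizes = catalog.chrom_sizes

    peaksets: dict[str, pk.PeakSet] = {}
    dedup: dict[str, annotation.ReadEndSet] = {}
    for cond in sim.CONDITIONS:
        bg4 = sim.simulate_lace_reads(truth, catalog, cfg, cond, "BG4")
        igg = sim.simulate_lace_reads(truth, catalog, cfg, cond, "IgG")
        peaksets[cond], dedup[cond] = call_condition_peaks(
            bg4, igg, chrom_sizes, params)

    densities = density_by_condition(dedup, catalog)

    # rG4 *signal* densities: reads restricted to the called peak space
    # (union over conditions), so density ratios track site occupancy rather
    # than the uniform library background
    all_peaks = list(peaksets.values())
    site_reads = {cond: quant.reads_in_peaks(reads, *all_peaks)
                  for cond, reads in dedup.items()}
    site_densities = density_by_condition(site_reads, catalog)
    full = site_densities.xs("full", level="region")

    # stage dynamics: GV vs MII (vehicle)
    sets_gv_mii = dyn.rg4_transcript_sets(
        peaksets["GV"], peaksets["MII_DMSO"], catalog,
        condition_a="GV", condition_b="MII_DMSO")
    n_a = sets_gv_mii.counts["A"]
    n_b = sets_gv_mii.counts["B"]
    n_ab = sets_gv_mii.counts["shared"]
    overlap_p = dyn.overlap_significance(n_a, n_b, n_ab, len(catalog)) \
        if min(n_a, n_b) > 0 else 1.0

    rg4_gv = dyn.rg4_containing_transcripts(peaksets["GV"], catalog)
    removal = dyn.removal_categories(
        full["GV"], full["MII_DMSO"], full["MII_BYBX"], rg4_at_gv=rg4_gv,
        removal_fc=params.removal_fc, lo=params.rho_lo, hi=params.rho_hi,
        eps=params.density_eps)

    delta_rg4 = pd.DataFrame({
        region: dyn.density_ratio(
            site_densities.xs(region, level="region")["MII_BYBX"],
            site_densities.xs(region, level="region")["MII_DMSO"],
            eps=params.density_eps)
        for region in ("full", "5UTR", "3UTR")})

    # translatome
    mrna_counts, rpf_counts = {}, {}
    for cond in sim.CONDITIONS:
        mrna_counts[cond], rpf_counts[cond] = sim.simulate_expression(
            truth, cfg, cond)
    mrna_df = pd.DataFrame(mrna_counts)
    rpf_df = pd.DataFrame(rpf_counts)
    mrna_fpkm = tl.fpkm(mrna_df, sim.expression_lengths(truth, cfg))
    rpf_fpkm = tl.fpkm(rpf_df, sim.expression_lengths(truth, cfg, use_cds=True))
    te = tl.translational_efficiency(rpf_fpkm, mrna_fpkm, eps=params.te_eps,
                                     min_mrna_fpkm=params.min_mrna_fpkm)
    te_bybx_cls = tl.fold_change_classes(te["TE_MII_DMSO"], te["TE_MII_BYBX"],
                                         fc_up=params.fc_up, fc_down=params.fc_down)
    maturation_cls = tl.fold_change_classes(te["TE_GV"], te["TE_MII_DMSO"],
                                            fc_up=params.fc_up,
                                            fc_down=params.fc_down)
    maturation_up = set(maturation_cls.index[maturation_cls == tl.CLASS_UP])
    integration = tl.integrate_rg4_te(delta_rg4, te_bybx_cls,
                                      region="full",
                                      maturation_up=maturation_up)

    rbp = tl.classify_rbp_binding(sim.simulate_rbp_intensities(cfg))

    report = {
        "parameters": asdict(params),
        "simulation": sim.config_echo(cfg),
        "notes": {
            "overlap_test": ("hypergeometric upper tail; replaces ad hoc "
                             "Venn tests because it is the standard exact "
                             "overlap test"),
            "rpkm_denominator": "total deduplicated mapped reads per library",
            "signal_density": ("removal categories and density ratios use "
                               "reads restricted to the cross-condition peak "
                               "space; raw-read densities are also written"),
        },
        "clusters_gv_vs_mii": {k: sets_gv_mii.counts[k] for k in
                               ("A-specific", "shared", "B-specific", "A", "B")},
        "overlap_p_value": overlap_p,
        "removal_categories": removal["category"].value_counts().to_dict(),
        "te_change_classes_bybx_vs_dmso": te_bybx_cls.value_counts().to_dict(),
        "quadrant_counts": integration["quadrant_counts"],
        "headline_set_sizes": {k: len(v) for k, v in integration["sets"].items()},
        "rbp_classes": rbp["class"].value_counts().to_dict(),
        "n_peaks": {cond: len(ps) for cond, ps in peaksets.items()},
    }

    results = {
        "genome": genome, "catalog": catalog, "truth": truth,
        "peaks": peaksets, "dedup_reads": dedup, "densities": densities,
        "site_densities": site_densities,
        "sets_gv_mii": sets_gv_mii, "removal": removal,
        "delta_rg4": delta_rg4, "te": te, "te_bybx_classes": te_bybx_cls,
        "maturation_classes": maturation_cls, "integration": integration,
        "rbp": rbp, "report": report, "params": params,
    }
    if outdir is not None:
        _write_artifacts(results, cfg, Path(outdir))
    return results


def _write_artifacts(results: dict, cfg: sim.SimulationConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = results["catalog"]
    sim.write_fasta(results["genome"], outdir / "genome.fa")
    sim.write_bed12(catalog, outdir / "catalog.bed12")
    annotation.write_chrom_sizes(catalog.chrom_sizes, outdir / "chrom.sizes")
    for cond, ps in results["peaks"].items():
        pk.write_narrowpeak(ps, outdir / f"peaks_{cond}.narrowPeak")
        annotation.write_bed6(results["dedup_reads"][cond],
                              outdir / f"readends_{cond}_BG4.dedup.bed")
    results["densities"].to_csv(outdir / "region_density.tsv", sep="\t")
    results["site_densities"].to_csv(outdir / "region_density_in_peaks.tsv",
                                     sep="\t")
    results["removal"].to_csv(outdir / "removal_categories.tsv", sep="\t")
    results["te"].to_csv(outdir / "translational_efficiency.tsv", sep="\t")
    results["te_bybx_classes"].to_csv(outdir / "te_classes_bybx.tsv", sep="\t")
    results["rbp"].to_csv(outdir / "rbp_classes.tsv", sep="\t")
    results["truth"].sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    results["truth"].transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t")
    with open(outdir / "report.json", "wt") as fh:
        json.dump(results["report"], fh, indent=2, sort_keys=True, default=str)
    _write_markdown_report(results["report"], outdir / "report.md")


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# rG4 dynamics summary", ""]
    lines += ["## Peaks", ""]
    for cond, n in report["n_peaks"].items():
        lines.append(f"- {cond}: {n} peaks")
    c = report["clusters_gv_vs_mii"]
    lines += ["", "## rG4-containing transcript clusters (GV vs MII)", "",
              f"- GV total: {c['A']} (GV-specific {c['A-specific']}, "
              f"shared {c['shared']})",
              f"- MII total: {c['B']} (MII-specific {c['B-specific']})",
              f"- overlap p (hypergeometric upper tail): "
              f"{report['overlap_p_value']:.3g}",
              "", "## Removal blockade categories", ""]
    for k, v in sorted(report["removal_categories"].items()):
        lines.append(f"- {k}: {v}")
    lines += ["", "## TE change classes (ligand vs vehicle)", ""]
    for k, v in sorted(report["te_change_classes_bybx_vs_dmso"].items()):
        lines.append(f"- {k}: {v}")
    lines += ["", "## RBP binding classes", ""]
    for k, v in sorted(report["rbp_classes"].items()):
        lines.append(f"- {k}: {v}")
    path.write_text("\n".join(lines) + "\n")


def write_simulated_inputs(cfg: sim.SimulationConfig, outdir: str | Path) -> None:
    """Generate and write only the raw simulated inputs (no analysis)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, catalog, truth = sim.simulate_transcriptome(cfg)
    sim.write_fasta(genome, outdir / "genome.fa")
    sim.write_bed12(catalog, outdir / "catalog.bed12")
    annotation.write_chrom_sizes(catalog.chrom_sizes, outdir / "chrom.sizes")
    for cond in sim.CONDITIONS:
        for lib in ("BG4", "IgG"):
            reads = sim.simulate_lace_reads(truth, catalog, cfg, cond, lib)
            annotation.write_bed6(reads, outdir / f"readends_{cond}_{lib}.bed")
    mrna, rpf = {}, {}
    for cond in sim.CONDITIONS:
        mrna[cond], rpf[cond] = sim.simulate_expression(truth, cfg, cond)
    pd.DataFrame(mrna).to_csv(outdir / "mrna_counts.tsv", sep="\t")
    pd.DataFrame(rpf).to_csv(outdir / "rpf_counts.tsv", sep="\t")
    sim.expression_lengths(truth, cfg).rename("length").to_csv(
        outdir / "feature_lengths.tsv", sep="\t")
    sim.simulate_rbp_intensities(cfg).to_csv(outdir / "rbp_intensities.tsv",
                                             sep="\t")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t")
    with open(outdir / "config.json", "wt") as fh:
        json.dump(sim.config_echo(cfg), fh, indent=2, sort_keys=True)


def read_narrowpeak(path) -> pk.PeakSet:
    """Load a narrowPeak-style BED6+4 file written by this package."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                continue
            start, end = int(f[1]), int(f[2])
            peaks.append(pk.Peak(
                chrom=f[0], strand=f[5], start=start, end=end,
                summit=start + int(f[9]),
                fold_enrichment=float(f[6]),
                p_value=10 ** -float(f[7]), q_value=10 ** -float(f[8]),
                treatment_count=0, control_lambda=0.0))
    return pk.PeakSet(peaks)
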