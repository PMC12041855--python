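"""RT-stop peak calling: dedup, binned stranded coverage, Poisson enrichment.

The caller compares a treatment (BG4 capture) track against an isotype (IgG)
control track bin by bin. Per bin the control expectation is scaled to the
treatment depth and floored at the genome-wide background rate; a bin is
significant when the Poisson upper tail P(X >= treat) <= p_cutoff *and* the
fold enrichment treat/lambda >= fe_cutoff. Significant bins closer than
``min_gap`` bins are merged into peaks. This is a deliberately transparent
single-pass rule (no sliding local lambda, no model building) and it is
strand-aware, since RT-stop libraries are stranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .annotation import ReadEnd, ReadEndSet, TranscriptCatalog

__all__ = [
    "CoverageTrack",
    "Peak",
    "PeakSet",
    "deduplicate",
    "coverage",
    "call_peaks",
    "annotate_peaks",
    "write_bedgraph",
    "write_narrowpeak",
]


@dataclass
class CoverageTrack:
    """Binned, stranded read-5'-end counts.

    ``bins[(chrom, strand)]`` is an int array of length ceil(size / bin_size);
    ``total`` is the library's mapped-read count used for depth scaling.
    """

    bins: dict[tuple[str, str], np.ndarray]
    bin_size: int
    total: int
    chrom_sizes: dict[str, int]

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def counted(self) -> int:
        return int(sum(arr.sum() for arr in self.bins.values()))


@dataclass(frozen=True)
class Peak:
    """A merged run of enriched bins."""

    chrom: str
    strand: str
    start: int
    end: int
    summit: int            # nt position: center of the max-treatment bin
    fold_enrichment: float
    p_value: float
    q_value: float
    treatment_count: int
    control_lambda: float

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class PeakSet:
    peaks: list[Peak]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def deduplicate(reads: ReadEndSet) -> ReadEndSet:
    """Collapse PCR duplicates: one record per (chrom, strand, pos5, length).

    Order-independent: survivors are emitted in sorted key order. ``total``
    becomes the deduplicated count so downstream depth normalization reflects
    the reads actually used.
    """
    seen: dict[tuple, ReadEnd] = {}
    for r in reads.reads:
        seen.setdefault((r.chrom, r.strand, r.pos5, r.length), r)
    kept = [seen[k] for k in sorted(seen)]
    return ReadEndSet(kept, total=len(kept), library=reads.library,
                      condition=reads.condition, n_skipped=reads.n_skipped)


def coverage(reads: ReadEndSet, chrom_sizes: dict[str, int],
             bin_size: int = 10) -> CoverageTrack:
    """Bin read 5' ends at ``bin_size`` nt, strands kept separate."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins: dict[tuple[str, str], np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_size)
        bins[(chrom, "+")] = np.zeros(n, dtype=np.int64)
        bins[(chrom, "-")] = np.zeros(n, dtype=np.int64)
    by_key: dict[tuple[str, str], list[int]] = {}
    for r in reads.reads:
        size = chrom_sizes.get(r.chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        if not 0 <= r.pos5 < size:
            raise ValueError(f"read 5' end {r.pos5} beyond {r.chrom} ({size} nt)")
        by_key.setdefault((r.chrom, r.strand), []).append(r.pos5)
    for key, positions in by_key.items():
        idx = np.asarray(positions, dtype=np.int64) // bin_size
        np.add.at(bins[key], idx, 1)
    return CoverageTrack(bins=bins, bin_size=bin_size, total=reads.total,
                         chrom_sizes=dict(chrom_sizes))


def _poisson_sf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper tail P(X >= k) for Poisson(lam)."""
    return stats.poisson.sf(k - 1, lam)


def call_peaks(treat: CoverageTrack, ctrl: CoverageTrack | None,
               p_cutoff: float = 0.05, fe_cutoff: float = 2.0,
               min_gap: int = 3, local_bins: int = 100) -> PeakSet:
    """Call enriched RT-stop peaks from treatment vs control coverage.

    The per-bin expectation is the largest of the depth-scaled control bin,
    the depth-scaled local control mean over ``local_bins`` bins (~1 kb at the
    default grid), and the genome background floor. The local mean is taken
    over *covered* (nonzero) control bins only, so that transcript-confined
    signal is not diluted by empty intergenic bins at transcript edges; the
    term keeps a single under-sampled control bin from faking enrichment on
    sparsely covered transcripts, and taking the max keeps the rule
    conservative.

    With ``ctrl=None`` the expectation is the flat genome background
    (control-free mode). Peak p-value is the smallest member-bin p-value;
    fold enrichment is the summed treatment count over the summed expectation,
    which cannot fall below ``fe_cutoff`` because every member bin passes it.
    """
    if ctrl is not None and ctrl.bin_size != treat.bin_size:
        raise ValueError("treatment and control tracks have different bin sizes")
    if ctrl is not None and ctrl.total <= 0:
        raise ValueError("control track has zero total reads")

    lam_floor = treat.total * treat.bin_size / max(treat.genome_size, 1)
    scale = treat.total / ctrl.total if ctrl is not None else None

    peaks: list[Peak] = []
    all_p: list[np.ndarray] = []
    sig_runs: list[tuple[tuple[str, str], np.ndarray, np.ndarray, np.ndarray]] = []
    for key in sorted(treat.bins):
        t = treat.bins[key].astype(float)
        if ctrl is not None:
            c = ctrl.bins.get(key)
            if c is None:
                lam = np.zeros_like(t)
            else:
                raw = c.astype(float) * scale
                lam = raw
                if local_bins > 1 and raw.size > 1:
                    w = min(local_bins, raw.size)
                    local_mean = uniform_filter1d(raw, size=w, mode="nearest")
                    covered = uniform_filter1d((raw > 0).astype(float), size=w,
                                               mode="nearest")
                    local = np.divide(local_mean, covered,
                                      out=np.zeros_like(raw),
                                      where=covered > 0)
                    lam = np.maximum(raw, local)
        else:
            lam = np.zeros_like(t)
        lam = np.maximum(lam, lam_floor)
        pvals = _poisson_sf(treat.bins[key], lam)
        fe = np.divide(t, lam, out=np.zeros_like(t), where=lam > 0)
        sig = (pvals <= p_cutoff) & (fe >= fe_cutoff) & (treat.bins[key] > 0)
        all_p.append(pvals[sig])
        sig_runs.append((key, sig, lam, pvals))

    # BH q-values over significant bins, emitted for information only:
    # peak acceptance uses the raw p-value, matching a raw-p calling rule.
    flat_p = np.concatenate(all_p) if all_p else np.array([])
    qmap: dict[float, float] = {}
    if flat_p.size:
        order = np.argsort(flat_p)
        ranked = flat_p[order]
        q = ranked * flat_p.size / (np.arange(flat_p.size) + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        qmap = dict(zip(ranked.tolist(), np.minimum(q, 1.0).tolist()))

    b = treat.bin_size
    for (chrom, strand), sig, lam, pvals in sig_runs:
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > min_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        tvec = treat.bins[(chrom, strand)]
        size = treat.chrom_sizes[chrom]
        for a, z in zip(starts, ends):
            member = idx[a:z + 1]
            tsum = int(tvec[member].sum())
            lsum = float(lam[member].sum())
            summit_bin = member[int(np.argmax(tvec[member]))]  # leftmost max
            summit = min(summit_bin * b + b // 2, size - 1)
            pmin = float(pvals[member].min())
            peaks.append(Peak(
                chrom=chrom, strand=strand,
                start=int(member[0]) * b,
                end=min(int(member[-1] + 1) * b, size),
                summit=int(summit),
                fold_enrichment=tsum / lsum if lsum > 0 else float("inf"),
                p_value=pmin,
                q_value=qmap.get(pmin, 1.0),
                treatment_count=tsum,
                control_lambda=lsum,
            ))
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.start))
    return PeakSet(peaks, params={
        "p_cutoff": p_cutoff, "fe_cutoff": fe_cutoff, "min_gap": min_gap,
        "bin_size": treat.bin_size, "lambda_floor": lam_floor,
        "control": "IgG" if ctrl is not None else "genome-background",
    })


# feature precedence for summit annotation, highest first
_PRECEDENCE = ("5UTR", "3UTR", "CDS", "intron", "upstream", "intergenic")


def annotate_peaks(peaks: PeakSet, catalog: TranscriptCatalog,
                   repeats: dict[tuple[str, str], list[tuple[int, int, str]]] | None = None,
                   upstream_window: int = 2000) -> list[dict]:
    """Label each peak by its summit with 5UTR > 3UTR > CDS > intron >
    upstream(TSS-2kb, same strand) > intergenic precedence, plus an optional
    repeat-class co-label."""
    out: list[dict] = []
    for pk in peaks:
        labels: set[str] = set()
        for tid in catalog.transcripts_at(pk.chrom, pk.strand, pk.summit):
            t = catalog[tid]
            tpos = t.genomic_to_transcript(pk.summit)
            region = t.region_of(tpos)
            labels.add(region if region else "CDS")  # non-coding exon -> body
        # intron / upstream need a body scan
        if not labels:
            for t in catalog:
                if t.chrom != pk.chrom or t.strand != pk.strand:
                    continue
                if t.start <= pk.summit < t.end:
                    labels.add("intron")
                elif t.strand == "+" and t.start - upstream_window <= pk.summit < t.start:
                    labels.add("upstream")
                elif t.strand == "-" and t.end <= pk.summit < t.end + upstream_window:
                    labels.add("upstream")
        label = next((lab for lab in _PRECEDENCE if lab in labels), "intergenic")
        repeat_class = None
        if repeats:
            for s, e, cls in repeats.get((pk.chrom, pk.strand), []) + \
                    repeats.get((pk.chrom, "."), []):
                if s <= pk.summit < e:
                    repeat_class = cls
                    break
        out.append({"peak": pk, "feature": label, "repeat_class": repeat_class})
    return out


def write_bedgraph(track: CoverageTrack, path_plus, path_minus) -> None:
    """Dump a coverage track as one bedGraph text file per strand."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "wt") as out:
            for (chrom, st), arr in sorted(track.bins.items()):
                if st != strand:
                    continue
                size = track.chrom_sizes[chrom]
                nz = np.flatnonzero(arr)
                for i in nz:
                    s = int(i) * track.bin_size
                    e = min(s + track.bin_size, size)
                    out.write(f"{chrom}\t{s}\t{e}\t{int(arr[i])}\n")


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """narrowPeak-style BED6+4: FE, -log10 p, -log10 q, summit offset."""
    with open(path, "wt") as out:
        for i, pk in enumerate(peaks):
            mlog = lambda x: -np.log10(max(x, 1e-300))
            out.write("\t".join(map(str, [
                pk.chrom, pk.start, pk.end, f"peak_{i}", 0, pk.strand,
                f"{pk.fold_enrichment:.4f}", f"{mlog(pk.p_value):.4f}",
                f"{mlog(pk.q_value):.4f}", pk.summit - pk.start,
            ])) + "\n")
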