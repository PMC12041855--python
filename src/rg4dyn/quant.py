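"""Quantifying rG4 signal: metaprofiles, peak matrices, region densities,
putative-quadruplex scanning and k-mer enrichment.

Region density follows the RPKM convention: reads whose 5' end falls in a
transcript region, per kilobase of region, per million mapped reads of the
library. Metaprofiles are depth-normalized to counts per ten million mapped
reads and are strand-aware, so the bin axis always runs 5'->3'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import REGIONS, ReadEndSet, TranscriptCatalog
from .peaks import CoverageTrack, PeakSet

__all__ = [
    "MetaProfile",
    "PqsMatch",
    "metaprofile",
    "peak_matrix",
    "region_density",
    "reads_in_peaks",
    "scan_pqs",
    "peak_upstream_sequences",
    "g_enrichment",
    "revcomp",
]

# normalization scale for profile signal: counts per 10 million mapped reads
_CPTM = 1e7


@dataclass
class MetaProfile:
    """Mean depth-normalized signal in fixed bins around a set of anchors."""

    values: np.ndarray          # length 2w / bin_size
    n_anchors: int
    window: int
    bin_size: int
    anchor_type: str = "custom"

    @property
    def offsets(self) -> np.ndarray:
        """Left edge (nt, anchor-relative) of each profile bin."""
        return np.arange(-self.window, self.window, self.bin_size)


class PqsMatch(NamedTuple):
    """One putative quadruplex sequence: four G-tracts with 1-7 nt loops."""

    sequence_id: str
    start: int
    end: int
    loop_lengths: tuple[int, int, int]


def _anchor_window(track: CoverageTrack, chrom: str, strand: str,
                   pos: int, w: int) -> np.ndarray:
    """Signal bins spanning +/- ``w`` nt around an anchor, 5'->3' oriented.

    The anchor's own bin sits at index w/bin_size on both strands; for minus
    anchors the genomic window is shifted by one bin before reversal so the
    axis mirrors exactly. Windows beyond chromosome ends are clipped (the
    missing bins contribute zero) and the anchor is retained.
    """
    b = track.bin_size
    nbins = (2 * w) // b
    half = w // b
    out = np.zeros(nbins, dtype=float)
    arr = track.bins.get((chrom, strand))
    if arr is None:
        return out
    center = pos // b
    lo = center - half if strand == "+" else center - half + 1
    src_lo, src_hi = max(lo, 0), min(lo + nbins, arr.shape[0])
    if src_hi > src_lo:
        out[src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
    if strand == "-":
        out = out[::-1]
    return out


def metaprofile(track: CoverageTrack,
                anchors: Sequence[tuple[str, int, str]],
                w: int = 1000,
                anchor_type: str = "custom") -> MetaProfile:
    """Average signal across anchors in a +/- ``w`` nt window.

    ``anchors`` are (chrom, position, strand) triples — e.g. TSS/TES bases or
    peak summits; interval anchors should be reduced to their midpoint by the
    caller. Window bins use the track's own bin size so profile and coverage
    grids coincide. Signal is normalized to counts per 10 million mapped reads.
    """
    if not anchors:
        raise ValueError("metaprofile needs at least one anchor")
    if w % track.bin_size != 0:
        raise ValueError("window must be a multiple of the track bin size")
    acc = np.zeros((2 * w) // track.bin_size, dtype=float)
    for chrom, pos, strand in anchors:
        acc += _anchor_window(track, chrom, strand, pos, w)
    norm = _CPTM / max(track.total, 1)
    return MetaProfile(values=acc / len(anchors) * norm, n_anchors=len(anchors),
                       window=w, bin_size=track.bin_size, anchor_type=anchor_type)


def peak_matrix(track: CoverageTrack, peaks: PeakSet, w: int = 500
                ) -> tuple[np.ndarray, list[str]]:
    """Per-peak signal matrix around summits, rows sorted by mean descending.

    Returns (matrix, row names). Row order is deterministic: mean descending,
    peak name ascending on ties. Column means of the matrix equal the
    metaprofile over the same summits by construction.
    """
    if len(peaks) == 0:
        raise ValueError("peak_matrix needs a non-empty peak set")
    norm = _CPTM / max(track.total, 1)
    rows, names = [], []
    for pk in peaks:
        rows.append(_anchor_window(track, pk.chrom, pk.strand, pk.summit, w) * norm)
        names.append(pk.name)
    mat = np.vstack(rows)
    order = sorted(range(len(names)), key=lambda i: (-mat[i].mean(), names[i]))
    return mat[order], [names[i] for i in order]


def region_density(reads: ReadEndSet, catalog: TranscriptCatalog,
                   regions: Sequence[str] = REGIONS,
                   include_full: bool = True) -> pd.DataFrame:
    """Per-transcript, per-region RPKM of read 5' ends.

    A read is counted in a region when its 5' end maps through the exon chain
    into that region of the mature transcript; reads overlapping several
    transcripts count toward each (no multi-mapping rescue). RPKM =
    reads_in_region * 1e9 / (region_length_nt * total_mapped_reads). Rows are
    indexed (transcript_id, region); zero-length regions get RPKM = NaN as an
    explicit undefined marker. The 'full' region is the whole mature transcript.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in reads.reads:
        for tid in catalog.transcripts_at(r.chrom, r.strand, r.pos5):
            t = catalog[tid]
            tpos = t.genomic_to_transcript(r.pos5)
            region = t.region_of(tpos)
            if region in regions:
                counts[(tid, region)] = counts.get((tid, region), 0) + 1
            if include_full:
                counts[(tid, "full")] = counts.get((tid, "full"), 0) + 1

    total = max(reads.total, 1)
    rows = []
    region_list = list(regions) + (["full"] if include_full else [])
    for tid in sorted(catalog.transcripts):
        t = catalog[tid]
        for region in region_list:
            length = t.mature_length if region == "full" else t.region_length(region)
            n = counts.get((tid, region), 0)
            rpkm = n * 1e9 / (length * total) if length > 0 else np.nan
            rows.append((tid, region, n, length, rpkm))
    df = pd.DataFrame(rows, columns=["transcript_id", "region", "count",
                                     "length", "rpkm"])
    return df.set_index(["transcript_id", "region"])


def reads_in_peaks(reads: ReadEndSet, *peak_sets: PeakSet) -> ReadEndSet:
    """Restrict a library to reads whose 5' end falls inside any peak.

    Used for rG4 *signal* densities: in an enrichment library simulated with
    an explicit uniform background, restricting to the called peak space (the
    union over the given peak sets) measures the site-bound signal rather
    than the background. ``total`` is preserved so RPKM stays normalized to
    the full library depth and remains comparable across conditions.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for ps in peak_sets:
        for pk in ps:
            trees.setdefault((pk.chrom, pk.strand), IntervalTree()).addi(
                pk.start, pk.end)
    kept = [r for r in reads.reads
            if (t := trees.get((r.chrom, r.strand))) is not None
            and t.overlaps_point(r.pos5)]
    return ReadEndSet(kept, total=reads.total, library=reads.library,
                      condition=reads.condition, n_skipped=reads.n_skipped)


# -- putative quadruplex scanning -------------------------------------------

# four G-tracts (>=3 G) separated by 1-7 nt loops; loops are matched lazily so
# a loop never swallows a G-tract that could start the next stem
_PQS_RE = re.compile(
    r"(G{3,})([ACGTN]{1,7}?)(G{3,})([ACGTN]{1,7}?)(G{3,})([ACGTN]{1,7}?)(G{3,})")

_RC = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


def scan_pqs(seq: str, sequence_id: str = "") -> list[PqsMatch]:
    """Scan a nucleotide string for canonical putative quadruplex sequences.

    Pattern: G{>=3}(N{1-7}G{>=3}){3}. T and U are equivalent; matches are
    non-overlapping, scanned left to right.
    """
    s = seq.upper().replace("U", "T")
    matches = []
    for m in _PQS_RE.finditer(s):
        loops = tuple(len(m.group(i)) for i in (2, 4, 6))
        matches.append(PqsMatch(sequence_id, m.start(), m.end(), loops))
    return matches


def peak_upstream_sequences(peaks: PeakSet, genome, ext: int = 30
                            ) -> list[tuple[str, str]]:
    """Extract strand-aware peak sequences extended ``ext`` nt to 5' upstream.

    ``genome`` is a FASTA path (opened with pyfaidx), a pyfaidx.Fasta, or any
    mapping of contig -> sliceable sequence. Plus-strand peaks yield genomic
    [start-ext, end); minus-strand peaks yield the reverse complement of
    [start, end+ext). Slices are clipped at contig bounds.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from pyfaidx import Fasta
        genome = Fasta(str(genome))
    out = []
    for i, pk in enumerate(peaks):
        contig = genome[pk.chrom]
        clen = len(contig)
        if pk.strand == "+":
            s, e = max(pk.start - ext, 0), min(pk.end, clen)
            seq = str(contig[s:e])
        else:
            s, e = max(pk.start, 0), min(pk.end + ext, clen)
            seq = revcomp(str(contig[s:e]))
        out.append((f"peak_{i}|{pk.name}", seq.upper()))
    return out


def _kmer_freqs(seqs: Iterable[str], k: int) -> tuple[pd.Series, int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return pd.Series(counts, dtype=float), total


def g_enrichment(foreground: Iterable[str], background: Iterable[str],
                 k: int = 6) -> pd.Series:
    """Per-k-mer log2 enrichment of foreground over background sequences.

    enrichment = log2((freq_fg + eps) / (freq_bg + eps)) with eps = one
    pseudo-observation per set (1 / total k-mers in that set). Returned sorted
    descending, so G-rich quadruplex-forming k-mers surface at the top on
    RT-stop peak sequences.
    """
    fg = foreground if isinstance(foreground, (list, tuple)) else list(foreground)
    bg = background if isinstance(background, (list, tuple)) else list(background)
    fg = [s[1] if isinstance(s, tuple) else s for s in fg]
    bg = [s[1] if isinstance(s, tuple) else s for s in bg]
    cf, nf = _kmer_freqs(fg, k)
    cb, nb = _kmer_freqs(bg, k)
    if nf == 0 or nb == 0:
        raise ValueError("both sequence sets must contain at least one k-mer")
    all_kmers = cf.index.union(cb.index)
    ff = cf.reindex(all_kmers, fill_value=0.0) / nf
    fb = cb.reindex(all_kmers, fill_value=0.0) / nb
    eps_f, eps_b = 1.0 / nf, 1.0 / nb
    enr = np.log2((ff + eps_f) / (fb + eps_b))
    return enr.sort_values(ascending=False)
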