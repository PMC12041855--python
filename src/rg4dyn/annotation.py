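"""Transcript models, read-end records, and the coordinate arithmetic they share.

Everything downstream of alignment works in 0-based half-open genomic
coordinates. GTF (1-based closed) is converted on ingest; BED dialects are
native. The RT-stop signal that the rest of the pipeline consumes is the
5' end of each aligned read: for a minus-strand alignment that is the
*rightmost* genomic base of the alignment interval.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "TranscriptModel",
    "TranscriptCatalog",
    "ReadEnd",
    "ReadEndSet",
    "load_transcripts",
    "read_read_ends",
    "write_bed6",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR)


class AnnotationError(ValueError):
    """Malformed annotation or read record; message names the input line."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with optional CDS and derived UTR/CDS segments.

    ``exons`` are genomic, 0-based half-open, sorted and non-overlapping.
    ``cds_start``/``cds_end`` bound the coding span genomically (half-open);
    both are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.transcript_id}: bad exon [{s},{e})")
            if s < prev_end:
                raise AnnotationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise AnnotationError(f"{self.transcript_id}: empty CDS")
            # Both CDS boundary bases must be exonic, and no intron may cut the
            # CDS span out of the exon chain entirely.
            if (self.genomic_to_transcript(self.cds_start) is None
                    or self.genomic_to_transcript(self.cds_end - 1) is None):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS boundary outside exons")

    # -- derived geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic position of the transcription end site base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def _cds_tx_span(self) -> tuple[int, int]:
        """CDS bounds in transcript coordinates, half-open 5'->3'."""
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end - 1)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    @property
    def utr5_length(self) -> int:
        if not self.is_coding:
            return 0
        return self._cds_tx_span()[0]

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        lo, hi = self._cds_tx_span()
        return hi - lo

    @property
    def utr3_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.mature_length - self._cds_tx_span()[1]

    def region_length(self, region: str) -> int:
        return {REGION_5UTR: self.utr5_length,
                REGION_CDS: self.cds_length,
                REGION_3UTR: self.utr3_length}[region]

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic base to its 0-based offset on the mature transcript.

        Returns ``None`` for intronic or out-of-bounds positions. The offset
        runs 5'->3' in transcript orientation, so on the minus strand the
        rightmost exonic base maps to 0.
        """
        off = 0
        plus_off = None
        for s, e in self.exons:
            if s <= gpos < e:
                plus_off = off + (gpos - s)
                break
            off += e - s
        if plus_off is None:
            return None
        if self.strand == "+":
            return plus_off
        return self.mature_length - 1 - plus_off

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` (exonic positions only)."""
        if not 0 <= tpos < self.mature_length:
            raise ValueError(f"transcript position {tpos} out of range")
        plus_off = tpos if self.strand == "+" else self.mature_length - 1 - tpos
        for s, e in self.exons:
            if plus_off < e - s:
                return s + plus_off
            plus_off -= e - s
        raise AssertionError("unreachable")

    def region_of(self, tpos: int) -> str | None:
        """Region label of a transcript-coordinate base; None if non-coding."""
        if not self.is_coding:
            return None
        lo, hi = self._cds_tx_span()
        if tpos < lo:
            return REGION_5UTR
        if tpos < hi:
            return REGION_CDS
        return REGION_3UTR


@dataclass
class TranscriptCatalog:
    """Indexed transcript collection plus chromosome sizes."""

    transcripts: dict[str, TranscriptModel]
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    n_rejected: int = 0
    _exon_index: dict[tuple[str, str], IntervalTree] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for tid, t in self.transcripts.items():
            if tid != t.transcript_id:
                raise AnnotationError(f"catalog key {tid!r} != id {t.transcript_id!r}")
            size = self.chrom_sizes.get(t.chrom)
            if size is not None and t.end > size:
                raise AnnotationError(
                    f"{tid}: exceeds {t.chrom} size {size}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def exon_index(self) -> dict[tuple[str, str], IntervalTree]:
        """(chrom, strand) -> IntervalTree of exons carrying transcript ids."""
        if self._exon_index is None:
            idx: dict[tuple[str, str], IntervalTree] = {}
            for t in self:
                tree = idx.setdefault((t.chrom, t.strand), IntervalTree())
                for s, e in t.exons:
                    tree.addi(s, e, t.transcript_id)
            self._exon_index = idx
        return self._exon_index

    def transcripts_at(self, chrom: str, strand: str, gpos: int) -> list[str]:
        """Ids of all transcripts whose exons cover a stranded position."""
        tree = self.exon_index().get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(gpos)})

    def longest_cds_isoform_per_gene(self) -> "TranscriptCatalog":
        """One representative isoform per gene: longest CDS, then longest
        mature length, then lexicographic id (deterministic)."""
        best: dict[str, TranscriptModel] = {}
        for t in self:
            cur = best.get(t.gene_id)
            key = (t.cds_length, t.mature_length, t.transcript_id)
            if cur is None:
                best[t.gene_id] = t
                continue
            cur_key = (cur.cds_length, cur.mature_length, cur.transcript_id)
            # prefer bigger CDS/length; on full tie keep smaller id
            if (key[0], key[1]) > (cur_key[0], cur_key[1]) or (
                    (key[0], key[1]) == (cur_key[0], cur_key[1]) and key[2] < cur_key[2]):
                best[t.gene_id] = t
        return TranscriptCatalog(
            {t.transcript_id: t for t in best.values()},
            chrom_sizes=dict(self.chrom_sizes))


class ReadEnd(NamedTuple):
    """A single aligned read reduced to its RT-stop-relevant 5' end."""

    chrom: str
    strand: str
    pos5: int
    length: int
    sample_id: str = ""


@dataclass
class ReadEndSet:
    """Stranded read 5'-end records for one library.

    ``total`` is the number of records read before any filtering, so that
    depth normalization is stable across filtering steps.
    """

    reads: list[ReadEnd]
    total: int
    library: str = "BG4"
    condition: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.total < len(self.reads):
            raise ValueError("total mapped count below record count")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# annotation ingest


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _open(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    return open(source, "rt")


def load_transcripts(source, dialect: str = "GTF",
                     chrom_sizes: dict[str, int] | None = None) -> TranscriptCatalog:
    """Parse a GTF or BED12 annotation into a :class:`TranscriptCatalog`.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Records whose CDS falls outside their exon chain are rejected and counted
    in ``catalog.n_rejected`` rather than aborting the load.
    """
    dialect = dialect.upper()
    if dialect == "GTF":
        models, n_rej = _parse_gtf(source)
    elif dialect == "BED12":
        models, n_rej = _parse_bed12(source)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return TranscriptCatalog(models, chrom_sizes=chrom_sizes or {}, n_rejected=n_rej)


def _parse_gtf(source) -> tuple[dict[str, TranscriptModel], int]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    fh = _open(source)
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise AnnotationError(f"GTF line {lineno}: expected 9 fields, got {len(parts)}")
        chrom, _, feature, start, end, _, strand, _, attrs = parts
        if feature not in ("exon", "CDS"):
            continue
        try:
            s, e = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
        except ValueError:
            raise AnnotationError(f"GTF line {lineno}: non-numeric coordinates") from None
        if s < 0 or s >= e:
            raise AnnotationError(f"GTF line {lineno}: bad interval {start}-{end}")
        attr = dict(_GTF_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        if tid is None:
            raise AnnotationError(f"GTF line {lineno}: missing transcript_id")
        gene = attr.get("gene_id", tid)
        known = meta.setdefault(tid, (gene, chrom, strand))
        if (known[1], known[2]) != (chrom, strand):
            raise AnnotationError(f"GTF line {lineno}: {tid} switches chrom/strand")
        (exons if feature == "exon" else cds).setdefault(tid, []).append((s, e))

    models: dict[str, TranscriptModel] = {}
    n_rejected = 0
    for tid, (gene, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            n_rejected += 1
            continue
        cs = ce = None
        if tid in cds:
            spans = cds[tid]
            cs, ce = min(s for s, _ in spans), max(e for _, e in spans)
        try:
            models[tid] = TranscriptModel(tid, gene, chrom, strand, tuple(ex), cs, ce)
        except AnnotationError:
            n_rejected += 1
    return models, n_rejected


def _parse_bed12(source) -> tuple[dict[str, TranscriptModel], int]:
    models: dict[str, TranscriptModel] = {}
    n_rejected = 0
    fh = _open(source)
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise AnnotationError(f"BED12 line {lineno}: expected 12 fields, got {len(parts)}")
        try:
            chrom = parts[0]
            start, end = int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            thick_s, thick_e = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offs = [int(x) for x in parts[11].rstrip(",").split(",")]
        except ValueError:
            raise AnnotationError(f"BED12 line {lineno}: numeric field malformed") from None
        if len(sizes) != n_blocks or len(offs) != n_blocks:
            raise AnnotationError(f"BED12 line {lineno}: block count mismatch")
        exons = tuple((start + o, start + o + sz) for o, sz in zip(offs, sizes))
        if exons[-1][1] != end:
            raise AnnotationError(f"BED12 line {lineno}: blocks do not span chromEnd")
        cs = ce = None
        if thick_e > thick_s:  # thickStart == thickEnd marks non-coding
            cs, ce = thick_s, thick_e
        gene = name.split(".")[0]
        try:
            models[name] = TranscriptModel(name, gene, chrom, strand, exons, cs, ce)
        except AnnotationError:
            n_rejected += 1
    return models, n_rejected


# ---------------------------------------------------------------------------
# read-end ingest / output


def read_read_ends(source, dialect: str = "BED6", library: str = "BG4",
                   condition: str = "", sample_id: str = "") -> ReadEndSet:
    """Load aligned reads as 5'-end records from BED6 or (headered) SAM.

    BED6: the 5' end of a plus read is ``start``; of a minus read, ``end-1``.
    SAM: parsed with pysam; reverse-flag records take the rightmost aligned
    base. Records with an unknown strand character are skipped and counted.
    """
    dialect = dialect.upper()
    if dialect == "BED6":
        reads, total, skipped = _read_bed6(source, sample_id)
    elif dialect in ("SAM", "SAM-MINIMAL"):
        reads, total, skipped = _read_sam(source, sample_id)
    else:
        raise ValueError(f"unknown read dialect {dialect!r}")
    return ReadEndSet(reads, total=total, library=library,
                      condition=condition, n_skipped=skipped)


def _read_bed6(source, sample_id: str):
    reads: list[ReadEnd] = []
    total = skipped = 0
    fh = _open(source)
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise AnnotationError(f"BED6 line {lineno}: expected 6 fields")
        chrom, start, end, _name, _score, strand = parts[:6]
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise AnnotationError(f"BED6 line {lineno}: non-numeric coordinates") from None
        if s < 0 or s >= e:
            raise AnnotationError(f"BED6 line {lineno}: bad interval")
        total += 1
        if strand == "+":
            reads.append(ReadEnd(chrom, "+", s, e - s, sample_id))
        elif strand == "-":
            reads.append(ReadEnd(chrom, "-", e - 1, e - s, sample_id))
        else:
            skipped += 1
    return reads, total, skipped


def _read_sam(source, sample_id: str):
    import pysam

    reads: list[ReadEnd] = []
    total = skipped = 0
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                skipped += 1
                continue
            total += 1
            length = aln.reference_length or aln.query_length or 1
            if aln.is_reverse:
                pos5 = aln.reference_end - 1
                reads.append(ReadEnd(aln.reference_name, "-", pos5, length, sample_id))
            else:
                reads.append(ReadEnd(aln.reference_name, "+", aln.reference_start,
                                     length, sample_id))
    return reads, total, skipped


def write_bed6(reads: ReadEndSet | Iterable[ReadEnd], path) -> None:
    """Write read ends back to BED6; inverse of the BED6 ingest convention."""
    records = reads.reads if isinstance(reads, ReadEndSet) else list(reads)
    with open(path, "wt") as out:
        for i, r in enumerate(records):
            if r.strand == "+":
                s, e = r.pos5, r.pos5 + r.length
            else:
                s, e = r.pos5 + 1 - r.length, r.pos5 + 1
            name = r.sample_id or f"r{i}"
            out.write(f"{r.chrom}\t{s}\t{e}\t{name}\t0\t{r.strand}\n")


def read_chrom_sizes(source) -> dict[str, int]:
    sizes: dict[str, int] = {}
    fh = _open(source)
    for lineno, line in enumerate(fh, 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AnnotationError(f"chrom.sizes line {lineno}: expected 2 columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "wt") as out:
        for chrom, size in sizes.items():
            out.write(f"{chrom}\t{size}\n")
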