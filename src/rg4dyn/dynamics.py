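"""Classifying transcripts by rG4 occupancy across stages and treatments.

A transcript is "rG4-containing" in a condition when at least one called peak
summit maps into its exons (configurable to any-overlap). Cross-condition
comparisons then follow: specific/shared Venn clusters between two stages,
hypergeometric overlap significance, log2 density ratios, and the
removal-blockade categories for a quadruplex-stabilizing ligand arm
(how much of the maturation-coupled rG4 clearance the ligand prevented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptCatalog
from .peaks import PeakSet

__all__ = [
    "Rg4SetClassification",
    "rg4_containing_transcripts",
    "rg4_transcript_sets",
    "overlap_significance",
    "removal_categories",
    "density_ratio",
]

CATEGORY_NOT_AFFECTED = "not_affected"
CATEGORY_PARTIAL = "partially_blocked"
CATEGORY_COMPLETE = "completely_blocked"
CATEGORY_NOT_EVALUABLE = "not_evaluable"


@dataclass
class Rg4SetClassification:
    """Per-transcript membership flags for two conditions plus Venn clusters."""

    labels: pd.Series                 # index transcript_id; values cluster label
    counts: dict[str, int] = field(default_factory=dict)
    condition_a: str = "A"
    condition_b: str = "B"

    def members(self, cluster: str) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster])


def rg4_containing_transcripts(peaks: PeakSet, catalog: TranscriptCatalog,
                               rule: str = "summit") -> set[str]:
    """Transcripts carrying at least one peak, by summit (default) or by
    any exonic overlap of the peak interval."""
    hit: set[str] = set()
    for pk in peaks:
        if rule == "summit":
            hit.update(catalog.transcripts_at(pk.chrom, pk.strand, pk.summit))
        elif rule == "overlap":
            tree = catalog.exon_index().get((pk.chrom, pk.strand))
            if tree is not None:
                hit.update(iv.data for iv in tree.overlap(pk.start, pk.end))
        else:
            raise ValueError(f"unknown membership rule {rule!r}")
    return hit


def rg4_transcript_sets(peaks_a: PeakSet, peaks_b: PeakSet,
                        catalog: TranscriptCatalog,
                        condition_a: str = "A", condition_b: str = "B",
                        rule: str = "summit") -> Rg4SetClassification:
    """Classify every catalog transcript as A-specific / shared / B-specific /
    neither from two peak sets, with Venn counts.

    Cluster-count identities hold exactly: |A-specific| + |shared| = |A| and
    |B-specific| + |shared| = |B|.
    """
    if len(catalog) == 0:
        raise ValueError("empty transcript catalog")
    in_a = rg4_containing_transcripts(peaks_a, catalog, rule=rule)
    in_b = rg4_containing_transcripts(peaks_b, catalog, rule=rule)
    labels = {}
    for tid in catalog.transcripts:
        a, b = tid in in_a, tid in in_b
        labels[tid] = ("shared" if a and b else
                       "A-specific" if a else
                       "B-specific" if b else "neither")
    ser = pd.Series(labels, name="cluster").sort_index()
    counts = ser.value_counts().to_dict()
    for k in ("A-specific", "shared", "B-specific", "neither"):
        counts.setdefault(k, 0)
    counts["A"] = counts["A-specific"] + counts["shared"]
    counts["B"] = counts["B-specific"] + counts["shared"]
    return Rg4SetClassification(labels=ser, counts=counts,
                                condition_a=condition_a, condition_b=condition_b)


def overlap_significance(n_a: int, n_b: int, n_ab: int, universe_n: int) -> float:
    """Hypergeometric upper-tail probability of seeing >= ``n_ab`` shared
    transcripts between sets of size ``n_a`` and ``n_b`` drawn from a universe.

    This replaces ad hoc tests sometimes attached to Venn diagrams; the
    hypergeometric tail is the standard exact overlap test.
    """
    if not (0 <= n_ab <= min(n_a, n_b) <= universe_n) or max(n_a, n_b) > universe_n:
        raise ValueError(f"impossible overlap counts ({n_a=}, {n_b=}, {n_ab=}, "
                         f"{universe_n=})")
    # P(X >= n_ab), X ~ Hypergeom(N=universe, K=n_a, n=n_b)
    return float(stats.hypergeom.sf(n_ab - 1, universe_n, n_a, n_b))


def density_ratio(d_a: pd.Series, d_b: pd.Series, eps: float) -> pd.Series:
    """Per-transcript log2((d_a + eps)/(d_b + eps)); antisymmetric in A/B."""
    if eps <= 0 and ((d_a == 0) | (d_b == 0)).any():
        raise ValueError("eps must be > 0 when any density is zero")
    d_a, d_b = d_a.align(d_b, join="inner")
    return np.log2((d_a + eps) / (d_b + eps)).rename("log2_ratio")


def removal_categories(d_gv: pd.Series, d_mii_dmso: pd.Series,
                       d_mii_bybx: pd.Series,
                       rg4_at_gv: set[str] | pd.Index | None = None,
                       removal_fc: float = 2.0, lo: float = 0.25,
                       hi: float = 0.75, eps: float = 0.1) -> pd.DataFrame:
    """Categorize how strongly ligand treatment blocked maturation-coupled
    rG4 removal, per transcript.

    A transcript is evaluable when it carried rG4 signal at the immature (GV)
    stage and normal removal occurred in the vehicle arm:
    d_GV + eps >= removal_fc * (d_DMSO + eps). The retention ratio
    rho = clamp((d_BYBX - d_DMSO) / (d_GV - d_DMSO), 0, 1) (densities with eps
    added) then splits transcripts into not_affected (rho <= lo),
    partially_blocked (lo < rho < hi) and completely_blocked (rho >= hi).
    Categories are invariant to rescaling all densities and eps by c > 0.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    idx = d_gv.index
    for other, name in ((d_mii_dmso, "d_mii_dmso"), (d_mii_bybx, "d_mii_bybx")):
        if not idx.equals(other.index):
            raise ValueError(f"{name} does not share the transcript index")
    g = d_gv.astype(float) + eps
    m = d_mii_dmso.astype(float) + eps
    b = d_mii_bybx.astype(float) + eps

    contains = pd.Series(True, index=idx) if rg4_at_gv is None \
        else pd.Series(idx.isin(list(rg4_at_gv)), index=idx)
    removed = g >= removal_fc * m
    evaluable = contains & removed

    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (b - m) / (g - m)
    rho = rho.clip(0.0, 1.0)
    rho[~evaluable] = np.nan

    cat = pd.Series(CATEGORY_NOT_EVALUABLE, index=idx, dtype=object)
    cat[evaluable & (rho <= lo)] = CATEGORY_NOT_AFFECTED
    cat[evaluable & (rho > lo) & (rho < hi)] = CATEGORY_PARTIAL
    cat[evaluable & (rho >= hi)] = CATEGORY_COMPLETE
    return pd.DataFrame({"rho": rho, "category": cat,
                         "d_gv": d_gv, "d_mii_dmso": d_mii_dmso,
                         "d_mii_bybx": d_mii_bybx})
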