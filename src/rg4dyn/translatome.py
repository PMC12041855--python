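"""Spike-normalized expression, translational efficiency, and integration.

Expression is normalized to external spike-in controls of known
concentration: FPKM_t = count_t * 1e9 / (L_t * E_s), where E_s is the total
spike-mapped read count of sample s. Because every library's spike pool is
the same input amount, E_s absorbs the per-sample depth/efficiency nuisance
factor and the resulting values are comparable on an absolute scale — the
property that matters in oocytes, where total mRNA itself changes between
stages. Translational efficiency is the ribosome-footprint to mRNA ratio,
TE = (RPF + eps)/(mRNA + eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "fpkm",
    "translational_efficiency",
    "fold_change_classes",
    "integrate_rg4_te",
    "classify_rbp_binding",
]

ERCC_PREFIX = "ERCC-"

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_BLOCKED = "completely_blocked"
CLASS_EXCLUDED = "excluded"


@dataclass
class ExpressionTable:
    """Spike-normalized FPKM per transcript x sample.

    Spike rows are excluded from ``values`` but their per-sample totals and
    the normalization mode are kept in metadata.
    """

    values: pd.DataFrame        # transcripts x samples, FPKM
    counts: pd.DataFrame        # raw counts, same shape
    lengths: pd.Series
    spike_totals: pd.Series     # per-sample total spike-mapped reads
    meta: dict = field(default_factory=dict)


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         ercc_ids: list[str] | None = None,
         method: str = "total") -> ExpressionTable:
    """Spike-in-normalized FPKM from a raw count table.

    ``counts`` has transcripts (plus spike rows) as index, samples as columns.
    Spike rows are detected by ``ercc_ids`` or by the ``ERCC-`` id prefix.
    Default normalizer: E_s = total spike-mapped reads of the sample
    (``method="total"``); ``method="median_ratio"`` instead uses the
    median across spike species of count/first-sample count, times the first
    sample's spike total — a median-of-ratios variant for heavy-tailed ladders.
    """
    if ercc_ids is None:
        ercc_ids = [i for i in counts.index if str(i).startswith(ERCC_PREFIX)]
    ercc_ids = [i for i in ercc_ids if i in counts.index]
    if not ercc_ids:
        raise ValueError("no spike-in rows found in the count table")
    spikes = counts.loc[ercc_ids]
    totals = spikes.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero spike-in reads: {list(zero.index)}")

    if method == "total":
        e_s = totals
    elif method == "median_ratio":
        ref = spikes.iloc[:, 0].replace(0, np.nan)
        ratios = spikes.div(ref, axis=0)
        e_s = ratios.median(axis=0, skipna=True) * totals.iloc[0]
    else:
        raise ValueError(f"unknown spike normalization method {method!r}")

    tx = counts.drop(index=ercc_ids)
    lens = lengths.reindex(tx.index)
    if lens.isna().any():
        missing = list(lens.index[lens.isna()])[:5]
        raise ValueError(f"missing lengths for transcripts, e.g. {missing}")
    vals = tx.mul(1e9).div(lens, axis=0).div(e_s, axis=1)
    return ExpressionTable(values=vals, counts=tx, lengths=lens,
                           spike_totals=totals,
                           meta={"normalization": method, "n_spikes": len(ercc_ids)})


def translational_efficiency(rpf: ExpressionTable | pd.DataFrame,
                             mrna: ExpressionTable | pd.DataFrame,
                             eps: float = 0.1,
                             min_mrna_fpkm: float = 1.0) -> pd.DataFrame:
    """TE = (RPF + eps)/(mRNA + eps) per transcript and condition.

    Columns of the two tables are matched by name (conditions). Transcripts
    whose mRNA FPKM never reaches ``min_mrna_fpkm`` in any condition are
    flagged ``low_confidence`` rather than dropped. With both signals at zero,
    TE = eps/eps = 1 by the degenerate-case contract.
    """
    r = rpf.values if isinstance(rpf, ExpressionTable) else rpf
    m = mrna.values if isinstance(mrna, ExpressionTable) else mrna
    common = r.index.intersection(m.index)
    cols = [c for c in r.columns if c in m.columns]
    if not cols:
        raise ValueError("RPF and mRNA tables share no condition columns")
    r, m = r.loc[common, cols], m.loc[common, cols]
    te = (r + eps) / (m + eps)
    te.columns = [f"TE_{c}" for c in cols]
    out = pd.concat([te,
                     m.add_prefix("mRNA_"),
                     r.add_prefix("RPF_")], axis=1)
    out["low_confidence"] = (m < min_mrna_fpkm).all(axis=1)
    return out


def fold_change_classes(values_ref: pd.Series, values_alt: pd.Series,
                        fc_up: float = 2.0, fc_down: float = 0.5,
                        eps: float = 0.0) -> pd.Series:
    """Label transcripts up / down / unchanged by the alt/ref ratio.

    Thresholds are strict ("more than ``fc_up``-fold"): a ratio of exactly
    ``fc_up`` or ``fc_down`` is unchanged. ``eps`` may be supplied to shift
    both values when zeros are possible; without it a non-positive reference
    is an error.
    """
    if not fc_down < 1 < fc_up:
        raise ValueError("need fc_down < 1 < fc_up")
    ref, alt = values_ref.align(values_alt, join="inner")
    ref, alt = ref.astype(float) + eps, alt.astype(float) + eps
    if (ref <= 0).any():
        raise ValueError("non-positive reference values; supply eps > 0")
    ratio = alt / ref
    cls = pd.Series(CLASS_UNCHANGED, index=ratio.index, dtype=object)
    cls[ratio > fc_up] = CLASS_UP
    cls[ratio < fc_down] = CLASS_DOWN
    return cls.rename("class")


def integrate_rg4_te(delta_rg4: pd.DataFrame | pd.Series,
                     te_classes: pd.Series,
                     region: str = "full",
                     maturation_up: set[str] | None = None,
                     rg4_band: float = 0.0) -> dict:
    """Cross rG4 density change with TE change per transcript.

    ``delta_rg4``: log2 density ratios (e.g. ligand vs vehicle); either one
    Series or a DataFrame with one column per region ('full', '5UTR', '3UTR')
    so the integration can be restricted by ``region``. Each transcript gets
    a quadrant label (rG4 up/down/flat x TE class); headline sets are
    returned: TE-down & rG4-up overall and within each UTR, the 5'UTR/3'UTR
    set intersection, and (if given) the overlap with the maturation
    TE-activated set.
    """
    if isinstance(delta_rg4, pd.Series):
        delta_rg4 = delta_rg4.to_frame("full")
    if region not in delta_rg4.columns:
        raise ValueError(f"region {region!r} not in the density-ratio table; "
                         f"have {list(delta_rg4.columns)}")
    common = delta_rg4.index.intersection(te_classes.index)
    d = delta_rg4.loc[common]
    te = te_classes.loc[common]

    def rg4_dir(col: pd.Series) -> pd.Series:
        out = pd.Series("rG4-flat", index=col.index, dtype=object)
        out[col > rg4_band] = "rG4-up"
        out[col < -rg4_band] = "rG4-down"
        return out

    direction = rg4_dir(d[region])
    quadrant = direction + " & TE-" + te.astype(str)
    table = pd.DataFrame({"delta_rg4": d[region], "rg4_direction": direction,
                          "te_class": te, "quadrant": quadrant})

    te_down = set(te.index[te == CLASS_DOWN])
    sets: dict[str, set[str]] = {
        "te_down_rg4_up": te_down & set(direction.index[direction == "rG4-up"]),
    }
    for reg in ("5UTR", "3UTR"):
        if reg in d.columns:
            up_in_reg = set(d.index[d[reg] > rg4_band])
            sets[f"te_down_rg4_up_{reg}"] = te_down & up_in_reg
    if "te_down_rg4_up_5UTR" in sets and "te_down_rg4_up_3UTR" in sets:
        sets["te_down_rg4_up_both_utrs"] = (sets["te_down_rg4_up_5UTR"]
                                            & sets["te_down_rg4_up_3UTR"])
    if maturation_up is not None:
        sets["te_down_and_maturation_activated"] = te_down & set(maturation_up)
    counts = table["quadrant"].value_counts().to_dict()
    return {"table": table, "sets": sets, "quadrant_counts": counts}


def classify_rbp_binding(intensities: pd.DataFrame,
                         fc_down: float = 0.5, fc_up: float = 2.0
                         ) -> pd.DataFrame:
    """Classify RNA-binding proteins by the change in RNA-bound signal after
    ligand treatment.

    Requires columns ``input``, ``IP_mock``, ``IP_bybx``. Proteins without
    input signal (input <= 0) are excluded; proteins bound in the vehicle arm
    but undetectable after treatment (IP_mock > 0, IP_bybx = 0) are
    completely_blocked; the rest are classed by FC = IP_bybx / IP_mock with
    strict < ``fc_down`` / > ``fc_up`` cutoffs.
    """
    needed = {"input", "IP_mock", "IP_bybx"}
    missing = needed - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (intensities[list(needed)] < 0).any().any():
        raise ValueError("negative intensities are not meaningful")
    df = intensities.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fc"] = df["IP_bybx"] / df["IP_mock"]
    cls = pd.Series(CLASS_UNCHANGED, index=df.index, dtype=object)
    cls[df["fc"] < fc_down] = CLASS_DOWN
    cls[df["fc"] > fc_up] = CLASS_UP
    cls[(df["IP_mock"] > 0) & (df["IP_bybx"] == 0)] = CLASS_BLOCKED
    cls[df["input"] <= 0] = CLASS_EXCLUDED
    df["class"] = cls
    return df
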