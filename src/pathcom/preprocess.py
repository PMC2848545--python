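"""Probe-level ChIP-chip signals -> 0-100% occupancy tables and gene groups.

The chain mirrors a low-density tiling-array design with one probe near
each transcription start site (TSS) plus tail-to-tail (T-T) intergenic
probes between convergently transcribed genes, which are expected to be
factor-free and anchor the background:

1. background replicates are each normalized to their own grand median and
   combined per probe by the median;
2. each factor's signal is divided by the combined background probe-by-probe
   and then by the median of the resulting ratios over T-T probes, so the
   fold over background is centered at 1 in non-promoter regions;
3. folds are scaled to percent occupancy: fold <= 1 -> 0%, fold at or above
   the 99th-percentile value -> 100%, linear in between — putting every
   factor on a common scale and cancelling factor-specific crosslinking
   efficiency;
4. genes are binarized per factor at a 10% cutoff into low (L) / high (H)
   patterns, under-populated child groups are consolidated as factors are
   added, and group medians form the modeling input.
"""

from __future__ import annotations

import logging
import math
import re
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "combine_background",
    "fold_over_background",
    "scale_percent",
    "assign_groups",
    "consolidate_groups",
    "consolidate_incremental",
    "group_medians",
    "probe_dataset_to_occupancy",
    "read_probe_table",
    "write_probe_table",
]

logger = logging.getLogger(__name__)

#: H/L cutoff in percent: below -> L, at or above -> H.
DEFAULT_CUTOFF = 10.0
#: Percentile whose fold value is re-coded as 100%.
DEFAULT_PERCENTILE = 99.0

PROBE_META_COLUMNS = ("probe_id", "probe_class", "gene_id")
PROBE_CLASSES = ("TSS", "TT_intergenic", "other")


def combine_background(replicates: pd.DataFrame) -> pd.Series:
    """Combine background-strain replicates into one per-probe background.

    Each replicate column is divided by its own grand median, then the
    per-probe median across replicates is taken.
    """
    if replicates.shape[1] < 1:
        raise ValueError("at least one background replicate required")
    vals = replicates.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("background signals must be positive and finite")
    normed = replicates / replicates.median(axis=0)
    return normed.median(axis=1)


def fold_over_background(
    factor_signal: pd.Series,
    background: pd.Series,
    tt_mask: pd.Series,
) -> pd.Series:
    """Per-probe fold over background, centered so T-T regions sit at 1.

    The signal is divided by the background probe-by-probe, then by the
    median ratio over T-T intergenic probes (expected factor-free), so the
    median fold over T-T probes is exactly 1 after centering.
    """
    if not factor_signal.index.equals(background.index):
        raise ValueError("factor signal and background probe sets differ")
    if int(tt_mask.sum()) == 0:
        raise ValueError("no T-T intergenic probes: cannot center background")
    ratio = factor_signal / background
    tt_median = float(ratio[tt_mask.astype(bool)].median())
    if not (tt_median > 0):
        raise ValueError(f"non-positive T-T median ratio: {tt_median}")
    return ratio / tt_median


def _percentile_value(folds: np.ndarray, percentile: float) -> float:
    """Value at rank ceil(q * N) of the sorted folds (1-based)."""
    n = len(folds)
    rank = min(max(int(math.ceil(percentile / 100.0 * n)), 1), n)
    return float(np.sort(folds)[rank - 1])


def scale_percent(
    folds: pd.Series | np.ndarray,
    upper_percentile: float = DEFAULT_PERCENTILE,
) -> pd.Series | np.ndarray:
    """Scale fold-over-background values to percent occupancy.

    Fold <= 1 is background (0%); folds at or above the value at the
    ``upper_percentile`` rank become 100%; the rest scale linearly as
    ``100 * (fold - 1) / (p - 1)`` where ``p`` is the percentile value
    (background of 1 subtracted from both numerator and denominator so the
    percentile value itself lands exactly on 100%).
    """
    arr = np.asarray(folds, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("folds must be finite and nonnegative")
    p = _percentile_value(arr, upper_percentile)
    if p <= 1.0:
        raise ValueError(
            f"degenerate dataset: {upper_percentile}th-percentile fold {p} <= 1"
        )
    pct = 100.0 * (arr - 1.0) / (p - 1.0)
    pct = np.clip(pct, 0.0, 100.0)
    if isinstance(folds, pd.Series):
        return pd.Series(pct, index=folds.index, name=folds.name)
    return pct


def assign_groups(
    table: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    codes: Sequence[str] | None = None,
    cutoffs: Sequence[float] | None = None,
) -> pd.Series:
    """Label each gene with its H/L pattern, e.g. ``"(L,H,H)"``.

    Occupancy below ``cutoff`` is low (L); all others high (H) — an exact
    tie goes to H.  Passing ``cutoffs`` (e.g. ``(10, 20)``) switches to a
    multi-tier labeling L/M/H used for robustness checks.
    """
    codes = list(codes) if codes is not None else list(table.columns)
    tiers = sorted(cutoffs) if cutoffs is not None else [cutoff]
    letters = ["L", "M", "H"] if len(tiers) == 2 else ["L", "H"]
    if len(tiers) + 1 != len(letters):
        raise ValueError("cutoffs must define 2 or 3 tiers")

    def label(row: pd.Series) -> str:
        parts = []
        for c in codes:
            v = float(row[c])
            tier = sum(v >= t for t in tiers)
            parts.append(letters[tier])
        return "(" + ",".join(parts) + ")"

    return table.apply(label, axis=1)


def _split_pattern(label: str) -> tuple[str, ...]:
    return tuple(re.sub(r"[()\s]", "", label).split(","))


def _join_pattern(parts: Sequence[str]) -> str:
    return "(" + ",".join(parts) + ")"


def consolidate_groups(
    parent_labels: pd.Series,
    child_labels: pd.Series,
    exempt_size: int = 100,
    min_size: int = 10,
    max_ratio: float = 4.0,
) -> pd.Series:
    """Merge under-populated children created by adding one factor.

    Each parent group splits into at most two children on the added
    factor's L/H call.  Both children survive only if each exceeds
    ``exempt_size`` genes, or if the split is no worse than ``max_ratio``:1
    with both at least ``min_size``; otherwise the children are merged and
    the merged group carries the larger child's label.  Total membership is
    conserved.
    """
    if not parent_labels.index.equals(child_labels.index):
        raise ValueError("parent and child labels cover different genes")
    out = child_labels.copy()
    for parent, idx in parent_labels.groupby(parent_labels).groups.items():
        children = child_labels.loc[idx]
        counts = children.value_counts()
        for lab in counts.index:
            if _split_pattern(lab)[: len(_split_pattern(parent))] != _split_pattern(parent):
                raise ValueError(
                    f"child label {lab!r} does not refine parent {parent!r}"
                )
        if len(counts) != 2:
            continue
        big, small = counts.index[0], counts.index[1]
        n_big, n_small = int(counts.iloc[0]), int(counts.iloc[1])
        both_exempt = n_big > exempt_size and n_small > exempt_size
        if both_exempt:
            continue
        if n_small < min_size or n_big > max_ratio * n_small:
            out.loc[idx] = big
            logger.info(
                "consolidated %s (%d) into %s (%d) under parent %s",
                small, n_small, big, n_big, parent,
            )
    return out


def consolidate_incremental(
    table: pd.DataFrame,
    codes: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
    min_factors_for_consolidation: int = 4,
    **kwargs,
) -> pd.Series:
    """Label genes factor-by-factor, consolidating at each addition.

    Factors are added one at a time (2 -> 3 -> ... -> n); from
    ``min_factors_for_consolidation`` factors onward each newly created
    split is consolidated before the next factor is added.  With three or
    fewer factors no consolidation is applied, keeping the full 2^n
    pattern set.
    """
    codes = list(codes)
    labels = assign_groups(table, cutoff=cutoff, codes=codes[:1])
    for k in range(2, len(codes) + 1):
        new_calls = assign_groups(table, cutoff=cutoff, codes=[codes[k - 1]])
        child = pd.Series(
            [
                _join_pattern(_split_pattern(p) + _split_pattern(c))
                for p, c in zip(labels, new_calls)
            ],
            index=table.index,
        )
        if k >= min_factors_for_consolidation:
            child = consolidate_groups(labels, child, **kwargs)
        labels = child
    return labels


def group_medians(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Median occupancy per group and factor — the modeling input.

    Grouping similarly behaving genes and taking medians damps gene-level
    crosslinking and detection variability.
    """
    if len(table) == 0:
        raise ValueError("empty occupancy table")
    if labels.isna().any():
        raise ValueError("every gene needs a group label")
    med = table.groupby(labels).median()
    med.index.name = "group"
    return med


def read_probe_table(path_or_buf) -> pd.DataFrame:
    """Read a tab-delimited probe table.

    Expected columns: ``probe_id``, ``probe_class`` (TSS / TT_intergenic /
    other), ``gene_id`` (empty outside TSS probes), then one signal column
    per replicate named ``FACTOR_rep#`` or ``BG_rep#``.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": "string"})
    missing = set(PROBE_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table lacks columns {sorted(missing)}")
    bad = set(df["probe_class"].unique()) - set(PROBE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe classes {sorted(bad)}")
    return df.set_index("probe_id")


def write_probe_table(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, sep="\t", index=True, lineterminator="\n")


def _replicate_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    pat = re.compile(rf"^{re.escape(prefix)}_rep\d+$")
    return [c for c in df.columns if pat.match(c)]


def probe_dataset_to_occupancy(
    probes: pd.DataFrame,
    codes: Sequence[str],
    upper_percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Full normalization chain: probe signals -> per-gene percent occupancy.

    Background replicates are combined, each factor's replicates are
    median-combined and converted to centered fold over background, folds
    are scaled to percent (percentile computed over all probes of the
    factor), and the TSS probes are collected into a gene x factor table.
    Genes lacking a TSS probe signal for any modeled factor are dropped
    with a logged count.
    """
    bg_cols = _replicate_columns(probes, "BG")
    if not bg_cols:
        raise ValueError("no background replicate columns (BG_rep#)")
    background = combine_background(probes[bg_cols])
    tt_mask = probes["probe_class"] == "TT_intergenic"

    pct = {}
    for code in codes:
        rep_cols = _replicate_columns(probes, code)
        if not rep_cols:
            raise ValueError(f"no replicate columns for factor {code!r}")
        signal = probes[rep_cols].median(axis=1)
        folds = fold_over_background(signal, background, tt_mask)
        pct[code] = scale_percent(folds, upper_percentile)
    pct_df = pd.DataFrame(pct)

    tss = probes["probe_class"] == "TSS"
    occ = pct_df[tss].copy()
    occ["gene_id"] = probes.loc[tss, "gene_id"]
    n_before = occ["gene_id"].nunique()
    occ = occ.dropna(subset=list(codes) + ["gene_id"])
    table = occ.groupby("gene_id")[list(codes)].median()
    n_dropped = n_before - len(table)
    if n_dropped:
        logger.info("dropped %d genes lacking complete TSS measurements", n_dropped)
    table.index.name = "gene_id"
    return table
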