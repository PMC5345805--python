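"""From a differential-expression table to a ternary direction map.

A gene is called *misregulated* versus the ancestor when its signed fold
change clears a magnitude threshold (default 1.5, inclusive) and its
FDR-adjusted p-value (Benjamini-Hochberg) is below a significance threshold
(default 0.05).  Every measured gene receives one of three values:
+1 (up-regulated), -1 (down-regulated) or 0 (no change).  The resulting
direction map over the full transcriptome is what the pathway
directionality test consumes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ratio_from_signed, signed_from_ratio


def average_replicate_fold_changes(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average signed fold changes across replicate DE tables, per gene.

    All replicates must cover the same gene universe.  The p-value column is
    carried from the first table: it holds the replicate-combined test's
    p-value supplied by the caller and is not recomputed here.

    If replicate signs disagree and the arithmetic mean lands inside the
    open interval (-1, 1) — which no signed fold change can occupy — the
    mean is snapped to the nearest boundary (+1.0 or -1.0, i.e. exactly
    "no change"), preserving the sign of the mean.
    """
    if len(tables) == 0:
        raise ValueError("need at least one replicate table")
    first = tables[0]
    universe = set(first["gene_id"])
    for i, t in enumerate(tables[1:], start=2):
        other = set(t["gene_id"])
        if other != universe:
            missing = sorted((universe - other) | (other - universe))
            raise ValueError(
                f"replicate {i} gene universe mismatch; differing genes: "
                + ", ".join(missing[:10])
            )
    if len(tables) == 1:
        return first.copy()
    fcs = pd.concat(
        [t.set_index("gene_id")["fold_change"] for t in tables], axis=1
    )
    mean_fc = fcs.mean(axis=1)
    inside = (mean_fc > -1.0) & (mean_fc < 1.0)
    mean_fc[inside] = np.where(mean_fc[inside] >= 0, 1.0, -1.0)
    out = first.copy()
    out["fold_change"] = out["gene_id"].map(mean_fc).astype(float)
    out.attrs = dict(first.attrs)
    return out


def adjust_fdr(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_i = min over j >= i of p_(j) * m / j after sorting, then mapped back.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method=method)
    return q


def call_misregulated(table: pd.DataFrame, fc_threshold: float = 1.5,
                      q_threshold: float = 0.05, *, strict: bool = False,
                      fdr_method: str = "fdr_bh") -> pd.Series:
    """Build the ternary direction map from a (replicate-averaged) DE table.

    Returns a Series mapping gene_id -> {-1, 0, +1} over every gene in the
    table.  Thresholds are inclusive on fold-change magnitude by default
    (|FC| >= 1.5); ``strict=True`` switches to strictly greater, under which
    a gene significant by q but sitting exactly at the threshold gets 0.
    If the table has no ``q_value`` column, q-values are computed here with
    :func:`adjust_fdr` over the whole table.
    """
    fc = table["fold_change"].to_numpy(float)
    if "q_value" in table.columns:
        q = table["q_value"].to_numpy(float)
    else:
        q = adjust_fdr(table["p_value"].to_numpy(float), method=fdr_method)
    sig = q < q_threshold
    if strict:
        up = sig & (fc > fc_threshold)
        down = sig & (fc < -fc_threshold)
    else:
        up = sig & (fc >= fc_threshold)
        down = sig & (fc <= -fc_threshold)
    values = np.zeros(len(table), dtype=np.int8)
    values[up] = 1
    values[down] = -1
    return pd.Series(values, index=pd.Index(table["gene_id"], name="gene_id"),
                     name="direction")


def write_direction_map(directions: pd.Series, path) -> None:
    """Write a direction map as a two-column TSV (gene_id, direction)."""
    directions.to_csv(path, sep="\t", header=True)


def read_direction_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    s = pd.Series(df["direction"].to_numpy(np.int8),
                  index=pd.Index(df["gene_id"], name="gene_id"),
                  name="direction")
    bad = ~s.isin([-1, 0, 1])
    if bad.any():
        raise ValueError(f"direction values outside {{-1,0,+1}} for "
                         f"{int(bad.sum())} genes")
    return s
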