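"""Proximity-proteomics enrichment selection and iBAQ quantification.

Turns a bait-vs-control protein intensity table into the enriched
interactome:

1. :func:`filter_min_peptides` drops single-peptide identifications.
2. :func:`compute_protein_stats` runs an unpaired, equal-variance,
   two-tailed Student's t-test on log2-transformed intensities per protein
   and computes the geometric-mean fold change
   ``FC = 2^(mean_log2_bait - mean_log2_control)``.
3. :func:`select_enriched` applies the joint gate FC >= fc_min (inclusive)
   and p < p_max (strict), the thresholds used to call a proximity hit.
4. :func:`compute_abundance` converts intensities to a control-subtracted
   iBAQ-style log2 abundance and expresses each protein as a percentage of
   the bait.

Zeros and missing intensities are treated as absent observations: a protein
needs at least two observed values per condition to be tested, and is
reported untested (never enriched) otherwise.  No imputation is performed
and no multiple-testing correction enters the gate; a Benjamini-Hochberg
q-value column is emitted for information only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import IntensityTable

__all__ = [
    "filter_min_peptides",
    "protein_t_test",
    "compute_protein_stats",
    "select_enriched",
    "compute_abundance",
    "infer_bait_log2",
    "category_breakdown",
]

logger = logging.getLogger(__name__)


def filter_min_peptides(table: IntensityTable, min_unique: int = 2
                        ) -> tuple[IntensityTable, int]:
    """Remove proteins identified by fewer than ``min_unique`` peptides.

    Returns the filtered table and the number of rows removed.
    """
    keep = table.df["unique_peptides"] >= min_unique
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_min_peptides: removed %d of %d proteins",
                    removed, len(table))
    out = IntensityTable(df=table.df.loc[keep].reset_index(drop=True),
                         n_replicates_per_condition=table.n_replicates_per_condition)
    return out, removed


def protein_t_test(bait_log2: np.ndarray, control_log2: np.ndarray
                   ) -> tuple[float, float]:
    """Equal-variance two-tailed two-sample t-test on log2 intensities.

    Returns ``(p_value, t_statistic)``; NaN observations are dropped and
    ``(nan, nan)`` is returned when either group has fewer than two
    observed values (the protein is not testable).
    """
    a = np.asarray(bait_log2, dtype=float)
    b = np.asarray(control_log2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p), float(t)


def _log2_observed(mat: np.ndarray) -> np.ndarray:
    """log2 of intensities with zeros/NaN mapped to NaN (absent)."""
    out = np.full(mat.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.nan_to_num(mat, nan=0.0) > 0
        out[pos] = np.log2(mat[pos])
    return out


def compute_protein_stats(table: IntensityTable) -> pd.DataFrame:
    """Per-protein volcano statistics: fold change, t-test p, BH q.

    Columns: protein_id, gene, mean_log2_bait, mean_log2_control, log2_fc,
    fold_change, t_statistic, p_value, q_value, tested.
    """
    bait = _log2_observed(table.bait_matrix())
    ctrl = _log2_observed(table.control_matrix())
    rows = []
    for i in range(len(table)):
        p, t = protein_t_test(bait[i], ctrl[i])
        mb = float(np.nanmean(bait[i])) if np.isfinite(bait[i]).any() else np.nan
        mc = float(np.nanmean(ctrl[i])) if np.isfinite(ctrl[i]).any() else np.nan
        rows.append((mb, mc, t, p))
    out = table.df[["protein_id", "gene"]].copy()
    arr = np.array(rows, dtype=float)
    out["mean_log2_bait"] = arr[:, 0]
    out["mean_log2_control"] = arr[:, 1]
    out["log2_fc"] = out["mean_log2_bait"] - out["mean_log2_control"]
    out["fold_change"] = 2.0 ** out["log2_fc"]
    out["t_statistic"] = arr[:, 2]
    out["p_value"] = arr[:, 3]
    out["tested"] = np.isfinite(out["p_value"])
    q = np.full(len(out), np.nan)
    tested = out["tested"].to_numpy()
    if tested.any():
        q[tested] = stats.false_discovery_control(
            out.loc[tested, "p_value"].to_numpy(), method="bh")
    out["q_value"] = q  # informational only; the gate uses raw p
    return out


def select_enriched(stats_df: pd.DataFrame, fc_min: float = 10.0,
                    p_max: float = 0.001,
                    fc_inclusive: bool = True) -> pd.DataFrame:
    """Apply the joint enrichment gate and return the stats with a flag.

    A protein is enriched iff it is testable, ``fold_change >= fc_min``
    (``>`` when ``fc_inclusive=False``) and ``p_value < p_max`` (always
    strict).
    """
    out = stats_df.copy()
    fc = out["fold_change"]
    fc_ok = fc >= fc_min if fc_inclusive else fc > fc_min
    out["enriched"] = out["tested"] & fc_ok & (out["p_value"] < p_max)
    return out


def compute_abundance(table: IntensityTable, enriched: Iterable[str],
                      bait_gene: str, subtract_scale: str = "linear"
                      ) -> pd.DataFrame:
    """Control-subtracted log2 abundance and percent-of-bait per hit.

    The default ``subtract_scale='linear'`` subtracts the linear-scale
    control average from the bait average and reports log2 of the result,
    which preserves the absolute-abundance scale that published iBAQ(log2)
    columns carry; ``'log2'`` instead subtracts the averages of the log2
    values (yielding a geometric bait/control ratio rather than an
    abundance).  Proteins with no observed control values fall back to the
    bait average alone.  Rows are ranked by descending abundance;
    ``pct_of_bait`` is ``100 * 2^(ibaq_log2 - ibaq_log2_bait)`` (exactly
    100 for the bait).
    """
    if subtract_scale not in ("log2", "linear"):
        raise ValueError("subtract_scale must be 'log2' or 'linear'")
    enriched = set(enriched)
    df = table.df[table.df["protein_id"].isin(enriched)
                  | (table.df["gene"] == bait_gene)]
    if not (df["gene"] == bait_gene).any():
        raise ValueError(f"bait gene {bait_gene!r} absent from table")
    sub = IntensityTable(df=df.reset_index(drop=True).copy(),
                         n_replicates_per_condition=table.n_replicates_per_condition)
    bait_l2 = _log2_observed(sub.bait_matrix())
    ctrl_l2 = _log2_observed(sub.control_matrix())
    vals = np.empty(len(sub))
    for i in range(len(sub)):
        if subtract_scale == "log2":
            mb = np.nanmean(bait_l2[i]) if np.isfinite(bait_l2[i]).any() else np.nan
            mc = np.nanmean(ctrl_l2[i]) if np.isfinite(ctrl_l2[i]).any() else 0.0
            vals[i] = mb - mc if np.isfinite(bait_l2[i]).any() else np.nan
            if not np.isfinite(ctrl_l2[i]).any():
                vals[i] = mb
        else:
            mb = np.nanmean(np.nan_to_num(sub.bait_matrix()[i], nan=0.0))
            mc = np.nanmean(np.nan_to_num(sub.control_matrix()[i], nan=0.0))
            diff = max(mb - mc, np.finfo(float).tiny)
            vals[i] = np.log2(diff)
    out = sub.df[["protein_id", "gene"]].copy()
    out["ibaq_log2"] = vals
    bait_val = float(out.loc[out["gene"] == bait_gene, "ibaq_log2"].iloc[0])
    out["pct_of_bait"] = 100.0 * 2.0 ** (out["ibaq_log2"] - bait_val)
    out = out.sort_values("ibaq_log2", ascending=False).reset_index(drop=True)
    return out


def infer_bait_log2(ibaq_log2: Iterable[float],
                    pct_of_bait: Iterable[float]) -> float:
    """Recover the bait reference abundance from published (iBAQ, %) rows.

    Each row satisfies ``pct = 100 * 2^(ibaq - bait)``, so
    ``bait = ibaq + log2(100 / pct)``; the estimate averages over rows,
    which damps the rounding of the printed percentages.
    """
    ibaq = np.asarray(list(ibaq_log2), dtype=float)
    pct = np.asarray(list(pct_of_bait), dtype=float)
    if ibaq.size == 0 or ibaq.shape != pct.shape:
        raise ValueError("need matching, non-empty iBAQ and percentage rows")
    return float(np.mean(ibaq + np.log2(100.0 / pct)))


def category_breakdown(records: pd.DataFrame,
                       category_map: Mapping[str, str] | None = None
                       ) -> pd.DataFrame:
    """Per-category shares by protein count and by linear-abundance sum.

    ``records`` must carry ``gene`` and ``ibaq_log2`` columns plus either a
    ``category`` column or a gene->category mapping; unmapped genes become
    ``unassigned``.  Both share columns sum to 100 (before rounding).
    """
    if len(records) == 0:
        raise ValueError("no abundance records to summarize")
    df = records.copy()
    if category_map is not None:
        df["category"] = [category_map.get(g, "unassigned") for g in df["gene"]]
    elif "category" not in df.columns:
        raise ValueError("need a category column or a category_map")
    df["weight"] = 2.0 ** df["ibaq_log2"]
    by_count = df.groupby("category").size()
    by_abund = df.groupby("category")["weight"].sum()
    out = pd.DataFrame({
        "count": by_count,
        "count_share_pct": 100.0 * by_count / by_count.sum(),
        "abundance_share_pct": 100.0 * by_abund / by_abund.sum(),
    }).sort_values("count_share_pct", ascending=False)
    return out.reset_index()
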