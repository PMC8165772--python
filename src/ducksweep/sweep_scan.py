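"""Joint FST / diversity-ratio outlier scan and candidate-region calling.

Windows in the top tail of both the between-population FST distribution and
the log2 diversity-ratio distribution (default: upper 5% of each) are joint
outliers; overlapping or book-ended outlier windows merge into candidate
domestication regions (CDRs).  Thresholds are realized empirical quantiles
computed over windows where both statistics are defined — they are data
properties, not constants — and are always reported alongside the outliers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import GeneModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepScanConfig:
    """Upper-quantile cutoffs of the joint outlier rule (defaults: top 5% of each arm)."""

    fst_quantile: float = 0.95
    ratio_quantile: float = 0.95

    def __post_init__(self) -> None:
        for q in (self.fst_quantile, self.ratio_quantile):
            if not (0.0 < q < 1.0):
                raise ValueError(f"quantiles must be in (0,1), got {q}")


def joint_outlier_windows(
    stats: pd.DataFrame,
    fst_col: str,
    ratio_col: str,
    cfg: SweepScanConfig = SweepScanConfig(),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Windows with fst >= q(fst) AND ratio >= q(ratio).

    Quantiles are linear-interpolation empirical quantiles (numpy default,
    "type 7") over windows where both statistics are non-missing.  Returns
    the outlier subset (original row order) and the realized thresholds.
    """
    fst = stats[fst_col].to_numpy(dtype=float)
    ratio = stats[ratio_col].to_numpy(dtype=float)
    defined = ~np.isnan(fst) & ~np.isnan(ratio)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("joint_outlier_windows: all windows have missing fst or ratio")
    if n_def < 20:
        raise ValueError(
            f"joint_outlier_windows: only {n_def} windows with both statistics defined (need >= 20)"
        )
    fst_thr = float(np.quantile(fst[defined], cfg.fst_quantile))
    ratio_thr = float(np.quantile(ratio[defined], cfg.ratio_quantile))
    mask = defined & (fst >= fst_thr) & (ratio >= ratio_thr)
    thresholds = {"fst": fst_thr, "ratio": ratio_thr}
    log.info(
        "joint_outlier_windows: realized thresholds fst >= %.4g, ratio >= %.4g; %d / %d windows",
        fst_thr,
        ratio_thr,
        int(mask.sum()),
        n_def,
    )
    return stats.loc[mask].copy(), thresholds


def merge_to_cdrs(
    outliers: pd.DataFrame,
    fst_col: str | None = None,
    ratio_col: str | None = None,
) -> pd.DataFrame:
    """Merge overlapping or book-ended outlier windows into CDRs.

    Returns chrom/start/end/n_windows/max_fst/max_log2_ratio (1-based
    inclusive bounds).  Idempotent and invariant to input row order.
    """
    cols = ["chrom", "start", "end", "n_windows", "max_fst", "max_log2_ratio"]
    if outliers.empty:
        return pd.DataFrame(columns=cols)
    if fst_col is None:
        cand = [c for c in outliers.columns if c.startswith("fst")]
        fst_col = cand[0] if cand else None
    if ratio_col is None:
        cand = [c for c in outliers.columns if c.startswith("log2ratio") or c.startswith("max_log2")]
        ratio_col = cand[0] if cand else None
    df = outliers.sort_values(["chrom", "start", "end"], kind="mergesort")
    n_win_col = "n_windows" if "n_windows" in df.columns else None
    rows = []
    cur = None
    for r in df.itertuples():
        fst = getattr(r, fst_col) if fst_col else np.nan
        ratio = getattr(r, ratio_col) if ratio_col else np.nan
        nw = getattr(r, n_win_col) if n_win_col else 1
        if cur is not None and r.chrom == cur["chrom"] and r.start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], r.end)
            cur["n_windows"] += nw
            cur["max_fst"] = np.nanmax([cur["max_fst"], fst])
            cur["max_log2_ratio"] = np.nanmax([cur["max_log2_ratio"], ratio])
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end),
                "n_windows": int(nw),
                "max_fst": fst,
                "max_log2_ratio": ratio,
            }
    rows.append(cur)
    return pd.DataFrame(rows, columns=cols)


def genes_in_cdrs(
    cdrs: pd.DataFrame, genes: list[GeneModel]
) -> tuple[pd.DataFrame, list[str]]:
    """Genes whose transcript span overlaps a CDR by at least 1 bp.

    Returns a per-CDR table with a comma-joined gene list, and the
    deduplicated list of selected gene ids (first-occurrence order).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_lists: list[str] = []
    selected: list[str] = []
    seen = set()
    for r in cdrs.itertuples():
        hits = [
            g.gene_id
            for g in by_chrom.get(r.chrom, [])
            if g.tx_start <= r.end and g.tx_end >= r.start
        ]
        gene_lists.append(",".join(hits))
        for gid in hits:
            if gid not in seen:
                seen.add(gid)
                selected.append(gid)
    out = cdrs.copy()
    out["genes"] = gene_lists
    return out, selected


def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U (U statistic of the first sample, p-value).

    Exact null distribution when both groups have <= 8 observations and no
    ties; otherwise the normal approximation with tie correction (no
    continuity correction, so identical groups give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Mann-Whitney groups must be non-empty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class TajimaDContrast:
    """Selected-gene vs genome-background contrast of per-gene Tajima's D."""

    median_selected: float
    median_background: float
    u_statistic: float
    p_value: float
    n_selected: int
    n_background: int


def gene_tajima_d(
    stats: pd.DataFrame, genes: list[GeneModel], d_col: str
) -> dict[str, float]:
    """Per-gene D: mean of the (non-missing) window D values over windows
    overlapping the gene's transcript span."""
    out: dict[str, float] = {}
    by_chrom = {c: g for c, g in stats.groupby("chrom")}
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] <= gene.tx_end) & (sub["end"] >= gene.tx_start)][d_col]
        hit = hit.dropna()
        if len(hit):
            out[gene.gene_id] = float(hit.mean())
    return out


def tajima_d_contrast(
    selected_gene_ids: list[str],
    stats: pd.DataFrame,
    genes: list[GeneModel],
    d_col: str,
    alternative: str = "two-sided",
) -> TajimaDContrast:
    """Compare per-gene Tajima's D of selected genes against all other genes.

    ``alternative='less'`` tests for *lower* D in the selected genes, the
    expected direction under a selective sweep.
    """
    per_gene = gene_tajima_d(stats, genes, d_col)
    sel_set = set(selected_gene_ids)
    sel = [d for g, d in per_gene.items() if g in sel_set]
    other = [d for g, d in per_gene.items() if g not in sel_set]
    if not sel or not other:
        raise ValueError("tajima_d_contrast: one of the gene groups is empty")
    u, p = mann_whitney_u(sel, other, alternative=alternative)
    return TajimaDContrast(
        median_selected=float(np.median(sel)),
        median_background=float(np.median(other)),
        u_statistic=u,
        p_value=p,
        n_selected=len(sel),
        n_background=len(other),
    )


def cdrs_to_bed(cdrs: pd.DataFrame, path) -> None:
    """Write CDRs as BED (0-based half-open) with n_windows/max_fst/max_ratio columns."""
    with open(path, "w") as fh:
        for r in cdrs.itertuples():
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_windows}"
                f"\t{r.max_fst:.6g}\t{r.max_log2_ratio:.6g}\n"
            )
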