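"""Sliding-window nucleotide diversity, Watterson's theta, Tajima's D and FST.

Conventions
-----------
* Windows are 1-based inclusive, start at 1 and advance by ``step`` bp
  (default 40-kb windows, 20-kb step); a trailing truncated window is
  emitted whenever the chromosome end is not yet covered, and is
  normalised by its true length.
* Per-bp values divide by the full window length, not callable sites
  (no accessibility mask is applied).
* Per site, with n genotyped chromosomes carrying a alt alleles,
  pi_site = 2*a*(n-a) / (n*(n-1)); a site is segregating iff 0 < a < n.
* Tajima's D follows the standard normalisation
  D = (sum pi_site - S/a1) / sqrt(e1*S + e2*S*(S-1)), with the constants
  evaluated at the window-median chromosome count (missingness can make n
  vary by site and D's constants need a single n).
* Window FST is ratio-of-sums: per-site variance components are summed
  across the window before the ratio is taken.  Weir & Cockerham (1984) is
  the default estimator; Hudson (as formulated by Bhatia et al. 2013) is
  selectable.  Negative estimates are reported as computed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import AlleleCounts, PopCounts

log = logging.getLogger(__name__)

FST_ESTIMATORS = ("weir_cockerham", "hudson")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``size`` bp windows every ``step`` bp."""

    size: int = 40_000
    step: int = 20_000

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError(f"need 0 < step <= size, got step={self.step}, size={self.size}")


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Enumerate sliding windows per chromosome.

    Starts are 1, 1+step, 1+2*step, ...; a window is emitted as long as the
    previous windows have not yet covered the chromosome end, and its end is
    clipped to the chromosome length.
    """
    rows = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has length {length}")
        k = 0
        covered = 0
        while covered < length:
            start = 1 + k * spec.step
            if start > length:
                break
            end = min(start + spec.size - 1, length)
            rows.append({"chrom": chrom, "start": start, "end": end})
            covered = end
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Tajima's D constants
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of the D normalisation for a sample of n chromosomes (n >= 2)."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


# ---------------------------------------------------------------------------
# Per-site building blocks
# ---------------------------------------------------------------------------

def _site_pi(n: np.ndarray, a: np.ndarray) -> np.ndarray:
    n = n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * a * (n - a) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def _segregating(n: np.ndarray, a: np.ndarray) -> np.ndarray:
    return (n >= 2) & (a > 0) & (a < n)


def hudson_site_components(p1: PopCounts, p2: PopCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of Hudson's FST, Bhatia et al. (2013).

    Sites with fewer than two genotyped chromosomes in either population
    contribute nothing; monomorphic sites contribute zero to both terms.
    """
    n1 = p1.n_chrom.astype(float)
    n2 = p2.n_chrom.astype(float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = p1.alt / n1
        f2 = p2.alt / n2
        num = (f1 - f2) ** 2 - f1 * (1 - f1) / (n1 - 1) - f2 * (1 - f2) / (n2 - 1)
        den = f1 * (1 - f2) + f2 * (1 - f1)
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)
    return num, den


def weir_cockerham_site_components(
    p1: PopCounts, p2: PopCounts
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (a, a+b+c) variance components of Weir & Cockerham (1984).

    Uses observed heterozygosity from the diploid genotypes (two populations,
    biallelic sites).  Sites where either population has no genotyped
    individual, or with a single individual overall, contribute nothing.
    """
    r = 2.0
    n1 = p1.n_chrom / 2.0  # genotyped individuals
    n2 = p2.n_chrom / 2.0
    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    n1 = np.where(valid, n1, 1.0)  # placeholder values; zeroed below
    n2 = np.where(valid, n2, 1.0)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = p1.alt / (2.0 * n1)
        f2 = p2.alt / (2.0 * n2)
        pbar = (n1 * f1 + n2 * f2) / (r * nbar)
        s2 = (n1 * (f1 - pbar) ** 2 + n2 * (f2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (p1.het + p2.het) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, a + b + c


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def _window_slices(
    counts: AlleleCounts, windows: pd.DataFrame
) -> list[tuple[int, int]]:
    """(lo, hi) site-index ranges per window row (sites are (chrom, pos)-sorted)."""
    out: list[tuple[int, int]] = []
    chrom_arr = counts.chrom.astype(str)
    pos = counts.pos
    # contiguous runs per chromosome
    bounds: dict[str, tuple[int, int]] = {}
    if len(pos):
        change = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(pos)]))
        bounds = {chrom_arr[s]: (int(s), int(e)) for s, e in zip(starts, ends)}
    for row in windows.itertuples():
        if str(row.chrom) not in bounds:
            out.append((0, 0))
            continue
        c_lo, c_hi = bounds[str(row.chrom)]
        p = pos[c_lo:c_hi]
        lo = c_lo + int(np.searchsorted(p, row.start, side="left"))
        hi = c_lo + int(np.searchsorted(p, row.end, side="right"))
        out.append((lo, hi))
    return out


def _diversity_from_slice(
    n: np.ndarray, a: np.ndarray, length: int
) -> tuple[int, float, float, float]:
    """(S, theta_pi, theta_w, tajimas_d) for the sites of one window."""
    if length <= 0:
        raise ValueError("window has non-positive length")
    seg = _segregating(n, a)
    S = int(seg.sum())
    if S == 0:
        return 0, 0.0, 0.0, math.nan
    n_seg = n[seg]
    sum_pi = float(_site_pi(n_seg, a[seg].astype(float)).sum())
    nbar = int(round(float(np.median(n_seg))))
    theta_pi = sum_pi / length
    if nbar < 2:
        return S, theta_pi, math.nan, math.nan
    a1, e1, e2 = tajima_constants(nbar)
    theta_w = S / (a1 * length)
    if nbar < 4:
        log.warning("window-median chromosome count %d < 4; Tajima's D not computed", nbar)
        return S, theta_pi, theta_w, math.nan
    d = (sum_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, theta_pi, theta_w, d


def window_diversity(
    counts: AlleleCounts,
    window: tuple[str, int, int],
    population: str,
) -> tuple[int, float, float, float]:
    """(S, theta_pi, theta_w, tajimas_d) of one population in one window."""
    chrom, start, end = window
    win = pd.DataFrame([{"chrom": chrom, "start": start, "end": end}])
    (lo, hi), = _window_slices(counts, win)
    pc = counts.pops[population]
    return _diversity_from_slice(pc.n_chrom[lo:hi], pc.alt[lo:hi], end - start + 1)


def window_fst(
    counts: AlleleCounts,
    window: tuple[str, int, int],
    pop_a: str,
    pop_b: str,
    estimator: str = "weir_cockerham",
) -> float:
    """Ratio-of-sums FST of one window; NaN when no site contributes."""
    if estimator not in FST_ESTIMATORS:
        raise ValueError(f"unknown FST estimator {estimator!r}; choose from {FST_ESTIMATORS}")
    chrom, start, end = window
    win = pd.DataFrame([{"chrom": chrom, "start": start, "end": end}])
    (lo, hi), = _window_slices(counts, win)
    fn = hudson_site_components if estimator == "hudson" else weir_cockerham_site_components
    num, den = fn(counts.pops[pop_a], counts.pops[pop_b])
    den_sum = float(den[lo:hi].sum())
    if den_sum == 0.0:
        return math.nan
    return float(num[lo:hi].sum() / den_sum)


def log2_pi_ratio(theta_pi_num: float, theta_pi_den: float) -> float:
    """log2 of a diversity ratio; NaN when either value is zero or undefined.

    With the numerator the wild population and the denominator the domestic
    one, positive values mark diversity loss in the domestic group.
    """
    if not (theta_pi_num > 0.0) or not (theta_pi_den > 0.0):
        return math.nan
    return math.log2(theta_pi_num / theta_pi_den)


def compute_window_stats(
    counts: AlleleCounts,
    windows: pd.DataFrame,
    populations: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    fst_estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Windowed statistics table for all populations and population pairs.

    ``pairs`` are (numerator, denominator) for the log2 diversity ratio —
    conventionally (wild, domestic) so positive ratios flag diversity loss in
    the denominator population.  Columns: chrom, start, end, n_snps (pooled
    segregating sites), then per population pi_/thetaw_/tajd_, then per pair
    fst_A_B and log2ratio_A_B.
    """
    if fst_estimator not in FST_ESTIMATORS:
        raise ValueError(f"unknown FST estimator {fst_estimator!r}; choose from {FST_ESTIMATORS}")
    if populations is None:
        populations = list(counts.pops)
    if pairs is None:
        pairs = (
            [(populations[0], populations[1])] if len(populations) >= 2 else []
        )
    slices = _window_slices(counts, windows)
    lengths = (windows["end"] - windows["start"] + 1).to_numpy()
    n_win = len(windows)

    pooled = counts.pooled(populations)
    pooled_seg = _segregating(pooled.n_chrom, pooled.alt)
    out: dict[str, np.ndarray] = {
        "chrom": windows["chrom"].to_numpy(),
        "start": windows["start"].to_numpy(),
        "end": windows["end"].to_numpy(),
        "n_snps": np.array(
            [int(pooled_seg[lo:hi].sum()) for lo, hi in slices], dtype=np.int64
        ),
    }

    div: dict[str, list[tuple[int, float, float, float]]] = {}
    for pop in populations:
        pc = counts.pops[pop]
        div[pop] = [
            _diversity_from_slice(pc.n_chrom[lo:hi], pc.alt[lo:hi], int(L))
            for (lo, hi), L in zip(slices, lengths)
        ]
        out[f"pi_{pop}"] = np.array([d[1] for d in div[pop]])
        out[f"thetaw_{pop}"] = np.array([d[2] for d in div[pop]])
        out[f"tajd_{pop}"] = np.array([d[3] for d in div[pop]])

    fn = (
        hudson_site_components
        if fst_estimator == "hudson"
        else weir_cockerham_site_components
    )
    for pa, pb in pairs:
        num, den = fn(counts.pops[pa], counts.pops[pb])
        cnum = np.concatenate(([0.0], np.cumsum(num)))
        cden = np.concatenate(([0.0], np.cumsum(den)))
        fst = np.full(n_win, np.nan)
        for w, (lo, hi) in enumerate(slices):
            d = cden[hi] - cden[lo]
            if d != 0.0:
                fst[w] = (cnum[hi] - cnum[lo]) / d
        out[f"fst_{pa}_{pb}"] = fst
        out[f"log2ratio_{pa}_{pb}"] = np.array(
            [
                log2_pi_ratio(out[f"pi_{pa}"][w], out[f"pi_{pb}"][w])
                for w in range(n_win)
            ]
        )
    return pd.DataFrame(out)
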