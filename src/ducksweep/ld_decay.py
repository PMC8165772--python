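"""Linkage-disequilibrium decay from unphased diploid dosages.

LD is measured as composite (Rogers-Huff) r-squared: the squared Pearson
correlation of diploid alt-allele dosages across samples, computed over
pairwise-complete samples.  It needs no phasing and converges to the
haplotype r^2 under random mating; its null expectation for unlinked loci is
1/(n-1) for n diploids.  The decay curve averages r^2 of all same-chromosome
SNP pairs within ``max_dist`` (default 500 kb), after a minor-allele-
frequency floor, binned by pair distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDConfig:
    """Pair-distance cap, MAF floor and distance-bin width of the decay curve."""

    max_dist: int = 500_000
    maf_min: float = 0.05
    bin_width: int = 1_000

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def pair_r2(dosages_a, dosages_b) -> float:
    """Composite r^2 between two dosage vectors (missing coded -1 or NaN).

    NaN when either locus is monomorphic among the pairwise-complete samples;
    error when fewer than two samples are complete at both loci.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dosage vectors differ in length: {a.shape} vs {b.shape}")
    ok = ~np.isnan(a) & ~np.isnan(b) & (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    x = a[ok]
    y = b[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _maf_mask(d: np.ndarray, maf_min: float) -> np.ndarray:
    """Keep polymorphic sites with minor-allele frequency >= maf_min (rows of d)."""
    present = d != MISSING
    n_chrom = 2.0 * present.sum(axis=1)
    alt = np.where(present, d, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_chrom
    maf = np.minimum(p, 1.0 - p)
    return (n_chrom >= 4) & (maf >= maf_min) & (p > 0.0) & (p < 1.0)


def decay_curve(
    gm: GenotypeMatrix,
    population: str | None = None,
    popmap: PopulationMap | None = None,
    cfg: LDConfig = LDConfig(),
) -> pd.DataFrame:
    """Mean composite r^2 by pair distance, averaged over the whole genome.

    All same-chromosome SNP pairs with distance <= max_dist and both MAF >=
    maf_min contribute; pairs are binned as (k*bin_width, (k+1)*bin_width]
    and empty bins are omitted.  Restrict to one population by passing
    ``population`` together with ``popmap``.
    """
    if population is not None:
        if popmap is None:
            raise ValueError("popmap is required when a population is given")
        idx = gm.sample_indices(popmap.samples_for(population))
    else:
        idx = np.arange(gm.n_samples)
    if len(idx) < 2:
        raise ValueError("LD needs at least 2 samples")

    sums: dict[int, float] = {}
    npairs: dict[int, int] = {}
    for chrom, group in gm.sites.groupby("chrom", sort=True):
        rows = group.index.to_numpy()
        d = gm.dosages[np.ix_(rows, idx)].astype(float)
        keep = _maf_mask(d.astype(np.int8), cfg.maf_min)
        d = d[keep]
        pos = group["pos"].to_numpy()[keep]
        if len(pos) < 2:
            continue
        has_missing = bool((d == MISSING).any())
        if not has_missing:
            centered = d - d.mean(axis=1, keepdims=True)
            norms = np.sqrt((centered**2).sum(axis=1))
        for i in range(len(pos) - 1):
            hi = int(np.searchsorted(pos, pos[i] + cfg.max_dist, side="right"))
            if hi <= i + 1:
                continue
            dists = pos[i + 1 : hi] - pos[i]
            if has_missing:
                r2 = np.array(
                    [pair_r2(d[i], d[j]) for j in range(i + 1, hi)], dtype=float
                )
            else:
                dots = centered[i + 1 : hi] @ centered[i]
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = (dots / (norms[i] * norms[i + 1 : hi])) ** 2
            ok = ~np.isnan(r2)
            bins = (dists[ok] - 1) // cfg.bin_width
            for b, v in zip(bins, r2[ok]):
                b = int(b)
                sums[b] = sums.get(b, 0.0) + float(v)
                npairs[b] = npairs.get(b, 0) + 1

    rows = [
        {
            "dist_lo": b * cfg.bin_width,
            "dist_hi": (b + 1) * cfg.bin_width,
            "mean_r2": sums[b] / npairs[b],
            "n_pairs": npairs[b],
        }
        for b in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "mean_r2", "n_pairs"])
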