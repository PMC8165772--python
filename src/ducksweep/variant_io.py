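"""Genotype matrices from multi-sample VCFs: reading, site filtering, allele counts.

The in-memory substrate for the whole pipeline is a :class:`GenotypeMatrix`
holding per-site metadata (a pandas DataFrame) plus an int8 dosage table of
alternate-allele counts per diploid sample (0/1/2, ``-1`` for a missing
genotype).  All coordinates are 1-based inclusive, as in VCF; BED interchange
converts to 0-based half-open at the boundary.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: sentinel for a missing diploid genotype in the dosage table
MISSING = -1

_BASES = frozenset("ACGT")

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "depth", "n_alt"]


@dataclass(frozen=True)
class SiteFilterConfig:
    """Hard site filters: phred site quality and aggregate read depth.

    Defaults mirror a resequencing-grade SAMtools mpileup callset filter
    (QUAL >= 20, 2 <= DP <= 1000, biallelic SNPs only).  Depth is the
    site-level aggregate DP, not per-sample depth.
    """

    min_qual: float = 20.0
    min_depth: int = 2
    max_depth: int = 1000
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError(
                f"min_depth ({self.min_depth}) must be <= max_depth ({self.max_depth})"
            )
        if self.min_qual < 0:
            raise ValueError(f"min_qual must be >= 0, got {self.min_qual}")


class PopulationMap:
    """Sample -> population assignment (each sample has exactly one label)."""

    def __init__(self, assignments: dict[str, str]):
        if not assignments:
            raise ValueError("population map is empty")
        self._assignments = dict(assignments)
        pops: list[str] = []
        for p in self._assignments.values():
            if p not in pops:
                pops.append(p)
        self._populations = pops

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a 2-column TSV of (sample, population). Lines starting with '#' are ignored."""
        assignments: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
        return cls(assignments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self._assignments.items():
                fh.write(f"{sample}\t{pop}\n")

    @property
    def samples(self) -> list[str]:
        return list(self._assignments)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(self._populations)

    def samples_for(self, population: str) -> list[str]:
        out = [s for s, p in self._assignments.items() if p == population]
        if not out:
            raise KeyError(f"no samples assigned to population {population!r}")
        return out

    def __getitem__(self, sample: str) -> str:
        return self._assignments[sample]

    def __len__(self) -> int:
        return len(self._assignments)

    def __contains__(self, sample: str) -> bool:
        return sample in self._assignments

    def items(self):
        return self._assignments.items()


@dataclass
class GenotypeMatrix:
    """Per-site, per-sample diploid alt-allele dosages with missingness.

    ``sites`` columns: chrom, pos, ref, alt, qual, depth, n_alt.  Sites are
    sorted by (chrom, pos) with no duplicates.  ``dosages`` is int8 of shape
    (n_sites, n_samples); entries are 0/1/2 or :data:`MISSING`.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=np.intp)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site positions (boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosages=self.dosages[index],
            samples=list(self.samples),
            chrom_lengths=dict(self.chrom_lengths),
        )

    def validate(self) -> None:
        if list(self.sites.columns) != SITE_COLUMNS:
            raise ValueError(f"sites columns must be {SITE_COLUMNS}")
        if self.dosages.shape != (self.n_sites, self.n_samples):
            raise ValueError("dosage table shape does not match sites/samples")
        d = self.dosages
        if d.size and not np.all((d == MISSING) | ((d >= 0) & (d <= 2))):
            raise ValueError("dosages must be in {0,1,2} or missing")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        srt = key.sort_values(["chrom", "pos"], kind="mergesort")
        if not (srt.index == np.arange(len(key))).all():
            raise ValueError("sites are not sorted by (chrom, pos)")

    @classmethod
    def from_arrays(
        cls,
        chrom,
        pos,
        dosages,
        samples,
        ref=None,
        alt=None,
        qual=None,
        depth=None,
        n_alt=None,
        chrom_lengths=None,
    ) -> "GenotypeMatrix":
        """Build a matrix from plain arrays; convenience for tests and simulation."""
        n = len(pos)
        chrom = np.asarray(chrom, dtype=object)
        if chrom.shape == ():
            chrom = np.full(n, str(chrom), dtype=object)
        sites = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.asarray(pos, dtype=np.int64),
                "ref": np.asarray(ref, dtype=object) if ref is not None else np.full(n, "A", dtype=object),
                "alt": np.asarray(alt, dtype=object) if alt is not None else np.full(n, "T", dtype=object),
                "qual": np.asarray(qual, dtype=float) if qual is not None else np.full(n, 60.0),
                "depth": np.asarray(depth, dtype=float) if depth is not None else np.full(n, 100.0),
                "n_alt": np.asarray(n_alt, dtype=np.int64) if n_alt is not None else np.ones(n, dtype=np.int64),
            }
        )
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy().astype(str)))
        sites = sites.iloc[order].reset_index(drop=True)
        dosages = np.asarray(dosages, dtype=np.int8)[order]
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(g["pos"].max()) for c, g in sites.groupby("chrom", sort=True)
            }
        gm = cls(sites=sites, dosages=dosages, samples=list(samples), chrom_lengths=dict(chrom_lengths))
        gm.validate()
        return gm


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Read SNP records from a VCF into a :class:`GenotypeMatrix`.

    Only records whose REF and every ALT are single bases are retained
    (indels and symbolic alleles are skipped and counted).  Multiallelic SNP
    records are retained with ``n_alt > 1`` so that the biallelic filter in
    :func:`apply_site_filters` can drop them explicitly; their dosages count
    any non-reference allele.

    Raises if a record lacks GT, or if ``popmap`` names samples absent from
    the header.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if popmap is not None:
        absent = [s for s in popmap.samples if s not in samples]
        if absent:
            raise ValueError(f"{path}: samples in population map absent from VCF header: {absent}")

    contig_lengths: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            contig_lengths[name] = int(length)
    except AttributeError:  # no ##contig headers
        pass

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    depth: list[float] = []
    n_alt: list[int] = []
    dosage_rows: list[np.ndarray] = []
    n_skipped = 0

    for v in vcf:
        alts = v.ALT
        if (
            len(v.REF) != 1
            or v.REF not in _BASES
            or not alts
            or any(len(a) != 1 or a not in _BASES for a in alts)
        ):
            n_skipped += 1
            continue
        if "GT" not in (v.FORMAT or []):
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} has no GT field")
        gt = np.asarray(v.gt_types)  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        row = np.where(gt == 3, MISSING, gt).astype(np.int8)
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(alts[0])
        qual.append(float(v.QUAL) if v.QUAL is not None else np.nan)
        dp = v.INFO.get("DP")
        depth.append(float(dp) if dp is not None else np.nan)
        n_alt.append(len(alts))
        dosage_rows.append(row)

    if n_skipped:
        log.info("read_vcf: skipped %d non-SNP record(s) in %s", n_skipped, path)
    if not dosage_rows:
        raise ValueError(f"{path}: no SNP records found")

    dosages = np.vstack(dosage_rows)
    chrom_lengths = dict(contig_lengths)
    if not chrom_lengths:
        tmp = pd.DataFrame({"chrom": chroms, "pos": pos})
        chrom_lengths = {c: int(g["pos"].max()) for c, g in tmp.groupby("chrom")}

    return GenotypeMatrix.from_arrays(
        chrom=np.asarray(chroms, dtype=object),
        pos=pos,
        dosages=dosages,
        samples=samples,
        ref=ref,
        alt=alt,
        qual=qual,
        depth=depth,
        n_alt=n_alt,
        chrom_lengths=chrom_lengths,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a biallelic genotype matrix as a minimal VCF 4.2 with QUAL, INFO/DP and GT."""
    if (gm.sites["n_alt"] > 1).any():
        raise ValueError("write_vcf only supports biallelic matrices")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in gm.chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    sites = gm.sites
    for i in range(gm.n_sites):
        row = sites.iloc[i]
        q = "." if np.isnan(row.qual) else f"{row.qual:g}"
        info = "." if np.isnan(row.depth) else f"DP={int(row.depth)}"
        gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[i])
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{q}\tPASS\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def apply_site_filters(gm: GenotypeMatrix, cfg: SiteFilterConfig = SiteFilterConfig()) -> GenotypeMatrix:
    """Retain sites with QUAL >= min_qual, min_depth <= DP <= max_depth and
    (optionally) exactly one ALT allele.  Order-preserving and idempotent;
    sites with missing QUAL or DP fail the corresponding test."""
    if gm.n_sites == 0:
        raise ValueError("apply_site_filters: empty genotype matrix")
    s = gm.sites
    qual = s["qual"].to_numpy()
    depth = s["depth"].to_numpy()
    keep = (qual >= cfg.min_qual) & (depth >= cfg.min_depth) & (depth <= cfg.max_depth)
    if cfg.biallelic_only:
        keep &= s["n_alt"].to_numpy() == 1
    keep &= ~np.isnan(qual) & ~np.isnan(depth)
    out = gm.take_sites(keep)
    if out.n_sites == 0:
        log.warning("apply_site_filters: no sites passed the filters")
    else:
        log.info("apply_site_filters: %d of %d sites retained", out.n_sites, gm.n_sites)
    return out


# ---------------------------------------------------------------------------
# Per-population allele counts
# ---------------------------------------------------------------------------

@dataclass
class PopCounts:
    """Per-site counts for one population: chromosomes genotyped, alt alleles, het genotypes."""

    n_chrom: np.ndarray
    alt: np.ndarray
    het: np.ndarray


@dataclass
class AlleleCounts:
    """Per-site, per-population allele counts; the substrate for diversity and FST."""

    chrom: np.ndarray
    pos: np.ndarray
    pops: dict[str, PopCounts]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pooled(self, populations: list[str] | None = None) -> PopCounts:
        """Counts summed over populations (all of them by default)."""
        pops = populations if populations is not None else list(self.pops)
        n = sum(self.pops[p].n_chrom for p in pops)
        a = sum(self.pops[p].alt for p in pops)
        h = sum(self.pops[p].het for p in pops)
        return PopCounts(n_chrom=n, alt=a, het=h)


def population_allele_counts(gm: GenotypeMatrix, popmap: PopulationMap) -> AlleleCounts:
    """Count, per site and population, genotyped chromosomes (2 x non-missing
    samples), alt alleles (sum of dosages) and heterozygous genotypes."""
    uncovered = [s for s in gm.samples if s not in popmap]
    if uncovered:
        raise ValueError(f"samples without population assignment: {uncovered}")
    pops: dict[str, PopCounts] = {}
    for pop in popmap.populations:
        idx = gm.sample_indices(popmap.samples_for(pop))
        d = gm.dosages[:, idx]
        present = d != MISSING
        pops[pop] = PopCounts(
            n_chrom=2 * present.sum(axis=1).astype(np.int64),
            alt=np.where(present, d, 0).sum(axis=1).astype(np.int64),
            het=(d == 1).sum(axis=1).astype(np.int64),
        )
    return AlleleCounts(
        chrom=gm.sites["chrom"].to_numpy(),
        pos=gm.sites["pos"].to_numpy(),
        pops=pops,
    )


def count_shared_private(gm: GenotypeMatrix, popmap: PopulationMap) -> dict[tuple[str, ...], int]:
    """SNP presence table over population subsets.

    A SNP is *present* in a population iff at least one alt allele is observed
    there.  Returns ``{subset-of-populations: count}`` for every non-empty
    subset, where each SNP is assigned to the exact subset of populations it
    is present in; subsets therefore partition the segregating sites, and the
    full-population key is the "common to all populations" count.
    """
    populations = popmap.populations
    if len(populations) < 2:
        raise ValueError("count_shared_private needs >= 2 populations")
    counts = population_allele_counts(gm, popmap)
    present = np.stack([counts.pops[p].alt >= 1 for p in populations], axis=1)
    table: dict[tuple[str, ...], int] = {
        tuple(subset): 0
        for r in range(1, len(populations) + 1)
        for subset in itertools.combinations(populations, r)
    }
    anywhere = present.any(axis=1)
    for row in present[anywhere]:
        key = tuple(p for p, flag in zip(populations, row) if flag)
        table[key] += 1
    return table


def shared_private_to_frame(table: dict[tuple[str, ...], int]) -> pd.DataFrame:
    """Presence table as a tidy DataFrame (populations joined by ',')."""
    return pd.DataFrame(
        {"populations": [",".join(k) for k in table], "n_snps": list(table.values())}
    )
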