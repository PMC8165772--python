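"""Coalescent simulation of two-population diploid SNP panels with planted sweeps.

Each 40-kb window of the simulated chromosome is an independent
non-recombining locus: a genealogy is drawn under the chosen demographic
model (single deme, clean split, or symmetric island), infinite-sites
mutations are dropped on it at rate ``mu`` per bp per generation, and
chromosomes are paired into diploids.  Windows designated as *swept* replace
the within-deme genealogy of the target deme with a star genealogy whose
lineages all coalesce at time ``tau``, giving the closed-form sweep
signature: expected pairwise diversity ``2*mu*tau`` per bp, strongly
negative Tajima's D (all within-deme variants are singletons), and elevated
FST against the other deme.

Time is measured in generations (one generation = one year for this system),
with a diploid effective size ``Ne`` per deme, so a sample of two chromosomes
in one deme coalesces at rate 1/(2*Ne) and E[TMRCA] = 2*Ne.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, PopulationMap, write_vcf

log = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class LocusSaturatedError(RuntimeError):
    """More infinite-sites mutations than available positions; lower theta or enlarge the locus."""


@dataclass(frozen=True)
class CoalescentParams:
    """Demographic and mutational parameters of the generator.

    Defaults are the neutral background of the emulated study system: a
    per-generation mutation rate of 1.6e-9 per bp and Ne = 78125 diploids so
    that theta = 4*Ne*mu = 5e-4 per bp, with ten diploid samples per
    population and a two-deme clean split ``split_time`` generations ago
    (default 0.2*Ne, i.e. expected Hudson FST of about 0.09, the order of the
    background differentiation in a wild/domestic contrast).
    """

    ne: float = 78_125.0
    mu: float = 1.6e-9
    samples_per_pop: tuple[int, ...] = (10, 10)
    model: str = "split"  # single_deme | split | island
    split_time: float | None = None  # generations; defaults to 0.2 * ne for the split model
    migration_rate: float = 0.0  # per lineage per generation (island model)
    chrom_length: int = 4_000_000
    window_size: int = 40_000
    chrom_name: str = "chr1"
    pop_names: tuple[str, ...] = ("wild", "domestic")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.mu < 0:
            raise ValueError("ne must be > 0 and mu >= 0")
        if self.model not in {"single_deme", "split", "island"}:
            raise ValueError(f"unknown model {self.model!r}")
        n_demes = 1 if self.model == "single_deme" else 2
        if len(self.samples_per_pop) != n_demes:
            raise ValueError(
                f"model {self.model!r} needs {n_demes} sample count(s), got {self.samples_per_pop}"
            )
        if any(n < 1 for n in self.samples_per_pop):
            raise ValueError("samples_per_pop entries must be >= 1")
        if self.model == "island" and self.migration_rate <= 0:
            raise ValueError("island model requires migration_rate > 0 (lineages could never coalesce)")
        if self.split_time is not None and self.split_time < 0:
            raise ValueError("split_time must be >= 0")

    @property
    def theta(self) -> float:
        """Population mutation rate 4*Ne*mu per bp."""
        return 4.0 * self.ne * self.mu

    @property
    def resolved_split_time(self) -> float:
        if self.split_time is not None:
            return self.split_time
        return 0.2 * self.ne


@dataclass(frozen=True)
class SweepSpec:
    """Genomic intervals forced to a star genealogy at time ``tau`` in one deme.

    ``tau`` defaults (via :func:`default_sweep_spec`) to 0.02 * 2Ne, i.e. a
    very recent, strong sweep: expected within-deme diversity 2*mu*tau is 2%
    of the neutral theta.
    """

    intervals: tuple[tuple[int, int], ...]  # 1-based inclusive
    tau: float
    deme: int = 1

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for s, e in self.intervals:
            if s < 1 or e < s:
                raise ValueError(f"bad sweep interval ({s}, {e})")


def default_sweep_spec(
    params: CoalescentParams,
    n_regions: int = 10,
    region_windows: int = 5,
    tau: float | None = None,
    deme: int = 1,
) -> SweepSpec:
    """Evenly spaced window-aligned sweep regions.

    By default 10 regions of five consecutive 40-kb windows (200 kb each),
    sized to the merged-CDR scale of resequencing sweep scans, with
    tau = 0.02 * 2Ne.
    """
    w = params.window_size
    n_windows = params.chrom_length // w
    span_w = n_regions * region_windows
    if span_w > n_windows:
        raise ValueError("sweep regions do not fit in the chromosome")
    gap = n_windows // n_regions
    intervals = []
    for k in range(n_regions):
        start_w = k * gap
        intervals.append((start_w * w + 1, (start_w + region_windows) * w))
    return SweepSpec(
        intervals=tuple(intervals),
        tau=tau if tau is not None else 0.02 * 2.0 * params.ne,
        deme=deme,
    )


@dataclass
class SimulatedDataset:
    """File bundle produced by :func:`simulate_dataset`."""

    vcf: Path
    popmap: Path
    fasta: Path
    genes_bed: Path
    truth: Path
    truth_table: pd.DataFrame
    params: CoalescentParams


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

class Genealogy:
    """A (possibly multifurcating) coalescent tree with node times in generations."""

    def __init__(self, n_leaves: int):
        self.n_leaves = n_leaves
        self.times: list[float] = [0.0] * n_leaves
        self.children: list[list[int]] = [[] for _ in range(n_leaves)]
        self.root: int | None = None

    def add_node(self, time: float, children: list[int]) -> int:
        self.times.append(time)
        self.children.append(list(children))
        return len(self.times) - 1

    def leaf_masks(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix of the leaves below each node."""
        n = len(self.times)
        masks = np.zeros((n, self.n_leaves), dtype=bool)
        masks[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for node in range(self.n_leaves, n):  # children are always created before parents
            for c in self.children[node]:
                masks[node] |= masks[c]
        return masks

    def branches(self) -> tuple[np.ndarray, np.ndarray]:
        """(node ids, branch lengths) for every non-root node."""
        parent = np.full(len(self.times), -1, dtype=np.int64)
        for node, kids in enumerate(self.children):
            for c in kids:
                parent[c] = node
        nodes = np.flatnonzero(parent >= 0)
        times = np.asarray(self.times)
        lengths = times[parent[nodes]] - times[nodes]
        return nodes, lengths

    @property
    def total_branch_length(self) -> float:
        return float(self.branches()[1].sum())

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])


def _coalesce_within(
    tree: Genealogy,
    lineages: list[int],
    t0: float,
    two_ne: float,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> tuple[list[int], float]:
    """Kingman coalescent within one deme from time t0, optionally capped at t_max."""
    t = t0
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / two_ne
        t_next = t + rng.exponential(1.0 / rate)
        if t_max is not None and t_next > t_max:
            return lineages, t_max
        t = t_next
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node = tree.add_node(t, [lineages[i], lineages[j]])
        del lineages[j], lineages[i]
        lineages.append(node)
    return lineages, t


def simulate_genealogy(
    params: CoalescentParams,
    rng: np.random.Generator,
    sweep_tau: float | None = None,
    sweep_deme: int = 1,
) -> Genealogy:
    """Draw one genealogy for all sampled chromosomes under the demographic model.

    With ``sweep_tau`` set, the target deme's lineages are forced into a
    single star coalescence at ``tau`` (supported for the single-deme and
    split models; the star ancestor then behaves as one ordinary lineage).
    """
    sizes = [2 * n for n in params.samples_per_pop]
    n_leaves = sum(sizes)
    tree = Genealogy(n_leaves)
    two_ne = 2.0 * params.ne
    demes: list[list[int]] = []
    start = 0
    for sz in sizes:
        demes.append(list(range(start, start + sz)))
        start += sz

    def star(deme_lineages: list[int], tau: float) -> list[int]:
        if len(deme_lineages) == 1:
            return list(deme_lineages)
        return [tree.add_node(tau, deme_lineages)]

    if params.model == "single_deme":
        lineages = demes[0]
        t = 0.0
        if sweep_tau is not None:
            lineages, t = star(lineages, sweep_tau), sweep_tau
        lineages, t = _coalesce_within(tree, lineages, t, two_ne, rng)
        tree.root = lineages[0]
        return tree

    if params.model == "split":
        t_split = params.resolved_split_time
        if sweep_tau is not None and sweep_tau > t_split:
            raise ValueError("sweep tau must not exceed the split time")
        remaining: list[int] = []
        for d, lineages in enumerate(demes):
            t = 0.0
            if sweep_tau is not None and d == sweep_deme:
                lineages, t = star(lineages, sweep_tau), sweep_tau
            lineages, _ = _coalesce_within(tree, lineages, t, two_ne, rng, t_max=t_split)
            remaining.extend(lineages)
        merged, _ = _coalesce_within(tree, remaining, t_split, two_ne, rng)
        tree.root = merged[0]
        return tree

    # island model: within-deme coalescence interleaved with symmetric migration
    if sweep_tau is not None:
        raise ValueError("planted sweeps are not supported under the island model")
    m = params.migration_rate
    t = 0.0
    while sum(len(d) for d in demes) > 1:
        k_total = sum(len(d) for d in demes)
        coal_rates = [len(d) * (len(d) - 1) / 2.0 / two_ne for d in demes]
        mig_rate = m * k_total
        total = sum(coal_rates) + mig_rate
        t += rng.exponential(1.0 / total)
        u = rng.uniform(0.0, total)
        if u < coal_rates[0] + coal_rates[1]:
            d = 0 if u < coal_rates[0] else 1
            lineages = demes[d]
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            node = tree.add_node(t, [lineages[i], lineages[j]])
            del lineages[j], lineages[i]
            lineages.append(node)
        else:
            flat = [(d, i) for d in (0, 1) for i in range(len(demes[d]))]
            d, i = flat[rng.integers(len(flat))]
            demes[1 - d].append(demes[d].pop(i))
    tree.root = (demes[0] + demes[1])[0]
    return tree


# ---------------------------------------------------------------------------
# Mutation dropping (infinite sites)
# ---------------------------------------------------------------------------

def mutate_genealogy(
    tree: Genealogy,
    mu: float,
    locus_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop Poisson(total branch length * mu * L) mutations on the genealogy.

    Returns ``(positions, haplotypes)`` where positions are distinct 1-based
    offsets within the locus (sorted) and haplotypes is a uint8 matrix of
    shape (n_mutations, n_chromosomes) with 1 marking the derived allele.
    """
    nodes, lengths = tree.branches()
    total = float(lengths.sum())
    n_mut = rng.poisson(total * mu * locus_length)
    if n_mut > locus_length:
        raise LocusSaturatedError(
            f"{n_mut} mutations for a {locus_length}-bp locus; reduce theta or enlarge the locus"
        )
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, tree.n_leaves), dtype=np.uint8)
    positions = np.sort(rng.choice(locus_length, size=n_mut, replace=False)) + 1
    branch_idx = rng.choice(len(nodes), size=n_mut, p=lengths / total)
    masks = tree.leaf_masks()
    haplotypes = masks[nodes[branch_idx]].astype(np.uint8)
    return positions, haplotypes


# ---------------------------------------------------------------------------
# Whole-dataset assembly
# ---------------------------------------------------------------------------

def _window_grid(chrom_length: int, window_size: int) -> list[tuple[int, int]]:
    """Non-overlapping locus tiling (1-based inclusive); the last tile may be short."""
    out = []
    start = 1
    while start <= chrom_length:
        out.append((start, min(start + window_size - 1, chrom_length)))
        start += window_size
    return out


def _window_swept(window: tuple[int, int], sweep: SweepSpec | None) -> bool:
    if sweep is None:
        return False
    s, e = window
    return any(s <= ie and ss <= e for ss, ie in sweep.intervals)


def simulate_genotype_matrix(
    params: CoalescentParams,
    sweep: SweepSpec | None = None,
    rng: np.random.Generator | None = None,
    depth_range: tuple[int, int] = (100, 400),
    qual: float = 60.0,
    contaminate: float = 0.0,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame, np.ndarray]:
    """Simulate the full panel in memory.

    Returns ``(matrix, popmap, truth_table, reference_codes)`` where
    reference_codes is the uint8-coded (0..3 = ACGT) reference sequence and
    the truth table records, per 40-kb locus, whether it was swept and its
    expected per-bp diversity in the (swept) deme.  ``contaminate`` is the
    fraction of sites given deliberately filter-failing QUAL or DP, for
    exercising the site filters.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if sweep is not None:
        if params.model == "single_deme" and sweep.deme != 0:
            raise ValueError("single-deme model has only deme 0")
        for s, e in sweep.intervals:
            if e > params.chrom_length:
                raise ValueError(f"sweep interval ({s}, {e}) outside chromosome of length {params.chrom_length}")

    ref_codes = rng.integers(0, 4, size=params.chrom_length, dtype=np.uint8)
    windows = _window_grid(params.chrom_length, params.window_size)

    all_pos: list[np.ndarray] = []
    all_dos: list[np.ndarray] = []
    truth_rows = []
    n_dip = sum(params.samples_per_pop)
    for (wstart, wend) in windows:
        swept = _window_swept((wstart, wend), sweep)
        tree = simulate_genealogy(
            params,
            rng,
            sweep_tau=sweep.tau if swept else None,
            sweep_deme=sweep.deme if swept else 1,
        )
        positions, haps = mutate_genealogy(tree, params.mu, wend - wstart + 1, rng)
        dosages = (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)  # chromosomes paired within deme
        all_pos.append(positions + wstart - 1)
        all_dos.append(dosages)
        truth_rows.append(
            {
                "chrom": params.chrom_name,
                "start": wstart,
                "end": wend,
                "swept": swept,
                "true_theta": 2.0 * params.mu * sweep.tau if swept else params.theta,
            }
        )

    pos = np.concatenate(all_pos)
    dosages = (
        np.concatenate(all_dos, axis=0) if pos.size else np.empty((0, n_dip), dtype=np.int8)
    )
    n_sites = len(pos)

    ref_idx = ref_codes[pos - 1]
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = np.frombuffer(_BASE_BYTES.tobytes(), dtype="S1")[ref_idx].astype("U1").astype(object)
    alt = np.frombuffer(_BASE_BYTES.tobytes(), dtype="S1")[alt_idx].astype("U1").astype(object)
    quals = np.full(n_sites, qual)
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_sites).astype(float)

    if contaminate > 0:
        n_bad = int(round(contaminate * n_sites))
        bad = rng.choice(n_sites, size=n_bad, replace=False)
        mode = rng.integers(0, 3, size=n_bad)
        quals[bad[mode == 0]] = rng.uniform(0.0, 19.9, size=(mode == 0).sum())
        depths[bad[mode == 1]] = 1.0
        depths[bad[mode == 2]] = 1001.0 + rng.integers(0, 100, size=(mode == 2).sum())

    sample_names: list[str] = []
    assignments: dict[str, str] = {}
    for pop_i, n in enumerate(params.samples_per_pop):
        pop = params.pop_names[pop_i]
        for k in range(n):
            name = f"{pop}_{k + 1:02d}"
            sample_names.append(name)
            assignments[name] = pop
    popmap = PopulationMap(assignments)

    gm = GenotypeMatrix.from_arrays(
        chrom=params.chrom_name,
        pos=pos,
        dosages=dosages,
        samples=sample_names,
        ref=ref,
        alt=alt,
        qual=quals,
        depth=depths,
        chrom_lengths={params.chrom_name: params.chrom_length},
    )
    truth = pd.DataFrame(truth_rows)
    return gm, popmap, truth, ref_codes


def make_gene_bed(
    chrom: str,
    chrom_length: int,
    spacing: int = 50_000,
    offset: int = 20_000,
    gene_length: int = 4_998,
) -> pd.DataFrame:
    """Single-exon, fully coding genes tiled every ``spacing`` bp (1-based coords).

    Gene length defaults to 4998 bp so the CDS is a whole number of codons;
    strands alternate so both orientations are exercised downstream.
    """
    rows = []
    k = 0
    while True:
        start = k * spacing + offset + 1
        end = start + gene_length - 1
        if end > chrom_length:
            break
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "gene_id": f"gene{k + 1:04d}",
                "strand": "+" if k % 2 == 0 else "-",
            }
        )
        k += 1
    return pd.DataFrame(rows)


def _write_bed12(genes: pd.DataFrame, path: Path) -> None:
    lines = []
    for r in genes.itertuples():
        start0, end0 = r.start - 1, r.end
        size = r.end - r.start + 1
        lines.append(
            f"{r.chrom}\t{start0}\t{end0}\t{r.gene_id}\t0\t{r.strand}"
            f"\t{start0}\t{end0}\t0\t1\t{size},\t0,"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_fasta(chrom: str, ref_codes: np.ndarray, path: Path, width: int = 70) -> None:
    seq = _BASE_BYTES[ref_codes].tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def simulate_dataset(
    params: CoalescentParams,
    outdir: str | Path,
    sweep: SweepSpec | None = None,
    seed: int | None = None,
    contaminate: float = 0.0,
) -> SimulatedDataset:
    """Simulate and write the full file bundle: VCF, popmap TSV, reference
    FASTA, gene BED12 and the per-window truth table.  Fully reproducible from
    the seed (``seed`` argument overrides ``params.seed``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    gm, popmap, truth, ref_codes = simulate_genotype_matrix(
        params, sweep=sweep, rng=rng, contaminate=contaminate
    )

    vcf_path = outdir / "sim.vcf"
    popmap_path = outdir / "popmap.tsv"
    fasta_path = outdir / "reference.fa"
    bed_path = outdir / "genes.bed"
    truth_path = outdir / "truth.tsv"

    write_vcf(gm, vcf_path)
    popmap.to_tsv(popmap_path)
    _write_fasta(params.chrom_name, ref_codes, fasta_path)
    genes = make_gene_bed(params.chrom_name, params.chrom_length)
    _write_bed12(genes, bed_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    log.info(
        "simulate_dataset: %d sites, %d samples, %d swept window(s) -> %s",
        gm.n_sites,
        gm.n_samples,
        int(truth["swept"].sum()),
        outdir,
    )
    return SimulatedDataset(
        vcf=vcf_path,
        popmap=popmap_path,
        fasta=fasta_path,
        genes_bed=bed_path,
        truth=truth_path,
        truth_table=truth,
        params=params,
    )
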