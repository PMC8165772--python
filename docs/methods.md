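# Methods

## The problem and the approach

Domestication scans compare a domesticated population against its wild
relatives and look for genomic windows where the domestic group has both
unusually high differentiation (F<sub>ST</sub>) and unusually low diversity
relative to the wild group (high log₂ θ<sub>π</sub> ratio) — the joint
signature of a selective sweep.  ducksweep implements that scan end to end
(VCF → filtered genotype matrix → windowed statistics → joint outliers →
merged candidate regions → gene lists and a Tajima's D contrast), together
with the accompanying descriptive analyses (SNP annotation, LD decay, an
individual-level NJ tree), and a coalescent generator that produces data
with known truth so the whole chain is testable.

## Statistics

All coordinates are 1-based inclusive internally; BED interchange converts
at the boundary.  Windows are 40 kb advancing by 20 kb by default; a
trailing truncated window is emitted whenever the chromosome end is not yet
covered and is normalised by its true length (silently dropping chromosome
ends would bias nothing but lose signal).  Per-bp values divide by the full
window length, not callable sites — no accessibility mask is applied, which
matches how genome-wide per-bp diversity is usually reported for
resequencing panels but slightly deflates diversity where callability is
poor; this is a documented limitation.

Per site with `n` genotyped chromosomes and `a` alternate alleles:

* π_site = 2a(n−a)/(n(n−1)); a site is segregating iff 0 < a < n.
* θ<sub>π</sub> = Σ π_site / L;  θ<sub>W</sub> = S/(a₁L), a₁ = Σ_{i<n} 1/i.
* Tajima's D = (Σπ_site − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants.  Missing genotypes make `n` vary by site while D's constants
  need a single n, so the constants are evaluated at the window-median
  chromosome count (robust to a few low-coverage sites); D is missing when
  S = 0 or the median count is below 4.
* F<sub>ST</sub> is ratio-of-sums: per-site variance components are summed
  over the window before dividing, the standard windowed ("weighted")
  convention in resequencing scans.  Weir–Cockerham (1984) with observed
  heterozygosity is the default; Hudson's estimator in the Bhatia et al.
  (2013) form is selectable.  Monomorphic sites contribute nothing;
  windows with no informative site are missing; negative estimates are
  reported as computed (clamping is presentation, not estimation).
* log₂ ratio = log₂(θ<sub>π,wild</sub>/θ<sub>π,domestic</sub>), missing when
  either diversity is zero; positive values mean diversity loss in the
  domestic group.

Mean Tajima's D across neutral single-genealogy 40-kb windows is not
exactly zero: for n = 20 chromosomes it sits near −0.10 (we verified the
same value with msprime/tskit), a finite-sample property of the
normalisation, not an estimator defect.

## The sweep scan

Thresholds are empirical quantiles (numpy's linear/"type 7" definition) of
the windowed F<sub>ST</sub> and log₂ ratio, computed over windows where both
are defined — they are properties of the data, which is why the pipeline
always reports the realized cutoffs rather than hardcoding published ones.
A window is a joint outlier iff it reaches both cutoffs (default: upper 5%
of each arm).  Overlapping or book-ended (0-gap) outlier windows merge into
CDRs; merging is idempotent and order-invariant.  Genes attach to a CDR on
≥ 1 bp of strict transcript overlap.  The per-gene Tajima's D (mean of
overlapping windows' D) of selected genes is compared against all other
genes with a Mann–Whitney U test: exact null distribution when both groups
have ≤ 8 tie-free observations, otherwise the normal approximation with tie
correction and no continuity correction (so identical groups give p = 1).

## Annotation

Category precedence is exonic > splicing > UTR > intronic > upstream >
downstream > intergenic, with a 2-bp splice window and 1-kb flanks —
the defaults of the ANNOVAR-style vocabulary this mirrors.  UTR (exon minus
CDS) is kept as its own category even though some summaries fold it into
"exonic"; UTR sites are never synonymous/nonsynonymous.  One gene model per
transcript; when several models overlap a site the most severe category
wins.  Coding effects rebuild the affected codon from the reference
(reverse-complementing for minus-strand genes, including codons split
across introns), substitute the alternate base and translate; any
amino-acid change, including stop gain/loss, is nonsynonymous.  A CDS whose
length is not a multiple of 3 is rejected at model construction.

## LD

Composite (Rogers–Huff) r² — the squared Pearson correlation of diploid
dosages over pairwise-complete samples — replaces two-locus EM haplotype
r²: the pipeline is phase-free and composite LD is the standard unphased
surrogate, with null expectation 1/(n−1) for n diploids at unlinked pairs.
Pairs within 500 kb on the same chromosome contribute after a 5% MAF floor
(rare variants make r² noisy); the decay curve bins pairs as
(k·1000, (k+1)·1000] bp and omits empty bins.

## Phylogeny

The p-distance between individuals i and j is Σ|g_i − g_j| / (2·m) over the
m jointly genotyped sites — the natural allele-sharing form of a p-distance
for unphased diploid genotypes.  Neighbor joining follows Saitou & Nei with
the Q-criterion; ties break on the lexicographically smallest pair of
cluster keys (a cluster's key is its smallest leaf label), so output is
deterministic.  Negative branch estimates are clamped to zero with the
deficit moved to the sibling edge, conserving the joined path length.  An
additive input matrix is reproduced exactly (tree-metric recovery, tested).
Bootstrap support resamples SNP columns with replacement (1000 replicates
by default), recomputes distance + NJ, and scores topology-only leaf
bipartitions.

## The generator

Each 40-kb window is an independent non-recombining locus: one genealogy
under the demographic model, infinite-sites mutations at rate μ per bp per
generation placed uniformly on branches at unique positions, chromosomes
paired into diploids.  This deliberately omits intra-window recombination
and linkage between windows — window statistics never look across windows,
and independent loci give clean closed-form expectations — so the synthetic
data cannot exercise recombination-sensitive analyses (haplotype statistics,
fine-scale LD structure within a window, block definitions), and within-
window LD is total where real data would decay.

Defaults are the emulated study's conditions: μ = 1.6 × 10⁻⁹ per bp per
generation, generation time 1 year, N<sub>e</sub> = 78 125 diploids so that
θ = 4N<sub>e</sub>μ = 5 × 10⁻⁴ per bp (the order of the real panel's
genome-wide diversity), ten diploid samples per population, and a clean
two-deme split 0.2·N<sub>e</sub> generations ago (expected Hudson
F<sub>ST</sub> = T/(T+2N) ≈ 0.09, the order of the study's background
differentiation).  An island model with symmetric migration is available.

Sweeps are emulated by forcing the target deme's lineages into a star
genealogy at time τ: expected within-deme diversity is exactly 2μτ per bp,
within-deme variants are all singletons (strongly negative D), and the
deme's long private stem branch carries near-fixed differences (elevated
F<sub>ST</sub>) — the detection signature, with closed-form truth, without
simulating an allele-frequency trajectory.  The default planted geometry is
10 regions of five consecutive 40-kb loci (200 kb) in a 1000-locus (40 Mb)
genome with τ = 0.02·2N<sub>e</sub>.  Region size matches the merged-CDR
scale the real scan implies (top-5% windows merging into regions of a few
windows each), and 10 × 5 windows ≈ 5% of the genome sizes the swept
fraction to the top-5% rule, so realized thresholds land at the edge of the
swept cluster — the regime the scan is designed for.  QUAL and DP fields
are synthesized inside the filter-passing ranges; a `contaminate` fraction
injects failing QUAL/DP records to exercise the filters.

Degenerate inputs: a locus drawing more mutations than positions raises a
saturation error; τ = 0 yields swept windows monomorphic within the deme;
μ = 0 yields no sites; an island model with zero migration is rejected at
construction (lineages could never coalesce).

## Validation design

The tests close the loop between generator and estimators rather than
trusting either alone: across-window means of θ<sub>π</sub> and
θ<sub>W</sub> must recover 4N<sub>e</sub>μ within 5% on 500 neutral
windows; mean windowed Hudson F<sub>ST</sub> must match T/(T+2N) within
0.05 and be monotone in T; the scan must recover ≥ 9/10 planted regions
with ≥ 90% of CDR span inside planted regions; unlinked composite r² must
sit at 1/(n−1).  Exact oracles: msprime/tskit for θ<sub>π</sub>, S and D on
a shared fixture (agreement to 10⁻⁶); an independently transcribed scalar
Weir–Cockerham implementation for windowed F<sub>ST</sub>; full-CDS
translation for every possible single-base CDS substitution on both
strands; brute-force enumeration for interval merging, the shared/private
table, LD bins and the small-sample Mann–Whitney distribution.  Problem
sizes (500/300/1000 windows, 10–20 diploids) keep any single check under a
couple of minutes while leaving Monte-Carlo bands at 3 standard errors.

Passing on synthetic data shows the estimators and the scan logic are
correct under the generator's assumptions; it does not certify behaviour
under features the generator omits — recombination, linked selection,
sequencing error beyond the QUAL/DP fields, callability variation, or
population structure more complex than two demes.

## Determinism

Every stochastic component (generator, bootstrap, pipeline) takes a seed;
identical config + seed reproduce byte-identical VCF/TSV/BED/Newick
outputs (tested).  Outputs are written atomically via temp-file rename, and
floats are formatted with fixed precision so reruns diff cleanly.
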