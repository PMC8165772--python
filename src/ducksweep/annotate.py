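"""SNP functional annotation against gene models: location categories and
synonymous/nonsynonymous calls.

Categories follow the common resequencing-annotation vocabulary with the
precedence exonic > splicing > UTR > intronic > upstream > downstream >
intergenic; "splicing" means an intronic position within 2 bp of an
exon/intron boundary, and up/downstream extend 1 kb (configurable) beyond
the transcript respecting strand.  When several gene models overlap a site,
the most severe category wins.  Coding changes are called by rebuilding the
affected codon from the reference (strand-aware) and translating under the
standard genetic code; any amino-acid change, including stop gain or loss,
is nonsynonymous.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

CATEGORIES = (
    "exonic",
    "splicing",
    "UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}

SPLICE_WINDOW = 2  # bp into the intron counted as a splice site
DEFAULT_FLANK = 1000  # bp of up/downstream context


@dataclass
class GeneModel:
    """One transcript: exon and CDS intervals, 1-based inclusive, sorted by genome coordinate."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")
            if any(s > e or s < 1 for s, e in ivs):
                raise ValueError(f"{self.gene_id}: invalid {name} interval")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model without exons")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} is not a multiple of 3"
            )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int, intervals: list[tuple[int, int]]) -> bool:
        return any(s <= pos <= e for s, e in intervals)


class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{chrom}: non-nucleotide characters {sorted(bad)}")
            self.sequences[chrom] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# Gene-model loading (GFF3 and BED12)
# ---------------------------------------------------------------------------

def load_gff3(path: str | Path) -> list[GeneModel]:
    """One :class:`GeneModel` per mRNA/transcript feature of a GFF3 file.

    gene_id is taken from the transcript's parent gene where present so
    multi-transcript genes deduplicate to one gene id downstream.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models: list[GeneModel] = []
    tx_types = ("mRNA", "transcript")
    for ftype in tx_types:
        for tx in db.features_of_type(ftype):
            parents = list(db.parents(tx, featuretype="gene"))
            gene_id = parents[0].id if parents else tx.id
            exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:
                exons = list(cds)
            if not exons:
                continue
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=exons,
                    cds=cds,
                )
            )
    if not models:  # gene features without transcript children
        for gene in db.features_of_type("gene"):
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
            if not exons:
                exons = cds or [(gene.start, gene.end)]
            models.append(
                GeneModel(gene.id, gene.seqid, gene.strand, exons, cds)
            )
    return models


def load_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12: blocks become exons, the thick interval the CDS."""
    models: list[GeneModel] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
        chrom, start0, end0, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_s0, thick_e0 = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start0 + off + 1, start0 + off + sz) for off, sz in zip(offsets, sizes)]
        cds: list[tuple[int, int]] = []
        if thick_e0 > thick_s0:
            for s, e in exons:
                cs, ce = max(s, thick_s0 + 1), min(e, thick_e0)
                if cs <= ce:
                    cds.append((cs, ce))
        if exons[-1][1] != end0:
            raise ValueError(f"{path}:{lineno}: blocks do not span chromEnd")
        models.append(GeneModel(name, chrom, strand, exons, cds))
    return models


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, .bed -> BED12."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return load_gff3(path)
    if suffix == ".bed":
        return load_bed12(path)
    raise ValueError(f"cannot infer gene-model format from {path}")


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------

def _classify_against_gene(pos: int, gene: GeneModel, flank: int) -> str | None:
    """Category of pos relative to one gene model, or None when out of reach."""
    if gene.tx_start <= pos <= gene.tx_end:
        if gene.contains(pos, gene.cds):
            return "exonic"
        in_exon = gene.contains(pos, gene.exons)
        if in_exon:
            return "UTR" if gene.cds else "exonic"
        # intronic: check distance to the nearest exon boundary
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            if e1 < pos < s2:
                if pos - e1 <= SPLICE_WINDOW or s2 - pos <= SPLICE_WINDOW:
                    return "splicing"
                return "intronic"
        return "intronic"
    if gene.strand == "+":
        if gene.tx_start - flank <= pos < gene.tx_start:
            return "upstream"
        if gene.tx_end < pos <= gene.tx_end + flank:
            return "downstream"
    else:
        if gene.tx_end < pos <= gene.tx_end + flank:
            return "upstream"
        if gene.tx_start - flank <= pos < gene.tx_start:
            return "downstream"
    return None


class GeneIndex:
    """Interval index over gene models (transcript span plus flank) for fast lookup."""

    def __init__(self, genes: list[GeneModel], flank: int = DEFAULT_FLANK):
        self.flank = flank
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.tx_start - flank, g.tx_end + flank + 1, g)

    def candidates(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def classify_location(
    chrom: str,
    pos: int,
    index: GeneIndex,
    warn_missing_chrom: bool = True,
) -> tuple[str, str | None]:
    """(category, gene_id) of a site; the most severe category across
    overlapping gene models wins.  Sites on chromosomes absent from the
    annotation are intergenic (with a warning)."""
    if warn_missing_chrom and chrom not in index._trees:
        log.warning("classify_location: chromosome %r absent from annotation", chrom)
    best: tuple[int, str, str | None] = (_SEVERITY["intergenic"], "intergenic", None)
    for gene in index.candidates(chrom, pos):
        cat = _classify_against_gene(pos, gene, index.flank)
        if cat is not None and _SEVERITY[cat] < best[0]:
            best = (_SEVERITY[cat], cat, gene.gene_id)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def classify_coding_effect(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    gene: GeneModel,
    ref: ReferenceGenome,
) -> str:
    """'synonymous' or 'nonsynonymous' for a SNP inside the gene's CDS.

    The affected codon is rebuilt from the reference sequence, the alternate
    base substituted, and both codons translated (reverse-complemented first
    for minus-strand genes).  Raises if the reference base at ``pos``
    disagrees with ``ref_allele`` or the CDS has a trailing partial codon.
    """
    if not gene.contains(pos, gene.cds):
        raise ValueError(f"{chrom}:{pos} is not inside the CDS of {gene.gene_id}")
    if gene.cds_length % 3 != 0:
        raise ValueError(f"{gene.gene_id}: partial codon at CDS end")
    genomic_base = ref.base(chrom, pos)
    if genomic_base != ref_allele:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: VCF says {ref_allele}, genome says {genomic_base}"
        )
    # genomic positions of the CDS, 5'->3' in genome coordinates
    offset = 0
    cds_offset = None
    for s, e in gene.cds:
        if s <= pos <= e:
            cds_offset = offset + (pos - s)
            break
        offset += e - s + 1
    assert cds_offset is not None
    if gene.strand == "-":
        cds_index = gene.cds_length - 1 - cds_offset
    else:
        cds_index = cds_offset
    codon_idx = cds_index // 3
    within = cds_index % 3

    # collect the three genomic positions of this codon, in coding order
    genomic_positions: list[int] = []
    for s, e in gene.cds:
        genomic_positions.extend(range(s, e + 1))
    if gene.strand == "-":
        genomic_positions = genomic_positions[::-1]
    codon_pos = genomic_positions[codon_idx * 3 : codon_idx * 3 + 3]

    def coding_base(p: int, substitute: bool) -> str:
        b = alt_allele if (substitute and p == pos) else ref.base(chrom, p)
        return str(Seq(b).reverse_complement()) if gene.strand == "-" else b

    codon_ref = "".join(coding_base(p, False) for p in codon_pos)
    codon_alt = "".join(coding_base(p, True) for p in codon_pos)
    assert codon_ref[within] != codon_alt[within] or ref_allele == alt_allele
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# Whole-matrix annotation and summaries
# ---------------------------------------------------------------------------

def annotate_sites(
    gm,
    genes: list[GeneModel],
    ref: ReferenceGenome | None = None,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Per-site annotation table: chrom, pos, category, effect, gene_id.

    ``effect`` is synonymous/nonsynonymous for biallelic exonic-CDS sites
    (requires ``ref``) and 'noncoding' otherwise.
    """
    index = GeneIndex(genes, flank=flank)
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    missing_chroms: set[str] = set()
    sites = gm.sites
    for r in sites.itertuples():
        if r.chrom not in index._trees:
            missing_chroms.add(r.chrom)
        category, gene_id = classify_location(r.chrom, r.pos, index, warn_missing_chrom=False)
        effect = "noncoding"
        if category == "exonic" and gene_id is not None and ref is not None and r.n_alt == 1:
            gene = gene_by_id[gene_id]
            if gene.contains(r.pos, gene.cds):
                effect = classify_coding_effect(r.chrom, r.pos, r.ref, r.alt, gene, ref)
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "category": category,
                "effect": effect,
                "gene_id": gene_id if gene_id is not None else ".",
            }
        )
    if missing_chroms:
        log.warning(
            "annotate_sites: chromosome(s) absent from annotation, classified intergenic: %s",
            sorted(missing_chroms),
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "category", "effect", "gene_id"])


def annotation_summary(annotations: pd.DataFrame) -> tuple[dict[str, int], float]:
    """Category counts and the nonsynonymous/synonymous ratio (NaN when no
    synonymous sites)."""
    counts = annotations["category"].value_counts().to_dict()
    n_syn = int((annotations["effect"] == "synonymous").sum())
    n_nonsyn = int((annotations["effect"] == "nonsynonymous").sum())
    ratio = n_nonsyn / n_syn if n_syn else math.nan
    counts["synonymous"] = n_syn
    counts["nonsynonymous"] = n_nonsyn
    return counts, ratio
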