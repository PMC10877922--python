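"""Gene-level interpretation of metabolite-associated SNPs.

Co-inherited SNPs are mapped onto gene models (exon / intron / intergenic;
1-based inclusive coordinates throughout, the GFF3 convention), coding
variants are classified synonymous / missense by codon substitution,
metabolite-associated genes are scanned for genomic hot spots with a 5 Mb
sliding window advanced by 1 Mb (qualifying when the frequency of
associated genes exceeds 0.075 and their count exceeds 10, both strict),
and gene sets are tested for ontology enrichment with a two-tailed
hypergeometric test under Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

REGION_EXON = "exon"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        for s, e in self.exons:
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def cds_complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0


@dataclass
class GeneAnnotation:
    genes: dict[str, GeneModel]

    def __post_init__(self) -> None:
        for g in self.genes.values():
            if g.cds and not g.cds_complete:
                logger.warning("gene %s: CDS length %d not divisible by 3 "
                               "(treated as incomplete)", g.gene_id, g.cds_length)

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        """Load gene/exon/CDS records from a GFF3 file (gffutils, in-memory)."""
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
        genes: dict[str, GeneModel] = {}
        for g in db.features_of_type("gene"):
            exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
            cds = [(c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
                   for c in db.children(g, featuretype="CDS")]
            genes[g.id] = GeneModel(gene_id=g.id, chrom=g.seqid, start=g.start,
                                    end=g.end, strand=g.strand or "+",
                                    exons=sorted(exons), cds=sorted(cds))
        return cls(genes=genes)

    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})


# ---------------------------------------------------------------------------
# SNP -> gene region mapping
# ---------------------------------------------------------------------------

@dataclass
class RegionAssignment:
    regions: pd.Series          # snp -> exon / intron / intergenic
    snp_genes: pd.DataFrame     # snp, gene (exonic overlaps)
    gene_features: pd.DataFrame  # gene, feature (via co-inherited sets)


def map_snps_to_genes(
    snps: pd.DataFrame,
    ann: GeneAnnotation,
    reference_of: pd.Series | None = None,
    associations: pd.DataFrame | None = None,
) -> RegionAssignment:
    """Label SNPs exon / intron / intergenic and link genes to features.

    ``snps`` is indexed by SNP id with columns ``chrom`` and ``pos``.  A SNP
    inside any exon is exonic (exon wins over intron for nested gene
    models); inside a gene span but outside exons, intronic; otherwise
    intergenic.  When ``reference_of`` (member -> reference SNP) and
    ``associations`` (feature, reference_snp) are given, a gene is linked to
    every feature whose reference SNP has a co-inherited member in one of
    the gene's exons.
    """
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in ann.genes.values():
        gt = gene_trees.setdefault(g.chrom, IntervalTree())
        gt.addi(g.start, g.end + 1, g.gene_id)  # half-open internally
        et = exon_trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            et.addi(s, e + 1, g.gene_id)

    regions = {}
    snp_gene_rows = []
    for snp, row in snps.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        exon_hits = exon_trees.get(chrom, IntervalTree())[pos]
        if exon_hits:
            regions[snp] = REGION_EXON
            for iv in sorted(exon_hits, key=lambda iv: iv.data):
                snp_gene_rows.append({"snp": snp, "gene": iv.data})
        elif gene_trees.get(chrom, IntervalTree())[pos]:
            regions[snp] = REGION_INTRON
        else:
            regions[snp] = REGION_INTERGENIC

    snp_genes = pd.DataFrame(snp_gene_rows, columns=["snp", "gene"]).drop_duplicates()

    gene_feature_rows = []
    if reference_of is not None and associations is not None and len(snp_genes):
        feat_by_ref: dict[str, set] = {}
        for _, arow in associations.iterrows():
            feat_by_ref.setdefault(arow["reference_snp"], set()).add(arow["feature"])
        for _, srow in snp_genes.iterrows():
            ref = reference_of.get(srow["snp"])
            for f in sorted(feat_by_ref.get(ref, ())):
                gene_feature_rows.append({"gene": srow["gene"], "feature": f})
    gene_features = pd.DataFrame(gene_feature_rows,
                                 columns=["gene", "feature"]).drop_duplicates()

    return RegionAssignment(
        regions=pd.Series(regions, name="region").loc[snps.index],
        snp_genes=snp_genes.reset_index(drop=True),
        gene_features=gene_features.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# coding-consequence classification
# ---------------------------------------------------------------------------

CONSEQ_SYNONYMOUS = "synonymous"
CONSEQ_MISSENSE = "missense"
CONSEQ_OTHER = "other"
CONSEQ_NA = "na"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class VariantEffect:
    snp_id: str
    gene_id: str | None
    region: str
    consequence: str
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive sequence fetch from a dict or pyfaidx.Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start - 1:end]
    return str(seq[start - 1:end])  # pyfaidx FastaRecord slice


def classify_variant_effect(
    snp_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    ann: GeneAnnotation,
    genome,
) -> VariantEffect:
    """Codon-substitution consequence of a SNP with known ref/alt alleles.

    Alleles are given on the + strand.  Synonymous iff the translated amino
    acid is unchanged; stop gain/loss collapses to "other"; SNPs outside a
    CDS return consequence "na".  Raises if the reference allele disagrees
    with the genome sequence.
    """
    from Bio.Seq import Seq

    host = None
    for g in ann.genes.values():
        if g.chrom == chrom and any(s <= pos <= e for s, e, _ in g.cds):
            host = g
            break
    if host is None:
        region = REGION_INTERGENIC
        for g in ann.genes.values():
            if g.chrom == chrom and g.start <= pos <= g.end:
                region = REGION_EXON if any(s <= pos <= e for s, e in g.exons) else REGION_INTRON
                return VariantEffect(snp_id, g.gene_id, region, CONSEQ_NA)
        return VariantEffect(snp_id, None, region, CONSEQ_NA)

    genome_base = _fetch(genome, chrom, pos, pos).upper()
    if genome_base != ref.upper():
        raise ValueError(
            f"{snp_id} at {chrom}:{pos}: reference allele {ref!r} does not "
            f"match genome base {genome_base!r}")

    segs = sorted(host.cds, key=lambda t: t[0])
    spliced = "".join(_fetch(genome, chrom, s, e) for s, e, _ in segs).upper()
    offset = 0
    pos_in_cds = None
    for s, e, _ in segs:
        if s <= pos <= e:
            pos_in_cds = offset + (pos - s)
            break
        offset += e - s + 1
    assert pos_in_cds is not None

    if host.strand == "-":
        spliced = spliced.translate(_COMPLEMENT)[::-1]
        pos_in_cds = len(spliced) - 1 - pos_in_cds
        ref_c = ref.upper().translate(_COMPLEMENT)
        alt_c = alt.upper().translate(_COMPLEMENT)
        phase = segs[-1][2]
    else:
        ref_c, alt_c = ref.upper(), alt.upper()
        phase = segs[0][2]

    coding = spliced[phase:]
    idx = pos_in_cds - phase
    if idx < 0:
        return VariantEffect(snp_id, host.gene_id, REGION_EXON, CONSEQ_OTHER)
    codon_i, within = divmod(idx, 3)
    ref_codon = coding[codon_i * 3: codon_i * 3 + 3]
    if len(ref_codon) < 3:
        return VariantEffect(snp_id, host.gene_id, REGION_EXON, CONSEQ_OTHER)
    assert ref_codon[within] == ref_c, "internal frame error"
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        conseq = CONSEQ_SYNONYMOUS
    elif "*" in (ref_aa, alt_aa):
        conseq = CONSEQ_OTHER
    else:
        conseq = CONSEQ_MISSENSE
    return VariantEffect(snp_id, host.gene_id, REGION_EXON, conseq,
                         ref_codon, alt_codon, ref_aa, alt_aa)


# ---------------------------------------------------------------------------
# hot spots
# ---------------------------------------------------------------------------

@dataclass
class HotSpot:
    chrom: str
    start: int
    end: int
    gene_count: int
    metabolite_gene_count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hot spot end must exceed start")


def detect_hotspots(
    ann: GeneAnnotation,
    metabolite_genes: set[str],
    window_bp: int = 5_000_000,
    step_bp: int = 1_000_000,
    freq_min: float = 0.075,
    count_min: int = 10,
    assign: str = "start",
) -> list[HotSpot]:
    """Sliding-window scan for clusters of metabolite-associated genes.

    A gene belongs to a window through its start coordinate (or midpoint
    with ``assign="midpoint"``).  A window qualifies when the frequency of
    metabolite-associated genes is strictly greater than ``freq_min`` AND
    their absolute number strictly greater than ``count_min``; overlapping
    or adjacent qualifying windows merge into one hot spot, whose stats are
    recomputed over the merged span.
    """
    if not ann.genes:
        raise ValueError("empty gene annotation")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if assign not in ("start", "midpoint"):
        raise ValueError("assign must be 'start' or 'midpoint'")

    coords: dict[str, list[tuple[int, str]]] = {}
    for g in ann.genes.values():
        c = g.start if assign == "start" else (g.start + g.end) // 2
        coords.setdefault(g.chrom, []).append((c, g.gene_id))

    spots: list[HotSpot] = []
    for chrom in sorted(coords):
        pts = sorted(coords[chrom])
        positions = np.array([p for p, _ in pts])
        ids = np.array([gid for _, gid in pts], dtype=object)
        is_met = np.array([gid in metabolite_genes for gid in ids])
        max_pos = int(positions.max())

        qualifying: list[tuple[int, int]] = []
        w = 1
        while True:
            lo, hi = w, w + window_bp - 1
            inside = (positions >= lo) & (positions <= hi)
            n_genes = int(inside.sum())
            n_met = int((inside & is_met).sum())
            freq = n_met / n_genes if n_genes else 0.0
            if freq > freq_min and n_met > count_min:
                qualifying.append((lo, hi))
            if hi >= max_pos:
                break
            w += step_bp

        # merge overlapping or adjacent qualifying windows
        merged: list[list[int]] = []
        for lo, hi in qualifying:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            inside = (positions >= lo) & (positions <= hi)
            n_genes = int(inside.sum())
            n_met = int((inside & is_met).sum())
            spots.append(HotSpot(chrom=chrom, start=lo, end=hi,
                                 gene_count=n_genes,
                                 metabolite_gene_count=n_met,
                                 frequency=n_met / n_genes if n_genes else 0.0))
    return spots


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich_hypergeometric(
    gene_set,
    ontology_map: dict[str, set],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed hypergeometric enrichment with Benjamini-Hochberg control.

    The two-tailed p-value of a term is the sum of point probabilities not
    exceeding the observed one (exact two-sided convention).  Returns one
    row per term: overlap k, term size K, set size n, universe N, p-value,
    BH-adjusted p-value, significance at ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set members outside the universe: {sorted(stray)[:5]}")

    N = len(universe)
    n = len(gene_set)
    rows = []
    for term, term_genes in ontology_map.items():
        tg = set(term_genes) & universe
        K = len(tg)
        k = len(tg & gene_set)
        rv = hypergeom(N, K, n)
        support = np.arange(max(0, n + K - N), min(K, n) + 1)
        pmf = rv.pmf(support)
        p_obs = rv.pmf(k)
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "pvalue": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    if len(table):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(table["pvalue"], method="fdr_bh")
        table["p_adj"] = adj
        table["significant"] = table["p_adj"] < alpha
        table = table.sort_values("p_adj", kind="stable").reset_index(drop=True)
    else:
        table["p_adj"] = []
        table["significant"] = []
    return table
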