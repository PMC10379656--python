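"""SNP -> gene -> gene-pair annotation and PPI overlap.

Significant SNP pairs are lifted to the gene level: a SNP inside one or more
gene bodies maps to all of them; an intergenic SNP maps to the nearest gene
whose body boundary lies within 100 kb (inclusive; equidistant ties all kept),
or, in ``all-in-window`` mode, to every gene within the window.  Each SNP pair
then expands to the cross-product of its two gene lists; gene pairs are
unordered and deduplicated, accumulating the SNP pairs that support them.
Gene pairs are categorized by membership of each gene in a user-supplied
AD-related gene set, and overlapped against a protein-protein interaction
edge list (unordered exact symbol match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .io_formats import GeneAnnotationRecord, PpiEdge, SnpInfo

DEFAULT_WINDOW_BP = 100_000

MAP_MODES = ("nearest", "all-in-window")


class AdCategory(str, Enum):
    BOTH_AD = "both_ad"
    ONE_AD = "one_ad"
    NONE_AD = "none_ad"


@dataclass
class GenePairRecord:
    """One unordered gene-gene interaction pair with its supporting SNP pairs."""

    gene1: str
    gene2: str
    supporting_snp_pairs: list[tuple[str, str]] = field(default_factory=list)
    category: AdCategory | None = None
    ppi_overlap: bool | None = None

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError(f"gene pair must join two distinct genes: {self.gene1}")
        if self.gene2 < self.gene1:  # canonical unordered form
            self.gene1, self.gene2 = self.gene2, self.gene1

    def key(self) -> frozenset:
        return frozenset((self.gene1, self.gene2))


@dataclass
class MappingResult:
    """Gene pairs plus the bookkeeping the gene-pair statistics exclude."""

    gene_pairs: list[GenePairRecord]
    #: SNP pairs whose two SNPs map to the same single gene.
    intragenic: list[tuple[str, str, str]]  # (snp1, snp2, gene)
    #: SNPs with no gene within the window; their pairs are not counted.
    unmapped_snps: list[str]


def map_snp_to_genes(
    snp: SnpInfo,
    annotation: list[GeneAnnotationRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    mode: str = "nearest",
) -> list[str]:
    """Gene symbols for one SNP under the positional +-window rule.

    Containment wins outright; otherwise ``nearest`` returns the closest
    gene(s) within the window and ``all-in-window`` every gene within it.
    Distance is measured to the closest gene-body boundary and the window is
    inclusive.  Result is sorted and deduplicated, hence independent of
    annotation record order.
    """
    if mode not in MAP_MODES:
        raise ValueError(f"unknown map mode {mode!r}; choose from {MAP_MODES}")
    pos = snp.position_bp
    containing: set[str] = set()
    dists: dict[str, int] = {}
    for rec in annotation:
        if rec.chromosome != snp.chromosome:
            continue
        if rec.start_bp <= pos <= rec.end_bp:
            containing.add(rec.gene_symbol)
            continue
        d = rec.start_bp - pos if pos < rec.start_bp else pos - rec.end_bp
        if d <= window_bp:
            prev = dists.get(rec.gene_symbol)
            if prev is None or d < prev:
                dists[rec.gene_symbol] = d
    if containing:
        return sorted(containing)
    if not dists:
        return []
    if mode == "all-in-window":
        return sorted(dists)
    d_min = min(dists.values())
    return sorted(g for g, d in dists.items() if d == d_min)


def pairs_to_gene_pairs(
    snp_pairs: list[tuple[str, str]],
    snp_lookup: dict[str, SnpInfo],
    annotation: list[GeneAnnotationRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    mode: str = "nearest",
) -> MappingResult:
    """Expand SNP pairs to unordered, deduplicated gene pairs.

    A pair whose two SNPs map to the same single gene is recorded as
    intragenic, not as a gene pair; pairs touching an unmapped SNP are
    excluded (the SNP is reported in ``unmapped_snps``).
    """
    gene_cache: dict[str, list[str]] = {}

    def genes_for(snp_id: str) -> list[str]:
        if snp_id not in gene_cache:
            gene_cache[snp_id] = map_snp_to_genes(
                snp_lookup[snp_id], annotation, window_bp, mode
            )
        return gene_cache[snp_id]

    records: dict[frozenset, GenePairRecord] = {}
    intragenic: list[tuple[str, str, str]] = []
    unmapped: set[str] = set()

    for snp1, snp2 in snp_pairs:
        genes1, genes2 = genes_for(snp1), genes_for(snp2)
        for sid, gl in ((snp1, genes1), (snp2, genes2)):
            if not gl:
                unmapped.add(sid)
        if not genes1 or not genes2:
            continue
        if genes1 == genes2 and len(genes1) == 1:
            intragenic.append((snp1, snp2, genes1[0]))
            continue
        for ga in genes1:
            for gb in genes2:
                if ga == gb:
                    continue
                key = frozenset((ga, gb))
                rec = records.get(key)
                if rec is None:
                    rec = GenePairRecord(ga, gb)
                    records[key] = rec
                if (snp1, snp2) not in rec.supporting_snp_pairs:
                    rec.supporting_snp_pairs.append((snp1, snp2))

    ordered = sorted(records.values(), key=lambda r: (r.gene1, r.gene2))
    return MappingResult(ordered, intragenic, sorted(unmapped))


def categorize_pairs(
    gene_pairs: list[GenePairRecord],
    ad_gene_set: set[str],
) -> dict[str, int]:
    """Annotate each pair by how many of its genes are AD-related; return counts."""
    ad = {g.strip() for g in ad_gene_set}
    counts = {c.value: 0 for c in AdCategory}
    for rec in gene_pairs:
        n_ad = (rec.gene1 in ad) + (rec.gene2 in ad)
        rec.category = (AdCategory.BOTH_AD, AdCategory.ONE_AD, AdCategory.NONE_AD)[2 - n_ad]
        counts[rec.category.value] += 1
    return counts


def overlap_with_ppi(
    gene_pairs: list[GenePairRecord],
    edges: list[PpiEdge],
) -> int:
    """Flag pairs present in the PPI edge set (unordered); return overlap count.

    Duplicate edges and orientation flips do not affect the count; symbols are
    compared exactly after whitespace trimming.
    """
    edge_set = {frozenset((e.gene_a.strip(), e.gene_b.strip())) for e in edges}
    count = 0
    for rec in gene_pairs:
        rec.ppi_overlap = rec.key() in edge_set
        count += rec.ppi_overlap
    return count
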