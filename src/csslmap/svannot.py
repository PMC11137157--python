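"""Structural-variant classification against gene models.

Each SV is assigned *every* genomic-region category it overlaps by at least
one base, out of five: coding region, intron (gene body outside coding
blocks), strand-aware upstream 2 kb, downstream 2 kb, and intergenic (the
complement of gene spans and their flanks).  Flanks of neighbouring genes
may overlap each other and other gene bodies; no truncation or precedence
is applied, since multi-assignment makes it unnecessary.  An SV is linked
to a gene (annotated as potentially affecting it) when it overlaps the gene
span or its 2-kb flanks.  Insertions are classified at their 1-bp anchor;
translocations contribute one breakend record per end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORIES = ("coding", "intron", "upstream_2kb", "downstream_2kb", "intergenic")

__all__ = [
    "SvRecord",
    "GeneModel",
    "RegionIndex",
    "SvAnnotation",
    "build_region_index",
    "classify_sv",
    "annotate_genes",
    "region_summary",
]


@dataclass
class GeneModel:
    """One gene: strand, span, exons, optional CDS (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i + 1][0] > ex[i][1]]

    def validate(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons + self.cds:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon/CDS outside gene span")


@dataclass
class SvRecord:
    """0-based half-open SV interval; INS anchors are 1 bp with the true
    inserted length stored in ``length``."""

    sv_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # DEL, INS, DUP, INV, TRA
    length: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"SV {self.sv_id}: end <= start")


@dataclass
class SvAnnotation:
    sv: SvRecord
    categories: set
    genes: list[str]


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """span minus the union of blocks (all 0-based half-open)."""
    out = []
    cur = span[0]
    for s, e in sorted(blocks):
        s, e = max(s, span[0]), min(e, span[1])
        if e <= s:
            continue
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


class RegionIndex:
    """Interval trees per category per chromosome, with gene provenance."""

    def __init__(self, chrom_lengths: dict[str, int], flank: int = 2000):
        self.chrom_lengths = dict(chrom_lengths)
        self.flank = flank
        self.trees: dict[str, dict[str, IntervalTree]] = {
            cat: {c: IntervalTree() for c in chrom_lengths} for cat in CATEGORIES
        }
        self.gene_reach: dict[str, IntervalTree] = {
            c: IntervalTree() for c in chrom_lengths
        }

    def add_interval(self, cat: str, chrom: str, start: int, end: int,
                     gene: str | None = None) -> None:
        start = max(0, start)
        end = min(self.chrom_lengths[chrom], end)
        if end > start:
            self.trees[cat][chrom].addi(start, end, gene)

    def overlapping(self, cat: str, chrom: str, start: int, end: int):
        return self.trees[cat][chrom].overlap(start, end)


def build_region_index(genes: list[GeneModel], chrom_lengths: dict[str, int],
                       flank: int = 2000,
                       merged_flanks: bool = False) -> RegionIndex:
    """Build the five-category region index from gene models.

    Coding blocks are CDS intervals when present, otherwise exons (the
    choice is logged); the intron category is the gene body outside coding
    blocks; flanks are strand-aware (swapped to a single ``upstream_2kb``-
    plus-``downstream_2kb`` merged category when ``merged_flanks``), clipped
    at chromosome ends and not truncated by neighbouring genes; intergenic
    is the complement of gene spans and their flanks.
    """
    idx = RegionIndex(chrom_lengths, flank)
    n_cds = sum(bool(g.cds) for g in genes)
    if genes:
        logger.info("coding blocks: CDS for %d/%d genes, exons otherwise",
                    n_cds, len(genes))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        g.validate()
        coding = g.cds if g.cds else g.exons
        if not coding:
            coding = [(g.start, g.end)]
        for s, e in coding:
            idx.add_interval("coding", g.chrom, s, e, g.gene_id)
        for s, e in _subtract((g.start, g.end), list(coding)):
            idx.add_interval("intron", g.chrom, s, e, g.gene_id)
        if g.strand == "+":
            up = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        if merged_flanks:
            idx.add_interval("upstream_2kb", g.chrom, *up, gene=g.gene_id)
            idx.add_interval("upstream_2kb", g.chrom, *down, gene=g.gene_id)
        else:
            idx.add_interval("upstream_2kb", g.chrom, *up, gene=g.gene_id)
            idx.add_interval("downstream_2kb", g.chrom, *down, gene=g.gene_id)
        reach = (max(0, g.start - flank), min(chrom_lengths[g.chrom], g.end + flank))
        idx.gene_reach[g.chrom].addi(*reach, g.gene_id)
        occupied[g.chrom].append(reach)
    for chrom, length in chrom_lengths.items():
        for s, e in _subtract((0, length), occupied[chrom]):
            idx.add_interval("intergenic", chrom, s, e)
    return idx


def classify_sv(sv: SvRecord, index: RegionIndex) -> set:
    """All categories the SV interval intersects by >= 1 bp."""
    if sv.chrom not in index.chrom_lengths:
        raise ValueError(f"SV {sv.sv_id} on unknown chromosome {sv.chrom}")
    cats = {cat for cat in CATEGORIES
            if index.overlapping(cat, sv.chrom, sv.start, sv.end)}
    return cats


def classify_sv_records(svs: list[SvRecord], index: RegionIndex) -> dict[str, set]:
    """Classify a record list; breakend pairs (shared sv_id) are unioned."""
    out: dict[str, set] = {}
    for sv in svs:
        out.setdefault(sv.sv_id, set()).update(classify_sv(sv, index))
    return out


def annotate_genes(svs: list[SvRecord], genes: list[GeneModel],
                   chrom_lengths: dict[str, int], flank: int = 2000,
                   index: RegionIndex | None = None) -> list[SvAnnotation]:
    """Link every SV to each gene whose span or 2-kb flank it overlaps.

    Breakend pairs sharing an sv_id are merged into one annotation whose
    category set and gene list union both ends.
    """
    if index is None:
        index = build_region_index(genes, chrom_lengths, flank)
    by_id: dict[str, SvAnnotation] = {}
    for sv in svs:
        cats = classify_sv(sv, index)
        hit_genes = sorted({iv.data for iv in
                            index.gene_reach[sv.chrom].overlap(sv.start, sv.end)})
        if sv.sv_id in by_id:
            ann = by_id[sv.sv_id]
            ann.categories |= cats
            ann.genes = sorted(set(ann.genes) | set(hit_genes))
        else:
            by_id[sv.sv_id] = SvAnnotation(sv, cats, hit_genes)
    return list(by_id.values())


def region_summary(annotations: list[SvAnnotation]) -> pd.DataFrame:
    """Per-category SV counts and percentages (an SV counts once per
    category it carries, so percentages may total more than 100)."""
    n = len(annotations)
    rows = []
    for cat in CATEGORIES:
        count = sum(cat in a.categories for a in annotations)
        rows.append({"category": cat, "count": count,
                     "percent": 100.0 * count / n if n else 0.0})
    return pd.DataFrame(rows)


def svs_per_gene(annotations: list[SvAnnotation]) -> pd.Series:
    counts: dict[str, int] = {}
    for a in annotations:
        for g in a.genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
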