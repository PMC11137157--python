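"""Annotation and sequence fixtures with recorded ground truth.

Generates small genomes with gene models (exon/intron structure on both
strands), structural variants planted in known region categories, telomere
motif arrays at chromosome ends, and an internal satellite array — all at
recorded coordinates, so the SV annotator and sequence-feature detectors
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as csio
from .seqfeat import MOTIF_3P, MOTIF_5P
from .svannot import GeneModel, SvRecord

__all__ = [
    "FixtureConfig",
    "AnnotationFixture",
    "make_annotation_fixture",
    "random_svs",
    "telomere_assembly_fixture",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


@dataclass
class FixtureConfig:
    n_chroms: int = 2
    chrom_length: int = 300_000
    n_genes: int = 24
    n_svs: int = 40
    flank: int = 2000
    telomere_copies: int = 30       # per planted end; 0 disables
    satellite_monomer: int = 160
    satellite_copies: int = 200     # 0 disables
    with_sequences: bool = True


@dataclass
class AnnotationFixture:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    svs: list[SvRecord]
    sv_truth: dict[str, set]                  # sv_id -> planted category set
    sequences: dict[str, str] = field(default_factory=dict)
    telomere_truth: list[tuple[str, str, int, int]] = field(default_factory=list)
    satellite_truth: tuple[str, int, int] | None = None

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "genes.gff3",
            "sv": outdir / "svs.tsv",
        }
        csio.write_gff3(self.genes, paths["gff3"])
        csio.write_sv_table(self.svs, paths["sv"])
        if self.sequences:
            paths["fasta"] = outdir / "genome.fa"
            csio.write_fasta(self.sequences, paths["fasta"])
        return paths


def _place_genes(cfg: FixtureConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = cfg.n_genes // cfg.n_chroms + (cfg.n_genes % cfg.n_chroms > 0)
    # genes isolated by > 2*flank so planted-category truth is unambiguous
    spacing = cfg.chrom_length // (per_chrom + 1)
    min_gene, max_gene = 2400, 6000
    if spacing < max_gene + 3 * cfg.flank:
        raise ValueError("chromosomes too short for the requested gene count; "
                         "overlap constraints unsatisfiable")
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1:02d}"
        for k in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            anchor = (k + 1) * spacing
            length = int(rng.integers(min_gene, max_gene))
            start = anchor
            end = start + length
            strand = "+" if rng.integers(2) else "-"
            n_exons = int(rng.integers(1, 5))
            edges = np.sort(rng.choice(
                np.arange(start + 200, end - 200, 100),
                size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], int)
            bounds = [start, *edges.tolist(), end]
            exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
            g = GeneModel(f"gene{gid + 1:03d}", chrom, start, end, strand,
                          exons=exons, cds=list(exons))
            g.validate()
            genes.append(g)
            gid += 1
    return genes


def _plant_svs(cfg: FixtureConfig, genes: list[GeneModel],
               rng: np.random.Generator):
    """Plant SVs wholly inside single known categories, cycling through them."""
    svs: list[SvRecord] = []
    truth: dict[str, set] = {}
    plan = ["coding", "intron", "upstream_2kb", "downstream_2kb", "intergenic"]
    genes_with_introns = [g for g in genes if g.introns()]
    spacing = cfg.chrom_length // (len(genes) // cfg.n_chroms + 2)
    k = 0
    attempts = 0
    while k < cfg.n_svs:
        attempts += 1
        if attempts > 100 * max(cfg.n_svs, 1):
            raise RuntimeError("could not satisfy SV placement constraints")
        cat = plan[k % len(plan)]
        g = genes[int(rng.integers(len(genes)))]
        if cat == "coding":
            ex = g.exons[int(rng.integers(len(g.exons)))]
            if ex[1] - ex[0] < 60:
                continue
            a = int(rng.integers(ex[0] + 5, ex[1] - 50))
            b = a + int(rng.integers(20, min(50, ex[1] - a)))
            chrom = g.chrom
        elif cat == "intron":
            if not genes_with_introns:
                continue
            g = genes_with_introns[int(rng.integers(len(genes_with_introns)))]
            intr = g.introns()[0]
            if intr[1] - intr[0] < 60:
                continue
            a = int(rng.integers(intr[0] + 5, intr[1] - 50))
            b = a + int(rng.integers(20, min(50, intr[1] - a)))
            chrom = g.chrom
        elif cat in ("upstream_2kb", "downstream_2kb"):
            upstream = cat == "upstream_2kb"
            left = (g.strand == "+") == upstream
            if left:
                a = g.start - cfg.flank + 200
                b_max = g.start - 100
            else:
                a = g.end + 100
                b_max = g.end + cfg.flank - 200
            a = int(rng.integers(a, b_max - 50))
            b = a + int(rng.integers(20, 50))
            chrom = g.chrom
        else:  # intergenic: midway between gene anchors, > flank from genes
            chrom = g.chrom
            a = g.end + cfg.flank + 500 + int(rng.integers(0, max(spacing // 4, 1)))
            b = a + int(rng.integers(20, 50))
            if b >= cfg.chrom_length:
                continue
            near = [h for h in genes if h.chrom == chrom
                    and a < h.end + cfg.flank and b > h.start - cfg.flank]
            if near:
                continue
        svtype = "DEL" if k % 3 else "INS"
        sv_id = f"sv{k + 1:04d}"
        if svtype == "INS":
            svs.append(SvRecord(sv_id, chrom, a, a + 1, "INS",
                                int(rng.integers(60, 800))))
        else:
            svs.append(SvRecord(sv_id, chrom, a, b, "DEL", b - a))
        truth[sv_id] = {cat}
        k += 1
    return svs, truth


def make_annotation_fixture(cfg: FixtureConfig | None = None,
                            rng: np.random.Generator | None = None
                            ) -> AnnotationFixture:
    """Build a fixture genome with planted, ground-truthed features."""
    cfg = cfg or FixtureConfig()
    rng = rng or np.random.default_rng(0)
    chrom_lengths = {f"chr{i + 1:02d}": cfg.chrom_length
                     for i in range(cfg.n_chroms)}
    genes = _place_genes(cfg, rng)
    svs, sv_truth = _plant_svs(cfg, genes, rng) if cfg.n_svs else ([], {})
    fixture = AnnotationFixture(chrom_lengths, genes, svs, sv_truth)
    if cfg.with_sequences:
        for chrom, length in chrom_lengths.items():
            seq = list(random_sequence(rng, length))
            if cfg.telomere_copies:
                five = MOTIF_5P * cfg.telomere_copies
                three = MOTIF_3P * cfg.telomere_copies
                seq[:len(five)] = five
                seq[-len(three):] = three
                fixture.telomere_truth.append(
                    (chrom, "five_prime", 0, len(five)))
                fixture.telomere_truth.append(
                    (chrom, "three_prime", length - len(three), length))
            fixture.sequences[chrom] = "".join(seq)
        if cfg.satellite_copies:
            chrom = next(iter(chrom_lengths))
            monomer = random_sequence(rng, cfg.satellite_monomer)
            array = monomer * cfg.satellite_copies
            mid = chrom_lengths[chrom] // 2
            if mid + len(array) >= chrom_lengths[chrom] - 10_000:
                raise ValueError("satellite array does not fit the chromosome")
            s = fixture.sequences[chrom]
            fixture.sequences[chrom] = s[:mid] + array + s[mid + len(array):]
            fixture.satellite_truth = (chrom, mid, mid + len(array))
            fixture.satellite_monomer = monomer
    return fixture


def random_svs(fixture: AnnotationFixture, n: int,
               rng: np.random.Generator) -> list[SvRecord]:
    """Uniform random SV intervals over the fixture genome (for oracle tests)."""
    chroms = list(fixture.chrom_lengths)
    out = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, 5000))
        start = int(rng.integers(0, fixture.chrom_lengths[chrom] - length))
        svtype = ["DEL", "INS", "DUP", "INV"][int(rng.integers(4))]
        if svtype == "INS":
            out.append(SvRecord(f"rsv{k}", chrom, start, start + 1, "INS", length))
        else:
            out.append(SvRecord(f"rsv{k}", chrom, start, start + length,
                                svtype, length))
    return out


def telomere_assembly_fixture(rng: np.random.Generator, n_chroms: int = 12,
                              both_ends: int = 10, single_end: int = 2,
                              copies: int = 30, chrom_length: int = 30_000
                              ) -> tuple[dict[str, str], int]:
    """Synthetic assembly with a known number of telomere-bearing ends.

    The default plants telomeres on both ends of ``both_ends`` chromosomes
    and one end of ``single_end`` chromosomes (total 22 ends on 12
    chromosomes, mirroring a nearly telomere-complete rice assembly).
    """
    if both_ends + single_end > n_chroms:
        raise ValueError("more telomere-bearing chromosomes than chromosomes")
    seqs: dict[str, str] = {}
    total = 0
    for i in range(n_chroms):
        name = f"chr{i + 1:02d}"
        seq = list(random_sequence(rng, chrom_length))
        five = MOTIF_5P * copies
        three = MOTIF_3P * copies
        if i < both_ends:
            seq[:len(five)] = five
            seq[-len(three):] = three
            total += 2
        elif i < both_ends + single_end:
            if i % 2:
                seq[:len(five)] = five
            else:
                seq[-len(three):] = three
            total += 1
        seqs[name] = "".join(seq)
    return seqs, total
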