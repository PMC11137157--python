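"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion happens
only at format boundaries (GFF3/VCF are 1-based closed, BED is 0-based
half-open).  The marker-call TSV dialect is: a header row ``line`` followed
by marker ids, a ``chrom`` row, a ``pos`` row (1-based), then one row per
line with cells in {A, B, H, -} where A is the recurrent parent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bins import BinGenotypeMatrix, Tile
from .genotyper import IntrogressionSegment
from .simulate import MarkerCallMatrix, PhenotypeTable
from .states import CODE, DON, HET, MISSING, REC, STATE_NAME, to_symbols
from .svannot import GeneModel, SvRecord

logger = logging.getLogger(__name__)

SV_TYPES = {"DEL", "INS", "DUP", "INV", "TRA"}
_SV_ALIASES = {"DELETION": "DEL", "INSERTION": "INS", "DUPLICATION": "DUP",
               "INVERSION": "INV", "TRANSLOCATION": "TRA", "BND": "TRA"}


# ---------------------------------------------------------------------------
# marker-call matrix
# ---------------------------------------------------------------------------

def write_marker_calls(matrix: MarkerCallMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(matrix.marker_ids) + "\n")
        fh.write("chrom\t" + "\t".join(matrix.chroms.tolist()) + "\n")
        fh.write("pos\t" + "\t".join(str(p + 1) for p in matrix.positions.tolist()) + "\n")
        sym = to_symbols(matrix.calls)
        for i, name in enumerate(matrix.line_names):
            fh.write(name + "\t" + "\t".join(sym[i].tolist()) + "\n")


def read_marker_calls(path, fmt: str = "tsv", recurrent_parent: str | None = None,
                      donor_parent: str | None = None) -> MarkerCallMatrix:
    """Read a marker-call matrix from the TSV dialect or from a VCF."""
    if fmt == "tsv":
        return _read_marker_tsv(path)
    if fmt == "vcf":
        if recurrent_parent is None or donor_parent is None:
            raise ValueError("VCF input requires the two parent sample names")
        return _read_marker_vcf(path, recurrent_parent, donor_parent)
    raise ValueError(f"unknown marker format {fmt!r}")


def _read_marker_tsv(path) -> MarkerCallMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        chrom_row = fh.readline().rstrip("\n").split("\t")
        pos_row = fh.readline().rstrip("\n").split("\t")
        if header[0] != "line" or chrom_row[0] != "chrom" or pos_row[0] != "pos":
            raise ValueError("malformed marker TSV header rows")
        marker_ids = header[1:]
        chroms = np.array(chrom_row[1:])
        positions = np.array([int(p) - 1 for p in pos_row[1:]], dtype=np.int64)
        line_names, rows = [], []
        for r, raw in enumerate(fh):
            cells = raw.rstrip("\n").split("\t")
            line_names.append(cells[0])
            row = np.empty(len(marker_ids), dtype=np.int8)
            for cidx, cell in enumerate(cells[1:]):
                try:
                    row[cidx] = CODE[cell]
                except KeyError:
                    raise ValueError(
                        f"unknown call symbol {cell!r} at data row {r + 1}, "
                        f"column {cidx + 1}") from None
            rows.append(row)
    return MarkerCallMatrix(line_names, marker_ids, chroms, positions,
                            np.vstack(rows) if rows else
                            np.empty((0, len(marker_ids)), dtype=np.int8))


def _read_marker_vcf(path, recurrent_parent: str,
                     donor_parent: str) -> MarkerCallMatrix:
    """Derive parental-origin calls from a VCF with both parents included.

    A site is informative when both parents are homozygous for different
    alleles; progeny genotypes matching the recurrent parent map to REC,
    matching the donor to DON, mixed to HET, uncalled to MISSING.  Non-
    informative sites are dropped (count logged).
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        i_rec = samples.index(recurrent_parent)
        i_don = samples.index(donor_parent)
    except ValueError as exc:
        raise ValueError(f"parent sample missing from VCF: {exc}") from None
    progeny = [(i, s) for i, s in enumerate(samples)
               if i not in (i_rec, i_don)]
    ids, chroms, positions, cols = [], [], [], []
    dropped = 0
    for v in vcf:
        g = v.genotype.array()
        rec_gt = tuple(g[i_rec][:2])
        don_gt = tuple(g[i_don][:2])
        informative = (min(rec_gt) >= 0 and min(don_gt) >= 0
                       and rec_gt[0] == rec_gt[1] and don_gt[0] == don_gt[1]
                       and rec_gt[0] != don_gt[0])
        if not informative:
            dropped += 1
            continue
        col = np.empty(len(progeny), dtype=np.int8)
        for k, (i, _) in enumerate(progeny):
            a, b = g[i][:2]
            if a < 0 or b < 0:
                col[k] = MISSING
            elif (a, b) == rec_gt:
                col[k] = REC
            elif (a, b) == don_gt:
                col[k] = DON
            else:
                col[k] = HET
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)
        cols.append(col)
    logger.info("VCF markers: kept %d sites, dropped %d non-informative",
                len(ids), dropped)
    calls = np.stack(cols, axis=1) if cols else \
        np.empty((len(progeny), 0), dtype=np.int8)
    matrix = MarkerCallMatrix([s for _, s in progeny], ids,
                              np.array(chroms, dtype="U32"),
                              np.array(positions, dtype=np.int64), calls)
    matrix.dropped_sites = dropped
    return matrix


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = pd.DataFrame(table.traits, index=table.line_names)
    df.index.name = "line"
    df.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line", na_values=["NA"])


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read gene/mRNA/exon(/CDS) models from a GFF3 file.

    1-based closed GFF3 coordinates are converted to 0-based half-open.
    Raises on exons lying outside their gene's span, naming the gene.
    """
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        model = GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand,
        )
        for child in db.children(g, featuretype=("exon", "CDS"), order_by="start"):
            iv = (child.start - 1, child.end)
            if iv[0] < model.start or iv[1] > model.end:
                raise ValueError(
                    f"{child.featuretype} outside gene span for {g.id}")
            (model.exons if child.featuretype == "exon" else model.cds).append(iv)
        genes.append(model)
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{i};Parent={mrna}\n")
            for i, (s, e) in enumerate(sorted(g.cds), 1):
                fh.write(f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={mrna}.cds{i};Parent={mrna}\n")


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

def read_sv_table(path, fmt: str = "tsv") -> list[SvRecord]:
    """Read SVs from a TSV (chrom, start, end, type, length; 0-based
    half-open) or a VCF with SVTYPE and END/SVLEN INFO fields.

    Types are normalized to {DEL, INS, DUP, INV, TRA}; insertions become
    1-bp anchors with the true length retained; translocations yield two
    breakend records sharing one id.
    """
    if fmt == "tsv":
        return _read_sv_tsv(path)
    if fmt == "vcf":
        return _read_sv_vcf(path)
    raise ValueError(f"unknown SV format {fmt!r}")


def _norm_type(t: str, lineno) -> str:
    t = t.strip().upper()
    t = _SV_ALIASES.get(t, t)
    if t not in SV_TYPES:
        raise ValueError(f"unknown SV type {t!r} at line {lineno}")
    return t


def _read_sv_tsv(path) -> list[SvRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "start", "end", "type", "length"}
    if not need.issubset(df.columns):
        raise ValueError(f"SV TSV must have columns {sorted(need)}")
    out: list[SvRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        t = _norm_type(str(row.type), lineno)
        start, end, length = int(row.start), int(row.end), int(row.length)
        if end < start:
            raise ValueError(f"end < start at line {lineno}")
        sv_id = getattr(row, "id", None) or f"sv{lineno - 1}"
        if t == "INS":
            out.append(SvRecord(sv_id, str(row.chrom), start, start + 1, t, length))
        elif t == "TRA":
            # TSV convention: chrom:start is one breakend, a 'chrom2'/'end'
            # pair the other when provided, else a 1-bp anchor at each coord
            chrom2 = getattr(row, "chrom2", None) or str(row.chrom)
            out.append(SvRecord(sv_id, str(row.chrom), start, start + 1, t, length))
            out.append(SvRecord(sv_id, str(chrom2), end, end + 1, t, length))
        else:
            if end == start:
                raise ValueError(f"zero-length {t} at line {lineno}")
            out.append(SvRecord(sv_id, str(row.chrom), start, end, t, length))
    return out


def _read_sv_vcf(path) -> list[SvRecord]:
    from cyvcf2 import VCF
    out: list[SvRecord] = []
    for k, v in enumerate(VCF(str(path))):
        t = _norm_type(v.INFO.get("SVTYPE", ""), k + 1)
        start = v.POS - 1
        end = v.INFO.get("END")
        svlen = v.INFO.get("SVLEN")
        sv_id = v.ID or f"sv{k + 1}"
        if t == "INS":
            length = abs(int(svlen)) if svlen is not None else 0
            out.append(SvRecord(sv_id, v.CHROM, start, start + 1, t, length))
        elif t == "TRA":
            chr2 = v.INFO.get("CHR2", v.CHROM)
            end2 = int(end) - 1 if end is not None else start
            out.append(SvRecord(sv_id, v.CHROM, start, start + 1, t, 0))
            out.append(SvRecord(sv_id, str(chr2), end2, end2 + 1, t, 0))
        else:
            if end is None and svlen is not None:
                end = v.POS + abs(int(svlen))
            if end is None:
                raise ValueError(f"SV record {sv_id} lacks END/SVLEN")
            e = int(end)
            out.append(SvRecord(sv_id, v.CHROM, start, e, t, e - start))
    return out


def write_sv_table(svs: list[SvRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\ttype\tlength\n")
        for sv in svs:
            fh.write(f"{sv.sv_id}\t{sv.chrom}\t{sv.start}\t{sv.end}\t"
                     f"{sv.svtype}\t{sv.length}\n")


# ---------------------------------------------------------------------------
# BED / result tables
# ---------------------------------------------------------------------------

def write_bed(features, path, known_chroms: set | None = None) -> None:
    """Write (chrom, start, end[, name]) features as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if known_chroms is not None and chrom not in known_chroms:
                raise ValueError(f"unknown chromosome {chrom!r} in BED output")
            name = f[3] if len(f) > 3 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            parts = raw.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]),
                        parts[3] if len(parts) > 3 else "."))
    return out


def write_segments_bed(segments_by_line: dict[str, list[IntrogressionSegment]],
                       path) -> None:
    feats = [(s.chrom, s.start, s.end, f"{line}|{STATE_NAME[s.state]}")
             for line, segs in segments_by_line.items() for s in segs]
    write_bed(feats, path)


def write_bin_matrix(binmat: BinGenotypeMatrix, path) -> None:
    binmat.to_frame().rename_axis("line").to_csv(path, sep="\t")


def read_bin_matrix(path) -> BinGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line")
    bins = []
    for col in df.columns:
        chrom, span = col.rsplit(":", 1)
        s, e = span.split("-")
        bins.append(Tile(chrom, int(s), int(e)))
    from .states import from_symbols
    states = from_symbols(df.to_numpy(dtype="U1"))
    return BinGenotypeMatrix(list(df.index), bins, [1] * len(bins),
                             [(i, i + 1) for i in range(len(bins))], states,
                             bins)


def write_scan_table(results, path) -> None:
    results.scan.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
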