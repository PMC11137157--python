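"""Recombination-bin construction and population summaries.

The genome is tiled into fixed-width intervals (default 100 kb; a trailing
remainder is merged into the previous tile so every tile is *at least* the
tile width).  Each tile of each line takes the diploid state covering the
largest share of its bases.  Adjacent tiles whose state vectors across the
entire population are identical are collapsed into a single recombination
bin — the unit at which the population is genotyped and QTLs are mapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .genotyper import IntrogressionSegment
from .states import REC, DON, HET, MISSING

__all__ = [
    "Tile",
    "TileGenotypeMatrix",
    "BinGenotypeMatrix",
    "PopulationSummary",
    "tile_genome",
    "genotype_tiles",
    "merge_into_bins",
    "expand_bins_to_tiles",
    "population_summary",
]

DEFAULT_TILE = 100_000


@dataclass(frozen=True)
class Tile:
    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class TileGenotypeMatrix:
    line_names: list[str]
    tiles: list[Tile]
    states: np.ndarray  # int8 (n_lines, n_tiles)

    def chrom_tile_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.array([t.chrom for t in self.tiles]) == chrom)


@dataclass
class BinGenotypeMatrix:
    line_names: list[str]
    bins: list[Tile]               # (chrom, start, end) of each bin
    n_tiles: list[int]             # tiles merged into each bin
    tile_slices: list[tuple[int, int]]  # provenance: tile index range per bin
    states: np.ndarray             # int8 (n_lines, n_bins)
    source_tiles: list[Tile] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def dosage(self) -> np.ndarray:
        """Donor-dosage matrix: REC->0, HET->0.5, DON->1, MISSING->NaN."""
        lut = np.array([0.0, 1.0, 0.5, np.nan])
        return lut[self.states]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{b.chrom}:{b.start}-{b.end}" for b in self.bins]
        from .states import to_symbols
        return pd.DataFrame(to_symbols(self.states), index=self.line_names,
                            columns=cols)


def tile_genome(gmap: GeneticMap, tile_size: int = DEFAULT_TILE) -> list[Tile]:
    """Partition every chromosome into tiles of at least ``tile_size`` bp.

    The trailing remainder of each chromosome is merged into the previous
    tile; a chromosome shorter than ``tile_size`` becomes a single whole-
    chromosome tile (with a warning).
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    tiles: list[Tile] = []
    for c in gmap.chromosomes:
        if c.length_bp < tile_size:
            warnings.warn(f"chromosome {c.name} ({c.length_bp} bp) is shorter "
                          f"than the tile size {tile_size}; using one tile")
            tiles.append(Tile(c.name, 0, c.length_bp))
            continue
        n_full = c.length_bp // tile_size
        edges = [i * tile_size for i in range(n_full)] + [c.length_bp]
        tiles.extend(Tile(c.name, edges[i], edges[i + 1]) for i in range(n_full))
    return tiles


def genotype_tiles(segments_by_line: dict[str, list[IntrogressionSegment]],
                   tiles: list[Tile],
                   impute_flanked_missing: bool = True) -> TileGenotypeMatrix:
    """Assign each tile of each line the state covering most of its bases.

    Exact ties go to HET; tiles on chromosomes where a line has no segments
    are MISSING.  A single imputation pass then fills each MISSING tile whose
    immediate neighbours (same chromosome) share a state.
    """
    line_names = list(segments_by_line)
    n_tiles = len(tiles)
    tile_chroms = np.array([t.chrom for t in tiles])
    states = np.full((len(line_names), n_tiles), MISSING, dtype=np.int8)
    chrom_tiles: dict[str, np.ndarray] = {
        c: np.flatnonzero(tile_chroms == c) for c in dict.fromkeys(tile_chroms.tolist())
    }
    for li, line in enumerate(line_names):
        cover = np.zeros((3, n_tiles))  # bp covered per state REC/DON/HET
        seen_chroms = set()
        for seg in segments_by_line[line]:
            if seg.chrom not in chrom_tiles:
                continue
            seen_chroms.add(seg.chrom)
            idx = chrom_tiles[seg.chrom]
            starts = np.array([tiles[i].start for i in idx])
            ends = np.array([tiles[i].end for i in idx])
            ov = np.minimum(ends, seg.end) - np.maximum(starts, seg.start)
            pos = ov > 0
            if seg.state in (REC, DON, HET):
                cover[seg.state, idx[pos]] += ov[pos]
        tot = cover.sum(axis=0)
        have = tot > 0
        best = cover.max(axis=0)
        ties = (cover == best).sum(axis=0) > 1
        st = np.argmax(cover, axis=0).astype(np.int8)
        st[ties] = HET
        states[li, have] = st[have]
        # tiles on covered chromosomes but with zero overlap stay MISSING
    if impute_flanked_missing:
        orig = states.copy()
        for c, idx in chrom_tiles.items():
            if len(idx) < 3:
                continue
            sub = orig[:, idx]
            mid = sub[:, 1:-1]
            fill = (mid == MISSING) & (sub[:, :-2] == sub[:, 2:]) & (sub[:, :-2] != MISSING)
            patched = states[:, idx]
            patched[:, 1:-1][fill] = sub[:, :-2][fill]
            states[:, idx] = patched
    return TileGenotypeMatrix(line_names, list(tiles), states)


def merge_into_bins(tilemat: TileGenotypeMatrix) -> BinGenotypeMatrix:
    """Collapse adjacent tiles with identical across-population state vectors.

    MISSING counts as its own state during comparison.  Bin order follows
    tile order; provenance (the tile index range of every bin) is retained.
    """
    tiles, states = tilemat.tiles, tilemat.states
    n_tiles = len(tiles)
    if n_tiles == 0:
        return BinGenotypeMatrix(tilemat.line_names, [], [], [], states[:, :0], [])
    same_chrom = np.array([tiles[i].chrom == tiles[i + 1].chrom
                           for i in range(n_tiles - 1)])
    same_vec = np.all(states[:, :-1] == states[:, 1:], axis=0) if n_tiles > 1 \
        else np.empty(0, dtype=bool)
    new_bin = np.concatenate([[True], ~(same_chrom & same_vec)])
    bin_id = np.cumsum(new_bin) - 1
    n_bins = int(bin_id[-1]) + 1
    bins, n_in, slices = [], [], []
    for b in range(n_bins):
        idx = np.flatnonzero(bin_id == b)
        bins.append(Tile(tiles[idx[0]].chrom, tiles[idx[0]].start, tiles[idx[-1]].end))
        n_in.append(len(idx))
        slices.append((int(idx[0]), int(idx[-1]) + 1))
    bstates = states[:, new_bin]
    return BinGenotypeMatrix(tilemat.line_names, bins, n_in, slices, bstates,
                             list(tiles))


def expand_bins_to_tiles(binmat: BinGenotypeMatrix) -> TileGenotypeMatrix:
    """Inverse of :func:`merge_into_bins` (exact, via provenance)."""
    n_tiles = sum(binmat.n_tiles)
    states = np.empty((len(binmat.line_names), n_tiles), dtype=np.int8)
    for b, (a, e) in enumerate(binmat.tile_slices):
        states[:, a:e] = binmat.states[:, [b]]
    tiles = binmat.source_tiles or [
        t for b in binmat.bins for t in [b]  # degenerate fallback
    ]
    return TileGenotypeMatrix(list(binmat.line_names), list(tiles), states)


@dataclass
class DonorSegment:
    line: str
    chrom: str
    start: int
    end: int
    length_cm: float


@dataclass
class PopulationSummary:
    per_line: pd.DataFrame          # recurrent_fraction, n_donor_segments, ...
    segments: list[DonorSegment]    # all homozygous-donor segments
    donor_coverage: float           # fraction of genome donor in >= 1 line
    segment_length_cm: np.ndarray   # cM lengths of all donor segments

    def histogram(self, edges=(0, 5, 10, 20, 30, np.inf)) -> pd.Series:
        cats = pd.cut(self.segment_length_cm, bins=list(edges), right=False)
        return cats.value_counts().sort_index()


def population_summary(binmat: BinGenotypeMatrix, gmap: GeneticMap) -> PopulationSummary:
    """Per-line genome composition and population-level donor coverage.

    Recurrent fraction counts heterozygous bases half; a donor (substitution)
    segment is a maximal run of homozygous-donor bins, HET excluded.
    """
    widths = np.array([b.width for b in binmat.bins], dtype=float)
    genome = float(gmap.total_bp)
    chrom_arr = np.array([b.chrom for b in binmat.bins])
    rec_bp = ((binmat.states == REC) * widths).sum(axis=1)
    het_bp = ((binmat.states == HET) * widths).sum(axis=1)
    rows, segments = [], []
    donor_any = np.zeros(binmat.n_bins, dtype=bool)
    for li, line in enumerate(binmat.line_names):
        st = binmat.states[li]
        donor_any |= st == DON
        n_seg = 0
        don_cm = 0.0
        i = 0
        while i < binmat.n_bins:
            if st[i] == DON:
                j = i
                while (j + 1 < binmat.n_bins and st[j + 1] == DON
                       and chrom_arr[j + 1] == chrom_arr[i]):
                    j += 1
                start, end = binmat.bins[i].start, binmat.bins[j].end
                cm = gmap.cm_span(chrom_arr[i], start, end)
                segments.append(DonorSegment(line, str(chrom_arr[i]), start, end, cm))
                n_seg += 1
                don_cm += cm
                i = j + 1
            else:
                i += 1
        rows.append({
            "line": line,
            "recurrent_fraction": (rec_bp[li] + 0.5 * het_bp[li]) / genome,
            "n_donor_segments": n_seg,
            "donor_cm": don_cm,
        })
    per_line = pd.DataFrame(rows).set_index("line")
    coverage = float((widths * donor_any).sum() / genome)
    seg_cm = np.array([s.length_cm for s in segments])
    return PopulationSummary(per_line, segments, coverage, seg_cm)
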