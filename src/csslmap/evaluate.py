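"""Scoring called genotypes against simulator ground truth.

Used to quantify recovery of the genotyping pipeline on populations whose
true haplotypes are known: tile-level state accuracy and breakpoint
containment (whether each true recombination breakpoint lies inside the
uncertainty interval reported for the corresponding called breakpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bins import Tile, genotype_tiles
from .genmap import GeneticMap
from .genotyper import IntrogressionSegment
from .simulate import MarkerCallMatrix, SimTruth
from .states import MISSING

__all__ = ["tile_accuracy", "breakpoint_containment", "BreakpointScore"]


def tile_accuracy(truth: SimTruth,
                  segments_by_line: dict[str, list[IntrogressionSegment]],
                  tiles: list[Tile]) -> float:
    """Fraction of (line, tile) states matching the ground truth."""
    called = genotype_tiles(segments_by_line, tiles)
    expected = genotype_tiles(truth.to_segments(), tiles,
                              impute_flanked_missing=False)
    order = [called.line_names.index(n) for n in expected.line_names]
    return float(np.mean(called.states[order] == expected.states))


@dataclass
class BreakpointScore:
    n_true: int        # all true diploid-state transitions
    n_eligible: int    # transitions with informative flanking markers
    n_contained: int   # eligible transitions inside a reported uncertainty

    @property
    def containment(self) -> float:
        return self.n_contained / self.n_eligible if self.n_eligible else 1.0


def breakpoint_containment(truth: SimTruth, matrix: MarkerCallMatrix,
                           segments_by_line: dict[str, list[IntrogressionSegment]],
                           min_flank_markers: int = 15) -> BreakpointScore:
    """Check true breakpoints against reported uncertainty intervals.

    A true breakpoint is *eligible* when each of its two flanking true
    segments contains at least ``min_flank_markers`` markers (transitions
    below the sliding-window detection scale are excluded by construction)
    and the nearest non-missing marker on each side carries the correct
    (error-free) call — otherwise the observed data are indistinguishable
    from data generated by a shifted breakpoint.
    """
    gmap: GeneticMap = truth.gmap
    n_true = n_elig = n_cont = 0
    line_idx = {n: i for i, n in enumerate(matrix.line_names)}
    for line in truth.lines:
        li = line_idx[line.name]
        segs = segments_by_line.get(line.name, [])
        for c in gmap.chromosomes:
            sel = matrix.chrom_slice(c.name)
            pos = matrix.positions[sel]
            calls = matrix.calls[li, sel]
            ends, states = line.diploid_partition(c.name)
            unc = [s.right_uncertainty for s in segs
                   if s.chrom == c.name and s.right_uncertainty is not None]
            for k in range(len(ends) - 1):
                bp = int(ends[k])
                n_true += 1
                lstart = 0 if k == 0 else int(ends[k - 1])
                rend = int(ends[k + 1])
                if ((pos >= lstart) & (pos < bp)).sum() < min_flank_markers:
                    continue
                if ((pos >= bp) & (pos < rend)).sum() < min_flank_markers:
                    continue
                lidx = np.flatnonzero((pos < bp) & (calls != MISSING))
                ridx = np.flatnonzero((pos >= bp) & (calls != MISSING))
                if not len(lidx) or not len(ridx):
                    continue
                if calls[lidx[-1]] != states[k] or calls[ridx[0]] != states[k + 1]:
                    continue
                n_elig += 1
                if any(u[0] <= bp <= u[1] for u in unc):
                    n_cont += 1
    return BreakpointScore(n_true, n_elig, n_cont)
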