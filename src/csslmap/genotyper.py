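"""Sliding-window parental-origin caller and introgression-segment builder.

The core classification rule follows the published CSSL genotyping
procedure: consecutive SNP calls are examined in a sliding window of 15
SNPs and the window is called homozygous-recurrent when the ratio of
recurrent to donor calls exceeds 11:4, homozygous-donor when it is below
2:13, and heterozygous otherwise.  Both comparisons are strict and are done
in integer arithmetic on the informative (recurrent + donor) calls only;
windows with fewer than ``min_informative`` informative calls are UNKNOWN.

Per-marker consensus takes the plurality state over covering windows.
Because the two ratio thresholds are deliberately harsh, every ambiguous
region — the straddle zone of a homozygous-homozygous breakpoint, a truly
heterozygous region (whose windows are UNKNOWN for lack of informative
calls), or a donor segment too short to dominate any window — surfaces as
a consensus HET or UNKNOWN zone.  The high-level driver
:func:`call_line_segments` therefore refines the coarse window segmentation
against the raw marker calls: each ambiguous zone is re-segmented by a
penalized three-state changepoint fit, and every segment boundary is re-fit
by a minimal-mismatch changepoint whose set of optimal split points defines
the reported breakpoint-uncertainty interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .simulate import MarkerCallMatrix
from .states import REC, DON, HET, MISSING, UNKNOWN

__all__ = [
    "WindowCall",
    "IntrogressionSegment",
    "classify_window",
    "classify_window_counts",
    "scan_windows",
    "consensus_marker_states",
    "call_segments",
    "call_line_segments",
    "call_population_segments",
]

DEFAULT_WINDOW = 15
DEFAULT_MIN_INFORMATIVE = 8


@dataclass(frozen=True)
class WindowCall:
    line: str
    chrom: str
    window_index: int
    first_marker: int   # marker index of first marker in window (within chrom)
    last_marker: int
    first_pos: int
    last_pos: int
    n_rec: int
    n_don: int
    n_other: int
    state: int


@dataclass
class IntrogressionSegment:
    """A maximal run of one diploid state along one chromosome of one line.

    ``left_uncertainty``/``right_uncertainty`` are (bp, bp) marker-position
    intervals bracketing the recombination breakpoint at each segment edge
    (None at chromosome ends).
    """

    line: str
    chrom: str
    start: int
    end: int
    state: int
    n_markers: int
    left_uncertainty: tuple[int, int] | None = None
    right_uncertainty: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------

def classify_window(n_rec: int, n_don: int,
                    min_informative: int = DEFAULT_MIN_INFORMATIVE) -> int:
    """Classify one window from its recurrent/donor call counts.

    Integer-arithmetic transcription of the published ratio rule:
    recurrent-homozygous when rec:don is strictly larger than 11:4,
    donor-homozygous when strictly smaller than 2:13, otherwise
    heterozygous; UNKNOWN when fewer than ``min_informative`` informative
    calls are available.
    """
    if n_rec < 0 or n_don < 0:
        raise ValueError("window counts must be non-negative")
    if n_rec + n_don < min_informative:
        return UNKNOWN
    if n_rec * 4 > n_don * 11:
        return REC
    if n_rec * 13 < n_don * 2:
        return DON
    return HET


def classify_window_counts(n_rec: np.ndarray, n_don: np.ndarray,
                           min_informative: int = DEFAULT_MIN_INFORMATIVE) -> np.ndarray:
    """Vectorized :func:`classify_window` over count arrays."""
    n_rec = np.asarray(n_rec, dtype=np.int64)
    n_don = np.asarray(n_don, dtype=np.int64)
    if np.any(n_rec < 0) or np.any(n_don < 0):
        raise ValueError("window counts must be non-negative")
    out = np.full(n_rec.shape, HET, dtype=np.int8)
    out[n_rec * 4 > n_don * 11] = REC
    out[n_rec * 13 < n_don * 2] = DON
    out[n_rec + n_don < min_informative] = UNKNOWN
    return out


def scan_windows(calls: np.ndarray, positions: np.ndarray,
                 window_size: int = DEFAULT_WINDOW, step: int = 1,
                 min_informative: int = DEFAULT_MIN_INFORMATIVE,
                 line: str = "", chrom: str = "") -> list[WindowCall]:
    """Slide windows of ``window_size`` markers along one chromosome.

    Windows start at marker indices 0, step, 2*step, ...; a final truncated
    window is emitted when fewer than ``window_size`` trailing markers remain
    but at least ``min_informative`` do.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    calls = np.asarray(calls, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(calls)
    if n < 1:
        raise ValueError("at least one marker required")
    starts = []
    i = 0
    while i + window_size <= n:
        starts.append((i, i + window_size))
        i += step
    if not starts or starts[-1][1] < n:
        # truncated trailing window
        if n - i >= min_informative:
            starts.append((i, n))
    crec = np.concatenate([[0], np.cumsum(calls == REC)])
    cdon = np.concatenate([[0], np.cumsum(calls == DON)])
    out = []
    for w, (a, b) in enumerate(starts):
        nr = int(crec[b] - crec[a])
        nd = int(cdon[b] - cdon[a])
        state = classify_window(nr, nd, min_informative)
        out.append(WindowCall(line, chrom, w, a, b - 1,
                              int(positions[a]), int(positions[b - 1]),
                              nr, nd, (b - a) - nr - nd, state))
    return out


def consensus_marker_states(window_calls: list[WindowCall], n_markers: int) -> np.ndarray:
    """Per-marker plurality vote over covering non-UNKNOWN windows.

    Ties between states go to HET; markers covered only by UNKNOWN windows
    (or by none) are UNKNOWN.
    """
    votes = np.zeros((3, n_markers + 1), dtype=np.int32)  # diff arrays, REC/DON/HET
    covered = np.zeros(n_markers + 1, dtype=np.int32)
    for wc in window_calls:
        covered[wc.first_marker] += 1
        covered[wc.last_marker + 1] -= 1
        if wc.state != UNKNOWN:
            votes[wc.state, wc.first_marker] += 1
            votes[wc.state, wc.last_marker + 1] -= 1
    votes = np.cumsum(votes[:, :-1], axis=1)
    covered = np.cumsum(covered[:-1])
    best = votes.max(axis=0)
    n_best = (votes == best).sum(axis=0)
    states = np.where(n_best > 1, HET, np.argmax(votes, axis=0)).astype(np.int8)
    states[best == 0] = UNKNOWN
    states[covered == 0] = UNKNOWN
    return states


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal value: list of (start_idx, end_idx_excl, value)."""
    out = []
    i, n = 0, len(states)
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        out.append((i, j, int(states[i])))
        i = j
    return out


def _absorb_unknown(states: np.ndarray) -> np.ndarray:
    """Assign UNKNOWN runs to flanks: both flanks agree -> that state; else
    the longer flank; single flank at chromosome ends -> that flank."""
    states = states.copy()
    runs = _runs(states)
    known = [r for r in runs if r[2] != UNKNOWN]
    if not known:
        return states
    for k, (a, b, v) in enumerate(runs):
        if v != UNKNOWN:
            continue
        left = next((r for r in reversed(runs[:k]) if r[2] != UNKNOWN), None)
        right = next((r for r in runs[k + 1:] if r[2] != UNKNOWN), None)
        if left is None and right is None:
            continue
        if left is None:
            states[a:b] = right[2]
        elif right is None:
            states[a:b] = left[2]
        elif left[2] == right[2]:
            states[a:b] = left[2]
        else:
            llen, rlen = left[1] - left[0], right[1] - right[0]
            states[a:b] = left[2] if llen >= rlen else right[2]
    return states


def call_segments(marker_states: np.ndarray, positions: np.ndarray,
                  chrom_length: int, line: str = "",
                  chrom: str = "") -> list[IntrogressionSegment]:
    """Turn a per-marker state sequence into maximal-run segments.

    UNKNOWN markers are absorbed into their flanking runs; breakpoints are
    placed at the integer midpoint between the last marker of the left run
    and the first marker of the right run, with the uncertainty interval
    spanning those two markers.  The first segment starts at 0 and the last
    ends at ``chrom_length``.
    """
    marker_states = np.asarray(marker_states, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    if np.all(marker_states == UNKNOWN):
        warnings.warn(f"all markers UNKNOWN on {chrom} of {line}; no segments called")
        return []
    states = _absorb_unknown(marker_states)
    runs = _runs(states)
    return _segments_from_runs(runs, positions, chrom_length, line, chrom)


def _segments_from_runs(runs, positions, chrom_length, line, chrom,
                        uncertainties=None) -> list[IntrogressionSegment]:
    """Build segments from index runs; ``uncertainties`` optionally supplies
    (lo_idx, hi_idx) marker-index brackets per internal boundary."""
    segs: list[IntrogressionSegment] = []
    n_runs = len(runs)
    bounds_bp = [0]
    bounds_unc = []
    for k in range(n_runs - 1):
        if uncertainties is not None:
            lo, hi = uncertainties[k]
        else:
            lo, hi = runs[k][1] - 1, runs[k + 1][0]
        p_lo, p_hi = int(positions[lo]), int(positions[hi])
        mid = (p_lo + p_hi) // 2
        # keep boundaries strictly ordered even when uncertainty brackets of
        # neighbouring breakpoints overlap on very noisy input
        mid = min(max(mid, bounds_bp[-1] + 1), chrom_length - (n_runs - 1 - k))
        bounds_bp.append(mid)
        bounds_unc.append((p_lo, p_hi))
    bounds_bp.append(chrom_length)
    for k, (a, b, v) in enumerate(runs):
        segs.append(IntrogressionSegment(
            line=line, chrom=chrom,
            start=bounds_bp[k], end=bounds_bp[k + 1], state=v,
            n_markers=b - a,
            left_uncertainty=bounds_unc[k - 1] if k > 0 else None,
            right_uncertainty=bounds_unc[k] if k < n_runs - 1 else None,
        ))
    return segs


# ---------------------------------------------------------------------------
# raw-call refinement
# ---------------------------------------------------------------------------

def _changepoint(raw: np.ndarray, lo: int, hi: int, x: int, y: int):
    """Optimal 2-state splits of raw calls on [lo, hi): left should match x,
    right should match y.  Returns (split_min, split_max, best_split) over
    the minimal-mismatch split set; splits are indices in [lo, hi]."""
    seg = raw[lo:hi]
    is_y = (seg == y).astype(np.int64)
    is_x = (seg == x).astype(np.int64)
    # cost(s) = #(y-calls left of s) + #(x-calls at/after s)
    cy = np.concatenate([[0], np.cumsum(is_y)])
    cx_suffix = np.concatenate([np.cumsum(is_x[::-1])[::-1], [0]])
    cost = cy + cx_suffix
    best = cost.min()
    opt = np.flatnonzero(cost == best)
    return lo + int(opt[0]), lo + int(opt[-1]), lo + int(opt[len(opt) // 2])


DEFAULT_SWITCH_PENALTY = 3


def _segment_raw(raw: np.ndarray, a: int, b: int,
                 penalty: int = DEFAULT_SWITCH_PENALTY) -> np.ndarray:
    """Penalized three-state changepoint segmentation of raw calls [a, b).

    Each marker pays one unit when its raw call disagrees with the assigned
    state (MISSING is neutral); each state switch pays ``penalty``.  The
    minimal-cost assignment over {REC, DON, HET} is found by dynamic
    programming with deterministic (lowest-state-first) tie-breaks.  A new
    segment therefore needs more than ``penalty`` net supporting calls at a
    zone edge (one switch) or ``2 * penalty`` in the interior.
    """
    seg = raw[a:b]
    n = len(seg)
    state_codes = np.array([REC, DON, HET], dtype=np.int8)
    mis = ((seg[:, None] != state_codes[None, :]) &
           (seg[:, None] != MISSING)).astype(np.int32)
    dp = mis[0].astype(np.int64)
    back = np.zeros((n, 3), dtype=np.int8)
    for i in range(1, n):
        best_prev = int(np.argmin(dp))
        stay = dp
        jump = dp[best_prev] + penalty
        choose_stay = stay <= jump
        back[i] = np.where(choose_stay, np.arange(3), best_prev)
        dp = np.where(choose_stay, stay, jump) + mis[i]
    out = np.empty(n, dtype=np.int8)
    s = int(np.argmin(dp))
    for i in range(n - 1, -1, -1):
        out[i] = state_codes[s]
        s = int(back[i, s])
    return out


def refine_marker_states(consensus: np.ndarray, raw: np.ndarray,
                         switch_penalty: int = DEFAULT_SWITCH_PENALTY) -> np.ndarray:
    """Refine window-consensus marker states against the raw calls.

    The strict window thresholds make every ambiguous region — the straddle
    zone of a homozygous-homozygous breakpoint, a truly heterozygous region
    (whose windows are UNKNOWN for lack of informative calls), or a donor
    segment too short to dominate any window — surface as a consensus HET or
    UNKNOWN zone.  Each maximal such zone is re-segmented from its raw calls
    by :func:`_segment_raw`; homozygous consensus runs are left untouched
    (their edges are corrected later by per-boundary changepoint fits).
    """
    states = consensus.copy()
    in_zone = (states == HET) | (states == UNKNOWN)
    for a, b, v in _runs(in_zone.astype(np.int8)):
        if v:
            states[a:b] = _segment_raw(raw, a, b, switch_penalty)
    return states


def call_line_segments(calls: np.ndarray, positions: np.ndarray,
                       chrom_length: int, line: str = "", chrom: str = "",
                       window_size: int = DEFAULT_WINDOW, step: int = 1,
                       min_informative: int = DEFAULT_MIN_INFORMATIVE,
                       switch_penalty: int = DEFAULT_SWITCH_PENALTY,
                       refine: bool = True) -> list[IntrogressionSegment]:
    """Full per-chromosome pipeline: windows -> consensus -> refinement ->
    segments with changepoint-refined breakpoints and uncertainty intervals.
    """
    wcs = scan_windows(calls, positions, window_size, step, min_informative,
                       line, chrom)
    consensus = consensus_marker_states(wcs, len(calls))
    if not refine:
        return call_segments(consensus, positions, chrom_length, line, chrom)
    states = refine_marker_states(consensus, np.asarray(calls, dtype=np.int8),
                                  switch_penalty)
    if np.all(states == UNKNOWN):
        warnings.warn(f"all markers UNKNOWN on {chrom} of {line}; no segments called")
        return []
    states = _absorb_unknown(states)
    runs = _runs(states)
    # boundary refinement: re-fit every inter-run boundary on the raw calls;
    # the optimal-split set defines the uncertainty bracket
    raw = np.asarray(calls, dtype=np.int8)
    refined_runs = [list(r) for r in runs]
    uncertainties = []
    prev_bound = 0
    for k in range(len(refined_runs) - 1):
        a0 = max(refined_runs[k][0], prev_bound)
        b1 = refined_runs[k + 1][1]
        x, y = refined_runs[k][2], refined_runs[k + 1][2]
        s_lo, s_hi, split = _changepoint(raw, a0, b1, x, y)
        # keep at least one marker in each run
        split = min(max(split, a0 + 1), b1 - 1)
        s_lo = min(max(s_lo, a0 + 1), split)
        s_hi = max(min(s_hi, b1 - 1), split)
        refined_runs[k][1] = split
        refined_runs[k + 1][0] = split
        uncertainties.append((s_lo - 1, s_hi))
        prev_bound = split
    # splits are clamped to leave >= 1 marker per run, so runs never empty
    # and adjacent runs keep their (distinct) states
    merged = [tuple(r) for r in refined_runs]
    return _segments_from_runs(merged, positions, chrom_length, line, chrom,
                               uncertainties=uncertainties)


def call_population_segments(matrix: MarkerCallMatrix, gmap: GeneticMap,
                             window_size: int = DEFAULT_WINDOW, step: int = 1,
                             min_informative: int = DEFAULT_MIN_INFORMATIVE,
                             refine: bool = True,
                             ) -> dict[str, list[IntrogressionSegment]]:
    """Call introgression segments for every line of a marker matrix."""
    out: dict[str, list[IntrogressionSegment]] = {}
    chrom_idx = {c.name: matrix.chrom_slice(c.name) for c in gmap.chromosomes}
    for i, line in enumerate(matrix.line_names):
        segs: list[IntrogressionSegment] = []
        for c in gmap.chromosomes:
            sel = chrom_idx[c.name]
            if len(sel) == 0:
                continue
            segs.extend(call_line_segments(
                matrix.calls[i, sel], matrix.positions[sel], c.length_bp,
                line=line, chrom=c.name, window_size=window_size, step=step,
                min_informative=min_informative, refine=refine))
        out[line] = segs
    return out
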