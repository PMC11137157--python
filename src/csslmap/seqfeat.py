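"""Telomere and centromeric-satellite detection in assembled sequences.

Telomeres: the plant telomeric heptamer (5'-CCCTAAA-3' at the 5' end;
its reverse complement TTTAGGG at the 3' end) is searched directly within
a terminal window at each sequence end.  Tandem arrays may be interrupted
by at most one non-motif heptamer between consecutive matches; an end is
telomere-bearing when its best array reaches ``min_copies`` copies.

Centromeric satellite: candidate spans are found by ungapped comparison of
a monomer consensus (e.g. the ~155-165 bp rice CentO repeat) against every
sequence offset in both orientations; offsets reaching the identity
threshold mark their footprint as satellite bases, and windows dense in
satellite bases are merged into maximal candidate spans.  This is a direct
consensus-matching scan, suited to dense near-identical arrays; it is not a
profile-HMM search and will not find highly diverged monomers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TelomereHit",
    "SatelliteSpan",
    "find_telomeres",
    "count_assembly_telomeres",
    "scan_satellite",
    "revcomp",
]

MOTIF_5P = "CCCTAAA"
MOTIF_3P = "TTTAGGG"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TelomereHit:
    seq_id: str
    end: str            # 'five_prime' | 'three_prime'
    motif: str
    copy_count: int
    start: int          # absolute 0-based span of the best array
    stop: int


@dataclass(frozen=True)
class SatelliteSpan:
    seq_id: str
    start: int
    end: int
    monomer_length: int
    mean_identity: float
    copy_estimate: float


def _best_array(window: str, motif: str) -> tuple[int, int, int]:
    """Longest motif chain in ``window`` allowing <= 1 interrupting heptamer
    between consecutive matches.  Returns (count, start, stop)."""
    k = len(motif)
    starts = []
    i = window.find(motif)
    while i != -1:
        starts.append(i)
        i = window.find(motif, i + k)  # non-overlapping tandem matches
    if not starts:
        return 0, 0, 0
    best = (1, starts[0], starts[0] + k)
    count, first = 1, starts[0]
    for prev, cur in zip(starts, starts[1:]):
        if cur - (prev + k) <= k:  # gap of at most one heptamer
            count += 1
        else:
            count, first = 1, cur
        if count > best[0]:
            best = (count, first, cur + k)
    return best


def find_telomeres(seq: str, seq_id: str = "seq",
                   motifs: tuple[str, str] = (MOTIF_5P, MOTIF_3P),
                   terminal_window: int = 10_000,
                   min_copies: int = 10) -> list[TelomereHit]:
    """Scan both terminal windows of ``seq`` for both telomeric motifs."""
    if not seq:
        raise ValueError("empty sequence")
    for m in motifs:
        if len(m) != 7:
            raise ValueError("telomeric motifs must be 7-mers")
    seq = seq.upper()
    w = min(terminal_window, len(seq))
    hits: list[TelomereHit] = []
    windows = {
        "five_prime": (seq[:w], 0),
        "three_prime": (seq[-w:], len(seq) - w),
    }
    for end, (window, offset) in windows.items():
        for motif in motifs:
            count, a, b = _best_array(window, motif)
            if count >= min_copies:
                hits.append(TelomereHit(seq_id, end, motif, count,
                                        offset + a, offset + b))
    return hits


def count_assembly_telomeres(sequences: dict[str, str],
                             terminal_window: int = 10_000,
                             min_copies: int = 10,
                             motifs: tuple[str, str] = (MOTIF_5P, MOTIF_3P),
                             ) -> tuple[int, pd.DataFrame]:
    """Count telomere-bearing (sequence, end) pairs across an assembly.

    Returns the total and a per-sequence table with 0, 1, or 2 ends.
    """
    if not sequences:
        raise ValueError("empty assembly")
    rows = []
    total = 0
    for sid, seq in sequences.items():
        hits = find_telomeres(seq, sid, motifs, terminal_window, min_copies)
        ends = {h.end for h in hits}
        total += len(ends)
        rows.append({"sequence": sid,
                     "five_prime": "five_prime" in ends,
                     "three_prime": "three_prime" in ends,
                     "n_telomeres": len(ends)})
    return total, pd.DataFrame(rows)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _identity_profile(s: np.ndarray, cons: np.ndarray) -> np.ndarray:
    """Fraction of matching bases for the consensus placed at every offset."""
    k = len(cons)
    n = len(s) - k + 1
    if n <= 0:
        return np.zeros(0)
    matches = np.zeros(n, dtype=np.int32)
    for j in range(k):
        matches += s[j:j + n] == cons[j]
    return matches / k


def scan_satellite(seq: str, monomer_consensus: str,
                   identity_threshold: float = 0.8,
                   window: int = 10_000,
                   density_cutoff: float = 0.5,
                   seq_id: str = "seq") -> list[SatelliteSpan]:
    """Find satellite-dense candidate (centromere-like) spans.

    Every offset is compared ungapped against the consensus in both
    orientations; offsets at or above ``identity_threshold`` mark their
    k-bp footprint as satellite.  Non-overlapping ``window``-bp windows
    with satellite-base density >= ``density_cutoff`` are merged into
    maximal spans, trimmed to the marked bases they contain.
    """
    k = len(monomer_consensus)
    if not 100 <= k <= 300:
        raise ValueError("monomer consensus length must be in [100, 300]")
    s = _encode(seq)
    n = len(s)
    marked = np.zeros(n + 1, dtype=np.int32)  # diff array of footprints
    id_sum = np.zeros(n)
    id_cnt = np.zeros(n)
    for cons_str in (monomer_consensus, revcomp(monomer_consensus)):
        prof = _identity_profile(s, _encode(cons_str))
        hit = np.flatnonzero(prof >= identity_threshold)
        for h in hit.tolist():
            marked[h] += 1
            marked[min(h + k, n)] -= 1
            id_sum[h] += prof[h]
            id_cnt[h] += 1
    is_sat = np.cumsum(marked[:-1]) > 0
    if not is_sat.any():
        return []
    # window densities
    n_win = (n + window - 1) // window
    dense = np.zeros(n_win, dtype=bool)
    for w in range(n_win):
        a, b = w * window, min((w + 1) * window, n)
        dense[w] = is_sat[a:b].mean() >= density_cutoff
    spans: list[SatelliteSpan] = []
    w = 0
    while w < n_win:
        if not dense[w]:
            w += 1
            continue
        v = w
        while v + 1 < n_win and dense[v + 1]:
            v += 1
        a, b = w * window, min((v + 1) * window, n)
        inside = np.flatnonzero(is_sat[a:b])
        if len(inside):
            lo, hi = a + int(inside[0]), a + int(inside[-1]) + 1
            sat_bases = int(is_sat[lo:hi].sum())
            sel = (id_cnt[lo:hi] > 0)
            mean_id = float(id_sum[lo:hi][sel].sum() / id_cnt[lo:hi][sel].sum()) \
                if sel.any() else 0.0
            spans.append(SatelliteSpan(seq_id, lo, hi, k, mean_id,
                                       sat_bases / k))
        w = v + 1
    return spans
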