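"""Backcross / selfing simulator for CSSL populations with known ground truth.

Emulates the construction of chromosome segment substitution lines: an F1
between a donor (wild) and a recurrent (cultivated) parent is backcrossed to
the recurrent parent for ``n_backcross`` generations and then self-pollinated
for ``n_self`` generations, optionally with marker-assisted selection that
caps the number of retained donor segments per line.

Crossovers follow a Poisson model with no interference (count per
chromosome ~ Poisson(length_cM / 100), positions uniform in cM), i.e. the
Haldane mapping function, which is analytically checkable: the recombinant
fraction between loci d cM apart is (1 - exp(-2d/100)) / 2, and the mean
donor-genome fraction after n backcrosses (no selection) is 2^-(n+1).

Ground truth (the two haplotypes of every line, as exact bp partitions) is
retained so every downstream caller can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap
from .states import REC, DON, HET, MISSING

__all__ = [
    "Haplotype",
    "SimConfig",
    "QtlSpec",
    "LineTruth",
    "SimTruth",
    "MarkerCallMatrix",
    "PhenotypeTable",
    "simulate_gamete",
    "simulate_cssl_population",
    "genotype_markers",
    "simulate_phenotypes",
]


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

class Haplotype:
    """One gametic haplotype: per chromosome, a partition into origin runs.

    Stored per chromosome as ``(ends, origins)`` where ``ends`` are the
    right edges (exclusive) of maximal runs and ``origins`` their parental
    origin (REC or DON).  The last end equals the chromosome length, so the
    runs partition the chromosome exactly.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.data = data

    @classmethod
    def uniform(cls, gmap: GeneticMap, origin: int) -> "Haplotype":
        return cls({
            c.name: (np.array([c.length_bp], dtype=np.int64),
                     np.array([origin], dtype=np.int8))
            for c in gmap.chromosomes
        })

    def origin_at(self, chrom: str, pos) -> np.ndarray:
        """Origin of each (0-based) bp position on ``chrom`` (vectorized)."""
        ends, orgs = self.data[chrom]
        idx = np.searchsorted(ends, pos, side="right")
        return orgs[idx]

    def segments(self, chrom: str) -> list[tuple[int, int, int]]:
        ends, orgs = self.data[chrom]
        out, start = [], 0
        for e, o in zip(ends.tolist(), orgs.tolist()):
            out.append((start, int(e), int(o)))
            start = int(e)
        return out

    def validate(self, gmap: GeneticMap) -> None:
        for c in gmap.chromosomes:
            ends, orgs = self.data[c.name]
            if ends[-1] != c.length_bp or np.any(np.diff(ends) <= 0) or ends[0] <= 0:
                raise ValueError(f"haplotype does not partition {c.name}")
            if np.any(orgs[:-1] == orgs[1:]):
                raise ValueError(f"adjacent runs share origin on {c.name}")


def _merge_runs(ends: np.ndarray, orgs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(ends) <= 1:
        return ends, orgs
    keep = np.empty(len(ends), dtype=bool)
    keep[:-1] = orgs[:-1] != orgs[1:]
    keep[-1] = True
    return ends[keep], orgs[keep]


def simulate_gamete(gmap: GeneticMap, parent: tuple[Haplotype, Haplotype],
                    rng: np.random.Generator,
                    obligate_crossover: bool = False) -> Haplotype:
    """Draw one recombinant gamete from a diploid parent.

    Per chromosome the crossover count is Poisson(length_cM/100) (at least 1
    when ``obligate_crossover``), crossover positions are uniform in cM and
    mapped to bp through the genetic map, and the starting haplotype is a
    fair coin flip.
    """
    hap_a, hap_b = parent
    out = {}
    for c in gmap.chromosomes:
        k = int(rng.poisson(c.length_cm / 100.0))
        if obligate_crossover and k == 0:
            k = 1
        if k:
            xs_cm = rng.uniform(0.0, c.length_cm, size=k)
            xs = np.unique(np.rint(gmap.bp_at(c.name, np.sort(xs_cm))).astype(np.int64))
            xs = xs[(xs > 0) & (xs < c.length_bp)]
        else:
            xs = np.empty(0, dtype=np.int64)
        src = int(rng.integers(2))
        bounds = np.concatenate([xs, [c.length_bp]])
        ends_parts, org_parts = [], []
        start = 0
        haps = (hap_a, hap_b)
        for b in bounds.tolist():
            e_src, o_src = haps[src].data[c.name]
            i0 = int(np.searchsorted(e_src, start, side="right"))
            i1 = int(np.searchsorted(e_src, b, side="left"))
            seg_ends = np.concatenate([e_src[i0:i1], [b]]).astype(np.int64)
            seg_orgs = o_src[i0:i1 + 1].astype(np.int8)
            ends_parts.append(seg_ends)
            org_parts.append(seg_orgs)
            start = int(b)
            src ^= 1
        ends = np.concatenate(ends_parts)
        orgs = np.concatenate(org_parts)
        # remove zero-length pieces created at crossover points on run edges
        keep = np.empty(len(ends), dtype=bool)
        keep[0] = ends[0] > 0
        keep[1:] = np.diff(ends) > 0
        out[c.name] = _merge_runs(ends[keep], orgs[keep])
    return Haplotype(out)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Breeding-scheme parameters for a simulated CSSL population.

    Defaults emulate a CSSL population of the less-backcrossed kind
    (2 backcrosses + 3 selfings), which lands near ~87.5% recurrent genome
    before selection; use ``n_backcross=4`` for a highly backcrossed
    population (~96.9% recurrent).
    """

    n_lines: int = 225
    n_backcross: int = 2
    n_self: int = 3
    markers_per_chrom: int = 400
    call_error_rate: float = 0.0
    missing_rate: float = 0.0
    max_donor_segments: int | None = None  # selection rule; None = no selection
    max_selection_attempts: int = 10_000
    obligate_crossover: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.n_backcross < 1:
            raise ValueError("n_backcross must be >= 1")
        if self.n_self < 0:
            raise ValueError("n_self must be >= 0")
        for name in ("call_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QtlSpec:
    """Planted additive QTLs: y = mean + sum(a * dosage) + N(0, residual_sd).

    Dosage is the donor-allele dose scaled to {0, 0.5, 1}.  Either
    ``residual_sd`` is given directly or per-locus ``pve`` targets are given
    and the residual SD is derived from the realized genetic variance.
    """

    loci: list[tuple[str, int, float]] = field(default_factory=list)  # (chrom, pos, a)
    pve: list[float] | None = None
    residual_sd: float | None = 1.0
    mean: float = 0.0

    def validate(self) -> None:
        if self.pve is not None:
            if len(self.pve) != len(self.loci):
                raise ValueError("pve list must match loci")
            if sum(self.pve) >= 1.0:
                raise ValueError("requested PVE must sum to < 1")


@dataclass
class LineTruth:
    name: str
    hap1: Haplotype
    hap2: Haplotype

    def diploid_partition(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Exact diploid-state partition of ``chrom``: (run ends, states)."""
        e1, o1 = self.hap1.data[chrom]
        e2, o2 = self.hap2.data[chrom]
        ends = np.union1d(e1, e2)
        i1 = np.searchsorted(e1, ends - 1, side="right")
        i2 = np.searchsorted(e2, ends - 1, side="right")
        a, b = o1[i1], o2[i2]
        states = np.where(a == b, a, HET).astype(np.int8)
        return _merge_runs(ends, states)

    def state_at(self, chrom: str, pos) -> np.ndarray:
        ends, states = self.diploid_partition(chrom)
        return states[np.searchsorted(ends, pos, side="right")]

    def dosage_at(self, chrom: str, pos) -> np.ndarray:
        s = self.state_at(chrom, pos)
        return np.select([s == DON, s == HET], [1.0, 0.5], default=0.0)


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    gmap: GeneticMap
    config: SimConfig
    lines: list[LineTruth]
    qtl_spec: QtlSpec | None = None
    residual_sd_used: float | None = None

    @property
    def line_names(self) -> list[str]:
        return [ln.name for ln in self.lines]

    def donor_fraction(self, line: LineTruth) -> float:
        """Donor-origin fraction of the diploid genome (HET counts half)."""
        tot = don = 0.0
        for c in self.gmap.chromosomes:
            ends, states = line.diploid_partition(c.name)
            widths = np.diff(np.concatenate([[0], ends]))
            don += widths[states == DON].sum() + 0.5 * widths[states == HET].sum()
            tot += c.length_bp
        return don / tot

    def het_fraction(self, line: LineTruth) -> float:
        tot = het = 0.0
        for c in self.gmap.chromosomes:
            ends, states = line.diploid_partition(c.name)
            widths = np.diff(np.concatenate([[0], ends]))
            het += widths[states == HET].sum()
            tot += c.length_bp
        return het / tot

    def donor_segment_count(self, line: LineTruth) -> int:
        n = 0
        for c in self.gmap.chromosomes:
            _, states = line.diploid_partition(c.name)
            n += int(np.sum(states == DON))
        return n

    def to_segments(self) -> dict[str, list]:
        """Ground-truth diploid segments per line, in the caller's format
        (for scoring called segments/tiles against the truth)."""
        from .genotyper import IntrogressionSegment
        out: dict[str, list] = {}
        for ln in self.lines:
            segs = []
            for c in self.gmap.chromosomes:
                ends, states = ln.diploid_partition(c.name)
                start = 0
                for e, s in zip(ends.tolist(), states.tolist()):
                    segs.append(IntrogressionSegment(ln.name, c.name, start,
                                                     int(e), int(s), 0))
                    start = int(e)
            out[ln.name] = segs
        return out

    def true_breakpoints(self, line: LineTruth) -> list[tuple[str, int, int, int]]:
        """All diploid-state transitions: (chrom, bp, left_state, right_state)."""
        out = []
        for c in self.gmap.chromosomes:
            ends, states = line.diploid_partition(c.name)
            for i in range(len(ends) - 1):
                out.append((c.name, int(ends[i]), int(states[i]), int(states[i + 1])))
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "lines": [
                {
                    "name": ln.name,
                    "haplotypes": [
                        {c: [ends.tolist(), orgs.tolist()]
                         for c, (ends, orgs) in hap.data.items()}
                        for hap in (ln.hap1, ln.hap2)
                    ],
                }
                for ln in self.lines
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict, gmap: GeneticMap, config: SimConfig | None = None) -> "SimTruth":
        lines = []
        for rec in d["lines"]:
            haps = []
            for hap in rec["haplotypes"]:
                haps.append(Haplotype({
                    c: (np.asarray(ends, dtype=np.int64), np.asarray(orgs, dtype=np.int8))
                    for c, (ends, orgs) in hap.items()
                }))
            lines.append(LineTruth(rec["name"], haps[0], haps[1]))
        return cls(gmap, config or SimConfig(), lines)


def _line_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # per-line substreams derived deterministically from one master seed
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cssl_population(gmap: GeneticMap, config: SimConfig,
                             rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate a CSSL population and return its full ground truth.

    F1 = one donor + one recurrent haplotype; each backcross replaces one
    haplotype with a gamete from the current plant and the other with a pure
    recurrent gamete; each selfing draws two independent gametes from the
    same plant.  With ``max_donor_segments`` set, lines exceeding the cap are
    rejected and redrawn (marker-assisted selection emulation), up to
    ``max_selection_attempts`` per line.
    """
    config.validate()
    del rng  # reproducibility comes from config.seed via per-line substreams
    rec_hap = Haplotype.uniform(gmap, REC)
    don_hap = Haplotype.uniform(gmap, DON)
    rngs = _line_rngs(config.seed, config.n_lines)
    lines: list[LineTruth] = []
    truth = SimTruth(gmap, config, lines)
    for i, line_rng in enumerate(rngs):
        name = f"L{i + 1:04d}"
        for attempt in range(config.max_selection_attempts):
            plant = (don_hap, rec_hap)  # F1
            for _ in range(config.n_backcross):
                g = simulate_gamete(gmap, plant, line_rng,
                                    obligate_crossover=config.obligate_crossover)
                plant = (g, rec_hap)
            for _ in range(config.n_self):
                g1 = simulate_gamete(gmap, plant, line_rng,
                                     obligate_crossover=config.obligate_crossover)
                g2 = simulate_gamete(gmap, plant, line_rng,
                                     obligate_crossover=config.obligate_crossover)
                plant = (g1, g2)
            line = LineTruth(name, plant[0], plant[1])
            if config.max_donor_segments is None:
                break
            if truth.donor_segment_count(line) <= config.max_donor_segments:
                break
        else:
            raise RuntimeError(
                f"selection rule unsatisfied for line {name} within "
                f"{config.max_selection_attempts} attempts"
            )
        lines.append(line)
    return truth


# ---------------------------------------------------------------------------
# marker genotyping
# ---------------------------------------------------------------------------

@dataclass
class MarkerCallMatrix:
    """Lines x ordered markers of parental-origin calls.

    ``markers`` holds (id, chrom, pos) with pos 0-based and strictly
    increasing within each chromosome; ``calls`` is an int8 array of shape
    (n_lines, n_markers) over {REC, DON, HET, MISSING}.
    """

    line_names: list[str]
    marker_ids: list[str]
    chroms: np.ndarray      # str array, per marker
    positions: np.ndarray   # int64, 0-based, per marker
    calls: np.ndarray       # int8 (n_lines, n_markers)

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_names), len(self.marker_ids)):
            raise ValueError("call matrix shape inconsistent with line/marker lists")
        for chrom in dict.fromkeys(self.chroms.tolist()):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom} "
                    f"(marker index {bad} within chromosome)")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > MISSING):
            raise ValueError("calls contain values outside the REC/DON/HET/MISSING alphabet")

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerCallMatrix):
            return NotImplemented
        return (self.line_names == other.line_names
                and self.marker_ids == other.marker_ids
                and np.array_equal(self.chroms, other.chroms)
                and np.array_equal(self.positions, other.positions)
                and np.array_equal(self.calls, other.calls))


def _place_markers(gmap: GeneticMap, markers_per_chrom, rng: np.random.Generator):
    ids, chroms, positions = [], [], []
    for c in gmap.chromosomes:
        n = markers_per_chrom[c.name] if isinstance(markers_per_chrom, dict) \
            else int(markers_per_chrom)
        if n < 1:
            raise ValueError(f"zero markers requested on {c.name}")
        # uniform placement without replacement; oversample then trim
        pos = np.unique(rng.integers(0, c.length_bp, size=min(4 * n, c.length_bp)))
        while len(pos) < n:
            pos = np.unique(np.concatenate(
                [pos, rng.integers(0, c.length_bp, size=n)]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        chroms.extend([c.name] * n)
        positions.append(pos)
        ids.extend(f"{c.name}_{p + 1}" for p in pos.tolist())
    return ids, np.asarray(chroms), np.concatenate(positions)


def genotype_markers(truth: SimTruth, gmap: GeneticMap, markers_per_chrom,
                     error_rate: float = 0.0, missing_rate: float = 0.0,
                     rng: np.random.Generator | None = None) -> MarkerCallMatrix:
    """Observe the population at random marker positions with call noise.

    The true call is the line's diploid state at the marker; with probability
    ``missing_rate`` the call is replaced by MISSING, otherwise with
    probability ``error_rate`` by one of the two other (non-missing) states
    uniformly.
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = rng or np.random.default_rng(truth.config.seed + 1)
    ids, chroms, positions = _place_markers(gmap, markers_per_chrom, rng)
    n_lines, n_mark = len(truth.lines), len(ids)
    calls = np.empty((n_lines, n_mark), dtype=np.int8)
    for j, line in enumerate(truth.lines):
        for c in gmap.chromosomes:
            sel = chroms == c.name
            calls[j, sel] = line.state_at(c.name, positions[sel])
    if missing_rate > 0 or error_rate > 0:
        u_miss = rng.random(calls.shape)
        u_err = rng.random(calls.shape)
        pick = rng.integers(0, 2, size=calls.shape)
        # the two alternative states for each true call, in {REC, DON, HET}
        others = np.array([[DON, HET], [REC, HET], [REC, DON], [0, 0]], dtype=np.int8)
        err_vals = others[calls, pick]
        err_mask = (u_err < error_rate) & (u_miss >= missing_rate)
        calls[err_mask] = err_vals[err_mask]
        calls[u_miss < missing_rate] = MISSING
    return MarkerCallMatrix(list(truth.line_names), ids, chroms, positions, calls)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    line_names: list[str]
    traits: dict[str, np.ndarray]  # trait name -> float array (NaN = missing)

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name]


def simulate_phenotypes(truth: SimTruth, qtl_spec: QtlSpec,
                        rng: np.random.Generator | None = None,
                        trait_name: str = "trait") -> PhenotypeTable:
    """Simulate an additive trait on the population from planted QTLs.

    Dosages are read from the ground-truth haplotypes at the planted
    positions.  When per-locus PVE targets are requested, the residual SD is
    derived from the realized genetic variance so that the total planted PVE
    equals the requested sum in expectation.
    """
    qtl_spec.validate()
    rng = rng or np.random.default_rng(truth.config.seed + 2)
    for chrom, pos, _ in qtl_spec.loci:
        if chrom not in truth.gmap or not 0 <= pos < truth.gmap.chromosome(chrom).length_bp:
            raise ValueError(f"QTL position {chrom}:{pos} outside the map")
    n = len(truth.lines)
    g = np.zeros(n)
    for chrom, pos, a in qtl_spec.loci:
        dos = np.array([ln.dosage_at(chrom, pos) for ln in truth.lines], dtype=float)
        g += a * dos
    if qtl_spec.pve is not None:
        total_pve = float(sum(qtl_spec.pve))
        vg = float(np.var(g))
        if vg == 0.0:
            raise ValueError("planted QTLs are monomorphic; cannot target a PVE")
        sd = np.sqrt(vg * (1.0 - total_pve) / total_pve)
    else:
        sd = float(qtl_spec.residual_sd)
    y = qtl_spec.mean + g + rng.normal(0.0, sd, size=n)
    truth.qtl_spec = qtl_spec
    truth.residual_sd_used = sd
    return PhenotypeTable(list(truth.line_names), {trait_name: y})
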