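"""Genetic map: the bp <-> cM duality of each chromosome.

The map carries, per chromosome, a monotone list of (bp, cM) anchor points;
positions between anchors are linearly interpolated.  The default map built
by :func:`make_genetic_map` is linear (two anchors per chromosome), which is
the standard assumption when no empirical recombination map is available.
Internally all bp coordinates are 0-based half-open; serialized anchors are
written 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float


class GeneticMap:
    """Ordered chromosomes plus piecewise-linear bp<->cM interpolation.

    Parameters
    ----------
    chromosomes
        Ordered ``Chromosome`` records.
    anchors
        Optional mapping ``name -> (bp_array, cm_array)`` of interior anchor
        points (0-based bp).  End anchors (0, 0.0) and (length_bp, length_cM)
        are always installed; supplied anchors must lie strictly between
        them and be strictly increasing in both coordinates.
    """

    def __init__(self, chromosomes: Sequence[Chromosome], anchors: dict | None = None):
        self.chromosomes = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names in map")
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        anchors = anchors or {}
        for c in self.chromosomes:
            bp = [0.0, float(c.length_bp)]
            cm = [0.0, float(c.length_cm)]
            if c.name in anchors:
                abp, acm = anchors[c.name]
                abp = np.asarray(abp, dtype=float)
                acm = np.asarray(acm, dtype=float)
                if np.any(abp <= 0) or np.any(abp >= c.length_bp):
                    raise ValueError(f"interior anchors outside chromosome {c.name}")
                bp = [0.0, *abp.tolist(), float(c.length_bp)]
                cm = [0.0, *acm.tolist(), float(c.length_cm)]
            bp_a, cm_a = np.asarray(bp), np.asarray(cm)
            if np.any(np.diff(bp_a) <= 0) or np.any(np.diff(cm_a) <= 0):
                raise ValueError(f"anchors not strictly increasing on {c.name}")
            self._anchors[c.name] = (bp_a, cm_a)

    # -- lookup ------------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def total_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes)

    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    # -- interpolation -----------------------------------------------------
    def cm_at(self, chrom: str, bp) -> np.ndarray | float:
        bp_a, cm_a = self._anchors[self.chromosome(chrom).name]
        return np.interp(bp, bp_a, cm_a)

    def bp_at(self, chrom: str, cm) -> np.ndarray | float:
        bp_a, cm_a = self._anchors[self.chromosome(chrom).name]
        return np.interp(cm, cm_a, bp_a)

    def cm_span(self, chrom: str, start_bp: int, end_bp: int) -> float:
        """Genetic length of the bp interval [start_bp, end_bp)."""
        return float(self.cm_at(chrom, end_bp) - self.cm_at(chrom, start_bp))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "chromosomes": [
                {"name": c.name, "length_bp": c.length_bp, "length_cm": c.length_cm}
                for c in self.chromosomes
            ],
            # anchors serialized 1-based, per map-file convention
            "anchors": {
                name: [[int(b) + 1 if i not in (0, len(bp) - 1) else (1 if i == 0 else int(b)), c]
                       for i, (b, c) in enumerate(zip(bp, cm))]
                for name, (bp, cm) in self._anchors.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneticMap":
        chroms = [Chromosome(c["name"], int(c["length_bp"]), float(c["length_cm"]))
                  for c in d["chromosomes"]]
        anchors = {}
        for name, pts in d.get("anchors", {}).items():
            if len(pts) > 2:
                interior = pts[1:-1]
                anchors[name] = ([p[0] - 1 for p in interior], [p[1] for p in interior])
        return cls(chroms, anchors)

    @classmethod
    def from_json(cls, path) -> "GeneticMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self._anchors[n][0], other._anchors[n][0])
            and np.array_equal(self._anchors[n][1], other._anchors[n][1])
            for n in self._by_name
        )


def make_genetic_map(spec: Iterable[tuple[str, int, float]]) -> GeneticMap:
    """Build a linear genetic map from ``(name, length_bp, length_cM)`` triples.

    Raises ``ValueError`` naming the offending chromosome on duplicate names
    or non-positive lengths.
    """
    chroms = []
    seen = set()
    for name, length_bp, length_cm in spec:
        if name in seen:
            raise ValueError(f"duplicate chromosome name {name!r}")
        if length_bp <= 0 or length_cm <= 0:
            raise ValueError(f"non-positive length for chromosome {name!r}")
        seen.add(name)
        chroms.append(Chromosome(str(name), int(length_bp), float(length_cm)))
    return GeneticMap(chroms)


def rice_like_map(n_chrom: int = 12, length_bp: int = 30_000_000,
                  length_cm: float = 130.0) -> GeneticMap:
    """Convenience map resembling a 12-chromosome rice genome (~360 Mb, ~1560 cM)."""
    return make_genetic_map(
        (f"chr{i + 1:02d}", length_bp, length_cm) for i in range(n_chrom)
    )
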