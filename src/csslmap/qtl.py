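"""Bin-based additive QTL scan with LOD scoring.

The model at each recombination bin is the standard Gaussian single-QTL
regression: y = mu + a * x + (cofactors) + e, with donor-dosage coding
x in {0, 0.5, 1} for recurrent-homozygous / heterozygous / donor-homozygous
genotypes.  The test statistic is the likelihood-ratio LOD,

    LOD = (n / 2) * log10(RSS0 / RSS1),

equivalently LRT / (2 ln 10) under Gaussian residuals.  Background genetic
variation is absorbed by forward-stepwise cofactor bins (partial-F entry
test), excluded within a cM window of the tested bin — a stepwise-additive
scan in the spirit of composite interval mapping / the RSETP-LRT-ADD
procedure of QTL IciMapping, whose exact internals are not public.  Hits
are flagged at the conventional LOD >= 2.5; a permutation-derived
genome-wide threshold is available alongside.

Organised as a model/results pair: :class:`BinQtlScan` holds the data,
``fit()`` returns a :class:`QtlScanResults` carrying the per-bin estimates,
peak table, and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinGenotypeMatrix
from .genmap import GeneticMap

__all__ = [
    "QtlHit",
    "BinQtlScan",
    "QtlScanResults",
    "fit_additive",
    "lod_from_rss",
    "select_cofactors",
]

LOD_CEILING = 300.0  # reported when RSS1 underflows to ~0 (perfect fit)
DEFAULT_LOD_THRESHOLD = 2.5


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def fit_additive(y: np.ndarray, x: np.ndarray | None,
                 cofactors: np.ndarray | None = None):
    """OLS of y on intercept + cofactors (+ x); returns (RSS, a, se_a).

    ``x`` may be None (reduced model; a and se are NaN).  Rows containing
    NaN in any regressor or in y must already be removed.  Rank-deficient
    cofactor blocks are reduced by QR column selection with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    blocks = [np.ones((n, 1))]
    if cofactors is not None and cofactors.size:
        blocks.append(np.asarray(cofactors, dtype=float).reshape(n, -1))
    if x is not None:
        blocks.append(np.asarray(x, dtype=float).reshape(n, 1))
    X = np.hstack(blocks)
    p = X.shape[1]
    if n < p + 3:
        raise ValueError("need at least 3 more observations than parameters")
    coef, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        # drop dependent cofactor columns, keep intercept and x
        warnings.warn("rank-deficient design; dropping dependent cofactor columns")
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        if x is not None:
            keep[-1] = True
        keep[0] = True
        X = X[:, keep]
        p = X.shape[1]
        coef, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    if x is None:
        return rss, float("nan"), float("nan")
    a = float(coef[-1])
    dof = n - p
    if dof <= 0:
        return rss, a, float("nan")
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    return rss, a, se


def lod_from_rss(rss0: float, rss1: float, n: int,
                 ceiling: float = LOD_CEILING) -> float:
    """LOD = (n/2) * log10(RSS0/RSS1); capped at ``ceiling`` when RSS1 ~ 0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss1 < 0 or rss0 < rss1 - 1e-9 * max(rss0, 1.0):
        raise ValueError("require RSS0 >= RSS1 >= 0")
    if rss1 <= 1e-300 or rss0 <= 0:
        return ceiling if rss0 > 0 else 0.0
    return float(min((n / 2.0) * np.log10(rss0 / rss1), ceiling))


def _mean_impute(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float).copy()
    mask = np.isnan(D)
    if mask.any():
        mu = np.nanmean(np.where(mask, np.nan, D), axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        D[mask] = np.broadcast_to(mu, D.shape)[mask]
    return D


def select_cofactors(y: np.ndarray, dosage: np.ndarray,
                     p_enter: float = 1e-3,
                     max_cofactors: int | None = None) -> list[int]:
    """Forward stepwise selection of background (cofactor) bins.

    At each step the candidate with the smallest partial-F p-value below
    ``p_enter`` enters; ties break deterministically by (p-value, genomic
    order).  Missing dosages are column-mean imputed for this search.
    Returns selected bin indices in order of entry.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    D = _mean_impute(np.asarray(dosage, dtype=float)[ok])
    n, m = D.shape
    if max_cofactors is None:
        max_cofactors = max(1, n // 10)
    if max_cofactors == 0:
        return []
    selected: list[int] = []
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of current design
    y_r = y - Q @ (Q.T @ y)
    D_r = D - Q @ (Q.T @ D)
    active = np.ones(m, dtype=bool)
    while len(selected) < max_cofactors:
        rss = float(y_r @ y_r)
        norms = np.einsum("ij,ij->j", D_r, D_r)
        usable = active & (norms > 1e-12)
        if not usable.any() or rss <= 0:
            break
        proj = D_r.T @ y_r
        red = np.where(usable, proj ** 2 / np.where(usable, norms, 1.0), 0.0)
        dof = n - (len(selected) + 2)
        if dof < 1:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            F = red / np.maximum(rss - red, 1e-300) * dof
        pvals = np.where(usable, stats.f.sf(F, 1, dof), np.inf)
        j = int(np.lexsort((np.arange(m), pvals))[0])
        if pvals[j] >= p_enter:
            break
        selected.append(j)
        active[j] = False
        v = D_r[:, j] / np.sqrt(norms[j])
        Q = np.hstack([Q, v[:, None]])
        y_r = y_r - v * (v @ y_r)
        D_r = D_r - np.outer(v, v @ D_r)
    return selected


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class QtlHit:
    bin_index: int
    chrom: str
    start: int
    end: int
    lod: float
    additive_effect: float
    pve: float
    n_used: int
    passes_threshold: bool
    support_start: int | None = None  # 1.5-LOD drop interval
    support_end: int | None = None


class BinQtlScan:
    """Additive QTL scan of one trait over a recombination-bin matrix.

    Parameters
    ----------
    endog
        Phenotype values, one per line (NaN = missing).
    bin_matrix
        A :class:`~csslmap.bins.BinGenotypeMatrix`; its donor-dosage coding
        (0 / 0.5 / 1) is used as the regressor at each bin.
    genetic_map
        Needed for the cM exclusion window around the tested bin and for
        peak-distance reporting; optional when ``use_cofactors=False``.
    """

    def __init__(self, endog, bin_matrix: BinGenotypeMatrix,
                 genetic_map: GeneticMap | None = None,
                 trait_name: str = "trait"):
        self.endog = np.asarray(endog, dtype=float)
        if len(self.endog) != len(bin_matrix.line_names):
            raise ValueError("phenotype length does not match line count")
        self.bin_matrix = bin_matrix
        self.gmap = genetic_map
        self.trait_name = trait_name
        self.dosage = bin_matrix.dosage()
        self._chrom = np.array([b.chrom for b in bin_matrix.bins])
        if genetic_map is not None:
            self._bin_cm = np.array([
                genetic_map.cm_at(b.chrom, (b.start + b.end) / 2)
                for b in bin_matrix.bins
            ])
        else:
            self._bin_cm = None

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, bin_matrix: BinGenotypeMatrix,
                    trait: str, genetic_map: GeneticMap | None = None) -> "BinQtlScan":
        """Build from a phenotype table indexed by line name (subset-matched)."""
        y = phenotypes.reindex(bin_matrix.line_names)[trait].to_numpy(dtype=float)
        return cls(y, bin_matrix, genetic_map, trait_name=trait)

    # -- fitting -----------------------------------------------------------
    def fit(self, use_cofactors: bool = True, p_enter: float = 1e-3,
            max_cofactors: int | None = None, window_cm: float = 10.0,
            lod_threshold: float = DEFAULT_LOD_THRESHOLD) -> "QtlScanResults":
        y_all = self.endog
        have_y = ~np.isnan(y_all)
        if have_y.sum() < 30:
            raise ValueError("need >= 30 lines with phenotype")
        cof_idx: list[int] = []
        if use_cofactors:
            cof_idx = select_cofactors(y_all, self.dosage, p_enter, max_cofactors)
            if cof_idx and self._bin_cm is None:
                raise ValueError("genetic_map required for cofactor exclusion windows")
        lods = np.full(self.dosage.shape[1], np.nan)
        effects = np.full_like(lods, np.nan)
        pves = np.full_like(lods, np.nan)
        ns = np.zeros(len(lods), dtype=int)
        skipped: list[int] = []
        for j in range(self.dosage.shape[1]):
            xj = self.dosage[:, j]
            Zidx = [k for k in cof_idx if k != j and not self._within_window(k, j, window_cm)]
            Z = self.dosage[:, Zidx] if Zidx else None
            rows = have_y & ~np.isnan(xj)
            if Z is not None:
                rows &= ~np.isnan(Z).any(axis=1)
            yv = y_all[rows]
            xv = xj[rows]
            n = len(yv)
            if n < (2 + len(Zidx)) + 3 or np.ptp(xv) == 0:
                skipped.append(j)
                continue
            Zv = Z[rows] if Z is not None else None
            rss0, _, _ = fit_additive(yv, None, Zv)
            rss1, a, _ = fit_additive(yv, xv, Zv)
            tss = float(np.sum((yv - yv.mean()) ** 2))
            lods[j] = lod_from_rss(rss0, rss1, n)
            effects[j] = a
            pves[j] = (rss0 - rss1) / tss if tss > 0 else 0.0
            ns[j] = n
        return QtlScanResults(self, lods, effects, pves, ns, skipped, cof_idx,
                              lod_threshold)

    def _within_window(self, k: int, j: int, window_cm: float) -> bool:
        if self._chrom[k] != self._chrom[j]:
            return False
        if self._bin_cm is None:
            return True  # no map: conservatively exclude same-chromosome cofactors
        return abs(self._bin_cm[k] - self._bin_cm[j]) < window_cm

    # -- fast no-cofactor machinery (shared by permutations/calibration) ---
    def _single_marker_lods(self, Y: np.ndarray) -> np.ndarray:
        """Vectorized no-cofactor LOD for one or many phenotype columns.

        Missing dosages are column-mean imputed; Y is (n,) or (n, r).
        Returns LODs of shape (m,) or (m, r).
        """
        Y = np.asarray(Y, dtype=float)
        one_d = Y.ndim == 1
        Y = Y.reshape(len(Y), -1)
        D = _mean_impute(self.dosage)
        n = D.shape[0]
        Dc = D - D.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        tss = np.einsum("ij,ij->j", Yc, Yc)
        norms = np.einsum("ij,ij->j", Dc, Dc)
        proj = Dc.T @ Yc  # (m, r)
        with np.errstate(divide="ignore", invalid="ignore"):
            red = proj ** 2 / norms[:, None]
        red[norms <= 1e-12] = 0.0
        rss1 = np.maximum(tss[None, :] - red, 1e-300)
        lods = (n / 2.0) * np.log10(np.maximum(tss[None, :], 1e-300) / rss1)
        lods = np.minimum(lods, LOD_CEILING)
        return lods[:, 0] if one_d else lods

    def permutation_threshold(self, n_perm: int = 1000, alpha: float = 0.05,
                              rng: np.random.Generator | None = None) -> float:
        """Genome-wide LOD threshold: (1-alpha) quantile of max-LOD over
        phenotype permutations (no-cofactor scan; seed-reproducible)."""
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = rng or np.random.default_rng(0)
        y = self.endog
        ok = ~np.isnan(y)
        yv = y[ok]
        perms = np.stack([rng.permutation(yv) for _ in range(n_perm)], axis=1)
        sub = BinQtlScan(yv, _subset_binmat(self.bin_matrix, ok), self.gmap,
                         self.trait_name)
        max_lods = sub._single_marker_lods(perms).max(axis=0)
        return float(np.quantile(max_lods, 1.0 - alpha))


def _subset_binmat(binmat: BinGenotypeMatrix, row_mask: np.ndarray) -> BinGenotypeMatrix:
    names = [n for n, keep in zip(binmat.line_names, row_mask) if keep]
    return BinGenotypeMatrix(names, binmat.bins, binmat.n_tiles,
                             binmat.tile_slices, binmat.states[row_mask],
                             binmat.source_tiles)


class QtlScanResults:
    """Per-bin LOD/effect/PVE estimates plus peak calls."""

    def __init__(self, model: BinQtlScan, lods, effects, pves, ns, skipped,
                 cofactors, lod_threshold):
        self.model = model
        self.lod = lods
        self.additive_effect = effects
        self.pve = pves
        self.n_used = ns
        self.skipped_bins = skipped
        self.cofactors = cofactors
        self.lod_threshold = lod_threshold
        self.scan = self._scan_frame()
        self.peaks = self._find_peaks()

    def _scan_frame(self) -> pd.DataFrame:
        bm = self.model.bin_matrix
        return pd.DataFrame({
            "chrom": [b.chrom for b in bm.bins],
            "start": [b.start for b in bm.bins],
            "end": [b.end for b in bm.bins],
            "lod": self.lod,
            "additive_effect": self.additive_effect,
            "pve": self.pve,
            "n_used": self.n_used,
            "passes_threshold": self.lod >= self.lod_threshold,
        })

    def _find_peaks(self) -> pd.DataFrame:
        bm = self.model.bin_matrix
        chrom = np.array([b.chrom for b in bm.bins])
        above = np.nan_to_num(self.lod, nan=-1.0) >= self.lod_threshold
        peaks: list[QtlHit] = []
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1] and chrom[j + 1] == chrom[i]:
                j += 1
            block = slice(i, j + 1)
            k = i + int(np.nanargmax(self.lod[block]))
            lo, hi = self._support_interval(k)
            b = bm.bins[k]
            peaks.append(QtlHit(k, b.chrom, b.start, b.end, float(self.lod[k]),
                                float(self.additive_effect[k]), float(self.pve[k]),
                                int(self.n_used[k]), True,
                                support_start=lo, support_end=hi))
            i = j + 1
        return pd.DataFrame([vars(p) for p in peaks])

    def _support_interval(self, k: int) -> tuple[int, int]:
        """1.5-LOD drop interval around peak bin k (bp bounds)."""
        bm = self.model.bin_matrix
        chrom = bm.bins[k].chrom
        cut = self.lod[k] - 1.5
        lo = k
        while lo - 1 >= 0 and bm.bins[lo - 1].chrom == chrom and \
                np.nan_to_num(self.lod[lo - 1], nan=-np.inf) >= cut:
            lo -= 1
        hi = k
        while hi + 1 < bm.n_bins and bm.bins[hi + 1].chrom == chrom and \
                np.nan_to_num(self.lod[hi + 1], nan=-np.inf) >= cut:
            hi += 1
        return bm.bins[lo].start, bm.bins[hi].end

    def summary(self) -> str:
        bm = self.model.bin_matrix
        lines = [
            f"Bin-based additive QTL scan: trait {self.model.trait_name!r}",
            f"  lines: {len(bm.line_names)}   bins: {bm.n_bins}   "
            f"cofactors: {len(self.cofactors)}   skipped (monomorphic): "
            f"{len(self.skipped_bins)}",
            f"  LOD threshold: {self.lod_threshold:.2f}   "
            f"peaks: {len(self.peaks)}",
        ]
        if len(self.peaks):
            lines.append(self.peaks[["chrom", "start", "end", "lod",
                                     "additive_effect", "pve", "n_used"]]
                         .to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile along the genome (one panel, chromosome-concatenated)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        bm = self.model.bin_matrix
        x = np.arange(bm.n_bins)
        ax.plot(x, self.lod, lw=0.8)
        ax.axhline(self.lod_threshold, color="red", ls="--", lw=0.8)
        chrom = np.array([b.chrom for b in bm.bins])
        for c in dict.fromkeys(chrom.tolist()):
            ax.axvline(np.flatnonzero(chrom == c)[0], color="grey", lw=0.3)
        ax.set_xlabel("recombination bin")
        ax.set_ylabel("LOD")
        ax.set_title(f"QTL scan: {self.model.trait_name}")
        return ax
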