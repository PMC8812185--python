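"""Matrix-level statistics: ICE balancing, contact-probability decay,
chromatin compactness and interaction-range summaries.

The decay "strength" at a genomic gap d is
``log10(mean observed contacts per bin pair at gap d / average contacts per
observable cis bin-pair)``, so a flat contact field scores 0 at every gap;
the average is genome-wide by default (configurable to per-chromosome). Compactness of a 10-kb bin is its total contacts with all
bins within +-1 Mb. Interactions split into cis short-range (<= 2 Mb,
inclusive), cis long-range (> 2 Mb) and trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_io import BinnedMatrix


@dataclass
class DecayCurve:
    """Contact strength per genomic distance (bp grid, strictly increasing).

    ``strength`` is log10 of the per-pair mean contact at each gap over the
    global per-pair average; ``sums``/``n_pairs`` retain the raw per-gap
    totals and observable pair counts.
    """

    distance: np.ndarray
    strength: np.ndarray
    sums: np.ndarray | None = None
    n_pairs: np.ndarray | None = None

    def slope(self) -> float:
        """Least-squares slope of strength vs log10(distance)."""
        x = np.log10(self.distance.astype(float))
        return float(np.polyfit(x, self.strength, 1)[0])


@dataclass
class CompactnessTrack:
    """Per-bin contact totals within a fixed window around each bin."""

    bins: pd.DataFrame  # chrom, start
    values: np.ndarray
    truncated: np.ndarray  # True where the window ran off a chromosome end
    resolution: int

    def frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["compactness"] = self.values
        out["truncated"] = self.truncated
        return out


def ice_balance(
    matrix: BinnedMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    filter_low: float = 0.02,
) -> BinnedMatrix:
    """Iterative correction: find per-bin weights equalizing row sums.

    Bins in the lowest ``filter_low`` coverage quantile (and zero-coverage
    bins) are masked (weight NaN) and excluded from balancing. Returns a new
    matrix carrying the weights; raw counts are unchanged. Convergence is a
    coefficient of variation of balanced row sums below ``tol`` over unmasked
    bins; non-convergence warns and returns the best iterate.
    """
    full = matrix.sym().tocsr()
    n = full.shape[0]
    coverage = np.asarray(full.sum(axis=1)).ravel()
    if coverage.sum() == 0:
        raise ValueError("all-zero matrix cannot be balanced")
    nonzero = coverage > 0
    if filter_low > 0:
        cut = np.quantile(coverage[nonzero], filter_low)
        mask = nonzero & (coverage > cut)
        if not mask.any():  # degenerate: uniform coverage, keep all nonzero
            mask = nonzero
    else:
        mask = nonzero
    bias = np.ones(n)
    bias[~mask] = np.nan
    work = full[mask][:, mask]
    b = np.ones(mask.sum())
    converged = False
    for _ in range(max_iter):
        s = work.dot(b) * b
        mean = s.mean()
        if mean == 0:
            break
        cv = s.std() / mean
        if cv < tol:
            converged = True
            break
        adj = s / mean
        adj[adj == 0] = 1.0
        b = b / np.sqrt(adj)
    if not converged:
        s = work.dot(b) * b
        if s.mean() > 0 and s.std() / s.mean() >= tol:
            warnings.warn(
                f"ICE did not converge in {max_iter} iterations "
                f"(cv={s.std() / s.mean():.2e}); returning best iterate"
            )
    # normalize so the mean weight over unmasked bins is 1
    b = b / b.mean()
    bias[mask] = b
    out = BinnedMatrix(
        matrix.resolution, matrix.bins, matrix.matrix, weights=bias, stage=matrix.stage
    )
    return out


def balanced_row_sum_cv(matrix: BinnedMatrix) -> float:
    """Coefficient of variation of balanced row sums over unmasked bins."""
    w = matrix.weights
    if w is None:
        raise ValueError("matrix has no weights")
    full = matrix.sym().tocsr()
    mask = ~np.isnan(w)
    ww = np.where(mask, w, 0.0)
    s = (full.dot(ww) * ww)[mask]
    return float(s.std() / s.mean())


def contact_probability(
    matrix: BinnedMatrix,
    d_min: int = 10_000,
    d_max: int = 100_000_000,
    per_chromosome_mean: bool = False,
) -> DecayCurve:
    """Distance-decay curve from a cis matrix (conventionally at 10 kb).

    Strength(d) = log10(sum of contacts at gap d / average contacts per
    observable cis bin-pair). Gaps with no observable bin pair are omitted.
    """
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    res = matrix.resolution
    gap_lo = max(1, d_min // res)
    chroms = list(dict.fromkeys(matrix.bins["chrom"]))
    max_n = max(matrix.chrom_range(c)[1] - matrix.chrom_range(c)[0] for c in chroms)
    gap_hi = min(d_max // res, max_n - 1)
    n_gaps = gap_hi - gap_lo + 1
    if n_gaps <= 0:
        raise ValueError("no observable gaps in the requested range")
    sums = np.zeros(n_gaps)
    npairs = np.zeros(n_gaps)
    total = 0.0
    total_pairs = 0.0
    per_chrom = []
    g = np.arange(gap_lo, gap_hi + 1)
    for chrom in chroms:
        lo, hi = matrix.chrom_range(chrom)
        sub = matrix.matrix[lo:hi, lo:hi].tocoo()
        n = hi - lo
        gaps = sub.col - sub.row
        sel = (gaps >= gap_lo) & (gaps <= gap_hi)
        csums = np.zeros(n_gaps)
        np.add.at(csums, gaps[sel] - gap_lo, sub.data[sel])
        obs = np.maximum(n - g, 0)
        sums += csums
        npairs += obs
        total += sub.data[sel].sum()
        total_pairs += obs.sum()
        per_chrom.append((csums, obs))
    defined = npairs > 0
    with np.errstate(divide="ignore"):
        if per_chromosome_mean:
            # normalize each chromosome by its own per-pair mean, then pool
            norm = np.zeros(n_gaps)
            for csums, obs in per_chrom:
                avg_c = csums.sum() / obs.sum() if obs.sum() else np.nan
                if np.isfinite(avg_c) and avg_c > 0:
                    norm += csums / avg_c
            strength = np.log10(norm[defined] / npairs[defined])
        else:
            avg = total / total_pairs if total_pairs else np.nan
            strength = np.log10(sums[defined] / npairs[defined] / avg)
    dist = (np.arange(gap_lo, gap_hi + 1)[defined]) * res
    return DecayCurve(
        distance=dist,
        strength=strength,
        sums=sums[defined],
        n_pairs=npairs[defined],
    )


def fit_decay_exponent(curve: DecayCurve, d_lo: int = 20_000, d_hi: int = 2_000_000) -> float:
    """Estimate the power-law exponent alpha (positive) from a decay curve.

    Fits the per-pair mean strength against log10(distance); the per-pair
    normalization keeps the (n - d) observable-pair falloff out of the slope.
    """
    sel = (
        (curve.distance >= d_lo)
        & (curve.distance <= d_hi)
        & np.isfinite(curve.strength)
    )
    x = np.log10(curve.distance[sel].astype(float))
    return -float(np.polyfit(x, curve.strength[sel], 1)[0])


def compactness(matrix: BinnedMatrix, window: int = 1_000_000) -> CompactnessTrack:
    """Per-bin total contacts within +-window (default 1 Mb) at 10 kb.

    Chromosome-end bins use the truncated window and are flagged.
    """
    res = matrix.resolution
    if window < res:
        raise ValueError("window must be at least one bin")
    w = window // res
    n = matrix.n_bins
    values = np.zeros(n)
    truncated = np.zeros(n, dtype=bool)
    for chrom in dict.fromkeys(matrix.bins["chrom"]):
        lo, hi = matrix.chrom_range(chrom)
        nb = hi - lo
        sub = matrix.matrix[lo:hi, lo:hi].tocoo()
        # each stored (i, j, v) contributes to bin i and (if i != j) to bin j
        # whenever the partner lies within the window
        vals = np.zeros(nb)
        close = (sub.col - sub.row) <= w
        np.add.at(vals, sub.row[close], sub.data[close])
        off = close & (sub.col != sub.row)
        np.add.at(vals, sub.col[off], sub.data[off])
        values[lo:hi] = vals
        idx = np.arange(nb)
        truncated[lo:hi] = (idx < w) | (idx >= nb - w)
    return CompactnessTrack(
        bins=matrix.bins.copy(), values=values, truncated=truncated, resolution=res
    )


def compactness_by_group(
    track: CompactnessTrack, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Median/mean compactness per bin group (e.g. At vs Dt, rich vs poor)."""
    df = pd.DataFrame({"group": np.asarray(groups), "value": track.values})
    return df.groupby("group")["value"].agg(["median", "mean", "count"]).reset_index()


def range_summary(matrix: BinnedMatrix, short_max: int = 2_000_000) -> dict:
    """Counts of cis short-range (<= short_max, inclusive), cis long-range and
    trans contacts; the three classes sum to the matrix total."""
    coo = matrix.matrix.tocoo()
    chrom_idx = pd.factorize(matrix.bins["chrom"])[0]
    same = chrom_idx[coo.row] == chrom_idx[coo.col]
    gap_bp = (coo.col - coo.row) * matrix.resolution
    short = same & (gap_bp <= short_max)
    out = {
        "cis_short": float(coo.data[short].sum()),
        "cis_long": float(coo.data[same & ~short].sum()),
        "trans": float(coo.data[~same].sum()),
    }
    return out
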