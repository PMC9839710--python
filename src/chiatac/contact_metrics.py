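"""Binned contact matrices and matrix-level quality metrics.

Per-chromosome symmetric contact matrices binned from PET midpoints, with:

- Knight-Ruiz balancing (inner-outer Newton iteration, Sinkhorn fallback)
  producing weights w with row sums of diag(w) M diag(w) equal to 1 on
  non-empty bins;
- aggregate peak analysis (APA): the mean/summed balanced submatrix around
  a loop list at 10 kb resolution, scored as the Z of the central pixel
  against the lower-left corner (the 6x6 block nearest the diagonal);
- the stratum-adjusted correlation coefficient (scc): per-diagonal Pearson
  correlations of mean-filter-smoothed matrices combined with
  N_k * sd_x * sd_y stratum weights, summarised genome-wide by a
  chromosome-length-weighted mean;
- an insulation score (mean of the square window crossing each bin, log2
  versus the chromosome mean) at 25 kb bins;
- a compartment score: first principal component of the Pearson
  correlation of the observed/expected matrix at 200 kb bins, sign-
  oriented against a reference accessibility track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

from .linker_pets import PET
from .loops import Loop


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact counts."""

    chrom: str
    bin_size: int
    n_bins: int
    counts: sparse.coo_matrix  # upper triangle (i <= j)
    weights: np.ndarray | None = None  # KR weights, NaN on masked bins

    def dense(self, balanced: bool = False) -> np.ndarray:
        m = self.counts.toarray().astype(float)
        m = m + np.triu(m, 1).T
        if balanced:
            if self.weights is None:
                raise ValueError("matrix has no balancing weights")
            w = np.nan_to_num(self.weights, nan=0.0)
            m = m * w[:, None] * w[None, :]
        return m

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def bin_matrix(
    pets: Sequence[PET], chrom_lengths: dict[str, int], bin_size: int
) -> dict[str, ContactMatrix]:
    """Bin cis PET midpoints into per-chromosome symmetric matrices.

    Each PET increments the (bin(midA), bin(midB)) cell once (stored upper
    triangular; the diagonal is allowed). The matrix total equals the
    number of cis PETs on that chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for p in pets:
        if not p.is_cis or p.tag_a.chrom not in per_chrom:
            continue
        i = int(p.tag_a.midpoint // bin_size)
        j = int(p.tag_b.midpoint // bin_size)
        per_chrom[p.tag_a.chrom].append((min(i, j), max(i, j)))
    out = {}
    for c, ij in per_chrom.items():
        n = int(np.ceil(chrom_lengths[c] / bin_size))
        if ij:
            ii, jj = np.array(ij).T
            m = sparse.coo_matrix((np.ones(len(ij)), (ii, jj)), shape=(n, n))
            m.sum_duplicates()
        else:
            m = sparse.coo_matrix((n, n))
        out[c] = ContactMatrix(chrom=c, bin_size=bin_size, n_bins=n, counts=m)
    return out


def matrix_from_dense(dense: np.ndarray, chrom: str = "chr1", bin_size: int = 10_000) -> ContactMatrix:
    """Wrap a dense symmetric array as a ContactMatrix (testing/IO helper)."""
    dense = np.asarray(dense, dtype=float)
    if dense.shape[0] != dense.shape[1] or not np.allclose(dense, dense.T):
        raise ValueError("matrix must be square and symmetric")
    upper = sparse.coo_matrix(np.triu(dense))
    return ContactMatrix(chrom=chrom, bin_size=bin_size, n_bins=dense.shape[0], counts=upper)


class BalanceError(RuntimeError):
    """KR balancing failed to converge; carries the final residual."""

    def __init__(self, residual: float):
        super().__init__(f"matrix balancing did not converge (residual {residual:.3g})")
        self.residual = residual


def _kr_core(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration on a positive-row matrix.

    Translation of the classic algorithm: finds x > 0 with
    diag(x) A diag(x) doubly stochastic to relative tolerance ``tol``.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    i = 0  # outer iterations
    mvp = 0  # matrix-vector products
    while rout > rt:
        i += 1
        if i > max_iter:
            raise BalanceError(np.sqrt(rout))
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:  # inner CG iteration
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / float(p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            mvp += 1
            if mvp > max_iter * 50:
                raise BalanceError(np.sqrt(rho_km1))
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        # adaptive forcing term
        rat = rout / rold
        rold = rout
        eta = g * rat
        if g * etamax**2 > 0.1:
            eta = max(eta, g * etamax**2)
        eta = max(min(eta, etamax), 0.5 * tol / max(np.sqrt(rout), 1e-300))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    x = np.ones(A.shape[0])
    for _ in range(max_iter * 100):
        r = (x * (A @ x))
        if np.abs(r - 1).max() < tol:
            return x
        x = x / np.sqrt(r)
    raise BalanceError(float(np.abs(x * (A @ x) - 1).max()))


def kr_balance(
    matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 1000
) -> np.ndarray:
    """Knight-Ruiz balancing weights; empty bins masked as NaN.

    After balancing, every non-masked row of diag(w) M diag(w) sums to 1
    within ``tol``. Falls back to Sinkhorn iteration when the Newton
    scheme fails, with a warning; raises :class:`BalanceError` when
    neither converges.
    """
    m = matrix.dense()
    mask = m.sum(axis=1) > 0
    sub = m[np.ix_(mask, mask)]
    try:
        x = _kr_core(sub, tol, max_iter)
        res = np.abs(x * (sub @ x) - 1).max()
        if res > tol * 10:
            raise BalanceError(float(res))
    except (BalanceError, FloatingPointError):
        warnings.warn("Knight-Ruiz iteration failed; falling back to Sinkhorn balancing")
        x = _sinkhorn(sub, tol, max_iter)
    w = np.full(matrix.n_bins, np.nan)
    w[mask] = x
    matrix.weights = w
    return w


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------

@dataclass
class APAResult:
    agg: np.ndarray           # (2h+1) x (2h+1) aggregate submatrix
    z_score: float            # central pixel vs lower-left corner
    center_to_ll: float       # central pixel / mean(LL corner)
    n_loops: int
    n_excluded: int


LL_CORNER = 6  # side of the lower-left block used as the APA background


def apa(
    matrices: dict[str, ContactMatrix],
    loops: Sequence[Loop],
    half_window: int = 10,
    balanced: bool = True,
) -> APAResult:
    """Aggregate peak analysis over a loop list.

    For every eligible cis loop the (2h+1)^2 balanced submatrix centred on
    (bin(anchorA mid), bin(anchorB mid)) is summed; loops closer to the
    diagonal than the window, or whose window leaves the matrix, are
    excluded. Z = (center - mean(LL)) / sd(LL) with LL the bottom-left
    6x6 block of the aggregate (rows = A-side offsets increasing downward,
    so LL is the corner nearest the diagonal). Raises when no loop is
    eligible.
    """
    h = half_window
    size = 2 * h + 1
    agg = np.zeros((size, size))
    n_used = n_excl = 0
    dense_cache: dict[str, np.ndarray] = {}
    for l in loops:
        if not l.is_cis or l.chrom_a not in matrices:
            n_excl += 1
            continue
        cm = matrices[l.chrom_a]
        if l.chrom_a not in dense_cache:
            if balanced and cm.weights is None:
                kr_balance(cm)
            dense_cache[l.chrom_a] = cm.dense(balanced=balanced)
        m = dense_cache[l.chrom_a]
        bi = int((l.start_a + l.end_a) / 2 // cm.bin_size)
        bj = int((l.start_b + l.end_b) / 2 // cm.bin_size)
        bi, bj = min(bi, bj), max(bi, bj)
        if bj - bi <= 2 * h or bi - h < 0 or bj + h >= cm.n_bins:
            n_excl += 1
            continue
        sub = m[bi - h:bi + h + 1, bj - h:bj + h + 1]
        if np.isnan(sub).any():
            n_excl += 1
            continue
        agg += sub
        n_used += 1
    if n_used == 0:
        raise ValueError("no loop eligible for APA aggregation")
    ll = agg[-LL_CORNER:, :LL_CORNER]
    center = agg[h, h]
    sd = ll.std()
    z = float((center - ll.mean()) / sd) if sd > 0 else 0.0
    ratio = float(center / ll.mean()) if ll.mean() > 0 else float("inf")
    return APAResult(agg=agg, z_score=z, center_to_ll=ratio, n_loops=n_used, n_excluded=n_excl)


# ---------------------------------------------------------------------------
# stratum-adjusted correlation (HiCRep-style)
# ---------------------------------------------------------------------------

def _smooth(m: np.ndarray, h: int) -> np.ndarray:
    """2D mean filter with edge renormalisation (no zero-padding bias)."""
    if h <= 0:
        return m
    from scipy.ndimage import uniform_filter

    num = uniform_filter(m, size=2 * h + 1, mode="constant")
    den = uniform_filter(np.ones_like(m), size=2 * h + 1, mode="constant")
    return num / den


def scc_chrom(
    a: ContactMatrix,
    b: ContactMatrix,
    smoothing_half_width: int = 5,
    max_dist: int = 5_000_000,
) -> float:
    """Stratum-adjusted correlation between two matrices of one chromosome.

    Both matrices are 2D mean-filter smoothed; each diagonal (stratum) up
    to ``max_dist`` contributes its Pearson correlation weighted by
    N_k * sd(x_k) * sd(y_k). Strata with fewer than 3 bins or zero
    variance in either matrix are skipped.
    """
    if a.chrom != b.chrom or a.bin_size != b.bin_size or a.n_bins != b.n_bins:
        raise ValueError("matrices must share chromosome, bin size and shape")
    ma = _smooth(a.dense(), smoothing_half_width)
    mb = _smooth(b.dense(), smoothing_half_width)
    kmax = min(a.n_bins - 1, max_dist // a.bin_size)
    num = den = 0.0
    for k in range(1, kmax + 1):
        x = np.diagonal(ma, k)
        y = np.diagonal(mb, k)
        if x.size < 3:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        w = x.size * sx * sy
        num += w * r
        den += w
    if den == 0:
        return float("nan")
    return num / den


def scc(
    a_set: dict[str, ContactMatrix],
    b_set: dict[str, ContactMatrix],
    chrom_lengths: dict[str, int],
    smoothing_half_width: int = 5,
    max_dist: int = 5_000_000,
) -> tuple[dict[str, float], float]:
    """Per-chromosome scc plus the chromosome-length-weighted genome mean."""
    if set(a_set) != set(b_set):
        raise ValueError("matrix sets cover different chromosomes")
    per = {
        c: scc_chrom(a_set[c], b_set[c], smoothing_half_width, max_dist)
        for c in sorted(a_set)
    }
    ws = np.array([chrom_lengths[c] for c in sorted(a_set)], dtype=float)
    vals = np.array([per[c] for c in sorted(a_set)])
    ok = ~np.isnan(vals)
    genome = float((vals[ok] * ws[ok]).sum() / ws[ok].sum()) if ok.any() else float("nan")
    return per, genome


# ---------------------------------------------------------------------------
# insulation and compartments
# ---------------------------------------------------------------------------

def insulation_score(matrix: ContactMatrix, window: int = 25_000) -> np.ndarray:
    """Per-bin insulation: log2 of the cross-boundary window mean vs chrom mean.

    For bin i the score averages the ``w x w`` square upstream-by-downstream
    of i (rows i-w..i-1, columns i+1..i+w with w = window // bin_size) and
    is reported as log2 against the mean across scoreable bins. Bins within
    ``w`` of either edge are NaN.
    """
    if window % matrix.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // matrix.bin_size
    n = matrix.n_bins
    if w >= n:
        raise ValueError("window larger than the chromosome")
    m = matrix.dense()
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = m[i - w:i, i + 1:i + w + 1].mean()
    ok = ~np.isnan(raw)
    mean = raw[ok].mean()
    if mean <= 0:
        return np.full(n, np.nan)
    out = np.full(n, np.nan)
    out[ok] = np.log2(np.maximum(raw[ok], 1e-12) / mean)
    return out


def compartment_pc1(
    matrix: ContactMatrix, reference_track: np.ndarray | None = None
) -> np.ndarray:
    """Compartment score: PC1 of the O/E Pearson correlation matrix.

    Each diagonal of the dense matrix is divided by its mean (observed /
    expected); the first principal component of the bin-bin Pearson
    correlation of the O/E matrix is the compartment score, sign-oriented
    so that its correlation with ``reference_track`` (e.g. peak density)
    is non-negative. Empty bins are NaN. Requires >= 20 usable bins;
    degenerate (constant) O/E yields all-NaN.
    """
    m = matrix.dense()
    mask = m.sum(axis=1) > 0
    if mask.sum() < 20:
        raise ValueError("need at least 20 non-empty bins for compartment analysis")
    sub = m[np.ix_(mask, mask)]
    n = sub.shape[0]
    oe = np.zeros_like(sub)
    for k in range(-(n - 1), n):
        d = np.diagonal(sub, k)
        mu = d.mean()
        if mu > 0:
            rows = np.arange(max(0, -k), min(n, n - k))
            oe[rows, rows + k] = d / mu
    if np.allclose(oe, oe.flat[0]) or np.allclose(oe.std(axis=0), 0):
        return np.full(matrix.n_bins, np.nan)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eigh(corr)
    pc1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    out = np.full(matrix.n_bins, np.nan)
    out[mask] = pc1
    if reference_track is not None:
        ref = np.asarray(reference_track, dtype=float)[mask]
        ok = ~np.isnan(ref)
        if ok.any() and np.std(ref[ok]) > 0 and np.corrcoef(pc1[ok], ref[ok])[0, 1] < 0:
            out = -out
    return out


# ---------------------------------------------------------------------------
# serialization: sparse triplet TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrices: dict[str, ContactMatrix], path) -> None:
    with open(path, "w") as f:
        f.write("#chrom\tbin_size\tn_bins\tbin_i\tbin_j\tcount\n")
        for c in sorted(matrices):
            cm = matrices[c]
            coo = cm.counts.tocoo()
            for i, j, v in zip(coo.row, coo.col, coo.data):
                f.write(f"{c}\t{cm.bin_size}\t{cm.n_bins}\t{i}\t{j}\t{v:g}\n")


def read_matrix_tsv(path) -> dict[str, ContactMatrix]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment=None, header=0,
                     names=["chrom", "bin_size", "n_bins", "bin_i", "bin_j", "count"])
    out = {}
    for c, sub in df.groupby("chrom"):
        n = int(sub.n_bins.iloc[0])
        m = sparse.coo_matrix(
            (sub["count"].to_numpy(float), (sub.bin_i.to_numpy(int), sub.bin_j.to_numpy(int))),
            shape=(n, n),
        )
        out[str(c)] = ContactMatrix(chrom=str(c), bin_size=int(sub.bin_size.iloc[0]),
                                    n_bins=n, counts=m)
    return out
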