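"""Contact-matrix analytics: ICE balancing, observed/expected transform,
compartment eigenvector, diamond insulation with boundary calls, virtual 4C
and aggregate loop pileup.

Conventions
-----------
* Matrices are symmetric, dense and binned at a fixed width; masked bins
  (zero or near-zero coverage) are excluded from every statistic.
* Balancing follows iterative correction: raw counts are divided by the
  outer product of per-bin weights, iterated until all unmasked row sums
  agree to a relative tolerance.  Weights are normalized to mean 1 over
  unmasked bins.
* The insulation score at bin ``b`` is the log2 ratio of the diamond sum
  (pixels ``(i, j)`` with ``b - w <= i < b`` and ``b < j <= b + w``, where
  ``w = window // bin_width``) over the mean diamond sum of the
  chromosome.  Local minima with sufficient prominence are boundary calls.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import ndimage


@dataclasses.dataclass
class ContactMatrix:
    """Symmetric binned contact counts with bin table, weights and mask."""

    bins: pd.DataFrame                 # chrom, start, end
    counts: np.ndarray
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None     # True = excluded bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if len(self.bins) != n:
            raise ValueError("bin table length does not match matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")
        if self.mask is None:
            self.mask = self.counts.sum(axis=0) == 0
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_width(self) -> int:
        return int((self.bins["end"] - self.bins["start"]).iloc[0])

    def balanced(self) -> np.ndarray:
        """Balanced matrix with NaN at masked rows/columns."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_balance first")
        w = self.weights
        out = self.counts * np.outer(w, w)
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out


@dataclasses.dataclass
class BalanceResult:
    weights: np.ndarray
    n_iter: int
    converged: bool
    residual: float


def ice_balance(cm: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                min_nnz_frac: float = 0.02) -> BalanceResult:
    """Iterative-correction balancing.

    Bins whose fraction of nonzero pixels is below ``min_nnz_frac`` are
    pre-masked.  Iterates dividing by the outer product of current row
    sums (renormalized to mean 1 over unmasked bins) until the maximum
    relative row-sum deviation is below ``tol``.  On non-convergence the
    best iterate is kept and ``converged`` is False.

    Balancing is idempotent: rebalancing changes weights by < tol.
    """
    n = cm.n_bins
    mask = cm.mask.copy()
    nnz_frac = (cm.counts > 0).sum(axis=0) / n
    mask |= nnz_frac < min_nnz_frac
    w = np.ones(n)
    w[mask] = np.nan
    sub = cm.counts[np.ix_(~mask, ~mask)]
    b = np.ones(sub.shape[0])
    residual = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        s = (sub * np.outer(b, b)).sum(axis=1)
        s = s / s.mean()
        residual = float(np.abs(s - 1.0).max())
        if residual < tol:
            converged = True
            break
        b = b / s
    b = b / b.mean()
    w[~mask] = b
    cm.weights = w
    cm.mask = mask
    return BalanceResult(weights=w, n_iter=n_iter,
                         converged=converged, residual=residual)


# ---------------------------------------------------------------------------
# observed / expected
# ---------------------------------------------------------------------------

def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean balanced contact over the unmasked pixels of each diagonal."""
    m = cm.balanced()
    n = cm.n_bins
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        valid = np.isfinite(diag)
        if valid.any():
            exp[d] = diag[valid].mean()
    return exp


def obs_exp(cm: ContactMatrix) -> np.ndarray:
    """Observed/expected matrix; masked pixels are NaN."""
    m = cm.balanced()
    exp = expected_by_distance(cm)
    n = cm.n_bins
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    denom = exp[np.abs(i - j)]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = m / denom
    return oe


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def compartment_eigenvector(oe: np.ndarray,
                            reference_track: np.ndarray | None = None,
                            min_bins: int = 10) -> np.ndarray:
    """Leading eigenvector of the Pearson correlation of log O/E.

    The sign is fixed so the vector correlates positively with
    ``reference_track`` (e.g. ATAC coverage) when supplied.  Degenerate
    input (constant O/E) raises a ValueError.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    valid = np.array([np.isfinite(oe[i]).any() and np.nanmax(oe[i]) > 0
                      for i in range(n)])
    if valid.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} unmasked bins")
    sub = oe[np.ix_(valid, valid)]
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.log(sub)
    logm[~np.isfinite(logm)] = np.nan
    col_mean = np.nanmean(logm, axis=0)
    inds = np.where(np.isnan(logm))
    logm[inds] = np.take(col_mean, inds[1])
    if np.allclose(logm, logm.flat[0]):
        raise ValueError("degenerate O/E: constant matrix, eigenvector undefined")
    sd = logm.std(axis=0)
    if (sd == 0).any():
        logm = logm + 0.0  # zero-variance columns yield nan rows in corrcoef
    corr = np.corrcoef(logm, rowvar=False)
    corr[~np.isfinite(corr)] = 0.0
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    out = np.full(n, np.nan)
    out[valid] = lead
    if reference_track is not None:
        ref = np.asarray(reference_track, dtype=float)
        score = np.nansum(out * ref)
        if score < 0:
            out = -out
    return out


# ---------------------------------------------------------------------------
# insulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class InsulationProfile:
    """Per-bin diamond insulation score and boundary calls.

    ``scores`` is ``log2(diamond_sum / mean_diamond_sum)``; NaN where the
    diamond window falls off the matrix edge or covers masked bins only.
    ``boundaries`` is a table with columns ``bin`` and ``prominence``.
    """

    scores: np.ndarray
    window: int
    bin_width: int
    boundaries: pd.DataFrame
    valid: np.ndarray


def _diamond_sums(balanced: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    n = balanced.shape[0]
    sums = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for b in range(w, n - w):
        block = balanced[b - w:b, b + 1:b + 1 + w]
        finite = np.isfinite(block)
        if finite.any():
            sums[b] = np.nansum(block)
            valid[b] = True
    return sums, valid


def insulation(cm: ContactMatrix, window: int = 100_000,
               prominence: float = 0.2) -> InsulationProfile:
    """Diamond insulation profile with boundary calls.

    ``window`` must be a multiple of the bin width and smaller than the
    chromosome.  Boundaries are local minima of the score with prominence
    at least ``prominence`` (log2 units).
    """
    bw = cm.bin_width
    if window % bw != 0:
        raise ValueError("window must be a multiple of the bin width")
    w = window // bw
    if w < 1 or 2 * w >= cm.n_bins:
        raise ValueError("window larger than the chromosome")
    bal = cm.balanced()
    sums, valid = _diamond_sums(bal, w)
    mean_sum = np.nanmean(sums[valid]) if valid.any() else np.nan
    scores = np.full(cm.n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores[valid] = np.log2(sums[valid] / mean_sum)

    filled = np.where(np.isfinite(scores), scores, np.nanmax(scores[valid])
                      if valid.any() else 0.0)
    peaks, props = _signal.find_peaks(-filled, prominence=prominence)
    peaks_ok = [k for k, p in enumerate(peaks) if valid[peaks[k]]]
    boundaries = pd.DataFrame(
        {"bin": peaks[peaks_ok].astype(int),
         "prominence": props["prominences"][peaks_ok]}
    )
    return InsulationProfile(scores=scores, window=window, bin_width=bw,
                             boundaries=boundaries, valid=valid)


# ---------------------------------------------------------------------------
# virtual 4C
# ---------------------------------------------------------------------------

def virtual_4c(cm: ContactMatrix, viewpoint_bin: int,
               smooth_bins: int = 0) -> pd.DataFrame:
    """Balanced contact profile of one viewpoint bin.

    The viewpoint self-bin is reported but flagged.  ``smooth_bins > 0``
    applies a centered moving average of that half-width.
    """
    if cm.mask[viewpoint_bin]:
        raise ValueError("viewpoint bin is masked")
    row = cm.balanced()[viewpoint_bin].copy()
    if smooth_bins > 0:
        filled = np.where(np.isfinite(row), row, 0.0)
        weight = np.isfinite(row).astype(float)
        k = 2 * smooth_bins + 1
        num = ndimage.uniform_filter1d(filled, k, mode="nearest")
        den = ndimage.uniform_filter1d(weight, k, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            row = num / den
    out = pd.DataFrame({"bin": np.arange(cm.n_bins), "contact": row})
    out["is_viewpoint"] = out["bin"] == viewpoint_bin
    return out


# ---------------------------------------------------------------------------
# aggregate loop pileup
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PileupResult:
    mean_matrix: np.ndarray
    enrichment: float
    n_used: int
    n_skipped: int


def loop_pileup(oe: np.ndarray, anchors: list[tuple[int, int]],
                flank_bins: int = 10) -> PileupResult:
    """Average O/E windows centered on anchor pixel pairs.

    Each window is ``(2*flank_bins + 1)`` square around pixel ``(i, j)``.
    Central enrichment is the center pixel of the mean window divided by
    the mean of the four corner quadrants (each ``max(1, flank//2)``
    square).  Anchors within ``flank_bins`` of the matrix edge or closer
    than ``flank_bins`` to the diagonal are skipped.
    """
    n = oe.shape[0]
    f = flank_bins
    windows = []
    skipped = 0
    for bi, bj in anchors:
        bi, bj = int(min(bi, bj)), int(max(bi, bj))
        if bi - f < 0 or bj + f >= n or bi + f >= n or bj - f < 0 \
                or (bj - bi) <= f:
            skipped += 1
            continue
        windows.append(oe[bi - f:bi + f + 1, bj - f:bj + f + 1])
    if not windows:
        raise ValueError("no usable anchors for pileup")
    stack = np.stack(windows)
    mean = np.nanmean(stack, axis=0)
    q = max(1, f // 2)
    corners = [mean[:q, :q], mean[:q, -q:], mean[-q:, :q], mean[-q:, -q:]]
    corner_mean = float(np.nanmean([np.nanmean(c) for c in corners]))
    center = float(mean[f, f])
    enrichment = center / corner_mean if corner_mean > 0 else np.nan
    return PileupResult(mean_matrix=mean, enrichment=enrichment,
                        n_used=len(windows), n_skipped=skipped)
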