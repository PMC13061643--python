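"""Per-cell QC, pseudobulk tracks, smoothing, V-plots and the k-means
mark-profile gene clustering.

The TSS enrichment score (TSSe) is an ArchR-style center/background ratio:
the mean per-bp Tn5 insertion rate within ``+/- flank`` of a TSS divided by
the mean rate in the outermost 100 bp at each end of the ``+/- window``
region, pooled over all TSSs.  Uniform insertion coverage scores ~1.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from sklearn.cluster import KMeans

from .fragio import BinnedSignalTrack, BinScheme, FragmentSet

_BG_BP = 100  # width of each outer background stripe, bp


@dataclasses.dataclass
class CellQC:
    barcode: str
    unique_fragments: int
    tss_enrichment: float
    flagged: bool = False


def tss_enrichment(
    fragments: FragmentSet,
    tss_positions: Sequence[int],
    window: int = 2_000,
    flank: int = 100,
    barcodes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell TSS enrichment score.

    For every cell: pool insertion events over all TSSs; the score is
    ``(center count / center bp) / (background count / background bp)``
    with the center ``[-flank, flank)`` and the background the outermost
    100 bp of ``[-window, window)`` on each side.  Cells with zero
    background signal get score 0 with a warning flag.

    Returns a frame with columns ``barcode, unique_fragments,
    tss_enrichment, flagged``.
    """
    if window <= flank:
        raise ValueError("window must exceed flank")
    tss = np.asarray(sorted(tss_positions))
    if tss.size == 0:
        raise ValueError("need at least one TSS")
    if barcodes is None:
        barcodes = fragments.barcodes
    barcodes = list(barcodes)
    code = {b: i for i, b in enumerate(barcodes)}

    ins = fragments.insertions()
    ins = ins[ins["barcode"].isin(code)]
    pos = ins["pos"].to_numpy()
    cnt = ins["count"].to_numpy()
    rows = ins["barcode"].map(code).to_numpy(dtype=int) if len(ins) else \
        np.array([], dtype=int)

    center = np.zeros(len(barcodes))
    background = np.zeros(len(barcodes))
    for t in tss:
        off = pos - t
        in_center = (off >= -flank) & (off < flank)
        in_bg = ((off >= -window) & (off < -window + _BG_BP)) | \
                ((off >= window - _BG_BP) & (off < window))
        np.add.at(center, rows[in_center], cnt[in_center])
        np.add.at(background, rows[in_bg], cnt[in_bg])

    center_rate = center / (2 * flank)
    bg_rate = background / (2 * _BG_BP)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = center_rate / bg_rate
    flagged = bg_rate == 0
    score[flagged] = 0.0

    per_bc = fragments.per_barcode_counts()
    uniq = np.array([int(per_bc.get(b, 0)) for b in barcodes])
    return pd.DataFrame(
        {"barcode": barcodes, "unique_fragments": uniq,
         "tss_enrichment": score, "flagged": flagged}
    )


def qc_filter(qc: pd.DataFrame, tsse_min: float = 7.0,
              frag_min: int = 3_000) -> tuple[list[str], pd.DataFrame]:
    """Retain cells with TSSe strictly above ``tsse_min`` and unique
    fragments strictly above ``frag_min``.

    Both inequalities are strict: a cell at exactly the threshold is
    rejected.  Returns the retained barcodes and a per-cell report with a
    ``reason`` column (empty string for retained cells).
    """
    if qc.empty:
        return [], qc.assign(retained=pd.Series(dtype=bool),
                             reason=pd.Series(dtype=str))
    reasons = []
    for tsse, frags in zip(qc["tss_enrichment"], qc["unique_fragments"]):
        why = []
        if not tsse > tsse_min:
            why.append(f"tsse<={tsse_min}")
        if not frags > frag_min:
            why.append(f"fragments<={frag_min}")
        reasons.append(";".join(why))
    report = qc.copy()
    report["reason"] = reasons
    report["retained"] = report["reason"] == ""
    retained = report.loc[report["retained"], "barcode"].tolist()
    return retained, report


def frip(fragments: FragmentSet, peaks: Sequence[tuple[str, int, int]]) -> float:
    """Fraction of fragment counts overlapping peak intervals.

    Fragment-overlap (not termini) based; reporting metric only.
    """
    total = fragments.total_count
    if total == 0:
        return 0.0
    df = fragments.df
    in_peaks = np.zeros(len(df), dtype=bool)
    for chrom, start, end in peaks:
        hit = (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        in_peaks |= hit.to_numpy()
    return float(df.loc[in_peaks, "count"].sum() / total)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk_track(
    matrix: sparse.spmatrix,
    cells: Sequence[str],
    groups: Mapping[str, Sequence[str]],
    scheme: BinScheme,
    region: tuple[str, int, int] | None = None,
    normalization: str = "CPM",
) -> dict[str, BinnedSignalTrack]:
    """Per-group pseudobulk signal tracks from a cell-by-bin matrix.

    Groups must reference barcodes present in ``cells``; each group's
    per-bin sums are scaled to counts-per-million of the group total over
    the track extent (so every CPM track sums to 1e6).  ``region``
    restricts the track to ``(chrom, start, end)``; default is the first
    chromosome of the scheme.
    """
    cells = list(cells)
    idx = {b: i for i, b in enumerate(cells)}
    if region is None:
        chrom = scheme.chroms[0]
        region = (chrom, 0, scheme.chrom_sizes[chrom])
    chrom, start, end = region
    lo, hi = scheme.region_bins(chrom, start, end)
    bin_start = (start // scheme.width) * scheme.width

    tracks: dict[str, BinnedSignalTrack] = {}
    csr = matrix.tocsr()
    for name, members in groups.items():
        rows = [idx[b] for b in members if b in idx]
        missing = [b for b in members if b not in idx]
        if missing:
            raise ValueError(f"group {name!r} references unknown barcodes: "
                             f"{missing[:3]}...")
        sums = np.asarray(csr[rows].sum(axis=0)).ravel()[lo:hi].astype(float)
        if normalization == "CPM":
            total = sums.sum()
            values = sums / total * 1e6 if total > 0 else sums
        elif normalization == "raw":
            values = sums
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        tracks[name] = BinnedSignalTrack(
            chrom=chrom, start=bin_start, width=scheme.width, values=values,
            normalization=normalization, label=name,
        )
    return tracks


def smooth_track(track: BinnedSignalTrack, sigma_bins: float) -> BinnedSignalTrack:
    """Discrete Gaussian smoothing with reflected boundaries.

    Reflection folds out-of-range kernel mass back into the track, so the
    total signal is conserved; non-negative input stays non-negative.
    """
    if sigma_bins <= 0:
        raise ValueError("sigma_bins must be positive")
    smoothed = ndimage.gaussian_filter1d(track.values, sigma_bins,
                                         mode="reflect")
    return dataclasses.replace(track, values=smoothed)


# ---------------------------------------------------------------------------
# V-plots
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VPlot:
    """2D fragment histogram (midpoint offset x length) around a center,
    plus the per-position insertion-density profile."""

    hist: np.ndarray
    offset_edges: np.ndarray
    length_edges: np.ndarray
    insertion_density: np.ndarray      # per-bp termini counts in the window
    center: int
    half_window: int


def vplot(
    fragments: FragmentSet,
    chrom: str,
    center: int,
    half_window: int = 1_750,
    max_len: int = 600,
    len_bin: int = 5,
    pos_bin: int = 5,
) -> VPlot:
    """Build a V-plot around ``center``.

    A fragment enters the 2D histogram if its midpoint offset lies within
    ``+/- half_window`` and its length is at most ``max_len``; fragments
    fully outside the window are excluded.  The insertion density counts
    fragment termini per bp within the window.
    """
    df = fragments.df
    df = df[df["chrom"] == chrom]
    if df.empty and chrom not in set(fragments.df["chrom"]):
        raise ValueError(f"no fragments on chromosome {chrom!r}")
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    cnt = df["count"].to_numpy()
    length = end - start
    mid = (start + end) / 2.0
    offset = mid - center
    keep = (np.abs(offset) <= half_window) & (length <= max_len)

    offset_edges = np.arange(-half_window, half_window + pos_bin, pos_bin,
                             dtype=float)
    length_edges = np.arange(0, max_len + len_bin, len_bin, dtype=float)
    hist, _, _ = np.histogram2d(
        offset[keep], length[keep],
        bins=(offset_edges, length_edges), weights=cnt[keep],
    )

    density = np.zeros(2 * half_window + 1)
    for p, c in ((start, cnt), (end - 1, cnt)):
        rel = p - (center - half_window)
        ok = (rel >= 0) & (rel <= 2 * half_window)
        np.add.at(density, rel[ok], c[ok])
    return VPlot(hist=hist, offset_edges=offset_edges,
                 length_edges=length_edges, insertion_density=density,
                 center=center, half_window=half_window)


# ---------------------------------------------------------------------------
# gene clustering by mark profiles
# ---------------------------------------------------------------------------

def cluster_genes_by_marks(tss_signal: pd.DataFrame, k: int = 10,
                           seed: int = 0) -> tuple[pd.Series, np.ndarray]:
    """k-means clustering of genes on row-scaled joint mark profiles.

    ``tss_signal`` is genes x features (e.g. H3K27ac and H3K27me3 signal
    around the 1-kb-padded TSS).  Rows are z-scored before clustering
    (zero-variance rows become zeros).  Returns labels and centroids;
    fixed ``seed`` gives identical labels across runs.
    """
    if k > len(tss_signal):
        raise ValueError("k must not exceed the number of genes")
    x = tss_signal.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(xs)
    return pd.Series(labels, index=tss_signal.index, name="cluster"), \
        km.cluster_centers_
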