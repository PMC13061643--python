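"""Gene-activity matrix, metagene cell-type scoring and differential
accessibility with Benjamini-Hochberg correction.

Differential testing is a two-sided Welch t-test on log1p CPM values per
feature, BH-corrected across features, with default significance
thresholds adjusted p <= 0.001 and |log2 fold change| >= 1.5 (both
configurable).  The log fold change is ``log2`` of the ratio of group
mean CPM with a pseudocount of 1.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .fragio import BinScheme
from .simulate import GeneModel


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    monotone, order-equivariant)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def gene_activity(
    matrix: sparse.spmatrix,
    cells: Sequence[str],
    scheme: BinScheme,
    genes: Sequence[GeneModel],
    chrom: str | None = None,
    promoter_flank: int = 5_000,
    knn: int = 0,
) -> pd.DataFrame:
    """Cell-by-gene activity: summed bin counts over the promoter window.

    The window is ``[TSS - flank, TSS + flank)`` (the TSS is already the
    strand-aware transcription start).  ``knn > 0`` optionally averages
    each cell's activity with its k nearest neighbors in PC space
    (simple smoothing for sparse data; off by default).
    """
    chrom = chrom or scheme.chroms[0]
    size = scheme.chrom_sizes[chrom]
    acts = np.zeros((matrix.shape[0], len(genes)))
    csc = matrix.tocsc()
    for g_i, gene in enumerate(genes):
        lo_bp = max(gene.tss - promoter_flank, 0)
        hi_bp = min(gene.tss + promoter_flank, size)
        if promoter_flank == 0:
            hi_bp = min(gene.tss + 1, size)
        lo, hi = scheme.region_bins(chrom, lo_bp, hi_bp)
        acts[:, g_i] = np.asarray(csc[:, lo:hi].sum(axis=1)).ravel()
    out = pd.DataFrame(acts, index=pd.Index(list(cells), name="barcode"),
                       columns=[g.name for g in genes])
    if knn > 0:
        out = _knn_smooth(out, knn)
    return out


def _knn_smooth(activity: pd.DataFrame, k: int, n_pcs: int = 20) -> pd.DataFrame:
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    x = np.log1p(activity.to_numpy(dtype=float))
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(x))).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    smoothed = activity.to_numpy(dtype=float)[idx].mean(axis=1)
    return pd.DataFrame(smoothed, index=activity.index,
                        columns=activity.columns)


@dataclasses.dataclass
class MetageneResult:
    scores: pd.DataFrame          # cell x cell-type score
    labels: pd.Series             # argmax label; None where unlabeled
    margin: pd.Series             # best minus runner-up score
    flagged: pd.Series            # all-zero or tied cells
    overlap_report: dict


def metagene_score(activity: pd.DataFrame,
                   marker_sets: Mapping[str, Sequence[str]]) -> MetageneResult:
    """Metagene score per cell and cell type: mean of per-gene z-scored
    activity over the marker set; the label is the argmax.

    Ties and all-zero cells are left unlabeled with a flag.  Overlapping
    marker sets are permitted but reported.
    """
    overlap: dict[str, list[str]] = {}
    sets = {k: [g for g in v if g in activity.columns]
            for k, v in marker_sets.items()}
    for k, v in marker_sets.items():
        missing = [g for g in v if g not in activity.columns]
        if missing:
            raise ValueError(f"marker set {k!r} has unknown genes: {missing[:3]}")
        if not v:
            raise ValueError(f"marker set {k!r} is empty")
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = sorted(set(sets[a]) & set(sets[b]))
            if shared:
                overlap[f"{a}&{b}"] = shared

    x = activity.to_numpy(dtype=float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = pd.DataFrame((x - mu) / sd, index=activity.index,
                     columns=activity.columns)
    scores = pd.DataFrame(
        {k: z[list(v)].mean(axis=1) for k, v in sets.items()}
    )
    arr = scores.to_numpy()
    order = np.argsort(arr, axis=1)
    best = arr[np.arange(len(arr)), order[:, -1]]
    runner = arr[np.arange(len(arr)), order[:, -2]] if arr.shape[1] > 1 \
        else np.full(len(arr), -np.inf)
    margin = best - runner
    zero_cells = x.sum(axis=1) == 0
    tied = margin == 0
    labels = pd.Series(
        [None if (zero_cells[i] or tied[i]) else scores.columns[order[i, -1]]
         for i in range(len(arr))],
        index=activity.index, name="label",
    )
    return MetageneResult(
        scores=scores, labels=labels,
        margin=pd.Series(margin, index=activity.index, name="margin"),
        flagged=pd.Series(zero_cells | tied, index=activity.index,
                          name="flagged"),
        overlap_report=overlap,
    )


def differential_accessibility(
    matrix: sparse.spmatrix,
    cells: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    feature_ids: Sequence | None = None,
    alpha: float = 0.001,
    lfc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-feature differential test between two cell groups.

    Counts are CPM-normalized per cell, log1p-transformed, and compared
    with a two-sided Welch t-test; BH correction is applied across all
    tested features.  ``logFC = log2((mean CPM_A + 1)/(mean CPM_B + 1))``.
    A feature is significant when adjusted p <= ``alpha`` and
    ``|logFC| >= lfc_min``.

    Returns a frame with columns ``feature, log_fc, p_value, adj_p,
    significant``.
    """
    cells = list(cells)
    idx = {b: i for i, b in enumerate(cells)}
    rows_a = [idx[b] for b in group_a]
    rows_b = [idx[b] for b in group_b]
    if len(rows_a) < 3 or len(rows_b) < 3:
        raise ValueError("need at least 3 cells per group")
    dense = np.asarray(matrix.todense(), dtype=float) \
        if sparse.issparse(matrix) else np.asarray(matrix, dtype=float)
    totals = dense.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    cpm = dense / totals * 1e6
    log_cpm = np.log1p(cpm)

    a = log_cpm[rows_a]
    b = log_cpm[rows_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)    # zero variance in both groups
    adj = bh_adjust(p)
    mean_a = cpm[rows_a].mean(axis=0)
    mean_b = cpm[rows_b].mean(axis=0)
    log_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    features = feature_ids if feature_ids is not None \
        else np.arange(dense.shape[1])
    return pd.DataFrame(
        {"feature": features, "log_fc": log_fc, "p_value": p, "adj_p": adj,
         "significant": (adj <= alpha) & (np.abs(log_fc) >= lfc_min)}
    )
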