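"""Within-cell joint-mark analysis.

Joint profiling links H3K27ac and H3K27me3 (and optionally ATAC) measured
in the same nucleus through a shared cell barcode.  This module computes
per-cell, depth-normalized regional signal, splits cells into a
high-H3K27me3 group 1 and a low-H3K27me3 group 2, and tests whether the
H3K27ac signal is exchangeable between the two groups with a permutation
test.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragio import FragmentSet


def percell_region_signal(
    fragments: Mapping[str, FragmentSet],
    region: tuple[str, int, int],
    barcodes: Sequence[str],
) -> pd.DataFrame:
    """Per-cell raw and depth-normalized counts in a region, per modality.

    Normalization is counts per thousand of the cell's total count in
    that modality (joint-modality depths differ systematically, so each
    modality is normalized on its own).  Cells with zero total depth in a
    modality are flagged and get normalized value 0.

    Returns a frame indexed by barcode with columns ``raw_<mod>``,
    ``norm_<mod>`` and ``zero_depth_<mod>``.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError("empty region")
    barcodes = list(barcodes)
    out = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for mod, fs in fragments.items():
        df = fs.df
        hit = (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        raw = df.loc[hit].groupby("barcode")["count"].sum()
        total = fs.per_barcode_counts()
        raw = raw.reindex(barcodes, fill_value=0).astype(float)
        total = total.reindex(barcodes, fill_value=0).astype(float)
        zero = total == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = raw / total * 1_000.0
        norm[zero] = 0.0
        out[f"raw_{mod}"] = raw
        out[f"norm_{mod}"] = norm
        out[f"zero_depth_{mod}"] = zero
    return out


@dataclasses.dataclass
class GroupSplit:
    """Two-group split of cells by one mark's normalized signal.

    Group 1 is the higher-signal group.  ``ok`` is False when the split
    was refused (degenerate input); ``silhouette`` is the mean silhouette
    coefficient of the 1-D split as a separation diagnostic.
    """

    labels: pd.Series            # barcode -> 1 | 2
    centers: tuple[float, float]
    silhouette: float
    ok: bool
    message: str = ""


def split_groups_by_mark(signals: pd.Series) -> GroupSplit:
    """1-D two-means split on normalized mark values.

    Deterministic initialization at the 10th and 90th percentiles; labels
    ordered so group 1 has the higher mean.  Identical values (or a split
    that empties one group) refuse with a diagnostic instead of forcing
    two groups.  Label assignment is invariant to input permutation.
    """
    if len(signals) < 4:
        raise ValueError("need at least 4 cells to split")
    x = signals.to_numpy(dtype=float)
    c_lo, c_hi = np.percentile(x, [10, 90])
    if c_lo == c_hi:
        return GroupSplit(
            labels=pd.Series(1, index=signals.index, name="group"),
            centers=(float(c_hi), float(c_lo)), silhouette=0.0, ok=False,
            message="values indistinguishable; single group declared",
        )
    centers = np.array([c_lo, c_hi], dtype=float)
    for _ in range(200):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == k].mean() if (assign == k).any() else centers[k]
            for k in (0, 1)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    if (assign == 0).all() or (assign == 1).all():
        return GroupSplit(
            labels=pd.Series(1, index=signals.index, name="group"),
            centers=(float(centers.max()), float(centers.min())),
            silhouette=0.0, ok=False,
            message="two-means collapsed to one cluster",
        )
    hi = int(np.argmax(centers))
    labels = np.where(assign == hi, 1, 2)

    # 1-D silhouette: within-cluster vs other-cluster mean absolute distance
    sil = _silhouette_1d(x, labels)
    return GroupSplit(
        labels=pd.Series(labels, index=signals.index, name="group"),
        centers=(float(centers[hi]), float(centers[1 - hi])),
        silhouette=sil, ok=True,
    )


def _silhouette_1d(x: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for k in (1, 2):
        own = x[labels == k]
        other = x[labels != k]
        for v in own:
            if len(own) > 1:
                a = np.abs(own - v).sum() / (len(own) - 1)
            else:
                a = 0.0
            b = np.abs(other - v).mean()
            denom = max(a, b)
            vals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(vals))


@dataclasses.dataclass
class UniformityTest:
    observed_diff: float
    p_value: float
    n_perm: int
    group_means: tuple[float, float]


def test_mark_uniformity(
    signals: pd.Series,
    groups: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
) -> UniformityTest:
    """Two-sided permutation test of equal group means.

    The statistic is the difference in group means of ``signals``
    (e.g. per-cell normalized H3K27ac); the null shuffles the group
    labels.  ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``.
    """
    groups = groups.reindex(signals.index)
    g1 = groups == 1
    g2 = groups == 2
    if not g1.any() or not g2.any():
        raise ValueError("both groups must be non-empty")
    x = signals.to_numpy(dtype=float)
    n1 = int(g1.sum())
    obs = x[g1.to_numpy()].mean() - x[g2.to_numpy()].mean()

    rng = np.random.default_rng(seed)
    total = x.sum()
    n = len(x)
    n2 = n - n1
    # vectorized label shuffles: random subsets of size n1 via argpartition
    r = rng.random((n_perm, n))
    idx = np.argpartition(r, n1 - 1, axis=1)[:, :n1]
    sum1 = x[idx].sum(axis=1)
    perm = sum1 / n1 - (total - sum1) / n2
    p = (1 + int((np.abs(perm) >= abs(obs)).sum())) / (1 + n_perm)
    return UniformityTest(
        observed_diff=float(obs), p_value=float(p), n_perm=n_perm,
        group_means=(float(x[g1.to_numpy()].mean()),
                     float(x[g2.to_numpy()].mean())),
    )
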