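"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a package operation by the most direct
method available (double loops, textbook formulas), deliberately sharing
no code with the implementation it checks.
"""

import numpy as np


def diamond_sums_bruteforce(balanced, w):
    """Diamond insulation sums by explicit double loop."""
    n = balanced.shape[0]
    out = np.full(n, np.nan)
    for b in range(w, n - w):
        total = 0.0
        any_finite = False
        for i in range(b - w, b):
            for j in range(b + 1, b + 1 + w):
                v = balanced[i, j]
                if np.isfinite(v):
                    total += v
                    any_finite = True
        if any_finite:
            out[b] = total
    return out


def bh_stepup(p):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def pearson(x, y):
    """Textbook Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() /
                 np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def interval_counts(fragment_df, chrom, start, end, barcode):
    """Sum of counts of one barcode's fragments overlapping a region."""
    total = 0
    for row in fragment_df.itertuples():
        if (row.chrom == chrom and row.barcode == barcode
                and row.start < end and row.end > start):
            total += row.count
    return total


def gaussian_smooth_reflect(values, sigma, truncate=4.0):
    """Direct convolution with a reflected-boundary Gaussian kernel."""
    radius = int(truncate * sigma + 0.5)
    xs = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (xs / sigma) ** 2)
    kernel /= kernel.sum()
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for k, w in zip(xs, kernel):
            j = i - k
            # scipy 'reflect' boundary: (d c b a | a b c d | d c b a)
            while j < 0 or j >= n:
                if j < 0:
                    j = -j - 1
                else:
                    j = 2 * n - j - 1
            acc += w * values[j]
        out[i] = acc
    return out


def expected_profile_bruteforce(balanced):
    """Per-diagonal means by explicit pixel enumeration."""
    n = balanced.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        vals = []
        for i in range(n - d):
            v = balanced[i, i + d]
            if np.isfinite(v):
                vals.append(v)
        if vals:
            out[d] = float(np.mean(vals))
    return out


def pileup_mean_bruteforce(oe, anchors, flank):
    """Mean of O/E windows by explicit accumulation over usable anchors."""
    n = oe.shape[0]
    used = []
    for bi, bj in anchors:
        bi, bj = int(min(bi, bj)), int(max(bi, bj))
        if bi - flank < 0 or bj + flank >= n or bi + flank >= n \
                or bj - flank < 0 or (bj - bi) <= flank:
            continue
        used.append(oe[bi - flank:bi + flank + 1, bj - flank:bj + flank + 1])
    size = 2 * flank + 1
    out = np.zeros((size, size))
    for a in range(size):
        for b in range(size):
            out[a, b] = np.nanmean([w[a, b] for w in used])
    return out
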