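"""Readers, writers and binning for fragment files, bedGraph tracks and
contact-matrix triplets.

All coordinates in this package are 0-based, half-open (BED dialect).
Fragment records follow the 10x ``fragments.tsv`` layout::

    chrom  start  end  barcode  count

A fragment represents two Tn5 insertion events, one at ``start`` and one at
``end - 1`` (10x fragment coordinates are already shifted to the insertion
sites).  Binning therefore credits each fragment to the bin of *each* of its
two termini, which conserves the total number of insertion events.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

FRAGMENT_COLUMNS = ("chrom", "start", "end", "barcode", "count")


class FragmentParseError(ValueError):
    """Malformed fragment/bedGraph input; message carries the line number."""


# ---------------------------------------------------------------------------
# Bin scheme
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BinScheme:
    """Fixed-width genomic binning.

    Parameters
    ----------
    width
        Bin width in bp (e.g. 2_000 for count matrices, 10_000 for
        contact matrices and trimodal clustering).
    chrom_sizes
        Ordered mapping of chromosome name to length in bp.  The last bin
        of each chromosome may be truncated.

    A position ``p`` on chromosome ``c`` maps to local bin ``p // width``;
    global bin ids concatenate chromosomes in the order given.
    """

    width: int
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-int(self.chrom_sizes[chrom]) // self.width)

    def offset(self, chrom: str) -> int:
        off = 0
        for c in self.chrom_sizes:
            if c == chrom:
                return off
            off += self.n_bins(c)
        raise KeyError(chrom)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_sizes)

    def bin_ids(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Global bin ids for an array of positions on one chromosome."""
        positions = np.asarray(positions)
        size = self.chrom_sizes[chrom]
        if positions.size and (positions.min() < 0 or positions.max() >= size):
            raise ValueError(f"position outside chromosome {chrom!r} bounds")
        return self.offset(chrom) + positions // self.width

    def region_bins(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global ``[lo, hi)`` bin-id range covering the region ``[start, end)``."""
        if not 0 <= start < end <= self.chrom_sizes[chrom]:
            raise ValueError("region outside chromosome bounds")
        off = self.offset(chrom)
        return off + start // self.width, off + -(-end // self.width)

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for chrom, size in self.chrom_sizes.items():
            starts = np.arange(0, size, self.width)
            ends = np.minimum(starts + self.width, size)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["bin_id"] = np.arange(len(table))
        return table


# ---------------------------------------------------------------------------
# Fragment sets
# ---------------------------------------------------------------------------

class FragmentSet:
    """In-memory collection of fragment records (one modality).

    Wraps a validated :class:`pandas.DataFrame` with the 10x fragment
    columns.  Duplicate ``(chrom, start, end, barcode)`` rows are legal and
    are summed when binned.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        df = df.loc[:, list(FRAGMENT_COLUMNS)].reset_index(drop=True)
        if len(df):
            if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
                raise ValueError("fragment with start >= end")
            if (df["count"].to_numpy() < 1).any():
                raise ValueError("fragment with count < 1")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    @property
    def barcodes(self) -> list[str]:
        return sorted(self.df["barcode"].unique())

    def sorted(self) -> "FragmentSet":
        df = self.df.sort_values(
            ["chrom", "start", "end", "barcode"], kind="mergesort"
        ).reset_index(drop=True)
        return FragmentSet(df)

    def insertions(self) -> pd.DataFrame:
        """Expand fragments into per-terminus insertion events.

        Returns a frame with columns ``chrom, pos, barcode, count`` holding
        two rows per fragment (positions ``start`` and ``end - 1``).
        """
        df = self.df
        return pd.DataFrame(
            {
                "chrom": np.concatenate([df["chrom"], df["chrom"]]),
                "pos": np.concatenate([df["start"], df["end"] - 1]),
                "barcode": np.concatenate([df["barcode"], df["barcode"]]),
                "count": np.concatenate([df["count"], df["count"]]),
            }
        )

    def per_barcode_counts(self) -> pd.Series:
        return self.df.groupby("barcode")["count"].sum().sort_index()


def read_fragments(path: str | Path) -> FragmentSet:
    """Read a fragments TSV (``#`` header lines permitted).

    Malformed lines raise :class:`FragmentParseError` naming the 1-based
    line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "barcode": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FragmentParseError(f"{path}: unparsable fragments file: {exc}") from exc
    if df.empty:
        return FragmentSet(
            pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                          zip(FRAGMENT_COLUMNS, (str, int, int, str, int))})
        )
    for col in ("start", "end", "count"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = _data_line_number(path, int(bad[0]) if len(bad) else 0)
            raise FragmentParseError(f"{path}:{line}: non-integer {col!r} field")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        line = _data_line_number(path, int(bad[0]))
        raise FragmentParseError(f"{path}:{line}: fragment start >= end")
    bad = df.index[df["count"].to_numpy() < 1]
    if len(bad):
        line = _data_line_number(path, int(bad[0]))
        raise FragmentParseError(f"{path}:{line}: fragment count < 1")
    return FragmentSet(df)


def _data_line_number(path: Path, data_index: int) -> int:
    """Map a data-row index to a 1-based file line number, skipping '#' headers."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            if n == data_index:
                return lineno
            n += 1
    return data_index + 1


def write_fragments(fragments: FragmentSet, path: str | Path,
                    header: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("# fragments TSV: chrom\tstart\tend\tbarcode\tcount\n")
            fh.write("# coordinates 0-based half-open\n")
        fragments.sorted().df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_counts(
    fragments: FragmentSet,
    scheme: BinScheme,
    cells: Sequence[str],
) -> tuple[sparse.csr_matrix, dict]:
    """Build a cell-by-bin insertion count matrix.

    Each fragment contributes its ``count`` to the bin of each of its two
    insertion termini (``start`` and ``end - 1``), so the matrix total is
    exactly ``2 * sum(count)`` over retained barcodes.  Fragments whose
    barcode is not in ``cells`` are silently dropped and tallied in the
    returned report.

    Returns
    -------
    matrix : scipy.sparse.csr_matrix, shape (len(cells), scheme.total_bins)
    report : dict with ``n_dropped_fragments`` and ``dropped_barcodes``
    """
    cells = list(cells)
    cell_index = {b: i for i, b in enumerate(cells)}
    ins = fragments.insertions()
    keep = ins["barcode"].map(cell_index)
    dropped_mask = keep.isna()
    report = {
        # each fragment appears twice in the insertion table
        "n_dropped_fragments": int(dropped_mask.sum()) // 2,
        "dropped_barcodes": sorted(ins.loc[dropped_mask, "barcode"].unique()),
    }
    ins = ins.loc[~dropped_mask].reset_index(drop=True)
    if ins.empty:
        return sparse.csr_matrix((len(cells), scheme.total_bins), dtype=np.int64), report
    rows = ins["barcode"].map(cell_index).to_numpy(dtype=np.int64)
    cols = np.empty(len(ins), dtype=np.int64)
    for chrom, sub in ins.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        cols[idx] = scheme.bin_ids(str(chrom), sub["pos"].to_numpy())
    mat = sparse.coo_matrix(
        (ins["count"].to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(cells), scheme.total_bins),
    ).tocsr()
    return mat, report


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BinnedSignalTrack:
    """Fixed-width binned signal vector for one modality/group.

    ``values[i]`` covers ``[start + i*width, start + (i+1)*width)`` on
    ``chrom``.  ``normalization`` is ``"raw"`` or ``"CPM"``; ``label`` is a
    free-form group tag (cell type, region or modality).
    """

    chrom: str
    start: int
    width: int
    values: np.ndarray
    normalization: str = "raw"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("track values must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.width

    def bin_start(self, i: int | np.ndarray) -> int | np.ndarray:
        return self.start + np.asarray(i) * self.width

    def bin_of(self, pos: int) -> int:
        return (pos - self.start) // self.width

    def slice_mean(self, start: int, end: int) -> float:
        """Mean value over bins fully or partially inside ``[start, end)``."""
        lo = max(0, (start - self.start) // self.width)
        hi = min(self.n_bins, -(-(end - self.start) // self.width))
        if hi <= lo:
            raise ValueError("interval does not overlap track")
        return float(self.values[lo:hi].mean())


def write_bedgraph(track: BinnedSignalTrack, path: str | Path,
                   merge: bool = True) -> None:
    """Write a 4-column bedGraph; adjacent equal-value bins may be merged."""
    path = Path(path)
    v = track.values
    with open(path, "w") as fh:
        fh.write("# bedGraph, 0-based half-open coordinates\n")
        i = 0
        while i < len(v):
            j = i + 1
            if merge:
                while j < len(v) and v[j] == v[i]:
                    j += 1
            fh.write(
                f"{track.chrom}\t{track.start + i * track.width}"
                f"\t{track.start + j * track.width}\t{v[i]:.10g}\n"
            )
            i = j


def read_bedgraph(path: str | Path, width: int) -> BinnedSignalTrack:
    """Read a bedGraph and re-expand merged runs onto ``width``-bp bins.

    Intervals must be non-overlapping and ascending on a single
    chromosome; gaps are filled with zeros.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        raise FragmentParseError(f"{path}: empty bedGraph")
    if df["chrom"].nunique() != 1:
        raise FragmentParseError(f"{path}: expected a single chromosome")
    df = df.sort_values("start", kind="mergesort").reset_index(drop=True)
    if (df["end"].to_numpy()[:-1] > df["start"].to_numpy()[1:]).any():
        raise FragmentParseError(f"{path}: overlapping bedGraph intervals")
    chrom = str(df["chrom"].iloc[0])
    start = int(df["start"].iloc[0])
    end = int(df["end"].max())
    n = -(-(end - start) // width)
    values = np.zeros(n)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        lo = (int(s) - start) // width
        hi = -(-(int(e) - start) // width)
        values[lo:hi] = v
    return BinnedSignalTrack(chrom=chrom, start=start, width=width, values=values)


# ---------------------------------------------------------------------------
# Contact-matrix triplets
# ---------------------------------------------------------------------------

def read_contacts(triplets_path: str | Path, bins_path: str | Path):
    """Read COO contact triplets plus a bin table into a ContactMatrix.

    Upper-triangle storage is accepted; the matrix is symmetrized.
    Conflicting asymmetric duplicates (``(i, j)`` and ``(j, i)`` with
    different values) raise a :class:`FragmentParseError`.
    """
    from .hic import ContactMatrix  # deferred: hic does not import fragio

    bins = pd.read_csv(bins_path, sep="\t", comment="#", header=None,
                       names=["chrom", "start", "end", "bin_id"])
    trip = pd.read_csv(triplets_path, sep="\t", comment="#", header=None,
                       names=["bin_i", "bin_j", "count"])
    n = len(bins)
    counts = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for i, j, c in zip(trip["bin_i"], trip["bin_j"], trip["count"]):
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise FragmentParseError(
                f"{triplets_path}: triplet references invalid bin id ({i},{j})")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != c:
            raise FragmentParseError(
                f"{triplets_path}: conflicting duplicate for pixel {key}")
        seen[key] = c
        counts[i, j] = c
        counts[j, i] = c
    return ContactMatrix(bins=bins[["chrom", "start", "end"]], counts=counts)


def write_contacts(cm, triplets_path: str | Path, bins_path: str | Path) -> None:
    """Write upper-triangle COO triplets and the bin table."""
    table = cm.bins.copy()
    table["bin_id"] = np.arange(len(table))
    with open(bins_path, "w") as fh:
        fh.write("# bin table: chrom\tstart\tend\tbin_id (0-based half-open)\n")
        table.to_csv(fh, sep="\t", header=False, index=False)
    iu = np.triu_indices(cm.counts.shape[0])
    vals = cm.counts[iu]
    nz = vals != 0
    trip = pd.DataFrame({"bin_i": iu[0][nz], "bin_j": iu[1][nz], "count": vals[nz]})
    with open(triplets_path, "w") as fh:
        fh.write("# contact triplets: bin_i\tbin_j\tcount (upper triangle)\n")
        trip.to_csv(fh, sep="\t", header=False, index=False)
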