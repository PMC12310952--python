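"""Lineage-barcode evidence: extraction, filtering, and the cell x barcode matrix.

The processing order is fixed: flank trimming -> insert length filter (>= 37 bp)
-> aggregation of identical (cell, UMI, barcode) observations into triples ->
read-support filter (>= 10 reads per triple) -> UMI-support filter (>= 6
distinct UMIs per cell-barcode pair) -> binary sparse incidence matrix.
Every filter reports its in/out counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

TRIPLE_COLUMNS = ["cell_bc", "umi", "lineage_bc", "reads"]


class TripleRecord(NamedTuple):
    """One (cell barcode, UMI, lineage barcode) observation with read support."""

    cell_bc: str
    umi: str
    lineage_bc: str
    reads: int

    def validate(self) -> "TripleRecord":
        if not (self.cell_bc and self.umi and self.lineage_bc):
            raise ValueError(f"empty field in triple {self!r}")
        if self.reads < 1:
            raise ValueError(f"reads must be >= 1, got {self.reads}")
        return self


class MalformedFastqError(ValueError):
    """Raised with the index of the offending FASTQ record."""


@dataclass
class ExtractionReport:
    n_reads: int = 0
    n_missing_flank: int = 0
    n_short_insert: int = 0
    n_not_whitelisted: int = 0
    n_kept: int = 0


def _hamming_find(seq: str, probe: str, tol: int) -> int:
    """Index of the first occurrence of ``probe`` in ``seq`` within ``tol``
    mismatches, or -1."""
    if tol == 0:
        return seq.find(probe)
    L = len(probe)
    for i in range(len(seq) - L + 1):
        if sum(a != b for a, b in zip(seq[i:i + L], probe)) <= tol:
            return i
    return -1


def _iter_fastq(path: str | Path):
    """Yield (index, name, seq) from a FASTQ file, gzip-transparently."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise MalformedFastqError(
                    f"malformed FASTQ record at index {idx}: {e}"
                ) from e
            yield idx, title, seq
            idx += 1


def extract_barcodes(
    reads: str | Path | Iterable[tuple[int, str, str]],
    flank5: str,
    flank3: str,
    min_len: int = 37,
    whitelist: Optional[set] = None,
    flank_mismatch_tol: int = 0,
) -> tuple[pd.DataFrame, ExtractionReport]:
    """Extract lineage barcodes from read-2 records and aggregate to triples.

    The cell barcode and UMI are taken from the read name
    (``...:<cell_bc>:<umi>``); the lineage barcode is the insert between the
    two exact flank matches (a Hamming tolerance is available but defaults to
    0).  Inserts shorter than ``min_len`` (default 37 bp) and cells outside
    ``whitelist`` are excluded.  Identical observations are aggregated into
    triples whose ``reads`` column is the observation count.
    """
    if not flank5 or not flank3:
        raise ValueError("flank sequences must be non-empty")
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)
    report = ExtractionReport()
    obs: dict[tuple[str, str, str], int] = {}
    for idx, name, seq in reads:
        report.n_reads += 1
        parts = name.split(":")
        if len(parts) < 3:
            raise MalformedFastqError(
                f"read name without cell/UMI fields at record {idx}: {name!r}"
            )
        cell, umi = parts[-2], parts[-1]
        i5 = _hamming_find(seq, flank5, flank_mismatch_tol)
        if i5 < 0:
            report.n_missing_flank += 1
            continue
        start = i5 + len(flank5)
        i3 = _hamming_find(seq[start:], flank3, flank_mismatch_tol)
        if i3 < 0:
            report.n_missing_flank += 1
            continue
        insert = seq[start:start + i3]
        if len(insert) < min_len:
            report.n_short_insert += 1
            continue
        if whitelist is not None and cell not in whitelist:
            report.n_not_whitelisted += 1
            continue
        report.n_kept += 1
        obs[(cell, umi, insert)] = obs.get((cell, umi, insert), 0) + 1
    triples = pd.DataFrame(
        [(c, u, b, r) for (c, u, b), r in obs.items()], columns=TRIPLE_COLUMNS
    )
    triples = triples.sort_values(
        ["cell_bc", "lineage_bc", "umi"], kind="mergesort"
    ).reset_index(drop=True)
    return triples, report


# ---------------------------------------------------------------------------
# triple table I/O

def read_triples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"triple table {path} lacks required columns {sorted(missing)}")
    return df[TRIPLE_COLUMNS]


def write_triples(triples: pd.DataFrame, path: str | Path) -> None:
    triples[TRIPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def _validate_triples(triples: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIPLE_COLUMNS) - set(triples.columns)
    if missing:
        raise ValueError(f"triple table lacks required columns {sorted(missing)}")
    if len(triples) and triples["reads"].min() < 1:
        raise ValueError("triples with reads < 1")
    if triples.duplicated(["cell_bc", "umi", "lineage_bc"]).any():
        raise ValueError("triples must be unique on (cell_bc, umi, lineage_bc); aggregate first")
    return triples


@dataclass
class FilterReport:
    """Per-stage in/out counts of :func:`filter_triples`."""

    n_triples_in: int = 0
    n_triples_read_pass: int = 0
    n_pairs_in: int = 0
    n_pairs_umi_pass: int = 0
    min_reads: int = 10
    min_umis: int = 6


def filter_triples(
    triples: pd.DataFrame, min_reads: int = 10, min_umis: int = 6
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the read- and UMI-support thresholds to aggregated triples.

    Triples supported by fewer than ``min_reads`` reads are removed first;
    cell-barcode pairs whose surviving distinct UMIs number fewer than
    ``min_umis`` are then removed.  Returns the surviving pairs
    (``cell_bc, lineage_bc, umi_count``) and a per-stage report.  Empty input
    yields an empty table, not an error.
    """
    if min_reads < 1 or min_umis < 1:
        raise ValueError("min_reads and min_umis must be >= 1")
    _validate_triples(triples)
    report = FilterReport(min_reads=min_reads, min_umis=min_umis, n_triples_in=len(triples))
    if not len(triples):
        return (
            pd.DataFrame(columns=["cell_bc", "lineage_bc", "umi_count"]),
            report,
        )
    kept = triples[triples["reads"] >= min_reads]
    report.n_triples_read_pass = len(kept)
    pairs = (
        kept.groupby(["cell_bc", "lineage_bc"], sort=True)["umi"]
        .nunique()
        .rename("umi_count")
        .reset_index()
    )
    report.n_pairs_in = triples.groupby(["cell_bc", "lineage_bc"]).ngroups
    pairs = pairs[pairs["umi_count"] >= min_umis].reset_index(drop=True)
    report.n_pairs_umi_pass = len(pairs)
    return pairs, report


# ---------------------------------------------------------------------------
# cell x barcode matrix

@dataclass
class CellBarcodeMatrix:
    """Binary incidence of cells (rows) x lineage barcodes (columns).

    Rows/columns are lexicographically ordered by ID; only nonzeros are
    stored; every row and every column has at least one nonzero.
    ``n_dropped_cells`` counts whitelisted cells that had no surviving pair.
    """

    cell_ids: np.ndarray
    barcode_ids: np.ndarray
    matrix: sparse.csr_matrix
    n_dropped_cells: int = 0

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.cell_ids), len(self.barcode_ids)):
            raise ValueError("matrix shape inconsistent with ID lists")
        if len(self.cell_ids):
            rows = np.asarray(self.matrix.sum(axis=1)).ravel()
            cols = np.asarray(self.matrix.sum(axis=0)).ravel()
            if (rows == 0).any():
                raise ValueError("cells without any barcode must be dropped upstream")
            if (cols == 0).any():
                raise ValueError("columns with zero support must not exist")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def barcode_set(self, cell_index: int) -> frozenset:
        row = self.matrix.indices[
            self.matrix.indptr[cell_index]:self.matrix.indptr[cell_index + 1]
        ]
        return frozenset(self.barcode_ids[row])

    def equals(self, other: "CellBarcodeMatrix") -> bool:
        return (
            np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.barcode_ids, other.barcode_ids)
            and (self.matrix != other.matrix).nnz == 0
        )

    # -- I/O ---------------------------------------------------------------
    def to_long_csv(self, path: str | Path) -> None:
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.col, coo.row))
        pd.DataFrame(
            {
                "cell_id": self.cell_ids[coo.row[order]],
                "lineage_bc": self.barcode_ids[coo.col[order]],
                "value": np.ones(coo.nnz, dtype=int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "CellBarcodeMatrix":
        df = pd.read_csv(path)
        return build_matrix(df.rename(columns={"cell_id": "cell_bc"})[["cell_bc", "lineage_bc"]])

    def to_mtx(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.matrix.tocoo())
        prefix.with_suffix(".cells.txt").write_text("\n".join(self.cell_ids) + "\n")
        prefix.with_suffix(".barcodes.txt").write_text("\n".join(self.barcode_ids) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str | Path) -> "CellBarcodeMatrix":
        prefix = Path(prefix)
        m = sparse.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        cells = np.array(prefix.with_suffix(".cells.txt").read_text().splitlines())
        bcs = np.array(prefix.with_suffix(".barcodes.txt").read_text().splitlines())
        return cls(cell_ids=cells, barcode_ids=bcs, matrix=m)


def build_matrix(
    pairs: pd.DataFrame, whitelist: Optional[Sequence[str]] = None
) -> CellBarcodeMatrix:
    """Binary cell x barcode matrix from filtered pairs.

    Row and column order is lexicographic by ID.  Duplicate pair rows are
    rejected.  If ``whitelist`` is given, whitelisted cells with no surviving
    pair are counted into ``n_dropped_cells``.
    """
    for col in ("cell_bc", "lineage_bc"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks column {col!r}")
    if pairs.duplicated(["cell_bc", "lineage_bc"]).any():
        raise ValueError("duplicate (cell, barcode) pair rows")
    cells = np.array(sorted(pairs["cell_bc"].unique()))
    bcs = np.array(sorted(pairs["lineage_bc"].unique()))
    n_dropped = 0
    if whitelist is not None:
        n_dropped = len(set(whitelist) - set(cells))
    ci = pd.Series(np.arange(len(cells)), index=cells)
    bi = pd.Series(np.arange(len(bcs)), index=bcs)
    m = sparse.csr_matrix(
        (
            np.ones(len(pairs), dtype=np.int8),
            (ci[pairs["cell_bc"]].to_numpy(), bi[pairs["lineage_bc"]].to_numpy()),
        ),
        shape=(len(cells), len(bcs)),
    )
    return CellBarcodeMatrix(
        cell_ids=cells, barcode_ids=bcs, matrix=m, n_dropped_cells=n_dropped
    )
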