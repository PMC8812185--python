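"""Data model and I/O for genomes, intervals, binned contact matrices and loops.

All coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted on read/write; BED and BEDPE are native. Contact matrices use the
two-file sparse text dialect (a bin table plus upper-triangle COO triples) at a
fixed resolution drawn from {5, 10, 20, 40, 200} kb by default.

Loops are cis-only: ``anchor1 < anchor2`` in genome order, anchors snapped to
the declared resolution grid. BEDPE columns 8 and 9 (1-based) carry the contact
count and FDR by this package's convention; column 10, when present, carries
the raw p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Developmental stages, days post anthesis, in temporal order.
STAGES = ("0DPA", "5DPA", "10DPA", "20DPA")

#: The three assayed histone marks.
MARKS = ("H3K27ac", "H3K4me3", "H3K9me2")

#: Marks associated with active vs. repressed chromatin.
ACTIVE_MARKS = ("H3K27ac", "H3K4me3")
INACTIVE_MARKS = ("H3K9me2",)

DEFAULT_RESOLUTIONS = (5_000, 10_000, 20_000, 40_000, 200_000)


class FormatError(ValueError):
    """A file did not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# Interval sets
# ---------------------------------------------------------------------------

_INTERVAL_COLS = ["chrom", "start", "end"]


class GenomicIntervalSet:
    """Sorted intervals on named chromosomes with arbitrary payload columns.

    Thin wrapper over a DataFrame with at least ``chrom``, ``start``, ``end``
    columns; rows are kept sorted by (chrom, start, end).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _INTERVAL_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"interval frame missing columns {missing}")
        if len(frame) and (frame["end"] <= frame["start"]).any():
            bad = frame.index[frame["end"] <= frame["start"]][0]
            raise ValueError(f"interval with end <= start at row {bad}")
        if (frame["start"] < 0).any():
            raise ValueError("negative interval start")
        self.frame = (
            frame.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def midpoints(self) -> pd.Series:
        return (self.frame["start"] + self.frame["end"]) // 2

    def subset(self, chrom: str) -> "GenomicIntervalSet":
        return GenomicIntervalSet(self.frame[self.frame["chrom"] == chrom])

    @classmethod
    def from_records(cls, records, columns=None) -> "GenomicIntervalSet":
        cols = columns or _INTERVAL_COLS
        return cls(pd.DataFrame.from_records(records, columns=cols))


@dataclass
class GenomeModel:
    """Chromosomes of a two-subgenome genome plus annotated features.

    ``chromosomes`` maps name -> (length bp, subgenome label in {"At", "Dt"});
    insertion order is genome order. Peak sets are keyed by (stage, mark).
    """

    chromosomes: dict[str, tuple[int, str]]
    genes: GenomicIntervalSet | None = None
    transposable_elements: GenomicIntervalSet | None = None
    peaks: dict[tuple[str, str], GenomicIntervalSet] = field(default_factory=dict)

    def __post_init__(self):
        for name, (length, sub) in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if sub not in ("At", "Dt"):
                raise ValueError(f"chromosome {name}: subgenome must be At or Dt")
        if self.genes is not None and len(self.genes):
            gf = self.genes.frame
            if "gene_id" in gf.columns and gf["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids")
            self._check_bounds(gf, "gene")
        for (stage, mark) in self.peaks:
            if mark not in MARKS:
                raise ValueError(f"unknown histone mark {mark!r}")

    def _check_bounds(self, frame: pd.DataFrame, what: str):
        for chrom, grp in frame.groupby("chrom"):
            if chrom not in self.chromosomes:
                raise ValueError(f"{what} on unknown chromosome {chrom}")
            if (grp["end"] > self.chromosomes[chrom][0]).any():
                raise ValueError(f"{what} beyond end of {chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom][0]

    def subgenome(self, chrom: str) -> str:
        return self.chromosomes[chrom][1]

    def chroms_of(self, subgenome: str) -> list[str]:
        return [c for c, (_, s) in self.chromosomes.items() if s == subgenome]


# ---------------------------------------------------------------------------
# Binned contact matrix
# ---------------------------------------------------------------------------


class BinnedMatrix:
    """Symmetric sparse contact matrix at a fixed resolution.

    Only the upper triangle (i <= j) is stored; queries are symmetric.
    ``weights`` are per-bin multiplicative balancing factors (NaN = masked).
    Bin identity is (chrom, start // resolution).
    """

    def __init__(
        self,
        resolution: int,
        bins: pd.DataFrame,
        matrix: sp.spmatrix,
        weights: np.ndarray | None = None,
        stage: str | None = None,
    ):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.bins = bins.reset_index(drop=True)
        n = len(self.bins)
        mat = sp.coo_matrix(matrix)
        if mat.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")
        if len(mat.data) and (mat.data < 0).any():
            raise ValueError("negative contact counts")
        lower = mat.row > mat.col
        if lower.any():  # fold anything below the diagonal up
            r = np.where(lower, mat.col, mat.row)
            c = np.where(lower, mat.row, mat.col)
            mat = sp.coo_matrix((mat.data, (r, c)), shape=mat.shape)
        self.matrix = mat.tocsr()
        self.matrix.sum_duplicates()
        self.weights = weights
        self.stage = stage
        self._offsets: dict[str, tuple[int, int]] = {}
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            if not (np.diff(idx) == 1).all():
                raise ValueError("bin table not contiguous per chromosome")
            step = np.diff(grp["start"].to_numpy())
            if len(step) and not (step == self.resolution).all():
                raise ValueError("non-constant bin step")
            self._offsets[chrom] = (int(idx[0]), len(idx))

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls, genome: GenomeModel, resolution: int, stage=None) -> "BinnedMatrix":
        bins = bin_table(genome, resolution)
        n = len(bins)
        return cls(resolution, bins, sp.csr_matrix((n, n)), stage=stage)

    # -- bin bookkeeping ----------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        off, n = self._offsets[chrom]
        return off, off + n

    def bin_id(self, chrom: str, pos: int) -> int:
        off, n = self._offsets[chrom]
        i = pos // self.resolution
        if not 0 <= i < n:
            raise IndexError(f"position {pos} outside {chrom}")
        return off + i

    def bin_chrom(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    # -- queries ------------------------------------------------------------

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.matrix[i, j]

    def total(self) -> float:
        """Total contacts, diagonal counted once."""
        return float(self.matrix.sum())

    def sym(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal not doubled)."""
        d = sp.diags(self.matrix.diagonal())
        return self.matrix + self.matrix.T - d

    def chrom_dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense symmetric cis block for one chromosome."""
        lo, hi = self.chrom_range(chrom)
        block = self.matrix[lo:hi, lo:hi].toarray()
        dense = block + block.T - np.diag(np.diag(block))
        if balanced:
            w = self.chrom_weights(chrom)
            dense = dense * np.outer(w, w)
            dense[np.isnan(dense)] = 0.0
        return dense

    def chrom_weights(self, chrom: str) -> np.ndarray:
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run ice_balance")
        lo, hi = self.chrom_range(chrom)
        return self.weights[lo:hi]

    # -- resolution changes -------------------------------------------------

    def aggregate(self, resolution: int) -> "BinnedMatrix":
        """Exact aggregation to a coarser resolution (counts conserved)."""
        if resolution % self.resolution:
            raise ValueError("target resolution must be a multiple of the current one")
        if resolution == self.resolution:
            return self
        factor = resolution // self.resolution
        new_rows = []
        mapping = np.empty(self.n_bins, dtype=np.int64)
        pos = 0
        for chrom, (off, n) in self._offsets.items():
            n_new = -(-n // factor)
            starts = np.arange(n_new) * resolution
            new_rows.append(pd.DataFrame({"chrom": chrom, "start": starts}))
            mapping[off : off + n] = pos + np.arange(n) // factor
            pos += n_new
        new_bins = pd.concat(new_rows, ignore_index=True)
        coo = self.matrix.tocoo()
        r, c = mapping[coo.row], mapping[coo.col]
        swap = r > c
        r2 = np.where(swap, c, r)
        c2 = np.where(swap, r, c)
        mat = sp.coo_matrix((coo.data, (r2, c2)), shape=(pos, pos))
        return BinnedMatrix(resolution, new_bins, mat, stage=self.stage)


def bin_table(genome: GenomeModel, resolution: int) -> pd.DataFrame:
    rows = []
    for chrom, (length, _) in genome.chromosomes.items():
        n = -(-length // resolution)
        rows.append(pd.DataFrame({"chrom": chrom, "start": np.arange(n) * resolution}))
    return pd.concat(rows, ignore_index=True)


def interval_bins(matrix: BinnedMatrix, intervals: GenomicIntervalSet) -> np.ndarray:
    """Assign each interval to a bin by midpoint. Returns global bin ids."""
    mids = intervals.midpoints().to_numpy()
    chroms = intervals.frame["chrom"].to_numpy()
    out = np.empty(len(mids), dtype=np.int64)
    for k, (chrom, mid) in enumerate(zip(chroms, mids)):
        out[k] = matrix.bin_id(chrom, int(mid))
    return out


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

_LOOP_COLS = ["chrom", "anchor1", "anchor2", "contact_count", "p_value", "fdr", "stage"]


class LoopSet:
    """Cis chromatin loops: 5-kb anchor-bin pairs with counts and FDR.

    ``anchor1``/``anchor2`` are bin start coordinates on the resolution grid,
    with anchor1 < anchor2. Taxonomy columns (anchor_class, homoeolog_class,
    hn_subtype) are appended by the loops module.
    """

    def __init__(self, frame: pd.DataFrame, resolution: int = 5_000):
        for c in _LOOP_COLS:
            if c not in frame.columns:
                raise ValueError(f"loop frame missing column {c!r}")
        frame = frame.reset_index(drop=True).copy()
        a1 = frame["anchor1"].to_numpy()
        a2 = frame["anchor2"].to_numpy()
        if ((a1 % resolution) != 0).any() or ((a2 % resolution) != 0).any():
            raise ValueError("anchors not on the resolution grid")
        swap = a1 > a2
        if swap.any():
            frame.loc[swap, ["anchor1", "anchor2"]] = frame.loc[
                swap, ["anchor2", "anchor1"]
            ].to_numpy()
        if (frame["contact_count"] < 0).any():
            raise ValueError("negative contact count")
        if ((frame["fdr"] < 0) | (frame["fdr"] > 1)).any():
            raise ValueError("fdr outside [0, 1]")
        self.frame = frame.sort_values(
            ["chrom", "anchor1", "anchor2"], kind="mergesort"
        ).reset_index(drop=True)
        self.resolution = int(resolution)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "LoopSet":
        return LoopSet(self.frame[mask], self.resolution)

    def anchor_keys(self) -> set[tuple[str, int, int]]:
        return set(
            zip(self.frame["chrom"], self.frame["anchor1"], self.frame["anchor2"])
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_annotation(path, format: str = None) -> GenomicIntervalSet:
    """Read gene-like intervals from GFF3 or BED.

    GFF3 coordinates (1-based closed) become 0-based half-open; only ``gene``
    features are kept from GFF3, other feature types are skipped with a logged
    count. The result carries chrom/start/end/gene_id/strand columns.
    """
    import pyranges as pr

    path = str(path)
    if format is None:
        format = "GFF3" if path.endswith((".gff", ".gff3")) else "BED"
    fmt = format.upper()
    _prevalidate_lines(path, fmt)
    if fmt == "GFF3":
        try:
            g = pr.read_gff3(path).df
        except Exception as exc:  # pragma: no cover - parser-specific messages
            raise FormatError(f"{path}: not parseable as GFF3: {exc}") from exc
        n_skip = int((g["Feature"] != "gene").sum())
        if n_skip:
            logger.info("%s: skipped %d non-gene features", path, n_skip)
        g = g[g["Feature"] == "gene"]
        frame = pd.DataFrame(
            {
                "chrom": g["Chromosome"].astype(str),
                "start": g["Start"].astype(int),
                "end": g["End"].astype(int),
                "gene_id": g["ID"].astype(str),
                "strand": g["Strand"].astype(str),
            }
        )
    elif fmt == "BED":
        try:
            b = pr.read_bed(path).df
        except Exception as exc:  # pragma: no cover
            raise FormatError(f"{path}: not parseable as BED: {exc}") from exc
        frame = pd.DataFrame(
            {
                "chrom": b["Chromosome"].astype(str),
                "start": b["Start"].astype(int),
                "end": b["End"].astype(int),
                "gene_id": b["Name"].astype(str)
                if "Name" in b.columns
                else [f"iv{i}" for i in range(len(b))],
                "strand": b["Strand"].astype(str)
                if "Strand" in b.columns
                else ["."] * len(b),
            }
        )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GenomicIntervalSet(frame)


def _prevalidate_lines(path: str, fmt: str):
    """Cheap per-line sanity pass so errors can name the offending line."""
    min_cols = 9 if fmt == "GFF3" else 3
    start_col, end_col = (3, 4) if fmt == "GFF3" else (1, 2)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < min_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {min_cols} columns"
                )
            try:
                s, e = int(parts[start_col]), int(parts[end_col])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if e < s:
                raise FormatError(f"{path}: line {lineno}: end < start")


def write_annotation(intervals: GenomicIntervalSet, path, format: str = "BED"):
    fmt = format.upper()
    f = intervals.frame
    with open(path, "w") as fh:
        for row in f.itertuples(index=False):
            name = getattr(row, "gene_id", ".")
            strand = getattr(row, "strand", ".")
            if fmt == "BED":
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{strand}\n")
            elif fmt == "GFF3":
                fh.write(
                    f"{row.chrom}\t.\tgene\t{row.start + 1}\t{row.end}\t.\t{strand}"
                    f"\t.\tID={name}\n"
                )
            else:
                raise ValueError(f"unknown annotation format {format!r}")


def read_matrix(path_bins, path_coo, stage=None) -> BinnedMatrix:
    """Read the two-file sparse dialect: bin table TSV + upper-triangle COO TSV.

    Bin table columns: chrom, start, end, bin index (0-based). COO columns:
    i, j, count with i <= j.
    """
    bins = pd.read_csv(
        path_bins, sep="\t", header=None, names=["chrom", "start", "end", "index"]
    )
    if not (bins["index"].to_numpy() == np.arange(len(bins))).all():
        raise FormatError(f"{path_bins}: bin indices not consecutive from 0")
    res = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    try:
        coo = pd.read_csv(
            path_coo, sep="\t", header=None, names=["i", "j", "count"]
        )
    except pd.errors.EmptyDataError:
        coo = pd.DataFrame(columns=["i", "j", "count"])
    n = len(bins)
    if len(coo) and (
        (coo["i"] < 0).any()
        or (coo["j"] < 0).any()
        or (coo["i"] >= n).any()
        or (coo["j"] >= n).any()
    ):
        raise FormatError(f"{path_coo}: bin index out of range")
    mat = sp.coo_matrix(
        (coo["count"].to_numpy(float), (coo["i"].to_numpy(int), coo["j"].to_numpy(int))),
        shape=(n, n),
    )
    return BinnedMatrix(res, bins[["chrom", "start"]], mat, stage=stage)


def write_matrix(matrix: BinnedMatrix, path_bins, path_coo):
    bins = matrix.bins.copy()
    bins["end"] = bins["start"] + matrix.resolution
    bins["index"] = np.arange(len(bins))
    bins[["chrom", "start", "end", "index"]].to_csv(
        path_bins, sep="\t", header=False, index=False
    )
    coo = matrix.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    out = pd.DataFrame(
        {"i": coo.row[order], "j": coo.col[order], "count": coo.data[order]}
    )
    if (out["count"] == out["count"].astype(np.int64)).all():
        out["count"] = out["count"].astype(np.int64)
    out.to_csv(path_coo, sep="\t", header=False, index=False)


def read_loops(path_bedpe, resolution: int = 5_000) -> LoopSet:
    """Read cis loops from BEDPE (columns 8, 9 = contact_count, fdr).

    Anchors are snapped to the resolution grid; anchor order is normalized.
    """
    rows = []
    with open(path_bedpe) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path_bedpe}: line {lineno}: expected >= 9 columns")
            c1, s1, e1, c2, s2, e2, name = parts[:7]
            if c1 != c2:
                raise FormatError(
                    f"{path_bedpe}: line {lineno}: trans loop not supported"
                )
            if int(e1) - int(s1) != int(e2) - int(s2):
                raise FormatError(
                    f"{path_bedpe}: line {lineno}: anchors on different resolutions"
                )
            a1 = (int(s1) // resolution) * resolution
            a2 = (int(s2) // resolution) * resolution
            pval = float(parts[9]) if len(parts) > 9 else np.nan
            rows.append(
                (c1, a1, a2, int(float(parts[7])), pval, float(parts[8]), name)
            )
    frame = pd.DataFrame(rows, columns=_LOOP_COLS)
    return LoopSet(frame, resolution)


def write_loops(loops: LoopSet, path):
    res = loops.resolution
    extra = [
        c for c in loops.frame.columns if c not in _LOOP_COLS
    ]
    with open(path, "w") as fh:
        for row in loops.frame.itertuples(index=False):
            fields = [
                row.chrom,
                row.anchor1,
                row.anchor1 + res,
                row.chrom,
                row.anchor2,
                row.anchor2 + res,
                row.stage,
                row.contact_count,
                row.fdr,
                row.p_value,
            ] + [getattr(row, c) for c in extra]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def write_bedgraph(bins: pd.DataFrame, values: np.ndarray, resolution: int, path):
    """Write a per-bin track (PC1, insulation, compactness) as bedgraph."""
    with open(path, "w") as fh:
        for (chrom, start), v in zip(
            zip(bins["chrom"], bins["start"]), np.asarray(values, dtype=float)
        ):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{start + resolution}\t{v:.6g}\n")
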