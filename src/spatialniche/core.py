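"""Data model and core operations for segmented imaging-based spatial transcriptomics.

The unit of input is the output of a transcript-to-cell segmenter (e.g. Baysor):
a per-molecule table (x, y in micrometres, gene, assigned cell id, optional
molecule-cluster label and confidence) and a per-cell statistics table
(centroid, transcript count, area, elongation, mean segmentation confidence).
``cell_id`` 0 is reserved for noise / unassigned molecules throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

NOISE_CELL_ID = 0
UNLABELED = "unlabeled"

TRANSCRIPT_COLUMNS = ("x", "y", "gene", "cell_id", "molecule_cluster", "confidence")
CELL_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "n_transcripts",
    "area",
    "elongation",
    "mean_confidence",
    "type_label",
)


class ColumnMappingError(KeyError):
    """A configured input column is absent from the file."""


# ---------------------------------------------------------------------------
# transcript and cell tables
# ---------------------------------------------------------------------------

def read_transcripts(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-molecule transcript table from a delimited text file.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping from canonical names (``x``, ``y``, ``gene``, ``cell_id``,
        optionally ``molecule_cluster``, ``confidence``) to the column names
        used in the file. Identity mapping by default.

    Returns
    -------
    DataFrame with canonical columns. Rows whose coordinates are not finite
    are dropped; the number dropped is recorded in
    ``df.attrs["n_dropped_nonfinite"]``.
    """
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in TRANSCRIPT_COLUMNS:
        src = column_map.get(canonical, canonical)
        if canonical in ("x", "y", "gene", "cell_id") and src not in raw.columns:
            raise ColumnMappingError(
                f"required column {canonical!r} (mapped to {src!r}) "
                f"not found in {path}"
            )
        if src in raw.columns:
            rename[src] = canonical
    df = raw.rename(columns=rename)
    keep = [c for c in TRANSCRIPT_COLUMNS if c in df.columns]
    df = df[keep]

    finite = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
    n_dropped = int((~finite).sum())
    df = df.loc[finite].reset_index(drop=True)
    df["cell_id"] = df["cell_id"].astype(np.int64)
    if "confidence" in df.columns:
        conf = df["confidence"].to_numpy(float)
        bad = np.isfinite(conf) & ((conf < 0) | (conf > 1))
        if bad.any():
            raise ValueError("confidence values outside [0, 1]")
    df.attrs["n_dropped_nonfinite"] = n_dropped
    return df


def write_transcripts(df: pd.DataFrame, path: str | Path) -> None:
    """Write a transcript table as CSV with canonical column names."""
    df.to_csv(path, index=False)


def read_cells(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-cell segmentation-statistics table (CSV)."""
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CELL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if canonical in ("cell_id", "x", "y", "n_transcripts") and src not in raw.columns:
            raise ColumnMappingError(
                f"required column {canonical!r} (mapped to {src!r}) "
                f"not found in {path}"
            )
        if src in raw.columns:
            rename[src] = canonical
    df = raw.rename(columns=rename)
    df = df[[c for c in CELL_COLUMNS if c in df.columns]]
    df["cell_id"] = df["cell_id"].astype(np.int64)
    if (df["cell_id"] <= 0).any():
        raise ValueError("cell ids must be positive (0 is the reserved noise id)")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in cell table")
    return df.reset_index(drop=True)


def write_cells(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene-by-cell nonnegative integer count matrix.

    Rows are genes, columns are cells; ``cell_ids`` carries the column
    identity so the matrix can be subset consistently with a cell table.
    """

    genes: np.ndarray            # (G,) gene symbols
    cell_ids: np.ndarray         # (C,) positive integer cell ids
    X: scipy.sparse.csr_matrix   # (G, C) counts

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.X = scipy.sparse.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.cell_ids)):
            raise ValueError("matrix shape does not match gene/cell name vectors")
        if len(set(self.cell_ids.tolist())) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in count matrix")

    @property
    def total(self) -> int:
        return int(self.X.sum())

    def subset_cells(self, cell_ids: Iterable[int]) -> "CountMatrix":
        wanted = np.asarray(list(cell_ids), dtype=np.int64)
        pos = {c: i for i, c in enumerate(self.cell_ids.tolist())}
        idx = np.array([pos[c] for c in wanted if c in pos], dtype=np.intp)
        kept = wanted[np.isin(wanted, self.cell_ids)]
        return CountMatrix(self.genes.copy(), kept, self.X[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=pd.Index(self.genes, name="gene"),
            columns=self.cell_ids,
        )

    # -- I/O: MatrixMarket triplet + sidecar name files, or dense CSV --------

    def to_mtx(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), self.X.astype(np.int64))
        prefix.with_name(prefix.name + ".genes.txt").write_text(
            "\n".join(map(str, self.genes)) + "\n")
        prefix.with_name(prefix.name + ".cells.txt").write_text(
            "\n".join(str(c) for c in self.cell_ids) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str | Path) -> "CountMatrix":
        prefix = Path(prefix)
        X = scipy.io.mmread(str(prefix.with_suffix(".mtx")))
        genes = prefix.with_name(prefix.name + ".genes.txt").read_text().split()
        cells = [int(t) for t in
                 prefix.with_name(prefix.name + ".cells.txt").read_text().split()]
        return cls(np.array(genes, dtype=object), np.array(cells), X)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(object),
                   df.columns.astype(np.int64).to_numpy(),
                   scipy.sparse.csr_matrix(df.to_numpy()))


def build_count_matrix(transcripts: pd.DataFrame) -> CountMatrix:
    """Count transcripts per (gene, cell), excluding noise (cell_id 0).

    The matrix total equals the number of cell-assigned transcript rows.
    """
    assigned = transcripts.loc[transcripts["cell_id"] != NOISE_CELL_ID]
    genes = np.array(sorted(assigned["gene"].unique()), dtype=object)
    cells = np.sort(assigned["cell_id"].unique())
    if len(cells) == 0:
        return CountMatrix(genes, cells, scipy.sparse.csr_matrix((len(genes), 0), dtype=np.int64))
    gi = pd.Categorical(assigned["gene"], categories=genes).codes
    ci = pd.Categorical(assigned["cell_id"], categories=cells).codes
    X = scipy.sparse.coo_matrix(
        (np.ones(len(assigned), dtype=np.int64), (gi, ci)),
        shape=(len(genes), len(cells)),
    ).tocsr()
    return CountMatrix(genes, cells, X)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class SpatialCellSet:
    """Segmented cells with optional molecule table and count matrix.

    All coordinates are continuous positions in micrometres.
    """

    cells: pd.DataFrame
    transcripts: pd.DataFrame | None = None
    counts: CountMatrix | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids")
        if (self.cells["cell_id"] <= 0).any():
            raise ValueError("cell ids must be positive (0 is the noise id)")
        if self.counts is not None:
            if set(self.counts.cell_ids.tolist()) - set(self.cells["cell_id"].tolist()):
                raise ValueError("count matrix contains cells absent from the cell table")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(self, cell_ids: Iterable[int], keep_noise_in: "object | None" = None) -> "SpatialCellSet":
        """Return the dataset restricted to the given cells.

        Transcripts assigned to dropped cells are removed; noise transcripts
        (cell_id 0) are kept only if their own position lies inside
        ``keep_noise_in`` (a shapely geometry), and dropped entirely when it
        is None.
        """
        wanted = pd.Index(np.asarray(list(cell_ids), dtype=np.int64))
        cells = self.cells.loc[self.cells["cell_id"].isin(wanted)].reset_index(drop=True)
        transcripts = None
        if self.transcripts is not None:
            mask = self.transcripts["cell_id"].isin(wanted).to_numpy(bool)
            if keep_noise_in is not None:
                import shapely

                noise = (self.transcripts["cell_id"] == NOISE_CELL_ID).to_numpy(bool)
                if noise.any():
                    pts = shapely.points(
                        self.transcripts.loc[noise, ["x", "y"]].to_numpy(float))
                    mask[noise] |= shapely.covers(keep_noise_in, pts)
            transcripts = self.transcripts.loc[mask].reset_index(drop=True)
        counts = self.counts.subset_cells(cells["cell_id"]) if self.counts is not None else None
        return SpatialCellSet(cells, transcripts, counts, self.provenance)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Cell-level quality gates on segmentation statistics.

    ``min_transcripts`` is a strict lower bound: a cell is retained only if
    it has more than ``min_transcripts`` transcripts. The area, elongation
    and confidence gates are optional and off by default.
    """

    min_transcripts: int = 5
    min_area: float | None = None
    max_area: float | None = None
    max_elongation: float | None = None
    min_confidence: float | None = None

    def __post_init__(self) -> None:
        if self.min_transcripts < 0:
            raise ValueError("min_transcripts must be >= 0")
        if (self.min_area is not None and self.max_area is not None
                and self.min_area > self.max_area):
            raise ValueError("min_area > max_area")
        if self.min_confidence is not None and not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must lie in [0, 1]")


@dataclass
class FilterReport:
    n_in: int
    n_retained: int
    n_removed: int
    per_gate_removals: dict[str, int] = field(default_factory=dict)
    thresholds: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def qc_filter(
    dataset: SpatialCellSet, thresholds: QCThresholds
) -> tuple[SpatialCellSet, FilterReport]:
    """Drop low-quality cells; never alters the retained cells' fields.

    A cell survives iff ``n_transcripts > min_transcripts`` (strict) and
    passes every optional gate that is switched on. The count matrix and
    transcript table are subset to the surviving cells.
    """
    cells = dataset.cells
    fails: dict[str, pd.Series] = {}
    fails["min_transcripts"] = cells["n_transcripts"] <= thresholds.min_transcripts
    if thresholds.min_area is not None and "area" in cells:
        fails["min_area"] = cells["area"] < thresholds.min_area
    if thresholds.max_area is not None and "area" in cells:
        fails["max_area"] = cells["area"] > thresholds.max_area
    if thresholds.max_elongation is not None and "elongation" in cells:
        fails["max_elongation"] = cells["elongation"] > thresholds.max_elongation
    if thresholds.min_confidence is not None and "mean_confidence" in cells:
        fails["min_confidence"] = cells["mean_confidence"] < thresholds.min_confidence

    any_fail = np.zeros(len(cells), dtype=bool)
    per_gate = {}
    for gate, mask in fails.items():
        m = mask.fillna(False).to_numpy(bool)
        per_gate[gate] = int(m.sum())
        any_fail |= m

    kept = cells.loc[~any_fail, "cell_id"]
    out = dataset.subset(kept)
    report = FilterReport(
        n_in=len(cells),
        n_retained=len(kept),
        n_removed=int(any_fail.sum()),
        per_gate_removals=per_gate,
        thresholds={k: v for k, v in thresholds.__dict__.items() if v is not None},
    )
    if report.n_retained == 0:
        warnings.warn("QC thresholds excluded all cells", stacklevel=2)
    return out, report


# ---------------------------------------------------------------------------
# transcript-majority cell labeling
# ---------------------------------------------------------------------------

def label_cells_by_transcript_majority(
    transcripts: pd.DataFrame,
    cell_ids: Sequence[int] | None = None,
    unlabeled: str = UNLABELED,
) -> pd.Series:
    """Assign each cell the most frequent molecule-cluster label it contains.

    Noise molecules (cell_id 0) and molecules without a cluster label are
    ignored. Ties are broken by lexicographic order of the label strings so
    the result is deterministic. Cells with zero labeled molecules receive
    ``unlabeled``.
    """
    t = transcripts.loc[
        (transcripts["cell_id"] != NOISE_CELL_ID)
        & transcripts["molecule_cluster"].notna()
    ]
    counts = (
        t.groupby(["cell_id", "molecule_cluster"], sort=False)
        .size()
        .reset_index(name="n")
    )
    counts["molecule_cluster"] = counts["molecule_cluster"].astype(str)
    counts = counts.sort_values(
        ["cell_id", "n", "molecule_cluster"], ascending=[True, False, True]
    )
    winner = counts.drop_duplicates("cell_id").set_index("cell_id")["molecule_cluster"]
    if cell_ids is not None:
        winner = winner.reindex(np.asarray(cell_ids, dtype=np.int64), fill_value=None)
        winner = winner.fillna(unlabeled)
    winner.name = "type_label"
    return winner


# ---------------------------------------------------------------------------
# FOV grid
# ---------------------------------------------------------------------------

@dataclass
class FovGrid:
    """Regular row x column tiling of a dataset's bounding box.

    Tiles are indexed (row, col) from 1, row-major. Tiles partition the box:
    points on an interior shared edge belong to the tile with the larger
    index along that edge; the outer max edges fold into the last tile.
    """

    n_rows: int
    n_cols: int
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate bounding box")

    @classmethod
    def from_points(cls, xy: np.ndarray, n_rows: int, n_cols: int) -> "FovGrid":
        xy = np.asarray(xy, float)
        return cls(n_rows, n_cols, xy[:, 0].min(), xy[:, 1].min(),
                   xy[:, 0].max(), xy[:, 1].max())

    def tile_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """1-based (row, col) of each point; row follows y, col follows x."""
        xy = np.asarray(xy, float)
        col = np.floor((xy[:, 0] - self.x0) / (self.x1 - self.x0) * self.n_cols).astype(int)
        row = np.floor((xy[:, 1] - self.y0) / (self.y1 - self.y0) * self.n_rows).astype(int)
        return (np.clip(row, 0, self.n_rows - 1) + 1,
                np.clip(col, 0, self.n_cols - 1) + 1)

    def tile_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise IndexError(f"tile ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        w = (self.x1 - self.x0) / self.n_cols
        h = (self.y1 - self.y0) / self.n_rows
        return (self.x0 + (col - 1) * w, self.y0 + (row - 1) * h,
                self.x0 + col * w, self.y0 + row * h)


def select_fov(
    dataset: SpatialCellSet,
    grid: FovGrid | None = None,
    tile: tuple[int, int] | None = None,
    bbox: tuple[float, float, float, float] | None = None,
) -> SpatialCellSet:
    """Subset the dataset to one grid tile or to an explicit bounding box.

    Tile selection uses the half-open partition rule of :class:`FovGrid`
    so the tiles are disjoint and jointly exhaustive; explicit bboxes are
    closed on all sides (the full-extent bbox is an identity subset).
    """
    xy = dataset.cells[["x", "y"]].to_numpy(float)
    if tile is not None:
        if grid is None:
            raise ValueError("tile selection requires a grid")
        r, c = tile
        grid.tile_bounds(r, c)  # bounds check
        rows, cols = grid.tile_of(xy)
        mask = (rows == r) & (cols == c)
    elif bbox is not None:
        x0, y0, x1, y1 = bbox
        mask = (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
    else:
        raise ValueError("either tile or bbox must be given")
    return dataset.subset(dataset.cells.loc[mask, "cell_id"])


# ---------------------------------------------------------------------------
# GeoJSON polygon export
# ---------------------------------------------------------------------------

def write_cell_polygons_geojson(path: str | Path, cell_ids: Sequence[int],
                                polygons: Sequence) -> None:
    """Write cell polygons (shapely Polygons) as a GeoJSON FeatureCollection."""
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"cell_id": int(cid)},
         "geometry": mapping(poly)}
        for cid, poly in zip(cell_ids, polygons)
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}) + "\n")


def read_cell_polygons_geojson(path: str | Path) -> dict[int, "object"]:
    from shapely.geometry import shape

    data = json.loads(Path(path).read_text())
    return {int(f["properties"]["cell_id"]): shape(f["geometry"])
            for f in data["features"]}
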