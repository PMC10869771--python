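"""Registration of single-cell-resolution spatial data onto a spot grid,
nearest-spot binning, directly measured per-spot cell-type composition, and
correlation benchmarking of external deconvolution predictions.

A segmented in situ dataset and a spot-based dataset (e.g. a 55 μm capture
grid) from adjacent sections are brought into one frame with a landmark-based
least-squares similarity transform; each cell is then binned to its nearest
spot centre, which turns the segmentation's per-cell type labels into a
*measured* per-spot composition — ground truth against which computational
spot deconvolution can be benchmarked with Pearson correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import pearsonr


class DegenerateLandmarksError(ValueError):
    """Landmark configuration does not determine a transform."""


class ReflectionError(ValueError):
    """Best-fit transform requires a reflection, which is forbidden."""


class AlignmentError(ValueError):
    """Measured and predicted tables share no spots."""


# ---------------------------------------------------------------------------
# similarity transform
# ---------------------------------------------------------------------------

@dataclass
class Transform2D:
    """Rotation by theta, isotropic scaling by s > 0, then translation.

    Maps a point p to ``s * R(theta) @ p + t``. Reflections are represented
    and composed nowhere: fitting rejects them.
    """

    theta: float = 0.0
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "Transform2D":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        R = inv_scale * np.array([[c, -s], [s, c]])
        t = -R @ np.array([self.tx, self.ty])
        return Transform2D(-self.theta, inv_scale, float(t[0]), float(t[1]))

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Return the transform equivalent to applying ``other`` then self."""
        t = self.apply(np.array([[other.tx, other.ty]]))[0]
        return Transform2D(self.theta + other.theta, self.scale * other.scale,
                           float(t[0]), float(t[1]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"theta": self.theta, "scale": self.scale,
             "tx": self.tx, "ty": self.ty}, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Transform2D":
        return cls(**json.loads(Path(path).read_text()))


def fit_similarity_transform(
    landmarks_src: np.ndarray,
    landmarks_dst: np.ndarray,
    allow_scale: bool = True,
) -> tuple[Transform2D, float]:
    """Least-squares similarity (or rigid) transform from paired landmarks.

    Solves the orthogonal Procrustes problem for ``dst ≈ s R src + t`` by
    SVD of the landmark cross-covariance; with ``allow_scale=False`` the
    scale is fixed at 1 (rigid). Reflection solutions raise
    :class:`ReflectionError`. Returns the transform and the RMS landmark
    residual after alignment.
    """
    src = np.asarray(landmarks_src, float)
    dst = np.asarray(landmarks_dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmark lists must be equal-length (N, 2) arrays")
    if len(src) < 2:
        raise DegenerateLandmarksError("need at least 2 landmark pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = float(np.sum(xs ** 2))
    if var_s == 0:
        raise DegenerateLandmarksError("source landmarks are coincident")

    H = xd.T @ xs  # cross-covariance
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    if det < 0:
        raise ReflectionError(
            "best-fit transform is a reflection; flip one coordinate axis "
            "explicitly if the sections are mirrored")
    R = U @ Vt
    scale = float(np.sum(S)) / var_s if allow_scale else 1.0
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    t = mu_d - scale * (R @ mu_s)
    tf = Transform2D(theta, scale, float(t[0]), float(t[1]))
    residual = float(np.sqrt(np.mean(np.sum((tf.apply(src) - dst) ** 2, axis=1))))
    return tf, residual


def read_landmarks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a landmark-pair CSV with columns x_src, y_src, x_dst, y_dst."""
    df = pd.read_csv(path)
    return (df[["x_src", "y_src"]].to_numpy(float),
            df[["x_dst", "y_dst"]].to_numpy(float))


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_region(dataset, region) -> "object":
    """Subset a :class:`~spatialniche.core.SpatialCellSet` to a region.

    ``region`` is a bbox tuple (x0, y0, x1, y1) or a shapely geometry.
    Containment is closed (boundary points retained), consistent with
    explicit-bbox FOV selection.
    """
    xy = dataset.cells[["x", "y"]].to_numpy(float)
    if isinstance(region, tuple):
        x0, y0, x1, y1 = region
        mask = ((xy[:, 0] >= x0) & (xy[:, 0] <= x1)
                & (xy[:, 1] >= y0) & (xy[:, 1] <= y1))
        geom = shapely.box(x0, y0, x1, y1)
    else:
        geom = region
        mask = shapely.covers(geom, shapely.points(xy))
    if not mask.any():
        warnings.warn("crop region contains no cells", stacklevel=2)
    return dataset.subset(dataset.cells.loc[mask, "cell_id"], keep_noise_in=geom)


# ---------------------------------------------------------------------------
# spot grids and binning
# ---------------------------------------------------------------------------

@dataclass
class SpotGrid:
    """Capture-spot layout: ids, centre positions (μm), diameter and pitch.

    The geometry (square or hexagonally offset rows) is carried entirely by
    the positions table; nothing downstream assumes a lattice.
    """

    spots: pd.DataFrame          # columns: spot_id, x, y, in_tissue (bool)
    diameter: float
    pitch: float

    def __post_init__(self) -> None:
        if self.diameter > self.pitch:
            raise ValueError("spot diameter cannot exceed centre-to-centre pitch")
        if self.spots["spot_id"].duplicated().any():
            raise ValueError("duplicate spot ids")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def to_csv(self, path: str | Path) -> None:
        df = self.spots.copy()
        df["in_tissue"] = df["in_tissue"].astype(int)
        df.attrs = {}
        header = f"# diameter={self.diameter} pitch={self.pitch}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, diameter: float | None = None,
                 pitch: float | None = None) -> "SpotGrid":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(tok.split("=") for tok in first[1:].split())
                diameter = diameter if diameter is not None else float(meta["diameter"])
                pitch = pitch if pitch is not None else float(meta["pitch"])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if diameter is None or pitch is None:
            raise ValueError("diameter and pitch must be in the file header or given")
        df["in_tissue"] = df["in_tissue"].astype(bool)
        return cls(df, float(diameter), float(pitch))


def assign_to_spots(
    points: np.ndarray,
    grid: SpotGrid,
    max_distance: float | None = None,
) -> np.ndarray:
    """Assign each point to the nearest spot centre.

    Returns an array of spot ids, with -1 for unassigned points (farther
    than ``max_distance`` from every centre, when a cutoff is given).
    Distance ties go to the smallest spot id.
    """
    if grid.n_spots == 0:
        raise ValueError("spot grid is empty")
    pts = np.asarray(points, float)
    centers = grid.spots[["x", "y"]].to_numpy(float)
    ids = grid.spots["spot_id"].to_numpy()
    tree = cKDTree(centers)
    dist, idx = tree.query(pts, k=1)
    assigned = ids[idx].astype(np.int64)

    # deterministic tie-break: among equidistant centres pick the lowest id
    eps = 1e-9
    ties = tree.query_ball_point(pts, dist + eps)
    for i, cand in enumerate(ties):
        if len(cand) > 1:
            close = [j for j in cand if abs(np.hypot(*(centers[j] - pts[i])) - dist[i]) <= eps]
            assigned[i] = ids[close].min() if len(close) > 1 else assigned[i]

    if max_distance is not None:
        assigned[dist > max_distance] = -1
    return assigned


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionMatrix:
    """Spots x cell-types table of counts and row-normalised proportions."""

    counts: pd.DataFrame         # index: spot_id, columns: type labels
    proportions: pd.DataFrame    # same shape; rows sum to 1 where occupied
    empty_spots: np.ndarray      # spot ids with zero assigned cells

    @property
    def total_cells(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, counts_path: str | Path, proportions_path: str | Path) -> None:
        self.counts.to_csv(counts_path)
        self.proportions.to_csv(proportions_path)


def spot_composition(
    assignments: np.ndarray,
    type_labels: np.ndarray,
    spot_ids: np.ndarray | None = None,
) -> CompositionMatrix:
    """Tabulate per-spot cell-type counts and proportions.

    ``assignments`` maps each cell to a spot id (-1 = unassigned, dropped).
    ``spot_ids`` optionally enumerates the full grid so spots with zero
    assigned cells appear (flagged empty and excluded from the proportions
    table rather than emitting NaN rows).
    """
    assignments = np.asarray(assignments)
    type_labels = np.asarray(type_labels, dtype=object)
    if len(assignments) != len(type_labels):
        raise ValueError("assignments and labels differ in length")
    keep = assignments != -1
    df = pd.DataFrame({"spot_id": assignments[keep], "type": type_labels[keep]})
    counts = df.groupby(["spot_id", "type"], observed=True).size().unstack(fill_value=0)
    if spot_ids is not None:
        counts = counts.reindex(np.asarray(spot_ids), fill_value=0)
        counts.index.name = "spot_id"
    totals = counts.sum(axis=1)
    empty = counts.index[totals == 0].to_numpy()
    occupied = counts.loc[totals > 0]
    proportions = occupied.div(occupied.sum(axis=1), axis=0)
    return CompositionMatrix(counts.astype(np.int64), proportions, empty)


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------

def benchmark_predictions(
    measured: CompositionMatrix | pd.DataFrame,
    predicted: pd.DataFrame,
    scope: str = "pooled",
    label_map: dict[str, str] | None = None,
    spot_filter: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation between measured and predicted spot compositions.

    ``scope``: ``pooled`` (one r over all spot x type entries), ``per-type``
    (one r per cell type across spots), or ``per-spot`` (one r per spot
    across types). ``label_map`` renames predicted columns onto measured
    type labels when the naming differs (explicit mapping, never fuzzy).
    ``spot_filter`` restricts to a subset of spot ids (e.g. one region).
    Spots present in only one table are dropped and counted in the report.
    Zero-variance vectors give NaN with the reason recorded.
    """
    meas = measured.proportions if isinstance(measured, CompositionMatrix) else measured
    pred = predicted.copy()
    if label_map:
        pred = pred.rename(columns=label_map)
    shared_types = [t for t in meas.columns if t in pred.columns]
    if not shared_types:
        raise AlignmentError("no shared cell-type columns after label mapping")
    shared_spots = meas.index.intersection(pred.index)
    if spot_filter is not None:
        shared_spots = shared_spots.intersection(pd.Index(spot_filter))
    if len(shared_spots) == 0:
        raise AlignmentError("no overlapping spots between measured and predicted")
    n_dropped = (len(meas.index) - len(shared_spots)) + (len(pred.index) - len(shared_spots))
    m = meas.loc[shared_spots, shared_types]
    p = pred.loc[shared_spots, shared_types]

    def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), "zero variance"
        if len(x) < 2:
            return float("nan"), "fewer than 2 entries"
        return float(pearsonr(x, y).statistic), ""

    rows = []
    if scope == "pooled":
        r, reason = _corr(m.to_numpy().ravel(), p.to_numpy().ravel())
        rows.append({"scope": "pooled", "unit": "all", "r": r,
                     "n": m.size, "reason": reason})
    elif scope == "per-type":
        for t in shared_types:
            r, reason = _corr(m[t].to_numpy(), p[t].to_numpy())
            rows.append({"scope": "per-type", "unit": t, "r": r,
                         "n": len(m), "reason": reason})
    elif scope == "per-spot":
        for s in shared_spots:
            r, reason = _corr(m.loc[s].to_numpy(), p.loc[s].to_numpy())
            rows.append({"scope": "per-spot", "unit": s, "r": r,
                         "n": len(shared_types), "reason": reason})
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = pd.DataFrame(rows)
    out.attrs["n_spots_dropped"] = int(n_dropped)
    out.attrs["n_spots_used"] = int(len(shared_spots))
    return out
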