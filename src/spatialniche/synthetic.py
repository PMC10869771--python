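"""Seeded generator of kidney-like synthetic spatial transcriptomics data.

The generator emulates the inputs the rest of the package consumes: zoned
cell-type point patterns inside a circular organ boundary (cortex at the
rim, papilla at the centre, matching the depth convention: 0 at the capsule,
1 at the origin), per-cell transcript clouds drawn from type-specific
expression programs, uniformly sprinkled noise molecules, planted type-pair
doublet niches for proximity tests, and an overlaid capture-spot grid with
the per-spot composition recorded as ground truth.

All randomness flows through ``numpy.random.default_rng`` (PCG64) from an
explicit seed; a fixed seed reproduces every output byte-for-byte. What is
deliberately *not* modelled: gene–gene covariance beyond the per-type means,
irregular cell shapes (cells are disks, polygons regular 12-gons), 3D
structure, and segmentation errors other than noise molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import (
    SpatialCellSet,
    build_count_matrix,
    write_cell_polygons_geojson,
    write_cells,
    write_transcripts,
)
from .integration import CompositionMatrix, SpotGrid, Transform2D, assign_to_spots, spot_composition
from .organ_coords import Circle, OrganFrame


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CellTypeSpec:
    name: str
    zone: str
    intensity: float                 # cells per μm² within the zone's annulus
    program: dict[str, float]        # gene -> mean transcripts per cell


@dataclass
class NicheSpec:
    """Planted doublets of a type pair at a fixed intra-pair distance."""

    type_a: str
    type_b: str
    distance: float                  # μm between the two cells of a doublet
    n_doublets: int
    zone: str | None = None          # None: anywhere in the tissue


@dataclass
class TissueConfig:
    """Study conditions for one synthetic tissue.

    ``zones`` are depth intervals within [0, 1]; a circular boundary of
    radius ``radius`` centred on ``center`` maps depth d to the annulus of
    radii [R(1−d1), R(1−d0)].
    """

    radius: float = 1000.0
    center: tuple[float, float] = (0.0, 0.0)
    zones: dict[str, tuple[float, float]] = field(default_factory=dict)
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    niches: list[NicheSpec] = field(default_factory=list)
    noise_rate: float = 1e-4         # noise molecules per μm²
    cell_radius: float = 6.0         # μm, transcript-scatter disk
    confidence_range: tuple[float, float] = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (d0, d1) in self.zones.items():
            if not (0 <= d0 < d1 <= 1):
                raise ValueError(f"zone {name!r} interval must satisfy 0 <= d0 < d1 <= 1")
        for ct in self.cell_types:
            if ct.zone not in self.zones:
                raise ValueError(f"cell type {ct.name!r} references unknown zone {ct.zone!r}")
            if ct.intensity < 0 or any(v < 0 for v in ct.program.values()):
                raise ValueError("intensities and program means must be nonnegative")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct in self.cell_types:
            for g in ct.program:
                seen.setdefault(g, None)
        return list(seen)


def default_config(seed: int = 0) -> TissueConfig:
    """Demo configuration: 13 cell types, 200 genes, three kidney zones.

    Qualitatively kidney-like — cortical types (proximal tubule, podocytes,
    glomerular/arterial endothelium...) at low depth, papillary types
    (principal cells, urothelium) at high depth, a glomerular niche
    (podocyte + glomerular-EC doublets) and an immune niche pair (C3+
    monocyte + failed-repair PT) — but synthetic throughout, not fitted to
    any real section.
    """
    n_genes = 200
    genes = [f"Gene{i:03d}" for i in range(n_genes)]
    type_names = [
        "Podo", "gEC", "aEC", "JGA", "Fib", "HealthyPT", "InjPT", "FRPT",
        "TAL", "DCT", "CD-PC", "Uro", "C3Mono",
    ]
    zone_of = {
        "Podo": "cortex", "gEC": "cortex", "aEC": "cortex", "JGA": "cortex",
        "HealthyPT": "cortex", "InjPT": "cortex", "FRPT": "cortex",
        "Fib": "medulla", "TAL": "medulla", "DCT": "medulla", "C3Mono": "medulla",
        "CD-PC": "papilla", "Uro": "papilla",
    }
    rng = np.random.default_rng(seed)
    cell_types = []
    for i, name in enumerate(type_names):
        markers = genes[i * 15:(i + 1) * 15] or genes[-15:]
        program = {g: 2.5 for g in markers}
        background = rng.choice(genes, size=10, replace=False)
        for g in background:
            program.setdefault(g, 0.2)
        cell_types.append(CellTypeSpec(name, zone_of[name], 6e-5, program))
    return TissueConfig(
        radius=1000.0,
        zones={"cortex": (0.0, 0.35), "medulla": (0.35, 0.7), "papilla": (0.7, 1.0)},
        cell_types=cell_types,
        niches=[NicheSpec("Podo", "gEC", 8.0, 25, zone="cortex"),
                NicheSpec("C3Mono", "FRPT", 6.0, 25, zone="medulla")],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tissue simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generator bookkeeping: what each emitted file should recover."""

    cells: pd.DataFrame                       # cell_id, type, zone, depth
    seed: int
    spot_composition: CompositionMatrix | None = None
    transform: Transform2D | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.csv", index=False)
        meta: dict = {"seed": self.seed}
        if self.transform is not None:
            meta["transform"] = {
                "theta": self.transform.theta, "scale": self.transform.scale,
                "tx": self.transform.tx, "ty": self.transform.ty,
            }
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        if self.spot_composition is not None:
            self.spot_composition.to_csv(outdir / "truth_spot_counts.csv",
                                         outdir / "truth_spot_proportions.csv")


@dataclass
class SimulatedTissue:
    dataset: SpatialCellSet
    frame: OrganFrame
    truth: GroundTruth
    config: TissueConfig
    polygons: list[Polygon]


def _sample_annulus(rng: np.random.Generator, n: int, r_in: float, r_out: float,
                    center: tuple[float, float]) -> np.ndarray:
    u = rng.random(n)
    r = np.sqrt(u * (r_out ** 2 - r_in ** 2) + r_in ** 2)
    theta = rng.uniform(-np.pi, np.pi, n)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def _zone_radii(config: TissueConfig, zone: str) -> tuple[float, float]:
    d0, d1 = config.zones[zone]
    return config.radius * (1 - d1), config.radius * (1 - d0)


def simulate_tissue(config: TissueConfig, seed: int | None = None) -> SimulatedTissue:
    """Draw one synthetic tissue from the configured study conditions.

    Cell centroids are a homogeneous Poisson process within each type's zone
    annulus; planted niche doublets are laid out on a deterministic coarse
    lattice of well-separated anchor positions. Per-cell transcript counts
    are Poisson with the type's per-gene means; molecule positions are
    uniform in a disk of ``cell_radius`` around the centroid and carry the
    cell's type as their molecule-cluster label. Noise molecules (cell_id 0,
    no cluster label) are sprinkled uniformly over the whole disk.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cx, cy = config.center
    R = config.radius

    rows = []  # (x, y, type, zone)
    for ct in config.cell_types:
        r_in, r_out = _zone_radii(config, ct.zone)
        area = np.pi * (r_out ** 2 - r_in ** 2)
        n = rng.poisson(ct.intensity * area)
        xy = _sample_annulus(rng, n, r_in, r_out, config.center)
        for p in xy:
            rows.append((p[0], p[1], ct.name, ct.zone))

    # planted doublets: anchors on a ring lattice inside the niche's zone,
    # guaranteed farther apart than any test radius
    for niche in config.niches:
        zone = niche.zone or next(iter(config.zones))
        r_in, r_out = _zone_radii(config, zone)
        r_mid = 0.5 * (r_in + r_out)
        angles = np.linspace(-np.pi, np.pi, niche.n_doublets, endpoint=False)
        for k, ang in enumerate(angles):
            ax = cx + r_mid * np.cos(ang)
            ay = cy + r_mid * np.sin(ang)
            direction = rng.uniform(-np.pi, np.pi)
            bx = ax + niche.distance * np.cos(direction)
            by = ay + niche.distance * np.sin(direction)
            rows.append((ax, ay, niche.type_a, zone))
            rows.append((bx, by, niche.type_b, zone))

    cells = pd.DataFrame(rows, columns=["x", "y", "type_label", "zone"])
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1, dtype=np.int64))

    program_of = {ct.name: ct.program for ct in config.cell_types}
    genes = config.genes
    gene_index = {g: i for i, g in enumerate(genes)}

    t_rows = {"x": [], "y": [], "gene": [], "cell_id": [],
              "molecule_cluster": [], "confidence": []}
    n_per_cell = np.zeros(len(cells), dtype=np.int64)
    for pos, (cid, x0, y0, tname) in enumerate(
            cells[["cell_id", "x", "y", "type_label"]].itertuples(index=False)):
        program = program_of.get(tname)
        if program is None:  # niche type not in cell_types: give it a flat program
            program = {g: 0.05 for g in genes[:40]}
        means = np.array(list(program.values()))
        counts = rng.poisson(means)
        total = int(counts.sum())
        n_per_cell[pos] = total
        if total == 0:
            continue
        gs = np.repeat(list(program.keys()), counts)
        rr = config.cell_radius * np.sqrt(rng.random(total))
        th = rng.uniform(-np.pi, np.pi, total)
        t_rows["x"].append(x0 + rr * np.cos(th))
        t_rows["y"].append(y0 + rr * np.sin(th))
        t_rows["gene"].append(gs)
        t_rows["cell_id"].append(np.full(total, cid, dtype=np.int64))
        t_rows["molecule_cluster"].append(np.full(total, tname, dtype=object))
        lo, hi = config.confidence_range
        t_rows["confidence"].append(rng.uniform(lo, hi, total))

    n_noise = rng.poisson(config.noise_rate * np.pi * R ** 2)
    if n_noise:
        noise_xy = _sample_annulus(rng, n_noise, 0.0, R, config.center)
        t_rows["x"].append(noise_xy[:, 0])
        t_rows["y"].append(noise_xy[:, 1])
        t_rows["gene"].append(rng.choice(genes, n_noise))
        t_rows["cell_id"].append(np.zeros(n_noise, dtype=np.int64))
        t_rows["molecule_cluster"].append(np.full(n_noise, np.nan, dtype=object))
        t_rows["confidence"].append(rng.uniform(0.0, 0.5, n_noise))

    transcripts = pd.DataFrame({
        k: np.concatenate(v) if v else np.array([]) for k, v in t_rows.items()
    })
    transcripts["cell_id"] = transcripts["cell_id"].astype(np.int64)

    rng_shape = rng  # polygons share the stream to stay deterministic
    phase = rng_shape.uniform(-np.pi, np.pi, len(cells))
    polygons = []
    ring_angles = np.linspace(-np.pi, np.pi, 12, endpoint=False)
    for (x0, y0), ph in zip(cells[["x", "y"]].to_numpy(float), phase):
        ang = ring_angles + ph
        polygons.append(Polygon(np.column_stack([
            x0 + config.cell_radius * np.cos(ang),
            y0 + config.cell_radius * np.sin(ang)])))

    counts = build_count_matrix(transcripts)
    # segmentation statistics derived from the emitted molecules/shapes
    conf = (transcripts.loc[transcripts["cell_id"] != 0]
            .groupby("cell_id")["confidence"].mean())
    cell_table = cells[["cell_id", "x", "y", "type_label"]].copy()
    cell_table["n_transcripts"] = n_per_cell
    cell_table["area"] = np.pi * config.cell_radius ** 2
    cell_table["elongation"] = 1.0
    cell_table["mean_confidence"] = cell_table["cell_id"].map(conf).fillna(0.0)
    cell_table = cell_table[["cell_id", "x", "y", "n_transcripts", "area",
                             "elongation", "mean_confidence", "type_label"]]

    frame = OrganFrame(Circle((cx, cy), R), (cx, cy))

    truth_cells = cells.copy()
    r = np.hypot(cells["x"] - cx, cells["y"] - cy)
    truth_cells["depth"] = 1.0 - r / R
    truth = GroundTruth(cells=truth_cells.rename(columns={"type_label": "type"}),
                        seed=seed)

    dataset = SpatialCellSet(cell_table, transcripts, counts,
                             provenance=f"synthetic seed={seed}")
    return SimulatedTissue(dataset, frame, truth, config, polygons)


# ---------------------------------------------------------------------------
# spot grid simulation
# ---------------------------------------------------------------------------

def simulate_spot_grid(
    tissue: SimulatedTissue,
    pitch: float = 100.0,
    diameter: float = 55.0,
    transform: Transform2D | None = None,
    hexagonal: bool = True,
) -> tuple[SpotGrid, GroundTruth, np.ndarray, np.ndarray]:
    """Overlay a capture-spot grid on the (transformed) tissue.

    The grid lives in the *destination* frame: cell positions are mapped
    through ``transform`` (identity if None) and covered with a hexagonally
    offset (or square) lattice. The true per-spot composition is recorded by
    applying the same nearest-spot rule used by the integration pipeline to
    the transformed ground-truth positions.

    Returns the grid, the ground truth (composition + transform), and a
    4-landmark pair (source frame, destination frame) for registration.
    """
    if diameter > pitch:
        raise ValueError("spot diameter cannot exceed pitch")
    transform = transform or Transform2D()
    src_xy = tissue.dataset.cells[["x", "y"]].to_numpy(float)
    dst_xy = transform.apply(src_xy)

    x0, y0 = dst_xy.min(axis=0) - pitch
    x1, y1 = dst_xy.max(axis=0) + pitch
    row_step = pitch * (np.sqrt(3) / 2 if hexagonal else 1.0)
    ys = np.arange(y0, y1 + row_step, row_step)
    centers = []
    for i, y in enumerate(ys):
        offset = (pitch / 2 if (hexagonal and i % 2) else 0.0)
        xs = np.arange(x0 + offset, x1 + pitch, pitch)
        centers.append(np.column_stack([xs, np.full(len(xs), y)]))
    centers = np.vstack(centers)
    spots = pd.DataFrame({
        "spot_id": np.arange(1, len(centers) + 1, dtype=np.int64),
        "x": centers[:, 0], "y": centers[:, 1],
    })
    # in-tissue flag: within one pitch of any transformed cell
    from scipy.spatial import cKDTree

    tree = cKDTree(dst_xy)
    d, _ = tree.query(centers, k=1)
    spots["in_tissue"] = d <= pitch
    grid = SpotGrid(spots, diameter=diameter, pitch=pitch)

    assignments = assign_to_spots(dst_xy, grid)
    comp = spot_composition(
        assignments, tissue.dataset.cells["type_label"].to_numpy(object))
    truth = GroundTruth(cells=tissue.truth.cells, seed=tissue.truth.seed,
                        spot_composition=comp, transform=transform)

    bx0, by0 = src_xy.min(axis=0)
    bx1, by1 = src_xy.max(axis=0)
    landmarks_src = np.array([[bx0, by0], [bx1, by0], [bx1, by1], [bx0, by1]])
    landmarks_dst = transform.apply(landmarks_src)
    return grid, truth, landmarks_src, landmarks_dst


# ---------------------------------------------------------------------------
# niche fixtures for proximity tests
# ---------------------------------------------------------------------------

def make_niche_fixture(
    n_doublets: int = 30,
    doublet_distance: float = 5.0,
    doublet_spacing: float = 500.0,
    background_types: tuple[str, ...] = ("BgC", "BgD"),
    n_background: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell table with planted A–B doublets plus CSR background types.

    Doublet anchors sit on a square lattice ``doublet_spacing`` apart, so at
    any test radius below the spacing the planted pair is the only pair in
    systematic proximity. Background cells of each named type are uniform
    over the same extent.
    """
    if doublet_distance >= doublet_spacing:
        raise ValueError("doublet distance must be below the spacing between doublets")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_doublets)))
    rows = []
    k = 0
    for i in range(side):
        for j in range(side):
            if k >= n_doublets:
                break
            ax = i * doublet_spacing
            ay = j * doublet_spacing
            ang = rng.uniform(-np.pi, np.pi)
            rows.append((ax, ay, "NicheA"))
            rows.append((ax + doublet_distance * np.cos(ang),
                         ay + doublet_distance * np.sin(ang), "NicheB"))
            k += 1
    extent = side * doublet_spacing
    for t in background_types:
        xy = rng.uniform(0, extent, size=(n_background, 2))
        for p in xy:
            rows.append((p[0], p[1], t))
    cells = pd.DataFrame(rows, columns=["x", "y", "type_label"])
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1, dtype=np.int64))
    return cells


def make_csr_fixture(
    types: tuple[str, ...] = ("A", "B"),
    n_per_type: int = 500,
    extent: float = 2000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell table with each type uniformly random over a square (CSR)."""
    rng = np.random.default_rng(seed)
    frames = []
    for t in types:
        xy = rng.uniform(0, extent, size=(n_per_type, 2))
        frames.append(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "type_label": t}))
    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1, dtype=np.int64))
    return cells


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(tissue: SimulatedTissue, outdir: str | Path,
                  grid: SpotGrid | None = None,
                  landmarks: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """Emit the full file bundle in the dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts(tissue.dataset.transcripts, outdir / "transcripts.csv")
    write_cells(tissue.dataset.cells, outdir / "cells.csv")
    tissue.dataset.counts.to_mtx(outdir / "counts")
    write_cell_polygons_geojson(outdir / "cell_polygons.geojson",
                                tissue.dataset.cells["cell_id"], tissue.polygons)
    tissue.frame.to_geojson(outdir / "boundary.geojson")
    tissue.truth.write(outdir / "truth")
    if grid is not None:
        grid.to_csv(outdir / "spots.csv")
    if landmarks is not None:
        src, dst = landmarks
        pd.DataFrame({"x_src": src[:, 0], "y_src": src[:, 1],
                      "x_dst": dst[:, 0], "y_dst": dst[:, 1]}
                     ).to_csv(outdir / "landmarks.csv", index=False)
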