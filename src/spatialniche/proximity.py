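"""Cell-proximity statistics: nearest-neighbour distances, multi-scale density
profiles, and neighbourhood pair-enrichment with a random-pairing permutation
null.

The enrichment statistic asks, for every unordered pair of cell types, how
often cells of those two types fall within a search radius of each other
(default 50 μm) relative to what random pairing of type labels to the same
fixed positions would produce. Because the null shuffles labels over the
observed geometry, boundary effects and density gradients cancel in the
observed/null ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

DEFAULT_RADIUS_UM = 50.0
DEFAULT_N_PERMUTATIONS = 1000


class MissingTypeError(ValueError):
    """A requested cell type has no cells in the dataset."""


def _xy(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x", "y"]].to_numpy(float)


# ---------------------------------------------------------------------------
# nearest-neighbour distances
# ---------------------------------------------------------------------------

def nearest_distance_distribution(
    cells: pd.DataFrame, ref_type: str, target_type: str
) -> np.ndarray:
    """Distance from each reference-type cell to its nearest target-type cell.

    When the two types coincide the cell itself is excluded, so the result is
    the nearest *other* cell of the same type.
    """
    ref = cells.loc[cells["type_label"] == ref_type]
    tgt = cells.loc[cells["type_label"] == target_type]
    if ref.empty:
        raise MissingTypeError(f"no cells of reference type {ref_type!r}")
    if tgt.empty:
        raise MissingTypeError(f"no cells of target type {target_type!r}")
    tree = cKDTree(_xy(tgt))
    if ref_type == target_type:
        if len(tgt) < 2:
            raise MissingTypeError(
                f"self-distance for {ref_type!r} needs at least 2 cells")
        d, _ = tree.query(_xy(ref), k=2)
        return d[:, 1]
    d, _ = tree.query(_xy(ref), k=1)
    return d


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Mean per-reference-cell neighbourhood readout at increasing scales.

    ``mode`` is one of ``count`` (cells within radius), ``density``
    (count / πr²), or ``fraction`` (radius mode: target share of all
    neighbours within r; k-NN mode: target share of the k nearest cells).
    """

    ref_type: str
    target_type: str
    scales: np.ndarray
    scale_kind: str              # "radius" (μm) or "knn"
    mode: str
    mean: np.ndarray
    sd: np.ndarray
    n_ref: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ref_type": self.ref_type, "target_type": self.target_type,
            "scale": self.scales, "scale_kind": self.scale_kind,
            "mode": self.mode, "mean": self.mean, "sd": self.sd,
            "n_ref": self.n_ref,
        })


def density_profile(
    cells: pd.DataFrame,
    ref_type: str,
    target_type: str,
    scales,
    mode: str = "count",
    scale_kind: str = "radius",
) -> DensityProfile:
    """Profile the abundance of a target type around a reference type.

    In radius mode the per-reference readout at radius r counts target cells
    within r (reference cell itself excluded), optionally normalised to an
    areal density or to the fraction of all neighbouring cells. In k-NN mode
    the readout is the fraction of the k nearest cells (of any type) that
    are target-type — the scale axis is then a cell count, matching how
    proximity is often read out in numbers of cells rather than micrometres.
    """
    scales = np.asarray(scales, float)
    if len(scales) == 0 or np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing and non-empty")
    ref = cells.loc[cells["type_label"] == ref_type]
    if ref.empty:
        raise MissingTypeError(f"no cells of reference type {ref_type!r}")

    ref_xy = _xy(ref)
    all_xy = _xy(cells)
    is_ref = np.zeros(len(cells), dtype=bool)
    is_ref[cells.index.get_indexer(ref.index)] = True
    is_target = (cells["type_label"] == target_type).to_numpy()

    means, sds = [], []
    if scale_kind == "radius":
        tree = cKDTree(all_xy)
        ref_pos = cells.index.get_indexer(ref.index)
        for r in scales:
            neigh = tree.query_ball_point(ref_xy, r)
            readout = np.empty(len(ref_xy))
            for i, (nb, self_idx) in enumerate(zip(neigh, ref_pos)):
                nb = [j for j in nb if j != self_idx]
                n_target = int(np.sum(is_target[nb])) if nb else 0
                if mode == "count":
                    readout[i] = n_target
                elif mode == "density":
                    readout[i] = n_target / (np.pi * r * r)
                elif mode == "fraction":
                    readout[i] = n_target / len(nb) if nb else 0.0
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            means.append(readout.mean())
            sds.append(readout.std(ddof=1) if len(readout) > 1 else 0.0)
    elif scale_kind == "knn":
        if mode != "fraction":
            raise ValueError("k-NN scale supports the 'fraction' readout")
        tree = cKDTree(all_xy)
        kmax = int(scales[-1])
        if kmax > len(cells) - 1:
            raise IndexError(f"k={kmax} exceeds n-1={len(cells) - 1}")
        _, idx = tree.query(ref_xy, k=kmax + 1)  # +1 for self
        ref_pos = cells.index.get_indexer(ref.index)
        for k in scales.astype(int):
            readout = np.empty(len(ref_xy))
            for i, row in enumerate(idx):
                nb = [j for j in row if j != ref_pos[i]][:k]
                readout[i] = np.sum(is_target[nb]) / k
            means.append(readout.mean())
            sds.append(readout.std(ddof=1) if len(readout) > 1 else 0.0)
    else:
        raise ValueError(f"unknown scale_kind {scale_kind!r}")

    return DensityProfile(ref_type, target_type, scales, scale_kind, mode,
                          np.asarray(means), np.asarray(sds), len(ref))


# ---------------------------------------------------------------------------
# neighbourhood pair enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Permutation-test result for one unordered cell-type pair."""

    type_a: str
    type_b: str
    radius: float
    observed_pairs: int
    total_pairs: int
    observed_probability: float
    null_mean: float
    null_sd: float
    enrichment: float
    z: float
    p_value: float
    n_permutations: int
    seed: int
    insufficient_cells: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.type_a, self.type_b)))


def _pair_counts_by_type(pi: np.ndarray, pj: np.ndarray, codes: np.ndarray,
                         n_types: int) -> np.ndarray:
    """Count proximal pairs per unordered type pair, as an upper-tri matrix."""
    a = codes[pi]
    b = codes[pj]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    flat = np.bincount(lo * n_types + hi, minlength=n_types * n_types)
    return flat.reshape(n_types, n_types)


def neighborhood_enrichment(
    cells: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_UM,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Pair-enrichment of all unordered cell-type pairs within a radius.

    The observed probability of a type pair is the number of unordered cell
    pairs of those types with distance <= radius, divided by the number of
    all unordered cell pairs within the radius (self-pairs excluded). The
    null redistributes the observed type labels uniformly over the fixed
    positions ``n_permutations`` times; enrichment is observed / null mean,
    and p = (1 + #{null >= observed}) / (1 + n_permutations).

    Same-type pairs for a type with fewer than 2 cells are returned flagged
    ``insufficient_cells`` with NaN statistics.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = cells["type_label"].astype(str).to_numpy()
    types = np.array(sorted(set(labels)))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    code_of = {t: i for i, t in enumerate(types)}
    codes = np.array([code_of[t] for t in labels])
    n_types = len(types)

    tree = cKDTree(_xy(cells))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    pi, pj = (pairs[:, 0], pairs[:, 1]) if len(pairs) else (
        np.empty(0, int), np.empty(0, int))
    total = len(pairs)

    observed = _pair_counts_by_type(pi, pj, codes, n_types)

    rng = np.random.default_rng(seed)
    null = np.zeros((n_permutations, n_types, n_types))
    for m in range(n_permutations):
        null[m] = _pair_counts_by_type(pi, pj, rng.permutation(codes), n_types)

    type_counts = np.bincount(codes, minlength=n_types)
    results = []
    for ia, ib in combinations_with_replacement(range(n_types), 2):
        insufficient = ia == ib and type_counts[ia] < 2
        obs = int(observed[ia, ib])
        obs_p = obs / total if total else 0.0
        null_counts = null[:, ia, ib]
        null_mean = float(null_counts.mean())
        null_sd = float(null_counts.std(ddof=1))
        if insufficient or total == 0:
            enr = z = p = float("nan")
        else:
            enr = obs / null_mean if null_mean > 0 else float("inf") if obs else float("nan")
            z = (obs - null_mean) / null_sd if null_sd > 0 else float("nan")
            p = (1 + int(np.sum(null_counts >= obs))) / (1 + n_permutations)
        results.append(EnrichmentResult(
            type_a=str(types[ia]), type_b=str(types[ib]), radius=float(radius),
            observed_pairs=obs, total_pairs=total,
            observed_probability=obs_p,
            null_mean=null_mean / total if total else float("nan"),
            null_sd=null_sd / total if total else float("nan"),
            enrichment=enr, z=z, p_value=p,
            n_permutations=n_permutations, seed=seed,
            insufficient_cells=bool(insufficient),
        ))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tidy one-row-per-pair table of enrichment results."""
    return pd.DataFrame([{
        "type_a": r.type_a, "type_b": r.type_b, "radius": r.radius,
        "observed_pairs": r.observed_pairs, "total_pairs": r.total_pairs,
        "observed": r.observed_probability,
        "null_mean": r.null_mean, "null_sd": r.null_sd,
        "enrichment": r.enrichment, "z": r.z, "p": r.p_value,
        "n_perm": r.n_permutations, "seed": r.seed,
        "insufficient_cells": r.insufficient_cells,
    } for r in results])


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    u_statistic: float    # U for sample a
    p_value: float        # two-sided
    method: str           # "exact" or "asymptotic"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{(i, j): a_i > b_j}, ties counting one half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def rank_sum_test(sample_a, sample_b, exact_max_n: int = 20) -> RankSumResult:
    """Two-sided Mann–Whitney U test of two distance samples.

    For small samples (combined n <= ``exact_max_n``) the null distribution
    of U is enumerated exhaustively over all assignments of the pooled
    values to the two groups (ties handled by half-counting, so identical
    samples give p = 1 exactly). Larger samples use the normal approximation
    with continuity and tie correction.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    n1, n2 = len(a), len(b)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        hits = 0
        n_assign = 0
        for idx_a in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            hits += abs(u - mid) >= dev_obs - 1e-12
            n_assign += 1
        return RankSumResult(u_obs, hits / n_assign, "exact")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue), "asymptotic")
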