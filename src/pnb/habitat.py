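"""Topographic variables, the 13-variable habitat table, and its PCA reduction.

Topography is computed at subplot (20 x 20 m) resolution from a grid of
subplot-corner elevations and assigned to the contained seedling quadrat:

* elevation — mean of the four corner elevations;
* slope — mean angular deviation from horizontal of the four triangular
  planes obtained by dropping each corner in turn;
* convexity — focal elevation minus the mean of the eight neighboring
  subplot elevations; on plot edges the available neighbors are pooled with
  the subplot's own four corner elevations.

The PCA is a correlation-matrix PCA of 13 variables (3 topographic + 10
soil). Canopy openness (gli) stays out of the PCA and enters models
directly. Components are sign-fixed so the largest-|loading| entry of each
is positive, making the output deterministic across eigen-solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import PlotDataset, SUBPLOT_SIZE

__all__ = [
    "SOIL_VARIABLES",
    "TOPO_VARIABLES",
    "PCA_VARIABLES",
    "PCAResult",
    "HabitatError",
    "elevation",
    "slope",
    "convexity_grid",
    "subplot_topography",
    "assemble_habitat",
    "habitat_pca",
]

TOPO_VARIABLES = ["elevation", "convexity", "slope"]
SOIL_VARIABLES = [
    "ph",
    "ec",
    "c",
    "ap",
    "ak",
    "tn",
    "tp",
    "tk",
    "soil_temp",
    "soil_moist",
]
PCA_VARIABLES = TOPO_VARIABLES + SOIL_VARIABLES  # 13 variables; gli excluded
LIGHT_VARIABLE = "gli"


class HabitatError(ValueError):
    """Raised for incomplete or degenerate habitat inputs."""


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # quadrat_id + pca1..pcaK
    variance_fraction: np.ndarray  # per component, sums to 1 over all K


def elevation(corner_elevations) -> float:
    """Mean of the four corner elevations."""
    corners = np.asarray(corner_elevations, dtype=float)
    if corners.shape != (4,) or np.any(np.isnan(corners)):
        raise HabitatError("four corner elevations required")
    return float(corners.mean())


def slope(corner_elevations, side_m: float = SUBPLOT_SIZE) -> float:
    """Mean angular deviation (degrees) of the four corner-triple planes.

    Corners are ordered around the square (SW, SE, NE, NW) at the vertices of
    a side_m x side_m cell; each triangle drops one corner, and its deviation
    is the angle between the plane normal and the vertical.
    """
    z = np.asarray(corner_elevations, dtype=float)
    if z.shape != (4,):
        raise HabitatError("four corner elevations required")
    s = float(side_m)
    pts = np.array(
        [[0, 0, z[0]], [s, 0, z[1]], [s, s, z[2]], [0, s, z[3]]], dtype=float
    )
    angles = []
    for drop in range(4):
        tri = pts[[i for i in range(4) if i != drop]]
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        cosang = abs(n[2]) / np.linalg.norm(n)
        angles.append(math.degrees(math.acos(min(1.0, max(-1.0, cosang)))))
    return float(np.mean(angles))


def convexity_grid(
    mean_elev: np.ndarray, corner_grid: np.ndarray | None = None
) -> np.ndarray:
    """Convexity for every cell of a grid of subplot mean elevations.

    Interior cells: elev(focal) - mean of the 8 neighbors. Edge cells: the
    available neighbors are pooled with the cell's own four corner
    elevations (from ``corner_grid``, shape (R+1, C+1)) before averaging;
    without a corner grid, edge cells fall back to the available neighbors
    alone.
    """
    m = np.asarray(mean_elev, dtype=float)
    R, C = m.shape
    out = np.empty_like(m)
    for r in range(R):
        for c in range(C):
            neigh = [
                m[rr, cc]
                for rr in range(r - 1, r + 2)
                for cc in range(c - 1, c + 2)
                if (rr, cc) != (r, c) and 0 <= rr < R and 0 <= cc < C
            ]
            on_edge = len(neigh) < 8
            if on_edge and corner_grid is not None:
                g = np.asarray(corner_grid, dtype=float)
                corners = [g[r, c], g[r, c + 1], g[r + 1, c], g[r + 1, c + 1]]
                neigh = neigh + corners
            out[r, c] = m[r, c] - float(np.mean(neigh))
    return out


def _corner_grid_from_quadrats(plot: PlotDataset) -> np.ndarray:
    """Reconstruct the (R+1, C+1) subplot-corner elevation grid.

    Quadrat rows carry their subplot's corner elevations ordered
    (SW, SE, NE, NW); shared corners between adjacent subplots are averaged.
    """
    R, C = plot.n_subplots
    acc = np.zeros((R + 1, C + 1))
    cnt = np.zeros((R + 1, C + 1))
    offsets = [(0, 0), (0, 1), (1, 1), (1, 0)]  # SW, SE, NE, NW
    for q in plot.quadrats:
        for k, (dr, dc) in enumerate(offsets):
            acc[q.subplot_row + dr, q.subplot_col + dc] += q.corner_elevations[k]
            cnt[q.subplot_row + dr, q.subplot_col + dc] += 1
    if np.any(cnt == 0):
        raise HabitatError("incomplete corner-elevation coverage of the subplot grid")
    return acc / cnt


def subplot_topography(plot: PlotDataset) -> pd.DataFrame:
    """Per-quadrat elevation, convexity, and slope at subplot resolution."""
    grid = _corner_grid_from_quadrats(plot)
    R, C = plot.n_subplots
    mean_elev = np.empty((R, C))
    slopes = np.empty((R, C))
    for r in range(R):
        for c in range(C):
            corners = [grid[r, c], grid[r, c + 1], grid[r + 1, c + 1], grid[r + 1, c]]
            mean_elev[r, c] = float(np.mean(corners))
            slopes[r, c] = slope(corners, side_m=SUBPLOT_SIZE)
    conv = convexity_grid(mean_elev, corner_grid=grid)
    rows = []
    for q in plot.quadrats:
        r, c = q.subplot_row, q.subplot_col
        rows.append(
            {
                "quadrat_id": q.quadrat_id,
                "elevation": mean_elev[r, c],
                "convexity": conv[r, c],
                "slope": slopes[r, c],
            }
        )
    return pd.DataFrame(rows)


def assemble_habitat(plot: PlotDataset) -> pd.DataFrame:
    """The full habitat table: topography + 10 soil variables + gli per quadrat.

    If the habitat CSV already provides elevation/convexity/slope they are
    passed through; otherwise they are derived from the corner-elevation
    grid.
    """
    hab = plot.habitat.copy()
    hab["quadrat_id"] = hab["quadrat_id"].astype(str)
    missing = [v for v in SOIL_VARIABLES + [LIGHT_VARIABLE] if v not in hab.columns]
    if missing:
        raise HabitatError(f"habitat table missing columns: {missing}")
    if not all(v in hab.columns for v in TOPO_VARIABLES):
        topo = subplot_topography(plot)
        hab = hab.merge(topo, on="quadrat_id", how="left")
    cols = ["quadrat_id"] + PCA_VARIABLES + [LIGHT_VARIABLE]
    out = hab[cols].copy()
    if out[PCA_VARIABLES + [LIGHT_VARIABLE]].isna().any().any():
        bad = [
            v
            for v in PCA_VARIABLES + [LIGHT_VARIABLE]
            if out[v].isna().any()
        ]
        raise HabitatError(f"missing habitat values in columns: {bad}")
    return out


def habitat_pca(table: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of the 13 topographic + soil variables.

    Returns all components; the analysis pipeline keeps the first three.
    Raises :class:`HabitatError` for zero-variance variables or < 4 quadrats.
    """
    if len(table) < 4:
        raise HabitatError("PCA requires at least 4 quadrats")
    X = table[PCA_VARIABLES].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dead = [v for v, s in zip(PCA_VARIABLES, sd) if s == 0]
    if dead:
        raise HabitatError(f"zero-variance habitat variable(s): {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = Z @ eigvecs
    k = eigvecs.shape[1]
    comp_names = [f"pca{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs, index=PCA_VARIABLES, columns=comp_names)
    score_df = pd.DataFrame(scores, columns=comp_names)
    score_df.insert(0, "quadrat_id", table["quadrat_id"].astype(str).to_numpy())
    return PCAResult(
        loadings=loadings,
        scores=score_df,
        variance_fraction=eigvals / eigvals.sum(),
    )
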