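"""Static 2-D cellular tessellation of a shoot-apical-meristem section.

The simulated tissue is an artificial longitudinal section through the dome
of the meristem: cell centres are placed on concentric semicircular layers
over a half-disc (the flat base is the cut through the stem), and cell walls
are obtained from the Voronoi decomposition of the centres.  Cells are
discrete entities; the only spatial structure the model uses is the
neighbour graph (shared Voronoi walls), an outer-layer competence mask and a
tip-peaked "anchoring" field that biases where WUS production is strongest.

The tessellation is static: growth and cell division are outside the scope
of the model, so a geometry is built once and only ever modified by ablation
(removing cells, e.g. to mimic laser ablation of the meristem centre).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Voronoi

__all__ = [
    "MeristemGeometry",
    "AnchoringParams",
    "build_dome_geometry",
    "build_anchoring",
    "ablate",
    "save_geometry",
    "load_geometry",
]


@dataclass(frozen=True)
class AnchoringParams:
    """Shape of the tip-peaked WUS/facX production-rate field.

    ``peak`` is the reaction rate at the tip cell, ``width`` the Gaussian
    decay width in units of graph distance (cell hops) from the tip and
    ``floor`` the rate far from the tip.  ``mode="constant"`` replaces the
    distribution by the uniform rate ``constant_value`` (the no-positional-
    information variant of the model).
    """

    peak: float = 0.013
    width: float = 2.75
    floor: float = 0.0013
    mode: str = "distribution"  # "distribution" | "constant"
    constant_value: float = 0.006

    def __post_init__(self) -> None:
        if self.mode not in ("distribution", "constant"):
            raise ValueError(f"unknown anchoring mode {self.mode!r}")
        if min(self.peak, self.width, self.floor, self.constant_value) < 0:
            raise ValueError("anchoring parameters must be nonnegative")
        if self.peak < self.floor:
            raise ValueError("anchoring peak must be >= floor")


@dataclass(frozen=True)
class MeristemGeometry:
    """Static cell tessellation: centres, adjacency, masks and anchoring.

    Arrays are positional (index ``0..n_cells-1``); ``cell_ids`` keeps the
    original identifiers stable across ablation so that removed cells never
    get recycled ids.
    """

    cell_ids: np.ndarray          # (n,) int — stable identifiers
    centres: np.ndarray           # (n, 2) float — cell centre coordinates
    edges: np.ndarray             # (m, 2) int — positional index pairs, a < b
    layer: np.ndarray             # (n,) int — 0 = outermost layer
    competent: np.ndarray         # (n,) bool — may express stemness
    boundary: np.ndarray          # (n,) bool — on the section's outer rim
    anchoring: np.ndarray         # (n,) float — WUS/facX production rate
    tip_cell: int                 # positional index of the apex cell

    # ------------------------------------------------------------------
    # Derived structure
    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def adjacency_matrix(self) -> csr_matrix:
        """Symmetric unweighted adjacency matrix (CSR)."""
        n = self.n_cells
        if self.edges.size == 0:
            return csr_matrix((n, n))
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return csr_matrix((np.ones(i.size), (i, j)), shape=(n, n))

    def neighbors(self, cell: int) -> np.ndarray:
        mask = (self.edges[:, 0] == cell) | (self.edges[:, 1] == cell)
        pairs = self.edges[mask]
        return np.unique(pairs[pairs != cell])

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def graph_distance_from(self, cell: int) -> np.ndarray:
        """Geodesic hop distance from ``cell`` to every cell."""
        d = shortest_path(self.adjacency_matrix(), method="D",
                          unweighted=True, indices=cell)
        return d

    def tip_distance(self) -> np.ndarray:
        return self.graph_distance_from(self.tip_cell)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency_matrix(),
                                         directed=False)
        return bool(n_comp == 1)

    def validate(self) -> None:
        """Raise ``ValueError`` on a structurally invalid geometry."""
        n = self.n_cells
        if n == 0:
            raise ValueError("geometry has no cells")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge index out of range")
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loop in adjacency")
        if np.any(self.anchoring < 0):
            raise ValueError("anchoring must be nonnegative")
        if not (0 <= self.tip_cell < n):
            raise ValueError("tip_cell out of range")
        if n > 1 and not self.is_connected():
            raise ValueError("cell graph is not connected")


# ----------------------------------------------------------------------
# Construction
# ----------------------------------------------------------------------

def _default_profile(n_layers: int, spacing: float) -> list[int]:
    """Cells per layer (outermost first) at roughly unit arc spacing."""
    return [int(round(np.pi * (n_layers - k))) + 1 for k in range(n_layers)]


def _voronoi_adjacency(points: np.ndarray,
                       max_edge_factor: float | None,
                       spacing: float) -> np.ndarray:
    """Neighbour pairs sharing a Voronoi wall.

    Two cells are adjacent when their Voronoi regions share a ridge.
    Ridges between centres further apart than ``max_edge_factor * spacing``
    are discarded: the unbounded Voronoi regions of rim cells meet in the
    far field outside the tissue, producing spurious walls between distant
    base cells that no finite section would realize.
    """
    vor = Voronoi(points)
    pairs = np.asarray(vor.ridge_points, dtype=int)
    if max_edge_factor is not None:
        lengths = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]],
                                 axis=1)
        pairs = pairs[lengths <= max_edge_factor * spacing]
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    return pairs


def build_dome_geometry(
    n_layers: int = 7,
    cells_per_layer_profile: Sequence[int] | None = None,
    competent_depth: int = 2,
    seed: int = 0,
    spacing: float = 1.0,
    jitter: float = 0.02,
    anchoring_params: AnchoringParams | None = None,
    max_edge_factor: float | None = 2.5,
) -> MeristemGeometry:
    """Build the semicircular dome section used for all simulations.

    Layer ``k`` (0 = outermost) carries its cells on a semicircle of radius
    ``(n_layers - k) * spacing`` above the flat base.  A small seeded jitter
    removes co-circular degeneracies from the Voronoi construction while
    keeping the tessellation deterministic per seed.
    """
    if n_layers < 3:
        raise ValueError("n_layers must be >= 3 for a dome section")
    if not (1 <= competent_depth < n_layers):
        raise ValueError("competent_depth must be in [1, n_layers)")
    if cells_per_layer_profile is None:
        cells_per_layer_profile = _default_profile(n_layers, spacing)
    profile = [int(m) for m in cells_per_layer_profile]
    if len(profile) != n_layers:
        raise ValueError("layer profile length must equal n_layers")
    if any(m <= 0 for m in profile):
        raise ValueError("every layer must contain at least one cell")

    rng = np.random.default_rng(seed)
    centres, layers, base_flags = [], [], []
    for k, m in enumerate(profile):
        r = (n_layers - k) * spacing
        if m == 1:
            thetas = np.array([np.pi / 2.0])
        else:
            thetas = np.linspace(0.0, np.pi, m)
        for j, th in enumerate(thetas):
            centres.append((r * np.cos(th), r * np.sin(th)))
            layers.append(k)
            base_flags.append(m > 1 and (j == 0 or j == m - 1))
    centres = np.asarray(centres, dtype=float)
    layers = np.asarray(layers, dtype=int)
    base_flags = np.asarray(base_flags, dtype=bool)

    # apex cell: top of the outermost layer, pinned before jitter
    tip_cell = int(np.argmin(np.hypot(centres[:, 0],
                                      centres[:, 1] - n_layers * spacing)))
    pert = rng.uniform(-jitter, jitter, size=centres.shape) * spacing
    pert[tip_cell, 0] = 0.0
    centres = centres + pert

    edges = _voronoi_adjacency(centres, max_edge_factor, spacing)
    geom = MeristemGeometry(
        cell_ids=np.arange(centres.shape[0], dtype=int),
        centres=centres,
        edges=edges,
        layer=layers,
        competent=layers < competent_depth,
        boundary=(layers == 0) | base_flags,
        anchoring=np.zeros(centres.shape[0]),
        tip_cell=tip_cell,
    )
    anchoring = build_anchoring(geom, anchoring_params or AnchoringParams())
    geom = replace(geom, anchoring=anchoring)
    geom.validate()
    return geom


def build_anchoring(geometry: MeristemGeometry,
                    shape_params: AnchoringParams) -> np.ndarray:
    """Per-cell WUS/facX production-rate field, maximal at the tip.

    The distribution mode is a Gaussian-like decay in geodesic (hop)
    distance from the tip cell with a constant floor; the constant mode
    returns a uniform rate (used to show patterning does not depend on the
    positional bias).
    """
    p = shape_params
    n = geometry.n_cells
    if p.mode == "constant":
        return np.full(n, p.constant_value, dtype=float)
    d = geometry.tip_distance()
    rho = p.floor + (p.peak - p.floor) * np.exp(-0.5 * (d / p.width) ** 2)
    return rho


def ablate(geometry: MeristemGeometry,
           cells_to_remove: Iterable[int]) -> MeristemGeometry:
    """Remove cells (by positional index) and all incident edges.

    The remaining arrays are re-indexed but ``cell_ids`` keeps the original
    identifiers.  Competence and anchoring are restricted, not re-derived:
    the wound does not change the identity of the surviving cells.
    """
    remove = np.unique(np.asarray(list(cells_to_remove), dtype=int))
    if remove.size == 0:
        return geometry
    n = geometry.n_cells
    if remove.size and (remove.min() < 0 or remove.max() >= n):
        raise ValueError("cell index out of range")
    keep = np.setdiff1d(np.arange(n), remove)
    if keep.size == 0:
        raise ValueError("cannot ablate every cell")
    if geometry.tip_cell in remove:
        # tip re-assigned to the surviving cell closest to the old apex
        apex = geometry.centres[geometry.tip_cell]
        new_tip_old = keep[np.argmin(
            np.linalg.norm(geometry.centres[keep] - apex, axis=1))]
    else:
        new_tip_old = geometry.tip_cell
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(keep.size)
    kept_mask = np.all(np.isin(geometry.edges, keep), axis=1)
    new_edges = remap[geometry.edges[kept_mask]]
    return MeristemGeometry(
        cell_ids=geometry.cell_ids[keep],
        centres=geometry.centres[keep],
        edges=new_edges,
        layer=geometry.layer[keep],
        competent=geometry.competent[keep],
        boundary=geometry.boundary[keep],
        anchoring=geometry.anchoring[keep],
        tip_cell=int(remap[new_tip_old]),
    )


# ----------------------------------------------------------------------
# Plain-text serialization (one geometry per directory)
# ----------------------------------------------------------------------

def save_geometry(geometry: MeristemGeometry, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame({
        "id": geometry.cell_ids,
        "x": geometry.centres[:, 0],
        "y": geometry.centres[:, 1],
        "layer": geometry.layer,
        "competent": geometry.competent.astype(int),
        "boundary": geometry.boundary.astype(int),
        "anchoring": geometry.anchoring,
        "tip": (np.arange(geometry.n_cells) == geometry.tip_cell).astype(int),
    })
    cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
    edges = pd.DataFrame({
        "id_a": geometry.cell_ids[geometry.edges[:, 0]],
        "id_b": geometry.cell_ids[geometry.edges[:, 1]],
    })
    edges.to_csv(directory / "edges.tsv", sep="\t", index=False)


def load_geometry(directory: str | Path) -> MeristemGeometry:
    directory = Path(directory)
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")
    edges = pd.read_csv(directory / "edges.tsv", sep="\t")
    ids = cells["id"].to_numpy(dtype=int)
    pos = {cid: k for k, cid in enumerate(ids)}
    pairs = np.array(
        [[pos[a], pos[b]] for a, b in zip(edges["id_a"], edges["id_b"])],
        dtype=int).reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    tip = int(np.flatnonzero(cells["tip"].to_numpy())[0])
    geom = MeristemGeometry(
        cell_ids=ids,
        centres=cells[["x", "y"]].to_numpy(dtype=float),
        edges=pairs,
        layer=cells["layer"].to_numpy(dtype=int),
        competent=cells["competent"].to_numpy(dtype=bool),
        boundary=cells["boundary"].to_numpy(dtype=bool),
        anchoring=cells["anchoring"].to_numpy(dtype=float),
        tip_cell=tip,
    )
    geom.validate()
    return geom
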