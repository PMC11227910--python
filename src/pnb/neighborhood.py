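"""Density covariates and heterospecific neighbor profiles.

Two conspecific density covariates:

* ``s_con`` — count of other alive conspecific seedlings sharing the focal
  seedling's quadrat at a census.
* ``a_con`` — sum over conspecific adults within a closed 20 m ball of the
  quadrat center of basal area (cm^2, from dbh in cm) divided by distance
  (m), with a configurable distance floor.

Heterospecific neighbor profiles (species -> individual count) are assembled
per layer: seedlings from the same quadrat, adults from the radius query.
No edge correction is applied at plot boundaries; the truncated neighborhood
is used as-is. The adult census is static across seedling censuses.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_core import PlotDataset, SeedlingRecord

__all__ = [
    "NeighborProfile",
    "DensityVars",
    "NotAliveError",
    "s_con",
    "a_con",
    "neighbor_profiles",
    "NeighborhoodContext",
    "DEFAULT_RADIUS",
    "DEFAULT_D_FLOOR",
]

DEFAULT_RADIUS = 20.0
DEFAULT_D_FLOOR = 0.1


class NotAliveError(ValueError):
    """The focal seedling is not alive at the requested census (undefined observation)."""


@dataclass
class NeighborProfile:
    """Heterospecific neighbor abundances for one focal individual and layer."""

    focal_species: str
    layer: str  # "seedling" | "adult"
    abundance: dict[str, int]
    census_year: int
    quadrat_id: str

    def __post_init__(self) -> None:
        if self.focal_species in self.abundance:
            raise ValueError("profile must be heterospecific: focal species present")
        if any(c < 1 for c in self.abundance.values()):
            raise ValueError("profile counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.abundance.values())

    @property
    def empty(self) -> bool:
        return not self.abundance


@dataclass
class DensityVars:
    s_con: int
    a_con: float
    n_adult_neighbors: int


def basal_area(dbh_cm: float) -> float:
    """Basal area in cm^2 from dbh in cm: pi (dbh/2)^2."""
    return math.pi * (dbh_cm / 2.0) ** 2


def a_con(
    focal_species: str,
    quadrat_center: tuple[float, float],
    adults,
    radius_m: float = DEFAULT_RADIUS,
    d_floor: float = DEFAULT_D_FLOOR,
) -> float:
    """Conspecific adult density index: sum of BA_i / max(distance_i, d_floor).

    Brute-force O(n) scan over the adult list; the spatially indexed
    :class:`NeighborhoodContext` must agree with this exactly.
    """
    cx, cy = quadrat_center
    total = 0.0
    for ad in adults:
        if ad.species != focal_species:
            continue
        dist = math.hypot(ad.x - cx, ad.y - cy)
        if dist <= radius_m:
            total += basal_area(ad.dbh) / max(dist, d_floor)
    return total


def s_con(focal: SeedlingRecord, plot: PlotDataset, census_year: int) -> int:
    """Count of other alive conspecific seedlings in the focal's quadrat."""
    if not focal.is_alive(census_year):
        raise NotAliveError(f"seedling {focal.tag} not alive at {census_year}")
    return sum(
        1
        for s in plot.seedlings
        if s.quadrat_id == focal.quadrat_id
        and s.tag != focal.tag
        and s.species == focal.species
        and s.is_alive(census_year)
    )


def neighbor_profiles(
    focal: SeedlingRecord,
    plot: PlotDataset,
    census_year: int,
    radius_m: float = DEFAULT_RADIUS,
) -> tuple[NeighborProfile, NeighborProfile]:
    """Assemble (seedling-layer, adult-layer) heterospecific profiles for one focal."""
    if not focal.is_alive(census_year):
        raise NotAliveError(f"seedling {focal.tag} not alive at {census_year}")
    seed_counts: Counter[str] = Counter()
    for s in plot.seedlings:
        if (
            s.quadrat_id == focal.quadrat_id
            and s.tag != focal.tag
            and s.species != focal.species
            and s.is_alive(census_year)
        ):
            seed_counts[s.species] += 1
    q = plot.quadrat_map()[focal.quadrat_id]
    adult_counts: Counter[str] = Counter()
    for ad in plot.adults:
        if ad.species == focal.species:
            continue
        if math.hypot(ad.x - q.center_x, ad.y - q.center_y) <= radius_m:
            adult_counts[ad.species] += 1
    mk = lambda layer, counts: NeighborProfile(
        focal_species=focal.species,
        layer=layer,
        abundance=dict(counts),
        census_year=census_year,
        quadrat_id=focal.quadrat_id,
    )
    return mk("seedling", seed_counts), mk("adult", adult_counts)


class NeighborhoodContext:
    """Spatially indexed neighborhood queries over one plot (or plot subset).

    Builds a KD-tree over adult stems and per-(year, quadrat) registers of
    alive seedlings so the whole-pipeline index computation does not rescan
    the censuses per focal individual.
    """

    def __init__(
        self,
        plot: PlotDataset,
        radius_m: float = DEFAULT_RADIUS,
        d_floor: float = DEFAULT_D_FLOOR,
    ):
        self.plot = plot
        self.radius_m = radius_m
        self.d_floor = d_floor
        self._xy = np.array([[a.x, a.y] for a in plot.adults], dtype=float).reshape(
            -1, 2
        )
        self._species = np.array([a.species for a in plot.adults], dtype=object)
        self._ba = np.array([basal_area(a.dbh) for a in plot.adults], dtype=float)
        self._tree = cKDTree(self._xy) if len(plot.adults) else None
        self._by_qy: dict[tuple[int, str], list[SeedlingRecord]] = {}
        for s in plot.seedlings:
            for y, tok in s.status.items():
                if tok == "alive":
                    self._by_qy.setdefault((y, s.quadrat_id), []).append(s)
        self._qmap = plot.quadrat_map()

    def _adults_near(self, center: tuple[float, float]) -> np.ndarray:
        if self._tree is None:
            return np.empty(0, dtype=int)
        idx = self._tree.query_ball_point(center, self.radius_m)
        return np.asarray(sorted(idx), dtype=int)

    def a_con(self, focal_species: str, quadrat_id: str) -> tuple[float, int]:
        """Return (a_con, number of adult neighbors of any species in radius)."""
        q = self._qmap[quadrat_id]
        center = (q.center_x, q.center_y)
        idx = self._adults_near(center)
        if idx.size == 0:
            return 0.0, 0
        d = np.hypot(
            self._xy[idx, 0] - center[0], self._xy[idx, 1] - center[1]
        )
        con = self._species[idx] == focal_species
        val = float(
            np.sum(self._ba[idx][con] / np.maximum(d[con], self.d_floor))
        )
        return val, int(idx.size)

    def s_con(self, focal: SeedlingRecord, year: int) -> int:
        if not focal.is_alive(year):
            raise NotAliveError(f"seedling {focal.tag} not alive at {year}")
        mates = self._by_qy.get((year, focal.quadrat_id), [])
        return sum(
            1 for s in mates if s.tag != focal.tag and s.species == focal.species
        )

    def density_vars(self, focal: SeedlingRecord, year: int) -> DensityVars:
        ac, n_adults = self.a_con(focal.species, focal.quadrat_id)
        return DensityVars(
            s_con=self.s_con(focal, year), a_con=ac, n_adult_neighbors=n_adults
        )

    def profiles(
        self, focal: SeedlingRecord, year: int
    ) -> tuple[NeighborProfile, NeighborProfile]:
        if not focal.is_alive(year):
            raise NotAliveError(f"seedling {focal.tag} not alive at {year}")
        seed_counts: Counter[str] = Counter()
        for s in self._by_qy.get((year, focal.quadrat_id), []):
            if s.tag != focal.tag and s.species != focal.species:
                seed_counts[s.species] += 1
        q = self._qmap[focal.quadrat_id]
        idx = self._adults_near((q.center_x, q.center_y))
        adult_counts: Counter[str] = Counter()
        for i in idx:
            sp = self._species[i]
            if sp != focal.species:
                adult_counts[sp] += 1
        mk = lambda layer, counts: NeighborProfile(
            focal_species=focal.species,
            layer=layer,
            abundance=dict(counts),
            census_year=year,
            quadrat_id=focal.quadrat_id,
        )
        return mk("seedling", seed_counts), mk("adult", adult_counts)
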