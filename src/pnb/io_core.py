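"""Plot data model, tabular I/O, validation, and coordinate conventions.

Coordinate frame: origin at the plot's south-west corner, x east, y north,
meters, continuous. Subplot (r, c) spans [20c, 20c+20) x [20r, 20r+20) for
the default 20 m subplot size. One 2 x 2 m seedling quadrat per subplot.

Seedling status tokens per census: ``alive``, ``dead``, ``unrecruited``.
Once a seedling has recruited, a status must exist for every later census
and death is absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdultRecord",
    "SeedlingRecord",
    "Quadrat",
    "PlotDataset",
    "ValidationError",
    "SchemaError",
    "ReferentialError",
    "ConsistencyError",
    "STATUS_ALIVE",
    "STATUS_DEAD",
    "STATUS_UNRECRUITED",
    "read_plot",
    "write_plot",
    "quadrat_center",
    "validate_species",
]

STATUS_ALIVE = "alive"
STATUS_DEAD = "dead"
STATUS_UNRECRUITED = "unrecruited"
_STATUSES = {STATUS_ALIVE, STATUS_DEAD, STATUS_UNRECRUITED}

SUBPLOT_SIZE = 20.0
QUADRAT_SIZE = 2.0
MIN_RECRUIT_HEIGHT = 20.0


class ValidationError(ValueError):
    """Base class for plot-data validation failures."""


class SchemaError(ValidationError):
    """A required column is missing or a value has the wrong type."""


class ReferentialError(ValidationError):
    """A cross-reference (quadrat id, species name) does not resolve."""


class ConsistencyError(ValidationError):
    """A record violates a domain invariant (status order, dbh bound, ...)."""


@dataclass
class AdultRecord:
    tag: str
    species: str
    x: float
    y: float
    dbh: float


@dataclass
class SeedlingRecord:
    tag: str
    quadrat_id: str
    species: str
    status: dict[int, str]  # census year -> status token
    height: dict[int, float]  # census year -> height (cm); NaN when unmeasured

    def is_alive(self, year: int) -> bool:
        return self.status.get(year) == STATUS_ALIVE

    def first_alive_year(self) -> int | None:
        for year in sorted(self.status):
            if self.status[year] == STATUS_ALIVE:
                return year
        return None


@dataclass
class Quadrat:
    quadrat_id: str
    subplot_row: int
    subplot_col: int
    center_x: float
    center_y: float
    corner_elevations: np.ndarray  # 4 values: SW, SE, NE, NW of the subplot


@dataclass
class PlotDataset:
    """Validated container for one plot's censuses plus habitat covariates."""

    adults: list[AdultRecord]
    seedlings: list[SeedlingRecord]
    quadrats: list[Quadrat]
    habitat: pd.DataFrame  # quadrat_id + soil/light columns (see habitat module)
    census_years: list[int]
    extent: tuple[float, float] = (200.0, 200.0)
    validation_report: list[str] = field(default_factory=list)

    def quadrat_map(self) -> dict[str, Quadrat]:
        return {q.quadrat_id: q for q in self.quadrats}

    def seedlings_in_quadrat(self, quadrat_id: str) -> list[SeedlingRecord]:
        return [s for s in self.seedlings if s.quadrat_id == quadrat_id]

    def species_pool(self) -> set[str]:
        pool = {a.species for a in self.adults}
        pool.update(s.species for s in self.seedlings)
        return pool

    @property
    def n_subplots(self) -> tuple[int, int]:
        w, h = self.extent
        return int(round(h / SUBPLOT_SIZE)), int(round(w / SUBPLOT_SIZE))


# ---------------------------------------------------------------------------
# quadrat placement


def quadrat_center(
    subplot_row: int,
    subplot_col: int,
    placement_rule: str = "top_right_inset",
    extent: tuple[float, float] = (200.0, 200.0),
) -> tuple[float, float]:
    """Center of the seedling quadrat for one subplot under a placement rule.

    ``top_right_inset`` (default): the quadrat occupies
    [20c+16, 20c+18] x [20r+16, 20r+18] (2 m inset from the subplot's NE
    corner), center (20c+17, 20r+17).
    ``top_right_corner``: flush against the NE corner,
    [20c+18, 20c+20] x [20r+18, 20r+20], center (20c+19, 20r+19).
    """
    n_rows = int(round(extent[1] / SUBPLOT_SIZE))
    n_cols = int(round(extent[0] / SUBPLOT_SIZE))
    if not (0 <= subplot_row < n_rows and 0 <= subplot_col < n_cols):
        raise IndexError(
            f"subplot ({subplot_row}, {subplot_col}) outside {n_rows} x {n_cols} grid"
        )
    x0 = SUBPLOT_SIZE * subplot_col
    y0 = SUBPLOT_SIZE * subplot_row
    if placement_rule == "top_right_inset":
        off = SUBPLOT_SIZE - 2.0 - QUADRAT_SIZE / 2.0  # 17 m
    elif placement_rule == "top_right_corner":
        off = SUBPLOT_SIZE - QUADRAT_SIZE / 2.0  # 19 m
    else:
        raise ValueError(f"unknown placement rule {placement_rule!r}")
    return (x0 + off, y0 + off)


# ---------------------------------------------------------------------------
# reading


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _census_years_from_columns(columns: list[str]) -> list[int]:
    years = sorted(
        int(c.split("_")[-1]) for c in columns if c.startswith("status_")
    )
    if not years:
        raise SchemaError("seedlings table has no status_<year> columns")
    return years


def read_plot(
    adult_path,
    seedling_path,
    quadrat_path,
    habitat_path,
    extent: tuple[float, float] = (200.0, 200.0),
) -> PlotDataset:
    """Read and validate the four input tables into a :class:`PlotDataset`.

    Raises :class:`SchemaError`, :class:`ReferentialError` or
    :class:`ConsistencyError` on the first violated contract; softer issues
    (carried-forward heights) are appended to ``validation_report``.
    """
    adults_df = pd.read_csv(adult_path, float_precision="round_trip")
    seedlings_df = pd.read_csv(seedling_path, float_precision="round_trip")
    quadrats_df = pd.read_csv(quadrat_path, float_precision="round_trip")
    habitat_df = pd.read_csv(habitat_path, float_precision="round_trip")

    _require_columns(adults_df, ["tag", "species", "x", "y", "dbh"], "adults")
    _require_columns(
        quadrats_df,
        ["quadrat_id", "subplot_row", "subplot_col"]
        + [f"elev_c{i}" for i in range(1, 5)],
        "quadrats",
    )
    _require_columns(seedlings_df, ["tag", "quadrat_id", "species"], "seedlings")
    _require_columns(habitat_df, ["quadrat_id"], "habitat")

    years = _census_years_from_columns(list(seedlings_df.columns))
    for y in years:
        _require_columns(seedlings_df, [f"status_{y}", f"height_{y}"], "seedlings")

    report: list[str] = []

    adults = [
        AdultRecord(
            tag=str(r.tag),
            species=str(r.species),
            x=float(r.x),
            y=float(r.y),
            dbh=float(r.dbh),
        )
        for r in adults_df.itertuples()
    ]

    quadrats = []
    for r in quadrats_df.itertuples():
        row, col = int(r.subplot_row), int(r.subplot_col)
        if "center_x" in quadrats_df.columns and not pd.isna(r.center_x):
            cx, cy = float(r.center_x), float(r.center_y)
        else:
            cx, cy = quadrat_center(row, col, extent=extent)
        quadrats.append(
            Quadrat(
                quadrat_id=str(r.quadrat_id),
                subplot_row=row,
                subplot_col=col,
                center_x=cx,
                center_y=cy,
                corner_elevations=np.array(
                    [getattr(r, f"elev_c{i}") for i in range(1, 5)], dtype=float
                ),
            )
        )

    seedlings = []
    for r in seedlings_df.itertuples():
        status: dict[int, str] = {}
        height: dict[int, float] = {}
        for y in years:
            tok = getattr(r, f"status_{y}")
            if pd.isna(tok):
                tok = STATUS_UNRECRUITED
            tok = str(tok)
            if tok not in _STATUSES:
                raise SchemaError(
                    f"seedling {r.tag}: unknown status token {tok!r} for {y}"
                )
            status[y] = tok
            h = getattr(r, f"height_{y}")
            height[y] = float(h) if not pd.isna(h) else math.nan
        seedlings.append(
            SeedlingRecord(
                tag=str(r.tag),
                quadrat_id=str(r.quadrat_id),
                species=str(r.species),
                status=status,
                height=height,
            )
        )

    plot = PlotDataset(
        adults=adults,
        seedlings=seedlings,
        quadrats=quadrats,
        habitat=habitat_df,
        census_years=years,
        extent=extent,
        validation_report=report,
    )
    _validate(plot)
    return plot


def _validate(plot: PlotDataset) -> None:
    w, h = plot.extent
    bad_dbh = [a.tag for a in plot.adults if a.dbh < 1.0]
    if bad_dbh:
        raise ConsistencyError(f"adults with dbh < 1: {bad_dbh}")
    out = [
        a.tag
        for a in plot.adults
        if not (0 <= a.x <= w and 0 <= a.y <= h)
    ]
    if out:
        raise ConsistencyError(f"adults outside plot extent: {out}")

    seen_subplots: dict[tuple[int, int], str] = {}
    for q in plot.quadrats:
        key = (q.subplot_row, q.subplot_col)
        if key in seen_subplots:
            raise ConsistencyError(
                f"subplot {key} has two quadrats: {seen_subplots[key]}, {q.quadrat_id}"
            )
        seen_subplots[key] = q.quadrat_id

    qids = {q.quadrat_id for q in plot.quadrats}
    hab_ids = set(plot.habitat["quadrat_id"].astype(str))
    missing_hab = qids - hab_ids
    if missing_hab:
        raise ReferentialError(f"quadrats missing from habitat table: {sorted(missing_hab)}")

    years = plot.census_years
    if years != sorted(set(years)):
        raise ConsistencyError("census years not strictly increasing")

    offenders_revive: list[str] = []
    offenders_gap: list[str] = []
    offenders_height: list[str] = []
    for s in plot.seedlings:
        if s.quadrat_id not in qids:
            raise ReferentialError(
                f"seedling {s.tag}: unknown quadrat_id {s.quadrat_id!r}"
            )
        recruited = False
        dead = False
        for y in years:
            tok = s.status[y]
            if tok == STATUS_ALIVE:
                if dead:
                    offenders_revive.append(s.tag)
                recruited = True
            elif tok == STATUS_DEAD:
                if not recruited:
                    offenders_gap.append(s.tag)
                recruited = True
                dead = True
            else:  # unrecruited
                if recruited:
                    offenders_gap.append(s.tag)
        fy = s.first_alive_year()
        if fy is not None:
            h0 = s.height.get(fy, math.nan)
            if not math.isnan(h0) and h0 < MIN_RECRUIT_HEIGHT:
                offenders_height.append(s.tag)
        # carry forward missing heights for alive censuses
        last = math.nan
        for y in years:
            if s.is_alive(y):
                if math.isnan(s.height.get(y, math.nan)):
                    if not math.isnan(last):
                        s.height[y] = last
                        plot.validation_report.append(
                            f"seedling {s.tag}: height carried forward into {y}"
                        )
                else:
                    last = s.height[y]
    if offenders_revive:
        raise ConsistencyError(
            f"dead -> alive status transition for tags: {sorted(set(offenders_revive))}"
        )
    if offenders_gap:
        raise ConsistencyError(
            f"status gap after recruitment (or dead before recruit) for tags: "
            f"{sorted(set(offenders_gap))}"
        )
    if offenders_height:
        raise ConsistencyError(
            f"height < {MIN_RECRUIT_HEIGHT} cm at first alive census: "
            f"{sorted(set(offenders_height))}"
        )


def validate_species(plot: PlotDataset, tip_labels: set[str] | list[str]) -> list[str]:
    """Report every census species absent from the phylogeny tip set.

    Returns the sorted list of missing species (empty when fully resolved);
    never drops anything silently.
    """
    tips = set(tip_labels)
    missing = sorted(plot.species_pool() - tips)
    for sp in missing:
        plot.validation_report.append(f"species {sp!r} absent from phylogeny")
    return missing


# ---------------------------------------------------------------------------
# writing


def _fmt_float(v) -> str:
    """Shortest round-tripping decimal repr (numpy scalars included)."""
    return repr(float(v))


def write_plot(plot: PlotDataset, directory) -> dict[str, str]:
    """Write adults/seedlings/quadrats/habitat CSVs into ``directory``.

    Floats are written with Python's shortest round-tripping repr so that
    ``read_plot(write_plot(x)) == x`` field for field.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "adults": os.path.join(directory, "adults.csv"),
        "seedlings": os.path.join(directory, "seedlings.csv"),
        "quadrats": os.path.join(directory, "quadrats.csv"),
        "habitat": os.path.join(directory, "habitat.csv"),
    }

    pd.DataFrame(
        {
            "tag": [a.tag for a in plot.adults],
            "species": [a.species for a in plot.adults],
            "x": [a.x for a in plot.adults],
            "y": [a.y for a in plot.adults],
            "dbh": [a.dbh for a in plot.adults],
        }
    ).to_csv(paths["adults"], index=False, float_format=_fmt_float)

    rows = []
    for s in plot.seedlings:
        row: dict[str, object] = {
            "tag": s.tag,
            "quadrat_id": s.quadrat_id,
            "species": s.species,
        }
        for y in plot.census_years:
            row[f"status_{y}"] = s.status[y]
            hy = s.height.get(y, math.nan)
            row[f"height_{y}"] = hy if not math.isnan(hy) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["seedlings"], index=False)

    pd.DataFrame(
        {
            "quadrat_id": [q.quadrat_id for q in plot.quadrats],
            "subplot_row": [q.subplot_row for q in plot.quadrats],
            "subplot_col": [q.subplot_col for q in plot.quadrats],
            "center_x": [q.center_x for q in plot.quadrats],
            "center_y": [q.center_y for q in plot.quadrats],
            **{
                f"elev_c{i + 1}": [q.corner_elevations[i] for q in plot.quadrats]
                for i in range(4)
            },
        }
    ).to_csv(paths["quadrats"], index=False, float_format=_fmt_float)

    plot.habitat.to_csv(paths["habitat"], index=False, float_format=_fmt_float)
    return paths
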