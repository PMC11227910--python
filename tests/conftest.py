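import numpy as np
import pandas as pd
import pytest

from pnb.io_core import PlotDataset, Quadrat, SeedlingRecord, AdultRecord
from pnb.phylogeny import patristic_matrix, read_newick
from pnb.synthetic import SimConfig, simulate

TOY_NEWICK = "((A:1,B:1):2,(C:1.5,D:0.5):1);"


@pytest.fixture(scope="session")
def toy_phylo():
    return read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def toy_dmat(toy_phylo):
    return patristic_matrix(toy_phylo)


@pytest.fixture(scope="session")
def small_sim():
    """Small plot (25 quadrats, 3 censuses) shared across read-only tests."""
    cfg = SimConfig(
        seed=7,
        extent=(100.0, 100.0),
        n_species_adult=20,
        n_species_seedling=12,
        n_adults=400,
        n_seedlings=160,
        census_years=(2020, 2021, 2022),
        n_null=49,
    )
    plot, phylo, truth = simulate(cfg)
    return cfg, plot, phylo, truth


@pytest.fixture(scope="session")
def medium_sim():
    """Full-extent plot (100 quadrats) for spatial-scale geometry tests."""
    cfg = SimConfig(
        seed=11,
        extent=(200.0, 200.0),
        n_species_adult=30,
        n_species_seedling=18,
        n_adults=1200,
        n_seedlings=400,
        census_years=(2020, 2021),
        n_null=29,
    )
    plot, phylo, truth = simulate(cfg)
    return cfg, plot, phylo, truth


def make_manual_plot(
    adults=(),
    seedlings=(),
    quadrats=None,
    census_years=(2020, 2021),
    extent=(100.0, 100.0),
):
    """Hand-built plot for targeted neighborhood/model tests."""
    if quadrats is None:
        quadrats = [
            Quadrat("q00", 0, 0, 17.0, 17.0, np.zeros(4)),
            Quadrat("q01", 0, 1, 37.0, 17.0, np.zeros(4)),
        ]
    habitat = pd.DataFrame(
        {
            "quadrat_id": [q.quadrat_id for q in quadrats],
            **{
                v: np.linspace(1, 2, len(quadrats))
                for v in [
                    "ph", "ec", "c", "ap", "ak", "tn", "tp", "tk",
                    "soil_temp", "soil_moist", "gli",
                ]
            },
        }
    )
    return PlotDataset(
        adults=list(adults),
        seedlings=list(seedlings),
        quadrats=list(quadrats),
        habitat=habitat,
        census_years=list(census_years),
        extent=extent,
    )


def make_seedling(tag, quadrat_id, species, statuses, heights=None, years=(2020, 2021)):
    status = dict(zip(years, statuses))
    if heights is None:
        heights = {y: 30.0 for y, s in status.items() if s == "alive"}
    return SeedlingRecord(
        tag=tag, quadrat_id=quadrat_id, species=species, status=status,
        height=dict(heights),
    )


def make_adult(tag, species, x, y, dbh=10.0):
    return AdultRecord(tag=tag, species=species, x=x, y=y, dbh=dbh)
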