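"""Phylogenetic neighborhood indices and their null-model standardizations.

For a focal species ``f`` with heterospecific neighbor abundances
``{i: n_i}`` and patristic distances ``X_i = d(f, i)``:

* ``TOTPd = sum_i X_i * n_i``
* ``AVEPd = sum_i X_i * n_i / sum_i n_i``
* ``MINPd = min_i X_i``
* ``APd'  = (AVEPd - mean(AVEPd_null)) / SD(AVEPd_null)``
* ``NTPd' = (MINPd - mean(MINPd_null)) / SD(MINPd_null)``

The null shuffles species labels across the full tip pool of the supplied
tree (999 draws by default), holding the profile's abundance structure and
the focal's identity slot fixed. Both null statistics are recomputed from
the same permutation draws (paired nulls). The observed value is not added
to the null distribution, and SD_null is the sample (n-1) standard
deviation. SES values are undefined (NaN) for empty profiles or when
SD_null = 0.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import PlotDataset, SeedlingRecord
from .neighborhood import (
    DEFAULT_D_FLOOR,
    DEFAULT_RADIUS,
    NeighborhoodContext,
    NeighborProfile,
)
from .phylogeny import DistanceMatrix

__all__ = [
    "PhyloIndexSet",
    "totpd",
    "avepd",
    "minpd",
    "ses",
    "null_moments",
    "index_set",
    "compute_covariate_table",
    "derive_rng",
]

DEFAULT_N_NULL = 999

INDEX_COLUMNS = [
    "totpd",
    "avepd",
    "minpd",
    "apd_prime",
    "ntpd_prime",
    "null_mean_ave",
    "null_sd_ave",
    "null_mean_min",
    "null_sd_min",
    "n_null",
]


@dataclass
class PhyloIndexSet:
    """The four indices plus null diagnostics for one focal x layer x census."""

    totpd: float
    avepd: float
    minpd: float
    apd_prime: float
    ntpd_prime: float
    n_null: int
    null_mean_ave: float
    null_sd_ave: float
    null_mean_min: float
    null_sd_min: float

    @property
    def empty(self) -> bool:
        return math.isnan(self.totpd)


def _profile_arrays(
    profile: NeighborProfile, dmat: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(distances to focal, abundance weights) in a stable species order."""
    species = sorted(profile.abundance)
    f = dmat.index(profile.focal_species)
    dists = np.array([dmat.d[f, dmat.index(s)] for s in species], dtype=float)
    weights = np.array([profile.abundance[s] for s in species], dtype=float)
    return dists, weights


def totpd(profile: NeighborProfile, dmat: DistanceMatrix) -> float:
    """Abundance-weighted total patristic distance; NaN for an empty profile.

    Accumulated in sorted species order with plain scalar arithmetic so the
    result is bit-identical to a naive loop (profiles are small).
    """
    if profile.empty:
        return math.nan
    f = dmat.index(profile.focal_species)
    total = 0.0
    for s in sorted(profile.abundance):
        total += float(dmat.d[f, dmat.index(s)]) * profile.abundance[s]
    return total


def avepd(profile: NeighborProfile, dmat: DistanceMatrix) -> float:
    """Abundance-weighted mean patristic distance; NaN for an empty profile."""
    if profile.empty:
        return math.nan
    return totpd(profile, dmat) / profile.total


def minpd(profile: NeighborProfile, dmat: DistanceMatrix) -> float:
    """Minimum patristic distance to any heterospecific neighbor; NaN if empty."""
    if profile.empty:
        return math.nan
    f = dmat.index(profile.focal_species)
    return min(float(dmat.d[f, dmat.index(s)]) for s in profile.abundance)


def _null_draws(
    profile: NeighborProfile,
    dmat: DistanceMatrix,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (AVEPd, MINPd) values under ``n_null`` label permutations.

    Each draw permutes the full label pool; the focal slot and each neighbor
    species slot are re-read through the permutation, so the draw equals the
    observed statistic computed on a relabeled tree.
    """
    species = sorted(profile.abundance)
    pos = np.array(
        [dmat.index(profile.focal_species)] + [dmat.index(s) for s in species],
        dtype=int,
    )
    w = np.array([profile.abundance[s] for s in species], dtype=float)
    S = dmat.n
    perms = rng.permuted(
        np.broadcast_to(np.arange(S), (n_null, S)).copy(), axis=1
    )
    mapped = perms[:, pos]  # (n_null, 1 + k)
    D = dmat.d[mapped[:, :1], mapped[:, 1:]]  # (n_null, k)
    ave = D @ w / w.sum()
    mn = D.min(axis=1)
    return ave, mn


def null_moments(
    statistic: str,
    profile: NeighborProfile,
    dmat: DistanceMatrix,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(mean, sample SD) of the null distribution of ``avepd`` or ``minpd``."""
    if statistic not in ("avepd", "minpd"):
        raise ValueError(f"unknown statistic {statistic!r}")
    ave, mn = _null_draws(profile, dmat, n_null, rng)
    vals = ave if statistic == "avepd" else mn
    return float(vals.mean()), float(vals.std(ddof=1))


def ses(
    statistic: str,
    profile: NeighborProfile,
    dmat: DistanceMatrix,
    n_null: int = DEFAULT_N_NULL,
    rng: np.random.Generator | None = None,
) -> float:
    """Standardized effect size of AVEPd or MINPd against the permutation null.

    Returns NaN when the profile is empty or the null SD is zero.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    if profile.empty:
        return math.nan
    if rng is None:
        raise ValueError("rng must be provided (seeded) for reproducibility")
    obs = avepd(profile, dmat) if statistic == "avepd" else minpd(profile, dmat)
    mean, sd = null_moments(statistic, profile, dmat, n_null, rng)
    if sd == 0.0:
        return math.nan
    return (obs - mean) / sd


def _empty_index_set(n_null: int) -> PhyloIndexSet:
    nan = math.nan
    return PhyloIndexSet(nan, nan, nan, nan, nan, n_null, nan, nan, nan, nan)


def _index_set_for_profile(
    profile: NeighborProfile,
    dmat: DistanceMatrix,
    n_null: int,
    rng: np.random.Generator,
) -> PhyloIndexSet:
    if profile.empty:
        return _empty_index_set(n_null)
    tot = totpd(profile, dmat)
    ave = avepd(profile, dmat)
    mn = minpd(profile, dmat)
    null_ave, null_min = _null_draws(profile, dmat, n_null, rng)
    m_ave, s_ave = float(null_ave.mean()), float(null_ave.std(ddof=1))
    m_min, s_min = float(null_min.mean()), float(null_min.std(ddof=1))
    apd = (ave - m_ave) / s_ave if s_ave > 0 else math.nan
    ntpd = (mn - m_min) / s_min if s_min > 0 else math.nan
    return PhyloIndexSet(
        totpd=tot,
        avepd=ave,
        minpd=mn,
        apd_prime=apd,
        ntpd_prime=ntpd,
        n_null=n_null,
        null_mean_ave=m_ave,
        null_sd_ave=s_ave,
        null_mean_min=m_min,
        null_sd_min=s_min,
    )


def derive_rng(master_seed: int, tag: str, layer: str, year: int) -> np.random.Generator:
    """Deterministic per-(focal, layer, census) stream from a master seed.

    Uses a stable byte hash of the key so the stream does not depend on
    Python's randomized ``hash()`` or on evaluation order.
    """
    key = f"{tag}|{layer}|{year}".encode()
    h = int.from_bytes(hashlib.blake2s(key, digest_size=8).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


def index_set(
    focal: SeedlingRecord,
    plot: PlotDataset,
    dmat: DistanceMatrix,
    census_year: int,
    n_null: int = DEFAULT_N_NULL,
    master_seed: int = 0,
    ctx: NeighborhoodContext | None = None,
) -> tuple[PhyloIndexSet, PhyloIndexSet]:
    """All four indices with null diagnostics for both layers of one focal.

    Deterministic given ``master_seed``: each (tag, layer, year) evaluation
    draws from its own derived stream.
    """
    if ctx is None:
        ctx = NeighborhoodContext(plot)
    prof_seed, prof_adult = ctx.profiles(focal, census_year)
    out = []
    for layer, prof in (("seedling", prof_seed), ("adult", prof_adult)):
        rng = derive_rng(master_seed, focal.tag, layer, census_year)
        out.append(_index_set_for_profile(prof, dmat, n_null, rng))
    return out[0], out[1]


def compute_covariate_table(
    plot: PlotDataset,
    dmat: DistanceMatrix,
    years,
    master_seed: int = 0,
    n_null: int = DEFAULT_N_NULL,
    radius_m: float = DEFAULT_RADIUS,
    d_floor: float = DEFAULT_D_FLOOR,
) -> pd.DataFrame:
    """Per-(focal, census) covariates for every alive seedling: density + indices.

    One row per alive focal per requested census year, with ``s_con``/``a_con``
    and, per layer prefix ``s_``/``a_``, the four phylogenetic indices and
    their null diagnostics. This is the table the model module consumes and
    the ``indices.csv`` CLI output.
    """
    ctx = NeighborhoodContext(plot, radius_m=radius_m, d_floor=d_floor)
    rows = []
    for focal in plot.seedlings:
        for year in years:
            if not focal.is_alive(year):
                continue
            dv = ctx.density_vars(focal, year)
            set_seed, set_adult = index_set(
                focal,
                plot,
                dmat,
                year,
                n_null=n_null,
                master_seed=master_seed,
                ctx=ctx,
            )
            row: dict[str, object] = {
                "tag": focal.tag,
                "species": focal.species,
                "quadrat_id": focal.quadrat_id,
                "year": year,
                "height": focal.height.get(year, math.nan),
                "s_con": dv.s_con,
                "a_con": dv.a_con,
            }
            for prefix, iset in (("s", set_seed), ("a", set_adult)):
                row[f"{prefix}_totpd"] = iset.totpd
                row[f"{prefix}_avepd"] = iset.avepd
                row[f"{prefix}_minpd"] = iset.minpd
                row[f"{prefix}_apd"] = iset.apd_prime
                row[f"{prefix}_ntpd"] = iset.ntpd_prime
                row[f"{prefix}_null_mean_ave"] = iset.null_mean_ave
                row[f"{prefix}_null_sd_ave"] = iset.null_sd_ave
                row[f"{prefix}_null_mean_min"] = iset.null_mean_min
                row[f"{prefix}_null_sd_min"] = iset.null_sd_min
            row["n_null"] = n_null
            rows.append(row)
    return pd.DataFrame(rows)
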