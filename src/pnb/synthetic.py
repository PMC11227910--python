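"""Synthetic forest-plot generator with known ground truth.

Produces a complete input set — stem-mapped adults, quadrat seedling
censuses, habitat table, ultrametric phylogeny — whose statistical structure
matches what the analysis assumes:

* pure-birth ultrametric tree over the species pool, scaled to a fixed depth;
* log-series species abundances, Thomas cluster process stem maps,
  lognormal dbh (truncated at the 1 cm census threshold);
* smooth elevation surface plus soil variables built as linear mixtures of
  three latent spatial factors (low-rank PCA structure by construction) and
  lognormal canopy openness;
* seedlings placed in quadrats with species drawn preferentially from
  nearby adults (dispersal kernel), so conspecific density and phylogenetic
  index covariates have realistic nonzero variance;
* survival simulated per 1-year census step from
  ``logit p = beta0 + sum_j beta_j x_j + u_quadrat + v_species`` where the
  ``x_j`` are the *same standardized covariates the model module builds*
  (the generator literally calls that code), so the fitted model is
  correctly specified under the default configuration. Death is absorbing;
  multi-year outcomes emerge as products of yearly draws.

Everything is deterministic given ``SimConfig.seed``. Null permutations
inside covariate computation use a separate derived seed stream so data
generation and index computation are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import habitat as habitat_mod
from . import indices as indices_mod
from . import model as model_mod
from .io_core import (
    STATUS_ALIVE,
    STATUS_DEAD,
    STATUS_UNRECRUITED,
    AdultRecord,
    PlotDataset,
    Quadrat,
    SeedlingRecord,
    quadrat_center,
    write_plot,
)
from .phylogeny import Phylogeny, read_newick, to_newick

__all__ = ["SimConfig", "GroundTruth", "simulate", "covariate_effect_check", "write_simulation"]


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    seed: int = 0
    extent: tuple[float, float] = (200.0, 200.0)
    n_species_adult: int = 95
    n_species_seedling: int = 56
    n_adults: int = 10546
    n_seedlings: int = 900
    census_years: tuple[int, ...] = (2020, 2021, 2022, 2023)
    tree_depth: float = 200.0
    logseries_p: float = 0.98
    thomas_parents_mean: float = 8.0
    thomas_cluster_sd: float = 20.0
    dbh_meanlog: float = 1.3
    dbh_sdlog: float = 0.7
    recruit_rate: float = 0.03
    dispersal_kappa: float = 0.5
    n_null: int = 199
    radius_m: float = 20.0
    d_floor: float = 0.1
    index_variant: str = "apd"
    beta0: float = 1.5
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "s_con": -0.2,
            "s_apd": 0.3,
            "light": 0.3,
            "pca2": -0.2,
        }
    )
    sigma_q: float = 0.5
    sigma_s: float = 0.5

    def __post_init__(self) -> None:
        if self.n_species_adult < 2 or self.n_species_seedling < 2:
            raise ConfigError("need at least 2 species in each pool")
        if self.n_species_seedling > self.n_species_adult:
            raise ConfigError("seedling species pool must be a subset of the adult pool")
        if self.n_adults < 1 or self.n_seedlings < 1:
            raise ConfigError("counts must be positive")
        if self.sigma_q < 0 or self.sigma_s < 0:
            raise ConfigError("random-effect SDs must be >= 0")
        if len(self.census_years) < 2:
            raise ConfigError("need at least 2 census years")
        known = set(model_mod.fixed_effect_names(self.index_variant))
        unknown = set(self.beta) - known
        if unknown:
            raise ConfigError(
                f"beta names {sorted(unknown)} are not covariates of the "
                f"{self.index_variant!r} model ({sorted(known)})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("extent", "census_years"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["extent"] = list(self.extent)
        data["census_years"] = list(self.census_years)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    beta0: float
    beta: dict[str, float]
    sigma_q: float
    sigma_s: float
    quadrat_effects: dict[str, float]
    species_effects: dict[str, float]
    survival_probs: pd.DataFrame  # tag, start_year, end_year, prob

    def to_json(self, path) -> None:
        payload = {
            "beta0": self.beta0,
            "beta": self.beta,
            "sigma_q": self.sigma_q,
            "sigma_s": self.sigma_s,
            "quadrat_effects": self.quadrat_effects,
            "species_effects": self.species_effects,
            "survival_probs": self.survival_probs.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# tree simulation


def covariate_null_seed(config: SimConfig) -> int:
    """Base seed of the null-permutation stream the generator's covariates use.

    Passing ``covariate_null_seed(cfg) + start_year`` as the master seed to
    :func:`pnb.indices.compute_covariate_table` reproduces the exact SES
    values the survival generator consumed for that census step.
    """
    return int(
        np.random.SeedSequence([config.seed, 0x6E756C6C]).generate_state(1)[0]
    )


class _Node:
    __slots__ = ("birth", "split", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.split: float | None = None
        self.children: list["_Node"] = []
        self.label: str | None = None


def yule_newick(labels: list[str], rng: np.random.Generator, depth: float) -> str:
    """Ultrametric pure-birth tree over ``labels``, scaled to root-tip ``depth``."""
    n = len(labels)
    root = _Node(0.0)
    t = 0.0
    active = [root]
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.split = t
        kids = [_Node(t), _Node(t)]
        node.children = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / n)
    order = rng.permutation(n)
    for node, k in zip(active, order):
        node.label = labels[int(k)]
    scale = depth / t_end if t_end > 0 else 1.0

    def emit(node: _Node) -> str:
        end = node.split if node.children else t_end
        length = (end - node.birth) * scale
        if node.children:
            inner = ",".join(emit(c) for c in node.children)
            return f"({inner}):{length:.10g}"
        return f"{node.label}:{length:.10g}"

    inner = ",".join(emit(c) for c in root.children) if root.children else labels[0]
    return f"({inner});"


# ---------------------------------------------------------------------------
# spatial fields


def _smooth_field(rng: np.random.Generator, extent, n_bumps=6, amp=8.0, base=0.0,
                  gradient=(0.0, 0.0)):
    """A low-order polynomial plus random Gaussian bumps, as a callable f(x, y)."""
    w, h = extent
    centers = rng.uniform([0, 0], [w, h], size=(n_bumps, 2))
    amps = rng.uniform(-amp, amp, size=n_bumps)
    sds = rng.uniform(0.15 * min(w, h), 0.4 * min(w, h), size=n_bumps)
    gx, gy = gradient

    def f(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        val = base + gx * x + gy * y
        for (cx, cy), a, s in zip(centers, amps, sds):
            val = val + a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s**2))
        return val

    return f


_SOIL_UNITS = {  # plausible measurement-scale means and spreads
    "ph": (5.2, 0.4),
    "ec": (120.0, 30.0),
    "c": (45.0, 12.0),
    "ap": (8.0, 2.5),
    "ak": (90.0, 25.0),
    "tn": (2.5, 0.6),
    "tp": (0.5, 0.15),
    "tk": (12.0, 3.0),
    "soil_temp": (14.0, 1.5),
    "soil_moist": (30.0, 8.0),
}


# ---------------------------------------------------------------------------
# main generator


def simulate(config: SimConfig) -> tuple[PlotDataset, Phylogeny, GroundTruth]:
    """Generate a full synthetic dataset with stored ground truth."""
    ss = np.random.SeedSequence(config.seed)
    (
        rng_tree,
        rng_abund,
        rng_space,
        rng_hab,
        rng_seedling,
        rng_effects,
        rng_survival,
    ) = [np.random.default_rng(s) for s in ss.spawn(7)]
    # null permutations use an independent derived stream
    null_seed = covariate_null_seed(config)

    w, h = config.extent
    species = [f"sp{i + 1:03d}" for i in range(config.n_species_adult)]
    newick = yule_newick(species, rng_tree, config.tree_depth)
    phylo = read_newick(newick)
    from .phylogeny import patristic_matrix

    dmat = patristic_matrix(phylo)

    # --- adults -----------------------------------------------------------
    from scipy.stats import logser

    raw = logser.rvs(
        config.logseries_p,
        size=config.n_species_adult,
        random_state=np.random.RandomState(int(rng_abund.integers(2**31 - 1))),
    ).astype(float)
    probs = raw / raw.sum()
    counts = rng_abund.multinomial(
        max(config.n_adults - config.n_species_adult, 0), probs
    ) + 1

    adults: list[AdultRecord] = []
    tag_i = 0
    for sp, cnt in zip(species, counts):
        n_par = 1 + rng_space.poisson(config.thomas_parents_mean)
        parents = rng_space.uniform([0, 0], [w, h], size=(n_par, 2))
        picks = rng_space.integers(0, n_par, size=cnt)
        pos = parents[picks] + rng_space.normal(
            0.0, config.thomas_cluster_sd, size=(cnt, 2)
        )
        pos = np.clip(pos, [0, 0], [w, h])
        dbh = np.maximum(
            rng_space.lognormal(config.dbh_meanlog, config.dbh_sdlog, size=cnt), 1.0
        )
        for (x, y), d in zip(pos, dbh):
            tag_i += 1
            adults.append(
                AdultRecord(
                    tag=f"ad{tag_i:05d}", species=sp, x=float(x), y=float(y),
                    dbh=float(d),
                )
            )

    # --- quadrats + habitat ----------------------------------------------
    n_rows = int(round(h / 20.0))
    n_cols = int(round(w / 20.0))
    elev_f = _smooth_field(
        rng_hab, config.extent, n_bumps=6, amp=10.0, base=2200.0,
        gradient=(0.35, 0.1),
    )
    quadrats: list[Quadrat] = []
    for r in range(n_rows):
        for c in range(n_cols):
            cx, cy = quadrat_center(r, c, extent=config.extent)
            x0, y0 = 20.0 * c, 20.0 * r
            corners = np.array(
                [
                    elev_f(x0, y0),
                    elev_f(x0 + 20, y0),
                    elev_f(x0 + 20, y0 + 20),
                    elev_f(x0, y0 + 20),
                ],
                dtype=float,
            )
            quadrats.append(
                Quadrat(
                    quadrat_id=f"q{r:02d}{c:02d}",
                    subplot_row=r,
                    subplot_col=c,
                    center_x=cx,
                    center_y=cy,
                    corner_elevations=corners,
                )
            )

    centers = np.array([[q.center_x, q.center_y] for q in quadrats])
    factors = []
    for _ in range(3):
        f = _smooth_field(rng_hab, config.extent, n_bumps=5, amp=1.0)
        vals = f(centers[:, 0], centers[:, 1])
        factors.append((vals - vals.mean()) / (vals.std() + 1e-12))
    F = np.column_stack(factors)  # (n_quadrats, 3)
    loadings = rng_hab.uniform(-1.0, 1.0, size=(len(_SOIL_UNITS), 3))
    noise_sd = 0.35
    hab_rows = {"quadrat_id": [q.quadrat_id for q in quadrats]}
    for k, (var, (mu, sc)) in enumerate(_SOIL_UNITS.items()):
        raw_v = F @ loadings[k] + noise_sd * rng_hab.normal(size=len(quadrats))
        hab_rows[var] = mu + sc * raw_v / math.sqrt(1 + noise_sd**2)
    hab_rows["gli"] = np.exp(rng_hab.normal(2.3, 0.4, size=len(quadrats)))
    habitat_df = pd.DataFrame(hab_rows)

    # --- seedlings --------------------------------------------------------
    seedling_order = np.argsort(-counts, kind="stable")[: config.n_species_seedling]
    seedling_pool = [species[i] for i in sorted(seedling_order)]
    pool_set = set(seedling_pool)

    adult_xy = np.array([[a.x, a.y] for a in adults])
    adult_sp = np.array([a.species for a in adults], dtype=object)
    from scipy.spatial import cKDTree

    kdt = cKDTree(adult_xy)

    def local_species_probs(center) -> np.ndarray:
        near = kdt.query_ball_point(center, config.radius_m)
        local = pd.Series(adult_sp[near]).value_counts() if near else pd.Series(dtype=int)
        weights = np.array(
            [local.get(sp, 0) + config.dispersal_kappa for sp in seedling_pool],
            dtype=float,
        )
        return weights / weights.sum()

    years = list(config.census_years)
    first = years[0]
    seedlings: list[SeedlingRecord] = []
    per_quadrat = config.n_seedlings / len(quadrats)
    tag_i = 0
    for q in quadrats:
        n_here = rng_seedling.poisson(per_quadrat)
        if n_here == 0:
            continue
        p_sp = local_species_probs((q.center_x, q.center_y))
        picks = rng_seedling.choice(len(seedling_pool), size=n_here, p=p_sp)
        for k in picks:
            tag_i += 1
            h0 = 20.0 + float(rng_seedling.lognormal(2.5, 0.6))
            seedlings.append(
                SeedlingRecord(
                    tag=f"sdl{tag_i:05d}",
                    quadrat_id=q.quadrat_id,
                    species=seedling_pool[int(k)],
                    status={first: STATUS_ALIVE},
                    height={first: h0},
                )
            )
    if not seedlings:
        raise ConfigError("configuration produced zero seedlings")

    plot = PlotDataset(
        adults=adults,
        seedlings=seedlings,
        quadrats=quadrats,
        habitat=habitat_df,
        census_years=years,
        extent=config.extent,
    )

    # --- random effects ---------------------------------------------------
    u_q = {
        q.quadrat_id: float(config.sigma_q * rng_effects.normal())
        for q in quadrats
    }
    v_s = {sp: float(config.sigma_s * rng_effects.normal()) for sp in seedling_pool}

    pca = habitat_mod.habitat_pca(habitat_mod.assemble_habitat(plot))

    # --- survival, census step by census step -----------------------------
    prob_rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        # provisional: everyone alive at y0 survives to y1 (overwritten below)
        for s in seedlings:
            if s.status.get(y0) == STATUS_ALIVE:
                s.status[y1] = STATUS_ALIVE
                s.height[y1] = s.height[y0]
            elif s.status.get(y0) == STATUS_DEAD:
                s.status[y1] = STATUS_DEAD
            elif y0 in s.status:
                s.status[y1] = s.status[y0]

        cov = indices_mod.compute_covariate_table(
            plot,
            dmat,
            [y0],
            master_seed=null_seed + y0,
            n_null=config.n_null,
            radius_m=config.radius_m,
            d_floor=config.d_floor,
        )
        ds = model_mod.build_dataset(
            plot, cov, pca.scores, (y0, y1), None, config.index_variant
        )
        X, terms = ds.design_matrix()
        beta_vec = np.array(
            [config.beta0]
            + [config.beta.get(t, 0.0) for t in terms[1:]],
            dtype=float,
        )
        eta_fixed = dict(zip(ds.df["tag"], X @ beta_vec))

        for s in seedlings:
            if s.status.get(y0) != STATUS_ALIVE:
                continue
            eta = eta_fixed.get(s.tag, config.beta0)  # dropped rows: intercept only
            eta += u_q[s.quadrat_id] + v_s[s.species]
            prob = 1.0 / (1.0 + math.exp(-eta))
            alive = rng_survival.random() < prob
            prob_rows.append(
                {"tag": s.tag, "start_year": y0, "end_year": y1, "prob": prob}
            )
            if alive:
                s.status[y1] = STATUS_ALIVE
                s.height[y1] = s.height[y0] * float(
                    rng_survival.lognormal(0.1, 0.05)
                )
            else:
                s.status[y1] = STATUS_DEAD
                s.height.pop(y1, None)

        # recruits appearing at y1
        n_new = rng_seedling.poisson(config.recruit_rate * config.n_seedlings)
        for _ in range(n_new):
            q = quadrats[int(rng_seedling.integers(len(quadrats)))]
            p_sp = local_species_probs((q.center_x, q.center_y))
            sp = seedling_pool[int(rng_seedling.choice(len(seedling_pool), p=p_sp))]
            tag_i += 1
            rec = SeedlingRecord(
                tag=f"sdl{tag_i:05d}",
                quadrat_id=q.quadrat_id,
                species=sp,
                status={yy: STATUS_UNRECRUITED for yy in years if yy < y1},
                height={},
            )
            rec.status[y1] = STATUS_ALIVE
            rec.height[y1] = 20.0 + float(rng_seedling.lognormal(2.5, 0.6))
            seedlings.append(rec)

    # complete status dicts across all censuses
    for s in seedlings:
        for y in years:
            s.status.setdefault(y, STATUS_UNRECRUITED)

    truth = GroundTruth(
        beta0=config.beta0,
        beta=dict(config.beta),
        sigma_q=config.sigma_q,
        sigma_s=config.sigma_s,
        quadrat_effects=u_q,
        species_effects=v_s,
        survival_probs=pd.DataFrame(prob_rows),
    )
    return plot, phylo, truth


def write_simulation(plot, phylo, truth, directory) -> dict[str, str]:
    """Write the full file set: plot CSVs plus tree.nwk and truth.json."""
    paths = write_plot(plot, directory)
    tree_path = os.path.join(directory, "tree.nwk")
    with open(tree_path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(phylo) + "\n")
    truth_path = os.path.join(directory, "truth.json")
    truth.to_json(truth_path)
    paths.update(tree=tree_path, truth=truth_path)
    return paths


def covariate_effect_check(
    config: SimConfig,
    n_reps: int,
    master_seed: int = 1,
    analysis_n_null: int | None = None,
) -> pd.DataFrame:
    """Simulate -> full pipeline -> fit, repeatedly; report recovery per coefficient.

    Returns one row per fixed-effect term with the true value, mean bias,
    RMSE, empirical 95% Wald CI coverage, sign-recovery rate, and the
    fraction of |z| >= 1.96. Failed fits are counted, not fatal.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    from .phylogeny import patristic_matrix

    records: dict[str, list[tuple[float, float]]] = {}
    n_failed = 0
    for rep in range(n_reps):
        cfg = dataclasses.replace(config, seed=master_seed + 7919 * rep)
        try:
            plot, phylo, truth = simulate(cfg)
            dmat = patristic_matrix(phylo)
            pca = habitat_mod.habitat_pca(habitat_mod.assemble_habitat(plot))
            y0, y1 = cfg.census_years[0], cfg.census_years[1]
            cov = indices_mod.compute_covariate_table(
                plot,
                dmat,
                [y0],
                master_seed=master_seed + rep,
                n_null=analysis_n_null or cfg.n_null,
                radius_m=cfg.radius_m,
                d_floor=cfg.d_floor,
            )
            ds = model_mod.build_dataset(
                plot, cov, pca.scores, (y0, y1), None, cfg.index_variant
            )
            fit = model_mod.fit_glmm(ds)
            if not fit.converged:
                n_failed += 1
                continue
        except Exception:
            n_failed += 1
            continue
        for term, est, se in zip(fit.terms, fit.estimates, fit.se):
            records.setdefault(term, []).append((float(est), float(se)))

    rows = []
    for term, pairs in records.items():
        est = np.array([p[0] for p in pairs])
        se = np.array([p[1] for p in pairs])
        truth_val = config.beta0 if term == "(Intercept)" else config.beta.get(term, 0.0)
        cover = np.mean(
            (est - 1.96 * se <= truth_val) & (truth_val <= est + 1.96 * se)
        )
        rows.append(
            {
                "term": term,
                "true": truth_val,
                "n_fits": len(pairs),
                "n_failed": n_failed,
                "mean_estimate": est.mean(),
                "bias": est.mean() - truth_val,
                "rmse": float(np.sqrt(np.mean((est - truth_val) ** 2))),
                "coverage_95": float(cover),
                "sign_recovery": float(np.mean(np.sign(est) == np.sign(truth_val)))
                if truth_val != 0
                else math.nan,
                "reject_rate": float(np.mean(np.abs(est / se) >= 1.96)),
            }
        )
    return pd.DataFrame(rows)
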