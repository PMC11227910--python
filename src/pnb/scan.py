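"""Factorial scan: index variants x temporal intervals x spatial windows.

For every (interval, window) cell the four index-variant models are fitted
and compared by AIC: delta_aic_i = aic_i - min(aic), models with
delta_aic <= 2 flagged valid, the minimum-AIC model flagged best (ties
resolved by variant order). Spatial windows truncate both the focal rows
and the neighbor pools, emulating a smaller plot; PCA scores are computed
once on the full plot and subset, never recomputed per window.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import habitat as habitat_mod
from . import indices as indices_mod
from . import model as model_mod
from .io_core import PlotDataset
from .phylogeny import DistanceMatrix

__all__ = [
    "TemporalDesign",
    "SpatialWindow",
    "ScanError",
    "ScanResult",
    "temporal_design",
    "default_windows",
    "spatial_subset",
    "delta_aic",
    "run_scan",
]

VALID_DELTA_AIC = 2.0


class ScanError(RuntimeError):
    """Raised when every cell of a scan fails."""


@dataclass
class SpatialWindow:
    label: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_range[0] <= x <= self.x_range[1]
            and self.y_range[0] <= y <= self.y_range[1]
        )


@dataclass
class TemporalDesign:
    intervals: list[tuple[int, int]]

    def by_span(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {}
        for s, e in self.intervals:
            out.setdefault(e - s, []).append((s, e))
        return out


def temporal_design(census_years, spans=(1, 2, 3)) -> TemporalDesign:
    """All (start, end) census pairs whose span (in census steps' years) is requested."""
    years = sorted(census_years)
    intervals = [
        (s, e)
        for i, s in enumerate(years)
        for e in years[i + 1 :]
        if (e - s) in spans
    ]
    if not intervals:
        raise ValueError("no intervals match the requested spans")
    return TemporalDesign(intervals=intervals)


def default_windows(
    extent: tuple[float, float] = (200.0, 200.0),
    labels=("1ha", "2ha", "4ha"),
) -> list[SpatialWindow]:
    """Nested SW-anchored windows: 1 ha = 100x100, 2 ha = 200x100, 4 ha = full."""
    presets = {
        "1ha": SpatialWindow("1ha", (0.0, 100.0), (0.0, 100.0)),
        "2ha": SpatialWindow("2ha", (0.0, 200.0), (0.0, 100.0)),
        "4ha": SpatialWindow("4ha", (0.0, extent[0]), (0.0, extent[1])),
    }
    return [presets[lab] for lab in labels]


def spatial_subset(
    plot: PlotDataset, window: SpatialWindow, truncate_neighbors: bool = True
) -> PlotDataset:
    """Restrict a plot to one window, emulating a smaller plot.

    Quadrats (and their seedlings) are kept when the quadrat center lies in
    the window. With ``truncate_neighbors`` (default) the adult pool is also
    clipped, so neighborhoods are recomputed within the truncated pool; the
    alternative keeps full-plot neighborhoods and subsets only focal rows.
    """
    keep_q = [q for q in plot.quadrats if window.contains(q.center_x, q.center_y)]
    if not keep_q:
        raise ScanError(f"window {window.label} contains no quadrat")
    qids = {q.quadrat_id for q in keep_q}
    seedlings = [copy.deepcopy(s) for s in plot.seedlings if s.quadrat_id in qids]
    adults = (
        [a for a in plot.adults if window.contains(a.x, a.y)]
        if truncate_neighbors
        else list(plot.adults)
    )
    habitat = plot.habitat[
        plot.habitat["quadrat_id"].astype(str).isin(qids)
    ].reset_index(drop=True)
    return PlotDataset(
        adults=adults,
        seedlings=seedlings,
        quadrats=[copy.deepcopy(q) for q in keep_q],
        habitat=habitat,
        census_years=list(plot.census_years),
        extent=plot.extent,
    )


def delta_aic(aics) -> np.ndarray:
    """delta_i = AIC_i - min(AIC)."""
    a = np.asarray(aics, dtype=float)
    return a - np.nanmin(a)


def _window_seed(master_seed: int, label: str) -> int:
    h = int.from_bytes(
        hashlib.blake2s(f"window|{label}".encode(), digest_size=6).digest(), "big"
    )
    return (int(master_seed) * 1_000_003 + h) % (2**63)


@dataclass
class ScanResult:
    comparison: pd.DataFrame
    effects: pd.DataFrame
    fits: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def run_scan(
    plot: PlotDataset,
    dmat: DistanceMatrix,
    master_seed: int = 0,
    n_null: int = indices_mod.DEFAULT_N_NULL,
    windows: list[SpatialWindow] | None = None,
    spans=(1, 2, 3),
    variants=model_mod.VARIANTS,
    radius_m: float = 20.0,
    d_floor: float = 0.1,
    truncate_neighbors: bool = True,
) -> ScanResult:
    """Run the full factorial analysis and assemble comparison/effect tables.

    Deterministic given ``master_seed``. Per-cell failures are recorded and
    skipped; only a fully failed scan raises :class:`ScanError`.
    """
    if windows is None:
        windows = default_windows(plot.extent)
    design = temporal_design(plot.census_years, spans=spans)
    start_years = sorted({s for s, _ in design.intervals})

    # PCA once on the full-plot habitat table; scores subset per window.
    full_hab = habitat_mod.assemble_habitat(plot)
    pca = habitat_mod.habitat_pca(full_hab)

    comparison_rows = []
    effect_rows = []
    fits: dict[tuple, model_mod.ModelFit] = {}
    failures: list[tuple] = []

    for window in windows:
        sub = spatial_subset(plot, window, truncate_neighbors=truncate_neighbors)
        cov = indices_mod.compute_covariate_table(
            sub,
            dmat,
            start_years,
            master_seed=_window_seed(master_seed, window.label),
            n_null=n_null,
            radius_m=radius_m,
            d_floor=d_floor,
        )
        for interval in design.intervals:
            cell_fits = {}
            for variant in variants:
                key = (interval, window.label, variant)
                try:
                    ds = model_mod.build_dataset(
                        sub, cov, pca.scores, interval, None, variant
                    )
                    fit = model_mod.fit_glmm(ds)
                except Exception as exc:  # record, keep scanning
                    failures.append((key, repr(exc)))
                    continue
                r2 = model_mod.conditional_r2(fit, ds)
                cell_fits[variant] = (fit, ds, r2)
                fits[key] = fit
            if not cell_fits:
                continue
            aics = {v: cf[0].aic for v, cf in cell_fits.items()}
            deltas = delta_aic(list(aics.values()))
            dmap = dict(zip(aics.keys(), deltas))
            best_variant = min(
                aics, key=lambda v: (aics[v], list(variants).index(v))
            )
            for variant, (fit, ds, r2) in cell_fits.items():
                comparison_rows.append(
                    {
                        "start_year": interval[0],
                        "end_year": interval[1],
                        "span": interval[1] - interval[0],
                        "window": window.label,
                        "variant": variant,
                        "aic": fit.aic,
                        "r2_conditional": r2,
                        "delta_aic": dmap[variant],
                        "valid": bool(dmap[variant] <= VALID_DELTA_AIC),
                        "best": variant == best_variant,
                        "n_obs": fit.n_obs,
                        "converged": fit.converged,
                    }
                )
                for term, est, se_, p_ in zip(
                    fit.terms, fit.estimates, fit.se, fit.pvalues
                ):
                    if term == "(Intercept)":
                        continue
                    band, sign = model_mod.classify_effect(float(p_), float(est))
                    effect_rows.append(
                        {
                            "start_year": interval[0],
                            "end_year": interval[1],
                            "window": window.label,
                            "variant": variant,
                            "term": term,
                            "estimate": float(est),
                            "se": float(se_),
                            "p": float(p_),
                            "class": band,
                            "sign": sign,
                        }
                    )

    if not comparison_rows:
        raise ScanError(f"every scan cell failed: {failures}")
    comparison = pd.DataFrame(comparison_rows).sort_values(
        ["window", "span", "start_year", "variant"], kind="stable"
    ).reset_index(drop=True)
    effects = pd.DataFrame(effect_rows).sort_values(
        ["window", "start_year", "end_year", "variant", "term"], kind="stable"
    ).reset_index(drop=True)
    return ScanResult(
        comparison=comparison, effects=effects, fits=fits, failures=failures
    )
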