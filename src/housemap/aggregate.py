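"""Population-weighted prevalence, head counts and between-year change.

Cell-level prevalence surfaces are aggregated to strata (country x
urban/rural/all) with per-cell population weights; head counts are expected
counts pop * mu and pop * (1 - mu).  When an ensemble of surfaces is
supplied, intervals come from recomputing each summary per ensemble member.
Cells whose surface value is missing are excluded from both numerator and
denominator, and their population is reported rather than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import RasterStack

__all__ = ["popweighted_prevalence", "people_counts", "change_summary"]

ALL_COUNTRIES = -1  # country code for the whole-grid stratum


def _strata(grid: RasterStack):
    pop = grid.layer("population").ravel()
    urban = grid.layer("urban").ravel().astype(bool)
    country = grid.layer("country").ravel().astype(int)
    if np.any(pop < 0):
        raise ValueError("population raster has negative cells")
    countries = [ALL_COUNTRIES, *sorted(np.unique(country))]
    for c in countries:
        cmask = np.ones_like(urban) if c == ALL_COUNTRIES else (country == c)
        for stratum, smask in (
            ("all", np.ones_like(urban)),
            ("urban", urban),
            ("rural", ~urban),
        ):
            yield c, stratum, cmask & smask, pop


def _check_surface(surface: np.ndarray, grid: RasterStack) -> np.ndarray:
    mu = np.asarray(surface, dtype=float)
    if mu.shape != grid.shape:
        raise ValueError(f"surface shape {mu.shape} does not match grid {grid.shape}")
    return mu.ravel()


def _stratum_rows(mu_flat, grid, year, members=None, ci=0.95):
    rows = []
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    for c, stratum, mask, pop in _strata(grid):
        valid = mask & ~np.isnan(mu_flat)
        p = pop[valid]
        excluded_pop = float(pop[mask & np.isnan(mu_flat)].sum())
        total = float(p.sum())
        row = {
            "country": c, "stratum": stratum, "year": year,
            "population": total, "excluded_population": excluded_pop,
        }
        if total == 0:
            row.update(prevalence=np.nan, improved=0.0, unimproved=0.0,
                       undefined=True)
        else:
            mu_s = mu_flat[valid]
            prev = float((p * mu_s).sum() / total)
            row.update(
                prevalence=prev,
                improved=float((p * mu_s).sum()),
                unimproved=float((p * (1 - mu_s)).sum()),
                undefined=False,
            )
            if members is not None:
                prevs = [float((p * m[valid]).sum() / total) for m in members]
                row["prevalence_lower"] = float(np.percentile(prevs, lo_q))
                row["prevalence_upper"] = float(np.percentile(prevs, hi_q))
                imps = [float((p * m[valid]).sum()) for m in members]
                row["improved_lower"] = float(np.percentile(imps, lo_q))
                row["improved_upper"] = float(np.percentile(imps, hi_q))
        rows.append(row)
    return pd.DataFrame(rows)


def popweighted_prevalence(
    surface: np.ndarray,
    grid: RasterStack,
    year=None,
    ensemble_surfaces: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-stratum population-weighted prevalence (and head counts).

    ``surface`` is a (ny, nx) prevalence array co-registered with ``grid``
    (which supplies population, the static urban/rural mask and country
    ids).  ``ensemble_surfaces`` adds 95% interval columns computed by
    recomputing the summary for each member surface.  A stratum with zero
    resolvable population is flagged ``undefined`` rather than propagating
    NaN arithmetic.
    """
    mu = _check_surface(surface, grid)
    members = (
        [_check_surface(m, grid) for m in ensemble_surfaces]
        if ensemble_surfaces is not None else None
    )
    return _stratum_rows(mu, grid, year, members)


def people_counts(
    surface: np.ndarray,
    grid: RasterStack,
    year=None,
    ensemble_surfaces: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Expected numbers of people in improved / unimproved housing per stratum."""
    df = popweighted_prevalence(surface, grid, year, ensemble_surfaces)
    cols = ["country", "stratum", "year", "population", "excluded_population",
            "improved", "unimproved", "undefined"]
    cols += [c for c in ("improved_lower", "improved_upper") if c in df.columns]
    return df[cols]


def change_summary(
    surface_y1: np.ndarray,
    surface_y2: np.ndarray,
    grid: RasterStack,
    years: tuple = (None, None),
    population_y1: np.ndarray | None = None,
    population_y2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Prevalence and head-count change between two years.

    Each year uses its own population raster (defaults to the grid's static
    layer); head-count change is the difference of expected counts, i.e.
    sum(pop2 * mu2) - sum(pop1 * mu1) per stratum.
    """

    def _with_pop(pop):
        if pop is None:
            return grid
        pop = np.asarray(pop, dtype=float)
        if pop.shape != grid.shape:
            raise ValueError("population raster does not match grid")
        ds = grid.data.copy()
        ds["population"] = (("y", "x"), pop)
        return RasterStack(ds)

    t1 = popweighted_prevalence(surface_y1, _with_pop(population_y1), years[0])
    t2 = popweighted_prevalence(surface_y2, _with_pop(population_y2), years[1])
    keys = ["country", "stratum"]
    merged = t1.merge(t2, on=keys, suffixes=("_1", "_2"))
    merged["prevalence_change"] = merged["prevalence_2"] - merged["prevalence_1"]
    merged["improved_change"] = merged["improved_2"] - merged["improved_1"]
    merged["unimproved_change"] = merged["unimproved_2"] - merged["unimproved_1"]
    return merged[keys + [
        "year_1", "year_2", "prevalence_1", "prevalence_2", "prevalence_change",
        "improved_1", "improved_2", "improved_change", "unimproved_change",
    ]]
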