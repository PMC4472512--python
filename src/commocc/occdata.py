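"""Canonical data model for roadside point-count monitoring.

A monitoring *route* is a string of equally spaced survey points partitioned
into *sites* (consecutive segments of ``points_per_site`` points).  For every
surveyed (route, year) each point yields a 0/1 detection record per species;
route–years that were never surveyed are missing, never zero.  Site-level
land-use/land-cover (LULC) covariates are proportions in [0, 1] per
(site, year); detection additionally depends on point-level forest cover.

This module owns the preprocessing rules the downstream model assumes:
route partitioning, LULC aggregation to sites, correlation screening of
covariates, the minimum-detections species filter, and coordinate centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OCC_COVARIATES",
    "SurveyDesign",
    "DetectionHistory",
    "SiteCovariates",
    "PointCovariates",
    "TableSchema",
    "partition_route",
    "read_detection_tables",
    "write_detection_tables",
    "read_site_covariates",
    "write_site_covariates",
    "read_point_covariates",
    "write_point_covariates",
    "aggregate_site_lulc",
    "screen_covariates",
    "filter_species",
    "center_coordinates",
]

#: Site-level occupancy covariates, in the order the linear predictor uses.
OCC_COVARIATES = ("lat", "long", "soy", "corn", "per_past", "forest")


@dataclass(frozen=True)
class SurveyDesign:
    """Which routes exist, how they are partitioned, and when they were run.

    Parameters
    ----------
    routes
        Ordered route identifiers.
    years
        Ordered season labels (e.g. calendar years).
    route_years
        The (route, year) pairs actually surveyed.  Designs are typically
        ragged: routes are added to the program over the years.
    points_per_route, points_per_site
        Survey geometry; ``points_per_route`` must be divisible by
        ``points_per_site``.
    """

    routes: tuple
    years: tuple
    route_years: frozenset
    points_per_route: int = 30
    points_per_site: int = 5

    def __post_init__(self):
        if self.points_per_route % self.points_per_site != 0:
            raise ValueError(
                f"points_per_route={self.points_per_route} is not divisible "
                f"by points_per_site={self.points_per_site}"
            )
        routes, years = set(self.routes), set(self.years)
        for r, t in self.route_years:
            if r not in routes or t not in years:
                raise ValueError(f"route_year ({r!r}, {t!r}) references an undeclared route or year")

    @property
    def sites_per_route(self) -> int:
        return self.points_per_route // self.points_per_site

    @property
    def n_sites(self) -> int:
        return len(self.routes) * self.sites_per_route

    @property
    def n_years(self) -> int:
        return len(self.years)

    def site_index(self) -> tuple:
        """Global site ordering: ``(route, segment)`` pairs, segment 0-based."""
        return tuple((r, s) for r in self.routes for s in range(self.sites_per_route))

    def surveyed_matrix(self) -> np.ndarray:
        """Boolean (n_sites, n_years) mask of surveyed site–years."""
        out = np.zeros((self.n_sites, self.n_years), dtype=bool)
        ridx = {r: i for i, r in enumerate(self.routes)}
        tidx = {t: i for i, t in enumerate(self.years)}
        spr = self.sites_per_route
        for r, t in self.route_years:
            i = ridx[r]
            out[i * spr:(i + 1) * spr, tidx[t]] = True
        return out


def partition_route(points_per_route: int, points_per_site: int) -> np.ndarray:
    """Map 1-based point numbers to 1-based site numbers along a route.

    Consecutive points are grouped in order: site ``s`` contains points
    ``(s-1)*k+1 … s*k`` for ``k = points_per_site``.

    Returns an integer array of length ``points_per_route`` where entry
    ``k-1`` is the site of point ``k``.
    """
    if points_per_route % points_per_site != 0:
        raise ValueError(
            f"points_per_route={points_per_route} is not divisible by "
            f"points_per_site={points_per_site}"
        )
    points = np.arange(points_per_route)
    return points // points_per_site + 1


@dataclass
class DetectionHistory:
    """Binary detections ``y`` over (site, point, species, year).

    ``y`` is a float array of shape (S, K, N, Y); non-missing cells are 0.0 or
    1.0 and unsurveyed route–years are NaN.  Missingness is constant across
    points and species within a (site, year): either a survey happened or it
    did not.
    """

    y: np.ndarray
    species: tuple
    design: SurveyDesign
    group: str = "all"

    def __post_init__(self):
        S, K, N, Y = self.y.shape
        if S != self.design.n_sites or K != self.design.points_per_site \
                or N != len(self.species) or Y != self.design.n_years:
            raise ValueError(
                f"y shape {self.y.shape} inconsistent with design "
                f"({self.design.n_sites}, {self.design.points_per_site}, "
                f"{len(self.species)}, {self.design.n_years})"
            )
        vals = self.y[~np.isnan(self.y)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise ValueError(f"non-binary detection value {bad!r} in detection history")

    @property
    def site_index(self) -> tuple:
        return self.design.site_index()

    @property
    def surveyed(self) -> np.ndarray:
        """(S, Y) mask derived from the array itself (NaN = unsurveyed)."""
        return ~np.isnan(self.y).all(axis=(1, 2))

    def total_detections(self) -> np.ndarray:
        """Per-species detection totals over all non-missing cells and years."""
        return np.nansum(self.y, axis=(0, 1, 3))

    def subset_species(self, keep: Sequence[str]) -> "DetectionHistory":
        idx = [self.species.index(s) for s in keep]
        return replace(self, y=self.y[:, :, idx, :], species=tuple(keep))


@dataclass
class SiteCovariates:
    """Per (site, year) covariates: centered coordinates + LULC proportions.

    Each field is an (S, Y) float array, NaN where the site–year is missing.
    Proportions lie in [0, 1] and the four LULC categories sum to at most 1
    (the remainder is unmodelled cover).
    """

    lat: np.ndarray
    long: np.ndarray
    soy: np.ndarray
    corn: np.ndarray
    per_past: np.ndarray
    forest: np.ndarray

    def __post_init__(self):
        shapes = {f: getattr(self, f).shape for f in OCC_COVARIATES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"covariate arrays disagree in shape: {shapes}")
        for f in ("soy", "corn", "per_past", "forest"):
            v = getattr(self, f)
            ok = np.isnan(v) | ((v >= 0) & (v <= 1))
            if not ok.all():
                raise ValueError(f"covariate {f} outside [0, 1]")
        total = self.soy + self.corn + self.per_past + self.forest
        if np.nanmax(total, initial=0.0) > 1 + 1e-9:
            raise ValueError("LULC proportions sum above 1 at some site-year")

    def stack(self, names: Sequence[str] = OCC_COVARIATES) -> np.ndarray:
        """(S, Y, C) stack of the named covariates in order."""
        return np.stack([getattr(self, n) for n in names], axis=-1)


@dataclass
class PointCovariates:
    """Point-level forest proportion, (S, K, Y), NaN where unsurveyed."""

    p_fors: np.ndarray

    def __post_init__(self):
        v = self.p_fors
        ok = np.isnan(v) | ((v >= 0) & (v <= 1))
        if not ok.all():
            raise ValueError("p_fors outside [0, 1]")


@dataclass(frozen=True)
class TableSchema:
    """Column names and geometry of the long-format monitoring tables.

    The package's canonical layout is one detection row per
    (route, point, year, species) actually surveyed; supplementary tables in
    other dialects are mapped by renaming columns here.
    """

    route: str = "route"
    point: str = "point"
    year: str = "year"
    species: str = "species"
    detection: str = "detection"
    site: str = "site"
    points_per_route: int = 30
    points_per_site: int = 5


def _read_concat(paths: Iterable) -> pd.DataFrame:
    frames = [pd.read_csv(Path(p)) for p in paths]
    return pd.concat(frames, ignore_index=True)


def read_detection_tables(paths: Sequence, schema: TableSchema | None = None,
                          group: str = "all") -> DetectionHistory:
    """Read long-format detection tables into a :class:`DetectionHistory`.

    Route–years absent from the tables are marked missing (NaN), not zero.
    Rejects non-binary detection values and duplicate
    (route, point, year, species) records, naming the offending rows.
    """
    schema = schema or TableSchema()
    df = _read_concat(paths)
    cols = [schema.route, schema.point, schema.year, schema.species, schema.detection]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"detection tables lack required columns {missing}")

    det = df[schema.detection]
    bad = ~det.isin((0, 1))
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"non-binary detection value {det[row]!r} at row {row} "
            f"(route={df.loc[row, schema.route]!r}, point={df.loc[row, schema.point]!r})"
        )
    key = [schema.route, schema.point, schema.year, schema.species]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df.index[dup][0]
        raise ValueError(f"duplicate detection record at row {row}: "
                         f"{df.loc[row, key].to_dict()}")

    routes = tuple(sorted(df[schema.route].unique()))
    years = tuple(sorted(df[schema.year].unique()))
    species = tuple(sorted(df[schema.species].unique()))
    route_years = frozenset(
        (r, t) for r, t in df[[schema.route, schema.year]].drop_duplicates().itertuples(index=False)
    )
    design = SurveyDesign(routes=routes, years=years, route_years=route_years,
                          points_per_route=schema.points_per_route,
                          points_per_site=schema.points_per_site)

    S, K, N, Y = design.n_sites, design.points_per_site, len(species), design.n_years
    y = np.full((S, K, N, Y), np.nan)
    surveyed = design.surveyed_matrix()
    # Surveyed cells default to 0; tables may list only the detections.
    y[surveyed[:, None, None, :] & np.ones((1, K, N, 1), dtype=bool)] = 0.0

    ridx = {r: i for i, r in enumerate(routes)}
    tidx = {t: i for i, t in enumerate(years)}
    sidx = {s: i for i, s in enumerate(species)}
    spr = design.sites_per_route
    site_of_point = partition_route(schema.points_per_route, schema.points_per_site)

    r = df[schema.route].map(ridx).to_numpy()
    pt = df[schema.point].to_numpy(dtype=int)
    if (pt < 1).any() or (pt > schema.points_per_route).any():
        raise ValueError("point numbers must lie in 1..points_per_route")
    j = r * spr + (site_of_point[pt - 1] - 1)
    k = (pt - 1) % schema.points_per_site
    i = df[schema.species].map(sidx).to_numpy()
    t = df[schema.year].map(tidx).to_numpy()
    y[j, k, i, t] = det.to_numpy(dtype=float)

    return DetectionHistory(y=y, species=species, design=design, group=group)


def write_detection_tables(history: DetectionHistory, path,
                           schema: TableSchema | None = None) -> pd.DataFrame:
    """Write the canonical long table (every non-missing cell) to CSV."""
    schema = schema or TableSchema()
    design = history.design
    k_site = design.points_per_site
    rows_j, rows_k, rows_i, rows_t = np.nonzero(~np.isnan(history.y))
    site_index = design.site_index()
    route = [site_index[j][0] for j in rows_j]
    point = [site_index[j][1] * k_site + k + 1 for j, k in zip(rows_j, rows_k)]
    df = pd.DataFrame({
        schema.route: route,
        schema.point: point,
        schema.year: [design.years[t] for t in rows_t],
        schema.species: [history.species[i] for i in rows_i],
        schema.detection: history.y[rows_j, rows_k, rows_i, rows_t].astype(int),
    })
    df.to_csv(path, index=False)
    return df


def write_site_covariates(cov: SiteCovariates, design: SurveyDesign, path,
                          schema: TableSchema | None = None) -> pd.DataFrame:
    schema = schema or TableSchema()
    site_index = design.site_index()
    rows = []
    surveyed = ~np.isnan(cov.lat)
    for j, (r, seg) in enumerate(site_index):
        for t, year in enumerate(design.years):
            if not surveyed[j, t]:
                continue
            rows.append({schema.route: r, schema.site: seg + 1, schema.year: year,
                         **{n: getattr(cov, n)[j, t] for n in OCC_COVARIATES}})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_site_covariates(path, design: SurveyDesign,
                         schema: TableSchema | None = None) -> SiteCovariates:
    schema = schema or TableSchema()
    df = pd.read_csv(path)
    shape = (design.n_sites, design.n_years)
    arrays = {n: np.full(shape, np.nan) for n in OCC_COVARIATES}
    ridx = {r: i for i, r in enumerate(design.routes)}
    tidx = {t: i for i, t in enumerate(design.years)}
    spr = design.sites_per_route
    j = df[schema.route].map(ridx).to_numpy() * spr + df[schema.site].to_numpy(dtype=int) - 1
    t = df[schema.year].map(tidx).to_numpy()
    for n in OCC_COVARIATES:
        arrays[n][j, t] = df[n].to_numpy(dtype=float)
    return SiteCovariates(**arrays)


def write_point_covariates(cov: PointCovariates, design: SurveyDesign, path,
                           schema: TableSchema | None = None) -> pd.DataFrame:
    schema = schema or TableSchema()
    site_index = design.site_index()
    k_site = design.points_per_site
    rows_j, rows_k, rows_t = np.nonzero(~np.isnan(cov.p_fors))
    df = pd.DataFrame({
        schema.route: [site_index[j][0] for j in rows_j],
        schema.point: [site_index[j][1] * k_site + k + 1 for j, k in zip(rows_j, rows_k)],
        schema.year: [design.years[t] for t in rows_t],
        "p_fors": cov.p_fors[rows_j, rows_k, rows_t],
    })
    df.to_csv(path, index=False)
    return df


def read_point_covariates(path, design: SurveyDesign,
                          schema: TableSchema | None = None) -> PointCovariates:
    schema = schema or TableSchema()
    df = pd.read_csv(path)
    shape = (design.n_sites, design.points_per_site, design.n_years)
    arr = np.full(shape, np.nan)
    ridx = {r: i for i, r in enumerate(design.routes)}
    tidx = {t: i for i, t in enumerate(design.years)}
    spr = design.sites_per_route
    site_of_point = partition_route(design.points_per_route, design.points_per_site)
    pt = df[schema.point].to_numpy(dtype=int)
    j = df[schema.route].map(ridx).to_numpy() * spr + site_of_point[pt - 1] - 1
    k = (pt - 1) % design.points_per_site
    t = df[schema.year].map(tidx).to_numpy()
    arr[j, k, t] = df["p_fors"].to_numpy(dtype=float)
    return PointCovariates(p_fors=arr)


def aggregate_site_lulc(point_props: np.ndarray) -> np.ndarray:
    """Aggregate per-point LULC proportions of one site–year to site level.

    ``point_props`` has shape (K, n_categories), each entry in [0, 1].  The
    site proportion of category c is the category's summed cover across points
    renormalized by the total classified cover of the site::

        site_c = sum_k prop[k, c] / sum_k sum_c' prop[k, c']

    When every point is fully classified this reduces to the per-point mean.
    If no point recorded any cover the site–year covariate is missing (NaN).
    """
    point_props = np.asarray(point_props, dtype=float)
    if point_props.ndim != 2:
        raise ValueError("point_props must be (n_points, n_categories)")
    if np.nanmin(point_props, initial=0) < 0 or np.nanmax(point_props, initial=0) > 1:
        raise ValueError("point proportions must lie in [0, 1]")
    total = np.nansum(point_props)
    if total <= 0:
        return np.full(point_props.shape[1], np.nan)
    return np.nansum(point_props, axis=0) / total


def screen_covariates(candidates: pd.DataFrame, r_threshold: float = 0.5,
                      representation: pd.Series | None = None):
    """Discard correlated covariates, keeping the better-represented one.

    For every pair with |Pearson r| > ``r_threshold`` the covariate with the
    greater mean representation (landscape cover) is kept.  Covariates with
    zero variance are discarded outright (their correlation is undefined).

    Returns ``(retained, report)`` where ``report`` is a DataFrame listing
    each discarded covariate with the reason and the triggering correlation.
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least two candidate covariates")
    if representation is None:
        representation = candidates.mean(skipna=True)
    report_rows = []

    live = []
    for name in candidates.columns:
        col = candidates[name].dropna()
        if col.nunique() <= 1:
            report_rows.append({"covariate": name, "reason": "zero variance",
                                "against": None, "r": np.nan})
        else:
            live.append(name)

    corr = candidates[live].corr(method="pearson")
    # Greedy in decreasing representation: order-independent for distinct means.
    order = sorted(live, key=lambda n: (-representation[n], n))
    retained = []
    for name in order:
        conflict = None
        for kept in retained:
            r = corr.loc[name, kept]
            if abs(r) > r_threshold:
                conflict = (kept, r)
                break
        if conflict is None:
            retained.append(name)
        else:
            report_rows.append({"covariate": name,
                                "reason": f"|r| > {r_threshold} with {conflict[0]}",
                                "against": conflict[0], "r": conflict[1]})
    retained = [n for n in candidates.columns if n in retained]
    report = pd.DataFrame(report_rows, columns=["covariate", "reason", "against", "r"])
    return retained, report


def filter_species(history: DetectionHistory, min_obs: int = 200) -> list:
    """Species with at least ``min_obs`` total detections across all years.

    The boundary is inclusive: a species with exactly ``min_obs`` detections
    is retained.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    totals = history.total_detections()
    return [s for s, n in zip(history.species, totals) if n >= min_obs]


def center_coordinates(raw: np.ndarray) -> np.ndarray:
    """Center a coordinate axis on zero over all non-missing site–years."""
    raw = np.asarray(raw, dtype=float)
    if np.isnan(raw).all():
        raise ValueError("cannot center an all-missing coordinate axis")
    return raw - np.nanmean(raw)
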