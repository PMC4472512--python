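"""Synthetic communities, landscapes and detection histories with known truth.

The generator runs the package's own model forward: a ragged multi-route
survey design, spatially patterned land-cover proportions, species-level
parameters drawn from community normal hyper-distributions, latent Bernoulli
occupancy states and Bernoulli point detections.  Because the truth is
retained, every downstream stage (fitting, diagnostics, summaries) can be
tested for recovery without any external data.

The landscape generator is deliberately simple — smooth low-order spatial
trends plus truncated noise, not a geostatistical model: the analysis only
needs covariate variation of a realistic magnitude and pattern (row crops
concentrated centrally, forest in one corner, pasture in the north), not
realistic rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityParams, inv_logit, N_OCC_COV
from .occdata import (DetectionHistory, PointCovariates, SiteCovariates,
                      SurveyDesign, center_coordinates)

__all__ = [
    "LandscapeGradient", "LandscapeSpec", "CommunityTruth", "TruthBundle",
    "default_design", "simulate_landscape", "simulate_community",
    "zero_effect_truth", "moderate_truth", "strong_effect_truth",
]


@dataclass(frozen=True)
class LandscapeGradient:
    """Spatial trend of one land-cover category's intensity.

    intensity = baseline + east*x + north*y + bump_amp * Gaussian bump,
    with coordinates on the centered unit square, plus N(0, noise_sd) noise
    per site-year, truncated at zero.
    """

    baseline: float = 0.2
    east: float = 0.0
    north: float = 0.0
    bump_amp: float = 0.0
    bump_center: tuple = (0.0, 0.0)
    bump_width: float = 0.5
    noise_sd: float = 0.05

    def __post_init__(self):
        if not np.isfinite([self.baseline, self.east, self.north, self.bump_amp,
                            self.bump_width]).all():
            raise ValueError("gradient parameters must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LandscapeSpec:
    """Gradients for the four modelled categories plus unclassified background.

    Defaults emulate the study region's broad patterns: soybean widespread
    and strongest centrally, native forest concentrated in one (north-east)
    corner, perennial pasture increasing northward, corn patchy.
    """

    soy: LandscapeGradient = LandscapeGradient(baseline=0.15, bump_amp=0.55,
                                               bump_center=(0.0, 0.0), bump_width=0.7,
                                               noise_sd=0.12)
    corn: LandscapeGradient = LandscapeGradient(baseline=0.10, noise_sd=0.15)
    per_past: LandscapeGradient = LandscapeGradient(baseline=0.10, north=0.20,
                                                    noise_sd=0.10)
    forest: LandscapeGradient = LandscapeGradient(baseline=0.02, bump_amp=0.65,
                                                  bump_center=(0.8, 0.8), bump_width=0.5,
                                                  noise_sd=0.08)
    #: unmodelled cover (other crops/pastures, urban, water) competing for area
    background: float = 0.25
    #: Beta concentration of point forest cover around the site value
    point_concentration: float = 25.0


def default_design(n_routes: int = 20, n_years: int = 3,
                   points_per_route: int = 30, points_per_site: int = 5,
                   ragged: bool = False) -> SurveyDesign:
    """A desk-scale survey design; ``ragged=True`` phases routes in over years
    the way a growing monitoring program does (first two thirds of the routes
    in year 1, all routes from the final third of the years on)."""
    routes = tuple(f"R{i + 1:03d}" for i in range(n_routes))
    years = tuple(range(2003, 2003 + n_years))
    if ragged and n_years > 1 and n_routes >= 3:
        cut = max(1, (2 * n_routes) // 3)
        ry = set()
        for t_i, t in enumerate(years):
            active = routes if t_i >= (n_years + 1) // 3 else routes[:cut]
            ry.update((r, t) for r in active)
        route_years = frozenset(ry)
    else:
        route_years = frozenset((r, t) for r in routes for t in years)
    return SurveyDesign(routes=routes, years=years, route_years=route_years,
                        points_per_route=points_per_route,
                        points_per_site=points_per_site)


def _site_positions(design: SurveyDesign, rng) -> tuple:
    """Lay routes on a jittered grid over the centered unit square; sites get
    a small along-route offset.  Returns (x_east, y_north) of shape (S,)."""
    n_routes = len(design.routes)
    side = int(np.ceil(np.sqrt(n_routes)))
    gx, gy = np.meshgrid(np.linspace(-1, 1, side), np.linspace(-1, 1, side))
    route_xy = np.stack([gx.ravel()[:n_routes], gy.ravel()[:n_routes]], axis=1)
    route_xy = route_xy + rng.uniform(-0.05, 0.05, size=route_xy.shape)
    spr = design.sites_per_route
    offsets = (np.arange(spr) - (spr - 1) / 2) / (spr * 4)
    x = (route_xy[:, 0:1] + offsets[None, :]).ravel()
    y = np.repeat(route_xy[:, 1], spr)
    return x, y


def simulate_landscape(design: SurveyDesign, spec: LandscapeSpec | None = None,
                       seed: int = 0):
    """Generate :class:`SiteCovariates` and :class:`PointCovariates`.

    Category intensities from the gradients are truncated at zero and jointly
    renormalized with the unclassified background so the four modelled
    proportions sum to at most 1 at every site-year.  Point-level forest
    cover is Beta-distributed around the site value (exact in expectation).
    Identical seeds give identical landscapes.
    """
    spec = spec or LandscapeSpec()
    rng = np.random.default_rng(seed)
    S, Y = design.n_sites, design.n_years
    x, y_n = _site_positions(design, rng)
    surveyed = design.surveyed_matrix()

    cats = {}
    for name in ("soy", "corn", "per_past", "forest"):
        g: LandscapeGradient = getattr(spec, name)
        bump = g.bump_amp * np.exp(-((x - g.bump_center[0]) ** 2 +
                                     (y_n - g.bump_center[1]) ** 2) / (2 * g.bump_width ** 2))
        trend = g.baseline + g.east * x + g.north * y_n + bump
        vals = trend[:, None] + rng.normal(0.0, g.noise_sd, size=(S, Y)) if g.noise_sd > 0 \
            else np.repeat(trend[:, None], Y, axis=1)
        cats[name] = np.clip(vals, 0.0, None)

    total = sum(cats.values()) + spec.background
    scale = np.where(total > 1.0, 1.0 / total, 1.0)
    for name in cats:
        cats[name] = np.clip(cats[name] * scale, 0.0, 1.0)
        cats[name][~surveyed] = np.nan

    lat = np.repeat(center_coordinates(y_n)[:, None], Y, axis=1)
    lon = np.repeat(center_coordinates(x)[:, None], Y, axis=1)
    lat[~surveyed] = np.nan
    lon[~surveyed] = np.nan
    site_cov = SiteCovariates(lat=lat, long=lon, **cats)

    K = design.points_per_site
    fors = np.repeat(site_cov.forest[:, None, :], K, axis=1)
    kappa = spec.point_concentration
    m = np.clip(fors, 1e-6, 1 - 1e-6)
    p_fors = np.where(np.isnan(fors), np.nan,
                      rng.beta(np.nan_to_num(m * kappa, nan=1.0),
                               np.nan_to_num((1 - m) * kappa, nan=1.0)))
    point_cov = PointCovariates(p_fors=p_fors)
    return site_cov, point_cov


@dataclass(frozen=True)
class CommunityTruth:
    """True community hyper-parameters of the generative model.

    Intercepts are on the logit scale.  ``sigma_occ_time``/``sigma_det_time``
    are the species-level year-to-year sds of the random time effects (shared
    across species in the generator); ``slope_means``/``slope_sds`` are the
    community normals of the six occupancy slopes in (lat, long, soy, corn,
    per_past, forest) order.
    """

    mean_occ_intercept: float = -0.6   # mean psi ~= 0.35
    sd_occ_intercept: float = 1.0
    sigma_occ_time: float = 0.3
    mean_det_intercept: float = -0.85  # mean p ~= 0.30, most species p < 0.5
    sd_det_intercept: float = 0.7
    sigma_det_time: float = 0.3
    slope_means: tuple = (0.0,) * N_OCC_COV
    slope_sds: tuple = (0.5,) * N_OCC_COV
    det_slope_mean: float = 0.0
    det_slope_sd: float = 0.5

    def __post_init__(self):
        sds = (self.sd_occ_intercept, self.sigma_occ_time, self.sd_det_intercept,
               self.sigma_det_time, self.det_slope_sd, *self.slope_sds)
        if any(s < 0 for s in sds):
            raise ValueError("hyper-sd values must be >= 0")


def zero_effect_truth(**kw) -> CommunityTruth:
    """Truth with every covariate slope exactly zero for every species —
    the null under which a 95% interval should misclassify ~5% of effects."""
    return CommunityTruth(slope_means=(0.0,) * N_OCC_COV,
                          slope_sds=(0.0,) * N_OCC_COV,
                          det_slope_mean=0.0, det_slope_sd=0.0, **kw)


def moderate_truth(**kw) -> CommunityTruth:
    """Moderate, mixed-sign community effects (soy -, forest +)."""
    return CommunityTruth(slope_means=(0.3, -0.3, -1.0, 0.0, 0.0, 1.0),
                          slope_sds=(0.5,) * N_OCC_COV, **kw)


def strong_effect_truth(covariate_index: int = 2, effect: float = 4.0, **kw) -> CommunityTruth:
    """All species share one strong slope (default: soybean, +4 on the logit
    scale) with little scatter — a power-check configuration."""
    means = [0.0] * N_OCC_COV
    means[covariate_index] = effect
    return CommunityTruth(slope_means=tuple(means), slope_sds=(0.2,) * N_OCC_COV, **kw)


@dataclass
class TruthBundle:
    """Everything the generator drew: the truth, the realized parameters, the
    latent states and the observable data."""

    truth: CommunityTruth
    params: CommunityParams
    z: np.ndarray                 # (S, N, Y), 0 at unsurveyed cells
    history: DetectionHistory
    site_cov: SiteCovariates
    point_cov: PointCovariates
    seed: int


def simulate_community(design: SurveyDesign, site_cov: SiteCovariates,
                       point_cov: PointCovariates, truth: CommunityTruth,
                       n_species: int, seed: int = 0,
                       group: str = "synthetic") -> TruthBundle:
    """Draw a community and its detection history from the generative model.

    Species intercept means and slopes come from the community normals; the
    species-year intercepts are random time effects around the species means;
    occupancy states are Bernoulli(psi) from the occupancy linear predictor
    and detections Bernoulli(p * z) from the detection predictor, only at
    surveyed site-years.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    S, K, Y = design.n_sites, design.points_per_site, design.n_years
    N = n_species
    surveyed = design.surveyed_matrix()

    mu_u = rng.normal(truth.mean_occ_intercept, truth.sd_occ_intercept, size=N)
    mu_v = rng.normal(truth.mean_det_intercept, truth.sd_det_intercept, size=N)
    u = rng.normal(mu_u[:, None], truth.sigma_occ_time, size=(N, Y))
    v = rng.normal(mu_v[:, None], truth.sigma_det_time, size=(N, Y))
    a = rng.normal(np.asarray(truth.slope_means)[None, :],
                   np.asarray(truth.slope_sds)[None, :], size=(N, N_OCC_COV))
    b = rng.normal(truth.det_slope_mean, truth.det_slope_sd, size=N)

    X = np.nan_to_num(site_cov.stack(), nan=0.0)          # (S, Y, C)
    xk = np.nan_to_num(point_cov.p_fors, nan=0.0)         # (S, K, Y)
    eta_occ = u[None, :, :] + np.einsum("syc,nc->sny", X, a)
    eta_det = v[None, None, :, :] + b[None, None, :, None] * xk[:, :, None, :]
    for name, eta in (("site covariates", eta_occ), ("point forest cover", eta_det)):
        if not np.isfinite(eta).all():
            raise ValueError(f"non-finite linear predictor from {name}")

    psi = inv_logit(eta_occ)
    p = inv_logit(eta_det)
    z = (rng.random((S, N, Y)) < psi) & surveyed[:, None, :]
    y = (rng.random((S, K, N, Y)) < p) & z[:, None, :, :]
    y = y.astype(float)
    y[~np.broadcast_to(surveyed[:, None, None, :], y.shape)] = np.nan

    species = tuple(f"sp{i + 1:03d}" for i in range(N))
    history = DetectionHistory(y=y, species=species, design=design, group=group)
    params = CommunityParams(
        u=u, v=v, a=a, b=b, mu_u=mu_u,
        sig_u=np.full(N, truth.sigma_occ_time), mu_v=mu_v,
        sig_v=np.full(N, truth.sigma_det_time),
        mu2_u=truth.mean_occ_intercept, sig2_u=truth.sd_occ_intercept,
        mu2_v=truth.mean_det_intercept, sig2_v=truth.sd_det_intercept,
        mu_a=np.asarray(truth.slope_means, dtype=float),
        sig_a=np.asarray(truth.slope_sds, dtype=float),
        mu_b=truth.det_slope_mean, sig_b=truth.det_slope_sd,
    )
    return TruthBundle(truth=truth, params=params, z=z.astype(np.int8),
                       history=history, site_cov=site_cov, point_cov=point_cov,
                       seed=seed)
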