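"""Likelihood and prior machinery for the zero-inflated binomial state-space model.

The process model is a Bernoulli occupancy state per (site j, species i,
year t),

    z(j,i,t) ~ Bern(psi_jit),
    logit psi_jit = u(i,t) + a1(i)*lat + a2(i)*long + a3(i)*soy
                    + a4(i)*corn + a5(i)*per_past + a6(i)*forest,

and the observation model is a Bernoulli detection per point k conditional on
presence,

    y(j,k,i,t) ~ Bern(p_jkit * z(j,i,t)),
    logit p_jkit = v(i,t) + b1(i)*p_fors(j,k,t).

Species-year intercepts are random time effects around species means,
u(i,t) ~ N(mu_u(i), sig_u(i)), and the species means and slopes are in turn
draws from community-level normal hyper-distributions — the hierarchy that
lets sparsely detected species borrow strength from the group.

All likelihood computation is in log space; the mixture term for an all-zero
detection history uses a stable log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "logit", "inv_logit", "log_sigmoid",
    "CommunityParams", "PriorSpec", "GroupData",
    "occupancy_linpred", "detection_linpred",
    "site_marginal_loglik", "z_full_conditional",
    "total_loglik", "log_prior", "log_posterior",
]

N_OCC_COV = 6  # lat, long, soy, corn, per_past, forest


def logit(x):
    """log(x / (1-x)); defined only on the open interval (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("logit requires arguments strictly inside (0, 1)")
    out = np.log(x) - np.log1p(-x)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Logistic function, bounded in (0, 1) and monotone."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                   np.exp(np.clip(x, None, 0)) / (1.0 + np.exp(np.clip(x, None, 0))))
    return float(out) if out.ndim == 0 else out


def log_sigmoid(x):
    """log(inv_logit(x)), computed stably."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


@dataclass
class CommunityParams:
    """All parameters of one group's community occupancy model.

    Shapes: N species, Y years, C = 6 occupancy covariates.

    u, v : (N, Y)        species-year occupancy/detection intercepts (logit)
    a : (N, C)           species occupancy slopes (lat, long, soy, corn,
                         per_past, forest order)
    b : (N,)             species detection slope on point forest cover
    mu_u, sig_u, mu_v, sig_v : (N,)  species intercept means/sds across years
    mu2_u, sig2_u, mu2_v, sig2_v : scalars, community level of the intercepts
    mu_a, sig_a : (C,)   community means/sds of the occupancy slopes
    mu_b, sig_b : scalars, community level of the detection slope
    """

    u: np.ndarray
    v: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mu_u: np.ndarray
    sig_u: np.ndarray
    mu_v: np.ndarray
    sig_v: np.ndarray
    mu2_u: float = 0.0
    sig2_u: float = 1.0
    mu2_v: float = 0.0
    sig2_v: float = 1.0
    mu_a: np.ndarray = field(default_factory=lambda: np.zeros(N_OCC_COV))
    sig_a: np.ndarray = field(default_factory=lambda: np.ones(N_OCC_COV))
    mu_b: float = 0.0
    sig_b: float = 1.0

    @property
    def n_species(self) -> int:
        return self.u.shape[0]

    @property
    def n_years(self) -> int:
        return self.u.shape[1]

    def validate(self):
        for name in ("sig_u", "sig_v", "sig_a"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("sig2_u", "sig2_v", "sig_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def copy(self) -> "CommunityParams":
        return CommunityParams(
            u=self.u.copy(), v=self.v.copy(), a=self.a.copy(), b=self.b.copy(),
            mu_u=self.mu_u.copy(), sig_u=self.sig_u.copy(),
            mu_v=self.mu_v.copy(), sig_v=self.sig_v.copy(),
            mu2_u=self.mu2_u, sig2_u=self.sig2_u,
            mu2_v=self.mu2_v, sig2_v=self.sig2_v,
            mu_a=self.mu_a.copy(), sig_a=self.sig_a.copy(),
            mu_b=self.mu_b, sig_b=self.sig_b,
        )


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration.

    ``hyper_mean_sd`` is the sd of the wide normal prior on every community
    hyper-mean (logit scale); ``sd_upper`` bounds the uniform priors on all
    sds (species level and community level).  With ``pooling="independent"``
    the hierarchy is dropped and every intercept/slope gets an independent
    N(0, independent_sd**2) prior — useful for single-species toys and for
    comparing against non-hierarchical fits.
    """

    hyper_mean_sd: float = 10.0
    sd_upper: float = 10.0
    pooling: str = "hierarchical"  # or "independent"
    independent_sd: float = 10.0

    def __post_init__(self):
        if self.hyper_mean_sd <= 0 or self.sd_upper <= 0 or self.independent_sd <= 0:
            raise ValueError("prior scales must be positive")
        if self.pooling not in ("hierarchical", "independent"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


def occupancy_linpred(params: CommunityParams, covariates, i: int, j: int, t: int) -> float:
    """logit psi for one (species, site, year) from site covariates.

    ``covariates`` is a :class:`~commocc.occdata.SiteCovariates`.  Raises if
    any covariate is missing at (j, t).
    """
    x = np.array([getattr(covariates, n)[j, t]
                  for n in ("lat", "long", "soy", "corn", "per_past", "forest")])
    if np.isnan(x).any():
        raise ValueError(f"missing site covariate at site {j}, year index {t}")
    return float(params.u[i, t] + params.a[i] @ x)


def detection_linpred(params: CommunityParams, point_covariates, i: int, j: int,
                      k: int, t: int) -> float:
    """logit p for one (species, site, point, year)."""
    x = point_covariates.p_fors[j, k, t]
    if np.isnan(x):
        raise ValueError(f"missing point forest cover at site {j}, point {k}, year index {t}")
    return float(params.v[i, t] + params.b[i] * x)


def _check_binary(y):
    vals = y[~np.isnan(y)]
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("detection history must be binary (0/1) or NaN")


def site_marginal_loglik(y_site: np.ndarray, psi: float, p: np.ndarray) -> float:
    """Marginal log-likelihood of one site's K-point history for one species-year.

    Marginalizes the latent state:

        log[ psi * prod_k p_k^y (1-p_k)^(1-y) + (1-psi) * 1{all y = 0} ]

    with the product taken over non-missing points.  NaN entries of
    ``y_site`` are dropped (no imputation).
    """
    y_site = np.asarray(y_site, dtype=float)
    _check_binary(y_site)
    p = np.broadcast_to(np.asarray(p, dtype=float), y_site.shape)
    if not (0 <= psi <= 1) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("psi and p must lie in [0, 1]")
    m = ~np.isnan(y_site)
    yv, pv = y_site[m], p[m]
    with np.errstate(divide="ignore"):
        lp = np.sum(special.xlogy(yv, pv) + special.xlog1py(1 - yv, -pv))
        if yv.sum() > 0:
            return float(np.log(psi) + lp)
        return float(np.logaddexp(np.log(psi) + lp, np.log1p(-psi)))


def z_full_conditional(y_site: np.ndarray, psi: float, p: np.ndarray) -> float:
    """P(z = 1 | y, psi, p) for one site-species-year.

    Equals 1 whenever any point detected the species; otherwise the Bayes
    inversion psi*prod(1-p) / (psi*prod(1-p) + 1 - psi).
    """
    y_site = np.asarray(y_site, dtype=float)
    _check_binary(y_site)
    p = np.broadcast_to(np.asarray(p, dtype=float), y_site.shape)
    m = ~np.isnan(y_site)
    if np.nansum(y_site) > 0:
        return 1.0
    with np.errstate(divide="ignore"):
        log_miss = np.sum(np.log1p(-p[m]))
    num = psi * np.exp(log_miss)
    return float(num / (num + 1 - psi))


def total_loglik(psi: np.ndarray, p: np.ndarray, y: np.ndarray) -> float:
    """Marginal log-likelihood of a whole group dataset.

    ``psi`` is (S, N, Y), ``p`` is (S, K, N, Y), ``y`` is (S, K, N, Y) with
    NaN at missing cells.  Unsurveyed site-years contribute exactly 0; the sum
    is over surveyed (site, species, year) marginals.
    """
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or psi.shape != (y.shape[0], y.shape[2], y.shape[3]):
        raise ValueError(f"dimension mismatch: psi {psi.shape}, p {p.shape}, y {y.shape}")
    _check_binary(y)
    m = ~np.isnan(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp_det = np.where(m, special.xlogy(y, p) + special.xlog1py(1 - y, -p),
                          0.0).sum(axis=1)
        any_det = np.nansum(y, axis=1) > 0
        surveyed = m.any(axis=1)
        log_psi = np.log(psi)
        occupied_branch = log_psi + lp_det
        mixed = np.logaddexp(occupied_branch, np.log1p(-psi))
        site_ll = np.where(any_det, occupied_branch, mixed)
    return float(np.where(surveyed, site_ll, 0.0).sum())


def _norm_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def log_prior(params: CommunityParams, prior: PriorSpec) -> float:
    """Log prior density of all parameters under the hierarchy.

    Hierarchical pooling: species-year intercepts ~ N(species mean, species
    sd); species means and slopes ~ N(community hyper-mean, hyper-sd);
    hyper-means ~ N(0, hyper_mean_sd); every sd ~ Uniform(0, sd_upper)
    (-inf outside support).  Independent pooling: N(0, independent_sd) on
    every intercept and slope.
    """
    if prior.pooling == "independent":
        s = prior.independent_sd
        total = _norm_logpdf(params.u, 0.0, s).sum()
        total += _norm_logpdf(params.v, 0.0, s).sum()
        total += _norm_logpdf(params.a, 0.0, s).sum()
        total += _norm_logpdf(params.b, 0.0, s).sum()
        return float(total)

    up = prior.sd_upper
    sds = np.concatenate([params.sig_u, params.sig_v, params.sig_a,
                          [params.sig2_u, params.sig2_v, params.sig_b]])
    if np.any(sds <= 0) or np.any(sds >= up):
        return -np.inf
    total = _norm_logpdf(params.u, params.mu_u[:, None], params.sig_u[:, None]).sum()
    total += _norm_logpdf(params.v, params.mu_v[:, None], params.sig_v[:, None]).sum()
    total += _norm_logpdf(params.mu_u, params.mu2_u, params.sig2_u).sum()
    total += _norm_logpdf(params.mu_v, params.mu2_v, params.sig2_v).sum()
    total += _norm_logpdf(params.a, params.mu_a[None, :], params.sig_a[None, :]).sum()
    total += _norm_logpdf(params.b, params.mu_b, params.sig_b).sum()
    hm = prior.hyper_mean_sd
    total += _norm_logpdf(np.array([params.mu2_u, params.mu2_v, params.mu_b]), 0.0, hm).sum()
    total += _norm_logpdf(params.mu_a, 0.0, hm).sum()
    total += len(sds) * (-np.log(up))  # uniform density inside support
    return float(total)


@dataclass
class GroupData:
    """One group's data, packaged and pre-masked for the fitter.

    ``X`` and ``x_det`` are the occupancy/detection design covariates with
    zeros substituted at unsurveyed cells — those cells are excluded from
    every likelihood sum through the masks, so the substitution only keeps
    array arithmetic finite.
    """

    y: np.ndarray            # (S, K, N, Y), NaN at missing cells
    X: np.ndarray            # (S, Y, C) occupancy covariates, 0 where unsurveyed
    x_det: np.ndarray        # (S, K, Y) point forest cover, 0 where unsurveyed
    surveyed: np.ndarray     # (S, Y) bool
    species: tuple
    years: tuple
    covariates: tuple
    site_index: tuple = ()

    def __post_init__(self):
        self.ymask = ~np.isnan(self.y)
        with np.errstate(invalid="ignore"):
            self.any_det = np.nansum(self.y, axis=1) > 0          # (S, N, Y)
            self.count = np.nan_to_num(np.nansum(self.y, axis=1))  # (S, N, Y)
        self.y0 = np.nan_to_num(self.y, nan=0.0)
        self.ysign = 2.0 * self.y0 - 1.0                          # +-1, junk at NaN
        # contiguous covariate columns for the per-covariate sampler blocks
        self.Xc = [np.ascontiguousarray(self.X[:, :, c]) for c in range(self.X.shape[-1])]

    @classmethod
    def from_inputs(cls, history, site_cov, point_cov,
                    covariates=("lat", "long", "soy", "corn", "per_past", "forest")):
        surveyed = history.surveyed
        X = np.stack([np.nan_to_num(getattr(site_cov, n), nan=0.0) for n in covariates],
                     axis=-1) if covariates else np.zeros(surveyed.shape + (0,))
        x_det = np.nan_to_num(point_cov.p_fors, nan=0.0)
        return cls(y=history.y, X=X, x_det=x_det, surveyed=surveyed,
                   species=tuple(history.species), years=tuple(history.design.years),
                   covariates=tuple(covariates), site_index=history.site_index)

    @property
    def shape(self):
        return self.y.shape

    def eta_occ(self, params: CommunityParams) -> np.ndarray:
        """(S, N, Y) occupancy linear predictor."""
        return params.u[None, :, :] + np.einsum("syc,nc->sny", self.X, params.a)

    def eta_det(self, params: CommunityParams) -> np.ndarray:
        """(S, K, N, Y) detection linear predictor."""
        return params.v[None, None, :, :] \
            + params.b[None, None, :, None] * self.x_det[:, :, None, :]

    def marginal_loglik(self, params: CommunityParams) -> float:
        """Marginal (z integrated out) log-likelihood of the group data."""
        psi = inv_logit(self.eta_occ(params))
        p = inv_logit(self.eta_det(params))
        return total_loglik(psi, p, self.y)


def log_posterior(params: CommunityParams, data: GroupData, prior: PriorSpec) -> float:
    """Marginal log-posterior density (up to a constant)."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    return lp + data.marginal_loglik(params)
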