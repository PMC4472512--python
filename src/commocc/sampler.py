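"""Data-augmentation MCMC for the hierarchical community occupancy model.

The sampler is written from scratch for this model family:

* the latent occupancy states ``z`` are Gibbs-sampled exactly from their
  Bernoulli full conditionals (forced to 1 wherever the species was detected);
* logit-scale intercepts and slopes move by random-walk Metropolis against
  the data-augmented log-posterior, proposed and accepted elementwise across
  independent blocks (all species-year intercepts at once, all species of one
  slope at once);
* species-level and community-level normal means are conjugate draws; the
  uniform-prior sds move by random-walk Metropolis.

Proposal scales adapt by Robbins-Monro toward a 0.44 acceptance rate during
burn-in only and are frozen afterwards, so the post-burn-in kernel satisfies
detailed balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import (det_it_accept, det_sp_accept, occ_it_accept,
                       occ_sp_accept, softplus)
from .model import (CommunityParams, GroupData, PriorSpec, _norm_logpdf,
                    inv_logit, log_prior, log_sigmoid)

__all__ = ["MCMCConfig", "PosteriorDraws", "ChainState",
           "initialize_chain", "gibbs_sweep", "run_mcmc"]

HIER_EXTRA = ("mu_u", "sig_u", "mu_v", "sig_v", "mu2_u", "sig2_u",
              "mu2_v", "sig2_v", "mu_a", "sig_a", "mu_b", "sig_b")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol.  Defaults follow the full monitoring analysis: three
    chains of 30,000 post-burn-in iterations after a 20,000 burn-in, thinned
    by 10 — 3000 stored draws per chain, 9000 pooled."""

    n_chains: int = 3
    n_iter: int = 30_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.44
    store_z: bool = False

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter % self.thin != 0:
            raise ValueError(f"n_iter={self.n_iter} not divisible by thin={self.thin}")
        if self.burn_in < 0 or self.n_iter < 1:
            raise ValueError("burn_in must be >= 0 and n_iter >= 1")

    @property
    def draws_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


@dataclass
class ChainState:
    params: CommunityParams
    z: np.ndarray                      # (S, N, Y) float 0/1
    eta_occ: np.ndarray                # cached (S, N, Y)
    eta_det: np.ndarray                # cached (S, K, N, Y)
    log_scales: dict
    sp_occ: np.ndarray = None          # cached softplus(eta_occ)
    sp_det: np.ndarray = None          # cached softplus(eta_det), 0 at missing
    accept_sums: dict = field(default_factory=dict)
    accept_counts: dict = field(default_factory=dict)

    def refresh_caches(self, data: GroupData):
        self.sp_occ = softplus(self.eta_occ)
        self.sp_det = np.where(data.ymask, softplus(self.eta_det), 0.0)


def _init_scales(N, Y, C):
    s = np.log(0.5)
    return {"u": np.full((N, Y), s), "v": np.full((N, Y), s),
            "a": np.full((N, C), s), "b": np.full(N, s),
            "sig_u": np.full(N, s), "sig_v": np.full(N, s),
            "sig_a": np.full(C, s),
            "sig2_u": np.full((), s), "sig2_v": np.full((), s),
            "sig_b": np.full((), s)}


def _augmented_log_posterior(state: ChainState, data: GroupData, prior: PriorSpec) -> float:
    lp = log_prior(state.params, prior)
    if not np.isfinite(lp):
        return -np.inf
    sv = data.surveyed[:, None, :]
    occ = np.where(sv, log_sigmoid((2 * state.z - 1) * state.eta_occ), 0.0).sum()
    w = data.ymask & (state.z[:, None, :, :] > 0.5)
    det = np.where(w, log_sigmoid(data.ysign * state.eta_det), 0.0).sum()
    return float(lp + occ + det)


def initialize_chain(data: GroupData, prior: PriorSpec, seed) -> ChainState:
    """Build a valid starting state.

    ``z`` starts at the observed maxima (1 wherever a detection exists, a
    naive-occupancy coin flip elsewhere); intercepts start at jittered
    empirical logits, slopes near zero, sds at 1 on the logit scale.  If the
    resulting augmented posterior is non-finite a neutral fallback state is
    tried before giving up.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, K, N, Y = data.shape
    C = data.X.shape[-1]
    sv = data.surveyed[:, None, :]

    n_surv = data.surveyed.sum(axis=0).astype(float)            # (Y,)
    naive_occ = data.any_det.sum(axis=0) / np.maximum(n_surv, 1.0)  # (N, Y)
    naive_occ = np.clip(naive_occ, 0.05, 0.95)
    u = np.log(naive_occ / (1 - naive_occ)) + 0.1 * rng.standard_normal((N, Y))

    occupied_pts = (data.any_det[:, None, :, :] & data.ymask).sum(axis=(0, 1))  # (N, Y)
    hits = np.where(data.any_det, data.count, 0.0).sum(axis=0)                  # (N, Y)
    naive_det = np.clip(hits / np.maximum(occupied_pts, 1.0), 0.05, 0.95)
    v = np.log(naive_det / (1 - naive_det)) + 0.1 * rng.standard_normal((N, Y))

    a = 0.05 * rng.standard_normal((N, C))
    b = 0.05 * rng.standard_normal(N)
    params = CommunityParams(
        u=u, v=v, a=a, b=b,
        mu_u=u.mean(axis=1), sig_u=np.ones(N),
        mu_v=v.mean(axis=1), sig_v=np.ones(N),
        mu2_u=float(u.mean()), sig2_u=1.0,
        mu2_v=float(v.mean()), sig2_v=1.0,
        mu_a=a.mean(axis=0), sig_a=np.ones(C),
        mu_b=float(b.mean()), sig_b=1.0,
    )

    psi0 = inv_logit(u.mean())
    z = (data.any_det | (rng.random((S, N, Y)) < psi0)) & data.surveyed[:, None, :]
    state = ChainState(params=params, z=z.astype(float), eta_occ=data.eta_occ(params),
                       eta_det=data.eta_det(params), log_scales=_init_scales(N, Y, C))
    state.refresh_caches(data)
    if np.isfinite(_augmented_log_posterior(state, data, prior)):
        return state

    # Fallback: neutral state at the prior center.
    params = CommunityParams(
        u=np.zeros((N, Y)), v=np.zeros((N, Y)), a=np.zeros((N, C)), b=np.zeros(N),
        mu_u=np.zeros(N), sig_u=np.ones(N), mu_v=np.zeros(N), sig_v=np.ones(N),
        mu_a=np.zeros(C), sig_a=np.ones(C),
    )
    z = (data.any_det | (rng.random((S, N, Y)) < 0.5)) & data.surveyed[:, None, :]
    state = ChainState(params=params, z=z.astype(float), eta_occ=data.eta_occ(params),
                       eta_det=data.eta_det(params), log_scales=_init_scales(N, Y, C))
    state.refresh_caches(data)
    if not np.isfinite(_augmented_log_posterior(state, data, prior)):
        raise RuntimeError("could not construct an initial state with finite posterior density")
    return state


def _record(state, name, accepted, adapt, gamma, target):
    ls = state.log_scales[name]
    if adapt:
        np.add(ls, gamma * (accepted.astype(float) - target), out=ls, casting="unsafe")
    else:
        state.accept_sums[name] = state.accept_sums.get(name, 0.0) + float(np.sum(accepted))
        state.accept_counts[name] = state.accept_counts.get(name, 0) + int(np.size(accepted))


def _mh_sd(rng, sig, ssq, n_terms, upper, scale):
    """Elementwise random-walk MH for a normal sd with a Uniform(0, upper)
    prior; the target is -n*log(sig) - ssq/(2 sig^2)."""
    prop = sig + np.exp(scale) * rng.standard_normal(np.shape(sig))
    valid = (prop > 0) & (prop < upper)
    safe = np.where(valid, prop, 1.0)
    ll_old = -n_terms * np.log(sig) - ssq / (2 * sig ** 2)
    ll_new = -n_terms * np.log(safe) - ssq / (2 * safe ** 2)
    acc = valid & (np.log(rng.random(np.shape(sig))) < ll_new - ll_old)
    return np.where(acc, prop, sig), acc


def _conj_normal_mean(rng, total, n, lik_sd, prior_mean, prior_sd):
    """Draw from N(mean | data) for a normal mean with known sd and normal prior."""
    prec = n / lik_sd ** 2 + 1.0 / prior_sd ** 2
    mean = (total / lik_sd ** 2 + prior_mean / prior_sd ** 2) / prec
    return mean + rng.standard_normal(np.shape(mean)) / np.sqrt(prec)


def gibbs_sweep(state: ChainState, data: GroupData, prior: PriorSpec,
                rng: np.random.Generator, adapt: bool = False, it: int = 0,
                target: float = 0.44) -> ChainState:
    """One full sweep over all blocks; mutates and returns ``state``."""
    pa = state.params
    S, K, N, Y = data.shape
    C = data.X.shape[-1]
    sv = data.surveyed[:, None, :]
    gamma = min(0.25, (it + 1.0) ** -0.6)
    hier = prior.pooling == "hierarchical"
    s0 = prior.independent_sd

    # --- 1. latent occupancy states: exact Bernoulli full conditional -------
    # log psi = eta - softplus(eta); log(1-psi) = -softplus(eta);
    # log prod_k (1-p_k) = -sum_k softplus(eta_det) over non-missing points.
    logmiss = -state.sp_det.sum(axis=1)
    pz = inv_logit(state.eta_occ + logmiss)
    z = (data.any_det | (rng.random((S, N, Y)) < pz)) & data.surveyed[:, None, :]
    state.z = z.astype(float)

    # --- 2. species-year occupancy intercepts u(i,t) ------------------------
    du = np.exp(state.log_scales["u"]) * rng.standard_normal((N, Y))
    e = state.eta_occ + du[None]
    sp_new = softplus(e)
    if hier:
        dprior = _norm_logpdf(pa.u + du, pa.mu_u[:, None], pa.sig_u[:, None]) \
            - _norm_logpdf(pa.u, pa.mu_u[:, None], pa.sig_u[:, None])
    else:
        dprior = _norm_logpdf(pa.u + du, 0.0, s0) - _norm_logpdf(pa.u, 0.0, s0)
    logu = np.log(rng.random((N, Y)))
    acc = occ_it_accept(state.eta_occ, state.sp_occ, e, sp_new, state.z,
                        data.surveyed, logu, dprior)
    pa.u += du * acc
    _record(state, "u", acc, adapt, gamma, target)

    # --- 3. occupancy slopes a_c(i), one covariate block at a time ----------
    for c in range(C):
        da = np.exp(state.log_scales["a"][:, c]) * rng.standard_normal(N)
        e = state.eta_occ + da[None, :, None] * data.Xc[c][:, None, :]
        sp_new = softplus(e)
        if hier:
            dprior = _norm_logpdf(pa.a[:, c] + da, pa.mu_a[c], pa.sig_a[c]) \
                - _norm_logpdf(pa.a[:, c], pa.mu_a[c], pa.sig_a[c])
        else:
            dprior = _norm_logpdf(pa.a[:, c] + da, 0.0, s0) - _norm_logpdf(pa.a[:, c], 0.0, s0)
        logu = np.log(rng.random(N))
        acc = occ_sp_accept(state.eta_occ, state.sp_occ, e, sp_new, state.z,
                            data.surveyed, logu, dprior)
        pa.a[:, c] += da * acc
        ls = state.log_scales["a"]
        if adapt:
            ls[:, c] += gamma * (acc.astype(float) - target)
        else:
            state.accept_sums["a"] = state.accept_sums.get("a", 0.0) + float(acc.sum())
            state.accept_counts["a"] = state.accept_counts.get("a", 0) + int(acc.size)

    # --- 4. species-year detection intercepts v(i,t) ------------------------
    dv = np.exp(state.log_scales["v"]) * rng.standard_normal((N, Y))
    e = state.eta_det + dv[None, None]
    sp_new = softplus(e)
    if hier:
        dprior = _norm_logpdf(pa.v + dv, pa.mu_v[:, None], pa.sig_v[:, None]) \
            - _norm_logpdf(pa.v, pa.mu_v[:, None], pa.sig_v[:, None])
    else:
        dprior = _norm_logpdf(pa.v + dv, 0.0, s0) - _norm_logpdf(pa.v, 0.0, s0)
    logu = np.log(rng.random((N, Y)))
    acc = det_it_accept(state.eta_det, state.sp_det, e, sp_new, data.y0,
                        data.ymask, state.z, logu, dprior)
    pa.v += dv * acc
    _record(state, "v", acc, adapt, gamma, target)

    # --- 5. detection slopes b(i) -------------------------------------------
    db = np.exp(state.log_scales["b"]) * rng.standard_normal(N)
    e = state.eta_det + db[None, None, :, None] * data.x_det[:, :, None, :]
    sp_new = softplus(e)
    if hier:
        dprior = _norm_logpdf(pa.b + db, pa.mu_b, pa.sig_b) \
            - _norm_logpdf(pa.b, pa.mu_b, pa.sig_b)
    else:
        dprior = _norm_logpdf(pa.b + db, 0.0, s0) - _norm_logpdf(pa.b, 0.0, s0)
    logu = np.log(rng.random(N))
    acc = det_sp_accept(state.eta_det, state.sp_det, e, sp_new, data.y0,
                        data.ymask, state.z, logu, dprior)
    pa.b += db * acc
    _record(state, "b", acc, adapt, gamma, target)

    if not hier:
        return state

    # --- 6. species-level means (conjugate) and sds (MH) --------------------
    up = prior.sd_upper
    pa.mu_u = _conj_normal_mean(rng, pa.u.sum(axis=1), Y, pa.sig_u, pa.mu2_u, pa.sig2_u)
    ssq = ((pa.u - pa.mu_u[:, None]) ** 2).sum(axis=1)
    pa.sig_u, acc = _mh_sd(rng, pa.sig_u, ssq, Y, up, state.log_scales["sig_u"])
    _record(state, "sig_u", acc, adapt, gamma, target)

    pa.mu_v = _conj_normal_mean(rng, pa.v.sum(axis=1), Y, pa.sig_v, pa.mu2_v, pa.sig2_v)
    ssq = ((pa.v - pa.mu_v[:, None]) ** 2).sum(axis=1)
    pa.sig_v, acc = _mh_sd(rng, pa.sig_v, ssq, Y, up, state.log_scales["sig_v"])
    _record(state, "sig_v", acc, adapt, gamma, target)

    # --- 7. community hyper-parameters --------------------------------------
    hm = prior.hyper_mean_sd
    pa.mu2_u = float(_conj_normal_mean(rng, pa.mu_u.sum(), N, pa.sig2_u, 0.0, hm))
    ssq = float(((pa.mu_u - pa.mu2_u) ** 2).sum())
    new, acc = _mh_sd(rng, np.asarray(pa.sig2_u), ssq, N, up, state.log_scales["sig2_u"])
    pa.sig2_u = float(new)
    _record(state, "sig2_u", acc, adapt, gamma, target)

    pa.mu2_v = float(_conj_normal_mean(rng, pa.mu_v.sum(), N, pa.sig2_v, 0.0, hm))
    ssq = float(((pa.mu_v - pa.mu2_v) ** 2).sum())
    new, acc = _mh_sd(rng, np.asarray(pa.sig2_v), ssq, N, up, state.log_scales["sig2_v"])
    pa.sig2_v = float(new)
    _record(state, "sig2_v", acc, adapt, gamma, target)

    if C:
        pa.mu_a = _conj_normal_mean(rng, pa.a.sum(axis=0), N, pa.sig_a, 0.0, hm)
        ssq = ((pa.a - pa.mu_a[None, :]) ** 2).sum(axis=0)
        pa.sig_a, acc = _mh_sd(rng, pa.sig_a, ssq, N, up, state.log_scales["sig_a"])
        _record(state, "sig_a", acc, adapt, gamma, target)

    pa.mu_b = float(_conj_normal_mean(rng, pa.b.sum(), N, pa.sig_b, 0.0, hm))
    ssq = float(((pa.b - pa.mu_b) ** 2).sum())
    new, acc = _mh_sd(rng, np.asarray(pa.sig_b), ssq, N, up, state.log_scales["sig_b"])
    pa.sig_b = float(new)
    _record(state, "sig_b", acc, adapt, gamma, target)
    return state


@dataclass
class PosteriorDraws:
    """Thinned multi-chain draws of every model parameter.

    ``draws[name]`` has shape (n_chains, draws_per_chain, *param_shape).
    """

    draws: dict
    species: tuple
    years: tuple
    covariates: tuple
    config: MCMCConfig
    pooling: str
    acceptance: dict = field(default_factory=dict)

    def pooled(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def draws_per_chain(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain

    def save(self, path):
        meta = {"species": list(self.species), "years": [str(y) for y in self.years],
                "covariates": list(self.covariates), "pooling": self.pooling,
                "acceptance": self.acceptance,
                "config": {k: getattr(self.config, k) for k in
                           ("n_chains", "n_iter", "burn_in", "thin", "seed",
                            "adapt", "target_accept", "store_z")}}
        np.savez_compressed(path, _meta=np.array(json.dumps(meta)),
                            **{f"d_{k}": v for k, v in self.draws.items()})

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            draws = {k[2:]: f[k] for k in f.files if k.startswith("d_")}
        return cls(draws=draws, species=tuple(meta["species"]),
                   years=tuple(meta["years"]), covariates=tuple(meta["covariates"]),
                   config=MCMCConfig(**meta["config"]), pooling=meta["pooling"],
                   acceptance=meta["acceptance"])


def run_mcmc(data: GroupData, prior: PriorSpec, config: MCMCConfig,
             progress: bool = False) -> PosteriorDraws:
    """Run ``config.n_chains`` independent chains and pool the thinned draws.

    Chains receive distinct child seeds of ``config.seed``; reruns with the
    same data and configuration are bit-identical.
    """
    S, K, N, Y = data.shape
    C = data.X.shape[-1]
    nd = config.draws_per_chain
    hier = prior.pooling == "hierarchical"

    shapes = {"u": (N, Y), "v": (N, Y), "a": (N, C), "b": (N,)}
    if hier:
        shapes.update({"mu_u": (N,), "sig_u": (N,), "mu_v": (N,), "sig_v": (N,),
                       "mu2_u": (), "sig2_u": (), "mu2_v": (), "sig2_v": (),
                       "mu_a": (C,), "sig_a": (C,), "mu_b": (), "sig_b": ()})
    if config.store_z:
        shapes["z"] = (S, N, Y)
    draws = {k: np.empty((config.n_chains, nd) + shp,
                         dtype=(np.int8 if k == "z" else float))
             for k, shp in shapes.items()}

    accept_sums, accept_counts = {}, {}
    for chain, ss in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_chains)):
        rng = np.random.default_rng(ss)
        state = initialize_chain(data, prior, rng)
        total = config.burn_in + config.n_iter
        for it in range(total):
            adapt = config.adapt and it < config.burn_in
            gibbs_sweep(state, data, prior, rng, adapt=adapt, it=it,
                        target=config.target_accept)
            post = it - config.burn_in
            if post >= 0 and (post + 1) % config.thin == 0:
                j = post // config.thin
                pa = state.params
                draws["u"][chain, j] = pa.u
                draws["v"][chain, j] = pa.v
                draws["a"][chain, j] = pa.a
                draws["b"][chain, j] = pa.b
                if hier:
                    draws["mu_u"][chain, j] = pa.mu_u
                    draws["sig_u"][chain, j] = pa.sig_u
                    draws["mu_v"][chain, j] = pa.mu_v
                    draws["sig_v"][chain, j] = pa.sig_v
                    draws["mu2_u"][chain, j] = pa.mu2_u
                    draws["sig2_u"][chain, j] = pa.sig2_u
                    draws["mu2_v"][chain, j] = pa.mu2_v
                    draws["sig2_v"][chain, j] = pa.sig2_v
                    draws["mu_a"][chain, j] = pa.mu_a
                    draws["sig_a"][chain, j] = pa.sig_a
                    draws["mu_b"][chain, j] = pa.mu_b
                    draws["sig_b"][chain, j] = pa.sig_b
                if config.store_z:
                    draws["z"][chain, j] = state.z.astype(np.int8)
        for k in state.accept_sums:
            accept_sums[k] = accept_sums.get(k, 0.0) + state.accept_sums[k]
            accept_counts[k] = accept_counts.get(k, 0) + state.accept_counts[k]
        if progress:
            print(f"chain {chain + 1}/{config.n_chains} done")

    acceptance = {k: accept_sums[k] / accept_counts[k] for k in accept_sums}
    return PosteriorDraws(draws=draws, species=data.species, years=data.years,
                          covariates=data.covariates, config=config,
                          pooling=prior.pooling, acceptance=acceptance)
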