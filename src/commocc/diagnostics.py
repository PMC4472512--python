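"""Convergence and goodness-of-fit diagnostics.

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor (classic, unsplit form; a split-chain variant is available), fit with
a posterior-predictive Bayesian p-value: for each retained draw a replicate
detection dataset is simulated from the model and a discrepancy statistic is
compared between the observed and replicated data.  Values near 0 or 1
signal misfit; a well-specified model gives values away from the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GroupData, inv_logit
from .sampler import PosteriorDraws

__all__ = ["gelman_rubin", "compute_rhat", "bayesian_pvalue",
           "DiagnosticReport", "diagnose", "DISCREPANCIES"]


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` is (m, n): m parallel chains of n draws.  With B the
    between-chain variance of the chain means (times n) and W the mean
    within-chain variance,

        Vhat = (n - 1)/n * W + B/n,    R-hat = sqrt(Vhat / W).

    ``split=True`` halves each chain first (2m chains of n/2 draws), which
    also detects within-chain drift.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    if split:
        m, n = chains.shape
        half = n // 2
        chains = np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains of at least 2 draws")
    if not np.isfinite(chains).all():
        raise ValueError("chains contain non-finite draws")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValueError("degenerate chains: within-chain variance is zero")
    B = n * means.var(ddof=1)
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def compute_rhat(draws: PosteriorDraws, names=None, split: bool = False) -> pd.DataFrame:
    """R-hat for every scalar element of the named parameter blocks."""
    names = names or [k for k in draws.draws if k != "z"]
    rows = []
    for name in names:
        arr = draws.draws[name]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for idx in range(flat.shape[2]):
            rows.append({"parameter": name, "index": idx,
                         "rhat": gelman_rubin(flat[:, :, idx], split=split)})
    return pd.DataFrame(rows)


def _freeman_tukey(count, expected):
    return float(np.sum((np.sqrt(count) - np.sqrt(expected)) ** 2))


def _deviance(count, expected, k_eff):
    # Binomial deviance on site counts against the marginal expectation.
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = expected / k_eff
        ll = count * np.log(rate) + (k_eff - count) * np.log1p(-rate)
    return float(-2 * np.nansum(ll))


DISCREPANCIES = ("freeman_tukey", "deviance")


def bayesian_pvalue(draws: PosteriorDraws, data: GroupData,
                    discrepancy: str = "freeman_tukey", max_draws: int = 300,
                    seed: int = 0) -> float:
    """Posterior-predictive p-value on per-(site, species, year) counts.

    For each retained draw theta: simulate a replicate dataset from the model
    at theta, compute the discrepancy T(data; theta) and T(replicate; theta)
    against the marginal expected counts psi * sum_k p_k, and report the
    fraction of draws with T(replicate) >= T(observed).  Ties count as
    "at least as extreme".
    """
    if discrepancy not in DISCREPANCIES:
        raise ValueError(f"unknown discrepancy {discrepancy!r}; options: {DISCREPANCIES}")
    rng = np.random.default_rng(seed)
    n_total = draws.total_draws
    take = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    u = draws.pooled("u")[take]
    v = draws.pooled("v")[take]
    a = draws.pooled("a")[take]
    b = draws.pooled("b")[take]

    surveyed = data.surveyed[:, None, :]
    k_eff = data.ymask.sum(axis=1)  # non-missing points per (site, species, year)
    obs_count = data.count
    extreme = 0
    for d in range(len(take)):
        eta_occ = u[d][None] + np.einsum("syc,nc->sny", data.X, a[d])
        eta_det = v[d][None, None] + b[d][None, None, :, None] * data.x_det[:, :, None, :]
        psi = inv_logit(eta_occ)
        p = inv_logit(eta_det)
        expected = np.where(surveyed, psi * np.where(data.ymask, p, 0.0).sum(axis=1), 0.0)

        z_rep = (rng.random(psi.shape) < psi) & surveyed
        y_rep = (rng.random(p.shape) < p) & z_rep[:, None, :, :] & data.ymask
        rep_count = y_rep.sum(axis=1)

        if discrepancy == "freeman_tukey":
            # unsurveyed cells have count 0 and expected 0: they contribute nothing
            t_obs = _freeman_tukey(obs_count, expected)
            t_rep = _freeman_tukey(rep_count, expected)
        else:
            t_obs = _deviance(np.where(surveyed, obs_count, 0), expected,
                              np.maximum(k_eff, 1))
            t_rep = _deviance(rep_count, expected, np.maximum(k_eff, 1))
        if t_rep >= t_obs:
            extreme += 1
    return extreme / len(take)


@dataclass
class DiagnosticReport:
    """Per-parameter R-hat table, convergence flags and fit p-value."""

    rhat: pd.DataFrame
    pvalue: float
    discrepancy: str
    rhat_threshold: float = 1.1
    flags: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.flags = self.rhat[self.rhat["rhat"] > self.rhat_threshold].copy()

    @property
    def converged(self) -> bool:
        return self.flags.empty

    @property
    def max_rhat(self) -> float:
        return float(self.rhat["rhat"].max())


def diagnose(draws: PosteriorDraws, data: GroupData,
             discrepancy: str = "freeman_tukey", rhat_threshold: float = 1.1,
             split: bool = False, max_draws: int = 300, seed: int = 0) -> DiagnosticReport:
    """Full diagnostic pass: R-hat for every stored parameter + Bayesian p-value."""
    rhat = compute_rhat(draws, split=split)
    pval = bayesian_pvalue(draws, data, discrepancy=discrepancy,
                           max_draws=max_draws, seed=seed)
    return DiagnosticReport(rhat=rhat, pvalue=pval, discrepancy=discrepancy,
                            rhat_threshold=rhat_threshold)
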