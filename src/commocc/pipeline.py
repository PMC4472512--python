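"""End-to-end orchestration: prepare -> fit -> diagnose -> summarize, plus the
parameter-recovery experiment used to validate the whole stack on synthetic
communities with known truth.

Also houses two small independent oracles used for validation: an exhaustive
latent-state enumeration of the marginal likelihood for tiny problems, and a
fine-grid numerical posterior for the single-species no-covariate toy model.
Both are deliberately brute force and share no code with the likelihood or
the sampler they check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import DiagnosticReport, diagnose
from .model import GroupData, PriorSpec, inv_logit
from .occdata import (OCC_COVARIATES, DetectionHistory, PointCovariates,
                      SiteCovariates, center_coordinates, filter_species,
                      screen_covariates)
from .sampler import MCMCConfig, PosteriorDraws, run_mcmc
from .summaries import classify_fractions, mean_area_occupancy, summarize_effects
from .synth import (CommunityTruth, default_design, simulate_community,
                    simulate_landscape, zero_effect_truth)

__all__ = ["PrepareReport", "prepare_group", "GroupResult", "fit_group",
           "fit_all_groups", "RecoveryReport", "recovery_experiment",
           "enumerate_loglik", "toy_grid_posterior", "toy_group_data",
           "RunConfig"]

log = logging.getLogger("commocc")

# Full monitoring-protocol defaults, named in one place so configs can reference them.
DEFAULT_MIN_OBS = 200
DEFAULT_R_THRESHOLD = 0.5


@dataclass
class PrepareReport:
    retained_species: list
    discarded_species: list
    retained_covariates: list
    covariate_report: pd.DataFrame


def prepare_group(history: DetectionHistory, site_cov: SiteCovariates,
                  point_cov: PointCovariates, min_obs: int = DEFAULT_MIN_OBS,
                  r_threshold: float = DEFAULT_R_THRESHOLD,
                  screen: bool = True):
    """Apply the preprocessing rules and package one group for the fitter.

    Centers latitude/longitude on zero, screens the four LULC covariates for
    pairwise correlation (keeping the better-represented member of each
    conflicting pair; coordinates are controls and always retained), and
    drops species below the detection threshold.
    """
    lat = center_coordinates(site_cov.lat)
    lon = center_coordinates(site_cov.long)
    site_cov = SiteCovariates(lat=lat, long=lon, soy=site_cov.soy, corn=site_cov.corn,
                              per_past=site_cov.per_past, forest=site_cov.forest)

    lulc = ("soy", "corn", "per_past", "forest")
    if screen:
        table = pd.DataFrame({n: getattr(site_cov, n)[history.surveyed] for n in lulc})
        retained_lulc, cov_report = screen_covariates(table, r_threshold=r_threshold)
    else:
        retained_lulc, cov_report = list(lulc), pd.DataFrame(
            columns=["covariate", "reason", "against", "r"])
    covariates = ("lat", "long") + tuple(retained_lulc)

    keep = filter_species(history, min_obs=min_obs)
    dropped = [s for s in history.species if s not in keep]
    for s in dropped:
        log.info("discarding species %s: fewer than %d detections", s, min_obs)
    for _, row in cov_report.iterrows():
        log.info("discarding covariate %s: %s", row["covariate"], row["reason"])
    if not keep:
        raise ValueError(f"no species with at least {min_obs} detections")
    history = history.subset_species(keep)

    data = GroupData.from_inputs(history, site_cov, point_cov, covariates=covariates)
    report = PrepareReport(retained_species=keep, discarded_species=dropped,
                           retained_covariates=list(covariates),
                           covariate_report=cov_report)
    return data, report


@dataclass
class GroupResult:
    group: str
    draws: PosteriorDraws
    report: DiagnosticReport
    effects: pd.DataFrame | None
    fractions: pd.DataFrame | None
    trends: pd.DataFrame | None
    withheld: bool = False


def fit_group(data: GroupData, prior: PriorSpec | None = None,
              config: MCMCConfig | None = None) -> PosteriorDraws:
    return run_mcmc(data, prior or PriorSpec(), config or MCMCConfig())


def fit_all_groups(groups: dict, prior: PriorSpec | None = None,
                   config: MCMCConfig | None = None, force: bool = False,
                   rhat_threshold: float = 1.1, pvalue_seed: int = 0) -> dict:
    """Fit each group independently and summarize; summaries are withheld for
    any fit with R-hat flags unless ``force`` is set."""
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    results = {}
    for name, data in groups.items():
        if data is None:
            log.warning("group %s has no data; skipped", name)
            continue
        draws = run_mcmc(data, prior, config)
        report = diagnose(draws, data, rhat_threshold=rhat_threshold, seed=pvalue_seed)
        if report.converged or force:
            effects = summarize_effects(draws)
            fractions = classify_fractions(effects)
            trends = mean_area_occupancy(draws, data)
            withheld = False
        else:
            log.warning("group %s: %d parameters with R-hat > %.2f; summaries withheld",
                        name, len(report.flags), rhat_threshold)
            effects = fractions = trends = None
            withheld = True
        results[name] = GroupResult(group=name, draws=draws, report=report,
                                    effects=effects, fractions=fractions,
                                    trends=trends, withheld=withheld)
    return results


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def enumerate_loglik(psi: np.ndarray, p: np.ndarray, y: np.ndarray) -> float:
    """Brute-force marginal log-likelihood by summing over every latent-state
    configuration.  Exponential in S*N*Y — tiny problems only."""
    S, K, N, Y = y.shape
    cells = [(j, i, t) for j in range(S) for i in range(N) for t in range(Y)
             if not np.isnan(y[j, :, i, t]).all()]
    total = 0.0
    for z_cfg in itertools.product((0, 1), repeat=len(cells)):
        joint = 1.0
        for (j, i, t), z in zip(cells, z_cfg):
            pr_z = psi[j, i, t] if z else 1 - psi[j, i, t]
            joint *= pr_z
            for k in range(K):
                yy = y[j, k, i, t]
                if np.isnan(yy):
                    continue
                pd_ = p[j, k, i, t] * z
                joint *= pd_ if yy == 1 else 1 - pd_
        total += joint
    return float(np.log(total))


def toy_group_data(y: np.ndarray) -> GroupData:
    """Wrap an (S, K) single-species, single-year history with no covariates."""
    S, K = y.shape
    return GroupData(y=y.astype(float)[:, :, None, None],
                     X=np.zeros((S, 1, 0)), x_det=np.zeros((S, K, 1)),
                     surveyed=np.ones((S, 1), dtype=bool),
                     species=("sp001",), years=(1,), covariates=())


def toy_grid_posterior(y: np.ndarray, prior_sd: float = 10.0,
                       half_width: float = 12.0, n_grid: int = 601) -> dict:
    """Fine-grid numerical posterior of (psi, p) for the no-covariate toy.

    The model is psi = inv_logit(u), p = inv_logit(v) with independent
    N(0, prior_sd) priors on u and v — the same model the sampler fits with
    ``pooling="independent"``.  Integrates on a (u, v) grid and returns
    posterior means and sds of psi and p.
    """
    S, K = y.shape
    counts = y.sum(axis=1).astype(int)
    n_c = np.bincount(counts, minlength=K + 1)

    g = np.linspace(-half_width, half_width, n_grid)
    psi = inv_logit(g)[:, None]          # over u
    p = inv_logit(g)[None, :]            # over v
    with np.errstate(divide="ignore"):
        ll = np.zeros((n_grid, n_grid))
        for c in range(1, K + 1):
            if n_c[c]:
                ll += n_c[c] * (np.log(psi) + c * np.log(p) + (K - c) * np.log1p(-p))
        if n_c[0]:
            ll += n_c[0] * np.logaddexp(np.log(psi) + K * np.log1p(-p), np.log1p(-psi))
    lp = ll - 0.5 * (g[:, None] / prior_sd) ** 2 - 0.5 * (g[None, :] / prior_sd) ** 2
    w = np.exp(lp - lp.max())
    w /= w.sum()
    psi_flat, p_flat = inv_logit(g), inv_logit(g)
    w_u, w_v = w.sum(axis=1), w.sum(axis=0)
    e_psi = float(psi_flat @ w_u)
    e_p = float(p_flat @ w_v)
    return {"psi_mean": e_psi, "p_mean": e_p,
            "psi_sd": float(np.sqrt((psi_flat - e_psi) ** 2 @ w_u)),
            "p_sd": float(np.sqrt((p_flat - e_p) ** 2 @ w_v))}


# ---------------------------------------------------------------------------
# Recovery experiment
# ---------------------------------------------------------------------------

HYPER_MEANS = ("mu2_u", "mu2_v", "mu_b") + tuple(f"mu_a[{c}]" for c in OCC_COVARIATES)


@dataclass
class RecoveryReport:
    """Coverage/bias of community hyper-means and effect-classification rates
    over repeated simulate -> fit -> summarize replicates."""

    params: pd.DataFrame          # per hyper-mean: truth, mean bias, coverage
    classification: pd.DataFrame  # per covariate: frac negative/positive/neutral
    n_replicates: int
    n_failed: int

    @property
    def overall_coverage(self) -> float:
        return float(self.params["coverage"].mean())

    @property
    def misclassification_rate(self) -> float:
        """Fraction of species x covariate effects classified non-neutral;
        under a zero-effect truth this is the empirical error rate of the
        95% interval rule (nominally 0.05)."""
        c = self.classification
        return float(1.0 - (c["frac_neutral"] * c["n_species"]).sum() / c["n_species"].sum())


def _truth_value(truth: CommunityTruth, name: str) -> float:
    if name == "mu2_u":
        return truth.mean_occ_intercept
    if name == "mu2_v":
        return truth.mean_det_intercept
    if name == "mu_b":
        return truth.det_slope_mean
    cov = name[5:-1]
    return truth.slope_means[OCC_COVARIATES.index(cov)]


def recovery_experiment(n_replicates: int = 20, seed: int = 0,
                        truth: CommunityTruth | None = None,
                        n_species: int = 15, n_routes: int = 20, n_years: int = 3,
                        config: MCMCConfig | None = None,
                        prior: PriorSpec | None = None) -> RecoveryReport:
    """Repeated simulate -> fit -> summarize with known truth.

    Defaults are the desk-scale study conditions: a zero-effect community of
    15 species on 20 routes (120 sites, 5 points per site) over 3 years,
    fitted with 3 chains x 4000 iterations after 2000 burn-in, thinned by 2.
    Reports per-hyper-mean bias and empirical 95% BCI coverage and the
    pooled effect-sign classification fractions.  Replicates whose fit raises
    are excluded and counted.
    """
    truth = truth or zero_effect_truth()
    prior = prior or PriorSpec()
    base_cfg = config or MCMCConfig(n_chains=3, n_iter=4000, burn_in=2000, thin=2)
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_replicates) % (2 ** 31)

    cov_rows, class_counts, n_failed = [], {}, 0
    for r in range(n_replicates):
        s_land, s_comm, s_mcmc = (int(s) for s in seeds[3 * r:3 * r + 3])
        design = default_design(n_routes=n_routes, n_years=n_years)
        try:
            site_cov, point_cov = simulate_landscape(design, seed=s_land)
            bundle = simulate_community(design, site_cov, point_cov, truth,
                                        n_species=n_species, seed=s_comm)
            data = GroupData.from_inputs(bundle.history, site_cov, point_cov)
            cfg = MCMCConfig(n_chains=base_cfg.n_chains, n_iter=base_cfg.n_iter,
                             burn_in=base_cfg.burn_in, thin=base_cfg.thin,
                             seed=s_mcmc, adapt=base_cfg.adapt,
                             target_accept=base_cfg.target_accept)
            draws = run_mcmc(data, prior, cfg)
        except Exception:
            log.exception("replicate %d failed; excluded", r)
            n_failed += 1
            continue

        for name in HYPER_MEANS:
            if name.startswith("mu_a["):
                ci = OCC_COVARIATES.index(name[5:-1])
                pooled = draws.pooled("mu_a")[:, ci]
            else:
                pooled = draws.pooled(name)
            lo, hi = np.percentile(pooled, (2.5, 97.5))
            tv = _truth_value(truth, name)
            cov_rows.append({"parameter": name, "replicate": r, "truth": tv,
                             "bias": float(pooled.mean() - tv),
                             "covered": bool(lo <= tv <= hi)})

        effects = summarize_effects(draws)
        occ = effects[effects["covariate"] != "p_fors"]
        for cov, sub in occ.groupby("covariate"):
            cnt = class_counts.setdefault(cov, {"negative": 0, "positive": 0,
                                                "neutral": 0, "n": 0})
            vc = sub["classification"].value_counts()
            for k in ("negative", "positive", "neutral"):
                cnt[k] += int(vc.get(k, 0))
            cnt["n"] += len(sub)

    cov_df = pd.DataFrame(cov_rows)
    params = cov_df.groupby("parameter").agg(
        truth=("truth", "first"), bias=("bias", "mean"),
        coverage=("covered", "mean"), n=("covered", "size")).reset_index()
    classification = pd.DataFrame(
        [{"covariate": cov, "n_species": d["n"],
          "frac_negative": d["negative"] / d["n"],
          "frac_positive": d["positive"] / d["n"],
          "frac_neutral": d["neutral"] / d["n"]} for cov, d in class_counts.items()])
    return RecoveryReport(params=params, classification=classification,
                          n_replicates=n_replicates - n_failed, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A single human-editable description of one full run."""

    out_dir: str = "runs/out"
    seed: int = 0
    min_obs: int = DEFAULT_MIN_OBS
    r_threshold: float = DEFAULT_R_THRESHOLD
    groups: dict = field(default_factory=dict)   # group name -> table paths
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        prior = PriorSpec(**raw.pop("prior", {}))
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(prior=prior, mcmc=mcmc, **raw)
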