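"""Posterior summaries: covariate-effect classification, regional occupancy
trends and per-site occupancy prediction tables.

A covariate "affects" a species when the 95% credible interval of its
coefficient excludes zero — negative when the 97.5% quantile is below zero,
positive when the 2.5% quantile is above zero, neutral otherwise.  Intervals
are empirical percentiles pooled across chains (linear interpolation);
occupancy summaries always transform draw-wise through the inverse logit
before averaging, never the other way around.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import GroupData, inv_logit
from .sampler import PosteriorDraws

__all__ = ["summarize_effects", "classify_fractions", "mean_area_occupancy",
           "predict_occupancy_surface"]

_Q = (2.5, 97.5)


def _classify(lo, hi):
    if hi < 0:
        return "negative"
    if lo > 0:
        return "positive"
    return "neutral"


def summarize_effects(draws: PosteriorDraws, min_draws: int = 100) -> pd.DataFrame:
    """Per species × covariate posterior mean, sd, 95% BCI and sign class.

    Includes the six occupancy slopes and the detection forest slope
    (covariate ``p_fors``).  Pooled across chains.
    """
    if draws.total_draws < min_draws:
        raise ValueError(f"need at least {min_draws} pooled draws, "
                         f"have {draws.total_draws}")
    a = draws.pooled("a")           # (D, N, C)
    b = draws.pooled("b")           # (D, N)
    rows = []
    for ci, cov in enumerate(draws.covariates):
        lo, hi = np.percentile(a[:, :, ci], _Q, axis=0)
        mean, sd = a[:, :, ci].mean(axis=0), a[:, :, ci].std(axis=0, ddof=1)
        for si, sp in enumerate(draws.species):
            rows.append({"species": sp, "covariate": cov, "mean": mean[si],
                         "sd": sd[si], "q2.5": lo[si], "q97.5": hi[si],
                         "classification": _classify(lo[si], hi[si])})
    lo, hi = np.percentile(b, _Q, axis=0)
    mean, sd = b.mean(axis=0), b.std(axis=0, ddof=1)
    for si, sp in enumerate(draws.species):
        rows.append({"species": sp, "covariate": "p_fors", "mean": mean[si],
                     "sd": sd[si], "q2.5": lo[si], "q97.5": hi[si],
                     "classification": _classify(lo[si], hi[si])})
    return pd.DataFrame(rows)


def classify_fractions(effects: pd.DataFrame, grouping: pd.Series | None = None) -> pd.DataFrame:
    """Fractions of species classified negative/positive/neutral per covariate.

    ``grouping`` optionally maps species to guilds/groups; fractions are then
    reported overall and per group.  Within each (group, covariate) row the
    three fractions sum to one.
    """
    if effects.empty:
        raise ValueError("effects table is empty")
    df = effects.copy()
    df["group"] = "overall" if grouping is None else df["species"].map(grouping)
    frames = []
    scopes = [("overall", effects)] if grouping is None else \
        [("overall", effects)] + [(g, sub) for g, sub in df.groupby("group")]
    for gname, sub in scopes:
        for cov, csub in sub.groupby("covariate"):
            n = len(csub)
            counts = csub["classification"].value_counts()
            frames.append({"group": gname, "covariate": cov, "n_species": n,
                           "frac_negative": counts.get("negative", 0) / n,
                           "frac_positive": counts.get("positive", 0) / n,
                           "frac_neutral": counts.get("neutral", 0) / n})
    return pd.DataFrame(frames)


def _psi_draws(draws: PosteriorDraws, data: GroupData, species_idx, year_idx) -> np.ndarray:
    """(D, S) draws of psi for one species and year over all sites."""
    u = draws.pooled("u")[:, species_idx, year_idx]            # (D,)
    a = draws.pooled("a")[:, species_idx, :]                   # (D, C)
    x = data.X[:, year_idx, :]                                 # (S, C)
    eta = u[:, None] + a @ x.T
    return inv_logit(eta)


def mean_area_occupancy(draws: PosteriorDraws, data: GroupData,
                        species=None, years=None) -> pd.DataFrame:
    """Posterior summary of regional mean occupancy per species and year.

    For each stored draw, psi is computed at every surveyed site and averaged
    over sites; the table reports the posterior mean, sd and 95% BCI of that
    site average.
    """
    species = list(species) if species is not None else list(draws.species)
    years = list(years) if years is not None else list(draws.years)
    rows = []
    for sp in species:
        si = draws.species.index(sp)
        for yr in years:
            ti = draws.years.index(yr)
            mask = data.surveyed[:, ti]
            if not mask.any():
                raise ValueError(f"no surveyed sites in year {yr!r}")
            psi = _psi_draws(draws, data, si, ti)[:, mask].mean(axis=1)
            lo, hi = np.percentile(psi, _Q)
            rows.append({"species": sp, "year": yr, "mean": psi.mean(),
                         "sd": psi.std(ddof=1), "q2.5": lo, "q97.5": hi})
    return pd.DataFrame(rows)


def predict_occupancy_surface(draws: PosteriorDraws, data: GroupData,
                              species, years=None,
                              site_coords: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site posterior occupancy table for mapping in external tools.

    One row per (site, species, year) with the site's coordinates (taken from
    the lat/long covariate columns unless given explicitly), posterior mean
    psi, sd and 95% BCI.  psi is transformed draw-wise (inverse logit of each
    draw's linear predictor) and then summarized.
    """
    species = [species] if isinstance(species, str) else list(species)
    years = list(years) if years is not None else list(draws.years)
    for sp in species:
        if sp not in draws.species:
            raise ValueError(f"species {sp!r} was not modelled")
    try:
        lat_i = draws.covariates.index("lat")
        lon_i = draws.covariates.index("long")
    except ValueError:
        lat_i = lon_i = None
    rows = []
    for sp in species:
        si = draws.species.index(sp)
        for yr in years:
            ti = draws.years.index(yr)
            psi = _psi_draws(draws, data, si, ti)      # (D, S)
            lo, hi = np.percentile(psi, _Q, axis=0)
            mean, sd = psi.mean(axis=0), psi.std(axis=0, ddof=1)
            for j in range(psi.shape[1]):
                if not data.surveyed[j, ti]:
                    continue
                if site_coords is not None:
                    lat, lon = site_coords[j]
                elif lat_i is not None:
                    lat, lon = data.X[j, ti, lat_i], data.X[j, ti, lon_i]
                else:
                    lat = lon = np.nan
                rows.append({"site": j, "species": sp, "year": yr,
                             "lat": lat, "long": lon, "psi_mean": mean[j],
                             "psi_sd": sd[j], "q2.5": lo[j], "q97.5": hi[j]})
    return pd.DataFrame(rows)
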