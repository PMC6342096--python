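"""Convergence diagnostics, interval summaries, posterior predictive checks,
and derived demographic maps."""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from . import particle
from .landscape import GridLandscape
from .mcmc import PosteriorDraws
from .observations import SurveyDataset, pellet_sample
from .params import PARAM_NAMES
from .dispersal import build_kernel


def gelman_rubin(draws, parameter: str) -> float:
    """Potential scale reduction factor R̂ from between/within-chain variance.

    Classic (non-split) form: with m chains of length n, W the mean
    within-chain variance and B/n the variance of chain means,
    R̂ = sqrt(((n−1)/n·W + B/n) / W).  Convergence practice requires
    R̂ < 1.1 for every parameter.
    """
    chains = draws.by_chain(parameter) if isinstance(draws, PosteriorDraws) \
        else [np.asarray(c, dtype=float) for c in draws]
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    n = min(len(c) for c in chains)
    if n < 10:
        raise ValueError("Gelman-Rubin needs at least 10 draws per chain")
    x = np.array([c[:n] for c in chains], dtype=float)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def hpd_interval(samples, mass: float = 0.95) -> Tuple[float, float]:
    """Shortest interval containing ⌈mass·n⌉ of the sorted samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = s[k - 1:] - s[: n - k + 1]
    j = int(np.argmin(widths))
    return float(s[j]), float(s[j + k - 1])


def freeman_tukey(y, expected) -> float:
    """Freeman–Tukey discrepancy Σ (√y − √E)² between counts and means."""
    y = np.asarray(y, dtype=float)
    expected = np.asarray(expected, dtype=float)
    return float(np.sum((np.sqrt(y) - np.sqrt(expected)) ** 2))


def sample_latent_trajectory(psi, data: SurveyDataset, land: GridLandscape,
                             P: int, rng: np.random.Generator,
                             dt: float = 1.0 / 16.0) -> dict:
    """Draw one latent state trajectory conditioned on the observed data.

    Runs the particle filter at ψ with unconditional yearly resampling,
    recording the genealogy, and returns the fields {year: N_r} of one
    lineage sampled at the final year — a (degenerate-genealogy) draw from
    the smoothing distribution, adequate for posterior predictive checks.
    Raises FilterFailureError when ψ cannot support the data.
    """
    from scipy.special import logsumexp

    growth = psi.growth()
    kernel = build_kernel(land, psi.movement(dt))
    obs = psi.observation()
    t0, t1 = data.year_range()
    ens = particle.init_particles_filtered(land, data, obs, P, rng)
    logw = ens.log_weights - logsumexp(ens.log_weights)
    idx = particle.systematic_resample(np.exp(logw), rng)
    seq = [ens.N_r[idx]]
    ens = particle.ParticleEnsemble(N_r=seq[0], log_weights=np.full(
        P, -np.log(P)), year=t0)
    for t in range(t0, t1):
        ens = particle.propagate(ens, growth, kernel, data.hunting_at(t),
                                 land, rng)
        logw = ens.log_weights + particle._year_obs_loglik(
            ens.N_r, data, ens.year, obs, land)
        norm = logsumexp(logw)
        if not np.isfinite(norm):
            raise particle.FilterFailureError(
                f"no particle supports the data in year {ens.year}")
        idx = particle.systematic_resample(np.exp(logw - norm), rng)
        seq = [s[idx] for s in seq] + [ens.N_r[idx]]
        ens = particle.ParticleEnsemble(N_r=seq[-1], log_weights=np.full(
            P, -np.log(P)), year=ens.year)
    j = int(rng.integers(P))
    return {t0 + k: s[j] for k, s in enumerate(seq)}


def posterior_predictive_p(draws: PosteriorDraws, data: SurveyDataset,
                           land: GridLandscape, rng: np.random.Generator,
                           dt: float = 1.0 / 16.0, max_draws: int = 200,
                           particles: int = 100) -> float:
    """Bayesian p-value from the Freeman–Tukey statistic.

    For each retained draw ψ, latent states are sampled *conditioned on the
    observed data* via a particle-filter genealogy draw (pseudo-marginal
    MCMC retains no state posteriors, so they are re-simulated here); the
    discrepancy T = Σ(√y − √E[y|ψ, states])², pooled over pellet and block
    counts, is then computed for the observed counts and for replicate
    counts drawn from the observation models at the same states, and p is
    the fraction of draws with T_rep ≥ T_obs.  Draws whose ψ cannot support
    the data (filter failure) are skipped.
    """
    idx = np.linspace(0, len(draws.df) - 1,
                      min(max_draws, len(draws.df))).astype(int)
    exceed = 0
    used = 0
    for row in idx:
        psi = draws.psi_at(int(row))
        obs = psi.observation()
        try:
            fields = sample_latent_trajectory(psi, data, land, particles,
                                              rng, dt)
        except particle.FilterFailureError:
            continue
        t_obs = t_rep = 0.0
        for _, r in data.pellet.iterrows():
            N = fields[int(r["year"])][int(r["cell"])]
            A = land.area[int(r["cell"])]
            e = obs.gamma * N / A
            rep = pellet_sample(np.array([N]), np.array([A]), obs, rng)[0]
            t_obs += (np.sqrt(r["count"]) - np.sqrt(e)) ** 2
            t_rep += (np.sqrt(rep) - np.sqrt(e)) ** 2
        for _, r in data.block.iterrows():
            N = fields[int(r["year"])][int(r["cell"])]
            A = land.area[int(r["cell"])]
            e = r["area_km2"] * N / A
            rep = rng.poisson(e)
            t_obs += (np.sqrt(r["count"]) - np.sqrt(e)) ** 2
            t_rep += (np.sqrt(rep) - np.sqrt(e)) ** 2
        used += 1
        if t_rep >= t_obs:
            exceed += 1
    if used == 0:
        raise particle.FilterFailureError(
            "no retained draw could reproduce the data")
    return exceed / used


def demographic_maps(draws: PosteriorDraws, land: GridLandscape) -> pd.DataFrame:
    """Per-cell posterior medians of the growth rate r_i and the staying
    preference h_ii = β1·FRT_i + β2·RIV_i, as a mappable table."""
    a0 = draws.parameter("alpha0")[:, None]
    a1 = draws.parameter("alpha1")[:, None]
    a2 = draws.parameter("alpha2")[:, None]
    b1 = draws.parameter("beta1")[:, None]
    b2 = draws.parameter("beta2")[:, None]
    r = np.exp(a0 + a1 * land.blf[None, :] + a2 * land.edge[None, :])
    h = b1 * land.frt[None, :] + b2 * land.riv[None, :]
    return pd.DataFrame({
        "cell_id": np.arange(1, land.n + 1),
        "x_km": land.x, "y_km": land.y,
        "growth_rate": np.median(r, axis=0),
        "habitat_preference": np.median(h, axis=0),
    })


def summarize(draws: PosteriorDraws, mass: float = 0.95,
              extra_mass: float = None) -> pd.DataFrame:
    """Posterior medians, HPD intervals and R̂ for the 8 parameters."""
    rows = []
    for name in PARAM_NAMES:
        x = draws.parameter(name)
        lo, hi = hpd_interval(x, mass)
        rec = {"name": name, "median": float(np.median(x)),
               f"hpd{100 * (1 - mass) / 2:g}": lo,
               f"hpd{100 * (1 + mass) / 2:g}": hi,
               "rhat": gelman_rubin(draws, name)}
        if extra_mass is not None:
            l2, h2 = hpd_interval(x, extra_mass)
            rec[f"hpd{100 * (1 - extra_mass) / 2:g}"] = l2
            rec[f"hpd{100 * (1 + extra_mass) / 2:g}"] = h2
        rows.append(rec)
    return pd.DataFrame(rows)
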