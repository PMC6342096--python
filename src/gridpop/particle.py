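"""Bootstrap particle filter over the spatial abundance field.

The filter returns an unbiased estimate of the (unnormalized) marginal
likelihood of the survey data given ψ, for use inside pseudo-marginal MCMC.
Its one non-standard ingredient is the initialization.  First-year fields
are built cell by cell in a fixed scan: cell i's initial-state prior is a
heavy-tailed negative binomial (dispersion κ, default 1) with mean

    μ_i = (1 − b)·λ̃_i + b · A_i Σ_{j∈n_i, sampled} N_j / Σ_{j∈n_i, sampled} A_j,

a blend of a data pilot λ̃ (survey densities, a floor, and a feasibility
allowance for first-year hunting records — ψ-free, see
:func:`pilot_lambda`) with the auto-model conditional mean over the
particle's already-sampled neighbours, giving a proper joint distribution
that expresses the spatial autocorrelation of the initial range.  Each cell
is then *sampled from its filtered conditional*
q(N_i) ∝ p0(N_i; μ_i)·L_obs(N_i), where L_obs is the product of first-year
pellet/block likelihoods at cell i (1 if unobserved), and the particle's
importance weight is the product of per-cell predictive normalizers
Σ_k p0(k; μ_i)·L_obs(k).  This is direct sampling of the first-year states
from their filtered distribution; it keeps the importance weights tight
where blind initialization collapses to an effective sample size near 1.

Subsequent years use the process model as the bootstrap proposal: Poisson
growth, multinomial allocation of recorded unit hunting totals (infeasible
draws zero the particle weight), multinomial dispersal; weights accumulate
the pellet and block log-likelihoods, with systematic resampling when the
effective sample size drops below half the particle count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom

from .dispersal import MovementKernel, MovementParams, build_kernel
from .landscape import GridLandscape
from .observations import ObservationParams, SurveyDataset, block_loglik, pellet_loglik
from .process import GrowthParams, dispersal_many

logger = logging.getLogger(__name__)


class FilterFailureError(RuntimeError):
    """All particles carry zero weight; the likelihood estimate is 0."""


class DegenerateProposalError(RuntimeError):
    """A cell's truncated initialization proposal has no admissible state."""


@dataclass
class PFConfig:
    """Tuning knobs of the filter (all have working defaults).

    ``nmax_floor``/``nmax_mult`` set the per-cell initialization truncation
    N_max = max(floor, mult·λ_i), extended until the Poisson(λ) tail mass
    beyond N_max is below ``tail_tol``.  ``lambda_floor`` keeps unobserved
    unmasked cells reachable.  Resampling triggers at ESS < ess_frac·P.
    """

    nmax_floor: int = 50
    nmax_mult: float = 5.0
    tail_tol: float = 1e-6
    lambda_floor: float = 0.1
    ess_frac: float = 0.5
    hunt_cover: float = 12.0      # pilot unit mass as a multiple of first-year records
    neighbor_blend: float = 0.5   # weight on sampled-neighbour mean in the proposal
    pilot_gamma: float = 50.0     # fixed pellets-per-density constant for the ψ-free pilot
    init_kappa: float = 1.0       # NB dispersion of the initial prior (heavy tail)


@dataclass
class ParticleEnsemble:
    """P replicate abundance fields with log-weights at one year."""

    N_r: np.ndarray                   # (P, n) int64
    log_weights: np.ndarray           # (P,)
    year: int
    trace: list = field(default_factory=list, repr=False)

    @property
    def P(self) -> int:
        return self.N_r.shape[0]

    def ess(self) -> float:
        """Effective sample size 1 / Σ w̃_i² of the normalized weights."""
        lw = self.log_weights - logsumexp(self.log_weights)
        return float(np.exp(-logsumexp(2.0 * lw)))


def pilot_lambda(land: GridLandscape, data: SurveyDataset,
                 obs: Optional[ObservationParams], year: int,
                 config: PFConfig = None) -> np.ndarray:
    """Data-driven pilot abundance λ̃_i for the first-year initial prior.

    Block cells use the observed density B/A^B scaled to the habitat area;
    pellet cells invert the NB mean, N ≈ F·A/γ; remaining unmasked cells
    take the value of the nearest observed unmasked cell (or the floor if
    nothing was observed), floored at ``lambda_floor``; masked cells get
    exactly 0.  Units with first-year hunting records get their pilot mass
    topped up to ``hunt_cover`` times the record, since the records bound
    unit abundance from below.

    The particle filter itself always calls this with ``obs=None``: the
    pellet inversion then uses the fixed constant ``config.pilot_gamma``
    (a literature-scale pellets-per-density value), so the pilot depends on
    the data but not on ψ, the initial prior it parameterizes is a fixed
    distribution, and the pseudo-marginal target is untouched.  Passing
    ``obs`` switches the inversion to the current γ, for pilot uses outside
    the filter (e.g. seeding posterior predictive replicates).
    """
    config = config or PFConfig()
    lam = np.full(land.n, np.nan)
    bl = data.block_at(year)
    for c, cnt, ab in zip(bl["cell"], bl["count"], bl["area_km2"]):
        lam[int(c)] = cnt / ab * land.area[int(c)]
    gamma_pilot = config.pilot_gamma if obs is None else obs.gamma
    pe = data.pellet_at(year)
    for c, cnt in zip(pe["cell"], pe["count"]):
        est = cnt * land.area[int(c)] / gamma_pilot
        lam[int(c)] = est if np.isnan(lam[int(c)]) else 0.5 * (lam[int(c)] + est)
    unmasked = land.present2000 != 0
    observed = np.flatnonzero(~np.isnan(lam) & unmasked)
    if observed.size == 0:
        observed = np.flatnonzero(~np.isnan(lam))
    missing = np.flatnonzero(np.isnan(lam))
    if observed.size and missing.size:
        d2 = ((land.x[missing, None] - land.x[observed]) ** 2
              + (land.y[missing, None] - land.y[observed]) ** 2)
        lam[missing] = lam[observed[np.argmin(d2, axis=1)]]
    elif missing.size:
        lam[missing] = 0.0
    lam[unmasked] = np.maximum(lam[unmasked], config.lambda_floor)
    lam[~unmasked] = 0.0
    for k, Hu in data.hunting_at(year).items():
        cells = np.flatnonzero((land.unit_id == int(k)) & unmasked)
        if cells.size and Hu > 0:
            deficit = config.hunt_cover * Hu - lam[cells].sum()
            if deficit > 0:
                lam[cells] += deficit / cells.size
    return lam


def init_prior_logpmf(k: np.ndarray, mu: np.ndarray,
                      config: PFConfig = None) -> np.ndarray:
    """Log-pmf of the per-cell initial prior: NB with mean μ, dispersion κ.

    A heavy-tailed (κ = 1: geometric-tailed) prior keeps large first-year
    abundances reachable even where the pilot under-pitches the mean — the
    overdispersed pellet counts make any moment-based pilot a rough guess.
    Broadcasts k (states) against mu (per-particle means).
    """
    config = config or PFConfig()
    kap = config.init_kappa
    return (gammaln(k + kap) - gammaln(kap) - gammaln(k + 1.0)
            + kap * np.log(kap / (kap + mu))
            + k * np.log(mu / (kap + mu)))


def cell_nmax(lam: float, config: PFConfig = None) -> int:
    """Per-cell truncation bound for the initialization proposal."""
    config = config or PFConfig()
    nmax = int(max(config.nmax_floor, np.ceil(config.nmax_mult * lam)))
    kap = config.init_kappa
    lam = max(lam, 1e-12)
    while nbinom.sf(nmax, kap, kap / (kap + lam)) > config.tail_tol:
        nmax *= 2
    return nmax


def _cell_obs_loglik(land, data, obs, year, i, k):
    """Σ first-year pellet/block log-likelihoods at cell i over a state grid."""
    obs_ll = np.zeros(k.size)
    pe = data.pellet_at(year)
    for c, cnt in zip(pe["cell"], pe["count"]):
        if int(c) == i:
            obs_ll += pellet_loglik(cnt, k, land.area[i], obs)
    bl = data.block_at(year)
    for c, cnt, ab in zip(bl["cell"], bl["count"], bl["area_km2"]):
        if int(c) == i:
            obs_ll += block_loglik(cnt, k, land.area[i], ab)
    return obs_ll


def init_particles_filtered(land: GridLandscape, data: SurveyDataset,
                            obs: ObservationParams, P: int,
                            rng: np.random.Generator,
                            config: PFConfig = None,
                            pilot: Optional[np.ndarray] = None,
                            year: Optional[int] = None) -> ParticleEnsemble:
    """Draw first-year fields cell-by-cell from their filtered distribution.

    Cells are visited in a fixed scan.  Cell i's initial prior is
    Poisson(μ_i) with μ_i = (1−b)·λ̃_i + b·(auto-model conditional mean over
    the particle's already-sampled neighbours); the cell is sampled from the
    filtered conditional q(N_i) ∝ Poisson(N_i; μ_i)·L_obs(N_i) truncated to
    [0, N_max], and the particle's importance log-weight accumulates the
    predictive normalizer log Σ_k Poisson(k; μ_i)·L_obs(k).  The resulting
    weights estimate (unnormalized) the first-year evidence, with the
    first-year observations entering exactly once.  Masked cells are fixed
    at zero.  ``pilot`` overrides the data-driven λ̃.
    """
    if P < 2:
        raise ValueError("need at least 2 particles")
    config = config or PFConfig()
    t0 = data.year_range()[0] if year is None else year
    lam = pilot_lambda(land, data, None, t0, config) if pilot is None \
        else np.asarray(pilot, dtype=float)
    blend = config.neighbor_blend
    fields = np.zeros((P, land.n), dtype=np.int64)
    logw = np.zeros(P)
    decided = land.present2000 == 0          # masked cells are fixed at 0
    for i in np.flatnonzero(land.present2000 != 0):
        nb = land.neighbors[i]
        done = nb[decided[nb]] if nb.size else nb
        if done.size:
            cond = land.area[i] * fields[:, done].sum(axis=1) / land.area[done].sum()
            mu = np.maximum((1 - blend) * lam[i] + blend * cond,
                            config.lambda_floor)
        else:
            mu = np.full(P, max(lam[i], config.lambda_floor))
        nmax = cell_nmax(float(mu.max()), config)
        k = np.arange(nmax + 1)
        obs_ll = _cell_obs_loglik(land, data, obs, t0, i, k)
        logq = init_prior_logpmf(k[None, :], mu[:, None], config) \
            + obs_ll[None, :]
        log_z = logsumexp(logq, axis=1)      # predictive normalizer per particle
        if not np.all(np.isfinite(log_z)):
            raise DegenerateProposalError(
                f"initialization proposal for cell {i} has no support on "
                f"[0, {nmax}]")
        cdf = np.cumsum(np.exp(logq - log_z[:, None]), axis=1)
        cdf[:, -1] = 1.0
        idx = np.minimum((cdf < rng.random(P)[:, None]).sum(axis=1), nmax)
        fields[:, i] = k[idx]
        logw += log_z
        decided[i] = True
    ens = ParticleEnsemble(N_r=fields, log_weights=logw, year=t0)
    logger.info("PF init: year=%d ESS=%.1f/%d", t0, ens.ess(), P)
    return ens


def init_particles_blind(land: GridLandscape, data: SurveyDataset,
                         obs: ObservationParams, P: int,
                         rng: np.random.Generator,
                         config: PFConfig = None,
                         pilot: Optional[np.ndarray] = None,
                         year: Optional[int] = None) -> ParticleEnsemble:
    """Reference initialization: blind sampling from the initial prior.

    Fields are drawn from the same sequential auto-regressive prior as
    :func:`init_particles_filtered` but *without* conditioning on the
    first-year observations, which enter only through the importance weight
    Σ_i log L_obs(N_i).  Targets the same distribution (for ESS
    comparisons), at the cost of far noisier weights.
    """
    if P < 2:
        raise ValueError("need at least 2 particles")
    config = config or PFConfig()
    t0 = data.year_range()[0] if year is None else year
    lam = pilot_lambda(land, data, None, t0, config) if pilot is None \
        else np.asarray(pilot, dtype=float)
    blend = config.neighbor_blend
    fields = np.zeros((P, land.n), dtype=np.int64)
    decided = land.present2000 == 0
    for i in np.flatnonzero(land.present2000 != 0):
        nb = land.neighbors[i]
        done = nb[decided[nb]] if nb.size else nb
        if done.size:
            cond = land.area[i] * fields[:, done].sum(axis=1) / land.area[done].sum()
            mu = np.maximum((1 - blend) * lam[i] + blend * cond,
                            config.lambda_floor)
        else:
            mu = np.full(P, max(lam[i], config.lambda_floor))
        kap = config.init_kappa
        fields[:, i] = rng.negative_binomial(kap, kap / (kap + mu))
        decided[i] = True
    logw = _year_obs_loglik(fields, data, t0, obs, land)
    return ParticleEnsemble(N_r=fields, log_weights=logw, year=t0)


def _year_obs_loglik(fields: np.ndarray, data: SurveyDataset, year: int,
                     obs: ObservationParams, land: GridLandscape) -> np.ndarray:
    """Σ pellet + block log-likelihoods at ``year`` for a (P, n) batch."""
    P = fields.shape[0]
    total = np.zeros(P)
    pe = data.pellet_at(year)
    if len(pe):
        c = pe["cell"].to_numpy(int)
        total += pellet_loglik(pe["count"].to_numpy(float)[None, :],
                               fields[:, c], land.area[c][None, :],
                               obs).sum(axis=1)
    bl = data.block_at(year)
    if len(bl):
        c = bl["cell"].to_numpy(int)
        total += block_loglik(bl["count"].to_numpy(float)[None, :],
                              fields[:, c], land.area[c][None, :],
                              bl["area_km2"].to_numpy(float)[None, :]).sum(axis=1)
    return total


def propagate(ens: ParticleEnsemble, growth: GrowthParams,
              kernel: MovementKernel, hunting_totals: dict,
              land: GridLandscape, rng: np.random.Generator) -> ParticleEnsemble:
    """Advance every particle one year: growth, hunting, dispersal.

    ``hunting_totals`` maps unit label -> recorded total for the current
    year.  Particles whose multinomial allocation is infeasible (unit
    abundance below the record, or a cell drawn past its holding) get weight
    −inf; if all do, the filter fails.
    """
    P, n = ens.N_r.shape
    r = growth.rates(land)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite growth rate")
    N_h = rng.poisson(r[None, :] * ens.N_r).astype(np.int64)
    feasible = np.ones(P, dtype=bool)
    H = np.zeros_like(N_h)
    units = land.units
    for k, Hu in hunting_totals.items():
        Hu = int(Hu)
        if Hu == 0:
            continue
        cells = units[int(k)]
        sub = N_h[:, cells]
        tot = sub.sum(axis=1)
        short = tot < Hu
        p = sub / np.maximum(tot, 1)[:, None]
        p[short] = 1.0 / cells.size
        draws = rng.multinomial(Hu, p)
        over = np.any(draws > sub, axis=1)
        feasible &= ~(short | over)
        H[:, cells] = draws
    N_d = np.maximum(N_h - H, 0)
    N_d[~feasible] = 0
    nxt = dispersal_many(N_d, kernel.annual, rng)
    logw = ens.log_weights.copy()
    logw[~feasible] = -np.inf
    if not np.any(np.isfinite(logw)):
        raise FilterFailureError(
            f"hunting records infeasible for all particles in year {ens.year}")
    return ParticleEnsemble(N_r=nxt, log_weights=logw, year=ens.year + 1,
                            trace=ens.trace)


def systematic_resample(weights: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Low-variance systematic resampling indices for normalized weights."""
    P = weights.size
    positions = (rng.random() + np.arange(P)) / P
    return np.searchsorted(np.cumsum(weights), positions)


def weight_and_resample(ens: ParticleEnsemble, data: SurveyDataset,
                        obs: ObservationParams, land: GridLandscape,
                        rng: np.random.Generator,
                        config: PFConfig = None):
    """Apply the year's observation weights; resample if ESS < ess_frac·P.

    Assumes the incoming log-weights are normalized (logsumexp 0), as
    maintained by :func:`log_likelihood`; the return value
    ``log_mean_weight`` is then the log incremental likelihood
    log Σ_i w̃_i exp(ℓ_i).  Years without observations contribute 0.
    """
    config = config or PFConfig()
    logw = ens.log_weights + _year_obs_loglik(ens.N_r, data, ens.year, obs, land)
    log_mean = logsumexp(logw)
    if not np.isfinite(log_mean):
        raise FilterFailureError(f"zero likelihood for all particles in year {ens.year}")
    logw = logw - log_mean
    ess = float(np.exp(-logsumexp(2.0 * logw)))
    resampled = ess < config.ess_frac * ens.P
    if resampled:
        idx = systematic_resample(np.exp(logw), rng)
        ens = ParticleEnsemble(N_r=ens.N_r[idx], log_weights=np.full(
            ens.P, -np.log(ens.P)), year=ens.year, trace=ens.trace)
    else:
        ens = ParticleEnsemble(N_r=ens.N_r, log_weights=logw, year=ens.year,
                               trace=ens.trace)
    ens.trace.append({"year": ens.year, "log_mean_weight": float(log_mean),
                      "ess": ess, "resampled": bool(resampled)})
    logger.info("PF year=%d ESS=%.1f/%d resampled=%s",
                ens.year, ess, ens.P, resampled)
    return ens, float(log_mean)


def log_likelihood(data: SurveyDataset, land: GridLandscape,
                   growth: GrowthParams, move: MovementParams,
                   obs: ObservationParams, P: int,
                   rng: np.random.Generator,
                   config: PFConfig = None,
                   kernel: MovementKernel = None,
                   trace: Optional[list] = None) -> float:
    """Particle-filter estimate of the log marginal likelihood of ``data``.

    Sums the initialization importance term and the yearly incremental
    log-likelihoods; returns −inf when the filter fails (a parameter value
    whose support excludes the data).  Bit-identical for identical seeds.
    """
    config = config or PFConfig()
    if kernel is None:
        kernel = build_kernel(land, move)
    t0, t1 = data.year_range()
    try:
        ens = init_particles_filtered(land, data, obs, P, rng, config, year=t0)
    except DegenerateProposalError:
        return float("-inf")
    if trace is not None:
        ens.trace = trace
    log_init = logsumexp(ens.log_weights)
    if not np.isfinite(log_init):
        return float("-inf")
    ll = float(log_init - np.log(P))
    ens.log_weights = ens.log_weights - log_init
    ess = ens.ess()
    ens.trace.append({"year": t0, "log_mean_weight": ll, "ess": ess,
                      "resampled": ess < config.ess_frac * P})
    if ess < config.ess_frac * P:
        idx = systematic_resample(np.exp(ens.log_weights), rng)
        ens = ParticleEnsemble(N_r=ens.N_r[idx],
                               log_weights=np.full(P, -np.log(P)),
                               year=t0, trace=ens.trace)
    try:
        for t in range(t0, t1):
            ens = propagate(ens, growth, kernel, data.hunting_at(t), land, rng)
            ens, lm = weight_and_resample(ens, data, obs, land, rng, config)
            ll += lm
    except FilterFailureError:
        return float("-inf")
    return ll
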