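"""The 8-parameter vector ψ of the state-space model, and its priors.

ψ = (α0, α1, α2, β0, β1, β2, γ, θ): growth intercept and covariate effects,
movement distance/forest/river effects, pellet proportionality constant, and
pellet NB dispersion.  Admissibility: β0 < 0, γ > 0, θ > 0, and the
biological cap max_i r_i < 1.5 over the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .dispersal import MovementParams
from .landscape import GridLandscape
from .observations import ObservationParams
from .process import GrowthParams

PARAM_NAMES = ("alpha0", "alpha1", "alpha2",
               "beta0", "beta1", "beta2", "gamma", "theta")


@dataclass
class Parameters:
    """ψ gathered into one object; convertible to/from a length-8 vector."""

    alpha0: float
    alpha1: float
    alpha2: float
    beta0: float
    beta1: float
    beta2: float
    gamma: float
    theta: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, v) -> "Parameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (8,):
            raise ValueError("parameter vector must have length 8")
        return cls(**dict(zip(PARAM_NAMES, v)))

    def growth(self) -> GrowthParams:
        return GrowthParams(self.alpha0, self.alpha1, self.alpha2)

    def movement(self, dt: float = 1.0 / 16.0) -> MovementParams:
        return MovementParams(self.beta0, self.beta1, self.beta2, dt=dt)

    def observation(self) -> ObservationParams:
        return ObservationParams(self.gamma, self.theta)

    def is_admissible(self, land: GridLandscape) -> bool:
        """All hard constraints, including the landscape-wide growth cap."""
        if not (self.beta0 < 0 and self.gamma > 0 and self.theta > 0):
            return False
        return self.growth().check_cap(land)

    def replace(self, **kw) -> "Parameters":
        return replace(self, **kw)


@dataclass
class Priors:
    """Prior hyper-parameters: vague normals and bounded uniforms.

    Defaults: N(0, sd 10) on α0, α1, α2, β1, β2; U(−10, 0) on β0;
    U(0, 200) on γ; U(0, 10) on θ.  All configurable.
    """

    normal_sd: float = 10.0
    beta0_bounds: tuple = (-10.0, 0.0)
    gamma_bounds: tuple = (0.0, 200.0)
    theta_bounds: tuple = (0.0, 10.0)

    _NORMAL = ("alpha0", "alpha1", "alpha2", "beta1", "beta2")

    def log_prior(self, psi: Parameters, land: GridLandscape) -> float:
        """Joint log prior; −inf outside the constrained support."""
        if not psi.is_admissible(land):
            return float("-inf")
        lo, hi = self.beta0_bounds
        if not lo < psi.beta0 < hi:
            return float("-inf")
        glo, ghi = self.gamma_bounds
        tlo, thi = self.theta_bounds
        if not (glo < psi.gamma < ghi and tlo < psi.theta < thi):
            return float("-inf")
        lp = -np.log(hi - lo) - np.log(ghi - glo) - np.log(thi - tlo)
        sd = self.normal_sd
        for name in self._NORMAL:
            x = getattr(psi, name)
            lp += -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
        return float(lp)

    def sample(self, rng: np.random.Generator,
               land: GridLandscape = None,
               max_tries: int = 1000) -> Parameters:
        """Draw from the prior; rejection against the growth cap if a
        landscape is given."""
        for _ in range(max_tries):
            vals = {n: rng.normal(0.0, self.normal_sd) for n in self._NORMAL}
            psi = Parameters(
                alpha0=vals["alpha0"], alpha1=vals["alpha1"],
                alpha2=vals["alpha2"],
                beta0=rng.uniform(*self.beta0_bounds),
                beta1=vals["beta1"], beta2=vals["beta2"],
                gamma=rng.uniform(*self.gamma_bounds),
                theta=rng.uniform(*self.theta_bounds),
            )
            if land is None or psi.is_admissible(land):
                return psi
        raise RuntimeError("could not draw an admissible parameter vector")


def log_prior(psi: Parameters, land: GridLandscape,
              priors: Priors = None) -> float:
    """Module-level convenience wrapper around Priors.log_prior."""
    return (priors or Priors()).log_prior(psi, land)
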