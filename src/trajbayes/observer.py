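"""Grid-based Bayesian ideal observer for the non-stationary endpoint
distribution (the "statistical model").

The observer assumes endpoints are drawn from a Gaussian N(mu, sigma^2)
whose mean and SD may each independently jump to fresh values on any trial
with per-trial hazard rates alpha_mu and alpha_sigma.  It maintains a joint
posterior over the 4-D lattice {mu, sigma, alpha_mu, alpha_sigma}:

* after feedback on trial i, the posterior is multiplied by the Gaussian
  likelihood of the observed endpoint (Bayes' rule, in log space);
* between trials a "leaky" propagation step redistributes, within each
  (alpha_mu, alpha_sigma) slice, a fraction of the mass uniformly over the
  mu and/or sigma axes, in proportion to the hazard rates of that slice.

The per-trial statistical belief (mu_s(i), sigma_s(i)) is the moment-matched
Gaussian summary of the posterior-predictive mixture over endpoints, taken
*before* observing trial i's endpoint — the distribution the observer
believes to be in force at the beginning of trial i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, GaussianBelief, NumericalError
from .task import Session

__all__ = [
    "GridConfig",
    "ObserverGrid",
    "init_grid",
    "update_bayes",
    "propagate_leaky",
    "predict_endpoint_belief",
    "run_filter",
    "beliefs_frame",
]

_MASS_TOL = 1e-10


@dataclass(frozen=True)
class GridConfig:
    """Axis specification for the observer lattice.

    Defaults: mean axis uniform over the screen; SD and hazard axes
    log-spaced, since those parameters are scale quantities.  A hazard axis
    may be a single fixed value (alphas known rather than inferred), but the
    mean and SD axes must carry at least two points each.
    """

    n_mu: int = 60
    mu_range: tuple[float, float] = (0.0, 1.0)
    n_sigma: int = 20
    sigma_range: tuple[float, float] = (0.005, 0.3)
    n_alpha: int = 8
    alpha_range: tuple[float, float] = (0.001, 0.3)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self.n_mu < 2 or self.n_sigma < 2:
            raise ConfigurationError("mu and sigma axes need >= 2 points")
        if self.n_alpha < 1:
            raise ConfigurationError("alpha axes need >= 1 point")
        for name, (lo, hi) in (
            ("mu_range", self.mu_range),
            ("sigma_range", self.sigma_range),
            ("alpha_range", self.alpha_range),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name} min exceeds max")
        if self.sigma_range[0] <= 0:
            raise ConfigurationError("sigma_range must be positive")
        if not (0.0 <= self.alpha_range[0] <= self.alpha_range[1] <= 1.0):
            raise ConfigurationError("alpha_range must lie in [0, 1]")
        mu = np.linspace(*self.mu_range, self.n_mu)
        sigma = np.geomspace(*self.sigma_range, self.n_sigma)
        if self.n_alpha == 1:
            alpha = np.array([self.alpha_range[0]])
        elif self.alpha_range[0] == 0.0:
            # log spacing needs a positive floor; include 0 explicitly
            alpha = np.concatenate(
                [[0.0], np.geomspace(1e-4, self.alpha_range[1], self.n_alpha - 1)]
            )
        else:
            alpha = np.geomspace(*self.alpha_range, self.n_alpha)
        return mu, sigma, alpha, alpha.copy()


@dataclass
class ObserverGrid:
    """Joint posterior mass over the {mu, sigma, alpha_mu, alpha_sigma}
    lattice; ``mass`` has shape (n_mu, n_sigma, n_alpha_mu, n_alpha_sigma)."""

    mu: np.ndarray
    sigma: np.ndarray
    alpha_mu: np.ndarray
    alpha_sigma: np.ndarray
    mass: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (
            len(self.mu),
            len(self.sigma),
            len(self.alpha_mu),
            len(self.alpha_sigma),
        )
        if self.mass.shape != expected:
            raise ConfigurationError(
                f"mass shape {self.mass.shape} != axes shape {expected}"
            )
        for name in ("mu", "sigma", "alpha_mu", "alpha_sigma"):
            ax = getattr(self, name)
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ConfigurationError(f"{name} axis must be strictly increasing")

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def marginal(self, axis: str) -> np.ndarray:
        idx = {"mu": 0, "sigma": 1, "alpha_mu": 2, "alpha_sigma": 3}[axis]
        other = tuple(i for i in range(4) if i != idx)
        return self.mass.sum(axis=other)

    def copy(self) -> "ObserverGrid":
        return ObserverGrid(
            self.mu, self.sigma, self.alpha_mu, self.alpha_sigma, self.mass.copy()
        )


def init_grid(grid_config: GridConfig | None = None) -> ObserverGrid:
    """Uniform joint prior: equal mass on every lattice cell."""
    cfg = grid_config or GridConfig()
    mu, sigma, a_mu, a_sg = cfg.axes()
    shape = (len(mu), len(sigma), len(a_mu), len(a_sg))
    mass = np.full(shape, 1.0 / np.prod(shape))
    return ObserverGrid(mu, sigma, a_mu, a_sg, mass)


def update_bayes(grid: ObserverGrid, x_i: float) -> ObserverGrid:
    """Multiply by the Gaussian likelihood of the observed endpoint and
    renormalize.  Accumulation is done in log space with max-subtraction."""
    if not np.isfinite(x_i):
        raise ConfigurationError("observed endpoint must be finite")
    loglik = stats.norm.logpdf(x_i, grid.mu[:, None], grid.sigma[None, :])
    with np.errstate(divide="ignore"):
        logpost = np.log(grid.mass) + loglik[:, :, None, None]
    peak = logpost.max()
    if not np.isfinite(peak):
        raise NumericalError(
            "posterior underflow: all cells at zero mass; accumulate in log space"
        )
    post = np.exp(logpost - peak)
    total = post.sum()
    if total <= 0:
        raise NumericalError(
            "posterior underflow after renormalization; accumulate in log space"
        )
    return ObserverGrid(
        grid.mu, grid.sigma, grid.alpha_mu, grid.alpha_sigma, post / total
    )


def propagate_leaky(grid: ObserverGrid) -> ObserverGrid:
    """Between-trial change-point step.

    Within each (alpha_mu, alpha_sigma) slice p(mu, sigma) the new slice is
    the four-way mixture

        (1-a_mu)(1-a_sg) p(mu,sigma) + a_mu(1-a_sg) U(mu) p(sigma)
      + (1-a_mu) a_sg    p(mu) U(sigma) + a_mu a_sg U(mu) U(sigma)

    where p(mu), p(sigma) are the slice marginals and U is uniform over the
    axis.  Slice masses — hence the alpha marginals — are unchanged.
    """
    m = grid.mass
    n_mu, n_sg = len(grid.mu), len(grid.sigma)
    a_mu = grid.alpha_mu.reshape(1, 1, -1, 1)
    a_sg = grid.alpha_sigma.reshape(1, 1, 1, -1)
    p_sigma = m.sum(axis=0, keepdims=True)
    p_mu = m.sum(axis=1, keepdims=True)
    slice_mass = m.sum(axis=(0, 1), keepdims=True)
    new = (
        (1 - a_mu) * (1 - a_sg) * m
        + a_mu * (1 - a_sg) * p_sigma / n_mu
        + (1 - a_mu) * a_sg * p_mu / n_sg
        + a_mu * a_sg * slice_mass / (n_mu * n_sg)
    )
    drift = abs(new.sum() - m.sum())
    if drift > _MASS_TOL:
        raise NumericalError(f"mass drift {drift:.3e} exceeds {_MASS_TOL:.0e}")
    return ObserverGrid(
        grid.mu, grid.sigma, grid.alpha_mu, grid.alpha_sigma, new / new.sum()
    )


def predict_endpoint_belief(grid: ObserverGrid) -> GaussianBelief:
    """Moment-matched Gaussian summary of the posterior-predictive mixture:
    mu_s = E[mu]; sigma_s^2 = E[sigma^2 + mu^2] - mu_s^2."""
    w_mu = grid.marginal("mu")
    w_sigma = grid.marginal("sigma")
    mu_s = float(w_mu @ grid.mu)
    second = float(w_sigma @ grid.sigma**2 + w_mu @ grid.mu**2)
    var = second - mu_s**2
    if var <= 0:
        raise NumericalError("degenerate grid: non-positive predictive variance")
    return GaussianBelief(mu_s, float(np.sqrt(var)), role="statistical")


def run_filter(
    session: Session, grid_config: GridConfig | None = None
) -> list[GaussianBelief]:
    """Run the observer over a session, one update per trial.

    For each trial i the emitted belief is the one in force at the beginning
    of trial i (i.e. after processing trials 1..i-1 but before seeing trial
    i's endpoint).  Every trial is then observed via its feedback endpoint —
    warmup trials included, since feedback is always shown.
    """
    if len(session) == 0:
        raise ConfigurationError("session is empty")
    grid = init_grid(grid_config)
    beliefs: list[GaussianBelief] = []
    for trial in session.trials:
        beliefs.append(predict_endpoint_belief(grid))
        grid = update_bayes(grid, trial.x_end)
        grid = propagate_leaky(grid)
    return beliefs


def beliefs_frame(beliefs: list[GaussianBelief]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(beliefs)),
            "mu_s": [b.mu for b in beliefs],
            "sigma_s": [b.sigma for b in beliefs],
            "log_precision_s": [b.log_precision for b in beliefs],
        }
    )
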