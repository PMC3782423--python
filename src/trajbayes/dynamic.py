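"""Dynamic forward model: quadratic extrapolation of the observed trajectory.

The observer's estimate of the current trajectory is an ordinary
least-squares fit of x(t) = c0 + c1 t + c2 t^2 to the noisy pre-occluder
samples.  The endpoint prediction mu_d is the fitted value at the landing
time t_end, and sigma_d is the standard error of that fitted value — not a
prediction interval, since the true landing point lies on the smooth curve
rather than being a further noisy sample.

A sequential variant treats the statistical belief over endpoints as a prior
by augmenting a weighted least-squares fit with one pseudo-observation
(t_end, prior.mu) of SD prior.sigma.  With all samples included this is
algebraically identical to precision-weighting the prior-free endpoint
estimate with the prior, so estimating the trajectory under a statistical
prior and fusing the two finished estimates predict the same endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, GaussianBelief, NumericalError
from .task import Session

__all__ = [
    "QuadraticFit",
    "fit_quadratic_ols",
    "endpoint_estimate",
    "sequential_estimate_with_prior",
    "run_dynamic",
]


@dataclass
class QuadraticFit:
    """OLS fit of a second-order polynomial to trajectory samples."""

    coef: np.ndarray  # (c0, c1, c2)
    s2: float  # residual variance, RSS / (n - 3)
    xtx: np.ndarray  # 3x3 normal-equations information matrix
    n_points: int

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.coef[0] + self.coef[1] * t + self.coef[2] * t**2


def _design(times: np.ndarray) -> np.ndarray:
    return np.vander(times, 3, increasing=True)


def fit_quadratic_ols(times: np.ndarray, obs_x: np.ndarray) -> QuadraticFit:
    times = np.asarray(times, dtype=float)
    obs_x = np.asarray(obs_x, dtype=float)
    if times.shape != obs_x.shape or times.ndim != 1:
        raise ConfigurationError("times and obs_x must be equal-length 1-D arrays")
    n = len(times)
    if n < 4:
        raise ConfigurationError(f"need >= 4 samples for a residual variance, got {n}")
    if len(np.unique(times)) < 3:
        raise NumericalError("rank-deficient design: need >= 3 distinct times")
    X = _design(times)
    coef, *_ = np.linalg.lstsq(X, obs_x, rcond=None)
    rss = float(np.sum((obs_x - X @ coef) ** 2))
    return QuadraticFit(coef=coef, s2=rss / (n - 3), xtx=X.T @ X, n_points=n)


def endpoint_estimate(
    fit: QuadraticFit, t_end: float, noise_sd: float | None = None
) -> GaussianBelief:
    """Endpoint belief (mu_d, sigma_d) from a quadratic fit.

    sigma_d = sqrt(s^2 * h' M^-1 h) with h = (1, t_end, t_end^2) and M the
    normal-equations matrix.  By default s^2 is the estimated residual
    variance (the observer does not know the noise level); passing
    ``noise_sd`` substitutes the known generative noise variance, the mode
    used for exact algebraic checks.
    """
    h = np.array([1.0, t_end, t_end**2])
    leverage = float(h @ np.linalg.solve(fit.xtx, h))
    s2 = fit.s2 if noise_sd is None else float(noise_sd) ** 2
    if fit.s2 == 0.0 and noise_sd is not None and noise_sd > 0:
        warnings.warn(
            "zero residual variance on a trial with declared noise",
            stacklevel=2,
        )
    sigma_d = float(np.sqrt(max(s2 * leverage, 0.0)))
    return GaussianBelief(float(h @ fit.coef), sigma_d, role="dynamic")


def sequential_estimate_with_prior(
    times: np.ndarray,
    obs_x: np.ndarray,
    prior: GaussianBelief,
    noise_sd: float,
    t_end: float,
    k: int | None = None,
) -> GaussianBelief:
    """Endpoint estimate after the first ``k`` samples, with the statistical
    belief acting as a prior over the endpoint.

    Weighted least squares on the first k samples (weights 1/noise_sd^2)
    augmented with a pseudo-observation (t_end, prior.mu) of SD prior.sigma;
    returns the fitted value and its SE at t_end.
    """
    if prior.sigma <= 0:
        raise ConfigurationError("prior.sigma must be > 0")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0 (known-variance mode)")
    times = np.asarray(times, dtype=float)
    obs_x = np.asarray(obs_x, dtype=float)
    k = len(times) if k is None else int(k)
    if k < 3:
        raise ConfigurationError("need >= 3 samples to constrain a quadratic")
    t_k, x_k = times[:k], obs_x[:k]
    h = np.array([1.0, t_end, t_end**2])

    X = np.vstack([_design(t_k) / noise_sd, h / prior.sigma])
    y = np.concatenate([x_k / noise_sd, [prior.mu / prior.sigma]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    info = X.T @ X
    se = float(np.sqrt(h @ np.linalg.solve(info, h)))
    return GaussianBelief(float(h @ coef), se, role="combined")


def run_dynamic(
    session: Session, use_known_noise: bool = False
) -> list[GaussianBelief]:
    """Per-trial dynamic endpoint beliefs for a session.

    Noise-free (warmup) trials get sigma_d = 0 and mu_d equal to the true
    endpoint; they are excluded from analysis downstream anyway.
    """
    t_end = session.config.traj_duration_s
    beliefs = []
    for trial in session.trials:
        fit = fit_quadratic_ols(trial.observed_times, trial.obs_x)
        noise_sd = trial.sigma_noise if use_known_noise else None
        if trial.sigma_noise == 0.0:
            beliefs.append(GaussianBelief(trial.x_end, 0.0, role="dynamic"))
        else:
            beliefs.append(endpoint_estimate(fit, t_end, noise_sd=noise_sd))
    return beliefs
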