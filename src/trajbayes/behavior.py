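"""Cue-combination response models, maximum-likelihood fitting, and model
comparison.

Three accounts of how the statistical belief (mu_s, sigma_s) and the dynamic
belief (mu_d, sigma_d) are merged into a single predicted endpoint mu_sd:

* ``weighted`` — precision-weighted combination.  With P_s = M/sigma_s^2 and
  P_d = (2-M)/sigma_d^2, mu_sd = b + (P_s mu_s + P_d mu_d)/(P_s + P_d) and
  sigma_sd = (P_s + P_d)^{-1/2}.  M in [0, 2]; M = 1 is the Bayes-optimal
  weighting, and M != 1 allows over-weighting of either source.
* ``unweighted`` — fixed-ratio mixing that ignores trial-to-trial precision:
  mu_sd = b + M mu_s + (1-M) mu_d, M in [0, 1].
* ``select`` — weighted, no combination: act on whichever source is the more
  precise, mu_sd = b + (mu_s if P_s >= P_d else mu_d), ties to statistical.

Responses are modelled as r ~ N(mu_sd, k^2) with response-noise SD k and
spatial bias b.  Fitting maximizes the summed log likelihood over (M, k, b)
by a coarse grid followed by bounded Nelder-Mead refinement; models are
compared by log likelihood ratios (identical free parameters) and by BIC for
nested versions with parameters frozen at defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ConfigurationError, GaussianBelief
from .task import Session

__all__ = [
    "MODEL_KINDS",
    "M_MAX",
    "CombinationParams",
    "ModelFitResult",
    "BeliefArrays",
    "combine_prediction",
    "combined_mean",
    "simulate_responses",
    "log_likelihood",
    "fit_mle",
    "compare_models",
    "attraction_slope_analysis",
]

MODEL_KINDS = ("weighted", "unweighted", "select")
M_MAX = {"weighted": 2.0, "unweighted": 1.0, "select": 2.0}
_M_DEFAULT = {"weighted": 1.0, "unweighted": 0.5, "select": 1.0}
K_BOUNDS = (1e-4, 0.5)
B_BOUNDS = (-0.25, 0.25)
_SIGMA_FLOOR = 1e-9  # sigma_d = 0 treated as (near-)infinite precision


@dataclass(frozen=True)
class CombinationParams:
    """Free parameters of a combination model: mixing factor M, response
    noise SD k (screen widths), spatial bias b (screen widths)."""

    M: float
    k: float
    b: float
    model_kind: str = "weighted"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.model_kind!r}")
        if not (0.0 <= self.M <= M_MAX[self.model_kind]):
            raise ConfigurationError(
                f"M={self.M} outside [0, {M_MAX[self.model_kind]}] "
                f"for model {self.model_kind!r}"
            )
        if self.k <= 0:
            raise ConfigurationError("response noise k must be > 0")


@dataclass(frozen=True)
class ModelFitResult:
    model_kind: str
    M: float
    k: float
    b: float
    log_lik: float
    bic: float
    n_trials: int
    free_params: tuple[str, ...]
    boundary: bool = False

    @property
    def params(self) -> CombinationParams:
        return CombinationParams(self.M, self.k, self.b, self.model_kind)


@dataclass(frozen=True)
class BeliefArrays:
    """Aligned per-trial statistical and dynamic beliefs as arrays."""

    mu_s: np.ndarray
    sigma_s: np.ndarray
    mu_d: np.ndarray
    sigma_d: np.ndarray

    @classmethod
    def from_beliefs(
        cls,
        stat: list[GaussianBelief],
        dyn: list[GaussianBelief],
        mask: np.ndarray | None = None,
    ) -> "BeliefArrays":
        if len(stat) != len(dyn):
            raise ConfigurationError("statistical and dynamic beliefs misaligned")
        arr = cls(
            mu_s=np.array([b.mu for b in stat]),
            sigma_s=np.array([b.sigma for b in stat]),
            mu_d=np.array([b.mu for b in dyn]),
            sigma_d=np.array([b.sigma for b in dyn]),
        )
        return arr if mask is None else arr.subset(np.asarray(mask))

    def subset(self, mask: np.ndarray) -> "BeliefArrays":
        return BeliefArrays(
            self.mu_s[mask], self.sigma_s[mask], self.mu_d[mask], self.sigma_d[mask]
        )

    def __len__(self) -> int:
        return len(self.mu_s)


def combined_mean(
    model_kind: str,
    M: float,
    b: float,
    mu_s: np.ndarray,
    sigma_s: np.ndarray,
    mu_d: np.ndarray,
    sigma_d: np.ndarray,
) -> np.ndarray:
    """Vectorized mu_sd for any of the three models."""
    mu_s = np.asarray(mu_s, dtype=float)
    mu_d = np.asarray(mu_d, dtype=float)
    sigma_s = np.asarray(sigma_s, dtype=float)
    sigma_d = np.maximum(np.asarray(sigma_d, dtype=float), _SIGMA_FLOOR)
    if np.any(sigma_s <= 0):
        raise ConfigurationError("sigma_s must be > 0")
    if model_kind == "weighted":
        p_s = M / sigma_s**2
        p_d = (2.0 - M) / sigma_d**2
        return b + (p_s * mu_s + p_d * mu_d) / (p_s + p_d)
    if model_kind == "unweighted":
        return b + M * mu_s + (1.0 - M) * mu_d
    if model_kind == "select":
        p_s = M / sigma_s**2
        p_d = (2.0 - M) / sigma_d**2
        return b + np.where(p_s >= p_d, mu_s, mu_d)
    raise ConfigurationError(f"unknown model kind {model_kind!r}")


def combine_prediction(
    stat: GaussianBelief, dyn: GaussianBelief, params: CombinationParams
) -> GaussianBelief:
    """Combine one trial's statistical and dynamic beliefs.

    sigma_sd is defined for the weighted model (the combined precision) and
    for the select model (the chosen source's sigma); the unweighted model
    prescribes no combined spread and returns NaN there.
    """
    mu = float(
        combined_mean(
            params.model_kind,
            params.M,
            params.b,
            stat.mu,
            stat.sigma,
            dyn.mu,
            dyn.sigma,
        )
    )
    sigma_d = max(dyn.sigma, _SIGMA_FLOOR)
    if params.model_kind == "weighted":
        p_s = params.M / stat.sigma**2
        p_d = (2.0 - params.M) / sigma_d**2
        sigma = float((p_s + p_d) ** -0.5)
    elif params.model_kind == "select":
        p_s = params.M / stat.sigma**2
        p_d = (2.0 - params.M) / sigma_d**2
        sigma = stat.sigma if p_s >= p_d else dyn.sigma
    else:
        sigma = float("nan")
    return GaussianBelief(mu, sigma, role="combined")


def simulate_responses(
    beliefs: BeliefArrays, params: CombinationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw responses r(i) ~ N(mu_sd(i), k^2)."""
    mu_sd = combined_mean(
        params.model_kind,
        params.M,
        params.b,
        beliefs.mu_s,
        beliefs.sigma_s,
        beliefs.mu_d,
        beliefs.sigma_d,
    )
    return rng.normal(mu_sd, params.k)


def log_likelihood(
    responses: np.ndarray, beliefs: BeliefArrays, params: CombinationParams
) -> float:
    """Sum over trials of log N(r_i; mu_sd(i), k^2)."""
    responses = np.asarray(responses, dtype=float)
    if not np.all(np.isfinite(responses)):
        raise ConfigurationError("responses must be finite")
    if len(responses) != len(beliefs):
        raise ConfigurationError("responses and beliefs misaligned")
    mu_sd = combined_mean(
        params.model_kind,
        params.M,
        params.b,
        beliefs.mu_s,
        beliefs.sigma_s,
        beliefs.mu_d,
        beliefs.sigma_d,
    )
    n = len(responses)
    sse = float(np.sum((responses - mu_sd) ** 2))
    return -0.5 * n * np.log(2.0 * np.pi * params.k**2) - sse / (2.0 * params.k**2)


def _grid_loglik(
    responses: np.ndarray,
    beliefs: BeliefArrays,
    model_kind: str,
    m_axis: np.ndarray,
    b_axis: np.ndarray,
    k_axis: np.ndarray,
) -> np.ndarray:
    """Log likelihood over the (M, b, k) lattice, vectorized over b and k."""
    n = len(responses)
    out = np.empty((len(m_axis), len(b_axis), len(k_axis)))
    for i, m in enumerate(m_axis):
        mu0 = combined_mean(
            model_kind, m, 0.0, beliefs.mu_s, beliefs.sigma_s,
            beliefs.mu_d, beliefs.sigma_d,
        )
        resid = responses[:, None] - mu0[:, None] - b_axis[None, :]
        sse = np.sum(resid**2, axis=0)  # (n_b,)
        out[i] = (
            -0.5 * n * np.log(2.0 * np.pi * k_axis[None, :] ** 2)
            - sse[:, None] / (2.0 * k_axis[None, :] ** 2)
        )
    return out


def fit_mle(
    responses: np.ndarray,
    beliefs: BeliefArrays,
    model_kind: str = "weighted",
    free_params: tuple[str, ...] = ("M", "k", "b"),
    n_grid: int = 21,
) -> ModelFitResult:
    """Joint MLE of the declared free parameters.

    Coarse grid (n_grid per free axis) followed by bounded Nelder-Mead
    refinement from the best cell.  Fixed parameters take defaults: M at the
    optimal value for the model kind, b = 0, and k at the residual SD under
    those defaults.  BIC = p ln(n) - 2 logL with p free parameters.
    """
    responses = np.asarray(responses, dtype=float)
    n = len(responses)
    if n < 30:
        raise ConfigurationError(f"need >= 30 trials to fit, got {n}")
    if model_kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {model_kind!r}")
    free = tuple(free_params)
    for p in free:
        if p not in ("M", "k", "b"):
            raise ConfigurationError(f"unknown free parameter {p!r}")

    m_default = _M_DEFAULT[model_kind]
    mu_default = combined_mean(
        model_kind, m_default, 0.0, beliefs.mu_s, beliefs.sigma_s,
        beliefs.mu_d, beliefs.sigma_d,
    )
    k_default = float(
        np.clip(np.std(responses - mu_default), K_BOUNDS[0], K_BOUNDS[1])
    )
    m_axis = (
        np.linspace(0.0, M_MAX[model_kind], n_grid)
        if "M" in free
        else np.array([m_default])
    )
    b_axis = np.linspace(*B_BOUNDS, n_grid) if "b" in free else np.array([0.0])
    k_axis = (
        np.geomspace(2e-3, K_BOUNDS[1], n_grid)
        if "k" in free
        else np.array([k_default])
    )
    grid = _grid_loglik(responses, beliefs, model_kind, m_axis, b_axis, k_axis)
    i, j, l = np.unravel_index(np.argmax(grid), grid.shape)
    start = {"M": m_axis[i], "b": b_axis[j], "k": k_axis[l]}

    bounds_map = {"M": (0.0, M_MAX[model_kind]), "k": K_BOUNDS, "b": B_BOUNDS}

    def unpack(theta: np.ndarray) -> CombinationParams:
        vals = {"M": m_default, "k": k_default, "b": 0.0}
        vals.update(dict(zip(free, theta)))
        return CombinationParams(
            M=float(np.clip(vals["M"], 0.0, M_MAX[model_kind])),
            k=float(np.clip(vals["k"], *K_BOUNDS)),
            b=float(np.clip(vals["b"], *B_BOUNDS)),
            model_kind=model_kind,
        )

    best = CombinationParams(
        M=float(start["M"]) if "M" in free else m_default,
        k=float(start["k"]) if "k" in free else k_default,
        b=float(start["b"]) if "b" in free else 0.0,
        model_kind=model_kind,
    )
    if free:
        x0 = np.array([start[p] for p in free])
        res = optimize.minimize(
            lambda th: -log_likelihood(responses, beliefs, unpack(th)),
            x0,
            method="Nelder-Mead",
            bounds=[bounds_map[p] for p in free],
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if not (res.success or res.status == 1):
            raise RuntimeError(f"MLE refinement failed to converge: {res.message}")
        cand = unpack(res.x)
        if log_likelihood(responses, beliefs, cand) >= log_likelihood(
            responses, beliefs, best
        ):
            best = cand

    logl = log_likelihood(responses, beliefs, best)
    p = len(free)
    boundary = any(
        np.isclose(getattr(best, name), bounds_map[name], atol=1e-6).any()
        for name in free
    )
    return ModelFitResult(
        model_kind=model_kind,
        M=best.M,
        k=best.k,
        b=best.b,
        log_lik=logl,
        bic=p * np.log(n) - 2.0 * logl,
        n_trials=n,
        free_params=free,
        boundary=boundary,
    )


def compare_models(fits: list[ModelFitResult]) -> pd.DataFrame:
    """Pairwise model comparison table.

    logLR (logL_A - logL_B) is reported only for fits with equally many free
    parameters; delta-BIC is reported for every pair.  Fits must share the
    trial set (same n).
    """
    if len({f.n_trials for f in fits}) > 1:
        raise ConfigurationError("fits were made on different trial sets")
    rows = []
    for a, b in combinations(fits, 2):
        same_p = len(a.free_params) == len(b.free_params)
        rows.append(
            {
                "model_a": a.model_kind,
                "model_b": b.model_kind,
                "loglr": a.log_lik - b.log_lik if same_p else np.nan,
                "delta_bic": a.bic - b.bic,
            }
        )
    return pd.DataFrame(rows)


def attraction_slope_analysis(
    session: Session,
    responses: np.ndarray,
    beliefs: BeliefArrays,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Attraction of responses toward the statistical mean, by trajectory
    noise level.

    Analysis trials are binned into sigma_d quantile bins (terciles by
    default).  Within each bin, y = x - r (displacement of the response from
    the true endpoint toward the statistical mean) is regressed on
    x - mu_s (displacement of the endpoint from the statistical mean); the
    reported slope is 0 for a purely dynamic responder (r = x) and 1 for a
    purely statistical one (r = mu_s).  A reference slope per bin is computed
    from noiseless optimal-observer responses (weighted model, M=1, b=0),
    which analytically approximates mean sigma_d^2/(sigma_d^2 + sigma_s^2).
    """
    mask = session.analysis_mask
    responses = np.asarray(responses, dtype=float)
    if len(responses) == len(session):
        responses = responses[mask]
    bel = beliefs if len(beliefs) == mask.sum() else beliefs.subset(mask)
    x = session.endpoints[mask]
    n = len(x)
    if n < n_bins * 10:
        raise ConfigurationError(f"need >= {n_bins * 10} analysis trials, got {n}")
    if len(responses) != n or len(bel) != n:
        raise ConfigurationError("responses/beliefs misaligned with session")

    r_opt = combined_mean(
        "weighted", 1.0, 0.0, bel.mu_s, bel.sigma_s, bel.mu_d, bel.sigma_d
    )
    edges = np.quantile(bel.sigma_d, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.inf
    rows = []
    for b in range(n_bins):
        in_bin = (bel.sigma_d >= edges[b]) & (bel.sigma_d < edges[b + 1])
        if in_bin.sum() < 2:
            raise ConfigurationError(f"sigma_d bin {b} is (nearly) empty")
        dx = x[in_bin] - bel.mu_s[in_bin]
        rows.append(
            {
                "bin": b,
                "n": int(in_bin.sum()),
                "sigma_d_mean": float(bel.sigma_d[in_bin].mean()),
                "slope": _slope(dx, x[in_bin] - responses[in_bin]),
                "slope_optimal": _slope(dx, x[in_bin] - r_opt[in_bin]),
            }
        )
    return pd.DataFrame(rows)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    slope, _intercept = np.polyfit(x, y, 1)
    return float(slope)
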