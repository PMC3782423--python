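"""Shared primitives: Gaussian endpoint beliefs and package errors.

All positions are expressed as fractions of the horizontal screen width
(screen spans [0, 1]); times are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

ROLES = ("statistical", "dynamic", "combined")


class ConfigurationError(ValueError):
    """An invalid configuration value (range, count, fraction, ...)."""


class GenerationError(RuntimeError):
    """Stimulus generation failed (e.g. rejection sampling exhausted)."""


class NumericalError(ArithmeticError):
    """A numerically degenerate state (underflow, rank deficiency, ...)."""


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian predictive distribution over the trajectory endpoint.

    The same container serves the statistical model (mu_s, sigma_s), the
    dynamic model (mu_d, sigma_d) and their combination (mu_sd, sigma_sd);
    ``role`` records which one it is.
    """

    mu: float
    sigma: float
    role: str = "statistical"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown belief role {self.role!r}")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")

    @property
    def precision(self) -> float:
        """Inverse variance, the weighting currency of cue combination."""
        return 1.0 / (self.sigma**2)

    @property
    def log_precision(self) -> float:
        """Natural log of the precision; precision is a log-scale quantity."""
        return -2.0 * math.log(self.sigma)

    def with_role(self, role: str) -> "GaussianBelief":
        return replace(self, role=role)
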