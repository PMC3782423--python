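"""Synthetic occluded-trajectory prediction task.

A session consists of trials on which a target moves down the screen along a
parabola (constant horizontal acceleration), disappears behind an occluder,
and "lands" at the horizontal coordinate where its path crosses the bottom of
the occluded zone.  Landing points are drawn from a Gaussian whose mean and
standard deviation each jump to new values every ``jump_gap_min`` to
``jump_gap_max`` trials, independently of one another.  The visible part of
each trajectory is corrupted by per-sample Gaussian position noise whose
magnitude varies from trial to trial; across the analysis trials of a session
the average noise SD is calibrated to a fixed fraction (default 0.67) of the
average generative endpoint SD, so that the dynamic (trajectory) and
statistical (endpoint-history) information sources are of comparable
reliability.

Coordinates: positions are fractions of the horizontal screen width in
[0, 1]; times are seconds; accelerations are screen widths per second
squared.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, GenerationError

__all__ = [
    "EnvironmentConfig",
    "EnvironmentTrace",
    "TrialRecord",
    "Session",
    "sample_environment",
    "sample_trial",
    "generate_session",
    "noise_calibration_ratio",
    "write_session",
    "read_session",
]


@dataclass(frozen=True)
class EnvironmentConfig:
    """Generative parameters of the task environment.

    ``accel_max`` defaults to the value at which the acceleration component
    of the motion sweeps half of the screen width over the full trajectory
    duration: ``0.5 * accel_max * traj_duration_s**2 = 0.5 * screen_width``.
    """

    screen_width: float = 1.0
    n_trials: int = 220
    jump_gap_min: int = 20
    jump_gap_max: int = 40
    mean_range: tuple[float, float] = (0.2, 0.8)
    sd_range: tuple[float, float] = (0.02, 0.12)
    noise_sd_range: tuple[float, float] = (0.01, 0.10)
    noise_calibration_ratio: float = 0.67
    traj_duration_s: float = 6.0
    traj_n_samples: int = 40
    observed_fraction: float = 0.75
    accel_max: float | None = None
    n_warmup_noisefree: int = 20
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.screen_width != 1.0:
            raise ConfigurationError(
                "positions are defined as fractions of screen width; "
                "screen_width must be 1.0"
            )
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not (1 <= self.jump_gap_min <= self.jump_gap_max):
            raise ConfigurationError(
                "need 1 <= jump_gap_min <= jump_gap_max, got "
                f"[{self.jump_gap_min}, {self.jump_gap_max}]"
            )
        for name in ("mean_range", "sd_range", "noise_sd_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ConfigurationError(f"{name} min exceeds max: ({lo}, {hi})")
        lo, hi = self.mean_range
        if not (0.0 <= lo and hi <= self.screen_width):
            raise ConfigurationError("mean_range must lie within the screen")
        if self.sd_range[0] <= 0 or self.noise_sd_range[0] < 0:
            raise ConfigurationError("SD ranges must be positive")
        if not (0.0 < self.observed_fraction < 1.0):
            raise ConfigurationError("observed_fraction must be in (0, 1)")
        if self.noise_calibration_ratio <= 0:
            raise ConfigurationError("noise_calibration_ratio must be > 0")
        if self.traj_n_samples < 4:
            raise ConfigurationError("traj_n_samples must be >= 4")
        if not (0 <= self.n_warmup_noisefree < self.n_trials):
            raise ConfigurationError("n_warmup_noisefree must be < n_trials")

    @property
    def accel_limit(self) -> float:
        """Acceleration bound; default sweeps 50% of the screen width."""
        if self.accel_max is not None:
            return self.accel_max
        return self.screen_width / self.traj_duration_s**2

    @property
    def n_observed(self) -> int:
        return round(self.observed_fraction * self.traj_n_samples)

    @property
    def times(self) -> np.ndarray:
        """Sample times, equally spaced with t=0 at the first sample and
        t = traj_duration_s at the landing point."""
        return np.linspace(0.0, self.traj_duration_s, self.traj_n_samples)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnvironmentConfig":
        raw = json.loads(text)
        for name in ("mean_range", "sd_range", "noise_sd_range"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class EnvironmentTrace:
    """Per-trial generative endpoint-distribution parameters and jumps."""

    mu_gen: np.ndarray
    sigma_gen: np.ndarray
    jump_mean: np.ndarray
    jump_sd: np.ndarray

    def __len__(self) -> int:
        return len(self.mu_gen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu_gen": self.mu_gen,
                "sigma_gen": self.sigma_gen,
                "jump_mean": self.jump_mean.astype(int),
                "jump_sd": self.jump_sd.astype(int),
            }
        )


@dataclass
class TrialRecord:
    """One trial: true motion parameters, noisy observations, endpoint."""

    trial_index: int
    x_end: float
    accel: float
    x0: float
    v0: float
    times: np.ndarray
    true_x: np.ndarray
    obs_x: np.ndarray  # observed (pre-occluder) samples only
    sigma_noise: float
    is_noisefree: bool

    @property
    def n_observed(self) -> int:
        return len(self.obs_x)

    @property
    def observed_times(self) -> np.ndarray:
        return self.times[: self.n_observed]


@dataclass
class Session:
    """A full task session: config, environment trace, trials, provenance."""

    config: EnvironmentConfig
    trace: EnvironmentTrace
    trials: list[TrialRecord]
    seed: int
    version: str = "trajbayes-0.1.0"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def analysis_mask(self) -> np.ndarray:
        idx = np.arange(len(self.trials))
        return idx >= self.config.n_warmup_noisefree

    @property
    def analysis_indices(self) -> np.ndarray:
        return np.flatnonzero(self.analysis_mask)

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([t.x_end for t in self.trials])

    @property
    def sigma_noise(self) -> np.ndarray:
        return np.array([t.sigma_noise for t in self.trials])

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for tr, mu, sg, jm, js, isa in zip(
            self.trials,
            self.trace.mu_gen,
            self.trace.sigma_gen,
            self.trace.jump_mean,
            self.trace.jump_sd,
            self.analysis_mask,
        ):
            rows.append(
                {
                    "trial_index": tr.trial_index,
                    "x_end": tr.x_end,
                    "accel": tr.accel,
                    "x0": tr.x0,
                    "v0": tr.v0,
                    "sigma_noise": tr.sigma_noise,
                    "is_noisefree": int(tr.is_noisefree),
                    "is_analysis": int(isa),
                    "mu_gen": mu,
                    "sigma_gen": sg,
                    "jump_mean": int(jm),
                    "jump_sd": int(js),
                }
            )
        return pd.DataFrame(rows)

    def samples_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            n_obs = tr.n_observed
            for k, (t, x) in enumerate(zip(tr.times, tr.true_x)):
                observed = k < n_obs
                rows.append(
                    {
                        "trial_index": tr.trial_index,
                        "k": k,
                        "t": t,
                        "true_x": x,
                        "obs_x": tr.obs_x[k] if observed else np.nan,
                        "observed_flag": int(observed),
                    }
                )
        return pd.DataFrame(rows)


def sample_environment(
    config: EnvironmentConfig, rng: np.random.Generator
) -> EnvironmentTrace:
    """Draw the piecewise-constant generative mean/SD schedule.

    Each parameter holds its value for a uniformly-drawn integer gap in
    [jump_gap_min, jump_gap_max] and then jumps to a fresh, independent draw:
    means uniform on ``mean_range``, SDs log-uniform on ``sd_range``.
    """
    n = config.n_trials
    jump_mean = _jump_schedule(n, config.jump_gap_min, config.jump_gap_max, rng)
    jump_sd = _jump_schedule(n, config.jump_gap_min, config.jump_gap_max, rng)
    mu = _piecewise(jump_mean, lambda: rng.uniform(*config.mean_range))
    sg = _piecewise(jump_sd, lambda: _log_uniform(rng, *config.sd_range))
    return EnvironmentTrace(mu, sg, jump_mean, jump_sd)


def _jump_schedule(
    n: int, gap_min: int, gap_max: int, rng: np.random.Generator
) -> np.ndarray:
    jumps = np.zeros(n, dtype=bool)
    i = int(rng.integers(gap_min, gap_max + 1))
    while i < n:
        jumps[i] = True
        i += int(rng.integers(gap_min, gap_max + 1))
    return jumps


def _piecewise(jumps: np.ndarray, draw) -> np.ndarray:
    out = np.empty(len(jumps))
    value = draw()
    for i, j in enumerate(jumps):
        if j:
            value = draw()
        out[i] = value
    return out


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_trial(
    mu_gen: float,
    sigma_gen: float,
    config: EnvironmentConfig,
    rng: np.random.Generator,
    trial_index: int = 0,
    noisefree_flag: bool = False,
    sigma_noise: float = 0.0,
) -> TrialRecord:
    """Sample one trial consistent with the generative endpoint distribution.

    The endpoint is drawn from N(mu_gen, sigma_gen^2), resampled (not
    clipped) until on screen, which preserves the Gaussian shape up to
    truncation.  Holding the endpoint fixed, the acceleration is uniform on
    [-accel_limit, +accel_limit] and the start point uniform on the screen;
    the initial velocity is then solved so the parabola passes through the
    endpoint at t_end.  (start point, curvature) pairs are rejection-sampled
    jointly until the whole path stays on screen, so neither alone predicts
    the endpoint.
    """
    if sigma_gen <= 0:
        raise ConfigurationError("sigma_gen must be > 0")
    W = config.screen_width
    T = config.traj_duration_s
    t = config.times

    x_end = np.nan
    for _ in range(config.max_attempts):
        cand = rng.normal(mu_gen, sigma_gen)
        if 0.0 <= cand <= W:
            x_end = float(cand)
            break
    else:
        raise GenerationError(
            f"could not draw an on-screen endpoint from N({mu_gen}, "
            f"{sigma_gen}^2) in {config.max_attempts} attempts"
        )

    amax = config.accel_limit
    for _ in range(config.max_attempts):
        accel = float(rng.uniform(-amax, amax))
        x0 = float(rng.uniform(0.0, W))
        v0 = (x_end - x0 - 0.5 * accel * T**2) / T
        true_x = x0 + v0 * t + 0.5 * accel * t**2
        if true_x.min() >= 0.0 and true_x.max() <= W:
            break
    else:
        raise GenerationError(
            f"no on-screen trajectory found for endpoint {x_end:.4f} "
            f"(mu_gen={mu_gen:.4f}, sigma_gen={sigma_gen:.4f}, "
            f"accel_limit={amax:.4f}) in {config.max_attempts} attempts"
        )

    n_obs = config.n_observed
    if noisefree_flag or sigma_noise == 0.0:
        obs_x = true_x[:n_obs].copy()
        sigma_noise = 0.0
    else:
        obs_x = true_x[:n_obs] + rng.normal(0.0, sigma_noise, n_obs)
    return TrialRecord(
        trial_index=trial_index,
        x_end=x_end,
        accel=accel,
        x0=x0,
        v0=v0,
        times=t,
        true_x=true_x,
        obs_x=obs_x,
        sigma_noise=float(sigma_noise),
        is_noisefree=bool(noisefree_flag),
    )


def generate_session(config: EnvironmentConfig) -> Session:
    """Generate a full session from the config's seed.

    Per-trial observation-noise SDs are drawn log-uniformly over
    ``noise_sd_range`` for the analysis trials and then rescaled by a common
    factor so that their mean equals ``noise_calibration_ratio`` times the
    mean generative endpoint SD over the analysis trials.  The first
    ``n_warmup_noisefree`` trials are noise free and excluded from analysis.
    """
    rng = np.random.default_rng(config.seed)
    trace = sample_environment(config, rng)
    n = config.n_trials
    n_warm = config.n_warmup_noisefree

    sigma_noise = np.zeros(n)
    n_analysis = n - n_warm
    raw = np.array(
        [_log_uniform(rng, *config.noise_sd_range) for _ in range(n_analysis)]
    )
    if raw.mean() > 0:
        target = config.noise_calibration_ratio * trace.sigma_gen[n_warm:].mean()
        sigma_noise[n_warm:] = raw * (target / raw.mean())

    trials = []
    for i in range(n):
        trials.append(
            sample_trial(
                trace.mu_gen[i],
                trace.sigma_gen[i],
                config,
                rng,
                trial_index=i,
                noisefree_flag=i < n_warm,
                sigma_noise=sigma_noise[i],
            )
        )
    return Session(config=config, trace=trace, trials=trials, seed=config.seed)


def noise_calibration_ratio(session: Session) -> float:
    """Mean per-sample noise SD over mean generative endpoint SD,
    computed over the analysis trials."""
    mask = session.analysis_mask
    if not mask.any():
        raise ConfigurationError("session has no analysis trials")
    mean_noise = session.sigma_noise[mask].mean()
    mean_gen = session.trace.sigma_gen[mask].mean()
    return float(mean_noise / mean_gen)


# ---------------------------------------------------------------------------
# Session I/O: TSV tables plus a JSON config, with a '#'-prefixed provenance
# header.  Identical (config, seed) pairs produce byte-identical files.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _write_tsv(frame: pd.DataFrame, path: Path, header_lines: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_session(session: Session, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"{session.version}",
        f"seed={session.seed}",
        f"config_hash={session.config.config_hash()}",
    ]
    (out / "config.json").write_text(session.config.to_json() + "\n")
    _write_tsv(session.trials_frame(), out / "trials.tsv", header)
    _write_tsv(session.samples_frame(), out / "samples.tsv", header)
    return out


def read_session(in_dir: str | Path) -> Session:
    src = Path(in_dir)
    config = EnvironmentConfig.from_json((src / "config.json").read_text())
    trials_df = pd.read_csv(src / "trials.tsv", sep="\t", comment="#")
    samples_df = pd.read_csv(src / "samples.tsv", sep="\t", comment="#")

    trace = EnvironmentTrace(
        mu_gen=trials_df["mu_gen"].to_numpy(),
        sigma_gen=trials_df["sigma_gen"].to_numpy(),
        jump_mean=trials_df["jump_mean"].to_numpy(dtype=bool),
        jump_sd=trials_df["jump_sd"].to_numpy(dtype=bool),
    )
    trials = []
    grouped = samples_df.groupby("trial_index")
    for row in trials_df.itertuples():
        grp = grouped.get_group(row.trial_index).sort_values("k")
        observed = grp["observed_flag"].to_numpy(dtype=bool)
        trials.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                x_end=float(row.x_end),
                accel=float(row.accel),
                x0=float(row.x0),
                v0=float(row.v0),
                times=grp["t"].to_numpy(),
                true_x=grp["true_x"].to_numpy(),
                obs_x=grp["obs_x"].to_numpy()[observed],
                sigma_noise=float(row.sigma_noise),
                is_noisefree=bool(row.is_noisefree),
            )
        )
    return Session(config=config, trace=trace, trials=trials, seed=config.seed)
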