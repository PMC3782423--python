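"""Trial-wise parametric regressors for event-related neuroimaging designs.

For each analysis trial the table carries: the (natural-)log precisions of
the statistical and dynamic endpoint predictions; the KL divergence from the
statistical prediction to the combined prediction (how much the prior must
be updated with trajectory information); the KL divergence from the current
to the next trial's statistical prediction (between-trial belief update);
the unsigned change in the statistical mean; and response accuracy in % of
screen width, optionally orthogonalized against the model-based regressors.
Only regressor values are produced here — no haemodynamic convolution or GLM
estimation.

Events are stamped as 0.1 s square waves at the onset of the decision phase
(the moment the target passes behind the occluder); trial onsets follow the
session timeline of 6 s trajectory, response period, 0.5 s feedback and an
exponentially jittered inter-trial interval with mean 6 s truncated to
[2, 12] s.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import CombinationParams, combine_prediction
from .core import ConfigurationError, GaussianBelief
from .task import Session

__all__ = [
    "gaussian_kl",
    "build_regressors",
    "orthogonalize",
    "correlation_table",
    "sample_onsets",
    "write_events_tsv",
]

MAIN_REGRESSORS = (
    "log_prec_stat",
    "log_prec_dyn",
    "kl_stat_combined",
    "kl_stat_update",
)

EVENT_DURATION_S = 0.1
RESPONSE_DURATION_S = 1.0
FEEDBACK_DURATION_S = 0.5
ITI_MEAN_S = 6.0
ITI_RANGE_S = (2.0, 12.0)


def gaussian_kl(p: GaussianBelief, q: GaussianBelief) -> float:
    """KL(N(mu1, s1^2) || N(mu2, s2^2)) in nats, closed form."""
    if p.sigma <= 0 or q.sigma <= 0:
        raise ConfigurationError("KL divergence requires positive sigmas")
    return _kl(p.mu, p.sigma, q.mu, q.sigma)


def _kl(mu1, s1, mu2, s2):
    return float(
        math.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2.0 * s2**2) - 0.5
    )


def sample_onsets(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Decision-phase onset times (s) for a session timeline.

    Each trial spans 6 s of trajectory (decision onset at its end), a 1 s
    response period, 0.5 s of feedback and a jittered ITI drawn from an
    exponential of mean 6 s, resampled until it falls in [2, 12] s.
    """
    onsets = np.empty(n_trials)
    start = 0.0
    for i in range(n_trials):
        onsets[i] = start + 6.0
        iti = rng.exponential(ITI_MEAN_S)
        while not (ITI_RANGE_S[0] <= iti <= ITI_RANGE_S[1]):
            iti = rng.exponential(ITI_MEAN_S)
        start = onsets[i] + RESPONSE_DURATION_S + FEEDBACK_DURATION_S + iti
    return onsets


def build_regressors(
    session: Session,
    stat: list[GaussianBelief],
    dyn: list[GaussianBelief],
    responses: np.ndarray,
    combine_params: CombinationParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assemble the per-analysis-trial regressor table.

    The combined prediction defaults to the optimal weighting (M=1, b=0);
    a fitted per-subject parameter set may be supplied instead.  The last
    analysis trial has no successor, so its between-trial update columns are
    left missing (NaN), not zero-filled.  ``accuracy_orth`` is the accuracy
    residual after OLS on the always-defined model regressors.
    """
    if combine_params is None:
        combine_params = CombinationParams(1.0, 1e-6, 0.0, "weighted")
    n = len(session)
    if not (len(stat) == len(dyn) == n):
        raise ConfigurationError("beliefs misaligned with session")
    responses = np.asarray(responses, dtype=float)
    if len(responses) == n:
        responses = responses[session.analysis_mask]
    idx = session.analysis_indices
    if len(responses) != len(idx):
        raise ConfigurationError("responses misaligned with analysis trials")

    rng = rng or np.random.default_rng(session.seed)
    onsets_all = sample_onsets(n, rng)

    x_end = session.endpoints
    rows = []
    for j, i in enumerate(idx):
        s_i = stat[i]
        comb = combine_prediction(s_i, dyn[i], combine_params)
        has_next = i + 1 < n
        rows.append(
            {
                "trial_index": int(i),
                "onset_s": onsets_all[i],
                "duration_s": EVENT_DURATION_S,
                "log_prec_stat": s_i.log_precision,
                "log_prec_dyn": dyn[i].log_precision
                if dyn[i].sigma > 0
                else np.nan,
                "kl_stat_combined": gaussian_kl(s_i, comb),
                "kl_stat_update": gaussian_kl(s_i, stat[i + 1])
                if has_next
                else np.nan,
                "mean_change": abs(stat[i + 1].mu - s_i.mu) if has_next else np.nan,
                "accuracy": 100.0 * abs(responses[j] - x_end[i]),
            }
        )
    table = pd.DataFrame(rows)
    others = table[["log_prec_stat", "log_prec_dyn", "kl_stat_combined"]].to_numpy()
    table["accuracy_orth"] = orthogonalize(table["accuracy"].to_numpy(), others)
    return table


def orthogonalize(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    """OLS residual of ``target`` on [intercept, others]."""
    target = np.asarray(target, dtype=float)
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.shape[0] != len(target):
        others = others.T
    if others.shape[0] != len(target):
        raise ConfigurationError("columns must share the target's length")
    X = np.column_stack([np.ones(len(target)), others])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError(
            "rank-deficient design: some columns are collinear "
            "(with each other or the intercept)"
        )
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    return target - X @ coef


def correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and p over the main regressors plus accuracy.

    Pairs involving a constant column are flagged with NaN r rather than
    raising.  Rows with missing values are dropped pairwise.
    """
    cols = [c for c in (*MAIN_REGRESSORS, "accuracy") if c in table.columns]
    if len(table) < 3:
        raise ConfigurationError("need >= 3 rows for correlations")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = table[[a, b]].dropna()
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(xa, xb)
            rows.append({"a": a, "b": b, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def write_events_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    """Export as a BIDS-style events table (missing values as 'n/a')."""
    path = Path(path)
    out = table.rename(columns={"onset_s": "onset", "duration_s": "duration"}).copy()
    lead = ["onset", "duration"]
    out = out[lead + [c for c in out.columns if c not in lead]]
    out.insert(2, "trial_type", "decision")
    out.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")
    return path
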