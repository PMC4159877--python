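"""Prediction-error metrics and bootstrap dispersion estimates.

For observed activities y_i and predictions y'_i:

* MAE = mean |y_i - y'_i|
* Q^2 = 1 - sum (y_i - y'_i)^2 / sum (y_i - ybar)^2, with ybar the mean
  of the observed values (training-set mean convention).

With only ~20 compounds a train/test split is wasteful, so dispersion
is estimated by a pair-resampling bootstrap: the (observation,
prediction) pairs of the fitted model are resampled with replacement
and both metrics recomputed on each replicate; the report carries the
mean and standard deviation over replicates next to the plain point
estimates.  A retraining bootstrap (model refit per replicate) is
available separately for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PredictionPairs",
    "ValidationReport",
    "mae",
    "q_square",
    "bootstrap_validate",
    "bootstrap_retrain",
]


@dataclass(frozen=True)
class PredictionPairs:
    """Matched experimental and predicted activities (% DPPH scavenged)."""

    y_obs: np.ndarray
    y_pred: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "y_obs", np.asarray(self.y_obs, dtype=float).ravel())
        object.__setattr__(self, "y_pred", np.asarray(self.y_pred, dtype=float).ravel())
        if self.y_obs.size != self.y_pred.size:
            raise ValueError(
                f"length mismatch: {self.y_obs.size} observed vs "
                f"{self.y_pred.size} predicted"
            )
        if self.y_obs.size < 2:
            raise ValueError("need at least 2 prediction pairs")
        if self.labels and len(self.labels) != self.y_obs.size:
            raise ValueError("labels length does not match pairs")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.y_obs.size


@dataclass(frozen=True)
class ValidationReport:
    """Point estimates plus bootstrap mean +/- SD for MAE and Q^2."""

    mae: float
    q2: float
    mae_boot_mean: float
    mae_boot_sd: float
    q2_boot_mean: float
    q2_boot_sd: float
    n_boot: int
    seed: int
    n_q2_skipped: int = 0

    def to_text(self) -> str:
        lines = [
            f"n_boot: {self.n_boot}",
            f"seed: {self.seed}",
            f"mae: {self.mae:.4f}",
            f"q2: {self.q2:.4f}",
            f"mae_bootstrap: {self.mae_boot_mean:.2f} +/- {self.mae_boot_sd:.2f}",
            f"q2_bootstrap: {self.q2_boot_mean:.2f} +/- {self.q2_boot_sd:.2f}",
        ]
        if self.n_q2_skipped:
            lines.append(
                f"q2_replicates_skipped: {self.n_q2_skipped} (constant resample)"
            )
        return "\n".join(lines)


def mae(pairs: PredictionPairs) -> float:
    """Mean absolute prediction error."""
    return float(np.mean(np.abs(pairs.y_obs - pairs.y_pred)))


def q_square(pairs: PredictionPairs) -> float:
    """Predictive squared correlation, 1 - SSE/SST about the observed mean."""
    y, yp = pairs.y_obs, pairs.y_pred
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("Q^2 undefined: observed activities are constant")
    return 1.0 - float(np.sum((y - yp) ** 2)) / sst


def bootstrap_validate(
    pairs: PredictionPairs,
    n_boot: int = 1000,
    seed: int = 0,
    return_replicates: bool = False,
):
    """Pair-resampling bootstrap of MAE and Q^2.

    Draws ``n_boot`` index resamples of size n with replacement and
    recomputes both metrics on each.  Replicates whose resampled
    observations are constant have no defined Q^2; they are skipped for
    Q^2 (MAE is still computed) and counted in ``n_q2_skipped``.  Same
    seed and ``n_boot`` give an identical report.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    n = len(pairs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    yo = pairs.y_obs[idx]   # (n_boot, n)
    yp = pairs.y_pred[idx]
    mae_rep = np.mean(np.abs(yo - yp), axis=1)
    sst = np.sum((yo - yo.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ok = sst > 0
    q2_rep = np.full(n_boot, np.nan)
    q2_rep[ok] = 1.0 - np.sum((yo[ok] - yp[ok]) ** 2, axis=1) / sst[ok]
    n_skipped = int(n_boot - ok.sum())
    report = ValidationReport(
        mae=mae(pairs),
        q2=q_square(pairs),
        mae_boot_mean=float(mae_rep.mean()),
        mae_boot_sd=float(mae_rep.std(ddof=1)) if n_boot > 1 else 0.0,
        q2_boot_mean=float(q2_rep[ok].mean()) if ok.any() else float("nan"),
        q2_boot_sd=float(q2_rep[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
        n_boot=n_boot,
        seed=seed,
        n_q2_skipped=n_skipped,
    )
    if return_replicates:
        return report, mae_rep, q2_rep
    return report


def bootstrap_retrain(
    X,
    y: Sequence[float],
    fit_predict: Callable,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Retraining bootstrap: refit the model on each resample.

    ``fit_predict(X_train, y_train, X_eval)`` must return predictions
    for ``X_eval``.  Each replicate trains on a with-replacement
    resample of the rows and evaluates on the full data; returns the
    per-replicate MAE and Q^2 arrays (Q^2 is nan where undefined).
    Considerably slower than :func:`bootstrap_validate`; intended for
    comparing the two bootstrap conventions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    mae_rep = np.empty(n_boot)
    q2_rep = np.full(n_boot, np.nan)
    sst = float(np.sum((y - y.mean()) ** 2))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yp = np.asarray(fit_predict(X[idx], y[idx], X), dtype=float).ravel()
        mae_rep[b] = np.mean(np.abs(y - yp))
        if sst > 0:
            q2_rep[b] = 1.0 - float(np.sum((y - yp) ** 2)) / sst
    return mae_rep, q2_rep
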