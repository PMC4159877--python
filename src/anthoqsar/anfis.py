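"""First-order Takagi-Sugeno neuro-fuzzy regression (ANFIS), from scratch.

The model covers each input with a small set of triangular membership
functions placed by uniform grid partition and enumerates every
combination of per-input membership functions as one if-then rule (two
functions on each of four inputs gives 2**4 = 16 rules).  Each rule i
carries a linear consequent g_i(x) = c_i0 + sum_j c_ij x_j; the output
is the firing-strength-weighted average

    f(x) = sum_i wbar_i g_i(x),   wbar_i = w_i / sum_k w_k,

with w_i the product of the rule's antecedent membership degrees.

Training is hybrid by default: each epoch solves the consequent
coefficients globally by (ridge-stabilized) linear least squares on the
normalized-firing design matrix, then takes one analytic gradient step
on the membership-function vertices.  A pure gradient mode updates both
parameter groups by backpropagation.  With many rules and few samples
the least-squares step is underdetermined; a tiny ridge penalty (or the
minimum-norm solution at ridge zero) keeps it well defined.
"""

from __future__ import annotations

import copy
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TriangularMF",
    "Rule",
    "ANFISModel",
    "TrainingConfig",
    "DegenerateRangeError",
    "AllRulesInactiveError",
    "TrainingError",
    "init_grid",
    "memberships",
    "predict",
    "train",
    "fit_anfis",
]

FORMAT_VERSION = 1


class DegenerateRangeError(ValueError):
    """An input column is constant, so no grid can be placed over it."""


class AllRulesInactiveError(ValueError):
    """Every rule fired with strength zero for some input vector."""


class TrainingError(RuntimeError):
    """Training aborted (non-finite gradient or loss)."""


@dataclass
class TriangularMF:
    """Triangular membership function with vertices left <= peak <= right.

    Membership is 0 outside [left, right], 1 at the peak and linear on
    each flank.
    """

    left: float
    peak: float
    right: float

    def __post_init__(self):
        if not (self.left <= self.peak <= self.right):
            raise ValueError(
                f"vertices must satisfy left <= peak <= right, got "
                f"({self.left}, {self.peak}, {self.right})"
            )
        if not self.left < self.right:
            raise ValueError("left must be strictly below right")

    def degree(self, x):
        """Membership degree(s) of ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        a, b, c = self.left, self.peak, self.right
        out = np.zeros_like(x)
        if b > a:
            rising = (x > a) & (x < b)
            out = np.where(rising, (x - a) / (b - a), out)
        if c > b:
            falling = (x >= b) & (x < c)
            out = np.where(falling, (c - x) / (c - b), out)
        out = np.where(x == b, 1.0, out)
        return out if out.ndim else float(out)

    def vertex_gradients(self, x):
        """d(degree)/d(left, peak, right) at ``x``.

        The subgradient at the non-differentiable vertices is taken as 0.
        Returns three arrays shaped like ``x``.
        """
        x = np.asarray(x, dtype=float)
        a, b, c = self.left, self.peak, self.right
        da = np.zeros_like(x)
        db = np.zeros_like(x)
        dc = np.zeros_like(x)
        if b > a:
            rising = (x > a) & (x < b)
            denom = (b - a) ** 2
            da = np.where(rising, (x - b) / denom, da)
            db = np.where(rising, -(x - a) / denom, db)
        if c > b:
            falling = (x > b) & (x < c)
            denom = (c - b) ** 2
            db = np.where(falling, (c - x) / denom, db)
            dc = np.where(falling, (x - b) / denom, dc)
        return da, db, dc


@dataclass
class Rule:
    """One if-then rule: per-input MF indices and a linear consequent.

    ``consequent`` holds (c0, c1, ..., cd) for g(x) = c0 + sum_j cj x_j.
    """

    antecedent: tuple[int, ...]
    consequent: np.ndarray

    def __post_init__(self):
        self.antecedent = tuple(int(i) for i in self.antecedent)
        self.consequent = np.asarray(self.consequent, dtype=float)
        if self.consequent.ndim != 1 or self.consequent.size != len(self.antecedent) + 1:
            raise ValueError(
                f"consequent must have {len(self.antecedent) + 1} coefficients, "
                f"got shape {self.consequent.shape}"
            )


@dataclass
class ANFISModel:
    """A grid-partition Takagi-Sugeno fuzzy model.

    ``input_ranges`` stores the observed (min, max) per input; when
    ``standardize`` is set, inputs are min-max scaled onto [0, 1] before
    membership evaluation and the grid lives on [0, 1].
    """

    input_names: list[str]
    mfs: list[list[TriangularMF]]
    rules: list[Rule]
    input_ranges: list[tuple[float, float]]
    standardize: bool = True

    def __post_init__(self):
        d = len(self.input_names)
        if len(self.mfs) != d or len(self.input_ranges) != d:
            raise ValueError("mfs and input_ranges must have one entry per input")
        expected = int(np.prod([len(m) for m in self.mfs]))
        if len(self.rules) != expected:
            raise ValueError(
                f"rule base must enumerate all {expected} antecedent "
                f"combinations, got {len(self.rules)} rules"
            )

    # -- helpers -----------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map raw inputs into the membership domain."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.standardize:
            return X
        lo = np.array([r[0] for r in self.input_ranges])
        hi = np.array([r[1] for r in self.input_ranges])
        return (X - lo) / (hi - lo)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "input_names": list(self.input_names),
            "standardize": self.standardize,
            "input_ranges": [list(r) for r in self.input_ranges],
            "mfs": [
                [{"left": mf.left, "peak": mf.peak, "right": mf.right} for mf in per_input]
                for per_input in self.mfs
            ],
            "rules": [
                {"antecedent": list(r.antecedent), "consequent": r.consequent.tolist()}
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANFISModel":
        version = d.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        return cls(
            input_names=list(d["input_names"]),
            mfs=[
                [TriangularMF(m["left"], m["peak"], m["right"]) for m in per_input]
                for per_input in d["mfs"]
            ],
            rules=[
                Rule(tuple(r["antecedent"]), np.array(r["consequent"], dtype=float))
                for r in d["rules"]
            ],
            input_ranges=[tuple(r) for r in d["input_ranges"]],
            standardize=bool(d["standardize"]),
        )

    def save(self, path: Union[str, Path]) -> None:
        """Write the model as human-readable structured text (JSON)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ANFISModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingConfig:
    """Hyperparameters for ANFIS training.

    ``epochs`` defaults to 100.  ``consequent_solver`` is
    ``least_squares`` (hybrid learning, the default) or ``gradient``
    (pure backpropagation).  ``ridge`` stabilizes the underdetermined
    least-squares step; set to 0 for the exact minimum-norm solution.
    The seed governs optional row shuffling only: grid initialization is
    deterministic.
    """

    epochs: int = 100
    learning_rate: float = 0.01
    consequent_solver: str = "least_squares"
    seed: int = 0
    standardize_inputs: bool = True
    ridge: float = 1e-6
    shuffle: bool = False

    def __post_init__(self):
        if int(self.epochs) < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        self.epochs = int(self.epochs)
        if self.learning_rate < 0:
            raise ValueError(
                "learning_rate must be non-negative (0 freezes the premises)"
            )
        if self.consequent_solver not in ("least_squares", "gradient"):
            raise ValueError(
                f"unknown consequent_solver {self.consequent_solver!r}"
            )
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


# ---------------------------------------------------------------------------
# Construction

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X, [f"x{j}" for j in range(X.shape[1])]


def init_grid(X, mfs_per_input: int = 2, standardize: bool = True) -> ANFISModel:
    """Build an untrained model by uniform grid partition over the data range.

    For m membership functions per input, peaks sit at m equally spaced
    points spanning the observed range and each triangle extends one
    grid step to either side, so with m = 2 the pair (left-shoulder,
    right-shoulder) sums to full membership everywhere on the range.
    Consequents start at zero.  Constant input columns raise
    :class:`DegenerateRangeError`.
    """
    if mfs_per_input < 2:
        raise ValueError("need at least 2 membership functions per input")
    mat, names = _as_matrix(X)
    if mat.size == 0:
        raise ValueError("empty training table")
    d = mat.shape[1]
    ranges: list[tuple[float, float]] = []
    mfs: list[list[TriangularMF]] = []
    for k in range(d):
        lo, hi = float(mat[:, k].min()), float(mat[:, k].max())
        if not lo < hi:
            raise DegenerateRangeError(
                f"input {names[k]!r} is constant ({lo}); cannot place a grid"
            )
        ranges.append((lo, hi))
        dlo, dhi = (0.0, 1.0) if standardize else (lo, hi)
        step = (dhi - dlo) / (mfs_per_input - 1)
        peaks = np.linspace(dlo, dhi, mfs_per_input)
        mfs.append([TriangularMF(p - step, p, p + step) for p in peaks])
    rules = [
        Rule(ant, np.zeros(d + 1))
        for ant in itertools.product(range(mfs_per_input), repeat=d)
    ]
    return ANFISModel(
        input_names=names, mfs=mfs, rules=rules,
        input_ranges=ranges, standardize=standardize,
    )


# ---------------------------------------------------------------------------
# Inference

def memberships(model: ANFISModel, x: Sequence[float]) -> list[np.ndarray]:
    """Layer-1 output: per-input arrays of membership degrees for one vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(
            f"expected {model.n_inputs} input values, got shape {x.shape}"
        )
    xt = model.transform(x)[0]
    return [
        np.array([mf.degree(xt[k]) for mf in model.mfs[k]])
        for k in range(model.n_inputs)
    ]


def _mu_per_input(model: ANFISModel, Xt: np.ndarray) -> list[np.ndarray]:
    """Membership degrees: one (n_mfs, n_samples) array per input."""
    return [
        np.stack([mf.degree(Xt[:, k]) for mf in model.mfs[k]])
        for k in range(model.n_inputs)
    ]


def _firing(model: ANFISModel, Xt: np.ndarray) -> np.ndarray:
    """Rule firing strengths, shape (n_samples, n_rules)."""
    mu = _mu_per_input(model, Xt)
    w = np.ones((Xt.shape[0], len(model.rules)))
    for i, rule in enumerate(model.rules):
        for k, m_idx in enumerate(rule.antecedent):
            w[:, i] *= mu[k][m_idx]
    return w


def _forward(model: ANFISModel, Xt: np.ndarray, X_raw: np.ndarray):
    w = _firing(model, Xt)
    S = w.sum(axis=1)
    dead = S <= 0
    if np.any(dead):
        bad = X_raw[dead][0]
        raise AllRulesInactiveError(
            f"all {len(model.rules)} rules fired with strength 0 for input "
            f"{dict(zip(model.input_names, bad.tolist()))}"
        )
    wbar = w / S[:, None]
    X1 = np.hstack([np.ones((Xt.shape[0], 1)), Xt])
    C = np.stack([r.consequent for r in model.rules])  # (R, d+1)
    G = X1 @ C.T                                       # (n, R)
    return wbar, X1, G, (wbar * G).sum(axis=1)


def predict(model: ANFISModel, X) -> np.ndarray:
    """Takagi-Sugeno inference for one or more input vectors."""
    mat, _ = _as_matrix(X)
    if mat.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} input columns, got {mat.shape[1]}"
        )
    Xt = model.transform(mat)
    _, _, _, f = _forward(model, Xt, mat)
    return f


# ---------------------------------------------------------------------------
# Training

def _solve_consequents(model: ANFISModel, wbar, X1, y, ridge: float) -> None:
    n, d1 = X1.shape
    R = len(model.rules)
    Phi = (wbar[:, :, None] * X1[:, None, :]).reshape(n, R * d1)
    if ridge > 0:
        A = Phi.T @ Phi + ridge * np.eye(R * d1)
        b = Phi.T @ y
        try:
            theta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular consequent system; falling back to minimum-norm "
                "least squares", RuntimeWarning,
            )
            theta = np.linalg.lstsq(Phi, y, rcond=None)[0]
    else:
        theta = np.linalg.lstsq(Phi, y, rcond=None)[0]
    for i, rule in enumerate(model.rules):
        rule.consequent = theta[i * d1:(i + 1) * d1].copy()


def _gradients(model: ANFISModel, Xt: np.ndarray, y: np.ndarray):
    """Analytic MSE gradients w.r.t. MF vertices and consequents.

    Returns (premise_grads, consequent_grad) where ``premise_grads[k]``
    is an (n_mfs_k, 3) array of d(MSE)/d(left, peak, right) and
    ``consequent_grad`` is (n_rules, d+1).
    """
    n, d = Xt.shape
    R = len(model.rules)
    mu = _mu_per_input(model, Xt)
    ants = np.array([r.antecedent for r in model.rules])  # (R, d)
    U = np.empty((R, d, n))
    for i in range(R):
        for k in range(d):
            U[i, k] = mu[k][ants[i, k]]
    w = U.prod(axis=1)            # (R, n)
    S = w.sum(axis=0)             # (n,)
    if np.any(S <= 0):
        raise AllRulesInactiveError(
            "a training sample activates no rule; premise update left a "
            "coverage gap"
        )
    wbar = w / S
    X1 = np.hstack([np.ones((n, 1)), Xt])
    C = np.stack([r.consequent for r in model.rules])
    G = C @ X1.T                  # (R, n)
    f = (wbar * G).sum(axis=0)
    e = f - y
    # dE/dw_i = (2/n) e (g_i - f) / S
    dE_dw = (2.0 / n) * e * (G - f) / S          # (R, n)
    cons_grad = (2.0 / n) * (wbar * e) @ X1      # (R, d+1)
    premise_grads = []
    for k in range(d):
        others = [kk for kk in range(d) if kk != k]
        Uexcl = U[:, others, :].prod(axis=1) if others else np.ones((R, n))
        dE_dmu_used = dE_dw * Uexcl              # (R, n)
        gk = np.zeros((len(model.mfs[k]), 3))
        xk = Xt[:, k]
        for m_idx, mf in enumerate(model.mfs[k]):
            mask = ants[:, k] == m_idx
            if not mask.any():
                continue
            dE_dmu = dE_dmu_used[mask].sum(axis=0)  # (n,)
            da, db, dc = mf.vertex_gradients(xk)
            gk[m_idx] = (dE_dmu @ da, dE_dmu @ db, dE_dmu @ dc)
        premise_grads.append(gk)
    return premise_grads, cons_grad


def _clipped_mf(a: float, b: float, c: float) -> TriangularMF:
    """Re-impose vertex ordering after a gradient step."""
    a = min(a, b)
    c = max(c, b)
    if not a < c:
        a -= 1e-9
        c += 1e-9
    return TriangularMF(a, b, c)


def _apply_premise_step(model: ANFISModel, grads, lr: float) -> None:
    for k in range(model.n_inputs):
        new = []
        for m_idx, mf in enumerate(model.mfs[k]):
            ga, gb, gc = grads[k][m_idx]
            new.append(
                _clipped_mf(mf.left - lr * ga, mf.peak - lr * gb, mf.right - lr * gc)
            )
        model.mfs[k] = new


def train(
    model: ANFISModel,
    X,
    y: Sequence[float],
    cfg: TrainingConfig = TrainingConfig(),
) -> tuple[ANFISModel, np.ndarray]:
    """Fit the model, returning a trained copy and the per-epoch MSE trace.

    Hybrid mode (``least_squares``): each epoch solves the consequents
    by ridge/minimum-norm least squares on the normalized-firing design
    matrix, records the training MSE at that optimum, then moves the
    membership vertices one gradient step (re-clipping the vertex
    ordering).  Pure ``gradient`` mode updates both groups by gradient
    descent and records the MSE after the update.
    """
    model = copy.deepcopy(model)
    mat, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if mat.shape[0] != y.size:
        raise ValueError(
            f"X has {mat.shape[0]} rows but y has {y.size} values"
        )
    rng = np.random.default_rng(cfg.seed)
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        if cfg.shuffle:
            order = rng.permutation(y.size)
            mat, y = mat[order], y[order]
        Xt = model.transform(mat)
        if cfg.consequent_solver == "least_squares":
            wbar, X1, G, _ = _forward(model, Xt, mat)
            _solve_consequents(model, wbar, X1, y, cfg.ridge)
            _, _, _, f = _forward(model, Xt, mat)
            trace[epoch] = float(np.mean((f - y) ** 2))
            if epoch < cfg.epochs - 1 and cfg.learning_rate > 0:
                # final epoch ends on the consequent solve, so the returned
                # model is least-squares-optimal for its premises
                premise_grads, _ = _gradients(model, Xt, y)
                _check_finite_grads(premise_grads, epoch)
                _apply_premise_step(model, premise_grads, cfg.learning_rate)
        else:
            premise_grads, cons_grad = _gradients(model, Xt, y)
            _check_finite_grads(premise_grads, epoch, cons_grad)
            for i, rule in enumerate(model.rules):
                rule.consequent = rule.consequent - cfg.learning_rate * cons_grad[i]
            _apply_premise_step(model, premise_grads, cfg.learning_rate)
            _, _, _, f = _forward(model, model.transform(mat), mat)
            trace[epoch] = float(np.mean((f - y) ** 2))
        if not np.isfinite(trace[epoch]):
            raise TrainingError(
                f"non-finite training MSE at epoch {epoch}; reduce the "
                f"learning rate (current {cfg.learning_rate})"
            )
    return model, trace


def _check_finite_grads(premise_grads, epoch: int, cons_grad=None) -> None:
    bad = any(not np.all(np.isfinite(g)) for g in premise_grads)
    if cons_grad is not None:
        bad = bad or not np.all(np.isfinite(cons_grad))
    if bad:
        raise TrainingError(
            f"non-finite gradient at epoch {epoch}; inputs may be degenerate "
            f"or the learning rate too large"
        )


def fit_anfis(
    X,
    y: Sequence[float],
    cfg: TrainingConfig = TrainingConfig(),
    mfs_per_input: int = 2,
) -> tuple[ANFISModel, np.ndarray]:
    """Grid-initialize and train in one call."""
    model = init_grid(X, mfs_per_input=mfs_per_input, standardize=cfg.standardize_inputs)
    return train(model, X, y, cfg)
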