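"""First-order Takagi–Sugeno ANFIS with Gaussian membership functions.

The network is the classical five-layer adaptive neuro-fuzzy inference
system on a grid partition: each of the ``d`` inputs carries ``m`` Gaussian
membership functions, every combination of one membership function per
input forms a rule (``m**d`` rules), a rule's firing strength is the
product of its membership degrees, strengths are normalized to sum to one,
and each rule contributes a first-order (linear) Sugeno consequent
weighted by its normalized strength:

    y(x) = sum_i  wbar_i(x) * (a_i . x + b_i)

Training follows the hybrid scheme: on each epoch the consequent
coefficients are solved exactly by linear least squares with the premise
(membership) parameters frozen — the system is linear in the consequents —
and the premise centers and widths then take one gradient step on the
training error.  A plain gradient-descent ("backprop") trainer over all
parameters is also provided; when no method is requested, both are run and
the one with the lower checking-set RMSE wins.

With a grid of 3 membership functions over 4 inputs the rule base has 81
rules and 405 consequent coefficients, far more than a 30-run design can
determine; the least-squares step therefore returns the minimum-norm
solution and the returned model is the epoch snapshot with the lowest
checking-set RMSE, which guards against the interpolation overfitting such
underdetermined systems invite.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AnfisState",
    "TrainingConfig",
    "TrainingHistory",
    "AnfisRegressor",
    "init_grid_partition",
    "gaussian_membership",
    "firing_strengths",
    "predict_state",
    "lse_consequents",
    "train",
    "split_train_check",
]

_SIGMA_FLOOR = 1e-3


@dataclass
class AnfisState:
    """Parameters of one single-output ANFIS.

    centers, sigmas : (d, m) Gaussian membership parameters per input.
    rule_index : (R, d) integer matrix; row r names the membership
        function each input contributes to rule r.
    consequents : (R, d+1) linear Sugeno coefficients, constant last.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    rule_index: np.ndarray
    consequents: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.rule_index = np.asarray(self.rule_index, dtype=int)
        self.consequents = np.asarray(self.consequents, dtype=float)
        d = self.centers.shape[0]
        if self.sigmas.shape != self.centers.shape:
            raise ValueError("sigma array must match center array shape")
        if np.any(self.sigmas <= 0):
            raise ValueError("all membership widths must be positive")
        if self.rule_index.ndim != 2 or self.rule_index.shape[1] != d:
            raise ValueError("rule index matrix must be (n_rules, d)")
        if self.consequents.shape != (self.rule_index.shape[0], d + 1):
            raise ValueError("consequents must be (n_rules, d+1)")

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[0]

    @property
    def n_rules(self) -> int:
        return self.rule_index.shape[0]

    def copy(self) -> "AnfisState":
        return AnfisState(
            self.centers.copy(), self.sigmas.copy(),
            self.rule_index.copy(), self.consequents.copy(),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the ANFIS trainer.

    ``method`` is ``"hybrid"``, ``"backprop"``, or ``None`` to train both
    and keep whichever checks better.  The step-size schedule is the
    classic heuristic: increase by ``step_adapt_up`` after four
    consecutive error decreases, decrease by ``step_adapt_down`` after
    two consecutive up/down oscillations.
    """

    epochs: int = 500
    method: str | None = "hybrid"
    initial_step: float = 0.01
    step_adapt_up: float = 1.1
    step_adapt_down: float = 0.9
    train_fraction: float = 0.7
    sigma_floor: float = _SIGMA_FLOOR
    lse_rcond: float | str | None = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.method not in (None, "hybrid", "backprop"):
            raise ValueError(f"unknown training method {self.method!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch RMSE traces and the snapshot-selection epoch."""

    train_rmse: list[float] = field(default_factory=list)
    check_rmse: list[float] = field(default_factory=list)
    best_checking_epoch: int = -1
    method: str = ""


# ---------------------------------------------------------------------------
# functional layer


def init_grid_partition(
    domains: Sequence[tuple[float, float]],
    m: int = 3,
    width_scale: float = 1.5,
) -> AnfisState:
    """Grid-partition initial state: ``m`` evenly spaced Gaussian membership
    functions per input, consequents zero, full ``m**d`` rule base.

    Membership widths are ``width_scale`` times the center spacing
    ``(high - low)/(m - 1)``.  The default 1.5 makes adjacent fuzzy sets
    overlap strongly, so the normalized firing strengths vary smoothly
    across the box; narrow, weakly overlapping sets make the rule-blend
    surface oscillate between data points whenever the consequent system
    is underdetermined.
    """
    if m < 2:
        raise ValueError("need at least two membership functions per input")
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    domains = [(float(lo), float(hi)) for lo, hi in domains]
    if not domains:
        raise ValueError("at least one input domain is required")
    for lo, hi in domains:
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo:
            raise ValueError(f"degenerate input domain ({lo}, {hi})")
    d = len(domains)
    centers = np.array([np.linspace(lo, hi, m) for lo, hi in domains])
    sigmas = np.array(
        [[width_scale * (hi - lo) / (m - 1)] * m for lo, hi in domains]
    )
    rule_index = np.array(list(itertools.product(range(m), repeat=d)), dtype=int)
    consequents = np.zeros((m**d, d + 1))
    return AnfisState(centers, sigmas, rule_index, consequents)


def gaussian_membership(x, center: float, sigma: float):
    """Gaussian membership degree exp(−(x − c)² / (2σ²)); peaks at 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def _memberships(state: AnfisState, X: np.ndarray) -> np.ndarray:
    # (n, d, m): membership of sample t's input j in MF i of input j
    diff = X[:, :, None] - state.centers[None, :, :]
    return np.exp(-(diff**2) / (2.0 * state.sigmas[None, :, :] ** 2))


def firing_strengths(
    state: AnfisState, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rule firing strengths and their normalization for a batch of inputs.

    Returns ``(w, wbar)`` of shape (n, n_rules); each row of ``wbar``
    sums to one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = _memberships(state, X)  # (n, d, m)
    # gather each rule's membership per input and multiply across inputs
    w = _rule_products(mu, state.rule_index)
    total = w.sum(axis=1, keepdims=True)
    # all-Gaussian strengths cannot vanish exactly; guard for underflow anyway
    safe = np.where(total > 0, total, 1.0)
    wbar = np.where(total > 0, w / safe, 1.0 / state.n_rules)
    return w, wbar


def _rule_products(mu: np.ndarray, rule_index: np.ndarray) -> np.ndarray:
    n, d, _ = mu.shape
    w = np.ones((n, rule_index.shape[0]))
    for j in range(d):
        w *= mu[:, j, rule_index[:, j]]
    return w


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def predict_state(state: AnfisState, X) -> np.ndarray:
    """Network output: normalized-strength-weighted sum of rule consequents."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, wbar = firing_strengths(state, X)
    f = _augment(X) @ state.consequents.T  # (n, R)
    return np.sum(wbar * f, axis=1)


#: Relative singular-value cutoff used for the underdetermined consequent
#: solve.  Directions of the regression matrix with singular values below
#: this fraction of the largest correspond to near-invisible, wildly
#: oscillating consequent combinations; truncating them keeps the fitted
#: surface in the smooth subspace and stops the solve from interpolating
#: measurement noise.
_LSE_RCOND_UNDERDETERMINED = 1e-2


def lse_consequents(state: AnfisState, X, y, rcond="auto") -> np.ndarray:
    """Least-squares consequents with the premise parameters frozen.

    The network output is linear in the consequents; the regression row
    for sample t is the concatenation over rules of ``wbar_i(x_t)*[x_t, 1]``.
    The minimum-norm least-squares solution is returned.  With the
    default ``rcond="auto"``, an underdetermined system (fewer records
    than consequent coefficients) is additionally solved with a spectral
    cutoff of 1e−2 — the exact-interpolation solution such systems admit
    generalizes terribly — while a determined system is solved at full
    numerical rank.  Pass ``rcond=None`` to force the plain minimum-norm
    solution, or a float to set the cutoff explicitly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 1:
        raise ValueError("need at least one record")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training values")
    _, wbar = firing_strengths(state, X)
    phi = (wbar[:, :, None] * _augment(X)[:, None, :]).reshape(X.shape[0], -1)
    if rcond == "auto":
        rcond = (
            _LSE_RCOND_UNDERDETERMINED if phi.shape[0] < phi.shape[1] else None
        )
    coef, *_ = np.linalg.lstsq(phi, y, rcond=rcond)
    return coef.reshape(state.n_rules, state.n_inputs + 1)


def split_train_check(
    n: int, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/check index split with ⌈fraction·n⌉ training rows."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if n < 1:
        raise ValueError("empty table")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = min(int(math.ceil(fraction * n)), n - 1) if n > 1 else 1
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _premise_gradient(
    state: AnfisState, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the training SSE w.r.t. centers, sigmas and consequents."""
    n, d = X.shape
    mu = _memberships(state, X)
    w = _rule_products(mu, state.rule_index)
    total = w.sum(axis=1, keepdims=True)
    total = np.where(total > 0, total, 1.0)
    wbar = w / total
    x1 = _augment(X)
    f = x1 @ state.consequents.T
    yhat = np.sum(wbar * f, axis=1)
    err = yhat - y
    # dSSE/dw_r = 2 e (f_r - yhat) / total
    g_w = 2.0 * err[:, None] * (f - yhat[:, None]) / total * w  # folded: g*w
    d_centers = np.zeros_like(state.centers)
    d_sigmas = np.zeros_like(state.sigmas)
    m = state.centers.shape[1]
    for j in range(d):
        z = X[:, j][:, None] - state.centers[j][None, :]  # (n, m)
        for i in range(m):
            mask = state.rule_index[:, j] == i
            a = g_w[:, mask].sum(axis=1)  # (n,)
            d_centers[j, i] = np.sum(a * z[:, i]) / state.sigmas[j, i] ** 2
            d_sigmas[j, i] = np.sum(a * z[:, i] ** 2) / state.sigmas[j, i] ** 3
    d_conseq = (2.0 * err[:, None] * wbar).T @ x1  # (R, d+1)
    return d_centers, d_sigmas, d_conseq


def _rmse_plain(yhat: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


class _StepSchedule:
    """Jang-style step-size adaptation on the training-error trace."""

    def __init__(self, step: float, up: float, down: float) -> None:
        self.step = step
        self.up = up
        self.down = down
        self.errors: list[float] = []

    def update(self, error: float) -> None:
        self.errors.append(error)
        e = self.errors
        if len(e) >= 5:
            last = e[-5:]
            if all(last[i + 1] < last[i] for i in range(4)):
                self.step *= self.up
                self.errors = []
            elif (last[1] > last[0] and last[2] < last[1]
                  and last[3] > last[2] and last[4] < last[3]):
                self.step *= self.down
                self.errors = []


def _train_one(
    state: AnfisState,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xck: np.ndarray,
    yck: np.ndarray,
    config: TrainingConfig,
    method: str,
) -> tuple[AnfisState, TrainingHistory]:
    state = state.copy()
    history = TrainingHistory(method=method)
    sched = _StepSchedule(config.initial_step, config.step_adapt_up,
                          config.step_adapt_down)
    best: AnfisState | None = None
    best_check = math.inf
    have_check = Xck.shape[0] > 0
    for epoch in range(config.epochs):
        if method == "hybrid":
            state.consequents = lse_consequents(state, Xtr, ytr,
                                                rcond=config.lse_rcond)
        tr = _rmse_plain(predict_state(state, Xtr), ytr)
        ck = _rmse_plain(predict_state(state, Xck), yck) if have_check else tr
        history.train_rmse.append(tr)
        history.check_rmse.append(ck)
        if ck < best_check:
            best_check = ck
            best = state.copy()
            history.best_checking_epoch = epoch
        d_c, d_s, d_q = _premise_gradient(state, Xtr, ytr)
        if method == "hybrid":
            norm = math.sqrt(float(np.sum(d_c**2) + np.sum(d_s**2)))
            if norm > 0:
                state.centers -= sched.step * d_c / norm
                state.sigmas -= sched.step * d_s / norm
        else:  # backprop: gradient on all parameters
            norm = math.sqrt(
                float(np.sum(d_c**2) + np.sum(d_s**2) + np.sum(d_q**2))
            )
            if norm > 0:
                state.centers -= sched.step * d_c / norm
                state.sigmas -= sched.step * d_s / norm
                state.consequents -= sched.step * d_q / norm
        np.clip(state.sigmas, config.sigma_floor, None, out=state.sigmas)
        sched.update(tr)
    assert best is not None
    return best, history


def train(
    state: AnfisState, X, y, config: TrainingConfig = TrainingConfig()
) -> tuple[AnfisState, TrainingHistory]:
    """Train an initialized state on (X, y) records.

    The records are split into training and checking subsets by a seeded
    shuffle; the returned state is the epoch snapshot with the lowest
    checking RMSE.  With ``method=None`` both the hybrid and the
    pure-gradient trainer run and the better-checking one is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    idx_tr, idx_ck = split_train_check(X.shape[0], config.train_fraction,
                                       config.seed)
    Xtr, ytr = X[idx_tr], y[idx_tr]
    Xck, yck = X[idx_ck], y[idx_ck]
    methods = [config.method] if config.method else ["hybrid", "backprop"]
    results = [
        _train_one(state, Xtr, ytr, Xck, yck, config, m) for m in methods
    ]
    results.sort(key=lambda sh: min(sh[1].check_rmse))
    return results[0]


# ---------------------------------------------------------------------------
# estimator layer


class AnfisRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style first-order Takagi–Sugeno ANFIS regressor.

    Inputs are internally rescaled to the coded box [−2, 2] (per-feature
    affine map from ``domain``, or from the training data range when
    ``domain`` is None) before grid partitioning, so membership widths
    are comparable across factors with different units.

    Parameters
    ----------
    n_mfs : membership functions per input (grid partition; rule count
        is ``n_mfs ** n_features``).
    epochs : training epochs.
    method : "hybrid", "backprop", or None for automatic selection by
        checking-set RMSE.
    train_fraction : share of records used for training; the remainder
        forms the checking set used for snapshot selection.
    domain : optional sequence of (low, high) per feature, in input units.
    random_state : seed for the train/check shuffle.

    Attributes
    ----------
    state_ : AnfisState in coded units.
    history_ : TrainingHistory of the selected trainer.
    method_ : the training method actually selected.
    domains_ : (n_features, 2) input domains in original units.
    """

    def __init__(
        self,
        n_mfs: int = 3,
        epochs: int = 500,
        method: str | None = "hybrid",
        initial_step: float = 0.01,
        step_adapt_up: float = 1.1,
        step_adapt_down: float = 0.9,
        train_fraction: float = 0.7,
        sigma_floor: float = _SIGMA_FLOOR,
        width_scale: float = 1.5,
        lse_rcond: float | str | None = "auto",
        domain: Sequence[tuple[float, float]] | None = None,
        random_state: int = 0,
    ) -> None:
        self.n_mfs = n_mfs
        self.epochs = epochs
        self.method = method
        self.initial_step = initial_step
        self.step_adapt_up = step_adapt_up
        self.step_adapt_down = step_adapt_down
        self.train_fraction = train_fraction
        self.sigma_floor = sigma_floor
        self.width_scale = width_scale
        self.lse_rcond = lse_rcond
        self.domain = domain
        self.random_state = random_state

    # -- coded-space mapping ------------------------------------------------
    def _encode(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.domains_[:, 0], self.domains_[:, 1]
        return -2.0 + 4.0 * (X - lo) / (hi - lo)

    def fit(self, X, y) -> "AnfisRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        if self.domain is not None:
            domains = np.asarray(self.domain, dtype=float)
        else:
            domains = np.column_stack([X.min(axis=0), X.max(axis=0)])
        if np.any(domains[:, 1] <= domains[:, 0]):
            raise ValueError("degenerate input domain (zero width)")
        self.domains_ = domains
        self.n_features_in_ = X.shape[1]
        z = -2.0 + 4.0 * (X - domains[:, 0]) / (domains[:, 1] - domains[:, 0])
        state = init_grid_partition(
            [(-2.0, 2.0)] * X.shape[1], self.n_mfs, self.width_scale
        )
        config = TrainingConfig(
            epochs=self.epochs,
            method=self.method,
            initial_step=self.initial_step,
            step_adapt_up=self.step_adapt_up,
            step_adapt_down=self.step_adapt_down,
            train_fraction=self.train_fraction,
            sigma_floor=self.sigma_floor,
            lse_rcond=self.lse_rcond,
            seed=self.random_state,
        )
        self.state_, self.history_ = train(state, z, y, config)
        self.method_ = self.history_.method
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "state_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return predict_state(self.state_, self._encode(X))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "state_")
        return {
            "params": self.get_params(deep=False),
            "domains": self.domains_.tolist(),
            "centers": self.state_.centers.tolist(),
            "sigmas": self.state_.sigmas.tolist(),
            "rule_index": self.state_.rule_index.tolist(),
            "consequents": self.state_.consequents.tolist(),
            "history": {
                "train_rmse": self.history_.train_rmse,
                "check_rmse": self.history_.check_rmse,
                "best_checking_epoch": self.history_.best_checking_epoch,
                "method": self.history_.method,
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AnfisRegressor":
        params = dict(doc["params"])
        if params.get("domain") is not None:
            params["domain"] = [tuple(p) for p in params["domain"]]
        est = cls(**params)
        est.domains_ = np.asarray(doc["domains"], dtype=float)
        est.n_features_in_ = est.domains_.shape[0]
        est.state_ = AnfisState(
            np.asarray(doc["centers"]), np.asarray(doc["sigmas"]),
            np.asarray(doc["rule_index"]), np.asarray(doc["consequents"]),
        )
        h = doc["history"]
        est.history_ = TrainingHistory(
            train_rmse=list(h["train_rmse"]),
            check_rmse=list(h["check_rmse"]),
            best_checking_epoch=int(h["best_checking_epoch"]),
            method=h["method"],
        )
        est.method_ = h["method"]
        return est

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "AnfisRegressor":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
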