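"""Ensemble multilayer-perceptron autoregression.

The network maps the previous ``lags`` demand values to the next one through
one or more logistic hidden layers and a linear output,

    y_t = b0 + sum_j b_j * psi(g_j0 + sum_i g_ji * y_{t-i}),

generalised layer-wise for deeper architectures.  Training minimises the
full-batch squared error of a random ~63% training subset with warm-started
quasi-Newton (L-BFGS) bursts; the mean squared error of the remaining
hold-out (sized floor(n * exp(-1))) is evaluated after every iteration
(burst) and training stops as soon as its improvement falls below a
tolerance, or after a hard iteration cap with the network flagged
non-converged.  The weights kept are those of the best hold-out error seen.

Because a single small network on a short series is a high-variance
estimator, the model is always an *ensemble*: many networks with the same
architecture but fresh initialisations and fresh validation splits, whose
forecast is the arithmetic mean of the member forecasts.  Architecture and
lag order can be chosen by a greedy search that grows neurons within a
layer, then layers, accepting only steps that improve mean validation MSE.

Inputs and targets are min-max scaled to [0, 1] (parameters fitted on the
training rows only); raw demand units would saturate the logistic layers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .series import MonthlySeries

__all__ = [
    "AnnArchitecture",
    "AnnNetwork",
    "AnnEnsemble",
    "MLPAutoregression",
    "build_design_matrix",
    "logistic",
    "split_validation",
    "train_network",
    "greedy_search",
    "fit_ensemble",
    "forecast_ensemble",
]

logger = logging.getLogger(__name__)

VALIDATION_FRACTION = math.exp(-1.0)


def logistic(z):
    """Logistic activation 1 / (1 + exp(-z)), elementwise."""
    return expit(z)


def _series_values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class AnnArchitecture:
    """Hidden-layer sizes, autoregressive lag count and ensemble size."""

    hidden_layers: tuple[int, ...] = (5,)
    lags: int = 12
    reps: int = 100

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(k < 1 for k in self.hidden_layers):
            raise ValueError("every hidden layer needs >= 1 neuron")
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def build_design_matrix(series, lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design: row t has inputs (y_{t-1}, ..., y_{t-lags}) and target
    y_t; returns (inputs, targets) with n - lags rows."""
    y = _series_values(series)
    n = y.size
    if lags >= n:
        raise ValueError(f"need more observations ({n}) than lags ({lags})")
    rows = n - lags
    X = np.empty((rows, lags))
    for j in range(lags):
        X[:, j] = y[lags - 1 - j : n - 1 - j]
    return X, y[lags:].copy()


def split_validation(
    n_rows: int,
    fraction: float = VALIDATION_FRACTION,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation partition with floor(n_rows * fraction)
    validation rows, uniform without replacement, deterministic per seed."""
    if n_rows < 5:
        raise ValueError("need at least 5 design rows to hold out a validation set")
    n_val = int(np.floor(n_rows * fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return train, val


def _forward(weights, X):
    a = X
    for W, b in weights[:-1]:
        a = logistic(a @ W + b)
    W, b = weights[-1]
    return (a @ W + b).ravel()


def _forward_cache(weights, X):
    acts = [X]
    a = X
    for W, b in weights[:-1]:
        a = logistic(a @ W + b)
        acts.append(a)
    W, b = weights[-1]
    return acts, (acts[-1] @ W + b).ravel()


def _gradients(weights, X, y):
    """Backpropagated gradients of mean squared error."""
    acts, out = _forward_cache(weights, X)
    m = y.size
    delta = (2.0 / m) * (out - y)[:, None]  # d loss / d output
    grads = [None] * len(weights)
    W_out, _ = weights[-1]
    grads[-1] = (acts[-1].T @ delta, delta.sum(axis=0))
    back = delta @ W_out.T
    for layer in range(len(weights) - 2, -1, -1):
        a = acts[layer + 1]
        local = back * a * (1.0 - a)  # logistic derivative
        grads[layer] = (acts[layer].T @ local, local.sum(axis=0))
        if layer > 0:
            back = local @ weights[layer][0].T
    loss = float(np.mean((out - y) ** 2))
    return grads, loss


@dataclass
class AnnNetwork:
    """One trained MLP autoregression: layer weights, the min-max scaling of
    the series, and training metadata."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    architecture: AnnArchitecture
    y_min: float
    y_scale: float
    converged: bool
    n_iter: int
    val_mse: float
    train_mse: float
    seed_key: int

    def _scale(self, x):
        return (np.asarray(x, float) - self.y_min) / self.y_scale

    def _unscale(self, z):
        return np.asarray(z, float) * self.y_scale + self.y_min

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step predictions for lagged input rows on the original scale."""
        return self._unscale(_forward(self.weights, self._scale(X)))

    def forecast(self, history: np.ndarray, h: int) -> np.ndarray:
        """Recursive multi-step forecast feeding predictions back as lags."""
        lags = self.architecture.lags
        window = list(self._scale(history[-lags:]))
        out = []
        for _ in range(h):
            x = np.asarray(window[::-1], float)[None, :]
            z = float(_forward(self.weights, x)[0])
            out.append(z)
            window = window[1:] + [z]
        return self._unscale(np.asarray(out))


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def _init_weights(arch: AnnArchitecture, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    # hidden layers: uniform with half-width 5/sqrt(fan_in) so the logistic
    # breakpoints spread across the [0,1]-scaled input range instead of
    # collapsing onto the unit's quasi-linear segment; linear output: ±0.5
    sizes = [arch.lags, *arch.hidden_layers, 1]
    weights = []
    for i in range(len(sizes) - 1):
        a = 5.0 / np.sqrt(sizes[i]) if i < len(sizes) - 2 else 0.5
        weights.append(
            (rng.uniform(-a, a, size=(sizes[i], sizes[i + 1])),
             rng.uniform(-a, a, size=sizes[i + 1]))
        )
    return weights


def train_network(
    inputs: np.ndarray,
    targets: np.ndarray,
    architecture: AnnArchitecture,
    seed=None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    val_fraction: float = VALIDATION_FRACTION,
    inner_steps: int = 3,
) -> AnnNetwork:
    """Train one network on a lagged design matrix.

    The validation hold-out (floor of ``val_fraction`` of the rows) is drawn
    from ``seed``; convergence is declared the first time the per-iteration
    improvement of its MSE drops below ``tol``; ``max_iter`` stops training
    regardless and marks the network non-converged.  The returned weights
    are those of the best validation MSE seen.  Deterministic per
    ``(inputs, targets, architecture, seed)``.
    """
    X = np.asarray(inputs, float)
    y = np.asarray(targets, float)
    if X.shape[0] != y.size:
        raise ValueError("inputs and targets disagree in length")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 design rows")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    split_ss, init_ss = ss.spawn(2)
    seed_key = int(ss.entropy if np.ndim(ss.entropy) == 0 else ss.entropy[0])

    train_idx, val_idx = split_validation(X.shape[0], val_fraction, split_ss)
    lo = float(min(X[train_idx].min(), y[train_idx].min()))
    hi = float(max(X[train_idx].max(), y[train_idx].max()))
    scale = hi - lo if hi - lo > 0 else 1.0
    Xs, ys = (X - lo) / scale, (y - lo) / scale
    Xtr, ytr = Xs[train_idx], ys[train_idx]
    Xva, yva = Xs[val_idx], ys[val_idx]

    rng = np.random.default_rng(init_ss)
    weights = _init_weights(architecture, rng)
    shapes = [(W.shape, b.shape) for W, b in weights]

    def pack(ws):
        return np.concatenate([np.concatenate([W.ravel(), b.ravel()]) for W, b in ws])

    def unpack(vec):
        out, pos = [], 0
        for w_shape, b_shape in shapes:
            nw = int(np.prod(w_shape))
            nb = int(np.prod(b_shape))
            out.append(
                (vec[pos : pos + nw].reshape(w_shape), vec[pos + nw : pos + nw + nb])
            )
            pos += nw + nb
        return out

    def objective(vec):
        ws = unpack(vec)
        grads, loss = _gradients(ws, Xtr, ytr)
        if not np.isfinite(loss):
            raise TrainingDiverged(f"non-finite loss (seed {seed_key})")
        return loss, pack(grads)

    from scipy.optimize import minimize

    w = pack(weights)
    prev_val = float(np.mean((_forward(weights, Xva) - yva) ** 2))
    best_val = prev_val
    best_w = w.copy()
    converged = False
    n_iter = 0
    train_loss = float(np.mean((_forward(weights, Xtr) - ytr) ** 2))

    for n_iter in range(1, max_iter + 1):
        res = minimize(
            objective, w, jac=True, method="L-BFGS-B",
            options={"maxiter": inner_steps, "gtol": 0.0, "ftol": 0.0},
        )
        w = res.x
        train_loss = float(res.fun)
        if not np.isfinite(train_loss):
            raise TrainingDiverged(f"non-finite loss at iteration {n_iter} (seed {seed_key})")
        val = float(np.mean((_forward(unpack(w), Xva) - yva) ** 2))
        if val < best_val:
            best_val = val
            best_w = w.copy()
        if prev_val - val < tol:
            converged = True
            break
        prev_val = val
    best_weights = unpack(best_w)

    return AnnNetwork(
        weights=best_weights,
        architecture=architecture,
        y_min=lo,
        y_scale=scale,
        converged=converged,
        n_iter=n_iter,
        val_mse=best_val,
        train_mse=train_loss,
        seed_key=seed_key,
    )


@dataclass
class AnnEnsemble:
    """A set of converged networks sharing one architecture.

    The ensemble forecast at every horizon is the arithmetic mean of the
    member forecasts.  ``training_values`` keeps the series the ensemble was
    fitted on so results-style forecasting needs no extra input.
    """

    members: list[AnnNetwork]
    architecture: AnnArchitecture
    training_values: np.ndarray
    n_excluded: int = 0
    seed: int | None = None

    @property
    def member_val_mses(self) -> np.ndarray:
        return np.asarray([m.val_mse for m in self.members])

    def fitted_values(self, values: np.ndarray | None = None) -> np.ndarray:
        """In-sample one-step predictions (member mean) for rows lags..n-1."""
        v = self.training_values if values is None else np.asarray(values, float)
        X, _ = build_design_matrix(v, self.architecture.lags)
        return np.mean([m.predict(X) for m in self.members], axis=0)

    def forecast(self, h: int, values: np.ndarray | None = None) -> np.ndarray:
        """Recursive ``h``-step ensemble forecast (member mean per horizon)."""
        if h < 1:
            raise ValueError("h must be >= 1")
        v = self.training_values if values is None else _series_values(values)
        if v.size < self.architecture.lags:
            raise ValueError("history shorter than the lag order")
        paths = np.stack([m.forecast(v, h) for m in self.members])
        return paths.mean(axis=0)

    def member_forecasts(self, h: int, values: np.ndarray | None = None) -> np.ndarray:
        v = self.training_values if values is None else _series_values(values)
        return np.stack([m.forecast(v, h) for m in self.members])

    def summary(self) -> str:
        a = self.architecture
        return "\n".join(
            [
                "MLP autoregression ensemble",
                f"  architecture: layers {a.hidden_layers}, lags {a.lags}, reps {a.reps}",
                f"  converged members: {len(self.members)} (excluded: {self.n_excluded})",
                f"  validation MSE (scaled): mean {self.member_val_mses.mean():.5f}, "
                f"min {self.member_val_mses.min():.5f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "hidden_layers": list(self.architecture.hidden_layers),
            "lags": self.architecture.lags,
            "reps": self.architecture.reps,
            "n_members": len(self.members),
            "n_excluded": self.n_excluded,
            "seed": self.seed,
            "member_val_mse": [float(v) for v in self.member_val_mses],
            "member_iterations": [m.n_iter for m in self.members],
            "member_converged": [m.converged for m in self.members],
        }


def fit_ensemble(
    series,
    architecture: AnnArchitecture,
    seed=None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    retry_cap: int = 3,
) -> AnnEnsemble:
    """Train ``architecture.reps`` networks with distinct derived seeds.

    Every member gets a fresh initialisation and a fresh validation split.
    A member that hits the iteration cap without converging (or diverges) is
    retrained with a new seed up to ``retry_cap`` times, then excluded with
    a warning.  Fewer than reps/2 converged members is an error.
    """
    values = _series_values(series)
    X, y = build_design_matrix(values, architecture.lags)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(architecture.reps * (retry_cap + 1))
    members: list[AnnNetwork] = []
    excluded = 0
    for rep in range(architecture.reps):
        net = None
        for attempt in range(retry_cap + 1):
            child = children[rep * (retry_cap + 1) + attempt]
            try:
                candidate = train_network(
                    X, y, architecture, seed=child, tol=tol, max_iter=max_iter
                )
            except TrainingDiverged as exc:
                logger.warning("member %d attempt %d diverged: %s", rep, attempt, exc)
                continue
            if candidate.converged:
                net = candidate
                break
            net = net or candidate  # keep the first non-converged as fallback record
        if net is not None and net.converged:
            members.append(net)
        else:
            excluded += 1
            warnings.warn(
                f"ensemble member {rep} failed to converge after "
                f"{retry_cap + 1} attempts; excluded",
                stacklevel=2,
            )
    if len(members) < architecture.reps / 2:
        raise RuntimeError(
            f"only {len(members)} of {architecture.reps} members converged"
        )
    seed_int = None
    if np.ndim(ss.entropy) == 0:
        seed_int = int(ss.entropy)
    return AnnEnsemble(
        members=members,
        architecture=architecture,
        training_values=values.copy(),
        n_excluded=excluded,
        seed=seed_int,
    )


def forecast_ensemble(ensemble: AnnEnsemble, series, h: int) -> np.ndarray:
    """Recursive ``h``-step forecast of an ensemble from the end of
    ``series`` (member mean at each horizon)."""
    return ensemble.forecast(h, values=_series_values(series))


def _score_architecture(X, y, arch, rep_seeds, tol, max_iter) -> float:
    # common random numbers: every architecture is scored with the same
    # seeds (hence the same validation splits), so score differences
    # reflect the architecture rather than split luck
    vals = []
    for child in rep_seeds:
        try:
            net = train_network(X, y, arch, seed=child, tol=tol, max_iter=max_iter)
        except TrainingDiverged:
            continue
        vals.append(net.val_mse)
    return float(np.mean(vals)) if vals else np.inf


def greedy_search(
    series,
    candidate_lags=(12, 24),
    max_layers: int = 3,
    max_neurons: int = 20,
    reps: int = 5,
    seed=None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    return_trace: bool = False,
):
    """Greedy architecture/lag search by mean validation MSE.

    For each candidate lag order the hidden layout starts at a single
    one-neuron layer; neurons are added to the newest layer while that
    improves the score, then a new layer is opened, until no step improves.
    The best (lags, layout) pair across candidates is returned; with
    ``return_trace`` the full list of evaluated steps comes along.
    """
    if not candidate_lags:
        raise ValueError("candidate_lags must be nonempty")
    values = _series_values(series)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trace: list[dict] = []
    best_arch, best_score = None, np.inf
    rep_seeds = ss.spawn(reps)

    for lags in candidate_lags:
        X, y = build_design_matrix(values, lags)
        layers = [1]
        arch = AnnArchitecture(tuple(layers), lags, reps)
        score = _score_architecture(X, y, arch, rep_seeds, tol, max_iter)
        trace.append({"lags": lags, "layers": tuple(layers), "score": score, "accepted": True})
        improved = True
        while improved:
            improved = False
            if layers[-1] < max_neurons:
                cand = layers[:-1] + [layers[-1] + 1]
                s = _score_architecture(
                    X, y, AnnArchitecture(tuple(cand), lags, reps), rep_seeds, tol, max_iter
                )
                accept = s < score
                trace.append({"lags": lags, "layers": tuple(cand), "score": s, "accepted": accept})
                if accept:
                    layers, score, improved = cand, s, True
                    continue
            if len(layers) < max_layers:
                cand = layers + [1]
                s = _score_architecture(
                    X, y, AnnArchitecture(tuple(cand), lags, reps), rep_seeds, tol, max_iter
                )
                accept = s < score
                trace.append({"lags": lags, "layers": tuple(cand), "score": s, "accepted": accept})
                if accept:
                    layers, score, improved = cand, s, True
        if score < best_score:
            best_score = score
            best_arch = AnnArchitecture(tuple(layers), lags, reps)
    logger.info("greedy search: best %s (score %.6f)", best_arch, best_score)
    if return_trace:
        return best_arch, trace
    return best_arch


class MLPAutoregression:
    """Model-style front end: configure on a series, ``fit`` returns the
    trained :class:`AnnEnsemble`.

    With ``architecture=None`` the architecture and lag order are chosen by
    :func:`greedy_search` before the final ensemble is trained.
    """

    def __init__(
        self,
        endog,
        architecture: AnnArchitecture | None = None,
        candidate_lags=(12, 24),
        reps: int = 100,
    ):
        self.endog = _series_values(endog)
        self.architecture = architecture
        self.candidate_lags = tuple(candidate_lags)
        self.reps = reps

    def fit(self, seed=None, tol: float = 1e-4, max_iter: int = 1000) -> AnnEnsemble:
        arch = self.architecture
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        search_ss, fit_ss = ss.spawn(2)
        if arch is None:
            found = greedy_search(
                self.endog, self.candidate_lags, seed=search_ss, tol=tol, max_iter=max_iter
            )
            arch = AnnArchitecture(found.hidden_layers, found.lags, self.reps)
        return fit_ensemble(self.endog, arch, seed=fit_ss, tol=tol, max_iter=max_iter)
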