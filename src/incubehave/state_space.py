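"""4-D behavioral states and the three-class likelihood classifier.

A behavioral state at a video frame is the 4-vector (position along the
stressor axis, speed, signed velocity along the axis, acceleration
magnitude).  A feedforward network with three hidden layers of 26, 30, and
24 log-sigmoid units maps states to a probability triple over reference
conditions (emulating caffeine-injected / foot-shocked / non-treated
recordings).  The network is trained full-batch with Moller's scaled
conjugate gradient on cross-entropy, with an 80/20 train/test split and
five termination conditions; the *local* likelihood of a single state is
the network output, and the *global* likelihood of a whole recording is the
arithmetic mean of its local likelihoods, classified by argmax.

Features are z-scored with training-split statistics before entering the
network, which makes results invariant to affine rescaling of the raw
units (mm, mm/s, mm/s^2 are not commensurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = [
    "BehavioralState",
    "StateClassifier",
    "build_state_vectors",
    "train_state_classifier",
    "local_likelihoods",
    "global_likelihood",
]

HIDDEN_SIZES = (26, 30, 24)

STATE_COLUMNS = ("axis_position", "speed", "axis_velocity", "acceleration_strength")


@dataclass(frozen=True)
class BehavioralState:
    axis_position: float  # mm along the stressor axis
    speed: float  # mm/s
    axis_velocity: float  # signed mm/s along the axis
    acceleration_strength: float  # mm/s^2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.axis_position, self.speed, self.axis_velocity, self.acceleration_strength]
        )


def build_state_vectors(trajectory: Trajectory) -> np.ndarray:
    """State vectors for the interior frames of a trajectory, (n-2, 4).

    With forward-difference velocities v_i = (p_{i+1} - p_i) * frame_rate,
    the state at interior frame i is (axis position at i, |v_i|,
    v_i . axis, |v_i - v_{i-1}| * frame_rate).
    """
    if trajectory.n_frames < 3:
        raise ValueError("need at least three frames for state vectors")
    fr = trajectory.frame_rate
    pos = trajectory.positions
    axis = np.asarray(trajectory.arena.axis_direction, dtype=float)
    vel = np.diff(pos, axis=0) * fr  # v_i for i = 0..n-2
    interior = slice(1, len(pos) - 1)
    axis_pos = trajectory.axis_positions()[interior]
    v = vel[1:]  # velocity at interior frames
    speed = np.hypot(v[:, 0], v[:, 1])
    axis_vel = v @ axis
    accel = np.linalg.norm(np.diff(vel, axis=0), axis=1) * fr
    return np.column_stack([axis_pos, speed, axis_vel, accel])


# ---------------------------------------------------------------------------
# network


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(sizes: tuple[int, ...], rng: np.random.Generator) -> list[np.ndarray]:
    params = []
    for n_in, n_out in zip(sizes, sizes[1:]):
        scale = 1.0 / np.sqrt(n_in)
        params.append(rng.uniform(-scale, scale, size=(n_in, n_out)))
        params.append(np.zeros(n_out))
    return params


def _flatten(params: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([p.ravel() for p in params])


def _unflatten(vec: np.ndarray, template: list[np.ndarray]) -> list[np.ndarray]:
    out, i = [], 0
    for p in template:
        out.append(vec[i : i + p.size].reshape(p.shape))
        i += p.size
    return out


def _forward(params: list[np.ndarray], x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Probabilities and per-layer activations (inputs first)."""
    acts = [x]
    h = x
    n_layers = len(params) // 2
    for layer in range(n_layers):
        w, b = params[2 * layer], params[2 * layer + 1]
        z = h @ w + b
        h = _softmax(z) if layer == n_layers - 1 else _logsig(z)
        acts.append(h)
    return h, acts


def _loss_grad(
    params: list[np.ndarray], x: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its flattened gradient (softmax output)."""
    probs, acts = _forward(params, x)
    n = len(x)
    eps = 1e-300
    loss = -float(np.sum(y_onehot * np.log(probs + eps)) / n)
    grads: list[np.ndarray] = [np.empty(0)] * len(params)
    delta = (probs - y_onehot) / n  # dCE/dz at the softmax layer
    n_layers = len(params) // 2
    for layer in range(n_layers - 1, -1, -1):
        h_in = acts[layer]
        grads[2 * layer] = h_in.T @ delta
        grads[2 * layer + 1] = delta.sum(axis=0)
        if layer > 0:
            w = params[2 * layer]
            h = acts[layer]  # logsig activation of the layer below
            delta = (delta @ w.T) * h * (1.0 - h)
    return loss, _flatten(grads)


@dataclass
class StateClassifier:
    """Trained (or initialized) state-likelihood network.

    ``params`` alternates weight matrices and bias vectors for the layer
    chain 4 -> 26 -> 30 -> 24 -> 3.  ``feature_mean``/``feature_std`` hold
    the training-split z-scoring statistics.
    """

    classes_: tuple[str, ...]
    params: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    training_log: dict = field(default_factory=dict)
    split_seed: int = 0
    trained: bool = False

    def predict_proba(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        z = (states - self.feature_mean) / self.feature_std
        probs, _ = _forward(self.params, z)
        return probs

    def predict(self, states: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(states)
        idx = np.argmax(probs, axis=1)
        return np.asarray(self.classes_)[idx]

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes_),
            "layer_sizes": [4, *HIDDEN_SIZES, len(self.classes_)],
            "params": [p.tolist() for p in self.params],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "training_log": self.training_log,
            "split_seed": self.split_seed,
            "trained": self.trained,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "StateClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes_=tuple(payload["classes"]),
            params=[np.asarray(p) for p in payload["params"]],
            feature_mean=np.asarray(payload["feature_mean"]),
            feature_std=np.asarray(payload["feature_std"]),
            training_log=payload["training_log"],
            split_seed=payload["split_seed"],
            trained=payload["trained"],
        )


def _scg_train(
    params: list[np.ndarray],
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    max_iter: int,
    min_grad: float = 1e-7,
    max_gain: float = 1e10,
    patience: int = 6,
) -> tuple[list[np.ndarray], dict]:
    """Full-batch scaled conjugate gradient (Moller 1993) on cross-entropy.

    Stops at the first satisfied condition of: iteration limit; zero MSE of
    the output probabilities against the one-hot targets; held-out error
    rate strictly increasing for more than ``patience`` consecutive epochs;
    objective gradient norm below ``min_grad``; SCG scale parameter (the
    'training gain') exceeding ``max_gain``.
    """
    w = _flatten(params)
    template = params

    def evaluate(vec: np.ndarray) -> tuple[float, np.ndarray]:
        return _loss_grad(_unflatten(vec, template), x_train, y_train)

    def test_error_rate(vec: np.ndarray) -> float:
        probs, _ = _forward(_unflatten(vec, template), x_test)
        pred = probs.argmax(axis=1)
        truth = y_test.argmax(axis=1)
        return float(np.mean(pred != truth))

    def train_mse(vec: np.ndarray) -> float:
        probs, _ = _forward(_unflatten(vec, template), x_train)
        return float(np.mean((probs - y_train) ** 2))

    sigma0 = 5e-5
    lam, lam_bar = 5e-7, 0.0
    loss, grad = evaluate(w)
    r = -grad
    p = r.copy()
    success = True
    n_params = w.size
    reason = "iteration limit"
    k = 0
    prev_test_err = np.inf
    n_increasing = 0
    delta = 1.0
    while k < max_iter:
        if train_mse(w) == 0.0:
            reason = "zero error"
            break
        if np.linalg.norm(grad) < min_grad:
            reason = "minimum gradient"
            break
        if lam > max_gain:
            reason = "maximum gain"
            break
        p_norm2 = float(p @ p)
        if p_norm2 == 0.0:
            reason = "minimum gradient"
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, grad_sigma = evaluate(w + sigma * p)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new, grad_new = evaluate(w + alpha * p)
        comparison = 2.0 * delta * (loss - loss_new) / (mu * mu)
        if comparison >= 0:
            w = w + alpha * p
            loss = loss_new
            r_new = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if (k + 1) % n_params == 0:
                p = r_new.copy()  # restart in the steepest-descent direction
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            r = r_new
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        k += 1
        test_err = test_error_rate(w)
        if test_err > prev_test_err:
            n_increasing += 1
            if n_increasing > patience:
                reason = "validation error increasing"
                break
        else:
            n_increasing = 0
        prev_test_err = test_err
    log = {
        "termination": reason,
        "iterations": k,
        "final_cross_entropy": loss,
        "final_gradient_norm": float(np.linalg.norm(grad)),
        "test_error_rate": test_error_rate(w),
    }
    return _unflatten(w, template), log


def train_state_classifier(
    states: np.ndarray,
    labels: np.ndarray,
    split_seed: int = 0,
    init_seed: int = 1,
    max_iter: int = 1000,
    min_per_class: int = 50,
    test_fraction: float = 0.2,
) -> StateClassifier:
    """Train the three-class likelihood network on labeled state samples.

    Data are split 80/20 into training and testing at random (by
    ``split_seed``); features are z-scored with training statistics; the
    network trains by scaled conjugate gradient until the first of the five
    termination conditions fires.  The held-out accuracy is recorded in
    ``training_log['test_accuracy']``.
    """
    states = np.asarray(states, dtype=float)
    labels = np.asarray(labels)
    if states.ndim != 2 or states.shape[1] != 4:
        raise ValueError("states must have shape (n, 4)")
    if not np.isfinite(states).all():
        raise ValueError("states contain non-finite features")
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 3:
        raise ValueError("need at least three classes represented")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    short = {c: n for c, n in counts.items() if n < min_per_class}
    if short:
        raise ValueError(f"classes below the {min_per_class}-sample minimum: {short}")
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    y[np.arange(len(labels)), [class_idx[c] for c in labels]] = 1.0

    rng_split = np.random.default_rng(split_seed)
    order = rng_split.permutation(len(states))
    n_test = max(int(round(test_fraction * len(states))), 1)
    test_idx, train_idx = order[:n_test], order[n_test:]
    x_train, y_train = states[train_idx], y[train_idx]
    x_test, y_test = states[test_idx], y[test_idx]

    mean = x_train.mean(axis=0)
    std = x_train.std(axis=0)
    std[std == 0] = 1.0
    zt = (x_train - mean) / std
    zs = (x_test - mean) / std

    sizes = (4, *HIDDEN_SIZES, len(classes))
    params = _init_params(sizes, np.random.default_rng(init_seed))
    if max_iter > 0:
        params, log = _scg_train(params, zt, y_train, zs, y_test, max_iter)
    else:
        log = {
            "termination": "iteration limit",
            "iterations": 0,
            "final_cross_entropy": float("nan"),
            "final_gradient_norm": float("nan"),
            "test_error_rate": float("nan"),
        }
    clf = StateClassifier(
        classes_=classes,
        params=params,
        feature_mean=mean,
        feature_std=std,
        training_log=log,
        split_seed=split_seed,
        trained=True,
    )
    probs = clf.predict_proba(x_test)
    acc = float(np.mean(probs.argmax(axis=1) == y_test.argmax(axis=1)))
    clf.training_log["test_accuracy"] = acc
    return clf


def local_likelihoods(classifier: StateClassifier, states: np.ndarray) -> np.ndarray:
    """Per-state class-probability triples from a trained classifier."""
    if not classifier.trained:
        raise ValueError("classifier is not trained")
    return classifier.predict_proba(states)


def global_likelihood(local: np.ndarray) -> tuple[np.ndarray, int]:
    """Recording-level likelihood: mean of local triples, argmax label.

    Ties break to the lowest class index (fixed class order).  Returns
    ``(mean_probabilities, class_index)``.
    """
    local = np.atleast_2d(np.asarray(local, dtype=float))
    if local.size == 0:
        raise ValueError("no local likelihoods given")
    mean = local.mean(axis=0)
    return mean, int(np.argmax(mean))
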