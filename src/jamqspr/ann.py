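"""Feed-forward network property predictor trained by Levenberg--Marquardt.

The predictor is a small multilayer perceptron — one or two tanh hidden
layers and a linear three-unit output (hardness, water activity,
adhesiveness) — trained by damped Gauss--Newton least squares with the
Jacobian assembled by backpropagation.  The surrounding protocol mirrors
the learn/test/predict workflow: a seeded random split of the dataset,
multi-restart training with the winner chosen by the lowest maximum
absolute percent deviation on the testing subset, and an architecture
search ranked on the prediction subset.

Percent deviations use the predicted value in the denominator:

    %dev = 100/N * sum |pred - exp| / |pred|

which is the convention of the published deviation tables; pass
``denominator="experimental"`` for the conventional alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkArchitecture",
    "NetworkWeights",
    "TrainingConfig",
    "SplitSpec",
    "DeviationReport",
    "init_network",
    "forward",
    "train_lm",
    "multi_restart_train",
    "random_split",
    "deviation_report",
    "architecture_search",
    "save_checkpoint",
    "load_checkpoint",
]

N_OUTPUTS = 3


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer sizes (input, one or two hidden, output)."""

    layers: tuple[int, ...]

    def __post_init__(self):
        if len(self.layers) not in (3, 4):
            raise ValueError("architecture must have one or two hidden layers")
        if any(n < 1 for n in self.layers):
            raise ValueError("layer sizes must be positive")
        if self.layers[-1] != N_OUTPUTS:
            raise ValueError(f"output layer must have {N_OUTPUTS} units")

    @property
    def n_parameters(self) -> int:
        return sum(
            o * i + o for i, o in zip(self.layers[:-1], self.layers[1:])
        )

    def __str__(self) -> str:
        return "-".join(map(str, self.layers))


@dataclass
class NetworkWeights:
    """Layer weight matrices (out x in) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def architecture(self) -> NetworkArchitecture:
        return NetworkArchitecture(
            layers=(self.weights[0].shape[1], *(w.shape[0] for w in self.weights))
        )

    # Named accessors matching the two-hidden-layer report convention
    @property
    def w_input(self) -> np.ndarray:
        """First-hidden x input matrix (w^I)."""
        return self.weights[0]

    @property
    def w_hidden(self) -> np.ndarray:
        """Second-hidden x first-hidden matrix (w^H1-H2); two-hidden only."""
        if len(self.weights) != 3:
            raise AttributeError("network has a single hidden layer")
        return self.weights[1]

    @property
    def w_output(self) -> np.ndarray:
        """Output x last-hidden matrix (w^H2)."""
        return self.weights[-1]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Levenberg--Marquardt training protocol settings.

    Defaults follow the reference protocol: stop when the total squared
    error improves by less than 1e-4 between accepted iterations, cap at
    500 iterations, 50 independent restarts.
    """

    tolerance: float = 1e-4
    max_iterations: int = 500
    restarts: int = 50
    seed: int = 0
    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 10.0
    damping_max: float = 1e10

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


@dataclass(frozen=True)
class SplitSpec:
    """Counts of the learning / testing / prediction subsets."""

    n_learning: int
    n_testing: int
    n_prediction: int
    seed: int = 0

    @property
    def total(self) -> int:
        return self.n_learning + self.n_testing + self.n_prediction


@dataclass(frozen=True)
class DeviationReport:
    """Per-variable average and maximum absolute percent deviations."""

    average: np.ndarray
    maximum: np.ndarray
    n_points: int

    @property
    def overall_max(self) -> float:
        return float(self.maximum.max())

    @property
    def overall_average(self) -> float:
        return float(self.average.mean())


# ---------------------------------------------------------------------------
# Core network
# ---------------------------------------------------------------------------

def init_network(arch: NetworkArchitecture, seed: int) -> NetworkWeights:
    """Seeded initial weights, uniform on [-0.5, 0.5]; biases zero."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(arch.layers[:-1], arch.layers[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetworkWeights(weights=weights, biases=biases)


def _forward_full(w: NetworkWeights, X: np.ndarray):
    """Forward pass keeping per-layer activations (for backprop)."""
    acts = [X]
    a = X
    for W, b in zip(w.weights[:-1], w.biases[:-1]):
        a = np.tanh(a @ W.T + b)
        acts.append(a)
    y = a @ w.weights[-1].T + w.biases[-1]
    return y, acts


def forward(w: NetworkWeights, x: np.ndarray) -> np.ndarray:
    """Network output: tanh hidden layers, identity output layer."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != w.weights[0].shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects "
            f"{w.weights[0].shape[1]}"
        )
    y, _ = _forward_full(w, X)
    return y[0] if single else y


def _pack(w: NetworkWeights) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in zip(w.weights, w.biases)]
    )


def _unpack(theta: np.ndarray, arch: NetworkArchitecture) -> NetworkWeights:
    weights, biases = [], []
    pos = 0
    for n_in, n_out in zip(arch.layers[:-1], arch.layers[1:]):
        weights.append(theta[pos : pos + n_out * n_in].reshape(n_out, n_in))
        pos += n_out * n_in
        biases.append(theta[pos : pos + n_out].copy())
        pos += n_out
    return NetworkWeights(weights=weights, biases=biases)


def _jacobian(w: NetworkWeights, X: np.ndarray):
    """Jacobian of the flattened predictions wrt the packed parameters.

    Rows are ordered (output k, sample n); columns follow the packing
    order (W1, b1, W2, b2, ...), each matrix row-major.
    """
    y, acts = _forward_full(w, X)
    n, k_out = X.shape[0], y.shape[1]
    p = _pack(w).size
    J = np.zeros((k_out, n, p))

    # parameter offsets per layer
    offsets = []
    pos = 0
    for W, b in zip(w.weights, w.biases):
        offsets.append((pos, pos + W.size))
        pos += W.size + b.size

    n_layers = len(w.weights)
    for k in range(k_out):
        # output layer: dY_k/dW_out[m, j] = delta_km * H_last[n, j]
        w_lo, w_hi = offsets[-1]
        out_dim = w.weights[-1].shape[0]
        block = J[k][:, w_lo:w_hi].reshape(n, out_dim, -1)
        block[:, k, :] = acts[-1]
        bias_block = J[k][:, w_hi : w_hi + out_dim]
        bias_block[:, k] = 1.0

        # walk back through tanh hidden layers
        g = w.weights[-1][k][None, :] * (1.0 - acts[-1] ** 2)  # N x n_last
        for layer in range(n_layers - 2, -1, -1):
            w_lo, w_hi = offsets[layer]
            h_dim = w.weights[layer].shape[0]
            np.einsum(
                "nj,ni->nji",
                g,
                acts[layer],
                out=J[k][:, w_lo:w_hi].reshape(n, h_dim, -1),
            )
            J[k][:, w_hi : w_hi + h_dim] = g
            if layer > 0:
                g = (g @ w.weights[layer]) * (1.0 - acts[layer] ** 2)

    return y, J.reshape(k_out * n, p)


def train_lm(
    w0: NetworkWeights,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[NetworkWeights, list[float], str]:
    """Levenberg--Marquardt minimisation of the total squared error.

    Damping is multiplied by ``damping_up`` on rejected steps and divided
    by ``damping_down`` on accepted ones.  Returns the trained weights,
    the loss history over accepted iterations (non-increasing) and a
    status string: ``converged``, ``max_iterations`` or
    ``max_damping_warning`` (normal-equation step unusable at the damping
    cap).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must be finite")
    arch = w0.architecture
    theta = _pack(w0)
    w = w0.copy()

    def loss_of(pred):
        return float(((pred - Y) ** 2).sum())

    y, J = _jacobian(w, X)
    loss = loss_of(y)
    history = [loss]
    lam = cfg.damping_init
    status = "max_iterations"

    for _ in range(cfg.max_iterations):
        r = (y - Y).T.ravel()  # (output k, sample n) row order, matches J
        g = J.T @ r
        JtJ = J.T @ J
        accepted = False
        while lam <= cfg.damping_max:
            A = JtJ + lam * np.eye(JtJ.shape[0])
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= cfg.damping_up
                continue
            theta_new = theta + step
            w_new = _unpack(theta_new, arch)
            pred_new, _ = _forward_full(w_new, X)
            loss_new = loss_of(pred_new)
            if np.isfinite(loss_new) and loss_new < loss:
                accepted = True
                break
            lam *= cfg.damping_up
        if not accepted:
            status = "max_damping_warning"
            break
        improvement = loss - loss_new
        theta, w, loss = theta_new, w_new, loss_new
        lam = max(lam / cfg.damping_down, 1e-15)
        history.append(loss)
        if improvement < cfg.tolerance:
            status = "converged"
            break
        y, J = _jacobian(w, X)
    return w, history, status


# ---------------------------------------------------------------------------
# Protocol: deviations, restarts, splits, architecture search
# ---------------------------------------------------------------------------

def deviation_report(
    pred: np.ndarray, exp: np.ndarray, denominator: str = "predicted"
) -> DeviationReport:
    """Average and maximum absolute percent deviation per output variable.

    The denominator is the predicted value (the published convention);
    ``denominator="experimental"`` switches to the conventional form.
    """
    pred = np.atleast_2d(np.asarray(pred, float))
    exp = np.atleast_2d(np.asarray(exp, float))
    if pred.shape != exp.shape:
        raise ValueError("prediction/observation shape mismatch")
    denom = pred if denominator == "predicted" else exp
    if np.any(denom == 0):
        raise ZeroDivisionError(f"{denominator} value of zero in deviation metric")
    dev = 100.0 * np.abs(pred - exp) / np.abs(denom)
    return DeviationReport(
        average=dev.mean(axis=0), maximum=dev.max(axis=0), n_points=pred.shape[0]
    )


def _report_in_units(w, X, Y, target_scaler):
    pred = forward(w, X)
    if target_scaler is not None:
        pred = target_scaler.inverse_transform(pred)
        Y = target_scaler.inverse_transform(Y)
    return deviation_report(pred, Y)


def multi_restart_train(
    arch: NetworkArchitecture,
    X_learn: np.ndarray,
    Y_learn: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    cfg: TrainingConfig,
    target_scaler=None,
) -> tuple[NetworkWeights, int, list[DeviationReport]]:
    """Train from ``cfg.restarts`` seeded initialisations.

    The winner is the run with the lowest maximum absolute percent
    deviation on the testing subset (deviations in original units when a
    target scaler is given).  Returns (best weights, winner index,
    per-run testing reports).
    """
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, cfg.restarts)
    best, best_idx, reports = None, -1, []
    for i, s in enumerate(seeds):
        w0 = init_network(arch, int(s))
        w, _, _ = train_lm(w0, X_learn, Y_learn, cfg)
        rep = _report_in_units(w, X_test, Y_test, target_scaler)
        reports.append(rep)
        if best is None or rep.overall_max < reports[best_idx].overall_max:
            best, best_idx = w, i
    return best, best_idx, reports


def random_split(n_records: int, spec: SplitSpec):
    """Seeded permutation partition into learning/testing/prediction indices."""
    if spec.total != n_records:
        raise ValueError(
            f"split counts sum to {spec.total}, dataset has {n_records} records"
        )
    perm = np.random.default_rng(spec.seed).permutation(n_records)
    i1 = spec.n_learning
    i2 = i1 + spec.n_testing
    return perm[:i1], perm[i1:i2], perm[i2:]


def architecture_search(
    candidates,
    X_learn, Y_learn, X_test, Y_test, X_pred, Y_pred,
    cfg: TrainingConfig,
    target_scaler=None,
) -> list[dict]:
    """Evaluate candidate architectures; rank on the prediction subset.

    Ranking: lowest maximum absolute deviation, ties broken by the average
    deviation across the three variables, then by fewer parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate architecture")
    results = []
    for cand in candidates:
        arch = cand if isinstance(cand, NetworkArchitecture) else NetworkArchitecture(tuple(cand))
        w, run_idx, _ = multi_restart_train(
            arch, X_learn, Y_learn, X_test, Y_test, cfg, target_scaler
        )
        rep = _report_in_units(w, X_pred, Y_pred, target_scaler)
        results.append(
            {
                "architecture": arch,
                "weights": w,
                "winning_run": run_idx,
                "prediction_report": rep,
            }
        )
    results.sort(
        key=lambda r: (
            r["prediction_report"].overall_max,
            r["prediction_report"].overall_average,
            r["architecture"].n_parameters,
        )
    )
    for rank, r in enumerate(results, start=1):
        r["rank"] = rank
    return results


# ---------------------------------------------------------------------------
# Checkpoint text format
# ---------------------------------------------------------------------------

def save_checkpoint(w: NetworkWeights, path) -> None:
    """Flat text checkpoint: layer sizes header, then each weight matrix
    and bias vector row-major."""
    path = Path(path)
    lines = ["# jamqspr network checkpoint",
             "layers " + " ".join(map(str, w.architecture.layers))]
    for idx, (W, b) in enumerate(zip(w.weights, w.biases)):
        lines.append(f"W{idx} {W.shape[0]} {W.shape[1]}")
        lines.extend(" ".join(f"{v:.17g}" for v in row) for row in W)
        lines.append(f"b{idx} {b.size}")
        lines.append(" ".join(f"{v:.17g}" for v in b))
    path.write_text("\n".join(lines) + "\n")


def load_checkpoint(path) -> NetworkWeights:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines[0].startswith("layers "):
        raise ValueError("not a jamqspr checkpoint")
    layers = tuple(int(t) for t in lines[0].split()[1:])
    weights, biases = [], []
    pos = 1
    for _ in range(len(layers) - 1):
        n_out, n_in = (int(t) for t in lines[pos].split()[1:])
        rows = [
            np.array(lines[pos + 1 + r].split(), dtype=float) for r in range(n_out)
        ]
        weights.append(np.vstack(rows))
        pos += 1 + n_out
        n_b = int(lines[pos].split()[1])
        biases.append(np.array(lines[pos + 1].split(), dtype=float)[:n_b])
        pos += 2
    w = NetworkWeights(weights=weights, biases=biases)
    if w.architecture.layers != layers:
        raise ValueError("checkpoint shapes inconsistent with header")
    return w
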