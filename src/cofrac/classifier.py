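"""Fully-connected co-elution classifier.

Architecture: input (147 features for a 72-fraction experiment) -> dense 100
(ReLU) -> dropout 0.2 -> dense 72 (ReLU) -> 1 sigmoid unit.  Trained with
Adam (learning rate 0.001) on binary cross-entropy for up to 100 epochs with
early stopping (patience 20) on a held-out validation split.  For the
default sizes this is 147*100+100 + 100*72+72 + 72+1 = 22,145 trainable
parameters.

Implemented directly on numpy: forward/backward passes, inverted dropout
and Adam are a few dozen lines, and full control makes training bit-for-bit
reproducible under a seed, which the pipeline's determinism contract needs.
Inputs are z-scored with statistics frozen at fit time (stored with the
model, not counted as parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the co-elution network (defaults are fixed)."""

    layer_sizes: tuple[int, int, int] = (147, 100, 72)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    max_epochs: int = 100
    early_stopping_patience: int = 20
    batch_size: int = 64
    validation_fraction: float = 0.2
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class CoelutionClassifier:
    """Three-layer MLP with a sigmoid output for pair co-elution probability."""

    def __init__(self, spec: ClassifierSpec = ClassifierSpec()):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)
        d_in, h1, h2 = spec.layer_sizes
        self.weights = [
            self._he(d_in, h1),
            self._he(h1, h2),
            self._he(h2, 1),
        ]
        self.biases = [np.zeros(h1), np.zeros(h2), np.zeros(1)]
        self.feat_mean = np.zeros(d_in)
        self.feat_std = np.ones(d_in)
        self.report: dict = {}

    def _he(self, fan_in: int, fan_out: int) -> np.ndarray:
        return self._rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    # ---- forward / backward -------------------------------------------------
    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        z1 = X @ self.weights[0] + self.biases[0]
        a1 = np.maximum(z1, 0.0)
        if dropout_rng is not None and self.spec.dropout_rate > 0:
            keep = 1.0 - self.spec.dropout_rate
            mask = (dropout_rng.random(a1.shape) < keep) / keep
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        z2 = a1d @ self.weights[1] + self.biases[1]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ self.weights[2] + self.biases[2]
        p = _sigmoid(z3)[:, 0]
        return p, (X, z1, a1d, mask, z2, a2)

    def _backward(self, p: np.ndarray, y: np.ndarray, cache) -> tuple[list, list]:
        X, z1, a1d, mask, z2, a2 = cache
        B = len(y)
        dz3 = ((p - y) / B)[:, None]
        gw3 = a2.T @ dz3
        gb3 = dz3.sum(axis=0)
        da2 = dz3 @ self.weights[2].T
        dz2 = da2 * (z2 > 0)
        gw2 = a1d.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ self.weights[1].T
        if mask is not None:
            da1 = da1 * mask
        dz1 = da1 * (z1 > 0)
        gw1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return [gw1, gw2, gw3], [gb1, gb2, gb3]

    # ---- training -----------------------------------------------------------
    def fit(self, features: np.ndarray, labels: np.ndarray) -> dict:
        """Train with Adam + early stopping; returns the training report.

        Raises if only one class is present.  The best-validation-loss
        weights are restored at the end.
        """
        spec = self.spec
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=float).ravel()
        if X.shape[1] != spec.layer_sizes[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != input layer {spec.layer_sizes[0]}")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training requires at least one example of each class")

        self.feat_mean = X.mean(axis=0)
        self.feat_std = np.where(X.std(axis=0) < 1e-8, 1.0, X.std(axis=0))
        Xs = (X - self.feat_mean) / self.feat_std

        rng = np.random.default_rng(spec.seed + 1)
        order = rng.permutation(len(y))
        n_val = int(round(spec.validation_fraction * len(y)))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[train_idx])) < 2:  # tiny datasets: fall back to no split
            train_idx, val_idx = order, np.array([], dtype=int)
        Xt, yt = Xs[train_idx], y[train_idx]
        Xv, yv = Xs[val_idx], y[val_idx]

        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_state = None
        no_improve = 0
        stop_after = max(1, spec.early_stopping_patience)
        epochs_run = 0
        train_loss = val_loss = np.nan

        for epoch in range(spec.max_epochs):
            epochs_run = epoch + 1
            idx = rng.permutation(len(yt))
            for lo in range(0, len(yt), spec.batch_size):
                batch = idx[lo:lo + spec.batch_size]
                p, cache = self._forward(Xt[batch], dropout_rng=rng)
                gw, gb = self._backward(p, yt[batch], cache)
                grads = gw + gb
                t += 1
                for k, (prm, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mh = m[k] / (1 - beta1 ** t)
                    vh = v[k] / (1 - beta2 ** t)
                    prm -= spec.learning_rate * mh / (np.sqrt(vh) + eps)

            train_loss = _bce(self._forward(Xt)[0], yt)
            monitor = _bce(self._forward(Xv)[0], yv) if len(yv) else train_loss
            val_loss = monitor
            if monitor < best_val - 1e-9:
                best_val = monitor
                best_state = ([w.copy() for w in self.weights],
                              [b.copy() for b in self.biases])
                no_improve = 0
            else:
                no_improve += 1
                if no_improve >= stop_after:
                    break

        if best_state is not None:
            self.weights = best_state[0]
            self.biases = best_state[1]
        self.report = {
            "epochs_run": epochs_run,
            "final_train_loss": train_loss,
            "final_val_loss": val_loss,
            "best_val_loss": float(best_val),
            "n_train": int(len(yt)),
            "n_val": int(len(yv)),
        }
        return self.report

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        """Co-elution probability in (0, 1); dropout disabled at inference."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.spec.layer_sizes[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != input layer {self.spec.layer_sizes[0]}")
        Xs = (X - self.feat_mean) / self.feat_std
        return self._forward(Xs)[0]

    # ---- persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        """Checkpoint as a numpy .npz archive (weights, biases, scaler, spec)."""
        np.savez(
            path,
            w0=self.weights[0], w1=self.weights[1], w2=self.weights[2],
            b0=self.biases[0], b1=self.biases[1], b2=self.biases[2],
            feat_mean=self.feat_mean, feat_std=self.feat_std,
            layer_sizes=np.array(self.spec.layer_sizes),
            hyper=np.array([self.spec.dropout_rate, self.spec.learning_rate,
                            self.spec.max_epochs, self.spec.early_stopping_patience,
                            self.spec.batch_size, self.spec.validation_fraction,
                            self.spec.seed]),
        )

    @classmethod
    def load(cls, path: str) -> "CoelutionClassifier":
        data = np.load(path)
        hyper = data["hyper"]
        spec = ClassifierSpec(
            layer_sizes=tuple(int(x) for x in data["layer_sizes"]),
            dropout_rate=float(hyper[0]), learning_rate=float(hyper[1]),
            max_epochs=int(hyper[2]), early_stopping_patience=int(hyper[3]),
            batch_size=int(hyper[4]), validation_fraction=float(hyper[5]),
            seed=int(hyper[6]),
        )
        model = cls(spec)
        model.weights = [data["w0"], data["w1"], data["w2"]]
        model.biases = [data["b0"], data["b1"], data["b2"]]
        model.feat_mean = data["feat_mean"]
        model.feat_std = data["feat_std"]
        return model


def build_classifier(spec: ClassifierSpec = ClassifierSpec()) -> CoelutionClassifier:
    """Untrained model with deterministic (seeded He) initialization."""
    return CoelutionClassifier(spec)


def train_classifier(model: CoelutionClassifier, features: np.ndarray,
                     labels: np.ndarray) -> tuple[CoelutionClassifier, dict]:
    report = model.fit(features, labels)
    return model, report
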