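"""A small batched LSTM sequence classifier in numpy.

Architecture: input sequence -> single LSTM layer -> dropout on the final
hidden state -> fully connected layer -> softmax.  Training is full
backpropagation through time with Adam, inverted dropout, global-norm
gradient clipping and early stopping on a held-out validation split.
Everything is driven by an explicit ``numpy.random.Generator`` so runs are
reproducible.

Gate layout in the fused weight matrices is (input, forget, cell, output).
The forget-gate bias starts at 1 so early training does not erase memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMNet", "TrainHistory"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainHistory:
    """Per-epoch loss/accuracy trace of one training run."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    n_epochs: int = 0


class LSTMNet:
    """Sequence-to-label LSTM with a softmax head.

    Parameters
    ----------
    n_features : int
        Input features per time step (EEG channels).
    n_units : int
        LSTM memory units.
    n_classes : int
        Output classes.
    dropout : float
        Drop probability on the final hidden state during training.
    rng : numpy.random.Generator
        Source of all randomness (init, dropout, shuffling).
    """

    def __init__(
        self,
        n_features: int,
        n_units: int,
        n_classes: int,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> None:
        if not 0.0 <= dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {dropout}")
        if n_units < 1 or n_classes < 2:
            raise ValueError("need n_units >= 1 and n_classes >= 2")
        self.n_features = n_features
        self.n_units = n_units
        self.n_classes = n_classes
        self.dropout = dropout
        rng = rng or np.random.default_rng()

        h, d, k = n_units, n_features, n_classes
        sx = 1.0 / np.sqrt(d + h)
        self.W = rng.uniform(-sx, sx, size=(d, 4 * h))   # input -> gates
        self.U = rng.uniform(-sx, sx, size=(h, 4 * h))   # hidden -> gates
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        so = 1.0 / np.sqrt(h)
        self.Wo = rng.uniform(-so, so, size=(h, k))
        self.bo = np.zeros(k)

    # -- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool):
        """Run the recurrence over X (batch, T, features)."""
        B, T, _ = X.shape
        h_dim = self.n_units
        h = np.zeros((B, h_dim))
        c = np.zeros((B, h_dim))
        caches = [] if cache else None
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if cache:
                caches.append((x_t, i, f, g, o, c_prev, tc, h))
        return h, caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for X (batch, T, features); no dropout."""
        h, _ = self._forward(np.asarray(X, dtype=np.float64), cache=False)
        return _softmax(h @ self.Wo + self.bo)

    # -- backward ---------------------------------------------------------

    def _loss_and_grads(self, X, y_onehot, rng):
        B = X.shape[0]
        h_dim = self.n_units
        h_last, caches = self._forward(X, cache=True)

        if self.dropout > 0:
            mask = (rng.random(h_last.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h_last)
        h_drop = h_last * mask

        probs = _softmax(h_drop @ self.Wo + self.bo)
        eps = 1e-12
        loss = -np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1))

        dlogits = (probs - y_onehot) / B
        gWo = h_drop.T @ dlogits
        gbo = dlogits.sum(axis=0)
        dh = (dlogits @ self.Wo.T) * mask

        gW = np.zeros_like(self.W)
        gU = np.zeros_like(self.U)
        gb = np.zeros_like(self.b)
        dc = np.zeros((B, h_dim))
        dz = np.empty((B, 4 * h_dim))
        for t in range(X.shape[1] - 1, -1, -1):
            x_t, i, f, g, o, c_prev, tc, _ = caches[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz[:, :h_dim] = di * i * (1.0 - i)
            dz[:, h_dim : 2 * h_dim] = df * f * (1.0 - f)
            dz[:, 2 * h_dim : 3 * h_dim] = dg * (1.0 - g * g)
            dz[:, 3 * h_dim :] = do * o * (1.0 - o)
            gW += x_t.T @ dz
            gb += dz.sum(axis=0)
            if t > 0:
                h_prev = caches[t - 1][7]
                gU += h_prev.T @ dz
                dh = dz @ self.U.T
            dc = dc * f
        acc = float(np.mean(probs.argmax(axis=1) == y_onehot.argmax(axis=1)))
        return loss, acc, (gW, gU, gb, gWo, gbo)

    # -- training ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 30,
        patience: int = 5,
        validation_fraction: float = 0.1,
        clip_norm: float = 5.0,
    ) -> TrainHistory:
        """Train with Adam + BPTT; ``y`` are integer labels in [0, n_classes)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.intp)
        n = X.shape[0]
        onehot = np.eye(self.n_classes)[y]

        n_val = int(round(validation_fraction * n)) if validation_fraction > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], onehot[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        params = [self.W, self.U, self.b, self.Wo, self.bo]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        hist = TrainHistory()
        best_val = np.inf
        best_params = [p.copy() for p in params]
        stall = 0

        for epoch in range(max_epochs):
            order = rng.permutation(len(Xtr))
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for s in range(0, len(order), batch_size):
                idx = order[s : s + batch_size]
                loss, acc, grads = self._loss_and_grads(Xtr[idx], ytr[idx], rng)
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if clip_norm and gnorm > clip_norm:
                    grads = [g * (clip_norm / gnorm) for g in grads]
                step += 1
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1**step)
                    vhat = v[j] / (1 - beta2**step)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
                ep_loss += loss
                ep_acc += acc
                n_batches += 1
            hist.train_loss.append(ep_loss / max(n_batches, 1))
            hist.train_acc.append(ep_acc / max(n_batches, 1))
            hist.n_epochs = epoch + 1

            if n_val:
                pv = self.predict_proba(Xval)
                vl = float(
                    -np.mean(np.log(pv[np.arange(len(yval)), yval] + 1e-12))
                )
                hist.val_loss.append(vl)
                hist.val_acc.append(float(np.mean(pv.argmax(axis=1) == yval)))
                if vl < best_val - 1e-5:
                    best_val = vl
                    best_params = [p.copy() for p in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
        if n_val:
            self.W, self.U, self.b, self.Wo, self.bo = best_params
        return hist

    # -- (de)serialization -------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b, "Wo": self.Wo, "bo": self.bo}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name in ("W", "U", "b", "Wo", "bo"):
            setattr(self, name, np.asarray(weights[name], dtype=np.float64))
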