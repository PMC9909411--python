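"""Minimal numpy neural nets used by the triage classifiers.

Implements a single-layer LSTM and a 1-D convolutional text classifier, both
over a frozen embedding lookup, trained with Adam on cross-entropy. Sized for
small corpora on one CPU; everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LSTMWeights:
    """Gate weights acting on the concatenation [h_prev, x].

    Column blocks of ``W`` are the forget, input, candidate and output gates,
    in that order; ``b`` is blocked the same way.
    """

    W: np.ndarray  # (hidden + input, 4*hidden)
    b: np.ndarray  # (4*hidden,)

    @property
    def hidden(self) -> int:
        return self.W.shape[1] // 4


@dataclass
class LSTMState:
    """Hidden state h and cell state c, same length (= number of units)."""

    h: np.ndarray
    c: np.ndarray


def lstm_step(x: np.ndarray, prev: LSTMState, weights: LSTMWeights) -> LSTMState:
    """One recurrence step of the standard LSTM cell.

    forget  g = sigmoid(W_g [h, x] + b_g)
    input   i = sigmoid(W_i [h, x] + b_i)
    cand    c~ = tanh  (W_c [h, x] + b_c)
    cell    c = g * c_prev + i * c~
    output  o = sigmoid(W_o [h, x] + b_o)
    hidden  h = o * tanh(c)
    """
    H = weights.hidden
    if prev.h.shape[-1] != H or prev.c.shape[-1] != H:
        raise ValueError("state size does not match weights")
    if prev.h.shape[-1] + x.shape[-1] != weights.W.shape[0]:
        raise ValueError("input size does not match weights")
    hx = np.concatenate([prev.h, x], axis=-1)
    z = hx @ weights.W + weights.b
    g = sigmoid(z[..., :H])
    i = sigmoid(z[..., H : 2 * H])
    c_tilde = np.tanh(z[..., 2 * H : 3 * H])
    c = g * prev.c + i * c_tilde
    o = sigmoid(z[..., 3 * H :])
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


class Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _SequenceNet:
    """Shared training loop: minibatch Adam over padded index sequences."""

    def __init__(self, embedding: np.ndarray, n_classes: int, seed: int):
        self.E = embedding  # frozen; row 0 is the pad vector (zeros)
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)
        self.history: list[dict] = []

    # subclasses define: params(), grads via _backward, _forward(X, train)

    def fit(self, X, y, epochs, batch_size, X_val=None, y_val=None, log=None,
            lr=3e-3):
        n = len(X)
        opt = Adam([p.shape for p in self.params()], lr=lr)
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, acc_n = self._train_batch(X[idx], y[idx], opt)
                losses.append(loss * len(idx))
                correct += acc_n
            rec = {
                "epoch": epoch,
                "train_loss": float(np.sum(losses) / n),
                "train_accuracy": correct / n,
            }
            if X_val is not None and len(X_val):
                probs = self.predict_proba(X_val)
                rec["val_loss"] = float(
                    -np.mean(np.log(probs[np.arange(len(y_val)), y_val] + 1e-12))
                )
                rec["val_accuracy"] = float(np.mean(probs.argmax(axis=1) == y_val))
            self.history.append(rec)
            if log is not None:
                log(rec)
        return self

    def _train_batch(self, Xb, yb, opt):
        probs, cache = self._forward(Xb, train=True)
        B = len(Xb)
        loss = float(-np.mean(np.log(probs[np.arange(B), yb] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(B), yb] -= 1.0
        dlogits /= B
        grads = self._backward(dlogits, cache)
        opt.step(self.params(), grads)
        return loss, int(np.sum(probs.argmax(axis=1) == yb))

    def predict_proba(self, X, batch_size=256):
        out = []
        for start in range(0, len(X), batch_size):
            probs, _ = self._forward(X[start : start + batch_size], train=False)
            out.append(probs)
        return np.vstack(out)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def _head_forward(self, feat, train):
        """Dense -> ReLU -> dropout -> softmax head shared by both nets."""
        a1 = feat @ self.W1 + self.b1
        r1 = np.maximum(a1, 0.0)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (self.rng.random(r1.shape) < keep) / keep
            r1d = r1 * mask
        else:
            mask = None
            r1d = r1
        logits = r1d @ self.W2 + self.b2
        return softmax(logits), (feat, a1, r1d, mask)

    def _head_backward(self, dlogits, head_cache):
        feat, a1, r1d, mask = head_cache
        dW2 = r1d.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dr1 = dlogits @ self.W2.T
        if mask is not None:
            dr1 = dr1 * mask
        dr1 = dr1 * (a1 > 0)
        dW1 = feat.T @ dr1
        db1 = dr1.sum(axis=0)
        dfeat = dr1 @ self.W1.T
        return dfeat, (dW1, db1, dW2, db2)


class LSTMClassifier(_SequenceNet):
    """Frozen embedding -> masked LSTM -> dense -> softmax.

    Padded positions (index 0) leave the recurrent state untouched, so the
    classifier reads the state at each sequence's true end.
    """

    def __init__(self, embedding, n_classes, units, dense_units, dropout=0.5, seed=0):
        super().__init__(embedding, n_classes, seed)
        d = embedding.shape[1]
        self.units, self.dropout = units, dropout
        rng = self.rng
        self.W = _glorot(rng, units + d, 4 * units)
        self.b = np.zeros(4 * units)
        self.b[:units] = 1.0  # forget-gate bias init keeps early memory open
        self.W1 = _glorot(rng, units, dense_units)
        self.b1 = np.zeros(dense_units)
        self.W2 = _glorot(rng, dense_units, n_classes)
        self.b2 = np.zeros(n_classes)

    def params(self):
        return [self.W, self.b, self.W1, self.b1, self.W2, self.b2]

    def _forward(self, X, train):
        B, T = X.shape
        H = self.units
        x_seq = self.E[X]  # (B, T, d)
        m_seq = (X != 0).astype(np.float64)[:, :, None]  # (B, T, 1)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            xt, mt = x_seq[:, t], m_seq[:, t]
            hx = np.concatenate([h, xt], axis=1)
            z = hx @ self.W + self.b
            g = sigmoid(z[:, :H])
            i = sigmoid(z[:, H : 2 * H])
            ct = np.tanh(z[:, 2 * H : 3 * H])
            c_new = g * c + i * ct
            o = sigmoid(z[:, 3 * H :])
            tc = np.tanh(c_new)
            h_new = o * tc
            h_next = mt * h_new + (1 - mt) * h
            c_next = mt * c_new + (1 - mt) * c
            steps.append((hx, g, i, ct, o, c, tc, mt))
            h, c = h_next, c_next
        probs, head_cache = self._head_forward(h, train)
        return probs, (steps, head_cache, X.shape)

    def _backward(self, dlogits, cache):
        steps, head_cache, (B, T) = cache
        H = self.units
        dh, head_grads = self._head_backward(dlogits, head_cache)
        dc = np.zeros_like(dh)
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        for t in range(T - 1, -1, -1):
            hx, g, i, ct, o, c_prev, tc, mt = steps[t]
            dh_m = mt * dh
            dc_m = mt * dc
            do = dh_m * tc
            dc_new = dc_m + dh_m * o * (1 - tc * tc)
            dg = dc_new * c_prev
            di = dc_new * ct
            dct = dc_new * i
            dz = np.concatenate(
                [dg * g * (1 - g), di * i * (1 - i), dct * (1 - ct * ct), do * o * (1 - o)],
                axis=1,
            )
            dW += hx.T @ dz
            db += dz.sum(axis=0)
            dhx = dz @ self.W.T
            dh = dhx[:, :H] + (1 - mt) * dh
            dc = dc_new * g + (1 - mt) * dc
        dW1, db1, dW2, db2 = head_grads
        return [dW, db, dW1, db1, dW2, db2]


class TextCNNClassifier(_SequenceNet):
    """Frozen embedding -> 1-D convolution -> max pool over time -> dense -> softmax."""

    def __init__(self, embedding, n_classes, filter_size=2, n_filters=256,
                 dense_units=512, dropout=0.5, seed=0):
        super().__init__(embedding, n_classes, seed)
        d = embedding.shape[1]
        self.fs, self.nf, self.dropout = filter_size, n_filters, dropout
        rng = self.rng
        self.Wc = _glorot(rng, filter_size * d, n_filters)
        self.bc = np.zeros(n_filters)
        self.W1 = _glorot(rng, n_filters, dense_units)
        self.b1 = np.zeros(dense_units)
        self.W2 = _glorot(rng, dense_units, n_classes)
        self.b2 = np.zeros(n_classes)

    def params(self):
        return [self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2]

    def _forward(self, X, train):
        B, T = X.shape
        x_seq = self.E[X]  # (B, T, d)
        L = T - self.fs + 1
        windows = np.concatenate([x_seq[:, i : L + i] for i in range(self.fs)], axis=2)
        conv = windows @ self.Wc + self.bc  # (B, L, F)
        relu = np.maximum(conv, 0.0)
        arg = relu.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(relu, arg[:, None, :], axis=1)[:, 0, :]
        probs, head_cache = self._head_forward(pooled, train)
        return probs, (windows, conv, arg, head_cache)

    def _backward(self, dlogits, cache):
        windows, conv, arg, head_cache = cache
        dpooled, head_grads = self._head_backward(dlogits, head_cache)
        drelu = np.zeros_like(conv)
        np.put_along_axis(drelu, arg[:, None, :], dpooled[:, None, :], axis=1)
        dconv = drelu * (conv > 0)
        dWc = np.einsum("blk,blf->kf", windows, dconv)
        dbc = dconv.sum(axis=(0, 1))
        dW1, db1, dW2, db2 = head_grads
        return [dWc, dbc, dW1, db1, dW2, db2]
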