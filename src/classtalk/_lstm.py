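"""Bidirectional LSTM sequence labeler in NumPy.

A small, dependency-free recurrent network for per-timestep binary
classification of fixed-rate feature sequences: a sequence input layer, one
bidirectional LSTM layer, an affine projection and a per-timestep softmax,
trained with masked cross-entropy and Adam by full backpropagation through
time.  Sequences of unequal length are padded and masked; padded steps
neither propagate state nor contribute loss.

Everything is deterministic given the initialization seed: full-batch or
fixed-order mini-batch gradient steps, no dropout, no shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTM"]


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class BiLSTM:
    """Per-timestep two-class sequence classifier.

    Parameters
    ----------
    n_features : input channel count per timestep.
    hidden_units : LSTM state size per direction.
    n_classes : output classes (default 2: not-interaction / interaction).
    seed : initialization seed; identical seeds give identical parameters.
    """

    def __init__(self, n_features: int, hidden_units: int, n_classes: int = 2, seed: int = 0):
        self.n_features = int(n_features)
        self.hidden = int(hidden_units)
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        F, H, C = self.n_features, self.hidden, self.n_classes
        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"Wx_{d}"] = _glorot(rng, (F, 4 * H))
            self.params[f"Wh_{d}"] = _glorot(rng, (H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias at 1: standard remember-by-default init
            self.params[f"b_{d}"] = bias
        self.params["Wy"] = _glorot(rng, (2 * H, C))
        self.params["by"] = np.zeros(C)
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def _direction_forward(self, X, mask, d: str):
        """Run one direction over a padded batch.

        X: (B, T, F); mask: (B, T) in {0,1}.  For the backward direction the
        caller passes time-reversed X and mask.  Returns hidden states
        (B, T, H) and a cache for BPTT.
        """
        B, T, _ = X.shape
        H = self.hidden
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        Xp = X.reshape(B * T, -1) @ Wx
        Xp = Xp.reshape(B, T, 4 * H) + b
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        cache = {"i": np.empty((B, T, H)), "f": np.empty((B, T, H)),
                 "o": np.empty((B, T, H)), "g": np.empty((B, T, H)),
                 "tc": np.empty((B, T, H)), "h_prev": np.empty((B, T, H)),
                 "c_prev": np.empty((B, T, H))}
        for t in range(T):
            m = mask[:, t][:, None]
            gates = Xp[:, t] + h @ Wh
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = _sigmoid(gates[:, 3 * H :])
            c_cand = f * c + i * g
            tc = np.tanh(c_cand)
            h_cand = o * tc
            cache["i"][:, t] = i
            cache["f"][:, t] = f
            cache["o"][:, t] = o
            cache["g"][:, t] = g
            cache["tc"][:, t] = tc
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            # padded steps carry state through unchanged
            h = m * h_cand + (1.0 - m) * h
            c = m * c_cand + (1.0 - m) * c
            Hs[:, t] = h
        cache["X"] = X
        return Hs, cache

    def _direction_backward(self, dHs, mask, cache, d: str):
        """BPTT for one direction; returns parameter grads and nothing else."""
        B, T, H = dHs.shape
        Wh = self.params[f"Wh_{d}"]
        dWx = np.zeros_like(self.params[f"Wx_{d}"])
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params[f"b_{d}"])
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        X = cache["X"]
        dG_all = np.empty((B, T, 4 * H))
        for t in range(T - 1, -1, -1):
            m = mask[:, t][:, None]
            dh = dh + dHs[:, t]
            i, f, o, g = cache["i"][:, t], cache["f"][:, t], cache["o"][:, t], cache["g"][:, t]
            tc = cache["tc"][:, t]
            c_prev = cache["c_prev"][:, t]
            dh_cand = m * dh
            do = dh_cand * tc
            dc_cand = m * dc + dh_cand * o * (1.0 - tc * tc)
            df = dc_cand * c_prev
            di = dc_cand * g
            dg = dc_cand * i
            dG = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g * g), do * o * (1.0 - o)],
                axis=1,
            )
            dG_all[:, t] = dG
            dWh += cache["h_prev"][:, t].T @ dG
            db += dG.sum(axis=0)
            dh = dG @ Wh.T + (1.0 - m) * dh
            dc = dc_cand * f + (1.0 - m) * dc
        dWx = X.reshape(B * T, -1).T @ dG_all.reshape(B * T, -1)
        return {f"Wx_{d}": dWx, f"Wh_{d}": dWh, f"b_{d}": db}

    def forward(self, X, mask):
        """Class probabilities (B, T, C) for a padded batch, plus BPTT caches."""
        Hf, cache_f = self._direction_forward(X, mask, "f")
        Hb_rev, cache_b = self._direction_forward(X[:, ::-1], mask[:, ::-1], "b")
        Hb = Hb_rev[:, ::-1]
        Hcat = np.concatenate([Hf, Hb], axis=2)
        B, T, _ = X.shape
        logits = Hcat.reshape(B * T, -1) @ self.params["Wy"] + self.params["by"]
        logits = logits.reshape(B, T, self.n_classes)
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=2, keepdims=True)
        return probs, (Hcat, cache_f, cache_b)

    # --------------------------------------------------------------- training

    def loss_and_grads(self, X, y, mask):
        """Masked mean cross-entropy and gradients for a padded batch.

        y: (B, T) integer class labels (ignored where mask == 0).
        """
        probs, (Hcat, cache_f, cache_b) = self.forward(X, mask)
        B, T, C = probs.shape
        n_valid = max(mask.sum(), 1.0)
        onehot = np.eye(C)[y.astype(int)]
        eps = 1e-12
        loss = -(mask[:, :, None] * onehot * np.log(probs + eps)).sum() / n_valid
        dlogits = (probs - onehot) * mask[:, :, None] / n_valid
        flatH = Hcat.reshape(B * T, -1)
        grads = {
            "Wy": flatH.T @ dlogits.reshape(B * T, C),
            "by": dlogits.sum(axis=(0, 1)),
        }
        dH = dlogits.reshape(B * T, C) @ self.params["Wy"].T
        dH = dH.reshape(B, T, 2 * self.hidden)
        grads.update(self._direction_backward(dH[:, :, : self.hidden], mask, cache_f, "f"))
        grads.update(
            self._direction_backward(dH[:, ::-1, self.hidden :], mask[:, ::-1], cache_b, "b")
        )
        return loss, grads

    def adam_step(self, grads, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    @staticmethod
    def _pad(seqs, labels=None):
        """Pad variable-length sequences into (B, T, F), mask (B, T)."""
        B = len(seqs)
        T = max(s.shape[0] for s in seqs)
        F = seqs[0].shape[1]
        X = np.zeros((B, T, F))
        mask = np.zeros((B, T))
        y = np.zeros((B, T)) if labels is not None else None
        for b, s in enumerate(seqs):
            X[b, : s.shape[0]] = s
            mask[b, : s.shape[0]] = 1.0
            if labels is not None:
                y[b, : s.shape[0]] = labels[b]
        return (X, y, mask) if labels is not None else (X, mask)

    def fit(self, seqs, labels, epochs=30, lr=0.01, window_bins=None, batch_size=32):
        """Train on a list of (T_i, F) sequences with (T_i,) 0/1 labels.

        When ``window_bins`` is set, sequences are chopped into consecutive
        fixed-length windows processed in deterministic-order mini-batches
        (more optimizer updates per epoch, less padding memory); otherwise one
        full-batch update per epoch over whole padded sessions.  Returns the
        per-epoch loss history.
        """
        if len(seqs) != len(labels):
            raise ValueError("sequence/label list length mismatch")
        for s, l in zip(seqs, labels):
            if s.shape[0] != l.shape[0]:
                raise ValueError("label sequence not aligned to feature series")
        if window_bins is not None:
            chunks, chunk_labels = [], []
            for s, l in zip(seqs, labels):
                for lo in range(0, s.shape[0], window_bins):
                    chunks.append(s[lo : lo + window_bins])
                    chunk_labels.append(l[lo : lo + window_bins])
            seqs, labels = chunks, chunk_labels
        else:
            batch_size = len(seqs)
        history = []
        for _ in range(int(epochs)):
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(seqs), batch_size):
                X, y, mask = self._pad(seqs[lo : lo + batch_size], labels[lo : lo + batch_size])
                loss, grads = self.loss_and_grads(X, y, mask)
                self.adam_step(grads, lr=lr)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / n_batches)
        return history

    def predict_proba(self, seq):
        """Per-timestep class probabilities (T, C) for one whole sequence."""
        X, mask = self._pad([seq])
        probs, _ = self.forward(X, mask)
        return probs[0]

    def predict(self, seq):
        """Per-timestep argmax class labels (T,)."""
        return self.predict_proba(seq).argmax(axis=1)
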