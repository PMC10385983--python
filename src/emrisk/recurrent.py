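"""A small, dependency-free LSTM for visit-token sequences.

Each visit is embedded as the sum of its token embeddings; a stacked LSTM
consumes the visit vectors in date order and the final hidden state is mapped
through a sigmoid readout to a risk probability.  Forward, full BPTT and Adam
are implemented in numpy; exact analytic gradients are verified against
finite differences in the test suite.

Padding: token id 0 is reserved and its embedding row is pinned at zero, so
masking a token to padding and deleting it are equivalent under sum pooling.
Sequences in a batch are right-padded; masked timesteps carry hidden and cell
state through unchanged, so the state at the last timestep is the state at
each sequence's last real visit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMNet"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMNet:
    def __init__(self, vocab_size: int, embed_dim: int = 128,
                 hidden_size: int = 128, n_layers: int = 2,
                 dropout: float = 0.2, seed: int = 0):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        self.vocab_size = int(vocab_size)
        self.embed_dim = int(embed_dim)
        self.hidden_size = int(hidden_size)
        self.n_layers = int(n_layers)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        D, H = self.embed_dim, self.hidden_size
        p: dict[str, np.ndarray] = {}
        p["E"] = rng.normal(0.0, 0.1, size=(self.vocab_size + 1, D))
        p["E"][0] = 0.0
        for l in range(self.n_layers):
            in_dim = D if l == 0 else H
            s_in = 1.0 / np.sqrt(in_dim)
            s_h = 1.0 / np.sqrt(H)
            p[f"W{l}"] = rng.uniform(-s_in, s_in, size=(in_dim, 4 * H))
            p[f"U{l}"] = rng.uniform(-s_h, s_h, size=(H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p[f"b{l}"] = b
        p["w_out"] = rng.uniform(-1.0 / np.sqrt(H), 1.0 / np.sqrt(H), size=H)
        p["b_out"] = np.zeros(1)
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()

    # -- batching ----------------------------------------------------------
    def _embed(self, seqs: list[list[list[int]]]):
        """Sum-pool token embeddings into visit vectors.

        Returns X (B,T,D), mask (B,T) and the flat (b,t,token) index arrays
        needed to scatter gradients back into the embedding table.
        """
        B = len(seqs)
        T = max(len(s) for s in seqs)
        D = self.embed_dim
        bt_idx, tok_idx = [], []
        mask = np.zeros((B, T))
        for b, seq in enumerate(seqs):
            if not seq:
                raise ValueError("empty visit sequence")
            mask[b, : len(seq)] = 1.0
            for t, visit in enumerate(seq):
                for tok in visit:
                    if tok == 0:
                        continue  # padding token: zero embedding by contract
                    if not (0 < tok <= self.vocab_size):
                        raise ValueError(f"token id {tok} outside vocabulary")
                    bt_idx.append(b * T + t)
                    tok_idx.append(tok)
        bt_idx = np.asarray(bt_idx, dtype=np.int64)
        tok_idx = np.asarray(tok_idx, dtype=np.int64)
        X = np.zeros((B * T, D))
        if len(tok_idx):
            np.add.at(X, bt_idx, self.params["E"][tok_idx])
        return X.reshape(B, T, D), mask, bt_idx, tok_idx

    # -- forward -----------------------------------------------------------
    def forward(self, seqs, train: bool = False, rng: np.random.Generator | None = None):
        X, mask, bt_idx, tok_idx = self._embed(seqs)
        B, T, _ = X.shape
        H = self.hidden_size
        layer_in = X
        caches = []
        drop_masks = []
        for l in range(self.n_layers):
            W, U, b = self.params[f"W{l}"], self.params[f"U{l}"], self.params[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            out_seq = np.zeros((B, T, H))
            for t in range(T):
                x_t = layer_in[:, t]
                z = x_t @ W + h @ U + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                m = mask[:, t][:, None]
                steps.append((x_t, h, c, i, f, g, o, tc))
                h = m * h_new + (1 - m) * h
                c = m * c_new + (1 - m) * c
                out_seq[:, t] = h
            caches.append(steps)
            # inter-layer dropout (torch convention: not after the top layer)
            if train and self.dropout > 0 and l < self.n_layers - 1:
                dm = (rng.random(out_seq.shape) >= self.dropout) / (1 - self.dropout)
                out_seq = out_seq * dm
                drop_masks.append(dm)
            else:
                drop_masks.append(None)
            layer_in = out_seq
        h_final = layer_in[:, -1]
        logits = h_final @ self.params["w_out"] + self.params["b_out"][0]
        probs = _sigmoid(logits)
        cache = dict(X=X, mask=mask, bt_idx=bt_idx, tok_idx=tok_idx,
                     caches=caches, drop_masks=drop_masks,
                     h_final=h_final, probs=probs, B=B, T=T)
        return probs, cache

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logit) per sample."""
        B, T = cache["B"], cache["T"]
        H = self.hidden_size
        mask = cache["mask"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["w_out"] = cache["h_final"].T @ dlogits
        grads["b_out"] = np.array([dlogits.sum()])
        d_out = np.zeros((B, T, H))
        d_out[:, -1] = dlogits[:, None] * self.params["w_out"][None, :]

        for l in reversed(range(self.n_layers)):
            dm = cache["drop_masks"][l]
            if dm is not None:
                d_out = d_out * dm
            W, U = self.params[f"W{l}"], self.params[f"U{l}"]
            steps = cache["caches"][l]
            in_dim = W.shape[0]
            dX_layer = np.zeros((B, T, in_dim))
            dh_carry = np.zeros((B, H))
            dc_carry = np.zeros((B, H))
            dW = np.zeros_like(W)
            dU = np.zeros_like(U)
            db = np.zeros(4 * H)
            for t in reversed(range(T)):
                x_t, h_prev, c_prev, i, f, g, o, tc = steps[t]
                m = mask[:, t][:, None]
                dh_total = d_out[:, t] + dh_carry
                dc_total = dc_carry
                dh = m * dh_total
                dh_skip = (1 - m) * dh_total
                dc = m * dc_total
                dc_skip = (1 - m) * dc_total
                do = dh * tc
                dc_inner = dh * o * (1 - tc * tc) + dc
                df = dc_inner * c_prev
                di = dc_inner * g
                dg = dc_inner * i
                dc_prev = dc_inner * f + dc_skip
                dz = np.concatenate([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ], axis=1)
                dW += x_t.T @ dz
                dU += h_prev.T @ dz
                db += dz.sum(axis=0)
                dX_layer[:, t] = dz @ W.T
                dh_carry = dz @ U.T + dh_skip
                dc_carry = dc_prev
            grads[f"W{l}"] = dW
            grads[f"U{l}"] = dU
            grads[f"b{l}"] = db
            d_out = dX_layer

        # scatter into the embedding table
        dX_flat = d_out.reshape(B * T, -1)
        if len(cache["tok_idx"]):
            np.add.at(grads["E"], cache["tok_idx"], dX_flat[cache["bt_idx"]])
        grads["E"][0] = 0.0
        return grads

    # -- training ----------------------------------------------------------
    def loss_and_grads(self, seqs, y: np.ndarray,
                       rng: np.random.Generator | None = None,
                       train: bool = True):
        probs, cache = self.forward(seqs, train=train, rng=rng)
        eps = 1e-12
        p = np.clip(probs, eps, 1 - eps)
        loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        dlogits = (probs - y) / len(y)
        return float(loss), self.backward(cache, dlogits)

    def adam_step(self, grads: dict[str, np.ndarray], lr: float = 1e-3,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        self.params["E"][0] = 0.0  # keep the padding embedding pinned

    def predict(self, seqs, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(seqs))
        for s in range(0, len(seqs), batch_size):
            probs, _ = self.forward(seqs[s:s + batch_size], train=False)
            out[s:s + len(probs)] = probs
        return out
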