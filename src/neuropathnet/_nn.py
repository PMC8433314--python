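"""NumPy implementation of the multi-task feed-forward network.

The network has a stack of shared ReLU layers followed by one ReLU branch
per task ending in a linear scalar output.  Forward, backward, masked loss
and the Adam update are written out explicitly: this gives exact control of
the gradient at masked label cells (identically zero), of the gradient with
respect to the *input* (needed for path-integrated attributions), and full
run-to-run determinism from a single integer seed.

Conventions follow common deep-learning defaults: Glorot-uniform weight
initialization, inverted dropout active only during training, per-array
gradient-norm clipping (the semantics of Keras ``clipnorm``), L2 penalty on
kernels but not biases, Adam with b1=0.9, b2=0.999, eps=1e-7.
"""

from __future__ import annotations

import numpy as np

ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 0.9, 0.999, 1e-7


def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean of squared errors over observed (sample, task) cells only."""
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return 0.0
    diff = np.where(mask, pred - np.where(mask, target, 0.0), 0.0)
    return float((diff * diff).sum() / n_obs)


def masked_mse_grad(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """d(masked MSE)/d(pred); exactly zero at masked cells.  An all-masked
    batch contributes zero loss and zero gradient."""
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return np.zeros_like(pred)
    diff = np.where(mask, pred - np.where(mask, target, 0.0), 0.0)
    return 2.0 * diff / n_obs


class MaskedMLP:
    """Shared-trunk / per-task-branch multilayer perceptron.

    Weights are plain numpy arrays: ``shared`` is a list of (W, b) pairs and
    ``branches[t]`` is the list of (W, b) pairs for task ``t`` whose final
    layer is linear with a single output unit.
    """

    def __init__(
        self,
        input_dim: int,
        shared_widths=(256, 100),
        branch_widths=(50,),
        n_tasks: int = 6,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        self.input_dim = int(input_dim)
        self.shared_widths = tuple(int(w) for w in shared_widths)
        self.branch_widths = tuple(int(w) for w in branch_widths)
        self.n_tasks = int(n_tasks)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.shared = []
        d = self.input_dim
        for w in self.shared_widths:
            self.shared.append([_glorot(rng, d, w), np.zeros(w)])
            d = w
        self.branches = []
        for _ in range(self.n_tasks):
            layers, db = [], d
            for w in self.branch_widths:
                layers.append([_glorot(rng, db, w), np.zeros(w)])
                db = w
            layers.append([_glorot(rng, db, 1), np.zeros(1)])
            self.branches.append(layers)

    # --- parameter traversal -------------------------------------------------
    def parameters(self):
        """Yield (name, [W, b]) for every layer."""
        for i, lay in enumerate(self.shared):
            yield f"shared:{i}", lay
        for t, branch in enumerate(self.branches):
            for i, lay in enumerate(branch):
                yield f"branch{t}:{i}", lay

    def get_weights(self) -> dict:
        return {
            name: {"W": lay[0].copy(), "b": lay[1].copy()}
            for name, lay in self.parameters()
        }

    def set_weights(self, weights: dict) -> None:
        for name, lay in self.parameters():
            lay[0][...] = weights[name]["W"]
            lay[1][...] = weights[name]["b"]

    # --- forward -------------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False, rng=None):
        """Return (predictions, cache).  Dropout multipliers are sampled only
        when ``training`` and recorded in the cache for the backward pass."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} does not match network "
                f"input_dim {self.input_dim}"
            )
        keep = 1.0 - self.dropout

        def dropmask(shape):
            if not training or self.dropout == 0.0:
                return None
            return (rng.random(shape) < keep) / keep

        h = X
        shared_cache = []
        for W, b in self.shared:
            z = h @ W + b
            relu = z > 0
            a = z * relu
            m = dropmask(a.shape)
            if m is not None:
                a = a * m
            shared_cache.append((h, relu, m))
            h = a
        shared_out = h

        preds = np.empty((X.shape[0], self.n_tasks))
        branch_cache = []
        for t, branch in enumerate(self.branches):
            hb = shared_out
            caches = []
            for W, b in branch[:-1]:
                z = hb @ W + b
                relu = z > 0
                a = z * relu
                m = dropmask(a.shape)
                if m is not None:
                    a = a * m
                caches.append((hb, relu, m))
                hb = a
            W, b = branch[-1]
            caches.append((hb, None, None))
            preds[:, t] = (hb @ W + b)[:, 0]
            branch_cache.append(caches)
        cache = {"X": X, "shared": shared_cache, "branches": branch_cache,
                 "shared_out": shared_out}
        return preds, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)[0]

    def shared_forward(self, X: np.ndarray) -> np.ndarray:
        """Activation of the last shared layer (dropout off) — identical to
        the truncated network with all branch layers removed."""
        h = np.asarray(X, dtype=float)
        for W, b in self.shared:
            h = np.maximum(h @ W + b, 0.0)
        return h

    # --- backward ------------------------------------------------------------
    def backward(self, cache, dpred: np.ndarray, dshared_extra: np.ndarray | None = None):
        """Backpropagate d(loss)/d(pred) (and optionally an upstream gradient
        seeded directly at the last shared layer) to parameter gradients and
        the gradient with respect to the input.

        Returns (grads, dX) where grads mirrors the parameter structure.
        """
        grads = {name: [np.zeros_like(lay[0]), np.zeros_like(lay[1])]
                 for name, lay in self.parameters()}
        dshared = np.zeros_like(cache["shared_out"])
        if dshared_extra is not None:
            dshared = dshared + dshared_extra

        if dpred is not None:
            for t, branch in enumerate(self.branches):
                caches = cache["branches"][t]
                W_out, _ = branch[-1]
                h_last = caches[-1][0]
                dz = dpred[:, t : t + 1]
                if not np.any(dz):
                    continue
                g = grads[f"branch{t}:{len(branch) - 1}"]
                g[0] += h_last.T @ dz
                g[1] += dz.sum(axis=0)
                dh = dz @ W_out.T
                for i in range(len(branch) - 2, -1, -1):
                    W, _ = branch[i]
                    h_in, relu, m = caches[i]
                    if m is not None:
                        dh = dh * m
                    dzz = dh * relu
                    g = grads[f"branch{t}:{i}"]
                    g[0] += h_in.T @ dzz
                    g[1] += dzz.sum(axis=0)
                    dh = dzz @ W.T
                dshared += dh

        dh = dshared
        for i in range(len(self.shared) - 1, -1, -1):
            W, _ = self.shared[i]
            h_in, relu, m = cache["shared"][i]
            if m is not None:
                dh = dh * m
            dzz = dh * relu
            g = grads[f"shared:{i}"]
            g[0] += h_in.T @ dzz
            g[1] += dzz.sum(axis=0)
            dh = dzz @ W.T
        return grads, dh

    def input_gradient(self, X: np.ndarray, target: int, kind: str = "output") -> np.ndarray:
        """d(target)/d(input) summed over nothing — one row per sample.

        ``kind='output'`` targets prediction column ``target``;
        ``kind='node'`` targets unit ``target`` of the last shared layer
        (the truncated network).  Dropout is off: the map is piecewise
        linear, so this is the exact gradient almost everywhere.
        """
        preds, cache = self.forward(X, training=False)
        n = X.shape[0]
        if kind == "output":
            dpred = np.zeros_like(preds)
            dpred[:, target] = 1.0
            _, dX = self.backward(cache, dpred)
        elif kind == "node":
            dshared = np.zeros_like(cache["shared_out"])
            dshared[:, target] = 1.0
            _, dX = self.backward(cache, None, dshared_extra=dshared)
        else:
            raise ValueError(f"unknown gradient target kind {kind!r}")
        return dX


class AdamState:
    """Per-parameter-array Adam accumulators with clipnorm and kernel L2."""

    def __init__(self, net: MaskedMLP, learning_rate: float, l2: float, clip_norm: float):
        self.lr = learning_rate
        self.l2 = l2
        self.clip = clip_norm
        self.t = 0
        self.m = {name: [np.zeros_like(lay[0]), np.zeros_like(lay[1])]
                  for name, lay in net.parameters()}
        self.v = {name: [np.zeros_like(lay[0]), np.zeros_like(lay[1])]
                  for name, lay in net.parameters()}

    def step(self, net: MaskedMLP, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - ADAM_BETA1 ** self.t
        b2t = 1.0 - ADAM_BETA2 ** self.t
        for name, lay in net.parameters():
            for j in range(2):  # 0 = kernel, 1 = bias
                g = grads[name][j]
                if j == 0 and self.l2 > 0:
                    g = g + self.l2 * lay[j]
                if self.clip is not None and self.clip > 0:
                    norm = np.sqrt((g * g).sum())
                    if norm > self.clip:
                        g = g * (self.clip / norm)
                m = self.m[name][j]
                v = self.v[name][j]
                m[...] = ADAM_BETA1 * m + (1 - ADAM_BETA1) * g
                v[...] = ADAM_BETA2 * v + (1 - ADAM_BETA2) * (g * g)
                lay[j] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + ADAM_EPS)


def train_network(
    net: MaskedMLP,
    X: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    learning_rate: float = 1e-3,
    l2: float = 1e-5,
    clip_norm: float = 0.1,
    epochs: int = 200,
    batch_size: int = 20,
    seed: int = 0,
) -> list[float]:
    """Mini-batch Adam training of the masked multi-task objective.

    Returns the per-epoch training log: the full-data masked loss evaluated
    in inference mode after each epoch.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no observed label cells in the training data")
    Y = np.where(mask, Y, 0.0)
    rng = np.random.default_rng(seed)
    adam = AdamState(net, learning_rate, l2, clip_norm)
    n = X.shape[0]
    log = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            preds, cache = net.forward(X[idx], training=True, rng=rng)
            dpred = masked_mse_grad(preds, Y[idx], mask[idx])
            grads, _ = net.backward(cache, dpred)
            adam.step(net, grads)
        loss = masked_mse(net.predict(X), Y, mask)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(lr={learning_rate}, clip_norm={clip_norm}, l2={l2})"
            )
        log.append(loss)
    return log
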