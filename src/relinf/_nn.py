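"""Minimal dense networks and Adam, in numpy.

The edge/node functions used by the decoders are small MLPs; batches are 2-D
arrays (n_samples, n_features). Parameters live in plain lists of arrays so
they can be copied, permuted and finite-difference checked trivially.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected network with tanh hidden units and a linear head.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths, ``[in_dim, hidden..., out_dim]``.
    rng : numpy.random.Generator
        Source for the (Glorot-scaled) initial weights.
    """

    def __init__(self, sizes, rng):
        self.sizes = list(sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        return self.weights + self.biases

    def set_params(self, params):
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:n]]
        self.biases = [np.asarray(p, dtype=float) for p in params[n:]]

    def copy(self):
        out = MLP.__new__(MLP)
        out.sizes = list(self.sizes)
        out.weights = [w.copy() for w in self.weights]
        out.biases = [b.copy() for b in self.biases]
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x, cache=None):
        """Forward pass; ``x`` is (batch, in_dim). Fills ``cache`` (a list)
        with activations when provided, for use by :meth:`backward`."""
        h = np.asarray(x, dtype=float)
        if cache is not None:
            cache.append(h)
        n_layers = len(self.weights)
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if li < n_layers - 1:
                h = np.tanh(h)
            if cache is not None:
                cache.append(h)
        return h

    def __call__(self, x):
        return self.forward(x)

    def backward(self, cache, dout):
        """Backprop ``dout`` (batch, out_dim) through a cached forward pass.

        Returns ``(grads, dx)`` where grads aligns with :attr:`params`.
        """
        n_layers = len(self.weights)
        grad_w = [None] * n_layers
        grad_b = [None] * n_layers
        delta = np.asarray(dout, dtype=float)
        for li in range(n_layers - 1, -1, -1):
            a_out = cache[li + 1]
            a_in = cache[li]
            if li < n_layers - 1:
                delta = delta * (1.0 - a_out**2)  # tanh'
            grad_w[li] = a_in.T @ delta
            grad_b[li] = delta.sum(axis=0)
            delta = delta @ self.weights[li].T
        return grad_w + grad_b, delta


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        """One in-place descent step (pass the gradient of the loss)."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
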