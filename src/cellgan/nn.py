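"""Neural-network building blocks on top of :mod:`cellgan.autodiff`.

Parameters live in plain ``dict[str, np.ndarray]`` containers; each forward
pass wraps them into leaf :class:`~cellgan.autodiff.Tensor` objects so the
graph is rebuilt per step (cheap at these sizes, and trivially reentrant).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, power, take_rows, tmean

BN_EPS = 1e-5


def he_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """He-initialized affine parameters (ReLU networks)."""
    w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
    b = np.zeros(fan_out)
    return w, b


def batch_norm(x, gamma, beta, running, key, training, momentum=0.99,
               update_running=True, labels=None):
    """Batch normalization with optional per-class (conditional) affine terms.

    ``running`` is a mutable dict holding ``{key}_mean`` / ``{key}_var``
    inference statistics, shared across classes in the conditional case so
    tiny classes still normalize stably. ``gamma``/``beta`` are ``(F,)``
    tensors, or ``(C, F)`` with ``labels`` given for the conditional variant.
    """
    x = as_tensor(x)
    if training:
        mu = tmean(x, axis=0, keepdims=True)
        var = tmean(power(x - mu, 2.0), axis=0, keepdims=True)
        if update_running:
            rm = running.setdefault(key + "_mean", np.zeros(x.shape[1]))
            rv = running.setdefault(key + "_var", np.ones(x.shape[1]))
            running[key + "_mean"] = momentum * rm + (1 - momentum) * mu.data.ravel()
            running[key + "_var"] = momentum * rv + (1 - momentum) * var.data.ravel()
        xhat = (x - mu) * power(var + BN_EPS, -0.5)
    else:
        mu = Tensor(running.get(key + "_mean", np.zeros(x.shape[1])))
        var = Tensor(running.get(key + "_var", np.ones(x.shape[1])))
        xhat = (x - mu) * power(var + BN_EPS, -0.5)
    g, b = as_tensor(gamma), as_tensor(beta)
    if labels is not None:
        g = take_rows(g, labels)
        b = take_rows(b, labels)
    return xhat * g + b


class AMSGrad:
    """AMSGrad optimizer (Adam with a non-decreasing second-moment estimate).

    Defaults follow the adversarial-training setup used throughout the
    package: beta1=0.5, beta2=0.9.
    """

    def __init__(self, lr=5e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        if not (0.0 < beta1 < 1.0 and 0.0 < beta2 < 1.0):
            raise ValueError("betas must lie in (0, 1)")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._vhat: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict, grads: dict):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self._t
        c2 = 1.0 - b2 ** self._t
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(params[k]))
            v = self._v.setdefault(k, np.zeros_like(params[k]))
            vh = self._vhat.setdefault(k, np.zeros_like(params[k]))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            np.maximum(vh, v, out=vh)
            params[k] -= self.lr * (m / c1) / (np.sqrt(vh / c2) + self.eps)


def wrap_params(params: dict) -> dict:
    """Wrap an array dict into leaf tensors for one forward/backward pass."""
    return {k: Tensor(v) for k, v in params.items()}


def grads_to_arrays(names, tensors) -> dict:
    return {k: t.data for k, t in zip(names, tensors)}
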