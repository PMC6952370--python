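"""Conditional WGAN: class-conditioned generation of cell types.

Conditioning follows the projection-discriminator recipe: the generator's
batch-normalization layers keep shared running statistics but per-class scale
and shift parameters (conditional batch normalization), while the critic adds
to its unconditional affine head the inner product of a learned per-class
vector with its final hidden features,

    score(x, y) = w . h(x) + b + <v_y, h(x)> + c_y,

with optional per-class biases c_y. Everything else — LSN output layer,
gradient penalty, 5:1 alternation, AMSGrad — is inherited from the
unconditional model; the only label-dependent generator parameters are the
CBN scales and shifts, so expression machinery learned on abundant classes is
shared with rare ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, matmul, take_rows, tsum
from .errors import ParameterError
from .gan import (CriticSpec, GeneratorSpec, TrainConfig, TrainState,
                  _generate_array, critic_features, generator_forward, train)
from .io import CountMatrix
from .preprocess import LabelVector


@dataclass
class ConditionalGeneratorSpec(GeneratorSpec):
    n_classes: int = 2

    def __post_init__(self):
        super().__post_init__()
        if self.n_classes < 1:
            raise ParameterError("n_classes must be >= 1")


@dataclass
class ProjectionCriticSpec(CriticSpec):
    n_classes: int = 2
    class_bias: bool = True

    def __post_init__(self):
        super().__post_init__()
        if self.n_classes < 1:
            raise ParameterError("n_classes must be >= 1")


def _check_labels(labels, n_classes, batch):
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (batch,):
        raise ParameterError("labels must align with the batch")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ParameterError("label out of range")
    return labels


def conditional_generator_forward(spec: ConditionalGeneratorSpec, params, z,
                                  labels, training: bool = False,
                                  bn_state: dict | None = None,
                                  update_running: bool = False) -> Tensor:
    """Generator forward with per-class CBN affine parameters; the LSN
    row-sum contract is unchanged."""
    z = ad.as_tensor(z)
    labels = _check_labels(labels, spec.n_classes, z.shape[0])
    return generator_forward(spec, params, z, training=training,
                             bn_state=bn_state, labels=labels,
                             update_running=update_running)


def projection_critic_forward(spec: ProjectionCriticSpec, params, x,
                              labels) -> Tensor:
    """Projection-conditioned critic score per cell."""
    x = ad.as_tensor(x)
    labels = _check_labels(labels, spec.n_classes, x.shape[0])
    h = critic_features(spec, params, x)
    s = matmul(h, params["w_head"]) + params["b_head"]
    s = ad.reshape(s, (s.shape[0],))
    s = s + tsum(h * take_rows(params["proj"], labels), axis=1)
    if "proj_bias" in params:
        s = s + _gather_bias(params["proj_bias"], labels)
    return s


def _gather_bias(bias, labels):
    b = ad.as_tensor(bias)
    return ad.reshape(take_rows(ad.reshape(b, (b.shape[0], 1)), labels),
                      (len(labels),))


def train_conditional(data: CountMatrix, labels: LabelVector,
                      gspec: ConditionalGeneratorSpec,
                      cspec: ProjectionCriticSpec,
                      cfg: TrainConfig,
                      label_sampling: str = "empirical") -> TrainState:
    """Train on (cell, label) pairs; generator labels are drawn from the
    empirical class frequencies of the training data (or uniformly)."""
    if len(labels) != data.n_cells:
        raise ParameterError("labels must align with data rows")
    if gspec.n_classes != labels.n_classes or cspec.n_classes != labels.n_classes:
        raise ParameterError("spec n_classes must match the label vector")
    if label_sampling not in ("empirical", "uniform"):
        raise ParameterError(f"unknown label_sampling: {label_sampling!r}")
    return train(data, gspec, cspec, cfg, labels=labels.labels,
                 n_classes=labels.n_classes, class_bias=cspec.class_bias,
                 projection_forward=projection_critic_forward,
                 label_stream_uniform=(label_sampling == "uniform"))


def generate_class(state: TrainState, class_id: int, n: int,
                   seed: int = 0) -> CountMatrix:
    """Sample ``n`` cells conditioned on ``class_id``."""
    if state.n_classes is None:
        raise ParameterError("state was not trained conditionally")
    if not (0 <= class_id < state.n_classes):
        raise ParameterError(f"unknown class: {class_id}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    lab = np.full(n, class_id, dtype=np.int64)
    vals = _generate_array(state, n, rng, labels=lab)
    return CountMatrix(sp.csr_matrix(vals), state.gene_ids,
                       [f"gen_c{class_id}_{i}" for i in range(n)],
                       state.gspec.phi)
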