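"""Unconditional WGAN for library-size-normalized scRNA-seq counts.

The generator is an MLP (FC -> batch norm -> ReLU per hidden layer) whose
output layer is a library-size normalization (LSN) layer: a final affine map
into gene space followed by ReLU and an exact rescaling of every cell to a
fixed total count phi,

    y_relu   = ReLU(x W + b)
    y_output = phi / sum_i (y_relu)_i * y_relu,

so generated cells are non-negative and satisfy the same row-sum contract as
the (normalized) training data. The critic is an MLP (FC -> ReLU, linear
unbounded output) scoring cells; training minimizes the WGAN objective with
the Gulrajani gradient penalty, alternating five critic updates with one
generator update under AMSGrad (beta1=0.5, beta2=0.9).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor, grad, matmul, power, relu, tmean, tsum
from .errors import ParameterError, TrainingDivergedError
from .io import CountMatrix
from .nn import AMSGrad, batch_norm, he_linear, wrap_params

LSN_EPS = 1e-8


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    n_genes: int
    latent_dim: int = 100
    hidden_sizes: tuple = (256, 512, 1024)
    phi: float = 20000.0
    batch_norm: bool = True

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ParameterError("hidden_sizes must be non-empty")
        if self.phi <= 0:
            raise ParameterError("phi must be positive")


@dataclass
class CriticSpec:
    n_genes: int
    hidden_sizes: tuple = (1024, 512, 256)

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ParameterError("hidden_sizes must be non-empty")


@dataclass
class TrainConfig:
    total_steps: int = 1000          # counted in generator updates
    critic_iters_per_gen: int = 5
    learning_rate: float = 5e-4
    beta1: float = 0.5
    beta2: float = 0.9
    gp_lambda: float = 10.0
    batch_size: int = 128
    seed: int = 0
    eval_interval: int = 100
    holdout_size: int = 3000         # capped at 10% of cells
    monitor_sample: int = 1000
    monitor_n_hvg: int = 1000

    def __post_init__(self):
        if self.critic_iters_per_gen < 1:
            raise ParameterError("critic_iters_per_gen must be >= 1")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ParameterError("betas must lie in (0, 1)")


@dataclass
class TrainState:
    gspec: GeneratorSpec
    cspec: CriticSpec
    cfg: TrainConfig
    gen_params: dict
    gen_bn_state: dict
    critic_params: dict
    gene_ids: list
    gen_steps: int = 0
    critic_steps: int = 0
    monitors: list = field(default_factory=list)
    holdout_indices: np.ndarray | None = None
    n_classes: int | None = None          # set by the conditional trainer
    class_freqs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# latent sampling and forward passes
# ---------------------------------------------------------------------------

def sample_latent(n: int, latent_dim: int, seed=None) -> np.ndarray:
    """Standard-normal latent draws (n x latent_dim), seeded."""
    if n < 1 or latent_dim < 1:
        raise ParameterError("n and latent_dim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim))


def init_generator_params(spec: GeneratorSpec, rng: np.random.Generator,
                          n_classes: int | None = None):
    """He-initialized generator parameters; BN scale/shift are per class when
    ``n_classes`` is given (conditional batch normalization)."""
    params, sizes = {}, [spec.latent_dim, *spec.hidden_sizes]
    for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"w{i}"], params[f"b{i}"] = he_linear(rng, fi, fo)
        if spec.batch_norm:
            shape = (fo,) if n_classes is None else (n_classes, fo)
            params[f"bn_gamma{i}"] = np.ones(shape)
            params[f"bn_beta{i}"] = np.zeros(shape)
    params["w_lsn"], params["b_lsn"] = he_linear(
        rng, sizes[-1], spec.n_genes)
    return params, {}


def generator_forward(spec: GeneratorSpec, params, z, training: bool = False,
                      bn_state: dict | None = None, labels=None,
                      update_running: bool = False) -> Tensor:
    """Forward pass; returns a (batch x n_genes) tensor whose rows are
    non-negative and sum to phi (up to the epsilon guard on all-zero rows)."""
    z = ad.as_tensor(z)
    if z.shape[1] != spec.latent_dim:
        raise ParameterError(
            f"latent batch has {z.shape[1]} columns, expected {spec.latent_dim}")
    bn_state = {} if bn_state is None else bn_state
    h = z
    for i in range(len(spec.hidden_sizes)):
        h = matmul(h, params[f"w{i}"]) + params[f"b{i}"]
        if spec.batch_norm:
            h = batch_norm(h, params[f"bn_gamma{i}"], params[f"bn_beta{i}"],
                           bn_state, f"bn{i}", training,
                           update_running=update_running, labels=labels)
        h = relu(h)
    y = relu(matmul(h, params["w_lsn"]) + params["b_lsn"])
    row = tsum(y, axis=1, keepdims=True)
    return y * (spec.phi / (row + LSN_EPS))


def critic_features(spec: CriticSpec, params, x) -> Tensor:
    x = ad.as_tensor(x)
    if x.shape[1] != spec.n_genes:
        raise ParameterError(
            f"expression batch has {x.shape[1]} columns, "
            f"expected {spec.n_genes}")
    h = x
    for i in range(len(spec.hidden_sizes)):
        h = relu(matmul(h, params[f"w{i}"]) + params[f"b{i}"])
    return h


def init_critic_params(spec: CriticSpec, rng: np.random.Generator,
                       n_classes: int | None = None,
                       class_bias: bool = True):
    params, sizes = {}, [spec.n_genes, *spec.hidden_sizes]
    for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"w{i}"], params[f"b{i}"] = he_linear(rng, fi, fo)
    params["w_head"], params["b_head"] = he_linear(rng, sizes[-1], 1)
    if n_classes is not None:
        params["proj"] = np.zeros((n_classes, sizes[-1]))
        if class_bias:
            params["proj_bias"] = np.zeros(n_classes)
    return params


def critic_forward(spec: CriticSpec, params, x) -> Tensor:
    """Unbounded real score per cell (no output activation)."""
    h = critic_features(spec, params, x)
    s = matmul(h, params["w_head"]) + params["b_head"]
    return ad.reshape(s, (s.shape[0],))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def generator_loss(fake_scores) -> Tensor:
    """-E[f_c(f_g(z))]; the generator maximizes its scores."""
    fake_scores = ad.as_tensor(fake_scores)
    if fake_scores.data.size == 0:
        raise ParameterError("empty score batch")
    return ad.neg(tmean(fake_scores))


def critic_loss(real_scores, fake_scores, gp, gp_lambda: float) -> Tensor:
    """-(E[real] - E[fake]) + lambda * gp, minimized by the critic."""
    real_scores, fake_scores = ad.as_tensor(real_scores), ad.as_tensor(fake_scores)
    return tmean(fake_scores) - tmean(real_scores) + ad.mul(gp_lambda, gp)


def gradient_penalty(spec: CriticSpec, params, x_real: np.ndarray,
                     x_fake: np.ndarray, rng: np.random.Generator,
                     score_fn=None) -> Tensor:
    """Mean over interpolates of (||grad_x f_c(x_hat)||_2 - 1)^2.

    ``score_fn(params, x_tensor)`` overrides the plain critic (used by the
    projection critic); the penalty differentiates through the critic only.
    """
    eps = rng.uniform(size=(x_real.shape[0], 1))
    xhat = Tensor(eps * x_real + (1.0 - eps) * x_fake)
    scores = (score_fn(params, xhat) if score_fn is not None
              else critic_forward(spec, params, xhat))
    (gx,) = grad(tsum(scores), [xhat], create_graph=True)
    norms = power(tsum(power(gx, 2.0), axis=1) + 1e-12, 0.5)
    return tmean(power(norms - 1.0, 2.0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _seed_streams(seed: int):
    """Independent, reproducible RNG streams per randomness source."""
    ss = np.random.SeedSequence(seed)
    names = ("init", "holdout", "data", "latent", "gp", "labels", "monitor")
    return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


def train(data: CountMatrix, gspec: GeneratorSpec, cspec: CriticSpec,
          cfg: TrainConfig, labels=None, n_classes: int | None = None,
          class_bias: bool = True, projection_forward=None,
          label_stream_uniform: bool = False) -> TrainState:
    """Adversarial training loop (shared by the conditional variant).

    Holds out a seeded subset of cells as "real test cells" before training
    and records the monitor metrics (mean-expression distance, sparsity, HVG
    intersection) on them every ``cfg.eval_interval`` generator steps.
    """
    if data.normalized_to is None or not np.isclose(
            data.normalized_to, gspec.phi, rtol=1e-6):
        raise ParameterError(
            "training data must be library-size normalized to phi="
            f"{gspec.phi} (found normalized_to={data.normalized_to})")
    if gspec.n_genes != data.n_genes or cspec.n_genes != data.n_genes:
        raise ParameterError("spec n_genes does not match the data")
    streams = _seed_streams(cfg.seed)

    n = data.n_cells
    holdout_n = max(1, min(cfg.holdout_size, n // 10))
    perm = streams["holdout"].permutation(n)
    holdout_idx, train_idx = perm[:holdout_n], perm[holdout_n:]
    X = np.asarray(data.values[train_idx].todense(), dtype=np.float64)
    holdout = data.subset_cells(holdout_idx)
    y = None if labels is None else np.asarray(labels)[train_idx]
    if n_classes is not None:
        counts = np.bincount(y, minlength=n_classes)
        if (counts == 0).any():
            raise ParameterError(
                f"class(es) with zero training cells: "
                f"{np.flatnonzero(counts == 0).tolist()}")
        freqs = counts / counts.sum()

    gen_params, bn_state = init_generator_params(
        gspec, streams["init"], n_classes)
    critic_params = init_critic_params(
        cspec, streams["init"], n_classes, class_bias)
    trainable_critic = [k for k in critic_params
                        if not (n_classes == 1 and k.startswith("proj"))]
    gen_opt = AMSGrad(cfg.learning_rate, cfg.beta1, cfg.beta2)
    critic_opt = AMSGrad(cfg.learning_rate, cfg.beta1, cfg.beta2)
    state = TrainState(gspec, cspec, cfg, gen_params, bn_state, critic_params,
                       list(data.gene_ids), holdout_indices=holdout_idx,
                       n_classes=n_classes,
                       class_freqs=None if n_classes is None else freqs)

    def draw_labels(size):
        if n_classes is None:
            return None
        if n_classes == 1:
            return np.zeros(size, dtype=np.int64)
        p = None if label_stream_uniform else freqs
        return streams["labels"].choice(n_classes, size=size, p=p)

    def score(params_t, x, lab):
        if projection_forward is not None:
            return projection_forward(cspec, params_t, x, lab)
        return critic_forward(cspec, params_t, x)

    B = min(cfg.batch_size, len(X))
    _record_monitor(state, holdout, streams["monitor"])  # step-0 baseline
    for step in range(cfg.total_steps):
        for _ in range(cfg.critic_iters_per_gen):
            idx = streams["data"].integers(0, len(X), size=B)
            xr = X[idx]
            lab_r = None if y is None else y[idx]
            z = sample_latent(B, gspec.latent_dim, streams["latent"])
            lab_f = draw_labels(B)
            xf = generator_forward(gspec, gen_params, z, training=True,
                                   bn_state=bn_state, labels=lab_f).data
            pt = wrap_params(critic_params)
            sr = score(pt, Tensor(xr), lab_r)
            sf = score(pt, Tensor(xf), lab_f)
            # interpolate labels follow the fake batch (both label sets are
            # draws from the same empirical mixture)
            gp = gradient_penalty(
                cspec, pt, xr, xf, streams["gp"],
                score_fn=None if projection_forward is None
                else (lambda p, x: projection_forward(cspec, p, x, lab_f)))
            loss = critic_loss(sr, sf, gp, cfg.gp_lambda)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"critic loss non-finite at generator step {step}",
                    state=state)
            gs = grad(loss, [pt[k] for k in trainable_critic])
            critic_opt.step(critic_params,
                            {k: g.data for k, g in zip(trainable_critic, gs)})
            state.critic_steps += 1

        z = sample_latent(B, gspec.latent_dim, streams["latent"])
        lab_f = draw_labels(B)
        gt = wrap_params(gen_params)
        xf = generator_forward(gspec, gt, z, training=True, bn_state=bn_state,
                               labels=lab_f, update_running=True)
        sf = score(wrap_params(critic_params), xf, lab_f)
        loss = generator_loss(sf)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(
                f"generator loss non-finite at step {step}", state=state)
        names = list(gt)
        gs = grad(loss, [gt[k] for k in names])
        gen_opt.step(gen_params, {k: g.data for k, g in zip(names, gs)})
        state.gen_steps += 1

        if (step + 1) % cfg.eval_interval == 0 or step + 1 == cfg.total_steps:
            _record_monitor(state, holdout, streams["monitor"])
    return state


def _record_monitor(state: TrainState, holdout: CountMatrix,
                    rng: np.random.Generator):
    from .evaluate import training_monitors

    n = min(state.cfg.monitor_sample, holdout.n_cells)
    fake = _generate_array(state, n, rng)
    gen = CountMatrix(sp.csr_matrix(fake), state.gene_ids,
                      [f"monitor_{i}" for i in range(n)],
                      state.gspec.phi)
    mon = training_monitors(
        holdout, gen, n_hvg=min(state.cfg.monitor_n_hvg, len(state.gene_ids)))
    mon["step"] = state.gen_steps
    state.monitors.append(mon)


def _generate_array(state: TrainState, n: int, rng, labels=None,
                    batch: int = 512) -> np.ndarray:
    if labels is None and state.n_classes is not None:
        # one class needs no draw (keeps RNG use identical to the
        # unconditional path, so degenerate conditioning matches exactly)
        labels = (np.zeros(n, dtype=np.int64) if state.n_classes == 1 else
                  rng.choice(state.n_classes, size=n, p=state.class_freqs))
    out = np.empty((n, len(state.gene_ids)))
    for start in range(0, n, batch):
        stop = min(start + batch, n)
        z = sample_latent(stop - start, state.gspec.latent_dim, rng)
        lab = None if labels is None else labels[start:stop]
        out[start:stop] = generator_forward(
            state.gspec, state.gen_params, z, training=False,
            bn_state=state.gen_bn_state, labels=lab).data
    return out


def generate(state: TrainState, n: int, seed: int = 0) -> CountMatrix:
    """Sample ``n`` cells from a trained model (inference-mode BN stats)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vals = _generate_array(state, n, rng)
    return CountMatrix(sp.csr_matrix(vals), state.gene_ids,
                       [f"gen_{i}" for i in range(n)], state.gspec.phi)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(state: TrainState, path):
    """Single-file archive: parameter arrays plus a JSON header."""
    header = {
        "schema": CHECKPOINT_SCHEMA,
        "gspec": asdict(state.gspec),
        "cspec": asdict(state.cspec),
        "cfg": asdict(state.cfg),
        "gene_ids": state.gene_ids,
        "gen_steps": state.gen_steps,
        "critic_steps": state.critic_steps,
        "monitors": state.monitors,
        "n_classes": state.n_classes,
    }
    arrays = {f"gen.{k}": v for k, v in state.gen_params.items()}
    arrays |= {f"bn.{k}": v for k, v in state.gen_bn_state.items()}
    arrays |= {f"critic.{k}": v for k, v in state.critic_params.items()}
    if state.class_freqs is not None:
        arrays["class_freqs"] = state.class_freqs
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path) -> TrainState:
    with np.load(path) as f:
        header = json.loads(bytes(f["__header__"]).decode())
        if header.get("schema") != CHECKPOINT_SCHEMA:
            raise ParameterError(
                f"unsupported checkpoint schema: {header.get('schema')}")
        gdict = {**header["gspec"],
                 "hidden_sizes": tuple(header["gspec"]["hidden_sizes"])}
        cdict = {**header["cspec"],
                 "hidden_sizes": tuple(header["cspec"]["hidden_sizes"])}
        if "n_classes" in gdict:
            from .conditional import (ConditionalGeneratorSpec,
                                      ProjectionCriticSpec)

            gspec = ConditionalGeneratorSpec(**gdict)
            cspec = ProjectionCriticSpec(**cdict)
        else:
            gspec = GeneratorSpec(**gdict)
            cspec = CriticSpec(**cdict)
        cfg = TrainConfig(**header["cfg"])
        gen, bn, critic = {}, {}, {}
        freqs = None
        for k in f.files:
            if k.startswith("gen."):
                gen[k[4:]] = f[k]
            elif k.startswith("bn."):
                bn[k[3:]] = f[k]
            elif k.startswith("critic."):
                critic[k[7:]] = f[k]
            elif k == "class_freqs":
                freqs = f[k]
    return TrainState(gspec, cspec, cfg, gen, bn, critic, header["gene_ids"],
                      header["gen_steps"], header["critic_steps"],
                      header["monitors"], None, header["n_classes"], freqs)


# ---------------------------------------------------------------------------
# diagnostic: 1-D Wasserstein recovery
# ---------------------------------------------------------------------------

def estimate_wasserstein_1d(real: np.ndarray, fake: np.ndarray,
                            steps: int = 1200, hidden=(32, 32),
                            lr: float = 1e-3, gp_lambda: float = 100.0,
                            seed: int = 0) -> float:
    """Train only a critic on two fixed 1-D samples and return the converged
    critic objective E[f(real)] - E[f(fake)], an estimate of W1.

    The penalized optimum overshoots by d^2/(2 lambda) for point masses at
    distance d (the critic settles at slope 1 + d/(2 lambda)), so this
    diagnostic defaults to a stiffer penalty than the training loop uses.
    """
    real = np.asarray(real, dtype=np.float64).reshape(-1, 1)
    fake = np.asarray(fake, dtype=np.float64).reshape(-1, 1)
    spec = CriticSpec(n_genes=1, hidden_sizes=tuple(hidden))
    streams = _seed_streams(seed)
    params = init_critic_params(spec, streams["init"])
    opt = AMSGrad(lr, 0.5, 0.9)
    est = 0.0
    for _ in range(steps):
        pt = wrap_params(params)
        sr = critic_forward(spec, pt, Tensor(real))
        sf = critic_forward(spec, pt, Tensor(fake))
        gp = gradient_penalty(spec, pt, real, fake, streams["gp"])
        loss = critic_loss(sr, sf, gp, gp_lambda)
        names = list(pt)
        gs = grad(loss, [pt[k] for k in names])
        opt.step(params, {k: g.data for k, g in zip(names, gs)})
        est = float(sr.data.mean() - sf.data.mean())
    return est
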