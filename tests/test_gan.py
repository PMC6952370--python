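import numpy as np
import pytest

from cellgan import autodiff as ad
from cellgan.autodiff import Tensor, grad
from cellgan.errors import ParameterError
from cellgan.gan import (CriticSpec, GeneratorSpec, TrainConfig,
                         critic_forward, critic_loss, generate,
                         generator_forward, generator_loss, gradient_penalty,
                         init_critic_params, init_generator_params,
                         load_checkpoint, sample_latent, save_checkpoint,
                         train)

RNG = np.random.default_rng(0)


def tiny_specs(n_genes=30):
    return (GeneratorSpec(n_genes=n_genes, latent_dim=8, hidden_sizes=(16,)),
            CriticSpec(n_genes=n_genes, hidden_sizes=(16,)))


# ---------------------------------------------------------------------------
# latent sampling
# ---------------------------------------------------------------------------

def test_latent_moments_and_independence():
    z = sample_latent(10000, 32, seed=0)
    assert np.all(np.abs(z.mean(axis=0)) < 0.05)
    assert np.all((z.var(axis=0) > 0.93) & (z.var(axis=0) < 1.07))
    corr = np.corrcoef(z, rowvar=False)
    off = corr[~np.eye(32, dtype=bool)]
    assert np.all(np.abs(off) <= 0.05)


def test_latent_seeded_and_validated():
    assert np.array_equal(sample_latent(5, 3, seed=1),
                          sample_latent(5, 3, seed=1))
    with pytest.raises(ParameterError):
        sample_latent(0, 3, seed=1)


# ---------------------------------------------------------------------------
# generator forward / LSN layer
# ---------------------------------------------------------------------------

def test_lsn_row_sums_and_nonnegativity():
    gspec, _ = tiny_specs()
    params, bn = init_generator_params(gspec, np.random.default_rng(1))
    z = sample_latent(40, 8, seed=2)
    out = generator_forward(gspec, params, z, training=True, bn_state=bn)
    sums = out.data.sum(axis=1)
    assert np.all(np.abs(sums - gspec.phi) / gspec.phi <= 1e-5)
    assert np.all(out.data >= 0)


def test_lsn_scale_invariance():
    """Doubling the LSN affine map leaves the output unchanged (the rescale
    cancels any positive scaling)."""
    gspec, _ = tiny_specs()
    params, bn = init_generator_params(gspec, np.random.default_rng(1))
    z = sample_latent(10, 8, seed=3)
    base = generator_forward(gspec, params, z, bn_state=dict(bn)).data
    doubled = dict(params)
    doubled["w_lsn"] = 2.0 * params["w_lsn"]
    doubled["b_lsn"] = 2.0 * params["b_lsn"]
    out = generator_forward(gspec, doubled, z, bn_state=dict(bn)).data
    assert np.allclose(out, base, rtol=1e-9)


def test_generator_rejects_wrong_latent_width():
    gspec, _ = tiny_specs()
    params, bn = init_generator_params(gspec, np.random.default_rng(1))
    with pytest.raises(ParameterError):
        generator_forward(gspec, params, np.zeros((4, 5)), bn_state=bn)


# ---------------------------------------------------------------------------
# critic forward
# ---------------------------------------------------------------------------

def test_critic_shapes_and_zero_weight_bias():
    _, cspec = tiny_specs()
    params = init_critic_params(cspec, np.random.default_rng(2))
    x = RNG.uniform(0, 20000, (12, 30))
    scores = critic_forward(cspec, params, Tensor(x))
    assert scores.shape == (12,)
    assert np.all(np.isfinite(scores.data))
    zeroed = {k: np.zeros_like(v) for k, v in params.items()}
    zeroed["b_head"] = np.array([3.5])
    s = critic_forward(cspec, zeroed, Tensor(x))
    assert np.allclose(s.data, 3.5)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_critic_loss_zero_when_scores_match():
    s = np.array([1.0, -2.0, 0.5])
    assert critic_loss(s, s, 0.0, 10.0).item() == pytest.approx(0.0)


def test_critic_loss_monotone_in_penalty():
    r, f = np.array([1.0, 2.0]), np.array([0.0, 1.0])
    l1 = critic_loss(r, f, 0.3, 10.0).item()
    l2 = critic_loss(r, f, 0.3, 20.0).item()
    assert l2 > l1


def test_gradient_penalty_vanishes_for_unit_norm_linear_critic():
    """f(x) = w.x with ||w||=1 has input gradient exactly w everywhere, so
    the penalty is 0 regardless of the interpolates."""
    cspec = CriticSpec(n_genes=5, hidden_sizes=(5,))
    w1 = np.eye(5)  # identity + all-positive inputs keeps ReLU transparent
    w = RNG.standard_normal(5)
    w /= np.linalg.norm(w)
    params = {"w0": w1, "b0": np.zeros(5), "w_head": w.reshape(5, 1),
              "b_head": np.zeros(1)}
    xr = RNG.uniform(1, 2, (20, 5))
    xf = RNG.uniform(1, 2, (20, 5))
    pt = {k: Tensor(v) for k, v in params.items()}
    gp = gradient_penalty(cspec, pt, xr, xf, np.random.default_rng(0))
    assert gp.item() == pytest.approx(0.0, abs=1e-10)


def test_generator_loss_value_and_gradient():
    scores = Tensor(np.full(4, 2.0))
    loss = generator_loss(scores)
    assert loss.item() == pytest.approx(-2.0)
    assert loss.item() + float(scores.data.mean()) == pytest.approx(0.0)
    (g,) = grad(loss, [scores])
    assert np.allclose(g.data, -0.25)  # -1/batch each


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def small_training_data():
    from conftest import random_count_matrix

    return random_count_matrix(np.random.default_rng(4), 120, 30,
                               density=0.5, normalized_to=20000.0)


def test_alternation_bookkeeping():
    data = small_training_data()
    gspec, cspec = tiny_specs()
    cfg = TrainConfig(total_steps=8, batch_size=16, seed=0, eval_interval=4,
                      monitor_sample=20, monitor_n_hvg=10)
    state = train(data, gspec, cspec, cfg)
    assert state.gen_steps == 8
    assert state.critic_steps == 5 * 8


def test_training_is_seed_deterministic():
    data = small_training_data()
    gspec, cspec = tiny_specs()
    cfg = TrainConfig(total_steps=6, batch_size=16, seed=9, eval_interval=3,
                      monitor_sample=20, monitor_n_hvg=10)
    a = train(data, gspec, cspec, cfg)
    b = train(data, gspec, cspec, cfg)
    assert a.monitors == b.monitors
    for k in a.gen_params:
        assert np.array_equal(a.gen_params[k], b.gen_params[k])


def test_train_rejects_unnormalized_data():
    from conftest import random_count_matrix

    data = random_count_matrix(np.random.default_rng(4), 50, 30, density=0.5)
    gspec, cspec = tiny_specs()
    with pytest.raises(ParameterError, match="normalized"):
        train(data, gspec, cspec, TrainConfig(total_steps=1, seed=0))


def test_generate_contract_and_checkpoint_roundtrip(tmp_path):
    data = small_training_data()
    gspec, cspec = tiny_specs()
    cfg = TrainConfig(total_steps=4, batch_size=16, seed=1, eval_interval=2,
                      monitor_sample=20, monitor_n_hvg=10)
    state = train(data, gspec, cspec, cfg)
    out = generate(state, 25, seed=5)
    assert (out.n_cells, out.n_genes) == (25, 30)
    sums = np.asarray(out.values.sum(axis=1)).ravel()
    assert np.allclose(sums, 20000.0, rtol=1e-5)
    assert np.array_equal(out.to_dense(), generate(state, 25, seed=5).to_dense())
    # not copies of training cells
    train_dense = data.to_dense()
    gen_dense = out.to_dense()
    dmin = min(np.linalg.norm(train_dense - row, axis=1).min()
               for row in gen_dense)
    assert dmin > 0
    # checkpoint round trip
    path = save_checkpoint(state, tmp_path / "ckpt.npz")
    back = load_checkpoint(path)
    assert np.array_equal(generate(back, 10, seed=2).to_dense(),
                          generate(state, 10, seed=2).to_dense())
    with pytest.raises(ParameterError):
        generate(state, 0, seed=1)


def test_wasserstein_estimate_on_point_masses_fast():
    """Desk check of the critic objective on two 1-D point masses (the full
    d in {1,2,5} sweep runs in the acceptance suite)."""
    from cellgan.gan import estimate_wasserstein_1d

    est = estimate_wasserstein_1d(np.full(64, 2.0), np.zeros(64),
                                  steps=400, seed=0)
    assert est == pytest.approx(2.0, rel=0.1)
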