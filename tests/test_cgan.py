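import numpy as np
import pytest

from ganlink.cgan import (
    TrainingConfig,
    build_critic,
    build_generator,
    generate,
    generate_batch,
    gradient_penalty,
    load_generator,
    save_generator,
    train,
)
from ganlink.nn.autograd import Tensor, tmean
from ganlink.representation import SubgraphAdjacency, TrainingPair
from ganlink.sampling import SubgraphSpec

L = 16  # small matrix side keeps the training smoke tests fast


def make_pair(rng, l=L, n_removed=3):
    nodes = tuple(f"n{i:02d}" for i in range(l))
    spec = SubgraphSpec(start=nodes[0], nodes=nodes, layer_sizes=(l - 1,), n_filled=0)
    target = np.zeros((l, l), dtype=np.float32)
    ii = rng.integers(0, l, size=(20, 2))
    for i, j in ii:
        if i != j:
            target[i, j] = target[j, i] = 1.0
    cond = target.copy()
    removed = []
    ones = np.argwhere(np.triu(target))
    rng.shuffle(ones)
    for i, j in ones[:n_removed]:
        cond[i, j] = cond[j, i] = 0.0
        removed.append((i, j))
    return (
        TrainingPair(
            spec=spec,
            condition=SubgraphAdjacency(spec, cond),
            target=SubgraphAdjacency(spec, target),
        ),
        removed,
    )


class TestBuilders:
    def test_generator_shape_range_determinism(self):
        gen1 = build_generator(36, seed=5, base_channels=8)
        gen2 = build_generator(36, seed=5, base_channels=8)
        cond = np.zeros((36, 36), dtype=np.float32)
        out1 = generate(gen1, cond)
        out2 = generate(gen2, cond)
        assert out1.shape == (36, 36)
        assert (0 <= out1).all() and (out1 <= 1).all()
        np.testing.assert_array_equal(out1, out2)

    def test_generator_output_depends_on_condition(self, rng):
        gen = build_generator(L, seed=1, base_channels=8)
        a = generate(gen, np.zeros((L, L), dtype=np.float32))
        cond = np.zeros((L, L), dtype=np.float32)
        cond[0, 1] = cond[1, 0] = 1
        b = generate(gen, cond)
        assert not np.array_equal(a, b)

    def test_generator_too_small_fatal(self):
        with pytest.raises(ValueError):
            build_generator(4, seed=0)

    def test_critic_scalar_and_sensitivity(self, rng):
        critic = build_critic(L, seed=2, base_channels=8)
        cond = Tensor(rng.integers(0, 2, size=(3, 1, L, L)).astype(np.float32))
        cand = Tensor(rng.uniform(size=(3, 1, L, L)).astype(np.float32))
        score = critic(cond, cand)
        assert score.shape == (3, 1)
        cand2 = Tensor(cand.data + 0.5)
        assert not np.array_equal(score.data, critic(cond, cand2).data)

    def test_critic_seeded_reproducibility(self, rng):
        cond = Tensor(rng.uniform(size=(2, 1, L, L)).astype(np.float32))
        cand = Tensor(rng.uniform(size=(2, 1, L, L)).astype(np.float32))
        s1 = build_critic(L, seed=3, base_channels=8)(cond, cand)
        s2 = build_critic(L, seed=3, base_channels=8)(cond, cand)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestGradientPenalty:
    @pytest.fixture
    def matrices(self, rng):
        shape = (4, 1, L, L)
        return (
            rng.normal(size=shape).astype(np.float32),
            rng.normal(size=shape).astype(np.float32),
            np.zeros(shape, dtype=np.float32),
        )

    def test_unit_gradient_critic_zero_penalty(self, matrices):
        real, fake, cond = matrices
        critic = lambda c, x: x.reshape(x.shape[0], -1)[:, 0:1]
        gp = gradient_penalty(critic, real, fake, cond, gp_lambda=10.0, rng=0)
        assert abs(gp.item()) < 1e-5

    def test_norm_two_critic_penalty_equals_lambda(self, matrices):
        """Closed form: gradient norm 2 everywhere gives lambda*(2-1)^2."""
        real, fake, cond = matrices
        critic = lambda c, x: 2.0 * x.reshape(x.shape[0], -1)[:, 0:1]
        gp = gradient_penalty(critic, real, fake, cond, gp_lambda=10.0, rng=0)
        assert abs(gp.item() - 10.0) < 1e-5

    def test_penalty_nonnegative_for_random_critics(self, matrices, rng):
        real, fake, cond = matrices
        for seed in range(3):
            critic = build_critic(L, seed=seed, base_channels=8)
            gp = gradient_penalty(critic, real, fake, cond, gp_lambda=10.0, rng=rng)
            assert gp.item() >= 0.0

    def test_shape_mismatch_fatal(self, matrices):
        real, fake, cond = matrices
        critic = build_critic(L, seed=0, base_channels=8)
        with pytest.raises(ValueError):
            gradient_penalty(critic, real, fake[:2], cond, rng=0)


class TestTraining:
    def test_smoke_run_finite_losses(self, rng):
        pairs = [make_pair(rng)[0] for _ in range(8)]
        cfg = TrainingConfig(epochs=1, batch_size=4, critic_steps=2,
                             base_channels=8, seed=0)
        gen = train(pairs, cfg)
        stats = gen.train_stats
        assert np.isfinite(stats["critic_loss"]).all()
        assert np.isfinite(stats["generator_loss"]).all()

    def test_update_ratio_matches_critic_steps(self, rng):
        pairs = [make_pair(rng)[0] for _ in range(6)]
        cfg = TrainingConfig(epochs=2, batch_size=3, critic_steps=5,
                             base_channels=8, seed=0)
        gen = train(pairs, cfg)
        s = gen.train_stats
        assert s["critic_updates"] / s["generator_updates"] == 5

    def test_empty_pairs_fatal(self):
        with pytest.raises(ValueError):
            train([], TrainingConfig())

    def test_overfit_single_pair_reduces_error(self, rng):
        """Training dynamics oracle: on one repeated sample the
        generator's reconstruction error must fall, and held-out edge
        positions must outrank never-edge positions."""
        pair, removed = make_pair(rng, n_removed=2)
        pairs = [pair] * 4
        cfg = TrainingConfig(
            epochs=100, batch_size=4, critic_steps=1, l1_weight=50.0,
            learning_rate=1e-3, base_channels=8, seed=1,
        )
        gen0 = build_generator(L, seed=gen_seed_of(cfg), base_channels=8)
        before = np.abs(
            generate(gen0, pair.condition.matrix) - pair.target.matrix
        ).mean()
        gen = train(pairs, cfg)
        out = generate(gen, pair.condition.matrix)
        after = np.abs(out - pair.target.matrix).mean()
        assert after < before

        held = [out[i, j] for i, j in removed]
        never = out[(pair.target.matrix == 0) & ~np.eye(L, dtype=bool)]
        assert min(held) > never.mean()

    def test_training_reproducible(self, rng):
        pairs = [make_pair(rng)[0] for _ in range(6)]
        cfg = TrainingConfig(epochs=1, batch_size=3, critic_steps=1,
                             base_channels=8, seed=9)
        probe = rng.integers(0, 2, size=(5, L, L)).astype(np.float32)
        out1 = generate_batch(train(pairs, cfg), probe)
        out2 = generate_batch(train(pairs, cfg), probe)
        np.testing.assert_allclose(out1, out2, atol=1e-6)

    def test_generator_loss_is_minus_critic_score(self, rng):
        """With no L1 term the generator objective equals minus the
        mean critic score of its fakes."""
        pairs = [make_pair(rng)[0] for _ in range(4)]
        cfg = TrainingConfig(epochs=1, batch_size=4, critic_steps=1,
                             base_channels=8, seed=2)
        gen = train(pairs, cfg)
        critic = build_critic(L, seed=3, base_channels=8)
        conds = Tensor(np.stack([p.condition.matrix for p in pairs])[:, None])
        fakes = gen(conds)
        loss = -tmean(critic(conds, fakes))
        np.testing.assert_allclose(
            loss.item(), -critic(conds, fakes).data.mean(), rtol=1e-6
        )


class TestGenerate:
    def test_repeated_calls_bitwise_identical(self, rng):
        gen = build_generator(L, seed=4, base_channels=8)
        cond = rng.integers(0, 2, size=(L, L)).astype(np.float32)
        np.testing.assert_array_equal(generate(gen, cond), generate(gen, cond))

    def test_output_range_many_conditions(self, rng):
        gen = build_generator(L, seed=4, base_channels=8)
        conds = rng.integers(0, 2, size=(200, L, L)).astype(np.float32)
        outs = generate_batch(gen, conds)
        assert (outs >= 0).all() and (outs <= 1).all()

    def test_wrong_shape_fatal(self, rng):
        gen = build_generator(L, seed=4, base_channels=8)
        with pytest.raises(ValueError):
            generate(gen, np.zeros((L, L + 1)))
        with pytest.raises(ValueError):
            generate(gen, np.full((L, L), 0.5))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        gen = build_generator(L, seed=6, base_channels=8)
        cond = rng.integers(0, 2, size=(L, L)).astype(np.float32)
        path = tmp_path / "gen.npz"
        save_generator(gen, path, TrainingConfig())
        back = load_generator(path)
        np.testing.assert_array_equal(generate(gen, cond), generate(back, cond))


def gen_seed_of(cfg: TrainingConfig) -> int:
    """The generator-init seed that train() derives from the config."""
    ss = np.random.SeedSequence(cfg.seed)
    return int(ss.generate_state(4)[0] >> 1)
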