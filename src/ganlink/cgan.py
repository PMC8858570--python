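"""Conditional Wasserstein GAN with gradient penalty for adjacency translation.

The generator is a small U-Net: strided convolutions encode the l-by-l
condition matrix into progressively smaller feature maps, transposed
convolutions decode them back, and mirror-depth encoder activations are
concatenated into the decoder (skip connections) so fine structure of
the input survives the bottleneck.  There is no noise input: the model
is a deterministic map from a sparser adjacency matrix to a confidence
matrix for the denser level.

The critic scores (condition, candidate) pairs with an unbounded real
number; it is trained to maximize the score gap between real targets
and generated candidates while a gradient penalty keeps it close to
1-Lipschitz.  The critic contains no batch normalization, which would
couple samples and break the per-sample penalty.

Defaults mirror the published training recipe: Adam(lr=2e-4, beta1=0.9,
beta2=0.99), 3 epochs, 5 critic updates per generator update, batch
size 64, penalty coefficient 10.  An optional L1 reconstruction term
(off by default) can be added to the generator loss in the pix2pix
style.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn.autograd import (
    Tensor,
    concat,
    grad,
    leaky_relu,
    relu,
    sigmoid,
    sqrt,
    tabs,
    tmean,
    tsum,
)
from .nn.layers import (
    Parameter,
    conv2d,
    conv_transpose2d,
    crop_square,
    init_normal,
    init_zeros,
    linear,
    pad_square,
)
from .nn.optim import Adam
from .representation import TrainingPair, stack_conditions, stack_targets


@dataclass
class TrainingConfig:
    learning_rate: float = 2e-4
    beta_1: float = 0.9
    beta_2: float = 0.99
    epochs: int = 3
    critic_steps: int = 5
    batch_size: int = 64
    gp_lambda: float = 10.0
    l1_weight: float = 0.0
    l1_balanced: bool = True
    base_channels: int = 64
    seed: int = 0

    def __post_init__(self):
        positives = dict(
            learning_rate=self.learning_rate,
            beta_1=self.beta_1,
            beta_2=self.beta_2,
            epochs=self.epochs,
            critic_steps=self.critic_steps,
            batch_size=self.batch_size,
            base_channels=self.base_channels,
        )
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.gp_lambda < 0 or self.l1_weight < 0:
            raise ValueError("gp_lambda and l1_weight must be >= 0")


def _padded_side(l: int) -> int:
    # three stride-2 stages need a multiple of 8
    return ((l + 7) // 8) * 8


class GeneratorModel:
    """U-Net mapping an l-by-l condition to an l-by-l confidence matrix."""

    def __init__(self, l: int, seed: int, base_channels: int = 64):
        if l < 8:
            raise ValueError(f"matrix side l={l} too small for 3 encoder stages")
        self.l = l
        self.base_channels = base_channels
        self.side = _padded_side(l)
        c = base_channels
        rng = np.random.default_rng(seed)
        k = (4, 4)
        self.params: dict[str, Parameter] = {
            "e1_w": init_normal(rng, (c, 1) + k),
            "e1_b": init_zeros((c,)),
            "e2_w": init_normal(rng, (2 * c, c) + k),
            "e2_b": init_zeros((2 * c,)),
            "e3_w": init_normal(rng, (4 * c, 2 * c) + k),
            "e3_b": init_zeros((4 * c,)),
            "d3_w": init_normal(rng, (4 * c, 2 * c) + k),
            "d3_b": init_zeros((2 * c,)),
            "d2_w": init_normal(rng, (4 * c, c) + k),
            "d2_b": init_zeros((c,)),
            "d1_w": init_normal(rng, (2 * c, 1) + k),
            "d1_b": init_zeros((1,)),
        }

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, l, l) -> (N, 1, l, l) in [0, 1]."""
        p = self.params
        x = pad_square(x, self.side)
        a1 = leaky_relu(conv2d(x, p["e1_w"], p["e1_b"]))
        a2 = leaky_relu(conv2d(a1, p["e2_w"], p["e2_b"]))
        a3 = leaky_relu(conv2d(a2, p["e3_w"], p["e3_b"]))
        d3 = relu(conv_transpose2d(a3, p["d3_w"], p["d3_b"]))
        d3 = concat([d3, a2], axis=1)
        d2 = relu(conv_transpose2d(d3, p["d2_w"], p["d2_b"]))
        d2 = concat([d2, a1], axis=1)
        out = sigmoid(conv_transpose2d(d2, p["d1_w"], p["d1_b"]))
        return crop_square(out, self.l)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class CriticModel:
    """Convolutional Wasserstein critic over (condition, candidate) pairs.

    Ends in one linear unit with no squashing activation and uses no
    batch normalization.
    """

    def __init__(self, l: int, seed: int, base_channels: int = 64):
        if l < 8:
            raise ValueError(f"matrix side l={l} too small for 3 conv stages")
        self.l = l
        self.base_channels = base_channels
        self.side = _padded_side(l)
        c = base_channels
        rng = np.random.default_rng(seed)
        k = (4, 4)
        feat = 4 * c * (self.side // 8) ** 2
        self.params: dict[str, Parameter] = {
            "c1_w": init_normal(rng, (c, 2) + k),
            "c1_b": init_zeros((c,)),
            "c2_w": init_normal(rng, (2 * c, c) + k),
            "c2_b": init_zeros((2 * c,)),
            "c3_w": init_normal(rng, (4 * c, 2 * c) + k),
            "c3_b": init_zeros((4 * c,)),
            "fc_w": init_normal(rng, (feat, 1)),
            "fc_b": init_zeros((1,)),
        }

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    def forward(self, condition: Tensor, candidate: Tensor) -> Tensor:
        """-> (N, 1) unbounded realness scores."""
        p = self.params
        x = concat(
            [pad_square(condition, self.side), pad_square(candidate, self.side)], axis=1
        )
        h = leaky_relu(conv2d(x, p["c1_w"], p["c1_b"]))
        h = leaky_relu(conv2d(h, p["c2_w"], p["c2_b"]))
        h = leaky_relu(conv2d(h, p["c3_w"], p["c3_b"]))
        h = h.reshape(h.shape[0], -1)
        return linear(h, p["fc_w"], p["fc_b"])

    def __call__(self, condition: Tensor, candidate: Tensor) -> Tensor:
        return self.forward(condition, candidate)


def build_generator(l: int, seed: int, base_channels: int = 64) -> GeneratorModel:
    return GeneratorModel(l, seed, base_channels)


def build_critic(l: int, seed: int, base_channels: int = 64) -> CriticModel:
    return CriticModel(l, seed, base_channels)


def gradient_penalty(
    critic,
    real,
    fake,
    condition,
    gp_lambda: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> Tensor:
    """lambda * E[(||grad_xhat D(cond, xhat)||_2 - 1)^2] on random
    interpolates xhat between real and fake candidates.

    The gradient is taken with respect to the candidate input only; the
    condition is held fixed.  One interpolation coefficient is drawn
    uniformly per sample.  Returns a scalar graph tensor so the penalty
    can sit inside the critic loss and be differentiated through.
    """
    real_t = real if isinstance(real, Tensor) else Tensor(np.asarray(real))
    fake_t = fake if isinstance(fake, Tensor) else Tensor(np.asarray(fake))
    cond_t = condition if isinstance(condition, Tensor) else Tensor(np.asarray(condition))
    if real_t.shape != fake_t.shape or real_t.shape != cond_t.shape:
        raise ValueError(
            f"shape mismatch: real {real_t.shape}, fake {fake_t.shape}, "
            f"condition {cond_t.shape}"
        )
    if gp_lambda < 0:
        raise ValueError("gp_lambda must be >= 0")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = real_t.shape[0]
    eps_shape = (n,) + (1,) * (real_t.ndim - 1)
    eps = rng.uniform(size=eps_shape).astype(np.float32)
    interp = Tensor(eps * real_t.data + (1.0 - eps) * fake_t.data)
    score = critic(cond_t.detach(), interp)
    total = tsum(score)
    (g,) = grad(total, [interp])
    sample_axes = tuple(range(1, real_t.ndim))
    norms = sqrt(tsum(g * g, axis=sample_axes) + Tensor(np.asarray(1e-12)))
    return Tensor(np.asarray(gp_lambda)) * tmean((norms - 1.0) ** 2)


def _l1_term(target: Tensor, fake: Tensor, balanced: bool) -> Tensor:
    """Reconstruction term of the generator loss.

    Adjacency targets are overwhelmingly zero; an unweighted pixel
    mean lets the majority class drive the sigmoid output into
    saturation at 0, after which the sparse positive entries see no
    gradient.  The balanced form reweights present-edge pixels by the
    batch zero/one ratio so both classes exert equal total pressure.
    """
    diff = tabs(target - fake)
    if not balanced:
        return tmean(diff)
    t = target.data
    n_pos = float(t.sum())
    n_neg = float(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return tmean(diff)
    w = np.where(t > 0, n_neg / n_pos, 1.0).astype(np.float32)
    weights = Tensor(w)
    return tsum(weights * diff) * Tensor(np.asarray(1.0 / float(w.sum())))


def _check_finite(value: float, what: str, step: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {what} ({value}) at optimizer step {step}")


def train(
    pairs: Sequence[TrainingPair],
    config: TrainingConfig,
    tracker: Sequence[TrainingPair] | None = None,
) -> GeneratorModel:
    """Adversarial training of the generator/critic pair.

    Per batch the critic takes ``config.critic_steps`` optimization
    steps (fresh interpolates each time), then the generator takes one.
    A ``tracker`` validation set, if given, is scored at the end of
    every epoch without influencing training.  Fully seeded and
    deterministic.

    Returns the trained generator; ``generator.train_stats`` holds the
    update counters and loss traces.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    l = pairs[0].spec.l
    ss = np.random.SeedSequence(config.seed)
    s_gen, s_crit, s_batch, s_gp = (int(s) for s in ss.generate_state(4) >> 1)
    generator = build_generator(l, s_gen, config.base_channels)
    critic = build_critic(l, s_crit, config.base_channels)
    opt_g = Adam(
        generator.parameters(), config.learning_rate, config.beta_1, config.beta_2
    )
    opt_c = Adam(critic.parameters(), config.learning_rate, config.beta_1, config.beta_2)
    batch_rng = np.random.default_rng(s_batch)
    gp_rng = np.random.default_rng(s_gp)

    conds = stack_conditions(pairs)
    targets = stack_targets(pairs)
    m = len(pairs)
    bs = min(config.batch_size, m)

    stats = {
        "critic_updates": 0,
        "generator_updates": 0,
        "critic_loss": [],
        "generator_loss": [],
        "validation": [],
    }
    g_params = generator.parameters()
    c_params = critic.parameters()

    for epoch in range(config.epochs):
        order = batch_rng.permutation(m)
        for lo in range(0, m, bs):
            idx = order[lo : lo + bs]
            cond_b = Tensor(conds[idx])
            real_b = Tensor(targets[idx])

            fake_static = generator(cond_b).detach()
            for _ in range(config.critic_steps):
                gp = gradient_penalty(
                    critic, real_b, fake_static, cond_b, config.gp_lambda, gp_rng
                )
                loss_c = (
                    tmean(critic(cond_b, fake_static))
                    - tmean(critic(cond_b, real_b))
                    + gp
                )
                _check_finite(loss_c.item(), "critic loss", opt_c.t)
                opt_c.step(grad(loss_c, c_params))
                stats["critic_updates"] += 1
                stats["critic_loss"].append(loss_c.item())

            fake = generator(cond_b)
            loss_g = -tmean(critic(cond_b, fake))
            if config.l1_weight > 0:
                loss_g = loss_g + Tensor(np.asarray(config.l1_weight)) * _l1_term(
                    real_b, fake, config.l1_balanced
                )
            _check_finite(loss_g.item(), "generator loss", opt_g.t)
            opt_g.step(grad(loss_g, g_params))
            stats["generator_updates"] += 1
            stats["generator_loss"].append(loss_g.item())

        if tracker:
            stats["validation"].append(
                {"epoch": epoch, **_validation_metrics(generator, critic, tracker)}
            )

    generator.train_stats = stats
    return generator


def _validation_metrics(generator, critic, tracker) -> dict:
    cond = Tensor(stack_conditions(tracker))
    target = stack_targets(tracker)
    out = generator(cond)
    mae = float(np.mean(np.abs(out.data - target)))
    score = float(np.mean(critic(cond, out).data))
    return {"mae": mae, "critic_score_fake": score}


def generate(generator: GeneratorModel, condition: np.ndarray) -> np.ndarray:
    """Deterministic confidence matrix for one binary l-by-l condition."""
    condition = np.asarray(condition)
    l = generator.l
    if condition.shape != (l, l):
        raise ValueError(f"condition shape {condition.shape} != ({l}, {l})")
    if not np.isin(condition, (0, 1)).all():
        raise ValueError("condition matrix must be binary")
    out = generator(Tensor(condition[None, None].astype(np.float32)))
    return np.clip(out.data[0, 0], 0.0, 1.0)


def generate_batch(generator: GeneratorModel, conditions: np.ndarray) -> np.ndarray:
    """(M, l, l) conditions -> (M, l, l) confidences in one forward pass."""
    out = generator(Tensor(np.asarray(conditions, dtype=np.float32)[:, None]))
    return np.clip(out.data[:, 0], 0.0, 1.0)


# ---------------------------------------------------------------------------
# checkpoints


def save_generator(generator: GeneratorModel, path: str | Path, config=None) -> None:
    path = Path(path)
    np.savez(path, **{k: p.data for k, p in generator.params.items()})
    meta = {"l": generator.l, "base_channels": generator.base_channels}
    if config is not None:
        meta["training_config"] = asdict(config)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_generator(path: str | Path) -> GeneratorModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    gen = GeneratorModel(meta["l"], seed=0, base_channels=meta["base_channels"])
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        for k in gen.params:
            gen.params[k].data[...] = data[k]
    return gen
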