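"""Deep-convolutional GAN for per-class WBC image synthesis at 128 x 128 x 3.

One generator/discriminator pair is trained per cell class (the models are
unconditional; class identity comes from the training subset).  The game is
the classic minimax value function

    min_G max_D  E_x[log D(x)] + E_z[log(1 - D(G(z)))]

with z drawn from a standard normal.  D maximizes its objective (both
terms); G by default minimizes log(1 - D(G(z))), with the non-saturating
-log D(G(z)) alternative behind a flag.  D's output drives the updates of
both players.

Default architecture (widths are a design choice; the layer counts — six
convolutional layers plus one dense in each network — are fixed):

* D: six stride-2 3x3 same-padded convs 32-64-128-256-512-512 (spatial
  128->64->32->16->8->4->2), LeakyReLU(0.2) + dropout after each, then a
  dense 2048 -> 1 layer and a sigmoid.
* G: dense latent(100) -> 4x4x512, then five stride-2 transposed convs
  512-256-128-64-32 (kernel 4, pad 1; spatial 4->8->16->32->64->128), batch
  norm + ReLU + dropout after each, and a sixth stride-1 transposed conv to
  3 channels with a final sigmoid, so outputs live in [0, 1] for any weights.

Stated training hyperparameters: LeakyReLU alpha 0.2, SGD momentum 0.9,
batch size 1, learning rate 1e-5, dropout 0.6, 10,000 epochs.  A reduced
``debug`` scale (32 x 32, narrow widths) mirrors the architecture for
desk-scale testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset_io import ImageRecord, LabeledDataset, canonical_class
from .models import BuiltModel, ArchitectureSpec, LayerSpec
from .nnops import (BatchNorm, Conv2D, ConvTranspose2D, Dense, Dropout,
                    Flatten, LeakyReLU, ReLU, Reshape, Sequential, Sigmoid,
                    AdamOptimizer, MomentumOptimizer)

__all__ = ["GanConfig", "GanState", "gan_value_terms", "build_generator",
           "build_discriminator", "train_dcgan", "sample_images"]

_CLAMP = 1e-7


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 100
    image_size: int = 128
    base_filters: int = 32  # D's first conv width; doubles per stride-2 layer
    alpha: float = 0.2
    learning_rate: float = 1e-5
    momentum: float = 0.9
    batch_size: int = 1
    dropout_p: float = 0.6
    epochs: int = 10_000
    optimizer: str = "momentum"  # momentum | adam
    non_saturating: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        size = self.image_size
        if size < 8 or size & (size - 1):
            raise ValueError("image_size must be a power of two >= 8")

    @classmethod
    def debug(cls, **overrides) -> "GanConfig":
        """Reduced 32x32 mirror of the architecture for desk-scale tests."""
        defaults = dict(image_size=32, base_filters=8, latent_dim=16,
                        learning_rate=2e-4, optimizer="adam",
                        non_saturating=True, epochs=30)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GanState:
    generator: BuiltModel
    discriminator: BuiltModel
    config: GanConfig
    class_label: str
    step: int = 0
    d_trace: list = None
    g_trace: list = None


def gan_value_terms(d_real: float, d_fake: float,
                    non_saturating: bool = False) -> tuple[float, float]:
    """(d_objective, g_objective) of the minimax value function.

    d_objective = log d_real + log(1 - d_fake), to be maximized by D.
    g_objective = log(1 - d_fake) to be minimized by G (default), or
    -log d_fake with the non-saturating flag.  Probabilities are clamped
    1e-7 away from {0, 1}.
    """
    dr = float(np.clip(d_real, _CLAMP, 1.0 - _CLAMP))
    df = float(np.clip(d_fake, _CLAMP, 1.0 - _CLAMP))
    d_obj = float(np.log(dr) + np.log1p(-df))
    g_obj = float(-np.log(df)) if non_saturating else float(np.log1p(-df))
    return d_obj, g_obj


def _n_doublings(size: int) -> int:
    return int(np.log2(size / 4))  # stride-2 stages between 4x4 and size


def build_generator(config: GanConfig, seed: int | None = None) -> BuiltModel:
    """Latent vector -> image in [0, 1]^(size x size x 3)."""
    seed = config.seed if seed is None else seed
    seeds = iter(np.random.SeedSequence(seed).generate_state(32) & 0x7FFFFFFF)
    n_up = _n_doublings(config.image_size)
    top = config.base_filters * 2 ** (n_up - 1)
    layers = [
        Dense(config.latent_dim, 4 * 4 * top, seed=int(next(seeds))),
        Reshape((4, 4, top)),
        BatchNorm(top), ReLU(), Dropout(config.dropout_p),
    ]
    c = top
    for i in range(n_up):
        cout = max(top // 2 ** i, 3)  # widths top, top/2, ..., base_filters
        layers.append(ConvTranspose2D(c, cout, kernel=4, stride=2, pad=1,
                                      seed=int(next(seeds))))
        layers += [BatchNorm(cout), ReLU(), Dropout(config.dropout_p)]
        c = cout
    # stride-1 transposed conv to RGB keeps the spatial size
    layers.append(ConvTranspose2D(c, 3, kernel=3, stride=1, pad=1,
                                  seed=int(next(seeds))))
    layers.append(Sigmoid())
    spec = ArchitectureSpec((LayerSpec("dense", filters=4 * 4 * top),)
                            + tuple(LayerSpec("conv", kernel=(4, 4), stride=2,
                                              filters=0)
                                    for _ in range(n_up + 1)),
                            input_shape=(1, 1, config.latent_dim),
                            num_classes=1, head="softmax")
    model = BuiltModel(spec, Sequential(layers), input_rank=2)
    return model


def build_discriminator(config: GanConfig, seed: int | None = None) -> BuiltModel:
    """Image -> probability of being real, strictly inside (0, 1)."""
    seed = (config.seed + 1) if seed is None else seed
    seeds = iter(np.random.SeedSequence(seed).generate_state(32) & 0x7FFFFFFF)
    n_down = _n_doublings(config.image_size) + 1  # run down to 2x2
    layers = []
    c = 3
    width = config.base_filters
    top = config.base_filters * 2 ** (_n_doublings(config.image_size) - 1)
    for _ in range(n_down):
        layers.append(Conv2D(c, width, kernel=3, stride=2, padding="same",
                             seed=int(next(seeds))))
        layers += [LeakyReLU(config.alpha), Dropout(config.dropout_p)]
        c = width
        width = min(width * 2, top)
    final_spatial = config.image_size // 2 ** n_down
    layers += [Flatten(),
               Dense(final_spatial * final_spatial * c, 1,
                     seed=int(next(seeds))),
               Sigmoid()]
    spec = ArchitectureSpec(tuple(LayerSpec("conv", kernel=(3, 3), stride=2,
                                            filters=0)
                                  for _ in range(n_down))
                            + (LayerSpec("dense", filters=1),),
                            input_shape=(config.image_size, config.image_size, 3),
                            num_classes=1, head="softmax")
    return BuiltModel(spec, Sequential(layers))


def _bce_real_grad(d_out):
    """d/d(D output) of -log D(x) (maximize log D(x))."""
    p = np.clip(d_out, _CLAMP, 1 - _CLAMP)
    return -1.0 / p


def _bce_fake_grad(d_out):
    """d/d(D output) of -log(1 - D(G(z)))."""
    p = np.clip(d_out, _CLAMP, 1 - _CLAMP)
    return 1.0 / (1.0 - p)


def _make_opt(config: GanConfig):
    if config.optimizer == "adam":
        return AdamOptimizer(lr=config.learning_rate, beta1=0.5)
    return MomentumOptimizer(lr=config.learning_rate, gamma=config.momentum)


def train_dcgan(dataset: LabeledDataset, config: GanConfig,
                generator: BuiltModel | None = None,
                discriminator: BuiltModel | None = None) -> GanState:
    """Train one G/D pair on a single-class dataset of [0,1] images.

    Per batch: one D step on a real batch and a fake batch (the value
    function's two expectation terms), then one G step through the frozen
    D.  Latents are seeded standard normal draws.
    """
    labels = set(dataset.labels())
    if len(labels) != 1:
        raise ValueError(
            f"train_dcgan expects a single-class dataset, got classes {sorted(labels)}")
    (class_label,) = labels
    x = dataset.pixel_stack().astype(np.float32)
    if x.shape[1:] != (config.image_size, config.image_size, 3):
        raise ValueError(
            f"images must be {config.image_size}x{config.image_size}x3, "
            f"got {x.shape[1:]}")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("images must be normalized to [0, 1]")

    G = generator or build_generator(config)
    D = discriminator or build_discriminator(config)
    g_opt, d_opt = _make_opt(config), _make_opt(config)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    latent_rng = np.random.default_rng(ss[0])
    shuffle_rng = np.random.default_rng(ss[1])
    dropout_rng = np.random.default_rng(ss[2])

    state = GanState(G, D, config, class_label, d_trace=[], g_trace=[])
    n = x.shape[0]
    b = config.batch_size
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, b):
            real = x[order[start:start + b]]
            nb = real.shape[0]
            z = latent_rng.standard_normal(
                (nb, config.latent_dim)).astype(np.float32)

            # --- D step: ascend log D(x) + log(1 - D(G(z)))
            fake = G.forward_logits(z, train=True, rng=dropout_rng)
            d_real = D.forward_logits(real, train=True, rng=dropout_rng)
            D.net.backward(_bce_real_grad(d_real) / nb)
            d_grads = {li: {k: g.copy() for k, g in layer.grads.items()}
                       for li, layer in enumerate(D.net.layers) if layer.params}
            d_fake = D.forward_logits(fake, train=True, rng=dropout_rng)
            D.net.backward(_bce_fake_grad(d_fake) / nb)
            for li, saved in d_grads.items():
                for k in saved:
                    D.net.layers[li].grads[k] += saved[k]
            d_opt.step(D.net)

            # --- G step: descend log(1 - D(G(z))) (or ascend log D(G(z)))
            z = latent_rng.standard_normal(
                (nb, config.latent_dim)).astype(np.float32)
            fake = G.forward_logits(z, train=True, rng=dropout_rng)
            d_fake2 = D.forward_logits(fake, train=True, rng=dropout_rng)
            if config.non_saturating:
                dout = _bce_real_grad(d_fake2) / nb  # -log D(fake)
            else:
                dout = -_bce_fake_grad(d_fake2) / nb  # +log(1 - D(fake))
            dfake = D.net.backward(dout)
            G.net.backward(dfake)
            g_opt.step(G.net)

            d_obj, g_obj = gan_value_terms(
                float(d_real.mean()), float(d_fake.mean()),
                non_saturating=config.non_saturating)
            state.d_trace.append(d_obj)
            state.g_trace.append(g_obj)
            state.step += 1
    return state


def sample_images(state: GanState, count: int, seed: int = 0) -> LabeledDataset:
    """Draw ``count`` images from the generator; labeled with the training class."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = state.config
    records = []
    for start in range(0, count, 64):
        nb = min(64, count - start)
        z = rng.standard_normal((nb, cfg.latent_dim)).astype(np.float32)
        imgs = state.generator.forward_logits(z, train=False)
        for j in range(nb):
            records.append(ImageRecord(
                np.asarray(imgs[j], dtype=np.float64),
                label=state.class_label,
                source_path=f"dcgan://{state.class_label}/{seed}/{start + j}"))
    return LabeledDataset(records)
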