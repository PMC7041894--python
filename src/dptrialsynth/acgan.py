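"""Auxiliary-classifier GAN over participant matrices, conditioned on treatment arm.

Two small dense networks compete: the generator maps (noise, arm label) to a
normalized participant matrix, and the discriminator maps a participant
matrix to a real-vs-synthetic source score plus an arm probability — the
auxiliary classification head that distinguishes an AC-GAN from a plain GAN.
Only the discriminator ever touches real data, so only its updates are run
through the clip-and-noise DP-SGD path and only they advance the privacy
ledger; generator updates and sample generation are post-processing.

Private and nonprivate training share one code path: nonprivate training is
the degenerate setting (clip norm = inf, noise multiplier = 0), which makes
the two modes step-for-step identical under a shared seed by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam, bce_with_logits, sigmoid
from .accountant import MomentsLedger, accumulate
from .cohort import Cohort, CohortSchema, DEFAULT_SCHEMA, denormalize, normalize
from .dp_sgd import LotSpec, clip_gradient, noisy_lot_gradient, sample_lot

__all__ = [
    "TrainConfig",
    "GeneratorModel",
    "DiscriminatorModel",
    "Checkpoint",
    "generator_forward",
    "discriminator_forward",
    "acgan_losses",
    "train",
    "generate",
    "discriminator_accuracy",
    "save_checkpoint",
    "load_checkpoint",
]

#: Label-smoothed target for real source labels; keeps the discriminator
#: from saturating early and is standard GAN practice.
REAL_SOURCE_TARGET = 0.9


@dataclass(frozen=True)
class TrainConfig:
    """GAN and DP-SGD hyperparameters for one training run.

    ``noise_multiplier`` and ``clip_norm`` only take effect when
    ``private=True``.  The defaults (lot size 100 on a cohort of 6000, so
    q = 1/60, with sigma = 7) keep the accountant's epsilon at
    delta = 1e-5 close to 3 after 1000 epochs of training.
    """

    latent_dim: int = 100
    lot_size: int = 100
    epochs: int = 1000
    learning_rate: float = 2e-4
    clip_norm: float = 1.0
    noise_multiplier: float = 7.0
    private: bool = False
    seed: int = 0
    checkpoint_every: int = 10
    dense_final: int = 100  # checkpoint every epoch in the last this-many epochs
    hidden: tuple[int, ...] = (128, 128)
    embed_dim: int = 8

    def __post_init__(self) -> None:
        if self.private and self.noise_multiplier <= 0:
            raise ValueError("private=True requires a positive noise multiplier")
        if self.private and not self.clip_norm > 0:
            raise ValueError("private=True requires a positive clip norm")
        if self.lot_size <= 0 or self.latent_dim <= 0:
            raise ValueError("lot_size and latent_dim must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


class GeneratorModel:
    """Maps (z, arm) to a normalized participant matrix in [-1, 1].

    The arm enters through a learned 2-row embedding concatenated to the
    latent vector; the output layer is tanh.
    """

    def __init__(self, latent_dim: int, out_dim: int, hidden: Sequence[int],
                 embed_dim: int, rng: np.random.Generator):
        self.latent_dim = latent_dim
        self.out_dim = out_dim
        self.embed_dim = embed_dim
        self.embedding = rng.normal(0.0, 0.5, (2, embed_dim))
        sizes = [latent_dim + embed_dim, *hidden, out_dim]
        acts = ["relu"] * len(hidden) + ["tanh"]
        self.mlp = MLP(sizes, acts, rng)

    @property
    def n_params(self) -> int:
        return self.embedding.size + self.mlp.n_params

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.embedding.ravel(), self.mlp.get_flat()])

    def set_flat(self, flat: np.ndarray) -> None:
        e = self.embedding.size
        self.embedding = flat[:e].reshape(self.embedding.shape).copy()
        self.mlp.set_flat(flat[e:])

    def copy(self) -> "GeneratorModel":
        clone = object.__new__(GeneratorModel)
        clone.latent_dim, clone.out_dim = self.latent_dim, self.out_dim
        clone.embed_dim = self.embed_dim
        clone.embedding = self.embedding.copy()
        clone.mlp = self.mlp.copy()
        return clone

    def forward(self, z: np.ndarray, arms: np.ndarray, want_cache: bool = False):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        arms = np.asarray(arms, dtype=int)
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent dim {self.latent_dim}, got {z.shape[1]}")
        if arms.shape[0] != z.shape[0]:
            raise ValueError("one arm label per latent vector is required")
        x = np.concatenate([z, self.embedding[arms]], axis=1)
        out = self.mlp.forward(x, want_cache=want_cache)
        return out if not want_cache else out

    def backward(self, cache, arms: np.ndarray, delta_out: np.ndarray) -> np.ndarray:
        """Flat gradient (embedding block first) from the output delta."""
        mlp_grad, delta_in = self.mlp.backward(cache, delta_out)
        d_embed = np.zeros_like(self.embedding)
        np.add.at(d_embed, arms, delta_in[:, self.latent_dim :])
        return np.concatenate([d_embed.ravel(), mlp_grad])


class DiscriminatorModel:
    """Maps a participant matrix to (source logit, arm logit).

    A shared leaky-ReLU trunk feeds a 2-unit linear layer: unit 0 is the
    real-vs-synthetic source score, unit 1 the auxiliary arm classifier.
    """

    def __init__(self, in_dim: int, hidden: Sequence[int], rng: np.random.Generator):
        self.in_dim = in_dim
        sizes = [in_dim, *hidden, 2]
        acts = ["lrelu"] * len(hidden) + ["linear"]
        self.mlp = MLP(sizes, acts, rng)

    @property
    def n_params(self) -> int:
        return self.mlp.n_params

    def get_flat(self) -> np.ndarray:
        return self.mlp.get_flat()

    def set_flat(self, flat: np.ndarray) -> None:
        self.mlp.set_flat(flat)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        return self.mlp.forward(x, want_cache=want_cache)


def generator_forward(z: np.ndarray, arms: np.ndarray, model: GeneratorModel) -> np.ndarray:
    """Generate normalized participant matrices; deterministic given (z, arms, model)."""
    return model.forward(z, arms)


def discriminator_forward(
    x: np.ndarray, model: DiscriminatorModel
) -> tuple[np.ndarray, np.ndarray]:
    """Return (source score, arm probability) per sample."""
    out = model.forward(x)
    return out[:, 0], sigmoid(out[:, 1])


def acgan_losses(
    real_x: np.ndarray,
    real_arms: np.ndarray,
    fake_x: np.ndarray,
    fake_arms: np.ndarray,
    generator: GeneratorModel,
    discriminator: DiscriminatorModel,
) -> tuple[float, float]:
    """Mean AC-GAN losses for reporting.

    Discriminator loss: source cross-entropy (real vs fake) plus arm
    cross-entropy on both real and fake samples.  Generator loss:
    adversarial source loss plus arm cross-entropy on fakes — the generator
    is rewarded for class-consistent fakes.
    """
    out_r = discriminator.forward(real_x)
    out_f = discriminator.forward(fake_x)
    d_loss = float(
        bce_with_logits(out_r[:, 0], np.ones(len(out_r))).mean()
        + bce_with_logits(out_f[:, 0], np.zeros(len(out_f))).mean()
        + bce_with_logits(out_r[:, 1], real_arms).mean()
        + bce_with_logits(out_f[:, 1], fake_arms).mean()
    )
    g_loss = float(
        bce_with_logits(out_f[:, 0], np.ones(len(out_f))).mean()
        + bce_with_logits(out_f[:, 1], fake_arms).mean()
    )
    return d_loss, g_loss


@dataclass(frozen=True)
class Checkpoint:
    """Generator snapshot at an epoch, with the accountant state at that point."""

    epoch: int
    generator: GeneratorModel
    ledger: MomentsLedger
    utility: float | None = None


def _checkpoint_epochs(config: TrainConfig) -> set[int]:
    dense_from = max(1, config.epochs - config.dense_final + 1)
    keep = {e for e in range(1, config.epochs + 1)
            if e >= dense_from or e % config.checkpoint_every == 0}
    if config.epochs > 0:
        keep.add(config.epochs)
    return keep


def train(
    cohort: Cohort, config: TrainConfig, *, return_discriminator: bool = False
) -> tuple:
    """Train the AC-GAN; returns per-epoch checkpoints and the final privacy ledger.

    With ``return_discriminator=True`` the final discriminator is appended
    as a third element (useful for diagnosing whether it settled near
    chance on held-out data).

    Lots are Poisson-sampled at rate q = L/n.  Per discriminator step the
    real-example loss gradients are clipped per participant and noised
    (when private) before averaging; the fake-example term is
    post-processing and is added unnoised.  The ledger advances once per
    discriminator step on real data and never on generator updates.
    """
    n = len(cohort)
    if config.lot_size > n:
        raise ValueError(f"lot_size {config.lot_size} exceeds cohort size {n}")

    X = normalize(cohort)
    arms = cohort.arms.astype(float)
    out_dim = X.shape[1]
    spec = LotSpec(n=n, L=config.lot_size)

    ss = np.random.SeedSequence(config.seed)
    rng_init_g, rng_init_d, rng_lot, rng_noise, rng_latent = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    G = GeneratorModel(config.latent_dim, out_dim, config.hidden, config.embed_dim, rng_init_g)
    D = DiscriminatorModel(out_dim, config.hidden, rng_init_d)
    opt_g = Adam(G.n_params, lr=config.learning_rate)
    opt_d = Adam(D.n_params, lr=config.learning_rate)

    # nonprivate mode is the degenerate DP setting: no clipping, no noise
    C = config.clip_norm if config.private else np.inf
    sigma = config.noise_multiplier if config.private else 0.0
    ledger = (
        MomentsLedger.create(spec.q, sigma)
        if config.private
        else MomentsLedger.nonprivate(spec.q)
    )

    lots_per_epoch = int(np.ceil(n / config.lot_size))
    keep_epochs = _checkpoint_epochs(config)
    checkpoints: list[Checkpoint] = []
    L = config.lot_size

    for epoch in range(1, config.epochs + 1):
        for _ in range(lots_per_epoch):
            # ---- discriminator step (the only real-data access) ----
            idx = sample_lot(spec, rng_lot)
            if idx.size:
                xr, ar = X[idx], arms[idx]
                out, cache = D.forward(xr, want_cache=True)
                delta = np.stack(
                    [
                        sigmoid(out[:, 0]) - REAL_SOURCE_TARGET,
                        sigmoid(out[:, 1]) - ar,
                    ],
                    axis=1,
                )
                per_ex, _ = D.mlp.per_example_backward(cache, delta)
                clipped = np.stack([clip_gradient(g, C) for g in per_ex])
            else:
                clipped = np.zeros((0, D.n_params))
            real_grad = noisy_lot_gradient(clipped, C, sigma, rng_noise, L=L)
            ledger = accumulate(ledger, 1)

            z = rng_latent.standard_normal((L, config.latent_dim))
            af = (rng_latent.random(L) < 0.5).astype(float)
            xf = G.forward(z, af.astype(int))
            out_f, cache_f = D.forward(xf, want_cache=True)
            delta_f = np.stack(
                [sigmoid(out_f[:, 0]) - 0.0, sigmoid(out_f[:, 1]) - af], axis=1
            )
            fake_grad, _ = D.mlp.backward(cache_f, delta_f / L)
            D.set_flat(opt_d.step(D.get_flat(), real_grad + fake_grad))

            # ---- generator step (post-processing; ledger untouched) ----
            z = rng_latent.standard_normal((L, config.latent_dim))
            ag = (rng_latent.random(L) < 0.5).astype(float)
            xg, cache_g = G.forward(z, ag.astype(int), want_cache=True)
            out_g, cache_d = D.forward(xg, want_cache=True)
            delta_g = np.stack(
                [sigmoid(out_g[:, 0]) - 1.0, sigmoid(out_g[:, 1]) - ag], axis=1
            )
            _, delta_x = D.mlp.backward(cache_d, delta_g / L)
            g_grad = G.backward(cache_g, ag.astype(int), delta_x)
            G.set_flat(opt_g.step(G.get_flat(), g_grad))

        if epoch in keep_epochs:
            checkpoints.append(Checkpoint(epoch=epoch, generator=G.copy(), ledger=ledger))

    if return_discriminator:
        return checkpoints, ledger, D
    return checkpoints, ledger


def generate(
    model: GeneratorModel,
    n: int,
    arm_mix: float = 0.5,
    seed: int = 0,
    schema: CohortSchema = DEFAULT_SCHEMA,
) -> Cohort:
    """Sample a denormalized synthetic cohort from a trained generator.

    ``arm_mix`` is the exact fraction of intensive-arm records (deterministic
    split, not a Bernoulli draw).  Generation is post-processing of the
    released model: it never reads or advances the privacy ledger.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= arm_mix <= 1.0:
        raise ValueError("arm_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_intensive = int(round(n * arm_mix))
    arms = np.zeros(n, dtype=int)
    arms[:n_intensive] = 1
    z = rng.standard_normal((n, model.latent_dim))
    matrix = model.forward(z, arms)
    return denormalize(matrix, arms, schema)


def discriminator_accuracy(
    discriminator: DiscriminatorModel, real_x: np.ndarray, fake_x: np.ndarray
) -> float:
    """Source-classification accuracy on a balanced real/fake set (0.5 = fooled)."""
    s_real, _ = discriminator_forward(real_x, discriminator)
    s_fake, _ = discriminator_forward(fake_x, discriminator)
    correct = int((s_real > 0).sum()) + int((s_fake <= 0).sum())
    return correct / (len(s_real) + len(s_fake))


# ---------------------------------------------------------------------------
# Checkpoint serialization


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Write generator parameters (.npz) plus a JSON sidecar with epoch/ledger."""
    path = Path(path)
    G = ckpt.generator
    np.savez(
        path.with_suffix(".npz"),
        flat=G.get_flat(),
        meta=np.array(
            [G.latent_dim, G.out_dim, G.embed_dim, len(G.mlp.sizes)] + list(G.mlp.sizes)
        ),
        activations=np.array(G.mlp.activations),
    )
    sidecar = {
        "epoch": ckpt.epoch,
        "utility": ckpt.utility,
        "ledger": {
            "q": ckpt.ledger.q,
            "sigma": ckpt.ledger.sigma,
            "steps": ckpt.ledger.steps,
            "lambdas": list(ckpt.ledger.lambdas),
            "log_moments": list(ckpt.ledger.log_moments),
            "tracks_moments": ckpt.ledger.tracks_moments,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"), allow_pickle=False)
    meta = data["meta"].astype(int)
    latent_dim, out_dim, embed_dim, n_sizes = meta[:4]
    sizes = meta[4 : 4 + n_sizes]
    hidden = tuple(int(s) for s in sizes[1:-1])
    rng = np.random.default_rng(0)
    G = GeneratorModel(int(latent_dim), int(out_dim), hidden, int(embed_dim), rng)
    G.set_flat(data["flat"])
    sidecar = json.loads(path.with_suffix(".json").read_text())
    led = sidecar["ledger"]
    ledger = MomentsLedger(
        q=led["q"],
        sigma=led["sigma"],
        steps=led["steps"],
        lambdas=tuple(led["lambdas"]),
        log_moments=tuple(led["log_moments"]),
        tracks_moments=led["tracks_moments"],
    )
    return Checkpoint(
        epoch=sidecar["epoch"], generator=G, ledger=ledger, utility=sidecar["utility"]
    )
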