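"""Conditional generative backends for pseudo-healthy synthesis.

Every backend satisfies one contract: ``train`` on healthy (conditioning,
target) pairs, then ``synthesize`` a healthy target slice from a conditioning
image.  The anomaly-detection framework downstream treats the generator as a
black box, so three implementations are interchangeable:

* :class:`CGANBackend` — Pix2Pix-style conditional GAN: a U-Net generator
  with tanh output trained against a patch-based discriminator, with an L1
  reconstruction term (weight ``lambda_l1``) added to the non-saturating
  adversarial loss to curb blurring.
* :class:`DiffusionBackend` — conditional denoising diffusion: a noise model
  eps_theta(x_t, c, t) trained with an L2 noise-prediction loss under a
  quadratic beta schedule; the undisturbed conditioning image c is
  concatenated at every forward and reverse step.
* :class:`OracleBackend` — a perfect generator that returns the phantom's
  known healthy target slice; isolates the postprocessing/threshold pipeline
  from generator quality in framework tests.

The quadratic schedule follows the square-of-linearly-spaced-square-roots
convention: beta_t = (sqrt(b1) + (t-1)/(T-1) * (sqrt(bT) - sqrt(b1)))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from ._nn import Adam, PatchDiscriminator, SmallUNet
from .tasks import ConditioningPair, TaskKind, build_pair

__all__ = [
    "GeneratorBackend",
    "CGANConfig",
    "DiffusionConfig",
    "NoiseSchedule",
    "quadratic_schedule",
    "cgan_generator_loss",
    "cgan_discriminator_loss",
    "diffusion_forward",
    "diffusion_reverse_step",
    "diffusion_train_step",
    "diffusion_sample",
    "CGANBackend",
    "DiffusionBackend",
    "OracleBackend",
    "oracle_synthesize",
]

_P_CLIP = 1e-7  # probability clip inside log-losses


class GeneratorBackend(Protocol):
    def train(self, pairs: Sequence[ConditioningPair], seed: int) -> None: ...

    def synthesize(self, pair: ConditioningPair) -> np.ndarray: ...


# --------------------------------------------------------------------------
# cGAN


@dataclass
class CGANConfig:
    """Desk-scale defaults; ``full_scale_preset`` carries the originally
    reported GPU-scale values (batch 36, learning rate 5e-4, zero init).
    Zero initialisation leaves a conv net at a symmetric
    saddle and is kept only as a documented option; the default is He-style
    ("standard")."""

    base_channels: int = 16
    disc_layers: int = 3
    lambda_l1: float = 100.0
    batch_size: int = 4
    learning_rate: float = 5e-4
    init: str = "standard"  # "standard" (He) or "zeros"
    steps: int = 200
    out_range: tuple[float, float] = (-1.0, 1.0)

    @classmethod
    def full_scale_preset(cls) -> "CGANConfig":
        return cls(batch_size=36, learning_rate=5e-4, init="zeros", steps=10_000)


def cgan_generator_loss(
    d_out_on_fake: np.ndarray,
    x: np.ndarray,
    x_hat: np.ndarray,
    lambda_l1: float = 100.0,
) -> float:
    """Non-saturating adversarial term plus weighted mean absolute error."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs x_hat {x_hat.shape}")
    p = np.clip(np.asarray(d_out_on_fake, dtype=np.float64), _P_CLIP, 1.0 - _P_CLIP)
    adv = -float(np.mean(np.log(p)))
    l1 = float(np.mean(np.abs(np.asarray(x, dtype=np.float64) - x_hat)))
    return adv + lambda_l1 * l1


def cgan_discriminator_loss(d_out_real: np.ndarray, d_out_fake: np.ndarray) -> float:
    """Binary cross-entropy: -E[log D(real)] - E[log(1 - D(fake))]."""
    pr = np.clip(np.asarray(d_out_real, dtype=np.float64), _P_CLIP, 1.0 - _P_CLIP)
    pf = np.clip(np.asarray(d_out_fake, dtype=np.float64), _P_CLIP, 1.0 - _P_CLIP)
    return -float(np.mean(np.log(pr))) - float(np.mean(np.log(1.0 - pf)))


def _stack_batch(pairs: Sequence[ConditioningPair]) -> tuple[np.ndarray, np.ndarray]:
    c = np.stack([p.conditioning for p in pairs])[:, None]
    x = np.stack([p.target for p in pairs])[:, None]
    return c, x


class CGANBackend:
    def __init__(self, config: CGANConfig | None = None):
        self.config = config or CGANConfig()
        self.generator: SmallUNet | None = None
        self.discriminator: PatchDiscriminator | None = None
        self.loss_history: list[dict[str, float]] = []

    def _build(self, seed: int) -> None:
        cfg = self.config
        init = "he" if cfg.init == "standard" else cfg.init
        rng = np.random.default_rng(seed)
        self.generator = SmallUNet(1, 1, base=cfg.base_channels, final="tanh",
                                   init=init, rng=rng)
        self.discriminator = PatchDiscriminator(2, base=cfg.base_channels,
                                                n_layers=cfg.disc_layers,
                                                init=init, rng=rng)

    def train(self, pairs: Sequence[ConditioningPair], seed: int) -> None:
        cfg = self.config
        self._build(seed)
        rng = np.random.default_rng(seed + 1)
        g, d = self.generator, self.discriminator
        opt_g = Adam(g.params(), lr=cfg.learning_rate, beta1=0.5)
        opt_d = Adam(d.params(), lr=cfg.learning_rate, beta1=0.5)
        n = len(pairs)
        for _ in range(cfg.steps):
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            c, x = _stack_batch([pairs[i] for i in idx])
            x_hat = g.forward(c)

            # discriminator update (generator output detached)
            opt_d.zero_grad()
            p_real = d.forward(np.concatenate([x, c], axis=1))
            dp_real = -1.0 / (np.clip(p_real, _P_CLIP, 1 - _P_CLIP) * p_real.size)
            d.backward(dp_real)
            p_fake = d.forward(np.concatenate([x_hat, c], axis=1))
            dp_fake = 1.0 / (np.clip(1.0 - p_fake, _P_CLIP, 1 - _P_CLIP) * p_fake.size)
            d.backward(dp_fake)
            d_loss = cgan_discriminator_loss(p_real, p_fake)
            opt_d.step()

            # generator update: non-saturating adversarial + L1
            opt_g.zero_grad()
            p_fake_g = d.forward(np.concatenate([x_hat, c], axis=1))
            dp = -1.0 / (np.clip(p_fake_g, _P_CLIP, 1 - _P_CLIP) * p_fake_g.size)
            for prm in d.params():  # D is frozen during the G step
                prm.grad[...] = 0.0
            d_input_grad = d.backward(dp)
            for prm in d.params():
                prm.grad[...] = 0.0
            dx_hat = d_input_grad[:, :1] + cfg.lambda_l1 * np.sign(x_hat - x) / x.size
            g_loss = cgan_generator_loss(p_fake_g, x, x_hat, cfg.lambda_l1)
            g.backward(dx_hat)
            opt_g.step()
            self.loss_history.append({"d_loss": d_loss, "g_loss": g_loss})

    def synthesize(self, pair: ConditioningPair) -> np.ndarray:
        if self.generator is None:
            raise RuntimeError("backend is untrained: call train() first")
        out = self.generator.forward(pair.conditioning[None, None].astype(np.float64))
        return np.clip(out[0, 0], *self.config.out_range)

    def held_out_l1(self, pairs: Sequence[ConditioningPair]) -> float:
        """Mean absolute reconstruction error over held-out pairs."""
        if self.generator is None:
            raise RuntimeError("backend is untrained: call train() first")
        errs = [float(np.mean(np.abs(self.synthesize(p) - p.target))) for p in pairs]
        return float(np.mean(errs))


# --------------------------------------------------------------------------
# conditional diffusion


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noise rates; ``alpha_bars[t-1]`` is the cumulative product
    for 1-indexed timestep t and must be strictly decreasing."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=np.float64)
        if b.ndim != 1 or len(b) < 1 or not (0 < b[0] <= b[-1] < 1) or np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("betas must be a 1D array with values in (0, 1)")
        object.__setattr__(self, "betas", b)

    @property
    def T(self) -> int:
        return len(self.betas)

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        return np.cumprod(self.alphas)


def quadratic_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 2e-2) -> NoiseSchedule:
    """beta_t as the square of linearly spaced square roots of the endpoints."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if T == 1:
        return NoiseSchedule(np.array([beta_start]))
    roots = np.linspace(np.sqrt(beta_start), np.sqrt(beta_end), T)
    return NoiseSchedule(roots**2)


def diffusion_forward(
    x0: np.ndarray, t: int | np.ndarray, noise: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) noise, for 1-indexed t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.int64))
    if np.any(t_arr < 1) or np.any(t_arr > schedule.T):
        raise ValueError(f"t must lie in [1, {schedule.T}], got {t}")
    abar = schedule.alpha_bars[t_arr - 1]
    if np.isscalar(t) or np.ndim(t) == 0:
        a = float(abar[0])
        return np.sqrt(a) * x0 + np.sqrt(1.0 - a) * noise
    shape = (len(t_arr),) + (1,) * (x0.ndim - 1)
    a = abar.reshape(shape)
    return np.sqrt(a) * x0 + np.sqrt(1.0 - a) * noise


def diffusion_reverse_step(
    x_t: np.ndarray,
    eps_hat: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One ancestral denoising step from x_t to x_{t-1}.

    Uses the x0-parameterised posterior mean; no noise is injected at t = 1,
    so with a noise model that predicts the exact forward noise the final
    step recovers x0 exactly.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t must lie in [1, {schedule.T}], got {t}")
    abar_t = schedule.alpha_bars[t - 1]
    abar_prev = schedule.alpha_bars[t - 2] if t > 1 else 1.0
    beta_t = schedule.betas[t - 1]
    alpha_t = schedule.alphas[t - 1]
    x0_hat = (x_t - np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(abar_t)
    mean = (
        np.sqrt(abar_prev) * beta_t / (1.0 - abar_t) * x0_hat
        + np.sqrt(alpha_t) * (1.0 - abar_prev) / (1.0 - abar_t) * x_t
    )
    if t == 1:
        return mean
    sigma = np.sqrt((1.0 - abar_prev) / (1.0 - abar_t) * beta_t)
    if noise is None:
        noise = np.zeros_like(x_t)
    return mean + sigma * noise


@dataclass
class DiffusionConfig:
    """Desk-scale defaults (T=100, width 16); ``full_scale_preset`` restores
    the originally reported configuration (T=1000, batch 6, lr 1e-4, Kaiming
    init)."""

    timesteps: int = 100
    beta_start: float = 1e-4
    beta_end: float = 2e-2
    base_channels: int = 16
    time_dim: int = 16
    batch_size: int = 6
    learning_rate: float = 1e-4
    init: str = "kaiming"
    steps: int = 200
    sampling_seed: int = 0
    out_range: tuple[float, float] = (-1.0, 1.0)

    @classmethod
    def full_scale_preset(cls) -> "DiffusionConfig":
        return cls(timesteps=1000, batch_size=6, learning_rate=1e-4,
                   init="kaiming", steps=100_000)


@dataclass
class DiffusionState:
    """Trainable state: the conditional noise model eps_theta(x_t, c, t),
    its optimizer, the noise schedule, and the training RNG."""

    model: SmallUNet
    optimizer: Adam
    schedule: NoiseSchedule
    rng: np.random.Generator
    trained_steps: int = 0
    loss_history: list[float] = field(default_factory=list)


def init_diffusion_state(config: DiffusionConfig, seed: int) -> DiffusionState:
    rng = np.random.default_rng(seed)
    model = SmallUNet(
        in_ch=2,  # noisy target concatenated with undisturbed conditioning
        out_ch=1,
        base=config.base_channels,
        final=None,
        time_dim=config.time_dim,
        init="he" if config.init in ("kaiming", "standard") else config.init,
        rng=rng,
    )
    opt = Adam(model.params(), lr=config.learning_rate)
    schedule = quadratic_schedule(config.timesteps, config.beta_start, config.beta_end)
    return DiffusionState(model=model, optimizer=opt, schedule=schedule,
                          rng=np.random.default_rng(seed + 1))


def diffusion_train_step(
    pairs_batch: Sequence[ConditioningPair],
    state: DiffusionState,
    config: DiffusionConfig,
) -> float:
    """One optimizer step of L2 noise-prediction; returns the batch loss."""
    c, x0 = _stack_batch(pairs_batch)
    n = x0.shape[0]
    t = state.rng.integers(1, state.schedule.T + 1, size=n)
    noise = state.rng.standard_normal(x0.shape)
    x_t = diffusion_forward(x0, t, noise, state.schedule)
    inp = np.concatenate([x_t, c], axis=1)
    eps_hat = state.model.forward(inp, t)
    diff = eps_hat - noise
    loss = float(np.mean(diff**2))
    state.optimizer.zero_grad()
    state.model.backward(2.0 * diff / diff.size)
    state.optimizer.step()
    state.trained_steps += 1
    state.loss_history.append(loss)
    return loss


def diffusion_sample(
    c: np.ndarray,
    state: DiffusionState,
    config: DiffusionConfig,
    sampling_seed: int,
) -> np.ndarray:
    """Ancestral sampling from pure noise down to t=1, conditioning on the
    undisturbed c at every step; output clamped to ``config.out_range``."""
    if state.trained_steps == 0:
        raise RuntimeError("diffusion state is untrained: run train steps first")
    rng = np.random.default_rng(sampling_seed)
    x = rng.standard_normal((1, 1) + c.shape)
    c4 = c[None, None].astype(np.float64)
    for t in range(state.schedule.T, 0, -1):
        eps_hat = state.model.forward(np.concatenate([x, c4], axis=1), np.array([t]))
        z = rng.standard_normal(x.shape) if t > 1 else None
        x = diffusion_reverse_step(x, eps_hat, t, state.schedule, noise=z)
    return np.clip(x[0, 0], *config.out_range)


class DiffusionBackend:
    def __init__(self, config: DiffusionConfig | None = None):
        self.config = config or DiffusionConfig()
        self.state: DiffusionState | None = None

    def train(self, pairs: Sequence[ConditioningPair], seed: int) -> None:
        cfg = self.config
        self.state = init_diffusion_state(cfg, seed)
        rng = np.random.default_rng(seed + 2)
        n = len(pairs)
        for _ in range(cfg.steps):
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            diffusion_train_step([pairs[i] for i in idx], self.state, cfg)

    def synthesize(self, pair: ConditioningPair) -> np.ndarray:
        if self.state is None:
            raise RuntimeError("backend is untrained: call train() first")
        return diffusion_sample(
            pair.conditioning.astype(np.float64),
            self.state,
            self.config,
            self.config.sampling_seed,
        )


# --------------------------------------------------------------------------
# oracle


@dataclass
class OracleBackendState:
    """Lookup from (study id, slice index, task) to the known healthy target
    slice, rendered through the same task masking as the real target."""

    lookup: dict[tuple[str, int, TaskKind], np.ndarray]


def oracle_synthesize(
    c: np.ndarray, pair_identity: tuple[str, int, TaskKind], state: OracleBackendState
) -> np.ndarray:
    if pair_identity not in state.lookup:
        raise KeyError(f"oracle has no healthy reference for {pair_identity}")
    out = state.lookup[pair_identity]
    if out.shape != c.shape:
        raise ValueError(f"stored healthy slice shape {out.shape} != conditioning {c.shape}")
    return out.copy()


class OracleBackend:
    """Perfect pseudo-healthy generator backed by the phantom's healthy
    reference volumes (already preprocessed into the target's intensity
    frame); lets the postprocessing pipeline be tested in isolation."""

    def __init__(self, state: OracleBackendState | None = None):
        self.state = state or OracleBackendState(lookup={})

    @classmethod
    def from_studies(cls, studies, task: TaskKind, fill_value: float = -1.0) -> "OracleBackend":
        lookup: dict[tuple[str, int, TaskKind], np.ndarray] = {}
        for study in studies:
            for k in range(study.target.shape[0]):
                pair = build_pair(study, k, task, fill_value, use_healthy_target=True)
                lookup[(study.study_id, k, task)] = pair.target
        return cls(OracleBackendState(lookup=lookup))

    def train(self, pairs: Sequence[ConditioningPair], seed: int) -> None:
        pass  # nothing to learn: the oracle already knows the healthy images

    def synthesize(self, pair: ConditioningPair) -> np.ndarray:
        return oracle_synthesize(
            pair.conditioning, (pair.study_id, pair.slice_index, pair.task), self.state
        )
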