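"""The DDPM core: noise schedule, forward corruption, loss, sampler, U-Net.

The generative model corrupts one-hot nucleotide matrices with Gaussian noise
over T timesteps under a linear variance schedule β_t, and trains a
conditional U-Net ε_θ(X_t, t, epitope) to predict the added noise by MSE.
Ancestral sampling runs the learned reverse chain from pure noise; every
denoiser block is conditioned on a sinusoidal timestep embedding and on a
1024-dimensional epitope embedding projected to the block's channel width.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autograd import Tensor, concat, upsample_nearest
from .nn import Adam, Conv1d, GroupNorm, Linear, Module
from .seq_codec import DEFAULT_L_MAX, one_hot_decode, one_hot_encode
from .epitope_encoder import EMBED_DIM, embed

__all__ = [
    "NoiseSchedule",
    "linear_schedule",
    "forward_sample",
    "step_kernel_sample",
    "sinusoidal_embed",
    "GeneratorConfig",
    "UNet",
    "diffusion_loss",
    "reverse_step",
    "ancestral_sample",
    "EarlyStopping",
    "train_generator",
    "generate_sequences",
    "reconstruct_sequences",
    "save_checkpoint",
    "load_checkpoint",
]


class ScheduleError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Noise schedule and forward process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    """β_t, α_t = 1−β_t, and ᾱ_t = Π_{s≤t} α_s for t = 1..T (index t−1)."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray


def linear_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.1) -> NoiseSchedule:
    """Equally spaced β from beta_start (t=1) to beta_end (t=T)."""
    if T < 1:
        raise ScheduleError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ScheduleError("require 0 < beta_start <= beta_end < 1")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def forward_sample(x0: np.ndarray, t: int | np.ndarray, schedule: NoiseSchedule,
                   eps: np.ndarray) -> np.ndarray:
    """Closed-form corruption X_t = √ᾱ_t·X_0 + √(1−ᾱ_t)·ε."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: {x0.shape} vs {eps.shape}")
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError("t out of range")
    ab = schedule.alpha_bar[t - 1]
    if t.ndim:  # per-sample timestep: broadcast over trailing axes
        ab = ab.reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def step_kernel_sample(x_prev: np.ndarray, t: int, schedule: NoiseSchedule,
                       eps: np.ndarray) -> np.ndarray:
    """One-step kernel X_t = √(1−β_t)·X_{t−1} + √β_t·ε."""
    x_prev = np.asarray(x_prev, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x_prev.shape != eps.shape:
        raise ValueError(f"shape mismatch: {x_prev.shape} vs {eps.shape}")
    if not 1 <= t <= schedule.T:
        raise ValueError("t out of range")
    b = schedule.beta[t - 1]
    return np.sqrt(1.0 - b) * x_prev + np.sqrt(b) * eps


def sinusoidal_embed(t: int | np.ndarray, dim: int) -> np.ndarray:
    """Standard sin/cos positional encoding of the timestep.

    Returns shape (dim,) for scalar t, else (len(t), dim); sines occupy the
    first dim/2 entries and cosines the rest.
    """
    if dim % 2:
        raise ValueError("dim must be even")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    angles = t_arr[:, None] * freqs[None, :]
    out = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


# ---------------------------------------------------------------------------
# Conditional U-Net denoiser
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Hyperparameters of the denoiser and its training loop.

    ``channels`` is the down-sampling ladder; its last entry is the encoder
    bottleneck width (512 by default). Positions halve at each level, so
    len(channels) must keep l_max divisible by 2^(len(channels)-1).
    """

    l_max: int = DEFAULT_L_MAX
    timesteps: int = 10
    beta_start: float = 1e-4
    beta_end: float = 0.1
    channels: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 3
    time_dim: int = 128
    cond_dim: int = EMBED_DIM
    lr: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_delta: float = 0.001
    early_stop_patience: int = 3
    rescale: bool = True  # diffuse {-1,+1} recentred encodings
    sampler_variance: str = "alphabar"  # forward-posterior σ_t², or "beta" (σ_t²=β_t)
    seed: int = 0

    @property
    def bottleneck(self) -> int:
        return self.channels[-1]


def _n_groups(c: int) -> int:
    for g in (8, 4, 2, 1):
        if c % g == 0:
            return g
    return 1


class ResBlock(Module):
    """Two convolutions with group norm and SiLU, residual add, and
    project-and-inject conditioning on (timestep, epitope) after the first
    convolution."""

    def __init__(self, c: int, time_dim: int, cond_dim: int, kernel: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(c, c, kernel, rng)
        self.norm1 = GroupNorm(_n_groups(c), c)
        self.conv2 = Conv1d(c, c, kernel, rng)
        self.norm2 = GroupNorm(_n_groups(c), c)
        self.time_proj = Linear(time_dim, c, rng)
        self.cond_proj = Linear(cond_dim, c, rng)

    def __call__(self, x: Tensor, temb: Tensor, cond: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        h = self.norm1(self.conv1(x))
        bias = self.time_proj(temb) + self.cond_proj(cond)
        h = (h + bias.reshape(n, c, 1)).silu()
        h = self.norm2(self.conv2(h)).silu()
        return x + h


class UNet(Module):
    """Mirrored encoder/decoder over the 72-position axis with skip
    connections, stride-2 down-sampling, nearest-neighbour up-sampling, and
    per-level conditioning. Maps (N, 4, L) noisy inputs to predicted noise of
    the same shape."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        chs = config.channels
        depth = len(chs) - 1
        if config.l_max % (2 ** depth):
            raise ValueError("l_max must be divisible by 2^levels")
        self.config = config
        k = config.kernel
        td, cd = config.time_dim, config.cond_dim
        self.time_mlp1 = Linear(td, td, rng)
        self.time_mlp2 = Linear(td, td, rng)
        self.stem = Conv1d(4, chs[0], k, rng)
        self.down_blocks = [ResBlock(chs[i], td, cd, k, rng) for i in range(depth)]
        self.down_convs = [Conv1d(chs[i], chs[i + 1], k, rng, stride=2) for i in range(depth)]
        self.mid_block = ResBlock(chs[-1], td, cd, k, rng)
        self.up_convs = [Conv1d(chs[i + 1], chs[i], k, rng) for i in reversed(range(depth))]
        self.fuse_convs = [Conv1d(2 * chs[i], chs[i], 1, rng, pad=0) for i in reversed(range(depth))]
        self.up_blocks = [ResBlock(chs[i], td, cd, k, rng) for i in reversed(range(depth))]
        self.head = Conv1d(chs[0], 4, k, rng)

    # -- conditioning ----------------------------------------------------
    def _prep_cond(self, t, cond, n: int) -> tuple[Tensor, Tensor]:
        t_arr = np.broadcast_to(np.atleast_1d(t), (n,))
        temb_np = sinusoidal_embed(t_arr, self.config.time_dim)
        temb = self.time_mlp2(self.time_mlp1(Tensor(temb_np)).silu())
        cond_np = np.asarray(cond, dtype=np.float64)
        if cond_np.ndim == 1:
            cond_np = np.broadcast_to(cond_np, (n, cond_np.size))
        return temb, Tensor(cond_np)

    def encode(self, x, t, cond) -> Tensor:
        """Down-sampling stage only; returns bottleneck features (N, C_b, L_b)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        temb, cond_t = self._prep_cond(t, cond, x.shape[0])
        h = self.stem(x)
        for block, down in zip(self.down_blocks, self.down_convs):
            h = block(h, temb, cond_t)
            h = down(h)
        return self.mid_block(h, temb, cond_t)

    def __call__(self, x, t, cond) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        temb, cond_t = self._prep_cond(t, cond, x.shape[0])
        h = self.stem(x)
        skips = []
        for block, down in zip(self.down_blocks, self.down_convs):
            h = block(h, temb, cond_t)
            skips.append(h)
            h = down(h)
        h = self.mid_block(h, temb, cond_t)
        for up, fuse, block in zip(self.up_convs, self.fuse_convs, self.up_blocks):
            h = up(upsample_nearest(h, 2))
            h = fuse(concat([h, skips.pop()], axis=1))
            h = block(h, temb, cond_t)
        return self.head(h)


# ---------------------------------------------------------------------------
# Loss, sampler, training
# ---------------------------------------------------------------------------

def diffusion_loss(network, x0: np.ndarray, cond, t, eps: np.ndarray,
                   schedule: NoiseSchedule) -> Tensor:
    """MSE between the drawn noise ε and the network's prediction ε_θ(X_t,t).

    Returns a scalar Tensor (differentiable); use ``float(loss.data)`` for
    the value. Mean is taken over every element.
    """
    xt = forward_sample(x0, t, schedule, eps)
    pred = network(xt, t, cond)
    if not np.all(np.isfinite(pred.data)):
        raise FloatingPointError("non-finite network output")
    diff = pred - Tensor(eps)
    return (diff ** 2.0).mean()


def _sigma(schedule: NoiseSchedule, t: int, variant: str) -> float:
    b = schedule.beta[t - 1]
    if variant == "beta":
        return float(np.sqrt(b))
    if variant == "alphabar":
        ab_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
        ab = schedule.alpha_bar[t - 1]
        return float(np.sqrt(b * (1.0 - ab_prev) / (1.0 - ab)))
    raise ValueError(f"unknown sampler variance {variant!r}")


def reverse_step(x_t: np.ndarray, t: int, eps_pred: np.ndarray,
                 schedule: NoiseSchedule, z: np.ndarray | float = 0.0,
                 sampler_variance: str = "beta") -> np.ndarray:
    """One ancestral step: X_{t−1} = (X_t − β_t/√(1−ᾱ_t)·ε_θ)/√α_t + σ_t·z."""
    a = schedule.alpha[t - 1]
    b = schedule.beta[t - 1]
    ab = schedule.alpha_bar[t - 1]
    mean = (x_t - (b / np.sqrt(1.0 - ab)) * eps_pred) / np.sqrt(a)
    return mean + _sigma(schedule, t, sampler_variance) * np.asarray(z)


def ancestral_sample(network, cond, n: int, schedule: NoiseSchedule,
                     seed: int = 0, l_max: int = DEFAULT_L_MAX,
                     sampler_variance: str = "beta") -> list[np.ndarray]:
    """Run the reverse chain from X_T ~ N(0, I) for ``n`` samples.

    Noise z is injected at every step except the last (t=1). Returns a list
    of L_max×4 matrices; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 4, l_max))
    for t in range(schedule.T, 0, -1):
        eps_pred = network(x, t, cond)
        data = eps_pred.data if isinstance(eps_pred, Tensor) else np.asarray(eps_pred)
        z = rng.standard_normal(x.shape) if t > 1 else 0.0
        x = reverse_step(x, t, data, schedule, z, sampler_variance)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"non-finite sample at timestep {t}")
    return [x[i].T for i in range(n)]


class EarlyStopping:
    """Stop when the loss fails to improve by at least ``delta`` for
    ``patience`` consecutive epochs."""

    def __init__(self, delta: float = 0.001, patience: int = 3):
        self.delta = delta
        self.patience = patience
        self.best = np.inf
        self.streak = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; return True when training should halt."""
        improvement = self.best - loss
        if improvement >= self.delta:
            self.streak = 0
        else:
            self.streak += 1
        self.best = min(self.best, loss)
        return self.streak >= self.patience


def _pairs_to_arrays(pairs, encoder, l_max: int, rescale: bool):
    """Stack one-hot matrices (N, 4, L) and epitope embeddings (N, 1024)."""
    from .corpus import BindingPair  # noqa: F401  (typing only)

    xs, conds = [], []
    cache: dict[str, np.ndarray] = {}
    for p in pairs:
        nt = p.tcr.with_nt().nt
        xs.append(one_hot_encode(nt, l_max).matrix.T)
        if p.epitope not in cache:
            cache[p.epitope] = embed(p.epitope, encoder).vector
        conds.append(cache[p.epitope])
    x0 = np.stack(xs)
    if rescale:
        x0 = 2.0 * x0 - 1.0
    return x0, np.stack(conds)


def train_generator(pairs, encoder=None, config: GeneratorConfig | None = None,
                    ) -> tuple[UNet, NoiseSchedule, list[float]]:
    """Train the conditional denoiser on (TCR, epitope) pairs.

    Adam at lr 1e-4 by default; per-epoch mean losses are returned as the
    trace; training halts by the early-stopping rule (no improvement ≥ δ for
    `patience` consecutive epochs) or at ``max_epochs``. Deterministic for a
    fixed ``config.seed``.
    """
    config = config or GeneratorConfig()
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(config.seed)
    schedule = linear_schedule(config.timesteps, config.beta_start, config.beta_end)
    x0, cond = _pairs_to_arrays(pairs, encoder, config.l_max, config.rescale)
    net = UNet(config, rng)
    opt = Adam(net.parameters(), lr=config.lr)
    stopper = EarlyStopping(config.early_stop_delta, config.early_stop_patience)
    trace: list[float] = []
    n = x0.shape[0]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            t = rng.integers(1, schedule.T + 1, size=idx.size)
            eps = rng.standard_normal(x0[idx].shape)
            loss = diffusion_loss(net, x0[idx], cond[idx], t, eps, schedule)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * idx.size)
        trace.append(sum(losses) / n)
        if stopper.update(trace[-1]):
            break
    return net, schedule, trace


def generate_sequences(net: UNet, schedule: NoiseSchedule, epitope: str, n: int,
                       encoder=None, seed: int = 0, pad_threshold: float = 0.5,
                       ) -> tuple[list[str], list[np.ndarray]]:
    """Sample ``n`` matrices conditioned on an epitope and decode them.

    Returns (nucleotide strings, raw L_max×4 matrices). When the model was
    trained on recentred {-1,+1} encodings the samples are mapped back to
    [0, 1] before threshold decoding.
    """
    cond = embed(epitope, encoder).vector
    mats = ancestral_sample(net, cond, n, schedule, seed=seed,
                            l_max=net.config.l_max,
                            sampler_variance=net.config.sampler_variance)
    seqs = []
    out_mats = []
    for m in mats:
        m_dec = (m + 1.0) / 2.0 if net.config.rescale else m
        out_mats.append(m_dec)
        seqs.append(one_hot_decode(m_dec, pad_threshold))
    return seqs, out_mats


def reconstruct_sequences(net: UNet, schedule: NoiseSchedule, pairs, epitope: str,
                          encoder=None, seed: int = 0, pad_threshold: float = 0.5,
                          ) -> tuple[list[str], list[np.ndarray]]:
    """Corrupt reference TCRs to X_T with the forward process, then denoise.

    With the short 10-step schedule the forward chain retains a substantial
    fraction of the signal (ᾱ_T ≈ 0.59), so the reverse chain is started from
    forward-corrupted reference encodings rather than pure noise; this is the
    regime the denoiser is trained in and yields paired original/generated
    sequences for evaluation. Deterministic for a fixed seed.
    """
    cfg = net.config
    x0, _ = _pairs_to_arrays(pairs, encoder, cfg.l_max, cfg.rescale)
    cond = embed(epitope, encoder).vector
    rng = np.random.default_rng(seed)
    x = forward_sample(x0, schedule.T, schedule, rng.standard_normal(x0.shape))
    for t in range(schedule.T, 0, -1):
        eps_pred = net(x, t, cond).data
        z = rng.standard_normal(x.shape) if t > 1 else 0.0
        x = reverse_step(x, t, eps_pred, schedule, z, cfg.sampler_variance)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"non-finite sample at timestep {t}")
    seqs, mats = [], []
    for m in x:
        m_dec = (m.T + 1.0) / 2.0 if cfg.rescale else m.T
        mats.append(m_dec)
        seqs.append(one_hot_decode(m_dec, pad_threshold))
    return seqs, mats


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(net: UNet, schedule: NoiseSchedule, path: str,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + config + schedule, versioned."""
    header = {
        "version": _CKPT_VERSION,
        "kind": "tcrdiff-generator",
        "config": asdict(net.config),
        "extra": extra or {},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(net.state_arrays())}
    arrays["schedule_beta"] = schedule.beta
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        fh.write(buf.getvalue())


def load_checkpoint(path: str) -> tuple[UNet, NoiseSchedule]:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("kind") != "tcrdiff-generator":
            raise ValueError("not a generator checkpoint")
        data = np.load(io.BytesIO(fh.read()))
    cfg_dict = header["config"]
    cfg_dict["channels"] = tuple(cfg_dict["channels"])
    config = GeneratorConfig(**cfg_dict)
    net = UNet(config, np.random.default_rng(0))
    n_params = len(net.parameters())
    net.load_state_arrays([data[f"param_{i}"] for i in range(n_params)])
    beta = data["schedule_beta"]
    schedule = linear_schedule(len(beta), float(beta[0]), float(beta[-1]))
    return net, schedule
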