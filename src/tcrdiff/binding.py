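"""TCR–epitope binding predictors built on the denoiser's encoder.

Two variants share the structure encoder → pooled feature vector, concatenated
with the 1024-dim epitope embedding, followed by a stack of linear layers with
SiLU and dropout 0.6 on all but the final layer:

* ``epiBP`` — seven head layers, no HLA information.
* ``epiStarBP`` — five head layers, with a locus-level HLA one-hot (A/B/C)
  concatenated to the input of every head layer.

The final layer outputs a single logit squashed to a binding probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, bce_with_logits
from .nn import Adam, Dropout, Linear, Module
from .diffusion import UNet
from .epitope_encoder import embed
from .seq_codec import one_hot_encode

__all__ = [
    "HlaOneHot",
    "PredictorConfig",
    "encode_hla",
    "BindingPredictor",
    "build_predictor",
    "train_predictor",
    "predict_binding",
]

_HLA_INDEX = {"A": 0, "B": 1, "C": 2}


class UnsupportedLocusError(ValueError):
    pass


@dataclass(frozen=True)
class HlaOneHot:
    """Locus-level one-hot over (A, B, C)."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.float64)
        if v.shape != (3,) or not (v.sum() in (0.0, 1.0) and set(v) <= {0.0, 1.0}):
            raise ValueError("HLA one-hot must be a 3-dim basis vector or all-zero")
        object.__setattr__(self, "vector", v)


def encode_hla(allele: str) -> HlaOneHot:
    """Map an HLA class-I allele name (any resolution) to its locus one-hot."""
    name = allele.strip().upper()
    if name.startswith("HLA-"):
        name = name[4:]
    locus = name[:1]
    rest = name[1:2]
    # reject multi-letter loci like DRB1, DQB1 and anything non-class-I
    if locus not in _HLA_INDEX or (rest.isalpha() and rest != ""):
        raise UnsupportedLocusError(f"unsupported HLA locus in {allele!r}")
    v = np.zeros(3)
    v[_HLA_INDEX[locus]] = 1.0
    return HlaOneHot(v)


@dataclass
class PredictorConfig:
    """Head architecture and training settings for a predictor variant."""

    variant: str = "epiBP"  # epiBP | epiStarBP
    dropout: float = 0.6
    encoder_frozen: bool = False
    lr: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 40
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("epiBP", "epiStarBP"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def head_depth(self) -> int:
        return 7 if self.variant == "epiBP" else 5

    @property
    def use_hla(self) -> bool:
        return self.variant == "epiStarBP"


def _taper_widths(d_in: int, depth: int) -> list[int]:
    """Geometric taper from d_in down to 1 over `depth` layers."""
    widths = [d_in]
    for i in range(1, depth):
        widths.append(max(1, int(round(d_in ** (1.0 - i / depth)))))
    widths.append(1)
    return widths


class BindingPredictor(Module):
    """Denoiser encoder + pooled features + epitope embedding → linear head."""

    def __init__(self, denoiser: UNet, config: PredictorConfig,
                 rng: np.random.Generator):
        self.config = config
        self.encoder = denoiser  # down-sampling stage is used via .encode
        d_in = denoiser.config.bottleneck + denoiser.config.cond_dim
        hla_extra = 3 if config.use_hla else 0
        widths = _taper_widths(d_in + hla_extra, config.head_depth)
        # He-style gain keeps the signal alive through the deep SiLU stack
        self.head_layers = [
            Linear(widths[i] + (hla_extra if i > 0 else 0), widths[i + 1], rng,
                   gain=np.sqrt(6.0))
            for i in range(config.head_depth)
        ]
        # dropout applied to the input of every layer except the final one
        self.head_dropouts = [Dropout(config.dropout) for _ in range(config.head_depth - 1)]

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if not self.config.encoder_frozen:
            params.extend(self.encoder.parameters())
        for layer in self.head_layers:
            params.extend(layer.parameters())
        return params

    def features(self, x: np.ndarray, cond: np.ndarray) -> Tensor:
        """Pooled encoder bottleneck, concatenated with the epitope embedding."""
        h = self.encoder.encode(x, 0, cond)  # clean input, t = 0
        pooled = h.mean(axis=2)  # global average over positions
        n = pooled.shape[0]
        cond_np = np.asarray(cond, dtype=np.float64)
        if cond_np.ndim == 1:
            cond_np = np.broadcast_to(cond_np, (n, cond_np.size))
        from ._autograd import concat

        return concat([pooled, Tensor(cond_np)], axis=1)

    def logits(self, x: np.ndarray, cond: np.ndarray, hla: np.ndarray | None,
               rng: np.random.Generator | None = None, train: bool = False) -> Tensor:
        from ._autograd import concat

        h = self.features(x, cond)
        n = h.shape[0]
        if self.config.use_hla:
            if hla is None:
                raise ValueError("epiStarBP requires HLA input")
            hla_np = np.asarray(hla, dtype=np.float64)
            if hla_np.ndim == 1:
                hla_np = np.broadcast_to(hla_np, (n, 3))
            hla_t = Tensor(hla_np)
        for i, layer in enumerate(self.head_layers):
            last = i == len(self.head_layers) - 1
            if self.config.use_hla:
                h = concat([h, hla_t], axis=1)
            if not last:
                h = self.head_dropouts[i](h, rng, train)
            h = layer(h)
            if not last:
                h = h.silu()
        return h.reshape(n)

    def __call__(self, x, cond, hla=None, rng=None, train=False) -> Tensor:
        return self.logits(x, cond, hla, rng, train).sigmoid()


def build_predictor(denoiser: UNet, config: PredictorConfig | None = None,
                    seed: int | None = None) -> BindingPredictor:
    """Attach the variant's linear head to a (trained or fresh) denoiser."""
    config = config or PredictorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return BindingPredictor(denoiser, config, rng)


def _pairs_to_tensors(pairs, encoder, l_max: int, rescale: bool):
    xs, conds, hlas, ys = [], [], [], []
    cache: dict[str, np.ndarray] = {}
    for p in pairs:
        nt = p.tcr.with_nt().nt
        m = one_hot_encode(nt, l_max).matrix.T
        xs.append(2.0 * m - 1.0 if rescale else m)
        if p.epitope not in cache:
            cache[p.epitope] = embed(p.epitope, encoder).vector
        conds.append(cache[p.epitope])
        if p.tcr.hla_locus is not None:
            v = np.zeros(3)
            v[_HLA_INDEX[p.tcr.hla_locus]] = 1.0
            hlas.append(v)
        else:
            hlas.append(np.zeros(3))
        ys.append(float(p.label))
    return np.stack(xs), np.stack(conds), np.stack(hlas), np.asarray(ys)


def train_predictor(predictor: BindingPredictor, pairs, encoder=None,
                    ) -> tuple[BindingPredictor, list[dict]]:
    """Train with binary cross-entropy and Adam; report held-out metrics.

    A fifth of the pairs (disjoint by (cdr3b, epitope) key from the training
    portion) is held out; per-epoch accuracy and F1 on it form the metric
    trace. Deterministic for a fixed ``config.seed``.
    """
    from .evaluation import classification_metrics

    cfg = predictor.config
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError("training pairs must contain both labels")
    rng = np.random.default_rng(cfg.seed)
    x, cond, hla, y = _pairs_to_tensors(
        pairs, encoder, predictor.encoder.config.l_max, predictor.encoder.config.rescale
    )
    n = len(pairs)
    order = rng.permutation(n)
    n_hold = max(1, int(round(n * cfg.holdout_fraction)))
    hold, tr = order[:n_hold], order[n_hold:]
    # leakage guard: no shared (cdr3b, epitope) key across the split
    tr_keys = {pairs[i].key for i in tr}
    hold = np.array([i for i in hold if pairs[i].key not in tr_keys], dtype=int)
    opt = Adam(predictor.parameters(), lr=cfg.lr)
    trace: list[dict] = []
    for _ in range(cfg.max_epochs):
        perm = tr[rng.permutation(tr.size)]
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = predictor.logits(x[idx], cond[idx], hla[idx], rng, train=True)
            loss = bce_with_logits(logits, y[idx])
            predictor.zero_grad()
            loss.backward()
            opt.step()
        probs = predictor(x[hold], cond[hold], hla[hold]).data
        m = classification_metrics(y[hold], probs)
        trace.append({"accuracy": m["accuracy"], "f1": m["f1"]})
    return predictor, trace


def predict_binding(predictor: BindingPredictor, cdr3b: str, epitope: str,
                    hla: str | None = None, encoder=None) -> float:
    """Binding probability for one (CDR3β, epitope[, HLA]) query (eval mode)."""
    from .corpus import TcrRecord

    rec = TcrRecord(cdr3b=cdr3b).with_nt()
    l_max = predictor.encoder.config.l_max
    m = one_hot_encode(rec.nt, l_max).matrix.T
    if predictor.encoder.config.rescale:
        m = 2.0 * m - 1.0
    cond = embed(epitope, encoder).vector[None, :]
    hla_vec = None
    if predictor.config.use_hla:
        if hla is None:
            raise ValueError("epiStarBP requires an HLA allele")
        hla_vec = encode_hla(hla).vector[None, :]
    prob = predictor(m[None], cond, hla_vec).data
    return float(prob[0])
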