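"""Two-level vector-quantized autoencoder with an identification pretext task.

The model distills a 100 x 100 x 2 crop (protein fluorescence + signed
nuclear distance) into two discrete representations: a *local* one (25 x 25
spatial grid, one 64-dimensional code per position) and a *global* one
(4 x 4 grid, 576 channels quantized as nine 64-dimensional subvectors).
Each level has its own codebook of 2,048 learnable codes.

Split quantization is the key codebook trick: instead of quantizing a
global position's whole 576-dimensional channel vector against one code, the
vector is cut into ``n_splits`` equal contiguous subvectors, each quantized
independently against the shared codebook.  This keeps the number of
quantized vectors high under aggressive spatial pooling and measurably
raises codebook perplexity (effective code usage).

Two classifier heads (two-layer perceptrons) predict the protein identifier
from the quantized local and global representations; together with image
reconstruction they form the self-supervision signal.  No localization
labels enter training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    Conv2d,
    Dense,
    Flatten,
    NearestResize,
    Param,
    ReLU,
    ResBlock,
    Sequential,
    softmax_cross_entropy,
)


class ConfigurationError(ValueError):
    pass


class InputError(ValueError):
    pass


class QuantizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation toggles.

    ``input_shape`` is (H, W, C); the spatial side must be divisible by 4
    (encoder1 pools twice).  The global channel count must equal
    ``n_splits * code_dim`` so split quantization produces subvectors of
    exactly the codebook dimension.
    """

    n_classes: int = 10
    input_shape: tuple[int, int, int] = (100, 100, 2)
    n_codes: int = 2048
    code_dim: int = 64
    global_shape: tuple[int, int, int] = (4, 4, 576)
    local_shape: tuple[int, int, int] = (25, 25, 64)
    n_splits: int = 9
    classifier_hidden: int = 1000
    width1: int = 32
    width2: int = 128
    ema_decay: float = 0.99
    commitment_cost: float = 0.25
    # ablation toggles
    use_nuclear_channel: bool = True
    use_distance_transform: bool = True
    use_vq: bool = True
    use_split_quantization: bool = True
    use_id_task: bool = True
    use_decoder: bool = True

    def __post_init__(self) -> None:
        h, w, c = self.input_shape
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.global_shape[2] % self.n_splits:
            raise ConfigurationError(
                "global channel count must be divisible by n_splits"
            )
        if self.global_shape[2] != self.n_splits * self.code_dim:
            raise ConfigurationError(
                "global channels must equal n_splits * code_dim"
            )
        if self.local_shape[2] != self.code_dim:
            raise ConfigurationError("local channels must equal code_dim")
        if h % 4 or w % 4:
            raise ConfigurationError("input side must be divisible by 4")
        if (h // 4, w // 4) != self.local_shape[:2]:
            raise ConfigurationError(
                "local grid must be input side / 4 "
                f"(expected {(h // 4, w // 4)}, got {self.local_shape[:2]})"
            )

    @property
    def in_channels(self) -> int:
        return self.input_shape[2] if self.use_nuclear_channel else 1

    @property
    def effective_global_splits(self) -> int:
        return self.n_splits if self.use_split_quantization else 1


# ---------------------------------------------------------------------------
# codebooks and (split) quantization
# ---------------------------------------------------------------------------


@dataclass
class Codebook:
    """A set of learnable code vectors updated by exponential moving average."""

    codes: np.ndarray  # (n_codes, dim)
    decay: float = 0.99
    epsilon: float = 1e-5
    update_mode: str = "ema"
    ema_cluster_size: np.ndarray = field(init=False)
    ema_sum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, np.float32)
        self.ema_cluster_size = np.ones(len(self.codes), np.float64)
        self.ema_sum = self.codes.astype(np.float64).copy()

    @classmethod
    def random(
        cls, n_codes: int, dim: int, rng: np.random.Generator, **kw
    ) -> "Codebook":
        return cls(rng.normal(0.0, 1.0, (n_codes, dim)), **kw)

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def ema_update(self, vectors: np.ndarray, indices: np.ndarray) -> None:
        """EMA codebook update with Laplace-smoothed cluster sizes."""
        counts = np.bincount(indices.ravel(), minlength=self.n_codes)
        sums = np.zeros_like(self.ema_sum)
        np.add.at(sums, indices.ravel(), vectors.reshape(-1, vectors.shape[-1]))
        d = self.decay
        self.ema_cluster_size = d * self.ema_cluster_size + (1 - d) * counts
        self.ema_sum = d * self.ema_sum + (1 - d) * sums
        n = self.ema_cluster_size.sum()
        size = (
            (self.ema_cluster_size + self.epsilon)
            / (n + self.n_codes * self.epsilon)
            * n
        )
        self.codes = (self.ema_sum / size[:, None]).astype(np.float32)


@dataclass
class QuantizationResult:
    """Outcome of (split) vector quantization of one latent tensor.

    ``indices`` has shape (B, H, W) for standard quantization and
    (B, H, W, n_splits) for split quantization; ``quantized`` matches the
    latent's shape and is a concatenation of code vectors at each position.
    The two loss terms are the same mean squared latent-to-code distance;
    they differ only in which side receives gradients during training.
    """

    indices: np.ndarray
    quantized: np.ndarray
    codebook_loss: float
    commitment_loss: float
    n_splits: int


def split_quantize(
    latent: np.ndarray, codebook: Codebook, n_splits: int
) -> QuantizationResult:
    """Quantize a (B, C, H, W) latent; each position's channel vector is cut
    into ``n_splits`` contiguous subvectors matched to nearest codes
    (Euclidean, ties to the lowest index).  ``n_splits=1`` is standard VQ.
    """
    latent = np.asarray(latent)
    if latent.ndim != 4:
        raise QuantizationError("latent must be (B, C, H, W)")
    bsz, c, h, w = latent.shape
    if n_splits < 1 or c % n_splits:
        raise QuantizationError(
            f"channel count {c} not divisible by n_splits={n_splits}"
        )
    dim = c // n_splits
    if dim != codebook.codes.shape[1]:
        raise QuantizationError(
            f"subvector length {dim} != codebook dim {codebook.codes.shape[1]}"
        )
    # (B, H, W, n_splits, dim) view of channel-wise subvectors
    vecs = latent.transpose(0, 2, 3, 1).reshape(bsz, h, w, n_splits, dim)
    flat = vecs.reshape(-1, dim).astype(np.float64)
    codes = codebook.codes.astype(np.float64)
    d2 = (
        (flat**2).sum(axis=1, keepdims=True)
        - 2.0 * flat @ codes.T
        + (codes**2).sum(axis=1)
    )
    idx = np.argmin(d2, axis=1)
    quant = codebook.codes[idx].reshape(bsz, h, w, n_splits, dim)
    mse = float(np.mean((quant - vecs.astype(np.float32)) ** 2))
    quantized = np.ascontiguousarray(
        quant.reshape(bsz, h, w, c).transpose(0, 3, 1, 2)
    )
    indices = idx.reshape(bsz, h, w, n_splits)
    if n_splits == 1:
        indices = indices[..., 0]
    return QuantizationResult(
        indices=indices,
        quantized=quantized,
        codebook_loss=mse,
        commitment_loss=mse,
        n_splits=n_splits,
    )


def perplexity(assignment_counts: np.ndarray) -> float:
    """exp(entropy) of code-usage frequencies: 1 (one code) .. n_codes
    (uniform use).  Invariant to rescaling the counts."""
    counts = np.asarray(assignment_counts, np.float64)
    if counts.ndim != 1 or (counts < 0).any():
        raise InputError("counts must be a non-negative vector")
    total = counts.sum()
    if total <= 0:
        raise InputError("all-zero assignment counts")
    p = counts / total
    nz = p[p > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def assignment_counts(indices: np.ndarray, n_codes: int) -> np.ndarray:
    return np.bincount(np.asarray(indices).ravel(), minlength=n_codes)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


@dataclass
class ForwardOutputs:
    reconstruction: np.ndarray | None
    intermediate_reconstruction: np.ndarray | None
    logits_local: np.ndarray | None
    logits_global: np.ndarray | None
    quant_local: QuantizationResult
    quant_global: QuantizationResult
    local_latent: np.ndarray
    global_latent: np.ndarray


@dataclass
class LossBundle:
    recon1: float = 0.0
    recon2: float = 0.0
    vq1: float = 0.0
    vq2: float = 0.0
    ce1: float = 0.0
    ce2: float = 0.0
    weights: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        w = self.weights
        return (
            w.get("recon1", 1.0) * self.recon1
            + w.get("recon2", 1.0) * self.recon2
            + w.get("vq1", 1.0) * self.vq1
            + w.get("vq2", 1.0) * self.vq2
            + w.get("ce1", 1.0) * self.ce1
            + w.get("ce2", 1.0) * self.ce2
        )


def _halvings(src: int, dst: int) -> int:
    n, s = 0, src
    while s > dst:
        s = -(-s // 2)
        n += 1
    if s != dst:
        raise ConfigurationError(
            f"global grid {dst} not reachable from local grid {src} by halving"
        )
    return n


class Model:
    """The assembled two-level quantized autoencoder.

    Component names follow the wiring: ``encoder1`` maps the input crop to
    the local latent; ``encoder2`` pools it into the global latent;
    ``decoder2`` (ending in the adapter convolution ``mselyr1``) reconstructs
    encoder2's input from the quantized global representation; ``decoder1``
    reconstructs the image from the quantized local representation
    concatenated with the upsampled global one; ``fc1``/``fc2`` are the
    identification heads.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        cfg = config
        h, w, _ = cfg.input_shape
        lh, lw, _ = cfg.local_shape
        gh, gw, gc = cfg.global_shape
        cd, w1, w2 = cfg.code_dim, cfg.width1, cfg.width2

        self.encoder1 = Sequential(
            Conv2d(cfg.in_channels, w1, rng, stride=2),
            ReLU(),
            ResBlock(w1, rng),
            Conv2d(w1, cd, rng, stride=2),
        )
        n_half = _halvings(lh, gh)
        enc2_layers: list = []
        prev = cd
        for i in range(n_half):
            nxt = gc if i == n_half - 1 else w2
            enc2_layers.append(Conv2d(prev, nxt, rng, stride=2))
            if i != n_half - 1:
                enc2_layers.append(ReLU())
            prev = nxt
        self.encoder2 = Sequential(*enc2_layers)

        self.decoder2 = Sequential(
            NearestResize((lh, lw)),
            Conv2d(gc, w2, rng),
            ReLU(),
            Conv2d(w2, cd, rng),  # mselyr1: adapt to encoder1's output dims
        )
        self.decoder1 = Sequential(
            Conv2d(cd + gc, w1, rng),
            ReLU(),
            ResBlock(w1, rng),
            NearestResize((lh * 2, lw * 2)),
            Conv2d(w1, w1, rng),
            ReLU(),
            NearestResize((h, w)),
            Conv2d(w1, cfg.in_channels, rng),
        )
        self.fc1 = Sequential(
            Flatten(),
            Dense(lh * lw * cd, cfg.classifier_hidden, rng),
            ReLU(),
            Dense(cfg.classifier_hidden, cfg.n_classes, rng),
        )
        self.fc2 = Sequential(
            Flatten(),
            Dense(gh * gw * gc, cfg.classifier_hidden, rng),
            ReLU(),
            Dense(cfg.classifier_hidden, cfg.n_classes, rng),
        )
        self.codebook_local = Codebook.random(
            cfg.n_codes, cd, rng, decay=cfg.ema_decay
        )
        gdim = gc // cfg.effective_global_splits
        self.codebook_global = Codebook.random(
            cfg.n_codes, gdim, rng, decay=cfg.ema_decay
        )
        self._global_resize = NearestResize((lh, lw))

    # -- parameter plumbing -------------------------------------------------

    def modules(self) -> list[Sequential]:
        mods = [self.encoder1, self.encoder2]
        if self.config.use_decoder:
            mods += [self.decoder1, self.decoder2]
        if self.config.use_id_task:
            mods += [self.fc1, self.fc2]
        return mods

    def params(self) -> list[Param]:
        out: list[Param] = []
        for m in self.modules():
            out.extend(m.params())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        arrays.append(self.codebook_local.codes.copy())
        arrays.append(self.codebook_global.codes.copy())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrays[: len(params)]):
            p.value[...] = a
        self.codebook_local.codes = arrays[-2].copy()
        self.codebook_global.codes = arrays[-1].copy()

    # -- forward ------------------------------------------------------------

    def forward(self, batch: np.ndarray) -> ForwardOutputs:
        cfg = self.config
        x = np.asarray(batch, np.float32)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise InputError(
                f"expected (B, {cfg.in_channels}, H, W) batch, got {x.shape}"
            )
        if x.shape[2:] != cfg.input_shape[:2]:
            raise InputError(
                f"expected spatial shape {cfg.input_shape[:2]}, got {x.shape[2:]}"
            )
        z_local = self.encoder1.forward(x)
        z_global = self.encoder2.forward(z_local)

        if cfg.use_vq:
            q1 = split_quantize(z_local, self.codebook_local, 1)
            q2 = split_quantize(
                z_global, self.codebook_global, cfg.effective_global_splits
            )
        else:
            empty = np.zeros(z_local.shape[:1] + z_local.shape[2:], np.intp)
            q1 = QuantizationResult(empty, z_local, 0.0, 0.0, 1)
            empty_g = np.zeros(z_global.shape[:1] + z_global.shape[2:], np.intp)
            q2 = QuantizationResult(empty_g, z_global, 0.0, 0.0, 1)

        recon = inter = None
        if cfg.use_decoder:
            inter = self.decoder2.forward(q2.quantized)
            g_res = self._global_resize.forward(q2.quantized)
            recon = self.decoder1.forward(
                np.concatenate([q1.quantized, g_res], axis=1)
            )
        logits1 = logits2 = None
        if cfg.use_id_task:
            logits1 = self.fc1.forward(q1.quantized)
            logits2 = self.fc2.forward(q2.quantized)
        return ForwardOutputs(
            reconstruction=recon,
            intermediate_reconstruction=inter,
            logits_local=logits1,
            logits_global=logits2,
            quant_local=q1,
            quant_global=q2,
            local_latent=z_local,
            global_latent=z_global,
        )


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    return Model(config, np.random.default_rng(seed))


def total_loss(
    outputs: ForwardOutputs,
    batch: np.ndarray,
    targets: np.ndarray | None,
    config: ModelConfig,
    weights: dict | None = None,
) -> LossBundle:
    """Assemble the six-term loss (reconstruction MSE at both levels, VQ
    commitment+codebook terms, cross entropy from both heads)."""
    weights = dict(weights or {})
    bundle = LossBundle(weights=weights)
    if config.use_decoder:
        bundle.recon1 = float(
            np.mean((outputs.reconstruction - batch) ** 2)
        )
        bundle.recon2 = float(
            np.mean(
                (outputs.intermediate_reconstruction - outputs.local_latent)
                ** 2
            )
        )
    if config.use_vq:
        beta = config.commitment_cost
        bundle.vq1 = outputs.quant_local.codebook_loss * (1.0 + beta)
        bundle.vq2 = outputs.quant_global.codebook_loss * (1.0 + beta)
    if config.use_id_task:
        if targets is None:
            raise InputError("targets required when the id task is enabled")
        targets = np.asarray(targets)
        if targets.min() < 0 or targets.max() >= config.n_classes:
            raise InputError("target id out of range")
        bundle.ce1, _ = softmax_cross_entropy(outputs.logits_local, targets)
        bundle.ce2, _ = softmax_cross_entropy(outputs.logits_global, targets)
    return bundle


# ---------------------------------------------------------------------------
# one optimization step (forward + manual backward + EMA codebook update)
# ---------------------------------------------------------------------------


def train_step(
    model: Model,
    batch: np.ndarray,
    targets: np.ndarray | None,
    optimizer: Adam,
    weights: dict | None = None,
) -> LossBundle:
    cfg = model.config
    weights = dict(weights or {})
    x = np.asarray(batch, np.float32)
    out = model.forward(x)
    bundle = total_loss(out, x, targets, cfg, weights)

    optimizer.zero_grad()
    d_q1 = np.zeros_like(out.quant_local.quantized)
    d_q2 = np.zeros_like(out.quant_global.quantized)

    if cfg.use_decoder:
        w_r1 = weights.get("recon1", 1.0)
        d_recon = (
            2.0 * w_r1 * (out.reconstruction - x) / out.reconstruction.size
        ).astype(np.float32)
        d_dec1_in = model.decoder1.backward(d_recon)
        cd = cfg.code_dim
        d_q1 += d_dec1_in[:, :cd]
        d_q2 += model._global_resize.backward(d_dec1_in[:, cd:])
        w_r2 = weights.get("recon2", 1.0)
        d_inter = (
            2.0
            * w_r2
            * (out.intermediate_reconstruction - out.local_latent)
            / out.intermediate_reconstruction.size
        ).astype(np.float32)
        d_q2 += model.decoder2.backward(d_inter)
    if cfg.use_id_task:
        _, d_log1 = softmax_cross_entropy(out.logits_local, targets)
        _, d_log2 = softmax_cross_entropy(out.logits_global, targets)
        d_q1 += model.fc1.backward(d_log1 * weights.get("ce1", 1.0))
        d_q2 += model.fc2.backward(d_log2 * weights.get("ce2", 1.0))

    # straight-through: gradients w.r.t. quantized tensors pass to the
    # latents unchanged; commitment pulls latents toward their codes
    if cfg.use_vq:
        beta1 = cfg.commitment_cost * weights.get("vq1", 1.0)
        beta2 = cfg.commitment_cost * weights.get("vq2", 1.0)
        d_z_global = d_q2 + (
            2.0
            * beta2
            * (out.global_latent - out.quant_global.quantized)
            / out.global_latent.size
        ).astype(np.float32)
        d_z_local_vq = (
            2.0
            * beta1
            * (out.local_latent - out.quant_local.quantized)
            / out.local_latent.size
        ).astype(np.float32)
    else:
        d_z_global = d_q2
        d_z_local_vq = 0.0
    d_z_local = d_q1 + d_z_local_vq + model.encoder2.backward(d_z_global)
    model.encoder1.backward(d_z_local)
    optimizer.step()

    if cfg.use_vq:
        bsz, c, h, w = out.local_latent.shape
        model.codebook_local.ema_update(
            out.local_latent.transpose(0, 2, 3, 1).reshape(-1, c),
            out.quant_local.indices,
        )
        ns = cfg.effective_global_splits
        gb, gc_, gh, gw = out.global_latent.shape
        gvecs = out.global_latent.transpose(0, 2, 3, 1).reshape(
            -1, gc_ // ns
        )
        model.codebook_global.ema_update(gvecs, out.quant_global.indices)
    return bundle


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: Model, path) -> None:
    import dataclasses as dc
    import json
    import pathlib

    path = pathlib.Path(path)
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)
    cfg = dc.asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_model(path) -> Model:
    import json
    import pathlib

    path = pathlib.Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    for key in ("input_shape", "global_shape", "local_shape"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(ModelConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[k] for k in data.files]
    model.load_state_arrays(arrays)
    return model
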