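"""Encoder/decoder inpainting network and classification-network baseline.

The generative model is a U-Net: a cascade of stride-2 convolutions halving
the spatial size down to a 1x1 bottleneck, mirrored by transposed
convolutions doubling it back, with skip connections concatenating each
encoder activation onto the matching-size decoder activation.  Every layer is
convolution + batch normalization + activation (leaky ReLU in the encoder,
ReLU in the decoder, sigmoid on the output so reconstructions stay in
[0, 1]).  Trained self-supervised: occluded image in, original image out,
L1 reconstruction loss concentrated on the occluded quadrant.  An optional
adversarial head (a small convolutional discriminator) is available but off
by default.

The baseline is the standard 16-layer classification topology (5 conv
blocks separated by max-pooling); only the last convolution of each block —
the ones feeding a pooling stage — is analyzed.

The default encoder kernel is 4 (stride 2, padding 1): this is the
configuration whose analytic receptive fields are 4 px at encoder_1 and
22 px at encoder_3.  Kernel 3 is equally supported via config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import rf_geometry as rfg
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    conv_out_size,
    make_activation,
    tconv_out_size,
)

__all__ = [
    "ConvLayerCfg",
    "ArchitectureConfig",
    "TrainingConfig",
    "EncoderDecoder",
    "TrainingDiverged",
    "default_architecture",
    "analyzed_layers",
    "encoder_rf_spec",
    "decoder_grids",
    "train_inpainting",
    "forward_collect",
    "reconstruction_error",
    "vgg16_topology",
    "vgg_analysis_layers",
    "build_vgg",
    "vgg_forward_collect",
]

DEFAULT_ENCODER_CHANNELS = (64, 128, 256, 512, 512, 512, 512, 1024)


@dataclass(frozen=True)
class ConvLayerCfg:
    name: str
    kind: str  # "conv" | "tconv"
    out_channels: int
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    norm: bool = True
    activation: str = "leaky_relu"
    dropout: float = 0.0
    skip_source: str | None = None  # encoder activation concatenated to this layer's INPUT


@dataclass(frozen=True)
class ArchitectureConfig:
    input_size: int
    in_channels: int
    encoder: tuple[ConvLayerCfg, ...]
    decoder: tuple[ConvLayerCfg, ...]

    def validate(self) -> None:
        size = self.input_size
        enc_sizes: dict[str, int] = {}
        for cfg in self.encoder:
            out = conv_out_size(size, cfg.kernel, cfg.stride, cfg.padding)
            if cfg.stride == 2 and out * 2 != size:
                raise ValueError(
                    f"encoder layer {cfg.name} does not halve spatial size "
                    f"({size} -> {out}); adjust kernel/padding")
            size = out
            enc_sizes[cfg.name] = size
        for cfg in self.decoder:
            out = tconv_out_size(size, cfg.kernel, cfg.stride, cfg.padding)
            if cfg.stride == 2 and out != 2 * size:
                raise ValueError(
                    f"decoder layer {cfg.name} does not double spatial size "
                    f"({size} -> {out})")
            if cfg.skip_source is not None:
                if cfg.skip_source not in enc_sizes:
                    raise ValueError(f"decoder layer {cfg.name}: unknown skip source {cfg.skip_source}")
                if enc_sizes[cfg.skip_source] != size:
                    raise ValueError(
                        f"skip-size mismatch: decoder layer {cfg.name} (input {size}px) "
                        f"vs encoder layer {cfg.skip_source} ({enc_sizes[cfg.skip_source]}px)")
            size = out
        if size != self.input_size:
            raise ValueError(f"decoder output {size}px does not match input {self.input_size}px")


@dataclass(frozen=True)
class TrainingConfig:
    loss: str = "l1"  # "l1" | "l1+adversarial"
    epochs: int = 5
    batch_size: int = 5
    learning_rate: float = 1e-3
    dropout: float = 0.0
    occluded_weight: float = 1.0
    full_image_weight: float = 0.1
    adversarial_weight: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class TrainingDiverged(RuntimeError):
    pass


def default_architecture(image_size: int = 256, in_channels: int = 1,
                         encoder_channels: Sequence[int] = DEFAULT_ENCODER_CHANNELS,
                         kernel: int = 4, dropout_decoder_layers: int = 3,
                         dropout: float = 0.0) -> ArchitectureConfig:
    """Symmetric U-Net config.

    With len(encoder_channels) == log2(image_size) the bottleneck is 1x1
    (default: 8 layers for 256px, bottleneck 1x1x1024, the smallest analyzed
    layer).  The decoder mirrors the encoder; decoder layer ``k`` (k >= 2)
    takes the skip concatenation from encoder layer ``n+1-k``.
    """
    n = len(encoder_channels)
    if image_size % (2 ** n) != 0 or image_size // (2 ** n) < 1:
        raise ValueError(
            f"{n} stride-2 encoder layers need image_size divisible by 2^{n}, got {image_size}")
    enc = tuple(
        ConvLayerCfg(f"encoder_{i + 1}", "conv", ch, kernel=kernel, stride=2,
                     padding=(kernel - 1) // 2, norm=(i > 0), activation="leaky_relu")
        for i, ch in enumerate(encoder_channels)
    )
    dec_channels = list(encoder_channels[-2::-1]) + [in_channels]
    dec = []
    for i, ch in enumerate(dec_channels):
        k = i + 1
        is_last = k == n
        # transposed convs double exactly only with even kernels; the decoder
        # stays at kernel 4 regardless of the encoder kernel choice
        dec.append(ConvLayerCfg(
            f"decoder_{k}", "tconv", ch, kernel=4, stride=2, padding=1,
            norm=not is_last, activation="sigmoid" if is_last else "relu",
            dropout=dropout if k <= dropout_decoder_layers else 0.0,
            skip_source=f"encoder_{n + 1 - k}" if k >= 2 else None))
    cfg = ArchitectureConfig(image_size, in_channels, enc, tuple(dec))
    cfg.validate()
    return cfg


def encoder_rf_spec(config: ArchitectureConfig) -> rfg.RFSpec:
    """RF table for the encoder cascade (input pseudo-layer + every encoder layer)."""
    return rfg.rf_recursion(
        [(c.kernel, c.stride, c.padding) for c in config.encoder],
        config.input_size, names=[c.name for c in config.encoder])


def decoder_grids(config: ArchitectureConfig) -> dict[str, tuple[int, int]]:
    size = config.input_size // (2 ** len(config.encoder))
    grids = {}
    for cfg in config.decoder:
        size = tconv_out_size(size, cfg.kernel, cfg.stride, cfg.padding)
        grids[cfg.name] = (size, size)
    return grids


def analyzed_layers(config: ArchitectureConfig, min_decoder_grid: int = 16) -> list[tuple[str, str]]:
    """Ordered (layer name, section tag) pairs: all encoder layers plus all
    decoder layers except the output layer."""
    spec = encoder_rf_spec(config)
    grids = decoder_grids(config)
    grids.pop(config.decoder[-1].name)  # output layer is not analyzed
    labels = rfg.classify_sections(spec, grids, config.input_size, min_decoder_grid)
    names = [c.name for c in config.encoder] + [c.name for c in config.decoder[:-1]]
    return [(n, labels[n]) for n in names]


class EncoderDecoder:
    """U-Net with retrievable per-layer activations and manual backprop."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        config.validate()
        self.config = config
        ss = np.random.SeedSequence(seed)
        self._drop_rng = np.random.default_rng(ss.spawn(1)[0])
        rng = np.random.default_rng(ss)
        self.blocks: dict[str, dict] = {}
        in_ch = config.in_channels
        enc_out: dict[str, int] = {}
        for cfg in config.encoder:
            self.blocks[cfg.name] = self._make_block(cfg, in_ch, rng, transposed=False)
            enc_out[cfg.name] = cfg.out_channels
            in_ch = cfg.out_channels
        for cfg in config.decoder:
            if cfg.skip_source is not None:
                in_ch += enc_out[cfg.skip_source]
            self.blocks[cfg.name] = self._make_block(cfg, in_ch, rng, transposed=True)
            in_ch = cfg.out_channels

    def _make_block(self, cfg: ConvLayerCfg, in_ch: int, rng, transposed: bool) -> dict:
        conv_cls = ConvTranspose2d if transposed else Conv2d
        return {
            "cfg": cfg,
            "conv": conv_cls(in_ch, cfg.out_channels, cfg.kernel, cfg.stride,
                             cfg.padding, rng=rng, name=cfg.name),
            "bn": BatchNorm2d(cfg.out_channels, name=cfg.name) if cfg.norm else None,
            "act": make_activation(cfg.activation),
            "drop": Dropout(cfg.dropout, rng=self._drop_rng) if cfg.dropout > 0 else None,
        }

    def params(self):
        out = []
        for b in self.blocks.values():
            out.extend(b["conv"].params())
            if b["bn"] is not None:
                out.extend(b["bn"].params())
        return out

    def layer_names(self) -> list[str]:
        return [c.name for c in self.config.encoder] + [c.name for c in self.config.decoder]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, b in self.blocks.items():
            for p in b["conv"].params():
                state[p.name] = p.value
            if b["bn"] is not None:
                for p in b["bn"].params():
                    state[p.name] = p.value
                state[f"{name}.running_mean"] = b["bn"].running_mean
                state[f"{name}.running_var"] = b["bn"].running_var
        return state

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for name, b in self.blocks.items():
                for p in b["conv"].params():
                    p.value[...] = data[p.name]
                if b["bn"] is not None:
                    for p in b["bn"].params():
                        p.value[...] = data[p.name]
                    b["bn"].running_mean = data[f"{name}.running_mean"].copy()
                    b["bn"].running_var = data[f"{name}.running_var"].copy()

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Returns (reconstruction, activations-by-layer-name)."""
        acts: dict[str, np.ndarray] = {}
        h = x
        for cfg in self.config.encoder:
            h = self._block_forward(cfg.name, h, training)
            acts[cfg.name] = h
        for cfg in self.config.decoder:
            if cfg.skip_source is not None:
                h = np.concatenate([h, acts[cfg.skip_source]], axis=3)
            h = self._block_forward(cfg.name, h, training)
            acts[cfg.name] = h
        return h, acts

    def _block_forward(self, name, h, training):
        b = self.blocks[name]
        h = b["conv"].forward(h, training)
        if b["bn"] is not None:
            h = b["bn"].forward(h, training)
        h = b["act"].forward(h, training)
        if b["drop"] is not None:
            h = b["drop"].forward(h, training)
        return h

    def _block_backward(self, name, dy):
        b = self.blocks[name]
        if b["drop"] is not None:
            dy = b["drop"].backward(dy)
        dy = b["act"].backward(dy)
        if b["bn"] is not None:
            dy = b["bn"].backward(dy)
        return b["conv"].backward(dy)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop the reconstruction-loss gradient; returns d/d(input)."""
        enc_names = [c.name for c in self.config.encoder]
        skip_grads: dict[str, np.ndarray] = {}
        dy = dout
        for cfg in reversed(self.config.decoder):
            dx = self._block_backward(cfg.name, dy)
            if cfg.skip_source is not None:
                keep = dx.shape[3] - self.blocks[cfg.skip_source]["cfg"].out_channels
                dy, dskip = dx[..., :keep], dx[..., keep:]
                skip_grads[cfg.skip_source] = skip_grads.get(cfg.skip_source, 0) + dskip
            else:
                dy = dx
        for name in reversed(enc_names):
            if name in skip_grads:
                dy = dy + skip_grads[name]
            dy = self._block_backward(name, dy)
        return dy


def forward_collect(net: EncoderDecoder, images: np.ndarray,
                    layer_names: Sequence[str] | None = None,
                    batch_size: int = 8) -> dict[str, np.ndarray]:
    """Inference-mode activations, image-major, for the requested layers.

    ``images`` is (n, H, W) or (n, H, W, C).  Dropout is disabled and batch
    normalization uses frozen running statistics, so two calls with the same
    weights and input are bit-identical.
    """
    valid = set(net.layer_names())
    names = list(layer_names) if layer_names is not None else [n for n, _ in analyzed_layers(net.config)]
    unknown = [n for n in names if n not in valid]
    if unknown:
        raise KeyError(f"unknown layer(s) {unknown}; valid layers: {sorted(valid)}")
    if images.ndim == 3:
        images = images[..., None]
    chunks: dict[str, list[np.ndarray]] = {n: [] for n in names}
    for i in range(0, len(images), batch_size):
        _, acts = net.forward(images[i:i + batch_size], training=False)
        for n in names:
            chunks[n].append(acts[n])
    return {n: np.concatenate(chunks[n], axis=0) for n in names}


def reconstruction_error(net: EncoderDecoder, occluded: np.ndarray, originals: np.ndarray,
                         mask: np.ndarray | None = None, batch_size: int = 8) -> float:
    """Mean absolute reconstruction error, optionally restricted to ``mask``."""
    if occluded.ndim == 3:
        occluded = occluded[..., None]
    if originals.ndim == 3:
        originals = originals[..., None]
    errs = []
    for i in range(0, len(occluded), batch_size):
        y, _ = net.forward(occluded[i:i + batch_size], training=False)
        d = np.abs(y - originals[i:i + batch_size])
        if mask is not None:
            d = d[:, mask, :]
        errs.append(d.mean())
    return float(np.mean(errs))


class Discriminator:
    """Small convolutional real/fake head for the optional adversarial loss."""

    def __init__(self, image_size: int, in_channels: int = 1, seed: int = 0,
                 channels: Sequence[int] = (16, 32, 64)):
        rng = np.random.default_rng(seed)
        from .nn import LeakyReLU
        self.layers = []
        ch = in_channels
        for i, out in enumerate(channels):
            self.layers.append(Conv2d(ch, out, 4, 2, 1, rng=rng, name=f"disc_{i}"))
            self.layers.append(LeakyReLU(0.2))
            ch = out
        self.head = Conv2d(ch, 1, 3, 1, 1, rng=rng, name="disc_head")

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        out.extend(self.head.params())
        return out

    def forward(self, x, training=True):
        h = x
        for l in self.layers:
            h = l.forward(h, training)
        return self.head.forward(h, training)  # patch logits (N, h, w, 1)

    def backward(self, dlogits):
        dy = self.head.backward(dlogits)
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _l1_loss_grad(y, target, mask, cfg: TrainingConfig):
    d = y - target
    n = y.shape[0]
    m = mask[None, :, :, None]
    n_occ = n * mask.sum() * y.shape[3]
    loss_occ = float((np.abs(d) * m).sum() / n_occ)
    loss_full = float(np.abs(d).mean())
    grad = cfg.occluded_weight * m * np.sign(d) / n_occ \
        + cfg.full_image_weight * np.sign(d) / d.size
    return cfg.occluded_weight * loss_occ + cfg.full_image_weight * loss_full, grad


def train_inpainting(net: EncoderDecoder, occluded: np.ndarray, originals: np.ndarray,
                     occluder_mask: np.ndarray, config: TrainingConfig,
                     holdout: tuple[np.ndarray, np.ndarray] | None = None) -> dict:
    """Train the network on (occluded -> original) pairs.

    Returns a trace dict with per-epoch mean training loss and, when a
    holdout pair is given, the held-out occluded-region L1 error measured
    before training and after every epoch.  Raises :class:`TrainingDiverged`
    on a non-finite loss.
    """
    if occluded.ndim == 3:
        occluded = occluded[..., None]
    if originals.ndim == 3:
        originals = originals[..., None]
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    use_adv = config.loss == "l1+adversarial"
    disc = opt_d = None
    if use_adv:
        disc = Discriminator(net.config.input_size, net.config.in_channels, seed=config.seed + 1)
        opt_d = Adam(disc.params(), lr=config.learning_rate)

    trace = {"epoch_loss": [], "holdout_error": []}
    if holdout is not None:
        # held-out reconstruction error over the full image (the network's
        # output is the complete image, visible regions included)
        trace["holdout_error"].append(
            reconstruction_error(net, holdout[0], holdout[1]))
    n = len(occluded)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, tb = occluded[idx], originals[idx]
            y, _ = net.forward(xb, training=True)
            loss, grad = _l1_loss_grad(y, tb, occluder_mask, config)
            if use_adv:
                adv_loss, adv_grad = _adversarial_step(disc, opt_d, y, tb)
                loss += config.adversarial_weight * adv_loss
                grad = grad + config.adversarial_weight * adv_grad
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch + 1}, batch {i // config.batch_size}: {loss}")
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        trace["epoch_loss"].append(float(np.mean(losses)))
        if holdout is not None:
            trace["holdout_error"].append(
                reconstruction_error(net, holdout[0], holdout[1]))
    return trace


def _adversarial_step(disc, opt_d, fake, real, eps=1e-7):
    """One discriminator update plus the generator's adversarial gradient."""
    # discriminator: real -> 1, fake -> 0
    for x, lab in ((real, 1.0), (fake, 0.0)):
        logits = disc.forward(x, training=True)
        p = 1.0 / (1.0 + np.exp(-logits))
        dlog = (p - lab) / logits.size
        opt_d.zero_grad()
        disc.backward(dlog)
        opt_d.step()
    # generator: push D(fake) toward 1; gradient flows through D into the image
    logits = disc.forward(fake, training=True)
    p = np.clip(1.0 / (1.0 + np.exp(-logits)), eps, 1 - eps)
    g_loss = float(-np.log(p).mean())
    dlog = (p - 1.0) / logits.size
    dfake = disc.backward(dlog)
    return g_loss, dfake


# ---------------------------------------------------------------------------
# classification-network baseline (feedforward, 5 conv blocks + pooling)
# ---------------------------------------------------------------------------

VGG16_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))


def vgg16_topology(in_channels: int = 1, channel_scale: float = 1.0) -> list[dict]:
    """Standard 16-layer classification topology as an ordered layer list.

    Entries are ``{"name", "kind": "conv"|"pool", "out_channels"}``; the
    fully connected head is irrelevant for activation analysis and omitted.
    ``channel_scale`` shrinks channel counts for desk-scale runs.
    """
    topo = []
    for b, (n_conv, ch) in enumerate(VGG16_BLOCKS, start=1):
        ch = max(1, int(round(ch * channel_scale)))
        for c in range(1, n_conv + 1):
            topo.append({"name": f"conv{b}_{c}", "kind": "conv", "out_channels": ch,
                         "kernel": 3, "stride": 1, "padding": 1})
        topo.append({"name": f"pool{b}", "kind": "pool"})
    return topo


def vgg_analysis_layers(topology: Sequence[dict]) -> list[str]:
    """The convolution immediately before each pooling stage (5 for the
    standard topology: conv1_2, conv2_2, conv3_3, conv4_3, conv5_3)."""
    names = []
    prev_conv = None
    for entry in topology:
        if entry["kind"] == "conv":
            prev_conv = entry["name"]
        elif entry["kind"] == "pool":
            if prev_conv is None:
                raise ValueError(f"pooling stage {entry['name']} has no preceding convolution")
            names.append(prev_conv)
            prev_conv = None
    if not names:
        raise ValueError("topology has no pooling markers; cannot select analysis layers")
    return names


def _maxpool2(x):
    n, h, w, c = x.shape
    return x[:, :h - h % 2, :w - w % 2, :].reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


def build_vgg(topology: Sequence[dict], in_channels: int = 1, seed: int = 0) -> list[tuple[str, object]]:
    """Random-weight forward-only network for the baseline topology."""
    rng = np.random.default_rng(seed)
    from .nn import ReLU
    net = []
    ch = in_channels
    for entry in topology:
        if entry["kind"] == "conv":
            conv = Conv2d(ch, entry["out_channels"], entry.get("kernel", 3), entry.get("stride", 1),
                          entry.get("padding", 1), rng=rng, name=entry["name"])
            net.append((entry["name"], conv))
            net.append((entry["name"] + ":relu", ReLU()))
            ch = entry["out_channels"]
        else:
            net.append((entry["name"], "pool"))
    return net


def vgg_forward_collect(net: list, images: np.ndarray, layer_names: Sequence[str],
                        batch_size: int = 4) -> dict[str, np.ndarray]:
    """Post-ReLU activations of the requested conv layers."""
    if images.ndim == 3:
        images = images[..., None]
    wanted = set(layer_names)
    out: dict[str, list] = {n: [] for n in layer_names}
    for i in range(0, len(images), batch_size):
        h = images[i:i + batch_size]
        current_conv = None
        for name, layer in net:
            if layer == "pool":
                h = _maxpool2(h)
            else:
                h = layer.forward(h, training=False)
                if name.endswith(":relu"):
                    base = name[:-5]
                    if base in wanted:
                        out[base].append(h)
    return {n: np.concatenate(v, axis=0) for n, v in out.items()}
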