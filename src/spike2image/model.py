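"""The spike-to-image decoder network and its training loop.

Architecture: the flattened, per-neuron-standardised spike-count vector
passes through two fully connected layers (the second sized to the image),
is reshaped to a one-channel image, and then runs through a convolutional
autoencoder whose first convolution is a Gabor filter bank.  The encoder is
four stride-2 convolution blocks (LeakyReLU, dropout); the decoder mirrors
them with four stride-2 transposed convolutions ending in one channel and a
sigmoid, so reconstructions live in [0, 1].

Training minimises the composite loss (mu * -SSIM + (1-mu) * RF-weighted
MSE) with Adam under a stepped learning-rate schedule:
``lr(epoch) = lr0 * decay^floor(epoch / decay_every)`` with defaults
0.02, 0.9 and 100 epochs per step.

Everything is seeded: building a model twice from the same config yields
bitwise-identical weights, and a training run is reproducible from the
config seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .gabor import GaborBank, gabor_first_layer, make_bank
from .images import GrayImage
from .layers import (
    DTYPE,
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LeakyReLU,
    Module,
)
from .losses import LossConfig, combined_loss_t
from .metrics import MetricConstants, mse, psnr, ssim_windowed, vifp
from .rf_weights import WeightMatrix
from .spike_data import SpikeCountMatrix

__all__ = [
    "DecoderConfig",
    "TrainingHistory",
    "SpikeImageDecoder",
    "build_model",
    "learning_rate",
    "train",
    "reconstruct",
    "evaluate_on_pairs",
    "compare_methods",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Full architecture + optimisation configuration of the decoder."""

    n_neurons: int = 60
    n_time_bins: int = 30
    image_shape: tuple[int, int] = (32, 32)
    fc_hidden: int = 512
    encoder_channels: tuple[int, int, int, int] = (128, 256, 512, 512)
    decoder_channels: tuple[int, int, int, int] = (512, 256, 128, 1)
    conv_stride: int = 2
    conv_padding: int = 1
    conv_ksize: int = 4
    leaky_slope: float = 0.2
    dropout_p: float = 0.5
    lr0: float = 0.02
    lr_decay: float = 0.9
    lr_decay_every: int = 100
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    mu_mix: float = 0.1
    ssim_mode: str = "global"
    # first-convolution options
    gabor_enabled: bool = True
    gabor_mode: str = "fixed"
    gabor_orientation_step_deg: float = 30.0
    gabor_ksizes: tuple[int, ...] = (7, 9, 11, 13)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        factor = self.conv_stride**4
        if rows % factor or cols % factor:
            raise ValueError(
                "image_shape must be divisible by conv_stride^4 "
                f"(four stride-{self.conv_stride} stages): got {self.image_shape}"
            )
        if len(self.encoder_channels) != 4 or len(self.decoder_channels) != 4:
            raise ValueError("encoder/decoder channel lists must have length 4")
        if self.decoder_channels[-1] != 1:
            raise ValueError("decoder_channels must end in 1 (grayscale output)")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "DecoderConfig":
        """CPU-friendly configuration for the 32x32 synthetic benchmark.

        A slimmed-down network (8/16-channel blocks, 128 hidden units, an
        8-kernel Gabor bank) and a gentler initial learning rate (2e-3)
        suited to minibatches of 32 on a few hundred samples; architecture
        and loss are otherwise identical to the default configuration.
        """
        base = dict(
            n_neurons=60,
            n_time_bins=100,
            image_shape=(32, 32),
            fc_hidden=128,
            encoder_channels=(8, 16, 16, 16),
            decoder_channels=(16, 16, 8, 1),
            epochs=50,
            batch_size=32,
            lr0=2e-3,
            gabor_orientation_step_deg=45.0,
            gabor_ksizes=(7, 9),
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def bank(self) -> GaborBank:
        return make_bank(self.gabor_orientation_step_deg, tuple(self.gabor_ksizes))

    def loss_config(self, weight_matrix: WeightMatrix | None = None) -> LossConfig:
        return LossConfig(
            mu_mix=self.mu_mix,
            ssim_mode=self.ssim_mode,
            metric_constants=MetricConstants.for_range(1.0),
            weight_matrix=weight_matrix,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["encoder_channels"] = list(self.encoder_channels)
        d["decoder_channels"] = list(self.decoder_channels)
        d["gabor_ksizes"] = list(self.gabor_ksizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderConfig":
        d = dict(d)
        for key in ("image_shape", "encoder_channels", "decoder_channels", "gabor_ksizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def learning_rate(cfg: DecoderConfig, epoch: int) -> float:
    """Stepped decay schedule: lr0 * decay^floor(epoch / decay_every)."""
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_decay_every)


class SpikeImageDecoder(Module):
    """FC x2 -> Gabor (or plain) first conv -> 4-down/4-up conv autoencoder."""

    def __init__(self, cfg: DecoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        rows, cols = cfg.image_shape
        n_in = cfg.n_neurons * cfg.n_time_bins

        from .layers import Linear

        self.fc1 = Linear(n_in, cfg.fc_hidden, rng)
        self.fc2 = Linear(cfg.fc_hidden, rows * cols, rng)
        self.act = LeakyReLU(cfg.leaky_slope)

        bank = cfg.bank()
        if cfg.gabor_enabled:
            self.first_conv = gabor_first_layer(bank, cfg.gabor_mode, rng=rng)
            first_out = self.first_conv.out_channels
        else:
            # plain learned first convolution with the same channel budget,
            # so the Gabor/no-Gabor ablation changes only the kernels' nature
            k = bank.max_ksize
            self.first_conv = Conv2d(1, len(bank), k, 1, k // 2, rng)
            first_out = len(bank)

        enc_in = (first_out,) + tuple(cfg.encoder_channels[:3])
        self.encoder = [
            Conv2d(
                enc_in[i],
                cfg.encoder_channels[i],
                cfg.conv_ksize,
                cfg.conv_stride,
                cfg.conv_padding,
                rng,
            )
            for i in range(4)
        ]
        dec_in = (cfg.encoder_channels[3],) + tuple(cfg.decoder_channels[:3])
        self.decoder = [
            ConvTranspose2d(
                dec_in[i],
                cfg.decoder_channels[i],
                cfg.conv_ksize,
                cfg.conv_stride,
                cfg.conv_padding,
                rng,
            )
            for i in range(4)
        ]
        self.dropouts = [
            Dropout(cfg.dropout_p, np.random.default_rng(cfg.seed + 1))
            for _ in range(4)
        ]
        # per-neuron standardisation, fitted on the training split
        self.norm_mean = np.zeros(cfg.n_neurons, dtype=DTYPE)
        self.norm_std = np.ones(cfg.n_neurons, dtype=DTYPE)

    # -- input handling -----------------------------------------------------

    def fit_normalizer(self, counts: np.ndarray) -> None:
        """counts: (n_samples, n_neurons, n_time_bins) from the train split."""
        m = counts.mean(axis=(0, 2))
        s = counts.std(axis=(0, 2))
        self.norm_mean = m.astype(DTYPE)
        self.norm_std = np.maximum(s, 1e-6).astype(DTYPE)

    def prepare_input(self, counts: np.ndarray) -> np.ndarray:
        """Standardise per neuron and flatten to (n_samples, features)."""
        counts = np.asarray(counts, dtype=DTYPE)
        if counts.ndim == 2:
            counts = counts[None]
        z = (counts - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]
        return z.reshape(counts.shape[0], -1)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for d in self.dropouts:
            d.rng = rng

    # -- forward ------------------------------------------------------------

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        rows, cols = cfg.image_shape
        n = x.shape[0]
        h = self.act(self.fc1(x))
        h = self.act(self.fc2(h))
        h = h.reshape(n, 1, rows, cols)
        h = self.act(self.first_conv(h))
        for conv, drop in zip(self.encoder, self.dropouts):
            h = drop(self.act(conv(h)))
        for deconv in self.decoder[:3]:
            h = self.act(deconv(h))
        return self.decoder[3](h).sigmoid()


def build_model(cfg: DecoderConfig) -> SpikeImageDecoder:
    return SpikeImageDecoder(cfg)


@dataclass
class TrainingHistory:
    """Per-epoch log: losses, learning rate, and test-split image metrics."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    test_psnr: list[float] = field(default_factory=list)
    test_ssim: list[float] = field(default_factory=list)
    test_vifp: list[float] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "epoch": e,
                "train_loss": tl,
                "test_loss": vl,
                "lr": lr,
                "test_mse": m,
                "test_psnr": p,
                "test_ssim": s,
                "test_vifp": v,
            }
            for e, tl, vl, lr, m, p, s, v in zip(
                self.epochs,
                self.train_loss,
                self.test_loss,
                self.lr,
                self.test_mse,
                self.test_psnr,
                self.test_ssim,
                self.test_vifp,
            )
        ]

    def save_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_records()).to_csv(path, index=False)


def _pairs_to_arrays(
    pairs: list[tuple[SpikeCountMatrix, GrayImage]]
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.stack([p[0].counts for p in pairs])
    targets = np.stack([p[1].to_unit() for p in pairs]).astype(DTYPE)
    return counts, targets


def _batch_metrics(recon: np.ndarray, targets: np.ndarray) -> dict[str, float]:
    """Mean of the four evaluation metrics, computed on the 0-255 scale."""
    consts = MetricConstants.for_range(255.0)
    vals = {"mse": [], "psnr": [], "ssim": [], "vifp": []}
    for r, t in zip(recon, targets):
        r255, t255 = r * 255.0, t * 255.0
        vals["mse"].append(mse(t255, r255))
        vals["psnr"].append(psnr(t255, r255, range_max=255.0))
        vals["ssim"].append(ssim_windowed(t255, r255, consts))
        vals["vifp"].append(vifp(t255, r255))
    finite_psnr = [p for p in vals["psnr"] if np.isfinite(p)]
    return {
        "mse": float(np.mean(vals["mse"])),
        "psnr": float(np.mean(finite_psnr)) if finite_psnr else float("inf"),
        "ssim": float(np.mean(vals["ssim"])),
        "vifp": float(np.mean(vals["vifp"])),
    }


def train(
    model: SpikeImageDecoder,
    train_pairs: list[tuple[SpikeCountMatrix, GrayImage]],
    test_pairs: list[tuple[SpikeCountMatrix, GrayImage]],
    cfg: DecoderConfig | None = None,
    weight_matrix: WeightMatrix | None = None,
    metrics_every: int = 10,
) -> tuple[SpikeImageDecoder, TrainingHistory]:
    """Minibatch Adam optimisation of the composite loss.

    ``metrics_every`` controls how often the four image metrics are computed
    on the test split (they are always computed on the final epoch); train
    and test losses and the learning rate are logged every epoch.
    """
    if cfg is None:
        cfg = model.cfg
    if not train_pairs or not test_pairs:
        raise ValueError("train and test splits must both be nonempty")

    loss_cfg = cfg.loss_config(weight_matrix)
    train_counts, train_targets = _pairs_to_arrays(train_pairs)
    test_counts, test_targets = _pairs_to_arrays(test_pairs)

    model.fit_normalizer(train_counts)
    x_train = model.prepare_input(train_counts)
    x_test = model.prepare_input(test_counts)

    rng = np.random.default_rng(cfg.seed + 9001)
    model.set_dropout_rng(rng)

    opt = Adam(model.parameters(), lr=cfg.lr0)
    history = TrainingHistory()
    n = x_train.shape[0]

    for epoch in range(cfg.epochs):
        opt.lr = learning_rate(cfg, epoch)
        model.train_mode(True)
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = Tensor(x_train[idx])
            yb = train_targets[idx][:, None]
            out = model(xb)
            loss = combined_loss_t(out, yb, loss_cfg)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(val)

        model.train_mode(False)
        from .autodiff import no_grad

        with no_grad():
            test_out = model(Tensor(x_test)).data
            test_loss = combined_loss_t(
                Tensor(test_out), test_targets[:, None], loss_cfg
            ).item()

        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.test_loss.append(float(test_loss))
        history.lr.append(opt.lr)
        if metrics_every and (epoch % metrics_every == 0 or epoch == cfg.epochs - 1):
            m = _batch_metrics(test_out[:, 0], test_targets)
        else:
            m = {"mse": np.nan, "psnr": np.nan, "ssim": np.nan, "vifp": np.nan}
        history.test_mse.append(m["mse"])
        history.test_psnr.append(m["psnr"])
        history.test_ssim.append(m["ssim"])
        history.test_vifp.append(m["vifp"])

    return model, history


def reconstruct(
    model: SpikeImageDecoder, spikes: "np.ndarray | list[SpikeCountMatrix]"
) -> np.ndarray:
    """Deterministic inference: (n, H, W) reconstructions in [0, 1]."""
    if isinstance(spikes, list):
        counts = np.stack([s.counts for s in spikes])
    else:
        counts = np.asarray(spikes)
    model.train_mode(False)
    from .autodiff import no_grad

    with no_grad():
        out = model(Tensor(model.prepare_input(counts))).data
    return out[:, 0].astype(np.float64)


def evaluate_on_pairs(
    model: SpikeImageDecoder, pairs: list[tuple[SpikeCountMatrix, GrayImage]]
) -> dict[str, float]:
    """Mean four-metric report of the model on a paired split (0-255 scale)."""
    counts, targets = _pairs_to_arrays(pairs)
    recon = reconstruct(model, counts)
    report = _batch_metrics(recon, targets)
    report["mse_sum"] = report["mse"] * targets.shape[1] * targets.shape[2]
    report["n_images"] = len(pairs)
    return report


METHOD_CONFIGS = {
    # plain autoencoder, plain MSE loss
    "method1": {"mu_mix": 0.0, "gabor_enabled": False, "use_weight_matrix": False},
    # plain autoencoder, pure SSIM loss
    "method2": {"mu_mix": 1.0, "gabor_enabled": False, "use_weight_matrix": False},
    # Gabor first layer + composite RF-weighted loss
    "proposed": {"mu_mix": 0.1, "gabor_enabled": True, "use_weight_matrix": True},
}


def compare_methods(
    train_pairs: list[tuple[SpikeCountMatrix, GrayImage]],
    test_pairs: list[tuple[SpikeCountMatrix, GrayImage]],
    base_cfg: DecoderConfig,
    weight_matrix: WeightMatrix | None = None,
    metrics_every: int = 0,
    methods: tuple[str, ...] | None = None,
) -> dict:
    """Train the two ablations and the proposed model; report all metrics.

    The three rows differ only in loss and first convolution: method 1 is a
    plain autoencoder with MSE loss, method 2 the same with pure SSIM loss,
    and the proposed method uses the Gabor first layer with the composite
    RF-weighted loss.  All share the seed, data and remaining
    hyperparameters.
    """
    report: dict = {"seed": base_cfg.seed, "methods": {}}
    for name, opts in METHOD_CONFIGS.items():
        if methods is not None and name not in methods:
            continue
        cfg = replace(
            base_cfg,
            mu_mix=opts["mu_mix"],
            gabor_enabled=opts["gabor_enabled"],
        )
        wm = weight_matrix if opts["use_weight_matrix"] else None
        model = build_model(cfg)
        model, history = train(
            model, train_pairs, test_pairs, cfg, wm, metrics_every=metrics_every
        )
        row = evaluate_on_pairs(model, test_pairs)
        row["final_train_loss"] = history.train_loss[-1]
        row["final_test_loss"] = history.test_loss[-1]
        report["methods"][name] = row
    return report


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(
    model: SpikeImageDecoder, path, weight_matrix: WeightMatrix | None = None
) -> None:
    """Write parameters + normaliser (NPZ) and the config (JSON sidecar)."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_std"] = model.norm_std
    if weight_matrix is not None:
        arrays["weight_matrix"] = weight_matrix.weights
        arrays["weight_matrix_normalized"] = np.array(weight_matrix.normalized)
    np.savez(path, **arrays)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(model.cfg.to_dict(), fh, indent=2)


def load_checkpoint(path) -> tuple[SpikeImageDecoder, WeightMatrix | None]:
    with open(str(path) + ".json") as fh:
        cfg = DecoderConfig.from_dict(json.load(fh))
    model = build_model(cfg)
    with np.load(path) as z:
        for i, p in enumerate(model.parameters()):
            arr = z[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {arr.shape}, "
                    f"model expects {p.data.shape}"
                )
            p.data = arr
        model.norm_mean = z["norm_mean"]
        model.norm_std = z["norm_std"]
        wm = None
        if "weight_matrix" in z:
            wm = WeightMatrix(
                z["weight_matrix"], normalized=bool(z["weight_matrix_normalized"])
            )
    return model, wm
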