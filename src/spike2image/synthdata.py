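"""Synthetic stimuli and simulated spike responses for the decoder.

The simulator is a linear-nonlinear-Poisson (LNP) population: each neuron
has a 2D Gaussian receptive field with ON or OFF polarity, its drive is the
RF-weighted mean stimulus contrast (images centred at mid-gray, scaled to
[-1, 1]), a static nonlinearity turns drive into a firing rate, and spike
counts over a stimulus-locked window are Poisson with uniform spike times.
This matches the statistical structure the decoder assumes (Gaussian RFs,
stimulus-driven rates, stimulus-locked windows) while remaining fully
seeded and generable at test time.

Stimuli are disc-windowed sinusoidal gratings (controllable orientation,
spatial frequency, phase, diameter) and 1/f "natural-like" random-phase
images.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import GrayImage
from .rf_weights import Polarity, ReceptiveFieldSpec, gaussian_kernel_2d
from .spike_data import PairedDataset, SpikeCountMatrix, SpikeTrainSet, bin_spike_times


# -- stimuli -----------------------------------------------------------------


def generate_grating(
    image_shape: tuple[int, int],
    orientation_rad: float,
    cycles_per_image: float,
    phase: float = 0.0,
    diameter_px: float | None = None,
) -> GrayImage:
    """Sinusoidal grating in a centred disc, mid-gray outside.

    ``cycles_per_image`` counts carrier cycles across the image's short
    side; phase 0 puts the sinusoid's maximum at the image centre.
    ``diameter_px=None`` gives a full-field grating.
    """
    if cycles_per_image < 1:
        raise ValueError("cycles_per_image must be >= 1")
    rows, cols = image_shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    y = np.arange(rows)[:, None] - r0
    x = np.arange(cols)[None, :] - c0
    u = x * np.cos(orientation_rad) + y * np.sin(orientation_rad)
    freq = cycles_per_image / min(rows, cols)
    img = 127.5 + 127.5 * np.cos(2 * np.pi * freq * u + phase)
    if diameter_px is not None:
        mask = (x**2 + y**2) <= (diameter_px / 2.0) ** 2
        img = np.where(mask, img, 127.5)
    return GrayImage.from_uint8(np.clip(img, 0, 255))


def generate_pink_noise_image(
    image_shape: tuple[int, int],
    spectral_exponent: float = 1.0,
    seed: int = 0,
) -> GrayImage:
    """Random-phase image with amplitude spectrum ~ f^(-exponent).

    The radially averaged *power* spectrum therefore falls as
    f^(-2*exponent).  The result is contrast-normalised to span [0, 255].
    """
    if not 0.5 <= spectral_exponent <= 2.5:
        raise ValueError("spectral_exponent must lie in [0.5, 2.5]")
    rows, cols = image_shape
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((rows, cols))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    f[0, 0] = 1.0  # DC untouched; removed below anyway
    shaped = spectrum * f ** (-spectral_exponent)
    shaped[0, 0] = 0.0
    img = np.fft.ifft2(shaped).real
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) * 255.0
    return GrayImage.from_uint8(img)


# -- the LNP population ------------------------------------------------------


class Nonlinearity(enum.Enum):
    RECTIFIED_LINEAR = "rectified_linear"
    SOFTPLUS = "softplus"
    EXPONENTIAL = "exponential"

    def __call__(self, drive: float) -> float:
        if self is Nonlinearity.RECTIFIED_LINEAR:
            return max(drive, 0.0)
        if self is Nonlinearity.SOFTPLUS:
            return float(np.log1p(np.exp(min(drive, 30.0))))
        return float(np.exp(min(drive, 8.0)))


@dataclass(frozen=True)
class SimulatedNeuron:
    """One LNP unit: RF, gain (spk/s per unit drive), baseline (spk/s)."""

    rf: ReceptiveFieldSpec
    gain: float
    baseline: float
    polarity_sign: int  # +1 ON, -1 OFF

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.baseline < 0:
            raise ValueError("gain must be positive and baseline nonnegative")
        if self.polarity_sign not in (-1, 1):
            raise ValueError("polarity_sign must be +1 or -1")


@dataclass(frozen=True)
class SimConfig:
    """Population and protocol parameters for the simulator."""

    n_neurons: int = 60
    image_shape: tuple[int, int] = (32, 32)
    rf_sigma_range: tuple[float, float] = (2.5, 5.0)
    gain_range: tuple[float, float] = (20.0, 40.0)
    baseline_range: tuple[float, float] = (0.5, 2.0)
    window_ms: float = 300.0
    bin_width_ms: float = 10.0
    nonlinearity: Nonlinearity = Nonlinearity.RECTIFIED_LINEAR
    on_probability: float = 0.5
    stimulus_exponent: float = 1.0  # 1/f slope of the natural-like stimuli
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rf_sigma_range", "gain_range", "baseline_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nondecreasing nonnegative range")
        if isinstance(self.nonlinearity, str):
            object.__setattr__(self, "nonlinearity", Nonlinearity(self.nonlinearity))


def simulate_population(cfg: SimConfig) -> list[SimulatedNeuron]:
    """Draw a seeded population: RF centres uniform over the image interior,
    scales/gains/baselines uniform over their ranges, ON/OFF by coin flip.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.image_shape
    neurons = []
    for _ in range(cfg.n_neurons):
        r = rng.uniform(0, rows - 1)
        c = rng.uniform(0, cols - 1)
        sigma = rng.uniform(*cfg.rf_sigma_range)
        gain = rng.uniform(*cfg.gain_range)
        baseline = rng.uniform(*cfg.baseline_range)
        on = rng.random() < cfg.on_probability
        neurons.append(
            SimulatedNeuron(
                ReceptiveFieldSpec(
                    r, c, sigma, Polarity.ON if on else Polarity.OFF
                ),
                gain,
                baseline,
                +1 if on else -1,
            )
        )
    return neurons


def population_rf_table(neurons: list[SimulatedNeuron]) -> pd.DataFrame:
    """Ground-truth RF table in the standard CSV schema."""
    return pd.DataFrame(
        {
            "neuron_id": np.arange(len(neurons)),
            "row": [n.rf.center_row for n in neurons],
            "col": [n.rf.center_col for n in neurons],
            "sigma_px": [n.rf.sigma_px for n in neurons],
            "polarity": [n.rf.polarity.value for n in neurons],
        }
    )


def _contrast(image: GrayImage) -> np.ndarray:
    """Pixels mapped to [-1, 1] about mid-gray; mid-gray is the null stimulus."""
    return image.to_unit() * 2.0 - 1.0


def neuron_drive(neuron: SimulatedNeuron, image: GrayImage) -> float:
    """Polarity-signed inner product of the mass-normalised RF with contrast."""
    kern = gaussian_kernel_2d(
        image.shape, (neuron.rf.center_row, neuron.rf.center_col), neuron.rf.sigma_px
    )
    kern = kern / kern.sum()
    return float(neuron.polarity_sign * (kern * _contrast(image)).sum())


def expected_rate(neuron: SimulatedNeuron, image: GrayImage, cfg: SimConfig) -> float:
    """Analytic firing rate (spikes/s) for a stimulus — the LNP mean."""
    return neuron.baseline + neuron.gain * cfg.nonlinearity(neuron_drive(neuron, image))


def expected_count(neuron: SimulatedNeuron, image: GrayImage, cfg: SimConfig) -> float:
    return expected_rate(neuron, image, cfg) * cfg.window_ms / 1000.0


def simulate_responses(
    population: list[SimulatedNeuron],
    stimuli: list[GrayImage],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeTrainSet, list[SpikeCountMatrix]]:
    """Poisson spike trains (and binned counts) for each stimulus."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    window_s = cfg.window_ms / 1000.0
    trains: list[list[np.ndarray]] = []
    ids: list[str] = []
    for s_idx, stim in enumerate(stimuli):
        if stim.shape != tuple(cfg.image_shape):
            raise ValueError(
                f"stimulus {s_idx} shape {stim.shape} != cfg {cfg.image_shape}"
            )
        trial = []
        for neuron in population:
            rate = expected_rate(neuron, stim, cfg)
            assert rate >= 0.0, "LNP rate must be nonnegative"
            n_spk = rng.poisson(rate * window_s)
            trial.append(np.sort(rng.uniform(0.0, window_s, size=n_spk)))
        trains.append(trial)
        ids.append(f"stim_{s_idx:05d}")
    spikes = SpikeTrainSet(trains, ids)
    counts = [
        SpikeCountMatrix(
            np.stack(
                [
                    bin_spike_times(ts, cfg.bin_width_ms, cfg.window_ms)
                    for ts in trial
                ]
            ),
            cfg.bin_width_ms,
            cfg.window_ms,
        )
        for trial in spikes.trains
    ]
    return spikes, counts


# -- benchmark assembly ------------------------------------------------------

# ON-rich, high-gain, long-window, smooth-stimulus conditions under which a
# plain ridge readout already decodes pixels well (mean test correlation
# comfortably above 0.4), so decoder failures cannot hide behind the data.
EASY_PRESET = SimConfig(
    n_neurons=60,
    image_shape=(32, 32),
    rf_sigma_range=(3.0, 5.0),
    gain_range=(100.0, 150.0),
    baseline_range=(0.0, 1.0),
    window_ms=1000.0,
    bin_width_ms=10.0,
    nonlinearity=Nonlinearity.RECTIFIED_LINEAR,
    on_probability=0.9,
    stimulus_exponent=1.8,
    seed=0,
)


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named simulator presets; ``easy`` is ON-rich, high-gain, low-noise."""
    if name == "easy":
        return replace(EASY_PRESET, seed=seed, **overrides)
    if name == "default":
        return replace(SimConfig(), seed=seed, **overrides)
    raise ValueError(f"unknown preset {name!r}")


def generate_stimuli(
    cfg: SimConfig,
    n_stimuli: int,
    stimulus_mix: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[GrayImage]:
    """A seeded mix of gratings (fraction ``stimulus_mix``) and 1/f images."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n_gratings = int(round(stimulus_mix * n_stimuli))
    stims: list[GrayImage] = []
    short = min(cfg.image_shape)
    for i in range(n_stimuli):
        if i < n_gratings:
            # low spatial frequencies only: gratings faster than the
            # population's RF scale average out and drive no response
            stims.append(
                generate_grating(
                    cfg.image_shape,
                    orientation_rad=rng.uniform(0, np.pi),
                    cycles_per_image=rng.integers(1, max(short // 10, 2) + 1),
                    phase=rng.uniform(0, 2 * np.pi),
                    diameter_px=rng.uniform(0.7, 1.0) * short,
                )
            )
        else:
            stims.append(
                generate_pink_noise_image(
                    cfg.image_shape,
                    spectral_exponent=cfg.stimulus_exponent,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return stims


def linear_decodability(
    ds: PairedDataset, train_fraction: float = 0.8, seed: int = 0, ridge: float = 10.0
) -> float:
    """Mean test-split correlation of ridge-decoded vs true pixel intensities.

    A benchmark a linear readout cannot decode is too hard for the network;
    the ``easy`` preset is constructed so this floor exceeds 0.4.
    """
    from .spike_data import split_dataset

    x = ds.counts.reshape(len(ds), -1).astype(np.float64)
    x = (x - x.mean(0)) / np.maximum(x.std(0), 1e-9)
    y = ds.images.reshape(len(ds), -1).astype(np.float64) / 255.0
    split = split_dataset(len(ds), train_fraction, seed)
    xtr, xte = x[split.train_indices], x[split.test_indices]
    ytr, yte = y[split.train_indices], y[split.test_indices]
    w = np.linalg.solve(xtr.T @ xtr + ridge * np.eye(x.shape[1]), xtr.T @ ytr)
    pred = xte @ w + ytr.mean(0) - (xtr @ w).mean(0)
    cors = [
        np.corrcoef(p, t)[0, 1]
        for p, t in zip(pred, yte)
        if p.std() > 0 and t.std() > 0
    ]
    return float(np.mean(cors))


def make_benchmark(
    cfg: SimConfig,
    n_stimuli: int = 300,
    stimulus_mix: float = 0.5,
    path=None,
) -> PairedDataset:
    """Simulate a full paired dataset; optionally write the NPZ container."""
    if n_stimuli < 10:
        raise ValueError("n_stimuli must be at least 10")
    population = simulate_population(cfg)
    stimuli = generate_stimuli(cfg, n_stimuli, stimulus_mix)
    _, counts = simulate_responses(population, stimuli, cfg)
    ds = PairedDataset(
        counts=np.stack([c.counts for c in counts]),
        images=np.stack([s.to_uint8() for s in stimuli]),
        rf_table=population_rf_table(population),
        bin_width_ms=cfg.bin_width_ms,
        window_ms=cfg.window_ms,
        stimulus_ids=[f"stim_{i:05d}" for i in range(n_stimuli)],
        meta={
            "seed": cfg.seed,
            "n_neurons": cfg.n_neurons,
            "image_shape": list(cfg.image_shape),
            "stimulus_mix": stimulus_mix,
            "nonlinearity": cfg.nonlinearity.value,
            "gain_range": list(cfg.gain_range),
            "baseline_range": list(cfg.baseline_range),
            "rf_sigma_range": list(cfg.rf_sigma_range),
            "on_probability": cfg.on_probability,
            "window_ms": cfg.window_ms,
        },
    )
    if path is not None:
        from .spike_data import save_dataset

        save_dataset(ds, path)
    return ds
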