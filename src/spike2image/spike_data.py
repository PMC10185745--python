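"""Spike-train binning, stimulus pairing, dataset containers and splits.

The decoder consumes per-stimulus spike-count matrices: for each presented
image, every neuron's spike timestamps (seconds, stimulus onset at time 0)
are counted into half-open time bins ``[b*dt, (b+1)*dt)`` covering a fixed
response window.  A cortical-style configuration uses a 105 ms window at
1 ms resolution; a retinal configuration uses 10 ms bins.

Datasets live in a single NPZ container holding the count tensor, the
8-bit stimulus images, the receptive-field table and provenance metadata,
and are split 80/20 (floor-based sizes, seeded shuffle) into train and test.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import GrayImage, load_png, resize_gray


@dataclass(frozen=True)
class SpikeCountMatrix:
    """Binned response of the whole population to one stimulus."""

    counts: np.ndarray  # (n_neurons, n_time_bins), nonnegative ints
    bin_width_ms: float
    window_ms: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2D (neurons x time bins)")
        if (c < 0).any():
            raise ValueError("spike counts must be nonnegative")
        expected = int(np.ceil(self.window_ms / self.bin_width_ms))
        if c.shape[1] != expected:
            raise ValueError(
                f"count matrix has {c.shape[1]} bins; window/bin width imply {expected}"
            )
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-trial, per-neuron spike timestamps aligned to stimulus onset.

    ``trains[trial][neuron]`` is a sorted array of times in seconds;
    ``stimulus_ids[trial]`` names the image shown on that trial.
    """

    trains: list[list[np.ndarray]]
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.trains) != len(self.stimulus_ids):
            raise ValueError("one stimulus id required per trial")
        for t, trial in enumerate(self.trains):
            for n, ts in enumerate(trial):
                ts = np.asarray(ts, dtype=np.float64)
                if ts.size and (ts < 0).any():
                    raise ValueError(f"negative timestamp in trial {t}, neuron {n}")
                if ts.size > 1 and (np.diff(ts) < 0).any():
                    raise ValueError(
                        f"unsorted timestamps in trial {t}, neuron {n}"
                    )

    @property
    def n_neurons(self) -> int:
        return len(self.trains[0]) if self.trains else 0


def bin_spike_times(
    timestamps_s: np.ndarray, bin_width_ms: float, window_ms: float
) -> np.ndarray:
    """Counts for one neuron; half-open bins, spikes at/after the window drop."""
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    if window_ms < bin_width_ms:
        raise ValueError("window_ms must be at least one bin wide")
    n_bins = int(np.ceil(window_ms / bin_width_ms))
    t_ms = np.asarray(timestamps_s, dtype=np.float64) * 1000.0
    t_ms = t_ms[(t_ms >= 0) & (t_ms < window_ms)]
    idx = np.minimum((t_ms / bin_width_ms).astype(np.int64), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def bin_spikes(
    spikes: SpikeTrainSet, bin_width_ms: float, window_ms: float
) -> list[SpikeCountMatrix]:
    """Bin every trial of a spike-train set into count matrices."""
    out = []
    for trial in spikes.trains:
        counts = np.stack(
            [bin_spike_times(ts, bin_width_ms, window_ms) for ts in trial]
        )
        out.append(SpikeCountMatrix(counts, bin_width_ms, window_ms))
    return out


@dataclass(frozen=True)
class DatasetSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices)
        te = np.asarray(self.test_indices)
        if np.intersect1d(tr, te).size:
            raise ValueError("train/test indices overlap")
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)


def split_dataset(
    n_items: int, train_fraction: float = 0.8, seed: int = 0, shuffle: bool = True
) -> DatasetSplit:
    """Seeded, floor-sized train/test index split (e.g. 1800 -> 1440/360)."""
    if n_items < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(np.floor(train_fraction * n_items))
    order = (
        np.random.default_rng(seed).permutation(n_items)
        if shuffle
        else np.arange(n_items)
    )
    return DatasetSplit(order[:n_train], order[n_train:], train_fraction, seed)


# -- the on-disk container ----------------------------------------------------


@dataclass
class PairedDataset:
    """Spike-count / stimulus-image pairs plus the population's RF table."""

    counts: np.ndarray  # (n_stimuli, n_neurons, n_time_bins)
    images: np.ndarray  # (n_stimuli, H, W) uint8
    rf_table: pd.DataFrame
    bin_width_ms: float
    window_ms: float
    stimulus_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape[0] != self.images.shape[0]:
            raise ValueError("counts and images disagree on the number of stimuli")
        if len(self.stimulus_ids) != self.counts.shape[0]:
            raise ValueError("one stimulus id required per pair")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def pairs(self) -> list[tuple[SpikeCountMatrix, GrayImage]]:
        return [
            (
                SpikeCountMatrix(self.counts[i], self.bin_width_ms, self.window_ms),
                GrayImage.from_uint8(self.images[i]),
            )
            for i in range(len(self))
        ]


def save_dataset(ds: PairedDataset, path) -> None:
    np.savez_compressed(
        path,
        counts=ds.counts.astype(np.int64),
        images=ds.images.astype(np.uint8),
        rf_json=np.frombuffer(
            ds.rf_table.to_json(orient="split").encode(), dtype=np.uint8
        ),
        bin_width_ms=np.float64(ds.bin_width_ms),
        window_ms=np.float64(ds.window_ms),
        stimulus_ids=np.array(ds.stimulus_ids, dtype=object),
        meta_json=np.frombuffer(json.dumps(ds.meta).encode(), dtype=np.uint8),
    )


def load_dataset(path) -> PairedDataset:
    with np.load(path, allow_pickle=True) as z:
        rf = pd.read_json(io.StringIO(bytes(z["rf_json"]).decode()), orient="split")
        for col in ("row", "col", "sigma_px", "deg_x", "deg_y"):
            if col in rf.columns:
                rf[col] = rf[col].astype(np.float64)
        return PairedDataset(
            counts=z["counts"],
            images=z["images"],
            rf_table=rf,
            bin_width_ms=float(z["bin_width_ms"]),
            window_ms=float(z["window_ms"]),
            stimulus_ids=[str(s) for s in z["stimulus_ids"]],
            meta=json.loads(bytes(z["meta_json"]).decode()),
        )


def load_paired_dataset(
    spike_file,
    image_source=None,
    pairing_manifest: pd.DataFrame | None = None,
    target_shape: tuple[int, int] | None = None,
) -> list[tuple[SpikeCountMatrix, GrayImage]]:
    """Assemble (counts, image) pairs.

    With only ``spike_file`` given, it is read as a native NPZ container.
    With a manifest (columns ``stimulus_id``, ``image_path``, ``spike_block``)
    the NPZ must map each spike block name to a (neurons x bins) count array
    with ``bin_width_ms``/``window_ms`` entries, and images are loaded from
    ``image_source`` (a directory), grayscale-converted and resized to
    ``target_shape``.  Orphan blocks or images raise with the offending ids.
    """
    if pairing_manifest is None:
        return load_dataset(spike_file).pairs()

    z = np.load(spike_file, allow_pickle=True)
    bin_width_ms = float(z["bin_width_ms"])
    window_ms = float(z["window_ms"])
    missing = [
        str(r.spike_block)
        for r in pairing_manifest.itertuples()
        if str(r.spike_block) not in z
    ]
    if missing:
        raise ValueError(f"manifest names spike blocks absent from file: {missing}")

    from pathlib import Path

    pairs: list[tuple[SpikeCountMatrix, GrayImage]] = []
    for rec in pairing_manifest.itertuples():
        img_path = Path(image_source) / str(rec.image_path)
        if not img_path.exists():
            raise ValueError(f"manifest image missing for {rec.stimulus_id}: {img_path}")
        img = load_png(img_path)
        if target_shape is not None and img.shape != tuple(target_shape):
            img = resize_gray(img, tuple(target_shape))
        counts = SpikeCountMatrix(z[str(rec.spike_block)], bin_width_ms, window_ms)
        pairs.append((counts, img))
    shapes = {img.shape for _, img in pairs}
    if len(shapes) > 1:
        raise ValueError(f"images are not shape-uniform: {shapes}")
    return pairs
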