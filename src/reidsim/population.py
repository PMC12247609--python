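"""Synthetic population ("gallery") and noisy-probe generation.

The simulated world is deliberately minimal: each individual in the
candidate pool is a vector of ``n_features`` iid standard-normal
features, and the attacker's query ("probe") for an individual is that
individual's vector plus iid Gaussian noise of standard deviation
``sigma``.  Only the noise-to-feature variance ratio matters for
identification accuracy, so the feature scale is fixed at 1 and all of
the signal-to-noise calibration lives in ``sigma``.

Galleries up to ~10^6 x 10^3 are supported either fully materialised or
streamed in row chunks; both paths produce bit-identical values because
every row has its own keyed counter-based stream (see ``_rng``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import pandas as pd

from ._rng import (
    GALLERY_STREAM,
    PROBE_NOISE_STREAM,
    row_block_normal,
    rows_normal,
)

__all__ = [
    "PopulationConfig",
    "FeatureMatrix",
    "NoiseModel",
    "ProbeSet",
    "generate_gallery",
    "gallery_row_block",
    "gallery_rows",
    "iter_gallery_chunks",
    "generate_probes",
    "save_fixture",
    "load_fixture",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Defines a synthetic candidate pool.

    Parameters
    ----------
    n_individuals:
        Number of enrolled individuals (gallery rows).
    n_features:
        Features per individual; the reference simulations use 1,000.
    seed:
        Seed of the gallery's random stream.  Identical configs produce
        bit-identical galleries.
    """

    n_individuals: int
    n_features: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")


@dataclass
class FeatureMatrix:
    """A fully materialised gallery with its generating config."""

    values: np.ndarray
    config: PopulationConfig

    def __post_init__(self) -> None:
        expected = (self.config.n_individuals, self.config.n_features)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != config {expected}")

    @property
    def n_individuals(self) -> int:
        return self.config.n_individuals

    @property
    def n_features(self) -> int:
        return self.config.n_features


# A gallery argument may be materialised or described by its config
# (in which case rows are regenerated on demand, chunk by chunk).
GallerySource = Union[FeatureMatrix, PopulationConfig]


@dataclass(frozen=True)
class NoiseModel:
    """Additive iid Gaussian probe noise with scalar standard deviation."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class ProbeSet:
    """Noisy copies of selected gallery rows.

    ``true_indices[i]`` is the gallery row probe ``i`` was derived from;
    the matcher is scored against it.
    """

    values: np.ndarray
    true_indices: np.ndarray
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.true_indices = np.asarray(self.true_indices, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[0] != self.true_indices.size:
            raise ValueError("values and true_indices are inconsistent")
        if self.values.shape[0] < 1:
            raise ValueError("a ProbeSet needs at least one probe")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _as_config(gallery: GallerySource) -> PopulationConfig:
    return gallery.config if isinstance(gallery, FeatureMatrix) else gallery


def gallery_row_block(
    config: PopulationConfig, start: int, stop: int
) -> np.ndarray:
    """Rows [start, stop) of the gallery, regenerated from the seed."""
    if not (0 <= start <= stop <= config.n_individuals):
        raise ValueError(f"row range [{start}, {stop}) invalid for {config.n_individuals} rows")
    return row_block_normal(config.seed, GALLERY_STREAM, start, stop, config.n_features)


def gallery_rows(gallery: GallerySource, indices: np.ndarray) -> np.ndarray:
    """Arbitrary gallery rows by index (materialised or regenerated)."""
    indices = np.asarray(indices, dtype=np.int64)
    config = _as_config(gallery)
    if indices.size and (indices.min() < 0 or indices.max() >= config.n_individuals):
        raise IndexError("gallery row index out of range")
    if isinstance(gallery, FeatureMatrix):
        return gallery.values[indices]
    return rows_normal(config.seed, GALLERY_STREAM, indices, config.n_features)


def iter_gallery_chunks(
    gallery: GallerySource, chunk_rows: int
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(start_row, block)`` covering the gallery in order."""
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    config = _as_config(gallery)
    for start in range(0, config.n_individuals, chunk_rows):
        stop = min(start + chunk_rows, config.n_individuals)
        if isinstance(gallery, FeatureMatrix):
            yield start, gallery.values[start:stop]
        else:
            yield start, gallery_row_block(config, start, stop)


def generate_gallery(config: PopulationConfig) -> FeatureMatrix:
    """Materialise the full gallery for ``config``.

    For galleries too large to hold in memory use ``iter_gallery_chunks``
    / ``gallery_row_block`` with the bare config instead; the values are
    identical.
    """
    values = gallery_row_block(config, 0, config.n_individuals)
    return FeatureMatrix(values=values, config=config)


def generate_probes(
    gallery: GallerySource,
    noise: NoiseModel,
    probe_indices: np.ndarray,
    seed: int,
) -> ProbeSet:
    """Noisy probes for the given gallery rows.

    Probe ``i`` equals gallery row ``probe_indices[i]`` plus iid
    ``N(0, sigma^2)`` noise drawn from a stream keyed by ``(seed, i)``,
    independent of the gallery stream.  Repeated indices get independent
    noise, which is how replicate probes of the same individual are made.
    """
    probe_indices = np.asarray(probe_indices, dtype=np.int64)
    if probe_indices.size < 1:
        raise ValueError("probe_indices must be non-empty")
    config = _as_config(gallery)
    values = gallery_rows(gallery, probe_indices)
    if noise.sigma > 0:
        for i in range(probe_indices.size):
            z = rows_normal(seed, PROBE_NOISE_STREAM, np.array([i]), config.n_features)
            values[i] += noise.sigma * z[0]
    return ProbeSet(
        values=values, true_indices=probe_indices, sigma=noise.sigma, seed=seed
    )


# ---------------------------------------------------------------------------
# Fixture serialisation: CSV for small human-readable fixtures, .npy cache
# with a JSON sidecar recording the generating config / seed.
# ---------------------------------------------------------------------------


def save_fixture(obj: FeatureMatrix | ProbeSet, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        if isinstance(obj, FeatureMatrix):
            df = pd.DataFrame(obj.values)
        else:
            df = pd.DataFrame(obj.values)
            df.insert(0, "true_index", obj.true_indices)
        df.to_csv(path, index=False)
    elif fmt == "npy":
        np.save(path.with_suffix(".npy"), obj.values)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    meta: dict = {"kind": type(obj).__name__, "format": fmt}
    if isinstance(obj, FeatureMatrix):
        meta["config"] = {
            "n_individuals": obj.config.n_individuals,
            "n_features": obj.config.n_features,
            "seed": obj.config.seed,
        }
    else:
        meta["sigma"] = obj.sigma
        meta["seed"] = obj.seed
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_fixture(path: str | Path) -> FeatureMatrix | ProbeSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta["format"] == "csv":
        df = pd.read_csv(path)
    else:
        df = pd.DataFrame(np.load(path.with_suffix(".npy")))
    if meta["kind"] == "FeatureMatrix":
        cfg = PopulationConfig(**meta["config"])
        return FeatureMatrix(values=df.to_numpy(dtype=np.float64), config=cfg)
    true_idx = df.pop("true_index").to_numpy(dtype=np.int64)
    return ProbeSet(
        values=df.to_numpy(dtype=np.float64),
        true_indices=true_idx,
        sigma=float(meta["sigma"]),
        seed=int(meta["seed"]),
    )
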