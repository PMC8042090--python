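"""Synthetic data generators.

Three generators cover the study conditions:

* :func:`generate_gaussian_features` — the high-dimensional Gaussian benchmark:
  6,424 features, each feature's mean drawn from the discrete grid
  {0, 0.1, 0.2, 0.3} and variance from {0.1, 0.2, ..., 2.3}.  By default one
  (mean, variance) pair is shared by both classes, so every feature is null
  and any above-chance leaky-protocol accuracy is pure selection bias.
  ``per_class_draw=True`` instead draws an independent pair per class per
  feature, planting genuine (mostly weak) group differences in three quarters
  of the features — a strong-signal regime useful for contrast experiments.
* :func:`generate_null_features` — the matched no-signal control: one
  (mean, variance) pair shared by both classes for every feature.
* :func:`generate_connectivity_features` — a stand-in for resting-state EEG
  phase-locking-value (PLV) tables: all channel-pair x band edges of a
  45-channel montage over six canonical bands (5,940 features), values in
  [0, 1], with group differences planted on chosen frontal edges.

Connectivity values are generated on the logit scale (Gaussian) and mapped
through the logistic function, which guarantees the [0, 1] PLV range; planted
effect sizes are therefore specified in logit units.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import BANDS, ConnectivityIndex, FeatureMatrix

logger = logging.getLogger(__name__)

#: 45-channel extended 10-20 montage (configurable in ConnectivitySpec).
DEFAULT_CHANNELS: list[str] = [
    "Fp1", "Fp2",
    "AF7", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "POz",
    "O1", "Oz", "O2",
]


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass
class GaussianGridSpec:
    """Configuration of the Gaussian feature simulator.

    ``grid_mode='discrete'`` draws uniformly over the grid points;
    ``'continuous'`` draws uniformly over [min(grid), max(grid)].
    """

    n_features: int = 6424
    n_per_class: int = 58
    mean_grid: tuple[float, ...] = _grid(0.0, 0.3, 0.1)
    var_grid: tuple[float, ...] = _grid(0.1, 2.3, 0.1)
    per_class_draw: bool = False
    grid_mode: str = "discrete"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not self.mean_grid or not self.var_grid:
            raise ValueError("mean_grid and var_grid must be non-empty")
        if min(self.var_grid) <= 0:
            raise ValueError("all variances must be > 0")
        if self.grid_mode not in ("discrete", "continuous"):
            raise ValueError("grid_mode must be 'discrete' or 'continuous'")


@dataclass
class GaussianParams:
    """Per-feature (mean, variance) pairs actually drawn; rows are classes."""

    class_means: np.ndarray  # (2, n_features)
    class_vars: np.ndarray  # (2, n_features)


def _draw_grid(rng: np.random.Generator, grid: tuple[float, ...], size, mode: str) -> np.ndarray:
    if mode == "discrete":
        return rng.choice(np.asarray(grid, dtype=float), size=size)
    return rng.uniform(min(grid), max(grid), size=size)


def _feature_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"f{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_per_class: int) -> tuple[list[str], np.ndarray]:
    ids = [f"c0_s{i:03d}" for i in range(1, n_per_class + 1)]
    ids += [f"c1_s{i:03d}" for i in range(1, n_per_class + 1)]
    labels = np.repeat([0, 1], n_per_class)
    return ids, labels


def generate_gaussian_features(
    spec: GaussianGridSpec, return_params: bool = False
) -> FeatureMatrix | tuple[FeatureMatrix, GaussianParams]:
    """Simulate a two-class Gaussian feature matrix from a grid specification.

    For every feature a (mean, variance) pair is drawn from the grids — per
    class when ``spec.per_class_draw``, otherwise one shared pair — and each
    class's samples are drawn i.i.d. from the corresponding normal
    distribution.  Returns a matrix with ``2 * n_per_class`` rows (class 0
    first) and ``n_features`` columns; bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    if spec.per_class_draw:
        means = _draw_grid(rng, spec.mean_grid, (2, d), spec.grid_mode)
        variances = _draw_grid(rng, spec.var_grid, (2, d), spec.grid_mode)
    else:
        means = np.tile(_draw_grid(rng, spec.mean_grid, (1, d), spec.grid_mode), (2, 1))
        variances = np.tile(_draw_grid(rng, spec.var_grid, (1, d), spec.grid_mode), (2, 1))

    n = spec.n_per_class
    values = np.empty((2 * n, d), dtype=float)
    values[:n] = rng.normal(means[0], np.sqrt(variances[0]), size=(n, d))
    values[n:] = rng.normal(means[1], np.sqrt(variances[1]), size=(n, d))

    sample_ids, labels = _sample_ids(n)
    matrix = FeatureMatrix(values, labels, _feature_ids(d), sample_ids)
    if return_params:
        return matrix, GaussianParams(means, variances)
    return matrix


def generate_null_features(
    n_features: int,
    n_per_class: int,
    seed: int | None = None,
    mean_grid: tuple[float, ...] | None = None,
    var_grid: tuple[float, ...] | None = None,
) -> FeatureMatrix:
    """No-signal control: per feature one (mean, variance) pair for BOTH classes.

    True class separation is zero by construction, so any above-chance
    accuracy estimated on this data is protocol bias, not signal.
    """
    spec = GaussianGridSpec(
        n_features=n_features,
        n_per_class=n_per_class,
        mean_grid=mean_grid or _grid(0.0, 0.3, 0.1),
        var_grid=var_grid or _grid(0.1, 2.3, 0.1),
        per_class_draw=False,
        seed=seed,
    )
    return generate_gaussian_features(spec)


def build_connectivity_index(channels: Sequence[str] | None = None) -> ConnectivityIndex:
    """Enumerate all channel-pair x band edges in canonical order."""
    channels = list(channels) if channels is not None else list(DEFAULT_CHANNELS)
    rows = []
    for (a, b), (band, (lo, hi)) in itertools.product(
        itertools.combinations(channels, 2), BANDS.items()
    ):
        rows.append((f"{a}-{b}_{band}", a, b, band, lo, hi))
    table = pd.DataFrame(rows, columns=ConnectivityIndex.REQUIRED)
    return ConnectivityIndex(table=table, channels=channels)


@dataclass
class ConnectivitySpec:
    """Configuration of the synthetic PLV connectivity generator.

    ``planted_edges`` maps (channel_a, channel_b, band) to a logit-scale group
    shift (class 1 minus class 0); all other edges are null.  ``baseline_mu``
    and ``noise_sd`` parameterize the edge-value distribution on the logit
    scale: values are logistic(N(mu, sd)) and hence lie strictly in (0, 1).
    """

    n_channels: int = 45
    n_per_class: int = 58
    planted_edges: list[tuple[str, str, str, float]] = field(
        default_factory=lambda: [
            ("Fp1", "F3", "theta", 1.5),
            ("Fp2", "F4", "gamma", 1.5),
            ("F3", "F4", "gamma", 1.5),
        ]
    )
    baseline_mu: float = -0.4
    noise_sd: float = 0.6
    channels: list[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.channels is None:
            if self.n_channels > len(DEFAULT_CHANNELS):
                raise ValueError(
                    f"default montage has {len(DEFAULT_CHANNELS)} channels; "
                    "pass an explicit channel list"
                )
            self.channels = DEFAULT_CHANNELS[: self.n_channels]
        if len(self.channels) != self.n_channels:
            raise ValueError("channels length must equal n_channels")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_connectivity_features(
    spec: ConnectivitySpec,
) -> tuple[FeatureMatrix, ConnectivityIndex]:
    """Simulate a PLV-style connectivity feature table with planted edges.

    Returns the feature matrix (values in (0, 1)) and the edge index mapping
    each feature to its channel pair and band.  Planted edges differ between
    classes by the configured logit-scale effect; every other edge is null.
    """
    index = build_connectivity_index(spec.channels)
    d = len(index)
    rng = np.random.default_rng(spec.seed)

    shift = np.zeros(d)
    for a, b, band, effect in spec.planted_edges:
        fid = index.feature_id_for(a, b, band)  # KeyError if edge not in index
        pos = index.feature_ids.index(fid)
        shift[pos] = effect

    n = spec.n_per_class
    z = rng.normal(spec.baseline_mu, spec.noise_sd, size=(2 * n, d))
    z[n:] += shift  # class 1 rows
    values = _logistic(z)

    sample_ids, labels = _sample_ids(n)
    matrix = FeatureMatrix(values, labels, index.feature_ids, sample_ids)
    return matrix, index


@dataclass
class ZScoreStats:
    """Per-feature mean/SD of a z-score transform, reusable on held-out data."""

    mean: np.ndarray
    sd: np.ndarray


def _zscore_fit(X: np.ndarray) -> ZScoreStats:
    return ZScoreStats(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1))


def _zscore_apply(X: np.ndarray, stats: ZScoreStats, warn: bool = True) -> np.ndarray:
    sd = stats.sd
    zero = sd == 0
    if zero.any() and warn:
        logger.warning("%d zero-SD feature(s) transformed to all zeros", int(zero.sum()))
    safe = np.where(zero, 1.0, sd)
    out = (X - stats.mean) / safe
    out[:, zero] = 0.0
    return out


def zscore_standardize(
    matrix: FeatureMatrix, reference_stats: ZScoreStats | None = None
) -> tuple[FeatureMatrix, ZScoreStats]:
    """Z-score each feature: (x - mean) / SD.

    With ``reference_stats`` (e.g. training-fold statistics) those are applied
    to this matrix; otherwise statistics are computed from the matrix itself
    (sample SD, ddof=1).  Zero-SD features are mapped to all zeros with a
    logged warning.  Returns the transformed matrix and the stats used.
    """
    stats = reference_stats if reference_stats is not None else _zscore_fit(matrix.values)
    if len(stats.mean) != matrix.n_features:
        raise ValueError("reference_stats dimension does not match matrix")
    out = _zscore_apply(matrix.values, stats)
    return (
        FeatureMatrix(out, matrix.labels, matrix.feature_ids, matrix.sample_ids),
        stats,
    )
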