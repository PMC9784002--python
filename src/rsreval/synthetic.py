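"""Synthetic indicator panels with the structure the RSR analysis assumes.

The raw provincial indicator values behind the published evaluation come
from statistical yearbooks and were never printed, so end-to-end testing of
the rank/RSR stage needs data with the same shape and statistical
structure: each dimension's indicators reflect one latent per-unit quality,
observed through indicator-specific monotone (affine) links plus noise, and
exactly one indicator (mirroring maternal mortality) is low-quality, i.e.
recorded on a worse-is-larger scale.

The default configuration mirrors the study panel: 31 units, 12 indicators
split 3/5/4 across needs/utilization/resources, the first needs indicator
low-quality, standard-normal latent quality, observation noise sd 0.1 (in
latent units, i.e. a tenth of the between-unit spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DIMENSIONS, IndicatorSpec, IndicatorTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "generate_rsr_vector"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``dims`` gives the per-dimension indicator counts; ``low_quality``
    lists (dimension_index, indicator_index) pairs recorded on an inverted
    scale; ``noise_sd`` is the observation-noise standard deviation in
    latent-quality units (latent quality is standard normal per dimension).
    """

    n_units: int = 31
    dims: tuple[int, int, int] = (3, 5, 4)
    noise_sd: float = 0.1
    low_quality: tuple[tuple[int, int], ...] = ((0, 0),)
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError(f"need at least 2 units, got {self.n_units}")
        if len(self.dims) != len(DIMENSIONS) or any(m < 1 for m in self.dims):
            raise ValueError(f"dims must be {len(DIMENSIONS)} counts >= 1, got {self.dims}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d, j in self.low_quality:
            if not (0 <= d < len(self.dims)) or not (0 <= j < self.dims[d]):
                raise ValueError(f"low_quality entry ({d}, {j}) out of range")


@dataclass
class SyntheticTruth:
    """A generated panel together with its latent per-unit quality."""

    latent: np.ndarray            # (n_units, 3)
    table: IndicatorTable
    config: SyntheticConfig


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticTruth:
    """Draw a synthetic indicator table.

    Each indicator value is ``offset + scale * (s * latent + noise)`` with
    ``scale > 0`` and ``s = -1`` for low-quality indicators: a strictly
    monotone (decreasing for low-quality) transform of latent quality when
    ``noise_sd = 0``.  Identical configs produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    latent = rng.standard_normal((n, len(config.dims)))
    low = set(config.low_quality)
    specs, cols = [], []
    for d, (dim_name, m) in enumerate(zip(DIMENSIONS, config.dims)):
        for j in range(m):
            orientation = "low_quality" if (d, j) in low else "high_quality"
            sign = -1.0 if orientation == "low_quality" else 1.0
            scale = rng.uniform(0.5, 2.0)
            offset = rng.normal(0.0, 5.0)
            noise = rng.normal(0.0, config.noise_sd, size=n)
            cols.append(offset + scale * (sign * latent[:, d] + noise))
            specs.append(IndicatorSpec(
                id=f"S{len(specs) + 1}",
                name=f"synthetic {dim_name} indicator {j + 1}",
                dimension=dim_name, orientation=orientation,
            ))
    table = IndicatorTable(
        units=[f"unit{i + 1:02d}" for i in range(n)],
        specs=specs, values=np.column_stack(cols),
    )
    return SyntheticTruth(latent=latent, table=table, config=config)


def generate_rsr_vector(n: int, seed: int, ties: bool = False) -> np.ndarray:
    """A random RSR-like vector: n values in [1/n, 1].

    With ``ties=True`` the first two entries are made exactly equal, for
    exercising tie handling in the probit stage.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    v = rng.uniform(1.0 / n, 1.0, size=n)
    if ties:
        v[1] = v[0]
    return v
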