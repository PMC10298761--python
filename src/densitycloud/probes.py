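"""Probe generation: where in d-space the density ratio is evaluated.

Probes are drawn with replacement from the pooled empirical data (both
groups, original sizes) and perturbed with independent per-variable
normal jitter. Jitter improves coverage of sparse regions and smooths
the clouds, at the cost of slightly blurring sharp features such as
floors/ceilings or quantized scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import GroupedDataset

logger = logging.getLogger(__name__)

__all__ = ["ProbeSet", "default_probe_count", "generate_probes"]

#: Default SD of the jitter as a multiple of each variable's pooled SD.
DEFAULT_JITTER = 0.2

_PROBE_MIN, _PROBE_MAX = 7000, 11000


@dataclass(frozen=True)
class ProbeSet:
    """A fixed set of evaluation points with its generation provenance."""

    coords: np.ndarray          # (P, d)
    jitter_multiplier: float
    jitter_sds: np.ndarray      # (d,) applied jitter SDs
    seed: int
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "jitter_sds",
                           np.asarray(self.jitter_sds, dtype=float))

    @property
    def n_probes(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def default_probe_count(d: int) -> int:
    """Probe-count schedule: ``round(6000 + 10000/d)`` clamped to [7000, 11000].

    The count shrinks with dimensionality because each scatterplot panel
    gets smaller as the d x d matrix grows: 11,000 probes at d=2 down to
    7,000 at d=10. Above d=10 the schedule stays at 7,000 (and the clouds
    become hard to read anyway; see :func:`densitycloud.knn_density.knn_cube_edge`
    for the distance-concentration argument).
    """
    if d < 2:
        raise ValueError("univariate data are not supported (d must be >= 2)")
    if d > 10:
        warnings.warn(
            f"d={d}: scatterplot matrices become visually crowded and "
            "nearest-neighbor distances concentrate beyond ~10 variables",
            stacklevel=2)
    count = _round_half_away(6000 + 10000 / d)
    return int(np.clip(count, _PROBE_MIN, _PROBE_MAX))


def generate_probes(ds: GroupedDataset,
                    n_probes: int | None = None,
                    jitter_multiplier: float = DEFAULT_JITTER,
                    seed: int = 0) -> ProbeSet:
    """Sample probes with replacement from the pooled data and jitter them.

    Jitter is independent zero-mean normal per variable, with SD equal to
    ``jitter_multiplier`` times that variable's pooled sample SD. With
    ``jitter_multiplier=0`` every probe coincides with a data row.
    Deterministic given ``seed``.
    """
    if jitter_multiplier < 0:
        raise ValueError("jitter_multiplier must be >= 0")
    if n_probes is None:
        n_probes = default_probe_count(ds.d)
    elif n_probes <= 0:
        raise ValueError("n_probes must be positive")

    rng = np.random.default_rng(seed)
    pooled = ds.values
    idx = rng.integers(0, pooled.shape[0], size=n_probes)
    coords = pooled[idx].astype(float, copy=True)
    jitter_sds = jitter_multiplier * pooled.std(axis=0, ddof=1)
    if jitter_multiplier > 0:
        coords += rng.standard_normal(coords.shape) * jitter_sds
    logger.info("generated %d probes (d=%d, jitter=%g, seed=%d)",
                n_probes, ds.d, jitter_multiplier, seed)
    return ProbeSet(coords=coords, jitter_multiplier=float(jitter_multiplier),
                    jitter_sds=jitter_sds, seed=int(seed),
                    source=f"pooled resample of N={pooled.shape[0]} rows")
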