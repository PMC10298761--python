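"""Random-split null diagnostic.

Even for two samples from identical distributions, estimated density
ratios fluctuate away from one. To judge whether the observed ratios
exceed pure estimation noise, the data are split into two pseudo-groups —
each containing half of group A and half of group B — and the relative
density is recomputed with the same probes and k. If the actual log-ratio
distribution has visibly heavier tails than this null, the extreme ratios
reflect genuine group differences rather than sampling error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import GroupedDataset
from .knn_density import _equalize_matrices, equalize_groups, relative_density
from .probes import ProbeSet

logger = logging.getLogger(__name__)

__all__ = ["NullComparison", "random_split_null"]


@dataclass(frozen=True)
class NullComparison:
    """Actual vs random-split log-ratio distributions at shared probes."""

    actual_log_ratios: np.ndarray   # (P,)
    null_log_ratios: np.ndarray     # (P, n_splits)
    n_splits: int
    seed: int

    @property
    def pooled_null(self) -> np.ndarray:
        return self.null_log_ratios.ravel()

    def ks_statistic(self) -> float:
        """Two-sample Kolmogorov-Smirnov statistic, actual vs pooled null."""
        return float(stats.ks_2samp(self.actual_log_ratios,
                                    self.pooled_null).statistic)


def _random_halves(X: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split rows into two random halves; an odd extra row goes to a random side."""
    n = X.shape[0]
    perm = rng.permutation(n)
    cut = n // 2 + (rng.integers(0, 2) if n % 2 else 0)
    return X[perm[:cut]], X[perm[cut:]]


def random_split_null(ds: GroupedDataset,
                      probes: ProbeSet,
                      k: int,
                      n_splits: int = 1,
                      seed: int = 0) -> NullComparison:
    """Compare actual density ratios with a random-split null.

    The actual field uses the ordinary pipeline (seeded group equalization,
    then the relative density at the shared probes). For each split, group A
    and group B are each halved at random; pseudo-group 1 takes one half of
    each, pseudo-group 2 the complements, so group membership cannot drive
    the pseudo-ratio. Pseudo-group sizes are equalized the same way as real
    groups. Deterministic given ``seed``.
    """
    n_a = ds.comparison_matrix.shape[0]
    n_b = ds.reference_matrix.shape[0]
    if min(n_a, n_b) < 2 * k:
        raise ValueError(
            f"each group needs at least 2k = {2 * k} cases for the split null")

    rng = np.random.default_rng(seed)
    A, B = equalize_groups(ds, seed=seed)
    actual = relative_density(A, B, probes, k)

    A_raw = ds.comparison_matrix
    B_raw = ds.reference_matrix
    nulls = np.empty((probes.n_probes, n_splits))
    for s in range(n_splits):
        a1, a2 = _random_halves(A_raw, rng)
        b1, b2 = _random_halves(B_raw, rng)
        p1 = np.vstack([a1, b1])
        p2 = np.vstack([a2, b2])
        p1, p2 = _equalize_matrices(p1, p2, rng)
        nulls[:, s] = relative_density(p1, p2, probes, k).log_ratio
    logger.info("random-split null: %d split(s), k=%d, probes=%d",
                n_splits, k, probes.n_probes)
    return NullComparison(actual_log_ratios=actual.log_ratio,
                          null_log_ratios=nulls,
                          n_splits=int(n_splits), seed=int(seed))
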