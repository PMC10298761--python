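"""Synthetic two-group Gaussian scenarios.

Every pipeline stage is testable without external data: this module draws
two multivariate normal groups with controlled differences in centroid,
per-variable scale, and correlation structure, optionally degraded by a
hard ceiling (upper clipping) to emulate bounded questionnaire scores.
Gaussian groups have closed-form densities, so the true log density ratio
at any point is available as an oracle for the k-NN estimates.

The reference group B is N(0, R_B) (unit variances). The comparison group
A is N(mu, D R_A D) with D = diag(sd_ratio); the centroid shift is
specified in units of the per-variable pooled population SD,
sqrt((1 + sd_ratio_j^2) / 2), so a shift of 1 means "one pooled SD apart"
regardless of the scale difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import GroupedDataset

__all__ = ["ScenarioSpec", "gaussian_groups", "apply_ceiling",
           "analytic_log_ratio"]


def _as_corr(M: np.ndarray | None, d: int, name: str) -> np.ndarray:
    if M is None:
        return np.eye(d)
    M = np.asarray(M, dtype=float)
    if M.shape != (d, d) or not np.allclose(M, M.T):
        raise ValueError(f"{name} must be a symmetric {d}x{d} matrix")
    if not np.allclose(np.diag(M), 1.0):
        raise ValueError(f"{name} must have unit diagonal")
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc
    return M


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one two-group Gaussian scenario."""

    n_per_group: int
    d: int
    centroid_shift: np.ndarray | float = 0.0   # units of pooled SD
    sd_ratio: np.ndarray | float = 1.0         # SD_A / SD_B per variable
    corr_A: np.ndarray | None = None
    corr_B: np.ndarray | None = None
    ceiling: np.ndarray | None = None          # upper clip limits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.n_per_group < 3:
            raise ValueError("need at least 3 cases per group")
        shift = np.broadcast_to(np.asarray(self.centroid_shift, float),
                                (self.d,)).copy()
        ratio = np.broadcast_to(np.asarray(self.sd_ratio, float),
                                (self.d,)).copy()
        if np.any(ratio <= 0):
            raise ValueError("sd_ratio must be positive")
        object.__setattr__(self, "centroid_shift", shift)
        object.__setattr__(self, "sd_ratio", ratio)
        object.__setattr__(self, "corr_A", _as_corr(self.corr_A, self.d, "corr_A"))
        object.__setattr__(self, "corr_B", _as_corr(self.corr_B, self.d, "corr_B"))
        if self.ceiling is not None:
            object.__setattr__(
                self, "ceiling",
                np.broadcast_to(np.asarray(self.ceiling, float), (self.d,)).copy())

    # population moments --------------------------------------------------

    @property
    def mean_A(self) -> np.ndarray:
        pooled_sd = np.sqrt((1.0 + self.sd_ratio ** 2) / 2.0)
        return self.centroid_shift * pooled_sd

    @property
    def cov_A(self) -> np.ndarray:
        D = np.diag(self.sd_ratio)
        return D @ self.corr_A @ D

    @property
    def cov_B(self) -> np.ndarray:
        return self.corr_B.copy()


def gaussian_groups(spec: ScenarioSpec,
                    reference_name: str = "B",
                    comparison_name: str = "A") -> GroupedDataset:
    """Draw the two Gaussian groups of a scenario as a GroupedDataset.

    If the spec carries ceiling limits they are applied to both groups.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_per_group, spec.d
    L_B = np.linalg.cholesky(spec.cov_B)
    L_A = np.linalg.cholesky(spec.cov_A)
    B = rng.standard_normal((n, d)) @ L_B.T
    A = rng.standard_normal((n, d)) @ L_A.T + spec.mean_A
    values = np.vstack([B, A])
    labels = np.array([reference_name] * n + [comparison_name] * n)
    ds = GroupedDataset(values=values, group_labels=labels,
                        var_names=tuple(f"V{j + 1}" for j in range(d)),
                        group_names=(reference_name, comparison_name))
    if spec.ceiling is not None:
        ds = apply_ceiling(ds, spec.ceiling)
    return ds


def apply_ceiling(ds: GroupedDataset, limits: np.ndarray,
                  group: str | None = None) -> GroupedDataset:
    """Clip values at per-variable upper limits (a hard ceiling).

    Clipping a ceiling into a variable shrinks its variance and induces
    negative skew — the signature of bounded scores. With ``group`` given,
    only that group's rows are clipped (e.g. to exaggerate an apparent
    scale difference in one group).
    """
    limits = np.broadcast_to(np.asarray(limits, dtype=float), (ds.d,))
    if not np.isfinite(limits).all():
        raise ValueError("ceiling limits must be finite")
    values = ds.values.copy()
    if group is None:
        mask = np.ones(ds.n, dtype=bool)
    else:
        mask = ds.group_labels == group
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
    values[mask] = np.minimum(values[mask], limits)
    return ds.with_values(values)


def analytic_log_ratio(spec: ScenarioSpec, points: np.ndarray) -> np.ndarray:
    """True log density ratio log f_A(x) - log f_B(x) of an (unclipped) scenario."""
    points = np.asarray(points, dtype=float)
    log_a = stats.multivariate_normal(mean=spec.mean_A, cov=spec.cov_A
                                      ).logpdf(points)
    log_b = stats.multivariate_normal(mean=np.zeros(spec.d), cov=spec.cov_B
                                      ).logpdf(points)
    return log_a - log_b
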