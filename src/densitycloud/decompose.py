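"""Decomposition of overall group differences into interpretable components.

The overall density ratio f_A/f_B is factored by comparing group A against
progressively transformed versions of the reference group B:

* ``B_shift`` — B translated to A's centroid (location removed);
* ``B_shift_scaled`` — additionally rescaled per variable to A's SDs
  (location and scale removed);
* ``B_shift_scaled_colored`` — additionally re-correlated to A's
  correlation matrix via ZCA-cor whitening/coloring (location, scale and
  covariation removed).

Each component is itself a density ratio between two adjacent stages, so
the components of a sequence multiply elementwise to the overall ratio
exactly. Sequences: LS (location, shape), LSS (location, scale, residual
shape), LSCS (location, scale, covariation, residual shape), plus the
augmented LSS+ / LSCS+ variants that include every intermediate plot.

ZCA-cor is the whitening transform whose output variables correlate
maximally with the originals, so the recolored data stay interpretable
variable-by-variable: W = R^(-1/2) V^(-1/2), with coloring inverse
W^(-1) = V^(1/2) R^(1/2) (R the correlation matrix, V the diagonal matrix
of variances, matrix square roots via symmetric eigendecomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GroupedDataset
from .knn_density import (RelativeDensityField, default_k, equalize_groups,
                          knn_density)
from .probes import ProbeSet, generate_probes

logger = logging.getLogger(__name__)

__all__ = [
    "WhiteningOp", "DecompositionResult", "mean_shift", "scale_to",
    "zca_cor_op", "recolor", "decompose", "SEQUENCES",
]

_EIG_FLOOR = 1e-10
_EIG_FATAL = 1e-8

#: component -> (numerator sample, denominator sample)
_COMPONENT_RATIOS = {
    "overall": ("A", "B"),
    "location": ("B_shift", "B"),
    "shape": ("A", "B_shift"),
    "scale": ("B_shift_scaled", "B_shift"),
    "covariation": ("B_shift_scaled_colored", "B_shift_scaled"),
}

#: sequence id -> ordered component list
SEQUENCES: dict[str, tuple[str, ...]] = {
    "overall": ("overall",),
    "LS": ("location", "shape"),
    "LSS": ("location", "scale", "residual_shape"),
    "LSCS": ("location", "scale", "covariation", "residual_shape"),
    "LSS+": ("overall", "location", "shape", "scale", "residual_shape"),
    "LSCS+": ("overall", "location", "shape", "scale", "residual_shape",
              "covariation", "residual_shape"),
}


@dataclass(frozen=True)
class WhiteningOp:
    """ZCA-cor whitening of one sample, with its coloring inverse."""

    centroid: np.ndarray   # (d,)
    V: np.ndarray          # (d, d) diagonal matrix of variances
    R: np.ndarray          # (d, d) correlation matrix
    W: np.ndarray          # (d, d) whitening matrix R^(-1/2) V^(-1/2)
    W_inv: np.ndarray      # (d, d) coloring matrix V^(1/2) R^(1/2)


@dataclass(frozen=True)
class DecompositionResult:
    """Ordered components of one decomposition sequence at shared probes."""

    sequence: str
    components: tuple[RelativeDensityField, ...]
    probes: ProbeSet
    global_max_abs_log_ratio: float

    @property
    def k(self) -> int:
        return self.components[0].k

    @property
    def n_equalized(self) -> int:
        return self.components[0].n_equalized


def mean_shift(X: np.ndarray, target_centroid: np.ndarray) -> np.ndarray:
    """Translate a sample so its centroid equals ``target_centroid``."""
    X = np.asarray(X, dtype=float)
    target = np.asarray(target_centroid, dtype=float)
    return X - X.mean(axis=0) + target


def scale_to(X: np.ndarray, target_sds: np.ndarray) -> np.ndarray:
    """Rescale each column about its own mean to the target SD (n-1).

    Correlations and the centroid are unchanged.
    """
    X = np.asarray(X, dtype=float)
    target = np.asarray(target_sds, dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = int(np.argmin(sds))
        raise ValueError(f"column {bad} has zero variance; cannot rescale")
    if np.any(target <= 0):
        raise ValueError("target SDs must be positive")
    mean = X.mean(axis=0)
    return (X - mean) * (target / sds) + mean


def _sym_power(M: np.ndarray, power: float) -> np.ndarray:
    """Symmetric matrix power via eigendecomposition with an eigenvalue floor."""
    vals, vecs = np.linalg.eigh(M)
    if vals.min() < _EIG_FATAL:
        raise np.linalg.LinAlgError(
            "near-singular correlation structure "
            f"(smallest eigenvalue {vals.min():.3g})")
    vals = np.maximum(vals, _EIG_FLOOR)
    return (vecs * vals ** power) @ vecs.T


def zca_cor_op(X: np.ndarray) -> WhiteningOp:
    """Build the ZCA-cor whitening/coloring operator for a sample."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more rows ({n}) than variables ({d})")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("zero-variance column; correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    R_isqrt = _sym_power(R, -0.5)
    R_sqrt = _sym_power(R, 0.5)
    W = R_isqrt @ np.diag(1.0 / sds)
    W_inv = np.diag(sds) @ R_sqrt
    return WhiteningOp(centroid=X.mean(axis=0), V=np.diag(sds ** 2), R=R,
                       W=W, W_inv=W_inv)


def recolor(X_B: np.ndarray, target: WhiteningOp) -> np.ndarray:
    """Impose the target sample's covariance structure (and centroid) on X_B.

    X_B is centered, whitened with its own ZCA-cor matrix, colored with the
    target's coloring matrix, and translated to the target centroid. The
    output's sample covariance equals the target's.
    """
    X_B = np.asarray(X_B, dtype=float)
    own = zca_cor_op(X_B)
    Z = (X_B - own.centroid) @ own.W.T
    return Z @ target.W_inv.T + target.centroid


def _build_samples(A: np.ndarray, B: np.ndarray,
                   needed: set[str]) -> dict[str, np.ndarray]:
    """Construct the transform chain from the equalized samples.

    Target moments (centroid, SDs, correlations) come from the equalized A
    sample — the same rows whose density is estimated.
    """
    samples: dict[str, np.ndarray] = {"A": A, "B": B}
    centroid_A = A.mean(axis=0)
    if {"B_shift", "B_shift_scaled", "B_shift_scaled_colored"} & needed:
        samples["B_shift"] = mean_shift(B, centroid_A)
    if {"B_shift_scaled", "B_shift_scaled_colored"} & needed:
        samples["B_shift_scaled"] = scale_to(samples["B_shift"],
                                             A.std(axis=0, ddof=1))
    if "B_shift_scaled_colored" in needed:
        samples["B_shift_scaled_colored"] = recolor(samples["B_shift_scaled"],
                                                    zca_cor_op(A))
    return samples


def decompose(ds: GroupedDataset,
              sequence: str = "overall",
              k: int | None = None,
              probes: ProbeSet | None = None,
              seed: int = 0,
              k_rule: str = "sqrt") -> DecompositionResult:
    """Run one decomposition sequence and return its component ratio fields.

    Groups are equalized once (seeded); every component's densities are
    evaluated at the single shared probe set, which makes the sequence
    exactly multiplicative: the elementwise product of the component ratios
    equals the overall ratio A/B.
    """
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}; "
                         f"choose from {sorted(SEQUENCES)}")
    if probes is None:
        probes = generate_probes(ds, seed=seed)
    A, B = equalize_groups(ds, seed=seed)
    n_eq = A.shape[0]
    if k is None:
        k = default_k(n_eq, rule=k_rule)

    comp_names = SEQUENCES[sequence]
    # residual_shape denominators differ by sequence depth
    resolved: list[tuple[str, str, str]] = []
    lscs = "covariation" in comp_names
    seen_cov = False
    for name in comp_names:
        if name == "residual_shape":
            if lscs and (seen_cov or sequence == "LSCS"):
                # adjusted for location, scale and covariation
                resolved.append((name, "A", "B_shift_scaled_colored"))
            else:
                resolved.append((name, "A", "B_shift_scaled"))
        else:
            num, den = _COMPONENT_RATIOS[name]
            resolved.append((name, num, den))
        if name == "covariation":
            seen_cov = True

    needed = {s for _, num, den in resolved for s in (num, den)}
    samples = _build_samples(A, B, needed)
    fields = {name: knn_density(X, probes, k, sample_id=name)
              for name, X in samples.items() if name in needed}

    components = []
    for name, num, den in resolved:
        ratio = fields[num].values / fields[den].values
        components.append(RelativeDensityField(
            component=name, ratio=ratio, log_ratio=np.log(ratio),
            k=int(k), n_equalized=int(n_eq)))
    global_max = max(c.max_abs_log_ratio for c in components)
    logger.info("sequence %s: n_eq=%d, k=%d, probes=%d, max|log ratio|=%.3f",
                sequence, n_eq, k, probes.n_probes, global_max)
    return DecompositionResult(sequence=sequence, components=tuple(components),
                               probes=probes,
                               global_max_abs_log_ratio=float(global_max))
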