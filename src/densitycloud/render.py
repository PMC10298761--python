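"""Rendering: scatterplot-matrix clouds and the diagnostic curve plot.

Each probe is drawn at its coordinates in every pairwise panel of a d x d
scatterplot matrix. The probe's color encodes the sign of its log density
ratio (comparison color where the comparison group is denser, reference
color where the reference group is denser) and its opacity encodes the
magnitude: alpha = |log ratio| / reference_max, clipped to 1. A ratio of
one is fully transparent; the most extreme ratio — identified globally
across a sequence or locally within one component — is fully opaque.
Normalizing on the log scale compresses outliers and keeps the clouds
readable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import to_rgb
from scipy import stats

from .decompose import DecompositionResult
from .diagnostics import NullComparison

logger = logging.getLogger(__name__)

__all__ = ["RenderConfig", "alpha_map", "plot_cloud", "plot_diagnostic"]


@dataclass(frozen=True)
class RenderConfig:
    """Aesthetic and layout options for cloud figures."""

    color_comparison: str = "#2166ac"   # blue
    color_reference: str = "#e0218a"    # pink/magenta
    alpha_reference: str = "global"     # global | local
    point_size: float | None = None     # None: auto-shrink with d
    output_format: str = "png"
    dpi: int = 150
    seed: int = 0                       # draw-order shuffle

    def __post_init__(self) -> None:
        if self.alpha_reference not in {"global", "local"}:
            raise ValueError("alpha_reference must be 'global' or 'local'")
        if self.output_format not in {"png", "pdf", "svg"}:
            raise ValueError("output_format must be png, pdf or svg")


def alpha_map(log_ratios: np.ndarray, reference_max: float) -> np.ndarray:
    """Map log ratios to opacities in [0, 1].

    ``alpha = min(1, |log ratio| / reference_max)``: a ratio of one gives
    alpha 0; |log ratio| at or beyond the reference maximum gives alpha 1.
    """
    log_ratios = np.asarray(log_ratios, dtype=float)
    if reference_max < 0:
        raise ValueError("reference_max must be nonnegative")
    if reference_max == 0:
        warnings.warn("all density ratios equal one; cloud is fully "
                      "transparent", stacklevel=2)
        return np.zeros_like(log_ratios)
    return np.minimum(1.0, np.abs(log_ratios) / reference_max)


def _probe_colors(log_ratios: np.ndarray, alphas: np.ndarray,
                  config: RenderConfig) -> np.ndarray:
    rgba = np.empty((log_ratios.size, 4))
    comp = to_rgb(config.color_comparison)
    ref = to_rgb(config.color_reference)
    positive = log_ratios >= 0
    rgba[positive, :3] = comp
    rgba[~positive, :3] = ref
    rgba[:, 3] = alphas
    return rgba


def plot_cloud(result: DecompositionResult,
               config: RenderConfig,
               out_path: str | Path,
               var_names: tuple[str, ...] | None = None) -> list[Path]:
    """Draw one d x d scatterplot-matrix figure per component.

    ``out_path`` is a directory; files are named
    ``<sequence>_<index>_<component>.<format>``. Returns the written paths.
    """
    out_dir = Path(out_path)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = result.probes.coords
    d = coords.shape[1]
    if var_names is None:
        var_names = tuple(f"V{j + 1}" for j in range(d))
    size = config.point_size if config.point_size is not None else max(1.0, 14.0 / d)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(coords.shape[0])

    paths: list[Path] = []
    for idx, comp in enumerate(result.components, start=1):
        ref_max = (result.global_max_abs_log_ratio
                   if config.alpha_reference == "global"
                   else comp.max_abs_log_ratio)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-ones component is legitimate
            alphas = alpha_map(comp.log_ratio, ref_max)
        rgba = _probe_colors(comp.log_ratio, alphas, config)

        fig, axes = plt.subplots(d, d, figsize=(2.1 * d, 2.1 * d),
                                 squeeze=False)
        for i in range(d):
            for j in range(d):
                ax = axes[i][j]
                ax.set_xticks([])
                ax.set_yticks([])
                if i == j:
                    ax.text(0.5, 0.5, var_names[i], ha="center", va="center",
                            fontsize=14, transform=ax.transAxes)
                    continue
                ax.scatter(coords[order, j], coords[order, i], s=size,
                           c=rgba[order], linewidths=0, rasterized=True)
        lo, hi = float(comp.ratio.min()), float(comp.ratio.max())
        fig.suptitle(f"{comp.component} — displayed relative densities "
                     f"[{lo:.3g}, {hi:.3g}]", fontsize=11)
        fig.tight_layout(rect=(0, 0, 1, 0.97))
        path = out_dir / (f"{result.sequence.replace('+', 'plus')}_"
                          f"{idx:02d}_{comp.component}.{config.output_format}")
        fig.savefig(path, dpi=config.dpi)
        plt.close(fig)
        paths.append(path)
        logger.info("wrote %s (ratio range [%.3g, %.3g])", path, lo, hi)
    return paths


def plot_diagnostic(nc: NullComparison, out_path: str | Path,
                    accent_color: str = "#6a3d9a") -> Path:
    """Overlay smoothed densities of actual vs random-split log ratios.

    The x axis is the log ratio, with tick labels in ratio units.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    actual = nc.actual_log_ratios
    null = nc.pooled_null
    lo = float(min(actual.min(), null.min()))
    hi = float(max(actual.max(), null.max()))
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, 512)

    fig, ax = plt.subplots(figsize=(6, 4))
    for sample, color, label in ((null, "0.6", "random split (null)"),
                                 (actual, accent_color, "actual groups")):
        if np.ptp(sample) > 0:
            ax.plot(grid, stats.gaussian_kde(sample)(grid), color=color,
                    label=label, lw=1.8)
        else:  # degenerate: all ratios identical
            ax.axvline(float(sample[0]), color=color, label=label, lw=1.8)
    ticks = [t for t in (0.1, 0.25, 0.5, 1, 2, 4, 10)
             if lo - pad <= np.log(t) <= hi + pad] or [1]
    ax.set_xticks([np.log(t) for t in ticks])
    ax.set_xticklabels([f"{t:g}" for t in ticks])
    ax.set_xlabel("relative density (log scale)")
    ax.set_ylabel("density of probes")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    logger.info("wrote diagnostic plot %s", out_path)
    return out_path
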