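"""Heat-map and P-P figure rendering.

Every figure is a view of numbers that the pipeline also writes as
CSV/TIFF; nothing is figure-only.  Percent-change maps use a diverging
colour map centred at zero; q-value maps use a sequential map truncated at
the significance boundary q = α so the significant extent reads directly
off the image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import PixelTestMap, PPPlotData, QValueMap
from .registration import ShapeTemplate

__all__ = ["render_maps"]


def _imshow(ax, data, mask, cmap, vmin, vmax, title):
    shown = np.where(mask, data, np.nan)
    im = ax.imshow(shown, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return im


def render_maps(
    out_dir: str | Path,
    template: ShapeTemplate,
    baseline_mean: np.ndarray,
    test_map: PixelTestMap,
    qmap: QValueMap,
    pp_data: PPPlotData | None,
    tag: str = "",
) -> list[Path]:
    """Render the four standard figures for one follow-up visit.

    Baseline mean BMD (0–4 g/cm² scale), mean percent change (diverging,
    centred at 0), the q-value map (annotated with the significant-pixel
    count), and the P-P plot with identity and slope-α lines.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = template.template_bone_mask
    written: list[Path] = []
    suffix = f"_{tag}" if tag else ""

    fig, ax = plt.subplots(figsize=(4, 5))
    im = _imshow(ax, baseline_mean, mask, "viridis", 0.0, 4.0, "Baseline mean BMD")
    fig.colorbar(im, ax=ax, label="BMD (g/cm$^2$), scale 0-4")
    p = out / f"fig_baseline_mean{suffix}.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    pct_masked = np.where(mask, test_map.pct_change, np.nan)
    finite = np.abs(pct_masked[np.isfinite(pct_masked)])
    span = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    fig, ax = plt.subplots(figsize=(4, 5))
    im = _imshow(
        ax, test_map.pct_change, mask, "RdBu_r", -span, span,
        f"BMD change at {test_map.followup_month:g} months (%)",
    )
    fig.colorbar(im, ax=ax, label="% of baseline BMD")
    p = out / f"fig_pct_change{suffix}.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    n_sig = int(qmap.significant.sum())
    fig, ax = plt.subplots(figsize=(4, 5))
    im = _imshow(ax, qmap.q_value, mask, "magma_r", 0.0, qmap.alpha, "FDR q-values")
    fig.colorbar(im, ax=ax, label=f"q (truncated at α = {qmap.alpha:g})")
    ax.set_xlabel(f"{n_sig} significant pixels" if n_sig else "0 significant pixels")
    p = out / f"fig_q_map{suffix}.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    if pp_data is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="identity")
        ax.plot(
            [0, 1],
            [0, pp_data.bh_line_slope],
            "r-",
            lw=0.8,
            label=f"slope-α (α = {pp_data.bh_line_slope:g})",
        )
        ax.plot(pp_data.uniform_quantiles, pp_data.sorted_p, "b-", lw=1.2, label="observed")
        ax.set_xlabel("uniform quantile i/(N+1)")
        ax.set_ylabel("sorted p-value")
        ax.legend(fontsize=8)
        p = out / f"fig_pp_plot{suffix}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
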